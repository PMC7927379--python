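import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from breedscan.genotypes import GenotypePanel, compute_maf, filter_maf, impute_missing
from breedscan.scan import (
    _permuted_coefficients_1comp,
    coefficient_zscores,
    encode_response,
    manhattan_table,
    pls_fit,
    scan_all_breeds,
    scan_summary,
    snp_pvalues,
    standardize_dosages,
)
from breedscan.simulate import SimulationConfig, simulate_panel
from conftest import random_panel


def standardized_matrix(n=30, m=80, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    return (X - X.mean(0)) / X.std(0)


def binary_response(n=30, frac=0.3, seed=0):
    rng = np.random.default_rng(seed + 1000)
    y = np.zeros(n)
    y[: max(2, int(frac * n))] = 1.0
    return rng.permutation(y)


class TestEncodeResponse:
    def test_indicator_counts_and_partition(self, small_panel):
        total = np.zeros(small_panel.n_samples)
        for code in small_panel.breed_codes:
            y = encode_response(small_panel, code)
            assert y.sum() == (small_panel.samples["breed"] == code).sum()
            total += y
        np.testing.assert_array_equal(total, np.ones(small_panel.n_samples))

    def test_unknown_breed_rejected(self, small_panel):
        with pytest.raises(KeyError):
            encode_response(small_panel, "NOPE")

    def test_constant_response_rejected(self):
        panel = random_panel(n_samples=6, n_snps=10, n_breeds=1)
        with pytest.raises(ValueError):
            encode_response(panel, "B1")


class TestPlsFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_first_weights_equal_normalized_cross_covariance(self, seed):
        X = standardized_matrix(seed=seed)
        y = binary_response(seed=seed)
        W, _ = pls_fit(X, y, 1)
        oracle = X.T @ (y - y.mean())
        oracle /= np.linalg.norm(oracle)
        np.testing.assert_allclose(W[:, 0], oracle, atol=1e-10)

    @pytest.mark.parametrize("n_components", [1, 2, 4])
    def test_matches_sklearn_pls_regression(self, n_components):
        from sklearn.cross_decomposition import PLSRegression

        X = standardized_matrix(seed=42)
        y = binary_response(seed=42)
        _, coef = pls_fit(X, y, n_components)
        sk = PLSRegression(n_components=n_components, scale=False).fit(X, y)
        np.testing.assert_allclose(coef, sk.coef_.ravel(), atol=1e-10)

    def test_column_orthogonal_to_response_gets_zero_weight(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        X = standardized_matrix(n=4, m=5, seed=3)
        X[:, 2] = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to y - mean(y)
        W, _ = pls_fit(X, y, 1)
        assert abs(W[2, 0]) < 1e-12

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            pls_fit(standardized_matrix(), np.ones(30), 1)

    def test_components_beyond_rank_rejected(self):
        X = standardized_matrix(n=5, m=3)
        with pytest.raises(ValueError):
            pls_fit(X, binary_response(n=5), 4)


class TestPvalues:
    def test_coefficient_at_genome_mean_has_p_one(self):
        p = snp_pvalues(np.array([1.0, 2.0, 3.0]), "zscore")
        assert p[1] == 1.0

    def test_zscore_matches_normal_tail_oracle(self):
        c = np.random.default_rng(0).normal(size=500)
        p = snp_pvalues(c, "zscore")
        z = (c - c.mean()) / c.std()
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(z)), atol=1e-12)
        # z = 2.576 corresponds to the two-sided 1% point
        assert 2 * stats.norm.sf(2.5758293) == pytest.approx(0.01, rel=1e-4)

    def test_permutation_add_one_lower_bound(self):
        X = standardized_matrix(n=40, m=20, seed=7)
        y = binary_response(n=40, seed=7)
        yc = y - y.mean()
        X[:, 0] = yc / yc.std()  # perfectly aligned SNP
        _, coef = pls_fit(X, y, 1)
        p = snp_pvalues(coef, "permutation", X=X, y=y, n_permutations=99, seed=5)
        assert p[0] == pytest.approx(1.0 / 100.0)
        assert p.min() >= 1.0 / 100.0

    def test_permutation_fast_path_equals_full_fit(self):
        X = standardized_matrix(n=25, m=30, seed=8)
        y = binary_response(n=25, seed=8)
        rng = np.random.default_rng(3)
        perms = np.stack([rng.permutation(y) for _ in range(6)], axis=1)
        fast = _permuted_coefficients_1comp(X, perms - perms.mean(0))
        for b in range(6):
            _, slow = pls_fit(X, perms[:, b], 1)
            np.testing.assert_allclose(fast[:, b], slow, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            snp_pvalues(np.ones(5), "zscore")  # zero spread
        with pytest.raises(ValueError):
            snp_pvalues(np.arange(5.0), "permutation", n_permutations=0)
        with pytest.raises(ValueError):
            snp_pvalues(np.arange(5.0), "bonferroni")


class TestScan:
    @pytest.fixture
    def filtered_panel(self, small_panel):
        panel = impute_missing(small_panel)
        compute_maf(panel)
        return filter_maf(panel, 0.05)

    def test_two_breed_scans_are_mirror_images(self):
        panel = random_panel(n_samples=20, n_snps=60, n_breeds=2, seed=9)
        res = scan_all_breeds(panel, seed=0)
        a, b = res
        np.testing.assert_allclose(np.abs(a.statistic), np.abs(b.statistic), atol=1e-12)
        np.testing.assert_allclose(a.pvalue, b.pvalue, atol=1e-12)

    def test_sample_order_invariance_of_pvalues(self, filtered_panel):
        perm = np.random.default_rng(1).permutation(filtered_panel.n_samples)
        shuffled = GenotypePanel(
            filtered_panel.dosages[perm],
            filtered_panel.snps.copy(),
            filtered_panel.samples.iloc[perm].reset_index(drop=True),
        )
        res_a = scan_all_breeds(filtered_panel, seed=0)
        res_b = {r.breed_code: r for r in scan_all_breeds(shuffled, seed=0)}
        for r in res_a:
            np.testing.assert_allclose(r.pvalue, res_b[r.breed_code].pvalue, atol=1e-10)

    def test_significant_set_matches_strict_threshold(self, filtered_panel):
        for r in scan_all_breeds(filtered_panel, alpha=0.05, seed=0):
            expected = filtered_panel.snps["id"].to_numpy()[r.pvalue < 0.05]
            assert r.significant == list(expected)

    def test_summary_counts_consistent(self, filtered_panel):
        results = scan_all_breeds(filtered_panel, seed=0)
        summary = scan_summary(results)
        assert summary["sum_significant"] == sum(
            r.n_significant for r in results
        )
        assert summary["union_significant"] <= summary["sum_significant"]

    def test_planted_loci_recovered_under_weak_drift(self):
        # strong planted shift, weak drift: the scan should call most
        # planted loci in their focal breed
        cfg = SimulationConfig(
            n_breeds=4, samples_per_breed=(20,) * 4, n_snps=1500, fst=0.02,
            n_planted_per_breed=4, planted_delta=0.5, missing_rate=0.0,
            n_chromosomes=3, chrom_length_bp=10_000_000, seed=21,
        )
        panel, truth, _ = simulate_panel(cfg)
        compute_maf(panel)
        panel = filter_maf(panel, 0.05)
        by_breed = {r.breed_code: set(r.significant) for r in scan_all_breeds(panel, seed=0)}
        hits = sum(
            1
            for j, code in zip(truth["snp_index"], truth["breed_code"])
            if f"snp{j:07d}" in by_breed[code]
        )
        assert hits / len(truth) >= 0.7

    def test_single_breed_panel_rejected(self):
        panel = random_panel(n_samples=10, n_snps=20, n_breeds=1)
        with pytest.raises(ValueError):
            scan_all_breeds(panel)


class TestManhattan:
    def test_neg_log10_values_and_row_count(self, small_panel):
        panel = impute_missing(small_panel)
        compute_maf(panel)
        panel = filter_maf(panel, 0.05)
        result = scan_all_breeds(panel, seed=0)[0]
        result.pvalue[0] = 0.01
        result.pvalue[1] = 1.0
        table = manhattan_table(result, panel)
        assert len(table) == panel.n_snps
        assert table["neg_log10_p"].iloc[0] == pytest.approx(2.0)
        assert table["neg_log10_p"].iloc[1] == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=6, max_value=40),
    m=st.integers(min_value=2, max_value=60),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_pls1_weight_closed_form_holds_for_any_input(n, m, seed):
    """Property: first-component weights are always the normalized X'(y - ybar)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    X = (X - X.mean(0)) / X.std(0)
    y = np.zeros(n)
    y[: int(rng.integers(1, n))] = 1.0
    y = rng.permutation(y)
    if y.sum() in (0, n):
        return
    W, _ = pls_fit(X, y, 1)
    oracle = X.T @ (y - y.mean())
    oracle /= np.linalg.norm(oracle)
    np.testing.assert_allclose(W[:, 0], oracle, atol=1e-10)


def test_standardize_requires_complete_polymorphic_matrix():
    X = np.array([[0.0, 1.0], [0.0, 2.0]])
    with pytest.raises(ValueError, match="MAF filter"):
        standardize_dosages(X)
    with pytest.raises(ValueError, match="impute"):
        standardize_dosages(np.array([[np.nan, 1.0], [0.0, 2.0]]))
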