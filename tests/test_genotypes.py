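import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedscan.genotypes import (
    GenotypePanel,
    compute_maf,
    filter_maf,
    impute_missing,
    read_vcf,
    snp_density,
    write_vcf,
)
from conftest import random_panel

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\tsnp2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1
1\t300\tmulti\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t0/2
1\t400\tindel\tA\tAT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t500\tsnp3\tG\tC\t.\t.\t.\tGT\t1/1\t1/1\t0/1
"""


@pytest.fixture
def vcf_paths(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(VCF_FIXTURE)
    breeds = tmp_path / "breeds.tsv"
    breeds.write_text("s1\tAA\ns2\tAA\ns3\tBB\n")
    return vcf, breeds


class TestReadVcf:
    def test_gt_to_dosage_and_missing(self, vcf_paths):
        panel = read_vcf(*vcf_paths)
        # multiallelic and indel records skipped
        assert list(panel.snps["id"]) == ["snp1", "snp2", "snp3"]
        np.testing.assert_array_equal(panel.dosages[:, 0], [0.0, 1.0, 2.0])
        assert np.isnan(panel.dosages[0, 1])
        np.testing.assert_array_equal(panel.dosages[:, 2], [2.0, 2.0, 1.0])
        assert list(panel.samples["breed"]) == ["AA", "AA", "BB"]

    def test_sample_missing_from_breed_table_is_an_error(self, tmp_path, vcf_paths):
        vcf, _ = vcf_paths
        partial = tmp_path / "partial.tsv"
        partial.write_text("s1\tAA\ns2\tAA\n")
        with pytest.raises(ValueError, match="missing from breed table"):
            read_vcf(vcf, partial)


class TestWriteVcf:
    def test_round_trip_reproduces_dosages(self, tmp_path, small_panel):
        vcf = tmp_path / "panel.vcf"
        breeds = tmp_path / "breeds.tsv"
        write_vcf(small_panel, vcf)
        breeds.write_text(
            "".join(f"{i}\t{b}\n" for i, b in zip(small_panel.samples["id"],
                                                  small_panel.samples["breed"]))
        )
        back = read_vcf(vcf, breeds)
        np.testing.assert_array_equal(back.dosages, small_panel.dosages)
        assert list(back.snps["id"]) == list(small_panel.snps["id"])

    def test_empty_panel_writes_header_only(self, tmp_path):
        panel = random_panel(n_samples=3, n_snps=5).subset_snps(np.zeros(5, dtype=bool))
        out = tmp_path / "empty.vcf"
        write_vcf(panel, out)
        lines = out.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)


class TestImpute:
    def test_identity_when_complete(self):
        panel = random_panel(seed=1)
        out = impute_missing(panel)
        np.testing.assert_array_equal(out.dosages, panel.dosages)

    def test_major_mode_uses_breed_majority(self):
        panel = random_panel(n_samples=6, n_snps=3, n_breeds=2, seed=2)
        # breed B1 = first 3 samples: dosages (2, 2, missing) at SNP 0
        panel.dosages[:3, 0] = [2.0, 2.0, np.nan]
        panel.dosages[3:, 0] = [0.0, 0.0, 0.0]
        out = impute_missing(panel, mode="major")
        assert out.dosages[2, 0] == 2.0

    def test_draw_mode_deterministic_under_seed(self):
        panel = random_panel(n_samples=30, n_snps=40, seed=3, missing_rate=0.2)
        a = impute_missing(panel, mode="draw", seed=9)
        b = impute_missing(panel, mode="draw", seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_never_alters_observed_entries(self):
        panel = random_panel(n_samples=25, n_snps=60, seed=4, missing_rate=0.15)
        observed = ~np.isnan(panel.dosages)
        for mode in ("major", "draw"):
            out = impute_missing(panel, mode=mode, seed=1)
            assert not out.has_missing
            np.testing.assert_array_equal(
                out.dosages[observed], panel.dosages[observed]
            )

    def test_unknown_mode_rejected(self, small_panel):
        with pytest.raises(ValueError):
            impute_missing(small_panel, mode="beagle")


class TestMaf:
    def test_hand_computed_examples(self):
        panel = random_panel(n_samples=4, n_snps=2, seed=5)
        panel.dosages[:, 0] = [0, 0, 0, 0]
        panel.dosages[:, 1] = [0, 1, 1, 2]
        maf = compute_maf(panel)
        assert maf[0] == 0.0
        assert maf[1] == 0.5  # f = 4/8

    def test_matches_brute_force_allele_counting(self):
        panel = random_panel(n_samples=40, n_snps=80, seed=6, missing_rate=0.1)
        maf = compute_maf(panel)
        for j in range(panel.n_snps):
            col = panel.dosages[:, j]
            obs = col[~np.isnan(col)]
            f = obs.sum() / (2 * len(obs))
            assert maf[j] == pytest.approx(min(f, 1 - f), abs=1e-12)

    def test_all_missing_snp_is_an_error(self):
        panel = random_panel(n_samples=5, n_snps=3, seed=7)
        panel.dosages[:, 1] = np.nan
        with pytest.raises(ValueError):
            compute_maf(panel)


class TestFilterMaf:
    def test_threshold_zero_keeps_everything(self, small_panel):
        imputed = impute_missing(small_panel)
        assert filter_maf(imputed, 0.0).n_snps == imputed.n_snps

    def test_boundary_is_inclusive(self):
        # 50 samples -> allele counts out of 100: mafs 0.04, 0.05, 0.30
        panel = random_panel(n_samples=50, n_snps=3, seed=8)
        panel.dosages[:] = 0.0
        panel.dosages[:4, 0] = 1.0
        panel.dosages[:5, 1] = 1.0
        panel.dosages[:30, 2] = 1.0
        out = filter_maf(panel, 0.05)
        assert list(out.snps["id"]) == ["s1", "s2"]

    def test_idempotent(self, small_panel):
        imputed = impute_missing(small_panel)
        once = filter_maf(imputed, 0.05)
        twice = filter_maf(once, 0.05)
        assert list(twice.snps["id"]) == list(once.snps["id"])

    def test_matches_brute_force_scan(self):
        panel = random_panel(n_samples=30, n_snps=100, seed=9)
        maf = compute_maf(panel)
        expected = [panel.snps["id"][j] for j in range(100) if maf[j] >= 0.05]
        assert list(filter_maf(panel, 0.05).snps["id"]) == expected

    def test_threshold_out_of_range_rejected(self, small_panel):
        with pytest.raises(ValueError):
            filter_maf(small_panel, 0.6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=3, max_value=30),
    m=st.integers(min_value=1, max_value=40),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    threshold=st.floats(min_value=0.0, max_value=0.5),
)
def test_maf_filter_retains_exactly_the_oracle_set(n, m, seed, threshold):
    """Property: the retained set always equals the brute-force MAF scan."""
    panel = random_panel(n_samples=n, n_snps=m, seed=seed)
    maf = compute_maf(panel)
    expected = [panel.snps["id"][j] for j in range(m) if maf[j] >= threshold]
    assert list(filter_maf(panel, threshold).snps["id"]) == expected


class TestSnpDensity:
    def test_window_boundaries(self):
        panel = random_panel(n_samples=4, n_snps=3, seed=10)
        panel.snps["pos"] = [1, 400_000, 400_001]
        table = snp_density(panel, 400_000)
        assert len(table) == 2
        assert list(table["count"]) == [2, 1]
        assert list(table["window_start"]) == [1, 400_001]
        assert list(table["window_end"]) == [400_000, 800_000]

    def test_counts_conserved(self, small_panel):
        table = snp_density(small_panel, 50_000)
        assert table["count"].sum() == small_panel.n_snps

    def test_matches_brute_force_binning_on_uniform_positions(self):
        panel = random_panel(n_samples=2, n_snps=10_000, seed=11)
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(1, 3_990_000, size=10_000))
        pos += np.arange(10_000)  # strictly increasing
        panel.snps["pos"] = pos
        w = 400_000
        table = snp_density(panel, w)
        brute: dict[int, int] = {}
        for p in pos:
            brute[(p - 1) // w] = brute.get((p - 1) // w, 0) + 1
        got = dict(zip((table["window_start"] - 1) // w, table["count"]))
        assert got == brute
        assert max(brute.values()) / min(brute.values()) < 2
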