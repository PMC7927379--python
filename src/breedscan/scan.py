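"""One-vs-rest partial-least-squares scan for breed-specific SNPs.

Each breed in turn is coded ``y = 1`` against ``y = 0`` for all remaining
breeds, and a PLS1 regression of the breed indicator on the column-
standardized dosage matrix yields one coefficient per SNP.  Because PLS
extracts latent components of maximal covariance with the response, the
first-component weights are exactly the normalized cross-covariances
``X'(y - mean(y))``; further components follow NIPALS deflation.

Two per-SNP significance conventions are provided:

``zscore`` (default)
    Coefficients are standardized against the genome-wide distribution
    (mean and SD over all SNPs) and referred to two-sided normal tails.
    Between-breed drift shifts every SNP's coefficient, so the genome-wide
    spread acts as the empirical null — a SNP is called only when it is an
    outlier relative to the panel's overall divergence.
``permutation``
    The breed labels are permuted B times; each permutation's coefficients
    are standardized the same way and the empirical two-sided p-value is
    ``(1 + #{|z_perm| >= |z_obs|}) / (B + 1)``.  Standardizing within each
    permutation keeps the test aligned with the same genome-relative null,
    so it remains calibrated under neutral drift.

Significant SNPs are those with ``p < alpha`` (strict), by default 0.01,
with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "BreedScanResult",
    "standardize_dosages",
    "encode_response",
    "pls_fit",
    "coefficient_zscores",
    "snp_pvalues",
    "scan_breed",
    "scan_all_breeds",
    "scan_summary",
    "manhattan_table",
]

_P_FLOOR = 1e-300  # keep p-values strictly positive


@dataclass
class BreedScanResult:
    """Per-breed scan output: one coefficient, z and p per SNP."""

    breed_code: str
    statistic: np.ndarray
    z: np.ndarray
    pvalue: np.ndarray
    alpha: float
    significant: list[str] = field(default_factory=list)
    method: str = "zscore"
    n_components: int = 1

    @property
    def n_significant(self) -> int:
        return len(self.significant)


def standardize_dosages(X: np.ndarray) -> np.ndarray:
    """Column z-scores of the dosage matrix (mean 0, unit variance)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("dosage matrix contains missing entries; impute first")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0.0):
        raise ValueError("constant SNP columns present; apply the MAF filter first")
    return (X - mu) / sd


def encode_response(panel: GenotypePanel, breed_code: str) -> np.ndarray:
    """0/1 breed-membership indicator over samples."""
    mask = (panel.samples["breed"] == breed_code).to_numpy()
    if not mask.any():
        raise KeyError(f"unknown breed code {breed_code!r}")
    if mask.all():
        raise ValueError("response is constant: breed covers every sample")
    return mask.astype(float)


def pls_fit(
    X: np.ndarray, y: np.ndarray, n_components: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """NIPALS PLS1 on a standardized matrix; returns (weights, coefficients).

    The response is centered internally.  For each component the weight
    vector is ``w = X' y`` normalized to unit length, scores are ``t = X w``,
    and both ``X`` and ``y`` are deflated by the score regression.  The
    regression coefficients are mapped back to SNP space as
    ``B = W (P' W)^{-1} q``; for one component this reduces to ``w * q``,
    i.e. coefficients proportional to the normalized cross-covariances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if np.ptp(y) == 0.0:
        raise ValueError("constant response")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, m):
        raise ValueError("n_components exceeds the rank bound min(n - 1, m)")

    Xd = X.copy()
    yc = y - y.mean()
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros(n_components)
    ref_norm = None
    for a in range(n_components):
        w = Xd.T @ yc
        nw = float(np.linalg.norm(w))
        if ref_norm is None:
            ref_norm = nw
        if nw <= max(ref_norm, 1.0) * 1e-12:
            raise ValueError("n_components exceeds the effective rank of (X, y)")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0.0:
            raise ValueError("degenerate score vector")
        p = Xd.T @ t / tt
        q = float(yc @ t) / tt
        Xd -= np.outer(t, p)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, p, q
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return W, coef


def coefficient_zscores(coefficients: np.ndarray) -> np.ndarray:
    """Genome-wide standardization of per-SNP coefficients."""
    c = np.asarray(coefficients, dtype=float)
    sd = c.std()
    if sd == 0.0:
        raise ValueError("coefficient vector has zero spread")
    return (c - c.mean()) / sd


def _permuted_coefficients_1comp(
    X: np.ndarray, Yc: np.ndarray
) -> np.ndarray:
    """Vectorized one-component PLS coefficients for many centered responses.

    For a single component ``P'w = 1`` exactly, so the coefficient vector is
    ``w * q`` with ``w = X'y / |X'y|`` and ``q = y't / t't``; this closed form
    lets all permutations run as dense matrix products.
    """
    A = X.T @ Yc  # (m, B)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0.0] = np.inf  # degenerate permutation -> zero coefficients
    Wp = A / norms
    T = X @ Wp  # (n, B)
    tt = np.einsum("ij,ij->j", T, T)
    tt[tt == 0.0] = np.inf
    q = np.einsum("ij,ij->j", Yc, T) / tt
    return Wp * q


def snp_pvalues(
    coefficients: np.ndarray,
    method: str = "zscore",
    *,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    n_components: int = 1,
    n_permutations: int = 1000,
    seed=0,
) -> np.ndarray:
    """Per-SNP p-values for a coefficient vector.

    ``zscore``: two-sided standard-normal tails of the genome-standardized
    coefficients.  ``permutation``: add-one empirical p-values against
    ``n_permutations`` label permutations, with genome-wide standardization
    applied inside every permutation (requires ``X`` and ``y``).
    """
    c = np.asarray(coefficients, dtype=float)
    if method == "zscore":
        z = coefficient_zscores(c)
        return np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    if method != "permutation":
        raise ValueError(f"unknown p-value method {method!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if X is None or y is None:
        raise ValueError("permutation p-values require X and y")
    rng = np.random.default_rng(seed)
    z_obs = np.abs(coefficient_zscores(c))
    n = X.shape[0]
    B = int(n_permutations)
    perms = np.empty((n, B))
    for b in range(B):
        perms[:, b] = rng.permutation(y)
    Yc = perms - perms.mean(axis=0)
    if n_components == 1:
        Cp = _permuted_coefficients_1comp(X, Yc)
    else:
        Cp = np.empty((X.shape[1], B))
        for b in range(B):
            _, Cp[:, b] = pls_fit(X, perms[:, b], n_components)
    mu = Cp.mean(axis=0)
    sd = Cp.std(axis=0)
    sd[sd == 0.0] = np.inf
    Zp = np.abs((Cp - mu) / sd)
    exceed = (Zp >= z_obs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (B + 1.0)


def scan_breed(
    panel: GenotypePanel,
    breed_code: str,
    Z: np.ndarray | None = None,
    n_components: int = 1,
    alpha: float = 0.01,
    method: str = "zscore",
    n_permutations: int = 1000,
    seed=0,
) -> BreedScanResult:
    """One-vs-rest scan for a single breed."""
    if Z is None:
        Z = standardize_dosages(panel.dosages)
    y = encode_response(panel, breed_code)
    _, coef = pls_fit(Z, y, n_components)
    z = coefficient_zscores(coef)
    pvals = snp_pvalues(
        coef,
        method,
        X=Z,
        y=y,
        n_components=n_components,
        n_permutations=n_permutations,
        seed=seed,
    )
    sig_mask = pvals < alpha
    significant = list(panel.snps["id"].to_numpy()[sig_mask])
    return BreedScanResult(
        breed_code=breed_code,
        statistic=coef,
        z=z,
        pvalue=pvals,
        alpha=alpha,
        significant=significant,
        method=method,
        n_components=n_components,
    )


def scan_all_breeds(
    panel: GenotypePanel,
    n_components: int = 1,
    alpha: float = 0.01,
    method: str = "zscore",
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[BreedScanResult]:
    """Run the one-vs-rest scan recursively for every breed in the panel."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    codes = panel.breed_codes
    if len(codes) < 2:
        raise ValueError("scanning requires at least two breeds")
    counts = panel.samples["breed"].value_counts()
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise ValueError(f"every breed needs >= 2 samples; too small: {small}")
    Z = standardize_dosages(panel.dosages)
    results = []
    for i, code in enumerate(codes):
        results.append(
            scan_breed(
                panel,
                code,
                Z=Z,
                n_components=n_components,
                alpha=alpha,
                method=method,
                n_permutations=n_permutations,
                seed=[seed, i],
            )
        )
    summary = scan_summary(results)
    logger.info(
        "scan_all_breeds: union %d, per-breed sum %d significant SNPs at p < %g",
        summary["union_significant"],
        summary["sum_significant"],
        alpha,
    )
    return results


def scan_summary(results: list[BreedScanResult]) -> dict:
    """Per-breed significant counts plus their union and sum over breeds."""
    per_breed = {r.breed_code: r.n_significant for r in results}
    union: set[str] = set()
    for r in results:
        union.update(r.significant)
    return {
        "per_breed": per_breed,
        "union_significant": len(union),
        "sum_significant": int(sum(per_breed.values())),
    }


def manhattan_table(result: BreedScanResult, panel: GenotypePanel) -> pd.DataFrame:
    """Per-SNP table of genomic coordinates and ``-log10(p)`` for plotting."""
    if len(result.pvalue) != panel.n_snps:
        raise ValueError("scan result does not match the panel")
    return pd.DataFrame(
        {
            "snp_id": panel.snps["id"],
            "chrom": panel.snps["chrom"],
            "pos": panel.snps["pos"],
            "coefficient": result.statistic,
            "z": result.z,
            "pvalue": result.pvalue,
            "neg_log10_p": -np.log10(result.pvalue),
        }
    )
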