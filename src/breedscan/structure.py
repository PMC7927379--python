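"""Population-structure summaries: GRM-based PCA, classical PCoA, t-SNE.

PCA follows the genetic-relationship-matrix convention: dosages are
standardized to ``(x - 2p) / sqrt(2p(1-p))`` with ``p`` the alt-allele
frequency, the sample-by-sample matrix ``G = Z Z' / m`` is eigendecomposed,
and coordinates are eigenvectors scaled by the square root of their
eigenvalues.  Variance-explained fractions come from the GRM eigenvalues.

PCoA (classical multidimensional scaling) embeds an arbitrary distance
matrix through Gower double-centering; on Euclidean distances of the
standardized dosages it reproduces the PCA configuration up to the GRM's
``1/m`` scaling, which serves as the module's primary cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genotypes import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingResult",
    "grm_standardize",
    "run_pca",
    "run_pcoa",
    "run_tsne",
    "pairwise_distance",
    "embedding_frame",
]


@dataclass
class EmbeddingResult:
    """Low-dimensional sample coordinates with per-axis variance fractions."""

    coordinates: np.ndarray
    variance_fraction: np.ndarray
    method: str
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if vf.size and np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1.0 + 1e-9:
            raise ValueError("variance fractions exceed 1")


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|value| entry of each axis > 0."""
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def grm_standardize(panel: GenotypePanel) -> np.ndarray:
    """Standardize dosages as ``(x - 2p)/sqrt(2p(1-p))``; requires no missing."""
    X = panel.dosages
    if np.isnan(X).any():
        raise ValueError("panel contains missing genotypes; impute first")
    p = X.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError(
            "monomorphic SNPs present (p in {0,1}); apply the MAF filter first"
        )
    return (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def run_pca(panel: GenotypePanel, k: int = 10) -> EmbeddingResult:
    """GRM PCA: eigendecompose ``Z Z' / m`` and scale eigenvectors by sqrt(eigenvalue)."""
    if k < 1 or k >= panel.n_samples:
        raise ValueError("k must satisfy 1 <= k < n_samples")
    Z = grm_standardize(panel)
    m = Z.shape[1]
    G = Z @ Z.T / m
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0.0) * 1e-12
    total = vals[pos].sum()
    lam_k = np.clip(vals[:k], 0.0, None)
    coords = _fix_signs(vecs[:, :k] * np.sqrt(lam_k))
    return EmbeddingResult(
        coordinates=coords,
        variance_fraction=vals[:k] / total,
        method="PCA",
        eigenvalues=vals,
    )


def pairwise_distance(panel: GenotypePanel, metric: str = "euclidean") -> np.ndarray:
    """Sample-by-sample distances on the imputed panel.

    ``"euclidean"`` acts on GRM-standardized dosages; ``"allele-sharing"`` is
    ``1 - IBS``, i.e. the mean absolute dosage difference divided by two.
    """
    X = panel.dosages
    if np.isnan(X).any():
        raise ValueError("panel contains missing genotypes; impute first")
    if metric == "euclidean":
        return squareform(pdist(grm_standardize(panel), metric="euclidean"))
    if metric == "allele-sharing":
        return squareform(pdist(X, metric="cityblock")) / (2.0 * panel.n_snps)
    raise ValueError(f"unknown distance metric {metric!r}")


def run_pcoa(distance_matrix: np.ndarray, k: int = 10) -> EmbeddingResult:
    """Classical MDS via Gower double-centering of the squared distances.

    Coordinates come from positive-eigenvalue axes only; negative eigenvalues
    (non-Euclidean distances) are retained in ``eigenvalues`` and logged.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-8) or np.any(D < -1e-12):
        raise ValueError("distances must be non-negative with a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(np.abs(vals).max(), 1.0)
    pos = vals > scale * 1e-12
    n_neg = int((vals < -scale * 1e-12).sum())
    if n_neg:
        logger.info("run_pcoa: %d negative eigenvalues excluded from coordinates", n_neg)
    n_axes = min(k, int(pos.sum()))
    total = vals[pos].sum() if pos.any() else 1.0
    coords = _fix_signs(vecs[:, :n_axes] * np.sqrt(vals[:n_axes])) if n_axes else np.zeros((n, 0))
    return EmbeddingResult(
        coordinates=coords,
        variance_fraction=vals[:n_axes] / total,
        method="PCoA",
        eigenvalues=vals,
    )


def run_tsne(panel: GenotypePanel, n_components: int = 2, seed: int = 0, **kwargs) -> EmbeddingResult:
    """Optional t-SNE wrapper (delegates to scikit-learn, no variance fractions)."""
    from sklearn.manifold import TSNE

    Z = grm_standardize(panel)
    perplexity = kwargs.pop("perplexity", min(30.0, max(2.0, (panel.n_samples - 1) / 3.0)))
    coords = TSNE(
        n_components=n_components, random_state=seed, perplexity=perplexity, **kwargs
    ).fit_transform(Z)
    return EmbeddingResult(
        coordinates=np.asarray(coords, dtype=float),
        variance_fraction=np.empty(0),
        method="tSNE",
    )


def embedding_frame(result: EmbeddingResult, samples: pd.DataFrame) -> pd.DataFrame:
    """Tabular embedding: sample id, breed, coord_1..k."""
    k = result.coordinates.shape[1]
    frame = samples[["id", "breed"]].copy()
    for j in range(k):
        frame[f"coord_{j + 1}"] = result.coordinates[:, j]
    return frame
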