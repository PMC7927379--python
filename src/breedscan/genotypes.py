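"""Genotype panels: VCF I/O, imputation, MAF filtering and windowed SNP density.

The central container is :class:`GenotypePanel`, a samples x SNPs matrix of
alternate-allele dosages (0, 1, 2; ``NaN`` marks a missing call) together with
SNP and sample metadata tables.  Breed membership travels with the sample
table and is consumed by every downstream stage of the scan.

Dosage convention: a diploid biallelic genotype is stored as the count of
alternate alleles, so ``0/0 -> 0``, ``0/1 -> 1``, ``1/1 -> 2`` and ``./.``
becomes ``NaN``.  Positions are 1-based, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "read_vcf",
    "write_vcf",
    "read_breed_table",
    "write_breed_table",
    "impute_missing",
    "compute_maf",
    "filter_maf",
    "snp_density",
]

SNP_COLUMNS = ("id", "chrom", "pos", "ref", "alt")


def _chrom_key(chrom: str) -> tuple:
    """Natural ordering for chromosome labels: numeric first, then lexical."""
    s = str(chrom)
    body = s[3:] if s.lower().startswith("chr") else s
    if body.isdigit():
        return (0, int(body), s)
    return (1, 0, s)


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix with metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, 2}`` or ``NaN`` for missing calls.
    snps
        DataFrame with columns ``id, chrom, pos, ref, alt`` (plus ``maf``
        once :func:`compute_maf` has run), sorted by (chromosome, position).
    samples
        DataFrame with columns ``id, breed``.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns {missing_cols}")
        for col in ("id", "breed"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table lacks column {col!r}")
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")
        if (self.snps["pos"].to_numpy() < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if (self.snps["ref"] == self.snps["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        chroms = self.snps["chrom"].astype(str).to_numpy()
        pos = self.snps["pos"].to_numpy()
        seen: set[str] = set()
        prev = None
        for i, c in enumerate(chroms):
            if c != prev:
                if c in seen:
                    raise ValueError("SNPs are not grouped by chromosome")
                seen.add(c)
                prev = c
            elif pos[i] < pos[i - 1]:
                raise ValueError("SNP positions are not sorted within chromosome")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def breed_codes(self) -> list[str]:
        """Breed codes in order of first appearance in the sample table."""
        return list(pd.unique(self.samples["breed"]))

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def breed_indices(self, breed_code: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["breed"] == breed_code).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown breed code {breed_code!r}")
        return idx

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.dosages.copy(), self.snps.copy(), self.samples.copy())

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            self.dosages[:, keep],
            self.snps.iloc[keep].reset_index(drop=True),
            self.samples.copy(),
        )

    def sort_snps(self) -> "GenotypePanel":
        order = sorted(
            range(self.n_snps),
            key=lambda j: (_chrom_key(self.snps["chrom"].iat[j]), self.snps["pos"].iat[j]),
        )
        return self.subset_snps(np.asarray(order))


# -- breed table ---------------------------------------------------------------


def read_breed_table(path: str | Path) -> pd.DataFrame:
    """Read a two-column, headerless sample->breed TSV."""
    table = pd.read_csv(path, sep="\t", header=None, names=["id", "breed"], dtype=str)
    if table["id"].duplicated().any():
        raise ValueError("duplicate sample ids in breed table")
    if table["breed"].isna().any() or (table["breed"].str.len() == 0).any():
        raise ValueError("empty breed code in breed table")
    return table


def write_breed_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples[["id", "breed"]].to_csv(path, sep="\t", header=False, index=False)


# -- VCF input / output --------------------------------------------------------


def read_vcf(path: str | Path, breed_table_path: str | Path) -> GenotypePanel:
    """Load biallelic SNP records from a VCF into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are skipped (a count is logged).  Every
    VCF sample must appear in the breed table; genotypes are converted to
    alt-allele dosages with ``./.`` as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    breeds = read_breed_table(breed_table_path).set_index("id")["breed"]
    unknown = [s for s in sample_ids if s not in breeds.index]
    if unknown:
        raise ValueError(f"samples missing from breed table: {unknown[:5]}")

    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        gt = var.gt_types.astype(float)  # gts012: 0/1/2 dosage, 3 = unknown
        gt[gt == 3.0] = np.nan
        rows.append(gt)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        meta.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)

    snps = pd.DataFrame(meta, columns=list(SNP_COLUMNS))
    dosages = (
        np.asarray(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    )
    samples = pd.DataFrame(
        {"id": sample_ids, "breed": [breeds[s] for s in sample_ids]}
    )
    return GenotypePanel(dosages, snps, samples).sort_snps()


_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as a VCF v4.2 file with a GT-only FORMAT field."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedscan\n")
        for chrom in pd.unique(panel.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["id"])
            + "\n"
        )
        snps = panel.snps
        for j in range(panel.n_snps):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT_CODES[d] for d in panel.dosages[:, j]
            )
            fh.write(
                f"{snps['chrom'].iat[j]}\t{snps['pos'].iat[j]}\t{snps['id'].iat[j]}\t"
                f"{snps['ref'].iat[j]}\t{snps['alt'].iat[j]}\t.\t.\t.\tGT\t{calls}\n"
            )


# -- imputation ----------------------------------------------------------------


def impute_missing(panel: GenotypePanel, mode: str = "major", seed: int = 0) -> GenotypePanel:
    """Fill missing dosages within each breed.

    ``mode="major"`` replaces a missing call by the most frequent dosage at
    that SNP within the sample's breed (ties resolved to the smaller dosage).
    ``mode="draw"`` samples ``Binomial(2, p)`` with ``p`` the breed's
    alt-allele frequency, reproducibly under ``seed``.  A SNP entirely missing
    within a breed falls back to the panel-wide genotypes (logged).
    """
    if mode not in ("major", "draw"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    if not panel.has_missing:
        return panel.copy()
    X = panel.dosages.copy()
    miss = np.isnan(X)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        raise ValueError(
            f"{fully_missing.sum()} SNPs have no observed genotypes at all"
        )
    rng = np.random.default_rng(seed)
    fallbacks = 0
    for breed in panel.breed_codes:
        idx = panel.breed_indices(breed)
        sub_miss = miss[idx]
        for j in np.flatnonzero(sub_miss.any(axis=0)):
            obs = X[idx][~sub_miss[:, j], j]
            if obs.size == 0:
                obs = X[~miss[:, j], j]
                fallbacks += 1
            hole = idx[sub_miss[:, j]]
            if mode == "major":
                vals, counts = np.unique(obs, return_counts=True)
                X[hole, j] = vals[np.argmax(counts)]
            else:
                p = obs.sum() / (2.0 * obs.size)
                X[hole, j] = rng.binomial(2, p, size=hole.size)
    if fallbacks:
        logger.info(
            "impute_missing: %d breed/SNP cells fell back to panel-wide frequency",
            fallbacks,
        )
    return GenotypePanel(X, panel.snps.copy(), panel.samples.copy())


# -- MAF -----------------------------------------------------------------------


def compute_maf(panel: GenotypePanel) -> np.ndarray:
    """Per-SNP minor allele frequency ``min(f, 1 - f)`` over non-missing calls.

    Also stores the result in the panel's SNP table under column ``maf``.
    """
    X = panel.dosages
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("SNP with zero non-missing calls; cannot compute MAF")
    with np.errstate(invalid="ignore"):
        f = np.nansum(X, axis=0) / (2.0 * n_obs)
    maf = np.minimum(f, 1.0 - f)
    panel.snps["maf"] = maf
    return maf


def filter_maf(panel: GenotypePanel, threshold: float = 0.05) -> GenotypePanel:
    """Retain SNPs with MAF >= ``threshold`` (inclusive), preserving order."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    if "maf" not in panel.snps.columns:
        compute_maf(panel)
    maf = panel.snps["maf"].to_numpy()
    keep = maf >= threshold
    logger.info(
        "filter_maf: removed %d / %d SNPs below MAF %.3f",
        int((~keep).sum()),
        panel.n_snps,
        threshold,
    )
    return panel.subset_snps(keep)


# -- SNP density ---------------------------------------------------------------


def snp_density(panel: GenotypePanel, window_bp: int = 400_000) -> pd.DataFrame:
    """Count SNPs in non-overlapping windows of ``window_bp`` per chromosome.

    Windows are ``[k*w + 1, (k+1)*w]`` in 1-based coordinates; counts over all
    windows sum to the panel's SNP count.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be positive")
    win = (panel.snps["pos"].to_numpy() - 1) // window_bp
    table = (
        panel.snps.assign(_win=win)
        .groupby(["chrom", "_win"], sort=False)
        .size()
        .reset_index(name="count")
    )
    table["window_start"] = table["_win"] * window_bp + 1
    table["window_end"] = (table["_win"] + 1) * window_bp
    return table[["chrom", "window_start", "window_end", "count"]]
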