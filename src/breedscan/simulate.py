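"""Synthetic multi-breed genotype panels with planted breed-specific loci.

Between-breed divergence follows the Balding-Nichols model: each SNP has an
ancestral allele frequency ``p`` and every breed independently draws its own
frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, where ``F`` is an Fst-like
divergence parameter.  On top of this neutral drift, a small set of loci is
made breed-specific by a deterministic frequency shift of ``planted_delta``
in exactly one breed — the one-vs-rest contrast the downstream scan targets.

Genotypes are then drawn as ``Binomial(2, breed frequency)`` dosages with
optional at-random missingness, which stands in for the incomplete call sets
typical of reduced-representation genotyping.

The default configuration mirrors a 24-breed pig panel of 1,069 animals with
unequal breed sizes (10-97) typed at ~60k autosomal SNPs.  Smaller panels for
testing are obtained by overriding the fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypePanel, write_breed_table, write_vcf

logger = logging.getLogger(__name__)

__all__ = [
    "STUDY_BREED_SIZES",
    "SimulationConfig",
    "draw_breed_frequencies",
    "plant_breed_specific_loci",
    "simulate_genotypes",
    "simulate_panel",
    "write_truth_table",
    "synthetic_annotation",
]

#: Breed abbreviations and sample sizes of the reference panel the generator
#: emulates (5 Western breeds followed by 19 Chinese indigenous breeds from
#: the Yangtze River Delta; 1,069 animals in total).
STUDY_BREED_SIZES: tuple[tuple[str, int], ...] = (
    ("D", 49), ("L", 21), ("Y", 53), ("P", 20), ("B", 16),
    ("SMS", 75), ("MI", 36), ("EH", 42), ("DC", 10), ("HB", 34),
    ("HD", 30), ("JQ", 38), ("SZ", 20), ("BH", 30), ("CA", 59),
    ("CL", 22), ("JHL", 57), ("LX", 40), ("SH", 64), ("JX", 91),
    ("MMS", 97), ("SW", 65), ("FJ", 32), ("PD", 68),
)

_STUDY_CODES = tuple(code for code, _ in STUDY_BREED_SIZES)
_STUDY_SIZES = tuple(size for _, size in STUDY_BREED_SIZES)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic panel generator.

    Defaults emulate the reference panel: 24 breeds of unequal size
    (1,069 animals), 62,822 SNPs on 18 autosomes, moderate between-breed
    divergence, five planted breed-specific loci per breed and a modest
    missing-call rate prior to imputation.
    """

    n_breeds: int = 24
    samples_per_breed: tuple[int, ...] = _STUDY_SIZES
    n_snps: int = 62_822
    fst: float = 0.15
    n_planted_per_breed: int = 5
    planted_delta: float = 0.4
    missing_rate: float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    n_chromosomes: int = 18
    chrom_length_bp: int = 140_000_000
    seed: int = 0
    breed_codes: tuple[str, ...] | None = None

    def validate(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly in (0, 1)")
        if self.n_breeds < 1 or len(self.samples_per_breed) != self.n_breeds:
            raise ValueError("samples_per_breed must list one size per breed")
        if any(s < 1 for s in self.samples_per_breed):
            raise ValueError("every breed needs at least one sample")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.n_planted_per_breed < 0:
            raise ValueError("n_planted_per_breed must be non-negative")
        if self.n_planted_per_breed * self.n_breeds > self.n_snps:
            raise ValueError("more planted loci requested than SNPs available")
        if not 0.0 <= self.planted_delta <= 1.0:
            raise ValueError("planted_delta must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_chromosomes < 1 or self.chrom_length_bp < self.n_snps:
            raise ValueError("chromosome layout cannot hold the requested SNPs")

    @property
    def codes(self) -> tuple[str, ...]:
        if self.breed_codes is not None:
            if len(self.breed_codes) != self.n_breeds:
                raise ValueError("breed_codes length must equal n_breeds")
            return self.breed_codes
        if self.n_breeds == len(_STUDY_CODES):
            return _STUDY_CODES
        return tuple(f"B{i + 1:02d}" for i in range(self.n_breeds))

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_breed))


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([config.seed, stage])


def draw_breed_frequencies(config: SimulationConfig) -> np.ndarray:
    """Draw the breeds x SNPs allele-frequency matrix under Balding-Nichols.

    Ancestral frequencies are uniform on ``ancestral_maf_range``; each breed's
    frequency is an independent Beta draw around the ancestral value with
    variance ``F * p * (1 - p)``.
    """
    config.validate()
    rng = _rng(config, 0)
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    f = config.fst
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    freqs = rng.beta(a, b, size=(config.n_breeds, config.n_snps))
    # Beta support is open (0,1); guard against floating underflow at the ends
    np.clip(freqs, 1e-9, 1.0 - 1e-9, out=freqs)
    return freqs


def plant_breed_specific_loci(
    freqs: np.ndarray, config: SimulationConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Shift ``n_planted_per_breed`` loci per breed by ``planted_delta``.

    Each planted locus belongs to exactly one breed; the focal breed's
    frequency moves toward the boundary with more room and is clipped to
    ``[0.02, 0.98]`` so the locus survives a MAF filter.  Returns the new
    frequency matrix and the truth table ``(snp_index, breed_code)``.
    """
    config.validate()
    n_breeds, n_snps = freqs.shape
    if (n_breeds, n_snps) != (config.n_breeds, config.n_snps):
        raise ValueError("frequency matrix does not match the configuration")
    k = config.n_planted_per_breed
    out = freqs.copy()
    if k == 0:
        truth = pd.DataFrame({"snp_index": pd.Series(dtype=int),
                              "breed_code": pd.Series(dtype=str)})
        return out, truth
    rng = _rng(config, 1)
    chosen = rng.choice(n_snps, size=n_breeds * k, replace=False)
    rows = []
    for b, code in enumerate(config.codes):
        for j in chosen[b * k : (b + 1) * k]:
            f = out[b, j]
            if config.planted_delta > 0:  # delta 0: record truth, leave f alone
                shifted = (
                    f + config.planted_delta if f <= 0.5 else f - config.planted_delta
                )
                out[b, j] = np.clip(shifted, 0.02, 0.98)
            rows.append((int(j), code))
    truth = pd.DataFrame(rows, columns=["snp_index", "breed_code"])
    return out, truth.sort_values("snp_index", ignore_index=True)


def _snp_layout(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced 1-based positions across the configured chromosomes."""
    blocks = np.array_split(np.arange(config.n_snps), config.n_chromosomes)
    chroms, positions = [], []
    for c, block in enumerate(blocks, start=1):
        if block.size == 0:
            continue
        step = max(config.chrom_length_bp // (block.size + 1), 1)
        chroms.extend([str(c)] * block.size)
        positions.extend(step * (i + 1) for i in range(block.size))
    return pd.DataFrame(
        {
            "id": [f"snp{j:07d}" for j in range(config.n_snps)],
            "chrom": chroms,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )


def simulate_genotypes(freqs: np.ndarray, config: SimulationConfig) -> GenotypePanel:
    """Draw dosages ``Binomial(2, breed frequency)`` and attach metadata.

    Missing entries are set independently with probability ``missing_rate``.
    SNPs receive evenly spaced positions across ``n_chromosomes``.
    """
    config.validate()
    if freqs.shape != (config.n_breeds, config.n_snps):
        raise ValueError("frequency matrix does not match the configuration")
    rng = _rng(config, 2)
    n = config.n_samples
    X = np.empty((n, config.n_snps), dtype=float)
    sample_ids, sample_breeds = [], []
    row = 0
    for b, (code, size) in enumerate(zip(config.codes, config.samples_per_breed)):
        X[row : row + size] = rng.binomial(2, freqs[b], size=(size, config.n_snps))
        sample_ids.extend(f"{code}_{i + 1:03d}" for i in range(size))
        sample_breeds.extend([code] * size)
        row += size
    if config.missing_rate > 0:
        miss = _rng(config, 3).random((n, config.n_snps)) < config.missing_rate
        X[miss] = np.nan
    samples = pd.DataFrame({"id": sample_ids, "breed": sample_breeds})
    return GenotypePanel(X, _snp_layout(config), samples)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypePanel, pd.DataFrame, np.ndarray]:
    """Full generator chain: frequencies -> planted loci -> genotypes.

    Returns ``(panel, truth_table, frequency_matrix)``; byte-identical for
    identical config + seed.
    """
    freqs = draw_breed_frequencies(config)
    freqs, truth = plant_breed_specific_loci(freqs, config)
    panel = simulate_genotypes(freqs, config)
    return panel, truth, freqs


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def export_panel(
    panel: GenotypePanel, outdir: str | Path, truth: pd.DataFrame | None = None
) -> dict[str, Path]:
    """Write VCF + breed TSV (+ truth TSV) for a simulated panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "breeds": outdir / "breeds.tsv",
    }
    write_vcf(panel, paths["vcf"])
    write_breed_table(panel.samples, paths["breeds"])
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        write_truth_table(truth, paths["truth"])
    return paths


# -- synthetic annotation resources -------------------------------------------


def synthetic_annotation(
    panel: GenotypePanel,
    seed: int = 0,
    snps_per_gene: int = 5,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 40),
    extra_edge_factor: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, set[str]], nx.Graph]:
    """Generate gene models, a term database and an interaction graph.

    Genes tile each chromosome over runs of ``snps_per_gene`` consecutive
    SNPs, so every SNP maps to a gene.  Terms are random gene sets; the
    interaction graph is a per-chromosome chain plus random long-range edges,
    giving a connected, sparse network with local structure.  This is a
    self-contained stand-in for curated annotation content (Ensembl gene
    models, GO/KEGG gene sets, interaction databases), adequate for
    exercising the mapping, enrichment and module-scoring machinery.
    """
    rng = np.random.default_rng([seed, 4])
    rows = []
    for chrom, block in panel.snps.groupby("chrom", sort=False):
        pos = block["pos"].to_numpy()
        for g, start_idx in enumerate(range(0, len(pos), snps_per_gene)):
            chunk = pos[start_idx : start_idx + snps_per_gene]
            rows.append(
                (f"G{chrom}_{g + 1:04d}", str(chrom), int(chunk.min()), int(chunk.max()), "+")
            )
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    gene_ids = genes["gene_id"].to_numpy()
    lo, hi = term_size_range
    hi = min(hi, len(gene_ids))
    termdb: dict[str, set[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(min(lo, hi), hi + 1))
        termdb[f"T{t + 1:03d}"] = set(rng.choice(gene_ids, size=size, replace=False))

    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)
    for _, block in genes.groupby("chrom", sort=False):
        ids = block["gene_id"].to_numpy()
        graph.add_edges_from(zip(ids[:-1], ids[1:]))
    n_extra = int(extra_edge_factor * len(gene_ids))
    pairs = rng.integers(0, len(gene_ids), size=(n_extra, 2))
    graph.add_edges_from(
        (gene_ids[a], gene_ids[b]) for a, b in pairs if a != b
    )
    return genes, termdb, graph
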