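"""SNP-to-gene mapping and hypergeometric term enrichment.

Significant SNPs are assigned to genes by positional overlap with a
configurable flank, and each breed's gene set is tested against a
term -> gene database (GMT) with the right-tail hypergeometric test —
Fisher's exact test on the right tail:

    p = P[Hypergeometric(N, K, n) >= k]

where ``N`` is the background size, ``K`` the term's genes in the
background, ``n`` the query set size and ``k`` the overlap.  No
multiple-testing correction is applied; terms are counted at the raw
thresholds p < 0.05 and p < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genotypes import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "read_gff3",
    "read_bed",
    "read_gmt",
    "map_snps_to_genes",
    "enrich_terms",
    "count_significant",
    "enrichment_table",
]

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's 2x2 overlap counts and right-tail hypergeometric p-value."""

    term_id: str
    k: int
    n: int
    K: int
    N: int
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError("inconsistent 2x2 counts")


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table lacks columns {missing}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene with start > end")
    return genes.reset_index(drop=True)


def read_gff3(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Load gene models from GFF3 (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        attrs = feat.attributes
        gene_id = (
            attrs.get("gene_id", [None])[0]
            or attrs.get("ID", [None])[0]
            or attrs.get("Name", [None])[0]
            or feat.id
        )
        gene_id = gene_id.removeprefix("gene:")
        rows.append((gene_id, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    if not rows:
        raise ValueError(f"no {feature_type!r} features found in {path}")
    return _validate_genes(pd.DataFrame(rows, columns=list(GENE_COLUMNS)))


def read_bed(path: str | Path) -> pd.DataFrame:
    """Load gene models from BED (0-based half-open -> 1-based inclusive)."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 3:
        raise ValueError("BED file needs at least chrom, start, end")
    genes = pd.DataFrame(
        {
            "gene_id": raw[3].astype(str)
            if raw.shape[1] >= 4
            else [f"region_{i + 1}" for i in range(len(raw))],
            "chrom": raw[0].astype(str),
            "start": raw[1].astype(int) + 1,
            "end": raw[2].astype(int),
            "strand": raw[5].astype(str) if raw.shape[1] >= 6 else "+",
        }
    )
    return _validate_genes(genes)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Load a term -> gene-set database from a GMT file.

    Each line is ``term<TAB>description<TAB>gene1<TAB>gene2...``; empty terms
    are rejected.
    """
    termdb: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"term {parts[0]!r} has no genes")
            termdb[parts[0]] = genes
    if not termdb:
        raise ValueError(f"no terms parsed from {path}")
    return termdb


def map_snps_to_genes(
    snp_ids: Sequence[str],
    panel: GenotypePanel,
    genes: pd.DataFrame,
    flank_bp: int = 10_000,
) -> list[str]:
    """Genes overlapped by any of the SNPs within ``[start - flank, end + flank]``.

    Strand is ignored; each gene is reported once, sorted by id.  Unknown SNP
    ids raise ``KeyError``.
    """
    genes = _validate_genes(genes)
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    index = pd.Index(panel.snps["id"])
    locs = index.get_indexer(list(snp_ids))
    if (locs < 0).any():
        bad = [s for s, l in zip(snp_ids, locs) if l < 0]
        raise KeyError(f"unknown SNP ids: {bad[:5]}")
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # 1-based inclusive span with flank -> half-open interval
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            row.start - flank_bp, row.end + flank_bp + 1, row.gene_id
        )
    hits: set[str] = set()
    chroms = panel.snps["chrom"].astype(str).to_numpy()
    pos = panel.snps["pos"].to_numpy()
    for loc in locs:
        tree = trees.get(chroms[loc])
        if tree is not None:
            hits.update(iv.data for iv in tree.at(int(pos[loc])))
    return sorted(hits)


def enrich_terms(
    gene_set: Iterable[str],
    termdb: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> list[EnrichmentRecord]:
    """Right-tail hypergeometric enrichment of ``gene_set`` for every term.

    Terms are intersected with the background; terms with no background gene
    are dropped.  Records are sorted by ascending p, then term id.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    query = set(gene_set)
    if not query <= bg:
        raise ValueError("background must contain every query gene")
    N, n = len(bg), len(query)
    records = []
    for term_id, genes in termdb.items():
        term_genes = set(genes) & bg
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(query & term_genes)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(
            EnrichmentRecord(term_id=term_id, k=k, n=n, K=K, N=N, pvalue=min(p, 1.0))
        )
    records.sort(key=lambda r: (r.pvalue, r.term_id))
    return records


def count_significant(
    records: Sequence[EnrichmentRecord], alphas: Sequence[float] = (0.05, 0.01)
) -> dict[float, int]:
    """Strict-inequality term counts at each threshold."""
    return {a: sum(r.pvalue < a for r in records) for a in alphas}


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.k, r.K, r.n, r.N, r.pvalue) for r in records],
        columns=["term_id", "k", "K", "n", "N", "pvalue"],
    )
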