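"""End-to-end orchestration: simulate/load -> QC -> structure -> scan ->
annotate -> enrich -> network, with a machine-readable run summary.

A run is a pure function of (inputs, configuration, seed): identical
configuration and seed reproduce the summary byte for byte.  Every stage
writes its tables under the configured output directory; the summary JSON
gathers per-breed counts of significant SNPs, genes, enriched terms and
network modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, network, scan, simulate, structure
from .genotypes import (
    GenotypePanel,
    compute_maf,
    filter_maf,
    impute_missing,
    read_vcf,
    snp_density,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one genotype source must be given: a ``simulation`` block or a
    ``vcf`` + ``breed_table`` pair.  Annotation inputs (gene models, GMT,
    edge list) are optional; in simulation mode, synthetic annotation is
    generated when they are absent so every stage runs.
    """

    outdir: Path
    simulation: simulate.SimulationConfig | None = None
    vcf: Path | None = None
    breed_table: Path | None = None
    genes: Path | None = None
    gmt: Path | None = None
    edges: Path | None = None
    maf_threshold: float = 0.05
    impute_mode: str = "major"
    window_bp: int = 400_000
    embed_k: int = 10
    n_components: int = 1
    alpha: float = 0.01
    pvalue_method: str = "zscore"
    n_permutations: int = 1000
    enrichment_alphas: tuple[float, ...] = (0.05, 0.01)
    flank_bp: int = 10_000
    network_score_threshold: float = 2.0
    module_max_size: int = 35
    seed: int = 0
    make_plots: bool = True
    synthetic_annotation: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        sim_mode = self.simulation is not None
        file_mode = self.vcf is not None
        if sim_mode == file_mode:
            raise ValueError("exactly one of simulation block or VCF input required")
        if file_mode and self.breed_table is None:
            raise ValueError("VCF input requires a breed table")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for a in self.enrichment_alphas:
            if not 0.0 < a < 1.0:
                raise ValueError("enrichment alphas must lie in (0, 1)")
        if self.flank_bp < 0 or self.network_score_threshold < 0:
            raise ValueError("flank_bp and network_score_threshold must be >= 0")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "samples_per_breed" in sim:
                sim["samples_per_breed"] = tuple(sim["samples_per_breed"])
            if "breed_codes" in sim and sim["breed_codes"] is not None:
                sim["breed_codes"] = tuple(sim["breed_codes"])
            if "ancestral_maf_range" in sim:
                sim["ancestral_maf_range"] = tuple(sim["ancestral_maf_range"])
            sim = simulate.SimulationConfig(**sim)
        if "enrichment_alphas" in raw:
            raw["enrichment_alphas"] = tuple(raw["enrichment_alphas"])
        for key in ("vcf", "breed_table", "genes", "gmt", "edges"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(simulation=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_gene_models(path: Path) -> pd.DataFrame:
    if str(path).endswith((".bed", ".bed.txt")):
        return annotate.read_bed(path)
    return annotate.read_gff3(path)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run summary."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("breedscan")
    root.addHandler(handler)
    try:
        return _run(config, out)
    except Exception as exc:  # re-raise with the failing stage in the message
        stage = getattr(exc, "_stage", "pipeline")
        raise RuntimeError(f"[{stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                exc._stage = name
                raise

        return wrapped

    return deco


@_stage("input")
def _obtain_panel(config: RunConfig, out: Path):
    truth = None
    if config.simulation is not None:
        logger.info("simulating panel: %s", config.simulation)
        panel, truth, _ = simulate.simulate_panel(config.simulation)
        simulate.export_panel(panel, out, truth)
    else:
        panel = read_vcf(config.vcf, config.breed_table)
    return panel, truth


@_stage("annotation-input")
def _obtain_annotation(config: RunConfig, panel: GenotypePanel):
    genes = termdb = graph = None
    if config.genes is not None:
        genes = _load_gene_models(config.genes)
    if config.gmt is not None:
        termdb = annotate.read_gmt(config.gmt)
    if config.edges is not None:
        graph = network.read_edge_list(config.edges)
    if (
        config.simulation is not None
        and config.synthetic_annotation
        and (genes is None or termdb is None or graph is None)
    ):
        sgenes, stermdb, sgraph = simulate.synthetic_annotation(
            panel, seed=config.seed
        )
        genes = genes if genes is not None else sgenes
        termdb = termdb if termdb is not None else stermdb
        graph = graph if graph is not None else sgraph
    return genes, termdb, graph


def _run(config: RunConfig, out: Path) -> dict:
    panel, truth = _obtain_panel(config, out)

    # QC ---------------------------------------------------------------------
    qc = _stage("qc")(_qc_stage)
    panel, n_snps_raw = qc(config, panel, out)

    # structure --------------------------------------------------------------
    struct = _stage("structure")(_structure_stage)
    pca, pcoa = struct(config, panel, out)

    # scan -------------------------------------------------------------------
    do_scan = _stage("scan")(_scan_stage)
    results, summary_counts = do_scan(config, panel, out)

    # annotation / enrichment / network ---------------------------------------
    genes, termdb, graph = _obtain_annotation(config, panel)
    annot = _stage("annotation")(_annotation_stage)
    breed_blocks = annot(config, panel, results, genes, termdb, graph, out)

    summary: dict = {
        "config": {
            "maf_threshold": config.maf_threshold,
            "impute_mode": config.impute_mode,
            "alpha": config.alpha,
            "pvalue_method": config.pvalue_method,
            "n_components": config.n_components,
            "enrichment_alphas": list(config.enrichment_alphas),
            "flank_bp": config.flank_bp,
            "network_score_threshold": config.network_score_threshold,
            "window_bp": config.window_bp,
            "seed": config.seed,
        },
        "n_samples": panel.n_samples,
        "n_breeds": len(panel.breed_codes),
        "n_snps_raw": n_snps_raw,
        "n_snps_post_filter": panel.n_snps,
        "pca_variance_fraction": [round(float(v), 10) for v in pca.variance_fraction[:2]],
        "pcoa_variance_fraction": [round(float(v), 10) for v in pcoa.variance_fraction[:2]],
        "significant_snps": summary_counts,
        "breeds": breed_blocks,
    }
    if truth is not None and len(truth):
        by_breed = {r.breed_code: set(r.significant) for r in results}
        # planted snp_index refers to the generator's original order; SNP ids
        # encode that index and are stable under filtering
        recovered = 0
        total = 0
        original_ids = truth["snp_index"].map(lambda j: f"snp{j:07d}")
        for sid, code in zip(original_ids, truth["breed_code"]):
            total += 1
            if code in by_breed and sid in by_breed[code]:
                recovered += 1
        summary["planted_truth"] = {
            "n_planted": total,
            "n_recovered": recovered,
            "recovery_rate": round(recovered / total, 6) if total else None,
        }
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _qc_stage(config: RunConfig, panel: GenotypePanel, out: Path):
    n_raw = panel.n_snps
    panel = impute_missing(panel, mode=config.impute_mode, seed=config.seed)
    compute_maf(panel)  # MAF computed after imputation
    panel = filter_maf(panel, config.maf_threshold)
    density = snp_density(panel, config.window_bp)
    _write_tsv(density, out / "snp_density.tsv")
    if config.make_plots:
        from . import plotting

        plotting.density_plot(density, out / "snp_density.png", config.window_bp)
    return panel, n_raw


def _structure_stage(config: RunConfig, panel: GenotypePanel, out: Path):
    k = min(config.embed_k, panel.n_samples - 1)
    pca = structure.run_pca(panel, k=k)
    D = structure.pairwise_distance(panel, metric="euclidean")
    pcoa = structure.run_pcoa(D, k=k)
    _write_tsv(structure.embedding_frame(pca, panel.samples), out / "pca.tsv")
    _write_tsv(structure.embedding_frame(pcoa, panel.samples), out / "pcoa.tsv")
    if config.make_plots:
        from . import plotting

        plotting.embedding_plot(pca, panel.samples, out / "pca.png", "PCA")
        plotting.embedding_plot(pcoa, panel.samples, out / "pcoa.png", "PCoA")
    return pca, pcoa


def _scan_stage(config: RunConfig, panel: GenotypePanel, out: Path):
    results = scan.scan_all_breeds(
        panel,
        n_components=config.n_components,
        alpha=config.alpha,
        method=config.pvalue_method,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    for r in results:
        table = scan.manhattan_table(r, panel)
        _write_tsv(table, out / f"scan_{r.breed_code}.tsv")
        if config.make_plots:
            from . import plotting

            plotting.manhattan_plot(
                table, out / f"manhattan_{r.breed_code}.png", r.breed_code, r.alpha
            )
    counts = scan.scan_summary(results)
    _write_tsv(
        pd.DataFrame(
            sorted(counts["per_breed"].items()), columns=["breed", "n_significant"]
        ),
        out / "scan_summary.tsv",
    )
    return results, counts


def _annotation_stage(config, panel, results, genes, termdb, graph, out: Path):
    breed_blocks: dict[str, dict] = {}
    modules_per_breed: dict[str, list] = {}
    background = None
    if genes is not None:
        background = annotate.map_snps_to_genes(
            list(panel.snps["id"]), panel, genes, config.flank_bp
        )
    for r in results:
        block: dict = {"n_significant_snps": r.n_significant}
        if genes is not None:
            breed_genes = annotate.map_snps_to_genes(
                r.significant, panel, genes, config.flank_bp
            )
            (out / f"genes_{r.breed_code}.txt").write_text(
                "\n".join(breed_genes) + ("\n" if breed_genes else "")
            )
            block["n_genes"] = len(breed_genes)
            if termdb is not None:
                records = annotate.enrich_terms(breed_genes, termdb, background)
                _write_tsv(
                    annotate.enrichment_table(records),
                    out / f"enrichment_{r.breed_code}.tsv",
                )
                counts = annotate.count_significant(records, config.enrichment_alphas)
                block["terms"] = {str(a): c for a, c in sorted(counts.items())}
            if graph is not None:
                modules = network.build_modules(
                    graph, breed_genes, config.module_max_size
                )
                network.score_modules(modules, breed_genes, graph.nodes)
                modules_per_breed[r.breed_code] = modules
        breed_blocks[r.breed_code] = block
    if modules_per_breed:
        ranking = network.rank_and_count(
            modules_per_breed, config.network_score_threshold
        )
        _write_tsv(network.module_table(modules_per_breed), out / "modules.tsv")
        _write_tsv(ranking, out / "network_summary.tsv")
        for row in ranking.itertuples(index=False):
            breed_blocks[row.breed]["n_modules"] = int(row.n_modules)
            breed_blocks[row.breed]["n_modules_scored"] = int(row.n_above_threshold)
    return breed_blocks
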