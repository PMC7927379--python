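# breedscan

Conservation genetics toolkit for finding what makes each population in a
multi-breed SNP panel *unique*. Given diploid genotypes for B breeds (e.g. a
panel of Chinese indigenous and Western pig breeds), `breedscan` runs a
one-vs-rest partial-least-squares (PLS) scan that scores every SNP for how
strongly it separates one breed from all the others, then carries the
significant loci through gene mapping, gene-set enrichment and
interaction-network module scoring — the analysis chain used to prioritise
breed-specific "structural modules" for precise conservation programmes.

## The statistic

For each breed in turn, samples are coded

```
y_i = 1  if sample i belongs to the focal breed
y_i = 0  otherwise
```

and `y` is regressed on the column-standardized dosage matrix
`X` (n samples × m SNPs, dosages 0/1/2) by PLS1. PLS extracts latent
components of maximal covariance with the response, so the first-component
weights are exactly the normalized cross-covariances

```
w ∝ Xᵀ(y − ȳ)
```

with further components obtained by NIPALS deflation. The per-SNP
regression coefficient `c_j` measures how much locus j contributes to the
focal-vs-rest discrimination. Significance is assessed genome-relative:
`z_j = (c_j − mean(c)) / sd(c)` with two-sided normal tails (default), or by
label permutation with the same genome-wide standardization inside every
permutation. SNPs with `p < 0.01` (strict, uncorrected) form the breed's
significant set.

Downstream, significant SNPs map to genes by positional overlap (configurable
flank), each breed's gene set is tested against GMT terms with the right-tail
hypergeometric (Fisher exact) test, and gene-interaction modules grown around
the breed's "focus genes" are scored as

```
score = −log10 P[Hypergeom(N, K, n) ≥ focus_count]
```

where N is the interaction-graph universe, K the focus genes in it and n the
module size.

Because deposited genotypes for the original 24-breed panel are not bundled,
the package ships a Balding–Nichols simulator: per SNP an ancestral frequency
`p`, per breed an independent draw from `Beta(p(1−F)/F, (1−p)(1−F)/F)` (F is
an Fst-like divergence), plus a small set of planted loci shifted by a known
amount in exactly one breed, so that scan power and calibration can be
measured against ground truth.

## Worked example

```python
from breedscan import SimulationConfig, RunConfig, run_pipeline

config = RunConfig(
    outdir="demo",
    simulation=SimulationConfig(
        n_breeds=6, samples_per_breed=(30,) * 6, n_snps=5000,
        fst=0.05, n_planted_per_breed=5, planted_delta=0.5,
        missing_rate=0.05, n_chromosomes=5, chrom_length_bp=50_000_000,
        seed=1,
    ),
    seed=1, make_plots=False,
)
summary = run_pipeline(config)
```

prints (via the summary dict):

```
SNPs after MAF filter : 4873
PCA PC1/PC2 variance  : ['2.41%', '2.34%']
significant SNPs union: 306
per-breed significant : {'B01': 49, 'B02': 66, 'B03': 44, 'B04': 55, 'B05': 49, 'B06': 43}
planted loci recovered: 80%
modules per breed     : {'B01': 11, 'B02': 15, 'B03': 11, 'B04': 15, 'B05': 9, 'B06': 10}
```

Reading this: 127 of 5,000 simulated SNPs fell below the MAF ≥ 0.05 filter
after imputation; the leading principal components are small because six
equally diverged breeds share the variance; each breed's scan calls ~1% of
loci plus the planted signal, and 24 of the 30 planted breed-specific loci
(delta 0.5 at divergence F = 0.05) are recovered in their focal breed's
significant set. Output files per run: SNP density table (400-kb windows),
PCA/PCoA embeddings, per-breed scan tables and Manhattan plots, gene lists,
enrichment tables, a module report and `summary.json`.

The same run is available from the shell:

```
breedscan simulate --n-breeds 6 --samples-per-breed 30 --n-snps 5000 \
    --fst 0.05 --delta 0.5 --seed 1 --out demo/
breedscan scan --vcf demo/genotypes.vcf --breeds demo/breeds.tsv --out demo/scan/
breedscan all --config run.yaml      # full pipeline from YAML
```

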