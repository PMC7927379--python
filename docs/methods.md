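# Methods

## Overview

`breedscan` implements a breed-specificity analysis for multi-population SNP
panels: quality control of called genotypes, population-structure summaries,
a one-vs-rest PLS scan per breed, and functional follow-up (gene mapping,
term enrichment, network-module scoring). This note records the models, the
parameter defaults and the numerical conventions, including the places where
the design was genuinely open and a choice had to be made.

## Genotype model and QC

Genotypes are diploid biallelic dosages (alt-allele counts 0/1/2) with
missing calls allowed, read from VCF v4.2 (multiallelic and non-SNP records
are skipped and counted). Imputation is deliberately simple and
breed-stratified: `major` (default) replaces a missing call with the most
frequent dosage at that SNP within the sample's breed; `draw` samples
`Binomial(2, p̂_breed)` reproducibly under a seed. Haplotype-aware imputation
is out of scope — the scan statistic consumes dosages only, so LD-free
imputation changes little at the allele-frequency level, but panels imputed
this way are not expected to reproduce SNP counts from LD-aware pipelines
exactly.

MAF is computed **after** imputation (`min(f, 1−f)` over all calls) and the
filter keeps SNPs with MAF ≥ threshold, inclusive, default 0.05. SNP density
uses non-overlapping windows `[k·w+1, (k+1)·w]` in 1-based coordinates,
default `w` = 400 kb.

## Synthetic panels

The generator emulates a 24-breed pig panel (1,069 animals in 24 unequal
breeds of 10–97, ~60k autosomal SNPs) but every dimension is a parameter.

* **Divergence.** Balding–Nichols: ancestral frequency `p ~ U(0.05, 0.5)`
  per SNP; each breed draws `f_b ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`
  independently, giving `Var(f_b) = F·p(1−p)`. The single parameter `F`
  (default 0.15) is the between-breed Fst; the true divergence of the
  reference panel is unknown, so `F` is exposed rather than fixed. A
  method-of-moments check (between-breed variance over `p̄(1−p̄)`, averaged
  over loci) recovers `F` to within a few percent at 10k SNPs.
* **Planted breed-specific loci.** Per breed, `n_planted_per_breed`
  (default 5) distinct SNPs are shifted by `planted_delta` (default 0.4) in
  the focal breed only, toward whichever allele-frequency boundary has room,
  clipped to [0.02, 0.98] so planted loci survive the MAF filter. A
  deterministic shift — not a sweep simulator — because it is exactly the
  focal-vs-rest frequency contrast the scan statistic tests. A delta of 0
  records the truth table without touching frequencies.
* **Genotypes.** `Binomial(2, f_b)` dosages; missing entries at random with
  `missing_rate` (default 0.05, the order of raw missingness in
  reduced-representation genotyping, exercised so imputation is always on the
  default path). Positions are evenly spaced over 18 chromosomes of 140 Mb
  (pig autosome scale); only density windows and gene mapping consume them.
* **Not modelled:** LD, recombination, demography, genotyping error. Planted
  signals are therefore "clean" single-locus contrasts; passing power tests
  says the statistic ranks such contrasts correctly, not that real selective
  sweeps (extended haplotypes, linked loci) would be recovered at the same
  rate.
* Synthetic annotation (genes tiling the SNP positions, random GMT terms, a
  chain-plus-random-edges interaction graph) exists so the full pipeline runs
  without external databases; it carries no biology.

All stages draw from per-stage `numpy` generators seeded as
`[seed, stage]`, so the full chain is byte-reproducible and stages are
independently stable.

## Structure summaries

PCA follows the genetic-relationship-matrix convention: standardize dosages
as `(x − 2p)/√(2p(1−p))`, eigendecompose `G = ZZᵀ/m`, scale eigenvectors by
`√λ`, report `λ_i / Σ_{λ>0} λ` as variance fractions. Monomorphic SNPs make
the standardization singular and raise an error directing users to the MAF
filter. PCoA is classical MDS: Gower double-centering `B = −½ J D∘D J`,
positive-eigenvalue axes only (negative eigenvalues are logged and kept in
the result for inspection). On Euclidean distances of the standardized
dosages, `B = ZZᵀ`, so PCoA reproduces the PCA configuration up to the GRM's
`1/m` scaling — the module's built-in cross-check. The PCoA distance is
configurable (`euclidean` on standardized dosages, default, or
allele-sharing `1 − IBS`) since the appropriate choice is data-dependent.
t-SNE is a thin wrapper over scikit-learn, provided for visualisation only.

## The PLS scan

`X` is column-standardized (z-scores of dosages, making weights comparable
across MAF); `y` is the 0/1 breed indicator, centered inside the fit.
NIPALS PLS1: `w = Xᵀy/‖Xᵀy‖`, scores `t = Xw`, loadings `p = Xᵀt/tᵀt`,
`q = yᵀt/tᵀt`, deflation of X and y, coefficients
`B = W(PᵀW)⁻¹q`. Default `n_components = 1`: a one-vs-rest contrast targets
a single discriminant direction, and the first component already carries the
full cross-covariance signal; the parameter is exposed for users who want
deflated refinements.

**Per-SNP significance.** Under neutral between-breed drift every SNP's
coefficient is shifted — drift is genuine breed structure, just not
breed-*specific* structure. Both p-value conventions therefore calibrate
against the genome-wide coefficient distribution:

* `zscore` (default): `z_j = (c_j − mean(c))/sd(c)`, two-sided normal
  tails. Fast; appropriate when the coefficient distribution is
  approximately normal, which holds for Beta-drift panels at moderate F.
* `permutation`: B label permutations (default 1000; add-one rule
  `p = (1 + #{|z_perm| ≥ |z_obs|})/(B+1)`, so p ≥ 1/(B+1) > 0). The
  genome-wide z-standardization is applied inside every permutation;
  comparing raw coefficients instead would test "is this SNP associated with
  the breed at all", which under drift is true of every SNP and yields an
  uncontrolled call rate. With standardization the null call fraction at
  α = 0.01 measures ≈ 0.011 on six-breed panels at F = 0.1.

For one component the permuted coefficients have the closed form `w·q`
(since `Pᵀw = 1`), so all permutations run as dense matrix products; the
multi-component path falls back to per-permutation NIPALS fits.

Significant sets use strict `p < α`, default α = 0.01, uncorrected; the
per-breed counts, their union and their sum are all reported (the union/sum
distinction matters when loci are shared between breeds).

**Power.** Detectability of a planted shift Δ is bounded by the
drift-to-shift ratio, not by sample size: the focal-vs-rest frequency gap
has neutral spread `≈ √(1.2·F·p(1−p))` (≈ 0.16 at F = 0.1), so Δ = 0.4 is a
~2.5σ signal and a calibrated 1% test recovers only ~25–30% of planted loci
on six-breed panels at F = 0.1. At weaker divergence the same shift is
easily found (≈ 90% at F = 0.02, ≈ 84% at F = 0.05 with Δ = 0.5). The test
suite pins both regimes: calibration at F = 0.1, recovery at low F.

## Enrichment

A gene is assigned to a breed if any significant SNP lies within
`[start − flank, end + flank]` on the same chromosome (strand ignored;
flank default 10 kb — an assignment-window choice, exposed and logged, not
an inference about any particular dataset). The enrichment background
defaults to all genes reachable from the post-filter panel under the same
rule: the universe the scan could possibly have hit, not the whole genome.
Term p-values are right-tail hypergeometric,
`p = P[Hypergeom(N, K, n) ≥ k]`, computed by `scipy.stats.hypergeom.sf`,
with `k = 0 ⇒ p = 1` exactly; no multiple-testing correction, and terms are
counted at strict p < 0.05 and p < 0.01. Note the direction of the
background effect: adding term-free genes enlarges N with k, K, n fixed and
weakly *decreases* every p (the same overlap is rarer in a larger universe).

## Network modules

Commercial network tools keep their module-generation algorithms
proprietary; `breedscan` uses a documented greedy stand-in so that module
membership is reproducible even though it is not comparable to any
particular tool's output. Seed on the unassigned focus gene of highest
degree (ties: lexicographic id); repeatedly add the outside neighbour
adjacent to the most module members (ties: higher degree, then id) until the
cap (default 35 genes, a conventional module size) or exhaustion; genes
belong to at most one kept module; modules with fewer than two focus genes
are discarded. Scores are `−log10` of the right-tail hypergeometric p of the
module's focus count against the graph universe, capped at 300 to keep
underflowed p-values finite. Modules rank by descending score (ties: larger
module, then gene ids); breeds rank by their count of modules with score ≥ a
threshold (default 2.0, i.e. p ≤ 0.01 — the counting cut is configurable
because published per-breed network counts rarely state one), with the total
module count reported alongside.

## Pipeline

`run_pipeline` is a pure function of (inputs, config, seed): simulate or
load → impute → MAF filter → density → PCA/PCoA → scan → genes → enrichment
→ modules → `summary.json` (sorted keys; floats rounded at 1e-10 where they
enter the summary). Every threshold and seed is echoed into the summary and
the run log; re-running an identical config reproduces the summary byte for
byte. Stage failures abort with a stage-labelled error.

## Problem sizes in the acceptance script

`scripts/acceptance.py` exercises the pipeline end to end on a 12-breed
panel using the first twelve reference breed sizes (424 animals) at 12,000
SNPs, plus five 6-breed null panels (180 × 5,000, F = 0.1, 500 permutations)
for the type-I fraction — sizes chosen so a complete from-scratch run
finishes in about a minute on one core while keeping unequal breed sizes and
a realistic SNP density per chromosome. All reported numbers are computed at
run time from these simulations; nothing is hard-coded.

## Known limitations

* No LD or haplotype structure anywhere; imputation and power statements
  carry over to real reduced-representation data only approximately.
* The z-score null assumes the genome-wide coefficient distribution is
  dominated by null loci; panels where a large fraction of loci are truly
  breed-specific would deflate significance.
* Module membership depends on the greedy construction order; only scores
  and counts, not memberships, should be compared across implementations.
* PCoA variance fractions are relative to positive eigenvalues only; with
  strongly non-Euclidean distances they overstate the represented variance.
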