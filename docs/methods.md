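# Methods

This note documents the models and procedures `spatprox` implements, the
defaults it ships, and the choices made where the design was genuinely
open. Nothing here states an empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Spatial neighbour graph

Spots become nodes of an undirected graph built either by Delaunay
triangulation (default) or by the symmetrised union of each spot's k
nearest neighbours. Delaunay edges longer than `prune_factor` (default
4.0) times the median edge length are removed; this strips the spurious
hull-spanning adjacencies a triangulation of a tissue outline always
contains, while leaving the regular-lattice interior untouched.
Collinear input makes the triangulation degenerate and is rejected with
a pointer to the kNN alternative.

## Proximity enrichment

For labels L over nodes and each unordered type pair (a, b), the
observed number of a–b edges O is compared against n_perm uniform
permutations of L over the nodes (label multiset preserved):

* expectation Ē = mean permuted count;
* log₂ enrichment = log₂((O+1)/(Ē+1)) — the +1 pseudocount keeps the
  ratio finite for empty pairs and shrinks noisy small counts;
* empirical two-sided p with add-one correction,
  p = min(1, 2·min(p_hi, p_lo)), p_hi = (1 + #{perm ≥ O})/(n_perm+1);
  the test is therefore never anti-conservative but is mildly
  conservative (its null rejection rate at .05 sits near .04 — measured
  by the calibration test, a consequence of doubling plus discreteness);
* Benjamini–Hochberg adjustment across the pairs of one sample;
* PI = log₂ enrichment × −log₁₀(adjusted p), with the adjusted p floored
  at the permutation resolution 1/(n_perm+1) so PI stays finite.

Labels carried by fewer than two nodes are flagged `low_support` but
still scored. With spatially contiguous domains, homotypic pairs (a = a)
are always massively enriched — domains are exactly same-label
adjacency — so analyses of between-type structure, including the
planted-effect recovery checks, rank PI over heterotypic pairs;
homotypic rows are reported but are trivial under this generator.

## Spatially restricted ligand–receptor test

For an ordered (sender, receiver) type pair, the sender interface is the
set of sender-labelled nodes with at least one receiver-labelled
neighbour (receiver interface symmetric). The interface score of a
catalogue pair (L, R) is

S = mean L expression over the sender interface
  + mean R expression over the receiver interface

on library-size log-normalised expression (counts per spot scaled to
10,000, log1p). The null redraws, n_perm times, |interface| spots
uniformly without replacement from all spots of the same type and
recomputes S: type identity is preserved and only the spatial interface
is broken, so cell-type composition effects cancel and the statistic
isolates interface-restricted co-elevation. Within a type, expression is
exchangeable under the generator, which makes this null exact; on real
data residual within-type spatial autocorrelation would make it
approximate. log₂FC = log₂((S+ε)/(S̄_null+ε)) with ε = 0.01 stabilising
near-zero scores; p as above; BH across all testable
(type pair × catalogue pair) rows of the sample; a row is significant
when adjusted p < .05 **and** |log₂FC| > .1. Interfaces smaller than
`min_cells` (default 4) per side are reported untestable.

A resolution constraint worth knowing: the smallest attainable
two-sided p is 2/(n_perm+1), so after BH over m rows the smallest
adjusted p is ≈ 2m/(n_perm+1). Detecting any row at adjusted p < .05
therefore requires n_perm ≳ 40·m; with the default 500 permutations and
a large catalogue the per-sample significance flag saturates and the
cross-sample PI differential is the sensitive readout. The recovery
checks in the acceptance suite use a compact catalogue (4 pairs, 3
types → 24 rows) with n_perm = 2000 for this reason.

## Heterogeneity metrics

From a spot × type prediction-score table: contributing-type count =
#{scores strictly > 0.01} (strict, matching the ">1%" convention);
per-sample high-heterogeneity fraction = share of spots with strictly
more than 5 contributing types; Shannon index H = −Σ p ln p in nats on
the row renormalised to sum one (no base is conventional here; natural
log is used throughout). Group inference is a two-sample t-test on the
per-sample summaries — with 3 samples per arm, per-sample summaries are
the only defensible unit — and a pooled spot-level rank-sum test is
reported as a secondary, explicitly pseudoreplicated view.

## PAGE spot annotation

PAGE scores each spot s against each cell-type signature of size m:
fold changes f_gs = x_gs − mean over spots of gene g (log-normalised),
Z = (S_m − μ_s)·√m / δ_s with S_m the mean f over signature genes and
μ_s, δ_s the mean and sd (ddof 1) of f over all genes in spot s. The
spot-centric standardisation makes Z invariant to per-spot additive
shifts and approximately N(0,1) under random signatures. Upstream
variance stabilisation of the expression matrix is out of scope; the
standard library-size log-normalisation stands in for it, and the
spot-wise standardisation absorbs most of the difference. Spots with
δ_s = 0 get NaN; signatures disjoint from the gene universe are dropped
with a warning.

## Cross-group differential on PI

Per unit (type pair, or sender→receiver : ligand–receptor tuple), PI
values are aligned across samples; units untestable or absent in a
sample are imputed PI = 0 with an imputation count reported, keeping the
3-vs-3 design balanced while letting users filter. The test is Student's
pooled-variance t (df = n₁+n₂−2) oriented recurrent − primary; Welch is
exposed but not default because its estimated df is unstable at n = 3
per arm. Degenerate inputs: both arms constant and equal → p = 1; zero
variance with unequal means → p = 0 with a `degenerate` flag.
Significance is p < .05 per unit (no multiplicity correction at this
level, mirroring the per-unit screening convention); direction is the
sign of the mean difference.

## Marker genes (rank-sum DEG caller)

Per gene, a two-sided Wilcoxon rank-sum on log-normalised expression
using the normal approximation with tie and continuity corrections
(validated against `scipy.stats.mannwhitneyu` in the tests);
log₂FC = log₂((mean expm1 + 1)in / (mean expm1 + 1)out); genes are tested
only when the in-group detected fraction exceeds 0.25 and log₂FC exceeds
0.25 (strict), and BH runs over tested genes only, so the prefilter
shrinks the multiplicity burden exactly as the upstream single-cell
convention does. A gene passes when additionally adjusted p < .05.
The overlap summary counts genes passing in exactly k per-type tables
and genes with opposite log₂FC signs between two tables where both pass.

## Synthetic cohort generator

The generator emulates, at desk scale, a six-section two-arm cohort:

* **Geometry** — hex-like offset grid (odd rows shifted half a spacing;
  row pitch = spacing), Gaussian positional jitter (sd 0.05 spacing).
  Default 45 × 45 = 2,025 spots per sample (real Visium sections run
  3,500–4,600 spots; the grid scales by config).
* **Domains** — one latent field per type from Gaussian-kernel-smoothed
  iid normals (bandwidth `domain_scale`, default 3 spacings), argmax per
  spot: contiguous, irregularly shaped domains with tunable patch size.
  A Potts/MRF sampler would add realism no downstream test consumes.
* **Deconvolution scores** — per spot, Dirichlet with the arm's
  concentration vector, the true type's component multiplied by a
  dominance factor (default 5). Defaults α = 0.40 (primary) and 0.53
  (recurrent) per component with K = 7 types reproduce the observed
  regime of 2–7 contributing types per spot and high-heterogeneity
  fractions near 41% vs 57% between arms — the planted heterogeneity
  effect.
* **Counts** — negative binomial, mean = `nb_mean` (1.0) × log-normal
  gene factor (σ = 0.5), dispersion θ = 2 (variance μ + μ²/θ); per-type
  marker genes (8 per type, fold 3) give PAGE signatures something to
  find. No UMI saturation, bleed-through, or batch structure.
* **Planted proximity** — a fraction s of type-b spots swaps labels with
  spots on the rim of type-a domains. The swap both embeds b spots in
  the a-boundary (several a-neighbours each) and scatters the displaced
  a labels into b territory, so a–b adjacency rises steeply and
  monotonically in s while the label multiset is conserved. A milder
  scheme that only parked b spots against the outside of a domains
  merely restored a–b adjacency to its random expectation and was
  replaced by the rim swap.
* **Planted communication** — ligand mean × e in sender-interface spots,
  receptor mean × e in receiver-interface spots (interfaces from the
  Delaunay graph of the true labels); e = 1 is a bitwise no-op.
* **Determinism** — per-sample seed = config seed + sample index, with
  fixed per-stage substreams; equal configs give byte-identical bundles.

The truth registry (labels, planted effects, realised interface spot
lists) is written to a separate file no analysis stage reads.

What passing tests on this generator do **not** show: robustness to
segmentation noise in real deconvolution scores, within-type expression
autocorrelation, irregular tissue boundaries, or batch effects — the
generator is iid within type by design so that the permutation nulls are
exact and calibration is checkable.

## Problem sizes used in the checks

Calibration and recovery properties are measured at: 200 random-label
samples of 1,024 spots (proximity null); exhaustive enumeration on a
6-node graph vs 20,000 permutations; 50 planted-proximity samples of 676
spots at n_perm = 1,000; 150 six-sample cohorts of 576 spots at
n_perm = 500 (differential power and size); 100 + 50 samples of 676
spots for the L–R null and planted recovery (n_perm = 500 / 2,000);
3,000-spot Dirichlet draws against the closed-form expected entropy
ψ(α₀+1) − Σ(αᵢ/α₀)ψ(αᵢ+1); and a 2,000-gene × 200-spot negative-binomial
matrix for the DEG caller. The full default pipeline (6 × 2,025 spots,
n_perm = 500) runs end to end in a few seconds per stage on one CPU.

## Known limitations

* Permutation resolution bounds per-sample L–R significance (see above).
* PI imputation at 0 biases differentials toward the null for units
  frequently untestable; the imputation count column is the filter.
* The homotypic-pair enrichment is uninformative under contiguous
  domains and should be ignored in between-type analyses.
* The per-sample t-test at n = 3 per arm has limited power and assumes
  approximate normality of per-sample summaries; the rank-sum
  alternative is reported at spot level only, with the pseudoreplication
  caveat attached.
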