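# Methods

This note records the statistical models implemented in `trisodeconv`, the
assumptions behind the synthetic-data generator, the defaults that matter and
why they were chosen, and the places where the design was genuinely open.

## Study design emulated

Six isogenic iPSC subclone lines (3 disomic, 3 trisomic for chromosome 21)
are differentiated to forebrain organoids in four independent batches. In
each batch every line contributes four pools of 12 organoids; two pools per
line per batch are bulk RNA-sequenced, for 48 samples (8 per line) and 576
organoids per trisomy state overall. Media from the sequenced pools is
assayed for secreted Aβ40 by ELISA, and all organoids are photographed for
size. `design.make_design` enumerates this roster deterministically; all
counts are configurable.

## Synthetic data generator

The generator is first-class, tested code: its outputs define the conditions
under which every downstream claim is demonstrated.

**Gene annotation.** 2,000 genes by default (a desk-scale stand-in for the
~20k of a real transcriptome), 1% on chr21 — matching chr21's ~1% share of
the genome — with log-normal exonic lengths (median ~1.5 kb) and ~2% flagged
ribosomal/mitochondrial. Scale is configurable; nothing in the pipeline
depends on the desk scale except runtime.

**Reference profiles.** Two cluster-level expression matrices emulate two
independent single-cell datasets covering 24 clusters mapped onto 13
cell-types (each type gets one cluster; the 11 extra clusters cycle over
types, so several types are multi-cluster). Each cluster owns a disjoint
marker set (40 per cluster by default) whose within-cluster expression
exceeds the recorded fold-change with margin. The two datasets differ by
per-gene log-normal capture noise (sd 0.3), deliberately per-gene rather
than per-gene-per-cluster so both datasets carry identical marker structure —
this makes basis averaging meaningful and the marker-enrichment invariant
exact. Marker rows that land on chr21 or ribo/mito genes are kept: they
exercise the exclusion rules downstream.

**Bulk counts.** Expected counts are library-scaled mixtures
`μ_gs ∝ (Σ_k p_sk T_gk) · dosage_g(s) · length_g · ε_g(line) · ε_g(batch)`,
with negative-binomial sampling (dispersion 0.1; dispersion 0 gives the
deterministic rounded limit used by exactness tests). `dosage_g` is 1.5 for
chr21 genes in trisomic samples (one extra copy, no compensation) and 1
otherwise. The gene-length factor makes bulk counts length-biased, which is
why the deconvolution front end FPKM-normalizes bulk data while the
single-cell reference is CPM-normalized (length-free); the simulator and the
pipeline are consistent by construction. Proportions follow a line → batch →
pool hierarchy: per-line Dirichlet propensities around a base composition
(concentration 100), logistic-normal perturbations per line×batch (sd 0.1)
and per pool (sd 0.05). Dirichlet at the top and logistic-normal below keep
every level on the simplex. The base composition is the measured cell-type
composition of this organoid system (interneurons and cortical neurons
dominant, substantial glial progenitors and astrocytes, a small mesodermal
off-target component modeled as one cell-type with its own propensity).
Per-gene line/batch noise (log-sd 0.05) supplies biological variability
between lines beyond composition. The gap is explicit: published organoid
panels do not quantify their line/batch variance components, so these are
order-of-magnitude choices exposed in config, chosen once so that
(i) the collapsed 3v3 analysis is calibrated, and (ii) line-to-line
differences are visible, as they are in real organoid panels.

**Sizes.** Log-normal areas with line-level medians drawn log-uniform from
2–4 mm², line×batch effects (log-sd 0.15) and within-pool noise (log-sd
0.2). The trisomy size effect defaults to 1.0 — the null the emulated study
could not reject.

**ELISA.** True Aβ40 concentration per pool is
`base · fold^trisomic · ε(line) · ε(line×batch) · ε(pool)` with base 150
pg/ml, trisomy fold 1.73, and log-sd 0.30/0.20/0.20 for the three
multiplicative effects. ODs come from a 4PL response (slope −1.2, lower
0.05, upper 3.0, midpoint 200 pg/ml) plus Gaussian read noise (sd 0.02);
the calibration series is seven two-fold dilutions from 500 pg/ml. RNA
concentrations are log-normal and by default independent of Aβ (the study
found the RNA coefficient negligible); a nonzero `rna_effect` couples them
for sensitivity experiments. Raising `base_conc` pushes trisomic pools past
the calibration range, reproducing the saturation problem the clamped curve
exists to handle.

**Seeding.** One global integer seed; every entity (line, batch, pool,
organoid, plate) gets an independent stream keyed by a hash of its label
path, so subsetting a design never changes the draws of the entities that
remain. All generators are bit-reproducible.

### What the generator does not emulate

No read-level sequencing artifacts (GC bias, duplicates, mapping error), no
gene–gene correlation beyond cell-type composition, no batch-specific
library-prep composition effects, no spatial organoid structure, no
epigenetic drift of subclones over passages. Passing tests therefore show
that the pipeline's statistics behave as designed under the stated
variance structure, not that real organoid data meet that structure.

## Deconvolution

Marker selection per cell-type: rank the cell-type's marker rows by
(p ascending, fold-change descending, gene id) — the gene-id tie-break makes
selection fully deterministic; drop ribo/mito and chr21 genes *before*
counting; take the top 30 (single-cluster types) or top 5 per constituent
cluster then fill to 30 from the merged ranked list (multi-cluster types). A
cell-type with no eligible marker is a hard error naming the type. Each
dataset's signature column is the type's mean cluster expression on a CPM
scale divided by 100; the division is a pure rescaling retained because
poorly scaled normal equations can stall NNLS-based solvers, and normalized
proportions are invariant to it in exact arithmetic (`scale_cpm_by_100`
toggles it). The final basis averages the two dataset signatures on the
union of selected markers.

The solver initializes at the NNLS solution, then iterates weighted NNLS
with weights `1/max(ε, fitted)²` (ε = 1e-12 guards zero fitted signal),
capped at `d · min(positive weights)`. The dampening constant `d` is chosen
once per sample from the grid 2⁰..2¹⁴ by minimizing the variance of the
normalized solution across 25 gene-bootstrap resamples (fixed internal seed;
ties to the smaller constant), then held fixed while iterating to
`max|Δp| < 1e-7` (cap 100 iterations; non-convergence returns the last
iterate flagged). Gene order is canonicalized internally so estimates cannot
depend on input row order. Whether the original dampened-WLS method caps
weights at a multiple of the minimum weight or at a percentile is not
specified by its description; the multiple-of-minimum rule is implemented
and documented as a solver option of this package. Basis genes missing from
a sample are treated as zero counts with a logged warning; per-sample solver
failures are collected without aborting the batch.

## Differential expression

Pipeline: collapse replicate pools to one unit per line (summing counts, so
library sizes add) → filter genes below CPM 0.25 in fewer than ⌈N/2⌉ samples
→ TMM factors → per-gene NB GLM → stratified BH. Collapsing to lines is the
pseudoreplication control: pools and batches of one line are not independent
evidence about trisomy. The uncollapsed mode (`collapse=None`) exists to
demonstrate the artifact and is labeled accordingly.

TMM follows the original definition exactly (reference = sample whose
75th-percentile CPM is closest to the mean; log-ratios doubly trimmed 30%/5%;
inverse-binomial-variance weights; factors rescaled to geometric mean 1) and
reproduces edgeR's `calcNormFactors` to 1e-6 on test fixtures.

The per-gene test is a quasi-likelihood F test on a NB log-linear model with
TMM-corrected library-size offsets, fitted by vectorized IRLS across all
genes at once. Dispersions: Poisson fit → per-gene Pearson moment estimate
(bisection) → log-scale shrinkage (weight 0.7) toward a lowess trend on log
mean CPM. Two numerical guards matter at 4 residual df: raw log-dispersions
are clamped to [trend−2, trend+4] before shrinkage (the moment estimator
collapses to ~0 by chance for a few genes, and an unclamped average would
hand them wildly inflated statistics), and the empirical-Bayes prior df for
the QL denominator (scaled-F moment estimator) is capped at 10 so a gene's
own deviance always keeps weight in its denominator. Both guards were
validated on null simulations: without them the null shows sporadic extreme
p-values; with them the type-I rate sits at the nominal 5% (±2 points across
seeds) and null FDR discoveries are rare. Log2 fold-changes are reported
from a fit with 2 library-size-scaled pseudo-counts added (prior count),
stabilizing low-count genes. This is a documented reimplementation of the
NB-QL approach, not a bit-level replication of any package's internals;
correctness is claimed through calibration properties, which is what the
downstream conclusions rest on. Tests are two-sided throughout; no sign
constraint is imposed on chr21 genes.

Stratified FDR: BH genome-wide, BH within chr21, BH within the complement;
each stratum's values depend only on its own p-values. Reported p-value
cut-offs follow the volcano-plot convention: the largest p with FDR < 0.1
in that stratum, else the Bonferroni cut-off 0.1/N. The optional cell-type
covariate is the type with the largest interquartile range of estimated
proportions across collapsed units (cortical-type neurons in typical runs) —
one covariate only, to preserve residual df in a 6-unit design.

"At least half the samples" in the expression filter uses ⌈N/2⌉ and is
applied to the matrix entering normalization — after collapsing when the
collapsed pipeline runs.

## Group tests

Welch's t with Satterthwaite df for all two-group comparisons; it tolerates
the variance collapse of near-zero proportions. Degenerate inputs follow a
stated convention: both groups zero-variance with equal means → p = 1; with
unequal means → p = 0. Cell-type proportion tests use line-level estimates
(deconvolution of the summed counts), 13 tests, Bonferroni-adjusted
(`min(1, 13p)`), with the difference reported as disomic − trisomic. Size
analysis reduces organoids → median per line×batch (midpoint convention for
even counts) → mean per line → 3v3 Welch, so neither organoids nor batches
masquerade as independent replicates. "Size" is treated as a generic
positive measure; the pipeline is agnostic between area- and
diameter-derived values.

## Aβ40 quantification

The LL.4 curve `OD(x) = c + (d−c)/(1+exp(b(ln x − ln e)))` is least-squares
fitted (Levenberg–Marquardt, data-driven starts) to the calibration series,
with `d` fixed to the clamp value (default 3.0) when clamping is enabled.
Clamping exists because above-calibration ODs have extrapolated
concentrations that depend strongly on `d`, which the calibration points
cannot identify; fixing it modestly above the observed ODs gives
conservative, stable extrapolations, and results are insensitive to the
exact clamp choice (the tests verify the insensitivity pattern). Inversion
is the closed form `x = e·((d−c)/(OD−c) − 1)^{1/b}`; ODs at/below `c` map to
0 and at/above `d` are censored (unquantifiable); ODs above the calibration
range but below `d` are conservatively extrapolated by default, or dropped
in strict mode. Inverted concentrations are multiplied by the media dilution
factor (default 2, i.e., 1:2 dilution).

The trisomy effect: regress log2 concentration on centred log2 RNA with
trisomy and batch fixed effects (trisomy is included so its signal cannot be
absorbed by chance RNA–trisomy correlation); subtract the fitted RNA term;
average normalized log2 values per line; Welch-compare 3v3; back-transform
the difference and its 95% interval to a fold. This per-line-averaging
estimator is the primary one; the full mixed-effects treatment (random line
and line×batch effects with Satterthwaite inference) is a possible extension
but the per-line average is its fixed-effect collapse and gives similar
answers in this design, at a fraction of the machinery. CI coverage of the
fold estimator is ~95% across repeated simulations at the generator
defaults, and the estimator is exactly equivariant under scaling of one
group's concentrations.

## Problem sizes and runtime

Defaults everywhere are desk-scale — 2,000 genes, 48 samples, 100-ish
simulation replicates where distributions are asserted — chosen so the whole
test suite and the acceptance script each run in well under a minute of
compute per stage on one CPU while leaving every distributional check
adequately powered. All sizes scale up through configuration.

## Known limitations

- Calibration claims are under the generator's variance structure; real
  organoid panels can be wilder (outlier lines, batch×line interactions in
  composition, ambient RNA).
- The QL implementation's p-values are not expected to match any specific
  external package per-gene; only calibration and power patterns are
  contractually tested.
- With 3 lines per group, the Aβ fold CI is wide by design truth — single
  simulated experiments routinely miss 1.73 by 30–50% while the estimator
  stays centred; this mirrors the power ceiling of a 3v3 line comparison.
- Deconvolution accuracy depends on the reference's fidelity; the generator
  shares its cell-type profiles between reference and bulk (up to dataset
  noise), which is the favorable case.
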