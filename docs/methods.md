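# Methods

This note documents the models, defaults and design choices behind
`citequant`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Bead calibration and flow quantification

QuantiBRITE-style beads carry four populations with known PE molecules per
bead. The standard curve is an ordinary least-squares fit of
log₁₀(PE/bead) on log₁₀(gMFI); the regression direction is fixed so that
prediction maps intensity → molecule count (for r² ≈ 1 the direction is
immaterial, but reproducibility requires fixing one). Per-cell ABC values
are left unrounded; rounding is a reporting concern.

Percent positivity uses an FMO (fluorescence-minus-one) threshold. When
only raw FMO events are supplied, the threshold is the 99.9th percentile
of the FMO intensity distribution — standard manual-gating practice.
Summaries are produced both conditional on positivity (mean/geometric-mean
ABC among positive cells) and unconditional, because assays differ in
whether they restrict to the positive population.

## ADT normalization

* **QC filter.** Cells with < 1,000 total RNA counts, < 200 detected
  features, or > 15% mitochondrial reads are removed. The rules are strict
  removal conditions, so cells exactly at a threshold are kept. The filter
  is idempotent and skipped (with a logged warning) when no RNA QC is
  available.
* **CLR** is the centered log-ratio within each cell across antibodies
  (ln(x+1), centered); used for the CD34/CD38 gate thresholds, which are
  defined on the CLR scale.
* **DSB-style correction** has two steps: (1) per antibody, z-score
  ln(x+1) against a background mean/sd; (2) per cell, subtract the mean of
  the isotype-control z-scores, an estimate of the cell's technical factor
  (droplet-level capture efficiency). The background should come from
  empty droplets; when none are available an in-sample proxy (lowest 10%
  of cells per antibody) is used and flagged, with the caveat that this
  proxy absorbs part of the biological level and therefore weakens
  cross-sample comparability. The full published DSB method additionally
  fits a per-cell mixture model; that refinement is deliberately out of
  scope.
* **Cell-profile quantile normalization.** Each cell's antibody profile is
  mapped onto the mean of sorted profiles (the reference), preserving
  within-cell ranks; ties receive the average of the tied reference
  values; a single-antibody matrix is returned unchanged. Whether this
  normalization should run across cells or across antibodies is ambiguous
  in general; cells-as-profiles was chosen because the downstream quantile
  map needs all cells of a sample on one common scale. Both ln-transforms
  use natural log with a +1 pseudocount.

## The ADT → ABC bridge

Flow and CITE-seq assay *different aliquots* of the same sample, so
distributions — not cells — are paired. For each (sample, bridge antigen),
empirical quantiles at levels 0.05, 0.10, …, 0.95 (19 points; the extreme
order statistics are excluded as noisy, and the grid is configurable) are
computed for the normalized ADT distribution and the log₁₀ ABC
distribution, with linear interpolation between order statistics (fixed so
maps are reproducible). Rank alignment is assumed: the lowest ADT quantile
corresponds to the lowest ABC quantile.

The training table has one row per (sample, antigen, level); features are
the ADT quantile value plus the sample's 13 antibody-library QC metrics
(total reads, reads/cell, barcode/UMI quality rates, saturation, etc.),
which absorb sample-specific capture artifacts. The grid level itself is
*not* a feature: per-cell prediction could not supply it. The regressor is
a random forest with 500 trees, ⌊p/3⌋ candidate features per split and
unlimited depth (classic randomForest regression defaults); CV error is
estimated by 10-fold × 10-repeat resampling before the final fit. At
prediction time the cell's normalized ADT value substitutes for the
quantile-value feature; predictions are clipped to the training target
range ± 0.5 log₁₀ before unlogging, preventing blow-ups outside the
calibrated range (clipping events are logged). Tree models are not
guaranteed monotone in the ADT value at fixed QC; monotonicity violations
are a diagnostic, not an error.

Leave-one-antigen-out validation retrains without each bridge antigen in
turn and compares sample-mean predicted ABC against the flow measurement;
the excluded antigen's rows are provably absent from its training table.
Antibodies known to be undersaturated at the staining concentration
(CD13, CD45, CD47, CD99, HLA-DR) carry a caution flag through to ranking
output; their estimates are reported, not suppressed. Within the
leave-one-antigen-out loop the inner CV is skipped (the held-out antigen
is the validation), keeping the procedure inexpensive.

## Target prioritization

Positivity on estimated counts uses a strict `>` at the threshold
(default 1,000 antigens/cell); co-expression is the fraction of cells with
both antigens strictly above threshold, hence bounded by each antigen's
own positivity. The ranking criterion (≥ 80% positivity AND ≥ 1,000
median count among positives) is evaluated per sample-timepoint-population
triple and aggregated as the fraction of triples passing; antigens are
ordered by pooled median count, ties broken alphabetically. A free-text
annotation column is reserved for external information such as
healthy-tissue expression screens, which this package does not perform.

The stemness (LSC17-style) module score bins genes into 24 equal-frequency
bins by pooled average expression (average ranks put tied genes in one
bin) and, for each gene-set gene, samples up to 100 control genes from the
same bin, excluding gene-set members when alternatives exist; the score is
mean(gene set) − mean(controls). The LSC-enriched gate is
score > 0 ∧ CD34 CLR > 1 ∧ CD38 CLR < 1, all strict.

## Composition and survival

Shannon diversity uses the natural log (the 9-state maximum is
ln 9 ≈ 2.197). Aitchison distance is the Euclidean distance between
CLR-transformed frequency vectors; a pseudocount of 10 is added in count
space to zero-count states only (adding it to all states is available by
flag), after which frequencies are recomputed. Two resampling procedures
probe robustness: the fraction curve subsamples 5–100% of cells *without*
replacement (a subsampling check), while the fixed-size procedure draws
344 cells *with* replacement (a bootstrap equalizing cell numbers across
samples); both are seeded.

Survival uses a mean split of the Aitchison distance (median available by
flag) compared by the log-rank test with Kaplan–Meier curves, and Cox
proportional-hazards regression of the hazard on the continuous distance
with patient sex (0/1 coded) as covariate, Wald p-values, and the Efron
tie approximation (the lifelines default). In the orchestrated pipeline a
failed Cox fit on a degenerate cohort is recorded in the output table
rather than aborting the run.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised; its defaults are fixed, not tuned per experiment.

* Per sample and antigen, log₁₀ ABC ~ Normal(μ, 0.25) with μ uniform on
  [log₁₀ 200, log₁₀ 10,000] — the range spanned by established myeloid
  targets on blasts.
* ADT counts are negative-binomial (dispersion size 10 — a count-noise
  choice, since no specific noise law is dictated by the assay) with mean
  = true ABC × sample capture efficiency e ∈ [0.2, 1] × per-cell
  technical factor t ~ lognormal(0, 0.3) shared across the cell's
  antibodies. Isotype controls have a constant background mean (20)
  scaled by e·t.
* Each sample carries an empty-droplet (ambient) matrix whose antibody
  means are proportional to e but independent of cell expression. This is
  what real ambient background looks like (it tracks antibody
  concentration, not cell biology) and is what makes DSB z-scores
  comparable across samples; it is generated precisely so the background
  correction has a real target to remove.
* The 13 QC metrics are deterministic monotone functions of e plus
  Gaussian noise (sd 0.05 on the relative scale), making them informative
  artifact covariates (|Spearman| with e well above 0.5 across samples).
* Flow cytometry is a separate aliquot: fresh cells from the same ABC law,
  pushed through a batch-specific affine instrument response on the
  log-log scale with multiplicative lognormal noise (sd 0.10); the bead
  gMFIs are generated from the same response, so the fitted curve inverts
  the instrument exactly. Flow and CITE-seq are conditionally independent
  given the ABC law, matching the separate-aliquot design.
* Lineage compositions: diagnosis ~ Dirichlet(2·1₉) over the nine blast
  states; relapse is the diagnosis composition perturbed in CLR space by a
  centered vector of patient-specific norm drawn from [0, 3], so the true
  Aitchison distance equals that norm exactly. Lineage labels are drawn
  independently of antigen levels (composition and antigen analyses are
  decoupled by design).
* Survival is exponential with log-hazard = log(ln 2 / 24 months) +
  β × true distance (default β = −0.6, protective), with administrative
  censoring at 60 months — simple and with a controllable event fraction.
* The minimal expression table for module-score gating is lognormal gene
  means with lognormal cell noise (200 genes); it makes no attempt to
  model transcriptome structure, doublets or ambient RNA.

What passing tests on this generator show — and what they do not: the
pipeline recovers known antigen numbers, artifact structure, compositional
shifts and hazard direction *under this generative model*. Real data add
antibody-specific binding kinetics, cell-type-dependent backgrounds,
gating impurity between the flow and CITE-seq blast populations, and
non-exponential hazards, none of which are emulated.

## Problem sizes and numerical choices

The acceptance script exercises: leave-one-antigen-out on 20 samples ×
2,000 cells × 12 antigens (4 bridge antigens); the bootstrap plateau on
5,000 cells per timepoint; Cox direction/coverage on 50 replicate cohorts
of 200 patients; and the end-to-end run on 4 patients × 500 cells × 8
antigens — sizes chosen as the smallest at which the statistical
properties of interest are stably measurable on a single CPU. A single
global seed deterministically derives per-stage seeds (SHA-256 of stage
name + seed, reduced below 2³¹), so stages re-run in isolation reproduce
the pipeline exactly; manifests record SHA-256 hashes of every output.

Degenerate-input conventions: background sds ≤ 1e-6 are replaced by 1
(constant background columns then z-score to ≈ 0); constant regression
targets train with a warning and predict the constant; empty gates,
all-zero compositions, constant covariates and vocabulary mismatches
raise informative errors.

## Known limitations

* The bridge assumes both assays gate the same blast population; gate
  labels are inputs, and no automated CD45-vs-SSC gating or compensation
  is performed.
* Estimates for antigens whose true abundance falls far outside the
  bridge antigens' range extrapolate and carry the clipping bound.
* No per-cell uncertainty intervals are produced, and no alternative
  regressors beyond the tree ensemble are offered (a linear baseline
  exists only as a test oracle).
* Lineage-state *assignment* (label transfer/classification) is out of
  scope; labels are inputs.
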