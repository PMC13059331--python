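# citequant

Absolute surface-antigen quantification for AML CITE-seq data, by bridging
relative antibody-derived tag (ADT) counts to bead-calibrated quantitative
flow cytometry — plus the downstream analyses that the resulting per-cell
antigen counts enable: immunotherapy target ranking, antigen co-expression,
blast lineage-state composition metrics, and survival association.

## The problem

Immunotherapies (ADCs, CAR-T cells) need their target antigen present on
most leukemic blasts *and* at sufficient density — roughly 1,000–10,000
molecules per cell for ADCs, fewer for CARs. Quantitative flow cytometry
with PE-calibration beads (e.g. BD QuantiBRITE) measures absolute
antibodies bound per cell (ABC) precisely, but only one antigen per panel
and with no per-cell multiplexing. CITE-seq measures ~100 antigens per cell
but only on a relative scale. `citequant` combines the two: a handful of
bridge antigens (CD33, CLL-1, CD123, ADGRE2) measured by both assays
calibrate a model that converts normalized ADT values into absolute
antigen counts for the whole panel in every blast.

## The method

For each sample and bridge antigen:

1. **Bead calibration** — OLS fit of log₁₀(PE/bead) on log₁₀(gMFI) across
   the bead populations gives a standard curve; blast fluorescence
   intensities map through it to a per-cell ABC distribution.
2. **ADT normalization** — cells failing RNA QC (<1,000 counts, <200
   features, >15% mitochondrial) are removed; ADT counts are
   background-corrected DSB-style (per-antibody z-score of ln counts
   against an empty-droplet background, then removal of a per-cell
   technical factor estimated from 3 isotype controls) and each cell
   profile is quantile-normalized to a common reference.
3. **Quantile mapping** — because flow and CITE-seq assay different
   aliquots, distributions are paired instead of cells: empirical 5%
   quantiles (0.05…0.95) of the normalized ADT distribution are matched to
   the same quantiles of the log₁₀ ABC distribution.
4. **Artifact-aware regression** — a random forest (500 trees, ⌊p/3⌋
   features/split, 10-fold × 10-repeat CV) predicts log₁₀ ABC quantiles
   from ADT quantile values plus 13 antibody-library QC metrics, then is
   applied per cell and unlogged: `ABC = 10^f(adt, qc)`.
5. **Validation** — leave-one-antigen-out: each bridge antigen is excluded
   from training, predicted per cell, and its sample-mean compared with
   the flow measurement (Spearman ρ and log₁₀ bias).

Downstream, per-cell counts feed positivity/co-expression summaries at a
count threshold (default ≥80% positivity and ≥1,000 antigens/cell for
target ranking), an LSC-enriched gate (stemness module score > 0, CD34
CLR > 1, CD38 CLR < 1), Shannon diversity −Σpᵢ ln pᵢ and Aitchison distance
(Euclidean distance of CLR-transformed lineage-state frequencies,
pseudocount 10 for empty states) with subsampling/bootstrap robustness
curves, and mean-split log-rank / Cox PH survival models of the
diagnosis→relapse compositional shift.

A fully specified synthetic cohort generator (`citequant.synthetic`)
produces paired flow + CITE-seq readouts with known ground-truth antigen
counts, capture artifacts correlated with QC metrics, lineage compositions
and hazard structure, so the entire pipeline is testable end to end.

## Worked example

Run the full pipeline on a synthetic cohort of 10 patients (20 paired
samples), 500 cells per sample, 8 antigens:

```bash
citequant run-all --outdir demo --seed 7
```

or equivalently in Python:

```python
from citequant import SyntheticConfig
from citequant.pipeline import PipelineConfig, run_pipeline
from citequant.synthetic import DEFAULT_PANEL

cfg = PipelineConfig(
    outdir="demo", seed=7,
    synthetic=SyntheticConfig(
        n_patients=10, n_cells_per_sample=500,
        antigen_panel=DEFAULT_PANEL[:8],
    ),
)
run_pipeline(cfg)
```

Selected outputs (`demo/`):

`ranking_blast.csv` — antigens ranked by pooled median estimated count,
with the fraction of samples meeting the ≥80%-positivity / ≥1,000-count
criterion:

```
antigen  n_samples  criterion_fraction  median_count  median_pct_positive
  CD244         20                0.65       3164.41                 0.94
  CLL-1         20                0.35       1888.96                 0.68
   CD33         20                0.45       1855.46                 0.75
  ITGA4         20                0.40       1813.37                 0.64
```

CD244's generated expression happened to be high in most samples of this
cohort, so it passes the dual criterion in 65% of samples and ranks first.

`co_expression.csv` — fraction of blasts with both CD33 and CLL-1 above
1,000 estimated antigens, per sample (e.g. 0.572 for P01 at relapse).

`composition_metrics.csv` — per-patient Shannon diversity at each
timepoint and the diagnosis→relapse Aitchison distance:

```
patient_id  shannon_diagnosis  shannon_relapse  aitchison_distance
       P01              2.057            1.869               1.699
       P02              1.919            1.878               1.500
```

(The maximum Shannon value for 9 states is ln 9 ≈ 2.20.)

`survival_summary.csv` — mean-split log-rank and the Cox hazard ratio per
unit Aitchison distance with sex as covariate. At this cohort size the
estimate is direction-consistent with the generator's protective hazard
coefficient but imprecise, as expected for n = 10:

```
          analysis  statistic  p_value  ci_lower  ci_upper
mean_split_logrank     0.3837   0.5356       NaN       NaN
  cox_distance_sex     0.6445   0.5751    0.1388    2.9939
```

Every run writes a `manifest.json` recording stage seeds and SHA-256
hashes of all outputs; identical configurations reproduce identical
hashes.

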