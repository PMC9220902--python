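# Methods

`pdmkit` implements the computational analysis of a patient-derived
microtumor (PDM) screening platform: protein-profiling of untreated models,
functional grading of drug cytotoxicity, derivation of responder protein
signatures, drug mode-of-action time courses, and quantification of
TIL-mediated killing in co-culture. This note records the models,
parameter choices and numerical conventions behind each stage, and what
the synthetic cohort generator does and does not emulate.

## RPPA processing

The abundance readout is the protein-normalized, background-corrected mean
fluorescence intensity (NFI), a non-negative linear ratio per protein and
sample, acquired as the mean of two technical replicates.

* **Blank filter.** Proteins whose *median* NFI across all samples is at or
  below the blank assay level (0.02 NFI, configurable) are excluded
  wholesale. The granularity is per protein rather than per value because
  downstream statistics require complete rows; retained values pass through
  unchanged.
* **Centering.** Each protein row is median-centered and log2-transformed.
  We center by subtracting the row median *on the log2 scale* (equivalently
  dividing by the geometric row median). For an odd number of samples this
  is identical to dividing by the linear-scale median before log2; for an
  even number only the log-scale form leaves every row with median exactly
  0, which is the invariant the rest of the pipeline relies on (tolerance
  1e-9).
* **Clustering.** Samples are clustered agglomeratively on the centered
  matrix with Pearson-correlation distance (1 − r) and average linkage —
  common defaults for protein heat-map software — both exposed as options.
  SciPy's linkage implementation provides deterministic tie handling.
  Average linkage is monotone, so merge heights are non-decreasing.
* **Pathway panels.** Proteins belong to exactly one of eight panels (cell
  cycle, DNA damage response, apoptosis, chromatin regulation, MAPK/RTK,
  PI3K/AKT–mTOR–Wnt–NFκB, tumor/stem-cell markers, other). Panel summaries
  report the median log2 NFI per sample plus the full member value sets,
  which feed the rank tests below.

## Cytotoxicity grading

Plate assays read cell death as RFU per (model, drug, dose, time) stratum
with 3–8 replicates and matched DMSO vehicle strata per model and time.

* **Outliers.** Replicates are screened with the Iglewicz–Hoaglin modified
  Z-score, M_i = 0.6745 (x_i − median)/MAD, flagged at |M_i| ≥ 3.5 in a
  single pass (the test scores all points at once; it is not iterated).
  When MAD = 0 the standard fallback M_i = (x_i − median)/(1.253314·meanAD)
  is used; if the mean absolute deviation is also zero the vector is
  constant and nothing is flagged. The test is undefined for fewer than
  three values.
* **Fold change.** FC per stratum is the arithmetic mean of surviving
  treated RFU over the surviving vehicle mean, separately per time point.
  Replicate-level FCs (each surviving replicate over the vehicle stratum
  mean) are retained for testing.
* **Testing.** A two-way dose × time ANOVA on treated replicate FCs serves
  as the omnibus. Each dose–time cell is then compared against the
  matched-time vehicle with a Dunnett-style t statistic whose error term is
  the residual mean square pooled over *all* cells (treated and vehicle);
  Holm adjusts across the nine cells of a model × drug family. We pool the
  error deliberately: with outlier screening applied to strata of only
  3–8 replicates, per-cell variance estimates are truncated and a per-cell
  two-sample t becomes anticonservative (measured ≈9.5% family-wise false
  responder calls at a nominal 5% over 200 null cohorts), whereas the
  pooled-error construction stays at the nominal rate (≈5–7% measured) and
  keeps its power when an artifact corrupts a single stratum.
* **Grade.** The minimum Holm-adjusted p across doses at the final (72 h)
  time point maps onto the ordinal grade: 0 (p > 0.05), 1 (p < 0.05),
  2 (p < 0.01), 3 (p < 0.001). A model is a responder iff its grade is ≥ 1
  — models responding only at higher dose still count as responders, which
  is why doses are combined by minimum rather than requiring the lowest
  dose to respond.

## Responder signatures

Models are split into responders and non-responders for the drug of
interest by the grade ≥ 1 rule; both groups must be non-empty.

* **20% filter.** Per protein, group means are computed on the log2 scale
  and the difference back-transformed, so the filter compares a ratio of
  geometric means against 1.2 (inclusive). A percentage criterion is
  well-defined on this linear ratio; it would not be on centered log2
  values near zero.
* **Pathway tests.** Per panel, the centered log2 values of signature
  proteins are pooled across proteins and samples and compared between
  groups with a two-sided Mann–Whitney U test (exact where sample sizes
  permit and ties are absent). Two caveats are inherent and documented
  rather than hidden: pooling protein × sample values pseudo-replicates
  samples, and conditioning on the 20% filter selects for large group
  differences. P-values downstream of the filter are therefore
  *descriptive*; calibration (≤7% rejections at nominal 5% over 200 null
  cohorts) holds for the unselected test, which is what the test suite
  verifies.
* **Grade correlation.** Per-protein Spearman rank correlation (average
  ranks) between abundance and the ordinal grade across models. With n ≤ 8
  models the two-sided p-value is an exact permutation enumeration (n! ≤
  40,320); beyond that the t-approximation is used. Zero variance in either
  vector yields an explicitly flagged undefined correlation, never a silent
  zero.

## Drug mode-of-action time course

Treated-to-vehicle NFI ratios TR = log2(treated/vehicle) are computed per
protein at 0.5, 4 and 72 h from matched matrices (technical replicates are
geometric-mean averaged first). The treatment-specific change threshold
(50% for carboplatin) retains a protein, with its whole trajectory, iff its
linear ratio differs from 1 by at least the threshold fraction in either
direction at one or more time points — |log2 TR| ≥ log2(1.5) ≈ 0.585,
boundary inclusive. Retained proteins are tested per panel with two-sided
Wilcoxon signed-rank tests: paired by protein between every pair of time
points, and one-sample against zero (vs vehicle) per time point. All-zero
difference vectors are degenerate and reported as p = 1.

## Co-culture killing

Each imaged PDM contributes three mask fluorescence sums: total dead,
dead TIL, and viable PDM. The killing readout is

    R = (FI_total_dead − FI_dead_TIL) / FI_viable_PDM,

stored as a fraction and rendered as a percentage. R is scale-invariant
and requires dead-TIL ≤ total-dead and viable > 0 (violations are load
errors, not silent clamps). Arms (untreated, isotype, checkpoint
inhibitors) are summarized by mean/SD over their nine imaged PDM (3 per
well × triplicate wells) and compared pairwise by exact-where-feasible
two-sided Mann–Whitney U; each imaged PDM is one observation and well
effects are not modeled (PDM are pooled across triplicate wells).
Viability QC reports the dead fraction dead/(dead+viable) of 3D volumes
and flags preparations above 7% dead cell mass.

## Synthetic cohort generator

All acceptance and power tests run on generated cohorts with known ground
truth; no patient data ships with the package.

* **Cohort shape.** Defaults mirror a small ovarian-cancer PDM study:
  7 models (4 planted responders), 116 proteins over the eight panels
  (20/15/15/12/18/20/10/6), plates at 3 doses × 24/48/72 h with
  6 replicates, TR pairs at 0.5/4/72 h, and 9 imaged PDM per killing arm.
* **Noise model.** Log-normal on every linear fluorescence scale (normal on
  log2), matching the ratio-based analysis scale. RPPA and TR samples are
  the mean of two technical-replicate draws of `noise_sd_log2` (default
  0.25 per draw), the standard duplicate-spot acquisition for NFI.
* **Planted effects.** Responder models shift whole panels by
  `effect_log2` (default: cell cycle +0.8, echoing the elevated cell-cycle
  activity of platinum-sensitive models); plate effects ramp
  multiplicatively with dose and time rank so the top dose at 72 h carries
  the model's full planted fold change (the functional form is a generator
  convenience, not an assay model); TR trajectories plant per-panel log2
  time courses (default: early mTOR-axis induction, late cell-cycle and
  MAPK collapse, progressive apoptosis); killing arms plant per-arm mean
  ratios with truncated-Gaussian per-PDM noise.
* **Artifacts.** A configurable fraction of proteins (default 5%) is forced
  below blank level to exercise the quality filter; plate records are
  multiplied by 5 with probability 2% to exercise outlier removal. All
  planted effects, blanks and outlier positions are recorded in a
  `SimTruth`.
* **Reproducibility.** One global seed; each generator draws from its own
  deterministic substream, so outputs are bitwise reproducible per
  component.
* **What it does not emulate.** Spot-level array structure, spatial plate
  effects, inter-protein correlation beyond pathway-block shifts, well
  random effects, dose–response curvature, or image formation — passing
  tests demonstrate correctness and calibration of the statistics under
  the stated noise model, not performance on raw instrument data.

## Problem sizes

Simulation-based checks use 100 cohorts (signature/HCL/TR/killing
recovery) or 200 simulations (grading power and null calibration,
pathway-test calibration), chosen as the smallest sizes at which the
binomial uncertainty of the measured rates is well inside the asserted
margins.

## Known limitations

* Pathway p-values after signature selection are descriptive (see above).
* The modified Z-score at 3.5 over-flags in 3-replicate strata; the pooled
  ANOVA error term absorbs most, but not all, of the resulting truncation.
* Missing values are not modeled anywhere; real data with gaps must be
  pre-imputed or the affected rows dropped.
* The grading map treats the Holm-adjusted p as an ordinal readout; it is
  not an effect-size estimate, and FC magnitude enters only through the
  test statistics.
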