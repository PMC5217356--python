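# Methods

## Data model

A **PeptideObservation** is one quantified peptide ion (sequence + charge
+ m/z) in one gel slice of one lane, with an XIC intensity. A **lane** is
the (stage, biological replicate) unit: all normalization and imputation
operate per lane. Observation and annotation tables are tab-delimited
UTF-8 with mandatory headers; stage labels are ordered categoricals whose
order comes from the pipeline configuration (default 9DAF, 13DAF, 19DAF).

## Quantification

**Lane correction factor.** Each lane's XICs are multiplied by
mean(lane totals) / (its lane total). After correction every lane total
equals the pre-correction mean to machine precision; lanes with zero
total cannot be corrected and raise/drop explicitly.

Total-signal normalization is compositional: when regulation is
asymmetric (e.g. many proteins induced at one stage), the lane totals of
that stage grow and *unregulated* proteins are pushed down after
correction. On synthetic data with 10% of proteins 4-fold induced at
19 DAF this shifts null proteins by about log₁₀(1.3) at that stage, and
a substantial fraction of them reach p < 0.001. This is a property of
the normalization scheme itself, not of its implementation; analyses that
need compositional robustness should interpret "significant" calls as
"changed relative to total signal".

**Aggregation.** Peptide-ion identity is (sequence, charge, m/z within
10 ppm); m/z values are clustered greedily along the sorted axis with a
new group wherever the relative gap exceeds the tolerance. Ion XICs are
summed over the slices of each lane, then charge states of one sequence
are summed into the per-peptide value ("aggregation" is summation at
both levels, matching the explicit protein-level summing). An ion whose
occurrences disagree on the attributed protein set, or a sequence whose
charge states disagree, is flagged inconsistent and dropped.

**Filters.** Peptides: specific to one protein AND observed in ≥ 2
replicates within at least one stage (the within-stage reading mirrors
the protein presence rule). Proteins: ≥ 2 distinct specific peptide
sequences overall (charge states of one sequence count once by default;
`merge_charge_states=False` counts them separately) and presence in ≥ 3
replicates within ≥ 1 stage. All thresholds live in `PipelineConfig`;
raising any of them can only shrink the retained sets.

## CWP selection

"Consensus" is the strict intersection: every signal-peptide predictor
(SignalP-, Phobius-like columns) must call "secreted", no targeting
predictor (TargetP-, Predotar-like) may call mitochondrial or plastid,
and the transmembrane-segment count outside the signal peptide must be
zero. A missing predictor call yields an explicit "unknown" verdict and
exclusion with a logged reason — never a silent pass or fail. ER
retention is tested on the exact final tetrapeptide (KDEL/HDEL) only;
internal occurrences do not count. Functional classes come from an
ordered, editable domain-label → class rule table (first match wins; a
`GH` rule also matches `GH17` etc.); proteins without a matching label
are "unknown". The predictors themselves and domain scanning are out of
scope: their outputs are inputs here.

## Statistics

**Imputation.** On the log₁₀ matrix, a protein's missing entry in lane L
is set to the minimum of the values present in lane L, only when the
protein is present in another replicate of the same stage. Whole-stage
absences are never filled; the stage comparison then runs on the stages
that carry data (three-stage and two-stage proteins are thereby analysed
separately, as reflected in `n_stages_tested`).

**ANOVA.** Classical one-way fixed-effects ANOVA per protein across
stage groups, implemented vectorised from group sums/sums-of-squares with
p-values from the F survival function; it agrees with
`scipy.stats.f_oneway` to relative 1e-9 (unit-tested) and handles 1e5
proteins in well under a second, which makes the null-calibration
simulation cheap. Proteins with < 2 stages of data or no residual
degrees of freedom are reported untestable. The significance rule is a
raw p < 0.001 with no multiple-testing correction, following the
published analysis; an FDR switch exists in the configuration but is off
by default.

**PCA.** Centered PCA of lanes (lanes as points) on proteins present in
every lane; coordinates plus explained-variance fractions are returned.

**Clustering.** Row distance is 1 − Pearson correlation of the
stage-replicate profiles (standardized-Euclidean available as
`euclidean_std`), complete linkage, flat clusters from a fixed-height cut
at 1.1. The distance/linkage pair is a documented choice: the original
heat-map clustering did not state its metric, so the 1.1 cut is
reproducible only under this convention. Cluster ids are reassigned by
decreasing size. Cuts above the root or below all merges degrade
gracefully to one cluster / all singletons.

**Preferential stages.** Cluster stage means are taken on the *linear*
abundance scale (the pipeline exponentiates its log₁₀ matrix before the
call); the preferential set is every stage whose mean is within 10% of
the maximum stage mean. On log values a 10% margin would span several
fold changes and mark every stage preferential; on the linear scale the
rule discriminates 4-fold effects cleanly while a flat profile still
yields all stages.

## Synthetic experiments

The generator emulates the study design: 3 stages × 5 biological
replicates × 12 gel slices, tryptic peptides (one allowed missed
cleavage, K/R-not-before-P) of random protein sequences sized to the
10–95 kDa separation range, monoisotopic m/z for 2+ (and 3+ where length
≥ 12) parent ions via pyteomics. Per-protein base abundance is
log₁₀-normal with mean 6 (matching the observed median log₁₀ XIC ≈ 6)
and SD 0.6; each peptide gets a log-normal ionisation factor; XIC noise
is multiplicative log-normal with unit mean and configurable CV (default
0.2); lane effects are log-normal with SD 0.2; observations drop with
probability 0.1. About 40% of proteins are secreted (the fraction
retained as CWPs in the study), 5% of those carry KDEL/HDEL tails, 10%
of proteins carry a 4-fold (log₁₀ 0.602) abundance effect at one stage.
Proteins map to slices by linear binning of 10–95 kDa (heavier → lower
slice index — a monotone surrogate for the unstated gel calibration),
with a 10% chance that an observation splits 80/20 into a neighbouring
slice. 5% of peptides are additionally attributed to a second random
protein to exercise the specificity filter; their XIC is generated from
the owning protein only. Predictor calls derive from true secretion
status with a configurable per-call error rate (default 0, i.e. perfect
calls; raise it for robustness experiments).

What the generator does *not* emulate: spectra, retention times and
alignment errors, shared-peptide intensity mixing, correlated peptide
missingness, contaminants, or realistic sequence composition. Passing
tests therefore demonstrate correctness of the quantification arithmetic
and calibration of the statistics under the stated noise model — not
robustness to raw-data pathologies upstream of the XIC table.

Fixed seeds make every output byte-identical; all randomness flows
through one `numpy` generator per simulation.

## Problem sizes and numerics

The test and acceptance runs use: 500 random sequences (length ≤ 30)
against the brute-force digestion oracle; 500 random membership maps
against inclusion-exclusion; 1e5 null proteins (3 × 5 lanes) for ANOVA
calibration, expecting a significant fraction in [0.0005, 0.002]; 1000
proteins with 10% affected for power (≥ 0.9) and preferential-stage
accuracy (≥ 0.95); lane-total conservation to 1e-6 relative on ≥ 1e4
observations. These sizes give stable statistics at interactive run
times. Ties in m/z grouping are resolved by the sorted-gap rule;
zero-variance ANOVA inputs return F = 0 (flat) or p = 0 (separated
groups with zero within-variance); correlation distance is undefined for
constant rows, which cannot become significant and hence never reach
clustering in the pipeline.

## Limitations

- The headline identification counts of the motivating study (1122
  proteins, 466 CWPs, 195 significant) depend on raw LC-MS/MS data and
  database search; they are not recomputable from tables alone. The
  published Venn and percentage arithmetic is reproduced exactly from
  the printed cell counts; everything else is validated on synthetic
  ground truth.
- The consensus rule treats all available predictors as equally binding;
  the original tooling may have weighed disagreements differently.
- Total-signal normalization's compositional bias (above) is inherited
  by design.
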