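# Methods

This note documents the models, defaults and numerical choices behind
`zfpheno`, and what the synthetic generators do and do not emulate.

## Trajectory model and assay geometry

A trajectory is a uniformly sampled series of (x, y) positions in mm, well
centre at the origin. Sampling must be exactly uniform: inter-sample
spacing may deviate from `1/rate_hz` by at most 1e-6 s, and a dropped
frame is a validation error rather than something to interpolate over —
interpolation would silently change distance and duration semantics. The
default rate is 25 Hz, always passed explicitly (typical tracking setups
run 10–30 Hz; the source videos' rate is not recoverable from the data,
so it is never inferred). Time zero is the start of the recording; the
dark-acclimation period that precedes it is not part of the trajectory.

The standard assay schedule is three cycles of 30 s light followed by 30 s
dark (180 s, light first). Schedules must be contiguous, alternating and
start at t = 0.

## Locomotor metrics

Per-interval speed is the Euclidean step length divided by dt, with no
smoothing by default. An optional centred moving average (odd window) can
be applied before classification only; distances always use raw speeds.
Whether trackers smooth before thresholding varies between setups, so the
choice is exposed in configuration and echoed into run reports.

Classification: active iff `v > theta_active` (default 0.1 mm/s);
phases stationary (`v <= 0.1`), normal (`0.1 < v <= 1.2`), abrupt
(`v > 1.2` mm/s). Boundary values fall to the lower class.

**Bolt segmentation.** There is no community-standard burst definition, so
the package uses the simplest robust one: maximal active runs, merging
runs separated by inactive gaps ≤ `merge_gap_s` (default 0.1 s, merging is
transitive along chains), then discarding merged runs shorter than
`min_duration_s` (default 0.2 s). The defaults tolerate single-frame
flicker at 10–30 Hz while rejecting sub-burst twitches. A bolt's distance
and peak speed accumulate over every interval in its span, including
merged-over gap intervals (the gap is part of the burst, and this keeps
`sum(bolt distances) <= total distance` exact). Gaps are whole interval
counts; an epsilon absorbs float error when `merge_gap_s` is an exact
multiple of dt.

Two related per-larva quantities are reported deliberately:
`distance_per_bolt_mm` (total bolt distance / bolt count) and
`bolt_distance_mm` (mean of per-bolt distances) — they coincide, but are
kept as separate columns because group summaries of the two diverge once
bolt counts differ between larvae. `bolt_interval_s` is gap-wise (end of
bolt *i* to start of bolt *i+1*), NA with fewer than two bolts; all bolt
means are NA with zero bolts.

**Condition assignment.** Intervals belong to the light/dark epoch
containing their midpoint; an interval straddling a boundary belongs
wholly to the epoch of its midpoint. This makes the light + dark
decomposition of any interval-additive metric (distance, active time) sum
*exactly* to the overall value. Bolts are likewise assigned by bolt
midpoint. Per-condition bolt intervals are computed between consecutive
bolts assigned to the same condition.

The per-second locomotor profile credits each interval's distance `v*dt`
to the 1 s bin containing the interval midpoint, so the profile sums
exactly to mean total distance per group.

**A note on threshold monotonicity.** Raising `theta_active` is monotone
for the active-time fraction, but *not* in general for the bolt count: a
threshold raised into the within-bolt speed distribution can split a run
whose interior dips between the two cuts. In the operating regime —
quiescent jitter far below the threshold, bolt speeds far above — raising
the threshold within the gap between the two speed populations cannot add
bolts, and that is the property the test suite asserts.

## Statistical primitives

- **Welch's t** (unequal variances) is the default two-group test, for the
  behavioral metric contrasts and per-protein DE alike; the
  pooled-variance Student's t is available behind `equal_var=True`. With
  n = 2 LFQ replicates per group, equal-variance pooling is an unneeded
  assumption; Welch–Satterthwaite df handles the heteroscedastic case and
  reduces to the same answer when variances happen to match.
- **Benjamini–Hochberg**: step-up adjusted p-values
  `q(i) = min_{j>=i} p(j)·m/j` capped at 1, returned in input order. The
  output is elementwise ≥ the input and order-preserving; it is *not*
  idempotent (re-adjusting adjusted values inflates them further). Ties
  share the smaller adjusted value via the cumulative minimum.
- **Two-way ANOVA** supports balanced designs only (the group ×
  light-condition design is balanced by construction); type I/II/III sums
  of squares coincide under balance. All-constant input returns F = 0,
  p = 1 for every effect rather than NaN. Unbalanced input raises — the
  package does not silently switch SS types.
- **Tukey HSD** runs on the labelled cells (4 cells in the group ×
  condition design) using the studentized range; with two cells it reduces
  to the pooled t-test via `q = |t|·√2`. All-constant input returns
  adjusted p = 1 for every pair.
- **Hypergeometric enrichment** is the exact upper tail P[X ≥ k] for k
  query hits in a term of size K within a background of size N.
- **Zero-variance rows** (both groups constant) cannot be tested; the DE
  stage excludes them from testing and from the BH family and reports them
  in a separate table, rather than assigning p = 0 — with n = 2 such rows
  would otherwise become unfalsifiable top hits.

## Proteomics pipeline

Detection per group uses the conservative `both_replicates` rule by
default (quantified in every replicate of the group); `any_replicate` is
available for sensitivity analysis. The shared/exclusive accounting runs
on whichever rule is configured.

The replicate-consistency filter keeps exactly the proteins with no
missing value in any sample of either group. No imputation exists anywhere
in the package; with duplicate replicates, imputed values would be
untestable. The filter is idempotent.

Intensities are log2-transformed; normalization defaults to per-sample
median centring (each sample's median log2 intensity subtracted). The
upstream normalization of any given dataset is rarely documented precisely,
so the method is named in the run report and `none` is available.
log2FC is the difference of group means of log2 values (not the log2 of
mean intensities), matching transform-then-compare semantics.

DE calls: up iff `p_adj < alpha` and `log2FC > fc_min`; down iff
`p_adj < alpha` and `log2FC < −fc_min`; otherwise ns (defaults
alpha = 0.05, fc_min = 1). BH runs across all tested proteins; enrichment
BH runs across all terms; the two families are adjusted separately.

Curated subsets — the packaged 40-protein neurodegeneration table and the
8-protein Parkinsonism panel — are *inputs*, not algorithmic selections:
their membership encodes biological curation (disease ontology, literature)
that is not computable from an intensity matrix. The panel file records two
spellings used for the proteasome members (e.g. PSMA5 vs PSMA8, PSMB vs
PSMB3/5/10) exactly as curated, pipe-separating alternatives; the
discrepancy is preserved, not resolved.

## Synthetic swim cohorts

`simulate_larva` draws an alternating-renewal process: quiescent durations
are exponential with hazard equal to the current bolt-initiation rate,
which switches instantaneously with the light condition (piecewise
hazard integrated across epoch boundaries, valid by memorylessness); bolt
durations are Gamma(shape 2, mean 0.6 s). Within a bolt, each sampling
step's speed is a fresh truncated-normal draw (mean 6, sd 2 mm/s,
truncated at 0) and the heading performs a Gaussian random walk
(sd 0.3 rad/step); during quiescence the larva jitters at a constant
0.02 mm/s in a fresh random direction each step — safely below the
0.1 mm/s activity threshold. Positions reflect radially at a 5 mm radius
(24-well plate scale; the fold shortens the measured step slightly when
the wall is hit, an accepted artefact of any reflecting boundary).

Defaults encode the two phenotypes: the control initiation rate is
0.25 events/s in dark and 0.75 in light (a ×3 light multiplier — the
minimal mechanism producing light-on activity peaks); the hypokinetic set
uses 0.05 events/s in both conditions. Within-bolt speed and duration are
*identical* between the sets: the emulated deficit is in movement
initiation, not execution, so simulated cohorts show large differences in
total distance, bolt count and inter-bolt interval while per-bolt distance
and duration do not differ — and the light response is abolished. No
printed effect sizes exist for the emulated assay, so these defaults are
calibrated qualitatively to that contrast and the corresponding tests are
directional, not numeric.

Per-larva RNG streams derive from the master seed via
`SeedSequence(seed, spawn_key=(index,))`, so cohorts are reproducible and
independent of generation order.

What the generator does **not** emulate: tail-beat kinematics, habituation
to repeated stimuli, startle latency structure, tracking noise/dropouts,
or wall-following behaviour. Passing tests therefore validate the metric
and inference machinery, not biological realism of any particular larva.

## Synthetic LFQ matrices

Protein base abundances are Normal(23, 2) on the log2 scale; a random
subset of `n_de` proteins receives a group effect of fixed magnitude
(default 2) and random sign; replicates add Normal(0, 0.25) log2 noise;
intensities are `2^value`. Missingness is Bernoulli per cell at a baseline
rate (default 0.05) plus a logistic low-abundance boost (default 0.15,
knee one sd below the mean base level) — missing-not-at-random, which is
what gives the consistency filter realistic work. The default design is 2
replicates per group, matching the emulated duplicate-pool design.

A duplicate design has essentially no BH-adjusted power at ~1–2k proteins
(df ≈ 2 caps how small a Welch p can get), which is why the demo fixture
bundle and the operating-characteristics checks use 4 replicates per
group: with |log2FC| = 2, noise sd 0.25 and 4 replicates, the pipeline's
sensitivity exceeds 0.9 at observed FDR below 0.1 (recomputed by
`scripts/acceptance.py`). Under the global null the fraction of runs with
any discovery estimates the FDR, bounded by alpha under BH.

What the LFQ generator does not emulate: correlated proteins, batch
effects, peptide-level aggregation noise, or intensity-dependent variance.

## Determinism and problem sizes

Every simulation is deterministic given its seed (bit-identical on one
platform). Monte-Carlo checks use 100 larvae vs a 1000-replicate renewal
oracle for bolt-count recovery, 200 null matrices for the FDR guarantee,
20 seeds for spiked operating characteristics, and 3 pooled cohorts for
the phenotype contrast — sizes chosen so each Monte-Carlo standard error
is far smaller than the effect being checked. The exhaustive
bolt-segmentation check enumerates every velocity series up to length 12
over the {0, 0.5, 2.0} mm/s alphabet against an independent run-length
oracle, for all six min-duration × merge-gap combinations.
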