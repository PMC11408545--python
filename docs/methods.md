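# Methods

This note documents the models, estimators and numerical choices behind
`surgskill`, the assumptions they rest on, and what the synthetic
validation does and does not demonstrate about real recordings.

## Signals and preprocessing

A trial carries four streams: two tool-tip pose series (tweezers =
left hand, needle holder = right hand) sampled uniformly at a nominal
120 Hz, in cm, and two per-finger force recordings (thumb, index,
middle per hand) at 40 Hz, in N.  Orientation triplets may accompany
positions but feed no metric; they are stored pass-through.  Task
segments S.1–S.4 are half-open, 0-based sample windows [k₀, k_f) on the
kinematic timeline, so segment durations are additive and
`completion_time = (k_f − k₀)/rate` holds exactly.  Force streams are
sliced by the derived [t₀, t_f) time window on their own 40 Hz
timeline, since the two streams run at different rates.

**Gap repair.** Motion-capture dropouts (NaN rows) are flagged at
ingestion and filled by per-coordinate linear interpolation when the
contiguous gap is at most `max_gap_s` (default 0.1 s, roughly 12
kinematic samples).  Longer gaps, or gaps touching a trace boundary,
are unrecoverable and abort the trial with the gap location.  The
repair is idempotent.  Negative force readings are clipped to 0 N with
a logged count; timestamps must be strictly increasing and within 1% of
the nominal sampling period.

**Derivatives.** Velocity, acceleration and jerk are estimated per
coordinate with a Savitzky-Golay differentiator, polynomial order 3
over a 5-sample window, scaled by `rate^d` to physical units.  Any
polynomial trajectory of degree ≤ 3 is therefore differentiated exactly
(up to float conditioning, which grows with `rate^d`).  Edge handling
defaults to fitting the edge polynomial over the terminal window
(`interp`), which keeps boundary derivative estimates unbiased for
smooth trajectories; mirror reflection zeroes odd derivatives at the
boundary and biases the jerk power of an isolated reach by several
percent, so it is offered only as an option, alongside
`truncate_to_valid` for users who prefer to drop the half-windows.
Derivatives are always computed on the full trial and sliced to
segments afterwards, so segment boundaries carry no edge artefacts.
Positions themselves are not smoothed: path length and economy of
volume operate on the raw (gap-repaired) coordinates.

## Metric definitions and conventions

- **Path length** is the chord sum Σ‖Δp‖₂, which carries the stated cm
  units; it equals Σ‖v‖Δt under the same discretization.
- **Motion smoothness** is the log dimensionless jerk,
  −ln(ΔT³/v²_max · Σ‖j(k)‖₂²·Δt), with v_max the peak speed within the
  segment.  Multiplying the jerk sum by the sampling period makes the
  quantity approximate the continuous squared-jerk integral and renders
  it sampling-rate independent; it is exactly invariant to spatial
  rescaling and invariant to joint time/grid rescaling up to
  discretization.  For a minimum-jerk reach the continuum value is
  −ln(720/1.875²) ≈ −5.322 regardless of distance and duration, which
  the implementation reproduces within 1% at 120 Hz.
- **Idle time** counts samples with speed ≤ v*.  The threshold is not
  dictated by any measurement standard; the default v* = 0.5 cm/s was
  chosen once as a value well below typical reach speeds (several cm/s)
  and above tremor-band speed noise, and is configurable.  The "both"
  scope counts simultaneous sub-threshold samples of the two tools, so
  it can never exceed either single-tool idle time.
- **Economy of volume** is 100·∛(bounding-box volume)/path length.  It
  is bounded in [0, 100] because the path length dominates the largest
  per-axis excursion, which dominates the cube root of the box volume.
  A degenerate zero-volume box yields 0 by default (configurable to a
  missing value); an all-stationary path has no defined value.
- **Bimanual dexterity** is the Pearson correlation of the two speed
  series — bounded, dimensionless and symmetric, which the raw printed
  cross-moment ratio without the square-rooted denominator would not
  be.  Speeds (not signed velocity components) are correlated.
- **Number of presses** counts prominent positive peaks of the hand
  activity signal A(t), the sum over the three instrumented fingers of
  the time derivative of the max-normalized force.  Normalization is by
  the trial-level per-finger maximum so all segments of a trial share
  one scale and the count is invariant to force-gain changes.  Raw
  local-maxima counting on a differentiated noisy signal would count
  noise, so detection requires prominence ≥ 10% of the segment's
  activity maximum and ≥ 0.25 s separation (closer peaks merge into
  one), after a light Savitzky-Golay presmooth; all three knobs are
  configurable and echoed into reports.  Release troughs (negative
  peaks) are ignored.  An activity maximum at the float-noise floor
  (≤ 1e-9) counts as a flat signal.

Degenerate metric evaluations (motionless tool, zero-variance speed,
zero path) are emitted as missing values, never as ±∞, and never drop
table rows.  Each segment yields 13 metric values across the legal
(metric, scope) pairs; a trial yields 52.

## Group comparison

Per (metric, scope, segment) cell, values pool across subjects and
trials (default: all trials, giving 15 novice and 18 intermediate
points at the default cohort size; a per-subject-mean option exists
because pooling choices are rarely reported).  The pipeline then runs,
in order: outlier exclusion → median/IQR descriptives → Shapiro–Wilk
per group → routed two-sided test.

**Outlier exclusion** uses Tukey fences at 1.5×IQR, single pass.  The
fences are computed on the *pooled* two-group cell sample by default: a
value is an outlier if it is extreme against the cell's overall
pattern.  The alternative — fencing each group by its own quartiles —
measurably inflates the false-positive rate of the downstream
two-sample tests at these group sizes (≈9% for a normal null, ≈13% for
a lognormal null, against a nominal 5%), because data-dependent
trimming shrinks each group's variance estimate.  With pooled fences
the measured null rejection rate is 0.053–0.055 for both families.
Per-group fencing remains available as `outlier_scope="per_group"` for
users replicating that convention.  Quantiles use linear interpolation
(numpy's default, R type 7) and the convention is named in every
output, since small-n quartiles depend on it.

**Routing.**  If both groups pass Shapiro–Wilk at α (p > .05), the cell
uses the pooled-variance independent t-test; otherwise the two-sample
Wilcoxon rank-sum (Mann-Whitney) test, two-sided in both cases.  The
rank-sum p-value is exact when both samples are small and tie-free and
otherwise uses the normal approximation; the reported statistic is the
continuity- and tie-corrected z.  Degrees of freedom are reported as
n_N + n_I − 2 for both routes.  A constant or too-small sample cannot
be normality-tested and routes to the rank-sum; cells with fewer than
3 values per group after exclusion are flagged not-testable.  No
multiple-testing correction is applied by default, matching common
practice for this study size; Benjamini–Hochberg is available behind a
flag.  Note the gate itself is a pretest at level α: even perfectly
Gaussian group pairs route to the t-test only ≈ 0.95² ≈ 90% of the
time, which bounds any "routing consistency" one can expect.

The model-style surface is `SkillComparison(metric_table).fit()`,
returning a results object with the 52-row frame, a `summary()` table
in median-(IQR) style, CSV export and box-plot figures (red "+"
outliers, green triangle means).

## Synthetic cohort

The generator emulates the structure the metrics assume, not the
biomechanics of suturing:

- **Reaching**: each segment chains n submovements — straight
  minimum-jerk reaches p(τ) = p₀ + D(10τ³ − 15τ⁴ + 6τ⁵) — toward
  uniformly drawn targets in a ±1.5 cm workspace box, separated by idle
  holds whose total duration implements the profile's idle fraction
  (Dirichlet-split across gaps).  Minimum-jerk reaching is the standard
  model of skilled point-to-point movement and gives closed forms
  (peak speed 1.875‖D‖/T, squared-jerk integral 720‖D‖²/T⁵) used as
  oracles.
- **Tremor**: per-axis sinusoids with random frequency in the 8–12 Hz
  physiological band and sub-millimetre amplitude (novice 30 µm,
  intermediate 15 µm per axis), so tremor dominates jerk power but its
  speed stays below the idle threshold.
- **Bimanual coupling**: both hands share one submovement/hold
  schedule; the left hand trails by the profile's inter-hand lag
  (novice 0.12 s, intermediate 0.08 s), which sets the speed
  correlation to ≈0.6 vs ≈0.7–0.8 — the realistic range for this task.
- **Forces**: per segment and hand, a planted number of raised-cosine
  pulses (width 0.3 s, ≥ 0.8 s spacing, per-finger amplitudes 1.5–4 N
  over a 0.3–0.8 N baseline, 0.01 N sensor noise) on all three fingers.
  The pulse count is capped by what fits the segment; the ground truth
  records the realized count.
- **Skill profiles**: novices get more, longer, noisier submovements,
  higher idle fractions and more presses (shipped in
  `presets/profiles.yaml`; per-segment means chosen once to mirror the
  reported descriptive contrasts, e.g. novice segment durations ≈
  40/27/34/13 s and an intermediate-to-novice path-length ratio ≈ 0.4).
  Each subject carries a lognormal skill multiplier (sd 0.10 on the log
  scale) for between-subject variability.  The default cohort is 5
  novice + 6 intermediate subjects × 3 trials.  A null mode draws both
  labelled groups from the novice profile.

Every trial carries a ground-truth record: realized press counts,
planted submovement path lengths, scheduled hold time, and the idle
time of the noiseless trajectory at the reference threshold (holds plus
the slow tails of each reach — a minimum-jerk reach spends a predictable
fraction of its duration below any fixed speed threshold near its
endpoints, so holds alone would understate the idle actually planted in
the trace).

**What passing the synthetic validation shows** — and what it does not:
the pipeline recovers planted quantities (press counts exactly in
> 99% of segments, path length to < 0.5% on tremor-free reaches, idle
fraction to < 0.1), its null false-positive rate is calibrated, and the
expected skill contrasts emerge with the planted effect directions in
every segment.  It does not show that real microsurgical recordings
satisfy the generator's assumptions: real tremor is broadband rather
than sinusoidal, real submovements overlap rather than chain, marker
occlusion produces structured (not random) gaps, and force baselines
drift.  Conclusions about real cohorts still require real recordings.

## Problem sizes and determinism

All simulations are seeded; cohorts are byte-identical across runs for
a fixed seed.  The validation script uses 2000 null studies per
distribution family for the calibration check (standard error ≈ 0.005
at the nominal 0.05), 500 segments for press-count recovery, 20
segments each for idle and path-length recovery, and 20 seeded cohorts
for the contrast replication — sizes at which every reported rate has
a margin well beyond its Monte-Carlo noise.

## Known limitations

- Segment annotations are taken as given; no automatic segmentation.
- The comparison pools trials within subjects, ignoring within-subject
  correlation (no mixed-effects model); this replicates the standard
  analysis for this design but anti-conservatively treats 3 trials as
  independent.
- The idle threshold v*, the peak-detection knobs and the outlier fence
  are conventions, not estimates; results at tiny n depend on them, and
  every output therefore echoes the full configuration and its hash.
- Orientation data are carried but unused; no orientation-based metrics
  (angular path, rotational smoothness) are defined.
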