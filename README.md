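# surgskill

Objective, quantitative assessment of microsurgical anastomosis skill
from sensor data: bimanual instrument kinematics (3-D tool-tip traces at
120 Hz for the tweezers/left hand and the needle holder/right hand) and
per-finger pinch forces (thumb, index, middle of each hand at 40 Hz).
The package targets surgical educators and motor-control researchers
who want to replace subjective error-count scoring with reproducible
kinematic evidence, and to study what separates novice from more
proficient operators.

## The metrics

Each suturing trial is split into four annotated task segments
(S.1–S.4: needle through the first vessel wall, through the second
wall, first knot, second knot), each a sample window [k₀, k_f) on the
kinematic timeline.  Per segment the framework scores:

| Metric | Scope | Definition |
|---|---|---|
| Completion time `M_ΔT` [s] | both | (k_f − k₀) × sampling period |
| Idle time `M_T_idle` [s] | per tool, both | total time with ‖**v**(k)‖₂ ≤ v* (default v* = 0.5 cm/s); "both" counts simultaneous idleness |
| Path length `M_PL` [cm] | per tool | Σ ‖**p**(k+1) − **p**(k)‖₂ |
| Motion smoothness `M_MS` [–] | per tool | log dimensionless jerk: −ln( ΔT³/v²_max · Σ‖**j**(k)‖₂² Δt ); larger (less negative) = smoother |
| Economy of volume `M_EoV` [%] | per tool | 100 · ∛M_MV / M_PL with M_MV = Π_j \|max p_j − min p_j\| |
| Bimanual dexterity `M_BD` [–] | both | Pearson correlation of the two tool-tip speed series |
| Number of presses `M_NoP` [#] | per hand | count of prominent peaks of the hand activity signal A(t) = Σ_i d/dt [f_i(t)/max\|f_i\|] |

Velocity, acceleration and jerk come from a Savitzky-Golay
differentiator (order 3, window 5) applied to the full trial and sliced
to segments afterwards.  Group comparison pools all trials per
(metric, scope, segment) cell, excludes Tukey-fence outliers, reports
median (IQR) descriptives, gates each group on Shapiro–Wilk normality,
and routes to a two-sided independent t-test (both normal) or a
two-sided Wilcoxon rank-sum test otherwise, with df = n_N + n_I − 2 and
significance at α = .05.

Because no public recordings exist for this task, the package ships a
synthetic-cohort generator (minimum-jerk submovement chains with idle
holds and 8–12 Hz tremor; raised-cosine force pulse trains) whose
ground truth validates every metric and whose default skill profiles
reproduce the qualitative novice/intermediate contrasts.

## Worked example

```python
import surgskill as sk

cohort = sk.generate_cohort(seed=1)                     # 5 + 6 subjects x 3 trials
table = sk.cohort_metric_table([t for t, _ in cohort])  # 33 x 52 metric values
results = sk.compare_cohort(table)                      # SkillComparisonResults
print(results.summary())
```

prints (excerpt):

```
Skill group comparison (novice vs intermediate)
alpha=0.05, pooling=all_trials, quantiles=linear, outlier fence=1.5xIQR
            metric         scope segment novice vs intermediate, M (IQR)              test statistic  df        p sig
   completion_time          both      S1   37.48 (18.75) vs 12.59 (2.02)            t_test     8.201  30 3.74e-09   *
   completion_time          both      S2     24.85 (8.57) vs 8.03 (2.13)            t_test     9.444  31 1.23e-10   *
       path_length      tweezers      S1   37.84 (11.71) vs 12.19 (2.52)            t_test     9.152  31 2.54e-10   *
 motion_smoothness      tweezers      S1  -25.07 (1.78) vs -19.46 (1.03)            t_test   -12.098  31 2.82e-13   *
...
```

Read: in segment S.1 the simulated novices needed a median 37.5 s
against 12.6 s for intermediates, travelled three times the path with
the tweezers, and moved less smoothly (more negative log dimensionless
jerk); each difference is significant at α = .05 under the routed test.
49 of the 52 cells differ significantly for this seed.

The same pipeline runs from the shell:

```sh
surgskill simulate --out cohort/ --seed 1
surgskill metrics cohort/ --out metrics.csv
surgskill compare metrics.csv --out comparison.csv
surgskill report comparison.csv
```

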