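# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Protocol engine

The engine is a discrete-event state machine on a float-seconds clock with a
single seeded `numpy` generator per session; nothing depends on wall-clock
time, so a session log is exactly reproducible from (config, seed, behaviour
parameters). Events are strictly time-ordered and serialized as JSON Lines
with a mandatory `schema_version` header.

**Staircase semantics.** The triggering streak counter resets to zero when
its adjustment fires (a *series of k*, not a sliding window), matching
transformed up-down staircases in the MIST family. A timeout counts toward
the failure streak ("incorrectly or not at all"); the separate rescue
counter counts only trials with no keypress at all, and any keypress —
including a late one — resets it. A wrong answer therefore resets the
no-input counter while extending the failure streak. The rescue exists only
in the stress condition (a config flag allows enabling it elsewhere; default
off) and forces exactly one addition problem before normal generation
resumes.

**Adaptation arithmetic.** Time limits keep full float precision (whether
the deployed app rounded is unknown; not rounding keeps the closed form
limit = initial · 0.9^a · 1.1^b exact for a shorten and b lengthen events,
which the property tests exploit). Limits are clamped to configurable
bounds, default [0.5 s, 30 s], purely to keep long simulations numerically
sane; the clamp is recorded in the config snapshot of every log.

**Problem sampling.** The operation is uniform over the condition's allowed
set, then an operand pair is drawn uniformly from the exhaustively
enumerated valid pairs for that operation (4851 for addition and
subtraction, 473 for multiplication and division over operands and solutions
in [1, 99]). Constructive enumeration rather than rejection sampling makes
the distribution exactly uniform and the draw O(1). No sampling
distribution is published; uniform is the natural uninformative choice.

**Keypad swap.** Each swapped task draws a fresh uniform non-identity
permutation of the ten digit keys. The control condition never swaps.

**Task cutoff.** The math task stops at exactly 90 s of task clock; a
problem in flight at the cutoff is truncated without an outcome and excluded
from the presented count. The live percent-correct display shows 0 before
the first problem (display convention; the source protocol is silent).

**Session schedule.** framing → baseline PANAS + VAS → math task →
intermediate VAS → speech task → post PANAS + VAS → element-rating
questionnaire. Dropout is tested at a checkpoint before each of the five
stages (intro, math, intermediate, speech, post). Questionnaire blocks and
the framing are booked at nominal 30 s / 60 s on the session clock so that
total durations are meaningful for the duration-outlier exclusion filter.

## Synthetic participants

The behaviour model is plumbing, not a claim about human cognition: it
exists so that every downstream stage can be exercised at realistic sample
sizes without deposited raw data (none exist for this protocol).

**Arithmetic skill.** Solve times are log-normal per operation (medians
2.0/2.6/3.4/3.4 s for add/sub/mul/div, log-SD 0.4 — plausible magnitudes for
two-digit mental arithmetic under time pressure), plus a 1 s motor penalty
while the keypad is permuted. Correctness is base accuracy (0.92) times a
logistic factor in limit/solve-time, making P(correct | limit) continuous
and strictly increasing — the premise of the staircase-equilibrium property.
A trial is silent with probability 0.02.

**PANAS generation.** Participants carry latent subscale means; items are
latent + N(0, item_sd) rounded and clipped to the 1–5 grid (item_sd 0.55,
chosen to give realistic within-scale item scatter). Discretization both
biases the mean upward (floor at 1) and compresses the variance, so the
latent population parameters are *moment-matched*: the population latent
mean inverts the exact expected-score map E[clip(round(X),1,5)] of the
marginal normal, and the latent between-subject and change-deviation SDs are
solved by Gauss–Hermite quadrature over the exact conditional score moments
so that the observed subscale means reproduce the configured baseline
mean/SD and change mean/SD. Post scores are baseline latent + an independent
change deviation; the post SD is therefore implied (slightly above a value
implied by a correlated model) rather than separately configurable — the
quantities the evaluation consumes are the baseline and change moments,
which are matched. The default parameter set (`cohort_table2_default.yaml`)
uses the published per-arm baseline/change summaries where printed; the
control-arm change SD (not printed) is set equal to the stress arm's 0.61.

**VAS generation.** Latent normal trajectories per scale (baseline level
plus intermediate/post change draws), clipped to [0, 100]. Defaults for the
`stressed` scale are solved from the published group and time marginal
means under equal-baseline assumptions (stress arm 32.9 → 60.0 → 34.3,
control 32.9 → 39.2 → 26.3, SDs 25/20); the other three scales follow the
same qualitative pattern at smaller levels, as described for the study.
Mid-scale truncation bias is negligible and left uncorrected.

**Dropout.** Independent Bernoulli hazards per stage, back-fitted to the
published funnel: the stress arm's intro hazard is the printed 89/300 and
the residual dropout is split evenly (in survival terms) over the four later
checkpoints so the overall completion probability equals 112/300; the
control arm uses a small 0.02 intro hazard (early cancellation was reported
absent there) and completion 206/247. The "unrealistic procedure duration"
exclusion threshold is unpublished; the filter defaults to [120 s, 1800 s]
and is configurable.

**What passing tests do and do not show.** The generator reproduces the
second-order moment structure the evaluation assumes (group × time affect
means and SDs, completion fractions), not human response processes: no
physiological coupling, no item-level factor structure beyond the two
subscale latents, no learning or fatigue within the math task, independent
(not state-dependent) dropout. Calibration results on this cohort therefore
validate the pipeline's statistics, not the stress induction itself.

## Statistical pipeline

The split-plot ANOVA (between factor group, within factor time) is computed
by pingouin — the same library the original analysis used — behind the
package's `mixed_anova` surface, with Mauchly's test and Greenhouse-Geisser
corrected dfs/p reported when the within factor has ≥3 levels (ε = 1 exactly
at 2 levels). Complete cases only: participants missing a time level are
removed listwise and reported under `exclusions`. Partial η² is recovered
as F·df1/(F·df1 + df2). A negligibly negative F from floating-point
cancellation in a null effect is clamped to 0.

Post hoc group comparisons use Welch's t (unequal n and variances) at every
time point, Bonferroni-adjusted with the family = the per-measure set of
time points. All tests are two-tailed at α = .05. Shapiro–Wilk and Levene
checks are advisory; the ANOVA proceeds regardless, as in the original
analysis (ANOVA is robust to the non-normality of bounded affect scores).

**Effect-size variants.** Published per-study values in this literature are
labelled d_z but numerically match the pooled pre/post-SD formula
(m₂ − m₁)/√((sd₁² + sd₂²)/2). Both variants are implemented, every
`EffectSize` records its variant, and summary-table reproduction defaults to
`pooled_prepost` because that is what reproduces the printed numbers; the
discrepancy is deliberate and documented, not silently "fixed" either way.
The two variants coincide exactly when pre/post SDs are equal and the
pre/post correlation is 0.5.

**Meta-analysis.** Weights are the inverse change-score variance 1/SD_Δ,i²
*without* a sample-size factor, applied to absolute per-study effects; both
readings are required to reproduce the published combined values (one
comparison study has a −0.01 mean change printed as a positive d). The
combined effect is then bounded by the smallest and largest |d| and
invariant to study order.

## Problem sizes and tolerances

Property checks run at: 10⁵ sampled problems for generator soundness
(against the exhaustive 99×99 enumeration oracle), 10⁴ staircase trials for
the 0.50 ± 0.03 equilibrium band, 500 replicates of n = 30 + 30 cohorts for
type-I calibration (0.05 ± 0.02), 100 replicates at the study's n = 103/181
for effect recovery (configured value inside the 95% CI in ≥90), and
relative tolerance 1e-8 for the 2×2 F = t² identity. Replicate-heavy checks
use the cohort generator's `affect_only` fast path (questionnaire data
without the event-level engine); single-cohort and replay checks run the
full engine.

## Known limitations

- The speech task models silence gaps as a Poisson process with exponential
  lengths; no acoustic content is represented.
- Dropout hazards are stage-independent Bernoulli draws; real cancellation
  is likely state-dependent (e.g. provoked by failure feedback).
- The element-rating questionnaire is generated as unstructured noise around
  a common mean; only the ranking operation itself is meaningfully tested
  (including against the published element means entered as degenerate
  single ratings).
- The I-PANAS-SF on-screen item wording/order in the deployed application is
  unpublished; the bundled item list uses the published instrument's item
  sets with a placeholder order (subscale membership is correct, which is
  all scoring needs).
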