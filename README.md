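# digistress

A simulatable implementation of a smartphone-delivered psychosocial
stress-induction protocol — the *digital stress test* — together with its
non-stressful control condition, affect-instrument scoring, and the complete
statistical evaluation pipeline used to assess its stress-induction
potential.

## The problem

Classic acute-stress paradigms (the Trier Social Stress Test and its
relatives) induce psychosocial stress through social-evaluative threat and
uncontrollability, but require a laboratory, experimenters, and actors, so
they do not scale. A fully digital variant replaces the human committee with
a time-pressured mental-arithmetic task plus a free-speech task in front of
the phone's front camera, wrapped in evaluative framing (a fabricated peer
comparison fixed at 75% correct, claimed algorithmic behaviour analysis).
This package provides:

- **`digistress.protocol`** — a deterministic, seeded state machine for the
  task logic. The math task is a transformed up-down staircase on the
  per-problem time limit: problems are addition, subtraction, multiplication
  or division of two integers in [1, 99] with integer solutions in [1, 99];
  three consecutive correct answers shorten the limit by 10% (and permute the
  number pad for the next 4 tasks), three consecutive failures lengthen it by
  10%, five consecutive no-input trials trigger a rescue (an easy addition
  problem plus motivational feedback), and the task stops after 90 s. With
  equal up/down run lengths the staircase balances where
  p³ = (1 − p)³, i.e. at 50% accuracy — guaranteed failure relative to the
  fabricated 75% benchmark. The control condition is addition-only with a
  5 s initial limit and an asymmetric staircase (lengthen after one failure,
  shorten only after four successes), no swap, no comparison, no camera.
- **`digistress.simulate`** — synthetic participants (solve-time and accuracy
  models, silence-gap speech behaviour, per-stage dropout hazards) and
  two-arm cohorts whose questionnaire data carry a configurable group × time
  affect structure.
- **`digistress.instruments`** — I-PANAS-SF scoring (10 Likert items, 5 per
  subscale, subscale score = item mean in [1, 5]) and VAS scoring (mark
  position relative to line length, 0–100), plus descriptive element
  ranking.
- **`digistress.stats`** — split-plot (mixed-design) ANOVA with
  Greenhouse-Geisser correction and partial η², Bonferroni-adjusted Welch
  post hocs, paired t tests, two standardized-mean-change variants of
  Cohen's *d* (`change_sd`, i.e. d_z = Δm / SD_Δ, and `pooled_prepost`,
  d = Δm / √((SD_pre² + SD_post²)/2)), and a two-step inverse-variance
  meta-analysis combining per-study effects with weights w_i = 1/SD_Δ,i².

## Worked example

Simulate a stress-condition math task for a median-skill participant:

```python
import numpy as np
from digistress import make_config, run_math_task
from digistress.simulate import SkillProfile, respond_math

cfg = make_config("stress")
skill = SkillProfile()
rng = np.random.default_rng(1)
log = run_math_task(cfg, lambda p, lim, kp, r: respond_math(skill, p, lim, kp, r), rng)
print(log.events[-1].payload)
```

```
{'task': 'math', 'percent_correct': 38.23529411764706, 'n_presented': 34,
 'n_correct': 13, 'final_time_limit_s': 3.5577630000000013, 'comparison_pct': 75.0}
```

The participant answered 34 problems in 90 s and lands at 38% correct —
well below the fabricated 75% comparison, as the staircase intends.

Simulate a full calibrated cohort at the study's sample sizes (103 stress /
181 control) and run the evaluation on the negative-affect subscale:

```python
from digistress.simulate import table2_default_spec, simulate_cohort
from digistress.stats import evaluate_study
from digistress.io import report_text

_, table = simulate_cohort(table2_default_spec(103, 181, seed=1), affect_only=True)
print(report_text(evaluate_study(table, measures=["panas_na"])))
```

```
== panas_na ==
  group        F(1,282) = 5.88, p = 0.01598, eta_p^2 = 0.020
  time         F(1,282) = 1.52, p = 0.2184, eta_p^2 = 0.005, GG eps=1.000
  interaction  F(1,282) = 23.06, p = 2.551e-06, eta_p^2 = 0.076, GG eps=1.000
  post hoc baseline     Welch t(222.6) = 0.30, p_bonf = 1
  post hoc post         Welch t(201.8) = -3.91, p_bonf = 0.0002506
  control: change -0.087 (SD 0.618), d_pooled = -0.140, d_z = -0.141
  stress: change +0.278 (SD 0.611), d_pooled = 0.439, d_z = 0.454
```

The stress arm's negative affect rises (standardized change ≈ 0.44) while
the control arm's does not; the group × time interaction is strongly
significant and the groups differ only after baseline — the signature of a
successful stress induction.

The same pipeline is scriptable from the shell:

```bash
digistress simulate --condition stress --n 50 --seed 7 --out runs/stress
digistress evaluate --input runs/questionnaires.csv --out runs/eval
digistress meta --subscale NA
```

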