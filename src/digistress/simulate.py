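"""Synthetic participants and cohorts for the protocol engine.

Real sessions of the web study were anonymous and never deposited, so every
downstream stage (scoring, ANOVA, effect sizes) is exercised against
simulated participants instead.  A participant bundles four behaviour
models:

* a :class:`SkillProfile` that answers arithmetic problems (log-normal solve
  times, accuracy attenuated by time pressure, motor penalty while the keypad
  is permuted, occasional no-input trials),
* a speech model emitting silence gaps during presentation windows,
* an :class:`AffectProfile` that generates PANAS/VAS questionnaire responses
  with a configurable group-by-time structure, and
* a :class:`DropoutModel` of independent per-stage quit hazards.

PANAS items are produced from participant-level latent subscale means through
a round-and-clip map onto the 1-5 Likert grid.  Rounding and the floor at 1
bias the observed mean upward, so the latent population mean is calibrated by
numerically inverting the exact expected-score function of the marginal
normal; configured subscale means are then recovered without bias.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .config import CONTROL, STRESS, ProtocolConfig, make_config
from .instruments import PANAS_ITEMS, VAS_SCALES, score_panas
from . import protocol
from .protocol import STAGES, ArithmeticProblem, KeypadLayout, SessionLog

# ---------------------------------------------------------------------------
# arithmetic behaviour


@dataclass(frozen=True)
class SkillProfile:
    """Behaviour model for the math task."""

    solve_time_median_s: dict = field(default_factory=lambda: {
        "add": 2.0, "sub": 2.6, "mul": 3.4, "div": 3.4})
    solve_time_log_sd: float = 0.4
    base_accuracy: float = 0.92
    time_pressure_slope: float = 3.0
    swap_penalty_s: float = 1.0
    no_input_p: float = 0.02
    silence_gap_rate_per_min: float = 2.0
    silence_gap_mean_s: float = 0.8

    def __post_init__(self) -> None:
        for p in (self.base_accuracy, self.no_input_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(t <= 0 for t in self.solve_time_median_s.values()):
            raise ValueError("solve times must be positive")


def respond_math(skill: SkillProfile, problem: ArithmeticProblem,
                 time_limit_s: float, keypad: KeypadLayout,
                 rng: np.random.Generator) -> tuple[int | None, float | None]:
    """Produce (typed_answer | None, latency_s | None) for one problem.

    The solve time is log-normal around the per-operation median, plus a
    motor penalty while the keypad is permuted.  The probability of a correct
    answer is the base accuracy attenuated by a logistic time-pressure factor
    in the limit/solve-time ratio, so P(correct | limit) is continuous and
    strictly increasing in the limit.
    """
    if rng.random() < skill.no_input_p:
        return None, None
    median = skill.solve_time_median_s.get(problem.op, 3.0)
    t = float(rng.lognormal(np.log(median), skill.solve_time_log_sd))
    if not keypad.is_identity:
        t += skill.swap_penalty_s
    pressure = 1.0 / (1.0 + np.exp(-skill.time_pressure_slope * (time_limit_s / t - 1.0)))
    p_correct = skill.base_accuracy * pressure
    if rng.random() < p_correct:
        typed = problem.solution
    else:
        delta = int(rng.integers(1, 10)) * (1 if rng.random() < 0.5 else -1)
        typed = max(0, problem.solution + delta)
        if typed == problem.solution:
            typed += 1
    return typed, t


def make_speaker(skill: SkillProfile):
    """Speech model: Poisson silence gaps with exponential lengths."""

    def speaker(scenario: int, present_s: float, rng: np.random.Generator):
        n = rng.poisson(skill.silence_gap_rate_per_min * present_s / 60.0)
        starts = np.sort(rng.uniform(0.0, present_s, size=n))
        lengths = rng.exponential(skill.silence_gap_mean_s, size=n)
        return [(float(s), float(min(l, present_s - s)))
                for s, l in zip(starts, lengths)]

    return speaker


# ---------------------------------------------------------------------------
# PANAS latent -> Likert calibration

_GRID_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def expected_likert_score(latent_mean, sd) -> np.ndarray:
    """Exact E[clip(round(X), 1, 5)] for X ~ N(latent_mean, sd^2).

    Follows from score = 1 + sum_{k=1..4} 1{X > k + 0.5}.
    """
    m = np.atleast_1d(np.asarray(latent_mean, dtype=float))
    e = 1.0 + sum(norm.sf((k + 0.5 - m) / sd) for k in range(1, 5))
    return e


def calibrated_latent_mean(target_mean, marginal_sd: float) -> np.ndarray:
    """Invert :func:`expected_likert_score` in its first argument.

    Returns the latent population mean whose rounded-and-clipped marginal has
    the requested observed mean.  Monotone, so inverted on a cached grid.
    """
    key = round(float(marginal_sd), 9)
    if key not in _GRID_CACHE:
        grid = np.linspace(-6.0, 12.0, 1801)
        _GRID_CACHE[key] = (expected_likert_score(grid, marginal_sd), grid)
    exp_grid, grid = _GRID_CACHE[key]
    target = np.clip(np.asarray(target_mean, dtype=float), exp_grid[0] + 1e-9,
                     exp_grid[-1] - 1e-9)
    return np.interp(target, exp_grid, grid)


def _likert_item_moments(mu, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and variance of clip(round(X), 1, 5) for X ~ N(mu, sd^2)."""
    mu = np.asarray(mu, dtype=float)
    edges = np.array([1.5, 2.5, 3.5, 4.5])
    cdf = norm.cdf((edges[:, None] - np.atleast_1d(mu)[None, :]) / sd)
    probs = np.vstack([cdf[0], np.diff(cdf, axis=0), 1.0 - cdf[-1]])
    k = np.arange(1, 6)[:, None]
    m = (k * probs).sum(axis=0)
    v = (k * k * probs).sum(axis=0) - m ** 2
    return m.reshape(np.shape(mu)), v.reshape(np.shape(mu))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()

_MOMENT_CACHE: dict[tuple, tuple[float, float, float, float]] = {}


def _solve_panas_latent_sds(baseline_mean: float, baseline_sd: float,
                            change_mean: float, change_sd: float,
                            item_sd: float, n_items: int = 5
                            ) -> tuple[float, float, float, float]:
    """Latent parameters whose discretized 5-item subscale means reproduce the
    configured observed moments.

    Returns (m_base, sigma_between, m_post, sigma_change_dev): the latent
    baseline population mean, between-subject SD, post population mean, and
    the SD of the independent change deviation.  The population means come
    from inverting the exact expected-score map; the SDs are solved by
    Gauss-Hermite quadrature over the exact conditional score moments, so the
    configured SDs are matched despite the compression of the 1..5 grid.
    """
    from scipy.optimize import brentq

    key = (round(baseline_mean, 6), round(baseline_sd, 6), round(change_mean, 6),
           round(change_sd, 6), round(item_sd, 6), n_items)
    if key in _MOMENT_CACHE:
        return _MOMENT_CACHE[key]

    def observed_baseline_var(sigma_b: float) -> float:
        m_star = float(calibrated_latent_mean(
            baseline_mean, float(np.hypot(sigma_b, item_sd))))
        mu = m_star + sigma_b * _GH_NODES
        g, v = _likert_item_moments(mu, item_sd)
        mean = float(np.dot(_GH_WEIGHTS, g))
        return float(np.dot(_GH_WEIGHTS, g ** 2 + v / n_items) - mean ** 2)

    hi = max(2.0 * baseline_sd, 0.5)
    try:
        sigma_b = float(brentq(lambda s: observed_baseline_var(s) - baseline_sd ** 2,
                               1e-4, hi))
    except ValueError:  # target SD outside the attainable range
        sigma_b = hi if observed_baseline_var(hi) < baseline_sd ** 2 else 1e-4
    m_base = float(calibrated_latent_mean(baseline_mean,
                                          float(np.hypot(sigma_b, item_sd))))

    u = sigma_b * _GH_NODES
    g_b, v_b = _likert_item_moments(m_base + u, item_sd)

    def observed_change_var(sigma_d: float) -> tuple[float, float]:
        marg = float(np.sqrt(sigma_b ** 2 + sigma_d ** 2 + item_sd ** 2))
        m_post = float(calibrated_latent_mean(baseline_mean + change_mean, marg))
        mu_p = m_post + u[:, None] + sigma_d * _GH_NODES[None, :]
        g_p, v_p = _likert_item_moments(mu_p.ravel(), item_sd)
        g_p = g_p.reshape(mu_p.shape)
        v_p = v_p.reshape(mu_p.shape)
        w2 = _GH_WEIGHTS[:, None] * _GH_WEIGHTS[None, :]
        diff = g_p - g_b[:, None]
        mean_change = float((w2 * diff).sum())
        var = float((w2 * (diff ** 2 + v_p / n_items)).sum()
                    + np.dot(_GH_WEIGHTS, v_b / n_items) - mean_change ** 2)
        return var, m_post

    hi_d = max(2.0 * change_sd, 0.5)
    try:
        sigma_d = float(brentq(
            lambda s: observed_change_var(s)[0] - change_sd ** 2, 1e-4, hi_d))
    except ValueError:
        sigma_d = hi_d if observed_change_var(hi_d)[0] < change_sd ** 2 else 1e-4
    m_post = observed_change_var(sigma_d)[1]
    _MOMENT_CACHE[key] = (m_base, sigma_b, m_post, sigma_d)
    return _MOMENT_CACHE[key]


@dataclass(frozen=True)
class PanasLatent:
    """Latent subscale means of one participant at one timepoint."""

    na: float
    pa: float
    item_sd: float = 0.55


def sample_panas_items(affect_state: PanasLatent, rng: np.random.Generator) -> list[int]:
    """Draw a 10-item I-PANAS-SF response (5 NA then 5 PA items, 1..5)."""
    raw = np.concatenate([
        rng.normal(affect_state.na, affect_state.item_sd, size=5),
        rng.normal(affect_state.pa, affect_state.item_sd, size=5),
    ])
    return [int(x) for x in np.clip(np.round(raw), 1, 5)]


# ---------------------------------------------------------------------------
# affect model


@dataclass(frozen=True)
class VasTrajectory:
    """Population VAS parameters for one scale in one arm (0-100 units)."""

    baseline_mean: float
    baseline_sd: float
    intermediate_change: float
    post_change: float
    change_sd: float


@dataclass(frozen=True)
class AffectProfile:
    """Population affect parameters for one study arm.

    PANAS parameters are on the observed 1-5 subscale-mean scale; the latent
    generator subtracts the item-noise and quantisation variance from the
    configured between-subject and change SDs (noise budgeting) so observed
    moments approximate the configured ones.
    """

    na_baseline_mean: float = 1.57
    na_baseline_sd: float = 0.56
    na_change_mean: float = 0.27
    na_change_sd: float = 0.61
    pa_baseline_mean: float = 3.08
    pa_baseline_sd: float = 0.65
    pa_change_mean: float = 0.29
    pa_change_sd: float = 0.61
    item_sd: float = 0.55
    vas: dict = field(default_factory=dict)  # scale -> VasTrajectory

    def sample_panas_latents(self, n: int, rng: np.random.Generator) -> dict:
        """Moment-matched latent subscale means for n participants at baseline
        and post: observed (discretized) subscale means reproduce the
        configured baseline/change means and SDs."""
        out = {}
        for sub in ("na", "pa"):
            m_base, sigma_b, m_post, sigma_d = _solve_panas_latent_sds(
                getattr(self, f"{sub}_baseline_mean"),
                getattr(self, f"{sub}_baseline_sd"),
                getattr(self, f"{sub}_change_mean"),
                getattr(self, f"{sub}_change_sd"),
                self.item_sd)
            u = rng.normal(0.0, sigma_b, size=n)
            dev = rng.normal(0.0, sigma_d, size=n)
            out[sub] = {"baseline": m_base + u, "post": m_post + u + dev}
        return out

    def sample_vas(self, n: int, rng: np.random.Generator) -> dict:
        """VAS values for n participants, per scale and timepoint, clipped to
        [0, 100]."""
        out = {}
        for scale in VAS_SCALES:
            traj = self.vas.get(scale, VasTrajectory(25.0, 20.0, 0.0, 0.0, 15.0))
            base = rng.normal(traj.baseline_mean, traj.baseline_sd, size=n)
            mid = base + rng.normal(traj.intermediate_change, traj.change_sd, size=n)
            post = base + rng.normal(traj.post_change, traj.change_sd, size=n)
            out[scale] = {"baseline": np.clip(base, 0, 100),
                          "intermediate": np.clip(mid, 0, 100),
                          "post": np.clip(post, 0, 100)}
        return out


# ---------------------------------------------------------------------------
# dropout


@dataclass(frozen=True)
class DropoutModel:
    """Independent Bernoulli quit hazards at the checkpoint before each stage."""

    hazards: dict = field(default_factory=lambda: {s: 0.0 for s in STAGES})

    def __post_init__(self) -> None:
        if any(not 0.0 <= h <= 1.0 for h in self.hazards.values()):
            raise ValueError("hazards must lie in [0, 1]")

    def hazard(self, stage: str) -> float:
        return self.hazards.get(stage, 0.0)

    def completion_probability(self) -> float:
        p = 1.0
        for s in STAGES:
            p *= 1.0 - self.hazard(s)
        return p


def hazards_from_completion(completion_frac: float, intro_hazard: float) -> DropoutModel:
    """Back-fit per-stage hazards to an overall completion fraction, given the
    intro-stage hazard; the residual dropout is split evenly (in survival
    terms) across the four later checkpoints."""
    rest = completion_frac / (1.0 - intro_hazard)
    if not 0.0 < rest <= 1.0:
        raise ValueError("completion fraction inconsistent with intro hazard")
    h_rest = 1.0 - rest ** 0.25
    hazards = {s: h_rest for s in STAGES}
    hazards["intro"] = intro_hazard
    return DropoutModel(hazards=hazards)


def default_dropout(condition: str) -> DropoutModel:
    """Hazards back-fitted to the study's printed completion fractions:
    112/300 completed the stress arm (89/300 quitting during the intro) and
    206/247 the control arm (early cancellation essentially absent)."""
    if condition == STRESS:
        return hazards_from_completion(112 / 300, 89 / 300)
    return hazards_from_completion(206 / 247, 0.02)


# ---------------------------------------------------------------------------
# participant bundle and cohort


class Participant:
    """Behaviour bundle consumed by :func:`digistress.protocol.run_session`."""

    def __init__(self, skill: SkillProfile, dropout: DropoutModel,
                 panas: dict, vas: dict, item_sd: float = 0.55,
                 prior_knowledge: bool = False, usability_issue: bool = False):
        self.skill = skill
        self.dropout = dropout
        self._panas = panas  # {"na": {"baseline": x, "post": y}, "pa": {...}}
        self._vas = vas      # {scale: {timepoint: value}}
        self._item_sd = item_sd
        self.prior_knowledge = prior_knowledge
        self.usability_issue = usability_issue
        self._speaker = make_speaker(skill)

    def responder(self, problem, time_limit_s, keypad, rng):
        return respond_math(self.skill, problem, time_limit_s, keypad, rng)

    def speaker(self, scenario, present_s, rng):
        return self._speaker(scenario, present_s, rng)

    def dropout_hazard(self, stage: str) -> float:
        return self.dropout.hazard(stage)

    def questionnaires(self, rng: np.random.Generator) -> dict:
        panas = {}
        for tp in ("baseline", "post"):
            latent = PanasLatent(na=self._panas["na"][tp], pa=self._panas["pa"][tp],
                                 item_sd=self._item_sd)
            panas[tp] = sample_panas_items(latent, rng)
        vas = {tp: {scale: float(self._vas[scale][tp]) for scale in VAS_SCALES}
               for tp in ("baseline", "intermediate", "post")}
        ratings = {el: float(np.clip(rng.normal(50.0, 25.0), 0, 100))
                   for el in ("framing", "math_overall", "time_limit",
                              "task_difficulty", "speech_overall")}
        return {"panas": panas, "vas": vas, "element_rating": ratings}


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm cohort specification (sizes, seed, behaviour parameters)."""

    n_stress: int
    n_control: int
    seed: int
    affect_stress: AffectProfile = field(default_factory=AffectProfile)
    affect_control: AffectProfile = field(default_factory=AffectProfile)
    skill: SkillProfile = field(default_factory=SkillProfile)
    dropout_stress: DropoutModel | None = None
    dropout_control: DropoutModel | None = None

    def __post_init__(self) -> None:
        if self.n_stress < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")


_TABLE_COLUMNS = ["participant", "group", "time", "measure", "value"]


def _arm_rows(arm: str, ids, panas_latents, vas_values, item_rngs) -> list:
    rows = []
    for i, pid in enumerate(ids):
        for tp in ("baseline", "post"):
            latent = PanasLatent(na=panas_latents["na"][tp][i],
                                 pa=panas_latents["pa"][tp][i])
            scores = score_panas(sample_panas_items(latent, item_rngs[i]))
            rows.append((pid, arm, tp, "panas_na", scores.na))
            rows.append((pid, arm, tp, "panas_pa", scores.pa))
        for scale in VAS_SCALES:
            for tp in ("baseline", "intermediate", "post"):
                rows.append((pid, arm, tp, f"vas_{scale}",
                             float(vas_values[scale][tp][i])))
    return rows


def simulate_cohort(spec: CohortSpec, affect_only: bool = False
                    ) -> tuple[list[SessionLog], pd.DataFrame]:
    """Simulate a two-arm cohort.

    Default mode runs the full event-level session per participant (so the
    questionnaire table contains completers only, as in the study analysis).
    ``affect_only`` skips the protocol engine and dropout and returns exactly
    the questionnaire table for ``n_stress + n_control`` completers — the
    fast path for replicate-heavy statistical calibration studies.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_stress, ss_control = root.spawn(2)
    logs: list[SessionLog] = []
    rows: list = []
    for arm, n, affect, ss in ((STRESS, spec.n_stress, spec.affect_stress, ss_stress),
                               (CONTROL, spec.n_control, spec.affect_control, ss_control)):
        if n == 0:
            continue
        arm_rng = np.random.default_rng(ss)
        panas = affect.sample_panas_latents(n, arm_rng)
        vas = affect.sample_vas(n, arm_rng)
        ids = [f"{arm[0]}{i:04d}" for i in range(n)]
        child_seeds = ss.spawn(n)
        if affect_only:
            item_rngs = [np.random.default_rng(cs) for cs in child_seeds]
            rows.extend(_arm_rows(arm, ids, panas, vas, item_rngs))
            continue
        config = make_config(arm)
        dropout = (spec.dropout_stress if arm == STRESS else spec.dropout_control)
        if dropout is None:
            dropout = DropoutModel()
        for i, pid in enumerate(ids):
            rng = np.random.default_rng(child_seeds[i])
            participant = Participant(
                skill=spec.skill, dropout=dropout,
                panas={sub: {tp: float(panas[sub][tp][i]) for tp in ("baseline", "post")}
                       for sub in ("na", "pa")},
                vas={scale: {tp: float(vas[scale][tp][i])
                             for tp in ("baseline", "intermediate", "post")}
                     for scale in VAS_SCALES},
                item_sd=affect.item_sd)
            log = protocol.run_session(config, participant, rng,
                                       participant_id=pid, seed=spec.seed)
            logs.append(log)
    if not affect_only:
        rows = _questionnaire_rows(logs)
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return logs, table


def _questionnaire_rows(logs) -> list:
    rows = []
    for log in logs:
        if not log.completed:
            continue
        pid = log.metadata.get("participant_id")
        arm = log.metadata.get("condition")
        for ev in log.events:
            if ev.type != "questionnaire":
                continue
            tp = ev.payload.get("timepoint")
            if ev.payload.get("instrument") == "panas":
                scores = score_panas(ev.payload["items"])
                rows.append((pid, arm, tp, "panas_na", scores.na))
                rows.append((pid, arm, tp, "panas_pa", scores.pa))
            elif ev.payload.get("instrument") == "vas":
                for scale, value in ev.payload["values"].items():
                    rows.append((pid, arm, tp, f"vas_{scale}", float(value)))
    return rows


def questionnaire_table(logs) -> pd.DataFrame:
    """Long questionnaire table (completers only) from session logs."""
    return pd.DataFrame(_questionnaire_rows(logs), columns=_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# exclusion bookkeeping


@dataclass(frozen=True)
class ExclusionFlags:
    incomplete: bool
    prior_knowledge: bool
    usability_issue: bool
    duration_outlier: bool

    @property
    def retained(self) -> bool:
        return not (self.incomplete or self.prior_knowledge
                    or self.usability_issue or self.duration_outlier)


def exclusion_flags(log: SessionLog, min_duration_s: float = 120.0,
                    max_duration_s: float = 1800.0) -> ExclusionFlags:
    """Flags mirroring the study's analysis-set filters: incomplete session,
    prior knowledge of the framing, self-reported usability issues, or an
    unrealistic total duration (bounds configurable; the study did not print
    its outlier threshold)."""
    complete = log.completed
    return ExclusionFlags(
        incomplete=not complete,
        prior_knowledge=bool(log.metadata.get("prior_knowledge", False)),
        usability_issue=bool(log.metadata.get("usability_issue", False)),
        duration_outlier=complete and not
        (min_duration_s <= log.duration_s <= max_duration_s),
    )


def retained_count(n_started: int, *excluded_counts: int) -> int:
    """Analyzable participants after subtracting disjoint exclusion counts."""
    n = n_started - sum(excluded_counts)
    if n < 0:
        raise ValueError("exclusions exceed started participants")
    return n


def completion_percent(n_completed: int, n_started: int) -> float:
    """Completion fraction as a percentage."""
    if n_started <= 0:
        raise ValueError("n_started must be positive")
    return 100.0 * n_completed / n_started


# ---------------------------------------------------------------------------
# bundled default cohort parameters


def _load_default_params() -> dict:
    ref = importlib.resources.files("digistress.data") / "cohort_table2_default.yaml"
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def _affect_from_dict(d: dict) -> AffectProfile:
    vas = {scale: VasTrajectory(**params) for scale, params in d.pop("vas", {}).items()}
    return AffectProfile(vas=vas, **d)


def table2_default_spec(n_stress: int = 103, n_control: int = 181,
                        seed: int = 0) -> CohortSpec:
    """Cohort specification calibrated to the study's printed summary
    statistics (PANAS group means/SDs and VAS marginal means)."""
    params = _load_default_params()
    return CohortSpec(
        n_stress=n_stress, n_control=n_control, seed=seed,
        affect_stress=_affect_from_dict(dict(params["affect_stress"])),
        affect_control=_affect_from_dict(dict(params["affect_control"])),
        dropout_stress=default_dropout(STRESS),
        dropout_control=default_dropout(CONTROL),
    )
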