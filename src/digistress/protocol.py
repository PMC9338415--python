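"""Deterministic, seeded state machine for the digital stress-test protocol.

The engine simulates one session end to end on a discrete-event clock (float
seconds from session start, no wall-clock dependence): framing, baseline
questionnaires, the adaptive math task, an intermediate questionnaire, the
speech task, post questionnaires, and an element-rating questionnaire.  Every
step is appended to an ordered :class:`SessionLog`, so a session is fully
replayable: identical (config, seed, behaviour parameters) produce an
identical log.

The math task is a transformed up-down staircase on the per-problem time
limit.  With equal up and down streak lengths (the stress condition uses
3/3) the staircase balances where p^3 = (1-p)^3, i.e. at 50% accuracy — the
induced-failure mechanism inherited from the MIST.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .config import CONTROL, STRESS, ProtocolConfig

SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ArithmeticProblem:
    """One arithmetic problem; operands and solution are integers in [1, 99]."""

    op: str
    operand_a: int
    operand_b: int
    solution: int
    rescue: bool = False


@dataclass(frozen=True)
class KeypadLayout:
    """Permutation of the ten digit keys; identity unless a swap is active."""

    mapping: tuple[int, ...] = tuple(range(10))

    def __post_init__(self) -> None:
        if sorted(self.mapping) != list(range(10)):
            raise ValueError("keypad mapping must be a permutation of 0..9")

    @property
    def is_identity(self) -> bool:
        return self.mapping == tuple(range(10))


IDENTITY_KEYPAD = KeypadLayout()


@dataclass(frozen=True)
class ResponseOutcome:
    """Classification of one trial.

    ``had_input`` records whether any keypress occurred; a late answer is a
    timeout for the accuracy staircase but still counts as input for the
    no-input rescue counter.
    """

    kind: str  # correct | wrong | timeout_no_input
    latency_s: float | None = None
    had_input: bool = False


@dataclass(frozen=True)
class MathTaskState:
    """Staircase controller state for the math task."""

    time_limit_s: float
    consecutive_correct: int = 0
    consecutive_wrong_or_timeout: int = 0
    consecutive_no_input: int = 0
    swap_remaining: int = 0
    rescue_pending: bool = False
    n_correct: int = 0
    n_presented: int = 0
    elapsed_s: float = 0.0


@dataclass(frozen=True)
class SessionEvent:
    t: float
    type: str
    payload: dict = field(default_factory=dict)


@dataclass
class SessionLog:
    """Ordered, timestamped record of one simulated session."""

    metadata: dict
    events: list[SessionEvent] = field(default_factory=list)

    def append(self, t: float, type: str, **payload) -> None:
        if self.events and t < self.events[-1].t:
            raise ValueError("events must be appended in time order")
        self.events.append(SessionEvent(t=float(t), type=type, payload=payload))

    def types(self) -> list[str]:
        return [e.type for e in self.events]

    def count(self, type: str) -> int:
        return sum(1 for e in self.events if e.type == type)

    @property
    def completed(self) -> bool:
        return any(e.type == "session_end" for e in self.events)

    @property
    def duration_s(self) -> float:
        return self.events[-1].t if self.events else 0.0


# ---------------------------------------------------------------------------
# problem generation

_PAIR_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _valid_pairs(op: str, operand_range: tuple[int, int],
                 solution_range: tuple[int, int]) -> np.ndarray:
    """All (a, b) pairs whose integer result falls in the solution range.

    Constructive enumeration (not rejection sampling) so the sampling
    distribution over valid pairs is exactly uniform.
    """
    key = (operand_range, solution_range)
    cache = _PAIR_CACHE.setdefault(key, {})
    if op not in cache:
        lo, hi = operand_range
        slo, shi = solution_range
        a = np.arange(lo, hi + 1)
        aa, bb = np.meshgrid(a, a, indexing="ij")
        if op == "add":
            sol = aa + bb
            ok = (sol >= slo) & (sol <= shi)
        elif op == "sub":
            sol = aa - bb
            ok = (sol >= slo) & (sol <= shi)
        elif op == "mul":
            sol = aa * bb
            ok = (sol >= slo) & (sol <= shi)
        elif op == "div":
            ok = (aa % bb == 0)
            sol = aa // bb
            ok &= (sol >= slo) & (sol <= shi)
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op!r}")
        pairs = np.stack([aa[ok], bb[ok], sol[ok]], axis=1)
        cache[op] = pairs
    return cache[op]


def valid_pair_count(op: str, operand_range=(1, 99), solution_range=(1, 99)) -> int:
    """Number of admissible operand pairs for one operation."""
    return len(_valid_pairs(op, operand_range, solution_range))


def generate_problem(rng: np.random.Generator, config: ProtocolConfig,
                     rescue: bool = False) -> ArithmeticProblem:
    """Draw a problem: operation uniform over allowed ops, then a uniform
    valid operand pair for that op.  Rescue problems are always addition."""
    op = "add" if rescue else str(rng.choice(list(config.allowed_ops)))
    pairs = _valid_pairs(op, config.operand_range, config.solution_range)
    a, b, sol = pairs[int(rng.integers(len(pairs)))]
    return ArithmeticProblem(op=op, operand_a=int(a), operand_b=int(b),
                             solution=int(sol), rescue=rescue)


# ---------------------------------------------------------------------------
# trial classification and staircase update


def classify_response(problem: ArithmeticProblem, typed_answer: int | None,
                      latency_s: float | None, time_limit_s: float) -> ResponseOutcome:
    """Classify one trial.

    No keypress, or an answer arriving at/after the limit, is a timeout; an
    in-time answer is correct iff it equals the solution.
    """
    if typed_answer is None:
        return ResponseOutcome(kind="timeout_no_input", had_input=False)
    if latency_s is None or latency_s < 0:
        raise ValueError("latency must be a non-negative number when an answer is given")
    if latency_s >= time_limit_s:
        return ResponseOutcome(kind="timeout_no_input", had_input=True)
    kind = "correct" if typed_answer == problem.solution else "wrong"
    return ResponseOutcome(kind=kind, latency_s=float(latency_s), had_input=True)


def apply_outcome(state: MathTaskState, outcome: ResponseOutcome,
                  config: ProtocolConfig) -> tuple[MathTaskState, list[str]]:
    """Advance the staircase by one classified trial.

    Returns the new state plus the adaptation events fired on this trial
    (subset of ``{"harder", "easier", "rescue"}``).  A success streak of
    ``harder_streak`` shortens the limit by ``adapt_factor`` (and, in the
    stress condition, arms the keypad swap for the next ``swap_task_count``
    tasks); a failure streak of ``easier_streak`` lengthens it; streak
    counters reset when their adjustment fires.  The limit is clamped to
    ``config.time_limit_bounds``.
    """
    events: list[str] = []
    correct = state.consecutive_correct
    wrong = state.consecutive_wrong_or_timeout
    no_input = state.consecutive_no_input
    limit = state.time_limit_s
    swap = state.swap_remaining
    rescue_pending = state.rescue_pending

    if outcome.kind == "correct":
        correct += 1
        wrong = 0
    else:
        wrong += 1
        correct = 0
    if outcome.had_input:
        no_input = 0
    else:
        no_input += 1

    if correct >= config.harder_streak:
        limit *= 1.0 - config.adapt_factor
        correct = 0
        if config.condition == STRESS:
            swap = config.swap_task_count
        events.append("harder")
    if wrong >= config.easier_streak:
        limit *= 1.0 + config.adapt_factor
        wrong = 0
        events.append("easier")
    if config.rescue_enabled and no_input >= config.rescue_no_input_streak:
        rescue_pending = True
        no_input = 0
        events.append("rescue")

    lo, hi = config.time_limit_bounds
    limit = min(max(limit, lo), hi)

    new = dataclasses.replace(
        state,
        time_limit_s=limit,
        consecutive_correct=correct,
        consecutive_wrong_or_timeout=wrong,
        consecutive_no_input=no_input,
        swap_remaining=swap,
        rescue_pending=rescue_pending,
        n_presented=state.n_presented + 1,
        n_correct=state.n_correct + (1 if outcome.kind == "correct" else 0),
    )
    return new, events


def next_keypad(state: MathTaskState, rng: np.random.Generator,
                config: ProtocolConfig) -> tuple[KeypadLayout, MathTaskState]:
    """Keypad for the next presented task.

    While ``swap_remaining`` > 0 (stress condition only) a fresh uniformly
    random non-identity permutation is drawn and the counter decremented;
    otherwise the identity layout is returned.
    """
    if config.condition == CONTROL or state.swap_remaining <= 0:
        return IDENTITY_KEYPAD, state
    while True:
        perm = tuple(int(x) for x in rng.permutation(10))
        if perm != tuple(range(10)):
            break
    return (KeypadLayout(mapping=perm),
            dataclasses.replace(state, swap_remaining=state.swap_remaining - 1))


def percent_correct(state: MathTaskState) -> float:
    """Live percent-correct display; 0 when nothing has been presented yet.
    Timeouts count in the denominator."""
    if state.n_presented == 0:
        return 0.0
    return 100.0 * state.n_correct / state.n_presented


# ---------------------------------------------------------------------------
# task runners

#: responder(problem, time_limit_s, keypad, rng) -> (typed_answer | None, latency_s | None)
Responder = Callable[[ArithmeticProblem, float, KeypadLayout, np.random.Generator],
                     tuple[int | None, float | None]]

#: speaker(scenario_index, present_s, rng) -> iterable of (gap_start_s, gap_length_s)
Speaker = Callable[[int, float, np.random.Generator],
                   Iterable[tuple[float, float]]]

_EVENT_CAP = 100_000


def run_math_task(config: ProtocolConfig, responder: Responder,
                  rng: np.random.Generator, log: SessionLog | None = None,
                  t0: float = 0.0, max_problems: int | None = None) -> SessionLog:
    """Run the adaptive math task until the task clock reaches
    ``config.math_duration_s`` (or ``max_problems`` problems, if given).

    The problem in flight when the cap strikes is truncated without an
    outcome and excluded from the presented count.
    """
    if log is None:
        log = SessionLog(metadata={"condition": config.condition})
    state = MathTaskState(time_limit_s=config.initial_time_limit_s)
    log.append(t0, "task_start", task="math")
    deadline = t0 + config.math_duration_s
    t = t0
    n_events = 0
    while t < deadline:
        n_events += 1
        if n_events > _EVENT_CAP:
            raise RuntimeError("math task exceeded event cap")
        if max_problems is not None and state.n_presented >= max_problems:
            break
        rescue = state.rescue_pending
        if rescue:
            state = dataclasses.replace(state, rescue_pending=False)
        keypad, state = next_keypad(state, rng, config)
        problem = generate_problem(rng, config, rescue=rescue)
        if not keypad.is_identity:
            log.append(t, "keypad_set", mapping=list(keypad.mapping))
        log.append(t, "problem_presented", op=problem.op, a=problem.operand_a,
                   b=problem.operand_b, rescue=problem.rescue,
                   time_limit_s=state.time_limit_s)
        typed, latency = responder(problem, state.time_limit_s, keypad, rng)
        consumed = state.time_limit_s
        if typed is not None and latency is not None and latency < state.time_limit_s:
            consumed = latency
        t_done = t + consumed
        if t_done > deadline:
            # cutoff mid-problem: truncate without outcome
            break
        outcome = classify_response(problem, typed, latency, state.time_limit_s)
        log.append(t_done, "response", kind=outcome.kind,
                   latency_s=outcome.latency_s, had_input=outcome.had_input,
                   typed=typed)
        feedback = {"correct": "ok", "wrong": "Wrong answer!",
                    "timeout_no_input": "Too slow!"}[outcome.kind]
        log.append(t_done, "feedback", message=feedback)
        prev_limit = state.time_limit_s
        state, fired = apply_outcome(state, outcome, config)
        for ev in fired:
            if ev == "rescue":
                log.append(t_done, "rescue_triggered", message="relevance feedback")
            else:
                log.append(t_done, "adaptation", direction=ev,
                           time_limit_s=state.time_limit_s,
                           previous_limit_s=prev_limit)
        t = t_done
    end_t = min(t, deadline) if max_problems is not None else deadline
    payload = {"task": "math", "percent_correct": percent_correct(state),
               "n_presented": state.n_presented, "n_correct": state.n_correct,
               "final_time_limit_s": state.time_limit_s}
    if config.comparison_pct is not None:
        payload["comparison_pct"] = config.comparison_pct
    log.append(end_t, "task_end", **payload)
    log.metadata.setdefault("math_final_state", payload)
    return log


def run_speech_task(config: ProtocolConfig, speaker: Speaker,
                    rng: np.random.Generator, log: SessionLog | None = None,
                    t0: float = 0.0) -> SessionLog:
    """Run the speech task: ``n_speech_scenarios`` scenarios, each with a
    preparation and a presentation window; one silence reminder per maximal
    silence gap of at least ``silence_reminder_s`` during presentation."""
    if log is None:
        log = SessionLog(metadata={"condition": config.condition})
    t = t0
    log.append(t, "task_start", task="speech")
    for i in range(config.n_speech_scenarios):
        log.append(t, "scenario_start", scenario=i,
                   prompt=config.speech_scenarios[i],
                   prep_s=config.prep_s, present_s=config.present_s)
        t += config.prep_s
        present_start = t
        gaps = sorted(speaker(i, config.present_s, rng))
        for gap_start, gap_len in gaps:
            if gap_len >= config.silence_reminder_s:
                log.append(present_start + gap_start + config.silence_reminder_s,
                           "silence_reminder", scenario=i, gap_length_s=gap_len)
        t = present_start + config.present_s
    log.append(t, "task_end", task="speech",
               duration_s=t - t0,
               n_scenarios=config.n_speech_scenarios)
    return log


# session stages, in checkpoint order (dropout is tested before each)
STAGES = ("intro", "math", "intermediate", "speech", "post")

_QUESTIONNAIRE_S = 30.0  # nominal time per questionnaire block
_FRAMING_S = 60.0  # nominal time reading the framing / introduction


def run_session(config: ProtocolConfig, participant, rng: np.random.Generator,
                participant_id: str = "p0", seed: int | None = None) -> SessionLog:
    """Simulate one full session for a participant behaviour bundle.

    ``participant`` must provide ``responder``, ``speaker``,
    ``dropout_hazard(stage) -> float`` and ``questionnaires(rng) -> dict``
    (the latter mapping timepoints to PANAS item lists and VAS values; see
    :mod:`digistress.simulate`).  A completed session contains exactly 2
    PANAS and 3 VAS questionnaire events.
    """
    log = SessionLog(metadata={
        "schema_version": SCHEMA_VERSION,
        "participant_id": participant_id,
        "condition": config.condition,
        "seed": seed,
        "config": {"condition": config.condition,
                   "initial_time_limit_s": config.initial_time_limit_s,
                   "math_duration_s": config.math_duration_s},
        "prior_knowledge": bool(getattr(participant, "prior_knowledge", False)),
        "usability_issue": bool(getattr(participant, "usability_issue", False)),
    })
    q = participant.questionnaires(rng)
    t = 0.0
    log.append(t, "session_start")

    def drops(stage: str) -> bool:
        return rng.random() < participant.dropout_hazard(stage)

    if drops("intro"):
        log.append(t, "framing_shown", comparison_pct=config.comparison_pct)
        log.append(t, "dropout", stage="intro")
        return log
    log.append(t, "framing_shown", comparison_pct=config.comparison_pct)
    t += _FRAMING_S
    log.append(t, "questionnaire", instrument="panas", timepoint="baseline",
               items=q["panas"]["baseline"])
    log.append(t, "questionnaire", instrument="vas", timepoint="baseline",
               values=q["vas"]["baseline"])
    t += _QUESTIONNAIRE_S

    if drops("math"):
        log.append(t, "dropout", stage="math")
        return log
    run_math_task(config, participant.responder, rng, log=log, t0=t)
    t = log.events[-1].t

    if drops("intermediate"):
        log.append(t, "dropout", stage="intermediate")
        return log
    log.append(t, "questionnaire", instrument="vas", timepoint="intermediate",
               values=q["vas"]["intermediate"])
    t += _QUESTIONNAIRE_S

    if drops("speech"):
        log.append(t, "dropout", stage="speech")
        return log
    run_speech_task(config, participant.speaker, rng, log=log, t0=t)
    t = log.events[-1].t

    if drops("post"):
        log.append(t, "dropout", stage="post")
        return log
    log.append(t, "questionnaire", instrument="panas", timepoint="post",
               items=q["panas"]["post"])
    log.append(t, "questionnaire", instrument="vas", timepoint="post",
               values=q["vas"]["post"])
    t += _QUESTIONNAIRE_S
    log.append(t, "questionnaire", instrument="element_rating",
               timepoint="post", values=q.get("element_rating", {}))
    t += _QUESTIONNAIRE_S
    log.append(t, "session_end")
    return log
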