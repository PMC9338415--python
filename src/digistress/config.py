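"""Protocol configuration for the stress and control conditions.

The digital stress test (DST) is a smartphone-delivered cognitive-verbal
protocol in the TSST/MIST family: a time-pressured mental-arithmetic task
driven by a transformed up-down staircase on the per-problem time limit,
followed by a free-speech task, wrapped in social-evaluative framing (camera,
fabricated peer comparison).  The control condition (C-DST) keeps the overall
structure but removes the stressors and biases the staircase toward success.

All timing and adaptation constants of one condition live in
:class:`ProtocolConfig`; :func:`make_config` returns the two published
constant sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

STRESS = "stress"
CONTROL = "control"

ALL_OPS = ("add", "sub", "mul", "div")

#: Inconvenient job-interview style prompts used in the stress condition and
#: neutral prompts used in the control condition.
STRESS_SCENARIOS = (
    "Describe a situation when you've been criticized by someone!",
    "Describe a personal weakness and how it has affected your work!",
    "Describe a situation in which you failed to reach a goal!",
)
CONTROL_SCENARIOS = (
    "Which season do you like best? Please describe any activities you "
    "enjoy doing during this time of the year!",
    "What is your favourite meal? Please describe how it is prepared!",
    "Describe a place you like to visit and what you enjoy doing there!",
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Constants of one protocol condition.

    Durations are in seconds; ``adapt_factor`` is the fractional step of the
    time-limit staircase (0.10 means -10% after a success streak and +10%
    after a failure streak); ``comparison_pct`` is the fabricated cohort
    average displayed during the math task (``None`` when no comparison is
    shown, i.e. in the control condition).
    """

    condition: str
    math_duration_s: float = 90.0
    initial_time_limit_s: float = 3.0
    adapt_factor: float = 0.10
    harder_streak: int = 3
    easier_streak: int = 3
    swap_task_count: int = 4
    rescue_enabled: bool = True
    rescue_no_input_streak: int = 5
    comparison_pct: float | None = 75.0
    allowed_ops: tuple[str, ...] = ALL_OPS
    operand_range: tuple[int, int] = (1, 99)
    solution_range: tuple[int, int] = (1, 99)
    n_speech_scenarios: int = 3
    prep_s: float = 10.0
    present_s: float = 20.0
    silence_reminder_s: float = 1.0
    time_limit_bounds: tuple[float, float] = (0.5, 30.0)
    speech_scenarios: tuple[str, ...] = STRESS_SCENARIOS

    def __post_init__(self) -> None:
        if self.condition not in (STRESS, CONTROL):
            raise ValueError(f"unknown condition: {self.condition!r}")
        for name in ("math_duration_s", "initial_time_limit_s", "prep_s",
                     "present_s", "silence_reminder_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.adapt_factor < 1.0:
            raise ValueError("adapt_factor must lie in (0, 1)")
        for name in ("harder_streak", "easier_streak"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.swap_task_count < 0:
            raise ValueError("swap_task_count must be >= 0")
        if self.rescue_enabled and self.rescue_no_input_streak < 1:
            raise ValueError("rescue_no_input_streak must be >= 1")
        if not self.allowed_ops or any(op not in ALL_OPS for op in self.allowed_ops):
            raise ValueError(f"allowed_ops must be a non-empty subset of {ALL_OPS}")
        lo, hi = self.time_limit_bounds
        if not lo <= self.initial_time_limit_s <= hi:
            raise ValueError("time_limit_bounds must contain initial_time_limit_s")
        if self.condition == CONTROL and self.swap_task_count != 0:
            raise ValueError("control condition never swaps the keypad")
        if len(self.speech_scenarios) < self.n_speech_scenarios:
            raise ValueError("not enough speech scenarios configured")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["allowed_ops"] = list(self.allowed_ops)
        d["speech_scenarios"] = list(self.speech_scenarios)
        d["operand_range"] = list(self.operand_range)
        d["solution_range"] = list(self.solution_range)
        d["time_limit_bounds"] = list(self.time_limit_bounds)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolConfig":
        d = yaml.safe_load(text)
        for key in ("allowed_ops", "speech_scenarios", "operand_range",
                    "solution_range", "time_limit_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def make_config(condition: str) -> ProtocolConfig:
    """Return the published constant set for ``stress`` or ``control``.

    Stress: 3 s initial limit, -10% after 3 consecutive correct answers (with
    the keypad permuted for the following 4 tasks), +10% after 3 consecutive
    wrong/timed-out answers, a rescue addition problem after 5 consecutive
    no-input tasks, a fabricated 75% comparison, all four operations, 90 s cap.

    Control: addition only, 5 s initial limit, +10% after a single failure,
    -10% only after 4 consecutive correct answers, no swap, no comparison,
    no rescue.
    """
    if condition == STRESS:
        return ProtocolConfig(condition=STRESS)
    if condition == CONTROL:
        return ProtocolConfig(
            condition=CONTROL,
            initial_time_limit_s=5.0,
            harder_streak=4,
            easier_streak=1,
            swap_task_count=0,
            rescue_enabled=False,
            comparison_pct=None,
            allowed_ops=("add",),
            speech_scenarios=CONTROL_SCENARIOS,
        )
    raise ValueError(f"unknown condition: {condition!r}")
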