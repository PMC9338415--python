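"""Engine-level behaviour: problem generation, staircase, keypad, tasks."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from digistress.config import CONTROL, STRESS, ProtocolConfig, make_config
from digistress.protocol import (IDENTITY_KEYPAD, MathTaskState,
                                 ResponseOutcome, SessionLog, apply_outcome,
                                 classify_response, generate_problem,
                                 next_keypad, percent_correct, run_math_task,
                                 run_session, run_speech_task,
                                 valid_pair_count)
from digistress.io import session_log_to_jsonl

OPS = {"add": lambda a, b: a + b, "sub": lambda a, b: a - b,
       "mul": lambda a, b: a * b, "div": lambda a, b: a / b}


def brute_force_pair_count(op):
    """Independent oracle: exhaustive double loop over operands 1..99."""
    n = 0
    for a in range(1, 100):
        for b in range(1, 100):
            s = OPS[op](a, b)
            if s == int(s) and 1 <= s <= 99:
                n += 1
    return n


# ---------------------------------------------------------------------------
# configs


@pytest.mark.parametrize("condition,expected", [
    (STRESS, dict(initial_time_limit_s=3.0, harder_streak=3, easier_streak=3,
                  swap_task_count=4, rescue_no_input_streak=5,
                  comparison_pct=75.0, math_duration_s=90.0,
                  allowed_ops=("add", "sub", "mul", "div"))),
    (CONTROL, dict(initial_time_limit_s=5.0, harder_streak=4, easier_streak=1,
                   swap_task_count=0, comparison_pct=None,
                   allowed_ops=("add",))),
])
def test_make_config_constants(condition, expected):
    cfg = make_config(condition)
    for key, value in expected.items():
        assert getattr(cfg, key) == value
    assert cfg.adapt_factor == 0.10
    assert cfg.n_speech_scenarios == 3
    assert cfg.prep_s == 10.0 and cfg.present_s == 20.0
    assert cfg.silence_reminder_s == 1.0


def test_make_config_rejects_unknown_condition():
    with pytest.raises(ValueError):
        make_config("placebo")


def test_config_yaml_round_trip():
    cfg = make_config(CONTROL)
    assert ProtocolConfig.from_yaml(cfg.to_yaml()) == cfg


# ---------------------------------------------------------------------------
# problem generation


@pytest.mark.parametrize("op", ["add", "sub", "mul", "div"])
def test_valid_pair_counts_match_exhaustive_oracle(op):
    assert valid_pair_count(op) == brute_force_pair_count(op)


def test_generated_problems_satisfy_invariants(rng):
    cfg = make_config(STRESS)
    for _ in range(5000):
        p = generate_problem(rng, cfg)
        assert p.op in cfg.allowed_ops
        assert 1 <= p.operand_a <= 99 and 1 <= p.operand_b <= 99
        assert 1 <= p.solution <= 99
        assert p.solution == int(OPS[p.op](p.operand_a, p.operand_b))


def test_control_generates_addition_only(rng):
    cfg = make_config(CONTROL)
    assert {generate_problem(rng, cfg).op for _ in range(200)} == {"add"}


def test_rescue_problem_is_always_addition(rng):
    cfg = make_config(STRESS)
    for _ in range(50):
        p = generate_problem(rng, cfg, rescue=True)
        assert p.op == "add" and p.rescue


# ---------------------------------------------------------------------------
# classification


def test_classify_response_cases():
    p = generate_problem(np.random.default_rng(0), make_config(STRESS))
    correct = classify_response(p, p.solution, 1.2, 3.0)
    assert correct.kind == "correct" and correct.had_input
    wrong = classify_response(p, p.solution + 1, 1.2, 3.0)
    assert wrong.kind == "wrong"
    silent = classify_response(p, None, None, 3.0)
    assert silent.kind == "timeout_no_input" and not silent.had_input
    late = classify_response(p, p.solution, 3.5, 3.0)
    assert late.kind == "timeout_no_input" and late.had_input
    with pytest.raises(ValueError):
        classify_response(p, p.solution, -0.1, 3.0)


# ---------------------------------------------------------------------------
# staircase updates


CORRECT = ResponseOutcome(kind="correct", latency_s=1.0, had_input=True)
WRONG = ResponseOutcome(kind="wrong", latency_s=1.0, had_input=True)
SILENT = ResponseOutcome(kind="timeout_no_input", had_input=False)


def drive(config, outcomes, state=None):
    if state is None:
        state = MathTaskState(time_limit_s=config.initial_time_limit_s)
    fired = []
    for out in outcomes:
        state, events = apply_outcome(state, out, config)
        fired.extend(events)
    return state, fired


def test_three_correct_shorten_limit_and_arm_swap_in_stress():
    cfg = make_config(STRESS)
    state, fired = drive(cfg, [CORRECT] * 3)
    assert state.time_limit_s == pytest.approx(2.7)
    assert state.swap_remaining == 4
    assert state.consecutive_correct == 0
    assert fired == ["harder"]


def test_three_failures_extend_limit_in_stress():
    cfg = make_config(STRESS)
    for outcomes in ([WRONG] * 3, [SILENT] * 3, [WRONG, SILENT, WRONG]):
        state, _ = drive(cfg, outcomes)
        assert state.time_limit_s == pytest.approx(3.3)


def test_single_failure_extends_limit_in_control():
    cfg = make_config(CONTROL)
    state, _ = drive(cfg, [WRONG])
    assert state.time_limit_s == pytest.approx(5.5)
    state, _ = drive(cfg, [CORRECT] * 4)
    assert state.time_limit_s == pytest.approx(4.5)
    assert state.swap_remaining == 0


def test_rescue_fires_after_five_silent_trials():
    cfg = make_config(STRESS)
    state, fired = drive(cfg, [SILENT] * 5)
    assert state.rescue_pending
    assert state.consecutive_no_input == 0
    assert "rescue" in fired


def test_wrong_answer_resets_no_input_counter():
    cfg = make_config(STRESS)
    state, fired = drive(cfg, [SILENT] * 4 + [WRONG] + [SILENT] * 4)
    assert not state.rescue_pending and "rescue" not in fired


def test_no_rescue_in_control():
    cfg = make_config(CONTROL)
    state, fired = drive(cfg, [SILENT] * 12)
    assert not state.rescue_pending and "rescue" not in fired


def test_time_limit_clamped_to_bounds():
    cfg = dataclasses.replace(make_config(STRESS), time_limit_bounds=(2.9, 3.2))
    state, _ = drive(cfg, [CORRECT] * 3)
    assert state.time_limit_s == 2.9
    state, _ = drive(cfg, [WRONG] * 3)
    assert state.time_limit_s == 3.2


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.sampled_from(["h", "e"]), max_size=12))
def test_time_limit_path_independence(pattern):
    """a shorten and b lengthen adjustments commute: limit = 3*0.9^a*1.1^b."""
    cfg = dataclasses.replace(make_config(STRESS), time_limit_bounds=(1e-6, 1e6))
    outcomes = []
    for step in pattern:
        outcomes.extend([CORRECT] * 3 if step == "h" else [WRONG] * 3)
    state, _ = drive(cfg, outcomes)
    a, b = pattern.count("h"), pattern.count("e")
    assert state.time_limit_s == pytest.approx(3.0 * 0.9 ** a * 1.1 ** b, rel=1e-9)


def test_control_limit_decreases_only_after_four_correct(rng):
    cfg = dataclasses.replace(make_config(CONTROL), time_limit_bounds=(1e-3, 1e3))
    state = MathTaskState(time_limit_s=cfg.initial_time_limit_s)
    for _ in range(500):
        out = CORRECT if rng.random() < 0.7 else WRONG
        prev_correct = state.consecutive_correct
        prev_limit = state.time_limit_s
        state, _ = apply_outcome(state, out, cfg)
        if state.time_limit_s < prev_limit:
            assert out.kind == "correct" and prev_correct == cfg.harder_streak - 1


# ---------------------------------------------------------------------------
# keypad


def test_keypad_identity_without_swap(rng):
    cfg = make_config(STRESS)
    state = MathTaskState(time_limit_s=3.0, swap_remaining=0)
    layout, state2 = next_keypad(state, rng, cfg)
    assert layout.is_identity and state2 is state


def test_keypad_swaps_then_reverts(rng):
    cfg = make_config(STRESS)
    state = MathTaskState(time_limit_s=3.0, swap_remaining=4)
    for expected_remaining in (3, 2, 1, 0):
        layout, state = next_keypad(state, rng, cfg)
        assert not layout.is_identity
        assert sorted(layout.mapping) == list(range(10))
        assert state.swap_remaining == expected_remaining
    layout, _ = next_keypad(state, rng, cfg)
    assert layout.is_identity


def test_keypad_always_identity_in_control(rng):
    cfg = make_config(CONTROL)
    state = MathTaskState(time_limit_s=5.0, swap_remaining=0)
    assert next_keypad(state, rng, cfg)[0].is_identity


# ---------------------------------------------------------------------------
# percent correct


def test_percent_correct_convention():
    assert percent_correct(MathTaskState(3.0, n_correct=3, n_presented=4)) == 75.0
    assert percent_correct(MathTaskState(3.0)) == 0.0
    assert percent_correct(MathTaskState(3.0, n_correct=0, n_presented=5)) == 0.0


# ---------------------------------------------------------------------------
# task runners


def instant_correct_responder(problem, limit, keypad, rng):
    return problem.solution, 0.0


def silent_responder(problem, limit, keypad, rng):
    return None, None


def test_staircase_follows_closed_form_for_perfect_responder(rng):
    cfg = dataclasses.replace(make_config(STRESS), time_limit_bounds=(1e-6, 1e6))
    k = 8
    log = run_math_task(cfg, instant_correct_responder, rng, max_problems=3 * k)
    final = log.events[-1].payload
    assert final["n_presented"] == 3 * k
    assert final["final_time_limit_s"] == pytest.approx(3.0 * 0.9 ** k, rel=1e-9)
    assert final["percent_correct"] == 100.0


def test_first_rescue_after_exactly_five_silent_problems(rng):
    cfg = make_config(STRESS)
    log = run_math_task(cfg, silent_responder, rng)
    types = log.types()
    first_rescue = types.index("rescue_triggered")
    presented_before = types[:first_rescue].count("problem_presented")
    assert presented_before == 5
    # the problem after a rescue trigger is an easy addition problem
    after = [e for e in log.events[first_rescue:] if e.type == "problem_presented"]
    assert after[0].payload["rescue"] and after[0].payload["op"] == "add"


def test_math_task_stops_at_duration_and_truncates_problem_in_flight(rng):
    cfg = make_config(STRESS)

    def slowish(problem, limit, keypad, rng):
        return problem.solution, limit * 0.9

    log = run_math_task(cfg, slowish, rng)
    assert log.events[-1].type == "task_end"
    assert log.events[-1].t == pytest.approx(90.0)
    n_presented = log.count("problem_presented")
    n_responses = log.count("response")
    assert n_presented - n_responses in (0, 1)  # at most the truncated one
    assert log.events[-1].payload["n_presented"] == n_responses


def test_math_task_replay_is_byte_identical():
    cfg = make_config(STRESS)

    def noisy(problem, limit, keypad, rng):
        if rng.random() < 0.1:
            return None, None
        typed = problem.solution if rng.random() < 0.6 else problem.solution + 1
        return typed, float(rng.uniform(0.2, limit * 1.1))

    logs = [run_math_task(cfg, noisy, np.random.default_rng(77)) for _ in range(2)]
    assert session_log_to_jsonl(logs[0]) == session_log_to_jsonl(logs[1])


def test_speech_task_timing_and_reminders(rng):
    cfg = make_config(STRESS)

    def one_gap(scenario, present_s, rng):
        return [(5.0, 1.2)] if scenario == 0 else []

    log = run_speech_task(cfg, one_gap, rng)
    assert log.count("scenario_start") == 3
    assert log.events[-1].payload["duration_s"] == pytest.approx(3 * (10 + 20))
    assert log.count("silence_reminder") == 1

    def short_gaps(scenario, present_s, rng):
        return [(2.0, 0.5), (9.0, 0.99)]

    log2 = run_speech_task(cfg, short_gaps, rng)
    assert log2.count("silence_reminder") == 0


# ---------------------------------------------------------------------------
# full sessions


class StubParticipant:
    prior_knowledge = False
    usability_issue = False

    def __init__(self, hazards=None):
        self.hazards = hazards or {}

    def responder(self, problem, limit, keypad, rng):
        return problem.solution, 1.0

    def speaker(self, scenario, present_s, rng):
        return []

    def dropout_hazard(self, stage):
        return self.hazards.get(stage, 0.0)

    def questionnaires(self, rng):
        return {"panas": {tp: [1] * 10 for tp in ("baseline", "post")},
                "vas": {tp: {s: 0.0 for s in ("stressed", "frustrated",
                                              "overstrained", "ashamed")}
                        for tp in ("baseline", "intermediate", "post")}}


def test_completed_session_has_two_panas_and_three_vas(rng):
    log = run_session(make_config(STRESS), StubParticipant(), rng)
    assert log.completed
    q = [e.payload for e in log.events if e.type == "questionnaire"]
    assert sum(p.get("instrument") == "panas" for p in q) == 2
    assert sum(p.get("instrument") == "vas" for p in q) == 3


def test_certain_intro_dropout_truncates_log(rng):
    log = run_session(make_config(STRESS), StubParticipant({"intro": 1.0}), rng)
    assert log.types() == ["session_start", "framing_shown", "dropout"]
    assert not log.completed


def test_control_session_emits_no_swap_rescue_or_comparison(rng):
    log = run_session(make_config(CONTROL), StubParticipant(), rng)
    types = set(log.types())
    assert "keypad_set" not in types and "rescue_triggered" not in types
    framing = next(e for e in log.events if e.type == "framing_shown")
    assert framing.payload["comparison_pct"] is None
    end = next(e for e in log.events
               if e.type == "task_end" and e.payload.get("task") == "math")
    assert "comparison_pct" not in end.payload
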