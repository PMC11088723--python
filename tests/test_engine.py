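"""Scoring engine: accumulation, stop semantics, additive total."""

import pytest
from hypothesis import given, settings, strategies as st

from branchsim.engine import (
    PlayStatus,
    choose,
    play_path,
    score_report,
    start,
    total_score,
)
from branchsim.errors import (
    InvalidScenarioError,
    PlayStateError,
    UnknownOptionError,
)
from branchsim.generate import ScenarioGenSpec, generate_scenario
from branchsim.scenario import (
    DecisionBlock,
    DecisionNode,
    NodeKind,
    Option,
    Scenario,
    TerminalStatus,
)
from conftest import linear_scenario, single_node_scenario


def test_start_state_is_clean(reference):
    state = start(reference)
    assert state.status == PlayStatus.ACTIVE
    assert state.current == reference.start
    assert state.log == ()
    assert set(state.block_sums) == set(DecisionBlock)
    assert len(state.block_sums) == 11
    assert total_score(state) == 0


def test_start_refuses_invalid_scenario():
    # Category-I option routed to a *finished* terminal: a blocking violation.
    root = DecisionNode(
        node_id="root", prompt="p", kind=NodeKind.DECISION,
        options=(Option(option_id="die", category="I",
                        block=DecisionBlock.T, target="fin"),),
    )
    fin = DecisionNode(node_id="fin", kind=NodeKind.TERMINAL,
                       terminal_status=TerminalStatus.FINISHED)
    bad = Scenario(scenario_id="bad", start="root", nodes=(root, fin))
    with pytest.raises(InvalidScenarioError) as exc:
        start(bad)
    assert any(v.code == "V1" for v in exc.value.violations)


def test_hand_summed_three_step_path():
    """C' then E then F' scores 1 - 3 + 4 = 2."""
    s = linear_scenario(["C'", "E", "F'"])
    state = play_path(s, ["n0_o", "n1_o", "n2_o"])
    assert state.status == PlayStatus.FINISHED
    assert total_score(state) == 2
    assert [step.points for step in state.log] == [1, -3, 4]


def test_zero_point_steps_leave_total_unchanged():
    s = linear_scenario(["A'", "B'"])
    state = play_path(s, ["n0_o", "n1_o"])
    assert total_score(state) == 0
    assert all(v == 0 for v in state.block_sums.values())


def test_category_i_stops_with_minus_ten():
    s = single_node_scenario(["I", "C'"])
    state = choose(start(s), "o0")
    assert state.status == PlayStatus.STOPPED
    assert state.log[-1].points == -10
    assert total_score(state) == -10
    with pytest.raises(PlayStateError):
        choose(state, "o1")  # no step may follow a STOP


def test_choose_is_functional_and_validates_option():
    s = single_node_scenario(["C'", "D"])
    s0 = start(s)
    s1 = choose(s0, "o0")
    assert total_score(s0) == 0  # original state untouched
    assert total_score(s1) == 1
    with pytest.raises(UnknownOptionError):
        choose(s0, "nope")


def test_block_sums_follow_option_blocks():
    s = linear_scenario(
        ["E'", "F'", "H"],
        blocks=[DecisionBlock.LT, DecisionBlock.MD, DecisionBlock.F],
    )
    state = play_path(s, ["n0_o", "n1_o", "n2_o"])
    assert state.block_sums[DecisionBlock.LT] == 3
    assert state.block_sums[DecisionBlock.MD] == 4
    assert state.block_sums[DecisionBlock.F] == -6
    assert state.block_sums[DecisionBlock.C] == 0
    assert total_score(state) == 1


def test_score_report_requires_completion(reference):
    state = start(reference)
    with pytest.raises(PlayStateError):
        score_report(state)
    state = choose(state, "intake_focused")
    state = choose(state, "exam_fatal")
    report = score_report(state)
    assert report.terminal_status == PlayStatus.STOPPED
    assert report.total == total_score(state) == -9
    assert report.path == ("intake_focused", "exam_fatal")
    assert sum(report.block_sums.values()) == report.total
    # untouched blocks report zero
    assert report.block_sums[DecisionBlock.F] == 0


def test_relabeling_blocks_preserves_total():
    """The total is invariant under block labeling; only sums move."""
    cats = ["C'", "E", "H'"]
    a = play_path(linear_scenario(cats), ["n0_o", "n1_o", "n2_o"])
    b = play_path(
        linear_scenario(cats, blocks=[DecisionBlock.OE] * 3),
        ["n0_o", "n1_o", "n2_o"],
    )
    assert total_score(a) == total_score(b) == 4
    assert a.block_sums != b.block_sums


@settings(derandomize=True, max_examples=40, deadline=None)
@given(seed=st.integers(0, 2**20), depth=st.integers(1, 4),
       branching=st.integers(2, 3))
def test_total_equals_block_sum_and_log_sum_on_random_playthroughs(
    seed, depth, branching
):
    """Additivity: block partition and step log always re-sum to the total."""
    import numpy as np

    mix = {c: 1.0 for c in
           ("A", "C", "D", "E", "G", "I", "A'", "C'", "E'", "G'", "I'")}
    s = generate_scenario(
        ScenarioGenSpec(depth=depth, branching=branching, seed=seed,
                        category_mix=mix)
    )
    rng = np.random.default_rng(seed)
    for _ in range(5):
        state = start(s)
        while state.is_active:
            options = s.node(state.current).options
            state = choose(state, options[rng.integers(len(options))].option_id)
        total = total_score(state)
        assert total == sum(state.block_sums.values())
        assert total == sum(step.points for step in state.log)
        k = len(state.log)
        assert -10 * k <= total <= 10 * k
        assert 1 <= k <= depth


def test_stop_semantics_on_enumerated_paths():
    """No path continues past a category-I option."""
    mix = {c: 1.0 for c in ("C", "I", "C'", "I'")}
    s = generate_scenario(
        ScenarioGenSpec(depth=3, branching=2, seed=11, category_mix=mix,
                        include_stop_path=True)
    )
    from branchsim.analytics import enumerate_paths

    for p in enumerate_paths(s):
        cats = [step.category for step in play_path(s, p.options).log]
        if "I" in cats:
            assert cats.index("I") == len(cats) - 1
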