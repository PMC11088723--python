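"""Scenario format: parsing, serialization, validation rules."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from branchsim.errors import ScenarioFormatError, ScenarioLinkError
from branchsim.generate import ScenarioGenSpec, generate_scenario
from branchsim.scenario import (
    DecisionBlock,
    DecisionNode,
    NodeKind,
    Option,
    Scenario,
    TerminalStatus,
    parse_scenario,
    serialize_scenario,
    validate,
)

MINIMAL = {
    "format_version": "1.0",
    "scenario_id": "mini",
    "title": "minimal",
    "start": "root",
    "nodes": [
        {
            "node_id": "root",
            "prompt": "pick",
            "kind": "decision",
            "options": [
                {"option_id": "good", "category": "C'", "block": "C",
                 "target": "ok"},
                {"option_id": "bad", "category": "C", "block": "C",
                 "target": "meh"},
            ],
        },
        {"node_id": "ok", "kind": "terminal", "terminal_status": "finished"},
        {"node_id": "meh", "kind": "terminal", "terminal_status": "finished"},
    ],
}


def test_parse_minimal_document():
    s = parse_scenario(json.dumps(MINIMAL))
    assert len(s.nodes) == 3
    assert s.start == "root"
    assert validate(s) == []


def test_dangling_target_is_link_error():
    doc = json.loads(json.dumps(MINIMAL))
    doc["nodes"][0]["options"][0]["target"] = "nowhere"
    with pytest.raises(ScenarioLinkError, match="nowhere"):
        parse_scenario(json.dumps(doc))


def test_missing_start_is_link_error():
    doc = json.loads(json.dumps(MINIMAL))
    doc["start"] = "absent"
    with pytest.raises(ScenarioLinkError, match="absent"):
        parse_scenario(json.dumps(doc))


@pytest.mark.parametrize(
    "mutate,match",
    [
        (lambda d: d["nodes"][0].update(surprise=1), "schema error"),
        (lambda d: d["nodes"][0]["options"][0].update(category="Z"), "category"),
        (lambda d: d["nodes"][0]["options"][0].update(block="XX"), "block"),
        (lambda d: d.update(format_version="9.9"), "format_version"),
        (lambda d: d["nodes"].append(dict(d["nodes"][1])), "duplicate node id"),
        (lambda d: d["nodes"][1].update(terminal_status="none"), "terminal"),
    ],
)
def test_malformed_documents_rejected(mutate, match):
    doc = json.loads(json.dumps(MINIMAL))
    mutate(doc)
    with pytest.raises(ScenarioFormatError, match=match):
        parse_scenario(json.dumps(doc))


def test_invalid_json_reports_location():
    with pytest.raises(ScenarioFormatError, match="line"):
        parse_scenario("{not json")


def test_serialization_is_canonical_and_round_trips():
    s = parse_scenario(json.dumps(MINIMAL))
    text = serialize_scenario(s)
    assert serialize_scenario(s) == text  # byte-identical determinism
    again = parse_scenario(text)
    assert again == s
    assert serialize_scenario(again) == text  # canonical fixed point


def _two_terminal(category_i_target_kind):
    """Root with a category-I option; target kind varies per test."""
    if category_i_target_kind == "decision":
        target_nodes = (
            DecisionNode(
                node_id="mid", prompt="p", kind=NodeKind.DECISION,
                options=(Option(option_id="m", category="A'",
                                block=DecisionBlock.M, target="fin"),),
            ),
            DecisionNode(node_id="fin", kind=NodeKind.TERMINAL,
                         terminal_status=TerminalStatus.FINISHED),
        )
        target = "mid"
    else:
        target_nodes = (
            DecisionNode(node_id="fin", kind=NodeKind.TERMINAL,
                         terminal_status=category_i_target_kind),
        )
        target = "fin"
    root = DecisionNode(
        node_id="root", prompt="p", kind=NodeKind.DECISION,
        options=(Option(option_id="die", category="I",
                        block=DecisionBlock.T, target=target),),
    )
    return Scenario(scenario_id="v1", start="root", nodes=(root,) + target_nodes)


def test_v1_category_i_must_stop():
    bad = _two_terminal("decision")
    assert any(v.code == "V1" for v in validate(bad))
    bad2 = _two_terminal(TerminalStatus.FINISHED)
    assert any(v.code == "V1" for v in validate(bad2))
    good = _two_terminal(TerminalStatus.STOPPED)
    assert validate(good) == []


def test_v2_cycle_detected():
    a = DecisionNode(
        node_id="a", prompt="p", kind=NodeKind.DECISION,
        options=(Option(option_id="a2b", category="A'",
                        block=DecisionBlock.C, target="b"),),
    )
    b = DecisionNode(
        node_id="b", prompt="p", kind=NodeKind.DECISION,
        options=(
            Option(option_id="b2a", category="B'", block=DecisionBlock.C,
                   target="a"),
            Option(option_id="b2t", category="C'", block=DecisionBlock.C,
                   target="t"),
        ),
    )
    t = DecisionNode(node_id="t", kind=NodeKind.TERMINAL,
                     terminal_status=TerminalStatus.FINISHED)
    s = Scenario(scenario_id="cyc", start="a", nodes=(a, b, t))
    assert any(v.code == "V2" for v in validate(s))


def test_v3_unreachable_node_flagged():
    s = parse_scenario(json.dumps(MINIMAL))
    orphan = DecisionNode(node_id="zz_orphan", kind=NodeKind.TERMINAL,
                          terminal_status=TerminalStatus.FINISHED)
    s2 = Scenario(scenario_id="orph", start=s.start,
                  nodes=s.nodes + (orphan,))
    assert any(v.code == "V3" and v.where == "zz_orphan" for v in validate(s2))


def test_v5_escalation_floor_warning():
    """A benign error right after an E-level harm draws an advisory warning."""
    root = DecisionNode(
        node_id="root", prompt="p", kind=NodeKind.DECISION,
        options=(Option(option_id="harm", category="E",
                        block=DecisionBlock.T, target="after"),),
    )
    after = DecisionNode(
        node_id="after", prompt="worsening", kind=NodeKind.DECISION,
        options=(
            Option(option_id="mild", category="C", block=DecisionBlock.M,
                   target="end"),  # below floor F -> warn
            Option(option_id="grave", category="G", block=DecisionBlock.M,
                   target="end"),  # at/above floor -> fine
            Option(option_id="fix", category="D'", block=DecisionBlock.M,
                   target="end"),  # improvement branch -> fine
        ),
    )
    end = DecisionNode(node_id="end", kind=NodeKind.TERMINAL,
                       terminal_status=TerminalStatus.FINISHED)
    s = Scenario(scenario_id="esc", start="root", nodes=(root, after, end))
    found = [v for v in validate(s) if v.code == "V5"]
    assert len(found) == 1
    assert found[0].warning
    assert "mild" in found[0].where


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 2**20),
    depth=st.integers(1, 3),
    branching=st.integers(2, 3),
    stop=st.booleans(),
)
def test_generated_scenarios_round_trip_losslessly(seed, depth, branching, stop):
    s = generate_scenario(
        ScenarioGenSpec(depth=depth, branching=branching, seed=seed,
                        include_stop_path=stop)
    )
    text = serialize_scenario(s)
    assert parse_scenario(text) == s
    assert serialize_scenario(parse_scenario(text)) == text
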