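"""Deterministic scenario generators.

Authored clinical content is out of scope; these generators produce
structurally realistic decision graphs (placeholder prompts, valid category
and block tags) so the engine, analytics, and simulator can be exercised and
cross-checked without any external input.

``generate_scenario`` builds a layered tree: ``depth`` decision layers with
``branching`` options per node, option categories drawn from a configurable
mix over the 18 category codes.  Category-I draws are routed to ``stopped``
terminals immediately (patient death ends the case), and categories drawn
right after an E–H option are escalated to that option's floor so generated
scenarios never carry escalation warnings.  Everything is reproducible from
the seed.

``reference_scenario`` is a fixed, hand-built case touching all 11 decision
blocks, used as a pinned fixture: its path count, envelope, and exact
expected score are frozen in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError
from .scenario import (
    FORMAT_VERSION,
    DecisionBlock,
    DecisionNode,
    NodeKind,
    Option,
    Scenario,
    TerminalStatus,
)
from .severity import ALL_CODES, ERROR_CODES, escalation_floor, is_error_code

__all__ = ["ScenarioGenSpec", "generate_scenario", "reference_scenario"]

_BLOCKS = tuple(DecisionBlock)


def _default_mix() -> dict[str, float]:
    # Uniform over everything except I: plain random trees should not be
    # dominated by death endpoints; authors opt in via the mix or the flag.
    return {c: (0.0 if c == "I" else 1.0) for c in ALL_CODES}


@dataclass(frozen=True)
class ScenarioGenSpec:
    """Shape and category mix of a generated scenario tree."""

    depth: int
    branching: int = 2
    category_mix: dict[str, float] = field(default_factory=_default_mix)
    include_stop_path: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError(f"depth must be >= 1, got {self.depth}")
        if self.branching < 2:
            raise ParameterError(
                f"branching must be >= 2, got {self.branching}"
            )
        unknown = set(self.category_mix) - set(ALL_CODES)
        if unknown:
            raise ParameterError(f"unknown category codes in mix: {unknown}")
        w = np.array([self.category_mix.get(c, 0.0) for c in ALL_CODES])
        if (w < 0).any() or w.sum() <= 0:
            raise ParameterError(
                "category_mix weights must be non-negative and not all zero"
            )


_ERR_ORDER = {c: i for i, c in enumerate(ERROR_CODES)}


def generate_scenario(spec: ScenarioGenSpec) -> Scenario:
    """Generate a valid, warning-free scenario tree from ``spec``.

    Layer ``l`` options carry block label ``l mod 11`` in canonical block
    order, so deep trees touch many blocks.  Same spec, same bytes:
    serialization of the result is deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([spec.category_mix.get(c, 0.0) for c in ALL_CODES])
    weights = weights / weights.sum()

    nodes: list[DecisionNode] = []
    terminal_count = 0

    def draw_category(floor: Optional[str]) -> str:
        code = str(rng.choice(ALL_CODES, p=weights))
        if floor is not None and is_error_code(code) and _ERR_ORDER[code] < _ERR_ORDER[floor]:
            return floor  # escalate worsening steps to the inherited floor
        return code

    def new_terminal(stopped: bool) -> str:
        nonlocal terminal_count
        nid = f"t{terminal_count}"
        terminal_count += 1
        nodes.append(
            DecisionNode(
                node_id=nid,
                prompt="case end",
                kind=NodeKind.TERMINAL,
                terminal_status=(
                    TerminalStatus.STOPPED if stopped else TerminalStatus.FINISHED
                ),
            )
        )
        return nid

    def build(layer: int, path: str, floor: Optional[str], force_stop: bool) -> str:
        """Create the decision node at ``layer`` reached via ``path``."""
        nid = f"d{layer}_{path}" if path else f"d{layer}"
        block = _BLOCKS[layer % len(_BLOCKS)]
        opts: list[Option] = []
        for j in range(spec.branching):
            cat = draw_category(floor)
            # include_stop_path: the first-spine leaf's last option becomes a
            # category-I death branch, guaranteeing one stopped path.
            if (
                force_stop
                and layer == spec.depth - 1
                and j == spec.branching - 1
            ):
                cat = "I"
            if cat == "I":
                target = new_terminal(stopped=True)
            elif layer == spec.depth - 1:
                target = new_terminal(stopped=False)
            else:
                target = build(
                    layer + 1,
                    f"{path}{j}",
                    escalation_floor(cat) if is_error_code(cat) else None,
                    force_stop and j == 0,
                )
            opts.append(
                Option(
                    option_id=f"{nid}_o{j}",
                    text=f"choice {j} at layer {layer}",
                    category=cat,
                    block=block,
                    target=target,
                )
            )
        nodes.append(
            DecisionNode(
                node_id=nid,
                prompt=f"decision point {nid}",
                kind=NodeKind.DECISION,
                options=tuple(opts),
            )
        )
        return nid

    start_id = build(0, "", None, spec.include_stop_path)
    return Scenario(
        format_version=FORMAT_VERSION,
        scenario_id=f"gen-d{spec.depth}-b{spec.branching}-s{spec.seed}",
        title="generated scenario",
        start=start_id,
        nodes=tuple(nodes),
        metadata={
            "generator": "branchsim.generate",
            "depth": spec.depth,
            "branching": spec.branching,
            "seed": spec.seed,
        },
    )


def reference_scenario() -> Scenario:
    """Fixed hand-built case whose options touch all 11 decision blocks.

    Five decision nodes (history intake, examination, work-up, management,
    salvage) and three terminals.  The best path scores +12, the worst -15
    (rushed intake, then anchoring, procedural harm, and a mishandled
    follow-up), and the exact uniform-choice expectation is -29/18 over its
    50 root-to-terminal paths — values pinned by the enumeration oracle in
    the test suite.
    """
    B = DecisionBlock
    mk = Option

    def decision(nid, prompt, *options):
        return DecisionNode(
            node_id=nid, prompt=prompt, kind=NodeKind.DECISION, options=options
        )

    def terminal(nid, prompt, status):
        return DecisionNode(
            node_id=nid, prompt=prompt, kind=NodeKind.TERMINAL,
            terminal_status=status,
        )

    nodes = (
        decision(
            "intake", "Greet the patient and take the history.",
            mk(option_id="intake_focused", text="Focused, empathetic history",
               category="C'", block=B.C, target="exam"),
            mk(option_id="intake_rushed", text="Rushed history, key allergy missed",
               category="D", block=B.C, target="exam"),
        ),
        decision(
            "exam", "Examine the patient and frame the syndrome.",
            mk(option_id="exam_thorough", text="Thorough objective examination",
               category="D'", block=B.OE, target="workup"),
            mk(option_id="exam_syndrome", text="Sound initial differential",
               category="C'", block=B.DD1, target="workup"),
            mk(option_id="exam_fatal", text="Critical sign dismissed",
               category="I", block=B.OE, target="deceased"),
        ),
        decision(
            "workup", "Order and interpret the work-up.",
            mk(option_id="workup_labs", text="Targeted labs, correctly read",
               category="E'", block=B.LT, target="manage"),
            mk(option_id="workup_imaging", text="Reasonable imaging choice",
               category="C'", block=B.DT, target="manage"),
            mk(option_id="workup_anchor", text="Anchors on the wrong diagnosis",
               category="E", block=B.DD2, target="manage"),
        ),
        decision(
            "manage", "Settle the diagnosis and treat.",
            mk(option_id="manage_optimal", text="Right strategy, marked improvement",
               category="H'", block=B.T, target="recovered"),
            mk(option_id="manage_diagnosis", text="Correct diagnosis made",
               category="F'", block=B.MD, target="recovered"),
            mk(option_id="manage_botched", text="Procedure causes lasting harm",
               category="G", block=B.MP, target="salvage"),
        ),
        decision(
            "salvage", "Stabilize and plan aftercare.",
            mk(option_id="salvage_monitor", text="Close monitoring, improvement",
               category="G'", block=B.M, target="recovered"),
            mk(option_id="salvage_lost", text="Follow-up mishandled, near-fatal",
               category="H", block=B.F, target="discharged_worse"),
        ),
        terminal("recovered", "Patient recovers.", TerminalStatus.FINISHED),
        terminal("discharged_worse", "Patient survives with sequelae.",
                 TerminalStatus.FINISHED),
        terminal("deceased", "Patient dies; scenario stops.",
                 TerminalStatus.STOPPED),
    )
    return Scenario(
        format_version=FORMAT_VERSION,
        scenario_id="reference-v1",
        title="reference case (all 11 blocks)",
        start="intake",
        nodes=nodes,
        metadata={"fixture": "reference", "version": 1},
    )
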