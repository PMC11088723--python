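"""Scenario data model, JSON authoring format, and validation.

A scenario is a directed acyclic decision graph.  *Decision nodes* present a
prompt and an ordered list of options; each option is tagged with a severity
or correctness category (A–I / A'–I'), with one of the 11 decision blocks of
clinical care, and with the node it routes to.  *Terminal nodes* end the
playthrough, either ``finished`` (a successful or neutral end) or ``stopped``
(the patient-death endpoint reached through a category-I option).

Scenario scripts are JSON documents (UTF-8, ``format_version`` stamped).
``parse_scenario``/``serialize_scenario`` round-trip losslessly; the
canonical serialization orders nodes by id and options by their document
position, so two serializations of equal scenarios are byte-identical.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from functools import cached_property
from typing import Any, Iterator, Optional

import networkx as nx
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import severity
from .errors import ScenarioFormatError, ScenarioLinkError

__all__ = [
    "FORMAT_VERSION",
    "DecisionBlock",
    "NodeKind",
    "TerminalStatus",
    "Option",
    "DecisionNode",
    "Scenario",
    "Violation",
    "parse_scenario",
    "serialize_scenario",
    "validate",
    "load_scenario",
    "save_scenario",
]

FORMAT_VERSION = "1.0"


class DecisionBlock(str, enum.Enum):
    """The 11 stages of care over which step points are summed."""

    C = "C"
    OE = "OE"
    DD1 = "DD1"
    LT = "LT"
    DT = "DT"
    DD2 = "DD2"
    MD = "MD"
    T = "T"
    MP = "MP"
    M = "M"
    F = "F"

    @property
    def display_name(self) -> str:
        return _BLOCK_NAMES[self]


_BLOCK_NAMES = {
    DecisionBlock.C: "communication with the patient",
    DecisionBlock.OE: "objective examination",
    DecisionBlock.DD1: "differential diagnosis 1 (main syndrome)",
    DecisionBlock.LT: "lab test assignment and evaluation",
    DecisionBlock.DT: "diagnostic tests assignment and evaluation",
    DecisionBlock.DD2: "differential diagnosis 2 (after test results)",
    DecisionBlock.MD: "making a diagnosis",
    DecisionBlock.T: "prescribing treatment",
    DecisionBlock.MP: "manual skills and procedures",
    DecisionBlock.M: "monitoring",
    DecisionBlock.F: "follow-up",
}


class NodeKind(str, enum.Enum):
    DECISION = "decision"
    TERMINAL = "terminal"


class TerminalStatus(str, enum.Enum):
    STOPPED = "stopped"
    FINISHED = "finished"
    NONE = "none"


class Option(BaseModel):
    """One selectable choice at a decision node."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    option_id: str
    text: str = ""
    category: str
    block: DecisionBlock
    target: str

    @model_validator(mode="after")
    def _check_category(self) -> "Option":
        if self.category not in severity.ALL_CODES:
            raise ValueError(
                f"option {self.option_id!r}: unknown category {self.category!r}"
            )
        return self

    @property
    def points(self) -> int:
        return severity.category_points(self.category)


class DecisionNode(BaseModel):
    """A node of the scenario graph: a decision point or a terminal."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    node_id: str
    prompt: str = ""
    kind: NodeKind = NodeKind.DECISION
    terminal_status: TerminalStatus = TerminalStatus.NONE
    options: tuple[Option, ...] = ()

    @model_validator(mode="after")
    def _check_shape(self) -> "DecisionNode":
        if self.kind is NodeKind.TERMINAL:
            if self.options:
                raise ValueError(f"terminal node {self.node_id!r} has options")
            if self.terminal_status is TerminalStatus.NONE:
                raise ValueError(
                    f"terminal node {self.node_id!r} needs terminal_status"
                )
        else:
            if not self.options:
                raise ValueError(f"decision node {self.node_id!r} has no options")
            if self.terminal_status is not TerminalStatus.NONE:
                raise ValueError(
                    f"decision node {self.node_id!r} carries a terminal_status"
                )
            seen = set()
            for o in self.options:
                if o.option_id in seen:
                    raise ValueError(
                        f"duplicate option id {o.option_id!r} "
                        f"in node {self.node_id!r}"
                    )
                seen.add(o.option_id)
        return self

    @property
    def is_terminal(self) -> bool:
        return self.kind is NodeKind.TERMINAL


class Scenario(BaseModel):
    """A complete branching clinical case script."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    format_version: str = FORMAT_VERSION
    scenario_id: str
    title: str = ""
    start: str
    nodes: tuple[DecisionNode, ...]
    metadata: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_unique_ids(self) -> "Scenario":
        seen = set()
        for n in self.nodes:
            if n.node_id in seen:
                raise ValueError(f"duplicate node id {n.node_id!r}")
            seen.add(n.node_id)
        # Node order carries no meaning (options do); canonicalize by id so
        # structurally equal scenarios compare and serialize identically.
        ordered = tuple(sorted(self.nodes, key=lambda n: n.node_id))
        if ordered != self.nodes:
            object.__setattr__(self, "nodes", ordered)
        return self

    @cached_property
    def _by_id(self) -> dict[str, DecisionNode]:
        return {n.node_id: n for n in self.nodes}

    def node(self, node_id: str) -> DecisionNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise ScenarioLinkError(f"no node with id {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._by_id

    def iter_options(self) -> Iterator[tuple[DecisionNode, Option]]:
        for n in self.nodes:
            for o in n.options:
                yield n, o


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``warning`` findings do not block play."""

    code: str
    where: str
    message: str
    warning: bool = False

    def __str__(self) -> str:
        level = "warning" if self.warning else "error"
        return f"[{self.code}/{level}] {self.where}: {self.message}"


def _link_violations(s: Scenario) -> list[Violation]:
    out = []
    if not s.has_node(s.start):
        out.append(Violation("LINK", "start", f"start node {s.start!r} not found"))
    for n, o in s.iter_options():
        if not s.has_node(o.target):
            out.append(
                Violation(
                    "LINK",
                    f"{n.node_id}/{o.option_id}",
                    f"target {o.target!r} does not resolve to a node",
                )
            )
    return out


def _graph(s: Scenario) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(n.node_id for n in s.nodes)
    for n, o in s.iter_options():
        if s.has_node(o.target):
            g.add_edge(n.node_id, o.target)
    return g


def validate(s: Scenario) -> list[Violation]:
    """Check a parsed scenario against the engine's play rules.

    Rules (blocking unless noted):

    * ``LINK`` — start and every option target resolve to a node;
    * ``V1`` — every category-I option routes to a ``stopped`` terminal
      (category I means patient death: the scenario must stop there);
    * ``V2`` — the graph is acyclic;
    * ``V3`` — every node is reachable from start and at least one terminal
      is reachable;
    * ``V4`` — block labels are among the 11 decision blocks (guaranteed by
      the schema for parsed documents, re-checked for programmatic input);
    * ``V5`` (warning) — a worsening (error) step directly after an E–H
      option is categorized more benignly than that option's escalation
      floor, e.g. a C-level worsening right after an E-level harm.

    Violations are data, not exceptions; an empty list means fully valid.
    """
    out = _link_violations(s)
    if out:
        # Graph rules are not meaningful on a broken link structure.
        return out

    for n, o in s.iter_options():
        if o.block not in DecisionBlock:  # pragma: no cover - schema-enforced
            out.append(
                Violation("V4", f"{n.node_id}/{o.option_id}",
                          f"invalid block {o.block!r}")
            )
        if o.category == "I":
            tgt = s.node(o.target)
            if not (tgt.is_terminal and tgt.terminal_status is TerminalStatus.STOPPED):
                out.append(
                    Violation(
                        "V1",
                        f"{n.node_id}/{o.option_id}",
                        "category-I option (patient death) must target a "
                        "terminal with terminal_status=stopped",
                    )
                )

    g = _graph(s)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        out.append(Violation("V2", cycle[0][0], f"cycle detected: {path}"))

    reachable = nx.descendants(g, s.start) | {s.start}
    for n in s.nodes:
        if n.node_id not in reachable:
            out.append(
                Violation("V3", n.node_id, "node unreachable from start")
            )
    if not any(s.node(nid).is_terminal for nid in reachable):
        out.append(Violation("V3", s.start, "no terminal reachable from start"))

    # V5: escalation-floor advisory on consecutive error steps.
    order = {c: i for i, c in enumerate(severity.ERROR_CODES)}
    for n, o in s.iter_options():
        floor = (
            severity.escalation_floor(o.category)
            if severity.is_error_code(o.category)
            else None
        )
        if floor is None or not s.has_node(o.target):
            continue
        tgt = s.node(o.target)
        for nxt in tgt.options:
            if severity.is_error_code(nxt.category) and order[nxt.category] < order[floor]:
                out.append(
                    Violation(
                        "V5",
                        f"{tgt.node_id}/{nxt.option_id}",
                        f"worsening step category {nxt.category} is above the "
                        f"escalation floor {floor} set by option "
                        f"{n.node_id}/{o.option_id} (category {o.category})",
                        warning=True,
                    )
                )
    return out


def parse_scenario(document: str | bytes | dict) -> Scenario:
    """Parse a JSON scenario script into a fully linked :class:`Scenario`.

    Raises :class:`ScenarioFormatError` on malformed JSON or schema
    violations (with pydantic's error locations) and
    :class:`ScenarioLinkError` on dangling start/target references.
    """
    if isinstance(document, (str, bytes)):
        try:
            data = json.loads(document)
        except json.JSONDecodeError as e:
            raise ScenarioFormatError(
                f"invalid JSON at line {e.lineno}, column {e.colno}: {e.msg}"
            ) from e
    else:
        data = document
    if not isinstance(data, dict):
        raise ScenarioFormatError("scenario document must be a JSON object")
    version = data.get("format_version")
    if version is not None and str(version) != FORMAT_VERSION:
        raise ScenarioFormatError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION})"
        )
    try:
        s = Scenario.model_validate(data)
    except ValidationError as e:
        locs = "; ".join(
            "/".join(map(str, err["loc"])) + ": " + err["msg"] for err in e.errors()
        )
        raise ScenarioFormatError(f"schema error: {locs}") from e
    dangling = _link_violations(s)
    if dangling:
        raise ScenarioLinkError("; ".join(v.message for v in dangling))
    return s


def serialize_scenario(s: Scenario) -> str:
    """Canonical JSON serialization: nodes by id, options in document order.

    Deterministic — two serializations of equal scenarios are byte-identical.
    Raises :class:`ScenarioFormatError` for metadata that JSON cannot encode.
    """
    payload = s.model_dump(mode="json")
    payload["nodes"] = sorted(payload["nodes"], key=lambda n: n["node_id"])
    try:
        return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    except (TypeError, ValueError) as e:
        raise ScenarioFormatError(f"unserializable metadata: {e}") from e


def load_scenario(path) -> Scenario:
    """Read and parse a scenario script from a file path."""
    with open(path, encoding="utf-8") as fh:
        return parse_scenario(fh.read())


def save_scenario(s: Scenario, path) -> None:
    """Write the canonical serialization of ``s`` to a file path."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_scenario(s))
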