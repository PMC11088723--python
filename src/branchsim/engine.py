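"""Playthrough execution and the additive total score.

A playthrough walks the decision graph from the start node, one option
choice at a time.  Every choice appends a step record carrying the option's
category points and adds those points to the sum of the option's decision
block.  The total clinical decision-making score is the plain sum over the
11 block sums,

    total = sum_C + sum_OE + sum_DD1 + sum_LT + sum_DT + sum_DD2
          + sum_MD + sum_T + sum_MP + sum_M + sum_F,

which by construction equals the sum of step points in the log.  Blocks with
no steps contribute zero.

The engine is fully deterministic.  Only category I (patient death) forces a
stop — its development action is STOP and no further step may be scored;
every other "possible termination" or "successful finish" is realized by the
scenario author routing the option to a terminal node.  States are
immutable: :func:`choose` returns a new state, so branches of an analysis
can share a prefix safely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping

from .errors import InvalidScenarioError, PlayStateError, UnknownOptionError
from .scenario import DecisionBlock, Option, Scenario, TerminalStatus, validate
from .severity import DevelopmentAction, category_points, development_action

__all__ = ["PlayStatus", "StepRecord", "PlayState", "ScoreReport",
           "start", "choose", "play_path", "total_score", "score_report"]


class PlayStatus:
    ACTIVE = "active"
    STOPPED = "stopped"
    FINISHED = "finished"


@dataclass(frozen=True)
class StepRecord:
    """One scored choice: which option, its category, points, action, block."""

    node_id: str
    option_id: str
    category: str
    points: int
    action: DevelopmentAction
    block: DecisionBlock


def _zero_block_sums() -> Mapping[DecisionBlock, int]:
    return MappingProxyType({b: 0 for b in DecisionBlock})


@dataclass(frozen=True)
class PlayState:
    """An in-progress or completed playthrough.

    ``block_sums`` always has all 11 block keys and equals the per-block sum
    of the log's points; ``status`` is ``stopped`` exactly when the last
    step's action was STOP or the reached terminal is a ``stopped`` one.
    """

    scenario: Scenario
    current: str
    status: str = PlayStatus.ACTIVE
    log: tuple[StepRecord, ...] = ()
    block_sums: Mapping[DecisionBlock, int] = field(default_factory=_zero_block_sums)

    @property
    def is_active(self) -> bool:
        return self.status == PlayStatus.ACTIVE


@dataclass(frozen=True)
class ScoreReport:
    """Immutable score decomposition of a finished playthrough."""

    scenario_id: str
    path: tuple[str, ...]
    block_sums: Mapping[DecisionBlock, int]
    total: int
    terminal_status: str

    def as_rows(self) -> list[tuple[str, int]]:
        """(block code, sum) pairs in canonical block order, then the total."""
        rows = [(b.value, self.block_sums[b]) for b in DecisionBlock]
        rows.append(("total", self.total))
        return rows


def start(s: Scenario) -> PlayState:
    """Begin a playthrough at the scenario's start node.

    Refuses scenarios with blocking validation violations (warnings are
    allowed) by raising :class:`InvalidScenarioError` with the full list.
    """
    blocking = [v for v in validate(s) if not v.warning]
    if blocking:
        raise InvalidScenarioError(blocking)
    state = PlayState(scenario=s, current=s.start)
    if s.node(s.start).is_terminal:
        # Degenerate but legal: a scenario that is already over.
        status = _terminal_status(s, s.start)
        state = replace(state, status=status)
    return state


def _terminal_status(s: Scenario, node_id: str) -> str:
    ts = s.node(node_id).terminal_status
    return PlayStatus.STOPPED if ts is TerminalStatus.STOPPED else PlayStatus.FINISHED


def _find_option(s: Scenario, node_id: str, option_id: str) -> Option:
    for o in s.node(node_id).options:
        if o.option_id == option_id:
            return o
    raise UnknownOptionError(
        f"node {node_id!r} offers no option {option_id!r}"
    )


def choose(state: PlayState, option_id: str) -> PlayState:
    """Apply one option choice and return the successor state.

    Appends a step record with the option's category points, adds the points
    to the option's block sum, and moves to the target node.  If the
    category's development action is STOP, or the target is a terminal, the
    returned state is no longer active.
    """
    if not state.is_active:
        raise PlayStateError(f"cannot choose on a {state.status} playthrough")
    s = state.scenario
    opt = _find_option(s, state.current, option_id)
    action = development_action(opt.category)
    step = StepRecord(
        node_id=state.current,
        option_id=opt.option_id,
        category=opt.category,
        points=category_points(opt.category),
        action=action,
        block=opt.block,
    )
    sums = dict(state.block_sums)
    sums[opt.block] += step.points
    if action is DevelopmentAction.STOP:
        status = PlayStatus.STOPPED
    elif s.node(opt.target).is_terminal:
        status = _terminal_status(s, opt.target)
    else:
        status = PlayStatus.ACTIVE
    return PlayState(
        scenario=s,
        current=opt.target,
        status=status,
        log=state.log + (step,),
        block_sums=MappingProxyType(sums),
    )


def play_path(s: Scenario, option_ids: Iterable[str]) -> PlayState:
    """Replay a scripted sequence of option choices from the start."""
    state = start(s)
    for oid in option_ids:
        state = choose(state, oid)
    return state


def total_score(state: PlayState) -> int:
    """Total clinical decision-making score: the sum of the 11 block sums."""
    return sum(state.block_sums.values())


def score_report(state: PlayState) -> ScoreReport:
    """Freeze a completed playthrough into a :class:`ScoreReport`.

    Raises :class:`PlayStateError` if the playthrough is still active.
    """
    if state.is_active:
        raise PlayStateError("score_report requires a stopped or finished state")
    return ScoreReport(
        scenario_id=state.scenario.scenario_id,
        path=tuple(step.option_id for step in state.log),
        block_sums=MappingProxyType(dict(state.block_sums)),
        total=total_score(state),
        terminal_status=state.status,
    )
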