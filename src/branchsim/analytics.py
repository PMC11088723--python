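"""Exhaustive deterministic analysis of a scenario's decision graph.

Because scenarios are acyclic and finite, every root-to-terminal path can be
enumerated, each with the exact probability a learner choosing uniformly at
random would follow it (the product of 1/(option count) over the decision
nodes visited).  This yields:

* the full path census with each path's score decomposition,
* the score envelope (min/max attainable total, and per-block extrema),
* the exact expected total under uniform choice, computed two independent
  ways — by weighting the enumerated paths and by backward recursion over
  the graph — both in exact :class:`fractions.Fraction` arithmetic so
  equality checks are free of float drift.

These are the brute-force oracles the scoring engine and the learner
simulator are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from .engine import PlayState, ScoreReport, choose, score_report, start
from .errors import PathExplosionError
from .scenario import DecisionBlock, Scenario

__all__ = ["PathRecord", "ScoreEnvelope", "enumerate_paths", "count_paths",
           "score_envelope", "expected_score_uniform", "DEFAULT_PATH_CAP"]

DEFAULT_PATH_CAP = 10**6


@dataclass(frozen=True)
class PathRecord:
    """One root-to-terminal traversal with its score and uniform-choice mass."""

    options: tuple[str, ...]
    report: ScoreReport
    probability: Fraction


@dataclass(frozen=True)
class ScoreEnvelope:
    """Extrema of the total and of each block sum over all paths."""

    min_total: int
    max_total: int
    block_min: dict[DecisionBlock, int]
    block_max: dict[DecisionBlock, int]


def count_paths(s: Scenario) -> int:
    """Number of distinct root-to-terminal paths, without enumerating them."""

    @lru_cache(maxsize=None)
    def n_from(node_id: str) -> int:
        node = s.node(node_id)
        if node.is_terminal:
            return 1
        return sum(n_from(o.target) for o in node.options)

    # start() performs full validation; reuse it so cyclic graphs are refused.
    state = start(s)
    return n_from(state.current) if state.is_active else 1

def enumerate_paths(s: Scenario, cap: int = DEFAULT_PATH_CAP) -> list[PathRecord]:
    """All root-to-terminal paths, each replayed through the scoring engine.

    Paths are emitted in depth-first document order (first option first).
    Refuses scenarios whose path count exceeds ``cap`` with
    :class:`PathExplosionError`; refuses invalid scenarios like the engine.
    """
    n = count_paths(s)
    if n > cap:
        raise PathExplosionError(
            f"scenario has {n} root-to-terminal paths, above the cap of {cap}"
        )
    out: list[PathRecord] = []

    def walk(state: PlayState, prob: Fraction) -> None:
        if not state.is_active:
            out.append(
                PathRecord(
                    options=tuple(step.option_id for step in state.log),
                    report=score_report(state),
                    probability=prob,
                )
            )
            return
        options = s.node(state.current).options
        share = prob / len(options)
        for o in options:
            walk(choose(state, o.option_id), share)

    walk(start(s), Fraction(1))
    return out


def score_envelope(s: Scenario, cap: int = DEFAULT_PATH_CAP) -> ScoreEnvelope:
    """Min/max attainable total and per-block extrema over all paths."""
    paths = enumerate_paths(s, cap=cap)
    totals = [p.report.total for p in paths]
    return ScoreEnvelope(
        min_total=min(totals),
        max_total=max(totals),
        block_min={
            b: min(p.report.block_sums[b] for p in paths) for b in DecisionBlock
        },
        block_max={
            b: max(p.report.block_sums[b] for p in paths) for b in DecisionBlock
        },
    )


def expected_score_uniform(s: Scenario) -> Fraction:
    """Exact expected total under uniform choice, by backward recursion.

    E[terminal] = 0; at a decision node with k options,
    E[node] = (1/k) * sum over options of (points + E[target]).
    Agrees exactly with the probability-weighted sum over
    :func:`enumerate_paths` (a tested identity), but runs in graph size, not
    path count.
    """

    @lru_cache(maxsize=None)
    def e_from(node_id: str) -> Fraction:
        node = s.node(node_id)
        if node.is_terminal:
            return Fraction(0)
        total = Fraction(0)
        for o in node.options:
            total += o.points + e_from(o.target)
        return total / len(node.options)

    state = start(s)
    return e_from(state.current) if state.is_active else Fraction(0)
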