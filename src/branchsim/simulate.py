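"""Monte Carlo playthroughs under configurable learner policies.

The score model itself is deterministic; what varies is the learner.  A
*policy* maps each decision node of a scenario to a probability distribution
over its options.  Built-ins:

* ``uniform`` — every option equally likely (the distribution the exact
  expectation in :mod:`branchsim.analytics` refers to);
* ``best`` / ``worst`` — the option maximizing / minimizing the total score
  still achievable from here (option points plus the value of the target
  subgraph, computed by backward induction), ties broken by document order.
  On every run these land exactly on the score envelope's max / min;
* ``epsilon_best`` — the best option with probability 1 − ε, otherwise a
  uniform draw over all options (ε = 0 reproduces ``best``, ε = 1 is
  distributionally uniform).

Each run draws from its own substream ``default_rng([seed, run_index])``, so
results are reproducible and increasing ``n_runs`` extends — never
reshuffles — earlier runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import choose, start, total_score
from .errors import ParameterError
from .scenario import DecisionNode, Scenario

__all__ = ["Policy", "SimulationResult", "simulate",
           "uniform_policy", "best_policy", "worst_policy",
           "epsilon_best_policy", "get_policy"]


@dataclass(frozen=True)
class Policy:
    """A named rule assigning a choice distribution to each decision node."""

    name: str
    distribution: Callable[[Scenario, DecisionNode], np.ndarray]
    parameters: dict = field(default_factory=dict)

    def probabilities(self, s: Scenario, node: DecisionNode) -> np.ndarray:
        p = np.asarray(self.distribution(s, node), dtype=float)
        if p.shape != (len(node.options),) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ParameterError(
                f"policy {self.name!r} returned an invalid distribution "
                f"for node {node.node_id!r}"
            )
        return p


def uniform_policy() -> Policy:
    return Policy(
        "uniform",
        lambda s, node: np.full(len(node.options), 1.0 / len(node.options)),
    )


def _value_memo() -> Callable[[Scenario, str, int], int]:
    """Backward-induction node values, memoized per scenario object.

    ``value(s, node_id, +1)`` is the maximum total still achievable from the
    node; ``sign=-1`` gives the minimum.  Terminals are worth 0.
    """
    memos: dict[tuple[int, int], dict[str, int]] = {}

    def value(s: Scenario, node_id: str, sign: int) -> int:
        memo = memos.setdefault((id(s), sign), {})
        if node_id in memo:
            return memo[node_id]
        node = s.node(node_id)
        if node.is_terminal:
            v = 0
        else:
            vals = [o.points + value(s, o.target, sign) for o in node.options]
            v = max(vals) if sign > 0 else min(vals)
        memo[node_id] = v
        return v

    return value


def _extremal_index(s: Scenario, node: DecisionNode, sign: int,
                    value: Callable[[Scenario, str, int], int]) -> int:
    """Index of the first option attaining the sign-extremal achievable total."""
    vals = [o.points + value(s, o.target, sign) for o in node.options]
    return int(np.argmax(vals) if sign > 0 else np.argmin(vals))


def _extremal_policy(name: str, sign: int) -> Policy:
    value = _value_memo()

    def dist(s: Scenario, node: DecisionNode) -> np.ndarray:
        p = np.zeros(len(node.options))
        p[_extremal_index(s, node, sign, value)] = 1.0
        return p

    return Policy(name, dist)


def best_policy() -> Policy:
    """Always take the option with the highest achievable total score."""
    return _extremal_policy("best", +1)


def worst_policy() -> Policy:
    """Always take the option with the lowest achievable total score."""
    return _extremal_policy("worst", -1)


def epsilon_best_policy(epsilon: float) -> Policy:
    if not 0.0 <= epsilon <= 1.0:
        raise ParameterError(f"epsilon must be in [0, 1], got {epsilon}")
    value = _value_memo()

    def dist(s: Scenario, node: DecisionNode) -> np.ndarray:
        k = len(node.options)
        p = np.full(k, epsilon / k)
        p[_extremal_index(s, node, +1, value)] += 1.0 - epsilon
        return p

    return Policy("epsilon_best", dist, parameters={"epsilon": epsilon})


_BUILTINS: dict[str, Callable[..., Policy]] = {
    "uniform": uniform_policy,
    "best": best_policy,
    "worst": worst_policy,
    "epsilon_best": epsilon_best_policy,
}


def get_policy(name: str, **params) -> Policy:
    """Look up a built-in policy by name (``epsilon_best`` takes ``epsilon``)."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ParameterError(
            f"unknown policy {name!r}; built-ins: {sorted(_BUILTINS)}"
        ) from None
    return factory(**params)


@dataclass(frozen=True)
class SimulationResult:
    """Totals of ``n_runs`` seeded playthroughs plus summary statistics."""

    scenario_id: str
    policy_name: str
    seed: int
    n_runs: int
    totals: tuple[int, ...]

    def summary(self) -> dict[str, float]:
        t = np.asarray(self.totals, dtype=float)
        q25, q50, q75 = np.quantile(t, [0.25, 0.5, 0.75])
        return {
            "n": float(self.n_runs),
            "mean": float(t.mean()),
            "sd": float(t.std(ddof=1)) if self.n_runs > 1 else 0.0,
            "min": float(t.min()),
            "q25": float(q25),
            "median": float(q50),
            "q75": float(q75),
            "max": float(t.max()),
        }


def _run_once(s: Scenario, policy: Policy, rng: np.random.Generator) -> int:
    state = start(s)
    while state.is_active:
        node = s.node(state.current)
        p = policy.probabilities(s, node)
        idx = int(rng.choice(len(node.options), p=p))
        state = choose(state, node.options[idx].option_id)
    return total_score(state)


def simulate(s: Scenario, policy: Policy, n_runs: int, seed: int) -> SimulationResult:
    """Run ``n_runs`` complete playthroughs under ``policy``.

    Reproducible: identical (scenario, policy, n_runs prefix, seed) give
    identical totals.  Invalid scenarios are refused exactly as by the
    engine.
    """
    if n_runs < 1:
        raise ParameterError(f"n_runs must be >= 1, got {n_runs}")
    totals = tuple(
        _run_once(s, policy, np.random.default_rng([seed, i]))
        for i in range(n_runs)
    )
    return SimulationResult(
        scenario_id=s.scenario_id,
        policy_name=policy.name,
        seed=seed,
        n_runs=n_runs,
        totals=totals,
    )
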