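"""Shared builders for small hand-checkable scenarios."""

import pytest

from branchsim.scenario import (
    DecisionBlock,
    DecisionNode,
    NodeKind,
    Option,
    Scenario,
    TerminalStatus,
)


def single_node_scenario(categories, blocks=None):
    """One decision node whose options (one per category) go to terminals.

    Terminals are ``stopped`` for category-I options, ``finished`` otherwise.
    """
    blocks = blocks or [DecisionBlock.C] * len(categories)
    options, nodes = [], []
    for i, (cat, block) in enumerate(zip(categories, blocks)):
        status = TerminalStatus.STOPPED if cat == "I" else TerminalStatus.FINISHED
        nodes.append(
            DecisionNode(
                node_id=f"t{i}", prompt="end", kind=NodeKind.TERMINAL,
                terminal_status=status,
            )
        )
        options.append(
            Option(option_id=f"o{i}", text=f"option {i}", category=cat,
                   block=block, target=f"t{i}")
        )
    nodes.append(
        DecisionNode(node_id="root", prompt="choose", kind=NodeKind.DECISION,
                     options=tuple(options))
    )
    return Scenario(scenario_id="single", start="root", nodes=tuple(nodes))


def linear_scenario(categories, blocks=None):
    """A chain of one-option decision nodes: step i carries categories[i]."""
    blocks = blocks or [DecisionBlock.T] * len(categories)
    nodes = [
        DecisionNode(node_id="end", prompt="end", kind=NodeKind.TERMINAL,
                     terminal_status=TerminalStatus.FINISHED)
    ]
    for i, (cat, block) in enumerate(zip(categories, blocks)):
        target = f"n{i + 1}" if i + 1 < len(categories) else "end"
        nodes.append(
            DecisionNode(
                node_id=f"n{i}", prompt=f"step {i}", kind=NodeKind.DECISION,
                options=(
                    Option(option_id=f"n{i}_o", text="only move",
                           category=cat, block=block, target=target),
                ),
            )
        )
    return Scenario(scenario_id="linear", start="n0", nodes=tuple(nodes))


@pytest.fixture(scope="session")
def reference():
    from branchsim.generate import reference_scenario

    return reference_scenario()
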