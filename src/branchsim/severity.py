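"""Severity point system for branching clinical case scenarios.

Two mirrored nine-level taxonomies drive all scoring:

* **Error categories A–I** follow the NCCMERP index for the seriousness of
  medication errors, generalized to medical errors: from a potential error
  that never reaches the patient (A) through temporary or permanent harm
  (E–G), risk of death (H), and death (I).  Each category carries a
  non-positive point value; the scale is deliberately non-linear, jumping
  from -6 (H) to -10 (I).
* **Correct-decision categories A'–I'** are the specular taxonomy for
  beneficial decisions, from no change in patient state (A', B') to complete
  recovery (I'), with point values that exactly negate the error scale.

Each category also carries a *development action* — the scenario-flow
consequence of landing on it.  Only category I (patient death) forces the
scenario to stop; everything else continues, possibly with monitoring,
intervention, or an author-chosen successful finish.

Categories E–H additionally carry an *escalation floor*: when a step with
temporary/permanent harm is followed by a worsening step, the follow-up is
expected to be classified at or below that floor (e.g. after an E the
worsening continuation should use F–I).  The floor is advisory authoring
metadata checked by scenario validation; it never rewrites points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import InvalidCategoryError

__all__ = [
    "DevelopmentAction",
    "ErrorCategory",
    "CorrectCategory",
    "ERROR_CODES",
    "CORRECT_CODES",
    "ALL_CODES",
    "category_points",
    "error_points",
    "correct_points",
    "development_action",
    "escalation_floor",
    "is_error_code",
    "is_correct_code",
    "category_reference_table",
]


class DevelopmentAction(enum.Enum):
    """Scenario-flow consequence attached to a category."""

    CONTINUE = "continue"
    CONTINUE_WITH_MONITORING = "continue_with_monitoring"
    CONTINUE_WITH_INTERVENTION = "continue_with_intervention"
    CONTINUE_POSSIBLE_TERMINATION = "continue_possible_termination"
    STOP = "stop"
    FINISH_OR_CONTINUE = "finish_or_continue"
    FINISH_OR_FOLLOWUP = "finish_or_followup"


@dataclass(frozen=True)
class ErrorCategory:
    """One row of the medical-error severity classification.

    ``points`` is a dimensionless integer score; ``escalation_floor`` is the
    most benign category allowed for a subsequent worsening step, present
    only for E–H.
    """

    code: str
    occurrence: str  # "potential" or "actual"
    reached_patient: bool
    harm: str  # none | temporary | permanent | risk_of_death | death
    measures: str
    points: int
    action: DevelopmentAction
    escalation_floor: Optional[str] = None


@dataclass(frozen=True)
class CorrectCategory:
    """One row of the correct-decision classification (specular to errors)."""

    code: str
    reached_patient: bool
    state_effect: str
    points: int
    action: DevelopmentAction


_A = DevelopmentAction

ERROR_CATEGORIES: dict[str, ErrorCategory] = {
    c.code: c
    for c in (
        ErrorCategory("A", "potential", False, "none", "no", 0, _A.CONTINUE),
        ErrorCategory("B", "actual", False, "none", "no", 0, _A.CONTINUE),
        ErrorCategory("C", "actual", True, "none", "no", -1, _A.CONTINUE),
        ErrorCategory(
            "D", "actual", True, "none", "monitoring", -2,
            _A.CONTINUE_WITH_MONITORING,
        ),
        ErrorCategory(
            "E", "actual", True, "temporary", "medical intervention", -3,
            _A.CONTINUE_WITH_INTERVENTION, escalation_floor="F",
        ),
        ErrorCategory(
            "F", "actual", True, "temporary",
            "hospitalization or prolonged stay", -4,
            _A.CONTINUE_WITH_INTERVENTION, escalation_floor="F",
        ),
        ErrorCategory(
            "G", "actual", True, "permanent", "variable", -5,
            _A.CONTINUE_POSSIBLE_TERMINATION, escalation_floor="G",
        ),
        ErrorCategory(
            "H", "actual", True, "risk_of_death", "vital support intervention",
            -6, _A.CONTINUE_POSSIBLE_TERMINATION, escalation_floor="H",
        ),
        ErrorCategory("I", "actual", True, "death", "-", -10, _A.STOP),
    )
}

CORRECT_CATEGORIES: dict[str, CorrectCategory] = {
    c.code: c
    for c in (
        CorrectCategory("A'", False, "no change", 0, _A.CONTINUE),
        CorrectCategory("B'", False, "no change", 0, _A.CONTINUE),
        CorrectCategory(
            "C'", True, "right steps toward diagnosis, state unchanged", 1,
            _A.CONTINUE,
        ),
        CorrectCategory(
            "D'", True, "right steps with positive state change", 2,
            _A.CONTINUE,
        ),
        CorrectCategory(
            "E'", True, "significant right steps with positive state change",
            3, _A.CONTINUE,
        ),
        CorrectCategory(
            "F'", True, "correct diagnosis made", 4, _A.FINISH_OR_CONTINUE,
        ),
        CorrectCategory(
            "G'", True, "right treatment strategy with improvement", 5,
            _A.FINISH_OR_FOLLOWUP,
        ),
        CorrectCategory(
            "H'", True, "right treatment strategy with significant improvement",
            6, _A.FINISH_OR_FOLLOWUP,
        ),
        CorrectCategory("I'", True, "complete recovery", 10, _A.FINISH_OR_FOLLOWUP),
    )
}

ERROR_CODES: tuple[str, ...] = tuple(ERROR_CATEGORIES)
CORRECT_CODES: tuple[str, ...] = tuple(CORRECT_CATEGORIES)
ALL_CODES: tuple[str, ...] = ERROR_CODES + CORRECT_CODES


def is_error_code(code: str) -> bool:
    return code in ERROR_CATEGORIES


def is_correct_code(code: str) -> bool:
    return code in CORRECT_CATEGORIES


def error_points(code: str) -> int:
    """Point value of an error category A–I (0 down to -10)."""
    try:
        return ERROR_CATEGORIES[code].points
    except KeyError:
        raise InvalidCategoryError(f"unknown error category: {code!r}") from None


def correct_points(code: str) -> int:
    """Point value of a correct-decision category A'–I' (0 up to +10)."""
    try:
        return CORRECT_CATEGORIES[code].points
    except KeyError:
        raise InvalidCategoryError(f"unknown correct category: {code!r}") from None


def category_points(code: str) -> int:
    """Point value for any category code, error or correct."""
    if code in ERROR_CATEGORIES:
        return ERROR_CATEGORIES[code].points
    if code in CORRECT_CATEGORIES:
        return CORRECT_CATEGORIES[code].points
    raise InvalidCategoryError(f"unknown category: {code!r}")


def development_action(code: str) -> DevelopmentAction:
    """Scenario-flow action attached to any category code."""
    if code in ERROR_CATEGORIES:
        return ERROR_CATEGORIES[code].action
    if code in CORRECT_CATEGORIES:
        return CORRECT_CATEGORIES[code].action
    raise InvalidCategoryError(f"unknown category: {code!r}")


def escalation_floor(code: str) -> Optional[str]:
    """Most benign category allowed for a worsening follow-up step.

    Present only for error categories E–H; ``None`` elsewhere (A–D never
    escalate, and after I the scenario has stopped).
    """
    try:
        return ERROR_CATEGORIES[code].escalation_floor
    except KeyError:
        raise InvalidCategoryError(f"unknown error category: {code!r}") from None


def category_reference_table() -> pd.DataFrame:
    """Both category maps as a single tidy table for audit/export.

    One row per category code with its kind, points, development action and
    (for errors) escalation floor.
    """
    rows = []
    for c in ERROR_CATEGORIES.values():
        rows.append(
            {
                "code": c.code,
                "kind": "error",
                "reached_patient": c.reached_patient,
                "detail": c.harm,
                "measures": c.measures,
                "points": c.points,
                "action": c.action.value,
                "escalation_floor": c.escalation_floor or "",
            }
        )
    for c in CORRECT_CATEGORIES.values():
        rows.append(
            {
                "code": c.code,
                "kind": "correct",
                "reached_patient": c.reached_patient,
                "detail": c.state_effect,
                "measures": "",
                "points": c.points,
                "action": c.action.value,
                "escalation_floor": "",
            }
        )
    return pd.DataFrame(rows)
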