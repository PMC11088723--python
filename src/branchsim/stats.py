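"""Trainee-feedback statistics for scenario evaluation studies.

Evaluation studies of branching-scenario training typically collect 1–5
Likert ratings on a handful of criteria from two groups of trainees (e.g.
scenarios with vs. without the score model) and report per-criterion group
means ± SD, two-sample t-tests, and an equally weighted average of the
criterion means per group.  This module reproduces that analysis from
summary statistics alone — raw ratings are rarely deposited — and provides
a seeded synthetic Likert generator so the pipeline can be exercised and
power-checked without any participant data.

The default location test is Welch's unequal-variance t with Satterthwaite
degrees of freedom; a pooled-variance (Student) variant is available behind
a flag.  Both are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "CRITERIA",
    "GroupSummary",
    "ComparisonTable",
    "TTestResult",
    "welch_t_from_summary",
    "comparison_table",
    "simulate_likert",
    "round_half_up",
    "REFERENCE_FEEDBACK",
]

#: Canonical evaluation criteria, in reporting order.
CRITERIA: tuple[str, ...] = (
    "realism",
    "clarity_of_decision_making",
    "integration_of_clinical_knowledge",
    "adaptability",
    "engagement",
    "depth_of_learning_from_mistakes",
    "user_friendliness",
    "overall_satisfaction",
)


@dataclass(frozen=True)
class GroupSummary:
    """Per-criterion n/mean/SD for one trainee group."""

    label: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError(f"group {self.label!r}: n must be positive")
        if set(self.means) != set(self.sds):
            raise ParameterError(
                f"group {self.label!r}: means and sds cover different criteria"
            )
        for crit, m in self.means.items():
            if not 1.0 <= m <= 5.0:
                raise ParameterError(
                    f"group {self.label!r}, {crit}: mean {m} outside [1, 5]"
                )
            if self.sds[crit] < 0:
                raise ParameterError(
                    f"group {self.label!r}, {crit}: negative SD"
                )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def welch_t_from_summary(
    n1: int, m1: float, s1: float,
    n2: int, m2: float, s2: float,
    *, pooled: bool = False,
) -> TTestResult:
    """Two-sample t-test from group sizes, means, and SDs.

    Default is Welch's statistic t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2)
    with Satterthwaite degrees of freedom; ``pooled=True`` gives the
    classical equal-variance Student test.  The p-value is two-sided.  Both
    groups need n >= 2 and at least one nonzero SD.
    """
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ParameterError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        raise ParameterError("both SDs are zero: t statistic undefined")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    if pooled:
        sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given decimal (4.45 -> 4.5)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonTable:
    """Per-criterion group comparison plus the averaged-score row.

    The average row is the arithmetic mean of the per-criterion means for
    each group (equally weighted), rounded half-up to one decimal — the
    conventional "average score out of 5" line of feedback tables.
    """

    group1: str
    group2: str
    rows: pd.DataFrame = field(repr=False)
    average: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        """The full table, averaged-score row appended."""
        avg = pd.DataFrame(
            [{
                "criterion": "average_score",
                "mean_1": self.average[0], "sd_1": np.nan,
                "mean_2": self.average[1], "sd_2": np.nan,
                "t": np.nan, "df": np.nan, "p": np.nan,
            }]
        )
        return pd.concat([self.rows, avg], ignore_index=True)


def comparison_table(
    g1: GroupSummary, g2: GroupSummary, *, pooled: bool = False
) -> ComparisonTable:
    """Welch (or pooled) tests per criterion plus the average-score row."""
    if set(g1.means) != set(g2.means):
        raise ParameterError("groups cover different criterion sets")
    order = [c for c in CRITERIA if c in g1.means]
    order += [c for c in sorted(g1.means) if c not in CRITERIA]
    rows = []
    for crit in order:
        res = welch_t_from_summary(
            g1.n, g1.means[crit], g1.sds[crit],
            g2.n, g2.means[crit], g2.sds[crit],
            pooled=pooled,
        )
        rows.append(
            {
                "criterion": crit,
                "mean_1": g1.means[crit], "sd_1": g1.sds[crit],
                "mean_2": g2.means[crit], "sd_2": g2.sds[crit],
                "t": res.t, "df": res.df, "p": res.p,
            }
        )
    avg = (
        round_half_up(float(np.mean([g1.means[c] for c in order]))),
        round_half_up(float(np.mean([g2.means[c] for c in order]))),
    )
    return ComparisonTable(
        group1=g1.label, group2=g2.label,
        rows=pd.DataFrame(rows), average=avg,
    )


def _feasible_moments(target_mean: float, target_sd: float) -> None:
    if not 1.0 <= target_mean <= 5.0:
        raise ParameterError(f"target_mean {target_mean} outside [1, 5]")
    if target_sd < 0:
        raise ParameterError("target_sd must be non-negative")
    var = target_sd * target_sd
    var_max = (target_mean - 1.0) * (5.0 - target_mean)
    frac = target_mean - math.floor(target_mean)
    var_min = frac * (1.0 - frac)
    if var > var_max + 1e-9 or var < var_min - 1e-9:
        raise ParameterError(
            f"no distribution on {{1..5}} has mean {target_mean} and "
            f"SD {target_sd} (variance must lie in "
            f"[{var_min:.4f}, {var_max:.4f}])"
        )


def _likert_pmf(target_mean: float, target_sd: float) -> np.ndarray:
    """A pmf on {1..5} with exactly the requested mean and SD.

    Starts from a discretized, clipped normal at the targets and applies a
    minimal moment-matching correction (least-squares projection onto the
    two linear moment constraints, pmf kept non-negative).
    """
    support = np.arange(1, 6, dtype=float)
    scale = max(target_sd, 0.25)
    edges = np.array([-np.inf, 1.5, 2.5, 3.5, 4.5, np.inf])
    cdf = sps.norm.cdf(edges, loc=target_mean, scale=scale)
    p0 = np.diff(cdf)
    p0 /= p0.sum()

    m2_target = target_sd * target_sd + target_mean * target_mean
    constraints = [
        {"type": "eq", "fun": lambda p: p.sum() - 1.0},
        {"type": "eq", "fun": lambda p: p @ support - target_mean},
        {"type": "eq", "fun": lambda p: p @ support**2 - m2_target},
    ]
    res = optimize.minimize(
        lambda p: ((p - p0) ** 2).sum(),
        x0=p0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 5,
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    p = np.clip(res.x, 0.0, None)
    p /= p.sum()
    if abs(p @ support - target_mean) > 1e-6 or abs(
        math.sqrt(max(p @ support**2 - (p @ support) ** 2, 0.0)) - target_sd
    ) > 1e-6:
        raise ParameterError(
            f"could not match moments (mean {target_mean}, SD {target_sd}) "
            "on the 1-5 support"
        )
    return p


def simulate_likert(
    n: int, target_mean: float, target_sd: float, seed: int
) -> np.ndarray:
    """Seeded synthetic 1–5 ratings whose distribution has the given moments.

    Draws i.i.d. from a pmf on {1..5} whose population mean and SD equal the
    targets exactly, so sample moments converge to them as n grows.  Raises
    :class:`ParameterError` for moment pairs no distribution on {1..5} can
    attain.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    _feasible_moments(target_mean, target_sd)
    rng = np.random.default_rng(seed)
    if target_sd == 0.0:
        if abs(target_mean - round(target_mean)) > 1e-12:
            raise ParameterError(
                "zero SD requires an integer target_mean on {1..5}"
            )
        return np.full(n, int(round(target_mean)), dtype=np.int64)
    p = _likert_pmf(target_mean, target_sd)
    return rng.choice(np.arange(1, 6), size=n, p=p)


#: Reference feedback summaries from a two-group evaluation of branching
#: scenarios authored without (group 1, n=16) and with (group 2, n=18) the
#: severity-point score model; 1–5 Likert means ± SD per criterion.
REFERENCE_FEEDBACK: tuple[GroupSummary, GroupSummary] = (
    GroupSummary(
        label="without_model",
        n=16,
        means={
            "realism": 3.0,
            "clarity_of_decision_making": 2.5,
            "integration_of_clinical_knowledge": 3.2,
            "adaptability": 2.2,
            "engagement": 3.6,
            "depth_of_learning_from_mistakes": 2.5,
            "user_friendliness": 3.0,
            "overall_satisfaction": 2.5,
        },
        sds={
            "realism": 0.73,
            "clarity_of_decision_making": 0.52,
            "integration_of_clinical_knowledge": 0.4,
            "adaptability": 0.4,
            "engagement": 0.5,
            "depth_of_learning_from_mistakes": 0.5,
            "user_friendliness": 0.73,
            "overall_satisfaction": 0.52,
        },
    ),
    GroupSummary(
        label="with_model",
        n=18,
        means={
            "realism": 4.6,
            "clarity_of_decision_making": 4.2,
            "integration_of_clinical_knowledge": 4.5,
            "adaptability": 4.0,
            "engagement": 4.7,
            "depth_of_learning_from_mistakes": 4.4,
            "user_friendliness": 4.6,
            "overall_satisfaction": 4.7,
        },
        sds={
            "realism": 0.5,
            "clarity_of_decision_making": 0.42,
            "integration_of_clinical_knowledge": 0.51,
            "adaptability": 0.5,
            "engagement": 0.5,
            "depth_of_learning_from_mistakes": 0.5,
            "user_friendliness": 0.5,
            "overall_satisfaction": 0.5,
        },
    ),
)
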