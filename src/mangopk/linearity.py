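"""Group summaries and the dose-independence decision.

Dose proportionality is judged on dose-normalized parameters: if the
per-subject normalized values do not differ significantly across dose
groups (classical one-way ANOVA for three or more groups, unpaired
two-sided t-test for two), the parameter is declared dose-independent
at the chosen alpha. Tukey's HSD pairwise comparisons are reported as
supporting evidence, not as the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedParameter",
    "LinearityReport",
    "group_summary",
    "one_way_anova",
    "tukey_hsd",
    "two_sample_t",
    "linearity_verdict",
]


@dataclass
class GroupedParameter:
    """Per-subject values of one parameter, grouped by dose."""

    parameter: str
    groups: list[tuple[float, np.ndarray]]  # (dose mg/kg, values)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.groups = [(float(d), np.asarray(v, dtype=float)) for d, v in self.groups]
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def values(self) -> list[np.ndarray]:
        return [v for _, v in self.groups]

    def _require(self, min_groups: int) -> None:
        if len(self.groups) < min_groups:
            raise ValueError(
                f"{self.parameter}: need >= {min_groups} groups, have {len(self.groups)}"
            )
        for dose, v in self.groups:
            if len(v) < 2:
                raise ValueError(
                    f"{self.parameter}: group at {dose} mg/kg has < 2 values"
                )


def group_summary(gp: GroupedParameter) -> pd.DataFrame:
    """Mean +/- SD per dose group; median (range) for Tmax-like parameters.

    Sample SD (ddof=1) matches the usual reporting convention.
    """
    median_style = gp.parameter.lower().startswith("tmax")
    rows = []
    for dose, v in gp.groups:
        row: dict = {"parameter": gp.parameter, "dose_mg_kg": dose, "n": len(v)}
        if median_style:
            row.update(median=float(np.median(v)), min=float(v.min()), max=float(v.max()))
        else:
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            row.update(mean=float(v.mean()), sd=sd)
        rows.append(row)
    return pd.DataFrame(rows)


def one_way_anova(gp: GroupedParameter) -> tuple[float, float]:
    """Classical one-way ANOVA (F statistic, p-value) across dose groups."""
    gp._require(3)
    values = gp.values()
    f_stat, p = stats.f_oneway(*values)
    if not np.isfinite(f_stat):  # all values identical in every group
        pooled = np.concatenate(values)
        if np.allclose(pooled, pooled[0]):
            return 0.0, 1.0
    return float(f_stat), float(p)


def tukey_hsd(gp: GroupedParameter) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons on the ANOVA residual variance."""
    gp._require(2)
    res = stats.tukey_hsd(*gp.values())
    rows = []
    for i, j in combinations(range(len(gp.groups)), 2):
        rows.append(
            {
                "dose_a": gp.groups[i][0],
                "dose_b": gp.groups[j][0],
                "mean_diff": float(np.mean(gp.groups[i][1]) - np.mean(gp.groups[j][1])),
                "statistic": float(res.statistic[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Unpaired two-sided t-test p-value (equal variances assumed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass
class LinearityReport:
    """Outcome of the dose-independence decision for one parameter."""

    parameter: str
    verdict: str  # "dose_independent" or "dose_dependent"
    test: str  # "anova" or "t_test"
    statistic: float
    p_value: float
    alpha: float
    evidence: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": self.parameter,
                "comparison": "omnibus",
                "test": self.test,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "verdict": self.verdict,
            }
        ]
        if self.evidence is not None:
            for _, r in self.evidence.iterrows():
                rows.append(
                    {
                        "parameter": self.parameter,
                        "comparison": f"{r.dose_a:g} vs {r.dose_b:g} mg/kg",
                        "test": "tukey_hsd",
                        "statistic": r.statistic,
                        "p_value": r.p_adj,
                        "verdict": "",
                    }
                )
        return pd.DataFrame(rows)


def linearity_verdict(gp: GroupedParameter) -> LinearityReport:
    """Dose-independence verdict on dose-normalized per-subject values.

    Non-significance of the omnibus test at alpha means the parameter
    scales with dose (dose-independent after normalization). A single
    group is an error: the verdict is undefined.
    """
    if len(gp.groups) < 2:
        raise ValueError("verdict undefined for fewer than 2 dose groups")
    if len(gp.groups) == 2:
        gp._require(2)
        p = two_sample_t(gp.groups[0][1], gp.groups[1][1])
        stat = float(
            stats.ttest_ind(gp.groups[0][1], gp.groups[1][1], equal_var=True).statistic
        )
        test = "t_test"
        evidence = None
    else:
        stat, p = one_way_anova(gp)
        test = "anova"
        evidence = tukey_hsd(gp)
    verdict = "dose_independent" if p >= gp.alpha else "dose_dependent"
    return LinearityReport(
        parameter=gp.parameter,
        verdict=verdict,
        test=test,
        statistic=stat,
        p_value=p,
        alpha=gp.alpha,
        evidence=evidence,
    )
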