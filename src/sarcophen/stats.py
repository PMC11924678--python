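"""Group statistics shared across the phenotyping stages.

Two-group comparisons use a classical two-tailed Student t-test
(pooled-variance by default, Welch optional); multi-group comparisons a
one-way ANOVA; survival a Kaplan–Meier product-limit estimator with the
median read off the survival curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import f_oneway, ttest_ind

__all__ = [
    "TestResult",
    "SurvivalRecord",
    "two_group_test",
    "anova_oneway",
    "km_median",
    "km_median_by_group",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False  # zero variance everywhere: statistic undefined


@dataclass(frozen=True)
class SurvivalRecord:
    animal_id: str
    genotype: str
    time_days: float
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("survival time must be positive")


def two_group_test(values_a, values_b, equal_var: bool = True) -> TestResult:
    """Two-tailed two-sample t-test on group means.

    ``equal_var=True`` gives the classical pooled-variance Student test;
    ``False`` the Welch variant. Groups where both have zero variance are
    flagged degenerate (t undefined; p reported as 1 for identical constants).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        identical = a.mean() == b.mean()
        return TestResult(
            statistic=0.0 if identical else float("inf"),
            p_value=1.0 if identical else 0.0,
            degenerate=True,
        )
    t, p = ttest_ind(a, b, equal_var=equal_var)
    return TestResult(statistic=float(t), p_value=float(p))


def anova_oneway(groups) -> TestResult:
    """Classical one-way ANOVA over three or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("one-way ANOVA here requires at least 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(a) == 0.0 for a in arrays):
        means = [a.mean() for a in arrays]
        identical = len(set(means)) == 1
        return TestResult(
            statistic=0.0 if identical else float("inf"),
            p_value=1.0 if identical else 0.0,
            degenerate=True,
        )
    f, p = f_oneway(*arrays)
    return TestResult(statistic=float(f), p_value=float(p))


def km_median(times, events=None) -> float | None:
    """Kaplan–Meier median survival time.

    ``events`` defaults to all-observed. Returns ``None`` when the survival
    curve never drops to 0.5 (median undefined, e.g. heavy censoring).
    Requires at least one observed event.
    """
    times = np.asarray(times, dtype=float)
    if events is None:
        events = np.ones_like(times, dtype=bool)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        return None
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    median = kmf.median_survival_time_
    return None if np.isinf(median) else float(median)


def km_median_by_group(records: list[SurvivalRecord]) -> dict[str, float | None]:
    """Per-genotype Kaplan–Meier median survival (days)."""
    if not records:
        raise ValueError("no survival records")
    df = pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "time": [r.time_days for r in records],
            "event": [r.event for r in records],
        }
    )
    out: dict[str, float | None] = {}
    for genotype, group in df.groupby("genotype"):
        if not group["event"].any():
            out[str(genotype)] = None
        else:
            out[str(genotype)] = km_median(group["time"].to_numpy(), group["event"].to_numpy())
    return out
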