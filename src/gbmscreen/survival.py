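"""Kaplan-Meier estimation and log-rank comparison of signature classes.

Thin, validated wrappers around lifelines: the product-limit estimator with
median survival (smallest t with S(t) <= 0.5; undefined and flagged when S
never reaches 0.5) and the standard two-group log-rank test (chi-square, 1
df).  Events precede censorings at tied times, the usual convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import ValidationError


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time_days: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValidationError(f"negative follow-up time for {self.sample}")
        if self.event not in (0, 1):
            raise ValidationError(f"event flag must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class KMEstimate:
    """Step survival function over distinct event times, plus median survival."""

    times: np.ndarray
    survival: np.ndarray
    median_days: float
    median_defined: bool
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _validate(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise ValidationError("no survival records")
    t = np.array([r.time_days for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: list[SurvivalRecord]) -> KMEstimate:
    """Product-limit survival estimate for one group."""
    t, e = _validate(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    median = kmf.median_survival_time_
    defined = np.isfinite(median)
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median_days=float(median) if defined else float("nan"),
        median_defined=bool(defined),
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Groups are taken from the records' ``group`` labels; exactly two distinct
    labels are required and each group must be nonempty, with at least one
    event overall.
    """
    t, e = _validate(records)
    groups = np.array([r.group for r in records])
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {labels}")
    mask = groups == labels[0]
    if mask.all() or not mask.any():
        raise ValidationError("both groups must be nonempty")
    if e.sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    res = _ll_logrank(t[mask], t[~mask], event_observed_A=e[mask], event_observed_B=e[~mask])
    return float(res.test_statistic), float(res.p_value)


def survival_records_from_frame(
    clinical: pd.DataFrame, group_by: dict[str, str]
) -> list[SurvivalRecord]:
    """Build records from a clinical frame (index=sample, os_days, event columns).

    ``group_by`` maps sample id -> group label; samples absent from the map
    are skipped.
    """
    recs = []
    for sample, row in clinical.iterrows():
        if sample in group_by:
            recs.append(
                SurvivalRecord(str(sample), float(row["os_days"]), int(row["event"]), group_by[sample])
            )
    return recs
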