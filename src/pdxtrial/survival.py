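"""Doubling-time progression-free survival for PDX growth curves.

The progression event for a treated tumor is the first measured day on
which its volume reaches twice the treatment-start baseline; tumors that
never double within the treatment horizon are censored there. Group
survival is estimated with the Kaplan-Meier product-limit estimator and
compared across response groups with the k-sample log-rank (Mantel-Cox)
test.

Standard Kaplan-Meier conventions apply: at tied times events precede
censorings, and the curve starts at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .growth import DEFAULT_HORIZON, GrowthCurve


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-doubling of one model: ``event`` is True when doubling was
    observed at ``time_days``; censored records carry the horizon time."""

    model_id: str
    time_days: float
    event: bool
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("negative survival time")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate: survival probability and at-risk count at
    each distinct event time (times strictly increasing, survival
    non-increasing within [0, 1])."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def doubling_event(curve: GrowthCurve,
                   horizon_days: int = DEFAULT_HORIZON,
                   group: str | None = None) -> SurvivalRecord:
    """Time-to-doubling record for one growth curve.

    The baseline volume is the measurement at the day closest to day 0
    (ties to the earlier day); the event is the first later measured day
    with volume >= 2x baseline. Without such a day by ``horizon_days``
    the record is censored at the horizon.
    """
    base_day, v0 = curve.baseline()
    for day, vol in zip(curve.days, curve.volumes):
        if day <= base_day or day > horizon_days:
            continue
        if vol >= 2.0 * v0:
            return SurvivalRecord(curve.model_id, float(day), True, group)
    return SurvivalRecord(curve.model_id, float(horizon_days), False, group)


def km_fit(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit fit of a set of survival records."""
    if len(records) == 0:
        raise ValueError("km_fit needs at least one record")
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    ts = tuple(float(t) for t in event_rows.index)
    surv = tuple(float(kmf.survival_function_.loc[t].iloc[0]) for t in ts)
    at_risk = tuple(int(n) for n in event_rows["at_risk"])
    return KMEstimate(ts, surv, at_risk)


def logrank_test(records: Sequence[SurvivalRecord]) -> dict:
    """k-sample log-rank (Mantel-Cox) test across the records' groups.

    Returns ``{"chi2", "df", "p", "groups"}`` with df = k - 1. Requires at
    least two non-empty groups; every record must carry a group label.
    """
    if any(r.group is None for r in records):
        raise ValueError("all records need a group label")
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    df = pd.DataFrame({
        "time": [r.time_days for r in records],
        "event": [int(r.event) for r in records],
        "group": [r.group for r in records],
    })
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return {"chi2": float(res.test_statistic),
            "df": len(groups) - 1,
            "p": float(res.p_value),
            "groups": groups}


def records_from_curves(curves: dict[tuple[str, str], GrowthCurve],
                        groups: dict[str, str],
                        horizon_days: int = DEFAULT_HORIZON,
                        arm: str = "treated") -> list[SurvivalRecord]:
    """Doubling-time records for one arm of a scored cohort.

    ``groups`` maps model_id to its response class; models without a
    class (invalid T/C) are skipped.
    """
    records = []
    for (model_id, a), curve in sorted(curves.items()):
        if a != arm or model_id not in groups:
            continue
        records.append(doubling_event(curve, horizon_days, groups[model_id]))
    return records


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "model_id": [r.model_id for r in records],
        "time_days": [r.time_days for r in records],
        "event": [int(r.event) for r in records],
        "group": [r.group for r in records],
    })


def plot_km(records: Sequence[SurvivalRecord], path: str | None = None):
    """Kaplan-Meier step plot, one curve per response group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted({r.group for r in records}):
        sub = [r for r in records if r.group == g]
        kmf = KaplanMeierFitter()
        kmf.fit([r.time_days for r in sub], [r.event for r in sub], label=str(g))
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("days")
    ax.set_ylabel("P(progression-free)")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
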