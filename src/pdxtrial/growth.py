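"""Tumor-growth response scoring for 1x1x1 PDX trials.

Caliper readings (two perpendicular diameters per tumor per day) are
converted to volumes, each model's karonudib-treated growth is scored
against its matched vehicle-treated growth as a T/C percentage, and models
are classified into the three response groups used throughout the trial:

* progression  : T/C > 50 %
* suppression  : 0 % <= T/C <= 50 %
* regression   : T/C < 0 %

where ``T/C (%) = 100 * (T_i - T_0) / (C_i - C_0)`` with subscript ``i``
the end of treatment and ``0`` the treatment start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PROGRESSION = "progression"
SUPPRESSION = "suppression"
REGRESSION = "regression"
RESPONSE_GROUPS = (PROGRESSION, SUPPRESSION, REGRESSION)

#: Default length of the treatment window in days.
DEFAULT_HORIZON = 18

Arm = Literal["treated", "vehicle", "excluded"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCurve:
    """Ordered (day, volume) measurements of one tumor.

    Days are integers relative to treatment start (day 0); negative days
    are pre-treatment readings. Days must be strictly increasing and
    volumes strictly positive.
    """

    model_id: str
    arm: str
    days: tuple[int, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes):
            raise ValueError("days and volumes must have equal length")
        if len(self.days) == 0:
            raise ValueError("empty growth curve")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(v <= 0 for v in self.volumes):
            raise ValueError("volumes must be positive")

    def baseline(self) -> tuple[int, float]:
        """(day, volume) at treatment start: the day closest to 0, ties to
        the earlier day."""
        idx = min(range(len(self.days)),
                  key=lambda i: (abs(self.days[i]), self.days[i]))
        return self.days[idx], self.volumes[idx]

    def endpoint(self, horizon: int = DEFAULT_HORIZON) -> tuple[int, float]:
        """(day, volume) at end of treatment: the last day <= horizon."""
        eligible = [i for i, d in enumerate(self.days) if d <= horizon]
        if not eligible:
            raise ValueError(
                f"curve {self.model_id}/{self.arm} has no measurement "
                f"at or before day {horizon}")
        idx = eligible[-1]
        return self.days[idx], self.volumes[idx]


@dataclass(frozen=True)
class ResponseCall:
    """A model's T/C score and response class.

    ``valid`` is False when T/C is undefined (vehicle tumor did not grow),
    in which case ``group`` is None.
    """

    model_id: str
    tc_percent: float
    group: str | None
    valid: bool = True


# ---------------------------------------------------------------------------
# volume and scoring
# ---------------------------------------------------------------------------

def tumor_volume(shorter_mm: float, longer_mm: float) -> float:
    """Tumor volume (mm^3) from two caliper diameters.

    volume = shorter^2 * longer / 2

    Parameters
    ----------
    shorter_mm, longer_mm
        The shorter and longer perpendicular diameters in mm.
        Requires 0 < shorter <= longer.
    """
    if not (shorter_mm > 0 and longer_mm > 0):
        raise ValueError("diameters must be positive")
    if shorter_mm > longer_mm:
        raise ValueError(
            f"shorter diameter ({shorter_mm}) exceeds longer ({longer_mm})")
    return shorter_mm ** 2 * longer_mm / 2.0


def tc_ratio(treated: GrowthCurve, control: GrowthCurve,
             horizon: int = DEFAULT_HORIZON) -> tuple[float, bool]:
    """Treated-over-control growth percentage.

    Returns ``(tc_percent, valid)``. The score is
    ``100 * (T_i - T_0) / (C_i - C_0)`` with the baseline taken at the
    day closest to 0 and the endpoint at each arm's own last day within
    the horizon. When the vehicle tumor did not grow (C_i - C_0 <= 0) the
    ratio is meaningless; ``(nan, False)`` is returned.
    """
    _, t0 = treated.baseline()
    _, ti = treated.endpoint(horizon)
    _, c0 = control.baseline()
    _, ci = control.endpoint(horizon)
    denom = ci - c0
    if denom <= 0:
        return float("nan"), False
    return 100.0 * (ti - t0) / denom, True


def classify_response(tc_percent: float) -> str:
    """Map a T/C percentage to its response class.

    >50 -> progression; [0, 50] -> suppression; <0 -> regression.
    The three classes partition the finite reals.
    """
    if not math.isfinite(tc_percent):
        raise ValueError(f"T/C must be finite, got {tc_percent}")
    if tc_percent > 50.0:
        return PROGRESSION
    if tc_percent >= 0.0:
        return SUPPRESSION
    return REGRESSION


def growth_speed(curve: GrowthCurve, method: str = "secant") -> float:
    """Average growth speed in mm^3/day.

    ``secant`` (default) is the volume change over the full observation
    window divided by the elapsed days; ``regression`` is the slope of an
    ordinary least-squares fit of volume on day.
    """
    if len(curve.days) < 2:
        raise ValueError("growth speed needs at least two measurements")
    if method == "secant":
        return ((curve.volumes[-1] - curve.volumes[0])
                / (curve.days[-1] - curve.days[0]))
    if method == "regression":
        slope, _ = np.polyfit(curve.days, curve.volumes, 1)
        return float(slope)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ("model_id", "mouse_id", "arm", "day",
                       "shorter_mm", "longer_mm")


def measurements_to_curves(measurements: pd.DataFrame) -> dict[tuple[str, str], GrowthCurve]:
    """Build one GrowthCurve per (model, arm) from a caliper table.

    The table needs the columns ``model_id, mouse_id, arm, day, shorter_mm,
    longer_mm``; the excluded third mouse is ignored.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    curves: dict[tuple[str, str], GrowthCurve] = {}
    use = measurements[measurements["arm"].isin(["treated", "vehicle"])]
    for (model_id, arm), grp in use.groupby(["model_id", "arm"], sort=True):
        grp = grp.sort_values("day")
        vols = [tumor_volume(s, l)
                for s, l in zip(grp["shorter_mm"], grp["longer_mm"])]
        curves[(str(model_id), str(arm))] = GrowthCurve(
            model_id=str(model_id), arm=str(arm),
            days=tuple(int(d) for d in grp["day"]),
            volumes=tuple(vols))
    return curves


def score_cohort(measurements: pd.DataFrame,
                 horizon: int = DEFAULT_HORIZON) -> list[ResponseCall]:
    """Score every model in a caliper table: volume -> T/C -> class."""
    curves = measurements_to_curves(measurements)
    models = sorted({m for m, _ in curves})
    calls = []
    for model in models:
        try:
            treated = curves[(model, "treated")]
            control = curves[(model, "vehicle")]
        except KeyError:
            raise ValueError(f"model {model} lacks a treated or vehicle arm")
        tc, valid = tc_ratio(treated, control, horizon)
        group = classify_response(tc) if valid else None
        calls.append(ResponseCall(model, tc, group, valid))
    return calls


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def waterfall(calls: Iterable[ResponseCall]) -> pd.DataFrame:
    """Waterfall table: valid calls sorted by descending T/C.

    Columns: model_id, tc_percent, tc_rounded, group. Invalid calls are
    dropped with a warning; an all-invalid input yields an empty table.
    """
    calls = list(calls)
    valid = [c for c in calls if c.valid]
    n_dropped = len(calls) - len(valid)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} model(s) with undefined T/C "
                      "(vehicle tumor did not grow)")
    if not valid:
        warnings.warn("waterfall: no valid response calls")
        return pd.DataFrame(columns=["model_id", "tc_percent", "tc_rounded", "group"])
    rows = sorted(valid, key=lambda c: -c.tc_percent)
    return pd.DataFrame({
        "model_id": [c.model_id for c in rows],
        "tc_percent": [c.tc_percent for c in rows],
        "tc_rounded": [round_half_away(c.tc_percent) for c in rows],
        "group": [c.group for c in rows],
    })


def class_proportions(calls: Iterable[ResponseCall]) -> dict[str, int]:
    """Per-class percentages of valid calls, rounded half away from zero.

    With the trial's 8/13/10 split of 31 models this reports
    regression 26 %, suppression 42 %, progression 32 %.
    """
    valid = [c for c in calls if c.valid]
    if not valid:
        raise ValueError("no valid calls")
    n = len(valid)
    return {g: round_half_away(100.0 * sum(c.group == g for c in valid) / n)
            for g in RESPONSE_GROUPS}


def summarize_groups(calls: Sequence[ResponseCall],
                     curves: dict[tuple[str, str], GrowthCurve],
                     compare: tuple[str, str] | None = None,
                     method: str = "secant") -> tuple[pd.DataFrame, dict | None]:
    """Per-group growth-speed summary for both arms, plus an optional t test.

    Returns a table with one row per (group, arm): n, mean speed, SEM
    (NaN when n < 2), and, when ``compare`` names two groups, a two-sided
    two-sample t test between those groups' vehicle-arm speeds.
    """
    by_group: dict[str, dict[str, list[float]]] = {
        g: {"treated": [], "vehicle": []} for g in RESPONSE_GROUPS}
    for call in calls:
        if not call.valid:
            continue
        for arm in ("treated", "vehicle"):
            curve = curves.get((call.model_id, arm))
            if curve is not None and len(curve.days) >= 2:
                by_group[call.group][arm].append(growth_speed(curve, method))
    rows = []
    for g in RESPONSE_GROUPS:
        for arm in ("treated", "vehicle"):
            speeds = np.asarray(by_group[g][arm], dtype=float)
            n = speeds.size
            mean = speeds.mean() if n else float("nan")
            sem = float(stats.sem(speeds)) if n >= 2 else float("nan")
            rows.append({"group": g, "arm": arm, "n": n,
                         "mean_speed": mean, "sem_speed": sem})
    summary = pd.DataFrame(rows)
    test = None
    if compare is not None:
        a, b = compare
        xs = by_group[a]["vehicle"]
        ys = by_group[b]["vehicle"]
        if len(xs) >= 2 and len(ys) >= 2:
            t, p = stats.ttest_ind(xs, ys)
            test = {"groups": (a, b), "t": float(t), "p": float(p)}
        else:
            test = {"groups": (a, b), "t": float("nan"), "p": float("nan")}
    return summary, test


def plot_waterfall(table: pd.DataFrame, path: str | None = None):
    """Bar plot of the waterfall table, colored by response group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {PROGRESSION: "#3b6fb5", SUPPRESSION: "#e8c547", REGRESSION: "#c0392b"}
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(table)), table["tc_percent"],
           color=[colors[g] for g in table["group"]])
    ax.axhline(50, ls="--", lw=0.8, c="grey")
    ax.axhline(0, lw=0.8, c="black")
    ax.set_ylabel("T/C (%)")
    ax.set_xlabel("PDX model (sorted)")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
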