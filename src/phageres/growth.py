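"""Growth-curve metrics: lag, maximum rate, integral and yield from OD600.

All four parameters are computed on the linear OD scale (units OD600/h for
the rate), never log-transformed.  The maximum rate is the largest
least-squares slope over a sliding window of readings; lag is obtained by
the tangent method (where the line through the max-rate window's centroid
with the max-rate slope crosses the baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

NO_PHAGE = "no_phage"

#: slopes below this (OD600/h) mean "never grew" for lag purposes
DEFAULT_MIN_RATE = 0.005
DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series for a lineage under one condition."""

    lineage: str
    condition: str  # NO_PHAGE or a phage name
    times: np.ndarray  # hours, strictly increasing, starting at 0
    od: np.ndarray  # OD600, same length, each >= 0
    plate_id: str = "plate1"
    replicate: str = "t1"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(times) < 5:
            raise ValueError("a growth curve needs at least 5 timepoints")
        if times[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD readings must be non-negative")

    @property
    def duration_h(self) -> float:
        return float(self.times[-1])

    def od_at(self, t: float) -> float:
        """OD at time t, linearly interpolated between bracketing samples."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"time {t} h outside curve range [0, {self.duration_h}]")
        return float(np.interp(t, self.times, self.od))


@dataclass(frozen=True)
class GrowthMetrics:
    """Lag, max rate, integral, yield for one curve."""

    lineage: str
    condition: str
    plate_id: str
    lag_h: float
    max_rate: float  # OD600/h
    integral: float  # OD600 * h above baseline
    yield_od: float  # max OD600
    no_growth: bool = False
    replicate: str = "t1"


class LagResult(NamedTuple):
    lag_h: float
    no_growth: bool


def baseline_od(curve: GrowthCurve) -> float:
    """Baseline OD: min(median of the first 3 readings, first reading).

    The median guards against a single spuriously high initial read; taking
    the min with the first reading keeps the baseline at the starting OD for
    curves that grow from t = 0.
    """
    return float(min(np.median(curve.od[:3]), curve.od[0]))


def _window_slopes(times: np.ndarray, od: np.ndarray, window: int):
    """Least-squares slope and (t, od) centroid of every length-`window` run."""
    tw = np.lib.stride_tricks.sliding_window_view(times, window)
    yw = np.lib.stride_tricks.sliding_window_view(od, window)
    tc = tw.mean(axis=1)
    yc = yw.mean(axis=1)
    dt = tw - tc[:, None]
    denom = (dt**2).sum(axis=1)
    slopes = (dt * (yw - yc[:, None])).sum(axis=1) / denom
    return slopes, tc, yc


def max_growth_rate(curve: GrowthCurve, window: int = DEFAULT_WINDOW) -> float:
    """Maximum sliding-window least-squares slope of OD vs time (OD600/h)."""
    if window < 2 or window > len(curve.times):
        raise ValueError(
            f"window must be in [2, {len(curve.times)}], got {window}"
        )
    slopes, _, _ = _window_slopes(curve.times, curve.od, window)
    return float(slopes.max())


def lag_time(
    curve: GrowthCurve,
    window: int = DEFAULT_WINDOW,
    min_rate: float = DEFAULT_MIN_RATE,
) -> LagResult:
    """Tangent-method lag: where the max-rate tangent crosses the baseline.

    A curve whose maximum rate is below ``min_rate`` never grew within the
    assay; by convention its lag is the full duration, flagged ``no_growth``.
    """
    if window < 2 or window > len(curve.times):
        raise ValueError(
            f"window must be in [2, {len(curve.times)}], got {window}"
        )
    slopes, tc, yc = _window_slopes(curve.times, curve.od, window)
    i = int(np.argmax(slopes))
    rate = slopes[i]
    if rate < min_rate:
        return LagResult(curve.duration_h, True)
    lag = tc[i] - (yc[i] - baseline_od(curve)) / rate
    return LagResult(float(np.clip(lag, 0.0, curve.duration_h)), False)


def curve_integral(curve: GrowthCurve) -> float:
    """Trapezoidal area of (OD − baseline), clipped below at 0 (OD600·h)."""
    above = np.clip(curve.od - baseline_od(curve), 0.0, None)
    return float(np.trapezoid(above, curve.times))


def yield_od(curve: GrowthCurve) -> float:
    """Maximum OD600 reached."""
    return float(curve.od.max())


def extract_metrics(
    curve: GrowthCurve,
    window: int = DEFAULT_WINDOW,
    min_rate: float = DEFAULT_MIN_RATE,
) -> GrowthMetrics:
    lag = lag_time(curve, window=window, min_rate=min_rate)
    return GrowthMetrics(
        lineage=curve.lineage,
        condition=curve.condition,
        plate_id=curve.plate_id,
        replicate=curve.replicate,
        lag_h=lag.lag_h,
        max_rate=max_growth_rate(curve, window=window),
        integral=curve_integral(curve),
        yield_od=yield_od(curve),
        no_growth=lag.no_growth,
    )


METRIC_COLUMNS = ("lag_h", "max_rate", "integral", "yield_od")


def metrics_frame(metrics: Iterable[GrowthMetrics]) -> pd.DataFrame:
    rows = [
        {
            "lineage": m.lineage,
            "condition": m.condition,
            "plate_id": m.plate_id,
            "replicate": m.replicate,
            "lag_h": m.lag_h,
            "max_rate": m.max_rate,
            "integral": m.integral,
            "yield_od": m.yield_od,
            "no_growth": m.no_growth,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows)


def metric_correlations(metrics: Sequence[GrowthMetrics] | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r and R² across the four growth parameters.

    A metric with zero variance yields NaN (undefined) for its pairs rather
    than raising.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if len(df) < 3:
        raise ValueError("need at least 3 metric records for correlations")
    rows = []
    for i, a in enumerate(METRIC_COLUMNS):
        for b in METRIC_COLUMNS[i + 1 :]:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"metric_a": a, "metric_b": b, "r": r, "r2": r * r})
    return pd.DataFrame(rows)


DEFAULT_COLUMN_MAP = {
    "lineage": "lineage",
    "condition": "condition",
    "time_h": "time_h",
    "od600": "od600",
    "plate_id": "plate_id",
    "replicate": "replicate",
}


def read_plate_csv(path, column_map: dict | None = None) -> list[GrowthCurve]:
    """Read long-format plate-reader CSV into GrowthCurve objects.

    Expected columns (remappable via ``column_map`` for other dialects):
    lineage, condition, time_h, od600, and optionally plate_id, replicate.
    One curve is built per (lineage, condition, plate_id, replicate).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    for optional, default in (("plate_id", "plate1"), ("replicate", "t1")):
        if optional not in df.columns:
            df[optional] = default
    curves = []
    for (lineage, condition, plate, rep), grp in df.groupby(
        ["lineage", "condition", "plate_id", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                lineage=str(lineage),
                condition=str(condition),
                plate_id=str(plate),
                replicate=str(rep),
                times=grp["time_h"].to_numpy(float),
                od=grp["od600"].to_numpy(float),
            )
        )
    return curves
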