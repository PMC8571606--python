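"""Maximum growth-rate estimation from OD600 microplate time series.

The estimator is a sliding-window log-linear regression: a straight line is
fit to ``ln(OD - background)`` over every contiguous window of readings, and
the steepest slope among admissible windows is reported as the maximum
specific growth rate (per hour).  A window is admissible when its smallest
background-subtracted OD is at least ``min_od``, which keeps the logarithm
away from reader noise.

Calibration: OD600 of 1.0 corresponds to ~2.97e7 cells/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "CELLS_PER_ML_PER_OD",
    "estimate_max_growth_rate",
    "od_to_cells",
    "normalized_rate",
    "read_growth_curves",
]

#: Cells per ml per unit OD600 (plating calibration of the reference strain).
CELLS_PER_ML_PER_OD = 2.97e7


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series. Times in hours, strictly increasing."""

    well_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.shape != times.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError("need at least two readings")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("negative OD reading")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Winning window of the sliding-window fit.

    ``rate`` is the slope of ln(OD) in 1/h, ``window_start`` the first
    timestamp of the winning window (hours), ``r_squared`` the coefficient of
    determination of that window's fit.
    """

    well_id: str
    rate: float
    window_start: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate):
            raise ValueError("rate must be finite")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must be in [0, 1]")


def estimate_max_growth_rate(
    curve: GrowthCurve,
    window: int = 9,
    background: float | None = None,
    min_od: float = 0.005,
    min_r_squared: float = 0.95,
) -> GrowthRateEstimate | None:
    """Maximum specific growth rate by sliding-window log-linear regression.

    Parameters
    ----------
    curve
        The OD600 time series.
    window
        Number of consecutive readings per regression window (default 9,
        i.e. 3 h at 20-min sampling).
    background
        OD offset subtracted before taking logs.  ``None`` (default) uses
        the minimum of the first three readings — appropriate for real
        plate-reader data that includes a medium blank.  Pass ``0.0``
        explicitly for data known to be blank-free.
    min_od
        Admissibility floor: every background-subtracted OD in a window must
        be at least this value (default 0.005).
    min_r_squared
        Windows whose log-linear fit explains less than this share of the
        variance are skipped (default 0.95).  Taking the maximum over raw
        noisy windows is badly upward-biased at low OD; requiring a clean
        exponential fit removes that bias without touching noiseless data.

    Returns
    -------
    The :class:`GrowthRateEstimate` of the steepest admissible window
    (earliest window wins ties), or ``None`` when no window is admissible —
    an explicit "no growth detected" result rather than a zero estimate.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if len(curve) < window:
        raise ValueError(f"curve has {len(curve)} points, window is {window}")
    if background is None:
        background = float(np.min(curve.od[:3]))
    corrected = curve.od - background

    best: GrowthRateEstimate | None = None
    for start in range(len(curve) - window + 1):
        seg = corrected[start : start + window]
        if seg.min() < min_od:
            continue
        t = curve.times[start : start + window]
        y = np.log(seg)
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        if r2 < min_r_squared:
            continue
        if best is None or slope > best.rate:
            best = GrowthRateEstimate(
                curve.well_id, float(slope), float(t[0]), min(max(r2, 0.0), 1.0), window
            )
    return best


def od_to_cells(od: float, volume_ml: float) -> float:
    """Convert an OD600 reading to absolute cell number in ``volume_ml`` ml."""
    if od < 0:
        raise ValueError("od must be >= 0")
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    return od * CELLS_PER_ML_PER_OD * volume_ml


def normalized_rate(test: GrowthRateEstimate, reference: GrowthRateEstimate) -> float:
    """Growth rate of ``test`` as a fraction of ``reference`` (1.0 = equal)."""
    if reference.rate <= 0:
        raise ValueError("reference rate must be > 0")
    return test.rate / reference.rate


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """Read growth curves from CSV, auto-detecting the layout by header.

    Two layouts are supported:

    * long format with columns ``well, time_min, od600`` (the synthetic-data
      writer's format);
    * wide "Bioscreen-style": first column is time (minutes if named
      ``time_min`` or similar, hours if named ``time_h``), one column per
      well.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if {"well", "time_min", "od600"} <= set(cols):
        curves = []
        for well, grp in df.groupby("well", sort=False):
            grp = grp.sort_values("time_min")
            curves.append(
                GrowthCurve(str(well), grp["time_min"].to_numpy() / 60.0, grp["od600"].to_numpy())
            )
        return curves
    # wide layout: first column is time, the rest are wells
    time_col = cols[0]
    times = df[time_col].to_numpy(dtype=float)
    if "min" in time_col:
        times = times / 60.0
    elif "h" not in time_col:
        raise ValueError(
            f"cannot tell the time unit of column {time_col!r}; "
            "name it time_min or time_h"
        )
    return [GrowthCurve(str(c), times, df[c].to_numpy(dtype=float)) for c in cols[1:]]
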