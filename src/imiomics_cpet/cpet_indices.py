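"""CPET index computation and inclusion filtering.

Operates on breath-by-breath tables from an incremental ramp test
(10 W/min, starting at 50 W for males and 30 W for females) and derives
the standard clinical indices:

* V̇O2peak — maximum of the rolling-mean V̇O2 over the exercise phase;
* RERpeak — maximum of rolling-mean V̇CO2 / rolling-mean V̇O2;
* V̇E/V̇CO2-slope (ventilatory efficiency) — OLS slope of minute
  ventilation on CO2 output from exercise onset to the respiratory
  compensation point when one is detected, else over the whole
  exercise phase;
* ΔV̇O2/ΔWR (work efficiency) — OLS slope of V̇O2 on work rate over the
  loaded portion of the ramp;
* V̇O2kg, V̇O2lean, V̇O2HR — V̇O2peak scaled by body weight, lean mass and
  peak heart rate.

Inclusion criteria for a (near-)maximal test: peak heart rate at least
85% of predicted (220 minus age), RERpeak at least 1.0, and not an
active smoker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BREATH_COLUMNS = ("time_s", "wr_watt", "vo2_ml_min", "vco2_ml_min", "ve_l_min", "hr_bpm")


@dataclass
class BreathSeries:
    """One breath-by-breath test: time in s, WR in W, V̇O2/V̇CO2 in mL/min,
    V̇E in L/min, HR in bpm, plus exercise-phase sample indices
    (``exercise_end`` inclusive)."""

    time: np.ndarray
    wr: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray
    hr: np.ndarray
    exercise_start: int
    exercise_end: int
    subject_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time", "wr", "vo2", "vco2", "ve", "hr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if not all(getattr(self, k).size == n for k in ("wr", "vo2", "vco2", "ve", "hr")):
            raise ValueError("all breath channels must share one length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.exercise_end < self.exercise_start:
            raise ValueError("exercise phase is empty")
        if not (0 <= self.exercise_start <= self.exercise_end < n):
            raise ValueError("exercise phase indices out of range")

    @property
    def exercise(self) -> slice:
        return slice(self.exercise_start, self.exercise_end + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "wr_watt": self.wr,
                "vo2_ml_min": self.vo2,
                "vco2_ml_min": self.vco2,
                "ve_l_min": self.ve,
                "hr_bpm": self.hr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str | None = None) -> "BreathSeries":
        missing = [c for c in BREATH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"breath table missing columns {missing}")
        loaded = np.flatnonzero(df["wr_watt"].to_numpy() > 0)
        if loaded.size == 0:
            raise ValueError("no loaded (WR > 0) samples; exercise phase empty")
        return cls(
            time=df["time_s"].to_numpy(),
            wr=df["wr_watt"].to_numpy(),
            vo2=df["vo2_ml_min"].to_numpy(),
            vco2=df["vco2_ml_min"].to_numpy(),
            ve=df["ve_l_min"].to_numpy(),
            hr=df["hr_bpm"].to_numpy(),
            exercise_start=int(loaded[0]),
            exercise_end=int(loaded[-1]),
            subject_id=subject_id,
        )

    @classmethod
    def from_csv(cls, path, subject_id: str | None = None) -> "BreathSeries":
        return cls.from_frame(pd.read_csv(path), subject_id=subject_id)


@dataclass
class CpetIndices:
    vo2peak: float
    rerpeak: float
    peak_hr: float
    peak_wr: float
    vevco2_slope: float
    rcp_detected: bool
    dvo2_dwr: float
    vo2kg: float = math.nan
    vo2lean: float = math.nan
    vo2hr: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "vo2peak": self.vo2peak,
            "vo2kg": self.vo2kg,
            "vo2lean": self.vo2lean,
            "vo2hr": self.vo2hr,
            "vevco2_slope": self.vevco2_slope,
            "dvo2_dwr": self.dvo2_dwr,
            "rerpeak": self.rerpeak,
            "peak_wr": self.peak_wr,
            "peak_hr": self.peak_hr,
            "rcp_detected": self.rcp_detected,
        }


# ---------------------------------------------------------------------------
# Peak values
# ---------------------------------------------------------------------------

def _rolling_mean(time: np.ndarray, values: np.ndarray, window_s: float) -> np.ndarray:
    """Trailing rolling mean: at sample i, mean over samples j with
    time[i] - window_s < time[j] <= time[i]."""
    out = np.empty_like(values, dtype=float)
    j0 = 0
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(values.size):
        while time[j0] <= time[i] - window_s:
            j0 += 1
        out[i] = (csum[i + 1] - csum[j0]) / (i + 1 - j0)
    return out


def peak_values(series: BreathSeries, window_s: float = 30.0):
    """Rolling-mean peak V̇O2, peak RER, peak HR and end-exercise WR.

    Returns ``(vo2peak, rerpeak, peak_hr, peak_wr)``.  RER is the ratio
    of the rolling-mean V̇CO2 to the rolling-mean V̇O2, maximised over the
    exercise phase.
    """
    ex = series.exercise
    t, vo2, vco2 = series.time[ex], series.vo2[ex], series.vco2[ex]
    if t.size == 0:
        raise ValueError("exercise phase is empty")
    if t[-1] - t[0] < window_s and t.size > 1:
        raise ValueError(
            f"exercise phase ({t[-1] - t[0]:.0f} s) shorter than the "
            f"{window_s:.0f} s averaging window"
        )
    vo2_roll = _rolling_mean(t, vo2, window_s)
    vco2_roll = _rolling_mean(t, vco2, window_s)
    if np.any(vo2_roll <= 0):
        raise ValueError("non-positive rolling-mean V̇O2; RER undefined")
    vo2peak = float(vo2_roll.max())
    rerpeak = float((vco2_roll / vo2_roll).max())
    peak_hr = float(series.hr[ex].max())
    peak_wr = float(series.wr[series.exercise_end])
    return vo2peak, rerpeak, peak_hr, peak_wr


# ---------------------------------------------------------------------------
# Regression slopes
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line with intercept; returns (slope, intercept, rss)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate regressor (zero variance)")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    return slope, float(intercept), float((resid**2).sum())


def _two_segment_fit(x: np.ndarray, y: np.ndarray, min_seg: int = 5):
    """Exhaustive two-segment piecewise-linear fit.

    Splits after index k (segment 1 = [0..k], segment 2 = [k+1..n-1]);
    returns (k, slope1, slope2, total_rss) at the minimum-RSS split, or
    None if no admissible split exists.
    """
    n = x.size
    best = None
    for k in range(min_seg - 1, n - min_seg):
        x1, y1 = x[: k + 1], y[: k + 1]
        x2, y2 = x[k + 1 :], y[k + 1 :]
        if np.ptp(x1) == 0 or np.ptp(x2) == 0:
            continue
        s1, _, r1 = _ols_slope(x1, y1)
        s2, _, r2 = _ols_slope(x2, y2)
        rss = r1 + r2
        if best is None or rss < best[3]:
            best = (k, s1, s2, rss)
    return best


def ve_vco2_slope(
    series: BreathSeries,
    slope_ratio: float = 1.15,
    min_segment: int = 5,
) -> tuple[float, bool]:
    """Ventilatory efficiency: OLS slope of V̇E (L/min) on V̇CO2 (L/min)
    from exercise onset to the respiratory compensation point.

    The RCP is located by an exhaustive two-segment piecewise-linear fit
    of V̇E against V̇CO2 (breakpoint at minimum residual sum of squares)
    and accepted only when the second-segment slope exceeds the first by
    ``slope_ratio``.  Without an accepted RCP the slope is fitted over
    the full exercise phase.

    Returns ``(slope, rcp_detected)``.
    """
    ex = series.exercise
    x = series.vco2[ex] / 1000.0  # mL/min -> L/min
    y = series.ve[ex]
    if x.size < 10:
        raise ValueError("need at least 10 exercise-phase samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate V̇CO2 (zero variance)")
    fit = _two_segment_fit(x, y, min_seg=min_segment)
    if fit is not None:
        k, s1, s2, _ = fit
        if s1 > 0 and s2 > slope_ratio * s1:
            return s1, True
    slope, _, _ = _ols_slope(x, y)
    return slope, False


def delta_vo2_wr(series: BreathSeries, start_load: float | None = None) -> float:
    """Work efficiency ΔV̇O2/ΔWR: OLS slope of V̇O2 (mL/min) on WR (W)
    over the loaded ramp, using only samples with WR above the starting
    load (strictly, "from the start of work")."""
    ex = series.exercise
    wr = series.wr[ex]
    vo2 = series.vo2[ex]
    if start_load is None:
        start_load = float(wr[0])
    loaded = wr > start_load
    if loaded.sum() < 10:
        raise ValueError("need at least 10 samples above the starting load")
    x, y = wr[loaded], vo2[loaded]
    if np.ptp(x) == 0:
        raise ValueError("constant WR: ramp absent")
    slope, _, _ = _ols_slope(x, y)
    return slope


# ---------------------------------------------------------------------------
# Scaling and inclusion
# ---------------------------------------------------------------------------

def scale_indices(
    vo2peak: float,
    weight: float,
    lean_mass: float | None,
    peak_hr: float,
) -> tuple[float, float, float]:
    """Scale V̇O2peak by weight (V̇O2kg), lean mass (V̇O2lean) and peak HR
    (V̇O2HR, oxygen pulse).  A missing lean mass (None/NaN, mirroring
    participants without a DXA scan) yields NaN for V̇O2lean only."""
    if weight <= 0 or peak_hr <= 0:
        raise ValueError("weight and peak HR must be positive")
    vo2kg = vo2peak / weight
    if lean_mass is None or (isinstance(lean_mass, float) and math.isnan(lean_mass)):
        vo2lean = math.nan
    elif lean_mass <= 0:
        raise ValueError("lean mass must be positive when present")
    else:
        vo2lean = vo2peak / lean_mass
    vo2hr = vo2peak / peak_hr
    return vo2kg, vo2lean, vo2hr


@dataclass
class InclusionResult:
    included: bool
    reasons: tuple[str, ...]  # subset of {"low_peak_hr", "low_rer", "smoker", "missing"}


def inclusion_filter(
    peak_hr: float,
    rerpeak: float,
    age: float,
    smoker: bool,
    hr_fraction: float = 0.85,
    rer_min: float = 1.0,
) -> InclusionResult:
    """Near-maximal-test inclusion rule: peak HR >= 85% of predicted
    (220 - age), RERpeak >= 1.0 (the boundary value counts as included),
    and not an active smoker.  Missing values exclude with reason
    ``"missing"``."""
    reasons: list[str] = []
    vals = {"peak_hr": peak_hr, "rerpeak": rerpeak, "age": age}
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals.values()):
        reasons.append("missing")
    else:
        if peak_hr < hr_fraction * (220.0 - age):
            reasons.append("low_peak_hr")
        if rerpeak < rer_min:
            reasons.append("low_rer")
    if smoker:
        reasons.append("smoker")
    return InclusionResult(included=not reasons, reasons=tuple(reasons))


def compute_indices(
    series: BreathSeries,
    weight: float,
    lean_mass: float | None,
    window_s: float = 30.0,
    slope_ratio: float = 1.15,
) -> CpetIndices:
    """Full per-test index computation."""
    vo2peak, rerpeak, peak_hr, peak_wr = peak_values(series, window_s=window_s)
    slope, rcp = ve_vco2_slope(series, slope_ratio=slope_ratio)
    dwr = delta_vo2_wr(series)
    vo2kg, vo2lean, vo2hr = scale_indices(vo2peak, weight, lean_mass, peak_hr)
    return CpetIndices(
        vo2peak=vo2peak,
        rerpeak=rerpeak,
        peak_hr=peak_hr,
        peak_wr=peak_wr,
        vevco2_slope=slope,
        rcp_detected=rcp,
        dvo2_dwr=dwr,
        vo2kg=vo2kg,
        vo2lean=vo2lean,
        vo2hr=vo2hr,
    )


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))
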