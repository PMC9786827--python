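"""Per-eye temporal change detection by linear regression.

An eye progresses when the ordinary-least-squares slope of its GIP (or cup
area %) on time differs from zero at p < 0.01 with at least 4 examinations.
The test is two-sided with the direction reported separately, which keeps
the null calibration at exactly alpha; zero-residual (perfectly linear)
series are assigned p = 0 by convention.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ProgressionConfig

__all__ = [
    "ExamSeries",
    "TrendFit",
    "ProgressionResult",
    "fit_trend",
    "flag_progression",
    "analyse_series",
    "progression_table",
    "years_since_first",
]

DAYS_PER_YEAR = 365.25


def years_since_first(dates: list[str]) -> np.ndarray:
    """Decimal years (365.25 d/yr) from the first exam, from ISO-8601 dates."""
    ds = [_dt.date.fromisoformat(d) for d in dates]
    return np.array([(d - ds[0]).days / DAYS_PER_YEAR for d in ds])


@dataclass
class ExamSeries:
    eye_id: str
    dates: list  # ISO-8601 strings, strictly increasing
    gip: np.ndarray
    cup_area_pct: np.ndarray
    gdf: np.ndarray | None = None

    def __post_init__(self):
        self.gip = np.asarray(self.gip, dtype=float)
        self.cup_area_pct = np.asarray(self.cup_area_pct, dtype=float)
        if len(self.dates) < 1:
            raise ValueError("need at least one exam")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")

    @property
    def n_exams(self) -> int:
        return len(self.dates)

    @property
    def times(self) -> np.ndarray:
        return years_since_first(self.dates)


@dataclass
class TrendFit:
    slope: float
    se: float
    p: float  # NaN when fewer than 3 points
    r: float


@dataclass
class ProgressionResult:
    eye_id: str
    n_exams: int
    gip_trend: TrendFit
    cup_trend: TrendFit
    flagged: bool = False
    direction: str = "flat"  # worsening | improving | flat
    extras: dict = field(default_factory=dict)


def fit_trend(times_years: np.ndarray, values: np.ndarray) -> TrendFit:
    """OLS of value on time; two-sided p from t with n-2 df; r = Pearson.

    Fewer than 3 points leave p (and r for n=2 the trivial +/-1) undefined as
    NaN so the progression flag can never be set.  All-equal times are
    rejected.
    """
    t = np.asarray(times_years, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need at least two (time, value) pairs")
    if np.ptp(t) == 0:
        raise ValueError("times have zero variance")
    res = stats.linregress(t, y)
    n = t.size
    if n < 3:
        return TrendFit(slope=float(res.slope), se=float("nan"),
                        p=float("nan"), r=float("nan"))
    fitted = res.intercept + res.slope * t
    sse = float(np.sum((y - fitted) ** 2))
    if sse <= 1e-12 * max(1.0, float(np.sum(y ** 2))):
        # perfectly linear, zero residual variance: p = 0 by convention for
        # a non-zero slope, p = 1 for an exactly constant series
        p0 = 0.0 if abs(res.slope) > 1e-12 else 1.0
        return TrendFit(slope=float(res.slope), se=0.0, p=p0, r=float(res.rvalue))
    return TrendFit(slope=float(res.slope), se=float(res.stderr),
                    p=float(res.pvalue), r=float(res.rvalue))


def flag_progression(result: ProgressionResult,
                     cfg: ProgressionConfig | None = None) -> ProgressionResult:
    """Set the flag iff p < alpha and n_exams >= min_exams (GIP trend)."""
    cfg = cfg or ProgressionConfig()
    p = result.gip_trend.p
    slope = result.gip_trend.slope
    flagged = bool(np.isfinite(p) and p < cfg.alpha and result.n_exams >= cfg.min_exams)
    if cfg.require_negative_slope and slope >= 0:
        flagged = False
    result.flagged = flagged
    if flagged:
        result.direction = "worsening" if slope < 0 else "improving"
    else:
        result.direction = "flat"
    return result


def analyse_series(series: ExamSeries,
                   cfg: ProgressionConfig | None = None) -> ProgressionResult:
    """Fit GIP and cup-area trends for one eye and apply the flag rule."""
    t = series.times
    if series.n_exams >= 2 and np.ptp(t) > 0:
        gip_trend = fit_trend(t, series.gip)
        cup_trend = fit_trend(t, series.cup_area_pct)
    else:
        nan = float("nan")
        gip_trend = TrendFit(nan, nan, nan, nan)
        cup_trend = TrendFit(nan, nan, nan, nan)
    res = ProgressionResult(eye_id=series.eye_id, n_exams=series.n_exams,
                            gip_trend=gip_trend, cup_trend=cup_trend)
    return flag_progression(res, cfg)


def progression_table(cohort: list[ExamSeries],
                      cfg: ProgressionConfig | None = None) -> pd.DataFrame:
    """Per-exam-count summary of detected progression.

    One row per exam count from ``min_exams`` to the maximum observed:
    number of eyes, % progressed, and mean/sd of the GIP and cup-area slopes
    over the flagged eyes in that bin.
    """
    cfg = cfg or ProgressionConfig()
    if not cohort:
        raise ValueError("empty cohort")
    results = [analyse_series(s, cfg) for s in cohort]
    max_n = max(r.n_exams for r in results)
    rows = []
    for n in range(cfg.min_exams, max_n + 1):
        sub = [r for r in results if r.n_exams == n]
        if not sub:
            continue
        flagged = [r for r in sub if r.flagged]
        gip_slopes = np.array([r.gip_trend.slope for r in flagged])
        cup_slopes = np.array([r.cup_trend.slope for r in flagged])
        rows.append({
            "n_exams": n,
            "n_eyes": len(sub),
            "pct_progressed": 100.0 * len(flagged) / len(sub),
            "gip_slope_mean": float(gip_slopes.mean()) if flagged else np.nan,
            "gip_slope_sd": float(gip_slopes.std(ddof=1)) if len(flagged) > 1 else np.nan,
            "cup_slope_mean": float(cup_slopes.mean()) if flagged else np.nan,
            "cup_slope_sd": float(cup_slopes.std(ddof=1)) if len(flagged) > 1 else np.nan,
        })
    return pd.DataFrame(rows)
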