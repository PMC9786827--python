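"""Cross-sectional screening-rate and association analyses.

Operates on a per-eye results table (one row per eye at its last analysed
exam): screening-positive rates at the calibrated thresholds, age-binned
group comparison with chi-square tests, and the correlation panel
(GDF ~ disc area, GDF ~ vertical C/D, disc area ~ vertical C/D, inter-eye
GDF).  Pearson correlations throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "last_exam_per_eye",
    "screening_rates",
    "age_binned_comparison",
    "association_panel",
]


def last_exam_per_eye(records: pd.DataFrame) -> pd.DataFrame:
    """Keep each eye's most recent exam (cross-sectional selection rule)."""
    if "exam_date" not in records.columns:
        return records
    idx = records.sort_values("exam_date").groupby(
        ["patient_id", "eye"], sort=False).tail(1).index
    return records.loc[idx]


def screening_rates(records: pd.DataFrame,
                    thresholds: tuple[float, ...] = (0.0, -15.0)) -> dict:
    """Per-eye and per-patient screening-positive rates.

    Per-eye: percentage of eyes with GDF below each threshold.  Per-patient
    (patients with both eyes analysed): percentage with both eyes below -15,
    and with one eye below -15 while the other lies in [-15, 0).
    """
    if records.empty:
        raise ValueError("no records")
    gdf = records["GDF"].to_numpy()
    out = {
        "n_eyes": int(len(records)),
        "per_eye": {f"pct_below_{t:g}": float(100.0 * np.mean(gdf < t))
                    for t in thresholds},
    }
    wide = records.pivot_table(index="patient_id", columns="eye", values="GDF",
                               aggfunc="last")
    both = wide.dropna()
    if not both.empty:
        lo = both.min(axis=1)
        hi = both.max(axis=1)
        both_below = (hi < -15).mean()
        one_below_other_mid = ((lo < -15) & (hi >= -15) & (hi < 0)).mean()
        out["per_patient"] = {
            "n_patients_both_eyes": int(len(both)),
            "pct_both_eyes_below_-15": float(100.0 * both_below),
            "pct_one_below_-15_other_-15_0": float(100.0 * one_below_other_mid),
        }
    return out


def age_binned_comparison(
    diabetic: pd.DataFrame,
    control: pd.DataFrame,
    bins: np.ndarray | None = None,
    threshold: float = -15.0,
    min_per_group: int = 20,
) -> pd.DataFrame:
    """Per-age-bin screening-positive rates and 2x2 chi-square p-values.

    Decade bins by default.  A bin where either group has fewer than
    ``min_per_group`` eyes gets its p-value omitted and a small-sample flag
    (differences in sparse old-age bins are not testable).
    """
    if bins is None:
        lo = np.floor(min(diabetic["age"].min(), control["age"].min()) / 10) * 10
        hi = np.ceil(max(diabetic["age"].max(), control["age"].max()) / 10) * 10
        bins = np.arange(lo, hi + 10, 10)
    rows = []
    for lo_edge, hi_edge in zip(bins[:-1], bins[1:]):
        d = diabetic[(diabetic["age"] >= lo_edge) & (diabetic["age"] < hi_edge)]
        c = control[(control["age"] >= lo_edge) & (control["age"] < hi_edge)]
        nd, nc = len(d), len(c)
        pos_d = int((d["GDF"] < threshold).sum())
        pos_c = int((c["GDF"] < threshold).sum())
        small = nd < min_per_group or nc < min_per_group
        p = np.nan
        if not small:
            table = np.array([[pos_d, nd - pos_d], [pos_c, nc - pos_c]])
            if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
                p = float(stats.chi2_contingency(table, correction=False)[1])
            else:
                small = True
        rows.append({
            "age_lo": float(lo_edge), "age_hi": float(hi_edge),
            "n_diabetic": nd, "n_control": nc,
            "rate_diabetic_pct": 100.0 * pos_d / nd if nd else np.nan,
            "rate_control_pct": 100.0 * pos_c / nc if nc else np.nan,
            "p_chi2": p, "small_sample": small,
        })
    return pd.DataFrame(rows)


def association_panel(records: pd.DataFrame) -> dict:
    """Pearson r and p for the standard association checks.

    GDF ~ disc area (expected null after disc-area stratification),
    GDF ~ vertical C/D (expected strongly negative), disc area ~ vertical
    C/D, and inter-eye GDF correlation paired by patient id.
    """
    out = {}
    pairs = {
        "gdf_disc_area": ("GDF", "disc_area"),
        "gdf_vertical_cd": ("GDF", "vertical_cd"),
        "disc_area_vertical_cd": ("disc_area", "vertical_cd"),
    }
    for name, (x, y) in pairs.items():
        sub = records[[x, y]].dropna()
        r, p = stats.pearsonr(sub[x], sub[y])
        out[name] = {"r": float(r), "p": float(p), "n": int(len(sub))}

    wide = records.pivot_table(index="patient_id", columns="eye", values="GDF",
                               aggfunc="last")
    if {"left", "right"} <= set(wide.columns):
        both = wide[["left", "right"]].dropna()
        if len(both) >= 3:
            r, p = stats.pearsonr(both["left"], both["right"])
            out["inter_eye_gdf"] = {"r": float(r), "p": float(p), "n": int(len(both))}
    return out
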