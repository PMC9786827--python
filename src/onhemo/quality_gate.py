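"""Image analysability gate with the five standard exclusion categories.

Categories follow screening-programme practice: excessive illumination, low
image quality, disc absent, disc sectioned by the frame border, disc very
close to the edge.  Precedence is total and fixed — disc_absent, then
excessive_illumination, low_quality, disc_sectioned, disc_near_edge, else ok
— so every image receives exactly one category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import QualityConfig
from .segmentation import DiscSegmentation

__all__ = ["QualityReport", "assess_quality", "exclusion_summary", "CATEGORIES"]

CATEGORIES = (
    "ok",
    "excessive_illumination",
    "low_quality",
    "disc_absent",
    "disc_sectioned",
    "disc_near_edge",
)


@dataclass
class QualityReport:
    analysable: bool
    category: str
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        assert (self.category == "ok") == self.analysable


def _saturation_fraction(image: np.ndarray, margin: float) -> float:
    """Fraction of central-field pixels saturated in at least one channel."""
    h, w = image.shape[:2]
    mr, mc = int(margin * h), int(margin * w)
    central = image[mr:h - mr, mc:w - mc]
    return float(np.mean(np.any(central == 255, axis=-1)))


def _sharpness(image: np.ndarray) -> float:
    """Variance of the Laplacian of the median-denoised green channel.

    The 3x3 median suppresses sensor noise so the score reflects structural
    sharpness (edges) rather than the noise floor.
    """
    green = ndimage.median_filter(np.asarray(image[..., 1], dtype=float), size=3)
    return float(ndimage.laplace(green).var())


def _border_geometry(seg: DiscSegmentation, shape: tuple[int, int]
                     ) -> tuple[bool, float]:
    """(crosses_border, centre-to-border distance in disc radii)."""
    h, w = shape
    r0, c0 = seg.ellipse.center
    a, b = seg.ellipse.a, seg.ellipse.b
    crosses = (r0 - b < 0 or r0 + b > h - 1 or c0 - a < 0 or c0 + a > w - 1)
    dist = min(r0, h - 1 - r0, c0, w - 1 - c0)
    ratio = dist / seg.ellipse.r_major if seg.ellipse.r_major > 0 else np.inf
    return crosses, float(ratio)


def assess_quality(
    image: np.ndarray,
    disc: DiscSegmentation | None,
    cfg: QualityConfig | None = None,
) -> QualityReport:
    """Classify one image; ``disc`` may be None (no detection).

    All metrics are always populated so excluded images remain auditable.
    """
    cfg = cfg or QualityConfig()
    if image.ndim != 3 or image.shape[-1] != 3 or image.size == 0:
        raise ValueError("expected a non-empty RGB image")

    saturation = _saturation_fraction(image, cfg.central_margin)
    sharpness = _sharpness(image)
    confidence = disc.confidence if disc is not None else 0.0
    fit_failed = disc is not None and disc.ellipse is None
    if disc is not None and disc.ellipse is not None:
        crosses, border_ratio = _border_geometry(disc, image.shape[:2])
    else:
        crosses, border_ratio = False, np.inf

    metrics = {
        "saturation_fraction": saturation,
        "sharpness_score": sharpness,
        "disc_confidence": float(confidence),
        "border_distance_ratio": border_ratio,
    }

    if confidence < cfg.disc_confidence_threshold:
        category = "disc_absent"
    elif saturation > cfg.saturation_threshold:
        category = "excessive_illumination"
    elif sharpness < cfg.sharpness_threshold or fit_failed:
        # a located disc whose boundary cannot be fitted is unanalysable
        category = "low_quality"
    elif crosses:
        category = "disc_sectioned"
    elif border_ratio < cfg.near_edge_ratio:
        category = "disc_near_edge"
    else:
        category = "ok"
    return QualityReport(analysable=category == "ok", category=category,
                         metrics=metrics)


def exclusion_summary(reports: list[QualityReport]) -> tuple[pd.DataFrame, float]:
    """Frequency table of exclusion categories.

    Returns (table, analysable_fraction); percentages are over *excluded*
    images and sum to 100 when any image is excluded.
    """
    if not reports:
        raise ValueError("no reports")
    cats = pd.Series([r.category for r in reports])
    analysable_fraction = float((cats == "ok").mean())
    excluded = cats[cats != "ok"]
    if excluded.empty:
        table = pd.DataFrame(columns=["category", "count", "pct_of_excluded"])
    else:
        counts = excluded.value_counts()
        table = pd.DataFrame({
            "category": counts.index,
            "count": counts.values,
            "pct_of_excluded": 100.0 * counts.values / counts.sum(),
        }).reset_index(drop=True)
    return table, analysable_fraction
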