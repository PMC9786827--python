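"""Vessel-referenced haemoglobin colourimetry.

Haemoglobin absorbs green light and reflects most of the red, so the ratio
(R-G)/R of a pixel rises with its haemoglobin content.  The central vessels
carry ~100% haemoglobin and serve as the per-image colour standard: the
tissue Hb of a pixel is expressed as a percentage of the median vessel
(R-G)/R.  Because the quantity is a within-pixel ratio, any multiplicative
illumination change cancels exactly.

From the Hb map this module derives the 24-sector profile (3 equal-area
annuli x 8 wedges), the cup (connected low-Hb region), the vertical cup/disc
ratio and the 8 rim sector areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from . import geometry
from .config import ColorimetryConfig
from .segmentation import DiscSegmentation

__all__ = [
    "HbMap",
    "SectorProfile",
    "CupEstimate",
    "ReferenceError",
    "vessel_reference",
    "hb_map",
    "sector_profile",
    "estimate_cup",
]


class ReferenceError(RuntimeError):
    """Vessel reference unavailable (too few vessel pixels or zero ratio)."""


@dataclass
class HbMap:
    values: np.ndarray  # per-pixel Hb%, NaN outside disc tissue
    tissue_mask: np.ndarray  # disc minus vessels
    vessel_reference: float


@dataclass
class SectorProfile:
    values: np.ndarray  # (24,) mean Hb% per sector
    imputed: list = field(default_factory=list)  # sector indices with no tissue


@dataclass
class CupEstimate:
    cup_mask: np.ndarray
    cup_area_pct: float  # % of disc area
    vertical_cd: float
    cd_area_ratio: float  # == cup_area_pct / 100 by construction
    rim_sector_areas: np.ndarray  # (8,) mm^2, wedge 0 temporal


def vessel_reference(image: np.ndarray, vessel_mask: np.ndarray,
                     cfg: ColorimetryConfig | None = None) -> float:
    """Median (R-G)/R over vessel pixels — robust to specular highlights.

    Raises :class:`ReferenceError` when fewer than ``min_vessel_pixels``
    usable pixels exist or the reference is not positive.
    """
    cfg = cfg or ColorimetryConfig()
    img = np.asarray(image, dtype=float)
    red = img[..., 0][vessel_mask]
    green = img[..., 1][vessel_mask]
    ok = red > 0
    if int(ok.sum()) < cfg.min_vessel_pixels:
        raise ReferenceError(f"only {int(ok.sum())} usable vessel pixels")
    ref = float(np.median((red[ok] - green[ok]) / red[ok]))
    if ref <= 0:
        raise ReferenceError("vessel reference must be positive")
    return ref


def hb_map(image: np.ndarray, disc_mask: np.ndarray, vessel_mask: np.ndarray,
           reference: float, cfg: ColorimetryConfig | None = None) -> HbMap:
    """Per-pixel Hb% = 100 * [(R-G)/R] / reference on disc tissue.

    Vessel pixels (dilated by a small safety margin, since missed vessel
    pixels read as ~100% Hb) are excluded; pixels with R = 0 are treated as
    0% Hb; values are clipped to [0, ``hb_clip_max``].
    """
    cfg = cfg or ColorimetryConfig()
    if reference <= 0:
        raise ValueError("reference must be positive")
    excl = vessel_mask
    if cfg.vessel_exclusion_dilation > 0 and vessel_mask.any():
        excl = morphology.dilation(
            vessel_mask, morphology.disk(cfg.vessel_exclusion_dilation))
    tissue = disc_mask & ~excl
    if not tissue.any():
        raise ValueError("empty tissue region")
    img = np.asarray(image, dtype=float)
    red, green = img[..., 0], img[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(red > 0, (red - green) / np.maximum(red, 1e-12), 0.0)
    values = np.full(red.shape, np.nan)
    values[tissue] = np.clip(100.0 * ratio[tissue] / reference, 0.0, cfg.hb_clip_max)
    return HbMap(values=values, tissue_mask=tissue, vessel_reference=float(reference))


def sector_profile(hb: HbMap, disc: DiscSegmentation,
                   cfg: ColorimetryConfig | None = None) -> SectorProfile:
    """Mean Hb per 24 sectors (canonical orientation assumed applied).

    A sector with (almost) no tissue pixels — e.g. fully covered by vessels
    — is imputed from the adjacent wedges of the same annulus and flagged.
    """
    cfg = cfg or ColorimetryConfig()
    smap = geometry.sector_map(hb.values.shape, disc.ellipse)
    smap = np.where(hb.tissue_mask, smap, -1)
    values = np.full(geometry.N_SECTORS, np.nan)
    for s in range(geometry.N_SECTORS):
        sel = smap == s
        if int(sel.sum()) >= cfg.min_sector_pixels:
            values[s] = float(np.nanmean(hb.values[sel]))
    imputed = [int(s) for s in np.flatnonzero(np.isnan(values))]
    for s in imputed:
        ann, wed = divmod(s, geometry.N_WEDGES)
        neigh = [ann * geometry.N_WEDGES + (wed - 1) % geometry.N_WEDGES,
                 ann * geometry.N_WEDGES + (wed + 1) % geometry.N_WEDGES]
        vals = [values[n] for n in neigh if np.isfinite(values[n])]
        values[s] = float(np.mean(vals)) if vals else float(np.nanmean(values))
    return SectorProfile(values=values, imputed=imputed)


def estimate_cup(hb: HbMap, disc: DiscSegmentation, scale: float,
                 cfg: ColorimetryConfig | None = None) -> CupEstimate:
    """Cup from the haemoglobin distribution.

    The cup is the largest connected low-Hb component: the threshold is
    seeded at the 25th percentile of within-disc Hb and refined to the
    midpoint between the pale-region and rim means (a seeded two-class
    split), then morphologically smoothed.  The vertical C/D is the cup's
    vertical extent over the disc's vertical extent through the cup centroid
    column.  A map without a coherent pale region (cup/rim contrast below
    ``cup_min_contrast``) yields an empty cup with C/D 0.
    """
    cfg = cfg or ColorimetryConfig()
    shape = hb.values.shape
    tissue = hb.tissue_mask
    # normalised-convolution smoothing: suppresses pixel noise and
    # interpolates Hb across the excluded vessel corridors, so the pale cup
    # stays one connected region where vessels cross it
    filled = np.where(tissue, hb.values, 0.0)
    weight = ndimage.gaussian_filter(tissue.astype(float), cfg.cup_smooth_radius)
    smooth = ndimage.gaussian_filter(filled, cfg.cup_smooth_radius)
    smooth = np.where(weight > 1e-3, smooth / np.maximum(weight, 1e-3), np.inf)
    disc_px = int(disc.disc_mask.sum())

    def _component(thr: float) -> np.ndarray:
        low = disc.disc_mask & (smooth < thr)
        low = morphology.closing(low, morphology.disk(cfg.cup_smooth_radius))
        low = ndimage.binary_fill_holes(low) & disc.disc_mask
        low = morphology.opening(low, morphology.disk(cfg.cup_smooth_radius))
        labels, n = ndimage.label(low)
        if n == 0:
            return np.zeros(shape, dtype=bool)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        best = int(np.argmax(sizes))
        if sizes[best] < cfg.cup_min_area_fraction * disc_px:
            return np.zeros(shape, dtype=bool)
        return labels == best

    # seed threshold, then move it to the midpoint of the two class means
    thr = float(np.percentile(smooth[tissue], cfg.cup_threshold_percentile))
    cup_mask = _component(thr)
    for _ in range(cfg.cup_refine_iters):
        inside = cup_mask & tissue
        outside = tissue & ~cup_mask
        if not inside.any() or not outside.any():
            break
        mu_in = float(hb.values[inside].mean())
        mu_out = float(hb.values[outside].mean())
        if mu_out - mu_in < cfg.cup_min_contrast:
            cup_mask = np.zeros(shape, dtype=bool)
            break
        thr = 0.5 * (mu_in + mu_out)
        cup_mask = _component(thr)

    cup_px = int(cup_mask.sum())
    cup_area_pct = 100.0 * cup_px / disc_px if disc_px else 0.0

    if cup_px:
        rows, cols = np.nonzero(cup_mask)
        c_col = int(round(cols.mean()))
        band = slice(max(0, c_col - 2), c_col + 3)
        cup_rows = np.nonzero(cup_mask[:, band].any(axis=1))[0]
        disc_rows = np.nonzero(disc.disc_mask[:, band].any(axis=1))[0]
        cup_ext = cup_rows.max() - cup_rows.min() + 1
        disc_ext = disc_rows.max() - disc_rows.min() + 1
        vertical_cd = float(min(1.0, cup_ext / disc_ext)) if disc_ext else 0.0
    else:
        vertical_cd = 0.0

    # rim areas over 8 wedges (all annuli), disc minus cup
    _, theta = geometry.normalized_coords(shape, disc.ellipse)
    wedges = geometry.wedge_index(theta)
    rim = disc.disc_mask & ~cup_mask
    rim_areas = np.array([
        float((rim & (wedges == w)).sum()) * scale ** 2
        for w in range(geometry.N_WEDGES)
    ])
    return CupEstimate(cup_mask=cup_mask, cup_area_pct=float(cup_area_pct),
                       vertical_cd=vertical_cd,
                       cd_area_ratio=float(cup_area_pct) / 100.0,
                       rim_sector_areas=rim_areas)
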