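"""Rasterisation of ground-truth eyes into fundus-like RGB images.

The colour model is built so that colourimetry is exact by construction:
vessel pixels carry the 100%-haemoglobin reference colour with
(R-G)/R = ``vessel_reference_ratio``, and every tissue pixel satisfies
(R-G)/R = reference * Hb/100 before blur/noise.  Within each of the 24
sectors, haemoglobin is redistributed between the pale cup and the redder
rim so that the sector *mean* equals the ground-truth ``sector_hb`` exactly.

Multiplicative artefacts (vignette) cancel in the (R-G)/R ratio; additive
over-exposure clips channels and is what the quality gate must reject.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
from scipy import ndimage

from .. import geometry
from ..config import GeneratorConfig
from .profiles import AcquisitionParams, EyeGroundTruth, TruthMasks, advance_ground_truth

__all__ = ["render_fundus", "make_longitudinal_series"]

DAYS_PER_YEAR = 365.25
_EPOCH = _dt.date(2015, 1, 1)


def _disc_ellipse(gt: EyeGroundTruth, acq: AcquisitionParams,
                  rng: np.random.Generator) -> geometry.Ellipse | None:
    """Disc ellipse in the canonical frame, honouring the truncation mode."""
    if acq.truncation == "absent":
        return None
    area_px = gt.disc_area / gt.scale ** 2
    ell = geometry.from_area(area_px, gt.axis_ratio, gt.disc_center)
    h = w = acq.image_size
    r = ell.r_major
    if acq.truncation == "sectioned":
        # centre close enough to the border that the ellipse crosses it
        col = w - 1 - 0.4 * ell.a
        row = h / 2.0 + rng.uniform(-15, 15)
        ell = geometry.Ellipse((row, col), ell.a, ell.b)
    elif acq.truncation == "near_edge":
        # fully inside but closer than the near-edge ratio allows
        col = w - 1 - rng.uniform(1.02, 1.12) * r
        row = h / 2.0 + rng.uniform(-15, 15)
        ell = geometry.Ellipse((row, col), ell.a, ell.b)
    else:  # none
        r0, c0 = ell.center
        if (r0 - ell.b < 1 or r0 + ell.b > h - 2 or
                c0 - ell.a < 1 or c0 + ell.a > w - 2):
            raise ValueError(
                f"disc (area {gt.disc_area:.2f} mm^2 at scale {gt.scale}) does not "
                f"fit a {h}x{w} frame at centre {ell.center}"
            )
    return ell


def _cup_ellipse(gt: EyeGroundTruth, disc: geometry.Ellipse) -> geometry.Ellipse | None:
    geom = geometry.cup_geometry(gt.cup_fraction, gt.cup_elongation)
    if geom is None:
        return None
    dx, ac, bc = geom  # temporal offset and semi-axes, relative to the disc
    return geometry.Ellipse((disc.center[0], disc.center[1] + dx * disc.a),
                            ac * disc.a, bc * disc.b)


def _hb_field(gt: EyeGroundTruth, shape, disc: geometry.Ellipse,
              cup_mask: np.ndarray, vessel_mask: np.ndarray,
              cup_contrast: float) -> np.ndarray:
    """Per-pixel true Hb%.

    Within each sector the cup is paler (factor ``cup_contrast``) and the rim
    correspondingly redder, balanced so the mean over vessel-free tissue
    equals the ground-truth ``sector_hb`` exactly — a noise-free analysis
    therefore round-trips to the sector profile.
    """
    smap = geometry.sector_map(shape, disc)
    hb = np.zeros(shape, dtype=float)
    gamma = cup_contrast
    for s in range(geometry.N_SECTORS):
        sel = smap == s
        tissue = sel & ~vessel_mask
        n = int(tissue.sum())
        if n == 0:
            continue
        f = float((tissue & cup_mask).sum()) / n
        k_rim = 1.0 / (1.0 - f * (1.0 - gamma))
        val = gt.sector_hb[s]
        hb[sel] = val * k_rim
        hb[sel & cup_mask] = val * gamma * k_rim
    return np.clip(hb, 0.0, 140.0)


_DISK_CACHE: dict[int, np.ndarray] = {}


def _disk_offsets(radius: int) -> np.ndarray:
    if radius not in _DISK_CACHE:
        r = np.arange(-radius, radius + 1)
        dr, dc = np.meshgrid(r, r, indexing="ij")
        keep = dr ** 2 + dc ** 2 <= radius ** 2
        _DISK_CACHE[radius] = np.stack([dr[keep], dc[keep]], axis=1)
    return _DISK_CACHE[radius]


def _draw_vessels(shape, disc: geometry.Ellipse, rng: np.random.Generator,
                  pop: GeneratorConfig) -> np.ndarray:
    """Smooth curvilinear strokes radiating from the nasal disc edge."""
    mask = np.zeros(shape, dtype=bool)
    if pop.vessel_count <= 0:
        return mask
    h, w = shape
    rho_grid, _ = geometry.normalized_coords(shape, disc)
    for _ in range(pop.vessel_count):
        # origin near the nasal (-col) side, inside the disc
        a0 = np.radians(rng.uniform(130, 230))
        p0 = np.array([disc.center[0] - 0.25 * disc.b * np.sin(a0),
                       disc.center[1] + 0.25 * disc.a * np.cos(a0)])
        # end point beyond the disc, anywhere but the nasal pole
        a2 = np.radians(rng.uniform(-110, 110))
        p2 = np.array([disc.center[0] - 1.6 * disc.b * np.sin(a2),
                       disc.center[1] + 1.6 * disc.a * np.cos(a2)])
        ctrl = 0.5 * (p0 + p2) + rng.normal(0, 0.25 * disc.r_major, 2)
        t = np.linspace(0.0, 1.0, 150)[:, None]
        pts = ((1 - t) ** 2) * p0 + 2 * t * (1 - t) * ctrl + (t ** 2) * p2
        width = rng.integers(pop.vessel_width_min, pop.vessel_width_max + 1)
        offs = _disk_offsets(max(1, int(round(width / 2))))
        ij = np.round(pts).astype(int)
        ij = ij[:, None, :] + offs[None, :, :]
        ij = ij.reshape(-1, 2)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        ij = ij[ok]
        mask[ij[:, 0], ij[:, 1]] = True
    # keep vessels within 1.5 disc radii, the analysis region
    mask &= rho_grid <= 1.6
    return mask


def render_fundus(
    gt: EyeGroundTruth,
    acq: AcquisitionParams,
    pop: GeneratorConfig | None = None,
) -> tuple[np.ndarray, TruthMasks]:
    """Render one eye; returns an 8-bit RGB array and aligned truth masks.

    Deterministic: identical ``gt``/``acq`` (including ``acq.seed``) give
    byte-identical rasters.
    """
    pop = pop or GeneratorConfig()
    rng = np.random.default_rng(acq.seed)
    shape = (acq.image_size, acq.image_size)
    ref = pop.vessel_reference_ratio

    img = np.empty(shape + (3,), dtype=float)
    img[..., 0], img[..., 1], img[..., 2] = pop.background_rgb

    disc = _disc_ellipse(gt, acq, rng)
    if disc is not None:
        disc_mask = geometry.ellipse_mask(shape, disc)
        cup = _cup_ellipse(gt, disc)
        cup_mask = (geometry.ellipse_mask(shape, cup) & disc_mask
                    if cup is not None else np.zeros(shape, dtype=bool))
        vessel_mask = _draw_vessels(shape, disc, rng, pop)
        hb = _hb_field(gt, shape, disc, cup_mask, vessel_mask, gt.cup_contrast)
        red = float(pop.tissue_red)
        img[disc_mask, 0] = red
        img[disc_mask, 1] = red * (1.0 - ref * hb[disc_mask] / 100.0)
        img[disc_mask, 2] = 0.3 * img[disc_mask, 1] + 15.0
    else:
        disc_mask = np.zeros(shape, dtype=bool)
        cup_mask = np.zeros(shape, dtype=bool)
        # background vasculature so an absent disc is not a blank frame
        fake = geometry.Ellipse((shape[0] / 2.0, shape[1] * 0.1), 40, 42)
        vessel_mask = _draw_vessels(shape, fake, rng, pop)

    vr = float(pop.vessel_red)
    img[vessel_mask, 0] = vr
    img[vessel_mask, 1] = vr * (1.0 - ref)
    img[vessel_mask, 2] = 40.0

    if acq.vignette_strength:
        rows, cols = np.indices(shape)
        d2 = ((rows - shape[0] / 2) ** 2 + (cols - shape[1] / 2) ** 2)
        gain = 1.0 - acq.vignette_strength * d2 / d2.max()
        img *= gain[..., None]

    if acq.blur_sigma > 0:
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], acq.blur_sigma)

    if acq.overexposure_fraction > 0:
        h, w = shape
        c0 = (rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w))
        radius = np.sqrt(acq.overexposure_fraction * h * w / np.pi)
        rows, cols = np.indices(shape)
        d = np.hypot(rows - c0[0], cols - c0[1])
        img += 300.0 / (1.0 + np.exp((d - radius) / 3.0))[..., None]

    if acq.noise_sd > 0:
        img += rng.normal(0.0, acq.noise_sd, img.shape)

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    masks = TruthMasks(disc_mask, cup_mask, vessel_mask)
    if gt.eye == "left":
        img = np.flip(img, axis=1).copy()
        masks = masks.mirrored()
    return img, masks


def make_longitudinal_series(
    gt: EyeGroundTruth,
    n_exams: int,
    span_years: float,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
    pop: GeneratorConfig | None = None,
) -> list[tuple[str, np.ndarray, TruthMasks]]:
    """Time-stamped exam series; exam k reflects the ground truth advanced by
    the eye's hb/cup slopes, with acquisition noise independent across exams.

    Dates are ISO-8601; elapsed time is decimal years at 365.25 d/yr.
    """
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    if span_years < 0:
        raise ValueError("span_years must be non-negative")
    acq = acq or AcquisitionParams()
    ss = np.random.SeedSequence(seed)
    exam_seeds = ss.generate_state(n_exams)
    times = (np.linspace(0.0, span_years, n_exams) if n_exams > 1
             else np.array([0.0]))
    out = []
    for k, t in enumerate(times):
        gt_k = advance_ground_truth(gt, float(t))
        acq_k = AcquisitionParams(
            image_size=acq.image_size,
            vignette_strength=acq.vignette_strength,
            noise_sd=acq.noise_sd,
            overexposure_fraction=acq.overexposure_fraction,
            blur_sigma=acq.blur_sigma,
            truncation=acq.truncation,
            seed=int(exam_seeds[k] % (2 ** 31)),
        )
        img, masks = render_fundus(gt_k, acq_k, pop)
        date = _EPOCH + _dt.timedelta(days=float(t) * DAYS_PER_YEAR)
        out.append((date.isoformat(), img, masks))
    return out
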