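"""Ground-truth eye profiles and the feature-level measurement shortcut."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .. import geometry
from ..config import GeneratorConfig

__all__ = [
    "EyeGroundTruth",
    "AcquisitionParams",
    "TruthMasks",
    "make_eye_profile",
    "advance_ground_truth",
    "simulate_measurements",
]


@dataclass
class EyeGroundTruth:
    """Generative parameters of one eye.

    ``sector_hb`` holds the true per-sector mean haemoglobin (% of the vessel
    reference) over all disc tissue, pale cup included: sectors covered by
    the cup carry proportionally lower means.  ``rim_hb`` is the underlying
    cup-free tissue value per sector; the two are linked by
    ``sector_hb = rim_hb * (1 - f * (1 - cup_contrast))`` with ``f`` the
    geometric cup coverage of the sector.  The renderer reproduces these
    sector means exactly, so a noise-free analysis round-trips to
    ``sector_hb``.
    """

    patient_id: str
    eye: str  # "left" | "right"
    disc_area: float  # mm^2
    disc_center: tuple[float, float]  # (row, col), canonical orientation
    axis_ratio: float  # vertical/horizontal disc semi-axes
    cup_fraction: float  # fraction of disc area in [0, 1)
    cup_elongation: float  # vertical bias of the cup ellipse
    sector_hb: np.ndarray  # (24,) in [0, 120]
    severity: float  # g in [0, 1]
    scale: float  # mm per px
    hb_slope: float = 0.0  # Hb %/year
    cup_slope: float = 0.0  # disc-area-fraction/year
    cup_contrast: float = 0.75  # cup Hb relative to same-sector rim Hb
    rim_hb: np.ndarray | None = None  # (24,) cup-free tissue Hb

    def __post_init__(self):
        self.sector_hb = np.asarray(self.sector_hb, dtype=float)
        if self.rim_hb is not None:
            self.rim_hb = np.asarray(self.rim_hb, dtype=float)
        if self.eye not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.eye!r}")
        if self.sector_hb.shape != (geometry.N_SECTORS,):
            raise ValueError("sector_hb must have 24 values")
        if not np.all(np.isfinite(self.sector_hb)):
            raise ValueError("sector_hb must be finite")
        if not 0.0 <= self.cup_fraction < 1.0:
            raise ValueError("cup_fraction must lie in [0, 1)")

    @property
    def vertical_cd(self) -> float:
        """Ground-truth vertical cup/disc ratio implied by the geometry."""
        return geometry.vertical_cd_from_geometry(self.cup_fraction, self.cup_elongation)

    def cup_coverage(self) -> np.ndarray:
        """Geometric cup coverage fraction of each of the 24 sectors."""
        return geometry.cup_coverage_fractions(self.axis_ratio, self.cup_fraction,
                                               self.cup_elongation)


@dataclass
class AcquisitionParams:
    """Camera/session artefacts; identical seed and params give identical rasters."""

    image_size: int = 256
    vignette_strength: float = 0.0
    noise_sd: float = 2.0
    overexposure_fraction: float = 0.0
    blur_sigma: float = 0.0
    truncation: str = "none"  # none | sectioned | near_edge | absent
    seed: int = 0

    def __post_init__(self):
        if self.truncation not in ("none", "sectioned", "near_edge", "absent"):
            raise ValueError(f"unknown truncation mode {self.truncation!r}")
        if not 0.0 <= self.overexposure_fraction <= 1.0:
            raise ValueError("overexposure_fraction must lie in [0, 1]")


@dataclass
class TruthMasks:
    disc_mask: np.ndarray
    cup_mask: np.ndarray
    vessel_mask: np.ndarray

    def mirrored(self) -> "TruthMasks":
        return TruthMasks(*(np.flip(m, axis=1).copy() for m in
                            (self.disc_mask, self.cup_mask, self.vessel_mask)))


def make_eye_profile(
    pop: GeneratorConfig,
    severity: float = 0.0,
    seed: int | np.random.Generator = 0,
    patient_id: str = "p0",
    eye: str = "right",
) -> EyeGroundTruth:
    """Draw one eye from the population model.

    Severity ``g`` depresses haemoglobin preferentially in the superior and
    inferior wedges and enlarges/elongates the cup; the disc area is drawn
    independently of ``g``.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if pop.disc_area_sd <= 0 or pop.hb_between_eye_sd <= 0:
        raise ValueError("population standard deviations must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    disc_area = float(np.clip(rng.normal(pop.disc_area_mean, pop.disc_area_sd), 0.5, None))
    axis_ratio = float(np.clip(rng.normal(pop.axis_ratio_mean, pop.axis_ratio_sd), 0.9, 1.3))

    baseline = rng.normal(pop.hb_baseline_mean, pop.hb_between_eye_sd)
    rim_hb = baseline + rng.normal(0.0, pop.hb_sector_sd, geometry.N_SECTORS)
    rim_hb -= severity * pop.severity_hb_drop_max * geometry.sector_severity_profile()
    rim_hb = np.clip(rim_hb, 0.0, 120.0)

    cup_base = float(np.clip(rng.normal(pop.cup_fraction_mean, pop.cup_fraction_sd), 0.05, 0.40))
    cup_fraction = float(np.clip(cup_base + severity * pop.severity_cup_gain, 0.02, 0.75))
    cup_elongation = float(
        max(0.0, pop.cup_elongation_base + severity * pop.severity_elongation_gain
            + rng.normal(0.0, 0.02))
    )
    coverage = geometry.cup_coverage_fractions(axis_ratio, cup_fraction, cup_elongation)
    sector_hb = rim_hb * (1.0 - coverage * (1.0 - pop.cup_contrast))

    half = pop.image_size / 2.0
    center = (half + rng.uniform(-8, 8), half + rng.uniform(-8, 8))
    return EyeGroundTruth(
        patient_id=patient_id,
        eye=eye,
        disc_area=disc_area,
        disc_center=center,
        axis_ratio=axis_ratio,
        cup_fraction=cup_fraction,
        cup_elongation=cup_elongation,
        sector_hb=sector_hb,
        severity=float(severity),
        scale=pop.scale_mm_per_px,
        cup_contrast=pop.cup_contrast,
        rim_hb=rim_hb,
    )


def advance_ground_truth(gt: EyeGroundTruth, years: float) -> EyeGroundTruth:
    """Ground truth after ``years`` of linear progression at the eye's slopes.

    The Hb slope acts on the cup-free tissue value; the cup slope enlarges
    the cup, which further depresses the covered sector means.
    """
    if gt.rim_hb is not None:
        rim = gt.rim_hb
    else:
        cov0 = gt.cup_coverage()
        rim = gt.sector_hb / (1.0 - cov0 * (1.0 - gt.cup_contrast))
    rim = np.clip(rim + gt.hb_slope * years, 0.0, 120.0)
    cup_fraction = float(np.clip(gt.cup_fraction + gt.cup_slope * years, 0.02, 0.90))
    out = replace(gt, cup_fraction=cup_fraction)
    coverage = out.cup_coverage()
    sector_hb = np.clip(rim * (1.0 - coverage * (1.0 - gt.cup_contrast)), 0.0, 120.0)
    return replace(out, sector_hb=sector_hb, rim_hb=rim)


def simulate_measurements(
    gt: EyeGroundTruth,
    pop: GeneratorConfig,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
) -> dict:
    """Feature-level shortcut: what the image pipeline would measure.

    Adds independent measurement noise to the ground-truth sector means,
    vertical C/D, cup area and disc area at the magnitudes the image path
    exhibits, without rasterising.  ``noise_scale=0`` returns noise-free
    measurements.
    """
    sector = gt.sector_hb + rng.normal(0.0, pop.meas_sector_sd * noise_scale,
                                       geometry.N_SECTORS)
    vcd = gt.vertical_cd + rng.normal(0.0, pop.meas_vcd_sd * noise_scale)
    cup_pct = 100.0 * gt.cup_fraction + rng.normal(0.0, pop.meas_cup_pct_sd * noise_scale)
    disc_area = gt.disc_area * (1.0 + rng.normal(0.0, pop.meas_disc_area_rel_sd * noise_scale))
    return {
        "sector_hb": np.clip(sector, 0.0, 120.0),
        "vertical_cd": float(np.clip(vcd, 0.0, 1.0)),
        "cup_area_pct": float(np.clip(cup_pct, 0.0, 100.0)),
        "disc_area": float(max(disc_area, 0.1)),
    }
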