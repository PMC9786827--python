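"""Pipeline configuration: one declarative document with defaults.

Every stage of the pipeline reads its tunables from :class:`PipelineConfig`.
The configuration is fully serialisable (YAML in, YAML/JSON out) and carries a
stable content hash that is stamped into every output file so that a result
can always be traced back to the exact parameter set that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GeneratorConfig",
    "QualityConfig",
    "SegmentationConfig",
    "ColorimetryConfig",
    "IndexConfig",
    "ProgressionConfig",
    "PipelineConfig",
]


@dataclass
class GeneratorConfig:
    """Population and rendering parameters for the synthetic fundus generator.

    Disc-area and age distributions follow the reference diabetic cohort
    (disc area 1.93 +/- 0.35 mm^2, age 64.3 +/- 12.9 years).  Haemoglobin
    population parameters are package defaults: no published normative Hb
    distribution exists, so they are stated here and easy to change.
    """

    image_size: int = 256
    scale_mm_per_px: float = 0.0195  # a ~1.9 mm^2 disc spans ~80 px

    disc_area_mean: float = 1.93  # mm^2
    disc_area_sd: float = 0.35
    axis_ratio_mean: float = 1.05  # vertical/horizontal disc elongation
    axis_ratio_sd: float = 0.03

    hb_baseline_mean: float = 65.0  # % of the vessel reference
    hb_between_eye_sd: float = 6.0
    hb_sector_sd: float = 3.0  # within-eye sector-to-sector variation

    cup_fraction_mean: float = 0.20  # fraction of disc area
    cup_fraction_sd: float = 0.05
    cup_elongation_base: float = 0.05
    cup_contrast: float = 0.75  # cup Hb relative to same-sector rim Hb

    # severity g in [0,1] acts preferentially on superior/inferior wedges
    severity_hb_drop_max: float = 30.0  # Hb units at g=1 in sup/inf wedges
    severity_cup_gain: float = 0.45  # added cup fraction at g=1
    severity_elongation_gain: float = 0.55

    vessel_reference_ratio: float = 0.70  # (R-G)/R of rendered vessels
    vessel_count: int = 7
    vessel_width_min: int = 2
    vessel_width_max: int = 5

    tissue_red: int = 230
    vessel_red: int = 170
    background_rgb: tuple[int, int, int] = (150, 85, 50)

    noise_sd: float = 2.0  # channel units, default acquisition

    # feature-level measurement model (shortcut path, no rasterisation)
    meas_sector_sd: float = 2.5  # Hb units on each sector mean
    meas_vcd_sd: float = 0.03
    meas_cup_pct_sd: float = 2.0  # percentage points of disc area
    meas_disc_area_rel_sd: float = 0.03

    age_mean: float = 64.3
    age_sd: float = 12.9
    exam_interval_years: float = 1.0
    exam_interval_jitter: float = 0.2


@dataclass
class QualityConfig:
    """Thresholds for the five exclusion categories (package choices; the
    categories themselves are standard screening-programme exclusions)."""

    saturation_threshold: float = 0.25  # fraction of central-field pixels
    central_margin: float = 0.10  # border fraction excluded from the field
    sharpness_threshold: float = 10.0  # variance of Laplacian, 0-255 units^2
    disc_confidence_threshold: float = 0.30
    near_edge_ratio: float = 1.2  # disc radii from centre to nearest border


@dataclass
class SegmentationConfig:
    dog_sigma_inner: float = 15.0  # centre-surround scales matched to disc
    dog_sigma_outer: float = 45.0
    confidence_scale: float = 40.0  # DoG peak mapped through peak/scale
    window_fraction: float = 0.35  # boundary-fit crop half-size, of min(H,W)
    closing_radius: int = 3  # bridges vessel gaps across the disc rim
    min_axis_ratio: float = 0.5
    max_axis_ratio: float = 2.0
    vessel_region_factor: float = 1.5  # vessels kept within 1.5 disc radii
    vessel_rel_darkness: float = 0.30  # relative green drop vs local median
    vessel_median_radius: int = 9
    vessel_ratio_margin: float = 0.10  # (R-G)/R above the disc median ratio
    vessel_ratio_strong_margin: float = 0.15  # pure-colour call, no darkness
    vessel_min_object_px: int = 20


@dataclass
class ColorimetryConfig:
    hb_clip_max: float = 120.0  # admits tissue redder than vessels
    min_vessel_pixels: int = 50
    vessel_exclusion_dilation: int = 2  # safety margin around detected vessels
    cup_threshold_percentile: float = 25.0  # of within-disc Hb (seed threshold)
    cup_refine_iters: int = 2  # midpoint-threshold refinements of the split
    cup_min_contrast: float = 3.0  # Hb units cup-vs-rim below which no cup
    cup_smooth_radius: int = 3
    cup_min_area_fraction: float = 0.01  # of disc, below which cup is empty
    min_sector_pixels: int = 10  # below this a sector mean is imputed


@dataclass
class IndexConfig:
    """Discriminant weights and calibration anchors for GDF and GIP.

    Influence ordering only is prescribed by the method (classifier dominant
    in GDF, minimal in GIP; superior/inferior sectors emphasised); the actual
    weights are package configuration.
    """

    gdf_weight_sector: float = 0.35
    gdf_weight_cd: float = 0.15
    gdf_weight_classifier: float = 0.50
    gip_weight_sector: float = 0.70
    gip_weight_cd: float = 0.30
    supinf_multiplier: float = 2.0

    anchor_upper_pct: float = 5.0  # normal percentile mapped to 0
    anchor_lower_pct: float = 1.0  # normal percentile mapped to -15
    anchor_upper_value: float = 0.0
    anchor_lower_value: float = -15.0
    gdf_clip: tuple[float, float] = (-100.0, 85.0)
    gip_clip: tuple[float, float] = (-100.0, 100.0)

    min_reference_eyes: int = 200
    n_disc_area_strata: int = 3  # disc-area tertiles for percentile lookup


@dataclass
class ProgressionConfig:
    alpha: float = 0.01
    min_exams: int = 4
    require_negative_slope: bool = False  # flag both directions, label them


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    colorimetry: ColorimetryConfig = field(default_factory=ColorimetryConfig)
    indices: IndexConfig = field(default_factory=IndexConfig)
    progression: ProgressionConfig = field(default_factory=ProgressionConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            section = d.get(f.name, {})
            sub_cls = f.default_factory  # type: ignore[misc]
            sub = sub_cls()
            known = {sf.name for sf in dataclasses.fields(sub)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown keys in [{f.name}]: {sorted(unknown)}")
            for k, v in section.items():
                cur = getattr(sub, k)
                if isinstance(cur, tuple):
                    v = tuple(v)
                setattr(sub, k, v)
            kwargs[f.name] = sub
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Stable short hash of the full parameter set."""
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
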