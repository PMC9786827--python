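import numpy as np
import pytest

from onhemo.config import PipelineConfig
from onhemo.pipeline import build_models
from onhemo.synthetic_fundus import AcquisitionParams, make_eye_profile, render_fundus


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_bundle(cfg):
    """Models built on a small simulated normal cohort (fast; shared)."""
    return build_models(cfg, n_normals=600, n_glaucoma=300, seed=11)


@pytest.fixture(scope="session")
def rendered_eye(cfg):
    """One default severity-0 eye with its render and truth masks."""
    gt = make_eye_profile(cfg.generator, severity=0.0, seed=5)
    img, masks = render_fundus(gt, AcquisitionParams(noise_sd=2.0, seed=105),
                               cfg.generator)
    return gt, img, masks


def measurements_from_row(row, sector_columns):
    return {
        "sector_hb": row[sector_columns].to_numpy(dtype=float),
        "vertical_cd": float(row["vertical_cd"]),
        "cup_area_pct": float(row["cup_area_pct"]),
        "disc_area": float(row["disc_area"]),
    }
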