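"""Normative percentiles, classifier stand-in, discriminant and calibration."""

import numpy as np
import pandas as pd
import pytest

from onhemo.config import IndexConfig
from onhemo.indices import (
    SECTOR_COLUMNS,
    DiscriminantWeights,
    FeatureVector,
    build_normative_db,
    calibrate_index,
    compute_gdf,
    compute_gip,
    empirical_percentile,
    featureize,
    raw_discriminant,
    train_classifier_standin,
)
from onhemo.pipeline import simulate_feature_cohort, score_frame


def brute_percentile(ref, x):
    ref = np.asarray(ref)
    return 100.0 * ((ref < x).sum() + 0.5 * (ref == x).sum()) / ref.size


class TestEmpiricalPercentile:
    def test_worked_example(self):
        ref = np.array([40, 42, 44, 46, 48, 50, 52, 54, 56, 58], dtype=float)
        assert empirical_percentile(np.sort(ref), 45.0) == pytest.approx(30.0)

    def test_bounds(self):
        ref = np.sort(np.array([10.0, 20.0, 30.0]))
        assert empirical_percentile(ref, 5.0) == 0.0
        assert empirical_percentile(ref, 35.0) == 100.0

    def test_median_of_odd_set(self):
        ref = np.sort(np.arange(11, dtype=float))
        assert empirical_percentile(ref, 5.0) == pytest.approx(50.0)

    def test_agrees_with_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ref = np.sort(rng.integers(0, 20, size=rng.integers(3, 40)).astype(float))
            x = float(rng.integers(-2, 22))
            assert empirical_percentile(ref, x) == pytest.approx(brute_percentile(ref, x))


class TestNormativeDB:
    def test_too_few_reference_eyes_rejected(self, cfg):
        frame = simulate_feature_cohort(50, cfg, seed=0)
        with pytest.raises(ValueError, match=">= 200"):
            build_normative_db(frame, cfg.indices)

    def test_percentiles_uniform_on_reference(self, cfg, small_bundle):
        held = simulate_feature_cohort(500, cfg, seed=99)
        pcts = []
        for _, row in held.iterrows():
            sector = row[SECTOR_COLUMNS].to_numpy(dtype=float)
            pcts.append(small_bundle.db.sector_percentiles(sector, row["disc_area"]))
        pcts = np.concatenate(pcts)
        # exchangeable draws: percentiles near-uniform on [0, 100]
        assert abs(pcts.mean() - 50.0) < 2.0
        assert 22 < pcts.std() < 35

    def test_json_round_trip(self, small_bundle, tmp_path):
        path = tmp_path / "db.json"
        small_bundle.db.to_json(path)
        from onhemo.indices import NormativeDB
        db2 = NormativeDB.from_json(path)
        q = np.full(24, 60.0)
        assert np.allclose(db2.sector_percentiles(q, 1.9),
                           small_bundle.db.sector_percentiles(q, 1.9))


class TestClassifierStandin:
    def test_separates_held_out_normals_and_glaucoma(self, cfg, small_bundle):
        held_n = simulate_feature_cohort(200, cfg, seed=201, severity=0.0)
        held_g = simulate_feature_cohort(200, cfg, seed=202, severity=1.0)
        scored_n = score_frame(held_n, small_bundle, cfg)
        scored_g = score_frame(held_g, small_bundle, cfg)
        assert (scored_n["classifier_score"] > 0.5).mean() >= 0.95
        assert (scored_g["classifier_score"] < 0.5).mean() >= 0.95

    def test_deterministic_inference(self, cfg, small_bundle):
        x = np.r_[np.full(24, 55.0), 0.45, 20.0, 1.9]
        assert small_bundle.classifier.score(x) == small_bundle.classifier.score(x)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        with pytest.raises(ValueError, match="both"):
            train_classifier_standin(X, np.ones(30))


def _neutral_fv(classifier_score=1.0):
    return FeatureVector(sector_percentiles=np.full(24, 50.0), vertical_cd=0.45,
                         vcd_percentile=50.0, cup_area_pct=20.0, cup_percentile=50.0,
                         disc_area=1.9, classifier_score=classifier_score)


class TestRawDiscriminant:
    def test_neutral_input_scores_zero(self, cfg):
        w = DiscriminantWeights.gdf(cfg.indices)
        assert raw_discriminant(_neutral_fv(), w, True) == pytest.approx(0.0)

    def test_monotone_in_each_sector(self, cfg):
        w = DiscriminantWeights.gdf(cfg.indices)
        base = raw_discriminant(_neutral_fv(), w, True)
        for s in range(24):
            fv = _neutral_fv()
            fv.sector_percentiles[s] = 20.0
            assert raw_discriminant(fv, w, True) < base

    def test_classifier_toggle_shifts_by_exact_weight(self, cfg):
        w = DiscriminantWeights.gdf(cfg.indices)
        fv = _neutral_fv(classifier_score=0.0)
        on = raw_discriminant(fv, w, True)
        off = raw_discriminant(fv, w, False)
        assert off - on == pytest.approx(w.w_classifier)

    def test_supinf_sectors_weighted_double(self, cfg):
        w = DiscriminantWeights.gdf(cfg.indices)
        fv_sup = _neutral_fv()
        fv_sup.sector_percentiles[2] = 30.0  # superior wedge, outer annulus
        fv_tmp = _neutral_fv()
        fv_tmp.sector_percentiles[0] = 30.0  # temporal wedge
        drop_sup = raw_discriminant(_neutral_fv(), w, True) - raw_discriminant(fv_sup, w, True)
        drop_tmp = raw_discriminant(_neutral_fv(), w, True) - raw_discriminant(fv_tmp, w, True)
        assert drop_sup == pytest.approx(2.0 * drop_tmp)


class TestCalibration:
    def test_linear_solve_worked_example(self, cfg):
        """Anchor quantiles q05=2, q01=-1 give the affine map a=5, b=-10."""
        q = np.linspace(0, 1, 201)
        scores = 75.0 * q - 1.75  # quantile function with Q(.05)=2, Q(.01)=-1
        cal = calibrate_index(scores, cfg.indices, uses_classifier=True)
        assert cal.a == pytest.approx(5.0, abs=1e-9)
        assert cal.b == pytest.approx(-10.0, abs=1e-9)
        assert cal.a * 2.0 + cal.b == pytest.approx(0.0)
        assert cal.a * -1.0 + cal.b == pytest.approx(-15.0)

    def test_identity_when_anchors_already_met(self, cfg):
        q = np.linspace(0, 1, 201)
        scores = 375.0 * q - 18.75  # Q(.05)=0, Q(.01)=-15
        cal = calibrate_index(scores, cfg.indices, uses_classifier=False)
        assert cal.a == pytest.approx(1.0, abs=1e-9)
        assert cal.b == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_spread_rejected(self, cfg):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_index(np.zeros(300), cfg.indices)

    def test_held_in_fractions_near_anchor_targets(self, cfg, small_bundle):
        # reconstruct the exact normal cohort the bundle was built on
        ss = np.random.SeedSequence(11)
        norm_seed = int(ss.spawn(2)[0].generate_state(1)[0] % (2 ** 31))
        held_in = simulate_feature_cohort(600, cfg, seed=norm_seed)
        scored = score_frame(held_in, small_bundle, cfg)
        assert (scored["GDF"] < 0).mean() == pytest.approx(0.05, abs=0.015)
        assert (scored["GDF"] < -15).mean() == pytest.approx(0.01, abs=0.01)


class TestIndices:
    def test_median_normal_gdf_positive(self, cfg, small_bundle):
        fv = _neutral_fv()
        fv.classifier_score = small_bundle.classifier.score(fv)
        assert compute_gdf(fv, small_bundle.cal_gdf, cfg.indices) > 0

    def test_severe_eye_below_minus_15(self, cfg, small_bundle):
        sick = simulate_feature_cohort(100, cfg, seed=31, severity=1.0)
        scored = score_frame(sick, small_bundle, cfg)
        assert (scored["GDF"] < -15).mean() >= 0.95

    def test_clipping_to_range(self, cfg, small_bundle):
        # a raw score mapping far below the range is clipped to the floor
        assert small_bundle.cal_gdf.apply(-5.0) == -100.0
        assert small_bundle.cal_gdf.apply(+5.0) == 85.0
        assert small_bundle.cal_gip.apply(-5.0) == -100.0
        assert small_bundle.cal_gip.apply(+5.0) == 100.0

    def test_calibration_weight_set_mismatch_rejected(self, cfg, small_bundle):
        fv = _neutral_fv()
        with pytest.raises(ValueError):
            compute_gdf(fv, small_bundle.cal_gip, cfg.indices)
        with pytest.raises(ValueError):
            compute_gip(fv, small_bundle.cal_gdf, cfg.indices)

    def test_classifier_flip_moves_gdf_not_gip(self, cfg, small_bundle):
        fv0, fv1 = _neutral_fv(0.0), _neutral_fv(1.0)
        assert (compute_gip(fv0, small_bundle.cal_gip, cfg.indices)
                == compute_gip(fv1, small_bundle.cal_gip, cfg.indices))
        assert (compute_gdf(fv0, small_bundle.cal_gdf, cfg.indices)
                < compute_gdf(fv1, small_bundle.cal_gdf, cfg.indices))

    def test_gip_lower_for_severe_eye(self, cfg, small_bundle):
        normal = score_frame(simulate_feature_cohort(50, cfg, seed=41, severity=0.0),
                             small_bundle, cfg)
        severe = score_frame(simulate_feature_cohort(50, cfg, seed=42, severity=1.0),
                             small_bundle, cfg)
        assert severe["GIP"].mean() < normal["GIP"].mean() - 10

    def test_index_ranges_respected(self, cfg, small_bundle):
        mixed = simulate_feature_cohort(400, cfg, seed=51, severity=(0.0, 1.0))
        scored = score_frame(mixed, small_bundle, cfg)
        assert scored["GDF"].between(-100, 85).all()
        assert scored["GIP"].between(-100, 100).all()

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError):
            FeatureVector(sector_percentiles=np.full(24, 120.0), vertical_cd=0.4,
                          vcd_percentile=50.0, cup_area_pct=20.0, cup_percentile=50.0,
                          disc_area=1.9)
        with pytest.raises(ValueError):
            FeatureVector(sector_percentiles=np.full(24, np.nan), vertical_cd=0.4,
                          vcd_percentile=50.0, cup_area_pct=20.0, cup_percentile=50.0,
                          disc_area=1.9)
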