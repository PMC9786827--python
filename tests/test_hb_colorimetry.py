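"""Vessel-referenced colourimetry: reference, Hb map, sectors, cup."""

import numpy as np
import pytest

from onhemo import geometry, hb_colorimetry, segmentation
from onhemo.config import ColorimetryConfig
from onhemo.segmentation import DiscSegmentation
from onhemo.synthetic_fundus import AcquisitionParams, make_eye_profile, render_fundus


def _image_from_channels(shape, r, g):
    img = np.zeros(shape + (3,), dtype=float)
    img[..., 0] = r
    img[..., 1] = g
    img[..., 2] = 40.0
    return img


def _synthetic_disc(shape=(64, 64), radius=24):
    ell = geometry.Ellipse((shape[0] / 2, shape[1] / 2), radius, radius)
    mask = geometry.ellipse_mask(shape, ell)
    return DiscSegmentation(center=ell.center, ellipse=ell, disc_mask=mask,
                            disc_area=mask.sum() * 0.02 ** 2, confidence=1.0)


class TestVesselReference:
    def test_median_of_per_pixel_ratio(self):
        img = _image_from_channels((10, 10), 0.0, 0.0)
        vm = np.zeros((10, 10), dtype=bool)
        vm[:6, :] = True  # 60 pixels, alternating the two example colours
        img[:3, :, 0], img[:3, :, 1] = 200.0, 60.0   # ratio 0.70
        img[3:6, :, 0], img[3:6, :, 1] = 150.0, 45.0  # ratio 0.70
        ref = hb_colorimetry.vessel_reference(img, vm)
        assert ref == pytest.approx(0.70, abs=1e-12)

    def test_grey_vessels_rejected(self):
        img = _image_from_channels((10, 10), 120.0, 120.0)  # R == G
        vm = np.ones((10, 10), dtype=bool)
        with pytest.raises(hb_colorimetry.ReferenceError, match="positive"):
            hb_colorimetry.vessel_reference(img, vm)

    def test_too_few_pixels_rejected(self):
        img = _image_from_channels((10, 10), 200.0, 60.0)
        vm = np.zeros((10, 10), dtype=bool)
        vm[0, :5] = True
        with pytest.raises(hb_colorimetry.ReferenceError):
            hb_colorimetry.vessel_reference(img, vm)

    def test_rendered_reference_matches_generator(self, cfg):
        from onhemo.config import GeneratorConfig
        pop = GeneratorConfig(vessel_reference_ratio=0.6)
        gt = make_eye_profile(pop, seed=1)
        img, _ = render_fundus(gt, AcquisitionParams(noise_sd=2.0, seed=4), pop)
        seg = segmentation.detect_disc(img, gt.scale, cfg.segmentation)
        vm = segmentation.segment_vessels(img, seg, cfg.segmentation)
        ref = hb_colorimetry.vessel_reference(img, vm)
        assert ref == pytest.approx(0.60, abs=0.02)


class TestHbMap:
    def test_pixel_arithmetic(self):
        """(R=180, G=120) against reference 0.70 is 47.6% haemoglobin."""
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 180.0, 120.0)
        hb = hb_colorimetry.hb_map(img, disc.disc_mask,
                                   np.zeros_like(disc.disc_mask), 0.70)
        expected = 100.0 * (60.0 / 180.0) / 0.70
        assert np.nanmax(np.abs(hb.values[disc.disc_mask] - expected)) < 1e-9
        assert expected == pytest.approx(47.619, abs=1e-3)

    def test_vessel_coloured_tissue_reads_100(self):
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 200.0, 60.0)
        hb = hb_colorimetry.hb_map(img, disc.disc_mask,
                                   np.zeros_like(disc.disc_mask), 0.70)
        assert np.nanmax(np.abs(hb.values[disc.disc_mask] - 100.0)) < 1e-9

    def test_multiplicative_scale_invariance(self):
        """(R-G)/R cancels any global illumination gain exactly."""
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 180.0, 120.0)
        hb1 = hb_colorimetry.hb_map(img, disc.disc_mask,
                                    np.zeros_like(disc.disc_mask), 0.70)
        hb2 = hb_colorimetry.hb_map(img * 0.37, disc.disc_mask,
                                    np.zeros_like(disc.disc_mask), 0.70)
        assert np.allclose(hb1.values[disc.disc_mask],
                           hb2.values[disc.disc_mask], atol=1e-9)

    def test_clipping_and_reference_validation(self):
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 200.0, 0.0)  # ratio 1.0
        hb = hb_colorimetry.hb_map(img, disc.disc_mask,
                                   np.zeros_like(disc.disc_mask), 0.70)
        assert np.nanmax(hb.values) == pytest.approx(120.0)
        with pytest.raises(ValueError):
            hb_colorimetry.hb_map(img, disc.disc_mask,
                                  np.zeros_like(disc.disc_mask), 0.0)

    def test_empty_tissue_rejected(self):
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 180.0, 120.0)
        with pytest.raises(ValueError, match="tissue"):
            hb_colorimetry.hb_map(img, np.zeros_like(disc.disc_mask),
                                  np.zeros_like(disc.disc_mask), 0.7)


class TestSectorProfile:
    def test_uniform_map_uniform_sectors(self):
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 200.0, 123.0)
        ref = (200.0 - 123.0) / 200.0 / 0.55  # chosen so Hb = 55 exactly
        hb = hb_colorimetry.hb_map(img, disc.disc_mask,
                                   np.zeros_like(disc.disc_mask), ref)
        prof = hb_colorimetry.sector_profile(hb, disc)
        assert np.allclose(prof.values, 55.0, atol=1e-9)
        assert prof.imputed == []

    def test_superior_mid_annulus_indexing(self):
        """A pixel straight above the centre at mid radius falls in the
        superior wedge of the middle annulus (sector 8 + 2)."""
        ell = geometry.Ellipse((32, 32), 24, 24)
        smap = geometry.sector_map((64, 64), ell)
        # mid annulus: normalised radius between sqrt(1/3) and sqrt(2/3)
        assert smap[32 - 17, 32] == 1 * 8 + 2
        # temporal outer sector is sector 0
        assert smap[32, 32 + 23] == 0

    def test_depressed_superior_inferior_recovered(self, cfg):
        gt = make_eye_profile(cfg.generator, seed=6)
        gt.rim_hb = np.full(24, 65.0)
        gt.sector_hb = np.full(24, 65.0)
        supinf = geometry.supinf_sector_mask()
        gt.sector_hb[supinf] -= 20.0
        img, _ = render_fundus(gt, AcquisitionParams(noise_sd=0.0, seed=2),
                               cfg.generator)
        seg = segmentation.detect_disc(img, gt.scale, cfg.segmentation)
        vm = segmentation.segment_vessels(img, seg, cfg.segmentation)
        refv = hb_colorimetry.vessel_reference(img, vm)
        hb = hb_colorimetry.hb_map(img, seg.disc_mask, vm, refv)
        prof = hb_colorimetry.sector_profile(hb, seg)
        assert np.all(np.abs(prof.values[supinf] - 45.0) < 4.0)

    def test_roundtrip_uniform_60(self, cfg):
        """Full pipeline on a noise-free render recovers Hb 60 within 3."""
        gt = make_eye_profile(cfg.generator, seed=1)
        gt.sector_hb = np.full(24, 60.0)
        gt.rim_hb = None
        img, _ = render_fundus(gt, AcquisitionParams(noise_sd=0.0, seed=5),
                               cfg.generator)
        seg = segmentation.detect_disc(img, gt.scale, cfg.segmentation)
        vm = segmentation.segment_vessels(img, seg, cfg.segmentation)
        refv = hb_colorimetry.vessel_reference(img, vm)
        hb = hb_colorimetry.hb_map(img, seg.disc_mask, vm, refv)
        assert np.nanmean(hb.values) == pytest.approx(60.0, abs=3.0)
        prof = hb_colorimetry.sector_profile(hb, seg)
        assert np.all(np.abs(prof.values - 60.0) < 3.0)


class TestCupEstimate:
    def test_uniform_map_has_no_cup(self):
        disc = _synthetic_disc()
        img = _image_from_channels(disc.disc_mask.shape, 200.0, 110.0)
        hb = hb_colorimetry.hb_map(img, disc.disc_mask,
                                   np.zeros_like(disc.disc_mask), 0.70)
        cup = hb_colorimetry.estimate_cup(hb, disc, 0.02)
        assert cup.cup_area_pct == 0.0
        assert cup.vertical_cd == 0.0

    def test_cup_fraction_20_recovered(self, cfg):
        gt = make_eye_profile(cfg.generator, seed=4)
        gt.cup_fraction = 0.200
        gt.rim_hb = np.full(24, 65.0)
        cov = gt.cup_coverage()
        gt.sector_hb = gt.rim_hb * (1 - cov * (1 - gt.cup_contrast))
        img, _ = render_fundus(gt, AcquisitionParams(noise_sd=0.0, seed=8),
                               cfg.generator)
        seg = segmentation.detect_disc(img, gt.scale, cfg.segmentation)
        vm = segmentation.segment_vessels(img, seg, cfg.segmentation)
        refv = hb_colorimetry.vessel_reference(img, vm)
        hb = hb_colorimetry.hb_map(img, seg.disc_mask, vm, refv)
        cup = hb_colorimetry.estimate_cup(hb, seg, gt.scale)
        assert cup.cup_area_pct == pytest.approx(20.0, abs=4.0)
        assert cup.cd_area_ratio == pytest.approx(cup.cup_area_pct / 100.0)

    def test_vertical_cd_increases_with_elongation(self, cfg):
        vcds = []
        for elong in (0.05, 0.50):
            gt = make_eye_profile(cfg.generator, seed=4)
            gt.cup_fraction = 0.25
            gt.cup_elongation = elong
            cov = gt.cup_coverage()
            gt.rim_hb = np.full(24, 65.0)
            gt.sector_hb = gt.rim_hb * (1 - cov * (1 - gt.cup_contrast))
            img, _ = render_fundus(gt, AcquisitionParams(noise_sd=0.0, seed=8),
                                   cfg.generator)
            seg = segmentation.detect_disc(img, gt.scale, cfg.segmentation)
            vm = segmentation.segment_vessels(img, seg, cfg.segmentation)
            refv = hb_colorimetry.vessel_reference(img, vm)
            hb = hb_colorimetry.hb_map(img, seg.disc_mask, vm, refv)
            vcds.append(hb_colorimetry.estimate_cup(hb, seg, gt.scale).vertical_cd)
        assert vcds[1] > vcds[0]

    def test_rim_sector_areas_partition_disc(self, cfg, rendered_eye):
        gt, img, _ = rendered_eye
        seg = segmentation.detect_disc(img, gt.scale, cfg.segmentation)
        vm = segmentation.segment_vessels(img, seg, cfg.segmentation)
        refv = hb_colorimetry.vessel_reference(img, vm)
        hb = hb_colorimetry.hb_map(img, seg.disc_mask, vm, refv)
        cup = hb_colorimetry.estimate_cup(hb, seg, gt.scale)
        rim_total = cup.rim_sector_areas.sum()
        disc_minus_cup = (seg.disc_mask.sum() - cup.cup_mask.sum()) * gt.scale ** 2
        assert rim_total == pytest.approx(disc_minus_cup, rel=0.01)
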