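"""Scoring contracts: masks, set thresholds, perimeter fractions, pooling."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from fiberquant import scoring as sc
from fiberquant import segmentation as seg
from fiberquant import synthetic as syn


def _image(dys, lam, batch="batch0", sample="s"):
    return syn.SectionImage(dystrophin=np.asarray(dys, float),
                            laminin=np.asarray(lam, float),
                            sample_id=sample, exposure_batch=batch)


class TestLamininMask:
    def test_bimodal_image_masks_exactly_the_rings(self):
        lam = np.full((64, 64), 100.0)
        lam[10:20, 10:50] = 1000.0
        mask = sc.laminin_mask(lam)
        np.testing.assert_array_equal(mask, lam == 1000.0)

    def test_synthetic_section_coverage(self, noisy_section):
        r = noisy_section
        ring = np.zeros_like(r.gt.label_map, dtype=bool)
        for px in r.gt.ring_pixels.values():
            ring[px[:, 0], px[:, 1]] = True
        assert r.lam_mask[ring].mean() >= 0.90
        interior = r.gt.label_map > 0
        assert r.lam_mask[interior].mean() <= 0.05

    def test_scale_invariance(self, noisy_section):
        lam = noisy_section.pre.laminin
        np.testing.assert_array_equal(sc.laminin_mask(lam),
                                      sc.laminin_mask(lam * 2.5))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            sc.laminin_mask(np.full((32, 32), 7.0))


class TestDeriveThreshold:
    def test_uniform_background_gives_exact_multiple(self):
        lam = np.zeros((64, 64))
        lam[30:34, :] = 1000.0
        img = _image(np.full((64, 64), 200.0), lam)
        ts = sc.derive_threshold([img], [lam > 0])
        assert ts.set_threshold == pytest.approx(300.0)

    def test_two_image_mean(self):
        lam = np.zeros((64, 64))
        lam[30:34, :] = 1000.0
        a = _image(np.full((64, 64), 200.0), lam)
        b = _image(np.full((64, 64), 400.0), lam)
        ts = sc.derive_threshold([a, b], [lam > 0, lam > 0])
        assert ts.set_threshold == pytest.approx(450.0)   # mean of 300 and 600

    def test_matches_analytic_percentile_of_noise_model(self):
        rng = np.random.default_rng(12)
        bg, sd = 200.0, 30.0
        dys = np.clip(rng.normal(bg, sd, (512, 512)), 0, None)
        lam = np.zeros((512, 512))
        lam[200:220, :] = 1500.0
        img = _image(dys, lam)
        ts = sc.derive_threshold([img], [lam > 0])
        analytic = 1.5 * (bg + sd * sps.norm.ppf(0.998))
        assert ts.set_threshold == pytest.approx(analytic, rel=0.02)

    def test_mixed_exposure_batches_rejected(self):
        lam = np.zeros((32, 32))
        lam[10:12, :] = 1000.0
        a = _image(np.full((32, 32), 100.0), lam, batch="b1")
        b = _image(np.full((32, 32), 100.0), lam, batch="b2")
        with pytest.raises(ValueError, match="batch"):
            sc.derive_threshold([a, b], [lam > 0, lam > 0])

    def test_empty_non_sarcolemmal_region_rejected(self):
        lam = np.full((32, 32), 1000.0)
        img = _image(np.full((32, 32), 100.0), lam)
        with pytest.raises(ValueError, match="non-sarcolemmal"):
            sc.derive_threshold([img], [lam > 0])


def _single_fiber_score(fraction, seed=0, **score_kw):
    spec = syn.SectionSpec(n_fibers=1, mean_fiber_diameter=60,
                           image_shape=(160, 160),
                           per_fiber_dystrophin_fraction=[fraction],
                           shading_amplitude=0.0, noise_sd=0.0, seed=seed)
    image, gt = syn.generate_section(spec)
    fmap = seg.import_label_map(gt.label_map, image.laminin)
    lam_mask = sc.laminin_mask(image.laminin)
    ts = sc.derive_threshold([image], [lam_mask])
    return sc.score_fibers(image, fmap, lam_mask, ts,
                           band_halfwidth=3, **score_kw)[0]


class TestScoreFibers:
    def test_fully_ringed_fiber_is_fully_positive(self):
        s = _single_fiber_score(1.0)
        assert s.fraction == pytest.approx(1.0)
        assert s.positive

    def test_blank_fiber_is_negative(self):
        s = _single_fiber_score(0.0)
        assert s.fraction == 0.0
        assert not s.positive

    @pytest.mark.parametrize("fraction,call", [(0.29, False), (0.30, True),
                                               (0.31, True)])
    def test_cutoff_inclusive_at_30_percent(self, fraction, call):
        assert _single_fiber_score(fraction).positive is call

    def test_batch_mismatch_rejected(self, noisy_section):
        r = noisy_section
        alien = sc.ThresholdSet(per_image_p998={"x": 100.0},
                                exposure_batch="other")
        with pytest.raises(ValueError, match="batch"):
            sc.score_fibers(r.pre, r.fmap, r.lam_mask, alien)

    def test_fraction_equals_brute_force_boundary_count(self, clean_section):
        """Oracle: per-pixel count over the ground-truth boundary in the band."""
        r = clean_section
        ring = np.zeros_like(r.gt.label_map, dtype=bool)
        lit = np.zeros_like(r.gt.label_map, dtype=bool)
        for px in r.gt.ring_pixels.values():
            ring[px[:, 0], px[:, 1]] = True
        for px in r.gt.lit_pixels.values():
            lit[px[:, 0], px[:, 1]] = True
        for s in r.scores:
            band = sc.perimeter_band(r.fmap.labels == s.fiber_id, 2)
            denom = int((band & ring).sum())
            oracle = int((band & lit).sum()) / denom
            assert abs(s.fraction - oracle) <= 2.0 / denom

    def test_lower_threshold_never_decreases_fractions(self, noisy_section):
        r = noisy_section
        lower = sc.ThresholdSet(
            per_image_p998={k: v * 0.5 for k, v in
                            r.thresholds.per_image_p998.items()},
            exposure_batch=r.thresholds.exposure_batch)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            relaxed = sc.score_fibers(r.pre, r.fmap, r.lam_mask, lower)
        strict_by_id = {s.fiber_id: s.fraction for s in r.scores}
        for s in relaxed:
            assert s.fraction >= strict_by_id[s.fiber_id] - 1e-12
        pooled_lo = sc.pool_section([relaxed])
        pooled_hi = sc.pool_section([r.scores])
        assert pooled_lo.percent_positive >= pooled_hi.percent_positive

    def test_percent_positive_monotone_in_cutoff(self, noisy_section):
        r = noisy_section
        fractions = np.array([s.fraction for s in r.scores])
        cuts = [1e-9, 0.1, 0.3, 0.5, 0.9, 1.0]
        pct = [100.0 * (fractions >= c).mean() for c in cuts]
        assert all(a >= b for a, b in zip(pct, pct[1:]))
        assert pct[0] == pytest.approx(100.0 * (fractions > 0).mean())


class TestPooling:
    def test_counts_pool_before_percentage(self):
        def fake(n_pos, n_tot):
            return [sc.FiberScore(i, 100, 50 if i < n_pos else 0,
                                  0.5 if i < n_pos else 0.0, i < n_pos)
                    for i in range(n_tot)]
        pooled = sc.pool_section([fake(10, 20), fake(30, 40)])
        assert pooled.percent_positive == pytest.approx(100 * 40 / 60)

    def test_single_image_is_identity(self, noisy_section):
        r = noisy_section
        one = sc.pool_section([r.scores])
        n_pos = sum(s.positive for s in r.scores)
        assert one.n_total == len(r.scores)
        assert one.percent_positive == pytest.approx(100 * n_pos / len(r.scores))

    def test_pooled_percent_matches_concatenated_truth(self):
        per_image = []
        truth_pos = truth_tot = 0
        for s in range(3):
            spec = syn.SectionSpec(n_fibers=25, image_shape=(300, 300),
                                   shading_amplitude=0.0, noise_sd=0.0, seed=40 + s)
            image, gt = syn.generate_section(spec)
            fmap = seg.import_label_map(gt.label_map, image.laminin)
            lam_mask = sc.laminin_mask(image.laminin)
            ts = sc.derive_threshold([image], [lam_mask])
            per_image.append(sc.score_fibers(image, fmap, lam_mask, ts))
            truth_pos += gt.n_positive
            truth_tot += gt.n_total
        pooled = sc.pool_section(per_image)
        assert pooled.n_total == truth_tot
        assert pooled.percent_positive == pytest.approx(
            100.0 * truth_pos / truth_tot, abs=3.0)


class TestIntensity:
    def test_identical_channels_ratio_one(self):
        lam = np.full((32, 32), 500.0)
        img = _image(lam.copy(), lam)
        ratio, area = sc.intensity_ratio(img, lam > 0)
        assert ratio == pytest.approx(1.0)
        assert area == 32 * 32

    def test_zero_dystrophin_ratio_zero(self):
        lam = np.full((32, 32), 500.0)
        img = _image(np.zeros((32, 32)), lam)
        ratio, _ = sc.intensity_ratio(img, lam > 0)
        assert ratio == 0.0

    def test_half_intensity_rendering_recovered(self):
        spec = syn.SectionSpec(n_fibers=10, image_shape=(256, 256),
                               per_fiber_dystrophin_fraction=[1.0] * 10,
                               dystrophin_intensity=750.0,
                               laminin_intensity=1500.0, background_level=0.0,
                               shading_amplitude=0.0, noise_sd=0.0, seed=3)
        image, gt = syn.generate_section(spec)
        lam_mask = sc.laminin_mask(image.laminin)
        ratio, _ = sc.intensity_ratio(image, lam_mask)
        assert gt.true_intensity_ratio == pytest.approx(0.5)
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_area_weighted_pooling(self):
        assert sc.pool_intensity([(1.0, 3), (0.0, 1)]) == pytest.approx(0.75)
        assert sc.pool_intensity([(0.4, 7)]) == pytest.approx(0.4)
        assert sc.pool_intensity([(0.2, 5), (0.8, 5)]) == pytest.approx(0.5)

    def test_percent_of_control(self):
        pct, flagged = sc.percent_of_control(0.5, [0.8, 1.0, 1.2])
        assert pct == pytest.approx(50.0)
        assert not flagged
        pct, flagged = sc.percent_of_control(1.0, [1.0])
        assert pct == pytest.approx(100.0)
        pct, flagged = sc.percent_of_control(0.0, [0.9])
        assert pct == 0.0

    def test_fallback_controls_used_and_flagged(self):
        pct, flagged = sc.percent_of_control(0.5, [], fallback_controls=[1.0])
        assert pct == pytest.approx(50.0)
        assert flagged
        with pytest.raises(ValueError):
            sc.percent_of_control(0.5, [], fallback_controls=[])

    def test_cardiac_intensity_skips_segmentation(self):
        spec = syn.SectionSpec(n_fibers=10, image_shape=(256, 256),
                               per_fiber_dystrophin_fraction=[1.0] * 10,
                               dystrophin_intensity=750.0,
                               laminin_intensity=1500.0, background_level=0.0,
                               shading_amplitude=0.0, noise_sd=0.0, seed=3)
        image, _ = syn.generate_section(spec)
        pct, flagged = sc.cardiac_intensity(image, control_ratios=[0.5])
        assert pct == pytest.approx(100.0, rel=0.02)


class TestOverlay:
    def test_endpoint_colors_and_roundtrip(self):
        labels = np.zeros((40, 80), dtype=np.int32)
        labels[10:30, 5:35] = 1
        labels[10:30, 45:75] = 2
        fmap = seg.FiberLabelMap(labels=labels, n_fibers=2)
        scores = [sc.FiberScore(1, 100, 0, 0.0, False),
                  sc.FiberScore(2, 100, 100, 1.0, True)]
        image = _image(np.zeros((40, 80)), np.ones((40, 80)))
        rgb = sc.export_overlay(image, fmap, scores)
        import matplotlib
        cmap = matplotlib.colormaps[sc.OVERLAY_CMAP]
        band1 = sc.perimeter_band(labels == 1, 2)
        band2 = sc.perimeter_band(labels == 2, 2)
        np.testing.assert_array_equal(
            rgb[band1][0], (np.array(cmap(0.0)[:3]) * 255).astype(np.uint8))
        np.testing.assert_array_equal(
            rgb[band2][0], (np.array(cmap(1.0)[:3]) * 255).astype(np.uint8))
        for s, band in [(scores[0], band1), (scores[1], band2)]:
            decoded = sc.decode_overlay_fraction(rgb[band][0])
            assert abs(decoded - s.fraction) <= 1.0 / 255
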