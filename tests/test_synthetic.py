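"""Cohort generator: determinism, invariants, calibration, rasterization."""

import numpy as np
import pytest

from ctvshift import (GeneratorParams, Point2D, add_gas_pocket,
                      extract_cohort_features, locate_feature_points,
                      make_patient_baseline, rank_features, rasterize,
                      sample_fraction, simulate_cohort, spearman_rho,
                      superellipse)
from ctvshift.raster import fill_mask, grid_for


class TestBaseline:
    def test_deterministic_given_seed(self, default_params):
        a = make_patient_baseline(default_params, "p1", 42)
        b = make_patient_baseline(default_params, "p1", 42)
        for name in ("bladder", "rectum", "prostate", "ctv", "bone"):
            assert np.array_equal(getattr(a, name).vertices,
                                  getattr(b, name).vertices)

    def test_invariants_over_seeds(self, default_params):
        for seed in range(100):
            anat = make_patient_baseline(default_params, "p", seed)
            s_pt = locate_feature_points(anat.bone).S
            assert anat.rectum.centroid().a < s_pt.a
            assert anat.ctv.polygon.buffer(1e-9).contains(anat.prostate.polygon)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(sigma_u=-1.0)
        with pytest.raises(ValueError):
            GeneratorParams(eps_lr=1.0)


class TestFraction:
    def test_zero_variance_is_identity(self, default_params):
        params = GeneratorParams.zero_variance()
        base = make_patient_baseline(params, "p", 3)
        rec = sample_fraction(base, params, 1, 99)
        assert rec.reference_shift.as_array().tolist() == [0.0, 0.0, 0.0]
        for name in ("bladder", "rectum", "prostate", "ctv", "bone"):
            assert np.array_equal(getattr(rec.pretreatment, name).vertices,
                                  getattr(rec.planning, name).vertices)

    def test_reference_shift_matches_ctv_centroid_motion(self, small_cohort):
        for rec in small_cohort.all_fractions():
            c0 = rec.planning.ctv.centroid()
            c1 = rec.pretreatment.ctv.centroid()
            assert abs((c1.s - c0.s) - rec.reference_shift.si) < 1e-9
            assert abs((c1.a - c0.a) - rec.reference_shift.ap) < 1e-9

    def test_lateral_shifts_are_small_noise(self, small_cohort):
        lr = np.array([r.reference_shift.lr for r in small_cohort.all_fractions()])
        assert np.abs(lr).max() < 1.0  # pure sub-half-mm noise by construction


class TestCohort:
    def test_counts(self, default_params):
        cohort = simulate_cohort(default_params, 3, 5, seed=7)
        assert cohort.n_patients == 3
        assert cohort.n_fractions == 15

    def test_seed_changes_shifts(self, default_params):
        a = simulate_cohort(default_params, 2, 3, seed=1)
        b = simulate_cohort(default_params, 2, 3, seed=2)
        sa = [r.reference_shift.si for r in a.all_fractions()]
        sb = [r.reference_shift.si for r in b.all_fractions()]
        assert sa != sb

    def test_identical_seeds_identical_cohorts(self, default_params):
        a = simulate_cohort(default_params, 2, 3, seed=5)
        b = simulate_cohort(default_params, 2, 3, seed=5)
        for ra, rb in zip(a.all_fractions(), b.all_fractions()):
            assert np.array_equal(ra.pretreatment.rectum.vertices,
                                  rb.pretreatment.rectum.vertices)
            assert ra.reference_shift == rb.reference_shift

    def test_zero_variance_cohort_all_zero_shifts(self):
        cohort = simulate_cohort(GeneratorParams.zero_variance(), 3, 4, seed=9)
        shifts = np.array([r.reference_shift.as_array()
                           for r in cohort.all_fractions()])
        assert np.all(shifts == 0.0)

    def test_too_few_patients_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate_cohort(default_params, 1, 5, seed=0)


class TestCalibration:
    """Pooled statistics of a default cohort sit in the intended bands."""

    def test_shift_scale_and_f3_dominance(self, default_params):
        cohort = simulate_cohort(default_params, 10, 38, seed=31)
        feat = extract_cohort_features(cohort, default_params.click_noise_sd,
                                       seed=32,
                                       cop_click_noise_sd=default_params.cop_click_noise_sd)
        assert 0.5 <= np.abs(feat["si"]).mean() <= 1.5
        assert 0.8 <= np.abs(feat["ap"]).mean() <= 2.0
        rho_si, _ = spearman_rho(feat["f3"], feat["si"])
        rho_ap, _ = spearman_rho(feat["f3"], feat["ap"])
        assert rho_si < 0 and rho_ap < 0
        assert rank_features(feat).order[0] == "f3"


class TestGasPocket:
    def test_pocket_inside_rectum_and_walls_untouched(self, default_params):
        rng = np.random.default_rng(4)
        base = make_patient_baseline(default_params, "p", 4)
        with_gas = add_gas_pocket(base, rng, default_params)
        assert with_gas.gas_region is not None
        assert with_gas.rectum.polygon.contains(with_gas.gas_region.polygon)
        assert np.array_equal(with_gas.rectum.vertices, base.rectum.vertices)


class TestRasterize:
    def test_gas_flag_irrelevant_without_gas(self, default_params):
        anat = make_patient_baseline(default_params, "p", 11)
        a = rasterize(anat, 1.0, include_gas=True)
        b = rasterize(anat, 1.0, include_gas=False)
        assert np.array_equal(a.pixels, b.pixels)

    def test_translation_equivariance_on_aligned_grid(self, default_params):
        anat = make_patient_baseline(default_params, "p", 12)
        origin, shape = grid_for([anat], 1.0)
        img = rasterize(anat, 1.0, origin=origin, shape=shape)
        moved = rasterize(anat.translated(3.0, -2.0), 1.0, origin=origin, shape=shape)
        expected = np.roll(np.roll(img.pixels, -2, axis=0), 3, axis=1)
        core = (slice(10, -10), slice(10, -10))
        assert np.array_equal(moved.pixels[core], expected[core])

    def test_filled_area_matches_polygon_area(self, default_params):
        circle = superellipse(Point2D(0, 0), 20, 20, 2.0, 256)  # 40 mm circle
        anat = make_patient_baseline(default_params, "p", 13)
        origin, shape = grid_for([anat], 1.0)
        img = rasterize(anat, 1.0, origin=origin, shape=shape)
        filled = fill_mask(circle, img).sum() * 1.0  # 1 mm^2 pixels
        assert abs(filled - circle.area) / circle.area < 0.05
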