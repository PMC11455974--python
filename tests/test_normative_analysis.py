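"""Filtering, alignment, cohort stacking, meridian fits, total cones."""

import numpy as np
import pytest

from conemap.montage_io import ScalarMap, ValidationError
from conemap.normative_analysis import (
    MeridianProfile,
    apply_overlap_threshold,
    build_cohort_stack,
    downsample_map,
    exclude_nonmonotonic_fovea,
    extract_summary,
    filter_participant_map,
    fit_dual_cauchy,
    meridian_strip_profile,
    orient_and_align,
    pearson_with_ci,
    total_cones_vs_eccentricity,
)
from conemap.profiles import DualCauchyProfile
from conemap.synthetic_mosaic import ground_truth_density_map

TRUTH = DualCauchyProfile(120000, 40000, 0.12, 1.1, 0.10, 0.9)


def _dens(values, scale=1.0, origin=(0, 0)):
    return ScalarMap(np.asarray(values, float), origin, scale, "density")


def _conf(values, scale=1.0, origin=(0, 0)):
    return ScalarMap(np.asarray(values, float), origin, scale, "confidence")


class TestFilter:
    def test_uniform_confidence_removes_nothing(self):
        d = _dens(np.full((100, 100), 5000.0))
        c = _conf(np.full((100, 100), 0.8))
        fd, fc = filter_participant_map(d, c, (50, 50))
        assert np.isfinite(fd.values).all()

    def test_peripheral_density_spike_removed(self):
        shape = (200, 200)
        vals = np.full(shape, 10000.0)
        vals[100, 100] = 30000.0  # foveal median stays 10000
        vals[10, 10] = 25000.0  # spike at ~1.8 mm (scale 14 µm/px)
        d = _dens(vals, scale=14.0)
        c = _conf(np.full(shape, 0.8), scale=14.0)
        fd, _ = filter_participant_map(d, c, (100, 100))
        assert np.isnan(fd.values[10, 10])
        assert np.isfinite(fd.values[100, 100])

    def test_all_below_foveal_median_keeps_everything(self):
        shape = (200, 200)
        ys, xs = np.mgrid[0:200, 0:200]
        r = np.hypot(xs - 100, ys - 100)
        vals = 20000.0 - 50 * r  # strictly decreasing
        d = _dens(np.clip(vals, 100, None), scale=14.0)
        c = _conf(np.full(shape, 0.8), scale=14.0)
        fd, _ = filter_participant_map(d, c, (100, 100))
        assert np.isfinite(fd.values).all()

    def test_low_confidence_tail_removed(self):
        rng = np.random.default_rng(0)
        d = _dens(np.full((100, 100), 5000.0))
        c = _conf(rng.uniform(0.2, 1.0, (100, 100)))
        fd, fc = filter_participant_map(d, c, (50, 50))
        frac_removed = np.isnan(fd.values).mean()
        assert 0.03 <= frac_removed <= 0.07  # ≈ 5th percentile


class TestOrientAndAlign:
    def test_identical_od_maps_superimpose(self):
        d = _dens(np.arange(100.0).reshape(10, 10))
        c = _conf(np.full((10, 10), 0.5))
        out = orient_and_align([(d, c), (d, c)], ["OD", "OD"], [(4, 5), (4, 5)])
        np.testing.assert_array_equal(out[0][0].values, out[1][0].values)

    def test_mirrored_os_superimposes_on_od(self):
        vals = np.arange(100.0).reshape(10, 10)
        d_od = _dens(vals)
        d_os = _dens(vals[:, ::-1])
        c = _conf(np.full((10, 10), 0.5))
        out = orient_and_align(
            [(d_od, c), (d_os, c)], ["OD", "OS"], [(3, 5), (6, 5)]
        )
        np.testing.assert_array_equal(out[0][0].values, out[1][0].values)

    def test_flip_is_involutive(self):
        vals = np.arange(100.0).reshape(10, 10)
        d = _dens(vals)
        c = _conf(np.full((10, 10), 0.5))
        once = orient_and_align([(d, c)], ["OS"], [(3, 5)])[0]
        # the aligned fovea sits at montage coordinate (0, 0); flip again
        twice = orient_and_align([once], ["OS"], [(0, 0)])[0]
        finite = np.isfinite(twice[0].values)
        rows = np.any(finite, axis=1)
        cols = np.any(finite, axis=0)
        restored = twice[0].values[np.ix_(rows, cols)]
        np.testing.assert_array_equal(restored, vals)

    def test_offset_centers_translate_relatively(self):
        vals = np.zeros((20, 20))
        d = _dens(vals)
        c = _conf(np.full((20, 20), 0.5))
        out = orient_and_align(
            [(d, c), (d, c)], ["OD", "OD"], [(10, 10), (20, 5)]
        )
        # both maps share one canvas; the second is shifted by (-10, +5)
        assert out[0][0].values.shape == out[1][0].values.shape
        f0 = np.argwhere(np.isfinite(out[0][0].values))
        f1 = np.argwhere(np.isfinite(out[1][0].values))
        shift = f1.min(axis=0) - f0.min(axis=0)
        assert tuple(shift) == (5, -10)  # (row, col)

    def test_missing_center_skipped_with_warning(self):
        d = _dens(np.zeros((10, 10)))
        c = _conf(np.full((10, 10), 0.5))
        with pytest.warns(UserWarning):
            out = orient_and_align([(d, c), (d, c)], ["OD", "OD"], [(5, 5), None])
        assert len(out) == 1


class TestDownsample:
    def test_constant_map(self):
        m = downsample_map(_dens(np.full((40, 40), 3.0)), 4)
        assert m.values.shape == (10, 10)
        np.testing.assert_allclose(m.values, 3.0)
        assert m.scale_um_per_px == 4.0

    def test_factor_one_identity(self):
        src = _dens(np.arange(16.0).reshape(4, 4))
        m = downsample_map(src, 1)
        np.testing.assert_array_equal(m.values, src.values)

    def test_linear_gradient_block_means(self):
        xs = np.tile(np.arange(16.0), (16, 1))
        m = downsample_map(_dens(xs), 4)
        expected = np.tile(np.arange(4) * 4 + 1.5, (4, 1))
        np.testing.assert_allclose(m.values, expected, atol=1e-6)


class TestCohortStack:
    def test_identical_maps_sd_zero(self):
        d = _dens(np.full((10, 10), 7000.0))
        c = _conf(np.full((10, 10), 0.5))
        stack = build_cohort_stack([(d, c)] * 10)
        assert np.all(stack.overlap.values == 10)
        np.testing.assert_allclose(stack.sd_density.values, 0.0)

    def test_disjoint_footprints(self):
        a = np.full((10, 10), np.nan)
        b = np.full((10, 10), np.nan)
        a[:, :5] = 1000.0
        b[:, 5:] = 2000.0
        c = _conf(np.full((10, 10), 0.5))
        stack = build_cohort_stack([(_dens(a), c), (_dens(b), c)])
        assert np.all(stack.overlap.values == 1)
        assert np.isnan(stack.sd_density.values).all()
        np.testing.assert_allclose(stack.mean_density.values[:, :5], 1000.0)

    def test_mean_within_participant_range(self):
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(5):
            pairs.append(
                (_dens(rng.uniform(1e3, 1e4, (20, 20))),
                 _conf(np.full((20, 20), 0.5)))
            )
        stack = build_cohort_stack(pairs)
        lo = np.min([p[0].values for p in pairs], axis=0)
        hi = np.max([p[0].values for p in pairs], axis=0)
        assert np.all(stack.mean_density.values >= lo - 1e-9)
        assert np.all(stack.mean_density.values <= hi + 1e-9)

    @pytest.mark.parametrize("overlap,removed", [(10, False), (9, True)])
    def test_overlap_threshold_boundary(self, overlap, removed):
        d = _dens(np.full((8, 8), 5000.0))
        c = _conf(np.full((8, 8), 0.5))
        stack = build_cohort_stack([(d, c)] * overlap)
        thr = apply_overlap_threshold(stack, 10)
        assert np.isnan(thr.mean_density.values).all() == removed
        np.testing.assert_array_equal(thr.overlap.values, stack.overlap.values)


class TestMeridianProfiles:
    def test_radially_symmetric_map_has_equal_meridians(self):
        iso = DualCauchyProfile(120000, 40000, 0.12, 1.1, 0.12, 1.1)
        m = ground_truth_density_map(iso, (600, 600), (0, 0), (300, 300), 5.0)
        profs = {
            mer: meridian_strip_profile(m, (300, 300), mer)
            for mer in ("nasal", "temporal", "superior", "inferior")
        }
        n = min(p.density.size for p in profs.values())
        for mer in ("temporal", "superior", "inferior"):
            np.testing.assert_allclose(
                profs[mer].density[: n - 2],
                profs["nasal"].density[: n - 2],
                rtol=0.01,
            )

    def test_anisotropic_truth_orders_meridians(self):
        m = ground_truth_density_map(TRUTH, (600, 600), (0, 0), (300, 300), 5.0)
        h = meridian_strip_profile(m, (300, 300), "nasal")
        v = meridian_strip_profile(m, (300, 300), "superior")
        n = min(h.density.size, v.density.size)
        # beyond the strip half-width the cross-axis averaging no longer
        # dominates and the wider horizontal widths order the profiles
        sel = (h.ecc[: n - 2] > 0.3)
        assert np.all(h.density[: n - 2][sel] >= v.density[: n - 2][sel] - 1e-6)

    def test_x_only_map_profiles(self):
        xs = np.tile(np.arange(400.0) + 100.0, (400, 1))
        m = _dens(xs, scale=5.0)
        nasal = meridian_strip_profile(m, (200, 200), "nasal")
        sup = meridian_strip_profile(m, (200, 200), "superior")
        # nasal profile follows f(x); vertical profile is constant per bin
        np.testing.assert_allclose(
            nasal.density[:100], 300.0 + np.arange(100) + 0.0, atol=1.0
        )
        assert np.nanstd(sup.density[:100]) <= np.nanstd(nasal.density[:100])

    def test_empty_meridian_warns(self):
        vals = np.full((100, 100), np.nan)
        vals[:, 60:] = 1000.0
        m = _dens(vals, scale=5.0)
        with pytest.warns(UserWarning):
            prof = meridian_strip_profile(m, (50, 50), "temporal")
        assert prof.ecc.size == 0


class TestMonotoneExclusion:
    ECC = np.linspace(0.005, 1.0, 100)

    def test_monotone_profile_unchanged(self):
        d = TRUTH.meridian_density(self.ECC, "horizontal")
        p = exclude_nonmonotonic_fovea(MeridianProfile("horizontal", self.ECC, d))
        np.testing.assert_array_equal(p.density, d)

    def test_central_dip_excluded(self):
        d = TRUTH.meridian_density(self.ECC, "horizontal").copy()
        dip = self.ECC < 0.08
        d[dip] *= 0.4
        p = exclude_nonmonotonic_fovea(MeridianProfile("horizontal", self.ECC, d))
        assert np.isnan(p.density[dip]).all()
        assert np.isfinite(p.density[~dip]).all()

    def test_flat_profile_within_tolerance_retained(self):
        d = np.full_like(self.ECC, 50000.0)
        p = exclude_nonmonotonic_fovea(MeridianProfile("horizontal", self.ECC, d))
        assert np.isfinite(p.density).all()


class TestDualCauchyFit:
    def test_noiseless_recovery_within_2pct(self):
        ecc = np.linspace(0.005, 3.0, 200)
        h = MeridianProfile("horizontal", ecc, TRUTH.meridian_density(ecc, "horizontal"))
        v = MeridianProfile("vertical", ecc, TRUTH.meridian_density(ecc, "vertical"))
        fit = fit_dual_cauchy(h, v)
        assert fit.pcd == pytest.approx(TRUTH.peak_density, rel=0.02)
        assert fit.profile.gamma1_h == pytest.approx(0.12, rel=0.02)
        assert fit.profile.gamma2_v == pytest.approx(0.9, rel=0.02)

    def test_symmetric_input_gives_equal_widths(self):
        ecc = np.linspace(0.005, 3.0, 150)
        d = TRUTH.meridian_density(ecc, "horizontal")
        h = MeridianProfile("horizontal", ecc, d)
        v = MeridianProfile("vertical", ecc, d)
        fit = fit_dual_cauchy(h, v)
        assert fit.profile.gamma1_h == pytest.approx(fit.profile.gamma1_v, rel=0.01)
        assert fit.profile.gamma2_h == pytest.approx(fit.profile.gamma2_v, rel=0.01)

    def test_pcd_recovery_under_noise(self):
        errors = []
        ecc = np.linspace(0.01, 3.0, 100)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dh = TRUTH.meridian_density(ecc, "horizontal") * (
                1 + 0.05 * rng.standard_normal(100)
            )
            dv = TRUTH.meridian_density(ecc, "vertical") * (
                1 + 0.05 * rng.standard_normal(100)
            )
            fit = fit_dual_cauchy(
                MeridianProfile("horizontal", ecc, dh),
                MeridianProfile("vertical", ecc, dv),
            )
            errors.append(abs(fit.pcd / TRUTH.peak_density - 1))
        assert max(errors) <= 0.10


class TestTotalCones:
    def test_uniform_disc_analytic(self):
        h = w = 1500
        ys, xs = np.mgrid[0:h, 0:w]
        r = np.hypot(xs - 750, ys - 750) * 1.4 / 1000.0
        m = _dens(np.where(r <= 1.0, 10000.0, np.nan), scale=1.4)
        curve = total_cones_vs_eccentricity(m, (750, 750))
        assert curve.at(1.0) == pytest.approx(np.pi * 1e4, rel=0.01)

    def test_zero_density_gives_zero_counts(self):
        m = _dens(np.zeros((400, 400)), scale=5.0)
        curve = total_cones_vs_eccentricity(m, (200, 200))
        np.testing.assert_allclose(curve.cumulative_cones, 0.0)

    def test_counts_non_decreasing(self):
        m = ground_truth_density_map(TRUTH, (500, 500), (0, 0), (250, 250), 4.0)
        curve = total_cones_vs_eccentricity(m, (250, 250))
        assert np.all(np.diff(curve.cumulative_cones) >= -1e-9)

    def test_model_substitutes_for_excluded_fovea(self):
        m = ground_truth_density_map(TRUTH, (800, 800), (0, 0), (400, 400), 2.0)
        holed = m.values.copy()
        ys, xs = np.mgrid[0:800, 0:800]
        holed[np.hypot(xs - 400, ys - 400) * 2.0 < 150] = np.nan
        from conemap.normative_analysis import DualCauchyFit

        fit = DualCauchyFit(TRUTH, TRUTH.peak_density, 0.0, 0.0)
        full = total_cones_vs_eccentricity(m, (400, 400))
        filled = total_cones_vs_eccentricity(
            _dens(holed, scale=2.0), (400, 400), fit=fit
        )
        assert filled.at(0.5) == pytest.approx(full.at(0.5), rel=0.01)


class TestSummaries:
    def test_degenerate_correlation_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = pearson_with_ci(np.ones(10), np.arange(10))
        assert np.isnan(out["r"])

    def test_constructed_effect_recovered(self):
        rng = np.random.default_rng(0)
        mind = rng.uniform(1000, 4000, 50)
        total = mind * 30 * (1 + 0.05 * rng.standard_normal(50))
        out = pearson_with_ci(total, mind)
        assert out["r"] > 0.95
        assert out["ci_low"] < out["r"] < out["ci_high"]

    def test_null_effect_small_correlation(self):
        rng = np.random.default_rng(42)
        out = pearson_with_ci(rng.normal(size=50), rng.normal(size=50))
        assert abs(out["r"]) < 0.3
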