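"""Modality fusion: rescaling, radial profiles, seam selection, blending."""

import numpy as np
import pytest

from conemap.modality_fusion import (
    BlendSpec,
    RadialProfile,
    blend_maps,
    integrate_foveal_image,
    merge_modalities,
    radial_confidence_profile,
    rescale_to_common_scale,
    select_transition,
)
from conemap.montage_io import ScalarMap, ValidationError


def _conf(values, scale=1.0, origin=(0, 0)):
    return ScalarMap(values, origin, scale, "confidence")


def _dens(values, scale=1.0, origin=(0, 0)):
    return ScalarMap(values, origin, scale, "density")


class TestRescale:
    def test_coarser_map_doubles_in_size(self):
        a = _dens(np.ones((50, 50)), scale=1.0)
        b = _dens(np.full((25, 25), 3.0), scale=2.0)
        ra, rb = rescale_to_common_scale([a, b])
        assert ra.scale_um_per_px == 1.0 and rb.scale_um_per_px == 1.0
        assert rb.values.shape == (50, 50)

    def test_equal_scales_untouched(self):
        a = _dens(np.random.default_rng(0).random((20, 20)))
        b = _dens(np.random.default_rng(1).random((20, 20)))
        ra, rb = rescale_to_common_scale([a, b])
        assert ra is a and rb is b

    def test_constant_map_stays_constant(self):
        a = _dens(np.ones((30, 30)), scale=1.0)
        b = _dens(np.full((15, 15), 7.0), scale=2.0)
        _, rb = rescale_to_common_scale([a, b])
        ok = np.isfinite(rb.values)
        np.testing.assert_allclose(rb.values[ok], 7.0, atol=1e-6)

    def test_mixed_quantities_rejected(self):
        with pytest.raises(ValidationError):
            rescale_to_common_scale(
                [_dens(np.ones((10, 10))), _conf(np.ones((10, 10)), 2.0)]
            )


class TestRadialProfile:
    def test_constant_field(self):
        p = radial_confidence_profile(
            _conf(np.full((200, 200), 0.7)), (100, 100), bin_width_um=25
        )
        ok = p.n_pixels > 0
        np.testing.assert_allclose(p.mean_value[ok], 0.7)

    def test_step_field_steps_at_radius(self):
        h = w = 400
        ys, xs = np.mgrid[0:h, 0:w]
        r = np.hypot(xs - 200, ys - 200) * 2.0  # 2 µm/px
        vals = np.where(r < 500, 1.0, 0.0)
        p = radial_confidence_profile(_conf(vals, scale=2.0), (200, 200), 50)
        inner = p.radii < 450
        outer = (p.radii > 550) & (p.n_pixels > 0)
        np.testing.assert_allclose(p.mean_value[inner], 1.0)
        np.testing.assert_allclose(p.mean_value[outer], 0.0)

    def test_center_outside_rejected(self):
        with pytest.raises(ValidationError):
            radial_confidence_profile(_conf(np.ones((10, 10))), (50, 50))


class TestSelectTransition:
    def _prof(self, values):
        radii = (np.arange(len(values)) + 0.5) * 50.0
        return RadialProfile(radii, np.asarray(values, float),
                             np.ones(len(values), int))

    def test_global_dominance_gives_sole_source(self):
        a = self._prof([0.9] * 40)
        b = self._prof([0.5] * 40)
        spec = select_transition(a, b)
        assert spec.sole_source == 0
        assert spec.band is None

    def test_linear_crossing_band(self):
        radii = (np.arange(40) + 0.5) * 50.0
        a = self._prof(1 - radii / 2000.0)
        b = self._prof(radii / 2000.0)
        spec = select_transition(a, b)
        assert spec.transition_radius == pytest.approx(1000, abs=50)
        assert spec.band[0] == pytest.approx(800, abs=50)
        assert spec.band[1] == pytest.approx(1200, abs=50)
        assert spec.inner_source == 0 and spec.outer_source == 1

    def test_identical_profiles_tie_break_first_bin(self):
        a = self._prof([0.6] * 30)
        spec = select_transition(a, self._prof([0.6] * 30))
        assert spec.transition_radius == pytest.approx(25.0)

    def test_mismatched_grids_rejected(self):
        a = self._prof([0.5] * 10)
        b = RadialProfile(np.arange(1, 11) * 7.0, np.full(10, 0.5),
                          np.ones(10, int))
        with pytest.raises(ValidationError):
            select_transition(a, b)


def _radial_pair(inner_val, outer_val, shape=(300, 300), scale=2.0):
    dens_i = _dens(np.full(shape, float(inner_val)), scale)
    dens_o = _dens(np.full(shape, float(outer_val)), scale)
    conf_i = _conf(np.full(shape, 0.9), scale)
    conf_o = _conf(np.full(shape, 0.6), scale)
    return (dens_i, conf_i), (dens_o, conf_o)


class TestBlendMaps:
    CENTER = (150, 150)
    SPEC = BlendSpec(1000.0, (800.0, 1200.0), 0, 1)

    def test_midpoint_of_ramp(self):
        inner, outer = _radial_pair(100, 200)
        dens, _ = blend_maps(inner, outer, self.SPEC, self.CENTER)
        ys, xs = np.mgrid[0 : dens.values.shape[0], 0 : dens.values.shape[1]]
        r_um = np.hypot(xs - 150, ys - 150) * 2.0
        at_mid = np.abs(r_um - 1000) < 1.5
        np.testing.assert_allclose(dens.values[at_mid], 150.0, atol=2.0)

    def test_blend_of_equal_maps_is_identity(self):
        inner, _ = _radial_pair(123, 0)
        dens, conf = blend_maps(inner, inner, self.SPEC, self.CENTER)
        np.testing.assert_array_equal(dens.values, inner[0].values)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(5)
        shape = (300, 300)
        di = _dens(rng.uniform(50, 150, shape), 2.0)
        do = _dens(rng.uniform(100, 250, shape), 2.0)
        ci = _conf(np.full(shape, 0.8), 2.0)
        co = _conf(np.full(shape, 0.7), 2.0)
        dens, _ = blend_maps((di, ci), (do, co), self.SPEC, self.CENTER)
        lo = np.minimum(di.values, do.values)
        hi = np.maximum(di.values, do.values)
        assert np.all(dens.values >= lo - 1e-9)
        assert np.all(dens.values <= hi + 1e-9)

    def test_nan_in_one_source_falls_back_to_other(self):
        inner, outer = _radial_pair(100, 200)
        vals = inner[0].values.copy()
        vals[140:160, 140:160] = np.nan
        inner = (_dens(vals, 2.0), inner[1])
        dens, _ = blend_maps(inner, outer, self.SPEC, self.CENTER)
        assert np.isfinite(dens.values).all()

    def test_empty_band_without_sole_source_rejected(self):
        # such a spec cannot even be constructed
        with pytest.raises(ValidationError):
            BlendSpec(None, None, None, None, sole_source=None)


class TestMergeSymmetry:
    def test_label_swap_gives_identical_map(self):
        shape = (200, 200)
        ys, xs = np.mgrid[0:200, 0:200]
        r = np.hypot(xs - 100, ys - 100) * 2.0
        conf_a = _conf(np.clip(1 - r / 280.0, 0, 1), 2.0)
        conf_b = _conf(np.clip(r / 280.0, 0, 1), 2.0)
        dens_a = _dens(np.full(shape, 120.0), 2.0)
        dens_b = _dens(np.full(shape, 180.0), 2.0)
        m1, _ = merge_modalities((dens_a, conf_a), (dens_b, conf_b), (100, 100))
        m2, _ = merge_modalities((dens_b, conf_b), (dens_a, conf_a), (100, 100))
        np.testing.assert_allclose(m1[0].values, m2[0].values, atol=1e-9)

    def test_seam_continuity_along_rays(self):
        """No jump across the seam larger than in-band pixel variation."""
        shape = (200, 200)
        ys, xs = np.mgrid[0:200, 0:200]
        r = np.hypot(xs - 100, ys - 100) * 2.0  # max ≈ 283 µm
        conf_a = _conf(np.clip(1 - r / 280.0, 0, 1), 2.0)
        conf_b = _conf(np.clip(r / 280.0, 0, 1), 2.0)
        dens_a = _dens(np.full(shape, 100.0), 2.0)
        dens_b = _dens(np.full(shape, 200.0), 2.0)
        (dens, _), spec = merge_modalities(
            (dens_a, conf_a), (dens_b, conf_b), (100, 100)
        )
        row = dens.values[100, 100:]  # ray along +x
        jumps = np.abs(np.diff(row))
        # ramp over the band: max jump per pixel ≈ 100 / (band width in px)
        band_px = (spec.band[1] - spec.band[0]) / 2.0
        assert jumps.max() <= 100.0 / band_px * 1.5


class TestFovealIntegration:
    def test_no_foveal_dataset_is_identity(self):
        inner, _ = _radial_pair(100, 0)
        out = integrate_foveal_image(inner, None, (150, 150))
        assert out is inner

    def test_equal_foveal_map_changes_nothing(self):
        shape = (200, 200)
        dens = _dens(np.full(shape, 140.0), 2.0)
        conf = _conf(np.full(shape, 0.8), 2.0)
        sub_d = _dens(np.full((80, 80), 140.0), 2.0, origin=(60, 60))
        sub_c = _conf(np.full((80, 80), 0.8), 2.0, origin=(60, 60))
        out_d, _ = integrate_foveal_image((dens, conf), (sub_d, sub_c), (100, 100))
        np.testing.assert_allclose(out_d.values, 140.0)

    def test_footprint_must_cover_center(self):
        shape = (200, 200)
        dens = _dens(np.full(shape, 140.0), 2.0)
        conf = _conf(np.full(shape, 0.8), 2.0)
        sub_d = _dens(np.full((40, 40), 1.0), 2.0, origin=(0, 0))
        sub_c = _conf(np.full((40, 40), 0.9), 2.0, origin=(0, 0))
        with pytest.raises(ValidationError):
            integrate_foveal_image((dens, conf), (sub_d, sub_c), (100, 100))
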