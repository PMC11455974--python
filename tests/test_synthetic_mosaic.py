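"""Synthetic mosaic generator: lattice statistics, rendering, cohorts."""

import json

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.signal import fftconvolve

from conemap.montage_io import ValidationError
from conemap.profiles import DualCauchyProfile
from conemap.synthetic_mosaic import (
    generate_cohort,
    generate_participant,
    load_truth,
    render_modality,
    sample_cone_coordinates,
)

UNIFORM_11547 = DualCauchyProfile(11547.0, 1e-6, 1e3, 1e3, 1e3, 1e3)
HUMAN_LIKE = DualCauchyProfile(40000, 20000, 0.10, 1.05, 0.09, 0.95)


class TestSampling:
    def test_uniform_density_gives_10um_spacing(self):
        coords = sample_cone_coordinates(
            UNIFORM_11547, (-250, 250, -250, 250), jitter_frac=0.0, seed=0
        )
        nn = cKDTree(coords).query(coords, k=2)[0][:, 1]
        assert nn.mean() == pytest.approx(10.0, rel=0.02)

    def test_jitter_preserves_count_and_bounded_spacing(self):
        """Jitter moves points but neither adds nor removes them; the mean
        nearest-neighbour distance drops below the lattice constant (the
        minimum over ~6 jittered neighbours is biased short) but never
        below the hard-core floor of 0.8× the local spacing."""
        c0 = sample_cone_coordinates(
            UNIFORM_11547, (-250, 250, -250, 250), 0.0, seed=1
        )
        c1 = sample_cone_coordinates(
            UNIFORM_11547, (-250, 250, -250, 250), 0.15, seed=1
        )
        assert abs(len(c1) - len(c0)) <= 0.02 * len(c0)  # edge effects only
        nn = cKDTree(c1).query(c1, k=2)[0][:, 1]
        assert 8.0 <= nn.mean() <= 10.0
        assert nn.min() >= 0.8 * 10.0 * 0.97  # hard core (tolerance: edges)

    def test_same_seed_identical(self):
        a = sample_cone_coordinates(HUMAN_LIKE, (-300, 300, -300, 300), 0.1, 7)
        b = sample_cone_coordinates(HUMAN_LIKE, (-300, 300, -300, 300), 0.1, 7)
        np.testing.assert_array_equal(a, b)

    def test_local_count_density_matches_profile(self):
        """Counting density in windows matches the analytic field within 10%."""
        coords = sample_cone_coordinates(
            HUMAN_LIKE, (-400, 400, -400, 400), 0.1, seed=3
        )
        for cx, cy in [(0, 0), (200, 0), (0, -200), (250, 250)]:
            half = 50.0
            n = np.sum(
                (np.abs(coords[:, 0] - cx) < half)
                & (np.abs(coords[:, 1] - cy) < half)
            )
            measured = n / (2 * half / 1000.0) ** 2
            expected_grid = [
                HUMAN_LIKE.density((cx + dx) / 1000, (cy + dy) / 1000)
                for dx in (-35, 0, 35) for dy in (-35, 0, 35)
            ]
            expected = float(np.mean(expected_grid))
            assert measured == pytest.approx(expected, rel=0.10)

    def test_invalid_jitter_rejected(self):
        with pytest.raises(ValidationError):
            sample_cone_coordinates(UNIFORM_11547, (-10, 10, -10, 10), 0.5, 0)


class TestRendering:
    def test_single_cone_centroid(self):
        coords = np.array([[3.3, -2.1]])
        img = render_modality(
            coords, "confocal", (64, 64), (-32, -32), 1.0, 2.0,
            noise_sd=0.0, brightness_jitter=0.0, seed=0,
        )
        ys, xs = np.mgrid[0:64, 0:64]
        cx = (img * xs).sum() / img.sum() - 32
        cy = (img * ys).sum() / img.sum() - 32
        assert cx == pytest.approx(3.3, abs=0.1)
        assert cy == pytest.approx(-2.1, abs=0.1)

    def test_deterministic_rendering(self):
        coords = sample_cone_coordinates(
            UNIFORM_11547, (-50, 50, -50, 50), 0.1, 2
        )
        a = render_modality(coords, "confocal", (100, 100), (-50, -50), 1.0, 2.0, seed=5)
        b = render_modality(coords, "confocal", (100, 100), (-50, -50), 1.0, 2.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_rendering_does_not_translate_positions(self):
        """Cross-correlation of render vs impulse image peaks at lag 0."""
        coords = sample_cone_coordinates(
            UNIFORM_11547, (-100, 100, -100, 100), 0.1, 4
        )
        img = render_modality(
            coords, "confocal", (200, 200), (-100, -100), 1.0, 2.0,
            noise_sd=0.0, seed=1,
        )
        impulse = np.zeros((200, 200))
        px = np.round(coords + 100).astype(int)
        ok = (px[:, 0] >= 0) & (px[:, 0] < 200) & (px[:, 1] >= 0) & (px[:, 1] < 200)
        impulse[px[ok, 1], px[ok, 0]] = 1.0
        xc = fftconvolve(img - img.mean(), impulse[::-1, ::-1], mode="same")
        peak = np.unravel_index(np.argmax(xc), xc.shape)
        assert abs(peak[0] - 100) <= 1 and abs(peak[1] - 100) <= 1

    def test_empty_coords_blank_with_warning(self):
        with pytest.warns(UserWarning):
            img = render_modality(
                np.empty((0, 2)), "confocal", (32, 32), (0, 0), 1.0, 1.0,
                noise_sd=0.0, seed=0,
            )
        assert img.shape == (32, 32)


class TestCohort:
    def test_participant_directory_layout(self, small_participant):
        d = small_participant["dir"]
        assert (d / "layout.csv").exists()
        assert (d / "meta.json").exists()
        truth = json.loads((d / "truth.json").read_text())
        assert set(truth["profile"]) == {
            "a1", "a2", "gamma1_h", "gamma2_h", "gamma1_v", "gamma2_v",
        }
        meta = json.loads((d / "meta.json").read_text())
        assert 22.11 <= meta["axial_length"] <= 27.52
        assert meta["eye"] in ("OD", "OS")

    def test_same_seed_reproduces_pixels(self, tmp_path):
        plan = {"tile_px": 256, "rows": 1, "cols": 1, "overlap_px": 0}
        t1 = generate_participant(tmp_path / "a", "X", 99, "easy", plan)
        t2 = generate_participant(tmp_path / "b", "X", 99, "easy", plan)
        assert t1 == t2
        import tifffile

        a = tifffile.imread(tmp_path / "a/X/r0c0_confocal.tif")
        b = tifffile.imread(tmp_path / "b/X/r0c0_confocal.tif")
        np.testing.assert_array_equal(a, b)

    def test_cohort_peak_density_follows_sampling_distribution(self, tmp_path):
        """Drawn PCDs are consistent with the target lognormal (KS test)."""
        from scipy import stats

        from conemap.synthetic_mosaic import PRESETS, _draw_profile

        rng = np.random.default_rng(0)
        p = PRESETS["easy"]
        pcds = np.array(
            [_draw_profile(rng, p).peak_density for _ in range(200)]
        )
        var = np.log1p((p.peak_density_sd / p.peak_density_mean) ** 2)
        mu = np.log(p.peak_density_mean) - var / 2
        ks = stats.kstest(np.log(pcds), "norm", args=(mu, np.sqrt(var)))
        assert ks.pvalue > 0.01

    def test_generate_cohort_ids_and_truth_loadable(self, tmp_path):
        plan = {"tile_px": 256, "rows": 1, "cols": 1, "overlap_px": 0}
        ids = generate_cohort(2, tmp_path, seed=5, tile_plan=plan)
        assert ids == ["S001", "S002"]
        truth = load_truth(tmp_path, "S001")
        assert truth["profile_obj"].peak_density > 0
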