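"""Shared fixtures: synthetic lattices, montages, and pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conemap.profiles import DualCauchyProfile
from conemap.synthetic_mosaic import (
    generate_participant,
    render_modality,
    sample_cone_coordinates,
)



def uniform_lattice_roi(
    icd_px: float,
    side: int = 256,
    jitter: float = 0.0,
    seed: int = 0,
    modality: str = "confocal",
    noise_sd: float = 0.02,
):
    """Render a uniform-density jittered triangular lattice ROI.

    Returns ``(image, mean_nn_px, coords)`` where ``mean_nn_px`` is the
    mean nearest-neighbour distance of the generated coordinates — the
    oracle for spacing-recovery tests.
    """
    density = 2e6 / (np.sqrt(3) * icd_px**2)
    profile = DualCauchyProfile(
        density, 1e-9 * density, 1e3, 1e3, 1e3, 1e3
    )
    half = side / 2
    coords = sample_cone_coordinates(
        profile, (-half, half, -half, half), jitter, seed
    )
    img = render_modality(
        coords,
        modality,
        (side, side),
        (-half, -half),
        px_um=1.0,
        psf_sigma_um=1.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    nn = cKDTree(coords).query(coords, k=2)[0][:, 1].mean()
    return img, nn, coords


@pytest.fixture(scope="session")
def small_participant(tmp_path_factory):
    """One generated participant directory (default plan) plus its truth."""
    root = tmp_path_factory.mktemp("participant")
    truth = generate_participant(root, "P1", seed=11, preset="easy")
    return {"dir": root / "P1", "root": root, "truth": truth}


@pytest.fixture(scope="session")
def single_eye_result(small_participant):
    """Full per-eye pipeline run on the small participant (run once)."""
    from conemap.pipeline import RunConfig, run_single_eye

    config = RunConfig(input_dir=str(small_participant["dir"]))
    return run_single_eye(config)
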