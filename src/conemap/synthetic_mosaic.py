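"""Synthetic AOSLO-like cone mosaics with known ground truth.

Generates jittered triangular cone lattices whose local density follows a
bivariate dual-Cauchy profile, renders them as confocal-like (bright-spot)
and split-detection-like (relief) rasters, and writes whole multi-tile,
multi-modality cohorts to disk in the layout the pipeline consumes — so
every stage of the analysis is testable against an analytic oracle without
any external data.

Lattice synthesis uses a radially warped hexagonal tiling: a uniform
triangular lattice at the peak density is mapped radially so that the
enclosed-count function matches the target profile exactly (an
equal-measure warp), then an area-preserving anisotropic stretch imposes
the horizontal/vertical width ratio, and finally per-point Gaussian jitter
is added. The jitter fraction sets the rms of the 2-D displacement as a
fraction of the local spacing, and displacements are subject to a
hard-core constraint — cone inner segments are contact-packed, with
diameters of roughly 0.8× the local centre-to-centre spacing across the
retina, so two centres cannot approach closer than that. Because the
lattice is generated from the profile rather than thinned from a point
process, any downstream density error is attributable to the estimator,
not the generator.

Presets
-------
``easy``
    Resolvable mosaic: moderate peak densities (foveal spacing ≈ 4–5 px),
    the default for validation runs.
``hard``
    Peak densities matching the adult human cohort distribution
    (≈ 150 000 ± 53 000 cones/mm²) at a pixel scale where foveal spacing is
    ≈ 2.5 px — at the resolution limit, reproducing unresolvable foveae.
``rods``
    The easy mosaic with smaller, dimmer rod-like spots sprinkled between
    cones beyond the rod-free zone — an adversarial fixture for the
    single-peak spectral model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .density_mapping import SQRT3
from .montage_io import ScalarMap, ValidationError
from .profiles import DualCauchyProfile

__all__ = [
    "MosaicGroundTruth",
    "sample_cone_coordinates",
    "ground_truth_density_map",
    "render_modality",
    "generate_cohort",
    "PRESETS",
]


@dataclass
class MosaicGroundTruth:
    """Analytic ground truth for one generated eye."""

    cone_coords: np.ndarray  # (N, 2) µm, fovea at (0, 0)
    profile: DualCauchyProfile
    seed: int

    def density_at(self, x_um, y_um):
        """Analytic density (cones/mm²) at retinal position in µm."""
        return self.profile.density(
            np.asarray(x_um) / 1000.0, np.asarray(y_um) / 1000.0
        )


# ---------------------------------------------------------------------------
# Lattice sampling


def _enclosed_count_integral(profile: DualCauchyProfile, r_mm: np.ndarray):
    """∫₀ʳ D₀(t)·t dt for the isotropised profile (geometric-mean widths)."""
    g1 = np.sqrt(profile.gamma1_h * profile.gamma1_v)
    g2 = np.sqrt(profile.gamma2_h * profile.gamma2_v)
    return 0.5 * (
        profile.a1 * g1**2 * np.log1p(r_mm**2 / g1**2)
        + profile.a2 * g2**2 * np.log1p(r_mm**2 / g2**2)
    )


def _isotropic_density(profile: DualCauchyProfile, r_mm):
    g1 = np.sqrt(profile.gamma1_h * profile.gamma1_v)
    g2 = np.sqrt(profile.gamma2_h * profile.gamma2_v)
    r = np.asarray(r_mm, dtype=np.float64)
    return profile.a1 / (1 + r**2 / g1**2) + profile.a2 / (1 + r**2 / g2**2)


#: Minimum centre-to-centre separation as a fraction of the local spacing:
#: inner segments are contact-packed with diameters ≈ 0.8× the spacing.
HARD_CORE_FRACTION = 0.8


def _enforce_hard_core(
    pts_mm: np.ndarray, local_spacing_mm: np.ndarray, n_iter: int = 6
) -> np.ndarray:
    """Push apart point pairs closer than the hard-core separation.

    Offending pairs are displaced symmetrically along their joining axis
    until they sit at the minimum separation; a few sweeps suffice since
    jitter is small relative to the spacing. Deterministic.
    """
    pts = pts_mm.copy()
    for _ in range(n_iter):
        r_max = float(local_spacing_mm.max()) * HARD_CORE_FRACTION
        pairs = cKDTree(pts).query_pairs(r=r_max, output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs.T
        d_min = HARD_CORE_FRACTION * 0.5 * (
            local_spacing_mm[i] + local_spacing_mm[j]
        )
        delta = pts[j] - pts[i]
        dist = np.hypot(delta[:, 0], delta[:, 1])
        bad = dist < d_min
        if not bad.any():
            break
        i, j = i[bad], j[bad]
        push = (d_min[bad] - dist[bad]) / 2.0
        unit = delta[bad] / np.maximum(dist[bad], 1e-12)[:, None]
        moves = np.zeros_like(pts)
        np.add.at(moves, j, unit * push[:, None])
        np.add.at(moves, i, -unit * push[:, None])
        pts += moves
    return pts


def sample_cone_coordinates(
    profile: DualCauchyProfile,
    region_um: tuple[float, float, float, float],
    jitter_frac: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Sample cone positions (µm) over a rectangle around the fovea.

    *region_um* is ``(xmin, xmax, ymin, ymax)`` relative to the foveal
    centre at the origin. The point pattern is a locally triangular lattice
    whose local spacing satisfies the triangular-lattice density relation
    against *profile*, with per-point Gaussian jitter whose 2-D rms
    displacement is ``jitter_frac`` × local spacing, subject to the
    hard-core (non-overlap) constraint. Deterministic per seed.
    """
    if not (0.0 <= jitter_frac <= 0.3):
        raise ValidationError("jitter_frac must lie in [0, 0.3]")
    xmin, xmax, ymin, ymax = region_um
    if xmax <= xmin or ymax <= ymin:
        raise ValidationError("region must have positive area")
    if profile.peak_density <= 0:
        raise ValidationError("profile density must be positive")

    # farthest corner of the region, with margin for the anisotropic map
    corners_mm = np.array(
        [[xmin, ymin], [xmin, ymax], [xmax, ymin], [xmax, ymax]]
    ) / 1000.0
    aniso = np.sqrt(
        np.sqrt(
            (profile.gamma1_h * profile.gamma2_h)
            / (profile.gamma1_v * profile.gamma2_v)
        )
    )
    r_max = float(np.hypot(*corners_mm.T).max()) * max(aniso, 1 / aniso) * 1.1

    # uniform triangular base lattice at the peak density
    d_ref = profile.peak_density
    s_ref_mm = np.sqrt(2e6 / (SQRT3 * d_ref)) / 1000.0
    # base radius holding as many points as the warped disc of radius r_max
    m_max = _enclosed_count_integral(profile, np.array([r_max]))[0]
    r_base = np.sqrt(2.0 * m_max / d_ref) * 1.001

    row_pitch = s_ref_mm * SQRT3 / 2.0
    n_rows = int(np.ceil(r_base / row_pitch))
    n_cols = int(np.ceil(r_base / s_ref_mm))
    jj, ii = np.meshgrid(
        np.arange(-n_rows, n_rows + 1), np.arange(-n_cols, n_cols + 1),
        indexing="ij",
    )
    bx = (ii + 0.5 * (jj % 2)) * s_ref_mm
    by = jj * row_pitch
    base = np.column_stack([bx.ravel(), by.ravel()])
    r0 = np.hypot(base[:, 0], base[:, 1])
    base = base[r0 <= r_base]
    r0 = np.hypot(base[:, 0], base[:, 1])

    # equal-measure radial warp: R solves M(R) = d_ref * r0^2 / 2
    grid_r = np.linspace(0.0, r_max, 4096)
    grid_m = _enclosed_count_integral(profile, grid_r)
    target_m = 0.5 * d_ref * r0**2
    warped_r = np.interp(target_m, grid_m, grid_r)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r0 > 0, warped_r / r0, 1.0)
    pts = base * scale[:, None]

    # area-preserving anisotropic stretch setting the h/v width ratio
    pts[:, 0] *= aniso
    pts[:, 1] /= aniso

    # jitter: 2-D rms displacement = jitter_frac × local spacing, i.e.
    # per-axis sigma = jitter_frac / sqrt(2); then enforce the hard core
    rng = np.random.default_rng(seed)
    if jitter_frac > 0:
        local_density = profile.density(pts[:, 0], pts[:, 1])
        local_spacing_mm = np.sqrt(2e6 / (SQRT3 * local_density)) / 1000.0
        pts += rng.normal(size=pts.shape) * (
            jitter_frac / np.sqrt(2.0) * local_spacing_mm[:, None]
        )
        pts = _enforce_hard_core(pts, local_spacing_mm)

    pts_um = pts * 1000.0
    keep = (
        (pts_um[:, 0] >= xmin)
        & (pts_um[:, 0] <= xmax)
        & (pts_um[:, 1] >= ymin)
        & (pts_um[:, 1] <= ymax)
    )
    return pts_um[keep]


def ground_truth_density_map(
    profile: DualCauchyProfile,
    shape: tuple[int, int],
    origin: tuple[float, float],
    fovea_xy_px: tuple[float, float],
    px_um: float,
) -> ScalarMap:
    """Analytic density field sampled on a pixel grid (cones/mm²)."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    x_mm = ((xs + origin[0]) - fovea_xy_px[0]) * px_um / 1000.0
    y_mm = ((ys + origin[1]) - fovea_xy_px[1]) * px_um / 1000.0
    return ScalarMap(profile.density(x_mm, y_mm), origin, px_um, "density")


# ---------------------------------------------------------------------------
# Rendering


def _splat_bilinear(shape, px_x, px_y, weights):
    """Accumulate unit impulses at sub-pixel positions by bilinear splatting."""
    h, w = shape
    img = np.zeros((h + 2, w + 2))
    x = px_x + 1.0
    y = px_y + 1.0
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    ok = (x0 >= 0) & (x0 < w + 1) & (y0 >= 0) & (y0 < h + 1)
    x0, y0, fx, fy, wgt = x0[ok], y0[ok], fx[ok], fy[ok], weights[ok]
    np.add.at(img, (y0, x0), wgt * (1 - fx) * (1 - fy))
    np.add.at(img, (y0, x0 + 1), wgt * fx * (1 - fy))
    np.add.at(img, (y0 + 1, x0), wgt * (1 - fx) * fy)
    np.add.at(img, (y0 + 1, x0 + 1), wgt * fx * fy)
    return img[1 : h + 1, 1 : w + 1]


#: Gaussian-equivalent emitter width as a fraction of the local spacing.
#: The confocal spot is the waveguided *outer*-segment reflectance — an
#: extended emitter roughly 0.4× the spacing in diameter (about half the
#: inner-segment width) — so a cone renders at the larger of its aperture
#: width and the optical PSF, not as a PSF-width point.
APERTURE_SIGMA_FRACTION = 0.18


def render_modality(
    coords_um: np.ndarray,
    modality: str,
    shape: tuple[int, int],
    region_origin_um: tuple[float, float],
    px_um: float,
    psf_sigma_um: float = 1.0,
    noise_sd: float = 0.05,
    brightness_jitter: float = 0.2,
    seed: int = 0,
    local_spacing_um: np.ndarray | float | None = None,
) -> np.ndarray:
    """Render cone coordinates as one modality raster in [0, 1].

    ``confocal`` sums Gaussian bright spots (waveguided outer-segment
    reflectance look); ``split_detection`` renders the horizontal
    illumination gradient of the same cell profiles (inner-segment relief
    look). Each cone is an extended emitter: its spot width is the larger
    of its aperture width (∝ local spacing) and the optical PSF width
    ``psf_sigma_um``. *local_spacing_um* may be a per-cone array or a
    scalar; by default the median nearest-neighbour distance of the
    coordinate set is used. Additive Gaussian noise of ``noise_sd`` is
    applied last; the result is clipped to [0, 1]. Deterministic per seed.
    """
    if px_um <= 0 or psf_sigma_um <= 0:
        raise ValidationError("px_um and psf_sigma_um must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    coords_um = np.asarray(coords_um, dtype=np.float64).reshape(-1, 2)
    if coords_um.shape[0] == 0:
        warnings.warn("rendering empty coordinate list: blank raster")
        img = np.zeros(shape)
    else:
        px_x = (coords_um[:, 0] - region_origin_um[0]) / px_um
        px_y = (coords_um[:, 1] - region_origin_um[1]) / px_um
        bright = 1.0 + brightness_jitter * rng.standard_normal(coords_um.shape[0])
        bright = np.clip(bright, 0.2, None)
        if local_spacing_um is None:
            if coords_um.shape[0] > 3:
                # triangular-lattice spacing from the count density of the
                # set (jitter-invariant, unlike nearest-neighbour medians)
                area = np.prod(coords_um.max(axis=0) - coords_um.min(axis=0))
                count_density = coords_um.shape[0] / max(area, 1e-9)
                local_spacing_um = float(
                    np.sqrt(2.0 / (np.sqrt(3.0) * count_density))
                )
            else:
                local_spacing_um = 4.0 * psf_sigma_um
        spacing = np.broadcast_to(
            np.asarray(local_spacing_um, dtype=np.float64),
            (coords_um.shape[0],),
        )
        sigma_px = np.maximum(
            APERTURE_SIGMA_FRACTION * spacing, psf_sigma_um
        ) / px_um
        # render in a few width buckets (per-cone blur would be costly)
        n_buckets = min(5, max(1, coords_um.shape[0] // 50 + 1))
        edges = np.quantile(sigma_px, np.linspace(0, 1, n_buckets + 1))
        bucket = np.clip(
            np.searchsorted(edges[1:-1], sigma_px, side="right"), 0,
            n_buckets - 1,
        )
        blurred = np.zeros(shape)
        for b in range(n_buckets):
            sel = bucket == b
            if not sel.any():
                continue
            impulses = _splat_bilinear(
                shape, px_x[sel], px_y[sel], bright[sel]
            )
            blurred += gaussian_filter(
                impulses, float(sigma_px[sel].mean()), mode="constant"
            )
        if modality == "confocal":
            img = blurred
        elif modality == "split_detection":
            img = np.gradient(blurred, axis=1)
        else:
            raise ValidationError(f"unknown modality {modality!r}")
    peak = np.percentile(np.abs(img), 99.8) if np.any(img) else 1.0
    peak = peak if peak > 0 else 1.0
    if modality == "split_detection":
        img = 0.5 + 0.45 * img / peak
    else:
        img = 0.9 * img / peak
    if noise_sd > 0:
        img = img + rng.normal(scale=noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class Preset:
    """Generator condition set for one cohort style."""

    px_um: float
    psf_sigma_um: float
    noise_sd: float
    jitter_frac: float
    peak_density_mean: float  # cones/mm², lognormal
    peak_density_sd: float
    gamma1_mean: float  # mm, narrow (foveal) component width
    gamma2_mean: float  # mm, broad component width
    rod_fraction: float = 0.0  # rod intensity relative to cone density


# Width defaults follow the shape of adult human cone topography (density
# near half-peak by ~0.1 mm; ~8× falloff of the shallow component between
# 1 and 3 mm), so the foveal blob is compact relative to any field of view.
PRESETS: dict[str, Preset] = {
    # resolvable mosaic for validation: foveal spacing ~4.4 px
    "easy": Preset(
        px_um=1.0, psf_sigma_um=1.0, noise_sd=0.05, jitter_frac=0.10,
        peak_density_mean=60_000.0, peak_density_sd=15_000.0,
        gamma1_mean=0.10, gamma2_mean=1.05,
    ),
    # human-cohort peak densities at the resolution limit (~2.5 px spacing)
    "hard": Preset(
        px_um=1.1, psf_sigma_um=1.4, noise_sd=0.05, jitter_frac=0.10,
        peak_density_mean=152_906.0, peak_density_sd=53_209.0,
        gamma1_mean=0.10, gamma2_mean=1.05,
    ),
    # easy mosaic plus rod-like spots between cones (dual-peak outliers)
    "rods": Preset(
        px_um=1.0, psf_sigma_um=1.0, noise_sd=0.05, jitter_frac=0.10,
        peak_density_mean=60_000.0, peak_density_sd=15_000.0,
        gamma1_mean=0.10, gamma2_mean=1.05, rod_fraction=0.6,
    ),
}

#: Default tile plan: 2×2 overlapping tiles per modality (montage
#: 1152×1152 px ≈ ±0.58 mm around the fovea at the easy preset's scale —
#: large enough that the top-15% density region is a single central blob
#: well clear of noisy montage-edge estimates).
DEFAULT_TILE_PLAN = {"tile_px": 640, "rows": 2, "cols": 2, "overlap_px": 128}

#: Cohort biometry: axial length distribution of a normal adult cohort (mm).
AXIAL_LENGTH_MEAN = 24.34
AXIAL_LENGTH_SD = 1.35
AXIAL_LENGTH_CLIP = (22.11, 27.52)


def _lognormal(rng, mean, sd, size=None):
    var = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - var / 2.0
    return rng.lognormal(mu, np.sqrt(var), size=size)


def _draw_profile(rng, preset: Preset) -> DualCauchyProfile:
    pcd = float(_lognormal(rng, preset.peak_density_mean, preset.peak_density_sd))
    a1_frac = rng.uniform(0.6, 0.75)
    g1 = preset.gamma1_mean * rng.uniform(0.85, 1.15)
    g2 = preset.gamma2_mean * rng.uniform(0.85, 1.15)
    aniso = rng.uniform(1.02, 1.18)  # horizontal widths exceed vertical
    return DualCauchyProfile(
        a1=pcd * a1_frac,
        a2=pcd * (1.0 - a1_frac),
        gamma1_h=g1 * np.sqrt(aniso),
        gamma1_v=g1 / np.sqrt(aniso),
        gamma2_h=g2 * np.sqrt(aniso),
        gamma2_v=g2 / np.sqrt(aniso),
    )


def _sample_rods(profile, region_um, rod_fraction, seed):
    """Poisson rod-like points beyond the rod-free zone (~250 µm)."""
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = region_um
    area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    peak = profile.peak_density * rod_fraction
    n = rng.poisson(peak * area_mm2)
    pts = rng.uniform([xmin, ymin], [xmax, ymax], size=(n, 2))
    local = profile.density(pts[:, 0] / 1000.0, pts[:, 1] / 1000.0)
    r = np.hypot(pts[:, 0], pts[:, 1])
    accept = (rng.uniform(0, peak, n) < local * rod_fraction) & (r > 250.0)
    return pts[accept]


def generate_participant(
    out_dir: Path,
    participant_id: str,
    seed: int,
    preset: str = "easy",
    tile_plan: dict | None = None,
    axial_length: float | None = None,
    eye: str | None = None,
) -> dict:
    """Generate one participant's tiled two-modality montage on disk.

    Writes ``layout.csv``, per-tile TIFFs, ``meta.json`` and ``truth.json``
    into ``out_dir / participant_id``; returns the truth record.
    """
    p = PRESETS[preset]
    plan = dict(DEFAULT_TILE_PLAN, **(tile_plan or {}))
    ss = np.random.SeedSequence(seed)
    child = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_params, rng_coords, rng_render, rng_rods = child

    if axial_length is None:
        axial_length = float(
            np.clip(
                rng_params.normal(AXIAL_LENGTH_MEAN, AXIAL_LENGTH_SD),
                *AXIAL_LENGTH_CLIP,
            )
        )
    if eye is None:
        eye = "OD" if rng_params.uniform() < 0.5 else "OS"
    profile = _draw_profile(rng_params, p)

    tile, rows, cols, overlap = (
        plan["tile_px"], plan["rows"], plan["cols"], plan["overlap_px"],
    )
    step = tile - overlap
    mont_w = step * (cols - 1) + tile
    mont_h = step * (rows - 1) + tile
    # fovea near the montage centre, jittered so localisation is non-trivial
    fovea_px = (
        mont_w / 2.0 + rng_params.uniform(-30, 30),
        mont_h / 2.0 + rng_params.uniform(-30, 30),
    )
    region_um = (
        -fovea_px[0] * p.px_um,
        (mont_w - fovea_px[0]) * p.px_um,
        -fovea_px[1] * p.px_um,
        (mont_h - fovea_px[1]) * p.px_um,
    )
    coord_seed = int(rng_coords.integers(2**31))
    coords = sample_cone_coordinates(profile, region_um, p.jitter_frac, coord_seed)
    if p.rod_fraction > 0:
        rods = _sample_rods(
            profile, region_um, p.rod_fraction, int(rng_rods.integers(2**31))
        )
    else:
        rods = np.empty((0, 2))

    part_dir = Path(out_dir) / participant_id
    part_dir.mkdir(parents=True, exist_ok=True)
    rows_out = []
    margin = 6 * p.psf_sigma_um
    for r in range(rows):
        for c in range(cols):
            off_x, off_y = c * step, r * step
            tile_origin_um = (
                region_um[0] + off_x * p.px_um,
                region_um[2] + off_y * p.px_um,
            )
            in_tile = (
                (coords[:, 0] >= tile_origin_um[0] - margin)
                & (coords[:, 0] <= tile_origin_um[0] + tile * p.px_um + margin)
                & (coords[:, 1] >= tile_origin_um[1] - margin)
                & (coords[:, 1] <= tile_origin_um[1] + tile * p.px_um + margin)
            )
            tile_coords = coords[in_tile]
            tile_density = profile.density(
                tile_coords[:, 0] / 1000.0, tile_coords[:, 1] / 1000.0
            )
            tile_spacing_um = np.sqrt(2e6 / (SQRT3 * tile_density))
            if rods.size:
                in_t = (
                    (rods[:, 0] >= tile_origin_um[0] - margin)
                    & (rods[:, 0] <= tile_origin_um[0] + tile * p.px_um + margin)
                    & (rods[:, 1] >= tile_origin_um[1] - margin)
                    & (rods[:, 1] <= tile_origin_um[1] + tile * p.px_um + margin)
                )
            for modality in ("confocal", "split_detection"):
                render_seed = int(rng_render.integers(2**31))
                img = render_modality(
                    tile_coords,
                    modality,
                    (tile, tile),
                    tile_origin_um,
                    p.px_um,
                    p.psf_sigma_um,
                    noise_sd=0.0,
                    seed=render_seed,
                    local_spacing_um=tile_spacing_um,
                )
                if rods.size:
                    rod_img = render_modality(
                        rods[in_t],
                        modality,
                        (tile, tile),
                        tile_origin_um,
                        p.px_um,
                        0.6 * p.psf_sigma_um,
                        noise_sd=0.0,
                        seed=render_seed + 1,
                    )
                    img = np.clip(img + 0.35 * (rod_img - rod_img.mean()), 0, 1)
                if p.noise_sd > 0:
                    img = np.clip(
                        img + rng_render.normal(scale=p.noise_sd, size=img.shape),
                        0,
                        1,
                    )
                frame_id = f"r{r}c{c}_{modality}"
                fname = f"{frame_id}.tif"
                tifffile.imwrite(
                    part_dir / fname, (img * 65535).astype(np.uint16)
                )
                rows_out.append(
                    {
                        "frame_id": frame_id,
                        "filename": fname,
                        "x": off_x,
                        "y": off_y,
                        "modality": modality,
                    }
                )
    pd.DataFrame(rows_out, columns=["frame_id", "filename", "x", "y", "modality"]).to_csv(
        part_dir / "layout.csv", index=False
    )
    meta = {
        "participant_id": participant_id,
        "axial_length": axial_length,
        "eye": eye,
        "px_um": p.px_um,
    }
    (part_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    truth = {
        "profile": {
            "a1": profile.a1,
            "a2": profile.a2,
            "gamma1_h": profile.gamma1_h,
            "gamma2_h": profile.gamma2_h,
            "gamma1_v": profile.gamma1_v,
            "gamma2_v": profile.gamma2_v,
        },
        "fovea_px": list(fovea_px),
        "px_um": p.px_um,
        "montage_shape": [mont_h, mont_w],
        "seed": seed,
        "preset": preset,
    }
    (part_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def generate_cohort(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    preset: str = "easy",
    tile_plan: dict | None = None,
) -> list[str]:
    """Generate an *n*-participant synthetic cohort under *out_dir*.

    Each participant gets an independent seed derived from *seed*; returns
    the list of participant ids (subdirectory names).
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    ids = []
    for i, child in enumerate(ss.spawn(n)):
        pid = f"S{i + 1:03d}"
        generate_participant(
            out_dir, pid, int(child.generate_state(1)[0] % 2**31), preset, tile_plan
        )
        ids.append(pid)
    return ids


def load_truth(cohort_dir: str | Path, participant_id: str) -> dict:
    """Read back a participant's ground-truth record."""
    path = Path(cohort_dir) / participant_id / "truth.json"
    record = json.loads(path.read_text())
    record["profile_obj"] = DualCauchyProfile(**record["profile"])
    return record
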