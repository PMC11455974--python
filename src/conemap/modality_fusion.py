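"""Merging confocal and split-detection maps with a radial blended seam.

Each modality resolves the mosaic best at different eccentricities: the
confocal reflectance mosaic is usually cleaner near the fovea, while
split-detection inner-segment relief stays resolvable further out. The
merge therefore compares the modalities' radial confidence profiles around
the foveal centre, picks the "transition radius" where the better modality
changes, and linearly blends density/confidence over the band where the
confidence difference is smaller than 0.2 — so there is never a hard seam.
An optional separately analysed foveal image can be integrated as an inner
dataset of a second blend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .montage_io import ScalarMap, ValidationError

__all__ = [
    "RadialProfile",
    "BlendSpec",
    "rescale_to_common_scale",
    "radial_confidence_profile",
    "select_transition",
    "blend_maps",
    "integrate_foveal_image",
]

#: Confidence-difference threshold defining the blend band (absolute units
#: on the [0, 1] confidence scale).
BLEND_THRESHOLD = 0.2
#: A confidence-difference sign flip must persist this many radial bins to
#: count as the modality transition (guards against noise micro-crossings).
FLIP_PERSISTENCE_BINS = 3

DEFAULT_BIN_WIDTH_UM = 50.0


@dataclass
class RadialProfile:
    """Radial average of a map around a centre, in uniform-width bins."""

    radii: np.ndarray  # µm, bin centres, strictly increasing
    mean_value: np.ndarray  # NaN where a bin holds no pixels
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.mean_value = np.asarray(self.mean_value, dtype=np.float64)
        self.n_pixels = np.asarray(self.n_pixels, dtype=np.int64)
        if np.any(np.diff(self.radii) <= 0):
            raise ValidationError("radii must be strictly increasing")


@dataclass
class BlendSpec:
    """Radial seam between two datasets.

    ``band = (r_inner, r_outer)`` bounds the linear blend; an empty band
    with ``sole_source`` set means one dataset dominates everywhere.
    """

    transition_radius: float | None  # µm
    band: tuple[float, float] | None  # µm
    inner_source: int | None  # dataset index used inside the seam
    outer_source: int | None
    sole_source: int | None = None

    def __post_init__(self) -> None:
        if self.sole_source is None:
            if self.inner_source == self.outer_source:
                raise ValidationError("inner and outer sources must differ")
            r0, r1 = self.band
            if not (r0 <= self.transition_radius <= r1):
                raise ValidationError("transition radius must lie in the band")


def rescale_to_common_scale(maps: list[ScalarMap]) -> list[ScalarMap]:
    """Resample maps to the finest (smallest µm/px) scale among them.

    Bilinear, NaN-aware (normalised convolution); origins are scaled so
    that physical montage coordinates are preserved.
    """
    if len(maps) < 2:
        raise ValidationError("need at least two maps to co-scale")
    quantities = {m.quantity for m in maps}
    if len(quantities) > 1:
        raise ValidationError(f"mixed quantity tags: {quantities}")
    target = min(m.scale_um_per_px for m in maps)
    out = []
    for m in maps:
        factor = m.scale_um_per_px / target
        if abs(factor - 1.0) < 1e-12:
            out.append(m)
            continue
        h, w = m.values.shape
        new_h, new_w = int(round(h * factor)), int(round(w * factor))
        rows = (np.arange(new_h) + 0.5) / factor - 0.5
        cols = (np.arange(new_w) + 0.5) / factor - 0.5
        grid = np.meshgrid(rows, cols, indexing="ij")
        mask = np.isfinite(m.values)
        filled = np.where(mask, m.values, 0.0)
        num = ndimage.map_coordinates(filled, grid, order=1, mode="nearest")
        den = ndimage.map_coordinates(
            mask.astype(float), grid, order=1, mode="nearest"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            values = num / den
        values[den < 0.5] = np.nan
        out.append(
            ScalarMap(
                values,
                (m.origin[0] * factor, m.origin[1] * factor),
                target,
                m.quantity,
            )
        )
    return out


def _radius_map_um(map_: ScalarMap, center_xy: tuple[float, float]):
    xs, ys = map_.pixel_coords()
    return np.hypot(xs - center_xy[0], ys - center_xy[1]) * map_.scale_um_per_px


def radial_confidence_profile(
    conf: ScalarMap,
    center_xy: tuple[float, float],
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
) -> RadialProfile:
    """NaN-aware radial average of a confidence map around a centre.

    *center_xy* is in montage pixels (same frame as the map's origin).
    """
    if bin_width_um <= 0:
        raise ValidationError("bin_width_um must be positive")
    ox, oy = conf.origin
    h, w = conf.values.shape
    if not (ox <= center_xy[0] < ox + w and oy <= center_xy[1] < oy + h):
        raise ValidationError("centre lies outside the map")
    r_um = _radius_map_um(conf, center_xy)
    finite = np.isfinite(conf.values)
    n_bins = int(np.ceil(r_um.max() / bin_width_um))
    idx = np.minimum((r_um / bin_width_um).astype(int), n_bins - 1)
    counts = np.bincount(idx[finite], minlength=n_bins)
    sums = np.bincount(idx[finite], weights=conf.values[finite], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    radii = (np.arange(n_bins) + 0.5) * bin_width_um
    return RadialProfile(radii, means, counts)


def select_transition(
    prof_a: RadialProfile,
    prof_b: RadialProfile,
    threshold: float = BLEND_THRESHOLD,
) -> BlendSpec:
    """Choose the seam radius and blend band from two confidence profiles.

    The transition is the first radius where the sign of (A − B) flips and
    persists for at least three bins; the band is the contiguous run of
    radii around it where |A − B| < *threshold*. With no persistent flip
    the globally better dataset is used everywhere (empty band). When the
    profiles are globally similar (|A − B| < threshold at every radius) the
    transition is placed at the radius of highest similarity.
    """
    if prof_a.radii.shape != prof_b.radii.shape or not np.allclose(
        prof_a.radii, prof_b.radii
    ):
        raise ValidationError("profiles must share the same radii grid")
    radii = prof_a.radii
    diff = prof_a.mean_value - prof_b.mean_value
    valid = np.isfinite(diff)
    if not valid.any():
        raise ValidationError("profiles have no overlapping finite bins")
    dv = diff[valid]
    rv = radii[valid]

    def _band_around(idx: int) -> tuple[float, float]:
        inside = np.abs(dv) < threshold
        lo = idx
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        hi = idx
        while hi < len(dv) - 1 and inside[hi + 1]:
            hi += 1
        return float(rv[lo]), float(rv[hi])

    if np.all(np.abs(dv) < threshold):
        # globally similar: seam at the most similar radius (first on ties)
        idx = int(np.argmin(np.abs(dv)))
        band = _band_around(idx)
        inner = 0 if np.nanmean(dv[: idx + 1]) >= 0 else 1
        return BlendSpec(float(rv[idx]), band, inner, 1 - inner)

    signs = np.sign(dv)
    signs[signs == 0] = 1
    flip_idx = None
    for k in range(1, len(dv)):
        if signs[k] != signs[k - 1]:
            run = signs[k : k + FLIP_PERSISTENCE_BINS]
            if len(run) >= FLIP_PERSISTENCE_BINS and np.all(run == signs[k]):
                flip_idx = k
                break
    if flip_idx is None:
        dominant = 0 if np.nanmean(dv) > 0 else 1
        return BlendSpec(None, None, None, None, sole_source=dominant)

    inner = 0 if signs[flip_idx - 1] > 0 else 1
    band = _band_around(flip_idx)
    transition = float(rv[flip_idx])
    r0 = min(band[0], transition)
    r1 = max(band[1], transition)
    return BlendSpec(transition, (r0, r1), inner, 1 - inner)


def blend_maps(
    inner: tuple[ScalarMap, ScalarMap],
    outer: tuple[ScalarMap, ScalarMap],
    spec: BlendSpec,
    center_xy: tuple[float, float],
) -> tuple[ScalarMap, ScalarMap]:
    """Linearly blend two co-registered (density, confidence) map pairs.

    Inside ``r_inner`` the inner dataset is used, beyond ``r_outer`` the
    outer one, and across the band a linear radial ramp mixes them. Where
    one source is NaN the other is used directly, so coverage is the union
    of both datasets.
    """
    if spec.sole_source is None and spec.band is None:
        raise ValidationError("blend spec has neither a band nor a sole source")
    dens_i, conf_i = inner
    dens_o, conf_o = outer
    for a, b in ((dens_i, dens_o), (conf_i, conf_o)):
        if a.values.shape != b.values.shape or a.origin != b.origin:
            raise ValidationError("maps must be co-registered at common scale")

    if spec.sole_source is not None:
        # dominance: the designated dataset everywhere, other fills gaps
        src = inner if spec.sole_source == 0 else outer
        alt = outer if spec.sole_source == 0 else inner
        out = []
        for s, a, q in zip(src, alt, ("density", "confidence")):
            vals = np.where(np.isfinite(s.values), s.values, a.values)
            out.append(ScalarMap(vals, s.origin, s.scale_um_per_px, q))
        return out[0], out[1]

    r_um = _radius_map_um(dens_i, center_xy)
    r0, r1 = spec.band
    if r1 > r0:
        w = np.clip((r_um - r0) / (r1 - r0), 0.0, 1.0)
    else:
        w = (r_um >= r0).astype(float)
    out = []
    for vi_map, vo_map, q in (
        (dens_i, dens_o, "density"),
        (conf_i, conf_o, "confidence"),
    ):
        vi, vo = vi_map.values, vo_map.values
        blended = (1.0 - w) * vi + w * vo
        only_i = np.isfinite(vi) & ~np.isfinite(vo)
        only_o = ~np.isfinite(vi) & np.isfinite(vo)
        blended = np.where(only_i, vi, blended)
        blended = np.where(only_o, vo, blended)
        out.append(
            ScalarMap(blended, vi_map.origin, vi_map.scale_um_per_px, q)
        )
    return out[0], out[1]


def merge_modalities(
    maps_a: tuple[ScalarMap, ScalarMap],
    maps_b: tuple[ScalarMap, ScalarMap],
    center_xy: tuple[float, float],
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    threshold: float = BLEND_THRESHOLD,
) -> tuple[tuple[ScalarMap, ScalarMap], BlendSpec]:
    """Full modality merge: profiles → transition → blend.

    *maps_a* and *maps_b* are co-registered (density, confidence) pairs;
    returns the merged pair and the chosen :class:`BlendSpec`.
    """
    prof_a = radial_confidence_profile(maps_a[1], center_xy, bin_width_um)
    prof_b = radial_confidence_profile(maps_b[1], center_xy, bin_width_um)
    spec = select_transition(prof_a, prof_b, threshold)
    if spec.sole_source is not None:
        merged = blend_maps(maps_a, maps_b, spec, center_xy)
    else:
        inner = maps_a if spec.inner_source == 0 else maps_b
        outer = maps_b if spec.inner_source == 0 else maps_a
        merged = blend_maps(inner, outer, spec, center_xy)
    return merged, spec


def integrate_foveal_image(
    merged: tuple[ScalarMap, ScalarMap],
    foveal: tuple[ScalarMap, ScalarMap] | None,
    center_xy: tuple[float, float],
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
) -> tuple[ScalarMap, ScalarMap]:
    """Blend a separately analysed foveal-image dataset into a merged map.

    The foveal maps act as the inner dataset of a second radial blend,
    restricted to the foveal image's footprint; identity when *foveal* is
    None. The foveal footprint must cover the centre.
    """
    if foveal is None:
        return merged
    dens_f, conf_f = foveal
    ox, oy = dens_f.origin
    h, w = dens_f.values.shape
    if not (ox <= center_xy[0] < ox + w and oy <= center_xy[1] < oy + h):
        raise ValidationError("foveal maps do not cover the foveal centre")

    # embed the foveal maps into the merged frame (NaN outside footprint)
    dens_m, conf_m = merged
    full_dens = np.full_like(dens_m.values, np.nan)
    full_conf = np.full_like(conf_m.values, np.nan)
    c0 = int(round(ox - dens_m.origin[0]))
    r0 = int(round(oy - dens_m.origin[1]))
    H, W = dens_m.values.shape
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + h, H), min(c0 + w, W)
    full_dens[rr0:rr1, cc0:cc1] = dens_f.values[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    full_conf[rr0:rr1, cc0:cc1] = conf_f.values[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    foveal_full = (
        ScalarMap(full_dens, dens_m.origin, dens_m.scale_um_per_px, "density"),
        ScalarMap(full_conf, conf_m.origin, conf_m.scale_um_per_px, "confidence"),
    )
    merged_out, _ = merge_modalities(foveal_full, merged, center_xy, bin_width_um)
    return merged_out
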