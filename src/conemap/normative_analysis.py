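"""Per-participant summaries and cohort-level aggregation of density maps.

Covers the steps that follow the per-eye density pipeline: outlier/low-
confidence filtering, nasal/temporal orientation and foveal co-alignment,
down-sampling, overlap/mean/SD cohort maps, 1°-wide meridian strip
profiles, amplitude-linked dual-Cauchy meridian fits (giving peak and
minimum cone density), cumulative total-cone curves from annulus
integration, and Pearson summaries across participants.

Conventions: after :func:`orient_and_align` all eyes are in right-eye (OD)
orientation with the foveal centre at montage coordinate (0, 0); the
nasal meridian points along +x, temporal along −x, superior along −y and
inferior along +y.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .montage_io import BASE_UM_PER_DEG, ScalarMap, ValidationError
from .profiles import DualCauchyProfile

__all__ = [
    "MeridianProfile",
    "DualCauchyFit",
    "ConeCountCurve",
    "CohortStack",
    "FitNonConvergence",
    "filter_participant_map",
    "orient_and_align",
    "downsample_map",
    "build_cohort_stack",
    "apply_overlap_threshold",
    "meridian_strip_profile",
    "exclude_nonmonotonic_fovea",
    "fit_dual_cauchy",
    "total_cones_vs_eccentricity",
    "extract_summary",
    "pearson_with_ci",
]

logger = logging.getLogger(__name__)

MERIDIANS = ("temporal", "nasal", "superior", "inferior")
#: Unit direction (dx, dy) of each meridian in the aligned OD frame.
_MERIDIAN_DIR = {
    "nasal": (1, 0),
    "temporal": (-1, 0),
    "superior": (0, -1),
    "inferior": (0, 1),
}

CONFIDENCE_FILTER_PERCENTILE = 5.0
FOVEAL_DISC_RADIUS_UM = 400.0
DOWNSAMPLE_FACTOR = 4
MIN_OVERLAP_PARTICIPANTS = 10
ANNULUS_WIDTH_UM = 7.0  # ≈ 5 px at the common analysis scale
MONOTONE_ANCHOR_MM = 0.5
MONOTONE_TOLERANCE = 0.02


class FitNonConvergence(RuntimeError):
    """Raised when the meridian fit fails; carries the best-so-far fit."""

    def __init__(self, message: str, best_fit: "DualCauchyFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class MeridianProfile:
    """Density (and optionally confidence / SD) vs eccentricity along one
    meridian; eccentricities in mm, densities in cones/mm²."""

    meridian: str
    ecc: np.ndarray
    density: np.ndarray
    confidence: np.ndarray | None = None
    sd: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.meridian not in MERIDIANS + ("horizontal", "vertical"):
            raise ValidationError(f"unknown meridian {self.meridian!r}")
        self.ecc = np.asarray(self.ecc, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if np.any(np.diff(self.ecc) <= 0) or (
            self.ecc.size and self.ecc[0] < 0
        ):
            raise ValidationError("ecc must be non-negative and increasing")


@dataclass
class DualCauchyFit:
    """Result of the simultaneous two-meridian dual-Cauchy fit."""

    profile: DualCauchyProfile
    pcd: float  # cones/mm², model value at eccentricity 0
    min_density: float  # cones/mm², model minimum over the fitted range
    fit_rms: float  # cones/mm²
    converged: bool = True


@dataclass
class ConeCountCurve:
    """Cumulative cone count vs eccentricity (annulus integration)."""

    ecc: np.ndarray  # mm, outer radius of each annulus
    cumulative_cones: np.ndarray
    annulus_width_um: float = ANNULUS_WIDTH_UM

    def at(self, ecc_mm: float) -> float:
        """Cumulative count at an eccentricity (NaN beyond the curve)."""
        if ecc_mm > self.ecc[-1] + 1e-9:
            return float("nan")
        return float(np.interp(ecc_mm, self.ecc, self.cumulative_cones))


@dataclass
class CohortStack:
    """Co-registered cohort maps: overlap count, mean, SD, confidence."""

    mean_density: ScalarMap
    sd_density: ScalarMap
    mean_confidence: ScalarMap
    overlap: ScalarMap
    n_participants: int


# ---------------------------------------------------------------------------
# Per-participant filtering and alignment


def filter_participant_map(
    dens: ScalarMap, conf: ScalarMap, center_xy: tuple[float, float]
) -> tuple[ScalarMap, ScalarMap]:
    """Remove low-confidence regions and peripheral density outliers.

    Pixels whose confidence is strictly below the map's 5th percentile are
    dropped, as are pixels beyond 400 µm whose density exceeds the median
    density inside the central 400-µm disc (nothing can genuinely be
    denser than the fovea).
    """
    if center_xy is None:
        raise ValidationError("foveal centre required for filtering")
    if dens.values.shape != conf.values.shape or dens.origin != conf.origin:
        raise ValidationError("density and confidence maps must be co-registered")
    d = dens.values.copy()
    c = conf.values.copy()
    finite_c = np.isfinite(c)
    n_before = int(np.isfinite(d).sum())
    if finite_c.any():
        p5 = np.percentile(c[finite_c], CONFIDENCE_FILTER_PERCENTILE)
        low = finite_c & (c < p5)
        d[low] = np.nan
        c[low] = np.nan

    xs, ys = dens.pixel_coords()
    r_um = np.hypot(xs - center_xy[0], ys - center_xy[1]) * dens.scale_um_per_px
    central = (r_um <= FOVEAL_DISC_RADIUS_UM) & np.isfinite(d)
    if central.any():
        foveal_median = np.median(d[central])
        spurious = (r_um > FOVEAL_DISC_RADIUS_UM) & np.isfinite(d) & (
            d > foveal_median
        )
        d[spurious] = np.nan
        c[spurious] = np.nan
    logger.info(
        "participant filter removed %d of %d pixels",
        n_before - int(np.isfinite(d).sum()),
        n_before,
    )
    return (
        ScalarMap(d, dens.origin, dens.scale_um_per_px, "density"),
        ScalarMap(c, conf.origin, conf.scale_um_per_px, "confidence"),
    )


def orient_and_align(
    maps: list[tuple[ScalarMap, ScalarMap]],
    eyes: list[str],
    centers: list[tuple[float, float] | None],
) -> list[tuple[ScalarMap, ScalarMap]]:
    """Mirror left eyes to OD orientation and co-align on foveal centres.

    Returns maps on a common canvas sharing shape and origin, with every
    foveal centre at montage coordinate (0, 0). Participants without a
    centre are skipped with a warning.
    """
    prepared = []
    for (dens, conf), eye, center in zip(maps, eyes, centers):
        if center is None:
            warnings.warn("participant without foveal centre skipped")
            continue
        d, c = dens.values, conf.values
        cx = center[0] - dens.origin[0]
        cy = center[1] - dens.origin[1]
        if eye == "OS":  # mirror horizontally into OD orientation
            d = d[:, ::-1]
            c = c[:, ::-1]
            cx = d.shape[1] - 1 - cx
        prepared.append((d, c, cx, cy, dens.scale_um_per_px))
    if not prepared:
        raise ValidationError("no participant has a usable foveal centre")

    left = int(np.ceil(max(p[2] for p in prepared)))
    right = int(np.ceil(max(p[0].shape[1] - p[2] for p in prepared)))
    top = int(np.ceil(max(p[3] for p in prepared)))
    bottom = int(np.ceil(max(p[0].shape[0] - p[3] for p in prepared)))
    H, W = top + bottom, left + right
    out = []
    for d, c, cx, cy, scale in prepared:
        canvas_d = np.full((H, W), np.nan)
        canvas_c = np.full((H, W), np.nan)
        c0 = left - int(round(cx))
        r0 = top - int(round(cy))
        canvas_d[r0 : r0 + d.shape[0], c0 : c0 + d.shape[1]] = d
        canvas_c[r0 : r0 + c.shape[0], c0 : c0 + c.shape[1]] = c
        origin = (-float(left), -float(top))
        out.append(
            (
                ScalarMap(canvas_d, origin, scale, "density"),
                ScalarMap(canvas_c, origin, scale, "confidence"),
            )
        )
    return out


def downsample_map(map_: ScalarMap, factor: int = DOWNSAMPLE_FACTOR) -> ScalarMap:
    """NaN-aware block-mean down-sampling by an integer factor.

    The pixel pitch is multiplied by *factor* and the origin is divided by
    it, so physical montage coordinates are preserved.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError("factor must be a positive integer")
    if factor == 1:
        return map_.copy()
    v = map_.values
    h, w = v.shape
    H = int(np.ceil(h / factor)) * factor
    W = int(np.ceil(w / factor)) * factor
    padded = np.full((H, W), np.nan)
    padded[:h, :w] = v
    blocks = padded.reshape(H // factor, factor, W // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(blocks, axis=(1, 3))
    return ScalarMap(
        means,
        (map_.origin[0] / factor, map_.origin[1] / factor),
        map_.scale_um_per_px * factor,
        map_.quantity,
    )


# ---------------------------------------------------------------------------
# Cohort stacking


def build_cohort_stack(
    aligned: list[tuple[ScalarMap, ScalarMap]]
) -> CohortStack:
    """Overlap / mean / SD / confidence maps from co-aligned participants.

    SD is the sample standard deviation and is NaN wherever fewer than two
    participants contribute.
    """
    if not aligned:
        raise ValidationError("need at least one participant")
    ref = aligned[0][0]
    dens_stack = np.stack([d.values for d, _ in aligned])
    conf_stack = np.stack([c.values for _, c in aligned])
    finite = np.isfinite(dens_stack)
    overlap = finite.sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_d = np.nanmean(dens_stack, axis=0)
        sd_d = np.nanstd(dens_stack, axis=0, ddof=1)
        mean_c = np.nanmean(conf_stack, axis=0)
    mean_d[overlap == 0] = np.nan
    sd_d[overlap < 2] = np.nan
    mk = lambda v, q: ScalarMap(v, ref.origin, ref.scale_um_per_px, q)
    return CohortStack(
        mean_density=mk(mean_d, "density"),
        sd_density=mk(sd_d, "density"),
        mean_confidence=mk(np.clip(mean_c, 0, 1), "confidence"),
        overlap=mk(overlap, "overlap"),
        n_participants=len(aligned),
    )


def apply_overlap_threshold(
    stack: CohortStack, min_n: int = MIN_OVERLAP_PARTICIPANTS
) -> CohortStack:
    """NaN out regions observed in fewer than *min_n* participants.

    The overlap map itself is left unmodified so coverage stays auditable.
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    keep = stack.overlap.values >= min_n
    out = {}
    for name in ("mean_density", "sd_density", "mean_confidence"):
        m = getattr(stack, name)
        v = np.where(keep, m.values, np.nan)
        out[name] = ScalarMap(v, m.origin, m.scale_um_per_px, m.quantity)
    return CohortStack(
        overlap=stack.overlap.copy(),
        n_participants=stack.n_participants,
        **out,
    )


# ---------------------------------------------------------------------------
# Meridian profiles


def meridian_strip_profile(
    map_: ScalarMap,
    center_xy: tuple[float, float],
    meridian: str,
    strip_width_deg: float = 1.0,
    um_per_deg: float = BASE_UM_PER_DEG,
    conf_map: ScalarMap | None = None,
    sd_map: ScalarMap | None = None,
) -> MeridianProfile:
    """Average a 1°-wide strip along one cardinal meridian.

    The strip runs from the foveal centre along the meridian ray; values
    are averaged across the strip's short axis per 1-px eccentricity bin
    (NaN-aware). Eccentricities are returned in mm.
    """
    if meridian not in _MERIDIAN_DIR:
        raise ValidationError(f"unknown meridian {meridian!r}")
    if strip_width_deg <= 0:
        raise ValidationError("strip width must be positive")
    dx, dy = _MERIDIAN_DIR[meridian]
    scale = map_.scale_um_per_px
    half_px = strip_width_deg * um_per_deg / scale / 2.0
    xs, ys = map_.pixel_coords()
    along = (xs - center_xy[0]) * dx + (ys - center_xy[1]) * dy
    across = np.abs((xs - center_xy[0]) * dy - (ys - center_xy[1]) * dx)
    in_strip = (along >= 0) & (across <= half_px)

    def _bin(values: np.ndarray):
        sel = in_strip & np.isfinite(values)
        if not sel.any():
            return None
        idx = along[sel].astype(int)
        n_bins = idx.max() + 1
        counts = np.bincount(idx, minlength=n_bins)
        sums = np.bincount(idx, weights=values[sel], minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return means, counts

    binned = _bin(map_.values)
    if binned is None:
        warnings.warn(f"{meridian} meridian contains no finite data")
        return MeridianProfile(meridian, np.array([]), np.array([]))
    means, counts = binned
    ecc_mm = (np.arange(means.size) + 0.5) * scale / 1000.0
    conf = None
    if conf_map is not None:
        b = _bin(conf_map.values)
        if b is not None:
            conf = np.full(means.size, np.nan)
            conf[: b[0].size] = b[0][: means.size]
    sd = None
    if sd_map is not None:
        b = _bin(sd_map.values)
        if b is not None:
            sd = np.full(means.size, np.nan)
            sd[: b[0].size] = b[0][: means.size]
    return MeridianProfile(meridian, ecc_mm, means, conf, sd, counts)


def exclude_nonmonotonic_fovea(
    profile: MeridianProfile,
    anchor_mm: float = MONOTONE_ANCHOR_MM,
    tolerance: float = MONOTONE_TOLERANCE,
) -> MeridianProfile:
    """Drop central bins where density fails to rise toward the fovea.

    Cone spacing near the foveal centre can fall below the imaging
    resolution, producing spuriously *low* density estimates there.
    Scanning inward from *anchor_mm* toward eccentricity 0, any bin whose
    density is below the running maximum by more than *tolerance* (2 % per
    step by default) is excluded (set NaN); bins outside the anchor are
    untouched.
    """
    d = profile.density.copy()
    inside = np.nonzero(profile.ecc <= anchor_mm)[0]
    running = -np.inf
    for i in inside[::-1]:  # from the anchor inward to ecc 0
        if not np.isfinite(d[i]):
            continue
        if d[i] < running * (1.0 - tolerance):
            d[i] = np.nan
        else:
            running = max(running, d[i])
    return MeridianProfile(
        profile.meridian, profile.ecc, d, profile.confidence, profile.sd,
        profile.n,
    )


# ---------------------------------------------------------------------------
# Dual-Cauchy meridian fit


def _fit_residuals(params, ecc_h, dens_h, w_h, ecc_v, dens_v, w_v):
    a1, a2, g1h, g2h, g1v, g2v = params
    prof = DualCauchyProfile(a1, a2, g1h, g2h, g1v, g2v)
    res_h = (prof.meridian_density(ecc_h, "horizontal") - dens_h) * w_h
    res_v = (prof.meridian_density(ecc_v, "vertical") - dens_v) * w_v
    return np.concatenate([res_h, res_v])


def fit_dual_cauchy(
    horiz: MeridianProfile,
    vert: MeridianProfile,
    use_confidence_weights: bool = True,
) -> DualCauchyFit:
    """Simultaneous amplitude-linked dual-Cauchy fit of two meridians.

    The two Cauchy amplitudes are shared between the meridians (both reach
    the same central peak, PCD = A1 + A2) while the four widths are free,
    capturing the faster vertical falloff. Weighted least squares with
    multi-start; weights are the per-bin confidences when available.
    PCD is the model value at eccentricity 0 and the minimum density is
    the model minimum over the fitted eccentricity range.
    """

    def _prep(p: MeridianProfile):
        ok = np.isfinite(p.density)
        if not ok.any():
            raise ValidationError(f"{p.meridian or 'profile'} has no finite bins")
        ecc, dens = p.ecc[ok], p.density[ok]
        if use_confidence_weights and p.confidence is not None:
            w = np.sqrt(np.clip(np.nan_to_num(p.confidence[ok], nan=0.0), 0.05, 1.0))
        else:
            w = np.ones_like(dens)
        return ecc, dens, w

    ecc_h, dens_h, w_h = _prep(horiz)
    ecc_v, dens_v, w_v = _prep(vert)
    pcd0 = max(float(np.nanmax(dens_h)), float(np.nanmax(dens_v)), 1.0)
    ecc_max = max(ecc_h.max(), ecc_v.max())
    lower = [0.0, 0.0] + [1e-3] * 4
    upper = [10 * pcd0] * 2 + [50.0] * 4
    best = None
    for a1_frac in (0.5, 0.7):
        for g1 in (0.1, 0.3):
            for g2 in (0.8, 2.5):
                p0 = np.clip(
                    [pcd0 * a1_frac, pcd0 * (1 - a1_frac), g1, g1, g2, g2][
                        :2
                    ]
                    + [g1, g2, g1, g2],
                    lower,
                    upper,
                )
                try:
                    res = least_squares(
                        _fit_residuals,
                        p0,
                        args=(ecc_h, dens_h, w_h, ecc_v, dens_v, w_v),
                        bounds=(lower, upper),
                        x_scale=[pcd0, pcd0, 1, 1, 1, 1],
                    )
                except Exception:
                    continue
                if best is None or res.cost < best.cost:
                    best = res

    if best is None:
        raise FitNonConvergence("dual-Cauchy fit failed from every start", None)

    a1, a2, g1h, g2h, g1v, g2v = best.x
    # order components so component 1 is the narrower (foveal) one
    if (g1h + g1v) > (g2h + g2v):
        a1, a2 = a2, a1
        g1h, g2h = g2h, g1h
        g1v, g2v = g2v, g1v
    prof = DualCauchyProfile(a1, a2, g1h, g2h, g1v, g2v)
    grid = np.linspace(0, ecc_max, 512)
    model_min = min(
        float(prof.meridian_density(grid, "horizontal").min()),
        float(prof.meridian_density(grid, "vertical").min()),
    )
    n_pts = len(dens_h) + len(dens_v)
    rms = float(np.sqrt(2 * best.cost / n_pts))
    fit = DualCauchyFit(
        profile=prof,
        pcd=prof.peak_density,
        min_density=model_min,
        fit_rms=rms,
        converged=bool(best.success),
    )
    if not best.success:
        raise FitNonConvergence("dual-Cauchy fit did not converge", fit)
    return fit


# ---------------------------------------------------------------------------
# Total cone counts


def total_cones_vs_eccentricity(
    dens: ScalarMap,
    center_xy: tuple[float, float],
    fit: DualCauchyFit | None = None,
    annulus_width_um: float = ANNULUS_WIDTH_UM,
    max_ecc_mm: float | None = None,
) -> ConeCountCurve:
    """Cumulative cone count vs eccentricity by annulus integration.

    Each annulus (default width ≈7 µm) is split into horizontal wedges
    (polar angle within ±45° of the horizontal axis, both sides) and
    vertical wedges (the rest); the wedge mean densities are multiplied by
    the wedge areas (mm², from the pixel scale) and summed, then
    accumulated over annuli. Where the map is NaN (e.g. the excluded
    unresolved fovea) the dual-Cauchy model value substitutes when *fit*
    is given. Annuli are limited to radii fully inside the map.
    """
    ox, oy = dens.origin
    h, w = dens.values.shape
    if not (ox <= center_xy[0] < ox + w and oy <= center_xy[1] < oy + h):
        raise ValidationError("centre lies outside the density map")
    scale_mm = dens.scale_um_per_px / 1000.0
    xs, ys = dens.pixel_coords()
    dx_mm = (xs - center_xy[0]) * scale_mm
    dy_mm = (ys - center_xy[1]) * scale_mm
    r_mm = np.hypot(dx_mm, dy_mm)
    horizontal_wedge = np.abs(dx_mm) >= np.abs(dy_mm)

    values = dens.values
    if fit is not None:
        model = fit.profile.density(dx_mm, dy_mm)
        values = np.where(np.isfinite(values), values, model)

    # largest radius fully inside the map
    r_edge_mm = (
        min(
            center_xy[0] - ox,
            center_xy[1] - oy,
            ox + w - center_xy[0],
            oy + h - center_xy[1],
        )
        * scale_mm
    )
    r_limit = r_edge_mm if max_ecc_mm is None else min(max_ecc_mm, r_edge_mm)
    width_mm = annulus_width_um / 1000.0
    n_annuli = int(np.floor(r_limit / width_mm))
    if n_annuli < 1:
        raise ValidationError("map too small for a single annulus")

    idx = np.minimum((r_mm / width_mm).astype(int), n_annuli)
    in_range = idx < n_annuli
    finite = np.isfinite(values) & in_range

    def _wedge_mean(mask):
        sel = finite & mask
        counts = np.bincount(idx[sel], minlength=n_annuli)
        sums = np.bincount(idx[sel], weights=values[sel], minlength=n_annuli)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (
                np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
                counts,
            )

    mean_h, n_h = _wedge_mean(horizontal_wedge)
    mean_v, n_v = _wedge_mean(~horizontal_wedge)
    edges = np.arange(n_annuli + 1) * width_mm
    annulus_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)  # mm²
    cones = np.nan_to_num(mean_h, nan=0.0) * annulus_area / 2.0 + np.nan_to_num(
        mean_v, nan=0.0
    ) * annulus_area / 2.0
    # innermost annuli may have no pixels in one wedge at coarse scales;
    # fall back to the other wedge's mean there
    only_h = np.isfinite(mean_h) & ~np.isfinite(mean_v)
    only_v = ~np.isfinite(mean_h) & np.isfinite(mean_v)
    cones[only_h] = mean_h[only_h] * annulus_area[only_h]
    cones[only_v] = mean_v[only_v] * annulus_area[only_v]
    return ConeCountCurve(edges[1:], np.cumsum(cones), annulus_width_um)


# ---------------------------------------------------------------------------
# Summaries and correlations

SUMMARY_ECCENTRICITIES_MM = (0.1, 1.0, 3.0)


def extract_summary(
    fit: DualCauchyFit,
    curve: ConeCountCurve,
    participant_id: str = "",
) -> dict:
    """Per-participant summary record (PCD, minimum density, totals)."""
    record = {
        "participant_id": participant_id,
        "pcd": fit.pcd,
        "min_density": fit.min_density,
        "fit_rms": fit.fit_rms,
    }
    for ecc in SUMMARY_ECCENTRICITIES_MM:
        record[f"total_cones_{ecc:g}mm"] = curve.at(ecc)
    return record


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> dict:
    """Pearson correlation with a Fisher-z 95 % confidence interval.

    Degenerate inputs (zero variance or n < 3 after dropping non-finite
    pairs) return NaN with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    nan_result = {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                  "p": np.nan, "n": int(ok.sum())}
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("correlation undefined (degenerate input)")
        return nan_result
    r, p = pearsonr(x, y)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(len(x) - 3)
    from scipy.stats import norm

    zcrit = norm.ppf(1 - alpha / 2)
    return {
        "r": float(r),
        "ci_low": float(np.tanh(z - zcrit * se)),
        "ci_high": float(np.tanh(z + zcrit * se)),
        "p": float(p),
        "n": len(x),
    }


def summarize_cohort(records: list[dict]) -> tuple[pd.DataFrame, dict]:
    """Summary table plus the key cross-participant correlations.

    Returns the per-participant DataFrame and a dict of Pearson results
    for total cones (at 3 mm when available, else the largest shared
    eccentricity) against minimum density and against PCD.
    """
    table = pd.DataFrame(records)
    total_col = None
    for ecc in reversed(SUMMARY_ECCENTRICITIES_MM):
        col = f"total_cones_{ecc:g}mm"
        if col in table and np.isfinite(table[col]).sum() >= 3:
            total_col = col
            break
    correlations = {}
    if total_col is not None:
        correlations["total_vs_min_density"] = pearson_with_ci(
            table[total_col], table["min_density"]
        )
        correlations["total_vs_pcd"] = pearson_with_ci(
            table[total_col], table["pcd"]
        )
        correlations["total_column"] = total_col
    return table, correlations
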