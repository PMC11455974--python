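"""Automatic localisation of the peak-cone-density (foveal) position.

Works on the bootstrap density map (fixed-ROI pass): threshold at the 85th
percentile of finite density, take the largest 8-connected component's
bounding box, smooth within it (Gaussian σ = 8 px), contour at the
box-local 85th percentile, and fit an ellipse to the convex hull of the
contour; the ellipse centre is the foveal position. If a secondary
high-density component exceeds 40 % of the largest component's area, the
case is flagged ambiguous and the caller must supply a manual search box
(:func:`find_pcd_in_region`) — mirroring how unresolved or duplicated
density peaks are handled in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel, find_contours, points_in_poly

from .montage_io import ScalarMap, ValidationError
from .spectral_spacing import DegenerateInputError

__all__ = ["FovealEstimate", "find_pcd_location", "find_pcd_in_region"]

logger = logging.getLogger(__name__)

PERCENTILE = 85.0
SMOOTH_SIGMA_PX = 8.0
#: A secondary component larger than this fraction of the largest one
#: marks the automatic localisation as ambiguous.
SECONDARY_AREA_FRACTION = 0.40
MIN_FINITE_FRACTION = 0.01

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class FovealEstimate:
    """Location of peak cone density with provenance and ambiguity flag."""

    center: tuple[float, float] | None  # (x, y) montage pixels
    ellipse: tuple | None  # ((cx, cy), (a, b), theta_rad) or None
    ambiguous: bool
    source: str  # "automatic" | "manual_region"


def _nan_gaussian(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaN (normalised convolution)."""
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den < 1e-6] = np.nan
    return out


def _ellipse_center_from_region(
    sub: np.ndarray, percentile: float, sigma: float
) -> tuple[float, float] | None:
    """Steps 3–4 of the localisation on a (sub)map: smooth, contour at the
    local percentile, convex hull, ellipse fit. Returns (col, row) in the
    submap's own pixel coordinates, or None if no contour exists."""
    finite = np.isfinite(sub)
    if not finite.any():
        raise DegenerateInputError("region contains no finite density")
    smooth = _nan_gaussian(sub, sigma)
    finite_s = np.isfinite(smooth)
    level = np.percentile(smooth[finite_s], percentile)
    work = np.where(finite_s, smooth, -np.inf)
    contours = find_contours(work, level)
    contours = [c for c in contours if len(c) >= 5]
    if not contours:
        return None
    if len(contours) > 1:
        # keep the contour enclosing the maximum-density pixel; fall back
        # to the longest one for open contours that enclose nothing
        peak_rc = np.unravel_index(np.nanargmax(work), work.shape)
        enclosing = [
            c for c in contours if points_in_poly([peak_rc], c)[0]
        ]
        contour = enclosing[0] if enclosing else max(contours, key=len)
    else:
        contour = contours[0]
    try:
        hull = ConvexHull(contour)
        hull_pts = contour[hull.vertices]
    except QhullError:
        hull_pts = contour
    pts_xy = hull_pts[:, ::-1]  # (col, row) order
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts_xy)
        if not model:
            return None
        cx, cy = model.center
        a, b = model.axis_lengths
        theta = model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts_xy):
            return None
        cx, cy, a, b, theta = model.params
    return (cx, cy, a, b, theta)


def find_pcd_location(density: ScalarMap) -> FovealEstimate:
    """Locate the foveal (peak-density) position on a bootstrap density map.

    Returns an automatic :class:`FovealEstimate`; if the high-density mask
    has a secondary connected component larger than 40 % of the largest,
    ``ambiguous`` is set and no centre is returned.
    """
    values = density.values
    finite = np.isfinite(values)
    if finite.mean() < MIN_FINITE_FRACTION or not finite.any():
        raise DegenerateInputError("density map has too few finite pixels")

    threshold = np.percentile(values[finite], PERCENTILE)
    mask = finite & (values > threshold)
    if not mask.any():  # constant map: threshold equals every value
        mask = finite
    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONN)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
    order = np.argsort(areas)[::-1]
    largest_label = order[0] + 1
    if n_comp > 1 and areas[order[1]] > SECONDARY_AREA_FRACTION * areas[order[0]]:
        logger.warning(
            "ambiguous fovea: secondary high-density component is %.0f%% of "
            "the largest",
            100 * areas[order[1]] / areas[order[0]],
        )
        return FovealEstimate(None, None, ambiguous=True, source="automatic")

    rows, cols = np.nonzero(labels == largest_label)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = values[r0:r1, c0:c1]
    result = _ellipse_center_from_region(sub, PERCENTILE, SMOOTH_SIGMA_PX)
    if result is None:
        logger.warning("empty contour after smoothing; using component centroid")
        cx, cy = cols.mean(), rows.mean()
        ellipse = None
    else:
        cx_l, cy_l, a, b, theta = result
        cx, cy = c0 + cx_l, r0 + cy_l
        ellipse = ((cx + density.origin[0], cy + density.origin[1]), (a, b), theta)
    center = (cx + density.origin[0], cy + density.origin[1])
    return FovealEstimate(center, ellipse, ambiguous=False, source="automatic")


def find_pcd_in_region(
    density: ScalarMap, bbox: tuple[float, float, float, float]
) -> FovealEstimate:
    """Locate the foveal position within a user-supplied rectangle.

    *bbox* is ``(x, y, w, h)`` in montage coordinates. Runs the smoothing /
    contour / ellipse steps restricted to the box; the ambiguity check is
    skipped (the region is the human decision).
    """
    x, y, w, h = bbox
    ox, oy = density.origin
    c0, r0 = int(round(x - ox)), int(round(y - oy))
    c1, r1 = c0 + int(round(w)), r0 + int(round(h))
    H, W = density.values.shape
    if c0 < 0 or r0 < 0 or c1 > W or r1 > H:
        raise ValidationError("fovea search box extends outside the map")
    if (c1 - c0) < 64 or (r1 - r0) < 64:
        raise ValidationError("fovea search box must be at least 64×64 px")
    sub = density.values[r0:r1, c0:c1]
    result = _ellipse_center_from_region(sub, PERCENTILE, SMOOTH_SIGMA_PX)
    if result is None:
        finite = np.isfinite(sub)
        rows, cols = np.nonzero(finite)
        cx_l, cy_l = cols.mean(), rows.mean()
        ellipse = None
    else:
        cx_l, cy_l, a, b, theta = result
        ellipse = (
            (c0 + cx_l + ox, r0 + cy_l + oy), (a, b), theta,
        )
    center = (c0 + cx_l + ox, r0 + cy_l + oy)
    return FovealEstimate(center, ellipse, ambiguous=False, source="manual_region")
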