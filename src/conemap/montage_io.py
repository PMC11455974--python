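"""Montage and map I/O for adaptive-optics retinal imaging.

Defines the in-memory containers shared by the whole pipeline — montage
frames with global placement offsets, scalar maps (density / confidence /
spacing / overlap) with an origin and a micron-per-pixel scale — and
reads/writes them as plain rasters (TIFF/PNG) plus small CSV/JSON sidecars.

Conventions
-----------
* Coordinates are 0-based, x to the right, y down, anchored at the
  top-left; all frame offsets are integer pixels in the montage frame.
* Frame pixel values are normalised to [0, 1] on load (division by the
  dtype maximum); invalid regions are NaN.
* A scalar map is stored as a 32-bit float TIFF next to a JSON sidecar
  ``<name>.json`` holding ``{"origin": [x, y], "scale_um_per_px": s,
  "quantity": q}``; the round trip is lossless at 32-bit precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

__all__ = [
    "ParticipantMeta",
    "MontageFrame",
    "Montage",
    "ScalarMap",
    "ValidationError",
    "FormatError",
    "load_montage",
    "write_scalar_map",
    "read_scalar_map",
    "microns_per_degree",
]

#: Assumed retinal magnification at the reference axial length: microns of
#: retina per degree of visual angle for a 24 mm eye.
BASE_UM_PER_DEG = 291.0
REFERENCE_AXIAL_LENGTH_MM = 24.0

#: Plausible human axial-length range (mm); values outside are rejected.
AXIAL_LENGTH_RANGE_MM = (20.0, 30.0)

VALID_MODALITIES = ("confocal", "split_detection")
VALID_QUANTITIES = ("density", "confidence", "spacing", "overlap")


class ValidationError(ValueError):
    """Raised when inputs violate a documented invariant."""


class FormatError(ValueError):
    """Raised when an on-disk artefact is malformed (e.g. missing sidecar)."""


def microns_per_degree(axial_length_mm: float) -> float:
    """Retinal magnification (µm/deg) for a given axial length.

    Linear in axial length: 291 µm/deg at the 24 mm reference eye, scaled
    by ``axial_length / 24``.
    """
    lo, hi = AXIAL_LENGTH_RANGE_MM
    if not (lo <= axial_length_mm <= hi):
        raise ValidationError(
            f"axial length {axial_length_mm} mm outside plausible range "
            f"[{lo}, {hi}] mm"
        )
    return BASE_UM_PER_DEG * axial_length_mm / REFERENCE_AXIAL_LENGTH_MM


@dataclass(frozen=True)
class ParticipantMeta:
    """Identity and ocular biometry of one imaged eye."""

    participant_id: str
    axial_length: float  # mm
    eye: str  # "OD" (right) or "OS" (left)

    def __post_init__(self) -> None:
        lo, hi = AXIAL_LENGTH_RANGE_MM
        if not (lo <= self.axial_length <= hi):
            raise ValidationError(
                f"axial length {self.axial_length} mm outside [{lo}, {hi}] mm"
            )
        if self.eye not in ("OD", "OS"):
            raise ValidationError(f"eye must be 'OD' or 'OS', got {self.eye!r}")

    @property
    def um_per_deg(self) -> float:
        return microns_per_degree(self.axial_length)


@dataclass
class MontageFrame:
    """One registered image with its global placement in the montage."""

    pixels: np.ndarray  # 2-D float raster in [0, 1]; NaN = invalid
    offset: tuple[int, int]  # (x, y) of the top-left corner, montage pixels
    modality: str
    frame_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("frame pixels must be a 2-D raster")
        if self.modality not in VALID_MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.offset = (int(self.offset[0]), int(self.offset[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) exclusive bounding box in montage pixels."""
        h, w = self.pixels.shape
        x, y = self.offset
        return (x, y, x + w, y + h)


@dataclass
class Montage:
    """A set of single-modality frames sharing one global coordinate frame."""

    frames: list[MontageFrame]
    scale_um_per_px: float
    meta: ParticipantMeta

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("montage must contain at least one frame")
        modalities = {f.modality for f in self.frames}
        if len(modalities) > 1:
            raise ValidationError(f"mixed modalities in montage: {modalities}")
        ids = [f.frame_id for f in self.frames]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate frame_id in montage")
        if self.scale_um_per_px <= 0:
            raise ValidationError("scale_um_per_px must be positive")

    @property
    def modality(self) -> str:
        return self.frames[0].modality

    @property
    def scale_deg_per_px(self) -> float:
        return self.scale_um_per_px / self.meta.um_per_deg

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        boxes = np.array([f.bounds for f in self.frames])
        return (
            int(boxes[:, 0].min()),
            int(boxes[:, 1].min()),
            int(boxes[:, 2].max()),
            int(boxes[:, 3].max()),
        )

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the montage bounding box."""
        x0, y0, x1, y1 = self.bounds
        return (y1 - y0, x1 - x0)

    def flatten(self) -> np.ndarray:
        """Render all frames into one montage raster (later frames on top).

        Returns a float array of the bounding-box size with NaN where no
        frame provides data.
        """
        x0, y0, x1, y1 = self.bounds
        out = np.full((y1 - y0, x1 - x0), np.nan)
        for f in self.frames:
            fx, fy, fx1, fy1 = f.bounds
            region = out[fy - y0 : fy1 - y0, fx - x0 : fx1 - x0]
            valid = np.isfinite(f.pixels)
            region[valid] = f.pixels[valid]
        return out


@dataclass
class ScalarMap:
    """Dense raster of a scalar quantity in the montage coordinate frame."""

    values: np.ndarray  # 2-D float; NaN where undefined
    origin: tuple[float, float]  # (x, y) of pixel (0, 0) in montage px
    scale_um_per_px: float
    quantity: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("map values must be 2-D")
        if self.quantity not in VALID_QUANTITIES:
            raise ValidationError(f"unknown quantity tag {self.quantity!r}")
        if self.scale_um_per_px <= 0:
            raise ValidationError("scale_um_per_px must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        finite = self.values[np.isfinite(self.values)]
        if self.quantity in ("density", "spacing", "overlap") and finite.size:
            if finite.min() < 0:
                raise ValidationError(f"{self.quantity} values must be >= 0")
        if self.quantity == "confidence" and finite.size:
            if finite.min() < -1e-9 or finite.max() > 1 + 1e-9:
                raise ValidationError("confidence values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self, **changes) -> "ScalarMap":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Montage-frame (x, y) coordinate grids of every pixel."""
        h, w = self.values.shape
        ys, xs = np.mgrid[0:h, 0:w]
        return xs + self.origin[0], ys + self.origin[1]


# ---------------------------------------------------------------------------
# Loading montages from a layout file

LAYOUT_COLUMNS = ["frame_id", "filename", "x", "y", "modality"]


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse trivial channel axes (greyscale PNG w/ RGB)
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2-D greyscale raster")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def _read_layout(layout_file: Path) -> pd.DataFrame:
    if layout_file.suffix.lower() == ".json":
        rows = json.loads(layout_file.read_text())
        table = pd.DataFrame(rows)
    else:
        table = pd.read_csv(layout_file)
    missing = set(LAYOUT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"layout file missing columns: {sorted(missing)}")
    return table


def load_montage(
    image_dir: str | Path,
    layout_file: str | Path,
    meta: ParticipantMeta,
    modality: str,
    base_deg_per_px: float = 1 / 291.0,
) -> Montage:
    """Load every frame of one modality listed in a layout file.

    The layout file (CSV or JSON records) has columns
    ``frame_id, filename, x, y, modality``; only rows matching *modality*
    are loaded. The montage micron-per-pixel scale is derived from the
    configured base degrees-per-pixel and the participant's axial length.
    """
    image_dir = Path(image_dir)
    table = _read_layout(Path(layout_file))
    rows = table[table["modality"] == modality]
    if rows.empty:
        raise ValidationError(
            f"layout lists no frames for modality {modality!r}"
        )
    if rows["frame_id"].duplicated().any():
        dupes = rows.loc[rows["frame_id"].duplicated(), "frame_id"].tolist()
        raise ValidationError(f"duplicate frame_id(s) in layout: {dupes}")
    frames = []
    for row in rows.itertuples():
        path = image_dir / str(row.filename)
        if not path.exists():
            raise IOError(f"montage frame image not found: {row.filename}")
        frames.append(
            MontageFrame(
                pixels=_read_raster(path),
                offset=(int(row.x), int(row.y)),
                modality=modality,
                frame_id=str(row.frame_id),
            )
        )
    scale_um = base_deg_per_px * meta.um_per_deg
    return Montage(frames=frames, scale_um_per_px=scale_um, meta=meta)


# ---------------------------------------------------------------------------
# Scalar-map round trip: 32-bit float TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_scalar_map(map_: ScalarMap, path: str | Path) -> None:
    """Write a map as 32-bit float TIFF with origin/scale/quantity sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, map_.values.astype(np.float32))
    sidecar = {
        "origin": [map_.origin[0], map_.origin[1]],
        "scale_um_per_px": map_.scale_um_per_px,
        "quantity": map_.quantity,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_scalar_map(path: str | Path) -> ScalarMap:
    """Read a map written by :func:`write_scalar_map`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for map: {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    values = tifffile.imread(path).astype(np.float64)
    return ScalarMap(
        values=values,
        origin=tuple(sidecar["origin"]),
        scale_um_per_px=float(sidecar["scale_um_per_px"]),
        quantity=str(sidecar["quantity"]),
    )
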