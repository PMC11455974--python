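"""End-to-end per-eye and cohort pipelines.

Per eye (the three stages of the method): (1) a bootstrap density pass at a
fixed 256-px ROI to localise the fovea, (2) eccentricity-sized density
passes per modality, and (3) confidence-seamed modality fusion plus
optional separate analysis of the frame containing the foveal centre,
followed by outlier filtering. Cohort analysis then orients, aligns,
down-samples and stacks the per-eye maps, extracts meridian profiles,
fits the dual-Cauchy model and integrates total-cone curves.

Everything is driven by a :class:`RunConfig` whose defaults pin the
method's published constants; there are no interactive prompts — the
manual foveal fallback enters via ``fovea_box``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import density_mapping, modality_fusion, normative_analysis
from .density_mapping import RoiSizingRule, map_montage_density
from .fovea_localization import (
    FovealEstimate,
    find_pcd_in_region,
    find_pcd_location,
)
from .montage_io import (
    Montage,
    ParticipantMeta,
    ScalarMap,
    ValidationError,
    load_montage,
    microns_per_degree,
    write_scalar_map,
)

__all__ = [
    "RunConfig",
    "SingleEyeResult",
    "AmbiguousFoveaError",
    "analyze_eye",
    "run_single_eye",
    "run_cohort",
]

logger = logging.getLogger(__name__)


class AmbiguousFoveaError(RuntimeError):
    """Automatic fovea localisation refused; a manual box is required."""


class RunConfig(BaseModel):
    """All tunables of the per-eye pipeline.

    The defaults reproduce the method's published constants: 256-px
    bootstrap ROI, 128→384 px ROI sizing between 1° and 10°, 291 µm/deg at
    24 mm axial length, 0.2 blend threshold, 5th-percentile confidence
    filter, 400 µm foveal disc, factor-4 down-sampling, minimum overlap of
    10 participants, ≈7 µm annuli.
    """

    input_dir: str = "."
    output_dir: str | None = None
    units: str = "linear"  # "linear" (µm, cones/mm²) or "angular"
    stride_fraction: float = 0.5
    wedge_deg: float = 90.0
    bootstrap_roi_px: int = 256
    blend_threshold: float = 0.2
    blend_bin_width_um: float = 50.0
    downsample_factor: int = 4
    min_overlap: int = 10
    annulus_width_um: float = 7.0
    strip_width_deg: float = 1.0
    fovea_box: tuple[float, float, float, float] | None = None
    include_foveal_image: bool = True
    sizing: dict = Field(
        default_factory=lambda: dict(
            size_at_min=128, size_at_max=384, min_ecc=1.0, max_ecc=10.0
        )
    )

    def sizing_rule(self) -> RoiSizingRule:
        return RoiSizingRule(**self.sizing)


@dataclasses.dataclass
class SingleEyeResult:
    """Outputs of one per-eye run."""

    participant_id: str
    eye: str
    density: ScalarMap
    confidence: ScalarMap
    fovea: FovealEstimate
    blend_spec: modality_fusion.BlendSpec | None
    report: dict


def _load_participant(input_dir: Path):
    meta_file = input_dir / "meta.json"
    meta_raw = json.loads(meta_file.read_text())
    meta = ParticipantMeta(
        participant_id=str(meta_raw["participant_id"]),
        axial_length=float(meta_raw["axial_length"]),
        eye=str(meta_raw["eye"]),
    )
    if "px_um" in meta_raw:
        base_deg_per_px = float(meta_raw["px_um"]) / meta.um_per_deg
    else:
        base_deg_per_px = 1.0 / microns_per_degree(meta.axial_length)
    montages = {}
    for modality in ("confocal", "split_detection"):
        try:
            montages[modality] = load_montage(
                input_dir, input_dir / "layout.csv", meta, modality,
                base_deg_per_px=base_deg_per_px,
            )
        except ValidationError:
            continue
    if "confocal" not in montages:
        raise ValidationError(f"{input_dir}: no confocal frames in layout")
    return meta, montages


def _foveal_frame_montage(montage: Montage, center_xy) -> Montage | None:
    """Single-frame montage for the frame containing the foveal centre."""
    for frame in montage.frames:
        x0, y0, x1, y1 = frame.bounds
        if x0 <= center_xy[0] < x1 and y0 <= center_xy[1] < y1:
            return Montage([frame], montage.scale_um_per_px, montage.meta)
    return None


def analyze_eye(
    montages: dict[str, Montage], config: RunConfig
) -> SingleEyeResult:
    """Run the full per-eye pipeline on loaded montages.

    *montages* maps modality name → :class:`Montage`; confocal is
    required. Raises :class:`AmbiguousFoveaError` when the automatic
    foveal search is ambiguous and no ``fovea_box`` is configured.
    """
    confocal = montages["confocal"]
    meta = confocal.meta
    sizing = config.sizing_rule()

    # stage 1: bootstrap density pass and fovea localisation
    boot_dens, _, _ = map_montage_density(
        confocal,
        fovea=None,
        stride_fraction=config.stride_fraction,
        units="linear",
        fixed_roi_px=config.bootstrap_roi_px,
    )
    if config.fovea_box is not None:
        fovea = find_pcd_in_region(boot_dens, config.fovea_box)
    else:
        fovea = find_pcd_location(boot_dens)
        if fovea.ambiguous:
            raise AmbiguousFoveaError(
                "automatic fovea localisation is ambiguous (secondary "
                "high-density region); re-run with a manual search box "
                "(--fovea-box X,Y,W,H)"
            )
    center = fovea.center

    # stage 2: eccentricity-sized density pass per modality
    per_modality = {}
    for modality, montage in montages.items():
        dens, conf, _ = map_montage_density(
            montage,
            fovea=center,
            sizing=sizing,
            stride_fraction=config.stride_fraction,
            units=config.units,
        )
        per_modality[modality] = (dens, conf)

    # stage 3: confidence-seamed fusion
    blend_spec = None
    if "split_detection" in per_modality:
        pairs = [per_modality["confocal"], per_modality["split_detection"]]
        dens_maps = modality_fusion.rescale_to_common_scale(
            [pairs[0][0], pairs[1][0]]
        )
        conf_maps = modality_fusion.rescale_to_common_scale(
            [pairs[0][1], pairs[1][1]]
        )
        merged, blend_spec = modality_fusion.merge_modalities(
            (dens_maps[0], conf_maps[0]),
            (dens_maps[1], conf_maps[1]),
            center,
            bin_width_um=config.blend_bin_width_um,
            threshold=config.blend_threshold,
        )
    else:
        merged = per_modality["confocal"]

    if config.include_foveal_image:
        foveal_montage = _foveal_frame_montage(confocal, center)
        if foveal_montage is not None:
            f_dens, f_conf, _ = map_montage_density(
                foveal_montage,
                fovea=center,
                sizing=sizing,
                stride_fraction=config.stride_fraction,
                units=config.units,
            )
            merged = modality_fusion.integrate_foveal_image(
                merged, (f_dens, f_conf), center,
                bin_width_um=config.blend_bin_width_um,
            )

    dens_f, conf_f = normative_analysis.filter_participant_map(
        merged[0], merged[1], center
    )

    report = {
        "participant_id": meta.participant_id,
        "eye": meta.eye,
        "axial_length_mm": meta.axial_length,
        "scale_um_per_px": confocal.scale_um_per_px,
        "units": config.units,
        "fovea": {
            "center": list(center),
            "ambiguous": fovea.ambiguous,
            "source": fovea.source,
        },
        "blend": None
        if blend_spec is None
        else {
            "transition_radius_um": blend_spec.transition_radius,
            "band_um": blend_spec.band,
            "inner_source": blend_spec.inner_source,
            "sole_source": blend_spec.sole_source,
        },
        "valid_pixels": int(np.isfinite(dens_f.values).sum()),
    }
    return SingleEyeResult(
        participant_id=meta.participant_id,
        eye=meta.eye,
        density=dens_f,
        confidence=conf_f,
        fovea=fovea,
        blend_spec=blend_spec,
        report=report,
    )


def run_single_eye(config: RunConfig) -> SingleEyeResult:
    """Load one participant directory, analyse it, write the outputs.

    The participant directory must contain ``layout.csv``, the listed
    frame images and ``meta.json``. Maps and the JSON run report go to
    ``config.output_dir`` (default: ``<input_dir>/analysis``).
    """
    input_dir = Path(config.input_dir)
    meta, montages = _load_participant(input_dir)
    result = analyze_eye(montages, config)
    out_dir = Path(config.output_dir or (input_dir / "analysis"))
    out_dir.mkdir(parents=True, exist_ok=True)
    write_scalar_map(result.density, out_dir / "density.tif")
    write_scalar_map(result.confidence, out_dir / "confidence.tif")
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=1))
    return result


def run_cohort(
    participant_dirs: list[str | Path],
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Per-eye analysis of every participant, then cohort aggregation.

    Returns a dict with the cohort stack, per-participant results,
    meridian profiles, fits, the summary table and correlations; writes
    cohort maps and CSVs when *output_dir* is given. Participants whose
    per-eye run fails are skipped with a logged warning; if all fail, a
    RuntimeError summarising the per-eye errors is raised.
    """
    config = config or RunConfig()
    if config.units != "linear":
        raise ValidationError("cohort analysis runs in linear units")
    results: list[SingleEyeResult] = []
    failures: dict[str, str] = {}
    for d in participant_dirs:
        cfg = config.model_copy(update={"input_dir": str(d), "output_dir": None})
        try:
            input_dir = Path(cfg.input_dir)
            _, montages = _load_participant(input_dir)
            results.append(analyze_eye(montages, cfg))
        except Exception as exc:  # noqa: BLE001 - per-eye isolation
            failures[str(d)] = f"{type(exc).__name__}: {exc}"
            logger.warning("participant %s failed: %s", d, exc)
    if not results:
        raise RuntimeError(f"all per-eye runs failed: {failures}")

    aligned = normative_analysis.orient_and_align(
        [(r.density, r.confidence) for r in results],
        [r.eye for r in results],
        [r.fovea.center for r in results],
    )
    down = [
        (
            normative_analysis.downsample_map(d, config.downsample_factor),
            normative_analysis.downsample_map(c, config.downsample_factor),
        )
        for d, c in aligned
    ]
    stack = normative_analysis.build_cohort_stack(down)
    stack_thr = normative_analysis.apply_overlap_threshold(
        stack, config.min_overlap
    )

    # per-participant meridian profiles, fits, totals
    records = []
    fits = {}
    curves = {}
    profiles = {}
    for result, (dmap, cmap) in zip(results, down):
        um_per_deg = microns_per_degree(result.report["axial_length_mm"])
        merid = {
            m: normative_analysis.meridian_strip_profile(
                dmap, (0.0, 0.0), m,
                strip_width_deg=config.strip_width_deg,
                um_per_deg=um_per_deg,
                conf_map=cmap,
            )
            for m in normative_analysis.MERIDIANS
        }
        profiles[result.participant_id] = merid
        horiz = _combine_meridians(merid["nasal"], merid["temporal"], "horizontal")
        vert = _combine_meridians(merid["superior"], merid["inferior"], "vertical")
        horiz = normative_analysis.exclude_nonmonotonic_fovea(horiz)
        vert = normative_analysis.exclude_nonmonotonic_fovea(vert)
        try:
            fit = normative_analysis.fit_dual_cauchy(horiz, vert)
        except (normative_analysis.FitNonConvergence, ValidationError) as exc:
            logger.warning(
                "meridian fit failed for %s: %s", result.participant_id, exc
            )
            continue
        curve = normative_analysis.total_cones_vs_eccentricity(
            dmap, (0.0, 0.0), fit=fit,
            annulus_width_um=config.annulus_width_um,
        )
        fits[result.participant_id] = fit
        curves[result.participant_id] = curve
        records.append(
            normative_analysis.extract_summary(fit, curve, result.participant_id)
        )

    table, correlations = normative_analysis.summarize_cohort(records)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_scalar_map(stack_thr.mean_density, out / "cohort_mean_density.tif")
        write_scalar_map(stack_thr.sd_density, out / "cohort_sd_density.tif")
        write_scalar_map(
            stack_thr.mean_confidence, out / "cohort_mean_confidence.tif"
        )
        write_scalar_map(stack.overlap, out / "cohort_overlap.tif")
        table.to_csv(out / "summary.csv", index=False)
        _write_meridian_csv(profiles, out / "meridian_profiles.csv")
        (out / "cohort_report.json").write_text(
            json.dumps(
                {
                    "n_participants": stack.n_participants,
                    "n_fitted": len(records),
                    "failures": failures,
                    "correlations": {
                        k: v for k, v in correlations.items() if k != "total_column"
                    },
                },
                indent=1,
                default=float,
            )
        )

    return {
        "results": results,
        "failures": failures,
        "stack": stack,
        "stack_thresholded": stack_thr,
        "profiles": profiles,
        "fits": fits,
        "curves": curves,
        "summary": table,
        "correlations": correlations,
    }


def _combine_meridians(a, b, name):
    """NaN-aware per-bin mean of two opposite meridian profiles."""
    n = max(a.ecc.size, b.ecc.size)
    if n == 0:
        raise ValidationError("both meridian profiles are empty")

    def pad(p):
        dens = np.full(n, np.nan)
        conf = np.full(n, np.nan)
        dens[: p.density.size] = p.density
        if p.confidence is not None:
            conf[: p.confidence.size] = p.confidence
        return dens, conf

    da, ca = pad(a)
    db, cb = pad(b)
    ecc = a.ecc if a.ecc.size == n else b.ecc
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        dens = np.nanmean(np.stack([da, db]), axis=0)
        conf = np.nanmean(np.stack([ca, cb]), axis=0)
    return normative_analysis.MeridianProfile(name, ecc, dens, conf)


def _write_meridian_csv(profiles: dict, path: Path) -> None:
    rows = []
    for pid, merid in profiles.items():
        for m, prof in merid.items():
            for i in range(prof.ecc.size):
                rows.append(
                    {
                        "participant_id": pid,
                        "meridian": m,
                        "ecc_mm": prof.ecc[i],
                        "density": prof.density[i],
                        "confidence": np.nan
                        if prof.confidence is None
                        else prof.confidence[i],
                        "n": 0 if prof.n is None else int(prof.n[i]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
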