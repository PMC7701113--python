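"""End-to-end session analysis: segment -> localize -> fit -> report.

The seven-step workflow: acquire scans of the phantom at several table
positions (the first at isocenter), segment the fiducials per scan, localize
each phantom placement from the three landmark spheres, form displacement
observations, fit the joint multi-scan model, read the laser misalignment
from the centre series' rigid terms, and discard all per-series rigid terms
to leave the scanner's distortion field.

``analyze_session`` works on in-memory ``ScanSeries``; ``run_pipeline``
wraps it with file I/O and report writing so that the CLI subcommands and
the one-shot pipeline share every code path (and therefore produce identical
outputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import PhantomDesign, load_design
from .errors import MsemapError
from .fieldfit import (BasisSpec, DistortionFit, build_design_matrix, fit_multiscan,
                       laser_misalignment, select_orders)
from .io import ScanSeries, read_volume
from .localization import (DisplacementObservation, RigidTransform,
                           assign_correspondences, find_landmarks, procrustes)
from .metrics import radial_profile
from .segmentation import DetectedFiducial, segment_volume

__all__ = ["SessionParams", "SessionConfig", "SessionResult", "detections_to_frame",
           "detections_from_frame", "observations_to_frame", "localize_scan",
           "observations_for_scan", "analyze_session", "fit_observations",
           "run_pipeline"]

log = logging.getLogger("msemap")


@dataclass
class SessionParams:
    """Tunable analysis parameters with their working defaults."""

    threshold: float = 0.5
    min_separation: float = 15.0
    interp_factor: int = 8
    max_dist: float = 10.0
    landmark_tolerance: float = 3.0
    landmark_candidates: int = 12
    orders: tuple[int, int, int] | None = None
    sum_cap: int | None = None
    lam: float | str = "gcv"
    center_series: int = 0


@dataclass
class SessionConfig:
    """File-based session description for :func:`run_pipeline`."""

    design_path: str
    volume_paths: list[str]
    out_dir: str
    center_index: int = 0
    params: SessionParams = field(default_factory=SessionParams)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionConfig":
        payload = yaml.safe_load(Path(path).read_text())
        params = SessionParams(**payload.pop("params", {}))
        if params.orders is not None:
            params.orders = tuple(params.orders)
        return cls(params=params, **payload)


@dataclass
class SessionResult:
    fit: DistortionFit
    observations: list[DisplacementObservation]
    placements: dict[int, RigidTransform]
    detections: dict[int, pd.DataFrame]
    report: dict


# ---------------------------------------------------------------------------
# tabular detection / observation interchange
# ---------------------------------------------------------------------------

def detections_to_frame(detections: dict[float, list[DetectedFiducial]],
                        series: int) -> pd.DataFrame:
    rows = []
    for diameter, dets in sorted(detections.items()):
        for det in dets:
            rows.append({
                "series": series, "diameter": diameter,
                "x": det.position[0], "y": det.position[1], "z": det.position[2],
                "ncc_score": det.ncc_score, "refined": bool(det.refined),
            })
    return pd.DataFrame(rows)


def detections_from_frame(frame: pd.DataFrame) -> dict[float, list[DetectedFiducial]]:
    out: dict[float, list[DetectedFiducial]] = {}
    for diameter, sub in frame.groupby("diameter"):
        out[float(diameter)] = [
            DetectedFiducial(
                position=np.array([r.x, r.y, r.z]), ncc_score=float(r.ncc_score),
                diameter_used=float(diameter), refined=bool(r.refined))
            for r in sub.itertuples(index=False)
        ]
    return out


def observations_to_frame(observations: list[DisplacementObservation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "series": o.series, "fiducial_id": o.fiducial_id,
        "designed_x": o.designed[0], "designed_y": o.designed[1],
        "designed_z": o.designed[2],
        "segmented_x": o.segmented[0], "segmented_y": o.segmented[1],
        "segmented_z": o.segmented[2],
        "dx": o.d[0], "dy": o.d[1], "dz": o.d[2],
    } for o in observations])


# ---------------------------------------------------------------------------
# per-scan stages
# ---------------------------------------------------------------------------

def localize_scan(detections: dict[float, list[DetectedFiducial]],
                  design: PhantomDesign,
                  params: SessionParams) -> tuple[RigidTransform, float]:
    """Landmark identification + Procrustes placement for one scan."""
    landmark_diameter = max(f.diameter for f in design.landmarks)
    large = detections.get(landmark_diameter)
    if not large:
        raise MsemapError(
            f"no detections at the landmark diameter {landmark_diameter} mm")
    match = find_landmarks(large, design, tolerance=params.landmark_tolerance,
                           max_candidates=params.landmark_candidates)
    placement = procrustes(match.designed_positions, match.detected_positions)
    return placement, match.residual


def observations_for_scan(
    design: PhantomDesign,
    detections: dict[float, list[DetectedFiducial]],
    placement: RigidTransform,
    series: int,
    params: SessionParams,
) -> list[DisplacementObservation]:
    """Assign detections to designed fiducials, one matching pass per diameter."""
    observations: list[DisplacementObservation] = []
    diameters = np.unique(design.diameters)
    for diameter in diameters:
        subset = design.diameters == diameter
        dets = detections.get(float(diameter), [])
        if not dets:
            continue
        result = assign_correspondences(
            placement, (design.ids[subset], design.positions[subset]), dets,
            max_dist=params.max_dist, series=series)
        observations.extend(result.observations)
        if result.unmatched_designed:
            log.warning("series %d: %d designed fiducial(s) of diameter %.1f mm unmatched",
                        series, len(result.unmatched_designed), diameter)
    observations.sort(key=lambda o: o.fiducial_id)
    return observations


def fit_observations(observations: list[DisplacementObservation],
                     params: SessionParams) -> DistortionFit:
    """Order selection + design matrix + regularized multi-scan fit."""
    if params.orders is not None:
        pos = np.array([o.segmented for o in observations])
        lo, hi = pos.min(axis=0), pos.max(axis=0)
        extent = np.maximum(hi - lo, 1e-6)
        box = np.stack([lo - 0.05 * extent, hi + 0.05 * extent])
        cap = params.sum_cap or int(np.floor(1.5 * max(params.orders)))
        basis = BasisSpec(params.orders, cap, box)
    else:
        basis = select_orders(observations, center_series=params.center_series)
        if params.sum_cap is not None:
            basis = BasisSpec(basis.orders, params.sum_cap, basis.box)
    system = build_design_matrix(observations, basis)
    return fit_multiscan(system, lam=params.lam, center_series=params.center_series)


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def analyze_session(scans: list[ScanSeries], design: PhantomDesign,
                    params: SessionParams | None = None) -> SessionResult:
    """Run segmentation, localization and the multi-scan fit on in-memory scans."""
    params = params or SessionParams()
    centers = [s.series_id for s in scans if s.is_center]
    if len(centers) != 1:
        raise MsemapError(f"exactly one centre scan required, found {len(centers)}")
    params.center_series = centers[0]

    diameters = np.unique(design.diameters)
    observations: list[DisplacementObservation] = []
    placements: dict[int, RigidTransform] = {}
    detection_frames: dict[int, pd.DataFrame] = {}
    for scan in scans:
        dets = segment_volume(scan, diameters, threshold=params.threshold,
                              min_separation=params.min_separation,
                              factor=params.interp_factor)
        n_det = sum(len(v) for v in dets.values())
        placement, lm_residual = localize_scan(dets, design, params)
        obs = observations_for_scan(design, dets, placement, scan.series_id, params)
        log.info("series %d: %d detections, landmark residual %.2f mm, %d observations",
                 scan.series_id, n_det, lm_residual, len(obs))
        observations.extend(obs)
        placements[scan.series_id] = placement
        detection_frames[scan.series_id] = detections_to_frame(dets, scan.series_id)

    fit = fit_observations(observations, params)
    pos = np.array([o.segmented for o in observations])
    field_at_obs = fit.evaluate(pos, warn_extrapolation=False)
    mags = np.linalg.norm(field_at_obs, axis=1)
    profile = radial_profile(pos, field_at_obs)
    misalign = laser_misalignment(fit)
    report = {
        "n_scans": len(scans),
        "n_observations": len(observations),
        "orders": list(fit.basis.orders),
        "sum_cap": fit.basis.sum_cap,
        "lambda": fit.lam,
        "residual_rms_mm_per_series": fit.diagnostics.get("residual_rms_mm_per_series"),
        "max_field_at_fiducials_mm": float(mags.max()),
        "median_field_at_fiducials_mm": float(np.median(mags)),
        "laser_misalignment": {
            "delta_mm": fit.rigid[fit.center_series][0].tolist(),
            "epsilon_rad": fit.rigid[fit.center_series][1].tolist(),
            "rotation_angle_deg": float(np.rad2deg(np.linalg.norm(misalign.rotvec()))),
        },
        "radial_profile": profile.to_frame().to_dict(orient="list"),
    }
    return SessionResult(fit, observations, placements, detection_frames, report)


def run_pipeline(config: SessionConfig) -> SessionResult:
    """File-based pipeline: read volumes, analyze, write fit/observations/report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = load_design(config.design_path)
    scans = [
        read_volume(p, series_id=i, is_center=(i == config.center_index))
        for i, p in enumerate(config.volume_paths)
    ]
    result = analyze_session(scans, design, config.params)
    result.fit.save(out_dir / "fit.json")
    observations_to_frame(result.observations).to_csv(
        out_dir / "observations.csv", index=False, float_format="%.17g")
    pd.concat(result.detections.values(), ignore_index=True).to_csv(
        out_dir / "detections.csv", index=False, float_format="%.17g")
    (out_dir / "report.json").write_text(
        json.dumps(result.report, indent=1, sort_keys=True))
    log.info("pipeline outputs written to %s", out_dir)
    return result
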