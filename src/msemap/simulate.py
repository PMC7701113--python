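"""Synthetic phantom scans with a known ground-truth distortion field.

The renderer places each sphere at its *apparent* position -- the fixed point
of ``a = t + d(a)`` where ``t`` is the rigidly placed design position and
``d`` the truth displacement field in apparent-coordinate convention -- and
draws it dark into a bright volume with the same subdivision-based
partial-volume edge model used by the NCC template.  Sphere shapes are not
warped: at the few-mm distortion magnitudes this models, shape distortion of
a 10-15 mm sphere is second order, while fiducial-level ground truth stays
exact.

``simulate_observations`` skips image rendering entirely and produces
displacement observations directly at fiducial level; it is the fast path
for exercising the fitting stage with known placement perturbations and
localization noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PhantomDesign
from .errors import ConvergenceError, MsemapError
from .fieldfit import BasisSpec, DistortionFit
from .io import ScanSeries
from .localization import DisplacementObservation, RigidTransform, find_landmarks, procrustes
from .segmentation import OVERSAMPLE, sphere_voxel_fractions

__all__ = ["TruthField", "SceneSpec", "apparent_positions", "render_scan",
           "render_session", "simulate_observations", "SimulatedObservations"]


class TruthField:
    """Ground-truth distortion field, evaluable anywhere in the volume.

    Either wraps a closed-form callable ``f(points) -> (n, 3)`` or a
    polynomial coefficient set over the same Chebyshev basis family the
    fitting stage uses.  The polynomial block never contains a rigid
    component: truth is a pure distortion field (a global rigid part would be
    unobservable anyway -- it is indistinguishable from phantom placement).
    """

    def __init__(self, fn=None, fit: DistortionFit | None = None,
                 max_magnitude: float | None = None):
        if (fn is None) == (fit is None):
            raise ValueError("provide exactly one of fn or fit")
        self._fn = fn
        self._fit = fit
        self.max_magnitude = max_magnitude

    @classmethod
    def zero(cls) -> "TruthField":
        return cls(fn=lambda pts: np.zeros_like(np.atleast_2d(pts), dtype=float),
                   max_magnitude=0.0)

    @classmethod
    def from_callable(cls, fn, max_magnitude: float | None = None) -> "TruthField":
        return cls(fn=fn, max_magnitude=max_magnitude)

    @classmethod
    def from_coefficients(cls, basis: BasisSpec, A: np.ndarray,
                          strain=None) -> "TruthField":
        strain = np.zeros(6) if strain is None else np.asarray(strain, float)
        fit = DistortionFit(basis=basis, A=np.asarray(A, float), strain=strain,
                            rigid={0: (np.zeros(3), np.zeros(3))}, center_series=0,
                            lam=0.0)
        return cls(fit=fit, max_magnitude=None)

    @classmethod
    def random(cls, box, orders=(4, 4, 4), max_magnitude: float = 5.0,
               seed: int = 0, include_strain: bool = True) -> "TruthField":
        """Random smooth field inside the distortion-block span, scaled so the
        maximum displacement magnitude over the box is ``max_magnitude`` mm."""
        basis = BasisSpec(orders, int(np.floor(1.5 * max(orders))), np.asarray(box, float))
        rng = np.random.default_rng(seed)
        terms = basis.tensor_terms
        decay = np.array([1.0 / (1.0 + (m + n + p) ** 2) for (m, n, p) in terms])
        A = rng.standard_normal((len(terms), 3)) * decay[:, None]
        strain = rng.normal(0.0, 0.2, size=6) if include_strain else np.zeros(6)
        field_ = cls.from_coefficients(basis, A, strain)
        axes = [np.linspace(basis.box[0][ax], basis.box[1][ax], 21) for ax in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        peak = np.linalg.norm(field_.evaluate(grid), axis=1).max()
        scale = max_magnitude / peak if peak > 0 else 0.0
        return cls.from_coefficients(basis, A * scale, strain * scale)

    def evaluate(self, points: np.ndarray, warn_extrapolation: bool = False) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        if self._fn is not None:
            return np.asarray(self._fn(pts), float).reshape(pts.shape)
        return self._fit.evaluate(pts, warn_extrapolation=warn_extrapolation)

    def as_fit(self) -> DistortionFit:
        """The truth as a DistortionFit (polynomial representation only)."""
        if self._fit is None:
            raise MsemapError("closed-form truth field has no coefficient representation")
        return self._fit


def apparent_positions(field, true_points: np.ndarray, tol: float = 1e-9,
                       max_iter: int = 50) -> np.ndarray:
    """Solve ``a = t + d(a)`` per point: where a fiducial at ``t`` appears.

    ``d`` follows the apparent-coordinate convention (the displacement is
    parameterized at the location where the point appears in the image), so
    correcting points later is a single subtraction with no iteration.
    """
    t = np.atleast_2d(np.asarray(true_points, float))
    a = t + field.evaluate(t)
    for _ in range(max_iter):
        a_new = t + field.evaluate(a)
        step = np.abs(a_new - a).max()
        a = a_new
        if step < tol:
            return a
    raise ConvergenceError(
        f"apparent-position fixed point did not converge (last step {step:.2e} mm); "
        "the truth field gradient is too large"
    )


@dataclass
class SceneSpec:
    """Geometry and contrast of one synthetic acquisition.

    ``placement`` is the full phantom -> scanner rigid transform (including
    the table shift); ``table_shift`` is used to centre the imaging volume on
    the nominal phantom position, emulating a scan prescribed around the
    phantom at each table position.
    """

    design: PhantomDesign
    placement: RigidTransform = field(default_factory=RigidTransform.identity)
    table_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: np.ndarray = field(default_factory=lambda: np.array([1.5625, 1.5625, 1.0]))
    volume_shape: tuple[int, int, int] = (243, 192, 240)
    noise_model: str = "gaussian"
    noise_sd: float = 0.02
    background: float = 1.0
    sphere_level: float = 0.2
    origin: np.ndarray | None = None

    def __post_init__(self):
        self.table_shift = np.asarray(self.table_shift, float)
        self.voxel_size = np.asarray(self.voxel_size, float)
        if not self.sphere_level < self.background:
            raise MsemapError("spheres must be darker than the background")
        if self.noise_model not in {"none", "gaussian", "rician"}:
            raise MsemapError(f"unknown noise model {self.noise_model!r}")
        if self.origin is None:
            shape = np.asarray(self.volume_shape, float)
            self.origin = self.table_shift - self.voxel_size * (shape - 1) / 2.0
        self.origin = np.asarray(self.origin, float)

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxel_size)
        A[:3, 3] = self.origin
        return A


def render_scan(scene: SceneSpec, truth: TruthField, seed: int = 0,
                series_id: int = 0, is_center: bool = False
                ) -> tuple[ScanSeries, pd.DataFrame]:
    """Render one synthetic scan and return it with its truth fiducial table.

    Each sphere is drawn at its apparent position with subdivision-based
    partial-volume edge fractions; noise is then added per the scene's model.
    Deterministic for a fixed seed.  Fiducials whose apparent centre falls
    outside the volume are excluded from the truth table with a warning.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in scene.volume_shape)
    vol = np.full(shape, float(scene.background))
    true_pos = scene.placement.apply(scene.design.positions)
    app_pos = apparent_positions(truth, true_pos)
    vox = (app_pos - scene.origin) / scene.voxel_size

    rows = []
    excluded = 0
    for k, fid in enumerate(scene.design.fiducials):
        if np.any(vox[k] < 0) or np.any(vox[k] > np.asarray(shape) - 1):
            excluded += 1
            continue
        radius = fid.diameter / 2.0
        lo = np.maximum(np.floor(vox[k] - (radius + scene.voxel_size) / scene.voxel_size),
                        0).astype(int)
        hi = np.minimum(np.ceil(vox[k] + (radius + scene.voxel_size) / scene.voxel_size),
                        np.asarray(shape) - 1).astype(int)
        grids = np.stack(np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                                     indexing="ij"), axis=-1)
        centers = grids.reshape(-1, 3) * scene.voxel_size + scene.origin
        frac = sphere_voxel_fractions(centers, app_pos[k], radius, scene.voxel_size,
                                      OVERSAMPLE)
        block = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
        vol[block] -= (scene.background - scene.sphere_level) * frac.reshape(
            grids.shape[:3])
        rows.append({
            "series": series_id, "fiducial_id": fid.id,
            "x_true": true_pos[k, 0], "y_true": true_pos[k, 1], "z_true": true_pos[k, 2],
            "x_apparent": app_pos[k, 0], "y_apparent": app_pos[k, 1],
            "z_apparent": app_pos[k, 2],
        })
    if excluded:
        warnings.warn(f"{excluded} fiducial(s) fell outside the volume and were excluded",
                      stacklevel=2)

    if scene.noise_model == "gaussian" and scene.noise_sd > 0:
        vol = vol + rng.normal(0.0, scene.noise_sd * scene.background, size=shape)
    elif scene.noise_model == "rician" and scene.noise_sd > 0:
        sd = scene.noise_sd * scene.background
        vol = np.hypot(vol + rng.normal(0.0, sd, size=shape),
                       rng.normal(0.0, sd, size=shape))

    scan = ScanSeries(vol.astype(np.float32), scene.affine, series_id, is_center,
                      provenance={"synthetic": True, "seed": int(seed),
                                  "table_shift_mm": scene.table_shift.tolist()})
    return scan, pd.DataFrame(rows)


def render_session(
    design: PhantomDesign,
    truth: TruthField,
    table_shifts,
    placement_noise: tuple[float, float] = (0.3, 0.1),
    seed: int = 0,
    **scene_kwargs,
) -> tuple[list[ScanSeries], pd.DataFrame]:
    """Render one scan per table shift with a shared truth field.

    The first shift must be (0, 0, 0): it is the centre scan, nominally
    laser-aligned at isocenter.  Each scan's placement is its nominal shift
    composed with a small random rigid perturbation drawn within
    ``placement_noise`` = (max translation mm, max rotation degrees).
    """
    shifts = np.atleast_2d(np.asarray(table_shifts, float))
    if len(shifts) == 0:
        raise MsemapError("table_shifts must not be empty")
    if not np.allclose(shifts[0], 0.0):
        raise MsemapError("the first table shift must be (0, 0, 0): the centre scan")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(shifts))
    scans, tables = [], []
    for s, shift in enumerate(shifts):
        rng = np.random.default_rng(children[s])
        perturb = RigidTransform.random(rng, *placement_noise)
        placement = RigidTransform(perturb.rotation, perturb.translation + shift)
        scene = SceneSpec(design=design, placement=placement, table_shift=shift,
                          **scene_kwargs)
        scan_seed = int(children[s].generate_state(1)[0] % (2**31))
        scan, table = render_scan(scene, truth, seed=scan_seed, series_id=s,
                                  is_center=(s == 0))
        scans.append(scan)
        tables.append(table)
    return scans, pd.concat(tables, ignore_index=True)


@dataclass
class SimulatedObservations:
    """Fiducial-level simulation output: observations plus the truth that made them."""

    observations: list[DisplacementObservation]
    truth: TruthField
    placements: dict[int, RigidTransform]  # actual placement per series
    nominal: dict[int, RigidTransform]  # nominal (table-shift only) placement
    apparent: dict[int, np.ndarray]  # noise-free apparent positions per series


def simulate_observations(
    design: PhantomDesign,
    truth: TruthField,
    table_shifts,
    placement_noise: tuple[float, float] = (1.0, 0.3),
    localization_noise_sd: float = 0.0,
    seed: int = 0,
    small_angle: bool = True,
    designed_from: str = "nominal",
) -> SimulatedObservations:
    """Generate displacement observations directly at fiducial level.

    Per series the phantom gets a random rigid placement perturbation within
    ``placement_noise`` (max mm, max degrees).  With ``small_angle=True`` the
    perturbation displaces points by its linearization ``delta + eps x x``,
    matching the fit model exactly -- the construct-and-recover path; with
    ``False`` the exact rotation is applied, leaving the O(theta^2) remainder
    the model cannot represent.  ``designed_from`` selects how the 'designed'
    positions are computed: ``"nominal"`` uses the known table shift (the
    placement perturbation then shows up in the observations), while
    ``"landmarks"`` runs the landmark-Procrustes localization a real session
    would use.  Gaussian ``localization_noise_sd`` (mm, per axis) emulates
    segmentation error on the apparent positions.
    """
    shifts = np.atleast_2d(np.asarray(table_shifts, float))
    if len(shifts) == 0:
        raise MsemapError("table_shifts must not be empty")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(shifts))
    pos = design.positions
    ids = design.ids
    lm_mask = np.array([f.is_landmark for f in design.fiducials])

    observations: list[DisplacementObservation] = []
    placements, nominals, apparents = {}, {}, {}
    for s, shift in enumerate(shifts):
        rng = np.random.default_rng(children[s])
        perturb = RigidTransform.random(rng, *placement_noise)
        nominal = RigidTransform(np.eye(3), shift)
        nominals[s] = nominal
        base = pos + shift
        if small_angle:
            # Linearized rigid perturbation expressed, like the fit model, at
            # the apparent location: a = base + delta + eps x a + d(a).
            eps = perturb.rotvec()
            delta = perturb.translation

            class _Rigidized:
                def evaluate(self, pts):
                    return delta + np.cross(eps, pts) + truth.evaluate(pts)

            app = apparent_positions(_Rigidized(), base)
            placements[s] = RigidTransform.from_rotvec(eps, delta + shift)
        else:
            placement = RigidTransform(perturb.rotation, perturb.translation + shift)
            placements[s] = placement
            app = apparent_positions(truth, placement.apply(pos))
        apparents[s] = app
        segmented = app
        if localization_noise_sd > 0:
            segmented = app + rng.normal(0.0, localization_noise_sd, size=app.shape)
        if designed_from == "nominal":
            designed = nominal.apply(pos)
        elif designed_from == "landmarks":
            match = find_landmarks(segmented[lm_mask], design)
            placement_est = procrustes(match.designed_positions, match.detected_positions)
            designed = placement_est.apply(pos)
        else:
            raise ValueError(f"designed_from must be 'nominal' or 'landmarks', "
                             f"got {designed_from!r}")
        for k in range(len(pos)):
            observations.append(DisplacementObservation(
                fiducial_id=int(ids[k]), series=s,
                designed=designed[k], segmented=segmented[k]))
    return SimulatedObservations(observations, truth, placements, nominals, apparents)
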