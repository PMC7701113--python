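"""Phantom placement and displacement observations.

Placement of the phantom inside the scanner is established per scan from the
three enlarged landmark spheres: the detection triple whose pairwise-distance
triple best matches the designed landmark triangle identifies the landmarks
(the triangle is scalene, so the vertex correspondence is unique), and the
orthogonal Procrustes algorithm turns the three matched pairs into a rigid
transform phantom frame -> scanner frame.  Mapping every designed fiducial
through that transform and matching it to the nearest detection yields one
displacement observation d = segmented - designed per fiducial.

The landmark-based placement is only approximate -- the landmarks themselves
sit in a distorted image -- but the residual error is an almost-rigid motion
that the multi-scan fit absorbs into its per-series rigid terms, so it does
not propagate into the distortion estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .design import PhantomDesign, _triangle_sides
from .errors import AmbiguousLandmarksError, DegenerateGeometryError, LocalizationError

__all__ = [
    "RigidTransform",
    "DisplacementObservation",
    "LandmarkMatch",
    "AssignmentResult",
    "find_landmarks",
    "procrustes",
    "assign_correspondences",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an axis-angle rotation vector (radians) and a translation."""
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation_mm: float,
               max_angle_deg: float) -> "RigidTransform":
        """Random perturbation: uniform magnitudes up to the given bounds."""
        def _unit():
            v = rng.normal(size=3)
            n = np.linalg.norm(v)
            return v / n if n > 0 else np.array([1.0, 0.0, 0.0])

        t = _unit() * rng.uniform(0.0, max_translation_mm)
        angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
        return cls.from_rotvec(_unit() * angle, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()


@dataclass(frozen=True)
class DisplacementObservation:
    """One fiducial's displacement in one scan.

    ``designed`` is the design position mapped through the (approximate)
    placement transform; ``segmented`` is the sub-voxel detection, both in
    scanner mm.  ``d = segmented - designed`` by construction.
    """

    fiducial_id: int
    series: int
    designed: np.ndarray
    segmented: np.ndarray
    d: np.ndarray = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "designed", np.asarray(self.designed, float))
        object.__setattr__(self, "segmented", np.asarray(self.segmented, float))
        object.__setattr__(self, "d", self.segmented - self.designed)


@dataclass
class LandmarkMatch:
    """Result of landmark identification: design ids paired with detected positions."""

    design_ids: list[int]
    designed_positions: np.ndarray  # (3, 3) phantom frame
    detected_positions: np.ndarray  # (3, 3) scanner frame
    residual: float  # sum of absolute side-length differences, mm


def _detection_positions(detections) -> np.ndarray:
    """Accept a list of DetectedFiducial-like objects or a raw (n, 3) array."""
    arr = np.asarray(detections)
    if arr.dtype != object and arr.ndim == 2 and arr.shape[1] == 3:
        return arr.astype(float)
    return np.array([np.asarray(det.position, float) for det in detections])


def _detection_scores(detections, n: int) -> np.ndarray:
    try:
        return np.array([float(det.ncc_score) for det in detections])
    except (AttributeError, TypeError):
        return np.ones(n)


def find_landmarks(
    detections,
    design: PhantomDesign,
    tolerance: float = 3.0,
    ambiguity_margin: float = 1.0,
    max_candidates: int = 12,
) -> LandmarkMatch:
    """Identify the three landmark spheres among large-diameter detections.

    Every 3-subset of the ``max_candidates`` strongest detections is scored by
    the sum of absolute differences between its sorted pairwise distances and
    the designed landmark triangle's sorted sides.  Vertex correspondence is
    resolved by opposite-side ordering (valid because the triangle is scalene).

    Raises
    ------
    LocalizationError
        Fewer than three detections, or the best residual exceeds ``tolerance``.
    AmbiguousLandmarksError
        Two distinct triples score within ``ambiguity_margin`` of each other.
    """
    pos = _detection_positions(detections)
    if len(pos) < 3:
        raise LocalizationError(f"need >= 3 landmark-candidate detections, got {len(pos)}")
    scores = _detection_scores(detections, len(pos))
    # The enlarged landmarks outscore ordinary spheres decisively in the
    # large-template pass; preferring near-top scores avoids ambiguity with
    # grid triples that happen to be congruent to the landmark triangle.
    strong = np.flatnonzero(scores >= scores.max() - 0.15)
    if len(strong) >= 3:
        order = strong[np.argsort(-scores[strong], kind="stable")]
    else:
        order = np.argsort(-scores, kind="stable")
    candidates = order[:max_candidates]

    lms = design.landmarks
    des_pos = np.array([f.position for f in lms])
    des_sides = _triangle_sides(des_pos)
    des_sorted = np.sort(des_sides)

    best_triple, best_res, second_res = None, np.inf, np.inf
    for triple in itertools.combinations(candidates, 3):
        sides = _triangle_sides(pos[list(triple)])
        res = float(np.abs(np.sort(sides) - des_sorted).sum())
        if res < best_res:
            best_triple, best_res, second_res = triple, res, best_res
        elif res < second_res:
            second_res = res
    if best_res > tolerance:
        raise LocalizationError(
            f"no detection triple matches the landmark triangle: best residual "
            f"{best_res:.2f} mm exceeds tolerance {tolerance} mm"
        )
    if second_res - best_res < ambiguity_margin:
        raise AmbiguousLandmarksError(
            f"landmark identification ambiguous: two triples with residuals "
            f"{best_res:.2f} and {second_res:.2f} mm"
        )
    det_pts = pos[list(best_triple)]
    det_sides = _triangle_sides(det_pts)
    # vertex i is opposite side i; match by side-length rank
    order_des = np.argsort(des_sides)
    order_det = np.argsort(det_sides)
    designed = des_pos[order_des]
    detected = det_pts[order_det]
    ids = [lms[i].id for i in order_des]
    return LandmarkMatch(ids, designed, detected, best_res)


def procrustes(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst`` (no scaling).

    Solves ``min_R,t sum ||R @ src_i + t - dst_i||^2`` with ``det(R) = +1``
    enforced (Kabsch algorithm): even for reflected inputs the result is a
    proper rotation, at the cost of a nonzero residual.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3 or len(src) < 3:
        raise ValueError("src and dst must be matching (n>=3, 3) arrays")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - cs, dst - cd
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are (nearly) collinear")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, sign]) @ U.T
    return RigidTransform(R, cd - R @ cs)


@dataclass
class AssignmentResult:
    """Output of :func:`assign_correspondences`."""

    observations: list[DisplacementObservation]
    unmatched_designed: list[int]  # fiducial ids with no detection partner
    unmatched_detections: list[int]  # indices into the detection list


def assign_correspondences(
    transform: RigidTransform,
    design,
    detections,
    max_dist: float = 10.0,
    series: int = 0,
) -> AssignmentResult:
    """Match designed fiducials (mapped through ``transform``) to detections.

    Matching is mutual-nearest-neighbour within ``max_dist`` mm: a pair is
    accepted only when each member is the other's nearest neighbour, which
    makes the result one-to-one and independent of list order.  ``design`` may
    be a :class:`~msemap.design.PhantomDesign` or an ``(ids, positions)`` pair.

    Raises
    ------
    LocalizationError
        If fewer than half the designed fiducials are matched (the placement
        transform is then likely wrong).
    """
    if isinstance(design, PhantomDesign):
        ids, pos_design = design.ids, design.positions
    else:
        ids, pos_design = design
        ids = np.asarray(ids, int)
        pos_design = np.asarray(pos_design, float)
    designed_world = transform.apply(pos_design)
    det_pos = _detection_positions(detections)
    if len(det_pos) == 0:
        raise LocalizationError("no detections to assign")

    tree_det = cKDTree(det_pos)
    tree_des = cKDTree(designed_world)
    d_to_det, nearest_det = tree_det.query(designed_world)
    _, nearest_des = tree_des.query(det_pos)

    observations: list[DisplacementObservation] = []
    matched_det: set[int] = set()
    unmatched_designed: list[int] = []
    for k in range(len(designed_world)):
        j = int(nearest_det[k])
        if d_to_det[k] <= max_dist and int(nearest_des[j]) == k:
            observations.append(
                DisplacementObservation(
                    fiducial_id=int(ids[k]),
                    series=series,
                    designed=designed_world[k],
                    segmented=det_pos[j],
                )
            )
            matched_det.add(j)
        else:
            unmatched_designed.append(int(ids[k]))
    unmatched_detections = [j for j in range(len(det_pos)) if j not in matched_det]
    if len(observations) < 0.5 * len(designed_world):
        raise LocalizationError(
            f"only {len(observations)}/{len(designed_world)} designed fiducials matched; "
            "phantom placement is likely wrong"
        )
    return AssignmentResult(observations, unmatched_designed, unmatched_detections)
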