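"""Phantom fiducial layouts.

A distortion phantom carries several hundred dark plastic spheres ("fiducials")
at known positions in the phantom's own right-handed mm coordinate frame.
Three spheres of enlarged diameter sit near the phantom centre at the vertices
of a scalene triangle; their pairwise distances are pairwise distinct so that
they can be identified uniquely in any scan and used to establish the rigid
placement of the phantom inside the scanner.

This module defines the in-memory design types, JSON/CSV readers and writers,
and generators for synthetic designs, including a default layout that emulates
a commercial 505-sphere phantom (1 / 1.5 cm spheres at 3-4 cm spacing inside a
roughly 35 x 27 x 20 cm envelope).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, DesignParseError

__all__ = [
    "FiducialSpec",
    "PhantomDesign",
    "load_design",
    "save_design",
    "generate_synthetic_design",
    "default_phantom_design",
    "design_extent",
]

#: pairwise landmark distances must differ from each other by at least this (mm)
SCALENE_MARGIN_MM = 5.0


@dataclass(frozen=True)
class FiducialSpec:
    """One fiducial sphere in the phantom frame.

    Parameters
    ----------
    id : int
        Unique integer label within a design.
    position : ndarray, shape (3,)
        Sphere centre in mm, phantom coordinate frame.
    diameter : float
        Sphere diameter in mm; must be positive.
    is_landmark : bool
        Whether this sphere is one of the three enlarged landmark spheres.
    """

    id: int
    position: np.ndarray
    diameter: float
    is_landmark: bool = False

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise DesignError(f"fiducial {self.id}: position must be a 3-vector")
        if not self.diameter > 0:
            raise DesignError(f"fiducial {self.id}: diameter must be positive")


@dataclass
class PhantomDesign:
    """A full phantom layout: fiducials plus a note on the coordinate convention.

    Invariants (checked by :meth:`validate`): unique ids, exactly three
    landmarks whose triangle is scalene by :data:`SCALENE_MARGIN_MM`, and a
    minimum inter-fiducial distance larger than the largest sphere diameter.
    """

    fiducials: list[FiducialSpec]
    frame_note: str = "arbitrary right-handed mm frame centred on the phantom"

    _validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        if self._validate:
            self.validate()

    # -- array views ------------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return np.array([f.id for f in self.fiducials], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.fiducials], dtype=float)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([f.diameter for f in self.fiducials], dtype=float)

    @property
    def landmarks(self) -> list[FiducialSpec]:
        return [f for f in self.fiducials if f.is_landmark]

    def __len__(self) -> int:
        return len(self.fiducials)

    # -- invariants -------------------------------------------------------
    def validate(self, scalene_margin: float = SCALENE_MARGIN_MM) -> None:
        ids = self.ids
        if len(np.unique(ids)) != len(ids):
            dup = ids[pd.Series(ids).duplicated()][0]
            raise DesignError(f"duplicate fiducial id {dup}")
        lms = self.landmarks
        if len(lms) != 3:
            raise DesignError(f"design must have exactly 3 landmarks, found {len(lms)}")
        sides = _triangle_sides(np.array([f.position for f in lms]))
        diffs = np.abs(np.subtract.outer(sides, sides))[np.triu_indices(3, 1)]
        if np.any(diffs < scalene_margin):
            raise DesignError(
                "landmark triangle is not scalene by the required margin: "
                f"sides {np.round(sides, 2)} mm, margin {scalene_margin} mm"
            )
        if len(self.fiducials) >= 2:
            pos = self.positions
            from scipy.spatial.distance import pdist

            dmin = pdist(pos).min()
            if dmin <= self.diameters.max():
                raise DesignError(
                    f"fiducials overlap: minimum spacing {dmin:.2f} mm does not "
                    f"exceed the largest diameter {self.diameters.max():.2f} mm"
                )


def _triangle_sides(points: np.ndarray) -> np.ndarray:
    """Pairwise distances (p1p2, p0p2, p0p1): entry i is the side opposite vertex i."""
    return np.array(
        [
            np.linalg.norm(points[1] - points[2]),
            np.linalg.norm(points[0] - points[2]),
            np.linalg.norm(points[0] - points[1]),
        ]
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "x", "y", "z", "diameter", "is_landmark"]


def load_design(path: str | Path) -> PhantomDesign:
    """Load a phantom design from a JSON or CSV file (positions in mm).

    JSON layout: ``{"frame_note": str, "fiducials": [{"id", "position",
    "diameter", "is_landmark"}, ...]}``.  CSV columns:
    ``id,x,y,z,diameter,is_landmark``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise DesignParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
        try:
            fiducials = [
                FiducialSpec(
                    id=int(f["id"]),
                    position=np.asarray(f["position"], dtype=float),
                    diameter=float(f["diameter"]),
                    is_landmark=bool(f.get("is_landmark", False)),
                )
                for f in payload["fiducials"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise DesignParseError(f"{path}: malformed fiducial record: {exc}") from exc
        return PhantomDesign(fiducials, payload.get("frame_note", ""))
    # CSV
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise DesignParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DesignParseError(f"{path}: line 1: missing columns {missing}")
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        if not np.all(np.isfinite([row.x, row.y, row.z, row.diameter])):
            raise DesignParseError(f"{path}: line {row_no}: non-finite value")
    fiducials = [
        FiducialSpec(
            id=int(r.id),
            position=np.array([r.x, r.y, r.z], dtype=float),
            diameter=float(r.diameter),
            is_landmark=bool(r.is_landmark),
        )
        for r in frame.itertuples(index=False)
    ]
    return PhantomDesign(fiducials)


def save_design(design: PhantomDesign, path: str | Path) -> None:
    """Write a design to JSON or CSV depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "frame_note": design.frame_note,
            "fiducials": [
                {
                    "id": int(f.id),
                    "position": [float(v) for v in f.position],
                    "diameter": float(f.diameter),
                    "is_landmark": bool(f.is_landmark),
                }
                for f in design.fiducials
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        frame = pd.DataFrame(
            {
                "id": design.ids,
                "x": design.positions[:, 0],
                "y": design.positions[:, 1],
                "z": design.positions[:, 2],
                "diameter": design.diameters,
                "is_landmark": [f.is_landmark for f in design.fiducials],
            }
        )
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic designs
# ---------------------------------------------------------------------------


def _clipped_jitter(
    rng: np.random.Generator,
    n: int,
    jitter_sd: float,
    min_spacing: float,
    max_diameter: float,
) -> np.ndarray:
    """Gaussian positional jitter, re-drawn with clipping if it could cause overlap."""
    jitter = rng.normal(0.0, jitter_sd, size=(n, 3)) if jitter_sd > 0 else np.zeros((n, 3))
    # Componentwise clip guaranteeing min pairwise spacing stays above the
    # largest diameter: each centre moves by at most clip*sqrt(3).
    clip = 0.9 * (min_spacing - max_diameter) / (2.0 * np.sqrt(3.0))
    if clip <= 0:
        raise DesignError("grid spacing too small for the requested sphere diameters")
    if np.any(np.abs(jitter) > clip):
        warnings.warn(
            f"jitter sd {jitter_sd} mm risks overlapping spheres; clipping jitter to "
            f"+/-{clip:.2f} mm per axis",
            stacklevel=3,
        )
        jitter = np.clip(jitter, -clip, clip)
    return jitter


def _promote_landmarks(
    positions: np.ndarray,
    landmark_diameter: float,
    n_candidates: int = 10,
    margin: float = SCALENE_MARGIN_MM,
) -> tuple[int, int, int]:
    """Pick the near-central triple with the most scalene triangle.

    Returns indices of the three fiducials to promote.  Raises if no triple
    among the ``n_candidates`` centre-most fiducials is scalene by ``margin``.
    """
    centroid = positions.mean(axis=0)
    order = np.argsort(np.linalg.norm(positions - centroid, axis=1), kind="stable")
    candidates = order[: max(3, n_candidates)]
    best, best_score = None, -np.inf
    for triple in itertools.combinations(candidates, 3):
        sides = _triangle_sides(positions[list(triple)])
        diffs = np.abs(np.subtract.outer(sides, sides))[np.triu_indices(3, 1)]
        score = diffs.min()
        if score > best_score:
            best, best_score = triple, score
    if best is None or best_score < margin:
        raise DesignError(
            f"no scalene landmark triple (margin {margin} mm) among central fiducials"
        )
    return best


def generate_synthetic_design(
    grid_counts: tuple[int, int, int],
    spacing: tuple[float, float, float],
    jitter_sd: float = 0.0,
    seed: int = 0,
    diameter: float = 10.0,
    landmark_diameter: float = 15.0,
) -> PhantomDesign:
    """Generate an approximately gridded design with Gaussian positional jitter.

    The grid is centred on the origin.  Three near-central fiducials are
    promoted to landmarks with enlarged diameter, choosing the triple whose
    triangle is most scalene.  Deterministic for a fixed seed.
    """
    counts = np.asarray(grid_counts, dtype=int)
    spacing = np.asarray(spacing, dtype=float)
    if np.any(counts < 2):
        raise DesignError("grid_counts must be >= 2 along every axis")
    if jitter_sd < 0:
        raise DesignError("jitter_sd must be >= 0")
    axes = [(np.arange(c) - (c - 1) / 2.0) * s for c, s in zip(counts, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    grid = grid + _clipped_jitter(rng, len(grid), jitter_sd, spacing.min(), landmark_diameter)
    lm = _promote_landmarks(grid, landmark_diameter)
    fiducials = [
        FiducialSpec(
            id=i,
            position=grid[i],
            diameter=landmark_diameter if i in lm else diameter,
            is_landmark=i in lm,
        )
        for i in range(len(grid))
    ]
    return PhantomDesign(fiducials)


def default_phantom_design(seed: int = 0, n_fiducials: int = 505) -> PhantomDesign:
    """Default 505-sphere layout emulating a compact commercial distortion phantom.

    An 11 x 9 x 7 grid at (35, 33.75, 33.33) mm spacing (fiducial extent
    350 x 270 x 200 mm) is jittered by ~1 mm so the spheres do not sit on an
    exact lattice, then thinned to ``n_fiducials`` by keeping the centre-most
    spheres in axis-normalized coordinates, which rounds off the corners the
    way a phantom housing does while preserving the per-axis extent.  Three
    central spheres are promoted to 15 mm landmarks; the rest are 10 mm.
    """
    counts = np.array([11, 9, 7])
    spacing = np.array([35.0, 270.0 / 8.0, 200.0 / 6.0])
    axes = [(np.arange(c) - (c - 1) / 2.0) * s for c, s in zip(counts, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    grid = grid + _clipped_jitter(rng, len(grid), 1.0, spacing.min(), 15.0)
    if n_fiducials > len(grid):
        raise DesignError(f"cannot draw {n_fiducials} fiducials from a {len(grid)}-point grid")
    # Keep centre-most points in normalized coordinates; stable tie-break by index.
    half_extent = (counts - 1) / 2.0 * spacing
    radius = np.linalg.norm(grid / half_extent, axis=1)
    keep = np.sort(np.argsort(radius, kind="stable")[:n_fiducials])
    pos = grid[keep]
    lm = _promote_landmarks(pos, 15.0)
    fiducials = [
        FiducialSpec(
            id=i,
            position=pos[i],
            diameter=15.0 if i in lm else 10.0,
            is_landmark=i in lm,
        )
        for i in range(len(pos))
    ]
    return PhantomDesign(fiducials)


def design_extent(design: PhantomDesign | np.ndarray) -> np.ndarray:
    """Per-axis extent (max - min, mm) of the fiducial centres.

    Accepts a :class:`PhantomDesign` or a raw ``(n, 3)`` position array (for
    example the union of a design with shifted copies of itself).
    """
    pos = design.positions if isinstance(design, PhantomDesign) else np.asarray(design, float)
    if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) < 2:
        raise DesignError("need at least two 3-D fiducial positions")
    return pos.max(axis=0) - pos.min(axis=0)
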