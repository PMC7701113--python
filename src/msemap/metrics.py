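"""Applying a fitted distortion field and computing validation statistics.

The displacement field follows the apparent-coordinate convention: ``d(x)``
is the displacement of the point that *appears* at image location ``x``, so
correcting a point is the single subtraction ``corrected = x - d(x)``.
Correcting an image is the inverse problem -- the output voxel at true
location ``y`` must sample the input at the apparent location ``x`` solving
``x - d(x) = y`` -- handled by a short fixed-point iteration, valid because
distortion gradients are small (|grad d| << 1).

Validation statistics mirror common distortion-QA reporting: boxplot
summaries of displacement magnitude per radial-distance bin from the
isocenter, and rigid-invariant inter-sphere distance comparisons between two
matched fiducial sets (all n(n+1)/2 - n pairwise distances), which need no
assumption about absolute phantom position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import pdist

from .errors import ConvergenceError, MsemapError
from .io import ScanSeries

__all__ = [
    "correct_points",
    "correct_image",
    "RadialProfile",
    "radial_profile",
    "DistanceValidation",
    "intersphere_validation",
]


def correct_points(points: np.ndarray, fit, return_mask: bool = False):
    """Remove the fitted distortion from apparent-coordinate ``points``.

    ``corrected = apparent - d(apparent)``.  Points outside the basis box are
    still corrected (polynomial extrapolation) but flagged in the optional
    mask.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    corrected = pts - fit.evaluate(pts, warn_extrapolation=False)
    if return_mask:
        basis = getattr(fit, "basis", None)
        extrapolated = (~basis.contains(pts)) if basis is not None else np.zeros(
            len(pts), bool)
        return corrected, extrapolated
    return corrected


def _field_on_scan_grid(scan: ScanSeries, fit) -> np.ndarray:
    """Displacement (nx, ny, nz, 3) evaluated at every voxel centre."""
    A = scan.affine
    offdiag = A[:3, :3] - np.diag(np.diag(A[:3, :3]))
    axes = [np.arange(n) for n in scan.shape]
    if np.abs(offdiag).max() < 1e-12 and hasattr(fit, "evaluate_on_grid"):
        xs, ys, zs = (axes[i] * A[i, i] + A[i, 3] for i in range(3))
        return fit.evaluate_on_grid(xs, ys, zs)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    world = scan.voxel_to_world(grid)
    return fit.evaluate(world, warn_extrapolation=False).reshape(*scan.shape, 3)


def correct_image(
    scan: ScanSeries,
    fit,
    max_iter: int = 10,
    tol: float = 0.01,
    fill: float = 0.0,
) -> tuple[ScanSeries, np.ndarray]:
    """Resample a scan onto its distortion-corrected geometry.

    For every output voxel at true world location ``y`` the apparent source
    location is found by the fixed point ``x_{k+1} = y + d(x_k)`` starting
    from ``x_0 = y + d(y)`` (converges when ``|grad d| < 1``; ``tol`` in mm),
    then the input is sampled there by trilinear interpolation.  Out-of-volume
    samples receive ``fill`` and are cleared in the returned validity mask.
    """
    D = _field_on_scan_grid(scan, fit)
    inv = np.linalg.inv(scan.affine)
    shape = scan.shape

    def _sample_field(world_pts: np.ndarray) -> np.ndarray:
        vox = world_pts @ inv[:3, :3].T + inv[:3, 3]
        coords = [vox[:, i] for i in range(3)]
        return np.stack(
            [map_coordinates(D[..., i], coords, order=1, mode="nearest")
             for i in range(3)], axis=1)

    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                    axis=-1).reshape(-1, 3)
    y_world = scan.voxel_to_world(grid)
    x = y_world + D.reshape(-1, 3)
    prev_step = np.inf
    for it in range(max_iter):
        x_new = y_world + _sample_field(x)
        step = np.linalg.norm(x_new - x, axis=1)
        x = x_new
        max_step = float(step.max())
        if max_step < tol:
            break
        if max_step > prev_step * 1.5 and it >= 2:
            worst = y_world[int(np.argmax(step))]
            raise ConvergenceError(
                f"inverse-displacement fixed point diverges near world location "
                f"{np.round(worst, 1)} mm (|grad d| approaching 1)"
            )
        prev_step = max_step

    vox = x @ inv[:3, :3].T + inv[:3, 3]
    coords = [vox[:, i] for i in range(3)]
    corrected = map_coordinates(np.asarray(scan.voxels, float), coords, order=1,
                                mode="constant", cval=fill).reshape(shape)
    inside = np.ones(len(vox), bool)
    for i, n in enumerate(shape):
        inside &= (vox[:, i] >= 0) & (vox[:, i] <= n - 1)
    mask = inside.reshape(shape)
    out = ScanSeries(
        corrected.astype(scan.voxels.dtype), scan.affine.copy(), scan.series_id,
        scan.is_center,
        provenance={**scan.provenance, "distortion_corrected": True},
    )
    return out, mask


@dataclass
class RadialProfile:
    """Boxplot statistics of displacement magnitude per radial-distance bin.

    Whiskers follow the Tukey convention (Q3 + 1.5 IQR / Q1 - 1.5 IQR,
    clipped to the data range); points beyond them are outliers.  Quartiles
    use linear interpolation between order statistics.  Empty bins are
    reported with count 0 and NaN statistics, never dropped.
    """

    bin_edges: np.ndarray
    count: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    outliers: list[np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_lo_mm": self.bin_edges[:-1],
            "r_hi_mm": self.bin_edges[1:],
            "count": self.count,
            "median_mm": self.median,
            "q1_mm": self.q1,
            "q3_mm": self.q3,
            "whisker_lo_mm": self.whisker_lo,
            "whisker_hi_mm": self.whisker_hi,
            "n_outliers": [len(o) for o in self.outliers],
        })


def radial_profile(
    positions: np.ndarray,
    displacements: np.ndarray,
    isocenter=(0.0, 0.0, 0.0),
    bin_width: float = 20.0,
) -> RadialProfile:
    """Bin displacement magnitudes by radial distance from the isocenter."""
    pos = np.atleast_2d(np.asarray(positions, float))
    disp = np.atleast_2d(np.asarray(displacements, float))
    if len(pos) == 0:
        raise MsemapError("radial_profile needs at least one point")
    if disp.shape != pos.shape:
        raise MsemapError("positions and displacements must have matching shapes")
    r = np.linalg.norm(pos - np.asarray(isocenter, float), axis=1)
    mag = np.linalg.norm(disp, axis=1)
    n_bins = int(np.ceil(max(r.max(), bin_width) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((r // bin_width).astype(int), n_bins - 1)
    count = np.zeros(n_bins, int)
    med = np.full(n_bins, np.nan)
    q1 = np.full(n_bins, np.nan)
    q3 = np.full(n_bins, np.nan)
    wlo = np.full(n_bins, np.nan)
    whi = np.full(n_bins, np.nan)
    outliers: list[np.ndarray] = []
    for b in range(n_bins):
        vals = np.sort(mag[idx == b])
        count[b] = len(vals)
        if len(vals) == 0:
            outliers.append(np.empty(0))
            continue
        q1[b], med[b], q3[b] = np.percentile(vals, [25, 50, 75])
        iqr = q3[b] - q1[b]
        lo_fence, hi_fence = q1[b] - 1.5 * iqr, q3[b] + 1.5 * iqr
        in_fence = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        wlo[b] = in_fence.min() if len(in_fence) else q1[b]
        whi[b] = in_fence.max() if len(in_fence) else q3[b]
        outliers.append(vals[(vals < lo_fence) | (vals > hi_fence)])
    return RadialProfile(edges, count, med, q1, q3, wlo, whi, outliers)


@dataclass
class DistanceValidation:
    """Comparison of all pairwise inter-sphere distances between two sets."""

    n: int
    pair_count: int
    mean_abs_diff: float
    max_abs_diff: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pair_count": self.pair_count,
            "mean_abs_diff_mm": self.mean_abs_diff,
            "max_abs_diff_mm": self.max_abs_diff,
        }


def _as_id_positions(obj, ids):
    if isinstance(obj, dict):
        keys = sorted(obj)
        return np.asarray(keys), np.array([obj[k] for k in keys], float)
    arr = np.atleast_2d(np.asarray(obj, float))
    if ids is None:
        ids = np.arange(len(arr))
    return np.asarray(ids), arr


def intersphere_validation(positions_a, positions_b, ids_a=None, ids_b=None,
                           bins: int = 20) -> DistanceValidation:
    """Compare all inter-sphere distances between two matched fiducial sets.

    Both sets must cover the same fiducial ids (dicts keyed by id, or arrays
    with optional id vectors).  The statistic is invariant under independent
    rigid motions of either set, which is exactly why it needs no phantom
    pose: only relative geometry enters.
    """
    ids_a, pos_a = _as_id_positions(positions_a, ids_a)
    ids_b, pos_b = _as_id_positions(positions_b, ids_b)
    if len(ids_a) != len(ids_b) or not np.array_equal(np.sort(ids_a), np.sort(ids_b)):
        raise MsemapError("fiducial id sets differ between the two position sets")
    pos_a = pos_a[np.argsort(ids_a, kind="stable")]
    pos_b = pos_b[np.argsort(ids_b, kind="stable")]
    n = len(pos_a)
    if n < 2:
        raise MsemapError("need at least two fiducials")
    diffs = np.abs(pdist(pos_a) - pdist(pos_b))
    counts, edges = np.histogram(diffs, bins=bins)
    return DistanceValidation(
        n=n,
        pair_count=n * (n + 1) // 2 - n,
        mean_abs_diff=float(diffs.mean()),
        max_abs_diff=float(diffs.max()),
        histogram_counts=counts,
        histogram_edges=edges,
    )
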