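"""Multi-scan displacement-field fit.

The displacement observed at apparent location x in series s is modelled as

    d(x) = sum_j delta_{s,j} T_j  +  sum_j eps_{s,j} R_j(x)  +  sum'_{mnpi} A_mnpi Phi_mnpi(x)

where T_j are the three unit translations, R_j(x) = e_j x x are the three
linearized rotations about the scanner origin (R_x = (0,-z,y) etc., physical
mm, so eps is a true angle in radians), and Phi_mnpi are tensor products of
Chebyshev polynomials of the second kind U_m(x~)U_n(y~)U_p(z~) over
box-normalized coordinates, assigned to displacement component i.  The prime
marks the exclusion of the six rigid basis functions from the distortion
block: the constant terms are the translations, and the nine linear tensor
terms are reparameterized into 3 rotations (excluded) + 6 symmetric strain
terms (retained, built directly in physical mm so they contain no constant
part).  The rigid blocks carry the per-scan phantom placement error and are
supported only on the rows of their own series; the distortion block is
shared by all series because it is a property of the scanner.

After the joint fit the per-series rigid parameters are discarded (except for
the centre series, whose (delta, eps) measure the misalignment between the
laser alignment system and the scanner coordinate frame) and the distortion
block alone is the scanner's distortion field.  A consequence of this
parameterization is a gauge freedom: a globally rigid component of the true
field is indistinguishable from phantom placement and is not recoverable.

Tikhonov regularization with diagonal order weights w_mnp = 1 + (m+n+p)^2
controls the effective order of the over-complete basis; the penalty is never
applied to the rigid blocks.  The default weight is chosen by generalized
cross-validation (GCV) over a logarithmic grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import eval_chebyu

from .errors import FitRankError
from .localization import DisplacementObservation, RigidTransform

__all__ = [
    "BasisSpec",
    "MultiScanSystem",
    "DistortionFit",
    "select_orders",
    "build_design_matrix",
    "fit_multiscan",
    "evaluate_field",
    "laser_misalignment",
]

#: symmetric strain generators: d(x) = E @ x, retained in the distortion block
STRAIN_MATRICES = [
    np.diag([1.0, 0.0, 0.0]),
    np.diag([0.0, 1.0, 0.0]),
    np.diag([0.0, 0.0, 1.0]),
    np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
    np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
    np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]),
]
STRAIN_NAMES = ["xx", "yy", "zz", "xy", "xz", "yz"]

#: antisymmetric rotation generators: R_j(x) = G_j @ x = e_j cross x (excluded)
ROTATION_GENERATORS = [
    np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]),
    np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
    np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
]


@dataclass(frozen=True)
class BasisSpec:
    """Tensor Chebyshev-U basis specification.

    Parameters
    ----------
    orders : (M, N, P)
        Maximum per-axis polynomial orders.
    sum_cap : int
        Upper limit on m + n + p; must be >= max(M, N, P).
    box : ndarray, shape (2, 3)
        Per-axis (min, max) in mm mapping world coordinates to [-1, 1].
    """

    orders: tuple[int, int, int]
    sum_cap: int
    box: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "orders", tuple(int(o) for o in self.orders))
        box = np.asarray(self.box, dtype=float)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "sum_cap", int(self.sum_cap))
        if box.shape != (2, 3) or np.any(box[1] <= box[0]):
            raise ValueError("box must be (2, 3) with positive extent per axis")
        if self.sum_cap < max(self.orders):
            raise ValueError("sum_cap must be >= max per-axis order")

    def normalize(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return 2.0 * (pts - self.box[0]) / (self.box[1] - self.box[0]) - 1.0

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(points, float)
        return np.all((pts >= self.box[0] - atol) & (pts <= self.box[1] + atol), axis=-1)

    @property
    def tensor_terms(self) -> list[tuple[int, int, int]]:
        """Retained tensor exponents: 2 <= m+n+p <= sum_cap within per-axis caps.

        Terms with m+n+p <= 1 are the rigid/linear subspace handled separately
        (translations and rotations excluded, symmetric strain kept as six
        physical-mm terms).
        """
        M, N, P = self.orders
        return [
            (m, n, p)
            for m in range(M + 1)
            for n in range(N + 1)
            for p in range(P + 1)
            if 2 <= m + n + p <= self.sum_cap
        ]

    def tensor_block(self, points: np.ndarray) -> np.ndarray:
        """Evaluate all retained tensor terms at ``points``: (n_points, n_terms)."""
        xn = self.normalize(points)
        M, N, P = self.orders
        Ux = eval_chebyu(np.arange(M + 1)[None, :], xn[:, 0:1])
        Uy = eval_chebyu(np.arange(N + 1)[None, :], xn[:, 1:2])
        Uz = eval_chebyu(np.arange(P + 1)[None, :], xn[:, 2:3])
        terms = self.tensor_terms
        B = np.empty((len(xn), len(terms)))
        for c, (m, n, p) in enumerate(terms):
            B[:, c] = Ux[:, m] * Uy[:, n] * Uz[:, p]
        return B


def _cluster_count(values: np.ndarray) -> int:
    """Number of well-separated 1-D clusters (grid planes) in ``values``.

    Sorted gaps are split into 'between-plane' and 'within-plane' groups at
    the largest multiplicative jump; robust for grid-like data where the two
    scales are separated by an order of magnitude.
    """
    vals = np.sort(np.asarray(values, float))
    if len(vals) < 2:
        return 1
    span = vals[-1] - vals[0]
    if span < 1e-9:
        return 1
    gaps = np.diff(vals)
    gmax = gaps.max()
    big = gaps > 0.5 * gmax
    small = gaps[~big]
    # Demand a clear scale separation between plane spacing and in-plane
    # scatter; otherwise the data has no plane structure along this axis.
    if small.size and small.max() > 0 and gaps[big].min() < 3.0 * small.max():
        return 1
    return int(big.sum()) + 1


def _obs_arrays(observations: list[DisplacementObservation]):
    pos = np.array([o.segmented for o in observations])
    d = np.array([o.d for o in observations])
    series = np.array([o.series for o in observations], dtype=int)
    return pos, d, series


def select_orders(
    observations: list[DisplacementObservation],
    center_series: int = 0,
    box_margin: float = 0.05,
) -> BasisSpec:
    """Choose per-axis orders and the normalization box from the observations.

    The per-axis order is the number of distinct fiducial planes along that
    axis in the centre series; the cap on m+n+p is ``floor(1.5 * max_order)``.
    The box is the bounding box of all observations across series, expanded by
    ``box_margin`` (fraction of the extent) per side.
    """
    if not observations:
        raise ValueError("need at least one observation")
    pos, _, series = _obs_arrays(observations)
    center = pos[series == center_series]
    if len(center) == 0:
        raise ValueError(f"no observations in centre series {center_series}")
    orders = tuple(_cluster_count(center[:, ax]) for ax in range(3))
    sum_cap = int(np.floor(1.5 * max(orders)))
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    extent = np.maximum(hi - lo, 1e-6)
    box = np.stack([lo - box_margin * extent, hi + box_margin * extent])
    return BasisSpec(orders, sum_cap, box)


@dataclass
class MultiScanSystem:
    """Assembled linear system for the joint multi-scan fit.

    Rows are ordered observation-major: row 3k+i is component i of observation
    k.  Columns: tensor terms grouped by component, then the six strain terms,
    then per-series (T_1..T_3, R_1..R_3) blocks in ascending series order.
    """

    X: np.ndarray
    y: np.ndarray
    basis: BasisSpec
    weights: np.ndarray  # Tikhonov order weights per column; 0 marks rigid columns
    series_ids: list[int]
    n_obs: int
    positions: np.ndarray  # (n_obs, 3) apparent locations
    series: np.ndarray  # (n_obs,)

    @property
    def rigid_mask(self) -> np.ndarray:
        return self.weights == 0


def build_design_matrix(
    observations: list[DisplacementObservation], basis: BasisSpec
) -> MultiScanSystem:
    """Assemble the design matrix of the multi-scan model.

    The distortion block (shared by all series) holds the tensor Chebyshev
    terms and the six symmetric strain terms; each series gets six rigid
    columns supported only on its own rows.
    """
    pos, d, series = _obs_arrays(observations)
    if not np.all(basis.contains(pos)):
        bad = np.flatnonzero(~basis.contains(pos))[0]
        raise ValueError(f"observation at {np.round(pos[bad], 1)} lies outside the basis box")
    n = len(pos)
    terms = basis.tensor_terms
    nt = len(terms)
    series_ids = sorted(int(s) for s in np.unique(series))
    ncols = 3 * nt + 6 + 6 * len(series_ids)
    X = np.zeros((3 * n, ncols))
    B = basis.tensor_block(pos)
    for i in range(3):
        X[i::3, i * nt:(i + 1) * nt] = B
    weights = np.zeros(ncols)
    sums = np.array([m + n_ + p for (m, n_, p) in terms], dtype=float)
    for i in range(3):
        weights[i * nt:(i + 1) * nt] = 1.0 + sums**2
    for k, E in enumerate(STRAIN_MATRICES):
        X[:, 3 * nt + k] = (pos @ E.T).ravel()
        weights[3 * nt + k] = 2.0  # strain is an order-1 distortion term
    base = 3 * nt + 6
    for s_idx, s in enumerate(series_ids):
        rows_k = np.flatnonzero(series == s)
        for j in range(3):
            X[rows_k * 3 + j, base + 6 * s_idx + j] = 1.0
        for j, G in enumerate(ROTATION_GENERATORS):
            vals = pos[rows_k] @ G.T
            rr = (rows_k[:, None] * 3 + np.arange(3)[None, :]).ravel()
            X[rr, base + 6 * s_idx + 3 + j] = vals.ravel()
    return MultiScanSystem(
        X=X, y=d.ravel(), basis=basis, weights=weights,
        series_ids=series_ids, n_obs=n, positions=pos, series=series,
    )


@dataclass
class DistortionFit:
    """Fitted distortion field plus per-series rigid parameters.

    ``A`` holds the tensor coefficients (mm) aligned with
    ``basis.tensor_terms`` x component; ``strain`` the six dimensionless
    symmetric-strain coefficients; ``rigid`` maps series id to
    ``(delta [mm], eps [rad])``.  Evaluating the fit uses the distortion block
    only -- the rigid terms encode phantom placement, not distortion.
    """

    basis: BasisSpec
    A: np.ndarray  # (n_terms, 3)
    strain: np.ndarray  # (6,)
    rigid: dict[int, tuple[np.ndarray, np.ndarray]]
    center_series: int
    lam: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.center_series not in self.rigid and self.rigid:
            raise ValueError(f"centre series {self.center_series} absent from rigid blocks")

    def evaluate(self, points: np.ndarray, warn_extrapolation: bool = False) -> np.ndarray:
        """Distortion displacement (mm) at world ``points``; rigid terms excluded."""
        pts = np.atleast_2d(np.asarray(points, float))
        if warn_extrapolation and not np.all(self.basis.contains(pts)):
            n_out = int((~self.basis.contains(pts)).sum())
            warnings.warn(f"{n_out} point(s) outside the basis box: extrapolating",
                          stacklevel=2)
        Msym = np.tensordot(self.strain, np.array(STRAIN_MATRICES), axes=(0, 0))
        out = pts @ Msym.T
        if len(self.basis.tensor_terms):
            out = out + self.basis.tensor_block(pts) @ self.A
        return out

    def evaluate_on_grid(self, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
        """Separable evaluation on an axis-aligned grid: (nx, ny, nz, 3)."""
        M, N, P = self.basis.orders
        lo, hi = self.basis.box
        def _u(vals, order, ax):
            t = 2.0 * (np.asarray(vals, float) - lo[ax]) / (hi[ax] - lo[ax]) - 1.0
            return eval_chebyu(np.arange(order + 1)[None, :], t[:, None])
        Ux, Uy, Uz = _u(xs, M, 0), _u(ys, N, 1), _u(zs, P, 2)
        C = np.zeros((M + 1, N + 1, P + 1, 3))
        for c, (m, n, p) in enumerate(self.basis.tensor_terms):
            C[m, n, p, :] = self.A[c]
        tmp = np.einsum("xm,mnpi->xnpi", Ux, C)
        tmp = np.einsum("yn,xnpi->xypi", Uy, tmp)
        out = np.einsum("zp,xypi->xyzi", Uz, tmp)
        Msym = np.tensordot(self.strain, np.array(STRAIN_MATRICES), axes=(0, 0))
        grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        return out + grid @ Msym.T

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "basis": {
                "orders": list(self.basis.orders),
                "sum_cap": self.basis.sum_cap,
                "box": self.basis.box.tolist(),
            },
            "coefficients": [
                {"m": m, "n": n, "p": p, "values_mm": self.A[c].tolist()}
                for c, (m, n, p) in enumerate(self.basis.tensor_terms)
            ],
            "strain": dict(zip(STRAIN_NAMES, self.strain.tolist())),
            "rigid": [
                {
                    "series": int(s),
                    "delta_mm": delta.tolist(),
                    "epsilon_rad": eps.tolist(),
                    "is_center": int(s) == self.center_series,
                }
                for s, (delta, eps) in sorted(self.rigid.items())
            ],
            "lambda": self.lam,
            "diagnostics": self.diagnostics,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "DistortionFit":
        basis = BasisSpec(
            tuple(payload["basis"]["orders"]),
            payload["basis"]["sum_cap"],
            np.asarray(payload["basis"]["box"], float),
        )
        terms = basis.tensor_terms
        index = {t: c for c, t in enumerate(terms)}
        A = np.zeros((len(terms), 3))
        for rec in payload["coefficients"]:
            A[index[(rec["m"], rec["n"], rec["p"])]] = rec["values_mm"]
        strain = np.array([payload["strain"][k] for k in STRAIN_NAMES])
        rigid = {}
        center = 0
        for rec in payload["rigid"]:
            rigid[int(rec["series"])] = (
                np.asarray(rec["delta_mm"], float),
                np.asarray(rec["epsilon_rad"], float),
            )
            if rec.get("is_center"):
                center = int(rec["series"])
        return cls(basis, A, strain, rigid, center, payload.get("lambda", 0.0),
                   payload.get("diagnostics", {}))

    @classmethod
    def load(cls, path: str | Path) -> "DistortionFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


_GCV_GRID = np.logspace(-8, 2, 21)


def fit_multiscan(
    system: MultiScanSystem,
    lam: float | str = "gcv",
    center_series: int = 0,
) -> DistortionFit:
    """Solve the joint multi-scan system with Tikhonov regularization.

    Minimizes ``||X c - y||^2 + lam * ||W c||^2`` with the diagonal order
    weights W applied to the distortion coefficients only (never to the rigid
    blocks).  ``lam='gcv'`` selects the weight by generalized cross-validation
    over a logarithmic grid.  The rigid columns are partialled out exactly
    before the (penalized) distortion solve, so per-series translations and
    rotations absorb placement freely regardless of lam.
    """
    if center_series not in system.series_ids:
        raise ValueError(f"centre series {center_series} not present in {system.series_ids}")
    X, y, w = system.X, system.y, system.weights
    rigid = system.rigid_mask
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale

    if isinstance(lam, (int, float)) and lam == 0:
        coef_s, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
        if rank < Xs.shape[1]:
            raise FitRankError(
                f"system rank {rank} < {Xs.shape[1]} columns with lambda = 0; "
                "use lambda > 0 (Tikhonov) to stabilize the fit"
            )
        coef = coef_s / scale
        lam_used, diagnostics = 0.0, {"rank": int(rank)}
    else:
        diagnostics = {}
        if lam == "gcv":
            # Select lambda on the rigid-partialled problem: projecting the
            # rigid columns out is exact because they carry no penalty.
            Xr, Xa = Xs[:, rigid], Xs[:, ~rigid]
            da = w[~rigid] / scale[~rigid]  # penalty diag for scaled coefficients
            Qr, _ = np.linalg.qr(Xr)
            y_perp = y - Qr @ (Qr.T @ y)
            Ma = (Xa - Qr @ (Qr.T @ Xa)) / da[None, :]
            U, sv, _ = np.linalg.svd(Ma, full_matrices=False)
            Uty = U.T @ y_perp
            resid_out = float(y_perp @ y_perp - Uty @ Uty)
            n_rows = len(y)
            n_rigid = Xr.shape[1]
            gcv_path = []
            for lam_try in _GCV_GRID:
                shrink = lam_try / (sv**2 + lam_try)
                rss = float(np.sum((shrink * Uty) ** 2)) + resid_out
                edf = float(np.sum(sv**2 / (sv**2 + lam_try))) + n_rigid
                gcv = n_rows * rss / (n_rows - edf) ** 2 if n_rows > edf else np.inf
                gcv_path.append((float(lam_try), gcv))
            lam_used = min(gcv_path, key=lambda t: t[1])[0]
            diagnostics["gcv_path"] = gcv_path
            diagnostics["edf"] = float(np.sum(sv**2 / (sv**2 + lam_used))) + n_rigid
        else:
            lam_used = float(lam)
        # Exact solve of ||Xs c~ - y||^2 + lam ||diag(w/scale) c~||^2 as an
        # augmented least-squares problem (penalty rows are zero for the
        # rigid columns, which therefore absorb placement freely).
        pen = np.sqrt(lam_used) * (w / scale)
        aug = np.vstack([Xs, np.diag(pen)])
        rhs = np.concatenate([y, np.zeros(Xs.shape[1])])
        coef_s, _, _, _ = np.linalg.lstsq(aug, rhs, rcond=None)
        coef = coef_s / scale

    # unpack coefficients
    nt = len(system.basis.tensor_terms)
    A = np.column_stack([coef[i * nt:(i + 1) * nt] for i in range(3)])
    strain = coef[3 * nt:3 * nt + 6]
    base = 3 * nt + 6
    rigid_params = {}
    for s_idx, s in enumerate(system.series_ids):
        block = coef[base + 6 * s_idx: base + 6 * s_idx + 6]
        rigid_params[s] = (block[:3].copy(), block[3:].copy())

    resid = (y - X @ coef).reshape(-1, 3)
    rms = {}
    for s in system.series_ids:
        r = resid[system.series == s]
        rms[int(s)] = float(np.sqrt(np.mean(r**2)))
    diagnostics["residual_rms_mm_per_series"] = rms
    diagnostics["lambda"] = float(lam_used)

    return DistortionFit(
        basis=system.basis, A=A, strain=np.asarray(strain),
        rigid=rigid_params, center_series=center_series,
        lam=float(lam_used), diagnostics=diagnostics,
    )


def evaluate_field(fit: DistortionFit, points: np.ndarray,
                   warn_extrapolation: bool = True) -> np.ndarray:
    """Evaluate the distortion block of ``fit`` at world ``points`` (mm)."""
    return fit.evaluate(points, warn_extrapolation=warn_extrapolation)


def remove_rigid_component(points: np.ndarray, field_values: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the best-fit global rigid field from sampled field values.

    A global rigid component of a distortion field is a gauge freedom of the
    multi-scan method (it is indistinguishable from phantom placement), so
    comparisons between independently fitted fields are made modulo a single
    rigid field ``delta + eps x x``.  Returns the de-gauged values and the six
    removed parameters ``(delta, eps)``.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    vals = np.atleast_2d(np.asarray(field_values, float))
    A = np.zeros((len(pts) * 3, 6))
    for j in range(3):
        col = np.zeros((len(pts), 3))
        col[:, j] = 1.0
        A[:, j] = col.ravel()
    for j, G in enumerate(ROTATION_GENERATORS):
        A[:, 3 + j] = (pts @ G.T).ravel()
    c, *_ = np.linalg.lstsq(A, vals.ravel(), rcond=None)
    return (vals.ravel() - A @ c).reshape(-1, 3), c


def laser_misalignment(fit: DistortionFit) -> RigidTransform:
    """Rigid misalignment of the alignment lasers read from the centre series.

    The centre scan is the one placed at isocenter by the laser system, so its
    fitted (delta, eps) measure the translational and rotational mismatch
    between the laser and gradient coordinate systems (including any
    centre-frequency translation).  Returned as a proper rigid transform via
    the matrix exponential of eps; composing it with the landmark Procrustes
    placement gives the corrected phantom pose.
    """
    if fit.center_series not in fit.rigid:
        raise ValueError("fit has no centre series rigid block")
    delta, eps = fit.rigid[fit.center_series]
    if np.linalg.norm(eps) > 0.1:
        warnings.warn(
            f"|eps| = {np.linalg.norm(eps):.3f} rad strains the small-angle model",
            stacklevel=2,
        )
    return RigidTransform.from_rotvec(eps, delta)
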