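"""Co-registration of under-canopy (BLS) and above-canopy (ULS) clouds.

Coarse alignment comes from surveyed control poles via a least-squares 2D
rigid (rotation + translation, no scale) transform; fine alignment matches
the BLS-detected trunk positions to the ULS-detected treetop positions by
iterating optimal one-to-one assignment against re-estimation of the rigid
transform. Both clouds are height-normalized beforehand, so only a 2D
transform (plus an optional constant z offset) is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class RigidTransform2D:
    """A planar rotation-then-translation, with an optional z offset."""

    rotation: float = 0.0  # radians, counterclockwise
    translation: tuple[float, float] = (0.0, 0.0)
    z_offset: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix.T + np.asarray(self.translation)

    def apply_xyz(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        out = xyz.copy()
        out[:, :2] = self.apply(xyz[:, :2])
        out[:, 2] += self.z_offset
        return out

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self ∘ other: apply ``other`` first, then ``self``."""
        t = self.apply(np.asarray(other.translation))
        return RigidTransform2D(
            rotation=self.rotation + other.rotation,
            translation=(float(t[0]), float(t[1])),
            z_offset=self.z_offset + other.z_offset,
        )

    def inverse(self) -> "RigidTransform2D":
        rinv = -self.rotation
        c, s = np.cos(rinv), np.sin(rinv)
        tx, ty = self.translation
        return RigidTransform2D(
            rotation=rinv,
            translation=(-(c * tx - s * ty), -(s * tx + c * ty)),
            z_offset=-self.z_offset,
        )


@dataclass(frozen=True)
class TreeMatch:
    """A matched (treetop, trunk) pair with its post-alignment distance (m)."""

    uls_id: int
    bls_id: int
    distance_m: float


def rigid_from_control_points(
    src: np.ndarray, dst: np.ndarray
) -> tuple[RigidTransform2D, float]:
    """Least-squares rigid transform mapping ``src`` onto ``dst`` (2D Kabsch).

    Needs >= 2 point pairs that are not all coincident. Returns the transform
    and the RMS residual in meters.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape or src.shape[0] < 2:
        raise ValueError("need >= 2 corresponding 2D points on each side")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    s0, d0 = src - sc, dst - dc
    if np.allclose(s0, 0) or np.allclose(d0, 0):
        raise ValueError("degenerate configuration: control points coincide")
    Hm = s0.T @ d0
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    t = dc - R @ sc
    tf = RigidTransform2D(rotation=theta, translation=(float(t[0]), float(t[1])))
    rms = float(np.sqrt(np.mean(np.sum((tf.apply(src) - dst) ** 2, axis=1))))
    return tf, rms


class RigidAligner(TransformerMixin, BaseEstimator):
    """Estimate a 2D rigid transform from point correspondences.

    ``fit(X, y)`` takes source points ``X`` and target points ``y`` (both
    (n, 2)); ``transform`` maps new points into the target frame.

    Attributes
    ----------
    transform_ : RigidTransform2D
    rms_ : float
        RMS residual of the fit, meters.
    """

    def fit(self, X, y):
        self.transform_, self.rms_ = rigid_from_control_points(X, y)
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return self.transform_.apply(np.asarray(X, dtype=float).reshape(-1, 2))


_UNMATCHED = 1e9  # sentinel cost for pairs beyond max_pair_dist


def _assign(uls: np.ndarray, bls_t: np.ndarray, max_pair_dist: float):
    """Optimal one-to-one assignment of trunks to treetops within range."""
    cost = cdist(uls, bls_t)
    cost = np.where(cost <= max_pair_dist, cost, _UNMATCHED)
    rows, cols = linear_sum_assignment(cost)
    ok = cost[rows, cols] < _UNMATCHED
    return rows[ok], cols[ok]


def refine_by_tree_matching(
    uls_positions: np.ndarray,
    bls_positions: np.ndarray,
    init: RigidTransform2D | None = None,
    max_pair_dist: float = 2.0,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[RigidTransform2D, list[TreeMatch]]:
    """Fine co-registration by iterative closest-pattern matching.

    Alternates (a) optimal one-to-one assignment of BLS trunk positions to
    ULS treetop positions among pairs within ``max_pair_dist`` of each other
    under the current transform, and (b) re-estimation of the rigid
    transform from the matched pairs; stops when the transform update moves
    matched points by less than ``tol`` or after ``max_iter`` iterations.
    """
    uls = np.asarray(uls_positions, dtype=float).reshape(-1, 2)
    bls = np.asarray(bls_positions, dtype=float).reshape(-1, 2)
    if len(uls) < 3 or len(bls) < 3:
        raise ValueError("need at least 3 tree positions on each side")
    tf = init if init is not None else RigidTransform2D()
    rows = cols = np.array([], dtype=int)
    for _ in range(max_iter):
        bls_t = tf.apply(bls)
        rows, cols = _assign(uls, bls_t, max_pair_dist)
        if len(rows) < 3:
            raise RuntimeError(
                f"fine registration failed: only {len(rows)} pairs within "
                f"{max_pair_dist} m (ULS n={len(uls)}, BLS n={len(bls)})"
            )
        new_tf, _ = rigid_from_control_points(bls[cols], uls[rows])
        shift = float(np.max(np.abs(new_tf.apply(bls[cols]) - tf.apply(bls[cols]))))
        tf = new_tf
        if shift < tol:
            break
    bls_t = tf.apply(bls)
    rows, cols = _assign(uls, bls_t, max_pair_dist)
    dists = np.hypot(*(uls[rows] - bls_t[cols]).T)
    matches = [
        TreeMatch(uls_id=int(i), bls_id=int(j), distance_m=float(d))
        for i, j, d in zip(rows, cols, dists)
    ]
    return tf, matches


def registration_error(matches: list[TreeMatch]) -> float:
    """Mean horizontal treetop–trunk distance of the matches, in centimeters."""
    if not matches:
        raise ValueError("no matches")
    return 100.0 * float(np.mean([m.distance_m for m in matches]))
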