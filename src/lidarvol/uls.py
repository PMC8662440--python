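"""Individual-tree segmentation of the above-canopy (ULS) cloud.

Top-down distance-judgement clustering on the height-normalized cloud:
points are processed in descending height; the highest unassigned point
seeds a new tree (its treetop), and each subsequent point joins the nearest
existing tree when its 2D distance to that tree's already-assigned points is
within the spacing threshold T1. A point that cannot join a tree may seed a
new one only if it lies farther than the exclusion radius T2 from every
existing apex — T1 is chosen close to the planting spacing and T2 close to
the average crown radius. Tree height is the apex's normalized height;
crown radius is the mean horizontal apex-to-point distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .cloud import PointCloud


@dataclass(frozen=True)
class UlsSegConfig:
    """Thresholds for top-down clustering segmentation.

    ``t1``: spacing threshold (m), ``t2``: apex exclusion radius (m),
    ``h_min``: minimum normalized height considered (m), ``min_points``:
    smallest surviving tree.
    """

    t1: float = 2.0
    t2: float = 2.5
    h_min: float = 2.0
    min_points: int = 30

    def __post_init__(self):
        if self.t1 <= 0 or self.t2 <= 0 or self.h_min < 0:
            raise ValueError("T1, T2 must be positive and h_min non-negative")


@dataclass
class DetectedTree:
    """A segmented tree: apex, height, crown radius and member points."""

    id: int
    apex: tuple[float, float, float]  # (x, y, normalized z)
    height: float
    crown_radius: float
    point_index: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def position(self) -> tuple[float, float]:
        return (self.apex[0], self.apex[1])


class TreetopSegmenter(ClusterMixin, BaseEstimator):
    """Top-down distance-judgement clustering (scikit-learn estimator).

    ``fit(X)`` takes (n, 3) rows of (x, y, normalized height); ``labels_``
    assigns each point a tree id (-1 = below ``h_min``, barred from seeding,
    or in a dissolved fragment). ``trees_`` lists the surviving trees in
    seeding order.
    """

    def __init__(
        self,
        t1: float = 2.0,
        t2: float = 2.5,
        h_min: float = 2.0,
        min_points: int = 30,
    ):
        self.t1 = t1
        self.t2 = t2
        self.h_min = h_min
        self.min_points = min_points

    def fit(self, X, y=None):
        cfg = UlsSegConfig(self.t1, self.t2, self.h_min, self.min_points)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n, 3): x, y, normalized height")
        n = X.shape[0]
        labels = np.full(n, -1, dtype=int)
        # strictly descending height; ties broken by point index
        order = np.lexsort((np.arange(n), -X[:, 2]))
        order = order[X[order, 2] >= cfg.h_min]

        cell = cfg.t1
        grid: dict[tuple[int, int], list[int]] = {}
        apex_xy: list[tuple[float, float]] = []
        apex_idx: list[int] = []
        t1sq = cfg.t1**2

        def neighbors(cx: int, cy: int) -> list[int]:
            out: list[int] = []
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    out.extend(grid.get((cx + dx, cy + dy), ()))
            return out

        for i in order:
            x, y_, _ = X[i]
            cx, cy = int(np.floor(x / cell)), int(np.floor(y_ / cell))
            cand = neighbors(cx, cy)
            best_d2, best_tree = np.inf, -1
            if cand:
                pts = X[cand, :2]
                d2 = (pts[:, 0] - x) ** 2 + (pts[:, 1] - y_) ** 2
                k = int(np.argmin(d2))
                best_d2, best_tree = float(d2[k]), labels[cand[k]]
            if best_d2 <= t1sq:
                labels[i] = best_tree
            else:
                if apex_xy:
                    ax = np.asarray(apex_xy)
                    if np.min((ax[:, 0] - x) ** 2 + (ax[:, 1] - y_) ** 2) <= cfg.t2**2:
                        continue  # barred from seeding near an existing apex
                labels[i] = len(apex_xy)
                apex_xy.append((x, y_))
                apex_idx.append(i)
            grid.setdefault((cx, cy), []).append(i)

        # dissolve fragments below min_points and relabel compactly
        trees: list[DetectedTree] = []
        new_labels = np.full(n, -1, dtype=int)
        for tid, ai in enumerate(apex_idx):
            members = np.nonzero(labels == tid)[0]
            if members.size < cfg.min_points:
                continue
            new_id = len(trees)
            new_labels[members] = new_id
            apex = (float(X[ai, 0]), float(X[ai, 1]), float(X[ai, 2]))
            crown_r = float(
                np.mean(np.hypot(X[members, 0] - apex[0], X[members, 1] - apex[1]))
            )
            trees.append(
                DetectedTree(
                    id=new_id,
                    apex=apex,
                    height=apex[2],
                    crown_radius=crown_r,
                    point_index=members,
                )
            )
        self.labels_ = new_labels
        self.trees_ = trees
        self.n_features_in_ = 3
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def segment_trees(cloud: PointCloud, cfg: UlsSegConfig | None = None) -> list[DetectedTree]:
    """Segment a normalized cloud into individual trees (wrapper)."""
    if cloud.z_norm is None:
        raise ValueError("cloud must be height-normalized first")
    cfg = cfg or UlsSegConfig()
    seg = TreetopSegmenter(cfg.t1, cfg.t2, cfg.h_min, cfg.min_points)
    seg.fit(np.column_stack([cloud.x, cloud.y, cloud.z_norm]))
    return seg.trees_


def tree_attributes(tree: DetectedTree, cloud: PointCloud) -> tuple[float, float]:
    """(height, crown radius) of a segmented tree.

    Height is the maximum normalized height over the tree's points (the
    apex); crown radius is the mean horizontal distance from the apex.
    """
    if tree.point_index is None or len(tree.point_index) == 0:
        raise ValueError("tree has no points")
    h = cloud.heights()[tree.point_index]
    height = float(h.max())
    ax, ay = tree.apex[0], tree.apex[1]
    crown = float(
        np.mean(
            np.hypot(cloud.x[tree.point_index] - ax, cloud.y[tree.point_index] - ay)
        )
    )
    return height, crown
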