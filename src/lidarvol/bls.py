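"""Trunk detection, DBH and upper-stem diameters from the BLS cloud.

The height-normalized under-canopy cloud is sliced at breast height
(1.3 m ± 5 cm); trunks appear in the slice as dense rings and are found by
DBSCAN in the 2D projection (a core point has at least MinPts neighbors,
itself included, within Eps). Each trunk's diameter comes from the
gravity-center circle: the center is the mean of the cluster's points and
the radius the mean point-to-center distance. Upper-stem diameters repeat
the slice-and-fit at 1-m intervals up to the sensor's vertical reach,
tracking the stem center upward between slices.

Geometry inside this module is in meters; diameters cross the module
boundary in centimeters (the single m→cm conversion lives in
:func:`fit_circle_diameter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from .cloud import PointCloud

#: Breast-height ... 8.3 m sampling grid for upper-stem diameters.
DEFAULT_PROFILE_HEIGHTS = tuple(1.3 + k for k in range(8))


@dataclass(frozen=True)
class DbscanConfig:
    """Density-clustering thresholds and slice geometry."""

    eps: float = 0.2
    min_pts: int = 15
    slice_center: float = 1.3
    slice_width: float = 0.10

    def __post_init__(self):
        if self.eps <= 0 or self.min_pts < 1 or self.slice_width <= 0:
            raise ValueError("invalid DBSCAN/slice configuration")


@dataclass(frozen=True)
class TrunkRecord:
    """A detected trunk: gravity center at breast height and DBH (cm)."""

    id: int
    center: tuple[float, float]
    dbh_cm: float
    n_points: int


@dataclass
class StemProfile:
    """Diameter-height samples (h in m, d in cm) for one matched tree."""

    tree_id: int
    samples: list[tuple[float, float]] = field(default_factory=list)
    n_points: list[int] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.samples

    def heights(self) -> np.ndarray:
        return np.array([h for h, _ in self.samples])

    def diameters(self) -> np.ndarray:
        return np.array([d for _, d in self.samples])


def slice_cloud(cloud: PointCloud, center: float = 1.3, width: float = 0.10) -> PointCloud:
    """Points with normalized height in the half-open band [c-w/2, c+w/2)."""
    if width <= 0:
        raise ValueError("slice width must be positive")
    h = cloud.heights()
    return cloud.subset((h >= center - width / 2) & (h < center + width / 2))


class TrunkDetector(ClusterMixin, BaseEstimator):
    """DBSCAN trunk detector on the 2D projection of a height slice.

    ``fit(X)`` takes (n, 2) horizontal coordinates (or (n, 3); z is
    dropped); ``labels_`` follows the DBSCAN convention (-1 = noise) and
    ``trunks_`` holds a :class:`TrunkRecord` per cluster.
    """

    def __init__(self, eps: float = 0.2, min_pts: int = 15):
        self.eps = eps
        self.min_pts = min_pts

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        xy = X[:, :2]
        self.labels_ = DBSCAN(eps=self.eps, min_samples=self.min_pts).fit_predict(xy)
        trunks = []
        for lab in sorted(set(self.labels_) - {-1}):
            members = np.nonzero(self.labels_ == lab)[0]
            center, dbh = fit_circle_diameter(xy[members])
            trunks.append(
                TrunkRecord(
                    id=len(trunks), center=center, dbh_cm=dbh, n_points=len(members)
                )
            )
        self.trunks_ = trunks
        self.n_features_in_ = xy.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def detect_trunks(slice_pc: PointCloud, cfg: DbscanConfig | None = None) -> list[np.ndarray]:
    """Cluster a breast-height slice into trunk point sets.

    Returns one index array (into the slice) per detected trunk; points not
    density-reachable from any core point are noise.
    """
    cfg = cfg or DbscanConfig()
    if len(slice_pc) == 0:
        return []
    labels = DBSCAN(eps=cfg.eps, min_samples=cfg.min_pts).fit_predict(slice_pc.xyz[:, :2])
    return [np.nonzero(labels == lab)[0] for lab in sorted(set(labels) - {-1})]


def fit_circle_diameter(points_xy: np.ndarray) -> tuple[tuple[float, float], float]:
    """Gravity-center circle fit: center and diameter in centimeters.

    Center = mean (x, y); radius = mean distance to the center;
    D = 200 · radius converts the radius in meters to a diameter in cm.
    """
    pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points to estimate a diameter")
    center = pts.mean(axis=0)
    radius = float(np.mean(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])))
    return (float(center[0]), float(center[1])), 200.0 * radius


def trunk_records(slice_pc: PointCloud, cfg: DbscanConfig | None = None) -> list[TrunkRecord]:
    """Detect trunks in a slice and fit each one's gravity-center circle."""
    cfg = cfg or DbscanConfig()
    records = []
    for members in detect_trunks(slice_pc, cfg):
        center, dbh = fit_circle_diameter(slice_pc.xyz[members, :2])
        records.append(
            TrunkRecord(id=len(records), center=center, dbh_cm=dbh, n_points=len(members))
        )
    return records


def stem_profile(
    cloud: PointCloud,
    trunk: TrunkRecord,
    heights: tuple[float, ...] = DEFAULT_PROFILE_HEIGHTS,
    cfg: DbscanConfig | None = None,
    track_radius: float = 0.5,
) -> StemProfile:
    """Upper-stem diameters at the given heights for one detected trunk.

    At each height (ascending) the cloud is sliced, points within ``2·eps``
    of the tracked stem center are kept, and the gravity-center circle is
    fitted when at least ``min_pts`` points remain; the center then tracks
    the stem upward (a slice whose new center would jump more than
    ``track_radius`` from the previous one is treated as unmatched).
    Heights without a valid sample are omitted rather than guessed.
    """
    cfg = cfg or DbscanConfig()
    profile = StemProfile(tree_id=trunk.id)
    center = np.asarray(trunk.center, dtype=float)
    for h in sorted(heights):
        band = slice_cloud(cloud, center=h, width=cfg.slice_width)
        if len(band) == 0:
            continue
        d2c = np.hypot(band.x - center[0], band.y - center[1])
        near = d2c <= 2 * cfg.eps
        if near.sum() < cfg.min_pts:
            continue
        new_center, d_cm = fit_circle_diameter(band.xyz[near, :2])
        if np.hypot(new_center[0] - center[0], new_center[1] - center[1]) > track_radius:
            continue
        profile.samples.append((float(h), float(d_cm)))
        profile.n_points.append(int(near.sum()))
        center = np.asarray(new_center)
    return profile
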