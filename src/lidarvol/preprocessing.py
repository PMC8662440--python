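"""Cloud denoising, ground filtering, DEM building and height normalization.

The preprocessing chain mirrors standard forest-LiDAR practice: statistical
k-nearest-neighbor outlier removal, ground/vegetation separation by
progressive TIN densification (seed the lowest point per coarse cell,
triangulate, iteratively accept points close to and at a shallow angle from
their containing facet), a 1-m DEM from per-cell mean ground elevation with
inverse-distance-weighted gap filling, and per-point height-above-ground
normalization against that DEM.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .cloud import GROUND, VEGETATION, DEMGrid, PointCloud


def remove_outliers(cloud: PointCloud, k: int = 8, n_sigma: float = 3.0) -> PointCloud:
    """Drop points whose mean k-NN distance is anomalously large.

    A point is removed when its mean distance to its ``k`` nearest neighbors
    exceeds the global mean of that statistic by more than ``n_sigma``
    standard deviations. Clouds too small to have k neighbors are returned
    unchanged with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cloud) < k + 1:
        warnings.warn("cloud smaller than k+1 points; outlier removal skipped")
        return cloud
    nn = NearestNeighbors(n_neighbors=k + 1).fit(cloud.xyz)
    dist, _ = nn.kneighbors(cloud.xyz)
    mean_d = dist[:, 1:].mean(axis=1)  # exclude self
    keep = mean_d <= mean_d.mean() + n_sigma * mean_d.std()
    return cloud.subset(keep)


class KNNOutlierFilter(BaseEstimator):
    """scikit-learn-style wrapper over :func:`remove_outliers`.

    ``fit_predict(X)`` returns +1 for inliers and -1 for outliers, matching
    the convention of sklearn outlier detectors.
    """

    def __init__(self, k: int = 8, n_sigma: float = 3.0):
        self.k = k
        self.n_sigma = n_sigma

    def fit_predict(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.k + 1:
            return np.ones(X.shape[0], dtype=int)
        nn = NearestNeighbors(n_neighbors=self.k + 1).fit(X)
        dist, _ = nn.kneighbors(X)
        mean_d = dist[:, 1:].mean(axis=1)
        keep = mean_d <= mean_d.mean() + self.n_sigma * mean_d.std()
        return np.where(keep, 1, -1)


def _lowest_per_cell(xyz: np.ndarray, cell: float) -> np.ndarray:
    """Index of the lowest point in each occupied cell×cell block."""
    key = np.floor(xyz[:, :2] / cell).astype(int)
    order = np.lexsort((xyz[:, 2], key[:, 1], key[:, 0]))
    k_sorted = key[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(k_sorted[1:] != k_sorted[:-1], axis=1)
    return order[first]


def _fit_plane(xyz: np.ndarray) -> np.ndarray:
    """Least-squares plane z = c0 + c1*x + c2*y."""
    A = np.column_stack([np.ones(len(xyz)), xyz[:, 0], xyz[:, 1]])
    coef, *_ = np.linalg.lstsq(A, xyz[:, 2], rcond=None)
    return coef


def classify_ground(
    cloud: PointCloud,
    seed_cell: float = 5.0,
    max_angle: float = 8.0,
    max_dist: float = 0.5,
    max_rounds: int = 60,
    max_facet_slope: float = 30.0,
) -> PointCloud:
    """Label every point ground or vegetation by progressive TIN densification.

    Seeds are the lowest point per ``seed_cell`` block. The seed TIN is
    densified iteratively: an unlabeled point joins the ground set when its
    perpendicular distance to the containing triangle is at most ``max_dist``
    meters and the largest angle between the facet and the lines to the three
    vertices is at most ``max_angle`` degrees. Candidate facets steeper than
    ``max_facet_slope`` degrees never accept points — without this guard,
    dense vertical structures (tree stems) can be climbed by chains of
    near-vertical micro-facets. Four virtual corner vertices (on the seeds'
    least-squares plane) keep the triangulation covering the full extent.
    If the seeds are degenerate (collinear), the filter falls back to
    distance-from-plane labeling with a warning.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    xyz = cloud.xyz
    seed_idx = _lowest_per_cell(xyz, seed_cell)
    # vet seeds against their own robust plane: a block that holds only
    # canopy returns (crown overhang, gaps) would otherwise contribute a
    # canopy point as a "ground" seed
    for _ in range(3):
        if seed_idx.size < 3:
            break
        sp = _fit_plane(xyz[seed_idx])
        resid = xyz[seed_idx, 2] - (
            sp[0] + sp[1] * xyz[seed_idx, 0] + sp[2] * xyz[seed_idx, 1]
        )
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        keep = resid <= med + max(3 * 1.4826 * mad, 1.0)
        if keep.all():
            break
        seed_idx = seed_idx[keep]
    is_ground = np.zeros(len(cloud), dtype=bool)
    is_ground[seed_idx] = True

    plane = _fit_plane(xyz[is_ground]) if is_ground.sum() >= 3 else _fit_plane(xyz)
    lo = xyz[:, :2].min(axis=0) - seed_cell
    hi = xyz[:, :2].max(axis=0) + seed_cell
    corners_xy = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    corners = np.column_stack(
        [corners_xy, plane[0] + plane[1] * corners_xy[:, 0] + plane[2] * corners_xy[:, 1]]
    )

    tan_max = np.tan(np.radians(max_angle))
    cos_slope_min = np.cos(np.radians(max_facet_slope))
    for _ in range(max_rounds):
        gpts = np.vstack([xyz[is_ground], corners])
        try:
            tri = Delaunay(gpts[:, :2])
        except QhullError:
            warnings.warn(
                "degenerate ground seeds; falling back to lowest-plane labeling"
            )
            resid = np.abs(xyz[:, 2] - (plane[0] + plane[1] * xyz[:, 0] + plane[2] * xyz[:, 1]))
            is_ground = resid <= max_dist
            break
        cand = np.nonzero(~is_ground)[0]
        if cand.size == 0:
            break
        simplex = tri.find_simplex(xyz[cand, :2])
        inside = simplex >= 0
        cand, simplex = cand[inside], simplex[inside]
        if cand.size == 0:
            break
        v = gpts[tri.simplices[simplex]]  # (m, 3, 3)
        p = xyz[cand]
        normal = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        nrm = np.linalg.norm(normal, axis=1)
        ok_plane = (nrm > 1e-12) & (np.abs(normal[:, 2]) >= cos_slope_min * nrm)
        d = np.abs(np.einsum("ij,ij->i", normal, p - v[:, 0])) / np.maximum(nrm, 1e-12)
        # angle between the facet plane and the line from the point to each
        # vertex: tan(angle) = perp distance / in-plane distance
        edge = np.linalg.norm(p[:, None, :] - v, axis=2)  # (m, 3) slant distances
        horiz = np.sqrt(np.maximum(edge**2 - d[:, None] ** 2, 1e-24))
        tan_ang = (d[:, None] / horiz).max(axis=1)
        accept = ok_plane & (d <= max_dist) & (tan_ang <= tan_max)
        if not accept.any():
            break
        is_ground[cand[accept]] = True

    out = cloud.copy()
    out.classification = np.where(is_ground, GROUND, VEGETATION)
    return out


class GroundClassifier(BaseEstimator):
    """scikit-learn-style wrapper over :func:`classify_ground`.

    ``fit_predict(X)`` on (n, 3) coordinates returns 1 for ground, 0 for
    vegetation; labels are also stored as ``labels_``.
    """

    def __init__(self, seed_cell: float = 5.0, max_angle: float = 8.0, max_dist: float = 0.5):
        self.seed_cell = seed_cell
        self.max_angle = max_angle
        self.max_dist = max_dist

    def fit_predict(self, X, y=None):
        labeled = classify_ground(
            PointCloud(xyz=np.asarray(X, dtype=float)),
            seed_cell=self.seed_cell,
            max_angle=self.max_angle,
            max_dist=self.max_dist,
        )
        self.labels_ = (labeled.classification == GROUND).astype(int)
        return self.labels_


def build_dem(
    ground: PointCloud,
    cell: float = 1.0,
    idw_power: float = 2.0,
    idw_k: int = 12,
    refill_sigma: float = 3.0,
) -> DEMGrid:
    """Rasterize ground points to a DEM with IDW gap filling.

    Each cell takes the mean elevation of the ground points it contains
    (points labeled ground if the cloud is classified, else all points).
    Cells without returns — and populated cells whose mean is more than
    ``refill_sigma`` neighborhood standard deviations above their neighbors,
    a guard against residual low-noise — are filled by inverse-distance
    weighting over the ``idw_k`` nearest populated cell centers.
    """
    if ground.classification is not None:
        ground = ground.subset(ground.classification == GROUND)
    if len(ground) == 0:
        raise ValueError("no ground points to rasterize")
    xyz = ground.xyz
    origin = (float(xyz[:, 0].min()), float(xyz[:, 1].min()))
    nx = max(int(np.ceil((xyz[:, 0].max() - origin[0]) / cell)), 1)
    ny = max(int(np.ceil((xyz[:, 1].max() - origin[1]) / cell)), 1)
    j = np.clip(((xyz[:, 0] - origin[0]) / cell).astype(int), 0, nx - 1)
    i = np.clip(((xyz[:, 1] - origin[1]) / cell).astype(int), 0, ny - 1)
    flat = i * nx + j
    sums = np.bincount(flat, weights=xyz[:, 2], minlength=ny * nx)
    counts = np.bincount(flat, minlength=ny * nx)
    values = np.full(ny * nx, np.nan)
    pop = counts > 0
    values[pop] = sums[pop] / counts[pop]
    values = values.reshape(ny, nx)
    populated = pop.reshape(ny, nx)

    # guard against cells dominated by missed low vegetation: a populated
    # cell far above its populated neighbors gets re-filled by IDW
    if populated.sum() > 8:
        pi, pj = np.nonzero(populated)
        tree = cKDTree(np.column_stack([pj, pi]))
        _, idx = tree.query(np.column_stack([pj, pi]), k=min(9, populated.sum()))
        nb_vals = values[pi[idx[:, 1:]], pj[idx[:, 1:]]]
        nb_mean = nb_vals.mean(axis=1)
        nb_std = np.maximum(nb_vals.std(axis=1), 0.05)
        extreme = values[pi, pj] > nb_mean + refill_sigma * nb_std
        populated[pi[extreme], pj[extreme]] = False

    fill_mask = ~populated
    if fill_mask.any():
        if not populated.any():
            raise ValueError("no populated DEM cells")
        pi, pj = np.nonzero(populated)
        fi, fj = np.nonzero(fill_mask)
        src = np.column_stack([pj + 0.5, pi + 0.5]) * cell
        dst = np.column_stack([fj + 0.5, fi + 0.5]) * cell
        tree = cKDTree(src)
        kq = min(idw_k, len(src))
        dist, idx = tree.query(dst, k=kq)
        dist = np.atleast_2d(dist.T).T
        idx = np.atleast_2d(idx.T).T
        w = 1.0 / np.maximum(dist, 1e-9) ** idw_power
        vals = values[pi[idx], pj[idx]]
        values[fi, fj] = (w * vals).sum(axis=1) / w.sum(axis=1)

    return DEMGrid(origin=origin, cell=cell, values=values, fill_mask=fill_mask)


def normalize_heights(cloud: PointCloud, dem: DEMGrid) -> PointCloud:
    """Store per-point height above the DEM (z minus the cell elevation).

    Points outside the DEM extent use the nearest edge cell. Negative
    normalized heights are preserved, not clamped.
    """
    out = cloud.copy()
    out.z_norm = cloud.z - dem.elevation_at(cloud.x, cloud.y)
    return out
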