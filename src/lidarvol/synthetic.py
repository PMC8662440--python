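"""Synthetic planted-forest plots and simulated ULS/BLS scans.

Every downstream stage (ground filtering, segmentation, registration, taper
fitting) is testable against exact ground truth generated here: a square
plot with regular row planting, per-tree DBH/height drawn from plot-level
statistics, stems shaped by a configured taper equation, and two simulated
scans —

* a "top-down" ULS cloud (crown surfaces + ground, ~84 pts/m², apexes exact
  before noise, no stem returns), and
* a "bottom-up" BLS cloud (stem cylinders following the taper, ground and
  optional understory clutter, height-capped near 9 m) expressed in a frame
  displaced from the plot frame by a known rigid transform.

Every simulated point carries its source tree id (or -1 for ground/clutter),
so segmentation can be scored exactly. Crown shapes are a cone for
conifer-like species and an upper half-ellipsoid for broadleaf-like species;
the apex may lean horizontally off the stem base, which is what limits how
closely a treetop can predict its trunk position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import GROUND, VEGETATION, PointCloud
from .registration import RigidTransform2D
from .taper import eval_taper

#: Modified-Schumacher (M2) coefficients used as the default stem shape.
DEFAULT_TAPER_COEFFS = (0.598, 1.900, 1.417, 1.279)


@dataclass(frozen=True)
class SpeciesParams:
    """Plot-level distribution of tree attributes.

    DBH in centimeters, heights and crown radii in meters. ``lean_max``
    bounds the horizontal apex offset from the stem base.
    """

    mean_dbh: float
    sd_dbh: float
    mean_height: float
    sd_height: float
    crown_radius_mean: float = 2.5
    crown_radius_sd: float = 0.4
    lean_max: float = 0.3
    species_tag: str = "conifer-like"

    def __post_init__(self):
        if self.mean_dbh <= 0 or self.mean_height <= 0:
            raise ValueError("species means must be positive")
        if self.species_tag not in ("conifer-like", "broadleaf-like"):
            raise ValueError("species_tag must be conifer-like or broadleaf-like")


#: Medium-density conifer-like stand (dense crowns, small apex lean).
PLOT_B_LIKE = SpeciesParams(
    mean_dbh=31.57, sd_dbh=3.95, mean_height=27.30, sd_height=1.71,
    species_tag="conifer-like",
)
#: High-density conifer-like stand.
PLOT_C_LIKE = SpeciesParams(
    mean_dbh=27.11, sd_dbh=6.42, mean_height=23.22, sd_height=2.41,
    species_tag="conifer-like",
)
#: Broadleaf-like stand with extended crowns and larger apex lean.
PLOT_E_LIKE = SpeciesParams(
    mean_dbh=34.57, sd_dbh=5.22, mean_height=31.46, sd_height=1.90,
    crown_radius_mean=3.0, crown_radius_sd=0.5, lean_max=0.6,
    species_tag="broadleaf-like",
)


@dataclass(frozen=True)
class TrueTree:
    """Ground-truth tree: stem base position, size, crown, and apex lean."""

    id: int
    stem_x: float
    stem_y: float
    height: float  # m
    dbh: float  # cm
    crown_radius: float  # m
    lean_dx: float
    lean_dy: float
    species_tag: str

    def __post_init__(self):
        if self.height <= 1.3 or self.dbh <= 0 or self.crown_radius <= 0:
            raise ValueError("invalid tree attributes")
        if np.hypot(self.lean_dx, self.lean_dy) >= self.crown_radius:
            raise ValueError("apex lean must stay inside the crown")

    @property
    def apex_xy(self) -> tuple[float, float]:
        return (self.stem_x + self.lean_dx, self.stem_y + self.lean_dy)


@dataclass
class PlotTruth:
    """A generated plot: trees, layout, ground plane and stem taper."""

    trees: list[TrueTree]
    plot_size: float
    row_spacing: float
    col_spacing: float
    ground_coeffs: tuple[float, float, float]  # z = c0 + c1*x + c2*y
    taper_model_id: str = "M2"
    taper_coeffs: tuple[float, ...] = DEFAULT_TAPER_COEFFS
    seed: int = 0

    def ground_z(self, x, y):
        c0, c1, c2 = self.ground_coeffs
        return c0 + c1 * np.asarray(x, float) + c2 * np.asarray(y, float)

    def stem_positions(self) -> np.ndarray:
        return np.array([[t.stem_x, t.stem_y] for t in self.trees])

    def stem_diameter_cm(self, tree: TrueTree, h) -> np.ndarray | float:
        """True stem diameter (cm) at height h (m).

        Stems follow the configured taper's shape, normalized so that the
        diameter at breast height (1.3 m) equals the tree's DBH exactly —
        the physically consistent reading of "DBH" as the stem diameter a
        tape or a breast-height circle fit would measure.
        """
        d_h = eval_taper(self.taper_model_id, self.taper_coeffs, tree.dbh, tree.height, h)
        d_bh = eval_taper(self.taper_model_id, self.taper_coeffs, tree.dbh, tree.height, 1.3)
        return tree.dbh * d_h / d_bh

    def detection_reference(self) -> list[tuple[float, float, float]]:
        """(x, y, crown_radius) triples for scoring detections."""
        return [(t.stem_x, t.stem_y, t.crown_radius) for t in self.trees]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": t.id, "x": t.stem_x, "y": t.stem_y, "H": t.height,
                    "D": t.dbh, "crown_radius": t.crown_radius,
                    "lean_dx": t.lean_dx, "lean_dy": t.lean_dy,
                    "species": t.species_tag,
                }
                for t in self.trees
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


@dataclass
class SimulatedScan:
    """A simulated scan, its truth transform and acquisition settings."""

    cloud: PointCloud
    scan_kind: str  # "ULS" | "BLS"
    applied_transform: RigidTransform2D = field(default_factory=RigidTransform2D)
    noise_sigma: float = 0.0
    density: float | None = None  # pts/m² (ULS)
    pts_per_stem_slice: float | None = None  # pts per meter of stem (BLS)
    height_cap: float | None = None  # m (BLS)


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.maximum(out, low + 1e-6)


def generate_plot(
    species_params: SpeciesParams = PLOT_B_LIKE,
    plot_size: float = 30.0,
    row_spacing: float = 5.0,
    col_spacing: float = 5.0,
    thinning: float = 0.1,
    position_jitter: float = 0.1,
    ground_slope: float = 0.0004,
    ground_z0: float = 2.0,
    taper_coeffs: tuple[float, ...] = DEFAULT_TAPER_COEFFS,
    seed: int = 0,
) -> PlotTruth:
    """Generate a regular-planting plot with known tree attributes.

    Trees sit on a ``floor(plot/row) × floor(plot/col)`` grid (small position
    jitter, rows centered in the plot), randomly thinned by ``thinning``.
    DBH and height are truncated normals per ``species_params``; the ground
    is a plane with fractional slope ``ground_slope`` along x.
    """
    if plot_size <= 0 or row_spacing <= 0 or col_spacing <= 0:
        raise ValueError("plot size and spacings must be positive")
    if not 0 <= thinning < 1:
        raise ValueError("thinning must be in [0, 1)")
    rng = np.random.default_rng(seed)
    nr = int(np.floor(plot_size / row_spacing))
    nc = int(np.floor(plot_size / col_spacing))
    mx = (plot_size - (nr - 1) * row_spacing) / 2.0
    my = (plot_size - (nc - 1) * col_spacing) / 2.0
    gx, gy = np.meshgrid(
        mx + np.arange(nr) * row_spacing, my + np.arange(nc) * col_spacing
    )
    xs, ys = gx.ravel(), gy.ravel()
    n = xs.size
    if position_jitter > 0:
        xs = np.clip(xs + rng.uniform(-position_jitter, position_jitter, n), 0, plot_size)
        ys = np.clip(ys + rng.uniform(-position_jitter, position_jitter, n), 0, plot_size)
    keep = rng.random(n) >= thinning
    xs, ys = xs[keep], ys[keep]
    n = xs.size
    sp = species_params
    dbh = _truncated_normal(rng, sp.mean_dbh, sp.sd_dbh, 5.0, n)
    height = _truncated_normal(rng, sp.mean_height, sp.sd_height, 2.0, n)
    crown = _truncated_normal(rng, sp.crown_radius_mean, sp.crown_radius_sd, 0.8, n)
    lean_mag = rng.uniform(0, 1, n) * np.minimum(sp.lean_max, 0.9 * crown)
    lean_ang = rng.uniform(0, 2 * np.pi, n)
    trees = [
        TrueTree(
            id=i,
            stem_x=float(xs[i]), stem_y=float(ys[i]),
            height=float(height[i]), dbh=float(dbh[i]),
            crown_radius=float(crown[i]),
            lean_dx=float(lean_mag[i] * np.cos(lean_ang[i])),
            lean_dy=float(lean_mag[i] * np.sin(lean_ang[i])),
            species_tag=sp.species_tag,
        )
        for i in range(n)
    ]
    return PlotTruth(
        trees=trees,
        plot_size=plot_size,
        row_spacing=row_spacing,
        col_spacing=col_spacing,
        ground_coeffs=(ground_z0, ground_slope, 0.0),
        taper_coeffs=tuple(taper_coeffs),
        seed=seed,
    )


def _cone_points(rng, tree: TrueTree, apex_z: float, n: int) -> np.ndarray:
    """Points on a cone's lateral surface, apex up."""
    depth = min(0.4 * tree.height, 3.0 * tree.crown_radius)
    t = np.sqrt(rng.uniform(0, 1, n))  # area-weighted along the slant
    ang = rng.uniform(0, 2 * np.pi, n)
    ax, ay = tree.apex_xy
    r = t * tree.crown_radius
    return np.column_stack(
        [ax + r * np.cos(ang), ay + r * np.sin(ang), apex_z - t * depth]
    )


def _ellipsoid_cap_points(rng, tree: TrueTree, apex_z: float, n: int) -> np.ndarray:
    """Points on the upper half of an ellipsoid crown."""
    b = min(0.3 * tree.height, 2.0 * tree.crown_radius)
    cos_t = rng.uniform(0, 1, n)
    sin_t = np.sqrt(1 - cos_t**2)
    ang = rng.uniform(0, 2 * np.pi, n)
    ax, ay = tree.apex_xy
    return np.column_stack(
        [
            ax + tree.crown_radius * sin_t * np.cos(ang),
            ay + tree.crown_radius * sin_t * np.sin(ang),
            apex_z - b + b * cos_t,
        ]
    )


def sample_uls_cloud(
    truth: PlotTruth,
    density: float = 84.0,
    noise_sigma: float = 0.03,
    seed: int = 0,
) -> SimulatedScan:
    """Simulate an above-canopy scan: crown-surface + ground returns.

    The total point count is ``density × plot area``; crown points are split
    among trees proportionally to projected crown area, the remainder falls
    on the ground plane. Each tree's exact apex (ground + H at the leaning
    apex position) is always included, so with ``noise_sigma = 0`` the
    maximum z over a tree's points equals its true height above ground.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    area = truth.plot_size**2
    n_total = int(round(density * area))
    crown_areas = np.array([np.pi * t.crown_radius**2 for t in truth.trees])
    crown_frac = min(0.85, crown_areas.sum() / area) if len(truth.trees) else 0.0
    n_canopy = int(round(n_total * crown_frac))
    n_ground = n_total - n_canopy

    chunks, ids, classes = [], [], []
    if truth.trees:
        counts = rng.multinomial(n_canopy, crown_areas / crown_areas.sum())
        for tree, cnt in zip(truth.trees, counts):
            apex_z = float(truth.ground_z(tree.stem_x, tree.stem_y) + tree.height)
            cnt = max(int(cnt) - 1, 0)
            if tree.species_tag == "conifer-like":
                pts = _cone_points(rng, tree, apex_z, cnt)
            else:
                pts = _ellipsoid_cap_points(rng, tree, apex_z, cnt)
            ax, ay = tree.apex_xy
            pts = np.vstack([pts, [ax, ay, apex_z]])  # exact apex, last
            chunks.append(pts)
            ids.append(np.full(len(pts), tree.id))
            classes.append(np.full(len(pts), VEGETATION))
    gxy = rng.uniform(0, truth.plot_size, (n_ground, 2))
    gz = truth.ground_z(gxy[:, 0], gxy[:, 1])
    chunks.append(np.column_stack([gxy, gz]))
    ids.append(np.full(n_ground, -1))
    classes.append(np.full(n_ground, GROUND))

    xyz = np.vstack(chunks)
    if noise_sigma > 0:
        xyz = xyz + rng.normal(0, noise_sigma, xyz.shape)
    cloud = PointCloud(
        xyz=xyz, tree_id=np.concatenate(ids), classification=np.concatenate(classes)
    )
    return SimulatedScan(
        cloud=cloud, scan_kind="ULS", noise_sigma=noise_sigma, density=density
    )


def sample_bls_cloud(
    truth: PlotTruth,
    pts_per_stem_slice: float = 80.0,
    noise_sigma: float = 0.01,
    transform: RigidTransform2D | None = None,
    height_cap: float = 9.0,
    seed: int = 0,
    understory: bool = True,
    ground_density: float = 50.0,
) -> SimulatedScan:
    """Simulate an under-canopy scan: stem cylinders, ground and clutter.

    Stem points lie on circular cross-sections whose radius at height h
    follows the plot's configured taper, up to ``height_cap`` (the sensor's
    vertical reach). The whole cloud is expressed in a frame displaced from
    the plot frame by ``transform``, which is recorded as ground truth.
    ``pts_per_stem_slice`` is the expected number of stem returns inside one
    0.1-m-thick measurement slice (so 10× that per meter of trunk).
    """
    if height_cap <= 1.3:
        raise ValueError("height_cap must exceed breast height (1.3 m)")
    rng = np.random.default_rng(seed)
    tf = transform if transform is not None else RigidTransform2D()
    h_min = 0.2
    per_meter = pts_per_stem_slice / 0.1

    chunks, ids, classes = [], [], []
    for tree in truth.trees:
        h_max = min(tree.height - 0.1, height_cap)
        n_pts = max(int(round(per_meter * (h_max - h_min))), 1)
        h = rng.uniform(h_min, h_max, n_pts)
        r = np.asarray(truth.stem_diameter_cm(tree, h)) / 200.0  # cm -> m radius
        ang = rng.uniform(0, 2 * np.pi, n_pts)
        zg = float(truth.ground_z(tree.stem_x, tree.stem_y))
        chunks.append(
            np.column_stack(
                [
                    tree.stem_x + r * np.cos(ang),
                    tree.stem_y + r * np.sin(ang),
                    zg + h,
                ]
            )
        )
        ids.append(np.full(n_pts, tree.id))
        classes.append(np.full(n_pts, VEGETATION))

    n_ground = int(round(ground_density * truth.plot_size**2))
    gxy = rng.uniform(0, truth.plot_size, (n_ground, 2))
    chunks.append(np.column_stack([gxy, truth.ground_z(gxy[:, 0], gxy[:, 1])]))
    ids.append(np.full(n_ground, -1))
    classes.append(np.full(n_ground, GROUND))

    if understory:
        # clumped shrub returns below 1.5 m (locally dense, like real
        # understory, so they survive statistical denoising and genuinely
        # exercise the trunk detector's noise rejection)
        n_clumps = max(int(round(0.03 * truth.plot_size**2)), 1)
        centers = rng.uniform(0, truth.plot_size, (n_clumps, 2))
        for cx, cy in centers:
            n_u = 40
            uxy = rng.normal([cx, cy], 0.25, (n_u, 2))
            uh = np.clip(np.abs(rng.normal(0.0, 0.5, n_u)), 0.0, 1.5)
            uz = truth.ground_z(uxy[:, 0], uxy[:, 1]) + uh
            chunks.append(np.column_stack([uxy, uz]))
            ids.append(np.full(n_u, -1))
            classes.append(np.full(n_u, VEGETATION))

    xyz = np.vstack(chunks)
    if noise_sigma > 0:
        xyz = xyz + rng.normal(0, noise_sigma, xyz.shape)
    xyz = tf.apply_xyz(xyz)
    cloud = PointCloud(
        xyz=xyz, tree_id=np.concatenate(ids), classification=np.concatenate(classes)
    )
    return SimulatedScan(
        cloud=cloud,
        scan_kind="BLS",
        applied_transform=tf,
        noise_sigma=noise_sigma,
        pts_per_stem_slice=pts_per_stem_slice,
        height_cap=height_cap,
    )


def control_points(
    truth: PlotTruth,
    transform: RigidTransform2D,
    survey_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Surveyed reference poles in both frames for coarse registration.

    Four 2-m poles stand 1 m inside the plot corners. Returns
    ``(bls_xy, uls_xy)``: the pole positions as seen in the BLS frame (plot
    coordinates pushed through ``transform``) and in the ULS/plot frame,
    each perturbed by isotropic survey noise ``survey_sigma``.
    """
    s = truth.plot_size
    poles = np.array([[1.0, 1.0], [s - 1, 1.0], [s - 1, s - 1], [1.0, s - 1]])
    rng = np.random.default_rng(seed)
    uls = poles + (rng.normal(0, survey_sigma, poles.shape) if survey_sigma > 0 else 0.0)
    bls = transform.apply(poles)
    if survey_sigma > 0:
        bls = bls + rng.normal(0, survey_sigma, poles.shape)
    return bls, uls
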