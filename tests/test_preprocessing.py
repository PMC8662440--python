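"""Denoising, ground filtering, DEM construction and normalization."""

import numpy as np
import pytest

import lidarvol as lv
from lidarvol.cloud import GROUND, VEGETATION, DEMGrid, PointCloud
from lidarvol.preprocessing import (
    build_dem,
    classify_ground,
    normalize_heights,
    remove_outliers,
)


def _grid_cloud(n=20, spacing=1.0, z=0.0):
    gx, gy = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    return PointCloud(
        xyz=np.column_stack([gx.ravel(), gy.ravel(), np.full(n * n, z)])
    )


class TestRemoveOutliers:
    def test_gross_outlier_removed(self):
        base = _grid_cloud()
        cloud = PointCloud(xyz=np.vstack([base.xyz, [10.0, 10.0, 100.0]]))
        out = remove_outliers(cloud, k=8, n_sigma=3.0)
        assert len(out) == len(cloud) - 1
        assert out.z.max() < 50

    def test_homogeneous_cloud_interior_untouched(self):
        """On a uniform grid only hull-boundary artifacts may ever go; no
        interior point is an outlier at n_sigma >= 3."""
        cloud = _grid_cloud()
        for n_sigma in (3.0, 4.0, 6.0):
            out = remove_outliers(cloud, k=8, n_sigma=n_sigma)
            kept = {tuple(p) for p in out.xyz[:, :2]}
            interior = [
                (x, y)
                for x, y in cloud.xyz[:, :2]
                if 0 < x < 19 and 0 < y < 19
            ]
            assert all(p in kept for p in interior)
        assert len(remove_outliers(cloud, k=8, n_sigma=6.0)) == len(cloud)

    def test_injected_high_noise_mostly_removed(self, small_truth):
        scan = lv.sample_uls_cloud(small_truth, seed=3)
        n = len(scan.cloud)
        n_noise = n // 100
        rng = np.random.default_rng(0)
        noise = np.column_stack(
            [rng.uniform(0, 30, (n_noise, 2)), rng.uniform(50, 100, n_noise)]
        )
        cloud = PointCloud(
            xyz=np.vstack([scan.cloud.xyz, noise]),
            tree_id=np.concatenate([scan.cloud.tree_id, np.full(n_noise, -999)]),
        )
        out = remove_outliers(cloud, k=8, n_sigma=3.0)
        kept_noise = (out.tree_id == -999).sum()
        assert kept_noise <= 0.01 * n_noise

    def test_tiny_cloud_warns_and_passes_through(self):
        cloud = PointCloud(xyz=np.zeros((3, 3)))
        with pytest.warns(UserWarning):
            out = remove_outliers(cloud, k=8)
        assert len(out) == 3

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            remove_outliers(_grid_cloud(), k=0)


class TestClassifyGround:
    def test_pure_plane_is_all_ground(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 30, (3000, 2))
        cloud = PointCloud(
            xyz=np.column_stack([xy, 2.0 + 0.0004 * xy[:, 0]])
        )
        out = classify_ground(cloud)
        assert np.all(out.classification == GROUND)

    def test_plane_with_elevated_stems(self):
        """Ground recovered at >=99%; no elevated stem point labeled ground."""
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 30, (6000, 2))
        ground = np.column_stack([xy, np.zeros(6000)])
        n_s = 2000
        centers = rng.uniform(5, 25, (5, 2))
        which = rng.integers(0, 5, n_s)
        ang = rng.uniform(0, 2 * np.pi, n_s)
        stems = np.column_stack(
            [
                centers[which, 0] + 0.15 * np.cos(ang),
                centers[which, 1] + 0.15 * np.sin(ang),
                rng.uniform(0.6, 9.0, n_s),  # stems start above max_dist
            ]
        )
        cloud = PointCloud(
            xyz=np.vstack([ground, stems]),
            tree_id=np.concatenate([np.full(6000, -1), which]),
        )
        out = classify_ground(cloud)
        is_ground = out.classification == GROUND
        assert is_ground[:6000].mean() >= 0.99
        assert not np.any(is_ground[6000:])

    def test_partition_every_point_labeled_once(self, small_truth):
        scan = lv.sample_uls_cloud(small_truth, seed=5)
        out = classify_ground(scan.cloud)
        assert len(out.classification) == len(out)
        assert set(np.unique(out.classification)) <= {GROUND, VEGETATION}

    def test_degenerate_collinear_seeds_handled(self):
        """Collinear seeds don't crash the triangulation (the virtual corner
        vertices keep it 2D) and a flat line is still all ground."""
        xyz = np.column_stack(
            [np.linspace(0, 30, 50), np.zeros(50), np.zeros(50)]
        )
        out = classify_ground(PointCloud(xyz=xyz))
        assert np.all(out.classification == GROUND)

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            classify_ground(PointCloud(xyz=np.empty((0, 3))))


class TestBuildDem:
    def test_planar_recovery(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 20, (4000, 2))
        cloud = PointCloud(xyz=np.column_stack([xy, 2.0 + 0.001 * xy[:, 0]]))
        dem = build_dem(cloud, cell=1.0)
        cx, cy = dem.cell_centers()
        assert np.abs(dem.values - (2.0 + 0.001 * cx)).max() <= 0.001

    def test_idw_single_source(self):
        cloud = PointCloud(
            xyz=np.array([[0.5, 0.5, 3.0], [9.5, 0.5, 3.0], [0.5, 9.5, 3.0],
                          [9.5, 9.5, 3.0]])
        )
        dem = build_dem(cloud, cell=1.0)
        assert np.allclose(dem.values, 3.0)
        assert dem.fill_mask.sum() == dem.values.size - 4

    def test_8000_ground_returns_give_dem_within_5cm(self):
        """~8000 ground returns on a 30 m plot (the typical per-plot ground
        yield of the above-canopy scan) rasterize to within 5 cm of the
        generating plane, including ranging noise."""
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 30, (8000, 2))
        z = 2.0 + 0.0004 * xy[:, 0] + rng.normal(0, 0.03, 8000)
        dem = build_dem(PointCloud(xyz=np.column_stack([xy, z])), cell=1.0)
        cx, cy = dem.cell_centers()
        assert np.abs(dem.values - (2.0 + 0.0004 * cx)).max() <= 0.05

    def test_more_points_never_more_filled_cells(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 20, (100, 2))
        sparse = PointCloud(xyz=np.column_stack([xy, np.zeros(100)]))
        extra = rng.uniform(0, 20, (400, 2))
        dense = PointCloud(
            xyz=np.vstack([sparse.xyz, np.column_stack([extra, np.zeros(400)])])
        )
        # anchor the grid extent so both rasters cover the same cells
        corners = np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0], [20, 20, 0]])
        d_sparse = build_dem(PointCloud(xyz=np.vstack([sparse.xyz, corners])))
        d_dense = build_dem(PointCloud(xyz=np.vstack([dense.xyz, corners])))
        assert d_dense.fill_mask.sum() <= d_sparse.fill_mask.sum()

    def test_no_ground_points_raises(self):
        with pytest.raises(ValueError):
            build_dem(PointCloud(xyz=np.empty((0, 3))))


class TestNormalizeHeights:
    def test_simple_subtraction(self):
        dem = DEMGrid(origin=(0.0, 0.0), cell=1.0, values=np.full((3, 3), 1.2))
        cloud = PointCloud(xyz=np.array([[1.5, 1.5, 5.2]]))
        out = normalize_heights(cloud, dem)
        assert out.z_norm[0] == pytest.approx(4.0)

    def test_ground_normalizes_to_zero(self, small_truth):
        scan = lv.sample_uls_cloud(small_truth, noise_sigma=0.0, seed=7)
        labeled = classify_ground(scan.cloud)
        dem = build_dem(labeled.subset(labeled.classification == GROUND))
        out = normalize_heights(labeled, dem)
        true_ground = (out.classification == GROUND) & (out.tree_id == -1)
        assert np.abs(out.z_norm[true_ground]).max() <= 0.5

    def test_zero_dem_is_identity(self):
        dem = DEMGrid(origin=(0.0, 0.0), cell=1.0, values=np.zeros((5, 5)))
        cloud = _grid_cloud(5, z=3.3)
        out = normalize_heights(cloud, dem)
        assert np.array_equal(out.z_norm, cloud.z)

    def test_tree_heights_recovered(self, small_truth):
        """Per-tree max normalized height equals true height within noise
        plus DEM error."""
        sigma = 0.03
        scan = lv.sample_uls_cloud(small_truth, noise_sigma=sigma, seed=8)
        labeled = classify_ground(scan.cloud)
        dem = build_dem(labeled.subset(labeled.classification == GROUND))
        out = normalize_heights(labeled, dem)
        for t in small_truth.trees:
            got = out.z_norm[out.tree_id == t.id].max()
            assert got == pytest.approx(t.height, abs=5 * sigma + 0.05)
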