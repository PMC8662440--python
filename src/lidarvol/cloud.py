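"""Point-cloud and DEM containers shared by every pipeline stage.

Coordinates are always meters. Per-point attributes are parallel numpy
arrays; ``tree_id`` carries simulation/segmentation truth (-1 = no tree),
``classification`` uses LAS-style codes, and ``z_norm`` holds heights above
the ground DEM once :func:`lidarvol.preprocessing.normalize_heights` has run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# LAS-style classification codes
UNCLASSIFIED = 1
GROUND = 2
VEGETATION = 5
NOISE = 7


@dataclass
class PointCloud:
    """A 3D point cloud with optional per-point labels.

    Parameters
    ----------
    xyz : ndarray of shape (n, 3)
        Point coordinates in meters.
    tree_id : ndarray of shape (n,), optional
        Source/assigned tree id per point; -1 means ground or unassigned.
    classification : ndarray of shape (n,), optional
        LAS-style class codes (2 = ground, 5 = vegetation, 7 = noise).
    z_norm : ndarray of shape (n,), optional
        Height above the ground DEM, meters.
    """

    xyz: np.ndarray
    tree_id: np.ndarray | None = None
    classification: np.ndarray | None = None
    z_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        for name in ("tree_id", "classification"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int).reshape(-1)
                if arr.shape[0] != len(self):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)
        if self.z_norm is not None:
            self.z_norm = np.asarray(self.z_norm, dtype=float).reshape(-1)
            if self.z_norm.shape[0] != len(self):
                raise ValueError("z_norm length mismatch")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def heights(self) -> np.ndarray:
        """Normalized heights if available, otherwise raw z."""
        return self.z_norm if self.z_norm is not None else self.z

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to ``mask`` (bool or index array)."""
        return PointCloud(
            xyz=self.xyz[mask],
            tree_id=None if self.tree_id is None else self.tree_id[mask],
            classification=(
                None if self.classification is None else self.classification[mask]
            ),
            z_norm=None if self.z_norm is None else self.z_norm[mask],
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            xyz=self.xyz.copy(),
            tree_id=None if self.tree_id is None else self.tree_id.copy(),
            classification=(
                None if self.classification is None else self.classification.copy()
            ),
            z_norm=None if self.z_norm is None else self.z_norm.copy(),
        )


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    """Write an ASCII XYZ file: ``x y z [tree_id]``, one point per line."""
    path = Path(path)
    cols = [cloud.xyz]
    fmt = ["%.6f", "%.6f", "%.6f"]
    if cloud.tree_id is not None:
        cols.append(cloud.tree_id[:, None].astype(float))
        fmt.append("%d")
    np.savetxt(path, np.hstack(cols), fmt=fmt)


def read_xyz(path: str | Path) -> PointCloud:
    """Read an ASCII XYZ file written by :func:`write_xyz`."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 3:
        raise ValueError("XYZ file must have at least 3 columns")
    tree_id = data[:, 3].astype(int) if data.shape[1] >= 4 else None
    return PointCloud(xyz=data[:, :3], tree_id=tree_id)


@dataclass
class DEMGrid:
    """Regular 1-m-class elevation raster with an IDW fill mask.

    ``values[i, j]`` is the elevation of the cell whose lower-left corner is
    ``(origin[0] + j*cell, origin[1] + i*cell)``; ``fill_mask`` marks cells
    whose value was interpolated rather than averaged from ground returns.
    """

    origin: tuple[float, float]
    cell: float
    values: np.ndarray
    fill_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.fill_mask is None:
            self.fill_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.fill_mask = np.asarray(self.fill_mask, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DEM must be gap-free (finite everywhere)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing (x, y), clipped to the grid edge.

        Points outside the DEM extent use the nearest edge cell.
        """
        j = np.clip(
            np.floor((np.asarray(x) - self.origin[0]) / self.cell).astype(int),
            0,
            self.values.shape[1] - 1,
        )
        i = np.clip(
            np.floor((np.asarray(y) - self.origin[1]) / self.cell).astype(int),
            0,
            self.values.shape[0] - 1,
        )
        return i, j

    def elevation_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Ground elevation vertically below (x, y)."""
        i, j = self.cell_index(x, y)
        return self.values[i, j]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped like values."""
        ny, nx = self.values.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell
        return np.meshgrid(cx, cy)

    def to_ascii(self, path: str | Path) -> None:
        """Export as an ESRI ASCII grid (row 0 printed as the top row)."""
        ny, nx = self.values.shape
        header = (
            f"ncols {nx}\nnrows {ny}\n"
            f"xllcorner {self.origin[0]:.6f}\nyllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell:.6f}\nNODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values[::-1], fmt="%.4f")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "DEMGrid":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)[::-1]
        return cls(
            origin=(hdr["xllcorner"], hdr["yllcorner"]),
            cell=hdr["cellsize"],
            values=values,
        )
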