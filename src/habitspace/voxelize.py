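"""Point-cloud voxelization and the 32-cubed model-input pipeline.

The model consumes cubic occupancy grids: a normalized cloud (max norm 1)
is rasterized onto a [-1, 1]^3 grid at a working resolution (64 by
default), zero-padded to a common side if needed, then block-max
downsampled (non-overlapping max pooling, via skimage ``block_reduce``) to
the final 32^3 input.  ``voxels_to_points`` inverts the representation
well enough to measure aspect ratios of decoded volumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import block_reduce

from .geometry import PointCloud, principal_frame


class EmptyShapeError(ValueError):
    """No voxel reaches the requested threshold."""


@dataclasses.dataclass
class VoxelGrid:
    """Cubic occupancy grid with physical frame metadata.

    ``origin`` is the corner of voxel (0,0,0); the center of voxel
    (i, j, k) sits at origin + (i+0.5, j+0.5, k+0.5) * spacing.
    """

    values: np.ndarray
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([-1.0, -1.0, -1.0])
    )
    spacing: float = 0.0
    binary: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError(f"voxel grid must be cubic, got shape {v.shape}")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("voxel values must lie in [0, 1]")
        self.values = v
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing == 0.0:
            self.spacing = 2.0 / v.shape[0]
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def side(self) -> int:
        return self.values.shape[0]


def rasterize(
    pc: PointCloud,
    resolution: int = 64,
    fill: Literal["surface", "convex_solid"] = "convex_solid",
) -> VoxelGrid:
    """Rasterize a normalized cloud onto a [-1, 1]^3 occupancy grid.

    ``surface``: a voxel is occupied iff it contains at least one point.
    ``convex_solid``: a voxel is occupied iff its center lies inside the
    convex hull of the cloud, or it contains a point (the union keeps
    surface occupancy a subset of solid occupancy even where a face plane
    passes between a point and its voxel's center).
    """
    if len(pc) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    if resolution < 8 or resolution % 2:
        raise ValueError("resolution must be an even integer >= 8")
    spacing = 2.0 / resolution
    values = np.zeros((resolution,) * 3, dtype=np.float32)
    if fill == "surface":
        idx = np.floor((pc.points + 1.0) / spacing).astype(int)
        idx = np.clip(idx, 0, resolution - 1)
        values[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    elif fill == "convex_solid":
        hull = ConvexHull(pc.points)
        eqs = hull.equations.astype(np.float32)  # A x + b <= 0 inside
        axis = (np.arange(resolution) + 0.5) * spacing - 1.0
        # only voxels inside the cloud's bounding box can be occupied
        lo = np.searchsorted(axis, pc.points.min(axis=0) - spacing)
        hi = np.searchsorted(axis, pc.points.max(axis=0) + spacing)
        gx, gy, gz = np.meshgrid(
            axis[lo[0] : hi[0]], axis[lo[1] : hi[1]], axis[lo[2] : hi[2]],
            indexing="ij",
        )
        centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3).astype(np.float32)
        inside = np.empty(len(centers), dtype=bool)
        for start in range(0, len(centers), 16384):  # bound the F x chunk buffer
            chunk = centers[start : start + 16384]
            inside[start : start + 16384] = np.all(
                chunk @ eqs[:, :3].T <= -eqs[:, 3] + 1e-6, axis=1
            )
        sub = inside.reshape(gx.shape)
        values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
        idx = np.clip(
            np.floor((pc.points + 1.0) / spacing).astype(int), 0, resolution - 1
        )
        values[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    else:
        raise ValueError(f"unknown fill mode {fill!r}")
    return VoxelGrid(values, origin=np.array([-1.0, -1.0, -1.0]), spacing=spacing)


def pad_to_cube(grid: VoxelGrid, target: int) -> VoxelGrid:
    """Zero-pad a grid to ``target`` per side, content centered.

    An odd margin puts the extra zero layer on the high-index side.  The
    physical origin shifts so voxel centers of the original content are
    preserved; the value sum is conserved.
    """
    side = grid.side
    if target < side:
        raise ValueError(f"target side {target} smaller than current side {side}")
    if target == side:
        return grid
    lo = (target - side) // 2
    hi = target - side - lo
    values = np.pad(grid.values, [(lo, hi)] * 3)
    origin = grid.origin - lo * grid.spacing
    return VoxelGrid(values, origin=origin, spacing=grid.spacing, binary=grid.binary)


def block_max_downsample(grid: VoxelGrid, factor: int = 2) -> VoxelGrid:
    """Max over non-overlapping ``factor``-cubed blocks (skimage block_reduce)."""
    if factor < 1 or grid.side % factor:
        raise ValueError(
            f"grid side {grid.side} not divisible by downsample factor {factor}"
        )
    values = block_reduce(grid.values, (factor,) * 3, np.max)
    return VoxelGrid(
        values,
        origin=grid.origin,
        spacing=grid.spacing * factor,
        binary=grid.binary,
    )


def voxels_to_points(grid: VoxelGrid, threshold: float = 0.5) -> PointCloud:
    """Centers of voxels with value >= threshold, in physical coordinates."""
    idx = np.argwhere(grid.values >= threshold)
    if idx.size == 0:
        raise EmptyShapeError(f"no voxel reaches threshold {threshold}")
    pts = grid.origin + (idx + 0.5) * grid.spacing
    return PointCloud(pts)


def cloud_to_model_input(
    pc: PointCloud,
    final_side: int = 32,
    working_resolution: int = 64,
    fill: Literal["surface", "convex_solid"] = "convex_solid",
) -> VoxelGrid:
    """Full rasterize -> pad -> block-max pipeline to the model input side."""
    if working_resolution % final_side:
        raise ValueError("working_resolution must be a multiple of final_side")
    grid = rasterize(pc, resolution=working_resolution, fill=fill)
    return block_max_downsample(grid, factor=working_resolution // final_side)


def aligned_model_input(
    pc: PointCloud,
    final_side: int = 32,
    working_resolution: int | None = None,
    fill: Literal["surface", "convex_solid"] = "convex_solid",
) -> VoxelGrid:
    """Model-input grid for an arbitrarily oriented cloud.

    Rotates the cloud into its principal frame (L along z, M along y, S
    along x, third-moment sign convention), normalizes to max norm 1, then
    runs the rasterize -> block-max pipeline.  The convolutional model is
    not rotation invariant, so this alignment is applied to every input.
    """
    coords = principal_frame(pc)
    coords = coords / np.linalg.norm(coords, axis=1).max()
    aligned = PointCloud(coords, source_id=pc.source_id)
    if working_resolution is None:
        working_resolution = 2 * final_side
    return cloud_to_model_input(
        aligned, final_side=final_side, working_resolution=working_resolution, fill=fill
    )


# ---------------------------------------------------------------------------
# Persistence


def save_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Raw little-endian float32 block plus a JSON metadata sidecar."""
    path = Path(path)
    grid.values.astype("<f4").tofile(path)
    meta = {
        "side": grid.side,
        "origin": list(grid.origin),
        "spacing": grid.spacing,
        "binary": grid.binary,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def load_grid(path: str | Path) -> VoxelGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values = np.fromfile(path, dtype="<f4").reshape((meta["side"],) * 3)
    return VoxelGrid(
        values,
        origin=np.array(meta["origin"]),
        spacing=meta["spacing"],
        binary=meta["binary"],
    )


def save_dataset(
    grids: dict[str, VoxelGrid], path: str | Path, compression: str = "gzip"
) -> Path:
    """Batch container: one HDF5 dataset per sample id."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for sample_id, grid in grids.items():
            ds = fh.create_dataset(
                sample_id, data=grid.values, compression=compression
            )
            ds.attrs["origin"] = grid.origin
            ds.attrs["spacing"] = grid.spacing
            ds.attrs["binary"] = grid.binary
    return path


def load_dataset(path: str | Path) -> dict[str, VoxelGrid]:
    out: dict[str, VoxelGrid] = {}
    with h5py.File(path, "r") as fh:
        for sample_id in fh:
            ds = fh[sample_id]
            out[sample_id] = VoxelGrid(
                ds[()],
                origin=np.array(ds.attrs["origin"]),
                spacing=float(ds.attrs["spacing"]),
                binary=bool(ds.attrs["binary"]),
            )
    return out
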