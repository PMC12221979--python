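"""Point-cloud ingestion, normalization, PCA axis lengths, and hull metrics.

The ingestion path mirrors the standard preprocessing of simulated crystal
surfaces: read an ``.xyz``-style text file into an N x 3 array, move the
centroid to the origin, scale by the maximum Euclidean norm, and measure
the particle with (a) the singular values of the centered coordinates
(giving the S:M:L axis system) and (b) the convex hull's surface area and
volume via Qhull.

Singular values are divided by sqrt(N) so they are root-mean-square extents,
independent of how densely the surface was sampled; only their ratios feed
the Zingg classifier, so the convention does not affect class labels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull

from . import zingg


class DegenerateCloudError(ValueError):
    """Raised when a point cloud has no usable spatial extent."""


class XYZParseError(ValueError):
    """Raised when an XYZ file cannot be parsed; carries the line number."""


@dataclasses.dataclass
class PointCloud:
    """An N x 3 set of Cartesian surface coordinates with provenance."""

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be N x 3, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclasses.dataclass(frozen=True)
class AxisTriple:
    """Sorted RMS extents S <= M <= L of a centered cloud.

    ``degenerate`` flags rank-deficient clouds (S == 0), which are reported
    rather than raised so that batch runs never abort.
    """

    S: float
    M: float
    L: float
    degenerate: bool = False

    @property
    def s_m(self) -> float:
        return self.S / self.M if self.M > 0 else 0.0

    @property
    def m_l(self) -> float:
        return self.M / self.L if self.L > 0 else 0.0


@dataclasses.dataclass(frozen=True)
class ShapeRecord:
    """Per-particle shape features: aspect ratios, class, hull metrics."""

    s_m: float
    m_l: float
    zingg_class: str
    surface_area: float
    volume: float
    sa_vol: float


def read_xyz(path: str | Path, dialect: Literal["bare", "header"] = "bare") -> PointCloud:
    """Read a plain-text XYZ point cloud (one ``x y z`` triple per line).

    ``dialect="header"`` expects a leading point-count line (the common
    ``.xyz`` chemical-file convention, element symbols not required).
    Lines starting with ``#`` and blank lines are skipped.  Rows with an
    element symbol as first token (``C 1.0 2.0 3.0``) are accepted in
    either dialect: the trailing three tokens must parse as floats.
    """
    path = Path(path)
    rows: list[list[float]] = []
    expected: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if dialect == "header" and expected is None and len(tokens) == 1:
                try:
                    expected = int(tokens[0])
                    continue
                except ValueError as exc:
                    raise XYZParseError(
                        f"{path}:{lineno}: expected point-count header, got {line!r}"
                    ) from exc
            if len(tokens) == 4:  # element-symbol column
                tokens = tokens[1:]
            if len(tokens) != 3:
                raise XYZParseError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(tokens)} tokens"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise XYZParseError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                ) from exc
    if expected is not None and expected != len(rows):
        raise XYZParseError(
            f"{path}: header declares {expected} points but {len(rows)} were read"
        )
    return PointCloud(np.array(rows).reshape(-1, 3), source_id=str(path))


def write_xyz(
    pc: PointCloud | np.ndarray,
    path: str | Path,
    dialect: Literal["bare", "header"] = "bare",
) -> Path:
    """Write points as plain-text triples, ``%.6f``, optionally count-headed."""
    pts = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, dtype=float)
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "header":
            fh.write(f"{len(pts)}\n")
        for x, y, z in pts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    return path


def center_and_normalize(pc: PointCloud) -> PointCloud:
    """Translate the centroid to the origin and scale so max ||p|| == 1.

    Idempotent; raises :class:`DegenerateCloudError` when all points
    coincide (no scale can be defined).
    """
    pts = pc.points - pc.points.mean(axis=0)
    scale = np.linalg.norm(pts, axis=1).max()
    if scale <= 0.0:
        raise DegenerateCloudError("all points identical; cannot normalize")
    return PointCloud(pts / scale, source_id=pc.source_id)


def pca_axes(pc: PointCloud, rank_tol: float = 1e-9) -> AxisTriple:
    """RMS extents along the principal axes of the centered cloud.

    The singular values of the centered N x 3 coordinate matrix, divided by
    sqrt(N), are the RMS extents along the principal directions; sorted
    ascending they form (S, M, L).  A cloud of rank < 3 yields S == 0 with
    the ``degenerate`` flag set.
    """
    if len(pc) < 4:
        raise ValueError(f"need at least 4 points for PCA axes, got {len(pc)}")
    centered = pc.points - pc.points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False) / np.sqrt(len(pc))
    s, m, l = np.sort(sv)
    if l <= rank_tol:
        return AxisTriple(0.0, 0.0, float(l), degenerate=True)
    degenerate = bool(s / l < rank_tol)
    if degenerate:
        s = 0.0
    return AxisTriple(float(s), float(m), float(l), degenerate=degenerate)


def principal_frame(pc: PointCloud) -> np.ndarray:
    """Rotate a centered cloud into its principal frame (L->z, M->y, S->x).

    Axis signs are fixed by making each principal direction's third moment
    non-negative, giving a deterministic orientation for voxelization.
    Returns the rotated coordinates (the input cloud is not modified).
    """
    centered = pc.points - pc.points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    # rows of vt ordered by descending singular value: L, M, S -> map to z, y, x
    axes = vt[::-1]  # now S, M, L
    coords = centered @ axes.T  # columns: S, M, L extents -> x, y, z
    for k in range(3):
        if np.sum(coords[:, k] ** 3) < 0:
            coords[:, k] = -coords[:, k]
    return coords


def hull_metrics(pc: PointCloud) -> tuple[float, float]:
    """Surface area and volume of the cloud's convex hull (Qhull).

    Raises
    ------
    DegenerateCloudError
        For coplanar or collinear input, where no 3-D hull exists.
    """
    if len(pc) < 4:
        raise DegenerateCloudError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(pc.points)
    except Exception as exc:  # Qhull raises its own error hierarchy
        raise DegenerateCloudError(f"convex hull failed: {exc}") from exc
    return float(hull.area), float(hull.volume)


def shape_record(
    pc: PointCloud, threshold: float = zingg.DEFAULT_THRESHOLD
) -> ShapeRecord:
    """Full shape feature record: PCA ratios, Zingg class, hull metrics."""
    axes = pca_axes(pc)
    area, volume = hull_metrics(pc)
    label = zingg.classify(axes.s_m, axes.m_l, threshold)
    return ShapeRecord(
        s_m=axes.s_m,
        m_l=axes.m_l,
        zingg_class=label,
        surface_area=area,
        volume=volume,
        sa_vol=area / volume,
    )
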