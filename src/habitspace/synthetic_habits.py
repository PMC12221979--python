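"""Synthetic crystal-habit generator.

Real habit datasets come from kinetic Monte Carlo growth simulations whose
equilibrium shapes are simple convex polyhedra.  This module emulates that
output directly: a habit is the bounded intersection of facet halfspaces
(a Wulff-style construction), sampled on its surface to give an ``.xyz``
point cloud, with a ground-truth Zingg label attached at generation time.

Three crystal systems are supported, differing in the symmetry constraints
they impose on the facet families:

* ``monoclinic`` — a parallelepiped habit with the unique angle beta drawn
  from [95, 125] degrees; all three facet-pair distances independent, so
  all four Zingg classes (block, needle, lath, plate) are reachable.
* ``tetragonal`` — square-prism habit (gamma = 90, the two in-plane facet
  distances symmetry-equivalent).  The two in-plane principal extents are
  equal, so laths are geometrically impossible.
* ``hexagonal`` — hexagonal-prism habit (gamma = 120, one distance for the
  whole in-plane family); laths are impossible for the same reason.

Ground-truth aspect ratios come from the exact second moment of the uniform
solid over the polyhedron (closed-form tetrahedral decomposition), i.e. the
infinite-sample limit of the covariance-eigenvalue Zingg oracle.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, HalfspaceIntersection

from . import zingg
from .geometry import PointCloud, write_xyz

CrystalSystem = Literal["monoclinic", "tetragonal", "hexagonal"]

CRYSTAL_SYSTEMS = ("monoclinic", "tetragonal", "hexagonal")

#: Zingg classes reachable per crystal system: equal in-plane axes forbid laths.
ALLOWED_CLASSES = {
    "monoclinic": ("block", "needle", "lath", "plate"),
    "tetragonal": ("block", "needle", "plate"),
    "hexagonal": ("block", "needle", "plate"),
}


class UnboundedHabitError(ValueError):
    """The facet halfspaces do not enclose a bounded solid."""


class DegenerateHabitError(ValueError):
    """The halfspace intersection has (near-)zero volume."""


class HabitConfigurationError(ValueError):
    """A dataset request violates a crystallographic constraint."""


@dataclasses.dataclass
class HabitSpec:
    """A convex habit as facet normals and perpendicular facet distances."""

    crystal_system: str
    cell_angles: tuple[float, float, float]  # (alpha, beta, gamma) in degrees
    facet_normals: np.ndarray  # F x 3 unit vectors
    facet_distances: np.ndarray  # F positive lengths
    n_surface_points: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        self.facet_normals = np.asarray(self.facet_normals, dtype=float)
        self.facet_distances = np.asarray(self.facet_distances, dtype=float)
        if self.crystal_system not in CRYSTAL_SYSTEMS:
            raise ValueError(f"unknown crystal system {self.crystal_system!r}")
        norms = np.linalg.norm(self.facet_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("facet normals must be unit length (tol 1e-9)")
        if np.any(self.facet_distances <= 0):
            raise ValueError("facet distances must be positive")
        gamma = self.cell_angles[2]
        if self.crystal_system == "tetragonal" and abs(gamma - 90.0) > 1e-9:
            raise ValueError("tetragonal specs require gamma = 90 degrees")
        if self.crystal_system == "hexagonal" and abs(gamma - 120.0) > 1e-9:
            raise ValueError("hexagonal specs require gamma = 120 degrees")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Label attached to a generated habit at generation time."""

    zingg_class: str
    crystal_system: str
    generator_aspect_targets: tuple[float, float]  # (s_m, m_l) targets
    s_m: float = float("nan")  # measured on the exact solid
    m_l: float = float("nan")


# ---------------------------------------------------------------------------
# Halfspace intersection and exact solid moments


def _check_bounded(normals: np.ndarray) -> None:
    """A halfspace set {n_i . x <= d_i} (d_i > 0) is bounded iff the origin
    lies strictly inside the convex hull of the outward normals."""
    try:
        hull = ConvexHull(normals)
    except Exception as exc:
        raise UnboundedHabitError(
            f"unbounded habit: facet normals do not span 3-D ({exc})"
        ) from exc
    # hull facet planes: A.x + b <= 0 inside; origin strictly inside iff b < 0
    if np.any(hull.equations[:, 3] > -1e-9):
        raise UnboundedHabitError(
            "unbounded habit: facet normals do not positively span 3-D"
        )


def halfspace_vertices(
    normals: np.ndarray, distances: np.ndarray, merge_tol: float = 1e-9
) -> np.ndarray:
    """Vertices of the bounded intersection of {x : n_i . x <= d_i}.

    The origin must be an interior point (all distances positive).
    Duplicate intersections arising from >3 facets meeting at a vertex are
    merged within ``merge_tol``.
    """
    normals = np.asarray(normals, dtype=float)
    distances = np.asarray(distances, dtype=float)
    _check_bounded(normals)
    halfspaces = np.column_stack([normals, -distances])
    try:
        hi = HalfspaceIntersection(halfspaces, np.zeros(3))
    except Exception as exc:  # Qhull precision failure on sliver solids
        raise DegenerateHabitError(f"halfspace intersection failed: {exc}") from exc
    verts = hi.intersections
    # merge near-duplicates deterministically
    scale = max(np.abs(verts).max(), 1.0)
    keys = np.round(verts / (merge_tol * scale)).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return verts[np.sort(idx)]


def solid_moments(vertices: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact (volume, centroid, covariance) of the uniform solid hull.

    Uses a Delaunay tetrahedral decomposition and the closed-form second
    moment of a tetrahedron: for vertices v_1..v_4 with sum s,
    int_T x x^T dV = (V/20) (sum_i v_i v_i^T + s s^T).
    """
    vertices = np.asarray(vertices, dtype=float)
    try:
        tri = Delaunay(vertices)
    except Exception as exc:  # flat/sliver solids break the triangulation
        raise DegenerateHabitError(f"degenerate habit: {exc}") from exc
    tets = vertices[tri.simplices]  # (T, 4, 3)
    d = tets[:, 1:] - tets[:, :1]
    vols = np.abs(np.linalg.det(d)) / 6.0
    V = vols.sum()
    if V <= 1e-12:
        raise DegenerateHabitError(f"habit volume {V:.3e} below tolerance")
    cents = tets.mean(axis=1)
    centroid = (vols[:, None] * cents).sum(axis=0) / V
    ssum = tets.sum(axis=1)  # (T, 3)
    m2 = np.einsum("t,tia,tib->ab", vols / 20.0, tets, tets)
    m2 += np.einsum("t,ta,tb->ab", vols / 20.0, ssum, ssum)
    cov = m2 / V - np.outer(centroid, centroid)
    return float(V), centroid, cov


def oracle_ratios(vertices: np.ndarray) -> tuple[float, float]:
    """(S:M, M:L) aspect ratios of the uniform solid, from exact moments."""
    _, _, cov = solid_moments(vertices)
    eig = np.sort(np.linalg.eigvalsh(cov))
    eig = np.clip(eig, 0.0, None)
    s, m, l = np.sqrt(eig)
    return float(s / m), float(m / l)


def solid_sample(vertices: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of the solid hull (tetra decomposition; for oracles)."""
    vertices = np.asarray(vertices, dtype=float)
    tri = Delaunay(vertices)
    tets = vertices[tri.simplices]
    d = tets[:, 1:] - tets[:, :1]
    vols = np.abs(np.linalg.det(d)) / 6.0
    choice = rng.choice(len(tets), size=n, p=vols / vols.sum())
    # uniform barycentric coordinates in a tetrahedron (folded exponential trick)
    e = -np.log(rng.random((n, 4)))
    bary = e / e.sum(axis=1, keepdims=True)
    return np.einsum("nk,nkd->nd", bary, tets[choice])


# ---------------------------------------------------------------------------
# Habit specs per crystal system


def _prism_normals(n_sides: int) -> np.ndarray:
    """In-plane facet normals of a regular prism plus the two cap normals."""
    ang = 2.0 * np.pi * np.arange(n_sides) / n_sides
    side = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n_sides)])
    caps = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    return np.vstack([side, caps])


def tetragonal_spec(
    c_over_a: float, scale: float = 1.0, n_surface_points: int = 400, seed: int = 0
) -> HabitSpec:
    """Square prism: four equivalent in-plane facets at distance a, caps at c."""
    normals = _prism_normals(4)
    a = scale
    dists = np.array([a, a, a, a, c_over_a * a, c_over_a * a])
    return HabitSpec(
        "tetragonal", (90.0, 90.0, 90.0), normals, dists, n_surface_points, seed
    )


def hexagonal_spec(
    c_over_a: float, scale: float = 1.0, n_surface_points: int = 400, seed: int = 0
) -> HabitSpec:
    """Hexagonal prism: six-member in-plane family sharing one distance."""
    normals = _prism_normals(6)
    a = scale
    dists = np.array([a] * 6 + [c_over_a * a] * 2)
    return HabitSpec(
        "hexagonal", (90.0, 90.0, 120.0), normals, dists, n_surface_points, seed
    )


def monoclinic_spec(
    half_extents: Sequence[float],
    beta: float = 105.0,
    n_surface_points: int = 400,
    seed: int = 0,
) -> HabitSpec:
    """Parallelepiped habit with the monoclinic unique angle beta (degrees).

    Edge directions: a along x, b along y, c in the x-z plane at ``beta``
    from a.  Facet normals are the (normalized) cross products of edge
    pairs; ``half_extents`` are the three perpendicular facet distances.
    """
    b_rad = np.radians(beta)
    e_a = np.array([1.0, 0.0, 0.0])
    e_b = np.array([0.0, 1.0, 0.0])
    e_c = np.array([np.cos(b_rad), 0.0, np.sin(b_rad)])
    pairs = [np.cross(e_b, e_c), np.cross(e_c, e_a), np.cross(e_a, e_b)]
    normals, dists = [], []
    for n, h in zip(pairs, half_extents):
        n = n / np.linalg.norm(n)
        normals.extend([n, -n])
        dists.extend([h, h])
    return HabitSpec(
        "monoclinic",
        (90.0, beta, 90.0),
        np.array(normals),
        np.array(dists),
        n_surface_points,
        seed,
    )


def make_habit(spec: HabitSpec) -> tuple[np.ndarray, GroundTruth]:
    """Build the polyhedron for a spec and label it with the Zingg oracle.

    Returns the vertex set of the bounded halfspace intersection and a
    :class:`GroundTruth` whose class comes from the exact solid-covariance
    Zingg oracle (the infinite-sample limit of dense uniform sampling).
    """
    verts = halfspace_vertices(spec.facet_normals, spec.facet_distances)
    s_m, m_l = oracle_ratios(verts)
    gt = GroundTruth(
        zingg_class=zingg.classify(s_m, m_l),
        crystal_system=spec.crystal_system,
        generator_aspect_targets=(s_m, m_l),
        s_m=s_m,
        m_l=m_l,
    )
    return verts, gt


def sample_surface(
    vertices: np.ndarray,
    n_points: int,
    seed: int | np.random.Generator = 0,
    source_id: str = "",
) -> PointCloud:
    """Sample the hull surface uniformly by area (emulating surface output).

    Every sampled point lies exactly on a facet plane (barycentric
    construction on the hull triangles); expected counts per facet are
    proportional to facet area.  Deterministic under a fixed seed.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    vertices = np.asarray(vertices, dtype=float)
    try:
        hull = ConvexHull(vertices)
    except Exception as exc:
        raise DegenerateHabitError(f"open or degenerate surface: {exc}") from exc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tris = vertices[hull.simplices]  # (T, 3, 3)
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
    )
    choice = rng.choice(len(tris), size=n_points, p=areas / areas.sum())
    u, v = rng.random((2, n_points))
    flip = u + v > 1.0
    u[flip], v[flip] = 1.0 - u[flip], 1.0 - v[flip]
    t = tris[choice]
    pts = t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])
    return PointCloud(pts, source_id=source_id)


# ---------------------------------------------------------------------------
# Dataset generation


@dataclasses.dataclass
class DatasetConfig:
    """Per-class, per-system habit counts plus sampling parameters.

    ``counts`` maps (crystal_system, zingg_class) to the number of habits.
    ``jitter_sigma`` is the isotropic surface-noise scale as a fraction of
    the maximum extent, emulating growth-front roughness (0 disables).
    """

    counts: dict[tuple[str, str], int]
    n_surface_points: int = 400
    jitter_sigma: float = 0.003
    class_margin: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for (system, cls), n in self.counts.items():
            if system not in CRYSTAL_SYSTEMS:
                raise HabitConfigurationError(f"unknown crystal system {system!r}")
            if cls not in zingg.CLASSES:
                raise HabitConfigurationError(f"unknown Zingg class {cls!r}")
            if cls not in ALLOWED_CLASSES[system]:
                raise HabitConfigurationError(
                    f"{cls} habits are impossible in the {system} system "
                    "(two equal in-plane axes)"
                )
            if n < 0:
                raise HabitConfigurationError("counts must be non-negative")


def balanced_counts(
    n_per_class: int,
    systems: Sequence[str] = CRYSTAL_SYSTEMS,
) -> dict[tuple[str, str], int]:
    """Balanced class counts spread over the systems that allow each class."""
    counts: dict[tuple[str, str], int] = {}
    for cls in zingg.CLASSES:
        allowed = [s for s in systems if cls in ALLOWED_CLASSES[s]]
        base, extra = divmod(n_per_class, len(allowed))
        for i, system in enumerate(allowed):
            counts[(system, cls)] = base + (1 if i < extra else 0)
    return counts


_RATIO_RANGE = (0.15, 1.0)


def _sample_target_ratios(
    cls: str, margin: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Log-uniform (s_m, m_l) targets inside the class's quadrant.

    ``margin`` keeps targets away from the 0.66 boundary so that surface
    sampling and jitter do not flip the label.
    """
    lo, hi = _RATIO_RANGE
    t = zingg.DEFAULT_THRESHOLD

    def log_u(a: float, b: float) -> float:
        return float(np.exp(rng.uniform(np.log(a), np.log(b))))

    low_band = (lo, t - margin)
    high_band = (t + margin, hi)
    s_band = high_band if cls in ("block", "needle") else low_band
    m_band = high_band if cls in ("block", "plate") else low_band
    return log_u(*s_band), log_u(*m_band)


def _spec_for(
    system: str,
    cls: str,
    targets: tuple[float, float],
    n_surface_points: int,
    seed: int,
    rng: np.random.Generator,
) -> HabitSpec:
    s_m_t, m_l_t = targets
    if system == "monoclinic":
        beta = float(rng.uniform(95.0, 125.0))
        # half extents proportional to target S:M:L; the beta skew perturbs
        # the realized ratios, caught by the oracle-check/resample loop
        h = np.array([s_m_t * m_l_t, m_l_t, 1.0])
        return monoclinic_spec(h, beta=beta, n_surface_points=n_surface_points, seed=seed)
    # prisms: two in-plane extents equal.  needle -> tall (c/a > 1, m_l is
    # a:c); plate -> flat (c/a < 1, s_m is c:a); block -> near-isometric.
    ratio = m_l_t if cls == "needle" else s_m_t
    factory = tetragonal_spec if system == "tetragonal" else hexagonal_spec
    # calibrate cap distance so the solid extent ratio matches the target
    rho = _inplane_rms(system)
    if cls == "needle":
        c_over_a = rho / ratio * np.sqrt(3.0)
    elif cls == "plate":
        c_over_a = rho * ratio * np.sqrt(3.0)
    else:  # block: place the cap extent between the in-plane extent bounds
        c_over_a = rho * np.sqrt(3.0) * float(rng.uniform(ratio, 1.0 / ratio))
    return factory(c_over_a, n_surface_points=n_surface_points, seed=seed)


_INPLANE_RMS_CACHE: dict[str, float] = {}


def _inplane_rms(system: str) -> float:
    """RMS in-plane extent of the unit-distance prism cross-section.

    Computed once per system from the exact solid moments of a reference
    prism (cap distance 1); used to calibrate cap distances to aspect-ratio
    targets.  The cap RMS extent of a half-height-1 prism is 1/sqrt(3).
    """
    if system not in _INPLANE_RMS_CACHE:
        spec = (tetragonal_spec if system == "tetragonal" else hexagonal_spec)(1.0)
        verts = halfspace_vertices(spec.facet_normals, spec.facet_distances)
        _, _, cov = solid_moments(verts)
        _INPLANE_RMS_CACHE[system] = float(np.sqrt(cov[0, 0]))
    return _INPLANE_RMS_CACHE[system]


def _derive_seed(seed: int, *parts) -> int:
    """Stable per-item seed below 2**31 derived from a run seed and keys."""
    h = hashlib.sha256(("|".join(map(str, (seed, *parts)))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def generate_clouds(
    config: DatasetConfig,
) -> list[tuple[PointCloud, GroundTruth]]:
    """Generate labelled surface point clouds for every requested habit.

    Each habit gets its own derived seed, so the output is independent of
    generation order and reproducible item-by-item.  Habits whose realized
    (oracle) class misses the requested class — possible for skewed
    monoclinic cells — are resampled with a fresh derived seed.
    """
    out: list[tuple[PointCloud, GroundTruth]] = []
    for (system, cls), n in sorted(config.counts.items()):
        for i in range(n):
            for attempt in range(64):
                item_seed = _derive_seed(config.seed, system, cls, i, attempt)
                rng = np.random.default_rng(item_seed)
                targets = _sample_target_ratios(cls, config.class_margin, rng)
                spec = _spec_for(
                    system, cls, targets, config.n_surface_points, item_seed, rng
                )
                verts, gt = make_habit(spec)
                if gt.zingg_class == cls:
                    break
            else:
                raise RuntimeError(
                    f"could not realize a {cls} habit in the {system} system"
                )
            pc = sample_surface(
                verts,
                config.n_surface_points,
                seed=rng,
                source_id=f"{system}_{cls}_{i:05d}",
            )
            if config.jitter_sigma > 0:
                extent = np.abs(pc.points).max()
                pc = PointCloud(
                    pc.points
                    + rng.normal(0.0, config.jitter_sigma * extent, pc.points.shape),
                    source_id=pc.source_id,
                )
            gt = dataclasses.replace(
                gt, generator_aspect_targets=(round(targets[0], 6), round(targets[1], 6))
            )
            out.append((pc, gt))
    return out


def generate_dataset(config: DatasetConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write XYZ files plus a labels manifest; returns the manifest.

    Manifest columns: file, zingg_class, crystal_system, s_m, m_l, seed.
    Byte-identical output under identical config (fixed float formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pc, gt in generate_clouds(config):
        fname = f"{pc.source_id}.xyz"
        write_xyz(pc, out_dir / fname)
        rows.append(
            {
                "file": fname,
                "zingg_class": gt.zingg_class,
                "crystal_system": gt.crystal_system,
                "s_m": round(gt.s_m, 6),
                "m_l": round(gt.m_l, 6),
                "seed": config.seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["file", "zingg_class", "crystal_system", "s_m", "m_l", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
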