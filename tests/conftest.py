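"""Shared fixtures: canonical solids and small generated habit sets."""

import numpy as np
import pytest

from habitspace.geometry import PointCloud
from habitspace import synthetic_habits as sh


@pytest.fixture(scope="session")
def cube_vertices() -> np.ndarray:
    """Corners of the axis-aligned cube with half-width 1."""
    g = np.array([-1.0, 1.0])
    return np.array([[x, y, z] for x in g for y in g for z in g])


@pytest.fixture(scope="session")
def cube_cloud(cube_vertices) -> PointCloud:
    return PointCloud(cube_vertices, source_id="cube")


@pytest.fixture(scope="session")
def box_solid_cloud() -> PointCloud:
    """Dense uniform solid sample of the box with half-lengths (1, 2, 4)."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(-1.0, 1.0, (200_000, 3)) * np.array([1.0, 2.0, 4.0])
    return PointCloud(pts, source_id="box124")


@pytest.fixture(scope="session")
def small_habit_set():
    """A small balanced habit sample (monoclinic covers all four classes)."""
    cfg = sh.DatasetConfig(counts=sh.balanced_counts(8), seed=7)
    return sh.generate_clouds(cfg)
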