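"""Ingestion, normalization, PCA extents and hull metrics."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from habitspace import geometry
from habitspace.geometry import (
    DegenerateCloudError,
    PointCloud,
    XYZParseError,
    center_and_normalize,
    hull_metrics,
    pca_axes,
    read_xyz,
    shape_record,
    write_xyz,
)

from .oracles import tetra_fan_volume_oracle


class TestReadXYZ:
    def test_bare_triples(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("0 0 0\n1 0 0\n0 1 0\n")
        assert len(read_xyz(p)) == 3

    def test_count_header_dialect(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("3\n0 0 0\n1 0 0\n0 1 0\n")
        pc = read_xyz(p, dialect="header")
        assert len(pc) == 3

    def test_header_count_mismatch_raises(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("5\n0 0 0\n1 0 0\n")
        with pytest.raises(XYZParseError, match="declares 5"):
            read_xyz(p, dialect="header")

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("a b c\n")
        with pytest.raises(XYZParseError, match=":1:"):
            read_xyz(p)

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("0 0 0\n1 2\n")
        with pytest.raises(XYZParseError, match=":2:"):
            read_xyz(p)

    def test_comments_and_element_column_accepted(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("# comment\nC 1.0 2.0 3.0\n\n0 0 0\n")
        pc = read_xyz(p)
        assert len(pc) == 2
        np.testing.assert_allclose(pc.points[0], [1.0, 2.0, 3.0])

    def test_write_read_round_trip(self, tmp_path):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        p = write_xyz(PointCloud(pts), tmp_path / "rt.xyz", dialect="header")
        back = read_xyz(p, dialect="header")
        np.testing.assert_allclose(back.points, pts, atol=5e-7)


class TestCenterAndNormalize:
    def test_two_point_example(self):
        pc = center_and_normalize(PointCloud([[1, 0, 0], [3, 0, 0]]))
        np.testing.assert_allclose(
            sorted(map(tuple, pc.points)), [(-1, 0, 0), (1, 0, 0)], atol=1e-12
        )

    def test_idempotent_and_max_norm_one(self):
        pts = np.random.default_rng(1).normal(2.0, 3.0, (50, 3))
        once = center_and_normalize(PointCloud(pts))
        twice = center_and_normalize(once)
        np.testing.assert_allclose(once.points, twice.points, atol=1e-12)
        assert abs(np.linalg.norm(once.points, axis=1).max() - 1.0) < 1e-12
        np.testing.assert_allclose(once.points.mean(axis=0), 0.0, atol=1e-12)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateCloudError):
            center_and_normalize(PointCloud(np.ones((5, 3))))


class TestPCAAxes:
    def test_box_solid_ratios(self, box_solid_cloud):
        """Uniform solid box (1, 2, 4): RMS extents scale with the
        half-lengths, so S:M = M:L = 0.5."""
        axes = pca_axes(box_solid_cloud)
        assert axes.s_m == pytest.approx(0.5, abs=0.01)
        assert axes.m_l == pytest.approx(0.5, abs=0.01)

    def test_sphere_surface_isometric(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(20_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        axes = pca_axes(PointCloud(v))
        assert axes.s_m == pytest.approx(1.0, abs=0.02)
        assert axes.m_l == pytest.approx(1.0, abs=0.02)

    def test_planar_cloud_degenerate_flag(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(size=(50, 2)), np.zeros(50)])
        axes = pca_axes(PointCloud(pts))
        assert axes.degenerate
        assert axes.S == 0.0
        assert axes.s_m == 0.0

    def test_ratios_rotation_invariant(self, box_solid_cloud):
        R = Rotation.from_euler("zyx", [0.3, 1.1, -0.7]).as_matrix()
        rotated = PointCloud(box_solid_cloud.points @ R.T)
        a0 = pca_axes(box_solid_cloud)
        a1 = pca_axes(rotated)
        assert a1.s_m == pytest.approx(a0.s_m, abs=1e-9)
        assert a1.m_l == pytest.approx(a0.m_l, abs=1e-9)

    def test_normalization_preserves_ratios_and_class(self, small_habit_set):
        for pc, gt in small_habit_set[:8]:
            before = pca_axes(pc)
            after = pca_axes(center_and_normalize(pc))
            assert after.s_m == pytest.approx(before.s_m, abs=1e-9)
            assert after.m_l == pytest.approx(before.m_l, abs=1e-9)


class TestHullMetrics:
    def test_cube_closed_form(self, cube_cloud):
        area, volume = hull_metrics(cube_cloud)
        assert area == pytest.approx(24.0, rel=1e-12)
        assert volume == pytest.approx(8.0, rel=1e-12)

    def test_regular_tetrahedron_closed_form(self):
        # edge length 1: volume 1/(6 sqrt(2)), area sqrt(3)
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / (2 * np.sqrt(2))
        area, volume = hull_metrics(PointCloud(verts))
        assert volume == pytest.approx(1 / (6 * np.sqrt(2)), rel=1e-12)
        assert area == pytest.approx(np.sqrt(3), rel=1e-12)

    def test_interior_points_do_not_change_hull(self, cube_vertices):
        rng = np.random.default_rng(4)
        interior = rng.uniform(-0.9, 0.9, (100, 3))
        a1, v1 = hull_metrics(PointCloud(cube_vertices))
        a2, v2 = hull_metrics(PointCloud(np.vstack([cube_vertices, interior])))
        assert a2 == pytest.approx(a1, rel=1e-12)
        assert v2 == pytest.approx(v1, rel=1e-12)

    def test_coplanar_cloud_raises(self):
        pts = np.column_stack([np.random.default_rng(5).random((10, 2)), np.zeros(10)])
        with pytest.raises(DegenerateCloudError):
            hull_metrics(PointCloud(pts))

    def test_volume_matches_tetra_fan_oracle(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(40, 3))
        _, volume = hull_metrics(PointCloud(pts))
        hull = ConvexHull(pts)
        oracle = tetra_fan_volume_oracle(pts, hull.simplices, hull.vertices)
        assert volume == pytest.approx(oracle, rel=1e-9)


class TestShapeRecord:
    def test_cube_record(self, cube_cloud):
        rec = shape_record(cube_cloud)
        assert rec.zingg_class == "block"
        assert rec.sa_vol == pytest.approx(3.0, rel=1e-12)

    def test_box_solid_sample_is_lath(self, box_solid_cloud):
        rec = shape_record(box_solid_cloud)
        assert rec.zingg_class == "lath"
        assert rec.s_m == pytest.approx(0.5, abs=0.01)
        assert rec.m_l == pytest.approx(0.5, abs=0.01)

    def test_icosahedral_sphere_is_block(self):
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array(
            [
                [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
            ],
            dtype=float,
        )
        assert shape_record(PointCloud(verts)).zingg_class == "block"


def test_principal_frame_orients_long_axis_to_z(box_solid_cloud):
    coords = geometry.principal_frame(box_solid_cloud)
    spans = coords.max(axis=0) - coords.min(axis=0)
    assert spans[0] < spans[1] < spans[2]


# -- property-based checks ---------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


finite_clouds = arrays(
    np.float64,
    (12, 3),
    elements=st.floats(min_value=-50.0, max_value=50.0, allow_nan=False),
)


@settings(max_examples=50, derandomize=True)
@given(pts=finite_clouds)
def test_center_and_normalize_contract_on_arbitrary_clouds(pts):
    try:
        out = center_and_normalize(PointCloud(pts))
    except DegenerateCloudError:
        assert np.allclose(pts, pts[0])
        return
    assert np.linalg.norm(out.points, axis=1).max() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(out.points.mean(axis=0), 0.0, atol=1e-12)


@settings(max_examples=30, derandomize=True)
@given(pts=finite_clouds, scale=st.floats(min_value=0.01, max_value=100.0))
def test_pca_ratios_scale_invariant(pts, scale):
    pc = PointCloud(pts)
    try:
        base = pca_axes(pc)
    except ValueError:
        return
    scaled = pca_axes(PointCloud(pts * scale))
    assert scaled.s_m == pytest.approx(base.s_m, abs=1e-8)
    assert scaled.m_l == pytest.approx(base.m_l, abs=1e-8)
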