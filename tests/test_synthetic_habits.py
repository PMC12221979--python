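"""Halfspace habit construction, surface sampling, and dataset generation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from habitspace import synthetic_habits as sh
from habitspace import zingg
from habitspace.geometry import PointCloud, pca_axes

from .oracles import halfspace_vertex_oracle


def _match_vertex_sets(a: np.ndarray, b: np.ndarray, tol: float = 1e-6) -> bool:
    if len(a) != len(b):
        return False
    used = set()
    for pa in a:
        hit = np.where(np.linalg.norm(b - pa, axis=1) < tol)[0]
        hit = [h for h in hit if h not in used]
        if not hit:
            return False
        used.add(hit[0])
    return True


class TestHalfspaceVertices:
    def test_cube_spec_gives_eight_symmetric_corners(self):
        normals = np.vstack([np.eye(3), -np.eye(3)])
        d = 1.7
        verts = sh.halfspace_vertices(normals, np.full(6, d))
        expected = np.array(
            [[x, y, z] for x in (-d, d) for y in (-d, d) for z in (-d, d)]
        )
        assert _match_vertex_sets(verts, expected, tol=1e-9)

    def test_matches_triple_enumeration_oracle_on_random_specs(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n_facets = rng.integers(4, 13)
            normals = rng.normal(size=(n_facets, 3))
            normals /= np.linalg.norm(normals, axis=1, keepdims=True)
            # ensure boundedness by adding the 6 axis facets
            normals = np.vstack([normals, np.eye(3), -np.eye(3)])
            dists = rng.uniform(0.5, 2.0, len(normals))
            verts = sh.halfspace_vertices(normals, dists)
            oracle = halfspace_vertex_oracle(normals, dists)
            assert _match_vertex_sets(verts, oracle)

    def test_unbounded_system_rejected(self):
        # only upward-facing normals: open in -z
        normals = np.array([[0, 0, 1.0], [1, 0, 0.0], [-1, 0, 0.0], [0, 1, 0.0], [0, -1, 0.0]])
        with pytest.raises(sh.UnboundedHabitError):
            sh.halfspace_vertices(normals, np.ones(5))


class TestMakeHabit:
    def test_tall_square_prism_is_needle(self):
        """Square cross-section side s, height 6s: the Zingg oracle on the
        uniform solid gives S:M = 1, M:L = 1/6 -> needle."""
        verts, gt = sh.make_habit(sh.tetragonal_spec(c_over_a=6.0))
        assert gt.zingg_class == "needle"
        assert gt.s_m == pytest.approx(1.0, abs=1e-9)
        assert gt.m_l == pytest.approx(1 / 6, abs=1e-9)

    def test_hexagonal_cross_section_diagonals(self):
        """The hexagonal cross-section's vertex distances follow the rhombus
        diagonals a*sqrt(2 +/- 2 cos(alpha)) with alpha = 60 degrees."""
        spec = sh.hexagonal_spec(c_over_a=1.0)
        verts, _ = sh.make_habit(spec)
        top = verts[verts[:, 2] > 0.5]
        radii = np.linalg.norm(top[:, :2], axis=1)
        a = radii.max()  # hexagon side length = circumradius
        alpha = np.radians(60.0)
        # a rhombus of side a with the 60/120-degree cell angle has
        # diagonals a*sqrt(2 - 2 cos(alpha)) = a (adjacent vertices) and
        # a*sqrt(2 + 2 cos(alpha)) = sqrt(3) a (next-nearest vertices)
        short_diag = a * np.sqrt(2 - 2 * np.cos(alpha))
        long_diag = a * np.sqrt(2 + 2 * np.cos(alpha))
        d = np.sort(
            [np.linalg.norm(p - q) for i, p in enumerate(top) for q in top[i + 1 :]]
        )
        dist_set = np.unique(np.round(d, 9))
        assert dist_set[0] == pytest.approx(short_diag, rel=1e-9)
        assert dist_set[1] == pytest.approx(long_diag, rel=1e-9)
        assert dist_set[2] == pytest.approx(2 * a, rel=1e-9)  # opposite corners

    def test_degenerate_volume_rejected(self):
        normals = np.vstack([np.eye(3), -np.eye(3)])
        dists = np.array([1, 1, 1e-13, 1, 1, 1e-13])
        with pytest.raises(sh.DegenerateHabitError):
            sh.make_habit(
                sh.HabitSpec("tetragonal", (90, 90, 90), normals, dists)
            )

    def test_solid_moments_match_dense_sampling(self):
        spec = sh.monoclinic_spec([0.4, 1.0, 1.7], beta=112.0)
        verts, gt = sh.make_habit(spec)
        rng = np.random.default_rng(3)
        pts = sh.solid_sample(verts, 300_000, rng)
        axes = pca_axes(PointCloud(pts))
        assert axes.s_m == pytest.approx(gt.s_m, abs=0.01)
        assert axes.m_l == pytest.approx(gt.m_l, abs=0.01)

    def test_square_prisms_never_lath(self):
        """Two equal in-plane extents force one aspect ratio to 1, so a
        square prism of any height cannot be a lath."""
        for c_over_a in np.geomspace(0.05, 20.0, 25):
            _, gt = sh.make_habit(sh.tetragonal_spec(c_over_a))
            assert gt.zingg_class != "lath"


class TestSampleSurface:
    def test_points_lie_on_facet_planes(self, cube_vertices):
        pc = sh.sample_surface(cube_vertices, 500, seed=0)
        residual = np.abs(np.abs(pc.points).max(axis=1) - 1.0)
        assert residual.max() <= 1e-9

    def test_counts_proportional_to_facet_area(self, cube_vertices):
        pc = sh.sample_surface(cube_vertices, 5000, seed=1)
        # classify points by which cube face they lie on
        counts = []
        for axis in range(3):
            for sign in (-1.0, 1.0):
                on = np.abs(pc.points[:, axis] - sign) < 1e-9
                counts.append(on.sum())
        assert sum(counts) == 5000
        stat, p = chisquare(counts)
        assert p > 0.001

    def test_same_seed_identical_clouds(self, cube_vertices):
        a = sh.sample_surface(cube_vertices, 100, seed=9)
        b = sh.sample_surface(cube_vertices, 100, seed=9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_too_few_points_rejected(self, cube_vertices):
        with pytest.raises(ValueError):
            sh.sample_surface(cube_vertices, 3, seed=0)

    def test_degenerate_surface_rejected(self):
        flat = np.column_stack([np.random.default_rng(0).random((8, 2)), np.zeros(8)])
        with pytest.raises(sh.DegenerateHabitError):
            sh.sample_surface(flat, 10, seed=0)


class TestDatasetGeneration:
    def test_manifest_counts_and_columns(self, tmp_path):
        cfg = sh.DatasetConfig(
            counts={("monoclinic", c): 10 for c in zingg.CLASSES}, seed=1
        )
        man = sh.generate_dataset(cfg, tmp_path)
        assert len(man) == 40
        assert man["zingg_class"].value_counts().to_dict() == {
            c: 10 for c in zingg.CLASSES
        }
        assert list(man.columns) == [
            "file", "zingg_class", "crystal_system", "s_m", "m_l", "seed",
        ]
        assert all((tmp_path / f).exists() for f in man["file"])

    def test_high_symmetry_lath_request_rejected(self):
        with pytest.raises(sh.HabitConfigurationError):
            sh.DatasetConfig(counts={("tetragonal", "lath"): 1})
        with pytest.raises(sh.HabitConfigurationError):
            sh.DatasetConfig(counts={("hexagonal", "lath"): 1})

    def test_tetragonal_sweep_excludes_laths(self):
        cfg = sh.DatasetConfig(
            counts={("tetragonal", c): 5 for c in ("block", "needle", "plate")},
            seed=2,
        )
        for _, gt in sh.generate_clouds(cfg):
            assert gt.zingg_class in ("plate", "block", "needle")

    def test_same_seed_byte_identical_manifests(self, tmp_path):
        cfg = sh.DatasetConfig(counts={("monoclinic", "block"): 5}, seed=3)
        sh.generate_dataset(cfg, tmp_path / "a")
        sh.generate_dataset(cfg, tmp_path / "b")
        assert (tmp_path / "a/manifest.csv").read_bytes() == (
            tmp_path / "b/manifest.csv"
        ).read_bytes()
        for f in (tmp_path / "a").glob("*.xyz"):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_generated_labels_agree_with_cloud_classification(self, small_habit_set):
        """Away from the 0.66 boundary, classifying the sampled cloud
        reproduces the generator's label for nearly all shapes."""
        agree = sum(
            pca_axes(pc).s_m is not None
            and zingg.classify(pca_axes(pc).s_m, pca_axes(pc).m_l) == gt.zingg_class
            for pc, gt in small_habit_set
        )
        assert agree / len(small_habit_set) >= 0.95

    def test_balanced_counts_respect_allowed_classes(self):
        counts = sh.balanced_counts(30)
        assert sum(counts.values()) == 120
        assert ("tetragonal", "lath") not in counts
        assert ("hexagonal", "lath") not in counts
        assert counts[("monoclinic", "lath")] == 30
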