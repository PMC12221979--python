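"""Quantitative analysis of the DAE latent space.

Covers the downstream analytics: Pearson correlation matrices between
latent dimensions and shape features (aspect ratios, hull area/volume,
SA:V) or leading spherical-harmonic magnitudes; 2-D views of the latent
space (either the two most aspect-ratio-correlated dimensions, or a UMAP
embedding of all six); per-class latent centroids; and decoded linear
interpolation trajectories between class centroids, with the aspect-ratio
evolution measured on the decoded volumes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import zingg
from .dae import DisentanglingAutoencoder
from .geometry import PointCloud, pca_axes
from .voxelize import EmptyShapeError, VoxelGrid, voxels_to_points

#: Feature columns of the latent-feature correlation matrix, in order.
FEATURE_COLUMNS = ("s_m", "m_l", "surface_area", "volume", "sa_vol")


def pearson_matrix(
    rows: np.ndarray,
    cols: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation of every (row variable, column variable) pair.

    Constant variables have undefined correlation; those entries are NaN
    (flagged, not raised) so a uniform feature does not abort a report.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if rows.shape[0] != cols.shape[0]:
        raise ValueError("row/column variables must share the sample axis")
    if rows.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    rc = rows - rows.mean(axis=0)
    cc = cols - cols.mean(axis=0)
    rn = np.linalg.norm(rc, axis=0)
    cn = np.linalg.norm(cc, axis=0)
    const_r = rows.max(axis=0) - rows.min(axis=0) == 0
    const_c = cols.max(axis=0) - cols.min(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = (rc.T @ cc) / np.outer(np.where(const_r, 1, rn), np.where(const_c, 1, cn))
    mat[:, const_c] = np.nan
    mat[const_r, :] = np.nan
    mat = np.clip(mat, -1.0, 1.0)
    return pd.DataFrame(mat, index=list(row_labels), columns=list(col_labels))


def feature_correlations(
    latents: np.ndarray, records: pd.DataFrame
) -> pd.DataFrame:
    """Latent-dimension vs shape-feature Pearson matrix (latent_dim x 5).

    ``records`` needs columns s_m, m_l, surface_area, volume, sa_vol
    (``area`` accepted as an alias for surface_area).
    """
    records = records.rename(columns={"area": "surface_area"})
    feats = records[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    dims = [f"Dim_{i}" for i in range(latents.shape[1])]
    return pearson_matrix(latents, feats, dims, FEATURE_COLUMNS)


def harmonic_correlations(
    latents: np.ndarray, magnitudes: np.ndarray, n_mags: int = 6
) -> pd.DataFrame:
    """Latent-dimension vs leading SH-magnitude Pearson matrix.

    ``magnitudes`` is (N, >=n_mags), e.g. the descriptor table's Mag_0..;
    the first ``n_mags`` columns (Y00 .. Y22 for the default 6) are used.
    """
    mags = np.asarray(magnitudes, dtype=float)[:, :n_mags]
    dims = [f"Dim_{i}" for i in range(latents.shape[1])]
    cols = [f"Mag_{j}" for j in range(n_mags)]
    return pearson_matrix(latents, mags, dims, cols)


def aspect_correlated_dims(corr: pd.DataFrame) -> tuple[int, int]:
    """The two distinct latent dims most |correlated| with s_m and m_l."""
    abs_sm = corr["s_m"].abs().to_numpy()
    abs_ml = corr["m_l"].abs().to_numpy()
    i = int(np.nanargmax(abs_sm))
    j = int(np.nanargmax(abs_ml))
    if i == j:  # keep the stronger pairing, move the other to its runner-up
        if abs_sm[i] >= abs_ml[j]:
            j = int(np.nanargmax(np.where(np.arange(len(abs_ml)) == i, -1, abs_ml)))
        else:
            i = int(np.nanargmax(np.where(np.arange(len(abs_sm)) == j, -1, abs_sm)))
    return i, j


def project_2d(
    vectors: np.ndarray,
    method: str = "first_two_dims",
    seed: int = 0,
    corr: pd.DataFrame | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D view of the latent vectors.

    ``first_two_dims`` selects (no fitting) the two latent columns most
    correlated with the S:M and M:L aspect ratios, as given by ``corr``
    (a :func:`feature_correlations` output); ``umap`` embeds all
    dimensions with a seeded UMAP.
    """
    vectors = np.asarray(vectors, dtype=float)
    if method == "first_two_dims":
        if corr is None:
            raise ValueError(
                "first_two_dims requires the latent-feature correlation matrix"
            )
        i, j = aspect_correlated_dims(corr)
        return vectors[:, [i, j]]
    if method == "umap":
        if vectors.shape[0] <= n_neighbors:
            raise ValueError(
                f"umap needs more than n_neighbors={n_neighbors} samples"
            )
        import umap  # deferred: numba compilation is slow to import

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(vectors))
    raise ValueError(f"unknown projection method {method!r}")


def class_centroids(
    latents: np.ndarray, labels: Sequence[str]
) -> dict[str, np.ndarray]:
    """Arithmetic mean latent vector per Zingg class; all four required."""
    labels = np.asarray(labels)
    missing = [c for c in zingg.CLASSES if c not in labels]
    if missing:
        raise ValueError(f"no samples for class(es): {', '.join(missing)}")
    return {c: latents[labels == c].mean(axis=0) for c in zingg.CLASSES}


@dataclasses.dataclass
class Trajectory:
    """A decoded straight-line path between two latent points."""

    endpoints: tuple[str, str]
    latents: np.ndarray  # (n_steps, latent_dim)
    decoded: list[VoxelGrid]
    aspect_series: pd.DataFrame  # columns step, t, s_m, m_l, zingg_class, ok


def interpolate_trajectory(
    model: DisentanglingAutoencoder,
    z_a: np.ndarray,
    z_b: np.ndarray,
    n_steps: int = 8,
    endpoints: tuple[str, str] = ("a", "b"),
    threshold: float = 0.5,
) -> Trajectory:
    """Decode evenly spaced latents on the segment z_a -> z_b.

    Aspect ratios per step are measured on the decoded volume binarized at
    ``threshold`` (voxel centers -> PCA extents).  A step whose decode has
    no voxel above threshold, or too few for PCA, is flagged (ok=False)
    with NaN ratios rather than aborting.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    ts = np.linspace(0.0, 1.0, n_steps)
    latents = (1.0 - ts)[:, None] * z_a + ts[:, None] * z_b
    decoded, rows = [], []
    for k, t in enumerate(ts):
        grid = model.decode(latents[k])
        decoded.append(grid)
        try:
            pc = voxels_to_points(grid, threshold=threshold)
            if len(pc) < 4:
                raise EmptyShapeError("too few voxels above threshold")
            axes = pca_axes(pc)
            rows.append(
                {
                    "step": k,
                    "t": t,
                    "s_m": axes.s_m,
                    "m_l": axes.m_l,
                    "zingg_class": zingg.classify(axes.s_m, axes.m_l),
                    "ok": True,
                }
            )
        except EmptyShapeError:
            rows.append(
                {
                    "step": k,
                    "t": t,
                    "s_m": np.nan,
                    "m_l": np.nan,
                    "zingg_class": "",
                    "ok": False,
                }
            )
    return Trajectory(
        endpoints=endpoints,
        latents=latents,
        decoded=decoded,
        aspect_series=pd.DataFrame(rows),
    )


def class_trajectories(
    model: DisentanglingAutoencoder,
    latents: np.ndarray,
    labels: Sequence[str],
    pairs: Sequence[tuple[str, str]] = (
        ("lath", "block"),
        ("lath", "needle"),
        ("needle", "block"),
        ("plate", "block"),
        ("plate", "lath"),
        ("plate", "needle"),
    ),
    n_steps: int = 8,
) -> dict[tuple[str, str], Trajectory]:
    """Decoded trajectories between all requested class-centroid pairs."""
    cents = class_centroids(latents, labels)
    return {
        (a, b): interpolate_trajectory(
            model, cents[a], cents[b], n_steps=n_steps, endpoints=(a, b)
        )
        for a, b in pairs
    }
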