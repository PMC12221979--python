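"""Spherical-harmonic shape descriptors (SHSDs) for star-shaped particles.

A convex particle is star-shaped about its volume centroid, so its surface
is a single-valued radial function r(theta, phi).  Expanding r in
orthonormal spherical harmonics Y_l^m up to degree ``lmax`` gives the
coefficients

    c_{l,m} = integral r(theta, phi) conj(Y_l^m) dOmega,

evaluated here on a Gauss-Legendre (in cos theta) x uniform (in phi)
product quadrature chosen to integrate band-limited integrands of degree
2*lmax exactly.  For a real radial function, c_{l,-m} is fixed by
conjugation, so the m >= 0 coefficients carry all the information: their
magnitudes, in (l, m) lexicographic order, form the descriptor.  At the
standard truncation lmax = 10 this is a 66-vector (Mag_0 .. Mag_65), whose
leading entries Mag_0..Mag_5 correspond to Y00, Y10, Y11, Y20, Y21, Y22:
mean radius, dipole-like asymmetries along z and in-plane, and the
quadrupole (elongation/flattening) block.

Descriptors are computed in the fixed Cartesian frame of the input cloud:
no rotational alignment or invariant reduction is applied, so coefficient
comparisons between particles are direct frame-dependent comparisons.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import sph_harm_y

from .geometry import PointCloud


class QuadratureOrderError(ValueError):
    """The quadrature cannot integrate the requested band limit exactly."""


def coefficient_index(l: int, m: int, lmax: int = 10) -> int:
    """Flat index of (l, m) in (l, m)-lexicographic m >= 0 ordering.

    (0,0) -> 0, (1,0) -> 1, (1,1) -> 2, (2,0) -> 3, ... , (lmax, lmax) ->
    (lmax+1)(lmax+2)/2 - 1 (= 65 for lmax = 10).
    """
    if not (0 <= m <= l <= lmax):
        raise ValueError(f"need 0 <= m <= l <= {lmax}, got l={l}, m={m}")
    return l * (l + 1) // 2 + m


def n_coefficients(lmax: int) -> int:
    """Number of m >= 0 coefficients up to degree lmax (66 for lmax = 10)."""
    return (lmax + 1) * (lmax + 2) // 2


@dataclasses.dataclass
class RadialMap:
    """Radii sampled on a spherical quadrature grid.

    ``exact_degree`` is the largest polynomial band the (weights,
    directions) rule integrates exactly; expansion at ``lmax`` requires
    exact_degree >= 2*lmax.
    """

    directions: np.ndarray  # K x 3 unit vectors
    weights: np.ndarray  # K quadrature weights, summing to 4*pi
    radii: np.ndarray  # K positive radii
    theta: np.ndarray  # polar angles of the directions
    phi: np.ndarray  # azimuthal angles
    exact_degree: int

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 4.0 * np.pi) > 1e-9:
            raise ValueError("quadrature weights must sum to 4*pi")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")


@dataclasses.dataclass
class SHDescriptor:
    """Complex coefficients c_{l,m} (m >= 0) and their magnitudes."""

    lmax: int
    coefficients: np.ndarray  # complex, length (lmax+1)(lmax+2)/2

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def coefficient(self, l: int, m: int) -> complex:
        return complex(self.coefficients[coefficient_index(l, m, self.lmax)])


def quadrature_grid(
    n_theta: int = 24, n_phi: int = 48
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Gauss-Legendre x uniform product rule on the sphere.

    Returns (directions, weights, theta, phi, exact_degree).  ``n_theta``
    Gauss-Legendre nodes in cos(theta) are exact for polynomial degree
    2*n_theta - 1; ``n_phi`` uniform azimuthal nodes are exact for circular
    harmonics up to order n_phi - 1.
    """
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    wt = np.repeat(w[:, None], n_phi, axis=1) * (2.0 * np.pi / n_phi)
    st = np.sin(th)
    directions = np.stack(
        [st * np.cos(ph), st * np.sin(ph), np.cos(th)], axis=-1
    ).reshape(-1, 3)
    exact_degree = min(2 * n_theta - 1, n_phi - 1)
    return directions, wt.ravel(), th.ravel(), ph.ravel(), exact_degree


def hull_volume_centroid(points: np.ndarray) -> np.ndarray:
    """Volume centroid of the convex hull (fan of tetrahedra)."""
    hull = ConvexHull(points)
    apex = points[hull.vertices].mean(axis=0)
    tris = points[hull.simplices]
    d = tris - apex
    # apex is interior, so every fan tetrahedron contributes positively;
    # Qhull simplex orientation is not consistent, hence the abs
    vols = np.abs(np.einsum("ti,ti->t", np.cross(d[:, 0], d[:, 1]), d[:, 2])) / 6.0
    cents = (tris.sum(axis=1) + apex) / 4.0
    return (vols[:, None] * cents).sum(axis=0) / vols.sum()


def radial_function(
    points: np.ndarray | PointCloud,
    directions: np.ndarray | None = None,
    n_theta: int = 24,
    n_phi: int = 48,
) -> RadialMap:
    """Radial map of a convex cloud's hull about its volume centroid.

    The radius along a unit direction u is the distance from the centroid
    to the hull boundary: min over facets f of d_f / (n_f . u), restricted
    to facets with n_f . u > 0 (facing the ray).
    """
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points)
    hull = ConvexHull(pts)
    centroid = hull_volume_centroid(pts)
    normals = hull.equations[:, :3]
    # facet distances measured from the centroid
    offsets = -hull.equations[:, 3] - normals @ centroid
    if np.any(offsets <= 0):
        raise ValueError("hull centroid is not strictly interior")
    if directions is not None:
        directions = np.asarray(directions, dtype=float)
        theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
        phi = np.arctan2(directions[:, 1], directions[:, 0])
        weights = np.full(len(directions), 4.0 * np.pi / len(directions))
        exact_degree = 0  # ad-hoc direction sets carry no exactness contract
    else:
        directions, weights, theta, phi, exact_degree = quadrature_grid(
            n_theta, n_phi
        )
    proj = directions @ normals.T  # (K, F)
    with np.errstate(divide="ignore"):
        t = np.where(proj > 1e-12, offsets[None, :] / proj, np.inf)
    radii = t.min(axis=1)
    return RadialMap(directions, weights, radii, theta, phi, exact_degree)


def sh_expand(rmap: RadialMap, lmax: int = 10) -> SHDescriptor:
    """Project a radial map onto orthonormal spherical harmonics.

    Requires a quadrature exact for degree 2*lmax (the contract for
    recovering a band-limited map without aliasing).
    """
    if rmap.exact_degree < 2 * lmax:
        raise QuadratureOrderError(
            f"quadrature exact to degree {rmap.exact_degree}; expansion at "
            f"lmax={lmax} requires exactness to degree {2 * lmax} "
            f"(n_theta >= {lmax + 1}, n_phi >= {2 * lmax + 1})"
        )
    wr = rmap.weights * rmap.radii
    coeffs = np.empty(n_coefficients(lmax), dtype=complex)
    for l in range(lmax + 1):
        for m in range(l + 1):
            y = sph_harm_y(l, m, rmap.theta, rmap.phi)
            coeffs[coefficient_index(l, m, lmax)] = np.sum(wr * np.conj(y))
    return SHDescriptor(lmax=lmax, coefficients=coeffs)


def synthesize(desc: SHDescriptor, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Evaluate the truncated (real) SH series at given angles.

    Uses c_{l,-m} = (-1)^m conj(c_{l,m}), valid for real radial maps.
    """
    out = np.zeros(np.broadcast(theta, phi).shape, dtype=complex)
    for l in range(desc.lmax + 1):
        for m in range(l + 1):
            c = desc.coefficient(l, m)
            y = sph_harm_y(l, m, theta, phi)
            out += c * y
            if m > 0:
                out += (-1) ** m * np.conj(c) * (-1) ** m * np.conj(y)
    return out.real


def power(desc: SHDescriptor) -> float:
    """Total spectral power over the full (+/-m) spectrum.

    Equals the surface integral of r^2 for band-limited maps (Parseval).
    """
    mags2 = desc.magnitudes**2
    total = 0.0
    for l in range(desc.lmax + 1):
        for m in range(l + 1):
            p = mags2[coefficient_index(l, m, desc.lmax)]
            total += p if m == 0 else 2.0 * p
    return float(total)


def describe_cloud(
    pc: PointCloud, lmax: int = 10, n_theta: int = 24, n_phi: int = 48
) -> SHDescriptor:
    """Hull -> radial map -> SH expansion, in the cloud's fixed frame."""
    rmap = radial_function(pc, n_theta=n_theta, n_phi=n_phi)
    return sh_expand(rmap, lmax=lmax)
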