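"""Spherical-harmonic (SPHARM) surface representation.

A genus-zero surface with a spherical parameterization (θ, φ) is described
by truncating the expansions

    x(θ, φ) = Σ_l Σ_m c^x_lm Y_lm(θ, φ)     (same for y and z)

at a maximum degree L, giving (L+1)² coefficients per coordinate and
3(L+1)² in total.  Y_lm here is the *real orthonormal* spherical-harmonic
basis; the spherical Laplacian satisfies Δ_Ω Y_lm = −l(l+1) Y_lm.
Coefficients are estimated by least squares on the design matrix of basis
values at the parameterized surface vertices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy import linalg
from scipy.special import sph_harm_y_all

from .io import SurfaceMesh, log


@dataclasses.dataclass
class SpharmModel:
    """Degree-L real SPHARM coefficient sets for the x, y, z coordinates.

    ``coeffs`` has shape (3, (L+1)²); column order is (l, m) with l
    ascending and m from −l to l within each degree.
    """

    degree: int
    coeffs: np.ndarray
    convention: str = "real"

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        n = (self.degree + 1) ** 2
        if self.coeffs.shape != (3, n):
            raise ValueError(f"coeffs must have shape (3, {n}), got {self.coeffs.shape}")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")

    @property
    def n_coefficients(self) -> int:
        """Total number of coefficients, 3(L+1)²."""
        return 3 * (self.degree + 1) ** 2

    def lm_index(self, l: int, m: int) -> int:
        if abs(m) > l or l > self.degree:
            raise ValueError(f"invalid (l, m) = ({l}, {m}) for degree {self.degree}")
        return l * l + l + m


def lm_pairs(degree: int) -> list[tuple[int, int]]:
    """(l, m) pairs in design-matrix column order."""
    return [(l, m) for l in range(degree + 1) for m in range(-l, l + 1)]


def evaluate_basis(l: int, m: int, theta, phi):
    """Real orthonormal spherical harmonic Y_lm at (θ, φ).

    Built from the complex orthonormal harmonics:
    m = 0 → Y_l0; m > 0 → √2·(−1)^m·Re(Y_l^m); m < 0 → √2·(−1)^m·Im(Y_l^|m|).
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    col = design_matrix(l, np.atleast_1d(theta.ravel()), np.atleast_1d(phi.ravel()))
    vals = col[:, l * l + l + m]
    return vals.reshape(theta.shape) if theta.shape else float(vals[0])


def design_matrix(degree: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """All real basis values up to ``degree``: shape (N, (degree+1)²)."""
    theta = np.asarray(theta, dtype=np.float64).ravel()
    phi = np.asarray(phi, dtype=np.float64).ravel()
    ylm = sph_harm_y_all(degree, degree, theta, phi)  # (L+1, 2L+1, N) complex
    n_pts = len(theta)
    out = np.empty((n_pts, (degree + 1) ** 2))
    sqrt2 = np.sqrt(2.0)
    for l in range(degree + 1):
        out[:, l * l + l] = ylm[l, 0].real
        for m in range(1, l + 1):
            sign = -1.0 if m % 2 else 1.0
            out[:, l * l + l + m] = sqrt2 * sign * ylm[l, m].real
            out[:, l * l + l - m] = sqrt2 * sign * ylm[l, m].imag
    return out


def evaluate_model(model: SpharmModel, theta, phi) -> np.ndarray:
    """Evaluate the truncated series; returns points of shape (N, 3)."""
    phi_mat = design_matrix(model.degree, theta, phi)
    return phi_mat @ model.coeffs.T


class UnderdeterminedError(ValueError):
    """Fewer sample points than coefficients; lower the degree."""


def fit_spharm(mesh: SurfaceMesh, smap, degree: int,
               ridge: float = 1e-8) -> SpharmModel:
    """Least-squares SPHARM fit of the surface coordinates.

    Solves min ‖Φc − coord‖² for each of x, y, z on the shared design
    matrix Φ of basis values at the per-vertex (θ, φ).  Uses a QR-based
    solver; on rank deficiency a Tikhonov-regularized solve (λ = ``ridge``)
    is used instead, with a warning.
    """
    theta = np.asarray(smap.theta, dtype=np.float64)
    phi = np.asarray(smap.phi, dtype=np.float64)
    n_basis = (degree + 1) ** 2
    if len(theta) < n_basis:
        raise UnderdeterminedError(
            f"{len(theta)} vertices < {n_basis} coefficients; lower the degree")
    phi_mat = design_matrix(degree, theta, phi)
    coords = mesh.vertices  # (N, 3)
    sol, _, rank, _ = linalg.lstsq(phi_mat, coords, lapack_driver="gelsy")
    if rank < n_basis:
        log.warning("rank-deficient SPHARM design matrix (rank %d < %d); "
                    "using Tikhonov-regularized solve", rank, n_basis)
        gram = phi_mat.T @ phi_mat + ridge * np.eye(n_basis)
        sol = np.linalg.solve(gram, phi_mat.T @ coords)
    return SpharmModel(degree=degree, coeffs=sol.T)


# ---------------------------------------------------------------------------
# icosahedral resampling and error


def icosphere_grid(subdivision_level: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(θ, φ, faces) of a level-k subdivided icosahedron projected to the
    unit sphere; 10·4^k + 2 vertices."""
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    v = np.asarray(ico.vertices)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2.0 * np.pi)
    return theta, phi, np.asarray(ico.faces)


def reconstruct(model: SpharmModel, subdivision_level: int = 4) -> SurfaceMesh:
    """Sample the truncated series on an icosahedral (θ, φ) grid."""
    theta, phi, faces = icosphere_grid(subdivision_level)
    pts = evaluate_model(model, theta, phi)
    return SurfaceMesh(pts, faces)


@dataclasses.dataclass
class RmseReport:
    rmse: float
    n_samples: int


def compute_rmse(truth_points: np.ndarray, recon_points: np.ndarray) -> RmseReport:
    """Root-mean-square distance over corresponding parameter pairs:
    sqrt(Σ_i ‖M(p_i) − M̃(p_i)‖² / N)."""
    a = np.asarray(truth_points, dtype=np.float64)
    b = np.asarray(recon_points, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    d2 = np.sum((a - b) ** 2, axis=1)
    return RmseReport(rmse=float(np.sqrt(d2.mean())), n_samples=len(a))


def fit_rmse(mesh: SurfaceMesh, smap, degree: int) -> RmseReport:
    """RMSE of the degree-``degree`` fit evaluated at the mesh's own
    parameter pairs (the representation error of the truncated series)."""
    model = fit_spharm(mesh, smap, degree)
    recon = evaluate_model(model, smap.theta, smap.phi)
    return compute_rmse(mesh.vertices, recon)
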