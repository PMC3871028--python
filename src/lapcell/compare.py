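"""Time-point shape comparison of SPHARM models.

Correspondence between two surfaces is implied by the shared spherical
parameterization: points with the same (θ, φ) correspond.  Local membrane
deformation between two time points is the signed projection of the
displacement onto the outward normal of the earlier surface (positive =
protruding, negative = retracting).  Global deformation phases show up in
time series of per-degree coefficient magnitudes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh

from .spharm import SpharmModel, evaluate_model, icosphere_grid


@dataclasses.dataclass
class DeformationMap:
    theta: np.ndarray
    phi: np.ndarray
    displacement: np.ndarray  # signed, µm; + outward relative to surface a


@dataclasses.dataclass
class CoefficientSeries:
    times: np.ndarray
    selection: list[tuple[int, int]]
    values: np.ndarray  # (n_frames, n_selected) magnitudes

    def largest_change_frame(self) -> int:
        """Frame index of the largest first difference (simple change-point
        flag over the summed selected magnitudes)."""
        total = self.values.sum(axis=1)
        return int(np.argmax(np.abs(np.diff(total)))) + 1


def _check_compatible(a: SpharmModel, b: SpharmModel):
    if a.convention != b.convention:
        raise ValueError("models use different basis conventions")


def deformation_map(model_a: SpharmModel, model_b: SpharmModel,
                    grid=4) -> DeformationMap:
    """Signed normal displacement from surface a to surface b.

    ``grid`` is an icosphere subdivision level (int) or an explicit
    ``(theta, phi, faces)`` tuple; both models are sampled on the identical
    grid and the displacement is (p_b − p_a)·n̂_a with n̂_a the area-weighted
    outward vertex normal of surface a.
    """
    _check_compatible(model_a, model_b)
    if isinstance(grid, int):
        theta, phi, faces = icosphere_grid(grid)
    else:
        theta, phi, faces = grid
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        if theta.shape != phi.shape:
            raise ValueError("theta and phi grids differ in shape")
    pa = evaluate_model(model_a, theta, phi)
    pb = evaluate_model(model_b, theta, phi)
    normals = _surface_normals(model_a, theta, phi, pa, faces)
    disp = np.einsum("ij,ij->i", pb - pa, normals)
    return DeformationMap(theta=theta, phi=phi, displacement=disp)


def _surface_normals(model: SpharmModel, theta, phi, points, faces,
                     h: float = 1e-5) -> np.ndarray:
    """Outward unit normals of the smooth SPHARM surface: normalized
    ∂p/∂θ × ∂p/∂φ (central differences); degenerate points (poles) fall
    back to mesh vertex normals."""
    dth = (evaluate_model(model, theta + h, phi)
           - evaluate_model(model, theta - h, phi)) / (2 * h)
    dph = (evaluate_model(model, theta, phi + h)
           - evaluate_model(model, theta, phi - h)) / (2 * h)
    n = np.cross(dth, dph)
    norms = np.linalg.norm(n, axis=1)
    bad = norms < 1e-8
    if bad.any():
        mesh = trimesh.Trimesh(vertices=points, faces=faces, process=False)
        n[bad] = np.asarray(mesh.vertex_normals)[bad]
        norms = np.linalg.norm(n, axis=1)
    return n / norms[:, None]


def euclidean_deformation_map(model_a: SpharmModel, model_b: SpharmModel,
                              grid=4) -> DeformationMap:
    """Unsigned point-to-point distance variant."""
    _check_compatible(model_a, model_b)
    theta, phi, _ = icosphere_grid(grid) if isinstance(grid, int) else grid
    pa = evaluate_model(model_a, theta, phi)
    pb = evaluate_model(model_b, theta, phi)
    return DeformationMap(theta=theta, phi=phi,
                          displacement=np.linalg.norm(pb - pa, axis=1))


def coefficient_timeseries(models: list[SpharmModel],
                           selection: list[tuple[int, int]]) -> CoefficientSeries:
    """Per-frame magnitudes of selected (l, m) coefficients.

    The magnitude combines the x, y, z coefficient triplet as its Euclidean
    norm, making the series invariant to the split of shape across the
    three coordinate expansions.
    """
    if not models:
        raise ValueError("empty model sequence")
    deg = models[0].degree
    conv = models[0].convention
    for m in models:
        if m.degree != deg:
            raise ValueError("models differ in degree")
        if m.convention != conv:
            raise ValueError("models use different basis conventions")
    vals = np.empty((len(models), len(selection)))
    for t, model in enumerate(models):
        for j, (l, mm) in enumerate(selection):
            idx = model.lm_index(l, mm)
            vals[t, j] = np.linalg.norm(model.coeffs[:, idx])
    return CoefficientSeries(times=np.arange(len(models)), selection=list(selection),
                             values=vals)
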