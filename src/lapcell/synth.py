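"""Synthetic membrane-stained cells with known ground truth.

The generator emulates the failure modes of fast 3D fluorescence imaging of
motile cells: a membrane dye concentrated on a thin shell (so the interior
is nearly as dark as the background), thin protrusions, optional handle-
forming arcs (crossing-filopodia style bridges whose underside tunnels
create genus > 0), Gaussian blur and additive Gaussian noise.

Ground truth is exact: the returned mask has exactly ``n_handles`` tunnels
(Euler characteristic 1 − n_handles), verified constructively during
generation by rejection sampling of protrusion/handle placements.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import BinaryVolume, SurfaceMesh, VolumeStack
from .spharm import SpharmModel, evaluate_model, icosphere_grid
from .topology import euler_characteristic, is_spherical


class SpecError(ValueError):
    """The requested geometry cannot be generated on the grid."""


@dataclasses.dataclass
class SyntheticCellSpec:
    """Parameters of one synthetic cell.

    Geometric parameters are in voxels; intensities in normalized units.
    ``interior_dimming`` scales the interior intensity relative to the
    membrane shell (0 = interior at background, 1 = as bright as the
    membrane).
    """

    body_radii: tuple[float, float, float] = (16.0, 14.0, 12.0)
    n_protrusions: int = 3
    protrusion_length: float = 8.0
    protrusion_width: float = 3.0
    n_handles: int = 0
    noise_sigma: float = 0.1
    background_level: float = 0.1
    interior_dimming: float = 0.5
    blur_sigma: float = 1.0
    rng_seed: int = 0
    shape: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    membrane_thickness: int = 2

    def __post_init__(self):
        if any(r <= 0 for r in self.body_radii):
            raise SpecError("body radii must be positive")
        if self.protrusion_length <= 0 or self.protrusion_width <= 0:
            raise SpecError("protrusion dimensions must be positive")
        if self.n_protrusions < 0 or self.n_handles < 0:
            raise SpecError("counts must be non-negative")
        if not 0.0 <= self.interior_dimming <= 1.0:
            raise SpecError("interior_dimming must be in [0, 1]")
        if self.shape is None:
            ext = int(np.ceil(2 * (max(self.body_radii) + self.protrusion_length) + 10))
            self.shape = (ext, ext, ext)
        reach = max(self.body_radii) + self.protrusion_length + 2
        if 2 * reach + 2 > min(self.shape):
            raise SpecError(
                f"protrusions of length {self.protrusion_length} would exit the "
                f"grid of shape {self.shape}")


# ---------------------------------------------------------------------------
# geometry rasterization helpers


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _tube(shape, points, radius) -> np.ndarray:
    """Voxels within ``radius`` of the polyline sample ``points``."""
    out = np.zeros(shape, dtype=bool)
    r = int(np.ceil(radius))
    ball = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball_mask = (ball[0] ** 2 + ball[1] ** 2 + ball[2] ** 2) <= radius ** 2
    for p in points:
        c = np.rint(p).astype(int)
        sl = tuple(slice(c[d] - r, c[d] + r + 1) for d in range(3))
        if any(s.start < 0 or s.stop > shape[d] for d, s in enumerate(sl)):
            return out  # caller checks bounds; partial marks are discarded
        out[sl] |= ball_mask
    return out


def _surface_point(center, radii, direction):
    """Intersection of a ray from the centre with the ellipsoid surface."""
    d = direction / np.linalg.norm(direction)
    t = 1.0 / np.sqrt(np.sum((d / np.asarray(radii)) ** 2))
    return np.asarray(center) + t * d


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_cell_mask(spec: SyntheticCellSpec) -> BinaryVolume:
    """Ground-truth mask: ellipsoid body, straight protrusions, and
    ``n_handles`` handle-forming arc bridges; χ = 1 − n_handles exactly."""
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.shape
    center = np.array([(s - 1) / 2.0 for s in shape])
    mask = _ellipsoid(shape, center, spec.body_radii)
    radius = spec.protrusion_width / 2.0

    # straight protrusions: keep genus zero, stay inside the grid
    for _ in range(spec.n_protrusions):
        placed = False
        for _attempt in range(200):
            u = _random_unit(rng)
            base = _surface_point(center, spec.body_radii, u)
            pts = [base + u * s for s in
                   np.arange(-2.0, spec.protrusion_length + 0.25, 0.5)]
            tip = pts[-1]
            if np.any(tip - radius - 1 < 0) or np.any(tip + radius + 2 > np.array(shape)):
                continue
            tube = _tube(shape, pts, radius)
            cand = mask | tube
            if is_spherical(cand) and euler_characteristic(cand) == 1:
                mask = cand
                placed = True
                break
        if not placed:
            raise SpecError("could not place a protrusion inside the grid")

    # handles: arc bridges whose underside forms a tunnel against the body
    chi_target = 1
    for _ in range(spec.n_handles):
        placed = False
        for _attempt in range(300):
            u1 = _random_unit(rng)
            # second anchor a modest angle away from the first
            perp = _random_unit(rng)
            perp -= perp.dot(u1) * u1
            perp /= np.linalg.norm(perp)
            angle = 0.55 + 0.25 * rng.random()
            u2 = np.cos(angle) * u1 + np.sin(angle) * perp
            a = _surface_point(center, spec.body_radii, u1)
            b = _surface_point(center, spec.body_radii, u2)
            um = (u1 + u2)
            um /= np.linalg.norm(um)
            lift = spec.protrusion_length
            ctrl = _surface_point(center, spec.body_radii, um) + um * lift
            if np.any(ctrl - radius - 2 < 0) or np.any(ctrl + radius + 2 > np.array(shape)):
                continue
            # quadratic Bezier from just inside A to just inside B
            a_in, b_in = a - 2.0 * u1, b - 2.0 * u2
            s = np.linspace(0.0, 1.0, 80)[:, None]
            pts = ((1 - s) ** 2 * a_in + 2 * s * (1 - s) * ctrl + s ** 2 * b_in)
            tube = _tube(shape, pts, radius)
            cand = mask | tube
            chi = euler_characteristic(cand)
            n_fg = ndimage.label(cand, structure=np.ones((3, 3, 3), bool))[1]
            n_bg = ndimage.label(np.pad(~cand, 1, constant_values=True))[1]
            if chi == chi_target - 1 and n_fg == 1 and n_bg == 1:
                mask = cand
                chi_target = chi
                placed = True
                break
        if not placed:
            raise SpecError("could not place a handle-forming arc")
    return BinaryVolume(mask, spec.spacing)


def make_cell_volume(spec: SyntheticCellSpec) -> tuple[VolumeStack, BinaryVolume]:
    """Render the intensity stack for a spec and return it with its ground
    truth.  Deterministic for a fixed ``rng_seed``."""
    truth = make_cell_mask(spec)
    mask = truth.mask
    shell = mask & ~ndimage.binary_erosion(
        mask, iterations=spec.membrane_thickness,
        structure=ndimage.generate_binary_structure(3, 1))
    interior = mask & ~shell
    clean = np.full(spec.shape, spec.background_level, dtype=np.float64)
    span = 1.0 - spec.background_level
    clean[interior] = spec.background_level + span * spec.interior_dimming
    clean[shell] = 1.0
    if spec.blur_sigma > 0:
        clean = ndimage.gaussian_filter(clean, spec.blur_sigma)
    rng = np.random.default_rng(spec.rng_seed + 1)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape) \
        if spec.noise_sigma > 0 else clean
    lo, hi = noisy.min(), noisy.max()
    noisy = (noisy - lo) / (hi - lo)
    return VolumeStack(noisy, spec.spacing), truth


# ---------------------------------------------------------------------------
# surfaces with known SPHARM coefficients


def make_spharm_surface(model: SpharmModel, grid=3) -> SurfaceMesh:
    """Surface sampled from a truncated SPHARM series.

    ``grid`` is either an icosphere subdivision level (int) or a tuple
    ``(theta, phi, faces)`` of explicit sample parameters.
    """
    if isinstance(grid, int):
        theta, phi, faces = icosphere_grid(grid)
    else:
        theta, phi, faces = grid
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        if theta.size == 0:
            raise ValueError("empty (theta, phi) grid")
    pts = evaluate_model(model, theta, phi)
    return SurfaceMesh(pts, faces)


def random_spharm_model(degree: int, rng_seed: int = 0, scale: float = 0.3,
                        base_radius: float = 5.0) -> SpharmModel:
    """A random smooth model: a sphere of ``base_radius`` plus random
    coefficients decaying with degree (a plausibly cell-like blob)."""
    rng = np.random.default_rng(rng_seed)
    n = (degree + 1) ** 2
    coeffs = np.zeros((3, n))
    for l in range(degree + 1):
        cols = slice(l * l, (l + 1) ** 2)
        coeffs[:, cols] = rng.normal(0.0, scale / (1.0 + l), size=(3, 2 * l + 1))
    # degree-1 real harmonics span linear coordinates: Y_1,-1 ∝ y, Y_1,0 ∝ z, Y_1,1 ∝ x
    c = base_radius * np.sqrt(4.0 * np.pi / 3.0)
    coeffs[0, 3] += c
    coeffs[1, 1] += c
    coeffs[2, 2] += c
    return SpharmModel(degree=degree, coeffs=coeffs)


def unit_sphere_model(degree: int = 1) -> SpharmModel:
    """Coefficients of the identity map on the unit sphere (degree-1 only)."""
    coeffs = np.zeros((3, (degree + 1) ** 2))
    c = np.sqrt(4.0 * np.pi / 3.0)
    coeffs[0, 3] = c
    coeffs[1, 1] = c
    coeffs[2, 2] = c
    return SpharmModel(degree=degree, coeffs=coeffs)


# ---------------------------------------------------------------------------
# evaluation


def f_measure(pred: BinaryVolume | np.ndarray, truth: BinaryVolume | np.ndarray) -> float:
    """Harmonic mean of voxel precision and recall against ground truth."""
    p = pred.mask if isinstance(pred, BinaryVolume) else np.asarray(pred, bool)
    t = truth.mask if isinstance(truth, BinaryVolume) else np.asarray(truth, bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    n_truth = int(t.sum())
    if n_truth == 0:
        raise ValueError("ground truth is empty; F-measure undefined")
    tp = int((p & t).sum())
    n_pred = int(p.sum())
    if tp == 0:
        return 0.0
    precision = tp / n_pred
    recall = tp / n_truth
    return 2.0 * precision * recall / (precision + recall)
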