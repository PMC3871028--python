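"""Random-walker cell segmentation on a downsampled grid.

The stack is downsampled (bilinear, x/y only — z resolution is already
coarse), foreground/background seeds are detected on the spectral-residual
saliency map, and the seeded random-walker problem — a discrete Dirichlet
problem on the intensity-weighted graph Laplacian — is solved on the small
grid.  The probability field is upsampled back to full resolution with a
cubic interpolant re-weighted by a Tukey-biweight-style intensity term that
restores sharp edges, then thresholded by argmax, morphologically closed
and reduced to the largest connected component.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph, linalg as sla

from . import saliency as _saliency
from .io import BinaryVolume, VolumeStack, log, stage_timer

_OFFSETS6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_OFFSETS26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) > (0, 0, 0)]


class UnseededComponentError(RuntimeError):
    """A connected component of the graph holds no seed of either class."""


@dataclasses.dataclass
class AffinityGraph:
    """Sparse graph Laplacian L = D − A with Gaussian edge affinities
    A_ij = exp(−‖S_i−S_j‖²/σ_S − (I_i−I_j)²/σ_I) on a 6- or 26-connected
    voxel grid."""

    laplacian: sparse.csr_matrix
    shape: tuple[int, int, int]
    sigma_S: float
    sigma_I: float
    connectivity: int


def build_affinity(stack: VolumeStack, sigma_S: float = 1.0, sigma_I: float = 0.01,
                   connectivity: int = 6, physical_distance: bool = False) -> AffinityGraph:
    """Build the intensity-weighted grid Laplacian.

    Spatial distances are in voxel-index units by default (after x/y
    downsampling the grid is near-isotropic); ``physical_distance`` switches
    to µm using the stack spacing.
    """
    if sigma_S <= 0 or sigma_I <= 0:
        raise ValueError("sigma_S and sigma_I must be positive")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    data = stack.data
    shape = data.shape
    n = data.size
    offsets = _OFFSETS6 if connectivity == 6 else _OFFSETS26
    step = np.asarray(stack.spacing) if physical_distance else np.ones(3)
    rows, cols, vals = [], [], []
    idx = np.arange(n).reshape(shape)
    for off in offsets:
        sl_a = tuple(slice(None, -o) if o else slice(None) for o in off)
        sl_b = tuple(slice(o, None) if o else slice(None) for o in off)
        d2_sp = float(np.sum((np.asarray(off) * step) ** 2))
        di = data[sl_a] - data[sl_b]
        w = np.exp(-d2_sp / sigma_S - di * di / sigma_I)
        rows.append(idx[sl_a].ravel())
        cols.append(idx[sl_b].ravel())
        vals.append(w.ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    A = sparse.coo_matrix((np.concatenate([v, v]),
                           (np.concatenate([r, c]), np.concatenate([c, r]))),
                          shape=(n, n)).tocsr()
    lap = sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A
    return AffinityGraph(laplacian=lap.tocsr(), shape=shape, sigma_S=sigma_S,
                         sigma_I=sigma_I, connectivity=connectivity)


def solve_random_walker(graph: AffinityGraph, seeds: _saliency.SeedSet,
                        rtol: float = 1e-10, use_direct_below: int = 20000) -> np.ndarray:
    """Foreground probability of every voxel.

    Seeded voxels are fixed at 1 (foreground) / 0 (background); unseeded
    probabilities solve the sparse SPD system L_U x_U = −Bᵀ x_M.  Solved by
    ILU-preconditioned conjugate gradients (direct sparse LU for small
    systems).  The result is clipped to [0, 1] (discrete maximum principle
    up to solver tolerance).
    """
    fg = seeds.fg.ravel()
    bg = seeds.bg.ravel()
    if not fg.any() or not bg.any():
        raise _saliency.NoSeedError("both seed classes must be nonempty")
    if (fg & bg).any():
        raise ValueError("foreground and background seeds overlap")
    L = graph.laplacian
    n = L.shape[0]
    seeded = fg | bg
    # every graph component must contain at least one seed
    n_comp, comp = csgraph.connected_components(L, directed=False)
    if n_comp > 1:
        for ci in range(n_comp):
            if not seeded[comp == ci].any():
                raise UnseededComponentError(f"component {ci} holds no seed")
    x = np.zeros(n)
    x[fg] = 1.0
    un = ~seeded
    if not un.any():
        return x.reshape(graph.shape)
    L_uu = L[un][:, un].tocsc()
    rhs = -L[un][:, seeded] @ x[seeded]
    if L_uu.shape[0] <= use_direct_below:
        xu = sla.spsolve(L_uu, rhs)
    else:
        try:
            ilu = sla.spilu(L_uu, drop_tol=1e-5, fill_factor=12)
            M = sla.LinearOperator(L_uu.shape, ilu.solve)
        except RuntimeError:
            M = None
        xu, info = sla.cg(L_uu, rhs, rtol=rtol, atol=0.0, M=M, maxiter=4000)
        if info != 0:
            log.warning("random-walker CG did not fully converge (info=%d)", info)
    x[un] = xu
    return np.clip(x, 0.0, 1.0).reshape(graph.shape)


# ---------------------------------------------------------------------------
# resolution changes


def downsample(stack: VolumeStack, rate: int) -> VolumeStack:
    """Bilinear downsampling in x and y only; z is left untouched.

    Output sample j lies at input coordinate ``j*rate + (rate-1)/2``
    (block-centred), evaluated by linear interpolation.
    """
    if rate < 1:
        raise ValueError("rate must be >= 1")
    if rate == 1:
        return VolumeStack(stack.data.copy(), stack.spacing)
    nx, ny, nz = stack.shape
    mx, my = nx // rate, ny // rate
    if mx < 1 or my < 1:
        raise ValueError(f"rate {rate} exceeds stack extent {stack.shape[:2]}")
    xs = np.arange(mx) * rate + (rate - 1) / 2.0
    ys = np.arange(my) * rate + (rate - 1) / 2.0
    zs = np.arange(nz, dtype=float)
    coords = np.meshgrid(xs, ys, zs, indexing="ij")
    out = ndimage.map_coordinates(stack.data, np.stack([c.ravel() for c in coords]),
                                  order=1, mode="nearest").reshape(mx, my, nz)
    sx, sy, sz = stack.spacing
    return VolumeStack(out, (sx * rate, sy * rate, sz))


def _upsample_field(field: np.ndarray, full_shape, rate: int, order: int) -> np.ndarray:
    """Interpolate a downsampled x/y field back to the full grid (inverse of
    the block-centred downsampling convention)."""
    nx, ny, nz = full_shape
    xs = (np.arange(nx) - (rate - 1) / 2.0) / rate
    ys = (np.arange(ny) - (rate - 1) / 2.0) / rate
    zs = np.arange(nz, dtype=float)
    coords = np.meshgrid(xs, ys, zs, indexing="ij")
    return ndimage.map_coordinates(field, np.stack([c.ravel() for c in coords]),
                                   order=order, mode="nearest").reshape(full_shape)


def _upsample_seeds(mask: np.ndarray, full_shape, rate: int) -> np.ndarray:
    up = np.repeat(np.repeat(mask, rate, axis=0), rate, axis=1)
    out = np.zeros(full_shape, dtype=bool)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(up.shape, full_shape))
    out[sl] = up[sl]
    return out


@dataclasses.dataclass
class UpsampleParams:
    """Parameters of the edge-preserved probability upsampling."""

    eta: float = 1e-3
    tau_fg: float | None = None   # None → 2·std of class seed intensities
    tau_bg: float | None = None
    neighborhood: int = 6

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        for t in (self.tau_fg, self.tau_bg):
            if t is not None and t <= 0:
                raise ValueError("tau must be positive")


def tukey_weight(delta, tau: float):
    """w(d) = (1 − (d/τ)²)² for |d| ≤ τ, else 0."""
    d = np.abs(np.asarray(delta, dtype=np.float64))
    r = d / tau
    w = (1.0 - r * r) ** 2
    return np.where(d <= tau, w, 0.0)


def upsample_probability(p_down: np.ndarray, stack: VolumeStack,
                         seeds: _saliency.SeedSet, rate: int,
                         params: UpsampleParams | None = None,
                         neighbor_probabilities: bool = False):
    """Edge-preserved upsampling of the foreground probability.

    The downsampled probability is cubically interpolated to the full grid;
    the per-class score is q^c = w(I_i, μ^c_seed)·p^c_i + η with w the
    Tukey-style weight.  ``neighbor_probabilities`` averages the
    interpolated probability over the 6/26-neighbourhood (the alternative
    reading in which the neighbourhood sum runs over p_k rather than p_i).

    Returns (labels, q_fg, q_bg).  Label assignment is argmax over the two
    class scores; an exact tie (both intensity weights vanished) falls back
    to the random-walker argmax, and a residual tie is background.
    """
    params = params or UpsampleParams()
    full_shape = stack.shape
    p_fg = np.clip(_upsample_field(p_down, full_shape, rate, order=3), 0.0, 1.0)
    if neighbor_probabilities:
        if params.neighborhood == 26:
            p_fg_use = ndimage.uniform_filter(p_fg, size=3)
        else:
            foot = ndimage.generate_binary_structure(3, 1).astype(float)
            p_fg_use = ndimage.correlate(p_fg, foot / foot.sum(), mode="nearest")
    else:
        p_fg_use = p_fg
    p_bg_use = 1.0 - p_fg_use

    # Seed intensity statistics at full resolution: the weighting compares
    # original-image intensities with seed means, so μ and τ come from the
    # second-level threshold sets applied to the original image (the seed
    # criterion itself), not from downsample-smeared block values.
    img = stack.data
    _, _, t_f2, t_b2 = seeds.thresholds
    fg_full = img > t_f2
    bg_full = img < t_b2
    if not fg_full.any():
        fg_full = _upsample_seeds(seeds.fg, full_shape, rate)
    if not bg_full.any():
        bg_full = _upsample_seeds(seeds.bg, full_shape, rate)
    mu_fg = float(img[fg_full].mean())
    mu_bg = float(img[bg_full].mean())
    tau_fg = params.tau_fg if params.tau_fg is not None else \
        max(2.0 * float(img[fg_full].std()), 1e-6)
    tau_bg = params.tau_bg if params.tau_bg is not None else \
        max(2.0 * float(img[bg_full].std()), 1e-6)

    q_fg = tukey_weight(img - mu_fg, tau_fg) * p_fg_use + params.eta
    q_bg = tukey_weight(img - mu_bg, tau_bg) * p_bg_use + params.eta
    labels = q_fg > q_bg
    tie = q_fg == q_bg
    labels[tie] = p_fg[tie] > 0.5
    return labels, q_fg, q_bg


# ---------------------------------------------------------------------------
# full chain


@dataclasses.dataclass
class SegmentationConfig:
    rate: int = 4
    sigma_S: float = 1.0
    sigma_I: float = 0.01
    connectivity: int = 6
    kernel_sigma: float = 2.0
    eta: float = 1e-3
    tau_fg: float | None = None
    tau_bg: float | None = None
    close_size: int = 3
    seed_erosion: int = 1
    physical_distance: bool = False
    use_otsu_seeds: bool = False
    fg_multiplier: float = 1.0
    bg_multiplier: float = 1.0

    def validate(self):
        if self.rate < 1:
            raise ValueError("rate must be >= 1")
        if self.sigma_S <= 0 or self.sigma_I <= 0:
            raise ValueError("sigmas must be positive")
        for t in (self.tau_fg, self.tau_bg):
            if t is not None and t <= 0:
                raise ValueError("tau must be positive")
        return self


def segment(stack: VolumeStack, config: SegmentationConfig | None = None,
            seeds: _saliency.SeedSet | None = None) -> BinaryVolume:
    """Full automatic segmentation chain.

    downsample → saliency seeding → affinity graph → random walker →
    edge-preserved upsampling → argmax → morphological close → largest
    connected component.  ``seeds`` (on the downsampled grid) bypasses the
    automatic seeding.
    """
    config = (config or SegmentationConfig()).validate()
    with stage_timer("downsample"):
        down = downsample(stack, config.rate)
    if seeds is None:
        with stage_timer("saliency-seeding"):
            sal = _saliency.compute_saliency(down, config.kernel_sigma)
            seeds = _saliency.detect_seeds(sal, down, config.fg_multiplier,
                                           config.bg_multiplier, config.use_otsu_seeds)
            # conservative seeding: pull foreground seeds off the boundary so
            # blocks straddling the blurred cell edge do not anchor the walker
            # outside the cell ("clearly separated thresholds, on the safe side")
            for _ in range(config.seed_erosion):
                eroded = ndimage.binary_erosion(seeds.fg, structure=np.ones((3, 3, 3), bool))
                if eroded.any():
                    seeds.fg = eroded
    with stage_timer("random-walker"):
        graph = build_affinity(down, config.sigma_S, config.sigma_I,
                               config.connectivity, config.physical_distance)
        prob = solve_random_walker(graph, seeds)
    with stage_timer("upsample"):
        params = UpsampleParams(eta=config.eta, tau_fg=config.tau_fg, tau_bg=config.tau_bg)
        labels, _, _ = upsample_probability(prob, stack, seeds, config.rate, params)
    with stage_timer("cleanup"):
        st = np.ones((config.close_size,) * 3, dtype=bool)
        closed = ndimage.binary_closing(labels, structure=st)
        closed |= labels  # closing must not delete foreground
        lab, n = ndimage.label(closed, structure=np.ones((3, 3, 3), bool))
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
            closed = lab == (1 + int(np.argmax(sizes)))
    return BinaryVolume(closed, stack.spacing)
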