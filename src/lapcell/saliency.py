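"""Spectral-residual saliency and automatic seed detection.

Repetitive background texture concentrates in spikes of the log-amplitude
spectrum of the (downsampled) stack.  Smoothing the log spectrum with a
Gaussian and re-synthesizing the image from the smoothed amplitude and the
*original* phase suppresses the background and highlights the cell; a
two-level threshold on the saliency map and then on the image intensities
yields disjoint foreground/background seed sets for the random walker.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.fft import fftn, ifftn

from .io import VolumeStack

_LOG_EPS = 1e-12  # guards log(|F|) at exact spectral zeros


class NoSeedError(RuntimeError):
    """Thresholding produced an empty seed set; fall back to manual seeds."""


@dataclasses.dataclass
class SaliencyMap:
    values: np.ndarray
    kernel_sigma: float


@dataclasses.dataclass
class SeedSet:
    """Boolean foreground/background seed masks on the (downsampled) grid."""

    fg: np.ndarray
    bg: np.ndarray
    mu_fg: float
    mu_bg: float
    thresholds: tuple[float, float, float, float]  # (T_f1, T_b1, T_f2, T_b2)


def compute_saliency(stack_d: VolumeStack | np.ndarray, kernel_sigma: float = 2.0,
                     square_before_smooth: bool = True,
                     slicewise: bool = False) -> SaliencyMap:
    """Spectral-residual saliency of a volume.

    S = |IFFT(exp(A_s + iP))|² smoothed with a Gaussian of ``kernel_sigma``
    voxels, where A_s is the Gaussian-smoothed log-amplitude spectrum and P
    the original phase.  The FFT is 3D by default; ``slicewise`` applies the
    transform per z-slice instead.  ``square_before_smooth=False`` smooths
    the magnitude before squaring (the two orders differ only slightly).
    """
    data = stack_d.data if isinstance(stack_d, VolumeStack) else np.asarray(stack_d, float)
    if data.size == 0:
        raise ValueError("empty stack")

    def _residual(arr, axes):
        spec = fftn(arr, axes=axes)
        amp = np.abs(spec)
        phase = np.angle(spec)
        log_spec = np.log(amp + _LOG_EPS)
        sigma = [kernel_sigma if ax in axes else 0.0 for ax in range(arr.ndim)]
        smoothed = ndimage.gaussian_filter(log_spec, sigma=sigma, mode="wrap")
        recon = ifftn(np.exp(smoothed + 1j * phase), axes=axes)
        return np.abs(recon)

    axes = (0, 1) if slicewise else (0, 1, 2)
    mag = _residual(data, axes)
    sigma_sp = [kernel_sigma if ax in axes else 0.0 for ax in range(3)]
    if square_before_smooth:
        sal = ndimage.gaussian_filter(mag * mag, sigma=sigma_sp, mode="wrap")
    else:
        sal = ndimage.gaussian_filter(mag, sigma=sigma_sp, mode="wrap") ** 2
    return SaliencyMap(values=np.maximum(sal, 0.0), kernel_sigma=kernel_sigma)


def first_level_thresholds(S: np.ndarray) -> tuple[float, float]:
    """T_f1 = mean(S) + 2 std(S); T_b1 = mean(S) + std(S)."""
    mu, sd = float(S.mean()), float(S.std())
    return mu + 2.0 * sd, mu + sd


def detect_seeds(S: SaliencyMap, stack_d: VolumeStack | np.ndarray,
                 fg_multiplier: float = 1.0, bg_multiplier: float = 1.0,
                 use_otsu: bool = False) -> SeedSet:
    """Two-level threshold seed detection.

    Level 1 selects strongly/weakly salient voxels (strict inequalities) and
    records their image intensities; level 2 thresholds the image against
    T_f2 = mean of level-1 foreground intensities and T_b2 = mean + 2 std of
    level-1 background intensities.  ``fg_multiplier``/``bg_multiplier``
    scale T_f2 and the std term of T_b2 (multi-channel tuning knob).
    ``use_otsu`` replaces the level-1 saliency split by Otsu's threshold.
    """
    sal = S.values
    img = stack_d.data if isinstance(stack_d, VolumeStack) else np.asarray(stack_d, float)
    if sal.shape != img.shape:
        raise ValueError(f"saliency {sal.shape} and stack {img.shape} differ in shape")

    if use_otsu:
        from skimage.filters import threshold_otsu
        t = float(threshold_otsu(sal))
        t_f1 = t_b1 = t
    else:
        t_f1, t_b1 = first_level_thresholds(sal)
    f1_sel = sal > t_f1
    b1_sel = sal < t_b1
    if not f1_sel.any() or not b1_sel.any():
        raise NoSeedError("first-level saliency thresholding selected no voxels")

    f1 = img[f1_sel]
    b1 = img[b1_sel]
    t_f2 = fg_multiplier * float(f1.mean())
    t_b2 = float(b1.mean()) + bg_multiplier * 2.0 * float(b1.std())
    fg = img > t_f2
    bg = img < t_b2
    overlap = fg & bg  # possible when T_b2 > T_f2; ambiguous voxels seed neither class
    fg &= ~overlap
    bg &= ~overlap
    if not fg.any():
        raise NoSeedError(f"no foreground seeds above T_f2 = {t_f2:.4g}")
    if not bg.any():
        raise NoSeedError(f"no background seeds below T_b2 = {t_b2:.4g}")
    return SeedSet(fg=fg, bg=bg, mu_fg=float(img[fg].mean()), mu_bg=float(img[bg].mean()),
                   thresholds=(t_f1, t_b1, t_f2, t_b2))
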