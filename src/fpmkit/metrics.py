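"""Image-quality metrics.

``ssim`` follows the standard local-statistics definition with a Gaussian
window (11 px, σ = 1.5; C1 = (0.01·L)², C2 = (0.03·L)², C3 = C2/2).  The
luminance-omitted variant drops the luminance factor and compares only the
contrast and structure terms, which makes the score invariant to a constant
intensity offset — useful when comparing refocused coherent images whose mean
levels are not calibrated against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .field import ComplexField

__all__ = ["SsimOptions", "ssim", "nrmse_mod_phase", "gradient_energy"]


@dataclass(frozen=True)
class SsimOptions:
    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    omit_luminance: bool = False
    data_range: float | None = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("SSIM constants must be positive")


def _local(img: np.ndarray, opts: SsimOptions) -> np.ndarray:
    truncate = ((opts.window - 1) / 2.0) / opts.sigma
    return gaussian_filter(img, opts.sigma, truncate=truncate)


def ssim(a: np.ndarray, b: np.ndarray, opts: SsimOptions | None = None) -> float:
    """Mean local structural similarity of two real images, in [−1, 1]."""
    opts = opts or SsimOptions()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    L = opts.data_range
    if L is None:
        L = max(a.max() - a.min(), b.max() - b.min())
    if L <= 0:
        raise ValueError("data range must be positive")
    C1 = (opts.k1 * L) ** 2
    C2 = (opts.k2 * L) ** 2
    C3 = C2 / 2.0

    mu_a = _local(a, opts)
    mu_b = _local(b, opts)
    var_a = np.clip(_local(a * a, opts) - mu_a**2, 0.0, None)
    var_b = np.clip(_local(b * b, opts) - mu_b**2, 0.0, None)
    cov = _local(a * b, opts) - mu_a * mu_b
    sd_a = np.sqrt(var_a)
    sd_b = np.sqrt(var_b)

    contrast = (2.0 * sd_a * sd_b + C2) / (var_a + var_b + C2)
    structure = (cov + C3) / (sd_a * sd_b + C3)
    if opts.omit_luminance:
        smap = contrast * structure
    else:
        luminance = (2.0 * mu_a * mu_b + C1) / (mu_a**2 + mu_b**2 + C1)
        smap = luminance * contrast * structure
    return float(np.mean(smap))


def nrmse_mod_phase(a: ComplexField | np.ndarray, b: ComplexField | np.ndarray,
                    max_shift: int = 2) -> float:
    """NRMSE between complex fields, minimised over a global phase and shift.

    For each integer shift within ±``max_shift`` px the optimal global phase
    has the closed form θ = arg Σ a·conj(b); the reported value is the minimum
    ‖a − e^{iθ}·b_shifted‖ / ‖a‖ over all shifts (a 2-px border is excluded so
    wrap-around pixels never contribute).
    """
    av = a.values if isinstance(a, ComplexField) else np.asarray(a, dtype=complex)
    bv = b.values if isinstance(b, ComplexField) else np.asarray(b, dtype=complex)
    if av.shape != bv.shape:
        raise ValueError("fields must share a grid")
    m = max_shift
    core = (slice(m, av.shape[0] - m), slice(m, av.shape[1] - m))
    ac = av[core]
    norm_a = np.linalg.norm(ac)
    if norm_a == 0:
        raise ValueError("reference field is identically zero")
    best = np.inf
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            bs = np.roll(bv, (dy, dx), axis=(0, 1))[core]
            inner = np.vdot(bs, ac)  # sum conj(b)·a
            phase = inner / abs(inner) if abs(inner) > 0 else 1.0
            err = np.linalg.norm(ac - phase * bs) / norm_a
            best = min(best, float(err))
    return best


def gradient_energy(img: np.ndarray) -> float:
    """Sum of squared Sobel gradient magnitude; zero for constant images."""
    from skimage.filters import sobel_h, sobel_v

    img = np.asarray(img, dtype=float)
    return float(np.sum(sobel_h(img) ** 2 + sobel_v(img) ** 2))
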