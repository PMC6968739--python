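"""Iterative FPM recovery of the high-resolution complex object spectrum.

The solver is the sequential Gauss-Newton scheme: per raw frame the modelled
passband field is formed from the current object spectrum window and pupil,
its real-space amplitude is replaced by the square root of the measured
intensity (keeping the modelled phase), and the Fourier-domain mismatch drives
regularised object and — when embedded pupil function recovery (EPRY) is
enabled — pupil updates:

    O_win += conj(P)·|P| / (|P|_max·(|P|² + δ_obj)) · ΔF
    P     += conj(O_win)·|O_win| / (|O|_max·(|O|² + δ_pupil·|O|_max²)) · ΔF

The pupil support (binary CTF disc) and an amplitude cap are re-imposed after
every pupil update.  Frames are visited centre-out by illumination NA, the
usual ordering for this family of algorithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield, replace

import numpy as np

from . import _fft
from .field import ComplexField
from .optics import (
    IlluminationDirection,
    OpticalConfig,
    Pupil,
    make_ctf,
    make_frequency_grid,
)
from .phantom import LowResStack, passband_window

__all__ = [
    "ReconstructionOptions",
    "ReconstructionResult",
    "initialize_spectrum",
    "sequential_update",
    "reconstruct",
    "fit_zernike",
    "zernike_basis",
]


@dataclass(frozen=True)
class ReconstructionOptions:
    iterations: int = 50
    enable_epry: bool = True
    delta_obj: float = 1e-3
    delta_pupil: float = 1e-8
    update_order: str = "na"  # "na" (centre-out) or "given"
    upsample_ratio: int = 4
    convergence_tol: float = 1e-4
    initial_pupil: Pupil | None = None
    pupil_max_amplitude: float = 1.1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.delta_obj <= 0 or self.delta_pupil <= 0:
            raise ValueError("regularizers must be positive")
        if self.upsample_ratio < 1:
            raise ValueError("upsample_ratio must be >= 1")

    def with_initial_pupil(self, pupil: Pupil) -> "ReconstructionOptions":
        return replace(self, initial_pupil=pupil)


@dataclass
class ReconstructionResult:
    field: ComplexField
    pupil: Pupil
    iterations_run: int
    residual_history: list[float] = dfield(default_factory=list)


def initialize_spectrum(stack: LowResStack, options: ReconstructionOptions) -> np.ndarray:
    """Centred high-resolution spectrum initialised from the most on-axis frame.

    The square root of the most on-axis intensity image (zero phase) is
    band-limited upsampled by embedding its spectrum into the larger grid.
    """
    if len(stack) == 0:
        raise ValueError("stack is empty")
    r = options.upsample_ratio
    idx = int(np.argmin([d.na_illu for d in stack.directions]))
    amp = np.sqrt(stack.images[idx])
    my, mx = amp.shape
    ny, nx = my * r, mx * r
    grid_lr = make_frequency_grid((my, mx), stack.sample_pixel, "centered")
    # confine the seed spectrum to the synthetic passband so the recovered
    # spectrum never carries energy outside the synthetic NA disc
    na_syn = stack.config.na_obj + max(d.na_illu for d in stack.directions)
    band = grid_lr.radius <= na_syn / stack.config.wavelength + 1e-12
    F_lr = _fft.fftshift(_fft.fft2(amp)) * band
    O = np.zeros((ny, nx), dtype=complex)
    y0, x0 = ny // 2 - my // 2, nx // 2 - mx // 2
    O[y0 : y0 + my, x0 : x0 + mx] = F_lr * r**2
    return O


def sequential_update(
    spectrum: np.ndarray,
    pupil: Pupil,
    image: np.ndarray,
    direction: IlluminationDirection,
    options: ReconstructionOptions,
    *,
    wavelength: float,
    pixel_hr: float,
) -> tuple[np.ndarray, Pupil, float]:
    """One amplitude-replacement Gauss-Newton step for a single frame.

    Updates ``spectrum`` (centred layout) and ``pupil`` in place and returns
    them with the frame's data misfit Σ(√I − |modelled|)².  The modelled field
    is never divided by zero: a small guard keeps the phase factor finite.
    """
    my, mx = image.shape
    sy, sx = passband_window(spectrum.shape, (my, mx), direction, wavelength, pixel_hr)
    scale = (my * mx) / (spectrum.shape[0] * spectrum.shape[1])

    P = pupil.values
    win = spectrum[sy, sx]
    psi_f = win * P
    psi = _fft.ifft2(_fft.ifftshift(psi_f))
    meas_amp = np.sqrt(np.clip(image, 0.0, None))
    model_amp = np.abs(psi)
    residual = float(np.sum((meas_amp - model_amp * scale) ** 2))

    guard = 1e-12 * model_amp.max() + 1e-300
    psi_new = (meas_amp / scale) * psi / (model_amp + guard)
    dF = _fft.fftshift(_fft.fft2(psi_new)) - psi_f

    absP = np.abs(P)
    p_max = absP.max() + 1e-300
    win_old = win.copy() if options.enable_epry else None
    spectrum[sy, sx] += (np.conj(P) * absP) / (p_max * (absP**2 + options.delta_obj)) * dF

    if options.enable_epry:
        absO = np.abs(win_old)
        o_max = absO.max()
        if o_max > 0:
            delta_p = options.delta_pupil * o_max**2
            pupil.values = P + (
                (np.conj(win_old) * absO) / (o_max * (absO**2 + delta_p)) * dF
            )
            pupil.enforce()

    return spectrum, pupil, residual


def _check_overlap(stack: LowResStack, cutoff: float) -> None:
    centers = np.array(
        [
            (-d.beta / stack.config.wavelength, -d.alpha / stack.config.wavelength)
            for d in stack.directions
        ]
    )
    if len(centers) < 2:
        return
    from scipy.spatial import cKDTree

    dists, _ = cKDTree(centers).query(centers, k=2)
    # two discs of radius `cutoff` overlap ~39% in area at centre distance = cutoff
    if dists[:, 1].max() > 1.02 * cutoff:
        warnings.warn(
            "neighbouring passbands overlap by less than ~40% in area; "
            "reconstruction may not converge",
            stacklevel=3,
        )


def reconstruct(
    stack: LowResStack,
    config: OpticalConfig | None = None,
    options: ReconstructionOptions | None = None,
) -> ReconstructionResult:
    """Recover the high-resolution complex field (and pupil) from a raw stack.

    Iterates the sequential update over all frames per iteration, stopping at
    ``options.iterations`` or when the relative change of the summed data
    misfit drops below ``convergence_tol``.  Aborts with a diagnostic if the
    misfit grows for three consecutive iterations.
    """
    config = config if config is not None else stack.config
    options = options if options is not None else ReconstructionOptions()
    if len(stack) == 0:
        raise ValueError("stack is empty")
    r = options.upsample_ratio
    n, my, mx = stack.images.shape
    p_lr = stack.sample_pixel
    p_hr = p_lr / r

    na_max = max(d.na_illu for d in stack.directions)
    na_syn = config.na_obj + na_max
    if na_syn / config.wavelength > 1.0 / (2.0 * p_hr):
        raise ValueError(
            f"upsample_ratio {r} cannot represent the synthetic NA {na_syn:.2f}; "
            "increase upsample_ratio"
        )

    if options.initial_pupil is not None:
        pupil = options.initial_pupil.copy()
    else:
        grid_lr = make_frequency_grid((my, mx), p_lr, "centered")
        pupil = make_ctf(grid_lr, config.na_obj, config.wavelength)
        pupil.max_amplitude = options.pupil_max_amplitude
    _check_overlap(stack, pupil.cutoff)

    spectrum = initialize_spectrum(stack, options)
    if options.update_order == "na":
        order = sorted(range(n), key=lambda i: (stack.directions[i].na_illu, i))
    elif options.update_order == "given":
        order = list(range(n))
    else:
        raise ValueError(f"unknown update_order {options.update_order!r}")

    history: list[float] = []
    rising = 0
    it = 0
    for it in range(1, options.iterations + 1):
        total = 0.0
        for i in order:
            spectrum, pupil, res = sequential_update(
                spectrum,
                pupil,
                stack.images[i],
                stack.directions[i],
                options,
                wavelength=config.wavelength,
                pixel_hr=p_hr,
            )
            total += res
        history.append(total)
        if len(history) >= 2:
            prev = history[-2]
            if total > prev * 1.05:
                rising += 1
                if rising >= 3:
                    raise RuntimeError(
                        "reconstruction diverging: data misfit rose for three "
                        f"consecutive iterations (last values {history[-4:]})"
                    )
            else:
                rising = 0
            if prev > 0 and abs(total - prev) / prev < options.convergence_tol:
                break

    values = _fft.ifft2(_fft.ifftshift(spectrum))
    field = ComplexField(values, pixel=p_hr, wavelength=config.wavelength, z=0.0)
    return ReconstructionResult(
        field=field, pupil=pupil, iterations_run=it, residual_history=history
    )


_ZERNIKE_MODES = {
    (0, 0): lambda rho, th: np.ones_like(rho),
    (1, -1): lambda rho, th: 2.0 * rho * np.sin(th),
    (1, 1): lambda rho, th: 2.0 * rho * np.cos(th),
    (2, -2): lambda rho, th: np.sqrt(6.0) * rho**2 * np.sin(2 * th),
    (2, 0): lambda rho, th: np.sqrt(3.0) * (2.0 * rho**2 - 1.0),
    (2, 2): lambda rho, th: np.sqrt(6.0) * rho**2 * np.cos(2 * th),
}


def zernike_basis(pupil: Pupil, modes) -> tuple[np.ndarray, np.ndarray]:
    """Noll-normalised Zernike mode maps over the pupil support."""
    sup = pupil.support()
    rho = pupil.grid.radius / pupil.cutoff
    th = np.arctan2(pupil.grid.v, pupil.grid.u)
    cols = []
    for m in modes:
        if tuple(m) not in _ZERNIKE_MODES:
            raise ValueError(f"unsupported Zernike mode {m}")
        cols.append(_ZERNIKE_MODES[tuple(m)](rho[sup], th[sup]))
    return np.column_stack(cols), sup


def fit_zernike(pupil: Pupil, modes=((0, 0), (1, -1), (1, 1), (2, 0))) -> dict:
    """Least-squares Zernike coefficients (radians) of the pupil phase.

    The pupil phase is unwrapped over the support disc before projection onto
    the requested modes.  Coefficients use the Noll normalisation, e.g. defocus
    Z(2,0) = √3(2ρ²−1).
    """
    from skimage.restoration import unwrap_phase

    sup = pupil.support()
    if sup.sum() < 2 * len(tuple(modes)):
        raise ValueError("pupil support is degenerate; cannot fit Zernike modes")
    masked = np.ma.array(np.angle(pupil.values), mask=~sup)
    unwrapped = np.asarray(unwrap_phase(masked))
    A, sup = zernike_basis(pupil, modes)
    coef, *_ = np.linalg.lstsq(A, unwrapped[sup], rcond=None)
    return {tuple(m): float(c) for m, c in zip(modes, coef)}
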