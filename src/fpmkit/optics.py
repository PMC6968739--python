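"""Optical system model for an LED-array Fourier ptychographic microscope.

Holds the optical parameters, spatial-frequency geometry, pupil / coherent
transfer function (CTF) construction and the closed-form calculators that the
rest of the package builds on:

* incoherent depth of field, ``DoF = λ·n/NA² + n·e/(M·NA)``;
* the first-Born validity coefficient ``k·δn/2`` (the condition for treating a
  sample of thickness ``t`` as weakly scattering is ``k·t·δn/2 ≪ 1``);
* the thin-sample thickness limit ``h_max = π/|k_z|_max`` for angle-varied
  illumination, i.e. ``λ / (2·(1 − √(1 − NA_illu²)))``.

Spatial frequencies are expressed in cycles/µm throughout the package, so the
pupil cutoff radius is ``NA/λ``.  The radian convention is never exposed.

Sign convention for illumination: an LED displaced toward +x illuminates the
sample with direction cosine α < 0, so that the captured passband of the
object spectrum is shifted toward +u.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "OpticalConfig",
    "LEDArrayGeometry",
    "IlluminationDirection",
    "FrequencyGrid",
    "Pupil",
    "make_frequency_grid",
    "make_ctf",
    "zernike_defocus_phase",
    "depth_of_field",
    "born_thickness_coefficient",
    "ou_thickness_limit",
    "led_directions",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the imaging path.

    wavelength and camera_pixel are in µm; ``n_medium`` is the immersion
    refractive index (1.0 for air).
    """

    wavelength: float
    na_obj: float
    magnification: float
    camera_pixel: float
    n_medium: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.na_obj <= self.n_medium):
            raise ValueError("need 0 < na_obj <= n_medium")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.camera_pixel <= 0:
            raise ValueError("camera_pixel must be positive")
        if self.n_medium < 1:
            raise ValueError("n_medium must be >= 1")

    @property
    def sample_pixel(self) -> float:
        """Camera pixel size referred to the sample plane (e/M), µm."""
        return self.camera_pixel / self.magnification

    @property
    def cutoff(self) -> float:
        """Objective passband radius NA/λ, cycles/µm."""
        return self.na_obj / self.wavelength


@dataclass(frozen=True)
class IlluminationDirection:
    """Plane-wave illumination direction cosines (α, β), dimensionless."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha**2 + self.beta**2 >= 1.0:
            raise ValueError("direction cosines must satisfy alpha^2+beta^2 < 1")

    @property
    def na_illu(self) -> float:
        return float(np.hypot(self.alpha, self.beta))


@dataclass(frozen=True)
class LEDArrayGeometry:
    """Planar LED matrix below the sample.

    ``pitch`` and ``distance_to_sample`` in mm; ``center_offset`` is the (x, y)
    offset of the array centre from the optical axis in mm.  ``active_indices``
    is the subset of (row, col) positions that are switched on; ``None`` means
    the full grid.
    """

    grid_rows: int
    grid_cols: int
    pitch: float
    distance_to_sample: float
    center_offset: tuple[float, float] = (0.0, 0.0)
    active_indices: frozenset[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.distance_to_sample <= 0:
            raise ValueError("pitch and distance_to_sample must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one LED")
        if self.active_indices is not None:
            for r, c in self.active_indices:
                if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                    raise ValueError(f"active index {(r, c)} outside grid")

    def led_position(self, row: int, col: int) -> tuple[float, float]:
        """Planar (x, y) offset of one LED from the optical axis, mm."""
        x = (col - (self.grid_cols - 1) / 2.0) * self.pitch + self.center_offset[0]
        y = (row - (self.grid_rows - 1) / 2.0) * self.pitch + self.center_offset[1]
        return x, y

    def active_in_circle(self, diameter_mm: float) -> "LEDArrayGeometry":
        """Restrict the active set to LEDs inside a centred filled circle."""
        keep = set()
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                x, y = self.led_position(r, c)
                if np.hypot(x, y) <= diameter_mm / 2.0:
                    keep.add((r, c))
        return LEDArrayGeometry(
            self.grid_rows,
            self.grid_cols,
            self.pitch,
            self.distance_to_sample,
            self.center_offset,
            frozenset(keep),
        )


@dataclass(frozen=True)
class FrequencyGrid:
    """2D spatial-frequency coordinates (cycles/µm) for an image grid.

    ``layout`` is ``"centered"`` (zero frequency at the array centre) or
    ``"corner"`` (FFT-native ordering).
    """

    u: np.ndarray
    v: np.ndarray
    pixel: float
    layout: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel)

    def to_layout(self, layout: str) -> "FrequencyGrid":
        if layout not in ("centered", "corner"):
            raise ValueError(f"unknown layout {layout!r}")
        if layout == self.layout:
            return self
        shift = np.fft.fftshift if layout == "centered" else np.fft.ifftshift
        return FrequencyGrid(shift(self.u), shift(self.v), self.pixel, layout)


def make_frequency_grid(
    shape: tuple[int, int], pixel: float, layout: str = "centered"
) -> FrequencyGrid:
    """Frequency coordinates for an image of ``shape`` with pitch ``pixel`` µm.

    The spacing is Δu = 1/(N·pixel) along each axis and the zero frequency
    appears exactly once.
    """
    if pixel <= 0:
        raise ValueError("pixel must be positive")
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise ValueError("grid shape components must be >= 2")
    if layout not in ("centered", "corner"):
        raise ValueError(f"unknown layout {layout!r}")
    fy = np.fft.fftfreq(ny, d=pixel)
    fx = np.fft.fftfreq(nx, d=pixel)
    if layout == "centered":
        fy = np.fft.fftshift(fy)
        fx = np.fft.fftshift(fx)
    u, v = np.meshgrid(fx, fy)
    return FrequencyGrid(u=u, v=v, pixel=pixel, layout=layout)


@dataclass
class Pupil:
    """Complex pupil transmittance on a FrequencyGrid.

    The support |u| ≤ cutoff (cutoff = NA/λ, cycles/µm) is enforced: values
    outside are zero, and |values| inside is capped at ``max_amplitude``.
    """

    values: np.ndarray
    grid: FrequencyGrid
    cutoff: float
    max_amplitude: float = 1.1

    def support(self) -> np.ndarray:
        return self.grid.radius <= self.cutoff + 1e-12

    def enforce(self) -> "Pupil":
        """Re-impose the support and amplitude bound in place."""
        sup = self.support()
        self.values = np.where(sup, self.values, 0.0)
        amp = np.abs(self.values)
        over = amp > self.max_amplitude
        if np.any(over):
            self.values[over] *= self.max_amplitude / amp[over]
        return self

    def copy(self) -> "Pupil":
        return Pupil(self.values.copy(), self.grid, self.cutoff, self.max_amplitude)


def make_ctf(grid: FrequencyGrid, na: float, wavelength: float) -> Pupil:
    """Binary coherent transfer function: 1 inside NA/λ, 0 outside."""
    if na <= 0:
        raise ValueError("na must be positive")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    cutoff = na / wavelength
    if cutoff > grid.nyquist:
        warnings.warn(
            f"CTF cutoff {cutoff:.3f} cycles/um exceeds the grid Nyquist "
            f"{grid.nyquist:.3f}; support is truncated",
            stacklevel=2,
        )
    values = (grid.radius <= cutoff + 1e-12).astype(complex)
    return Pupil(values=values, grid=grid, cutoff=cutoff)


def zernike_defocus_phase(
    grid: FrequencyGrid, na: float, wavelength: float, z20: float
) -> np.ndarray:
    """Defocus phase z20·√3·(2ρ²−1) over the pupil disc, radians.

    ρ is the pupil radius normalised to the cutoff, ρ = λ·√(u²+v²)/NA; the
    Noll-normalised Z(2,0) polynomial is used.  Zero outside the support.
    """
    if na <= 0 or wavelength <= 0:
        raise ValueError("na and wavelength must be positive")
    rho = wavelength * grid.radius / na
    phase = z20 * np.sqrt(3.0) * (2.0 * rho**2 - 1.0)
    return np.where(rho <= 1.0 + 1e-12, phase, 0.0)


def depth_of_field(config: OpticalConfig, na_effective: float) -> float:
    """Incoherent-illumination depth of field, µm.

    DoF = λ·n/NA² + n·e/(M·NA) for effective numerical aperture ``na_effective``.
    """
    if na_effective <= 0:
        raise ValueError("na_effective must be positive")
    n = config.n_medium
    wave_term = config.wavelength * n / na_effective**2
    pixel_term = n * config.camera_pixel / (config.magnification * na_effective)
    return wave_term + pixel_term


def born_thickness_coefficient(
    wavelength: float, n_sample: float, n_medium: float
) -> float:
    """Coefficient c = k·|δn|/2 (per µm) in the first-Born condition c·t ≪ 1.

    k = 2π/λ and δn is the sample/immersion refractive-index difference.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    k = 2.0 * np.pi / wavelength
    return k * abs(n_sample - n_medium) / 2.0


def ou_thickness_limit(wavelength: float, na_illu: float) -> float:
    """Thin-sample thickness limit h_max = π/|k_z|_max, µm.

    |k_z|_max = k·(1 − √(1 − NA_illu²)) is the largest variation of the axial
    wavevector over the illumination angles, so
    h_max = λ / (2·(1 − √(1 − NA_illu²))).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if not (0 < na_illu < 1):
        raise ValueError("need 0 < na_illu < 1")
    return wavelength / (2.0 * (1.0 - np.sqrt(1.0 - na_illu**2)))


def led_directions(
    geom: LEDArrayGeometry, order: str = "na"
) -> list[IlluminationDirection]:
    """Illumination directions of the active LEDs.

    For an LED at planar offset (x, y) mm from the axis at distance d below
    the sample, α = −x/√(x²+y²+d²) and β = −y/√(x²+y²+d²).  ``order`` is
    ``"na"`` (increasing illumination NA, the centre-out reconstruction
    ordering; ties broken by grid index) or ``"grid"`` (row-major).
    """
    if geom.active_indices is not None:
        active: Iterable[tuple[int, int]] = sorted(geom.active_indices)
    else:
        active = [
            (r, c) for r in range(geom.grid_rows) for c in range(geom.grid_cols)
        ]
    active = list(active)
    if not active:
        raise ValueError("LED active set is empty")
    d = geom.distance_to_sample
    dirs = []
    for r, c in active:
        x, y = geom.led_position(r, c)
        norm = np.sqrt(x * x + y * y + d * d)
        dirs.append(IlluminationDirection(alpha=-x / norm, beta=-y / norm))
    if order == "na":
        idx = sorted(range(len(dirs)), key=lambda i: (dirs[i].na_illu, i))
        dirs = [dirs[i] for i in idx]
    elif order != "grid":
        raise ValueError(f"unknown order {order!r}")
    return dirs
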