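"""Synthetic objects and forward-model simulation of raw FPM image stacks.

The blood-film phantom emulates a thin Giemsa-stained peripheral blood smear:
annular red blood cells (RBCs, diameter 6–8 µm) with a dark rim, a weaker
interior amplitude drop and a biconcave optical-path (phase) profile, a
fraction of which host ring-stage malaria-parasite inclusions — a dark
chromatin spot (~1.2 µm) surrounded by a fainter cytoplasmic ring — placed at
per-parasite axial offsets within the film thickness.  The geometry is emitted
as a ground-truth record used as the oracle for segmentation and focal-plane
selection.

The forward model renders the raw low-resolution intensity stack: for each
illumination direction the object spectrum is shifted by the illumination
wavevector, the passband is cropped and multiplied by the pupil, and the
squared magnitude of the inverse transform gives the camera image
(I_i = |iFT[T(u−α_i/λ, v−β_i/λ)·P(u,v)]|²).  Downsampling to the camera grid
is performed by cropping the Fourier spectrum (band-limited resampling) with
an integer ratio; spectrum shifts are rounded to the nearest high-resolution
frequency pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from . import _fft
from .field import ComplexField
from .optics import IlluminationDirection, OpticalConfig, make_ctf, make_frequency_grid
from .refocus import propagate

__all__ = [
    "CellTruth",
    "ParasiteTruth",
    "PhantomTruth",
    "LowResStack",
    "OutOfBandError",
    "BloodFilmParams",
    "make_blood_film_phantom",
    "make_two_layer_target",
    "compose_layered_object",
    "simulate_low_res_stack",
]


class OutOfBandError(ValueError):
    """An illumination shift moved the passband outside the simulated spectrum."""


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float]  # (y, x) µm
    radius: float  # µm
    z: float  # membrane plane, µm


@dataclass(frozen=True)
class ParasiteTruth:
    center: tuple[float, float]  # (y, x) µm
    radius: float  # chromatin spot radius, µm
    z: float  # µm
    host: int  # index into PhantomTruth.cells


@dataclass
class PhantomTruth:
    cells: list[CellTruth]
    parasites: list[ParasiteTruth]
    medium: str
    debris: list[tuple[tuple[float, float], float]] = dfield(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "medium": self.medium,
            "cells": [
                {"center": list(c.center), "radius": c.radius, "z": c.z}
                for c in self.cells
            ],
            "parasites": [
                {"center": list(p.center), "radius": p.radius, "z": p.z, "host": p.host}
                for p in self.parasites
            ],
            "debris": [{"center": list(c), "radius": r} for c, r in self.debris],
        }


@dataclass
class LowResStack:
    """Raw FPM dataset: intensity images with per-frame illumination directions."""

    images: np.ndarray  # (n, h, w), nonnegative
    directions: list[IlluminationDirection]
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, h, w) array")
        if len(self.directions) != self.images.shape[0]:
            raise ValueError("number of directions must match number of images")
        if np.any(self.images < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def sample_pixel(self) -> float:
        """Camera pixel referred to the sample plane (e/M), µm."""
        return self.config.sample_pixel

    def __len__(self) -> int:
        return self.images.shape[0]


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _soft_disc(rho: np.ndarray, edge: float = 0.08) -> np.ndarray:
    """1 inside rho<~1, smooth roll-off of relative width ``edge``."""
    return 1.0 - _smoothstep((rho - (1.0 - edge)) / edge)


@dataclass(frozen=True)
class BloodFilmParams:
    """Blood-film phantom geometry and contrast (air defaults).

    Lengths in µm.  ``opd_peak`` is the peak optical path difference of a cell
    (phase = 2π/λ·OPD); in immersion oil the index mismatch nearly vanishes, so
    the oil medium uses a small negative OPD and a much weaker rim.
    """

    n_cells: int = 20
    shape: tuple[int, int] = (600, 600)
    pixel: float = 0.10625
    wavelength: float = 0.632
    medium: str = "air"
    infected_fraction: float = 0.3
    parasite_z_range: float = 1.5
    cell_radius_range: tuple[float, float] = (3.0, 4.0)
    cell_gap: float = 3.0
    rim_absorption: float = 0.45
    interior_absorption: float = 0.18
    opd_peak: float = 0.04
    parasite_diameter: float = 1.2
    parasite_absorption: float = 0.62
    parasite_ring_radius: float = 0.9
    parasite_ring_width: float = 0.21
    parasite_ring_absorption: float = 0.22
    parasite_phase: float = 0.0
    stain_texture: float = 0.2  # peak absorption of granular stain clumps
    stain_grain_um: float = 0.25  # correlation length of the mottle
    n_debris_small: int = 4
    n_debris_medium: int = 3
    max_place_tries: int = 2000

    def for_medium(self) -> "BloodFilmParams":
        if self.medium == "oil":
            from dataclasses import replace

            return replace(self, rim_absorption=0.10, interior_absorption=0.24,
                           opd_peak=-0.03)
        return self


def _render_cell(amp, phase, yy, xx, cy, cx, r, p: BloodFilmParams):
    rho = np.hypot(yy - cy, xx - cx) / r
    edge = _soft_disc(rho)
    rim = np.exp(-(((rho - 0.82) / 0.10) ** 2))
    interior = 1.0 - _smoothstep((rho - 0.70) / 0.12)
    drop = np.maximum(p.rim_absorption * rim, p.interior_absorption * interior)
    amp *= 1.0 - edge * drop
    # biconcave thickness: thickest near rho ~ 0.75, central dimple
    opd = p.opd_peak * (0.55 + 0.45 * np.exp(-(((rho - 0.75) / 0.30) ** 2))) * edge
    phase += (2.0 * np.pi / p.wavelength) * opd


def _render_parasite(amp, phase, yy, xx, cy, cx, p: BloodFilmParams):
    r = p.parasite_diameter / 2.0
    dist = np.hypot(yy - cy, xx - cx)
    spot = _soft_disc(dist / r, edge=0.25)
    ring = np.exp(-(((dist - p.parasite_ring_radius) / p.parasite_ring_width) ** 2))
    amp *= (1.0 - p.parasite_absorption * spot) * (1.0 - p.parasite_ring_absorption * ring)
    phase += p.parasite_phase * spot


def _render_speck(amp, yy, xx, cy, cx, r, absorption=0.5):
    dist = np.hypot(yy - cy, xx - cx)
    amp *= 1.0 - absorption * _soft_disc(dist / r, edge=0.3)


def make_blood_film_phantom(
    params: BloodFilmParams | None = None, *, seed: int, **overrides
) -> tuple[list[ComplexField], PhantomTruth]:
    """Render a blood-film phantom as per-z transmittance layers plus truth.

    Returns the layers sorted by z (the membrane/debris layer at z = 0 plus one
    thin layer per parasite at its axial offset) and the exact geometry record.
    Deterministic for a fixed seed.  Raises if the requested cells cannot be
    placed without overlap within a bounded number of attempts.
    """
    if params is None:
        params = BloodFilmParams(**overrides)
    elif overrides:
        from dataclasses import replace

        params = replace(params, **overrides)
    p = params.for_medium()
    ny, nx = p.shape
    if min(ny, nx) < 64:
        raise ValueError("field size must be at least 64 px")
    rng = np.random.default_rng(seed)
    fy, fx = ny * p.pixel, nx * p.pixel
    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) * p.pixel, (np.arange(nx) + 0.5) * p.pixel, indexing="ij"
    )

    # --- place cells by rejection sampling -------------------------------
    cells: list[CellTruth] = []
    tries = 0
    while len(cells) < p.n_cells:
        if tries >= p.max_place_tries:
            raise RuntimeError(
                f"could not place {p.n_cells} non-overlapping cells "
                f"in a {fy:.0f}x{fx:.0f} um field after {tries} attempts"
            )
        tries += 1
        r = rng.uniform(*p.cell_radius_range)
        cy = rng.uniform(r + 1.0, fy - r - 1.0)
        cx = rng.uniform(r + 1.0, fx - r - 1.0)
        if all(
            np.hypot(cy - c.center[0], cx - c.center[1]) > r + c.radius + p.cell_gap
            for c in cells
        ):
            cells.append(CellTruth(center=(cy, cx), radius=r, z=0.0))

    # --- infect a subset --------------------------------------------------
    n_inf = int(round(p.infected_fraction * len(cells)))
    hosts = rng.choice(len(cells), size=n_inf, replace=False) if n_inf else []
    parasites: list[ParasiteTruth] = []
    for h in sorted(int(h) for h in np.atleast_1d(hosts)):
        c = cells[h]
        margin = p.parasite_diameter  # keep spot + ring inside the cell disc
        rad = rng.uniform(0.0, max(c.radius - margin - 0.3, 0.2))
        ang = rng.uniform(0.0, 2.0 * np.pi)
        pz = float(rng.uniform(-p.parasite_z_range, p.parasite_z_range))
        parasites.append(
            ParasiteTruth(
                center=(c.center[0] + rad * np.sin(ang), c.center[1] + rad * np.cos(ang)),
                radius=p.parasite_diameter / 2.0,
                z=pz,
                host=h,
            )
        )

    # --- debris distractors (below the pipeline's size filters) ----------
    debris: list[tuple[tuple[float, float], float]] = []

    def _place_clear(r_deb):
        for _ in range(p.max_place_tries):
            cy = rng.uniform(r_deb + 0.5, fy - r_deb - 0.5)
            cx = rng.uniform(r_deb + 0.5, fx - r_deb - 0.5)
            if all(
                np.hypot(cy - c.center[0], cx - c.center[1]) > c.radius + r_deb + 1.0
                for c in cells
            ):
                return cy, cx
        return None

    for _ in range(p.n_debris_small):
        pos = _place_clear(0.15)  # few pixels: removed by the 50 px filter
        if pos:
            debris.append((pos, 0.15))
    for _ in range(p.n_debris_medium):
        pos = _place_clear(1.3)  # ~5 µm² blob: removed by the 12 µm² filter
        if pos:
            debris.append((pos, 1.3))

    # --- render layers ----------------------------------------------------
    amp0 = np.ones((ny, nx))
    phase0 = np.zeros((ny, nx))
    for c in cells:
        _render_cell(amp0, phase0, yy, xx, *c.center, c.radius, p)
    if p.stain_texture > 0:
        # granular Giemsa stain mottle confined to the cell bodies; its
        # high-frequency contrast decays within the DoF and anchors
        # gradient-based focus metrics to the membrane plane
        from scipy.ndimage import gaussian_filter as _gauss

        noise = _gauss(rng.standard_normal((ny, nx)), p.stain_grain_um / p.pixel)
        noise /= noise.std() + 1e-12
        mottle = 0.5 * (1.0 + np.tanh(noise))  # absorbing clumps in [0, 1]
        inside = np.zeros((ny, nx))
        for c in cells:
            rho = np.hypot(yy - c.center[0], xx - c.center[1]) / c.radius
            inside = np.maximum(inside, _soft_disc(rho, edge=0.12))
        amp0 *= 1.0 - p.stain_texture * inside * mottle
    for (dy, dx), dr in debris:
        _render_speck(amp0, yy, xx, dy, dx, dr)

    layer_maps: dict[float, tuple[np.ndarray, np.ndarray]] = {
        0.0: (amp0, phase0)
    }
    for par in parasites:
        key = round(par.z, 9)
        if key not in layer_maps:
            layer_maps[key] = (np.ones((ny, nx)), np.zeros((ny, nx)))
        a, ph = layer_maps[key]
        _render_parasite(a, ph, yy, xx, *par.center, p)

    layers = [
        ComplexField(a * np.exp(1j * ph), pixel=p.pixel, wavelength=p.wavelength, z=z)
        for z, (a, ph) in sorted(layer_maps.items())
    ]
    truth = PhantomTruth(cells=cells, parasites=parasites, medium=p.medium, debris=debris)
    return layers, truth


def make_texture_patch(
    shape: tuple[int, int] = (400, 400),
    pixel: float = 0.2125,
    wavelength: float = 0.632,
    *,
    seed: int,
    grain_um: float = 0.25,
    absorption: float = 0.5,
) -> ComplexField:
    """Granular absorbing calibration patch (stained-film mottle).

    A random field of absorbing clumps with correlation length ``grain_um``;
    its high-frequency amplitude contrast decays within the depth of field,
    which makes it the fixture of choice for focus ranking and chromatic
    focal-shift calibration.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    from scipy.ndimage import gaussian_filter as _gauss

    noise = _gauss(rng.standard_normal((ny, nx)), grain_um / pixel)
    noise /= noise.std() + 1e-12
    amp = 1.0 - absorption * 0.5 * (1.0 + np.tanh(noise))
    return ComplexField(amp.astype(complex), pixel=pixel, wavelength=wavelength, z=0.0)


def make_two_layer_target(
    shape: tuple[int, int] = (600, 600),
    pixel: float = 0.2125,
    wavelength: float = 0.632,
    separation: float = 170.0,
    disc_diameter: float = 65.0,
    bar_width: float = 2.0,
) -> tuple[list[ComplexField], dict]:
    """Two binary-amplitude chrome-on-glass style calibration layers.

    Layer 1 (z = 0) carries an opaque disc and a vertical line pair; layer 2
    (z = separation) carries a horizontal line pair and a digit-7 glyph.
    Returns the layers and a truth dict of glyph centres (µm).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    ny, nx = shape
    fy, fx = ny * pixel, nx * pixel
    if disc_diameter >= 0.55 * min(fy, fx):
        raise ValueError("disc glyph exceeds the field")
    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) * pixel, (np.arange(nx) + 0.5) * pixel, indexing="ij"
    )

    def _bar(amp, cy, cx, h, w):
        amp[(np.abs(yy - cy) < h / 2) & (np.abs(xx - cx) < w / 2)] = 0.0

    truth = {}
    amp1 = np.ones((ny, nx))
    disc_c = (0.30 * fy, 0.30 * fx)
    amp1[np.hypot(yy - disc_c[0], xx - disc_c[1]) <= disc_diameter / 2] = 0.0
    truth["disc"] = disc_c
    vl_c = (0.30 * fy, 0.72 * fx)
    bar_len = 0.22 * fy
    _bar(amp1, vl_c[0], vl_c[1] - 1.5 * bar_width, bar_len, bar_width)
    _bar(amp1, vl_c[0], vl_c[1] + 1.5 * bar_width, bar_len, bar_width)
    truth["vlines"] = vl_c

    amp2 = np.ones((ny, nx))
    hl_c = (0.72 * fy, 0.30 * fx)
    _bar(amp2, hl_c[0] - 1.5 * bar_width, hl_c[1], bar_width, bar_len)
    _bar(amp2, hl_c[0] + 1.5 * bar_width, hl_c[1], bar_width, bar_len)
    truth["hlines"] = hl_c
    # digit 7: top bar plus a diagonal stroke
    sv_c = (0.72 * fy, 0.72 * fx)
    g = 0.18 * min(fy, fx)
    _bar(amp2, sv_c[0] - g / 2, sv_c[1], bar_width, g)
    tt = np.linspace(0.0, 1.0, 200)
    for t in tt:
        cy = sv_c[0] - g / 2 + t * g
        cx = sv_c[1] + g / 2 - t * 0.7 * g
        amp2[(np.abs(yy - cy) < bar_width) & (np.abs(xx - cx) < bar_width)] = 0.0
    truth["seven"] = sv_c

    for name, (cy, cx) in truth.items():
        if not (0 < cy < fy and 0 < cx < fx):
            raise ValueError(f"glyph {name} exceeds the field")

    layers = [
        ComplexField(amp1.astype(complex), pixel=pixel, wavelength=wavelength, z=0.0),
        ComplexField(amp2.astype(complex), pixel=pixel, wavelength=wavelength,
                     z=separation),
    ]
    if separation == 0:
        layers = [
            ComplexField(
                (amp1 * amp2).astype(complex), pixel=pixel, wavelength=wavelength, z=0.0
            )
        ]
    return layers, truth


def compose_layered_object(layers: list[ComplexField], wavelength: float | None = None) -> ComplexField:
    """Collapse thin layers at distinct z into one exit field.

    A unit plane wave is propagated between consecutive layer planes and
    multiplied by each layer's transmittance; the result is the equivalent
    exit field tagged with the final layer's z.
    """
    if not layers:
        raise ValueError("no layers given")
    zs = [lay.z for lay in layers]
    if sorted(zs) != zs:
        raise ValueError("layers must be sorted by z")
    shape = layers[0].shape
    pixel = layers[0].pixel
    for lay in layers:
        if lay.shape != shape or abs(lay.pixel - pixel) > 1e-9:
            raise ValueError("layer grids do not match")
    wl = wavelength if wavelength is not None else layers[0].wavelength
    out = ComplexField(layers[0].values.copy(), pixel=pixel, wavelength=wl, z=layers[0].z)
    for lay in layers[1:]:
        out = propagate(out, lay.z - out.z)
        out = out.with_values(out.values * lay.values)
    return out


def passband_window(
    shape_hr: tuple[int, int],
    shape_lr: tuple[int, int],
    direction: IlluminationDirection,
    wavelength: float,
    pixel_hr: float,
) -> tuple[slice, slice]:
    """Slices selecting one illumination's passband in a centered HR spectrum.

    The captured portion of the object spectrum is centred at (−α/λ, −β/λ);
    the centre is rounded to the nearest high-resolution frequency pixel.
    """
    ny, nx = shape_hr
    my, mx = shape_lr
    du = 1.0 / (ny * pixel_hr)
    dv = 1.0 / (nx * pixel_hr)
    cy = ny // 2 + int(round((-direction.beta / wavelength) / du))
    cx = nx // 2 + int(round((-direction.alpha / wavelength) / dv))
    y0, x0 = cy - my // 2, cx - mx // 2
    if y0 < 0 or x0 < 0 or y0 + my > ny or x0 + mx > nx:
        raise OutOfBandError(
            f"passband for direction (alpha={direction.alpha:.3f}, "
            f"beta={direction.beta:.3f}) falls outside the simulated spectrum"
        )
    return slice(y0, y0 + my), slice(x0, x0 + mx)


def simulate_low_res_stack(
    obj: ComplexField,
    config: OpticalConfig,
    directions: list[IlluminationDirection],
    downsample: int = 1,
    noise: dict | None = None,
    seed: int | None = None,
    pupil=None,
) -> LowResStack:
    """Simulate the raw intensity stack for the given illumination directions.

    ``downsample`` is the integer ratio between the object grid and the camera
    grid; the object pixel must equal the sample-plane camera pixel divided by
    this ratio.  ``noise`` is ``None`` (noise-free, deterministic) or a dict
    with optional keys ``photons`` (Poisson shot-noise budget per unit
    intensity) and ``read_std`` (additive Gaussian std); a seed is then
    required.  ``pupil`` defaults to the ideal binary CTF of the objective.
    """
    if downsample < 1 or int(downsample) != downsample:
        raise ValueError("downsample must be a positive integer")
    downsample = int(downsample)
    ny, nx = obj.shape
    if ny % downsample or nx % downsample:
        raise ValueError("object shape must be divisible by downsample")
    expected = config.sample_pixel / downsample
    if abs(obj.pixel - expected) > 1e-6 * expected:
        raise ValueError(
            f"object pixel {obj.pixel:.6f} um does not match camera pixel at the "
            f"sample plane / downsample = {expected:.6f} um"
        )
    if noise is not None and seed is None:
        raise ValueError("a seed is required when simulating noise")

    my, mx = ny // downsample, nx // downsample
    if pupil is None:
        grid_lr = make_frequency_grid((my, mx), obj.pixel * downsample, "centered")
        pupil = make_ctf(grid_lr, config.na_obj, config.wavelength)
    P = pupil.values

    F = _fft.fftshift(_fft.fft2(obj.values))
    scale = 1.0 / downsample**2
    images = np.empty((len(directions), my, mx))
    for i, d in enumerate(directions):
        sy, sx = passband_window((ny, nx), (my, mx), d, config.wavelength, obj.pixel)
        field_lr = _fft.ifft2(_fft.ifftshift(F[sy, sx] * P)) * scale
        images[i] = np.abs(field_lr) ** 2

    if noise is not None:
        rng = np.random.default_rng(seed)
        photons = noise.get("photons")
        if photons:
            images = rng.poisson(np.clip(images, 0, None) * photons) / photons
        read_std = noise.get("read_std")
        if read_std:
            images = images + rng.normal(0.0, read_std, images.shape)
        images = np.clip(images, 0.0, None)

    return LowResStack(images=images, directions=list(directions), config=config)
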