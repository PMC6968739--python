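"""Shared fixtures: optics configurations and the blood-film test scene."""

from __future__ import annotations

import numpy as np
import pytest

from fpmkit.edof import run_edof_pipeline
from fpmkit.optics import OpticalConfig
from fpmkit.phantom import compose_layered_object, make_blood_film_phantom
from fpmkit.refocus import band_limit, focal_series

PIXEL_HR = 0.10625  # µm, camera pixel 4.25 µm / 10x magnification / 4x upsample
NA_SYN = 0.88
SERIES_Z = list(np.round(np.linspace(-1.5, 1.5, 13), 9))
SERIES_STEP = 0.25


@pytest.fixture(scope="session")
def paper_optics() -> OpticalConfig:
    """Red-LED FPM system: λ 632 nm, 10x/0.3 objective, 4.25 µm camera pixels."""
    return OpticalConfig(wavelength=0.632, na_obj=0.3, magnification=10.0,
                         camera_pixel=4.25)


@pytest.fixture(scope="session")
def blood_scene():
    """Seeded 20-cell blood-film phantom and its synthetic-NA focal series.

    Membranes at z = 0, six parasites within ±1.5 µm, 13 planes at 0.25 µm
    spacing; the exit field is band-limited to the synthetic NA as a
    reconstructed field would be.
    """
    layers, truth = make_blood_film_phantom(
        seed=7, n_cells=20, shape=(600, 600), pixel=PIXEL_HR, wavelength=0.632
    )
    obj = band_limit(compose_layered_object(layers), NA_SYN, taper=0.3)
    series = focal_series(obj, SERIES_Z)
    return series, truth


@pytest.fixture(scope="session")
def edof_result(blood_scene):
    series, truth = blood_scene
    image, cells = run_edof_pipeline(series, variant="air")
    return image, cells


def match_parasites(truth, cells, pixel, radius_um=2.0):
    """Pair each truth parasite with its nearest detected candidate (or None)."""
    out = []
    for p in truth.parasites:
        py, px = p.center[0] / pixel, p.center[1] / pixel
        best = None
        for cell in cells:
            for cand in cell.candidates:
                d = np.hypot(cand.centroid[0] - py, cand.centroid[1] - px) * pixel
                if d < radius_um and (best is None or d < best[0]):
                    best = (d, cand)
        out.append((p, best[1] if best else None))
    return out
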