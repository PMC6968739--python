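"""File interchange: multipage TIFF rasters with JSON metadata sidecars.

TIFF is the single raster format (float32 pages); JSON sidecars carry the
per-frame illumination directions, optics configuration, seeds and checksums
needed to re-run a processing step identically.  Complex fields are stored as
two-page (real, imaginary) TIFFs; focal series as interleaved real/imaginary
pages with a z list in the sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .field import ComplexField
from .optics import IlluminationDirection, LEDArrayGeometry, OpticalConfig
from .phantom import LowResStack
from .refocus import FocalSeries

__all__ = [
    "StackBundle",
    "write_stack",
    "read_stack",
    "write_complex_field",
    "read_complex_field",
    "write_focal_series",
    "read_focal_series",
    "load_optics_config",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


@dataclass(frozen=True)
class StackBundle:
    """Paths of a raw-stack TIFF and its JSON sidecar."""

    stack_path: Path
    sidecar_path: Path


def write_stack(
    stack: LowResStack, tiff_path, seed: int | None = None, provenance: dict | None = None
) -> StackBundle:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.images.astype(np.float32),
                     photometric="minisblack")
    sidecar = {
        "frames": len(stack),
        "directions": [[d.alpha, d.beta] for d in stack.directions],
        "config": asdict(stack.config),
        "seed": seed,
        "provenance": provenance or {},
        "checksum": _sha256(tiff_path),
    }
    sc_path = _sidecar_path(tiff_path)
    sc_path.write_text(json.dumps(sidecar, indent=1))
    return StackBundle(stack_path=tiff_path, sidecar_path=sc_path)


def read_stack(bundle: StackBundle | str | Path, verify_checksum: bool = True) -> LowResStack:
    if not isinstance(bundle, StackBundle):
        p = Path(bundle)
        bundle = StackBundle(stack_path=p, sidecar_path=_sidecar_path(p))
    meta = json.loads(bundle.sidecar_path.read_text())
    images = tifffile.imread(bundle.stack_path).astype(float)
    if images.ndim == 2:
        images = images[None]
    if meta["frames"] != images.shape[0] or len(meta["directions"]) != images.shape[0]:
        raise ValueError(
            f"sidecar lists {meta['frames']} frames but the TIFF holds "
            f"{images.shape[0]} pages"
        )
    if verify_checksum and meta.get("checksum"):
        actual = _sha256(bundle.stack_path)
        if actual != meta["checksum"]:
            raise ValueError("stack TIFF checksum does not match the sidecar")
    directions = [IlluminationDirection(a, b) for a, b in meta["directions"]]
    config = OpticalConfig(**meta["config"])
    return LowResStack(images=images, directions=directions, config=config)


def write_complex_field(field: ComplexField, path) -> Path:
    """Two-page float32 TIFF (real, imaginary) plus a JSON metadata sidecar."""
    path = Path(path)
    pages = np.stack([field.values.real, field.values.imag]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {"pixel": field.pixel, "wavelength": field.wavelength, "z": field.z}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_complex_field(path) -> ComplexField:
    path = Path(path)
    pages = tifffile.imread(path).astype(float)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ValueError("complex-field TIFF must have exactly two pages")
    meta = json.loads(_sidecar_path(path).read_text())
    return ComplexField(
        values=pages[0] + 1j * pages[1],
        pixel=meta["pixel"],
        wavelength=meta["wavelength"],
        z=meta["z"],
    )


def write_focal_series(series: FocalSeries, path) -> Path:
    path = Path(path)
    pages = []
    for _, f in series.planes:
        pages.append(f.values.real)
        pages.append(f.values.imag)
    tifffile.imwrite(path, np.stack(pages).astype(np.float32),
                     photometric="minisblack")
    f0 = series.planes[0][1]
    meta = {
        "z_values": [float(z) for z, _ in series.planes],
        "kind": series.kind,
        "source_z": series.source_z,
        "pixel": f0.pixel,
        "wavelength": f0.wavelength,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_focal_series(path) -> FocalSeries:
    path = Path(path)
    pages = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    zs = meta["z_values"]
    if pages.shape[0] != 2 * len(zs):
        raise ValueError("focal-series TIFF page count does not match z list")
    planes = []
    for i, z in enumerate(zs):
        values = pages[2 * i] + 1j * pages[2 * i + 1]
        planes.append(
            (
                float(z),
                ComplexField(values, pixel=meta["pixel"],
                             wavelength=meta["wavelength"], z=float(z)),
            )
        )
    return FocalSeries(planes=planes, kind=meta["kind"], source_z=meta["source_z"])


def load_optics_config(path) -> tuple[OpticalConfig, LEDArrayGeometry | None]:
    """Read optics and LED geometry from a YAML config file.

    Keys: wavelength_um, na_obj, magnification, camera_pixel_um, n_medium, and
    an optional ``led`` section with pitch_mm, distance_mm, rows, cols and
    ``active`` (list of [row, col] or the string "circle:<diameter_mm>").
    """
    data = yaml.safe_load(Path(path).read_text())
    try:
        config = OpticalConfig(
            wavelength=float(data["wavelength_um"]),
            na_obj=float(data["na_obj"]),
            magnification=float(data["magnification"]),
            camera_pixel=float(data["camera_pixel_um"]),
            n_medium=float(data.get("n_medium", 1.0)),
        )
    except KeyError as exc:
        raise KeyError(f"missing optics config key: {exc}") from exc
    geom = None
    if "led" in data:
        led = data["led"]
        geom = LEDArrayGeometry(
            grid_rows=int(led["rows"]),
            grid_cols=int(led["cols"]),
            pitch=float(led["pitch_mm"]),
            distance_to_sample=float(led["distance_mm"]),
        )
        active = led.get("active")
        if isinstance(active, str) and active.startswith("circle:"):
            geom = geom.active_in_circle(float(active.split(":", 1)[1]))
        elif isinstance(active, list):
            from dataclasses import replace

            geom = replace(
                geom, active_indices=frozenset((int(r), int(c)) for r, c in active)
            )
    return config, geom
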