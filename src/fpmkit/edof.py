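"""Extended depth-of-field rendering of refocused blood-film image series.

A numerically generated focal series (spanning the film thickness with a step
below the synthesised depth of field) is collapsed into a single 2D image in
which red blood cell (RBC) membranes come from the globally sharpest plane
while the intracellular region of each cell showing a candidate malaria
parasite (MP) is replaced by the plane where that parasite is best focused.

Two segmentation recipes are provided.  For air-dried films the RBC mask
combines a Sobel edge map of the unwrapped phase with adaptive (local-mean)
thresholding of the amplitude; small objects (< 50 px) are removed, the mask
is reflection-padded and hole-filled, a second closing-based mask supplies a
boundary ridge whose removal cuts thin bridges between clumped cells, and
components below 12 µm² (about half an RBC footprint) are dropped.  For
oil-immersed films — where index matching removes the dark cell rim — solid
masks binarised from amplitude and phase are intersected with a Sobel edge
mask before filling and filtering.

Candidate MPs are dark objects at least ~1 µm in equivalent diameter found by
global (Otsu) thresholding within the eroded cell footprint, searched across
all planes.  The focal plane of each candidate is chosen by matching the
Canny contour length to the 4 µm perimeter of a typical ring-stage MP (air)
or by maximising Michelson contrast against the intracellular surround (oil).
A median-based consistency check resets assignments implausibly far from the
consensus plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import (
    binary_closing as nd_closing,
    label as nd_label,
    binary_erosion as nd_erosion,
    binary_fill_holes,
    binary_opening as nd_opening,
    gaussian_filter,
)
from skimage.feature import canny
from skimage.filters import sobel, threshold_local, threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .chromatic import sharpness_rank
from .field import ComplexField
from .refocus import FocalSeries

__all__ = [
    "SegmentationParams",
    "CellRegion",
    "ParasiteCandidate",
    "EDoFImage",
    "unwrap_phase",
    "rbc_mask_air",
    "rbc_mask_oil",
    "label_cells",
    "detect_candidate_parasites",
    "select_plane_air",
    "select_plane_oil",
    "consistency_check",
    "compose_edof",
    "run_edof_pipeline",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the EDoF pipeline (lengths in µm, counts in px)."""

    min_object_px: int = 50
    min_cell_area_um2: float = 12.0
    min_parasite_diameter_um: float = 1.0
    max_parasite_diameter_um: float = 3.0  # larger dark objects are cell-scale
    target_parasite_perimeter_um: float = 4.0
    sample_thickness_um: float = 3.0
    adaptive_block_px: int | None = None  # default: ~2x expected cell diameter
    adaptive_offset: float = 0.02  # fraction of amplitude range
    closing_radius_px: int = 3
    pad_px: int = 25
    interior_margin_um: float = 1.0  # rim exclusion for parasite search
    membrane_rim_um: float = 0.6  # membrane band kept at the base plane
    candidate_min_contrast: float = 0.18  # chromatin vs stain-mottle contrast
    candidate_merge_um: float = 1.0
    canny_sigma: float = 1.2
    perimeter_depth_fraction: float = 0.7  # object depth for contour tracing
    expected_cell_diameter_um: float = 7.0

    def __post_init__(self) -> None:
        for name in (
            "min_object_px",
            "min_cell_area_um2",
            "min_parasite_diameter_um",
            "target_parasite_perimeter_um",
            "sample_thickness_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def block_px(self, pixel: float) -> int:
        if self.adaptive_block_px is not None:
            b = self.adaptive_block_px
        else:
            b = int(round(2.0 * self.expected_cell_diameter_um / pixel))
        return b if b % 2 == 1 else b + 1

    def min_cell_area_px(self, pixel: float) -> float:
        return self.min_cell_area_um2 / pixel**2

    def min_parasite_area_px(self, pixel: float) -> float:
        # "significantly smaller" than the nominal diameter: a thresholded
        # region of a true 1 µm object measures below its geometric footprint,
        # so the floor is the area of a disc at 80% of the nominal diameter
        return np.pi * (0.8 * self.min_parasite_diameter_um / 2.0) ** 2 / pixel**2


@dataclass
class ParasiteCandidate:
    centroid: tuple[float, float]  # px
    area_um2: float
    planes_detected: list[int]
    cell_label: int
    chosen_plane: int | None = None
    flagged: bool = False

    @property
    def equivalent_diameter_um(self) -> float:
        return 2.0 * np.sqrt(self.area_um2 / np.pi)


@dataclass
class CellRegion:
    label: int
    mask: np.ndarray  # full-frame boolean footprint
    area_um2: float
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]  # px
    assigned_plane: int | None = None
    candidates: list[ParasiteCandidate] = dfield(default_factory=list)


@dataclass
class EDoFImage:
    composite: np.ndarray
    plane_map: np.ndarray
    base_plane: int
    z_values: np.ndarray
    params: SegmentationParams
    variant: str


def unwrap_phase(field: ComplexField) -> np.ndarray:
    """Continuous phase surface of a complex field (2D unwrapping)."""
    from skimage.restoration import unwrap_phase as _unwrap

    field.check_finite()
    return np.asarray(_unwrap(field.phase))


def _otsu_mask(img: np.ndarray, above: bool) -> np.ndarray:
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    return img > t if above else img < t


def _raw_mask_air(amplitude, unwrapped_phase, params: SegmentationParams, pixel):
    edge = sobel(unwrapped_phase)
    edge_mask = _otsu_mask(edge, above=True)
    rng = np.ptp(amplitude)
    if rng > 0:
        block = params.block_px(pixel)
        t = threshold_local(amplitude, block_size=block, method="mean",
                            offset=params.adaptive_offset * rng)
        dark = amplitude < t
    else:
        dark = np.zeros(amplitude.shape, dtype=bool)
    return edge_mask | dark


def _drop_small(mask, min_px):
    lab, n = nd_label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]


def _pad_apply(mask, pad, fn):
    padded = np.pad(mask, pad, mode="reflect")
    return fn(padded)[pad:-pad, pad:-pad]


def _clean_mask_air(raw, params: SegmentationParams, pixel):
    raw = _drop_small(raw, params.min_object_px)
    m1 = _pad_apply(raw, params.pad_px, binary_fill_holes)
    foot = disk(params.closing_radius_px)
    m2 = _pad_apply(raw, params.pad_px, lambda m: nd_closing(m, structure=foot))
    # the ridge must be at least as deep as the closing is wide, otherwise a
    # bridge thickened by the closing survives its removal
    ridge = m2 & ~nd_erosion(m2, structure=foot)
    final = m1 & ~ridge
    return _area_filter(final, params, pixel)


def _area_filter(mask, params: SegmentationParams, pixel):
    lab = label(mask, connectivity=2)
    keep = np.zeros(mask.shape, dtype=bool)
    min_px = params.min_cell_area_px(pixel)
    for r in regionprops(lab):
        if r.area >= min_px:
            keep[lab == r.label] = True
    return keep


def rbc_mask_air(
    amplitude: np.ndarray,
    unwrapped_phase: np.ndarray,
    params: SegmentationParams,
    pixel: float,
) -> np.ndarray:
    """RBC segmentation mask for air-dried films (edge + adaptive threshold)."""
    if amplitude.size == 0 or amplitude.shape != unwrapped_phase.shape:
        raise ValueError("amplitude and phase must be non-empty and share a shape")
    raw = _raw_mask_air(amplitude, unwrapped_phase, params, pixel)
    return _clean_mask_air(raw, params, pixel)


def _raw_mask_oil(amplitude, phase, params: SegmentationParams, pixel):
    a_bin = _otsu_mask(amplitude, above=False)
    ph_dev = np.abs(phase - np.median(phase))
    p_bin = _otsu_mask(ph_dev, above=True)
    solid = a_bin | p_bin
    edges = _otsu_mask(sobel(amplitude), above=True) | _otsu_mask(sobel(phase), above=True)
    return solid & edges


def _clean_mask_oil(raw, params: SegmentationParams, pixel):
    raw = _drop_small(raw, params.min_object_px)
    m = _pad_apply(raw, params.pad_px, binary_fill_holes)
    return _area_filter(m, params, pixel)


def rbc_mask_oil(
    amplitude: np.ndarray,
    phase: np.ndarray,
    params: SegmentationParams,
    pixel: float,
) -> np.ndarray:
    """RBC segmentation mask for oil-immersed films (no dark rim variant)."""
    if amplitude.size == 0 or amplitude.shape != phase.shape:
        raise ValueError("amplitude and phase must be non-empty and share a shape")
    raw = _raw_mask_oil(amplitude, phase, params, pixel)
    return _clean_mask_oil(raw, params, pixel)


def label_cells(mask: np.ndarray, params: SegmentationParams, pixel: float) -> list[CellRegion]:
    """Connected components of the final mask as CellRegion records."""
    lab = label(mask, connectivity=2)
    cells = []
    min_px = params.min_cell_area_px(pixel)
    for r in regionprops(lab):
        if r.area < min_px:
            continue
        cells.append(
            CellRegion(
                label=r.label,
                mask=lab == r.label,
                area_um2=r.area * pixel**2,
                bbox=tuple(r.bbox),
                centroid=tuple(r.centroid),
            )
        )
    return cells


def detect_candidate_parasites(
    series: FocalSeries,
    cell: CellRegion,
    params: SegmentationParams,
) -> list[ParasiteCandidate]:
    """Dark intracellular objects of parasite scale, searched across all planes.

    Within the rim-eroded cell footprint each plane is globally (Otsu)
    thresholded; dark components above the 1 µm-equivalent-diameter floor and
    with sufficient Michelson contrast against the remaining intracellular
    background are kept and merged across planes by centroid proximity.
    """
    pixel = series.planes[0][1].pixel
    erode_px = max(int(round(params.interior_margin_um / pixel)), 1)
    interior = nd_erosion(cell.mask, structure=disk(erode_px))
    if interior.sum() < 16:
        return []
    min_area = params.min_parasite_area_px(pixel)
    max_area = np.pi * (params.max_parasite_diameter_um / 2.0) ** 2 / pixel**2
    merge_px = params.candidate_merge_um / pixel

    clusters: list[dict] = []
    for p_idx, (_, f) in enumerate(series.planes):
        a = f.amplitude
        vals = a[interior]
        if np.ptp(vals) == 0:
            continue
        # darkest of three automatic classes: parasite-dark vs interior
        # texture vs bright background
        try:
            t = threshold_multiotsu(vals, classes=3)[0]
        except ValueError:  # degenerate histogram
            t = threshold_otsu(vals)
        dark = interior & (a < t)
        # break thin bridges between parasite-scale objects and rim remnants
        dark = nd_opening(dark, structure=disk(2))
        bg = interior & ~dark
        if bg.sum() == 0:
            continue
        mean_bg = a[bg].mean()
        for r in regionprops(label(dark, connectivity=2)):
            if r.area < min_area or r.area > max_area:
                continue
            mean_obj = a[tuple(np.array(r.coords).T)].mean()
            denom = mean_bg + mean_obj
            contrast = (mean_bg - mean_obj) / denom if denom > 0 else 0.0
            if contrast < params.candidate_min_contrast:
                continue
            cy, cx = r.centroid
            for cl in clusters:
                if np.hypot(cy - cl["centroid"][0], cx - cl["centroid"][1]) < merge_px:
                    cl["planes"].append(p_idx)
                    cl["area"] = max(cl["area"], r.area)
                    # anchor the cluster at its highest-contrast appearance
                    if contrast > cl["contrast"]:
                        cl["contrast"] = contrast
                        cl["centroid"] = (cy, cx)
                    break
            else:
                clusters.append(
                    {"centroid": (cy, cx), "area": r.area, "planes": [p_idx],
                     "contrast": contrast}
                )

    return [
        ParasiteCandidate(
            centroid=cl["centroid"],
            area_um2=cl["area"] * pixel**2,
            planes_detected=sorted(set(cl["planes"])),
            cell_label=cell.label,
        )
        for cl in clusters
    ]


def _candidate_patch(
    candidate: ParasiteCandidate, img: np.ndarray, pixel: float, radius_um: float
) -> tuple[np.ndarray, int, int]:
    """Window around the candidate; returns (patch, centre_y, centre_x)."""
    r = int(round(radius_um / pixel))
    cy, cx = (int(round(c)) for c in candidate.centroid)
    y0, y1 = max(cy - r, 0), min(cy + r + 1, img.shape[0])
    x0, x1 = max(cx - r, 0), min(cx + r + 1, img.shape[1])
    return img[y0:y1, x0:x1], cy - y0, cx - x0


def _tie_to_membrane(indices: np.ndarray, series: FocalSeries, membrane_plane: int) -> int:
    z = series.z_values
    z_m = z[membrane_plane]
    return int(indices[np.argmin(np.abs(z[indices] - z_m))])


def select_plane_air(
    candidate: ParasiteCandidate,
    series: FocalSeries,
    params: SegmentationParams,
    membrane_plane: int = 0,
) -> tuple[int, bool]:
    """Plane whose Canny contour length best matches the typical MP perimeter.

    Returns (plane index, flagged).  Ties go to the plane nearest the
    membrane plane; if the candidate produces no contour in any plane the
    membrane plane is returned flagged.
    """
    pixel = series.planes[0][1].pixel
    radius_um = max(1.8, 1.5 * candidate.equivalent_diameter_um)
    patches = []
    cy = cx = 0
    for _, f in series.planes:
        patch, cy, cx = _candidate_patch(candidate, f.amplitude, pixel, radius_um)
        patches.append(gaussian_filter(patch, 1.0))
    yy, xx = np.ogrid[: patches[0].shape[0], : patches[0].shape[1]]
    clip = (yy - cy) ** 2 + (xx - cx) ** 2 <= (1.5 / pixel) ** 2
    if not clip.any():
        return membrane_plane, True
    # segmentation depth anchored to the candidate's darkest appearance over
    # the whole series, so the object shrinks monotonically away from focus
    gmin = min(p[clip].min() for p in patches)
    bg = float(np.median(np.stack(patches)))
    thresh = bg - params.perimeter_depth_fraction * (bg - gmin)
    perims = np.zeros(len(series))
    for i, patch in enumerate(patches):
        dark = (patch < thresh) & clip
        lab = label(dark, connectivity=2)
        lbl = lab[cy, cx]
        if lbl == 0:
            ys, xs = np.nonzero(dark)
            if len(ys) == 0:
                continue
            nearest = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            if (ys[nearest] - cy) ** 2 + (xs[nearest] - cx) ** 2 > (0.7 / pixel) ** 2:
                continue
            lbl = lab[ys[nearest], xs[nearest]]
        edges = canny((lab == lbl).astype(float), sigma=params.canny_sigma)
        perims[i] = edges.sum() * pixel * (np.pi / 4.0)
    if not np.any(perims > 0):
        return membrane_plane, True
    cost = np.abs(perims - params.target_parasite_perimeter_um)
    best = np.nanmin(cost)
    ties = np.flatnonzero(np.isclose(cost, best, rtol=0, atol=1e-9))
    return _tie_to_membrane(ties, series, membrane_plane), False


def select_plane_oil(
    candidate: ParasiteCandidate,
    series: FocalSeries,
    params: SegmentationParams | None = None,
    membrane_plane: int = 0,
) -> tuple[int, bool]:
    """Plane maximising the candidate's Michelson contrast against its surround."""
    params = params or SegmentationParams()
    pixel = series.planes[0][1].pixel
    contrasts = np.full(len(series), -np.inf)
    ny, nx = series.planes[0][1].shape
    yy, xx = np.ogrid[:ny, :nx]
    dist = np.hypot(yy - candidate.centroid[0], xx - candidate.centroid[1]) * pixel
    region = dist <= 0.6
    surround = (dist > 0.9) & (dist <= 1.6)
    if not region.any() or not surround.any():
        return membrane_plane, True
    for i, (_, f) in enumerate(series.planes):
        a = f.amplitude
        m_reg, m_sur = a[region].mean(), a[surround].mean()
        if m_reg + m_sur > 0:
            contrasts[i] = (m_sur - m_reg) / (m_sur + m_reg)
    best = contrasts.max()
    if not np.isfinite(best):
        return membrane_plane, True
    ties = np.flatnonzero(np.isclose(contrasts, best, rtol=0, atol=1e-12))
    return _tie_to_membrane(ties, series, membrane_plane), False


def consistency_check(
    assignments: list[int],
    series: FocalSeries,
    sample_thickness: float,
    trusted: list[bool] | None = None,
) -> tuple[list[int], list[bool]]:
    """Reset plane assignments far from the consensus (median) plane.

    Assignments whose z lies farther than ``sample_thickness`` from the median
    assigned z are replaced by the plane nearest the median and flagged:
    parasites legitimately occupy ±thickness/2 about the film centre and the
    median itself may sit up to thickness/2 off-centre, so only distances
    beyond the full thickness are physically impossible.  If ``trusted`` is
    given, the median is computed over the trusted subset only (fallback
    assignments should not drag the consensus).
    """
    if not assignments:
        return [], []
    z = series.z_values
    ref = np.asarray(assignments)
    if trusted is not None and any(trusted):
        ref = ref[np.asarray(trusted)]
    z_med = float(np.median(z[ref]))
    median_plane = int(np.argmin(np.abs(z - z_med)))
    corrected, flags = [], []
    for p in assignments:
        if abs(z[p] - z_med) > sample_thickness:
            corrected.append(median_plane)
            flags.append(True)
        else:
            corrected.append(p)
            flags.append(False)
    return corrected, flags


def compose_edof(
    series: FocalSeries,
    mask: np.ndarray,
    cells: list[CellRegion],
    params: SegmentationParams,
    variant: str = "air",
) -> EDoFImage:
    """Composite: sharpest-membrane base plane with per-cell refocused interiors.

    The intracellular region (footprint minus a membrane rim) of each cell
    with an assigned plane is replaced verbatim by that plane's amplitude; a
    1-px feather band at the region boundary is blended 50/50 with the base.
    """
    pixel = series.planes[0][1].pixel
    base_idx = sharpness_rank(series)
    base = series.planes[base_idx][1].amplitude
    composite = base.copy()
    plane_map = np.full(base.shape, base_idx, dtype=int)
    rim_px = max(int(round(params.membrane_rim_um / pixel)), 1)
    for cell in cells:
        p = cell.assigned_plane
        if p is None or p == base_idx:
            continue
        interior = nd_erosion(cell.mask, structure=disk(rim_px))
        if not interior.any():
            continue
        core = nd_erosion(interior, structure=disk(1))
        feather = interior & ~core
        repl = series.planes[p][1].amplitude
        composite[core] = repl[core]
        composite[feather] = 0.5 * (repl[feather] + base[feather])
        plane_map[interior] = p
    return EDoFImage(
        composite=composite,
        plane_map=plane_map,
        base_plane=base_idx,
        z_values=series.z_values,
        params=params,
        variant=variant,
    )


def run_edof_pipeline(
    series: FocalSeries,
    variant: str = "air",
    params: SegmentationParams | None = None,
    mask_planes: str = "base",
) -> tuple[EDoFImage, list[CellRegion]]:
    """Full EDoF pipeline: mask, candidate detection, plane selection, composite.

    The RBC mask is computed on the sharpest plane (``mask_planes="base"``,
    the default: per-plane masks of defocused planes inflate object footprints
    by the blur width, which merges neighbouring cells and defeats the area
    filters), or as the union of per-plane raw masks before cleaning
    (``"all"``).  Returns the composite image and the per-cell records
    (footprints, candidates, assigned planes).
    """
    if variant not in ("air", "oil"):
        raise ValueError("variant must be 'air' or 'oil'")
    params = params or SegmentationParams()
    pixel = series.planes[0][1].pixel
    base_idx = sharpness_rank(series)
    plane_ids = range(len(series)) if mask_planes == "all" else [base_idx]

    raw = np.zeros(series.planes[0][1].shape, dtype=bool)
    for i in plane_ids:
        f = series.planes[i][1]
        amp = f.amplitude
        ph = unwrap_phase(f)
        if variant == "air":
            raw |= _raw_mask_air(amp, ph, params, pixel)
        else:
            raw |= _raw_mask_oil(amp, ph, params, pixel)
    if variant == "air":
        mask = _clean_mask_air(raw, params, pixel)
    else:
        mask = _clean_mask_oil(raw, params, pixel)

    cells = label_cells(mask, params, pixel)
    select = select_plane_air if variant == "air" else select_plane_oil

    all_candidates: list[ParasiteCandidate] = []
    for cell in cells:
        cands = detect_candidate_parasites(series, cell, params)
        for c in cands:
            plane, flagged = select(c, series, params, membrane_plane=base_idx)
            c.chosen_plane = plane
            c.flagged = flagged
        cell.candidates = cands
        all_candidates.extend(cands)

    if all_candidates:
        planes = [c.chosen_plane for c in all_candidates]
        trusted = [not c.flagged for c in all_candidates]
        corrected, flags = consistency_check(
            planes, series, params.sample_thickness_um, trusted
        )
        for c, p, fl in zip(all_candidates, corrected, flags):
            c.chosen_plane = p
            c.flagged = c.flagged or fl
    for cell in cells:
        if cell.candidates:
            biggest = max(cell.candidates, key=lambda c: c.area_um2)
            cell.assigned_plane = biggest.chosen_plane

    image = compose_edof(series, mask, cells, params, variant)
    return image, cells
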