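"""RBC segmentation, parasite detection, focal-plane selection and compositing."""

import numpy as np
import pytest

from conftest import SERIES_STEP, match_parasites
from fpmkit.edof import (
    CellRegion,
    ParasiteCandidate,
    SegmentationParams,
    compose_edof,
    consistency_check,
    detect_candidate_parasites,
    label_cells,
    rbc_mask_air,
    rbc_mask_oil,
    run_edof_pipeline,
    select_plane_air,
    select_plane_oil,
    unwrap_phase,
)
from fpmkit.field import ComplexField
from fpmkit.phantom import compose_layered_object, make_blood_film_phantom
from fpmkit.refocus import FocalSeries, band_limit, focal_series

PIX = 0.10625


class TestUnwrapPhase:
    def test_constant_phase_stays_constant(self):
        f = ComplexField(np.full((32, 32), np.exp(0.7j)), pixel=0.2,
                         wavelength=0.632)
        out = unwrap_phase(f)
        assert np.ptp(out) < 1e-9

    def test_steep_ramp_unwraps_monotonically(self):
        x = np.linspace(0, 6 * np.pi, 128)
        ramp = np.tile(x, (128, 1))
        f = ComplexField(np.exp(1j * ramp), pixel=0.2, wavelength=0.632)
        out = unwrap_phase(f)
        rows = np.diff(out, axis=1)
        assert np.all(rows > 0)
        assert np.ptp(out) > 2 * np.pi  # beyond a single wrap

    def test_rewrap_identity(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        ph = 8.0 * gaussian_filter(rng.normal(size=(64, 64)), 6.0)
        f = ComplexField(np.exp(1j * ph), pixel=0.2, wavelength=0.632)
        out = unwrap_phase(f)
        assert np.allclose(np.angle(np.exp(1j * (out - f.phase))), 0.0, atol=1e-9)


@pytest.fixture(scope="module")
def flat_phantom_plane():
    """All features in one plane: clean input for mask unit tests."""
    layers, truth = make_blood_film_phantom(
        seed=5, n_cells=8, shape=(450, 450), pixel=PIX, wavelength=0.632,
        parasite_z_range=0.0,
    )
    obj = band_limit(compose_layered_object(layers), 0.88, taper=0.3)
    return obj, truth


class TestMasks:
    def test_blank_input_gives_empty_mask(self):
        params = SegmentationParams()
        blank = np.ones((128, 128))
        assert not rbc_mask_air(blank, np.zeros((128, 128)), params, PIX).any()
        assert not rbc_mask_oil(blank, np.zeros((128, 128)), params, PIX).any()

    def test_air_mask_recovers_cells(self, flat_phantom_plane):
        obj, truth = flat_phantom_plane
        params = SegmentationParams()
        mask = rbc_mask_air(obj.amplitude, unwrap_phase(obj), params, PIX)
        cells = label_cells(mask, params, PIX)
        assert len(cells) == len(truth.cells)
        yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
        for c in truth.cells:
            disc = np.hypot(yy * PIX - c.center[0], xx * PIX - c.center[1]) <= c.radius
            inter = (mask & disc).sum()
            union = (mask & disc).sum() + (mask ^ disc).sum() - (mask & ~disc).sum()
            iou = inter / (disc.sum() + (mask & ~disc).sum() * 0 + disc.sum() - inter)
            # IoU against the truth disc restricted to this cell's neighbourhood
            local = np.hypot(yy * PIX - c.center[0], xx * PIX - c.center[1]) <= (
                c.radius + 1.5)
            m_local = mask & local
            iou = (m_local & disc).sum() / float((m_local | disc).sum())
            assert iou > 0.7

    def test_bridged_cells_are_split(self):
        # two discs fused by a 2 px bridge: the closing-ridge step cuts it
        n = 200
        yy, xx = np.mgrid[:n, :n]
        d1 = np.hypot(yy - 100, xx - 60) < 30
        d2 = np.hypot(yy - 100, xx - 140) < 30
        bridge = ((yy == 100) | (yy == 101)) & (xx > 60) & (xx < 140)
        shape = d1 | d2 | bridge
        amp = 1.0 - 0.5 * shape
        phase = 1.5 * shape.astype(float)
        params = SegmentationParams()
        mask = rbc_mask_air(amp, phase, params, PIX)
        from skimage.measure import label as sklabel

        assert sklabel(mask, connectivity=2).max() == 2

    def test_oil_mask_counts_cells(self):
        layers, truth = make_blood_film_phantom(
            seed=5, n_cells=8, shape=(450, 450), pixel=PIX, wavelength=0.632,
            parasite_z_range=0.0, medium="oil",
        )
        obj = band_limit(compose_layered_object(layers), 0.88, taper=0.3)
        params = SegmentationParams()
        mask = rbc_mask_oil(obj.amplitude, unwrap_phase(obj), params, PIX)
        n = len(label_cells(mask, params, PIX))
        assert abs(n - len(truth.cells)) <= 1

    def test_area_floor_enforced(self, flat_phantom_plane):
        obj, _ = flat_phantom_plane
        params = SegmentationParams()
        mask = rbc_mask_air(obj.amplitude, unwrap_phase(obj), params, PIX)
        for cell in label_cells(mask, params, PIX):
            assert cell.area_um2 >= params.min_cell_area_um2

    def test_mask_cleaning_idempotent(self, flat_phantom_plane):
        from fpmkit.edof import _area_filter, _drop_small

        obj, _ = flat_phantom_plane
        params = SegmentationParams()
        mask = rbc_mask_air(obj.amplitude, unwrap_phase(obj), params, PIX)
        again = _area_filter(_drop_small(mask, params.min_object_px), params, PIX)
        assert np.array_equal(mask, again)


def _single_cell_series(parasite_diameter=None, speck_diameter=None, n_planes=3):
    """One centred cell (optionally with an inclusion) in a short focal series."""
    layers, truth = make_blood_film_phantom(
        seed=2, n_cells=1, shape=(256, 256), pixel=PIX, wavelength=0.632,
        infected_fraction=0.0, n_debris_small=0, n_debris_medium=0,
        stain_texture=0.0,
    )
    obj = compose_layered_object(layers)
    vals = obj.values.copy()
    c = truth.cells[0]
    yy, xx = np.mgrid[:256, :256]
    dist = np.hypot(yy * PIX - c.center[0], xx * PIX - c.center[1])
    if parasite_diameter:
        vals[dist < parasite_diameter / 2] *= 0.35
    if speck_diameter:
        vals[dist < speck_diameter / 2] *= 0.35
    f = band_limit(ComplexField(vals, pixel=PIX, wavelength=0.632), 0.88, taper=0.3)
    zs = list(np.round(np.linspace(-0.25, 0.25, n_planes), 9))
    series = focal_series(f, zs)
    mask = dist < c.radius
    cell = CellRegion(label=1, mask=mask, area_um2=mask.sum() * PIX**2,
                      bbox=(0, 0, 256, 256),
                      centroid=(c.center[0] / PIX, c.center[1] / PIX))
    return series, cell


class TestCandidateDetection:
    def test_uninfected_cell_has_no_candidates(self):
        series, cell = _single_cell_series()
        assert detect_candidate_parasites(series, cell, SegmentationParams()) == []

    def test_parasite_scale_inclusion_detected_once(self):
        series, cell = _single_cell_series(parasite_diameter=1.2)
        cands = detect_candidate_parasites(series, cell, SegmentationParams())
        assert len(cands) == 1
        # thresholded area understates the 1.2 um geometric footprint slightly
        assert cands[0].equivalent_diameter_um > 0.8

    def test_subresolution_speckle_filtered_out(self):
        series, cell = _single_cell_series(speck_diameter=0.5)
        assert detect_candidate_parasites(series, cell, SegmentationParams()) == []


def _toy_series(n_planes, value_maps=None, z0=0.0, step=1.0):
    planes = []
    for i in range(n_planes):
        vals = value_maps[i] if value_maps else np.ones((32, 32))
        planes.append(
            (z0 + i * step,
             ComplexField(vals, pixel=PIX, wavelength=0.632, z=z0 + i * step))
        )
    return FocalSeries(planes=planes, kind="angular_spectrum", source_z=0.0)


class TestPlaneSelectionContracts:
    def _candidate(self):
        return ParasiteCandidate(centroid=(16.0, 16.0), area_um2=1.1,
                                 planes_detected=[0], cell_label=1)

    def test_single_plane_series_returns_it(self):
        series = _toy_series(1)
        for select in (select_plane_air, select_plane_oil):
            plane, _ = select(self._candidate(), series, SegmentationParams(),
                              membrane_plane=0)
            assert plane == 0

    def test_identical_planes_tie_to_membrane(self):
        rng = np.random.default_rng(0)
        base = 1 - 0.3 * rng.random((32, 32))
        series = _toy_series(5, value_maps=[base] * 5)
        for select in (select_plane_air, select_plane_oil):
            plane, _ = select(self._candidate(), series, SegmentationParams(),
                              membrane_plane=2)
            assert plane == 2

    def test_blank_candidate_falls_back_flagged(self):
        series = _toy_series(3)
        plane, flagged = select_plane_air(self._candidate(), series,
                                          SegmentationParams(), membrane_plane=1)
        assert plane == 1 and flagged


class TestConsistencyCheck:
    def test_unanimous_assignments_unchanged(self):
        series = _toy_series(11)
        corrected, flags = consistency_check([4, 4, 4], series, 3.0)
        assert corrected == [4, 4, 4]
        assert flags == [False, False, False]

    def test_outlier_reset_to_median(self):
        series = _toy_series(11)  # z = 0..10 um
        assignments = [4, 5, 4, 5, 4, 10]
        corrected, flags = consistency_check(assignments, series, 3.0)
        assert corrected[-1] == 4  # plane nearest the median z
        assert flags == [False] * 5 + [True]

    def test_disagreement_within_tolerance_kept(self):
        series = _toy_series(11)
        corrected, flags = consistency_check([4, 6], series, 3.0)
        assert corrected == [4, 6]
        assert not any(flags)

    def test_untrusted_assignments_do_not_drag_median(self):
        series = _toy_series(11)
        assignments = [4, 4, 10, 10, 10]
        trusted = [True, True, False, False, False]
        corrected, _ = consistency_check(assignments, series, 3.0, trusted)
        assert corrected == [4, 4, 4, 4, 4]


class TestCompose:
    def test_identical_planes_composite_matches(self):
        rng = np.random.default_rng(1)
        base = 1 - 0.3 * rng.random((64, 64))
        series = _toy_series(3, value_maps=[base] * 3)
        image = compose_edof(series, np.zeros((64, 64), bool), [],
                             SegmentationParams())
        assert np.allclose(image.composite, np.abs(base))

    def test_no_cells_keeps_base_plane(self, blood_scene):
        series, _ = blood_scene
        image = compose_edof(series, np.zeros(series.planes[0][1].shape, bool), [],
                             SegmentationParams())
        assert np.array_equal(image.composite,
                              series.planes[image.base_plane][1].amplitude)
        assert np.all(image.plane_map == image.base_plane)

    def test_replaced_interiors_are_verbatim(self, blood_scene, edof_result):
        series, truth = blood_scene
        image, cells = edof_result
        for cell in cells:
            p = cell.assigned_plane
            if p is None or p == image.base_plane:
                continue
            region = image.plane_map == p
            if not region.any():
                continue
            repl = series.planes[p][1].amplitude
            base = series.planes[image.base_plane][1].amplitude
            # outside the 1-px feather band values come verbatim from plane p
            from scipy.ndimage import binary_erosion

            core = binary_erosion(region, np.ones((5, 5)))
            if core.any():
                assert np.array_equal(image.composite[core], repl[core])

    def test_plane_map_indices_valid(self, edof_result):
        image, _ = edof_result
        assert image.plane_map.min() >= 0
        assert image.plane_map.max() < len(image.z_values)


class TestFullPipeline:
    def test_distractors_removed_by_size_filters(self, blood_scene, edof_result):
        series, truth = blood_scene
        image, cells = edof_result
        assert truth.debris  # the phantom plants sub-threshold distractors
        union = np.zeros(series.planes[0][1].shape, bool)
        for cell in cells:
            union |= cell.mask
        for (dy, dx), _r in truth.debris:
            assert not union[int(dy / PIX), int(dx / PIX)]

    def test_oil_variant_recovers_parasite_planes(self):
        layers, truth = make_blood_film_phantom(
            seed=1, n_cells=15, shape=(600, 600), pixel=PIX, wavelength=0.632,
            medium="oil",
        )
        obj = band_limit(compose_layered_object(layers), 0.88, taper=0.3)
        zs = list(np.round(np.linspace(-1.5, 1.5, 13), 9))
        series = focal_series(obj, zs)
        image, cells = run_edof_pipeline(series, variant="oil")
        pairs = match_parasites(truth, cells, PIX)
        found = [(p, c) for p, c in pairs if c is not None]
        assert len(found) >= 0.9 * len(truth.parasites)
        good = sum(
            1 for p, c in found
            if abs(series.z_values[c.chosen_plane] - p.z) <= 1.5 * SERIES_STEP)
        assert good >= 0.9 * len(found)

    def test_invalid_variant_rejected(self, blood_scene):
        series, _ = blood_scene
        with pytest.raises(ValueError):
            run_edof_pipeline(series, variant="water")
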