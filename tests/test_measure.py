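"""Segmentation, per-cell measurement, calibration, abundance."""

import numpy as np
import pandas as pd
import pytest

from prokmorph import (Calibration, CountingSetup, FieldSpec,
                       abundance_from_counts, bead_field, calibrate_with_beads,
                       classify_curvature, measure_image, measure_region,
                       render_micrograph, sample_cells, segment_cells)
from prokmorph.measure import Region, RegionMeasure


def _cells(rows):
    return pd.DataFrame(
        [{"cell_id": i, "morphotype": m, "L_um": L, "W_um": W,
          "curvature_class": c, "arc_turning_deg": t}
         for i, (m, L, W, c, t) in enumerate(rows)])


class TestSegmentation:
    def test_noise_free_field_keeps_every_cell(self, profiles, nf_field):
        cells = sample_cells(profiles["NOVESAR-2013"], 10, seed=2)
        img, truth = render_micrograph(cells, nf_field, seed=2)
        kept, flagged = segment_cells(img)
        assert len(kept) == 10 and len(flagged) == 0

    def test_blank_image_yields_no_regions(self, nf_field):
        img, _ = render_micrograph(None, nf_field, seed=0)
        kept, flagged = segment_cells(img)
        assert kept == [] and flagged == []

    def test_noise_only_image_yields_no_regions(self):
        rng = np.random.default_rng(0)
        img = 100 + rng.normal(0, 50, (300, 300))
        kept, flagged = segment_cells(img)
        assert kept == []

    def test_border_cell_is_flagged_not_kept(self, nf_field):
        cells = _cells([("cocci", 0.8, 0.8, "straight", 0.0)])
        cells["x_px"] = 2.0
        cells["y_px"] = 500.0
        cells["orientation_rad"] = 0.0
        img, _ = render_micrograph(cells, nf_field, seed=0)
        kept, flagged = segment_cells(img)
        assert len(kept) == 0 and len(flagged) == 1
        assert flagged[0].touches_border


class TestMeasurement:
    def test_bead_diameter_recovered_within_two_pixels(self, nf_field):
        beads = bead_field(8, 2.13, nf_field, seed=3)
        img, _ = render_micrograph(beads, nf_field, seed=3)
        measured = measure_image(img, nf_field.pixel_size)
        tol = 2 * nf_field.pixel_size
        for c in measured:
            assert abs(c.L_um - 2.13) < tol and abs(c.W_um - 2.13) < tol

    def test_straight_capsule_recovered_within_two_pixels(self, nf_field,
                                                          nf_calibration):
        cells = _cells([("rods", 1.68, 0.41, "straight", 0.0)] * 6)
        img, _ = render_micrograph(cells, nf_field, seed=4)
        measured = measure_image(img, nf_field.pixel_size, nf_calibration)
        tol = 2 * nf_field.pixel_size
        assert len(measured) == 6
        assert abs(np.mean([c.L_um for c in measured]) - 1.68) < tol
        assert abs(np.mean([c.W_um for c in measured]) - 0.41) < tol

    def test_square_region_reports_equivalent_diameter(self):
        mask = np.ones((9, 9), dtype=bool)
        region = Region(1, mask, (0, 0, 9, 9), 81, False, (4.0, 4.0))
        cell = measure_region(region, pixel_size=1.0)
        assert cell.L_um == cell.W_um == pytest.approx(np.sqrt(4 * 81 / np.pi))

    def test_output_satisfies_length_width_order(self, profiles, nf_field):
        cells = sample_cells(profiles["BANSIC-2012"], 100, seed=5)
        img, _ = render_micrograph(cells, nf_field, seed=5)
        for c in measure_image(img, nf_field.pixel_size):
            assert c.L_um >= c.W_um > 0

    def test_tiny_region_rejected(self):
        mask = np.ones((1, 2), dtype=bool)
        region = Region(1, mask, (0, 0, 1, 2), 2, False, (0.0, 0.5))
        with pytest.raises(ValueError):
            measure_region(region, pixel_size=1.0)


class TestCurvatureClassification:
    @pytest.mark.parametrize("turning,inflections,expected", [
        (0.0, 0, "straight"),
        (10.0, 0, "straight"),
        (15.0, 0, "straight"),   # rule is strict: turning must exceed 15
        (40.0, 0, "curved"),
        (90.0, 0, "curved"),
        (160.0, 0, "C"),
        (91.0, 0, "C"),
        (120.0, 1, "S"),
        (10.0, 1, "straight"),   # an inflection without turning is noise
    ])
    def test_rule_table(self, turning, inflections, expected):
        rm = RegionMeasure(1, 50, 20.0, 3.0, 8.0, turning, inflections, False)
        assert classify_curvature(rm) == expected

    def test_rendered_arcs_classified_by_shape(self, nf_field, nf_calibration):
        cells = _cells([
            ("vibrios", 2.52, 0.40, "C", 160.0),
            ("curved_rods", 1.99, 0.38, "curved", 60.0),
            ("spirillae", 2.90, 0.35, "S", 200.0),
            ("rods", 1.68, 0.41, "straight", 0.0),
        ])
        img, truth = render_micrograph(cells, nf_field, seed=11)
        measured = measure_image(img, nf_field.pixel_size, nf_calibration)
        got = {}
        for c in measured:
            # match by measured length, the four cells are well separated
            got[min(("C", 2.52), ("curved", 1.99), ("S", 2.90), ("straight", 1.68),
                    key=lambda t: abs(t[1] - c.L_um))[0]] = c.curvature_class
        assert got == {"C": "C", "curved": "curved", "S": "S",
                       "straight": "straight"}


class TestBeadCalibration:
    def test_sharp_beads_give_unit_scales(self, nf_calibration):
        assert nf_calibration.length_scale == pytest.approx(1.0, abs=0.02)
        assert nf_calibration.width_scale == pytest.approx(1.0, abs=0.02)

    def test_blur_inflates_apparent_size_so_scale_drops(self):
        field = FieldSpec(psf_sigma=0.3, background_noise_sd=0.0)
        beads = bead_field(12, 2.13, field, seed=3)
        img, _ = render_micrograph(beads, field, seed=3)
        cal = calibrate_with_beads(img, 2.13, field.pixel_size)
        assert cal.width_scale < 1.0

    def test_too_few_beads_is_an_error(self, nf_field):
        img, _ = render_micrograph(None, nf_field, seed=0)
        with pytest.raises(ValueError):
            calibrate_with_beads(img, 2.13, nf_field.pixel_size)

    def test_calibration_json_round_trip(self, tmp_path, nf_calibration):
        path = tmp_path / "cal.json"
        nf_calibration.to_json(path)
        assert Calibration.from_json(path) == nf_calibration


class TestAbundance:
    def test_hand_computed_example(self):
        # 40 cells/field, 1300x1030 px at 0.106 um/px, 201.06 mm2 filter, 2 mL
        field_area = 1300 * 1030 * (0.106e-3) ** 2
        setup = CountingSetup(tuple([40] * 20), field_area, 201.06, 2.0)
        pa, se = abundance_from_counts(setup)
        assert pa == pytest.approx(2.672e5, rel=1e-3)
        assert se == 0.0

    def test_zero_counts_give_zero_abundance(self):
        setup = CountingSetup(tuple([0] * 20), 0.015, 201.06, 2.0)
        assert abundance_from_counts(setup)[0] == 0.0

    def test_linear_in_counts_and_inverse_in_volume(self, rng):
        counts = tuple(rng.integers(10, 60, 25).tolist())
        base, _ = abundance_from_counts(CountingSetup(counts, 0.015, 201.06, 2.0))
        double, _ = abundance_from_counts(
            CountingSetup(tuple(2 * c for c in counts), 0.015, 201.06, 2.0))
        half_vol, _ = abundance_from_counts(CountingSetup(counts, 0.015, 201.06, 1.0))
        assert double == pytest.approx(2 * base, rel=1e-12)
        assert half_vol == pytest.approx(2 * base, rel=1e-12)

    def test_few_fields_warns(self):
        with pytest.warns(UserWarning):
            abundance_from_counts(CountingSetup((5, 7), 0.015, 201.06, 2.0))

    def test_invalid_setups_rejected(self):
        with pytest.raises(ValueError):
            CountingSetup((), 0.015, 201.06, 2.0)
        with pytest.raises(ValueError):
            CountingSetup((1,), 0.015, 201.06, 0.0)
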