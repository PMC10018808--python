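"""Segmentation: stain splitting, geometry delineation, lumen detection,
shape-based vessel classification and tension-wood measurement."""

from dataclasses import replace

import numpy as np
import pytest

from xylotraits.segmentation import (
    LumenObject,
    SegmentationParams,
    _contour_perimeter,
    classify_vessels,
    delineate_geometry,
    detect_lumina,
    section_summary,
    segment_section,
    segment_section_tiled,
    split_stains,
    tension_wood_fraction,
)
from xylotraits.synthetic import DiameterLaw, SectionSpec, render_section


class TestSplitStains:
    def test_primary_colors(self):
        img = np.zeros((1, 3, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)      # pure safranin red
        img[0, 1] = (0, 0, 0)        # chlorazol black
        img[0, 2] = (255, 255, 255)  # unstained lumen
        lignin, cellulose = split_stains(img)
        assert lignin[0, 0] == pytest.approx(1.0)
        assert cellulose[0, 0] == pytest.approx(0.0)
        assert cellulose[0, 1] == pytest.approx(1.0)
        assert lignin[0, 2] == pytest.approx(0.0)
        assert cellulose[0, 2] == pytest.approx(0.0)

    def test_channels_in_unit_range(self, small_section):
        img, _ = small_section
        lignin, cellulose = split_stains(img)
        for ch in (lignin, cellulose):
            assert ch.min() >= 0.0 and ch.max() <= 1.0


class TestGeometry:
    def test_known_radii_recovered(self, small_spec, small_section):
        img, truth = small_section
        geom = delineate_geometry(img, small_spec.pixel_scale)
        assert geom.cross_section_area == pytest.approx(np.pi * small_spec.section_radius**2, rel=0.01)
        assert geom.pith_area == pytest.approx(truth.pith_area, rel=0.05)
        assert geom.xylem_area == pytest.approx(geom.cross_section_area - geom.pith_area)

    def test_zero_pith_radius(self):
        spec = SectionSpec(section_radius=150.0, pith_radius=0.0, pixel_scale=1.0, seed=2)
        img, _ = render_section(spec)
        geom = delineate_geometry(img, 1.0)
        assert geom.pith_area == 0.0

    def test_blank_image_errors(self):
        blank = np.full((50, 50, 3), 250, dtype=np.uint8)
        with pytest.raises(ValueError, match="foreground"):
            delineate_geometry(blank, 1.0)

    def test_manual_pith_mask_override(self, small_spec, small_section):
        img, _ = small_section
        n = img.shape[0]
        manual = np.zeros((n, n), dtype=bool)
        manual[: n // 2] = True
        geom = delineate_geometry(img, small_spec.pixel_scale, pith_mask=manual)
        assert geom.pith_area > 0.3 * geom.cross_section_area


class TestDescriptors:
    def test_square_circularity_near_pi_over_4(self):
        sq = np.zeros((60, 60), dtype=bool)
        sq[5:55, 5:55] = True
        area, perim = sq.sum(), _contour_perimeter(sq)
        circ = 4 * np.pi * area / perim**2
        assert circ == pytest.approx(np.pi / 4, abs=0.05)

    @pytest.mark.parametrize("diameter_px", [20, 40, 80])
    def test_disc_circularity_high(self, diameter_px):
        from skimage.draw import disk

        im = np.zeros((diameter_px + 10, diameter_px + 10), dtype=bool)
        rr, cc = disk((im.shape[0] / 2, im.shape[1] / 2), diameter_px / 2)
        im[rr, cc] = True
        circ = 4 * np.pi * im.sum() / _contour_perimeter(im) ** 2
        assert circ >= 0.85


class TestDetectLumina:
    def test_clean_render_finds_every_disc(self, clean_disc_spec):
        img, truth = render_section(clean_disc_spec)
        geom = delineate_geometry(img, clean_disc_spec.pixel_scale)
        objs = detect_lumina(img, geom, SegmentationParams(), clean_disc_spec.pixel_scale)
        assert len(objs) == truth.vessel_count == 50
        labeled = classify_vessels(objs, SegmentationParams())
        assert all(o.label == "vessel" for o in labeled)

    def test_fully_stained_xylem_empty(self):
        spec = SectionSpec(section_radius=120.0, pith_radius=0.0, pixel_scale=1.0,
                           vessel_density_target=0.0, fiber_cell_density_target=1.0,
                           tension_wood_fraction_target=0.0, n_lacunae=0, n_ray_lines=0,
                           noise_level=0.0, seed=1)
        img, _ = render_section(spec)
        geom = delineate_geometry(img, 1.0)
        assert detect_lumina(img, geom, SegmentationParams(), 1.0) == []

    def test_single_disc_area_within_3pct(self):
        law = DiameterLaw(meanlog=float(np.log(40.0)), sdlog=1e-6, d_lo=39.9, d_hi=40.1)
        spec = SectionSpec(section_radius=150.0, pith_radius=0.0, pixel_scale=0.5,
                           vessel_density_target=1.0 / (np.pi * 0.15**2),
                           diameter_law=law, fiber_cell_density_target=1.0,
                           tension_wood_fraction_target=0.0, n_lacunae=0,
                           n_ray_lines=0, noise_level=0.0, seed=4)
        # density chosen so round(density * xylem area) == 1
        img, truth = render_section(spec)
        assert truth.vessel_count == 1
        geom = delineate_geometry(img, 0.5)
        objs = detect_lumina(img, geom, SegmentationParams(), 0.5)
        assert len(objs) == 1
        assert objs[0].area_um2 == pytest.approx(np.pi * 20.0**2, rel=0.03)


class TestClassify:
    params = SegmentationParams()

    def _obj(self, area, circ, roundness):
        return LumenObject(centroid_um=(0, 0), area_um2=area, perimeter_um=1.0,
                           major_axis_um=1.0, circularity=circ, roundness=roundness)

    @pytest.mark.parametrize(
        "area, circ, roundness, expected",
        [
            (1100.0, 0.95, 0.98, "vessel"),     # typical mean-size vessel
            (600.0, 0.9, 0.2, "fiber_or_ray"),  # elongated ray lacuna
            (150.0, 0.95, 0.98, "fiber_or_ray"),  # below the minimum vessel area
            (3200.0, 0.95, 0.98, "fiber_or_ray"),  # above the maximum
            (600.0, 0.3, 0.9, "fiber_or_ray"),  # low circularity
        ],
    )
    def test_threshold_rule(self, area, circ, roundness, expected):
        [obj] = classify_vessels([self._obj(area, circ, roundness)], self.params)
        assert obj.label == expected


class TestTensionWood:
    def test_exact_fraction(self):
        darkness = np.zeros((10, 10))
        darkness[:4] = 0.9
        mask = np.ones((10, 10), dtype=bool)
        assert tension_wood_fraction(darkness, mask, 0.5) == pytest.approx(40.0)

    def test_no_black_pixels(self):
        assert tension_wood_fraction(np.zeros((5, 5)), np.ones((5, 5), bool)) == 0.0

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            tension_wood_fraction(np.zeros((5, 5)), np.zeros((5, 5), bool))

    def test_monotone_in_threshold(self, small_section):
        img, _ = small_section
        lignin, darkness = split_stains(img)
        mask = np.ones(darkness.shape, dtype=bool)
        fracs = [tension_wood_fraction(darkness, mask, t) for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_recovers_target_within_2_points(self):
        spec = SectionSpec(section_radius=250.0, pith_radius=50.0, pixel_scale=0.5,
                           tension_wood_fraction_target=0.398, seed=17)
        img, _ = render_section(spec)
        res = segment_section(img, 0.5)
        assert res.tension_wood_pct == pytest.approx(39.8, abs=2.0)


class TestSectionSummary:
    def _geom(self):
        from xylotraits.segmentation import SectionGeometry

        return SectionGeometry(cross_section_area=6e5, pith_area=1e5, xylem_area=5e5,
                               xylem_mask=np.ones((10, 10), bool), pixel_scale=1.0)

    def _objs(self, n_vessel, n_fiber):
        vs = [LumenObject((0, 0), 1000.0, 1.0, 1.0, 1.0, 1.0, label="vessel") for _ in range(n_vessel)]
        fs = [LumenObject((0, 0), 20.0, 1.0, 1.0, 1.0, 1.0, label="fiber_or_ray") for _ in range(n_fiber)]
        return vs + fs

    def test_vessel_density(self):
        s = section_summary(self._objs(100, 10), self._geom())
        assert s["vessel_density_per_mm2"] == pytest.approx(200.0)  # 100 per 0.5 mm²

    def test_density_ratio(self):
        from xylotraits.segmentation import SectionGeometry

        geom = SectionGeometry(2e7, 0.0, 2e7, np.ones((5, 5), bool), 1.0)
        vals = section_summary(self._objs(5, 100), geom)
        assert vals["vessel_fiber_density_ratio_pct"] == pytest.approx(5.0)

    def test_zero_fibers_ratios_missing(self):
        s = section_summary(self._objs(10, 0), self._geom())
        assert np.isnan(s["vessel_fiber_density_ratio_pct"])
        assert np.isnan(s["vessel_fiber_area_ratio_pct"])

    def test_recovered_density_close_to_truth(self, small_spec, small_section):
        img, truth = small_section
        res = segment_section(img, small_spec.pixel_scale)
        truth_n = truth.vessel_count / (truth.xylem_area / 1e6)
        assert res.summary["vessel_density_per_mm2"] == pytest.approx(truth_n, rel=0.05)


class TestScaleEquivariance:
    def test_total_vessel_area_stable_under_rescaling(self):
        base = SectionSpec(section_radius=200.0, pith_radius=40.0, pixel_scale=0.5,
                           tension_wood_fraction_target=0.2, seed=6)
        totals = []
        for scale in (0.5, 1.0):
            img, _ = render_section(replace(base, pixel_scale=scale))
            res = segment_section(img, scale)
            totals.append(res.vessel_table.areas_um2.sum())
        assert totals[1] == pytest.approx(totals[0], rel=0.05)


class TestTiledEquivalence:
    def test_whole_vs_tiled_identical(self, small_spec, small_section):
        img, _ = small_section
        whole = segment_section(img, small_spec.pixel_scale)
        # overlap exceeds the largest possible vessel diameter (61.8 µm -> px)
        overlap = int(np.ceil(70.0 / small_spec.pixel_scale))
        tiled = segment_section_tiled(img, small_spec.pixel_scale, tile_size=160, overlap=overlap)
        assert len(tiled.vessel_table) == len(whole.vessel_table)
        assert np.isclose(tiled.vessel_table.areas_um2.sum(), whole.vessel_table.areas_um2.sum())
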