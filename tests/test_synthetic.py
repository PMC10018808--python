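"""Synthetic slide generator: vessel sampling, rendering determinism,
ground-truth self-consistency, composition simulation and cohort output."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from xylotraits.composition import COMPONENTS
from xylotraits.stats import fit_regression
from xylotraits.synthetic import (
    CohortSpec,
    CompositionModel,
    DiameterLaw,
    SectionRenderError,
    SectionSpec,
    default_cohort,
    generate_cohort,
    render_section,
    sample_vessels,
    simulate_composition,
    simulate_cohort_records,
)


class TestDiameterLaw:
    def test_truncation_bounds_hold_over_many_draws(self):
        law = DiameterLaw(d_lo=17.8, d_hi=61.8)
        d = law.sample(np.random.default_rng(0), 10_000)
        assert d.min() >= 17.8 and d.max() <= 61.8

    def test_analytic_mean_matches_numerical_integration(self):
        law = DiameterLaw()
        dist = sps.lognorm(s=law.sdlog, scale=np.exp(law.meanlog))
        norm = dist.cdf(law.d_hi) - dist.cdf(law.d_lo)
        num, _ = integrate.quad(lambda x: x * dist.pdf(x) / norm, law.d_lo, law.d_hi)
        assert law.mean() == pytest.approx(num, rel=1e-8)

    def test_empirical_mean_within_2pct_of_analytic(self):
        law = DiameterLaw()
        d = law.sample(np.random.default_rng(1), 5000)
        assert d.mean() == pytest.approx(law.mean(), rel=0.02)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DiameterLaw(d_lo=40.0, d_hi=30.0)


class TestSampleVessels:
    def test_zero_density_empty(self, small_spec):
        spec = replace(small_spec, vessel_density_target=0.0)
        assert sample_vessels(spec, np.random.default_rng(0)) == []

    def test_count_matches_density_within_10pct(self):
        spec = SectionSpec(section_radius=450.0, pith_radius=60.0, pixel_scale=1.0, seed=0)
        xylem_mm2 = spec.xylem_area_um2 / 1e6
        spec = replace(spec, vessel_density_target=100.0 / xylem_mm2)
        got = len(sample_vessels(spec, np.random.default_rng(2)))
        assert 90 <= got <= 110

    def test_discs_inside_annulus_and_nonoverlapping(self, small_spec):
        vessels = sample_vessels(small_spec, np.random.default_rng(3))
        c = small_spec.section_radius
        for x, y, d in vessels:
            rad = np.hypot(x - c, y - c)
            assert rad - d / 2 >= small_spec.pith_radius
            assert rad + d / 2 <= small_spec.section_radius
        pts = np.array([(x, y) for x, y, _ in vessels])
        radii = np.array([d / 2 for _, _, d in vessels])
        for i in range(len(pts)):
            dist = np.hypot(*(pts[i] - pts[i + 1 :]).T)
            assert np.all(dist >= radii[i] + radii[i + 1 :])

    def test_unplaceable_density_fails_naming_density(self):
        spec = SectionSpec(section_radius=120.0, pith_radius=20.0, pixel_scale=1.0,
                           vessel_density_target=4000.0, seed=0)
        with pytest.raises(SectionRenderError, match="4000"):
            sample_vessels(spec, np.random.default_rng(0))


class TestRenderSection:
    def test_image_dimensions(self, small_spec, small_section):
        img, _ = small_section
        n = int(np.ceil(2 * small_spec.section_radius / small_spec.pixel_scale))
        assert img.shape == (n, n, 3)
        assert img.dtype == np.uint8

    def test_deterministic_for_fixed_seed(self, small_spec):
        img1, t1 = render_section(small_spec)
        img2, t2 = render_section(small_spec)
        assert np.array_equal(img1, img2)
        assert t1.to_dict() == t2.to_dict()

    def test_zero_tension_wood_target(self, clean_disc_spec):
        _, truth = render_section(clean_disc_spec)
        assert truth.tension_wood_mask_area == 0.0

    def test_ground_truth_lists_every_rendered_disc(self, clean_disc_spec):
        _, truth = render_section(clean_disc_spec)
        assert truth.vessel_count == 50

    def test_pixel_budget_exceeded(self, small_spec):
        with pytest.raises(SectionRenderError, match="tile"):
            render_section(replace(small_spec, pixel_scale=0.01), max_pixels=10_000)

    def test_ground_truth_self_consistency(self, small_spec, small_section):
        """Rasterized mask areas agree with analytic areas to boundary error."""
        _, truth = small_section
        scale = small_spec.pixel_scale
        r_s, r_p = small_spec.section_radius, small_spec.pith_radius
        for raster, radius in [(truth.cross_section_area, r_s), (truth.pith_area, r_p)]:
            analytic = np.pi * radius**2
            boundary = 2 * np.pi * radius * scale  # one pixel-row of boundary
            assert abs(raster - analytic) <= boundary
        assert truth.xylem_area == pytest.approx(truth.cross_section_area - truth.pith_area)

    def test_tension_wood_hits_target(self):
        spec = SectionSpec(section_radius=250.0, pith_radius=50.0, pixel_scale=0.5,
                           tension_wood_fraction_target=0.398, seed=21)
        _, truth = render_section(spec)
        assert truth.tension_wood_pct == pytest.approx(39.8, abs=0.5)


class TestSimulateComposition:
    def test_noise_free_line(self):
        model = CompositionModel(intercept=30.0, slope=0.24, residual_sd=0.0, baseline_rel_sd=0.0)
        rec = simulate_composition(40.0, model, np.random.default_rng(0))
        assert rec.glucan == pytest.approx(39.6)

    def test_zero_slope_kills_correlation(self):
        model = CompositionModel(slope=0.0, intercept=36.0)
        rng = np.random.default_rng(4)
        tw = rng.uniform(10, 60, 200)
        glu = [simulate_composition(t, model, rng).glucan for t in tw]
        assert abs(np.corrcoef(tw, glu)[0, 1]) < 0.2

    def test_out_of_range_tw_rejected(self):
        with pytest.raises(ValueError):
            simulate_composition(120.0, CompositionModel(), np.random.default_rng(0))

    def test_impossible_fraction_fails_after_resampling(self):
        model = CompositionModel(intercept=150.0, slope=0.0, residual_sd=0.1)
        with pytest.raises(SectionRenderError):
            simulate_composition(10.0, model, np.random.default_rng(0))


class TestCohort:
    def test_default_calibration_recovers_r2_band(self):
        """At the default calibration the cohort-level tw-glucan regression
        concentrates near r^2 = 0.59 (n = 36 per cohort)."""
        r2s = []
        for s in range(60):
            rec = simulate_cohort_records(default_cohort(seed=s))
            r2s.append(fit_regression(rec["tw_pct"], rec["glucan"]).r_squared)
        r2s = np.array(r2s)
        assert 0.44 <= r2s.mean() <= 0.74
        assert ((r2s >= 0.44) & (r2s <= 0.74)).mean() >= 0.8

    def test_slope_recovery(self):
        slopes = [
            fit_regression(
                (rec := simulate_cohort_records(default_cohort(seed=s)))["tw_pct"], rec["glucan"]
            ).slope
            for s in range(40)
        ]
        assert np.mean(slopes) == pytest.approx(0.46, abs=0.04)

    def test_replicates_below_two_rejected(self):
        with pytest.raises(ValueError):
            default_cohort(replicates=1)

    def test_records_deterministic(self):
        a = simulate_cohort_records(default_cohort(seed=7))
        b = simulate_cohort_records(default_cohort(seed=7))
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def tiny_cohort():
    return default_cohort(seed=13, replicates=2, section_radius=140.0,
                          pith_radius=35.0, pixel_scale=1.0)


class TestGenerateCohort:
    def test_full_design_file_count(self, tmp_path):
        cohort = default_cohort(seed=3, replicates=12, section_radius=120.0,
                                pith_radius=30.0, pixel_scale=1.0)
        out = generate_cohort(cohort, tmp_path / "data")
        images = sorted((out / "images").glob("*.png"))
        truths = json.loads((out / "ground_truth.json").read_text())
        assert len(images) == 36  # 3 treatments x 12 replicates
        assert len(truths) == 36
        design = pd.read_csv(out / "design.csv")
        assert design.groupby("treatment").size().tolist() == [12, 12, 12]

    def test_refuses_nonempty_dir(self, tmp_path, tiny_cohort):
        target = tmp_path / "data"
        target.mkdir()
        (target / "stale.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_cohort(tiny_cohort, target)
        generate_cohort(tiny_cohort, target, overwrite=True)  # explicit opt-in

    def test_same_seed_identical_outputs(self, tmp_path, tiny_cohort):
        a = generate_cohort(tiny_cohort, tmp_path / "a")
        b = generate_cohort(tiny_cohort, tmp_path / "b")
        for name in ("composition.csv", "density.csv", "design.csv", "manifest.yaml"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
        img = sorted((a / "images").iterdir())[0].name
        assert (a / "images" / img).read_bytes() == (b / "images" / img).read_bytes()

    def test_composition_schema(self, tmp_path, tiny_cohort):
        out = generate_cohort(tiny_cohort, tmp_path / "c")
        comp = pd.read_csv(out / "composition.csv")
        assert list(comp.columns) == ["sample_id"] + list(COMPONENTS)
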