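"""Shared fixtures: small rendered sections and a full synthetic cohort.

Everything is generated at test time from seeds; fixture sections use
coarser pixel scales and smaller radii than real slides so the suite stays
fast while exercising the same physical-unit code paths.
"""

from dataclasses import replace

import numpy as np
import pytest

from xylotraits.segmentation import SegmentationParams, segment_section
from xylotraits.synthetic import (
    DiameterLaw,
    SectionSpec,
    default_cohort,
    render_section,
    simulate_cohort_records,
)


@pytest.fixture(scope="session")
def small_spec() -> SectionSpec:
    return SectionSpec(
        section_radius=200.0,
        pith_radius=50.0,
        pixel_scale=1.0,
        vessel_density_target=172.0,
        tension_wood_fraction_target=0.3,
        fiber_cell_density_target=5800.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_section(small_spec):
    """(image, ground truth) of a quick 400×400 px section."""
    return render_section(small_spec)


@pytest.fixture(scope="session")
def clean_disc_spec() -> SectionSpec:
    """50 vessel discs, no distractors, no fibers, no noise, no tension wood."""
    spec = SectionSpec(
        section_radius=300.0,
        pith_radius=60.0,
        pixel_scale=1.0,
        tension_wood_fraction_target=0.0,
        fiber_cell_density_target=1.0,  # grid pitch exceeds the section: no fibers
        n_lacunae=0,
        n_ray_lines=0,
        noise_level=0.0,
        seed=9,
    )
    xylem_mm2 = spec.xylem_area_um2 / 1e6
    return replace(spec, vessel_density_target=50.0 / xylem_mm2)


@pytest.fixture(scope="session")
def cohort_results():
    """36-section synthetic cohort, rendered and segmented once per session.

    Returns a list of dicts with the spec, ground truth and segmentation
    result per section, in the 3 treatments × 12 replicates design.
    """
    cohort = default_cohort(seed=42, replicates=12, section_radius=260.0,
                            pith_radius=50.0, pixel_scale=0.5)
    records = simulate_cohort_records(cohort)
    by_label = {tr.label: tr for tr in cohort.treatments}
    params = SegmentationParams()
    out = []
    for _, row in records.iterrows():
        tr = by_label[row["treatment"]]
        spec = replace(
            tr.section,
            tension_wood_fraction_target=float(np.clip(row["tw_pct"] / 100.0, 0.0, 0.7)),
            seed=int(row["section_seed"]),
        )
        img, truth = render_section(spec)
        res = segment_section(img, spec.pixel_scale, params=params, section_id=row["sample_id"])
        out.append(
            {"sample_id": row["sample_id"], "treatment": row["treatment"],
             "spec": spec, "truth": truth, "result": res}
        )
    return out
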