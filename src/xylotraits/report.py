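"""End-to-end analysis of a dataset directory into treatment-report tables.

Given a dataset produced by :func:`xylotraits.synthetic.generate_cohort`
(or any directory with the same layout — ``images/``, ``design.csv``,
``composition.csv``, ``density.csv``), ``build_report`` segments every
section image, computes hydraulic traits and class decompositions,
aggregates composition, and writes four report tables plus a tension-wood /
glucan regression figure:

* ``table_xylem_traits.csv`` — per-treatment mean ± SE, Tukey letters and
  ANOVA p for wood density and the xylem/vessel traits,
* ``table_class_frequency.csv`` / ``table_ks_contribution.csv`` — diameter
  class decomposition per treatment,
* ``table_composition.csv`` — composition aggregates per treatment,
* ``figure_tw_glucan.png`` — scatter + OLS fit of glucan on tension wood,
* ``per_section_traits.csv``, ``correlations.csv`` and ``run_log.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import aggregate_table, wood_specific_gravity
from .hydraulics import VesselTable, bin_by_diameter, pool_class_tables, summarize
from .segmentation import SegmentationParams, objects_to_frame, segment_section
from .slide_io import read_image
from .stats import fit_regression, group_summary, pearson_matrix

__all__ = ["ReportBundle", "build_report", "analyze_sections"]

TRAIT_COLUMNS = [
    "wood_density",
    "tension_wood_pct",
    "mean_vessel_area_um2",
    "mean_vessel_diameter_um",
    "vessel_density_per_mm2",
    "ks",
    "xylem_pct_of_section",
    "vessel_area_pct_of_xylem",
    "fiber_ray_pct_of_xylem",
    "fiber_ray_density_per_mm2",
    "vessel_fiber_density_ratio_pct",
    "vessel_fiber_area_ratio_pct",
]


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict[str, Path]
    figures: dict[str, Path]
    per_section: pd.DataFrame
    run_log: dict


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing {stage} output: {path}")
    return path


def analyze_sections(
    dataset_dir,
    params: SegmentationParams = SegmentationParams(),
    pixel_scale: float | None = None,
) -> tuple[pd.DataFrame, list[pd.DataFrame], pd.DataFrame]:
    """Segment every section listed in design.csv and compute traits.

    Returns (per-section trait frame, list of class tables, per-object frame).
    PNG images take the pixel scale from ``manifest.yaml`` unless given.
    """
    root = Path(dataset_dir)
    design = pd.read_csv(_require(root / "design.csv", "design table"))
    images = _require(root / "images", "image directory")
    if pixel_scale is None:
        man = root / "manifest.yaml"
        if man.exists():
            scales = yaml.safe_load(man.read_text()).get("pixel_scale_um")
            if scales:
                pixel_scale = float(scales[0])
    rows, class_tables, obj_frames = [], [], []
    for _, entry in design.iterrows():
        sid = str(entry["sample_id"])
        matches = sorted(images.glob(f"{sid}.*"))
        if not matches:
            raise FileNotFoundError(f"missing section image for sample {sid}")
        rgb, scale = read_image(matches[0], pixel_scale=pixel_scale)
        res = segment_section(rgb, scale, params=params, section_id=sid)
        row = {"sample_id": sid, "treatment": entry["treatment"], "replicate": entry["replicate"]}
        row.update(res.summary)
        if len(res.vessel_table):
            summ = summarize(res.vessel_table)
            row.update(
                mean_vessel_area_um2=summ.mean_area_um2,
                mean_vessel_diameter_um=summ.mean_diameter_um,
                kh=summ.kh,
                ks=summ.ks,
                lumen_fraction=summ.lumen_fraction,
                mean_hydraulic_diameter_um=summ.mean_hydraulic_diameter_um,
            )
            class_tables.append(bin_by_diameter(res.vessel_table))
        rows.append(row)
        obj_frames.append(objects_to_frame(res.objects, section_id=sid))
    per_section = pd.DataFrame(rows)
    objects = pd.concat(obj_frames, ignore_index=True) if obj_frames else pd.DataFrame()
    return per_section, class_tables, objects


def _stat_table(df: pd.DataFrame, traits: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± SE + letters per treatment and ANOVA p, one row per treatment."""
    out: dict[str, dict] = {g: {} for g in pd.unique(df["treatment"])}
    anova = {}
    for trait in traits:
        if trait not in df.columns or df[trait].isna().all():
            continue
        sub = df[["treatment", trait]].dropna()
        try:
            gs = group_summary(sub[trait].to_numpy(), sub["treatment"].to_numpy(), alpha=alpha)
        except ValueError:
            continue
        for g in gs.table.index:
            out[g][f"{trait}_mean"] = gs.table.loc[g, "mean"]
            out[g][f"{trait}_se"] = gs.table.loc[g, "se"]
            out[g][f"{trait}_letters"] = gs.table.loc[g, "letters"]
        anova[trait] = gs.anova_p
    table = pd.DataFrame(out).T
    table.index.name = "treatment"
    prow = {}
    for trait, p in anova.items():
        prow[f"{trait}_mean"] = p
    table.loc["ANOVA_p"] = pd.Series(prow)
    return table.reset_index()


def build_report(
    dataset_dir,
    out_dir,
    params: SegmentationParams = SegmentationParams(),
    alpha: float = 0.05,
) -> ReportBundle:
    """Run the full pipeline on a dataset directory and write the report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    root = Path(dataset_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_section, class_tables, objects = analyze_sections(root, params=params)
    comp_raw = pd.read_csv(_require(root / "composition.csv", "composition table"))
    density = pd.read_csv(_require(root / "density.csv", "density table"))

    density["wood_density"] = [
        wood_specific_gravity(m, v) for m, v in zip(density["oven_dry_mass_g"], density["green_volume_cm3"])
    ]
    per_section = per_section.merge(density[["sample_id", "wood_density"]], on="sample_id")
    comp = aggregate_table(comp_raw).merge(
        per_section[["sample_id", "treatment", "tension_wood_pct"]], on="sample_id"
    )

    tables: dict[str, Path] = {}

    t2 = _stat_table(per_section, TRAIT_COLUMNS, alpha)
    tables["xylem_traits"] = out / "table_xylem_traits.csv"
    t2.to_csv(tables["xylem_traits"], index=False)

    sid_to_treatment = dict(zip(per_section["sample_id"], per_section["treatment"]))
    labels = [sid_to_treatment[str(ct["section_id"].iloc[0])] for ct in class_tables]
    pooled = pool_class_tables(class_tables, labels)
    freq = pooled.pivot(index="group", columns="class", values="frequency_pct_mean")
    freq_se = pooled.pivot(index="group", columns="class", values="frequency_pct_se")
    ksc = pooled.pivot(index="group", columns="class", values="ks_contribution_pct_mean")
    ksc_se = pooled.pivot(index="group", columns="class", values="ks_contribution_pct_se")
    order = [c for c in pooled["class"].unique()]
    freq, freq_se, ksc, ksc_se = (x[order] for x in (freq, freq_se, ksc, ksc_se))
    freq_out = pd.concat({"mean": freq, "se": freq_se}, axis=1).reset_index()
    ks_out = pd.concat({"mean": ksc, "se": ksc_se}, axis=1).reset_index()
    tables["class_frequency"] = out / "table_class_frequency.csv"
    freq_out.to_csv(tables["class_frequency"], index=False)
    tables["ks_contribution"] = out / "table_ks_contribution.csv"
    ks_out.to_csv(tables["ks_contribution"], index=False)

    comp_traits = [
        "glucan", "xylan", "galactan", "arabinan", "mannan", "hemicellulose",
        "total_sugars", "asl", "ail", "total_lignin", "extractives", "mass_closure",
    ]
    t5 = _stat_table(comp, comp_traits, alpha)
    tables["composition"] = out / "table_composition.csv"
    t5.to_csv(tables["composition"], index=False)

    per_section_path = out / "per_section_traits.csv"
    per_section.to_csv(per_section_path, index=False)
    tables["per_section"] = per_section_path

    corr_cols = ["wood_density", "tension_wood_pct", "vessel_density_per_mm2", "ks",
                 "mean_vessel_diameter_um"]
    corr_df = per_section.merge(comp[["sample_id", "glucan", "extractives"]], on="sample_id")
    r, p = pearson_matrix(corr_df[[c for c in corr_cols + ["glucan", "extractives"] if c in corr_df]])
    tables["correlations"] = out / "correlations.csv"
    r.to_csv(tables["correlations"])

    # tension wood vs glucan regression figure
    fit = fit_regression(comp["tension_wood_pct"], comp["glucan"])
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in comp.groupby("treatment"):
        ax.scatter(sub["tension_wood_pct"], sub["glucan"], label=str(grp), s=24)
    xs = np.linspace(comp["tension_wood_pct"].min(), comp["tension_wood_pct"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-", lw=1)
    ax.set_xlabel("Tension wood (% of xylem area)")
    ax.set_ylabel("Glucan (% oven-dry mass)")
    ax.set_title(f"r² = {fit.r_squared:.2f}, p = {fit.p_value:.2g}, n = {fit.n}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig_path = out / "figure_tw_glucan.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)

    manifest = root / "manifest.yaml"
    seed = yaml.safe_load(manifest.read_text()).get("seed") if manifest.exists() else None
    cfg_hash = hashlib.sha256(repr(params).encode()).hexdigest()[:16]
    run_log = {
        "version": __version__,
        "seed": seed,
        "config_hash": cfg_hash,
        "n_sections": int(len(per_section)),
        "regression": {"slope": fit.slope, "intercept": fit.intercept,
                       "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n},
        "note": "p-values are unadjusted across traits (no cross-trait multiplicity correction)",
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))

    return ReportBundle(
        out_dir=out,
        tables=tables,
        figures={"tw_glucan": fig_path},
        per_section=per_section,
        run_log=run_log,
    )
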