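"""Theoretical hydraulic traits of xylem from per-vessel lumen areas.

The water-transport capacity of a stem section is summarised from the list of
vessel lumen areas via the Hagen–Poiseuille law: each conduit of lumen
diameter ``D`` (the diameter of the circle with the measured lumen area)
contributes conductance proportional to ``D**4``, so

    K_h = (pi * rho / (128 * eta)) * sum_i D_i**4

with water density ``rho`` and dynamic viscosity ``eta``.  ``K_h`` is the
conductance per unit pressure gradient of all vessels in the section
(kg m MPa^-1 s^-1); dividing by the xylem cross-sectional area gives the
specific conductivity ``K_S`` (kg m^-1 MPa^-1 s^-1), comparable across stems
of different size.

All public functions take areas/diameters in micrometres and xylem areas in
square micrometres; SI conversion happens internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalConstants",
    "VesselTable",
    "HydraulicSummary",
    "DEFAULT_CLASS_EDGES",
    "diameter_from_area",
    "area_from_diameter",
    "kh",
    "ks",
    "summarize",
    "bin_by_diameter",
    "pool_class_tables",
    "read_vessel_tables",
]

#: Diameter class edges in µm; classes are half-open ``[a, b)``.
DEFAULT_CLASS_EDGES: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)

UM_PER_M = 1e6
UM2_PER_MM2 = 1e6
UM2_PER_M2 = 1e12


@dataclass(frozen=True)
class PhysicalConstants:
    """Water properties at 20 °C used in the Hagen–Poiseuille factor.

    water_density : kg m^-3
    water_viscosity : MPa s (1e-9 MPa s = 1.002e-3 Pa s rounded to 1e-3)
    """

    water_density: float = 998.0
    water_viscosity: float = 1e-9

    def __post_init__(self) -> None:
        if self.water_density <= 0 or self.water_viscosity <= 0:
            raise ValueError("physical constants must be positive")

    @property
    def poiseuille_factor(self) -> float:
        """pi*rho/(128*eta) in kg m^-3 MPa^-1 s^-1 — multiply by sum(D^4) in m^4."""
        return np.pi * self.water_density / (128.0 * self.water_viscosity)


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass
class VesselTable:
    """Per-section vessel lumen areas plus the section's xylem area.

    areas_um2 : lumen area of every vessel, µm²
    xylem_area_um2 : cross-sectional area minus pith area, µm²
    """

    areas_um2: np.ndarray
    xylem_area_um2: float
    section_id: str = ""

    def __post_init__(self) -> None:
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if self.areas_um2.ndim != 1:
            raise ValueError("areas_um2 must be one-dimensional")
        if np.any(self.areas_um2 <= 0):
            raise ValueError("all vessel lumen areas must be positive")
        if not self.xylem_area_um2 > 0:
            raise ValueError("xylem_area_um2 must be positive")

    @property
    def diameters_um(self) -> np.ndarray:
        return diameter_from_area(self.areas_um2)

    def __len__(self) -> int:
        return self.areas_um2.size


@dataclass
class HydraulicSummary:
    """Section-level hydraulic traits.

    mean_area : Ā, µm²; mean_diameter : D̄, µm; vessel_density : N, mm^-2;
    kh : kg m MPa^-1 s^-1; ks : kg m^-1 MPa^-1 s^-1;
    lumen_fraction F = n·Ā / xylem area (dimensionless);
    non_lumen_fraction NF = 1 − F;
    vulnerability_index VI = D̄ / N (µm mm²);
    composition_index S = Ā / N (µm² mm²);
    mean_hydraulic_diameter DH = (ΣD⁴/n)^(1/4), µm (quartic mean, ≥ D̄).

    F, NF, VI, S and DH follow the standard quantitative-wood-anatomy
    conventions (supplementary-convention indices).
    """

    section_id: str
    n_vessels: int
    xylem_area_um2: float
    mean_area_um2: float
    mean_diameter_um: float
    vessel_density_per_mm2: float
    kh: float
    ks: float
    lumen_fraction: float
    non_lumen_fraction: float
    vulnerability_index: float
    composition_index: float
    mean_hydraulic_diameter_um: float
    convention: str = field(default="supplementary-convention", repr=False)

    def to_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "n_vessels": self.n_vessels,
            "xylem_area_um2": self.xylem_area_um2,
            "mean_area_um2": self.mean_area_um2,
            "mean_diameter_um": self.mean_diameter_um,
            "vessel_density_per_mm2": self.vessel_density_per_mm2,
            "kh": self.kh,
            "ks": self.ks,
            "lumen_fraction": self.lumen_fraction,
            "non_lumen_fraction": self.non_lumen_fraction,
            "vulnerability_index": self.vulnerability_index,
            "composition_index": self.composition_index,
            "mean_hydraulic_diameter_um": self.mean_hydraulic_diameter_um,
        }


def diameter_from_area(area_um2):
    """Diameter (µm) of the circle with the given lumen area (µm²): D = sqrt(4A/π)."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("lumen area must be positive")
    d = np.sqrt(4.0 * area / np.pi)
    return float(d) if np.isscalar(area_um2) else d


def area_from_diameter(diameter_um):
    """Inverse of :func:`diameter_from_area`: A = π D² / 4."""
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    a = np.pi * d**2 / 4.0
    return float(a) if np.isscalar(diameter_um) else a


def kh(diameters_um: Sequence[float], constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Theoretical hydraulic conductivity K_h of a set of vessels.

    Additive over vessels; diameters in µm are converted to metres so the
    result carries kg m MPa^-1 s^-1 with the default constants.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        warnings.warn("kh of an empty vessel set is 0", stacklevel=2)
        return 0.0
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    d_m = d / UM_PER_M
    return float(constants.poiseuille_factor * np.sum(d_m**4))


def ks(kh_value: float, xylem_area_um2: float) -> float:
    """Specific conductivity K_S = K_h / xylem area (area converted to m²)."""
    if not xylem_area_um2 > 0:
        raise ValueError("xylem area must be positive")
    return float(kh_value / (xylem_area_um2 / UM2_PER_M2))


def summarize(table: VesselTable, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> HydraulicSummary:
    """Compute all section-level hydraulic traits from a vessel table."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty vessel table")
    areas = table.areas_um2
    diams = table.diameters_um
    n = areas.size
    xylem_mm2 = table.xylem_area_um2 / UM2_PER_MM2
    mean_area = float(areas.mean())
    mean_diam = float(diams.mean())
    density = n / xylem_mm2
    kh_val = kh(diams, constants)
    ks_val = ks(kh_val, table.xylem_area_um2)
    f = n * mean_area / table.xylem_area_um2
    dh = float((np.sum(diams**4) / n) ** 0.25)
    return HydraulicSummary(
        section_id=table.section_id,
        n_vessels=n,
        xylem_area_um2=table.xylem_area_um2,
        mean_area_um2=mean_area,
        mean_diameter_um=mean_diam,
        vessel_density_per_mm2=density,
        kh=kh_val,
        ks=ks_val,
        lumen_fraction=f,
        non_lumen_fraction=1.0 - f,
        vulnerability_index=mean_diam / density,
        composition_index=mean_area / density,
        mean_hydraulic_diameter_um=dh,
    )


def _class_label(lo: float, hi: float) -> str:
    return f"[{lo:g}-{hi:g})"


def bin_by_diameter(
    table: VesselTable,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Decompose vessel density and K_S into half-open diameter classes.

    Returns one row per class ``[a, b)`` (b excluded) with columns
    ``count``, ``density_per_mm2``, ``frequency_pct`` (% of all vessels),
    ``ks`` (class-wise specific conductivity), ``ks_contribution_pct``
    (% of total K_S) and ``cumulative_ks_pct``.  Vessels outside the edge
    range are never dropped: they land in flagged ``underflow``/``overflow``
    rows (emitted only when occupied) and a warning is raised.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be a strictly increasing 1-D sequence")
    diams = table.diameters_um
    n_total = diams.size
    xylem_mm2 = table.xylem_area_um2 / UM2_PER_MM2
    d4_total = float(np.sum(diams**4)) if n_total else 0.0

    # np.digitize with right=False puts d == edge into the upper class: a <= D < b
    idx = np.digitize(diams, edges, right=False) - 1  # -1 underflow, len-1 overflow
    rows = []
    labels: list[tuple[str, float, float, np.ndarray]] = []
    under = idx < 0
    over = idx >= edges.size - 1
    for k in range(edges.size - 1):
        labels.append((_class_label(edges[k], edges[k + 1]), edges[k], edges[k + 1], idx == k))
    if under.any():
        labels.insert(0, ("underflow", -np.inf, edges[0], under))
    if over.any():
        labels.append(("overflow", edges[-1], np.inf, over))
    if under.any() or over.any():
        warnings.warn(
            f"{int(under.sum() + over.sum())} vessel(s) outside diameter range "
            f"[{edges[0]:g}, {edges[-1]:g}) collected in flagged bins",
            stacklevel=2,
        )

    for label, lo, hi, sel in labels:
        d_sel = diams[sel]
        count = int(sel.sum())
        kh_cls = kh(d_sel, constants) if count else 0.0
        rows.append(
            {
                "class": label,
                "d_lo_um": lo,
                "d_hi_um": hi,
                "count": count,
                "density_per_mm2": count / xylem_mm2,
                "frequency_pct": 100.0 * count / n_total if n_total else 0.0,
                "ks": ks(kh_cls, table.xylem_area_um2),
                "ks_contribution_pct": 100.0 * np.sum(d_sel**4) / d4_total if d4_total else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out["cumulative_ks_pct"] = out["ks_contribution_pct"].cumsum()
    out.insert(0, "section_id", table.section_id)
    return out


def pool_class_tables(class_tables: Sequence[pd.DataFrame], group_labels: Sequence[str]) -> pd.DataFrame:
    """Average per-section class tables within groups (mean ± SE per class).

    ``group_labels`` gives the treatment of each section's table.  SE is
    sd/sqrt(n); for a single section per group SE is reported missing (NaN),
    never zero.
    """
    if len(class_tables) != len(group_labels):
        raise ValueError("need one group label per class table")
    if not class_tables:
        raise ValueError("no class tables given")
    frames = []
    for tab, grp in zip(class_tables, group_labels):
        t = tab.copy()
        t["group"] = grp
        frames.append(t)
    allt = pd.concat(frames, ignore_index=True)
    metrics = ["density_per_mm2", "frequency_pct", "ks", "ks_contribution_pct", "cumulative_ks_pct"]

    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    agg = allt.groupby(["group", "class", "d_lo_um"], sort=False).agg(
        n=("frequency_pct", "size"),
        **{f"{m}_mean": (m, "mean") for m in metrics},
        **{f"{m}_se": (m, _se) for m in metrics},
    )
    agg = agg.reset_index().sort_values(["group", "d_lo_um"], kind="stable").reset_index(drop=True)
    return agg


def read_vessel_tables(objects_csv, geometry_csv) -> list[VesselTable]:
    """Build vessel tables from a per-object CSV and a section-geometry CSV.

    ``objects_csv`` needs columns ``section_id, area_um2`` (rows are vessels);
    ``geometry_csv`` needs ``section_id, xylem_area_um2``.
    """
    obj = pd.read_csv(objects_csv)
    geo = pd.read_csv(geometry_csv)
    for col in ("section_id", "area_um2"):
        if col not in obj.columns:
            raise ValueError(f"objects CSV lacks required column {col!r}")
    for col in ("section_id", "xylem_area_um2"):
        if col not in geo.columns:
            raise ValueError(f"geometry CSV lacks required column {col!r}")
    geo = geo.set_index("section_id")["xylem_area_um2"]
    tables = []
    for sid, sub in obj.groupby("section_id", sort=False):
        if sid not in geo.index:
            raise ValueError(f"no geometry row for section {sid!r}")
        tables.append(VesselTable(sub["area_um2"].to_numpy(), float(geo.loc[sid]), section_id=str(sid)))
    return tables
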