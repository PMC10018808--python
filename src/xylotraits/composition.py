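"""Lignocellulosic composition arithmetic.

Structural-carbohydrate assays report sugar *monomers* (glucose, xylose, ...)
as percent of oven-dry mass; polymer-equivalent fractions (glucan, xylan, ...)
are obtained with the standard anhydro correction that removes the water of
hydrolysis: hexoses ×162/180 (0.90), pentoses ×132/150 (0.88).  Aggregates:

    hemicellulose = xylan + galactan + arabinan + mannan
    total_sugars  = glucan + hemicellulose
    total_lignin  = ASL + AIL  (acid-soluble + acid-insoluble)
    mass_closure  = total_sugars + total_lignin + extractives

Mass closure is a completeness check; values outside a plausibility band are
flagged suspect rather than rejected.  Wood specific gravity is oven-dry mass
over green (water-saturated) volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ANHYDRO_FACTORS",
    "COMPONENTS",
    "HEMICELLULOSE_COMPONENTS",
    "CompositionRecord",
    "DensityRecord",
    "anhydro_correct",
    "aggregate",
    "aggregate_table",
    "wood_specific_gravity",
]

#: monomer → polymer mass conversion (water of hydrolysis removed)
ANHYDRO_FACTORS = {"hexose": 162.0 / 180.0, "pentose": 132.0 / 150.0}

#: raw component columns, percent of oven-dry mass
COMPONENTS = ("glucan", "xylan", "galactan", "arabinan", "mannan", "asl", "ail", "extractives")
HEMICELLULOSE_COMPONENTS = ("xylan", "galactan", "arabinan", "mannan")

#: plausible mass-closure band (%); records outside are flagged suspect
MASS_CLOSURE_BAND = (80.0, 105.0)


@dataclass
class CompositionRecord:
    """Mass fractions (% oven-dry mass) of one sample with derived aggregates."""

    glucan: float
    xylan: float
    galactan: float
    arabinan: float
    mannan: float
    asl: float
    ail: float
    extractives: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v!r} outside [0, 100] % of oven-dry mass")

    @property
    def hemicellulose(self) -> float:
        return self.xylan + self.galactan + self.arabinan + self.mannan

    @property
    def total_sugars(self) -> float:
        return self.glucan + self.hemicellulose

    @property
    def total_lignin(self) -> float:
        return self.asl + self.ail

    @property
    def mass_closure(self) -> float:
        return self.total_sugars + self.total_lignin + self.extractives

    @property
    def closure_suspect(self) -> bool:
        lo, hi = MASS_CLOSURE_BAND
        return not lo <= self.mass_closure <= hi

    def to_dict(self) -> dict:
        d = {"sample_id": self.sample_id}
        d.update({name: getattr(self, name) for name in COMPONENTS})
        d.update(
            hemicellulose=self.hemicellulose,
            total_sugars=self.total_sugars,
            total_lignin=self.total_lignin,
            mass_closure=self.mass_closure,
            closure_suspect=self.closure_suspect,
        )
        return d


@dataclass
class DensityRecord:
    """Oven-dry mass (g) and green volume (cm³) of one wood sample."""

    oven_dry_mass_g: float
    green_volume_cm3: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.oven_dry_mass_g > 0:
            raise ValueError("oven-dry mass must be positive")
        if not self.green_volume_cm3 > 0:
            raise ValueError("green volume must be positive")

    @property
    def specific_gravity(self) -> float:
        return wood_specific_gravity(self.oven_dry_mass_g, self.green_volume_cm3)


def anhydro_correct(monomer_mass_fraction, sugar_class: str):
    """Convert a monomeric sugar mass fraction (%) to polymer equivalent.

    ``sugar_class`` is ``"hexose"`` (glucose, galactose, mannose; ×0.90) or
    ``"pentose"`` (xylose, arabinose; ×0.88).
    """
    try:
        factor = ANHYDRO_FACTORS[sugar_class]
    except KeyError:
        raise ValueError(f"unknown sugar class {sugar_class!r}; expected 'hexose' or 'pentose'") from None
    x = np.asarray(monomer_mass_fraction, dtype=float)
    if np.any(x < 0):
        raise ValueError("mass fraction must be non-negative")
    out = x * factor
    return float(out) if np.isscalar(monomer_mass_fraction) else out


def aggregate(components: dict, sample_id: str = "") -> CompositionRecord:
    """Build a :class:`CompositionRecord` from raw component fractions.

    Raises a ``ValueError`` naming the first missing component.
    """
    missing = [c for c in COMPONENTS if c not in components]
    if missing:
        raise ValueError(f"missing composition component(s): {', '.join(missing)}")
    return CompositionRecord(sample_id=sample_id, **{c: float(components[c]) for c in COMPONENTS})


def aggregate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate every row of a composition table; derived columns appended.

    Column order of the result follows the conventional report layout:
    glucan, hemicellulose monomers, hemicellulose, total sugars, lignins,
    extractives, mass closure.
    """
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"]) if "sample_id" in df.columns else ""
        records.append(aggregate(row.to_dict(), sample_id=sid).to_dict())
    out = pd.DataFrame(records)
    order = [
        "sample_id",
        "glucan",
        "xylan",
        "galactan",
        "arabinan",
        "mannan",
        "hemicellulose",
        "total_sugars",
        "asl",
        "ail",
        "total_lignin",
        "extractives",
        "mass_closure",
        "closure_suspect",
    ]
    return out[order]


def wood_specific_gravity(oven_dry_mass_g: float, green_volume_cm3: float) -> float:
    """Wood specific gravity: oven-dry mass / green volume (g cm⁻³)."""
    if not oven_dry_mass_g > 0:
        raise ValueError("oven-dry mass must be positive")
    if not green_volume_cm3 > 0:
        raise ValueError("green volume must be positive")
    return oven_dry_mass_g / green_volume_cm3
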