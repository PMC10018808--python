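"""Synthetic double-stained stem cross-sections with known ground truth.

Emulates transverse sections of young willow stems as they appear after
safranin / chlorazol-black double staining under brightfield scanning:

* lignified cell walls -> red-dominant background within the section,
* vessel and fiber lumina -> near-white (unstained) discs,
* pith -> pale unstained central disc,
* tension wood (gelatinous-fiber regions) -> near-black angular sectors,
* distractor objects (elongated lacunae, thin ray lines) that force the
  downstream shape-based vessel classifier to do nontrivial work.

All geometry is sampled in physical units (µm) and rasterized at the very
end, so the same spec + seed yields the same anatomy at any pixel scale.
Each rendered section comes with an exact :class:`GroundTruth` record, and
cohorts pair each section with composition and wood-density records whose
glucan fraction depends linearly on the tension-wood fraction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .composition import COMPONENTS, CompositionRecord, aggregate

__all__ = [
    "DiameterLaw",
    "SectionSpec",
    "GroundTruth",
    "CompositionModel",
    "TreatmentSpec",
    "CohortSpec",
    "SectionRenderError",
    "sample_vessels",
    "render_section",
    "simulate_composition",
    "simulate_cohort_records",
    "generate_cohort",
    "default_cohort",
]

# stain palette (8-bit RGB)
COLOR_BACKGROUND = (250, 250, 248)
COLOR_WALL = (178, 34, 52)       # safranin-red lignified walls
COLOR_PITH = (246, 240, 232)     # pale, unstained parenchyma
COLOR_LUMEN = (255, 255, 255)    # open lumina
COLOR_TENSION = (24, 20, 22)     # chlorazol-black G-fiber regions


class SectionRenderError(RuntimeError):
    """Raised when a section cannot be sampled or rendered as specified."""


@dataclass(frozen=True)
class DiameterLaw:
    """Truncated log-normal law for vessel lumen diameters (µm).

    ``meanlog``/``sdlog`` parameterize the underlying log-normal; samples are
    restricted to ``[d_lo, d_hi)`` by inverse-CDF truncation (no rejection).
    """

    meanlog: float = float(np.log(35.0))
    sdlog: float = 0.26
    d_lo: float = 17.8
    d_hi: float = 61.8

    def __post_init__(self) -> None:
        if not 0 < self.d_lo < self.d_hi:
            raise ValueError("need 0 < d_lo < d_hi")
        if self.sdlog <= 0:
            raise ValueError("sdlog must be positive")

    def _cdf_bounds(self) -> tuple[float, float]:
        dist = sps.lognorm(s=self.sdlog, scale=np.exp(self.meanlog))
        return dist.cdf(self.d_lo), dist.cdf(self.d_hi)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        dist = sps.lognorm(s=self.sdlog, scale=np.exp(self.meanlog))
        lo, hi = self._cdf_bounds()
        u = rng.uniform(lo, hi, size=n)
        return dist.ppf(u)

    def mean(self) -> float:
        """Analytic mean of the truncated law.

        E[D | d_lo <= D < d_hi] = e^{mu+s^2/2} [Phi(b-s)-Phi(a-s)] / [Phi(b)-Phi(a)]
        with a,b the standardized log-bounds.
        """
        mu, s = self.meanlog, self.sdlog
        a = (np.log(self.d_lo) - mu) / s
        b = (np.log(self.d_hi) - mu) / s
        num = sps.norm.cdf(b - s) - sps.norm.cdf(a - s)
        den = sps.norm.cdf(b) - sps.norm.cdf(a)
        return float(np.exp(mu + s**2 / 2) * num / den)


@dataclass(frozen=True)
class SectionSpec:
    """Parameters of one synthetic stem section.

    Units: µm for lengths, vessels·mm⁻² / cells·mm⁻² for densities;
    ``tension_wood_fraction_target`` is a fraction of xylem area in [0, 1];
    ``noise_level`` is the σ of additive Gaussian pixel noise on [0, 1]
    intensities.  ``pixel_scale`` is µm per pixel (0.25 matches a 40×
    whole-slide scan; coarser scales render faster for the same anatomy).
    """

    section_radius: float = 280.0
    pith_radius: float = 50.0
    pixel_scale: float = 0.25
    vessel_density_target: float = 172.0
    diameter_law: DiameterLaw = field(default_factory=DiameterLaw)
    tension_wood_fraction_target: float = 0.276
    fiber_cell_density_target: float = 5800.0
    fiber_lumen_diameter: float = 5.0
    n_lacunae: int = 4
    n_ray_lines: int = 3
    noise_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pith_radius < self.section_radius:
            raise ValueError("need 0 <= pith_radius < section_radius")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.vessel_density_target < 0 or self.fiber_cell_density_target <= 0:
            raise ValueError("densities must be positive (vessel density may be 0)")
        if not 0 <= self.tension_wood_fraction_target <= 0.7:
            raise ValueError("tension_wood_fraction_target must be in [0, 0.7]")
        if not 0 <= self.noise_level < 0.3:
            raise ValueError("noise_level must be in [0, 0.3)")

    @property
    def xylem_area_um2(self) -> float:
        return float(np.pi * (self.section_radius**2 - self.pith_radius**2))


@dataclass
class GroundTruth:
    """Exact description of one rendered section.

    ``vessels`` holds (x_um, y_um, area_um2) per vessel with image origin at
    the top-left corner (x right, y down).  Mask areas are rasterized pixel
    counts converted to µm²; vessel areas are analytic disc areas.
    """

    vessels: list[tuple[float, float, float]]
    tension_wood_mask_area: float
    xylem_area: float
    pith_area: float
    cross_section_area: float
    fiber_count: int
    tension_wood_fraction_target: float
    pixel_scale: float

    @property
    def vessel_count(self) -> int:
        return len(self.vessels)

    @property
    def tension_wood_pct(self) -> float:
        return 100.0 * self.tension_wood_mask_area / self.xylem_area

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["vessels"] = [tuple(v) for v in d["vessels"]]
        return cls(**d)


@dataclass(frozen=True)
class CompositionModel:
    """Linear glucan response to tension wood plus noisy baselines.

    glucan(%) = intercept + slope · tw(%) + N(0, residual_sd); the other
    components are drawn around fixed baselines.  Defaults are calibrated by
    moment matching to the willow fertigation reference tables (glucan means
    33.9–39.5 % across tw means 27.6–39.8 %, within-group sd ≈ 3.8 %), which
    centres the cohort-level tw–glucan r² near 0.59.
    """

    intercept: float = 20.9
    slope: float = 0.46
    residual_sd: float = 3.8
    baselines: dict = field(
        default_factory=lambda: {
            "xylan": 12.6,
            "galactan": 1.3,
            "arabinan": 1.2,
            "mannan": 1.9,
            "asl": 5.2,
            "ail": 22.5,
            "extractives": 9.3,
        }
    )
    baseline_rel_sd: float = 0.12


@dataclass(frozen=True)
class TreatmentSpec:
    """One irrigation treatment: a section template plus replicate variation."""

    label: str
    section: SectionSpec
    tw_sd_pct: float = 8.0            # replicate-to-replicate sd of tension wood, %
    wood_density_mean: float = 0.37   # g cm^-3
    wood_density_sd: float = 0.035
    green_volume_mean_cm3: float = 2.0
    green_volume_sd_cm3: float = 0.3


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic experiment: treatments × replicates, one root seed."""

    treatments: tuple[TreatmentSpec, ...]
    replicates_per_treatment: int = 12
    composition_model: CompositionModel = field(default_factory=CompositionModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_treatment < 2:
            raise ValueError("need at least 2 replicates per treatment")
        if len(self.treatments) < 1:
            raise ValueError("need at least one treatment")


def default_cohort(
    seed: int = 0,
    replicates: int = 12,
    section_radius: float = 280.0,
    pith_radius: float = 50.0,
    pixel_scale: float = 0.5,
) -> CohortSpec:
    """Cohort spec mirroring the willow fertigation reference experiment.

    Three irrigation treatments (UI unirrigated, PW potable water, WWD
    primary wastewater) × 12 replicates; per-treatment vessel densities,
    mean diameters, tension-wood means and wood densities follow the
    published group means, with replicate sd = printed SE·√12.
    """
    base = dict(section_radius=section_radius, pith_radius=pith_radius, pixel_scale=pixel_scale)
    mk = lambda dens, dmed, tw, fibers: SectionSpec(
        vessel_density_target=dens,
        diameter_law=DiameterLaw(meanlog=float(np.log(dmed))),
        tension_wood_fraction_target=tw,
        fiber_cell_density_target=fibers,
        **base,
    )
    sq12 = float(np.sqrt(12))
    treatments = (
        TreatmentSpec("UI", mk(172.0, 35.0, 0.276, 5695.0), tw_sd_pct=2.4 * sq12,
                      wood_density_mean=0.37, wood_density_sd=0.01 * sq12),
        TreatmentSpec("PW", mk(173.0, 34.8, 0.341, 5756.0), tw_sd_pct=3.0 * sq12,
                      wood_density_mean=0.39, wood_density_sd=0.01 * sq12),
        TreatmentSpec("WWD", mk(152.0, 34.3, 0.398, 6243.0), tw_sd_pct=2.0 * sq12,
                      wood_density_mean=0.32, wood_density_sd=0.01 * sq12),
    )
    return CohortSpec(treatments=treatments, replicates_per_treatment=replicates, seed=seed)


def derive_seed(root_seed: int, *tokens) -> int:
    """Stable sub-seed from a root seed and arbitrary tokens (order-independent
    across sections: each (treatment, replicate) stream is self-contained)."""
    h = hashlib.sha256(repr((int(root_seed),) + tuple(tokens)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# vessel sampling


def sample_vessels(
    spec: SectionSpec,
    rng: np.random.Generator,
    max_attempts_per_vessel: int = 200,
) -> list[tuple[float, float, float]]:
    """Place non-overlapping vessel discs in the xylem annulus.

    Returns (x_um, y_um, diameter_um) triples; the count equals
    round(density_target × xylem area).  Placement is rejection sampling with
    a bounded attempt budget; an unplaceable density raises
    :class:`SectionRenderError` naming the density.
    """
    xylem_mm2 = spec.xylem_area_um2 / 1e6
    n_target = int(round(spec.vessel_density_target * xylem_mm2))
    if n_target == 0:
        return []
    diams = np.sort(spec.diameter_law.sample(rng, n_target))[::-1]  # big first packs better
    margin = 2.0 * spec.pixel_scale
    centers = np.empty((0, 2))
    radii = np.empty(0)
    placed: list[tuple[float, float, float]] = []
    cx = cy = spec.section_radius
    budget = max_attempts_per_vessel * n_target
    attempts = 0
    for d in diams:
        r = d / 2.0
        lo = spec.pith_radius + r + margin
        hi = spec.section_radius - r - margin
        if lo >= hi:
            raise SectionRenderError(
                f"vessel of diameter {d:.1f} µm does not fit the xylem annulus"
            )
        while True:
            attempts += 1
            if attempts > budget:
                raise SectionRenderError(
                    f"could not place {n_target} vessels at density "
                    f"{spec.vessel_density_target:g} mm^-2 within the attempt budget"
                )
            rad = np.sqrt(rng.uniform(lo**2, hi**2))
            theta = rng.uniform(0, 2 * np.pi)
            x, y = cx + rad * np.cos(theta), cy + rad * np.sin(theta)
            if centers.shape[0]:
                dist = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
                if np.any(dist < radii + r + margin):
                    continue
            centers = np.vstack([centers, (x, y)])
            radii = np.append(radii, r)
            placed.append((float(x), float(y), float(d)))
            break
    return placed


# ---------------------------------------------------------------------------
# rendering helpers


def _paint_disc(mask: np.ndarray, x: float, y: float, r: float, scale: float) -> None:
    """Set pixels whose centers fall within the disc (coordinates in µm)."""
    n_rows, n_cols = mask.shape
    c0 = max(int((x - r) / scale) - 1, 0)
    c1 = min(int((x + r) / scale) + 2, n_cols)
    r0 = max(int((y - r) / scale) - 1, 0)
    r1 = min(int((y + r) / scale) + 2, n_rows)
    if c0 >= c1 or r0 >= r1:
        return
    cols = (np.arange(c0, c1) + 0.5) * scale
    rows = (np.arange(r0, r1) + 0.5) * scale
    dx = cols[None, :] - x
    dy = rows[:, None] - y
    mask[r0:r1, c0:c1] |= dx**2 + dy**2 <= r**2


def _paint_rot_ellipse(mask, x, y, a, b, phi, scale):
    """Filled rotated ellipse, semi-axes a,b (µm), orientation phi."""
    n_rows, n_cols = mask.shape
    rr = max(a, b)
    c0 = max(int((x - rr) / scale) - 1, 0)
    c1 = min(int((x + rr) / scale) + 2, n_cols)
    r0 = max(int((y - rr) / scale) - 1, 0)
    r1 = min(int((y + rr) / scale) + 2, n_rows)
    if c0 >= c1 or r0 >= r1:
        return
    cols = (np.arange(c0, c1) + 0.5) * scale
    rows = (np.arange(r0, r1) + 0.5) * scale
    dx = cols[None, :] - x
    dy = rows[:, None] - y
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    mask[r0:r1, c0:c1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_section(
    spec: SectionSpec, max_pixels: int = 200_000_000
) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize one section; deterministic for a fixed spec (incl. seed).

    Returns an 8-bit RGB image of side ``ceil(2·section_radius/pixel_scale)``
    and the exact ground truth.  A request exceeding ``max_pixels`` raises
    :class:`SectionRenderError` advising tile-wise rendering at a coarser
    scale.
    """
    scale = spec.pixel_scale
    n = int(np.ceil(2 * spec.section_radius / scale))
    if n * n > max_pixels:
        raise SectionRenderError(
            f"{n}×{n} pixels exceeds the {max_pixels:,} pixel budget; render "
            "at a coarser pixel_scale or process the section as tiles"
        )
    rng = np.random.default_rng(spec.seed)
    cx = cy = spec.section_radius

    cols = (np.arange(n) + 0.5) * scale
    dx = cols[None, :] - cx
    dy = cols[:, None] - cy
    rho2 = dx**2 + dy**2
    section = rho2 <= spec.section_radius**2
    pith = rho2 <= spec.pith_radius**2 if spec.pith_radius > 0 else np.zeros_like(section)
    xylem = section & ~pith

    vessels = sample_vessels(spec, rng)
    lumen = np.zeros_like(section)
    for x, y, d in vessels:
        _paint_disc(lumen, x, y, d / 2, scale)

    # distractors: elongated lacunae + thin ray lines, kept clear of vessels
    distract = np.zeros_like(section)
    v_xy = np.array([(x, y) for x, y, _ in vessels]) if vessels else np.empty((0, 2))
    v_r = np.array([d / 2 for _, _, d in vessels]) if vessels else np.empty(0)

    def _clear_of_vessels(x, y, reach):
        if not v_xy.shape[0]:
            return True
        return bool(np.all(np.hypot(v_xy[:, 0] - x, v_xy[:, 1] - y) > v_r + reach))

    for _ in range(spec.n_lacunae):
        for _attempt in range(100):
            a = rng.uniform(30.0, 60.0)   # semi-major, µm
            b = rng.uniform(3.0, 6.0)     # semi-minor -> roundness ~ b/a << threshold
            rad = np.sqrt(rng.uniform((spec.pith_radius + a) ** 2, max((spec.section_radius - a - 5) ** 2, (spec.pith_radius + a + 1) ** 2)))
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + rad * np.cos(th), cy + rad * np.sin(th)
            if _clear_of_vessels(x, y, a + 4 * scale):
                _paint_rot_ellipse(distract, x, y, a, b, rng.uniform(0, np.pi), scale)
                break
    for _ in range(spec.n_ray_lines):
        for _attempt in range(100):
            half_len = rng.uniform(50.0, 90.0)
            rad = np.sqrt(rng.uniform((spec.pith_radius + half_len) ** 2, max((spec.section_radius - half_len - 5) ** 2, (spec.pith_radius + half_len + 1) ** 2)))
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + rad * np.cos(th), cy + rad * np.sin(th)
            if _clear_of_vessels(x, y, half_len + 4 * scale):
                # radial orientation, like a parenchyma ray
                _paint_rot_ellipse(distract, x, y, half_len, 1.8, th, scale)
                break
    distract &= xylem & ~lumen

    # tension wood: angular sector of the xylem, painted black except lumina
    # and distractors; the sector angle is chosen on the realized raster so
    # the black-pixel share of xylem hits the target almost exactly.
    tension = np.zeros_like(section)
    xylem_px = int(xylem.sum())
    if spec.tension_wood_fraction_target > 0 and xylem_px:
        eligible = xylem & ~lumen & ~distract
        start = rng.uniform(0, 2 * np.pi)
        ang = (np.arctan2(dy, dx) - start) % (2 * np.pi)
        target_px = spec.tension_wood_fraction_target * xylem_px
        elig_ang = np.sort(ang[eligible])
        k = min(int(round(target_px)), elig_ang.size - 1)
        if k > 0:
            theta = elig_ang[k]
            tension = eligible & (ang <= theta)

    # fibers: jittered hex-like grid of small lumina outside tension wood
    fiber_r = spec.fiber_lumen_diameter / 2.0
    pitch = 1000.0 / np.sqrt(spec.fiber_cell_density_target)  # µm between cells
    jitter = max(pitch - 2 * fiber_r - 2 * scale, 0.0) / 2.0
    gx = np.arange(pitch / 2, 2 * spec.section_radius, pitch)
    gy = np.arange(pitch / 2, 2 * spec.section_radius, pitch * np.sqrt(3) / 2)
    fx, fy = np.meshgrid(gx, gy)
    fx = fx + (np.arange(gy.size) % 2)[:, None] * pitch / 2  # hex offset
    fx = fx.ravel() + rng.uniform(-jitter, jitter, fx.size)
    fy = fy.ravel() + rng.uniform(-jitter, jitter, fy.size)
    rad2 = (fx - cx) ** 2 + (fy - cy) ** 2
    keep = (rad2 < (spec.section_radius - fiber_r - 2 * scale) ** 2) & (
        rad2 > (spec.pith_radius + fiber_r + 2 * scale) ** 2
    )
    fx, fy = fx[keep], fy[keep]
    if v_xy.shape[0] and fx.size:
        # drop fiber cells too close to any vessel
        from scipy.spatial import cKDTree

        tree = cKDTree(v_xy)
        reach = float(v_r.max()) + fiber_r + 2 * scale
        near = tree.query_ball_point(np.column_stack([fx, fy]), r=reach)
        ok = np.array(
            [
                all(np.hypot(fx[i] - v_xy[j, 0], fy[i] - v_xy[j, 1]) > v_r[j] + fiber_r + 2 * scale for j in js)
                for i, js in enumerate(near)
            ]
        )
        fx, fy = fx[ok], fy[ok]
    fiber = np.zeros_like(section)
    fiber_count = 0
    for x, y in zip(fx, fy):
        ix, iy = int(y / scale), int(x / scale)
        if 0 <= ix < n and 0 <= iy < n and tension[ix, iy]:
            continue  # G-layer fills fiber lumina inside tension wood
        if distract[min(max(ix, 0), n - 1), min(max(iy, 0), n - 1)]:
            continue
        _paint_disc(fiber, x, y, fiber_r, scale)
        fiber_count += 1
    fiber &= xylem & ~tension & ~distract & ~lumen

    # compose image
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = COLOR_BACKGROUND
    img[section] = COLOR_WALL
    if spec.pith_radius > 0:
        img[pith] = COLOR_PITH
    img[tension] = COLOR_TENSION
    img[lumen & xylem] = COLOR_LUMEN
    img[fiber] = COLOR_LUMEN
    img[distract] = COLOR_LUMEN
    if spec.noise_level > 0:
        img += rng.normal(0.0, spec.noise_level * 255.0, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    um2 = scale * scale
    truth = GroundTruth(
        vessels=[(x, y, float(np.pi * (d / 2) ** 2)) for x, y, d in vessels],
        tension_wood_mask_area=float(tension.sum() * um2),
        xylem_area=float(xylem.sum() * um2),
        pith_area=float(pith.sum() * um2),
        cross_section_area=float(section.sum() * um2),
        fiber_count=fiber_count,
        tension_wood_fraction_target=spec.tension_wood_fraction_target,
        pixel_scale=scale,
    )
    return img, truth


# ---------------------------------------------------------------------------
# composition + cohort simulation


def simulate_composition(
    tw_fraction_pct: float,
    model: CompositionModel,
    rng: np.random.Generator,
    sample_id: str = "",
    max_resample: int = 10,
) -> CompositionRecord:
    """Draw one composition record given a tension-wood percentage.

    glucan follows the model line plus Gaussian noise; other components are
    drawn around their baselines.  Fractions falling outside [0, 100] are
    resampled up to ``max_resample`` times, then an error is raised.
    """
    if not 0.0 <= tw_fraction_pct <= 100.0:
        raise ValueError("tension-wood fraction must be in [0, 100] %")

    def _draw(mean: float, sd: float) -> float:
        for _ in range(max_resample):
            v = rng.normal(mean, sd)
            if 0.0 <= v <= 100.0:
                return float(v)
        raise SectionRenderError(
            f"could not draw a fraction in [0,100] around {mean:g} ± {sd:g}"
        )

    comp = {"glucan": _draw(model.intercept + model.slope * tw_fraction_pct, model.residual_sd)}
    for name, base in model.baselines.items():
        comp[name] = _draw(base, model.baseline_rel_sd * base)
    missing = [c for c in COMPONENTS if c not in comp]
    if missing:
        raise ValueError(f"composition model lacks baselines for: {missing}")
    return aggregate(comp, sample_id=sample_id)


def simulate_cohort_records(cohort: CohortSpec) -> pd.DataFrame:
    """Per-replicate tension wood, composition and density records (no images).

    The same derived random streams drive :func:`generate_cohort`, so this is
    the fast path for statistical calibration work.  Returns one row per
    sample with tw_pct, the eight composition components, oven-dry mass and
    green volume.
    """
    rows = []
    for tr in cohort.treatments:
        tw_mean = 100.0 * tr.section.tension_wood_fraction_target
        for rep in range(1, cohort.replicates_per_treatment + 1):
            sid = f"{tr.label}-{rep:02d}"
            rng = np.random.default_rng(derive_seed(cohort.seed, tr.label, rep, "records"))
            tw = float(np.clip(rng.normal(tw_mean, tr.tw_sd_pct), 0.0, 65.0))
            rec = simulate_composition(tw, cohort.composition_model, rng, sample_id=sid)
            volume = max(float(rng.normal(tr.green_volume_mean_cm3, tr.green_volume_sd_cm3)), 0.2)
            sg = max(float(rng.normal(tr.wood_density_mean, tr.wood_density_sd)), 0.05)
            row = {
                "sample_id": sid,
                "treatment": tr.label,
                "replicate": rep,
                "tw_pct": tw,
                "section_seed": derive_seed(cohort.seed, tr.label, rep, "section"),
                "green_volume_cm3": volume,
                "oven_dry_mass_g": sg * volume,
            }
            row.update({c: getattr(rec, c) for c in COMPONENTS})
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    cohort: CohortSpec,
    out_dir,
    overwrite: bool = False,
    image_format: str = "png",
) -> Path:
    """Write a full synthetic dataset directory.

    Layout: ``images/<sample>.png`` (or .tif with resolution metadata),
    ``ground_truth.json``, ``composition.csv``, ``density.csv``,
    ``design.csv`` and ``manifest.yaml`` (records the seed and the cohort
    configuration).  Refuses to write into an existing non-empty directory
    unless ``overwrite`` is set.
    """
    from .slide_io import write_image  # local import to avoid cycle at import time

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (pass overwrite=True)")
    (out / "images").mkdir(parents=True, exist_ok=True)

    records = simulate_cohort_records(cohort)
    truths: dict[str, dict] = {}
    design_rows = []
    by_label = {tr.label: tr for tr in cohort.treatments}
    for _, row in records.iterrows():
        tr = by_label[row["treatment"]]
        spec = replace(
            tr.section,
            tension_wood_fraction_target=float(np.clip(row["tw_pct"] / 100.0, 0.0, 0.7)),
            seed=int(row["section_seed"]),
        )
        img, truth = render_section(spec)
        ext = "tif" if image_format in ("tif", "tiff") else "png"
        write_image(out / "images" / f"{row['sample_id']}.{ext}", img, spec.pixel_scale)
        truths[row["sample_id"]] = truth.to_dict()
        design_rows.append(
            {"sample_id": row["sample_id"], "treatment": row["treatment"], "replicate": int(row["replicate"])}
        )

    (out / "ground_truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))
    records[["sample_id"] + list(COMPONENTS)].to_csv(out / "composition.csv", index=False)
    records[["sample_id", "oven_dry_mass_g", "green_volume_cm3"]].to_csv(out / "density.csv", index=False)
    pd.DataFrame(design_rows).to_csv(out / "design.csv", index=False)
    manifest = {
        "seed": int(cohort.seed),
        "replicates_per_treatment": int(cohort.replicates_per_treatment),
        "treatments": [tr.label for tr in cohort.treatments],
        "image_format": image_format,
        "pixel_scale_um": [tr.section.pixel_scale for tr in cohort.treatments],
        "n_samples": len(design_rows),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out
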