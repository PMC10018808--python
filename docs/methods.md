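# Methods

## Scope and model

The package analyses transverse stem sections of woody stems after double
staining: safranin O colours lignified cell walls red, chlorazol black E
colours cellulose-rich gelatinous (G) fiber layers near-black, and open
lumina stay unstained (near-white). Three measurement layers sit on top of
the segmentation:

1. **Hydraulic traits.** Water transport in xylem conduits is modelled as
   laminar Hagen–Poiseuille flow: a conduit of lumen diameter `D` (the
   diameter of the circle with the measured lumen area, `D = √(4A/π)`)
   conducts in proportion to `D⁴`. The section-level theoretical
   conductivity is `K_h = (πρ/128η)·ΣD⁴` with water density
   ρ = 998 kg m⁻³ and dynamic viscosity η = 10⁻⁹ MPa s (20 °C); diameters
   are converted to metres internally so `K_h` carries kg m MPa⁻¹ s⁻¹ and
   `K_S = K_h / xylem area (m²)` carries kg m⁻¹ MPa⁻¹ s⁻¹. The model
   ignores end-wall resistance, conduit length and taper; it is the
   standard *theoretical* capacity measure, not an empirical conductance.
2. **Diameter classes.** Vessel density and `K_S` are decomposed into
   half-open 10-µm classes [10–20) … [60–70) µm (`a ≤ D < b`). Vessels
   outside the edge range are never dropped; they go to flagged
   underflow/overflow rows with a warning. Class frequencies and `K_S`
   contributions each sum to 100 % by construction (partition identities,
   property-tested).
3. **Composition.** Sugar assays report monomers; polymer-equivalent
   fractions remove the water of hydrolysis (hexoses ×162/180 = 0.90,
   pentoses ×132/150 = 0.88). Aggregates: hemicellulose = xylan + galactan
   + arabinan + mannan; total sugars = glucan + hemicellulose; total lignin
   = ASL + AIL; mass closure = sugars + lignin + extractives. Closures
   outside [80, 105] % are flagged suspect, not rejected. Sums use
   unrounded components; rounding happens at display.

## Segmentation procedure

* **Stain split.** Lignin channel = red dominance `max(R − max(G,B), 0)/255`;
  cellulose/G-layer channel = darkness `1 − max(R,G,B)/255`. Both in [0, 1].
* **Geometry.** Stained pixels (lignin > 0.08 or darkness > 0.35) form the
  foreground; the largest connected component with holes filled is the
  cross-section. The pith is the unstained component containing the section
  centroid, accepted only above 5000 µm² so a central vessel lumen cannot
  masquerade as pith (vessel lumina stay below ~3000 µm²); a manual pith
  mask overrides detection for irregular real pith. Xylem = cross-section −
  pith.
* **Lumen detection.** Pixels with min-RGB brightness ≥ 190 (or Otsu)
  inside the xylem mask, 8-connected components, per-object hole filling,
  objects under 4 px discarded as noise. Objects touching the image border
  are flagged `border_clipped` and excluded from the vessel table by
  default (their area is understated); the policy is configurable.
* **Descriptors.** Circularity `4πA/P²` and roundness `4A/(π·major²)`,
  clipped to 1. The perimeter is the marching-squares contour length of the
  object mask. This estimator was chosen over pixel-edge counting and
  Crofton formulas because it satisfies both anchor properties: an
  axis-aligned square yields circularity ≈ π/4 (0.795 at 50 px) and
  rasterized discs ≥ 20 px yield ≥ 0.85. The perimeter estimator is the
  single biggest source of descriptor variance; thresholds were set with
  this estimator and should be re-tuned if it is swapped.
* **Classification.** Vessel iff area ∈ [250, 3000] µm² and circularity ≥
  0.5 and roundness ≥ 0.4; everything else is fiber-or-ray. The area window
  is anchored to the extreme vessel lumen areas of the reference dataset
  (250.015 and 2999.9 µm², i.e. D of 17.8–61.8 µm); the shape thresholds are
  this package's defaults, chosen to sit far below rasterized-disc values
  (≥ 0.85) and far above elongated lacunae/ray lines (≤ ~0.2), and all are
  exposed in `SegmentationParams`.
* **Tension wood.** 100 × (xylem pixels with darkness ≥ 0.5) / (xylem
  pixels). Monotone nonincreasing in the threshold; an Otsu option exists
  for real slides with stain-batch variation.
* **Tiling.** Default tiles of 2048 px with 128 px overlap (≥ 61.8 µm at
  0.25 µm/px, the largest expected vessel diameter, so every vessel lies
  wholly inside at least one tile). Objects clipped at interior tile
  borders are dropped; duplicates across overlaps are merged by centroid
  proximity (default 2 µm), keeping the larger-area instance. With overlap
  ≥ the largest object diameter, tiled and whole-image processing give
  identical vessel counts, areas and `K_S` (tested exactly).

Per-section anatomy reports vessel lumen % of xylem and defines the
fiber+ray proportion as the *non-vessel-lumen* share of xylem (tissue
including walls, 100 − vessel %): this is the only reading under which the
published vessel:fiber area ratios are internally consistent with the
printed vessel and fiber percentages, and it is what the vessel:fiber area
ratio divides by.

## Synthetic generator

The generator emulates what the analysis assumes, not histology:

* Geometry is sampled in µm and rasterized last, so anatomy is invariant to
  pixel scale (property-tested: areas shift < 5 % between 0.5 and 1.0
  µm/px). A cohort is a pure function of its spec including the root seed;
  per-section streams derive from SHA-256 of (seed, treatment, replicate),
  making generation order-independent.
* Vessels are non-overlapping discs with truncated log-normal diameters
  (inverse-CDF truncation; analytic truncated mean is unit-tested against
  numerical integration). Default law: median 35 µm, σ_log 0.26, truncated
  to [17.8, 61.8] µm, matching the reference D̄ ≈ 36 µm and K_S ≈ 9–11.
  Placement is rejection sampling with a bounded budget; the count equals
  round(density × xylem area).
* Tension wood is an angular sector of the xylem painted black except
  lumina; the sector angle is chosen on the realized raster (quantile of
  eligible-pixel angles) so the black share of xylem hits the target to
  sub-0.1 points before noise. Fiber lumina inside the sector are omitted —
  the G-layer fills them — so realized fiber counts are below the nominal
  fiber density; the ground truth records the rendered count.
* Distractors (4 elongated lacunae with roundness ≈ 0.1, 3 radial ray
  lines) are unstained objects in the vessel-area range that must be
  rejected by the shape thresholds.
* Default cohort: 3 treatments × 12 replicates mirroring the reference
  experiment — vessel densities 172/173/152 mm⁻², tension-wood means
  27.6/34.1/39.8 % with replicate SD = printed SE·√12, wood densities
  0.37/0.39/0.32 g cm⁻³. Glucan follows
  `glucan = 20.9 + 0.46·tw + N(0, 3.8)` (slope from the ratio of glucan to
  tension-wood group-mean spans; residual SD from the printed within-group
  variability), which centres the cohort-level tw–glucan r² at ≈ 0.59.
  Other components vary around fixed baselines with 12 % relative SD.
* Sections default to radius 280 µm with pith 50 µm at 0.5 µm/px in cohort
  work (test fixtures go smaller). Real stems are 9–10 mm across; the
  scaled-down sections keep all densities and fractions at their real
  per-area values, so trait recovery is exercised at identical intensities,
  only with fewer objects per section.

What passing tests on synthetic data do **not** show: robustness to uneven
staining, debris, torn sections, out-of-focus tiles, elliptical or
collapsed vessels, or growth-ring structure. Vessels are ideal circles
(roundness of true objects ≈ 1), so the classifier's shape thresholds are
stressed only by the injected distractors.

## Statistics

One-way ANOVA (scipy; equal to the brute-force sums-of-squares
decomposition to 1e-10 relative, enforced by test) with groups of n ≥ 2;
identical-values input returns F = 0 by convention. Tukey HSD uses the
studentized range with the Tukey–Kramer adjustment for unbalanced groups.
Compact letters come from the insert-and-absorb algorithm ordered by
descending group mean; coherence (two groups share a letter iff their
pairwise test is non-significant) is property-tested over random instances.
SE is always sd/√n; single-section groups report SE as missing, never 0.
Pearson matrices use pairwise-complete cases (≥ 3) and report constant
columns as missing. p-values are not adjusted across traits; the report
notes this in its run log.

## Numerical choices and degenerate inputs

* All internal hydraulic computation in SI; µm/mm² only at I/O boundaries
  (conversion factors unit-tested).
* `D = 20.0` µm falls in [20–30): bins use `np.digitize(right=False)`.
* Empty vessel list: `K_h = 0` with a warning; empty vessel *table* for
  summaries is an error; zero xylem area is an error.
* Zero fiber count makes vessel:fiber ratios missing (NaN), not 0.
* TIFF pixel scale: CENTIMETER resolution unit → 1e4/res µm/px; unit NONE
  is read as px/µm (the convention this package writes); inch units and
  missing scales are explicit errors — never a silent default.
* Renders beyond the pixel budget (default 2×10⁸) fail with advice to use
  tiles or a coarser scale rather than exhausting memory.

## Known limitations

* The regression-calibration example band (r² ∈ [0.44, 0.74] at n = 36) is
  met by the mean over seeds, but no calibration centred near 0.59 can put
  ≥ 90 % of individual cohorts in that band: the sampling SD of r̂² at
  n = 36 is ≈ 2r(1−r²)/√n ≈ 0.105, so ≈ 15 % of cohorts fall outside ±0.15
  regardless of parameter choice. Tests assert the mean-in-band and an
  80 % per-cohort fraction, which simulation shows is attainable.
* Supplementary-convention indices (F, NF, VI, S, DH) follow the common
  quantitative-wood-anatomy definitions and are labelled as such in output;
  DH is the quartic mean (ΣD⁴/n)^¼, which satisfies DH ≥ D̄.
* Springwood/summerwood rings are not separated, fiber wall thickness is
  not measured, and no conduit-length correction is applied to K_h.
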