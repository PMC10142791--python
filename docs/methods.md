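# Methods

This note records the models, parameter choices and numerical decisions
behind prokmorph, and what the synthetic validation does and does not
establish about real micrographs.

## Dimension distributions

Published morphometric tables give, per cruise and morphotype, the mean, sd,
minimum and maximum of cell length and width. The printed minima sit at the
optical resolution floor (~3 px ≈ 0.3 µm for round cells), so we model each
dimension as a **lognormal with its location offset at the printed minimum**,
right-truncated at the printed maximum, with (µ, σ) fit numerically so the
truncated distribution reproduces the printed mean and sd exactly. A plain
lognormal truncated to the printed [min, max] cannot, in general, attain the
printed moments: for the winter cocci (0.40 ± 0.09 µm on [0.32, 0.95]) the
attainable truncated-moment set of that family excludes (0.40, 0.09) in any
well-conditioned parameter region, and moment-matching the *untruncated* law
instead yields a truncated mean of 0.426 µm and a mean volume of 0.045 µm³ —
visibly inconsistent with the published 0.039 µm³. The offset parameterisation
resolves this while keeping positivity and right skew. Sampling is by inverse
CDF, so fixed seeds give byte-identical tables.

Two printed rows are internally inconsistent and handled explicitly:

- BANSIC-2013 curved rods print W min/max of 0.53/3.59 µm — a duplicate of
  the L column that contradicts the printed W mean (0.35). We substitute the
  neighbouring BANSIC-2013 rods' W range [0.15, 0.65] µm.
- BANSIC-2013 filamentous W prints 0.24 ± 0.012 on [0.21, 0.24]: a mean equal
  to the maximum with nonzero sd is unrealisable; the fit is best-effort
  least squares (achieving 0.221 ± 0.009) and the achieved moments are
  recorded on the distribution object.

## Joint (L, W) sampling and class consistency

Drawing L and W independently would generate, e.g., "coccobacilli" with
L ≥ 2W — cells that are rods by definition. Since the published classes are
*defined* by the L/W rules, the generator draws L from its marginal and then
W conditionally on the class-defining inequality (coccobacilli:
L/2 < W ≤ L − 0.10; rods: W ≤ L/2; cocci: W = L). The L marginals stay exact
(within 0.6% at n = 10⁵); the W marginals are compressed by up to ~10% for
rods and vibrios, which we accept as the cost of internal consistency — both
properties are asserted in the test suite at these tolerances. For strongly
curved cells the width is additionally capped so the bent capsule keeps an
open lumen (curvature radius ≥ width, C-shape end gap ≥ 1.5 widths); beyond
that cap a cell is geometrically a blob no microscope could score as a
vibrio.

Ground-truth arc turning is uniform on (15°, 90°] for curved rods, (90°,
270°] for C-shaped vibrios and (120°, 270°] for S-shaped spirillae (split
over two opposite arcs); straight classes turn 0°. Morphotype fractions are
not published; the defaults fix %rods/%cocci at the published morphological
index per cruise (0.5, 0.9, 0.44), weight coccobacilli at 0.8 of cocci, and
give the minor classes small fixed weights (curved rods 0.25, vibrios 0.08,
spirillae 0.05, filamentous 0.04, zeroed where the table marks a class
absent). Densities default to 1.2/0.8/1.0 × 10⁶ cells mL⁻¹, preserving the
published ordering of the three cruises at the published order of magnitude.
Environmental covariates are truncated normals with the published per-cruise
mean/sd/range; depth, which has no published distribution, is uniform on
0–100 m.

## Rendering

Cells are constant-width capsules around a centerline (segment, single arc,
or two opposite arcs), placed uniformly at random with a hard no-overlap
constraint (rejection sampling against a KD-tree of densified centerlines,
0.4 µm minimum gap, 10 px border margin). Pixel coverage is computed
analytically from the distance to the centerline with a linear
anti-aliasing ramp; the field is convolved with a Gaussian PSF and Gaussian
camera noise is added on a constant background. Defaults: 1300 × 1030 px,
0.106 µm/px, signal 1000, background 100, noise sd 50 (5% of signal).

The PSF default is σ = 0.1 µm. For a 100×/NA ≈ 1.3 objective at DAPI
emission (~460 nm) the Airy-derived Gaussian σ ≈ 0.21 λ/NA ≈ 0.08–0.1 µm; a
broader blur (σ = 0.2 µm) would make sub-0.3 µm-wide cells unmeasurable,
which contradicts the fact that the original operators measured widths down
to 0.11 µm. Calibration bead fields (monosized 2.13 µm discs) are rendered
by the same code path.

The renderer deliberately omits cell clumping, uneven filtration, defocus
and photobleaching. Closure results below therefore certify the measurement
algorithms on well-separated, in-focus cells only — on real fields with
touching cells or haloes the pipeline's accuracy is not established, and the
border/size discharge rules stand in for the original operator's judgment.

## Measurement

Segmentation is a global Otsu threshold followed by a 3×3 binary closing and
8-connected labelling; regions under 4 px or within 1 px of the image border
are flagged and excluded. When foreground is so sparse that Otsu lands
inside the background noise (threshold below median + 5·1.4826·MAD), the
robust background floor replaces it; a pure-noise image therefore yields no
regions.

Per region: the skeleton (scikit-image) is reduced to its longest geodesic
path (double Dijkstra over 8-neighbours); width = 2 × mean medial-axis
distance along the path − 1 px (half-pixel discretisation); length =
geodesic length + width (caps included). Regions whose geodesic length is
under half the equivalent-circle diameter are round: L = W = equivalent
diameter. Bead calibration rescales L and W so mean measured bead diameter
equals the true 2.13 µm.

Curvature is a small decision tree, because no single estimator spans 0–270°
at this resolution:

1. Regions with skeleton shorter than 1.5 widths are too compact for
   curvature to be resolved and report 0° (straight).
2. Skeleton chord offsets ≥ 0.6 px on *both* sides, with both halves
   circle-fitting to ≥ 10° of opposite turning, are an S (inflection = 1;
   turning = sum of the halves' Kasa circle fits).
3. A one-sided sagitta above 20% of the arc length is a strong bend: turning
   = arc length / radius from a Kasa circle fit to the (σ = 2 px smoothed)
   skeleton path — well-behaved past 180°, where any single-frame centerline
   function is multivalued.
4. Otherwise the region is straight-to-gently-curved, the regime where
   skeleton quantisation (±0.5 px) swamps the signal: the centerline is
   re-estimated at sub-pixel precision as the intensity-weighted mean
   transverse offset per unit-length bin along the chord (cap bins within
   0.35 widths of the ends trimmed, since cap pixels flatten curvature). A
   two-sided swing of these samples about their end-to-end chord (≥ 0.35 px
   both sides, quadratic halves ≥ 12°) is a gentle S; else a weighted
   quadratic fit gives κ, reported only when its coefficient exceeds 2
   standard errors — straight cells report exactly 0°. A 15° turn needs
   ≥ 6 px of usable centerline to clear the sampling floor; shorter spans
   report 0.

Shape classes then follow the operational thresholds: S = inflection with
≥ 15° total turning; C = no inflection, > 90°; curved = (15°, 90°];
straight otherwise. The 15° floor and the 90° C-boundary are operational
constants (the source rules are qualitative) and are arguments of
`classify_curvature`.

Validated closure, rendered truth vs. measurement, three cruises × 400–500
cells × three seeds: segmentation retains exactly the rendered cells;
per-morphotype mean L and W agree within 2 px (typically < 1 px) noise-free
and within the max(5%, 2 px) quantisation floor at default noise; curvature
class agreement is 95–99% both noise-free and at default noise. The
residual disagreements are physically marginal cells: near-boundary turning
angles (≈ 15° or ≈ 90°), and short wide cells whose sagitta never exceeds
quantisation.

## Traits and statistics

The morphotype classifier applies the rules in a fixed precedence
(filament → S → C → curved → rod → coccus → coccobacillus) with strict/
non-strict boundaries chosen once: L − W = 0.10 µm is a coccobacillus,
L = 2W a rod, L = 4.0 µm not filamentous. The filament test precedes
curvature so a 5 µm bent cell is filamentous. An exhaustive grid test pins
the whole decision table against an independently coded oracle.

Volume uses V = (π/4)W²(L − W/3); carbon defaults to the flat 350 fg C µm⁻³
conversion (which reproduces the published 14 fg C cell⁻¹ for winter cocci)
with the allometric 218·V^0.86 alternative available; biomass is
PA × mean CCC × 10⁻⁶. Volume size classes are uniform 0.03 µm³ bins between
0.02 and 0.20 µm³, open-topped — the published class labels (0.02–0.049,
0.05–0.079, > 0.20) fix the first edges and we interpolate the rest; length
classes are 0.4 µm wide from zero.

Shannon H′ defaults to bits (base 2, configurable): with at most seven
morphotypes H′ ≤ log₂7 ≈ 2.81, so the published per-station range reaching
3.22 must involve a finer category set (e.g. morphotype × size class); the
index is therefore generic over categories. Kruskal–Wallis uses the
tie-corrected H with a χ² reference (scipy) or an exact enumeration of
group assignments for total n ≤ 12. PCA operates on log10(x+1)-transformed,
standardised variables via SVD; component signs are fixed by making each
component's largest-magnitude loading positive, and cos² (squared scaled
loadings) is reported per variable. Rows with missing values are dropped
with a logged warning; constant columns under standardisation are an error
(the pipeline driver pre-drops them with a warning, since PA is constant
within a cruise by construction).

## Pipeline

`run_pipeline` splits each cruise into stations, attaches one environmental
record per station, optionally routes cells through render → segment →
measure with bead calibration, classifies, summarises per station, and runs
the cross-cruise Kruskal–Wallis on volume plus the station-level PCA.
Default problem sizes (2000 cells/cruise over 5 stations) keep a full run
under a second while every statistic is already stable; the acceptance
script uses 2 × 10⁵ cells for the Monte-Carlo volume so its sampling error
(≈ 1.3 × 10⁻⁴ µm³) is far inside the ±0.002 µm³ band. All outputs are plain
CSV/JSON stamped with the seed and a configuration hash; identical
configurations are byte-identical.

## Known limitations

- The generator's W marginals for aspect-constrained classes deviate from
  the printed summaries by up to ~10% (see above); per-cruise *total*-cell
  summaries are emergent and only approximately match the printed totals.
- Overlapping or border-truncated cells are discarded, not declumped; the
  abundance estimator assumes Poisson-like field counts and does not model
  filtration heterogeneity.
- The published H′ range and the exact Kruskal–Wallis variable set are not
  recoverable; the pipeline reports its own H′ (bits, morphotype counts)
  and volume contrast instead.
- Filamentous cells shorter than 4 µm (present in the BANSIC-2013 table)
  classify as rods under the operational rules — a divergence internal to
  the source material, kept visible rather than patched.
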