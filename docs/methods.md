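# Methods

## Scope and model

`seedshape` describes and quantifies two-dimensional seed outlines by
comparison with geometric model curves, the approach used in seed
morphometry of the Cactaceae and related groups. Four curve families are
implemented:

1. **Superellipses** `|x/a|^p + |y/b|^p = 1`, `p > 0`. With `p = 2` this is
   an ellipse; `p > 2` gives the squarish symmetric outlines of *Rebutia*
   seeds. Published parameter sets are shipped as presets
   (e.g. `REBUTIA_HELIOSA`: `p = 2.3, a = 1.5, b = 2`).
2. **Paired semi-ellipses** for symmetric, non-convex seeds with a straight
   hilum-side section (*Echinopsis*-type). Upper and lower lobes share the
   x-semi-axis `a` but have independent vertical semi-axes; the lower lobe
   is blended linearly (weight `flat_depth`, in `[0, 1)`) toward the chord
   `y = -b_lo(1 - flat_depth)`, so the lobe depth at `x = 0` is
   `b_lo(1 - flat_depth²)` and the hilum cup flattens continuously.
   The three `ECHINOPSIS_*` presets are approximate profiles kept as
   configuration data, not published equations (the source equations for
   these species are not recoverable in print).
3. **Generalized Archimedean spiral arcs** `r = t^α` in polar coordinates
   with `α = -1/3`, sampled on a polar-angle interval `[t_min, t_max]` and
   closed into a polygon. The asymmetric seeds of *Hylocereus*
   (`t ∈ [0.3, 5]`), *Pachycereus* (`[0.5, 5]`), *Ferocactus* and
   *Echinocactus* (`[1, 5]`) and *Pereskia* (`[1, 6]`) use progressively
   shorter or longer arcs of the same curve.
4. **The *Opuntia* curve** `r = 1/t + 1 - cos t` on `t ∈ [2, 6]` — a
   cardioid plus a hyperbolic-spiral term, reflecting the funicle's wrap
   around the developing ovule.

For the *Pereskia* spiral interval, both `[1, 6]` (used by the default
`PERESKIA1` preset) and `[2, 6]` (`PERESKIA1_T2`) are in circulation; the
default follows the more specific figure-level statement of the source
material. The two *Echinocactus* presets `ECHI1`/`ECHI2` share the `[1, 5]`
arc and differ by a stated aspect-ratio target (1.24 for the short-seed
model, 1.46 for the long-seed model, the published lot means), applied as a
minor-axis stretch after pose normalization.

### Discretization and closure

Curves are polygons of `n = 2000` vertices by default — enough that polygon
area error (~4×10⁻⁵ % against the superellipse Γ-function closed form
`4ab·Γ(1+1/p)²/Γ(1+2/p)`) is far below rasterization error. Superellipses
are sampled uniformly in the elliptic angle via
`x = a·sgn(cos t)|cos t|^(2/p)`, which covers corners evenly; spirals
uniformly in `t`. Open arcs are closed either by a chord between the
endpoints (default: deterministic and oracle-checkable) or by splicing in
the matching fragment of an average-silhouette contour when one is
available. Every closure is checked for self-intersection (shapely); a
failing closure raises rather than returning a broken polygon.

Model contours are pose-normalized: centroid at the origin, moment major
axis vertical, and the vertical flip chosen so the third central moment of
y is non-negative (skew tail up), which places the blunter hilum end down.

## Average silhouette

The representative outline of a seed lot is defined as an
occupancy-threshold construction rather than an image-editing recipe:
masks are pose-normalized (centroid + principal axis + the same
hilum-down flip rule, implemented on the row-mass profile), aligned by
integer centroid shifts onto a common grid, and averaged into an occupancy
map (fraction of masks covering each pixel, exactly `k/n`). The average
silhouette is the set of pixels with occupancy ≥ θ, largest component,
holes filled. Defaults: θ = 0.9 ("where most of the seeds coincide");
integer shifts make the stacked mass exactly conserved, and the
construction is monotone in θ by definition. The original opacity-stacking
/ magic-wand protocol is software-bound and has no exact mathematical
semantics; θ is exposed as a CLI flag instead.

Segmentation is a global Otsu threshold with hole filling and a minimum
component area (default 50 px): synthetic and bench photographs are
high-contrast, so no learned or watershed segmentation is attempted;
touching seeds deliberately merge and are flagged by a count mismatch.

## Descriptors and statistics

Seven descriptors per seed follow the ImageJ particle-analysis
conventions: area A (pixel count × scale², or shoelace for contours),
perimeter P, length L and width W as the full axes of the
moment-equivalent ellipse (`L = 4√λ₁` of the second-moment matrix — not
Feret diameters), aspect ratio AR = L/W, circularity C = 4πA/P², roundness
R = 4A/(πL²). Mask perimeters use the marching-squares sub-pixel boundary
with a 5-vertex circular moving average: the raw marching-squares polygon
carries a staircase that inflates P by ~6% and deflates C systematically
(a 100 px-radius disc measures C = 0.993 after smoothing). Mask second
moments include the 1/12 pixel-footprint term.

CV = 100·sd/mean with the n−1 denominator throughout, reported to two
decimals. One-way ANOVA (scipy) is followed by hand-computed Scheffé
contrasts — `T² = (m_i - m_j)² / (MSW(1/n_i + 1/n_j))`, compared as
`T²/(k-1)` against `F(k-1, N-k)` — and a compact letter display assigned
from the maximal cliques of the non-significance graph, which makes the
letters invariant to group input order.

## J index and registration

`J = 100·S/T` where S is the intersection and T the union of the seed and
model pixel sets — 100 × Jaccard/IoU. J > 90 is the conventional "good
adjustment" threshold. "Superimposed for maximum similarity" is realized
as a similarity transform (translation, rotation, uniform scale, optional
mirror; scale and mirror on by default since models are scaled to seeds
and photographed chirality is arbitrary). The seed's native grid is the
comparison grid; the model polygon is rasterized into it by an even-odd
scanline fill at pixel centers (this also defines the y-up → row-down
conversion).

Registration is deterministic: initialization matches centroids,
principal-axis orientation (both polarities), and area; Nelder–Mead then
refines `(dx, dy, θ, log s)` from the best start of each mirror state,
with one shrunk-simplex restart to step off pixel-flip plateaus. A mirror
branch whose best initialization is more than 10 J-points below an already
optimized branch is skipped (a local refinement cannot plausibly close
that gap). There is no RNG anywhere in the search, so results are
bit-reproducible. Self-recovery of rendered models under random similarity
transforms at ~400 px returns J = 100.0 in practice (acceptance floor
99.5). J is reported to one decimal.

## Synthetic lots

The generator emulates bench photographs: dark seeds (gray ≈ 45) on a
light background (≈ 235) with Gaussian pixel noise (sd 2/255), anti-aliased
by 4× supersampling, placed on a non-overlapping jittered grid in reading
order. Default scale 0.01 mm/px puts a 2.7 mm seed at ~270 px, comfortably
above the ≥ 200 px diameter where round-trip area error is < 1%.

Per-seed variation:

* **Size** — length L and width W are *independent* lognormals with the
  lot's mean and CV. Published lot tables show CV(A) ≈ √(CV(L)² + CV(W)²)
  and CV(AR) ≈ the same, i.e. L–W correlation ≈ 0; sampling L and an
  independent aspect ratio instead would give CV(A) ≈ √(4CV(L)² + CV(AR)²),
  nearly double the observed value. An explicit `mean_ar`/`cv_ar` mode
  exists for model-derived lots.
* **Outline** — multiplicative radial noise `r → r(1 + ε(θ))` with ε a
  random trigonometric polynomial of order 8, normalized so sd(ε) equals
  the amplitude; this preserves star-shapedness and gives one
  interpretable knob. Non-simple draws are retried with damped amplitude.
* **Pose** — rotation uniform in 0–360° plus grid-cell jitter.

The default amplitude 0.08 was calibrated once, before freezing, by
sweeping lots of the three spiral models against their source models: it
puts mean J at 91.3–91.9 with the majority of seeds above 90, the regime
reported for real lots (species means 90.5–91.2). Lots meant for J scoring
keep the model's intrinsic aspect ratio (`model_lot_spec`): an AR mismatch
between seed and model cannot be absorbed by a similarity transform and
caps J near 88 regardless of noise.

What the generator does **not** emulate: seed-coat texture and surface
ornamentation, shadows, perspective, uneven illumination, touching or
overlapping seeds, and any L–W correlation structure beyond independence.
Passing tests therefore demonstrate the pipeline's correctness on
high-contrast, well-separated, star-shaped silhouettes — the regime of the
composed bench photographs — not robustness to difficult imaging.

## Numerical choices and degenerate inputs

* Even-odd scanline rasterization at integer pixel centers; half-open rule
  on edge rows keeps crossing counts even. Contours larger than the target
  grid raise.
* Rotation of masks is bilinear with re-binarization at 0.5; pose
  normalization is idempotent to < 0.1° / 0.5 px.
* Near-isotropic masks (relative eigenvalue gap < 10⁻³) skip rotation:
  a disc's orientation is undefined and must not fail.
* A single-pixel mask converts to a 1-px square contour by convention.
* θ thresholds compare with a 10⁻⁹ tolerance so exact occupancy fractions
  `k/n` are never lost to float representation.
* CV requires n ≥ 2 and nonzero mean; ANOVA requires some within-group
  variance; both raise informative errors otherwise.

## Problem sizes used in checks

The shipped checks use: n = 4000 vertices for closed-form area
comparisons; 400 px renderings for registration self-recovery; lots of
n = 20 seeds (the typical photographed lot size) for J calibration; and an
oversampled n = 200 lot at 0.02 mm/px for recovering table-level
morphometry statistics, where sampling error of a CV estimate
(≈ CV/√(2n)) is comfortably below the comparison bands.

## Known limitations

* The Echinopsis profiles are approximations; no claim of identity with
  unpublished equations is made.
* Compact letter displays from maximal cliques can, for pathological
  non-significance graphs, produce more letters than the minimal display;
  for the small group counts used here they coincide.
* The J optimizer is local; it relies on moment initialization being in
  the right basin, which holds for star-shaped seed outlines but is not
  guaranteed for arbitrary blobs.
* No elastic registration, landmarks, or Fourier descriptors — shape
  difference beyond a similarity transform is deliberately left in J.
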