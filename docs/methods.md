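# Methods

## What the package measures

After professional cleaning, plaque regrows on tooth surfaces over a few
days of suspended oral hygiene. Two intraoral scans of the same tooth —
a clean baseline (T0) and a plaque-bearing follow-up (T4) — differ by the
deposited biofilm layer. `plaquemetry` superimposes the two scans rigidly
and integrates the surface deviation between them into a volume:

* **VPI** (volumetric plaque index, mm³) — the one-sided integral of the
  plaque thickness field over the delineated buccal region of interest
  (ROI), counting only thickness at or above the detection limit.
* **AVPI** (adjusted VPI, mm³/mm²) = VPI / ROI area — an area-normalized
  mean thickness, comparable across teeth of different size.

In parallel it measures plaque *coverage* (planimetry, all in percent of
the surface):

* **PLANItot / PLANIdark / PLANIlight** — fractions of the surface
  covered by any, dark/purple (mature), and light/pink (new) disclosed
  plaque, segmented from two-tone dye screenshots. PLANIlight is computed
  as PLANItot − PLANIdark, exactly.
* **PLANIvolmap** — coverage read off the Boolean (0.01 mm cutoff)
  rendering of the volumetric thickness map.
* **relPLANIdark / relPLANIlight** — dark/light share of total coverage
  (undefined and reported missing when PLANItot = 0).

The clinical reference is the Turesky-modified Quigley-Hein plaque index
(TMQHPlI): ordinal 0–5 scores at three sites per surface, for total (TDP)
and dark (DDP) disclosed plaque; per-surface summaries are site means.

## Superimposition

The T4 mesh is always moved into the T0 frame, so deposit appears as
positive deviation along T0 outward normals.

1. *Pre-alignment*: centroids matched, principal axes matched; the four
   proper sign choices are disambiguated by nearest-point RMS distance.
   Degenerate (equal-eigenvalue) clouds fall back to centroid-only
   alignment with a warning.
2. *Best fit*: trimmed point-to-plane ICP with symmetric correspondences
   (moving vertices against target surface and vice versa), correspondence
   cap 1.0 mm. Robustness has three ingredients: (a) fraction trimming —
   the best `trim_fraction` (default 0.6) of correspondences by absolute
   residual are kept; (b) graduated trimming — the kept fraction anneals
   from 1.0 to `trim_fraction` over the first 10 iterations, because hard
   trimming from the start can lock into an equilibrium where thin deposit
   margins balance the clean surface mode; (c) one-sided outlier
   rejection — deposit shows up as *negative* point-to-plane residual, so
   the noise scale is estimated from the upper (plaque-free) residual half
   and correspondences more than 3σ below the median are rejected before
   trimming. Iteration stops when the trimmed mean absolute distance
   changes by < 1e-6 mm (checked only after the annealing schedule), or
   at 100 iterations (then the best iterate is returned, flagged
   non-converged).

Plaque is a one-sided positive offset, so trimming lets the clean
geometry anchor the fit without knowing the plaque extent in advance.
This breaks down when coverage exceeds the trimmed fraction: with ~80% of
the ROI covered, the "consensus" surface *is* the plaque, the fit absorbs
part of the offset, and VPI is biased low. This is a property of best-fit
superimposition of ROI pairs as such, not of this implementation; results
at very high coverage should be read accordingly.

Noise floor: aligning two scans of the same clean surface, each with
0.005 mm Gaussian noise along the normals, yields a trimmed mean absolute
distance of ≈ 0.005–0.006 mm, the same order as the ≈ 0.01 mm
calibration such protocols report clinically.

## Thickness field and volumetric indices

For each T0 ROI vertex, the signed distance to the superimposed T4
surface is the Euclidean distance to the nearest point on the T4
triangulation, signed by which side of the T0 surface it falls on
(positive = outside = deposit). At interior foot points this equals the
perpendicular distance to the nearest triangle's plane. Nearest-triangle
candidates come from a k-d tree over triangle centroids plus the faces
incident to the nearest vertex; an all-triangles search is kept as a test
oracle. Vertices with no opposing surface within 1.0 mm are flagged
missing; more than 20% missing aborts the surface (bad scan coverage
fails loudly rather than silently truncating).

VPI sums `a_v · d_v` over vertices with `d_v ≥` detection limit, with
barycentric vertex areas `a_v` (one third of incident triangle areas —
first-order surface quadrature; Σa equals the ROI area exactly). The
detection limit defaults to 0.01 mm, the practical resolution of
point-to-plane scan comparison. Negative deviations (abrasion, noise) are
clamped out of the deposit integral; a `signed_volume` flag integrates
them instead for sensitivity analysis. Sampling the field on T0 keeps the
AVPI denominator plaque-independent.

## Projection maps

Screenshots in scanner software have an unrecoverable camera; the package
instead defines a canonical, fully reproducible orthographic projection:
view axis = area-weighted mean outward ROI normal, up axis = major
principal direction (occluso-gingival for buccal patches), default
0.02 mm/px. Rasterization interpolates per-vertex values barycentrically
with a z-buffer (front-most triangle wins). Boolean maps threshold at the
detection limit; PLANIvolmap = 100 × plaque pixels / ROI pixels.
Projection foreshortening is real and intentional: a flat patch tilted
60° from the view axis halves its pixel count (verified to cos θ within
2%), which is exactly the world-map-style distortion that makes 2D
planimetry differ from 3D area-weighted coverage on curved teeth. The
package reports both quantities so the discrepancy is measurable.

## Disclosed-image segmentation

The two-tone dye stains new plaque pink and thick/mature plaque purple;
both absorb green, so the green channel gives the best plaque/enamel
contrast. A random-forest pixel classifier (100 trees, fixed seed) is
trained on sparse annotations over a fixed feature bank: raw R/G/B, the
green channel, Gaussian blurs of it (σ = 1, 2, 4, 8 px), Sobel gradient
magnitude, differences of Gaussians, and local median/variance (r = 2,
5 px). Three classes are predicted jointly (non-plaque, light/pink,
dark/purple), which makes dark ⊆ total structural; a two-pass mode
reproduces the traditional two-run arithmetic and coincides with the
joint model through the subtraction identity. Connected plaque components
under 5 px are removed (speck filter, configurable). At least 50
annotated pixels per class are required.

## Statistics

The comparison plan, on per-surface records treated as independent,
non-nested observations (a deliberate simplification; a subject-level
bootstrap exists for the breakpoint CI):

* Shapiro-Wilk normality screen (scipy).
* Friedman test across the four planimetric measures, tie-corrected;
  for small problems (k!^n ≤ 1e5) the p-value is exact from full
  enumeration of the within-block permutation null, otherwise the
  chi-square tail with k−1 df.
* Wilcoxon signed-rank post-hoc tests, Bonferroni-corrected with m = the
  number of pairwise comparisons actually performed (6 for four
  measures). Zero differences are dropped; for n ≤ 25 the null is exact,
  computed by the shift algorithm on doubled midranks (valid under ties);
  above, a normal approximation with tie and continuity corrections.
* Spearman rank correlations (tie-corrected, pairwise-complete).
* Passing-Bablok regression on z-scored variables (marginal
  standardization): slope = shifted median of pairwise slopes excluding
  exact −1, shift K = #{slopes < −1}; CI by the binomial rank-quantile
  method; intercept = median(y − bx). Bias flags test whether the CIs
  exclude slope 1 / intercept 0.
* ROC of VPI against dichotomized coverage at 10/25/50%. Thresholds are
  read as absolute coverage cutoffs; a percentile-split option implements
  the alternative reading. AUC uses the rank (Mann-Whitney) identity with
  midrank tie handling.
* Sample size for a correlation study via the Fisher-z formula
  n = ((z₁₋α/₂ + z₁₋β)/atanh r)² + 3 (rounded); r = 0.66 at α = 0.05,
  β = 0.2 gives 15.
* Growth-regime breakpoint: VPI as a continuous two-segment linear
  function of PLANItot, grid-searched over coverage quantiles
  (10th–90th percentile, 41 candidates); if no breakpoint improves the
  residual sum of squares by more than 1% over a single line, the
  single-line model is returned flagged. The published one-third
  threshold may equally derive from intersecting the PLANIdark and
  PLANIlight linear fits, so `crossing_point` implements that reading
  too; neither is claimed to be the original computation.

## Synthetic study conditions

The simulator emulates the study design — 15 subjects × 8 maxillary
buccal surfaces (FDI 14–24), 4-day de-novo plaque — with exact ground
truth:

* Crown: superellipse-profiled dome patch, default 10 × 12 mm, 2 mm
  bulge, with a small asymmetric lean (a mirror-symmetric dome would make
  rigid recovery ambiguous). Grid spacing is 0.85× the requested edge
  length so grid edges and diagonals both stay within 20% of target.
  Default area ≈ 127 mm², in the premolar/incisor buccal range.
* Plaque: a smoothed random score field plus a gingival-margin bias is
  thresholded at the area-weighted quantile to hit the target coverage
  (default 35% — the study found total disclosed plaque covering about a
  third of surfaces on average). Thickness = 0.15 mm max × a gingival
  decay profile (3 mm decay length, floor 0.35) × smooth modulation ×
  an edge ramp. The thickest `maturity_fraction` (default 0.5, matching
  the observed ≈1:1 dark:light split) of covered area is "mature",
  stains purple, and is up to twice as thick (smooth ramp — mature
  plaque is denser and thicker). The field is then laterally smoothed
  (0.5 mm) and film below a 0.04 mm margin is smoothly suppressed:
  deposits taper to a finite edge thickness rather than an unbounded
  micron-scale apron, and a scan surface cannot express sub-resolution
  film anyway. Offsetting is along analytic surface normals; a flipped
  face normal (self-intersection) raises.
* Truth: volume and area by trapezoidal quadrature of the analytic area
  element on a fixed 257² parameter grid — never via the volumetry
  module. Mesh vertices sample the same grid realization by bilinear
  interpolation, so truth and mesh share one field.
* Scanner: Gaussian noise along normals (SD 0.005 mm in cohorts) and a
  random rigid pose offset (≤3°, ≤1 mm), both recorded.
* Disclosed images: orthographic render at 0.05 mm/px; pink covered
  region, purple mature sub-region, pale enamel, Gaussian pixel noise
  (SD 6 of 255). Per-pixel truth classes are returned for training and
  scoring.
* TMQHPlI synthesis: site scores from true coverage via the Turesky band
  thresholds (0 none; 1 flecks < 5%; 2 thin band < 10%; 3 < 1/3;
  4 1/3–2/3; 5 > 2/3), with ±30% site-level coverage jitter and ±1
  ordinal noise at probability 0.1 (examiner variability).

What the simulator does **not** emulate: real enamel texture and specular
scan artifacts, dye chemistry and colour calibration, inter-proximal
occlusion and neighbouring teeth, scan holes, non-rigid changes
(abrasion, eruption). Passing tests therefore demonstrate the numerical
chain — registration, integration, projection, segmentation, statistics
— not robustness to every property of clinical scans.

## Problem sizes and numerical choices

Default test and acceptance problem sizes are chosen for a laptop-class
run: volumetric recovery uses 20 crowns at 0.1 mm edge (~17k vertices
each); registration checks use 0.25 mm meshes; cohort/end-to-end checks
use 2–3 subjects at 0.25–0.3 mm; breakpoint recovery uses 50 simulated
record-level cohorts of n = 150. Mesh cleanup merges vertices within
1e-6 mm and drops zero-area faces — both far below the 0.01 mm detection
limit, so cleanup cannot create apparent plaque. Ties at x.5 in TMQHPlI
rounding go up (documented convention; the index defines none). All
randomness derives from explicit seeds; reruns are byte-identical.

## Known limitations

* High-coverage alignment bias (see Superimposition): VPI under-measures
  once coverage exceeds the trim fraction.
* Thin-plaque surfaces put proportionally more volume near the detection
  limit; measured VPI on simulated crowns stays within 2% of truth at
  0.1 mm edge (worst case ~1.7% over 160 seeds), with thin realizations
  dominating the tail.
* The 2D planimetric measures inherit projection distortion by design.
* Clustering of surfaces within subjects is ignored in the default
  statistics, which understates standard errors.
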