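# Methods

## Problem and scope

MRD1 (marginal reflex distance 1) is the signed vertical distance, in
millimetres, from the pupil center to the upper eyelid margin with the
eye in primary gaze; positive when the margin sits above the center.
`mrdeye` implements a fully automated desk-scale MRD1 measurement chain
for single-eye near-infrared close-ups, a synthetic renderer that
provides exact ground truth for it, and the method-agreement statistics
used to validate one MRD1 measurement method against others. Out of
scope by design: MRD2 and palpebral fissure height, neural-network
segmentation (externally produced masks can be injected instead),
RGB-image segmentation (the motivating failure mode: dark irises),
binocular face images, gaze-angle correction, and eye-within-patient
correlation modelling.

## Coordinate and label conventions

All modules share one frame: row 0 at the image top, y increasing
downward, so MRD1 in pixels is `center_row − margin_row` (positive for
an open lid). Label images use 0 = background/skin, 1 = sclera,
2 = iris, 3 = pupil. The physical frame is anchored at the image
center with a single isotropic scale in px/mm.

## Synthetic renderer

The renderer emulates what a two-camera IR measurement device captures:
a close-up of one eye with a dark pupil disk (default 2 mm radius)
inside a mid-gray iris annulus (5.9 mm, a typical adult iris radius),
bright sclera filling the palpebral aperture, skin elsewhere, an
optional specular glint, and a bright circular fiducial dot of nominal
5 mm diameter on the lower-lid skin.

Lid margins are parabolas in the mm frame. The reason for that choice
is pragmatic: a parabola gives a closed-form margin height
at every column, so the ground-truth MRD1 is *by construction* the
upper lid's apex offset above the pupil center at the pupil-center
column — no rasterization enters the truth value. Default curvatures
(0.03 mm⁻¹ upper, 0.025 mm⁻¹ lower) give a ~24 mm palpebral aperture
width, clinically plausible. Rendering is defined on pixel centers;
occlusion order is: lids clip iris and pupil; the glint changes only
image intensity (its pixels keep the underlying anatomical label —
a reflection is still pupil tissue); the dot must lie entirely outside
the aperture and stays labelled background. A configuration whose lid
parabolas cross at the pupil column is rejected as a closed aperture.

Default intensities (pupil 25, iris 90, skin 150, sclera 230, dot 245,
glint 250 on the 0–255 scale) reflect the IR ordering pupil < iris <
sclera with skin between iris and sclera; noise is additive Gaussian in
gray levels, then clipped and quantized to 8 bits. Defaults: 640×480 px
at 12 px/mm.

What the renderer does **not** model: eyelashes, skin texture, shading
gradients, defocus, off-axis gaze, partial blinks, and soft (blurred)
class boundaries. Passing tests on these images therefore demonstrates
the geometric and statistical machinery is correct, not that the
classical segmenter would survive clinical image quality; the
mask-injection path exists precisely so a stronger segmenter can feed
the same geometry.

### Cohort simulator

Each simulated eye has one true MRD1 drawn from a normal truncated to
(0, ∞) — comparison cohorts exclude eyes with non-positive manual MRD1
— with defaults mean 2.84 mm, SD 1.04 mm, matching the pooled moments
of the published four-method comparison the statistics module
reproduces. Each method column is truth + fixed method bias + zero-mean
Gaussian error (default SD 0.30 mm). Default biases relative to the
manual arm (DL +0.205 mm, IR +0.144 mm, RGB +0.433 mm) equal that
study's pairwise mean differences. The number of manual replicates
averaged per eye is exposed (`manual_replicates`) rather than fixed,
since published protocols vary in how many readings they average.

## Segmentation

Pipeline order is fixed: glint inpainting → multi-level thresholding →
per-class morphology → component selection.

*Glint inpainting.* Bright components no larger than a configurable
area are knocked down to the image minimum and regrown by grayscale
morphological reconstruction (dilation under the original image), which
fills isolated bright peaks from their surroundings without touching
anything else.

*Thresholding.* Three thresholds are placed by exact dynamic
programming over the 256-bin histogram, minimizing within-class
variance with each bin weighted by `log1p(count)`. Two numerical
failure modes of the standard raw-count multi-Otsu criterion motivated
this: (i) on noiseless synthetic images the histogram is a handful of
spikes separated by empty gaps, and heuristic threshold searches can
place two thresholds inside one gap, silently emptying a class; (ii) on
noisy images skin is >90 % of pixels, and the raw-count optimum splits
the heavy skin mode instead of separating pupil from iris. Log
weighting keeps each occupied mode comparably influential so the
optimal cuts fall in the valleys between modes; the DP guarantees the
global optimum of that criterion. Fixed thresholds can be supplied
instead.

*Class assignment.* The threshold ranks are mapped to anatomy by
position and brightness: the rank dominating the image border is skin,
the darkest rank is the pupil candidate, the brightest non-border rank
is sclera, the remainder iris. This assumes the IR ordering pupil <
iris < sclera with skin intermediate — the regime the package targets.
The pupil is the largest dark component above a minimum area (ties
within 10 % resolved toward the aperture centroid), hole-filled; the
iris is the connected iris-rank blob containing the pupil; sclera keeps
only components touching the dilated iris/pupil region, which is what
rejects the bright calibration dot. An image with no qualifying dark
component raises "pupil not found", the machine-failure case downstream.

## Geometry

*Pupil circle.* Kåsa's algebraic least-squares fit (minimize
Σ(x²+y²+Dx+Ey+F)² — a linear problem) over the boundary pixels of the
retained pupil component, requiring ≥ 6 points. Boundary pixels
adjacent to iris are preferred; pixels adjacent to background lie on a
lid-occlusion chord, not the pupil rim, and are excluded whenever
enough rim pixels remain. This makes the center estimate robust
precisely in the ptosis case where the lid clips the upper pupil —
and is why the pupil center comes from the circle fit rather than the
component centroid, which occlusion drags downward. Fitted radii are
reported with a +0.5 px edge correction because boundary pixel centers
sit about half a pixel inside the true edge; the center needs no
correction by symmetry.

*Lid margin.* Scan the pupil-center column upward from the center row;
the margin is the first background row beginning a run of ≥ k
consecutive background rows (k = 3 by default, skipping single-pixel
label speckle), reported as the transition midpoint (sub-pixel,
unbiased for an ideal step edge). If the pupil-center pixel itself is
background, the lid covers the center: the scan runs downward to the
first tissue run, yielding a negative MRD1 and the
`lid-covers-pupil-center` flag. Negative values are returned and
flagged, never clamped — the cohort exclusion filter, not the geometry,
enforces any study's MRD1 > 0 rule.

*Calibration.* The pixel scale is the equivalent-area diameter of the
detected fiducial dot divided by its nominal diameter (5 mm). Dot
detection thresholds at 75 % of the image intensity range and accepts
exactly one component inside a configurable area window with
circularity 4πA/P² ≥ 0.85 (Crofton perimeter); zero or multiple
candidates raise a calibration error carrying the candidate count, and
the caller may instead supply a known px/mm (the `no-dot` QC path).

*Composition.* `measure_image` chains segment → fit → margin →
calibrate → MRD1 and returns one record with all intermediates and QC
flags; sub-operation failures become structured failure records (with
the matching exclusion-rule tag where applicable), never exceptions, so
batch runs continue past unmeasurable eyes.

## Statistics

Eyes are treated as independent observations and methods as independent
groups — matching how the published comparisons analyze their data
(unpaired one-way ANOVA across methods despite the paired design); a
paired or mixed-effects alternative is deliberately out of scope. All
p-values are two-tailed; t and F quantiles are computed at full double
precision; the limits-of-agreement multiplier is fixed at 1.96 and
ΔLOA is defined as upper − lower.

The moments-based routes are first-class: ANOVA from per-group
(n, mean, sd) uses the exact decomposition SS_b = Σnᵢ(x̄ᵢ−x̄)²,
SS_w = Σ(nᵢ−1)sᵢ², so raw-data and moments variants agree to
floating-point error (tested against an independent raw-data oracle);
the Scheffé table needs only the moments plus MS_w; and the
Bland–Altman *mean* difference of a pair equals the difference of the
two means — which is why a printed descriptives table suffices to
reproduce those headline numbers, while the LOA themselves require the
per-pair difference SDs and hence raw data.

Zero within-group variance with unequal means yields a flagged
infinite-F result rather than an exception; zero-variance columns give
NaN correlations.

*Exclusion filter.* Six rules in fixed order with first-match
attribution (the source protocols state no ordering, so a deterministic
order was chosen and every row is counted exactly once): (1) missing
manual replicates, (2) manual ≤ 0, (3) indistinct RGB pupil boundary
(flag column or missing RGB value), (4) |manual − reference| > 1.0 mm
against the chosen reference method, (5) machine failure (flag or
missing DL value), (6) recent eyelid surgery.

## Numerical choices and degenerate inputs

- Histogram: 256 bins over the observed intensity range; constant
  images are rejected before thresholding (→ "pupil not found").
- Tie-break for equally large dark components: centroid nearest the
  aperture centroid.
- Circle fit degenerate cases: < 6 boundary points or non-positive
  fitted radius raise an explicit error.
- Margin scan at the image edge: a background run truncated by the
  image border counts as sustained.
- The renderer's closed-aperture test is evaluated at the pupil-center
  column, the column MRD1 is defined on.

## Problem sizes in the validation suite

The test and acceptance batteries use desk-scale sizes chosen to make
the statistical assertions sharp while keeping runs short: 200 noisy
renders (640×480, 12 px/mm, noise SD 8) for geometric recovery with
truths uniform on 0.5–5 mm; four noiseless control renders; 10⁴-eye
simulated cohorts for bias recovery (pair standard error ≈ 0.004 mm,
so a 3-SE band is ~±0.013 mm); 100 random cohorts for the
moments-vs-raw ANOVA equivalence. The noisy-recovery criterion (95 %
of eyes within 0.15 mm) and the noiseless criterion (within one pixel
equivalent, 1/12 mm) are properties of this synthetic regime; clinical
error will be dominated by factors the renderer does not model (see
above).

## Known limitations

- The classical segmenter assumes the IR intensity ordering and
  single-eye close-up framing; it is not a general periocular
  segmenter and will fail gracefully (pupil-not-found) outside that
  regime.
- Circularity-gated dot detection can reject a partially occluded or
  cropped fiducial dot; the explicit-scale fallback covers that case.
- MRD1 is measured along the column through the fitted pupil center;
  head tilt that rotates the lid margin relative to the image rows is
  not corrected.
- The cohort simulator draws independent Gaussian method errors; it
  does not model inter-eye correlation within a patient, rater
  correlation, or heteroscedastic error growing with MRD1.
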