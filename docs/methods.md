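# Methods

## The symmetry score

For one section the measurement is a function of (i) a label raster over
five tissue classes, (ii) a dorsoventral axis given by two user-placed end
points, and (iii) a window width in physical units.

The axis midpoint defines the mirror line. The raster is rotated (about
its center, canvas enlarged to fit) so the dorsoventral segment is
vertical; label rasters use nearest-neighbour interpolation so no
non-existent classes are invented, RGB rasters use bilinear. The rotation
angle is `atan2(Δcol, Δrow)` of the dorsal→ventral segment — the sign
convention is internal; the defining contract is that the rotated end
points share a column with dorsal on top.

A window of width 400 μm (the default; converted to pixels by the
per-image scale and forced even) is cut about a chosen column — by default
the axis column. Rows are split at the mirror line: when the mirror row is
half-integer the halves abut it; when it falls on a row, that row belongs
to neither half (avoiding double-counting the axis). Both halves are
cropped to the lesser half-height and the ventral half is flipped, so
index (i, j) in one half is the mirror partner of (i, j) in the other.

Per class *c*: `matching_c = |mask_dorsal ∧ mask_ventral|` and
`total_c = |mask_dorsal ∨ mask_ventral|`; `score_c = matching_c / total_c`
(a Jaccard index of the two halves), undefined (reported absent) when
`total_c = 0`. The combined score pools counts over scored classes and is
therefore the mediant of the per-class ratios — always between their
minimum and maximum. The union denominator is the default because it is
the only reading under which a perfect mirror scores exactly 1.0; a
literal "sum of both sides" denominator (`denominator="sum"`, under which
a perfect mirror scores 0.5) is kept for sensitivity analysis.

Masks are exact class equality on label rasters. On RGB rasters (scoring
exported class-colored images) a pixel matches a target color when all
three channel differences are within a per-channel tolerance; the default
tolerance is 0, appropriate for palette-exact images.

The manual step of aligning the outer contour symmetrically is formalised
as `refine_angle`: a grid search over rotation offsets (default ±5° in
0.5° steps) maximising the epidermis-class score of the window, ties going
to the smallest |offset| and negative before positive. This is an
interpretation of a qualitative criterion, not a reconstruction of one.

## Pixel classification

The features per channel are raw intensity plus Gaussian-smoothed
intensity, Gaussian gradient magnitude and Gaussian Laplacian at scales
σ ∈ {1, 2, 4} px (reflective boundaries), i.e. F = 3·(1 + 3·3) = 30
features — the standard color/edge/texture triad of interactive trainable
segmentation tools, whose exact feature bank is configurable here. The
truncated discrete Laplacian-of-Gaussian kernel has a small non-zero DC
response; it is subtracted (using the smoothed channel) so that a constant
image yields exactly zero edge features.

The learner is a random forest (100 trees, seeded, single-threaded) fit on
exactly the annotated pixels. Ties in the class vote resolve to the lowest
class index, making prediction a pure deterministic function of (model,
features). One classifier per sample is the default workflow because a
global intensity multiplier between samples moves absolute feature values
across learned thresholds; annotations may be shared across sections from
the same limb. The annotation-sampling helper draws seeded per-class
pixels from ground truth to emulate user scribbles on synthetic data.

## The synthetic generator

The generator emulates a transverse limb section as seen in a
trichrome-stained slide: a smooth outer contour (radius = low-order cosine
harmonics of the polar angle; cosine-only terms make the contour exactly
even in the dorsoventral offset, hence bit-exactly mirror-symmetric — the
external shape never confounds internal symmetry), an epidermis ring of
fixed thickness (default 6 px = 24 μm), a connective-tissue fill, and
elliptical cartilage (default 2 per half) and muscle (default 3 per half)
elements placed by rejection sampling in the dorsal half. The ventral half
receives each element's exact mirror image, except that with probability
`asymmetry` an element is re-drawn independently — giving an exact
mirror at 0, independent layouts at 1, and a graded knob between.
Elements that cannot be placed raise an error rather than being silently
truncated.

Rendering maps each class to a mean color (default: the display palette),
multiplies by a single per-sample intensity factor drawn uniformly from
(0.7, 1.3) — modelling slide-to-slide staining variation, the stated
motivation for per-sample training — and adds i.i.d. Gaussian pixel noise
(default sd 4 on the 0–255 scale). With zero noise and unit multiplier the
render reproduces the palette exactly. Cohorts derive per-sample layout
and stain seeds from one master seed, so everything downstream is
reproducible to the byte.

What the generator does *not* model: real trichrome texture within a
tissue, fixation distortion and section folding, partial-volume color
mixing at tissue boundaries, and uncertainty in placing the dorsal and
ventral end points (the contour extremes are used, mirroring the manual
choice). Passing tests therefore demonstrate the correctness and
discriminative behaviour of the pipeline, not segmentation performance on
real slides.

## Group statistics

Welch's t (Welch–Satterthwaite df) and the paired t are computed by the
closed formulas with explicit degenerate branches: two zero-variance
samples with equal means give t = 0, p = 1; zero variance with unequal
means gives p = 0 and a degeneracy flag rather than a NaN. Fisher's exact
test sums hypergeometric probabilities no larger than the observed
table's. Outcome percentages are kept as exact rationals internally and
formatted to one decimal for display. No multiple-testing correction is
applied by default, matching the convention of reporting per-class test
families raw; Benjamini–Hochberg adjustment is available.

## Problem sizes and numerical choices

The generator's default canvas is 512×512 px at 4 μm/px, making the
400 μm window 100 columns. Tests and the acceptance script run cohorts on
256×256 px canvases at the same scale — the window still fits with margin
and a 24-sample classified cohort completes in well under a minute — with
n = 12 scored areas per group, the study design the statistics module is
built around. Window widths round to the nearest even pixel count; the
mirror line of a generated section falls exactly between rows. Identity
rotations bypass resampling so symmetric ground truth scores exactly 1.0.
Angle refinement on nearest-neighbour-rotated rasters has a score profile
noisy at the ~0.5° grid scale when the epidermis ring is thin; the
inversion-recovery test uses a 10 px ring on a 384 px canvas where the
optimum is unambiguous.

## Known limitations

- Scores from multiple windows of one limb are treated as independent in
  the Welch tests (area-level testing); no mixed-effects nesting of
  windows within limbs is attempted.
- The pixel scale and the dorsal/ventral end points are required inputs,
  never inferred from the image.
- RGB-domain scoring assumes palette-exact class colors unless a tolerance
  is supplied; there is no color deconvolution of real stains.
- The classifier's exact-recovery guarantee holds for noiseless,
  color-separable renders when the annotations cover the feature profiles
  present (e.g. dense scribbles, or geometries whose boundary profiles
  repeat); sparse scribbles on complex geometry can leave boundary pixels
  imperfectly classified — which is why symmetric cohorts score ~0.999
  rather than 1.0 after classification.
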