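# Methods

## Shape model

Every simulated structure is a 2-D capsule (stadium): a rectangle of
length *L* − *w* capped by two semicircles of diameter *w*, with filled
area *A* = *w*(*L* − *w*) + π(*w*/2)².  At *L* = *w* the capsule
degenerates continuously to a disk, so a single parameterization covers
globular prestructures, circular spheroids and elongated tubules.  The
lumen is an inner capsule at uniform wall thickness: for lumen fraction
*f*, lumen width *f·w* and lumen length *L* − *w*(1 − *f*), which reduces
to a concentric disk in a spheroid and a slit in a tubule.  Ground-truth
area is the *net* area (capsule minus lumen), matching what a segmented
mask measures, since the lumen renders at background intensity and
becomes an enclosed hole.

Class priors (uniform bands, defaults):

| class | width (μm) | aspect L/w | lumen fraction |
|---|---|---|---|
| prestructure | 40–90 | 1.0–1.4 | 0 |
| spheroid | 60–120 | 1.0–1.2 | 0.4–0.7 |
| tubule | 35–60 | 2.5–3.5 | 0.2–0.4 |

Tubule widths sit in the 30–80 μm band around the ≈50 μm diameter of a
mouse nephron-scale tubule.  Orientations are drawn about a random field
axis with sd 0.05 rad: downstream descriptors are axis-aligned bounding
boxes (as drawn-ROI region statistics would be), and strongly oblique
tubules would inflate the apparent minimum dimension past the class band.
This near-axis alignment is a deliberate simulator simplification, read
as cultures whose tubule fragments settle along the gel spreading
direction; the bounding-box inflation of rotated objects is real and
documented rather than corrected.

## Time course and conversion dynamics

A scenario is a set of structures revisited at fixed timepoints (default
0, 48, 96, 168 h with induction at 0 h: one pre-dose baseline and three
post-induction visits).  In the doxycycline arm each differentiated
structure (spheroid or tubule) converts with probability
`conversion_prob` (default 0.8); prestructures never convert (Cre is
epithelium-restricted) and control arms force the probability to 0.
Converted structures relax their elongation *E* = *L*/*w* as

    E(t) = 1 + (E₀ − 1) · exp(−λ (t − t_ind)),   t ≥ t_ind

with width preserved and length shrinking; λ defaults to 0.008 h⁻¹, which
removes ≈74% of the excess elongation by 168 h.  On top of the dynamics,
width and length receive independent multiplicative log-normal jitter
(sd 3% per timepoint) and centroids random-walk with a 5 μm step — both
invented magnitudes chosen to look like gel-embedded culture imaging, as
no numeric baseline distributions or growth rates are available for this
assay.  Converted structures render a per-pixel Bernoulli mosaic of green
pixels at `mosaic_green_fraction` (default 0.8) from induction onward;
all other structure pixels are red (the membrane reporter is expressed
everywhere before recombination).

Tracked-assay priors: the individually tracked structures use a narrower
tubule prior (width 40–65 μm, aspect 2.00–2.15, lumen fraction
0.35–0.45).  The agreement score saturates at 0 for strongly elongated
shapes; structures pinned at the clamp carry no paired before/after
information and would give a control arm zero-variance differences.
Moderately elongated tubules keep baseline scores in the interior of the
scale (≈0.3–0.6 at these defaults), the regime in which a paired design
is informative.

## Rendering

Bright-field is a bright-object-on-dark proxy: background 2000,
structures 30000 on the 16-bit scale, lumens left at background
(enclosed holes), optional per-structure Gaussian defocus, additive
Gaussian noise (default sd 300) on all channels.  Default calibrations
are 1.6 μm/px (population, 4×-like) and 0.32 μm/px (individual,
20×-like).  A pixel belongs to a shape when its center falls inside the
analytic capsule; rasterized net areas agree with the closed forms to
well under 1% at 0.5 μm/px.  Single-pixel width quantization on an
elongated axis-aligned capsule scales with its length and can approach 2%
of net area at 1 μm/px, so raster-oracle checks sample at 0.5 μm/px.

## Segmentation and exclusions

Otsu thresholding on the bright-field channel, connected components,
minimum area 500 μm² (debris filter), holes kept separately as lumen
candidates.  Bounding boxes are half-open in pixels; reported μm extents
are inclusive (pixel count × pixel size).  Exclusion rules mirror manual
scoring practice: border-touching structures are dropped (`boundary`),
and structures whose mean Sobel gradient on the mask rim, normalized by
the image intensity range, falls below 0.21 are dropped (`focus`).  The
0.21 default was frozen from a calibration sweep (sharp rims score
0.63–0.70, σ=2 px blur 0.24–0.27, σ=3 px blur 0.14–0.19, with or without
default noise), placing the cut so defocus σ ≥ 3 px is excluded.

## Score conventions

The normalized convention (default) references the disk inscribed on the
shortest bounding-box dimension: *r* = min(*w*, *h*)/2, *A*ₛ = π*r*²,
*d* = |*A* − *A*ₛ|/*A*ₛ, *S* = max(0, 1 − *d*).  It is exactly 1 for a
disk, scale-invariant, monotone in elongation, and clamps (rather than
renormalizes) at 0 so arbitrarily long tubules saturate — matching a
bounded published-style scale.  The literal `as_printed` recipe
(*r* = min(*w*, *h*), *A*ₛ = 2π*r*²) cannot place a disk at 1 under any
reading, so it is retained only as a transparency flag.  The percent
difference divides by the reference area by default; dividing by the
measured area is a config option.  These conventions are declared
package choices where the originating lab practice is ambiguous, not
recovered values.

## Classification

Rules fire in order: (1) lumen area fraction < 0.05 → prestructure;
(2) largest-lumen circularity (4πA/P², Crofton perimeter, clamped at 1.1
for raster tolerance) ≥ 0.6 and bounding-box aspect ≤ 1.5 → spheroid;
(3) aspect ≥ 2.0 and minimum box dimension in 30–80 μm → tubule;
(4) otherwise ambiguous.  All cutoffs are invented operationalizations of
qualitative descriptions, live in `ClassifierThresholds`, and are echoed
in output metadata.  The explicit reject class has no manual-scoring
counterpart; a rule system needs it to avoid silent miscalls.  Wall
thickness ("1–2 cells wide") is not a feature — the generator has no
nuclei channel.

## Tracking

Greedy nearest-centroid linking in ascending distance order under a
50 μm gate (structures are nearly stationary in gel), ties broken by
smaller structure id; unmatched records become deaths/births.  A track
missing one timepoint may bridge a single gap within 1.5× the gate over
the doubled interval.  Greedy matching is deterministic and adequate for
sparse scenes; under crowding or crossings an optimal assignment would be
needed — a documented limitation.  A track is *complete* when observed at
≥1 pre- and ≥1 post-induction timepoint.

## Fluorescence quantification

Within a structure's mask a pixel counts as red (green) when its red
(green) intensity exceeds a threshold, default mean + 2 sd of background
estimated outside all masks; double-positives count in both channels
(membrane overlap), with a winner-takes-all alternative.  A structure is
called converted at green fraction ≥ 0.5 — a declared convention, echoed
in outputs, standing in for an unpublished plugin rule.

## Statistics

Paired *t*: *t* = mean(*d*)/(sd(*d*)/√n), *d* = after − before, df = n−1.
Two-sample: pooled-variance Student form, df = n₁+n₂−2 (matching the
"Student's t-test" usage this assay family reports, not Welch).  Tail
probabilities come from the regularized incomplete beta function
I_x(df/2, ½) with x = df/(df + t²); tests verify agreement with an
independent reference implementation to 1e-10 relative error.  Zero
variance raises a degenerate-input error rather than returning p = NaN.
ΔΔCt: fold change 2^(−ΔΔCt).  No multiple-testing correction is applied
in this layer.  The paired assay evaluates the last pre-induction
timepoint against the post-induction timepoint closest to a configurable
offset (default 168 h), since assay descriptions vary between 72 h and
168 h readouts.

## What the generator does and does not show

Passing tests demonstrate that the measurement chain — segmentation,
region statistics, scoring, classification, tracking, pixel counting,
statistics — is internally consistent and recovers known truth from
idealized renders: binary-contrast capsules, no optical PSF, no true
transmitted-light texture, no touching or dividing structures, no 3-D
effects, temporally incoherent mosaic patterns.  They do not validate
Otsu segmentation on real bright-field contrast, the focus proxy against
real defocus, or the class cutoffs against histology.  On real data the
entry point is the segmentation stage with measured pixel sizes, and the
thresholds should be re-examined.

## Problem sizes in the verification suite

Oracle and acceptance checks use: 125 random shapes for region
statistics (five 25-structure fields at 0.5 μm/px); 300 structures for
classifier recovery (twelve 25-structure fields); 10 seeds × 50
structures × 4 timepoints for tracking; 1000 seed sweeps for the type-I
rate of the paired analysis under the λ = 0 null and 100 seeds each for
power (λ = 0.008, n = 20/arm) and control behaviour; and a full two-arm
assay run repeated twice for byte-identical determinism.  Seed sweeps run
at the truth-table level (analytic geometry through tracking and
statistics) — rendering adds raster noise but no new information to those
particular contracts.
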