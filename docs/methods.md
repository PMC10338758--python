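# Methods

## Measurement model

A gimballed tracking linac aligns its MLC aperture to the predicted
center-of-mass (COM) of implanted fiducials while the EPID records the
exiting treatment beam.  On every cine frame both the delivered aperture
and the seed shadows are visible, so the *residual* tracking error is
directly measurable as the displacement between the aperture's geometric
center and the marker COM.  Quantities are reported in mm at the
isocenter plane: the panel sits at 221.2 cm from the source and its
pixels de-magnify to 0.18 × 0.18 mm² at 100 cm, so 1 px = 0.18 mm.  The
pan and tilt gimbal axes project to fixed column/row axes on the imager.

The tracking error is referenced to the first usable frame of each
series:

    E_T,pan(i)  = |pan(i) − pan(b)|
    E_T,tilt(i) = |tilt(i) − tilt(b)|
    E_T,2D(i)   = sqrt(E_T,pan(i)² + E_T,tilt(i)²)

with b the baseline frame (frame 1 whenever its markers are detectable;
otherwise the first included frame — the baseline definition presumes a
usable first image and is silent on that corner, so the first included
frame is the natural generalization).  Defining the 2D error as the norm
of the baseline-subtracted vector (rather than the variation of the
scalar 2D distance) guarantees per frame

    max(E_T,pan, E_T,tilt) ≤ E_T,2D ≤ E_T,pan + E_T,tilt,

which the test suite asserts on every analyzed series.  Baseline
subtraction makes E_T exactly invariant to any constant offset common to
all frames; a consequence worth knowing is that a patient-specific
constant *bias* cancels in E_T, which is why parameter-recovery tests for
the systematic error operate on the measured per-frame offsets rather
than on E_T.

## Detection chain

**Normalization.**  Raw counts are min-max scaled per frame and inverted
to the 0 = white / 1 = black convention (markers and blocked regions
dark).  Every later step is invariant to this affine stretch: the field
threshold is re-estimated per frame and the LoG/threshold chain is
scale-adaptive.  The vendor raw layout is not publicly documented, so the
reader takes a configurable dialect (default: headerless 16-bit unsigned
little-endian); "256-level grayscale" is treated as export quantization
only — processing keeps float precision.

**Field edge.**  In-field pixels are bright (low values).  The edge
threshold defaults to the midpoint between the modal in-field and modal
blocked grey levels (the standard 50 % field-edge convention), with the
two modes estimated as the medians of the Otsu split.  The largest
connected region wins, holes (marker shadows) are filled, and a
Moore-neighbor tracer walks the boundary clockwise from the
topmost-leftmost pixel emitting Freeman 8-direction codes until it
returns to its starting state.  The enclosed area is the shoelace sum
over the boundary-pixel polygon plus the Pick correction (steps/2 + 1),
which makes it agree with the interior pixel count — exact for simple
rectilinear outlines, and within 1.5 px² on random rectilinear apertures
in the acceptance checks.  The aperture center is the area centroid of
the filled interior (not the mean of boundary points), which is robust to
the MLC's stair-step pixelation.

**Markers.**  The LoG kernel is the Laplacian of the unit-integral
Gaussian, sampled to a half-width of ceil(3σ) and mean-subtracted so a
constant image maps to exactly zero.  Default σ = 2.0 px: the matched
blob radius σ√2 ≈ 2.8 px equals the projected half-width of a
1 mm-diameter seed.  Because dark structures are *high* values, marker
blobs appear as negative LoG extrema; the detection path negates the
response so markers peak positive.  Candidates are pixels above
median + k·(1.4826·MAD) with k = 5, with the median and scale estimated
over the aperture interior eroded by 8 px — the erosion both suppresses
the strong LoG ridge along the field edge and keeps the background
estimate free of the blocked region.  On an exactly noise-free background
the MAD degenerates to zero and the standard deviation over the same
region takes over.  Connected components (8-connectivity by default)
become blobs with response-magnitude-weighted sub-pixel centroids.

Plausibility filters: centroid inside the aperture and more than
1.24 mm from the traced edge (markers nearer the edge may be partially
occluded by the MLC); area in [4, 80] px², bracketing the ≈ 3 mm² seed
footprint across magnifications; elongation (major/minor axis ratio from
second moments) ≤ 8 — noise-free renders of the 3 × 1 mm seed measure
5–6.3 because the band-pass accentuates the seed's spine, so the cap
leaves headroom over the true geometry while still rejecting streaks.
If more candidates than implanted seeds survive, the strongest by
|mean response| are kept (ties: larger area, then smaller row, then
smaller column — a deterministic total order).  The frame COM is the
*unweighted* mean of the surviving centroids so each seed votes equally
regardless of overlying anatomy.  Frames with fewer detected markers
than implanted are excluded from the statistics by default
(`require_complete`), since a partial COM is biased toward the detected
subset; a permissive mode accepts ≥ 1 marker.

## Statistics

Per field: mean, sample SD (n−1), 90th percentile (linear interpolation
between order statistics) and max of E_T per direction, with the
baseline frame's zero included in the sample.  Per patient: the included
frames of all the patient's fields and fractions are pooled
frame-weighted (each frame votes once; fields are not averaged first).
Across patients:

    Σ = sample SD (divisor n−1) of the per-patient means
    σ = RMS (divisor n) of the per-patient SDs
    margin = 2.5 Σ + 0.7 σ   (90 % of patients / 95 % CTV coverage)

The divisor conventions are pinned deliberately: on the packaged
eight-patient reference cohort only the n−1 form of Σ reproduces the
published per-direction values (0.08/0.19/0.20 mm), while the plain-RMS
σ reproduces 0.42/0.73/0.79 mm; together they give the 1.1 mm 2D margin
contribution.  The margin is also reported per axis as a clearly
labelled extension of the same recipe.  Margins are rounded to 0.1 mm
for reporting with full precision retained internally.

## Synthetic scenes

The generator renders what the detection chain must cope with, not
detector physics: a polygonal aperture (interior bright, exterior dark)
translating with a respiratory trace; seed shadows as
constant-attenuation ellipses (3 × 1 mm projected) with a 1-px Gaussian
edge blur; an injected per-frame tracking offset between aperture center
and marker COM; additive Gaussian noise on the normalized grayscale; and
optional clipping of markers by the moving MLC edge.  The phantom-style
default is a 6 breaths-per-minute sinusoid of 20 mm amplitude imaged at
2 Hz for 21 frames (one and a half periods).  Edges are anti-aliased by
supersampled coverage in a band around the boundary, so sub-pixel motion
is representable; interiors come from a scanline fill.

What it does *not* emulate — and hence what passing tests do not show
about clinical data: anatomical background texture, signal-dependent
(Poisson-like) noise, pulsed-beam readout artifacts, detector MTF/glare,
seed migration or deformation.  Synthetic noise levels are calibration
knobs, not claims about the panel.

Population simulations draw each patient's per-frame offsets from
Normal(bias, sd) independently per axis, with per-field seeds derived
from one root seed (`numpy` SeedSequence), and return lazily renderable
fields so memory stays flat.  The population scenes use a 256-px matrix
with a compact 24 mm aperture and a 3 mm-amplitude trace — small enough
to render thousands of frames quickly, while the phantom-style tests
exercise the full 1024-px matrix with the 20 mm trace.  Verified
recovery at 8 patients × 7 fields × 50 frames: Σ matches the realized
bias SD and σ the within-patient SD within three standard errors plus a
0.01 mm sub-pixel localization allowance; noise-free offset recovery is
RMS ≤ 0.09 mm (half a pixel).

## Numerical choices and degenerate inputs

- Reflective padding for the LoG convolution (inert for interior
  apertures, pinned for reproducibility).
- All-constant frames raise a degenerate-image error on direct reads and
  are flagged (not dropped) in series mode, preserving acquisition
  indices.
- Single-pixel regions cannot be traced (degenerate-contour error);
  fields below 400 px² are rejected as no-field.
- A frame with zero detected markers has no COM (explicit error rather
  than NaN propagation).
- Field statistics require ≥ 2 included frames; Σ requires ≥ 2 patients
  (the CLI omits Σ with a warning for a single patient).
- Statistics contain no randomness: identical inputs and config give
  bit-identical outputs, and every run writes its resolved config.

## Known limitations

- The aperture center of a strongly non-convex aperture can fall outside
  the open region; the centroid convention is kept for continuity but
  per-leaf reconstructions are out of scope.
- Boundary tracing assumes the filled field is simply connected after
  hole-filling; pathological 1-px-wide pinches would make the Pick-based
  area approximate (bounded by the tested 1.5 px²).
- The edge-margin filter uses the centroid-to-boundary distance, which
  under-estimates occlusion for a seed oriented along the edge by up to
  half its length.
- Real frame rates, beam holds and couch corrections are not modelled;
  series timing assumes uniform acquisition at the configured rate.
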