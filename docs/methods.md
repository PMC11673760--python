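# Methods

This note documents the models and procedures `bubblekit` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what validation on synthetic data does and does not
show about real acquisitions.

## Optical segmentation chain

Brightfield micrographs of lipid-shelled microbubbles show each bubble as
a dark annulus (the defocused shell) around an interior slightly brighter
than the surrounding field; polystyrene calibration beads appear as solid
dark disks. The segmentation chain runs, in order:

1. **8-bit conversion.** 16-bit frames are mapped linearly from the
   frame's own [min, max] onto [0, 255], rounding halves away from zero
   (the display-range convention of common image-analysis tools). A
   constant frame maps to zeros with a warning. A fixed source range can
   be supplied instead; the acoustic pipeline uses the full 16-bit range
   so that intensity *ratios* survive conversion (see below).
2. **Polarity.** Bubbles and beads are darker than the background, so the
   frame is inverted before further processing (`polarity="dark"`, the
   default; a flag handles bright-object data).
3. **Gaussian blur**, σ = 1 px by default. A normalized convolution with
   reflective boundaries; σ = 0 is the identity. One pixel of smoothing
   suppresses shot noise without eroding the smallest objects the chain
   must size (0.5 µm-radius beads are ~3 px at the default 0.16 µm/px
   calibration; larger σ visibly biases their recovered radius upward).
4. **Background subtraction** by greyscale morphological opening with a
   disk (radius 50 px by default) — the rolling-ball analogue. Everything
   wider than the structuring element is treated as background
   (illumination gradients, slow shading) and subtracted; the result is
   clipped at 0. Radii ≤ 20 px use the exact disk footprint; larger radii
   use a sequence decomposition whose deviation from the exact opening is
   negligible at background scales. Near a frame edge the estimate is
   biased low by roughly `gradient × radius`, an artifact shared by all
   morphological background estimators; with the default radius this is
   well below any object's contrast.
5. **Autothreshold.** Either the Kapur maximum-entropy criterion (the sum
   of Shannon entropies of the normalized background and foreground
   grey-level distributions) or Otsu's between-class variance, maximized
   by exhaustive scan over the 256-level histogram. Only splits at
   occupied bins are scored: moving an empty bin between classes does not
   change the partition, so each distinct partition is scored once at its
   lowest level, which makes the lowest-level tie rule exact instead of
   at the mercy of floating-point round-off. A single occupied bin has no
   valid split and is an error (the full chain treats a featureless frame
   as "no particles").

   *Default method.* Both operators are implemented and selectable; the
   package default is **Otsu**. On fields of compact dark objects over a
   flat background the grey-level histogram is a large background mode
   plus a thin foreground tail; the entropy criterion then places the
   threshold deep in the background-noise tail and the binarized
   footprints grow by ~2 px of edge skirt, while the between-class
   variance criterion lands near half the object amplitude and recovers
   known radii to a few percent. On richly textured real micrographs the
   entropy criterion is often preferable; it remains one flag away.
6. **Binarization** with strict comparisons (`> level` for bright
   objects), making the two polarities exact mirror images under
   intensity inversion, followed by **hole filling**: a bubble's dark rim
   encloses a brighter core, and the particle is the filled footprint.
7. **Watershed declumping.** Touching objects are split along ridge lines
   of the Euclidean distance transform. Markers are the h-maxima
   (prominence ≥ 1 px, after smoothing the distance map with σ = 1 px) so
   shallow boundary noise does not over-segment; every connected
   component is guaranteed at least one marker (at its distance-transform
   maximum), so the watershed never merges components and never drops
   one. Two equal disks whose centers are separated by 1.2× their radius
   produce a neck 0.2 r shallower than the cores, so pairs of radius
   ≥ 5 px split reliably.
8. **Outlier-pixel removal**, applied to the mask after the watershed:
   any pixel deviating from its neighborhood median (disk radius 2 px) by
   more than the configured delta is replaced by that median. On a binary
   mask this deletes isolated speckle while leaving solid regions intact
   (a large disk changes area by well under 1%).
9. **Measurement.** Per labeled object: area (pixel count × pixel area),
   perimeter (Crofton four-direction estimator — the convention inherited
   from ImageJ-style tables; chain-code perimeters differ by a few
   percent and are *not* interchangeable), circularity `4πA/P²` clamped
   at 1, solidity `A/A_convex`, equivalent-circle radius `√(A/π)`, and
   centroid. Objects touching the frame border are flagged and excluded
   by default (a partially imaged bubble biases sizing); the flag is
   configurable. Digitized-disk circularity oscillates ~0.5% around 1
   under the Crofton estimator, so "circularity → 1 with radius" holds as
   convergence, not as per-step monotonicity.
10. **Shape filtering.** Closed-interval criteria on circularity,
    solidity and radius separate bubbles from debris; a 3:1 ellipse has
    circularity ≈ 0.7 and is rejected by the customary 0.8 floor while
    true disks (≥ 0.99) pass. Out-of-focus bubbles are real particles and
    are *counted* — the default criteria must not exclude them, only
    non-circular debris.

The chain is deterministic (no RNG anywhere) and stage errors propagate
with the stage name attached.

**Known sizing bias.** With threshold-based footprints the recovered
radius carries a positive bias of up to ~1 px where the intensity edge is
soft: the autothreshold sits somewhat below the half-amplitude point of
the blurred edge profile. For sharp-edged beads the bias is < 7% at the
default settings; for rim-rendered bubbles it is ~0.5–1 px. This mirrors
the ±10–17% biases reported when such chains are calibrated against
1–3 µm bead standards, and is why bead calibration is part of the
workflow rather than an afterthought.

## Population statistics

- **Binning rule**: `n_bins = round(√N)` (half away from zero, floor 1)
  over the pooled radii of all images of a sample; the histogram spans
  [min, max] with the last bin closed on both edges, so mass is conserved
  exactly. Radii are pooled across replicate images (five per chamber in
  the standard protocol), not averaged per image first.
- **Diameters** are `2 × radius`; size standards are specified by
  diameter, the pipeline measures radii.
- **Imaged volume**: `rows × cols × pixel_size² × chamber_height ×
  10⁻¹² mL`. For 1000×1000 px at 0.2 µm/px in a 10 µm chamber this is
  4×10⁻⁷ mL.
- **Concentration**: `mean per-image count / imaged volume × dilution`.
  The quoted ± is the *SD of the per-image counts* propagated through the
  same division — i.e. replicate-frame variability, not a standard error;
  the choice is labeled in every output. A single image yields SD 0 with
  a warning. A smaller imaged volume resolves smaller concentrations.

## Acoustic well analysis

Samples are injected into 8 mm wells bored in an agarose phantom and
imaged in B-mode before and after injection. Wells are circular in plan
but present as an echo band, so the default ROI is a rectangle of
physical width 8 mm (via the mm/px pitch) and a configurable on-screen
height, centered on the well; a circular ROI is available. Analysis
steps:

- 16-bit frames are converted to 8-bit using the **fixed full-scale
  mapping** (0 → 0, 65535 → 255) rather than per-frame min/max: the
  decibel statistic is a ratio of intensities across frames, and a
  per-frame offset-and-gain would not cancel from it.
- The pixelwise mean of the pre-injection (background) frames is
  subtracted from each post-injection frame, removing stationary
  transducer artifacts. Results are clipped at 0 by default (greyscale
  cannot go negative), which biases pure-noise wells slightly positive;
  `clip=False` gives the unbiased diagnostic. Because subtraction and ROI
  averaging commute (tested as a property), the order does not matter for
  mean intensities.
- `I_dB = 10·log₁₀(I_after/I_before)` uses the *raw* after/before ROI
  means, so a saline control well reads 0 dB. The statistic is invariant
  to common intensity scaling and antisymmetric under swapping its
  arguments. A zero baseline is an error; a zero post-injection mean
  reports −∞ with a warning.
- The panel summary reports mean ± SD of the after intensity across
  replicate wells, and the panel dB is computed from the panel *means*
  (not the mean of per-well dBs, which would weight noisy wells equally).

## Synthetic fixture generator

No public image sets with exact ground truth exist for this workflow, so
the generator is the test bed. It is a statistical stand-in, not a
physics model: no diffraction PSF, no wave propagation.

- **Brightfield**: a uniform background level (default 45 000 on the
  16-bit scale) shaded by a diagonal linear ramp of configurable
  fractional amplitude. Bubbles are rendered as a dark annulus
  (fractional depth 0.55, band width max(2.5 px, 0.3 r)) with a slightly
  brighter core (+0.10), with error-function edge profiles of 1 px
  softness and the outer intensity edge centered exactly on the true
  radius — this exercises both threshold polarities and the hole-filling
  step. Beads are solid disks (depth 0.60) with 0.5 px edges (solid
  polystyrene is sharp to within pixel antialiasing). Out-of-focus
  objects (a configurable fraction) get 2.5 px edges at 0.8× depth — they
  fade but remain countable, as defocused bubbles are in real chambers.
  Object count is Poisson around the target; radii are fixed or
  lognormal. Aggregate pairs are placed at center separations uniform in
  [1.2, 1.8] × (r₁+r₂)/2 so the watershed is genuinely exercised; all
  other placements are rejection-sampled to prevent accidental contact,
  and objects keep an 8 px margin from the frame border. Additive
  Gaussian noise (default SD 300 on the 16-bit scale, ≈1% of background)
  comes last. One seeded generator per call: the same seed re-renders
  bit-identically; the seed is recorded in the ground truth.
- **Ground truth** carries one row per object (center, radius, aggregate
  and defocus flags) and a noiseless footprint labeling whose
  per-object area matches πr² to sub-pixel accuracy.
- **B-mode**: intensities are specified on the 8-bit scale and stored as
  16-bit (×257). The background is `background_mean` times a
  multiplicative speckle field — Rayleigh noise smoothed with a 1 px
  kernel and rescaled to mean 1 and relative SD `speckle_scale` (default
  0.2) — and each well disk adds `well_intensity_lift` to the local mean,
  so the expected ROI mean is exactly `background + lift` and converges
  to it as the speckle scale → 0. The 1 px smoothing correlates
  neighboring pixels, so effective sample sizes in ROI means are roughly
  area/16, which the statistical tests account for. Real beamformed
  speckle has depth-dependent texture and range-dependent gain that this
  model deliberately omits.

**What passing tests show — and don't.** Parameter recovery on these
fixtures demonstrates that the chain is internally consistent: it returns
what the renderer put in, under noise, shading, aggregation and defocus.
It does not certify accuracy on real micrographs, where the point-spread
function, shell contrast and debris morphology differ; for real data the
bead-calibration step remains the ground truth anchor.

## Defaults and problem sizes

Blur σ 1 px, background radius 50 px, outlier radius 2 px / delta 50,
minimum area 4 px, Otsu threshold, dark polarity, border exclusion on —
all logged per run and written to `run_config.yaml` beside every batch
output. Fixture defaults: 0.16 µm/px, 10 µm chamber, 1024×1024 frames
(the validation suite uses 512×512 frames and 20-frame batches, which
give a few hundred objects per condition — enough that recovery error is
bias-dominated rather than count-limited). No canonical microscope pixel
size or field of view is claimed; both are configuration.

## Limitations

- Sizing near the resolution limit (object radius ≲ 2 px) is dominated by
  pixelation; the generator warns when asked to render such objects.
- The concentration route assumes every particle in the chamber volume is
  in (or near) the focal plane — the single-plane thin-chamber geometry;
  it is not valid for thick chambers.
- The decibel change quantifies relative echogenicity through the
  scanner's processed greyscale; absolute scattering cross-sections or
  attenuation in dB/cm would require raw channel data that beamformed
  B-mode images do not preserve.
- Multi-channel/fluorescence images and GUI workflows are out of scope.
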