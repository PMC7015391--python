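# Methods

## Scope and model

`sma-ultrasound` measures three architecture parameters of a pennate muscle
from a single longitudinal B-mode scan: the **pennation angle** θ, the
**fascicle length** L_f, and the **muscle thickness** t.  The scan is assumed
to show the proximal side on the left, fascicles angled upward to the left,
and the two aponeuroses as bright, near-horizontal bands (images can be
flipped on load when acquired the other way).  Fascicles are modelled as
straight lines; curved-path estimation is out of scope.

Angle conventions (degrees from the horizontal, image rows growing
downward):

* fascicle angle β — positive rising toward the left (pixel slope `+tan β`);
* aponeurosis angle α — positive descending toward the left (pixel slope
  `−tan α`);
* pennation θ = β + α, identical to the geometric angle between the
  composite fascicle line and the deep aponeurosis line.  The identity is
  asserted at run time against the signed vector angle
  `atan2(apo × fasc, apo · fasc)`.

L_f is the Euclidean length of the chord through an anchor point on the deep
aponeurosis (by default the midpoint of its detected support) at inclination
β, up to the superficial aponeurosis; t is the mean per-column vertical
distance between the two aponeurosis paths over their shared support.  For
the small aponeurosis inclinations the pipeline accepts (|α| < 45°, in
practice < 10°), vertical and perpendicular thickness differ by well under
1%.

## Pipeline

1. **Field of view.**  Scanner exports embed the echo image in a dark
   information frame.  A 5×5 box blur and a 7×7 median filter wash out the
   frame text, the image is binarized against a local median (window = 1/8
   of the image height, computed with a rank filter), the resulting speckle
   salt is consolidated by a 5×5 closing plus hole filling, and the bounding
   box of the largest bright connected component is taken as the field of
   view.  A component smaller than 20% of the image raises `FovNotFound`
   and the user is pointed to manual cropping (`--crop manual
   --crop-rect x,y,w,h`).  The comparison is strict (`>` the local median):
   a uniform frame sits exactly at its median and stays off, while speckle
   keeps roughly half of the echo field above it.  Consequence: detection
   requires a textured field of view; synthetic scans rendered without
   speckle are analysed with `--crop none` instead.

2. **Aponeuroses.**  Heavy denoise preset (CLAHE at clip limit 0.003 →
   non-local means with h = 1.6·σ̂ → 1-px Gaussian) → Sato tubeness at
   σ = 10 px (bands become smooth ridges) → FFT → brightness-proportional
   magnitude threshold → angular wedge mask suppressing feature angles
   10°–80° (the expected fascicle directions) → inverse FFT → Canny (σ = 2,
   hysteresis at the 0.85/0.95 gradient quantiles) → column-wise chaining
   of edge pixels into near-horizontal polylines (lateral gaps ≤ 10 px
   bridged, 3 px/column vertical tolerance, minimum span 50% of the width,
   fitted |angle| < 45°).  Polylines within 2.5·σ of one another are the two
   edges of a single band and are merged; the topmost cluster is the
   superficial aponeurosis, the bottommost the deep one, and intermediate
   lines (septa, fascia) are discarded.

   **Centerline registration.**  Each path represents the band *centerline*,
   so thickness is the centerline-to-centerline distance.  The Hessian ridge
   of a band flanked by the bright striated muscle belly on one side is
   displaced 1–2 px toward that side; the Canny midline inherits the bias.
   Each path is therefore registered per column onto the band itself in a
   stripe-suppressed image (the denoised image with the same wedge mask
   applied): within a window around the estimate, the band's top and bottom
   shoulders are the extrema of the vertical derivative-of-Gaussian
   (σ = 1.5 px) and the centerline is their midpoint.  Because the band's
   intensity profile is symmetric about its centerline, this registration is
   insensitive to asymmetric backgrounds; residual bias on phantoms is
   < 0.8 px at the strongest supported speckle.

   A total-least-squares (orthogonal PCA) line is fitted to each path.
   Fewer than two registrable bands raises `ApoNotFound`, whose message
   suggests manual cropping or a higher tubeness sigma — the two remedies
   that work in practice (higher σ helps weakly contrasted bands; cropping
   removes bright structures below the muscle).  Raising σ from 8 to 14
   changes recovered angles by < 1° on well-contrasted scans, but large σ
   can distort the band edges slightly, so 10 is the default and 8 is
   preferred when it works.

3. **Fascicle orientation.**  `n` overlapping ROIs (default 3, each 60% of
   the field width) are placed on the *unfiltered* field of view with left
   edges at `i·(W−w)/(n−1)`, spanning 90% of the local inter-aponeurosis
   gap upward from the deep aponeurosis, inset 10 px from both bands.
   Per ROI: light denoise (3×3 median → non-local means at h = 0.9·σ̂) →
   Hann-windowed FFT of the mean-subtracted ROI with the mean re-injected
   as a DC pedestal → brightness-proportional threshold → inverse FFT →
   Sato tubeness at σ = 2 px → cubic-B-spline gradients (prefilter to
   spline coefficients, exact derivative kernel [½, 0, −½] along one axis,
   smoothing kernel [⅙, ⅔, ⅙] along the other; quasi-isotropic) →
   structure tensor, Gaussian-smoothed with window σ (default 4; 0 = no
   smoothing) and pooled (averaged) over the ROI.  The dominant feature
   angle is `−½·atan2(2⟨I_xI_y⟩, ⟨I_y²⟩−⟨I_x²⟩)` (the sign converts the
   y-down tensor angle to the rising-left convention) and the coherency is
   `(λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1]`.

   Why the window: hard thresholding of an unwindowed, leaky DFT keeps an
   asymmetric subset of leakage bins and snaps the reconstructed
   orientation toward lattice angles (errors over 1° on 64–128 px ROIs);
   with the Hann window the surviving bins straddle the true frequency and
   the error drops to ±0.3°.  The windowed spectrum has its own
   auto-threshold constant (`spectrum_auto_k_fascicle`, default 0.05 ×
   mean brightness × peak magnitude), chosen from measured margins on
   phantoms: fascicle fundamentals sit near 0.16 on that scale, the
   strongest pure-speckle bins near 0.006, so 0.05 keeps the texture with a
   ~3× margin and rejects structureless ROIs with a ~7× margin.  A ROI
   whose spectrum is emptied by the threshold (flat or pure speckle) is
   flagged invalid with coherency 0.

   ROIs with coherency below 0.05 are dropped; the remaining per-ROI angles
   are combined by the configured statistic (greatest / mean / median;
   median by default, as the most outlier-resistant of the three).  No
   valid ROI at all raises `NoFascicleOrientation`.

   **σ sweep.**  `sigma_sweep` tabulates angle and coherency for σ = 0…7
   (`--sigma-test` prints it).  The quality warning fires when the
   orientation increases strictly with σ over the usable rows — the
   signature of insufficiently resolved fascicles — or when no σ yields a
   usable orientation at all.  The second branch is what a structureless
   (pure-speckle) ROI triggers: on an isotropic input the angle-vs-σ
   sequence has no preferred direction, so a monotonicity test alone
   cannot flag it reliably.

4. **Architecture.**  θ = β + α with α from the deep aponeurosis line fit;
   L_f from the parametric chord `P(t) = anchor + t·(cos β, sin β)`
   (numerically stable up to β = 90°), intersected with the detected
   superficial path inside its support and with its fitted line outside
   (setting `extrapolated=True`); t as the mean per-column gap.  A
   pennation below 0.5° has no well-defined intersection and raises
   `NoIntersection`.  Results carry px values, mm values when calibrated
   (`mm_per_px` from `calibrate(line_px, known_mm)`), per-ROI angles and
   coherencies, and optionally the full parameter echo.

Every stage is deterministic; analysing the same image twice yields
bit-identical results, which is why repeat-analysis reliability is not a
meaningful metric for this tool (agreement with an independent method is,
hence the Bland-Altman helper: bias = mean difference, limits = bias ±
1.96·sample SD).

## Synthetic phantoms

`sma.phantom` renders the validation targets: a muscle belly with a
rectified-sinusoid striation texture at a known fascicle angle (rectified so
the stripes are bright ridges, which the tubeness filter treats like real
fascicles), two flat-topped aponeurosis bands at known centerline positions
and inclinations, multiplicative speckle `pixel × (1 + N(0, σ_s))` clipped
to [0, 1], and optionally a dark information frame with text-like glyph
clutter and a tick-marked scale bar (4 mm tick spacing).  Ground truth is
computed analytically from the geometry: θ* = β + α_deep,
t* = centerline gap at mid-width, L_f* = t*/(sin β + tan α_sup·cos β).

Defaults define the standard study conditions: 512×400 px field, superficial
band at 80 px, gap 140 px, band thickness 6 px, β = 20°, stripe period 14 px,
speckle σ_s = 0.15.  The recovery grid crosses β ∈ {10°, 20°, 30°} ×
gap ∈ {80, 140, 200} px × σ_s ∈ {0, 0.15, 0.3} with seeds derived
deterministically from a base seed; σ_s = 0.3 is the documented upper limit
at which all recovery tolerances (pennation 2°, thickness 3%, length 5%)
hold.  These sizes keep the full grid under half a minute on one CPU.

What the phantom does **not** emulate: physical point-spread functions,
attenuation with depth, refraction and reverberation artifacts, curved
fascicle paths, fascicle thickness variation, intramuscular vessels and
fat, and inter-subject anatomical variability.  Passing the recovery grid
therefore demonstrates that the geometry and estimators are implemented
correctly and are robust to multiplicative speckle — not that the pipeline
will segment every clinical scan; on real data the documented failure modes
(low-contrast aponeuroses, bright sub-muscular structures) still require
the manual-crop / higher-σ escape hatches.

## Numerical choices and degenerate inputs

* All rasters are float64 in [0, 1]; RGB loads via BT.601 luma; 8/16-bit
  integers scale by their dtype maximum.  Quantization to 8 bits happens
  only on save.
* Rectangles are 0-based, top-left origin, half-open.
* TLS line fits use SVD; a vertical point set is rejected rather than
  fitted.
* Angles are folded to (−90°, 90°] with −90° mapped to +90°.
* Constant images: tubeness and denoise return them unchanged (response 0);
  orientation flags them invalid rather than emitting an arbitrary angle.
* The spectral threshold always preserves the DC bin, so an over-aggressive
  cut degrades to a flat image at the mean level instead of zero.
* Ties in the σ-sweep monotonicity test break toward "no warning" (strict
  inequality required).
* Batch mode isolates failures per file (logged, skipped) because a single
  unanalysable scan should not abort a session's worth of images; the exit
  status is 0 when at least one image succeeds.

## Known limitations

* Straight-fascicle and straight-aponeurosis models only; curvature is
  deliberately out of scope.
* Thickness uses vertical distances, which overestimates perpendicular
  thickness by `1/cos α − 1` (< 1% below 8°).
* The FoV detector assumes a rectangular (linear-probe) field with speckle
  texture; sector probes and noiseless synthetic images need manual or
  disabled cropping.
* At most two aponeuroses are modelled; intermediate bright lines are
  discarded rather than interpreted.
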