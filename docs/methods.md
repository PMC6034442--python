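# Methods

`cowmon` estimates three welfare traits of dairy cattle — body
condition, mobility/lameness and weight — from sequences of overhead
depth frames captured by a single downward-looking 3D camera above a
walkway.  This note records the models, the numerical choices, and what
the synthetic test bed does and does not demonstrate.

## Camera model and metric scaling

The camera is a pinhole at height `m` above the floor with lens opening
angles `theta_horz` (default 58°, along the walkway) and `theta_vert`
(default 45°).  The field of view at distance `d` from the camera is

    w(d) = 2 d tan(theta_horz / 2),    h(d) = 2 d tan(theta_vert / 2)

so at the default 2.3 m mount the walkway-axis FOV is 2.5 m.  Pixel
`(i, j)` of an `nr x nc` raster views ground coordinates
`x = d * kx * (j - cx)`, `y = d * ky * (i - cy)` with
`kx = 2 tan(theta_horz/2)/nc`; evaluating this at each pixel's own
measured depth converts the image to millimetres in all three axes.

**Pixel areas.**  Volume integration needs the physical ground area each
pixel covers.  The nominal product `(d kx)(d ky)` is exact only for
fronto-parallel surface; on sloped surface seen off-axis a pixel's
footprint is stretched by the factor `(1 + x E'/d)` that the nominal
product misses, which we measured as a 12–26 % volume deficit on curved
test bodies.  `pixel_areas` therefore evaluates the Jacobian determinant
of the metric coordinates, `|dx/dcol * dy/drow − dx/drow * dy/dcol|`,
with central differences between in-mask neighbours, one-sided
differences at the mask boundary (the metric jump across the silhouette
must not leak in), and the nominal pitch as fallback.  The depth field
is smoothed with a mask-aware Gaussian (σ = 1 px) first so sensor noise
does not alias into areas.  On a flat fronto-parallel slab this reduces
exactly to the nominal product.

## Pre-processing

1. **Detection and segmentation.**  A pixel is foreground when it is at
   least `background_diff_min` (100 mm) closer than the stored empty
   background and closer than `near_threshold` (1.5 m).  Detection
   requires a connected foreground object of `min_area` (500 px).  The
   one-sided difference is deliberate: objects of interest are always
   closer than the background.
2. **Range gating.**  Pixels further than `range_threshold` (1.35 m from
   the camera) are discarded, removing legs and low flanks.  Both the
   1.5 m and 1.35 m cuts are distances from the camera; the range cut is
   rig configuration tied to the mount height (re-mounting the camera
   implies re-setting it to keep the same height-above-floor cut).
3. **Cleanup.**  The largest 4-connected component is kept (ties broken
   towards the earliest scan-order pixel), interior holes are filled,
   and missing pixels inside the mask are inpainted with a 5×5 masked
   median (iterated until closed).  Heights are measured against the
   per-pixel background depth, so floor slope and walls cancel.
4. **Curvedness.**  For the Monge patch `z = h(x, y)` we compute the
   Gaussian (K) and mean (H) curvature from Gaussian-derivative filters
   (σ = 5 px; raw depth is too noisy for direct second differences),
   take the principal curvatures `k1,2 = H ± sqrt(max(H² − K, 0))`, and
   form the curvedness `C = sqrt(k1² + k2²)`, normalised by its in-mask
   maximum.  Numerical details that matter: the in-mask mean height is
   subtracted first (the truncated derivative kernels have a small
   residual sum that would otherwise couple to the ~1300 mm absolute
   height and swamp the signal — and curvature is translation-invariant
   anyway); kernels are truncated at 6σ; the array is padded by odd
   reflection, which continues linear trends exactly, so an inclined
   plane yields identically zero curvedness; a map whose maximum is
   below 1e−6/spacing is treated as flat.
5. **Region classification.**  Zero-normalised cross-correlation of
   curvedness templates (front / rear / front-and-rear), thresholded at
   0.5.  Curvedness, not raw depth, is the matching input: it is
   invariant to the animal's absolute height.  Templates are generated
   deterministically at run time from the synthetic body model at the
   session's raster and mount height — template matching is
   scale-sensitive, so a template must match the geometry it is used at.
6. **Alignment.**  The top 5 % of curvedness values are thresholded, the
   connected survivor region with the longest major axis is taken, and
   the major-axis angle of its minimum-area bounding rectangle (range
   (−90°, 90°]) is the orientation; the segment is rotated by its
   negative about the mask centroid (bilinear, coverage-weighted for
   heights; nearest for the mask).  Rotations below 0.5° are skipped.

## Body condition: rolling-ball angularity

A grayscale morphological opening with a hemispherical structuring
element (default diameter 70 px, applied on the pixel grid) is the
digital rolling ball: it follows smooth, well-fleshed surface but cannot
enter sharp bony protrusions.  The scalar **angularity** is the mean
positive residual `original − opened` over the mask, in millimetres —
size-invariant across animals, and requiring no landmark detection or
tracking.  A farm-specific linear calibration maps angularity to the 1–5
condition scale; the slope is negative by constraint (bonier = leaner)
and predictions are clamped to [1, 5].  A multi-diameter sweep is
exposed (`angularity_sweep`) but not used in default scoring.

Numerical choice: heights and ball profile are quantised to 1/1024 mm
inside the opening.  Every value the min/max algebra touches is then
exactly representable, so anti-extensivity (`opened ≤ original`) and
idempotence hold *bit-exactly* in floating point; the quantisation is
three orders of magnitude below sensor noise.  Out-of-mask pixels are
set to a large sentinel so they never constrain the ball.

With sensor noise present, the noise floor dominates the absolute
angularity value (≈ 9 mm at 3 mm noise versus ≈ 2.5 mm noiseless on the
same body); the calibration absorbs this, but it means calibration
pairs must be scored with the same protocol (same ball, same session
statistics) as predictions.

## Mobility: spine arch

The spine appears as a ridge of high curvedness along the aligned
body's major axis.  Per frame:

1. **ROI** — top-percentile curvedness pixels inside a central band
   (half-width 0.3 of the mask's bounding-box height), after eroding the
   mask by 10 px: the silhouette rim is a depth cliff whose spurious
   curvedness would otherwise drag low nose/tail points into the fit.
2. **Crest points** — the highest point of each occupied column, on a
   lightly denoised height field (mask-aware Gaussian, σ = 2 px).  The
   column maximum is an extreme-value statistic; without denoising its
   upward noise bias varies with per-column ROI occupancy and bends the
   fitted parabola.
3. **Fit** — least-squares quadratic `a x² + b x + c` in metric
   millimetres, x re-centred at the cow centroid so the linear term
   cannot absorb arch magnitude (the quadratic coefficient is then
   invariant to position along the walkway).  One trimmed refit at
   2.5 RMS discards crest points where the fading ridge near nose and
   tail lets noise pull isolated points off the spine line; clean data
   is never trimmed, so the fit stays exact on noiseless quadratics.

With heights measured upward, a hunched (lame-posture) back gives
`a < 0` and the dip of a sound walking topline gives `a > 0`.  The
size-invariant **arch statistic** is

    arch = −a · L² / H

(L = metric mask length, H = mean crest height), so an arched back is
positive and a dipped one negative.  The session statistic is the
*minimum* of the per-frame arch over frames in which the animal is
actually walking (median metric centroid step ≥ 10 mm/frame; stationary
postures such as neck craning are excluded): it is the least-arched
moment of the passage.  A sound cow drops well below the decision
threshold at some point; a lame cow never does.  The classification rule
is `arch ≥ −0.3 → lame`, inclusive at the boundary.  The −0.3 constant
is the default; like any dimensionless threshold it should be
re-calibrated per installation, and the synthetic study conditions were
chosen so that a sound dipped topline falls clearly below it.  Note that
under this convention an exactly flat spine (arch 0) classifies as lame;
real sound toplines dip when walking.

Lateral (x–y plane) spine curvature and the use of the linear
coefficient for fore/hind localisation are out of scope; `b` is fitted
and available in the per-frame curve objects.

## Weight

The segmented back is assumed to cap a solid extending to the floor:

    M = Σ h(x, y) · area(x, y) · D

with per-pixel heights above the local background, Jacobian pixel areas
(above) and the density of water (D = 1000 kg/m³, configurable).  No
correction is applied for the omitted head and neck: the solid-to-floor
assumption over-counts under the visible back, which compensates.  Per
session the largest retained per-frame mass — the most complete view —
is the estimate.  Frames whose mask area exceeds 1.6× the session
median are excluded first as bunching (a following animal overlapping
the imaged one).

## Synthetic scene generator

The generator emulates the capture rig: floor at the mount distance,
side-wall bands, and a parametric cow back translated along the walkway,
with additive Gaussian depth noise and missing-pixel dropout applied
last under a single seed.  The body is a superellipsoid cap on a
pedestal over an elliptical footprint; the spine ridge forces the
midline to the exact metric parabola `H + p + a x² + b x` with a
Gaussian cross-profile; hooks, pins and vertebral knobs are Gaussian
bumps whose amplitude grows (8 mm per unit) and width shrinks
(45 mm / sqrt(1+s)) with the sharpness knob `s`, making ground-truth
angularity ordering monotone in a single parameter.  Rendering projects
a fine metric surface grid (≥ 3 samples per pixel) through the pinhole
model and keeps the per-pixel minimum depth — the exact first
intersection for this camera-above geometry.

Default study conditions (chosen once):

| parameter | default | why |
| --- | --- | --- |
| body (L × W × H) | 950 × 520 × 1300 mm | the whole back fits the FOV at back height; a full-size cow is only partially visible at a 2.3 m mount and its volume is not recoverable frame-wise |
| cap exponent / base fraction | 2.0 / 0.95 | keeps surface slopes below the ray-tangency limit, so no part of the back is self-occluded and the volume is physically measurable from above |
| spine arch `a` | +7e−4 mm⁻¹ (sound dip) | `a` scales as 1/L², so fixture-scale values are several times a full-size animal's; this dip puts the sound arch statistic near −0.44, clearly below the −0.3 threshold |
| spine prominence / width | 30 mm / σ 55 mm | a visible but anatomically modest ridge |
| noise / dropout | 3 mm / 1 % | Kinect-class depth noise at ~1 m range |
| frame raster | 480 × 640 (sensor default); 240 × 320 for long sequences | half resolution keeps 150-frame end-to-end runs cheap while leaving > 30 k px on the animal |

The analytic volume oracle integrates the noiseless elevation field by
midpoint quadrature at 0.4 mm spacing (several times finer than any
pixel pitch) and is the independent reference for all weight checks.

**What the generator does not emulate** — and hence what passing tests
do *not* show about farm data: legs and gait kinematics (the motion gate
is exercised only by rigid translation), head/neck/tail anatomy, coat
and wetness artefacts of real depth sensors (only i.i.d. Gaussian noise
and i.i.d. dropout), deformation of the back during locomotion, RFID
mis-reads, and real bunching geometry (a second identical body at fixed
offset stands in for it).  Calibration constants fitted on synthetic
herds (angularity→BCS slope, the practical scale of the arch statistic)
do not transfer to a real installation; the *procedures* do.

## Known limitations

* Bodies with steep visible flanks are partially self-occluded from a
  single overhead camera; their occluded volume is unmeasurable in
  principle, and the weight estimate is a lower bound there.
* The angularity scale depends on the noise floor of the sensor;
  calibration must be refreshed when the sensor or mounting changes.
* The arch statistic's −0.3 default is inherited as a convention and
  needs per-installation calibration.
* Orientation estimation assumes one dominant ridge; two animals in
  frame must be prevented by the walkway (bunching is only detected, not
  resolved).
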