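# Methods

## Signal model and fixtures

An `ECGRecord` is a 12 × N matrix of trace values in millivolts at a fixed
sampling rate, rows ordered I, II, III, aVR, aVL, aVF, V1–V6. WFDB input is
restricted to single-segment, format-16 (16-bit little-endian,
sample-interleaved) 12-channel records; ADC counts convert to mV as
`(adc − baseline) / gain`, and rows are permuted into the canonical order on
read regardless of on-disk channel order. Writing uses gain 1000 ADC
units/mV (1 µV/LSB), so a write/read round trip is exact to half an ADC
quantum (0.0005 mV). Records longer than 10 s are truncated to their first
10 s for rendering; shorter records are rejected because the layout
requires four full 2.5 s epochs.

Two generator families make every downstream stage testable without any
external dataset:

- **Sine validation records**: a·sin(2πft) in exactly one lead, all other
  leads 0 mV, default (0.5 mV, 1.25 Hz), 10 s at 500 Hz. The 12-record
  suite places the sine in each lead position exactly once.
- **PQRST fixtures**: each beat is a per-lead sum of five Gaussians
  (P, Q, R, S, T) with fixed template coefficients chosen for a plausible
  frontal/precordial pattern (aVR inverted, R-wave progression across the
  chest leads), placed on a beat schedule at the requested heart rate with
  ±2% RR jitter, ±5% per-beat gain jitter and 0.04 mV respiratory baseline
  wander, clipped to ±3 mV. Everything derives from one `numpy` generator
  seed, so fixtures are bit-reproducible. This is a rendering fixture, not
  a physiological simulator: waveform morphology does not vary with
  pathology, and interval durations are fixed.

## Paper layout and rasterization

The layout is the standard simultaneous-lead format: four columns of three
leads covering consecutive 2.5 s epochs (I,II,III / aVR,aVL,aVF / V1,V2,V3 /
V4,V5,V6) and a fourth row holding a 10 s lead II rhythm strip.

Calibration follows standard ECG paper: 25 mm/s, 10 mm/mV, rendered at
5 px/mm → 125 px/s and 50 px/mV. Ten seconds of trace occupy 1250 px; the
default margins (97 px left, 50 px right, 40 px top, 29 px bottom, four
240 px rows) make the canvas exactly 1397 × 1029 px. Margins are
configuration on `RenderSpec`, not magic numbers; the canvas equality is
asserted in tests. Each row carries a 1 mV × 200 ms calibration pulse
(50 × 25 px) drawn in the left margin, a lead label near the panel's top
edge, and a short baseline tick marking each panel start.

Pixel conventions: origin top-left, y downward, positive deflection
decreases y; panel baselines sit at row centers (y = 160, 400, 640, 880).
The grid (1 mm minor, 5 mm major) is anchored on the plot origin and the
first baseline so signal features land on grid lines. Grid ink is drawn
under the traces in reds (high red-channel values); trace ink is
near-black. That color separation is what lets the validation extractor
suppress the grid by thresholding the red channel alone.

Traces are stroked by an in-package rasterizer: each segment's polyline is
resampled to at least 150 points/s, densified to ≤0.25 px steps, and each
point deposits its arc-length weight bilinearly into the four neighbouring
pixels of a coverage buffer; clipping coverage at 1 gives an anti-aliased
~1 px stroke (≈0.2 mm pen width at 5 px/mm) whose ink centroid tracks the
true line centre to sub-pixel accuracy. This direct rasterizer exists
because the round-trip validation needs exact, manifest-recorded pixel
geometry; a plotting library's transform stack would obscure it.

The `RenderManifest` records, per panel: lead, time window, integer
bounding box, float baseline y and x-origin, px/s and px/mV, and a clipping
flag (traces leaving the ±118 px row half-span are clipped, flagged, never
an error). Canvas-level `ink_masks` list the label and marker rectangles so
measurement can exclude non-trace ink. Rendering is deterministic:
identical inputs produce bit-identical rasters.

## Photographic degradation (2.5-D scene model)

The degradation emulates photographing a printout with an image-space
model rather than a full 3-D renderer: every controllable factor of such a
scene — sheet deformation, workspace, orientation, sheet pose, camera,
lights, noise — is an explicit `SceneConfig` field, and the realized
transform is returned, which a 3-D pipeline would not expose as cheaply.
The discrete factor space is 8 sheet templates × 11 workspaces × 4
orientations = 352 geometric variations.

- **Sheet warp.** The forward map is a projective homography composed with
  a smooth in-plane displacement. The homography comes from rotating the
  sheet in-plane, tilting it (pitch/yaw, sampled within ±25°) about a
  pinhole at distance 2·max(w, h), and solving the exact 4-point DLT on the
  projected corners; if the projection would leave the frame the sheet is
  shrunk about its centre to fit, so the four corners of every valid
  configuration land inside the output image. Sheet templates 1–7 are
  low-frequency displacement fields (sag, S-fold, side bow, corner lift,
  ripples, twist, central bump) scaled by a sampled amplitude (2–12 px);
  template 0 is flat. The inverse warp uses the exact homography inverse
  plus first-order inversion of the small displacement. An identity
  configuration reproduces the input bit-for-bit.
- **Workspace compositing.** Backgrounds are procedural textures (wood
  stripe, fabric crosshatch, plain + noise families over 11 base colors)
  generated from a seed derived from (workspace id, config seed), rotated
  by orientation × 90°, and alpha-composited under the warped sheet.
- **Lighting.** Gain field = mean over lights of
  `intensity + gradient_strength · (projection on light direction)`, times
  an optional soft-edged shadow band at the configured opacity. Intensity
  1.0 with zero gradient and shadow is the identity; mean brightness is
  monotone in intensity; two opposed equal lights cancel each other's
  asymmetry.
- **Stucci noise.** Multi-octave (4) value-noise turbulence at spatial
  scale `noise_size`; the `noise_turbulence` knob scales both a local
  intensity modulation (±12% per unit) and a sub-pixel displacement
  (1.2 px per unit), producing stucco-like holes and bumps. Turbulence 0 is
  the identity. The field is synthesized at half resolution and bilinearly
  upsampled — it is smooth at the scales used, so this is invisible while
  halving cost.

Sampling ranges (documented defaults, all overridable): tilt ±25°, sheet
rotation ±15°, translation ±20 px, camera distance 1.05–1.35, intensity
0.6–1.2, gradient 0–0.25, shadow opacity 0–0.35, noise size 6–32 px,
turbulence 0–2. Dataset builds derive each record's RNG stream from
(global seed, crc32(record id)), so any subset rebuilds identically in any
order.

Not modelled (by design): physically based rendering, sensor noise models
(ISO grain, rolling shutter), crumpled-paper topology changes, and text or
sticker occluders. Equivalence to a true photographed-paper pipeline is
structural — same factor space and knobs — not pixel-level.

## Round-trip validation

`extract_trace` recovers a panel's (t, mV) series from a clean render: per
pixel column (panel inset by 2 px so neighbouring ink cannot bleed in), the
darkness-weighted centroid of trace ink after red-channel grid suppression
and ink-mask exclusion gives the trace centre; masked or empty columns are
interpolated, and more than 20% gaps is an extraction failure. Amplitude is
half the peak-to-trough range; frequency is the reciprocal of the median
peak-to-peak interval (peaks found at 0.6 × amplitude prominence). On clean
default renders the error bounds are ±0.02 mV (1 px) and ±2% frequency;
tests assert both.

`validation_report` renders harness grids of amplitudes/frequencies,
verifies lead placement (sine present in the intended lead, all 11 others
flat within 0.05 mV, each lead hit exactly once across the suite), and
computes Spearman's rho between measured and true values. Rank correlation
over a grid with repeated true values needs tied measurements to be
well-defined at rho = 1; the harness therefore correlates *grid read-outs*
— amplitude read in millimetres of deflection at 0.5 mm precision
(0.05 mV) and cycle length read in whole millimetres of paper — exactly as
an observer reads a printed trace against the grid, while the raw
sub-pixel measurements are reported alongside. Sub-pixel measurement error
(≲0.01 mV, ≲0.5%) is an order of magnitude below the read-out quantum, so
the quantization never masks a real error. A constant truth vector raises
(the correlation would be undefined) with instructions to widen the grid.

## Turing-test statistics

Rating tables hold one row per (item, rater): truth and vote in
{real, synthetic}, optional confidence 1–5. Accuracy pools all responses;
the true recognition rate restricts to truly-real items and the false
recognition rate to synthetic items, so accuracy is exactly their
response-count-weighted mean. CIs are Wald by default (the symmetric
intervals conventional in these studies), Wilson via option.

Fleiss' kappa is computed over the two vote categories on the complete
common rater count (items with deviating counts are dropped with a
warning), with a 95% CI from the Fleiss (1971) large-sample null variance.
All votes in one category makes expected agreement 1 and kappa undefined —
an error, not a fabricated value.

The confidence AUC maps each response to a signed ordinal score
(+confidence for a "real" vote, −confidence for "synthetic") and computes
the Mann–Whitney rank AUC of that score for discriminating truly-real
items, ties averaged, with a Hanley–McNeil 95% CI. Conventions fixed here:
real is the positive class and positive scores point at "real"; an AUC
below 0.5 is reported as-is. The AUC is invariant to strictly increasing
transforms of the score (property-tested).

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data:
12-record sine suites, 3-value harness grids over all 12 lead positions
(72 renders), 10⁴ scene-sampler draws, a 200 item × 10 rater simulated
null, and a 20-record paired build run twice for bit-identity. A clean
render takes ~60 ms and a full degradation ~2 s on one core.

Degenerate inputs are handled explicitly: aliasing sine frequencies,
heart rates outside 30–250 bpm, records shorter than 10 s, non-12-channel
WFDB files, unmapped lead names, poses that project the sheet to near-zero
area, single-category rating tables, and constant truth vectors all raise
typed errors. Ties in the frequency estimator are broken by the median
interval; rasterization rounds symmetric half-pixels via `np.rint`.
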