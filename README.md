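# ecgforge

Synthesize paper-style 12-lead ECG images from signal data, then simulate
photographing the printout — producing paired clean/degraded image datasets
for image-based ECG algorithm development and for benchmarking ECG
digitization tools.

Most AI-ECG models consume digitized signals, but large parts of clinical
practice still run on printed or photographed ECGs. Bridging that gap needs
image datasets that look like what phones actually capture: paper at an
angle, curled sheets, desk backgrounds, uneven lighting, and sensor/paper
texture. `ecgforge` builds such data synthetically, with every degradation
fully parameterized, seeded, and invertible back to the clean render.

## What it does

1. **Signal layer** — reads 12-lead WFDB records (`.hea`/`.dat`, format 16,
   ADC counts converted to mV via each channel's gain/baseline) and
   generates two fixture families: sine-wave validation records
   (a·sin(2πft) in exactly one lead, 0 mV elsewhere) and plausible PQRST
   waveforms (per-lead sums of Gaussians with seeded jitter).
2. **Rendering** — composes the standard AHA-style layout (3 rows × 4
   columns of 2.5 s epochs: I,II,III / aVR,aVL,aVF / V1–V3 / V4–V6, plus a
   10 s lead II rhythm strip) and rasterizes it on standard ECG paper:
   25 mm/s, 10 mm/mV, 1 mm/5 mm grid, 1 mV × 200 ms calibration pulse per
   row, at 5 px/mm — a 1397 × 1029 px canvas for a 10 s trace. A JSON
   manifest records every panel's pixel geometry (baseline, origin, px/mV).
3. **Degradation** — a seeded 2.5-D photographic scene model: one of 8
   sheet-deformation templates × 11 procedural workspace backgrounds × 4
   orientations (352 geometric variations), perspective camera tilt,
   directional lighting with soft shadows, and stucci-style multi-octave
   turbulence noise with size and turbulence knobs. The realized homography
   and displacement field are saved, keeping each degraded image paired to
   its clean source pixel-for-pixel.
4. **Validation** — measures rendered sine traces back from the pixels
   (grid-suppressed ink centroid per column): amplitude as half
   peak-to-trough, frequency as the reciprocal median peak interval, and
   Spearman rank correlation of measured vs true values over harness grids.
5. **Turing-test statistics** — for observer studies of real vs synthetic
   images: accuracy, true/false recognition rates with 95% CIs, Fleiss'
   kappa for inter-observer agreement, and AUC-ROC of the signed-ordinal
   confidence score (vote = real → +confidence, vote = synthetic →
   −confidence).

## Worked example

```python
import numpy as np
from ecgforge import (
    make_sine_validation_record, render_clean_image, measure_sine,
    make_synthetic_pqrst_record, sample_scene_config, degrade_image,
)

# render a validation sine and measure it back from the pixels
rec = make_sine_validation_record(sine_lead=0, amplitude=0.5, frequency=1.25)
image, manifest = render_clean_image(rec)
m = measure_sine(image, manifest, "I", true_amplitude=0.5, true_frequency=1.25)
print(f"canvas: {manifest.canvas_px[0]} x {manifest.canvas_px[1]} px")
print(f"measured amplitude: {m.measured_amplitude:.3f} mV (true 0.5)")
print(f"measured frequency: {m.measured_frequency:.3f} Hz (true 1.25)")

# photograph-simulate a synthetic PQRST record
ecg = make_synthetic_pqrst_record(heart_rate=72, seed=7)
clean, man = render_clean_image(ecg)
config = sample_scene_config(np.random.default_rng(42))
photo, record = degrade_image(clean, man, config)
print(f"scene: sheet {config.sheet_id}, workspace {config.workspace_id}, "
      f"orientation {config.orientation_id}, turbulence {config.noise_turbulence:.2f}")
```

prints:

```
canvas: 1397 x 1029 px
measured amplitude: 0.500 mV (true 0.5)
measured frequency: 1.250 Hz (true 1.25)
scene: sheet 5, workspace 4, orientation 1, turbulence 0.45
```

The measured 0.500 mV / 1.250 Hz confirm the raster's calibration: 0.5 mV ×
10 mm/mV × 5 px/mm = 25 px of deflection, and one 1.25 Hz cycle spans
(1/1.25) s × 25 mm/s × 5 px/mm = 100 px.

## Command line

```bash
forge make-validation --amplitude 0.5 --frequency 1.25 --out suite/
forge make-fixture --hr 60 --seed 7 --n 5 --out fixtures/
forge render --in fixtures/pqrst_hr60_seed7 --out clean/
forge degrade --in clean/ --out degraded/ --seed 42
forge build --in fixtures/ --out dataset/ --seed 42     # paired A/B build
forge validate --out report/
forge turing-stats --ratings ratings.csv --out summary.json
```

`forge build` writes `clean/` and `degraded/` image pairs, per-image
manifests and degradation records, and a `dataset.csv` index. Rebuilding
with the same seed is bit-identical, record by record, in any order.

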