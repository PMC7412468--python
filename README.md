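# respidepth

Remote respiration monitoring from depth-camera image sequences.

Depth cameras see a person's chest move towards and away from the sensor
by roughly 10 mm per breath. Averaging depth pixels over a chest region
recovers that motion — but only while the person holds still: body sway
while standing, or a hand and cup in front of the torso, swamps the
10 mm breathing signal. `respidepth` implements a motion- and
occlusion-robust estimator for people sitting or standing and facing the
camera, together with the classic mean/median baselines, rate and
signal-quality measures, breathing-derived activity-recognition
features, and a seeded synthetic depth-scene simulator so that every
stage can be validated without recorded data.

The method, per frame:

* a fixed-size **torso window** is anchored on skeleton joints and
  stabilised by matching candidate positions against the prediction of an
  adaptive per-pixel torso model (argmin of the masked sum of squared
  differences);
* pixels measured more than z_threshold = 30 mm *in front of* the
  predicted surface are flagged as an **occlusion mask** (dilated by a
  halo margin), and the masked region is reconstructed by **normalized-
  convolution in-painting** plus the model's remembered surface detail;
* each pixel is tracked by a **damped double-exponential filter**
  (state x, velocity ẋ, acceleration ẍ; prediction x + ẋ + ½ẍ);
* the breathing sample is the **difference** between a quasi-static
  reference — the 90th percentile of depth in a small throat region —
  and the mean depth of the chest band (20 % lateral margins). Whole-body
  motion moves both terms equally and cancels; chest expansion moves only
  the chest term. Inhalation is positive.

The respiratory rate is the dominant 0.1–1.5 Hz component per sliding
FFT window, refined between bins with **Quinn's second estimator**.
Evaluation measures: windowed accuracy (bin-exact rate agreement), rate
error in breaths/min (refined), Pearson correlation with Fisher CI
(`SE = 1/√(n−3)`), and in-band SNR in dB. See `docs/methods.md` for the
full model description and parameter rationale.

## Worked example

Simulate a 60 s seated recording breathing at 15 breaths/min, extract the
breathing signal, estimate the rate, and score it against the generator's
ground truth:

```sh
respidepth simulate --preset sitting --rate 0.25 --duration 60 --seed 7 --out rec
respidepth extract --method proposed --in rec --out signal.csv
respidepth rate --window 48 --step 4 signal.csv rates.csv
respidepth evaluate --est signal.csv --ref rec/ground_truth.csv --out report.json
```

which prints

```
wrote 1800 frames to rec
wrote 1800 samples to signal.csv
wrote 4 window estimates to rates.csv
accuracy=1.000 mean_error=0.00 bpm r=1.000 snr=34.9 dB
```

`rates.csv` holds one row per 48 s sliding window; the first begins

```
t_start_s,t_end_s,bin_freq_hz,refined_freq_hz,refined_bpm
0.0,48.0,0.2499999986,0.2500069215,15.0004153
```

i.e. the dominant FFT bin sits at 0.25 Hz (15 breaths/min) and Quinn
refinement places the peak at 15.0004 bpm — a 0.0004 bpm error against
the paced rate. The evaluation line says every window's rate bin matched
the reference (accuracy 1.000), the band-passed signal correlates with
the ground-truth trace at r = 1.000, and the breathing peak stands
34.9 dB above the remaining in-band power.

The three activity presets mirror increasingly hostile conditions:
`sitting` (no body motion), `standing` (10 mm body sway), `drinking`
(sway plus a cup-sized occluder moved in front of the chest every 8 s).
`respidepth study` crosses presets × methods × seeds and summarises
accuracy, error and SNR per cell — under sway and occlusion the chest-only
mean/median baselines collapse while the difference-based method keeps
recovering the paced rate.

As a library: `respidepth.generate_sequence` → `respidepth.process_sequence`
→ `result.signals["proposed"]`, then `respidepth.sliding_rate_estimates`
/ `respidepth.evaluate_pair` / `respidepth.compute_features`.

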