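# Methods

`respidepth` estimates a person's breathing signal and respiratory rate
from a sequence of depth-camera frames while the person sits or stands
facing the camera, possibly swaying and occasionally occluding their own
torso. This note documents the model, its parameters, the synthetic
scenes used for validation, and the numerical choices made where the
design was genuinely open.

## Signal model

Breathing moves the chest and abdomen towards and away from the camera by
roughly 10 mm per cycle at normal depth-camera distances (2–3 m). Depth
pixels covering the torso therefore oscillate at the respiratory rate,
superimposed on sensor noise, whole-body motion, and occlusions.

The processing chain per frame:

1. **Torso window.** A fixed-size rectangle is anchored on the skeleton
   joints: width = shoulder span × 1.2 (the shoulder joints sit inside the
   silhouette), height = neck-to-hip-mid span. Size and aspect ratio are
   frozen at initialisation; the user is assumed to keep an approximately
   constant distance (rescaling is out of scope).
2. **Candidate fitting.** Joint estimates jitter by 1–2 px, so every
   integer window position between the previous window position and the
   joint-derived one is a candidate. Each candidate's content is compared
   pixel-wise against the model's one-step-ahead prediction; the candidate
   with the smallest sum of squared differences over its *non-occluded*
   pixels wins. The sum is unnormalised; a fully masked candidate is
   assigned infinite energy (otherwise occlusions would win trivially),
   and ties break by distance to the previous position, then row-major.
   If the joint anchor jumps more than `search_cap` (8 px) on an axis, the
   search falls back to a full ±8 px sweep around the previous position.
3. **Occlusion mask.** Occluders are nearer than the torso they cover: a
   pixel is masked when `prediction − measurement > z_threshold` (30 mm, a
   value large enough to tolerate model lag and sensor noise). Invalid
   (zero) readings are masked too. The mask is dilated by a 3 px square
   halo to absorb infrared interference fringes on occluder edges.
4. **Occlusion recovery.** Unmasked pixels run the ordinary filter
   update; the masked hole is reconstructed by (a) in-painting the partly
   updated state by normalized convolution with a Gaussian kernel,
   (b) in-painting the previous state's unmasked cut with the identical
   kernel, and (c) adding the difference between the previous state's
   masked patch and that in-painted cut onto (a). The difference patch
   carries the remembered surface detail; the in-painted base carries the
   current elevation of the surrounding visible surface. A fully occluded
   window falls back to the model's memory verbatim.
5. **Temporal filtering.** Each pixel's state x, velocity ẋ and
   acceleration ẍ follow a damped double-exponential recursion:

       x_t  = α(x_{t−1} + ẋ_{t−1} + ½ẍ_{t−1}) + (1−α)·m_t
       ẋ_t  = βẋ_{t−1} + (1−β)(x_t − x_{t−1})
       ẍ_t  = γẍ_{t−1} + (1−γ)((x_t − x_{t−1} − ẋ_{t−1}) − d·ẋ_{t−1})

   The prediction `x + ẋ + ½ẍ` is what masking and candidate fitting
   compare against. After a recovery frame the recovered state is fed
   through the velocity/acceleration recursions so the derivatives stay
   consistent.
6. **Difference-based extraction.** The breathing sample per frame is
   `throat_p90 − chest_mean`: the mean depth of a chest band (20 % window
   margins left/right, spanning shoulder-mid to spine-mid vertically)
   subtracted from the 90th percentile of depth in a small throat box
   (20 % × 10 % of the window, centred on the neck joint). The throat
   barely moves with breathing but moves fully with the body, so
   whole-body motion cancels; the far-tail percentile suppresses a moving
   collar. The sign convention is inhalation-positive.

The rate is the dominant 0.1–1.5 Hz frequency of the extracted signal per
sliding FFT window, refined between bins with Quinn's second estimator
(complex bins k−1, k, k+1; the result is clamped to within half a bin and
to the band).

## Filter coefficients

The recursion coefficients are not dictated by the model itself, only by
the design goals: follow the signal with small delay and little
overshoot, suppress per-pixel sensor noise, and keep prediction errors
well under the 30 mm masking threshold. The defaults α = 0.5, β = 0.9,
γ = 0.9, d = 0.3 give, at 30 Hz, a step response that settles (±2 %)
within ~0.5 s with 8.7 % overshoot, and a constant-velocity prediction
lag of 0.3·slope per frame — below 0.2 mm for breathing-speed motion.
With d = 0 the ramp lag vanishes exactly; a small positive d trades a
sub-millimetre residual lag for reduced overshoot. The property tests
cover both regimes.

## Evaluation measures

* **Windowed accuracy** — fraction of sliding FFT windows whose dominant
  in-band bin equals the reference's bin (bin-index comparison: the
  window length defines the precision; 48 s ⇒ 1/48 Hz ⇒ 1.25 bpm).
* **Rate error** — |Quinn-refined rate difference| per window, in bpm;
  summarised by mean and median.
* **PCC** — Pearson correlation of the band-passed (5th-order
  Butterworth 0.1–1.5 Hz, forward–backward so zero-phase) signals, with
  the Fisher-transform CI `tanh(artanh r ± z·SE)`, `SE = 1/√(n−3)`.
* **SNR** — per window, `10·log10(P_signal/P_noise)` with `P_signal` the
  in-band power in the dominant bin ± 1 bin and `P_noise` the remaining
  in-band power; dB values are averaged over windows. The ±1-bin split is
  a documented choice (the ratio itself does not prescribe one); the
  half-width is configurable.

Activity-study spectral defaults use 48 s rectangular windows stepped by
one breathing period (48 s makes both paced rates, 10 and 15 bpm, land
exactly on bins, so a rectangular window is leak-free); belt-comparison
defaults use 40 s Hann windows stepped by 10 s.

## Breathing features

Seven descriptors per signal: standard deviation, skew and kurtosis of
the in-band amplitude-spectrum values; the sliding-window SNR; the median
inter-peak interval (Med-PP; peaks = local maxima with prominence ≥ 0.25
signal SD and minimum separation of one upper-cutoff period); normalised
spectral entropy (ESP = Shannon entropy of the normalised in-band power
spectrum / log₂(#bins), 0 for a pure tone, → 1 for white noise); and the
SD of the first difference scaled to mm/s (Std-Deriv). ESP and the
standardised moments are amplitude-scale invariant. Spectral moments are
moments *of the amplitude values*, not amplitude-weighted frequency
moments.

## Synthetic scenes

The generator renders what the method assumes about real recordings, with
every random component driven by one seed:

* a half-cylinder torso (depth bulge 80 mm) at 2000 mm, ~60 px wide in a
  112×152 frame (the scale of a Kinect-class camera at 2 m);
* breathing: chest/abdomen pixels move nearer by amplitude (default
  10 mm) × a weight map (0 at the shoulder line ramping to 1 over the
  upper 15 % of the torso, cosine-tapered at the lateral silhouette) ×
  sin(2πft); the ground-truth trace is the noiseless chest-centre
  displacement;
* a flat, breathing-static neck/head strip (0.35 of the torso half-width,
  ~12 cm — a realistic neck width) serving as the throat reference
  region;
* sway (standing/drinking presets): a 0.1 Hz, 10 mm common-mode depth
  sinusoid plus a bounded random walk (0.5 mm steps, ±15 mm), and a small
  lateral drift (±2 px sinusoid + walk). The amplitude is a free
  parameter — no quantitative sway measurement exists to pin it;
* a hand-held occluder (drinking preset): a disk 400 mm in front of the
  torso, radius 15 px, raised from below the torso to the chest and back
  every 8 s from t = 20 s on, with a thin intermediate-depth halo ring on
  its rim;
* sensor artefacts: zero-mean Gaussian depth noise with σ = 1.5 mm at
  2 m, scaling with (d/2000)² (noise grows with distance; the quadratic
  law is an adopted simplification), salt-and-pepper holes (p = 0.002),
  and i.i.d. Gaussian joint jitter (σ = 1.5 px).

Random draws are consumed in a fixed order regardless of which features
are enabled, so runs with the same seed differ only where a toggled
feature acts — this is what makes the common-mode and occlusion-recovery
comparisons exact.

**What the generator does not emulate:** clothing folds and collars,
torso rotation, depth-dependent window rescaling, multi-person scenes,
and systematic (non-Gaussian) depth biases. Passing the synthetic studies
therefore demonstrates the mechanics of tracking, masking, recovery and
common-mode cancellation — not robustness to clothing or posture change,
which only real recordings can show.

## Numerical and procedural choices

* Initialisation holes are filled by an iterated 5×5 valid-neighbour
  median; derivatives start at zero.
* The in-paint kernel is a Gaussian with σ = 5 px truncated at 3σ,
  applied separably with zero boundary; unreached hole interiors are
  filled iteratively (filled pixels become valid), doubling σ only if an
  iteration makes no progress.
* The initial window and the chest/throat rectangles are anchored on
  joint positions averaged over the first second (30 frames). A single
  jittered estimate can shift the small throat box onto the silhouette
  edge, where chronic edge masking corrupts the reference; averaging
  removes the jitter from the geometry while per-frame tracking still
  uses the instantaneous joints.
* The printed inequality form of the masking rule would flag pixels
  *behind* the predicted surface; occluders are in front, so the mask
  triggers on `prediction − measurement > threshold` (nearer by more than
  the threshold), which is the semantics the surrounding description of
  the rule requires.
* Depth values are integers (mm) on disk and float64 in the model; the
  window is half-open `[x, x+w) × [y, y+h)` with x = column, y = row,
  0-based, origin top-left.
* Irregular signal timestamps are linearly interpolated to a uniform grid
  before any spectral step.
* Paced rates are 10 and 15 breaths/min, i.e. 1/6 Hz and 0.25 Hz exactly
  (the rounded "0.17 Hz" label would not be bin-aligned at 48 s).

## Problem sizes used in validation

The synthetic studies run 300 s recordings at 30 Hz (9000 frames) in a
112×152 px frame with a ~52×104 px torso window, five seeds per
condition: sitting at both paced rates for the parameter-recovery study,
standing and drinking at 15 bpm for the robustness study. Oracle
equivalence checks use 100 random 12×12 frames (window fitting), 100
random 16×16 images (normalized convolution), 200-step scalar recursions
(temporal filter), and a 50-point frequency sweep against a 32× zero-
padded FFT (Quinn refinement).

## Known limitations

* The throat reference is small; a covered or occluded throat (scarf,
  head tilted forward) breaks the common-mode cancellation — the raw
  failure mode the difference design inherits from its geometry.
* No window rescaling: users must hold an approximately constant
  distance.
* Sustained occlusion of the *entire* breathing-affected region is
  unrecoverable in principle; recovery preserves the signal only while
  part of the breathing surface stays visible (the recovery study
  occludes 30 % of the window at the held-cup position, leaving the upper
  chest visible).
* The dominant-frequency estimator can lock onto strong in-band
  low-frequency motion; the difference extractor suppresses common-mode
  motion but not differential motion such as torso rotation.
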