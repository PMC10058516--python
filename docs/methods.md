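# Methods

This note records the model, the defaults and the design decisions behind
`emgspeed`, and what the synthetic benchmarks do and do not establish.

## Problem and model

The task is to recognize which of seven treadmill speeds (3–9 km/h, 1 km/h
apart) a person is moving at, from two channels of thigh surface EMG
(e.g. rectus femoris and vastus lateralis).  Surface EMG precedes the
mechanical movement, which is why it is attractive for exoskeleton
control; its drawbacks are noise and large window-to-window variability.

The recognizer has two stages:

* **Per-window classification.**  Each 200 ms window (200 samples at
  1 kHz, 50 % overlap, so one label every 100 ms) is reduced to 28
  features and classified by a three-layer sigmoid perceptron trained
  with per-sample back-propagation on the half squared error
  `E_k = ½ Σ_j (ŷ_j − y_j)²` with one-hot targets.  The network is
  intentionally minimal — no momentum, regularization, minibatching or
  modern activations — because its role is to supply label probabilities
  to the smoother, not to maximize single-window accuracy.
* **Temporal smoothing.**  Gait speed is an ordinal state that changes
  rarely and almost always to an adjacent value.  A hidden Markov model
  encodes this: hidden states are the 7 true speeds, observations are the
  7 classifier labels, the initial distribution is uniform, the
  transition matrix is the unit-sd Gaussian kernel on the state index,
  and the emission matrix is the classifier's offline confusion matrix.
  Viterbi decoding returns the most probable speed path.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| sampling rate | 1000 Hz | makes a 200 ms window exactly 200 samples |
| window / overlap | 200 samples / 0.5 | step 100 samples; trailing partial windows discarded |
| wavelet denoising | db5, level 4, soft universal threshold | σ from finest-detail MAD / 0.6745 |
| network sizes | 28–10–7 | input = 2 channels × 14 features |
| learning rate η | 0.1 | per-sample updates, shuffled each epoch |
| epochs / stop_tol | 500 / 1e-6 | stop when the change in mean epoch loss falls below stop_tol (absolute change, so a single oscillation does not stop training) |
| initialization | uniform(−0.5, 0.5), seeded | |
| transition sd | 1.0 (in state-index units) | `a_ij = φ(j − i)`; 1 km/h per index step |
| transition normalization | off | rows are densities; edge rows sum to ≈ 0.70.  Viterbi only compares within-column scores times path weights, so normalization changes little (see below); `normalize=True` gives row-stochastic rows |
| emission floor | 1e-6 | printed confusion matrices contain exact zeros; flooring keeps every observation sequence feasible |
| decoding history | 9 windows | the number of 200-sample/50 %-overlap windows covering a 1 s online buffer |
| calibration split | 30 %, stratified, seeded | the emission matrix is measured on held-out windows so it is not optimistically biased; `resubstitution=True` measures it on the training windows instead |

Feature order is frozen (`features.FEATURE_NAMES`): RMS, MAV, SSC, WL,
ZC, max, min, variance, IAV, WAMP, then MDF, MNF, peak frequency, total
power, channel-major.  ZC and SSC use a zero amplitude threshold; WAMP's
threshold is 5 % of the window RMS.  The spectrum is a Hann-tapered
periodogram of the full window; a zero-power window returns zero spectral
features with a warning.  Serialized models store the feature-name
fingerprint; changing the order invalidates them.

The feature *set* deserves a note: standard EMG practice names many more
candidate features than any one study enumerates.  The ten time-domain
and four spectral features here are the common core (RMS, MAV, ZC,
extremes, MDF, MNF) completed with the usual members of the same families
(SSC, WL, variance, IAV, WAMP; peak frequency, total power) to fill the
2 × 14 layout.  No automated feature selection is performed.

## The synthetic data generator

`synth.generate_emg` produces band-limited Gaussian noise (carrier)
modulated by a gait-periodic raised-cosine-squared burst envelope, plus
wide-band measurement noise:

* burst rate follows cadence, one burst per gait cycle, cycle duration
  falling linearly from 1.3 s at 3 km/h to 1.0 s at 9 km/h;
* burst amplitude is `base_amplitude × (1 + speed index)`;
* the carrier band rises with speed (low edge 20 → ≈ 128 Hz, high edge
  ≈ 170 → 450 Hz), so mean spectral frequency rises with speed.  Both
  band edges move because with a fixed low edge the flat measurement
  noise dominates the quiet gait phases at the slowest speed and breaks
  the spectral ordering;
* channel 2 shares channel 1's envelope at 80 % amplitude with
  independent carrier and measurement noise.

This reproduces the two gross properties the classifier exploits —
speed-increasing energy and speed-increasing spectral content, in bursty
gait-periodic packets — and nothing else.  There is no motor-unit
physiology, no electrode or skin model, no inter-subject variability, no
fatigue.  Tests passing on this generator show the *pipeline mechanics*
are correct (shapes, determinism, monotone separability, the benefit of
smoothing on temporally coherent streams); they do not certify accuracy
on real recordings.

The emission-level simulator (`synth.sample_observation_sequence`) sits
one level up: it draws classifier labels directly from a confusion
matrix's rows.  This is exact for studying the smoother in isolation,
because to the HMM the classifier *is* its confusion matrix.

## Numerical and degenerate-input choices

* All Viterbi arithmetic is in the log domain; zero probabilities become
  −∞ via a guarded log.  Argmax ties break toward the lowest state index
  (and the lowest class index in the network's readout).
* Printed confusion matrices carry rounding slack (one benchmark row sums
  to 1.016); row-stochastic validation therefore accepts ±0.02 and all
  consumers renormalize, after which rows sum to 1 within 1e-12.
* Wavelet shrinkage with an estimated threshold of exactly zero (an
  all-zero or noiseless signal) is the identity, avoiding 0/0 in the soft
  threshold.
* Windows shorter than the analysis length yield an empty window list
  with a warning, not an error; a window of zeros yields zero features
  with a warning for the spectral ones.
* A constant feature column standardizes to 0 with its scale clamped
  to 1, keeping the affine map invertible.
* Normalized vs raw transition rows: row normalization multiplies each
  row by a constant, so a path's score changes by the product of the
  constants of the rows it leaves.  On the 140-window benchmark fixture
  the raw and normalized decodings agree on all but at most one window
  (observed 1/140, and not necessarily at a block edge); the default
  reproduces the published raw kernel, normalization is opt-in hygiene.

## The benchmark simulation and its headline number

`pipeline.fusion_benchmark` simulates the standard test protocol — one
constant-speed block of 20 windows per speed, 140 windows per replicate —
at the emission level from the benchmark offline confusion matrix, and
Viterbi-decodes each block.  Averaged over 100 replicates the smoothed
macro accuracy is ≈ 90 % against a raw-label baseline of ≈ 73 %, with the
smoother winning every paired replicate.

Two cautions.  First, ≈ 90 % is what the *offline* confusion matrix
supports: its 6 and 7 km/h rows have diagonals of only 0.679 and 0.553,
and no decoder can recover per-window truth that the emissions do not
carry.  Published online results for this architecture are higher
(≈ 95 %), but those come from live classifiers substantially better than
the offline matrix used as the emission model; reproducing them requires
the original recordings, which are not public.  Second, macro accuracy
here is the unweighted mean of per-class recall (the diagonal of the
row-normalized confusion matrix), reported alongside plain micro
accuracy; with balanced blocks the two coincide.

## Known limitations

* The synthetic EMG scaling laws (amplitude and band vs speed) are a
  stand-in; no quantitative physiological claim is made.
* The causal rolling-history decoder trades accuracy for latency: it
  emits the last state of each sub-path, which is noisier than smoothing
  in hindsight.  Around speed transitions it reduces errors relative to
  the raw classifier on average (226 vs 318 transition-window errors over
  100 paired stress-test seeds on a 3→5→7 km/h schedule) but not on every
  seed.
* No gait-event (heel-strike) anchoring: windows are free-running.
* No Baum–Welch re-estimation or forward–backward posteriors: A is fixed
  analytically and B is measured once, offline.
* The seven-speed alphabet is fixed; finer speed resolution would need a
  different transition kernel scale and retraining.
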