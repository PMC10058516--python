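# emgspeed

Walking/running **speed recognition from two-channel surface EMG** for
lower-limb exoskeleton control.  Surface EMG precedes the movement it
drives, so a classifier on short EMG windows can anticipate the wearer's
gait speed; but per-window classification is noisy, and raw label streams
jump between speeds in a way a human gait never does.  `emgspeed` fuses
the two standard remedies:

1. a deliberately plain **three-layer back-propagation network**
   (28–10–7, sigmoid everywhere, per-sample gradient descent) that maps a
   28-dimensional feature vector — 10 time-domain + 4 spectral features
   per channel, from 200 ms windows with 50 % overlap — to one of seven
   treadmill speeds, 3–9 km/h;
2. a **hidden Markov model over the ordinal speed states** that smooths
   the per-window labels.  Speeds change slowly and to adjacent values,
   so the transition matrix is a Gaussian kernel on the state index,
   `a_ij = φ(j − i)` (unit sd); the initial distribution is uniform,
   `π_i = 1/7`; and the emission matrix `b_ij = P(label j | true speed i)`
   is the classifier's *offline confusion matrix* (zeros floored at 1e-6).
   Decoding is Viterbi

   δ₁(i) = π_i b_i(o₁),  δ_t(i) = max_j [δ_{t-1}(j) a_ji] · b_i(o_t),

   run causally over a rolling 1 s history (9 windows), emitting the last
   state of each decoded sub-path.

No recordings ship with the package.  A synthetic-signal module generates
speed-dependent surrogate EMG (gait-periodic bursts of band-limited noise
whose amplitude and spectral content rise with speed), and an
emission-level simulator draws classifier labels directly from a confusion
matrix — so every stage is testable, and the smoothing stage can be
benchmarked against the published confusion matrices in
`emgspeed.reference`.

## Worked example

End to end on synthetic data — simulate 3 s of treadmill EMG at each of
the seven speeds, denoise (db5 wavelet, level 4, soft universal
threshold), window, extract features, train, and decode:

```python
import numpy as np
from emgspeed import (SpeedProfile, SynthConfig, generate_emg,
                      train_offline, decode_online, evaluate)
from emgspeed.preprocess import WindowSpec, denoise_wavelet, segment_windows
from emgspeed.features import extract_features

profile = SpeedProfile(tuple((s, 3.0) for s in range(3, 10)))
rec = denoise_wavelet(generate_emg(profile, SynthConfig(seed=1)))
windows = [extract_features(d, rec.sampling_rate, label=lab, index=i)
           for i, (d, lab) in enumerate(segment_windows(rec, WindowSpec()))]
clf, hmm = train_offline(windows, seed=2, epochs=200)

X = np.vstack([w.values for w in windows])
true = np.array([w.label for w in windows])
print("BP-only macro:", round(evaluate(clf.predict(X), true).overall_accuracy, 4))
print(evaluate(decode_online(X, clf, hmm), true).render_text())
```

prints

```
BP-only macro: 0.632
true\pred       3       4       5       6       7       8       9
        3   0.900   0.100   0.000   0.000   0.000   0.000   0.000
        4   0.333   0.600   0.067   0.000   0.000   0.000   0.000
        5   0.167   0.167   0.567   0.100   0.000   0.000   0.000
        6   0.100   0.067   0.100   0.733   0.000   0.000   0.000
        7   0.000   0.000   0.167   0.067   0.667   0.100   0.000
        8   0.000   0.000   0.000   0.067   0.100   0.567   0.267
        9   0.000   0.000   0.000   0.000   0.034   0.034   0.931
macro accuracy   : 0.7092
micro accuracy   : 0.7081
within one speed : 0.7049
mean abs dev km/h: 0.3923
```

The classifier alone gets 63.2 % of windows right on this hard synthetic
set (adjacent speeds overlap heavily within single 200 ms windows); HMM
smoothing lifts macro accuracy to 70.9 %, and the errors that remain are
almost all one speed step off (`within one speed`, `mean abs dev`).

The same workflow is available from the shell:

```sh
emgspeed synth --profile "3:3,4:3,5:3,6:3,7:3,8:3,9:3" --out rec.csv --seed 1
emgspeed preprocess --in rec.csv --out den.csv
emgspeed features --in den.csv --out feat.tsv
emgspeed train --features feat.tsv --bp-out bp.json --hmm-out hmm.json --seed 2
emgspeed decode --features feat.tsv --bp bp.json --hmm hmm.json --out decoded.csv
emgspeed evaluate --pred decoded.csv --truth feat.tsv
```

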