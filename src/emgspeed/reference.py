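"""Benchmark confusion matrices for the seven-speed EMG recognizer.

These matrices characterize an offline-trained two-channel thigh-EMG
speed classifier over the seven treadmill speeds 3..9 km/h (rows: true
speed, columns: emitted label, row-normalized).  They serve two roles:

* `REFERENCE_OFFLINE_CONFUSION` is the stock emission model for the HMM
  stage and the default input of the label-level simulators — it lets the
  smoothing stage be exercised and benchmarked without any recordings.
* `REFERENCE_BP_ONLINE_CONFUSION` is the matching classifier-only online
  benchmark; the macro-average of its diagonal (92.86 %) is the baseline
  the hybrid decoder is measured against.

Rows carry the rounding error of their printed source (one row sums to
1.016); consumers renormalize.
"""

from __future__ import annotations

import numpy as np

__all__ = ["REFERENCE_OFFLINE_CONFUSION", "REFERENCE_BP_ONLINE_CONFUSION"]

#: Offline confusion matrix of the benchmark classifier (true speed 3..9
#: km/h by row, emitted label 3..9 km/h by column).
REFERENCE_OFFLINE_CONFUSION: np.ndarray = np.array([
    [0.5469, 0.0,    0.0,    0.2188, 0.0,    0.1875, 0.0469],
    [0.0,    0.9296, 0.0,    0.0282, 0.0282, 0.0,    0.0141],
    [0.0,    0.0145, 0.7826, 0.0,    0.1719, 0.0,    0.0469],
    [0.1429, 0.0,    0.0,    0.6786, 0.1786, 0.0,    0.0],
    [0.0638, 0.0,    0.1064, 0.1277, 0.5532, 0.0,    0.1489],
    [0.0882, 0.0,    0.0,    0.0,    0.0,    0.9118, 0.0],
    [0.0769, 0.0,    0.0,    0.0,    0.1026, 0.0513, 0.7682],
])
REFERENCE_OFFLINE_CONFUSION.setflags(write=False)

#: Online (streaming) confusion matrix of the same classifier without HMM
#: smoothing, on 20 test windows per speed.
REFERENCE_BP_ONLINE_CONFUSION: np.ndarray = np.array([
    [0.95, 0.0,  0.0,  0.0,  0.05, 0.0,  0.0],
    [0.0,  0.95, 0.0,  0.0,  0.0,  0.05, 0.0],
    [0.0,  0.0,  0.95, 0.0,  0.0,  0.05, 0.0],
    [0.0,  0.0,  0.05, 0.85, 0.0,  0.05, 0.05],
    [0.0,  0.0,  0.05, 0.10, 0.90, 0.0,  0.0],
    [0.0,  0.0,  0.0,  0.05, 0.0,  0.90, 0.05],
    [0.0,  0.0,  0.0,  0.0,  0.0,  0.0,  1.00],
])
REFERENCE_BP_ONLINE_CONFUSION.setflags(write=False)
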