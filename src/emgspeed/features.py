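"""Per-window feature extraction: 14 features per channel, 28 total.

Ten time-domain statistics and four spectral statistics are computed on
each 200-sample analysis window, per channel, and concatenated
channel-major into a 28-vector — the input of the speed classifier.

The feature order is frozen (see `FEATURE_NAMES`); serialized models store
it as a fingerprint, and changing it invalidates them.

Time domain (zero amplitude threshold for ZC/SSC; WAMP threshold is
5 % of the window RMS):

=====  ==========================================================
RMS    root mean square
MAV    mean absolute value
SSC    slope-sign-change count
WL     waveform length, sum of absolute successive differences
ZC     zero-crossing count
MAX    maximum sample
MIN    minimum sample
VAR    population variance
IAV    integrated absolute value, sum of |x|
WAMP   Willison amplitude, count of large successive differences
=====  ==========================================================

Frequency domain, from a Hann-tapered periodogram:

=====  ==========================================================
MDF    median frequency (splits cumulative spectral power in half)
MNF    mean (power-weighted) frequency
PKF    frequency of the spectral peak
TTP    total spectral power (integrated PSD)
=====  ==========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "FeatureWindow",
    "FeatureScaler",
    "time_domain_features",
    "frequency_domain_features",
    "extract_features",
    "standardize_features",
    "write_features_tsv",
    "read_features_tsv",
]

#: Per-channel feature order. Frozen: serialized models depend on it.
FEATURE_NAMES: tuple[str, ...] = (
    "rms", "mav", "ssc", "wl", "zc", "max", "min", "var", "iav", "wamp",
    "mdf", "mnf", "peak_freq", "total_power",
)

#: Full 28-name order, channel-major.
ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"ch{c}_{name}" for c in (1, 2) for name in FEATURE_NAMES
)


@dataclass
class FeatureWindow:
    """One analysis window as a 28-vector plus optional label/provenance."""

    values: np.ndarray
    label: int | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (28,):
            raise ValueError(f"feature vector must have length 28; got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def time_domain_features(window: np.ndarray) -> np.ndarray:
    """The 10 time-domain statistics of a single-channel window, in order
    RMS, MAV, SSC, WL, ZC, MAX, MIN, VAR, IAV, WAMP."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("window must be a 1-D array of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    d = np.diff(x)
    rms = float(np.sqrt(np.mean(x**2)))
    # slope sign changes: interior points that are strict local extrema
    ssc = float(np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > 0))
    zc = float(np.sum(x[:-1] * x[1:] < 0))
    wamp = float(np.sum(np.abs(d) > 0.05 * rms))
    return np.array([
        rms,
        float(np.mean(np.abs(x))),
        ssc,
        float(np.sum(np.abs(d))),
        zc,
        float(np.max(x)),
        float(np.min(x)),
        float(np.var(x)),
        float(np.sum(np.abs(x))),
        wamp,
    ])


def frequency_domain_features(window: np.ndarray, sampling_rate: float) -> np.ndarray:
    """The 4 spectral statistics (MDF, MNF, peak frequency, total power).

    Spectrum is the Hann-tapered periodogram of the full window.  A
    zero-power window returns all zeros with a warning rather than an
    error (MDF/MNF are undefined there).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("window must be a 1-D array of length >= 8")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    f, pxx = periodogram(x, fs=sampling_rate, window="hann")
    total = pxx.sum()
    if total <= 0:
        warnings.warn("zero-power window: spectral features set to 0", stacklevel=2)
        return np.zeros(4)
    cum = np.cumsum(pxx)
    mdf = float(f[np.searchsorted(cum, 0.5 * total)])
    mnf = float((f * pxx).sum() / total)
    pkf = float(f[np.argmax(pxx)])
    ttp = float(np.trapezoid(pxx, f))
    return np.array([mdf, mnf, pkf, ttp])


def extract_features(
    window: np.ndarray, sampling_rate: float, label: int | None = None,
    index: int | None = None,
) -> FeatureWindow:
    """Extract the channel-major 28-vector from a (2, L) window."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[0] != 2:
        raise ValueError(f"window must have exactly 2 channels; got shape {w.shape}")
    values = np.concatenate([
        np.concatenate([
            time_domain_features(ch),
            frequency_domain_features(ch, sampling_rate),
        ])
        for ch in w
    ])
    return FeatureWindow(values=values, label=label, index=index)


@dataclass
class FeatureScaler:
    """Affine per-feature map fitted on training data (z-score).

    Constant features are mapped to 0 with the scale clamped to 1, so the
    map is always invertible.
    """

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean=np.asarray(d["mean"], float), scale=np.asarray(d["scale"], float))


def standardize_features(
    train: list[FeatureWindow], apply_to: list[FeatureWindow] | None = None
) -> tuple[list[FeatureWindow], FeatureScaler]:
    """Fit a z-score scaler on ``train`` and apply it to ``apply_to``.

    Returns the standardized ``apply_to`` windows (defaults to the training
    windows themselves) and the fitted scaler.
    """
    if not train:
        raise ValueError("training set must be nonempty")
    X = np.vstack([fw.values for fw in train])
    sk = StandardScaler().fit(X)  # zero-variance columns get scale 1
    scaler = FeatureScaler(mean=sk.mean_.copy(), scale=sk.scale_.copy())
    targets = train if apply_to is None else apply_to
    out = [
        FeatureWindow(scaler.transform(fw.values), label=fw.label, index=fw.index)
        for fw in targets
    ]
    return out, scaler


def write_features_tsv(windows: list[FeatureWindow], path) -> None:
    """TSV spill format: window_id, label_kmh, then the 28 named features."""
    rows = {
        "window_id": [fw.index if fw.index is not None else i
                      for i, fw in enumerate(windows)],
        "label_kmh": [fw.label if fw.label is not None else -1 for fw in windows],
    }
    mat = np.vstack([fw.values for fw in windows]) if windows else np.empty((0, 28))
    for j, name in enumerate(ALL_FEATURE_NAMES):
        rows[name] = mat[:, j]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> list[FeatureWindow]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("window_id", "label_kmh", *ALL_FEATURE_NAMES)
               if c not in df.columns]
    if missing:
        raise ValueError(f"feature TSV is missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        label = int(row["label_kmh"])
        out.append(FeatureWindow(
            values=row[list(ALL_FEATURE_NAMES)].to_numpy(dtype=float),
            label=None if label == -1 else label,
            index=int(row["window_id"]),
        ))
    return out
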