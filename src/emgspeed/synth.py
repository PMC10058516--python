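"""Synthetic two-channel EMG and emission-level label simulation.

Two generators live here.  `generate_emg` produces a surrogate treadmill
recording: band-limited Gaussian noise modulated by a gait-periodic burst
envelope, with burst amplitude and spectral bandwidth both increasing with
speed — the two gross properties a speed classifier exploits.  It makes no
claim of physiological fidelity (no motor-unit model, no electrode or skin
effects); it exists so the full pipeline is testable without recorded data.

`sample_observation_sequence` works one level up: given a row-stochastic
emission matrix (a classifier's confusion matrix), it draws the per-window
labels that classifier would emit for a known true-speed sequence.  This is
the natural way to study the HMM smoothing stage in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EmgRecording

__all__ = [
    "SPEEDS",
    "SpeedProfile",
    "SynthConfig",
    "generate_emg",
    "sample_observation_sequence",
    "write_recording_csv",
    "read_recording_csv",
]

#: The seven supported treadmill speeds, km/h.
SPEEDS: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)

# Gait cycle shortens from ~1.3 s at 3 km/h to ~1.0 s at 9 km/h.
_CYCLE_SLOW = 1.3
_CYCLE_FAST = 1.0


@dataclass(frozen=True)
class SpeedProfile:
    """A treadmill schedule: ordered (speed km/h, duration s) segments."""

    segments: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile must contain at least one segment")
        object.__setattr__(
            self, "segments", tuple((int(s), float(d)) for s, d in self.segments)
        )
        for i, (speed, duration) in enumerate(self.segments):
            if speed not in SPEEDS:
                raise ValueError(
                    f"segment {i}: speed {speed} km/h is not one of the "
                    f"supported speeds {SPEEDS}"
                )
            if not duration > 0:
                raise ValueError(f"segment {i}: duration must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the surrogate EMG generator.

    sampling_rate
        Hz; default 1000 so a 200 ms window is exactly 200 samples.
    base_amplitude
        Envelope amplitude unit; burst amplitude at speed s is
        ``base_amplitude * (1 + speed_index)`` with speed_index = s - 3.
    noise_sd
        Standard deviation of additive wide-band measurement noise.  At
        the default level the speed-dependent carrier dominates, so both
        channel RMS and mean frequency rise monotonically with speed; a
        much larger value drowns the spectral trend at the slowest speeds.
    band_low, band_high
        Hz limits of the simulated muscle-activity band (default 20-450,
        the usual surface-EMG energy band); the per-speed upper band edge
        grows from 35 % to 100 % of this range so mean frequency rises
        with speed.
    """

    sampling_rate: float = 1000.0
    base_amplitude: float = 0.15
    noise_sd: float = 0.02
    band_low: float = 20.0
    band_high: float = 450.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 2 * self.band_high:
            raise ValueError(
                "sampling_rate must exceed twice band_high (Nyquist): "
                f"{self.sampling_rate} <= 2 * {self.band_high}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")


def _burst_envelope(t: np.ndarray, speed: int) -> np.ndarray:
    """Gait-periodic burst train; burst rate follows cadence."""
    k = speed - SPEEDS[0]
    cycle = _CYCLE_SLOW + k * (_CYCLE_FAST - _CYCLE_SLOW) / (len(SPEEDS) - 1)
    # raised-cosine squared: one burst per gait cycle, quiet between bursts
    return (0.5 * (1.0 - np.cos(2.0 * np.pi * t / cycle))) ** 2


def _carrier(
    n: int, speed: int, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise; the pass band shifts upward with speed.

    Both band edges rise with the speed index so the carrier's mean
    frequency increases monotonically even when wide-band measurement
    noise is added on top.
    """
    k = speed - SPEEDS[0]
    span = config.band_high - config.band_low
    kmax = len(SPEEDS) - 1
    lo = config.band_low + 0.25 * span * k / kmax
    hi = config.band_low + (0.35 + 0.65 * k / kmax) * span
    sos = signal.butter(
        4, [lo, hi], btype="bandpass", fs=config.sampling_rate,
        output="sos",
    )
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_emg(profile: SpeedProfile, config: SynthConfig = SynthConfig()) -> EmgRecording:
    """Simulate a two-channel treadmill EMG recording.

    Each schedule segment produces ``sampling_rate * duration`` samples of
    enveloped band-limited noise plus white measurement noise, labeled with
    the segment speed.  Channel 2 shares channel 1's envelope at 80 %
    amplitude with independent carrier and measurement noise, mimicking the
    co-activation of two knee extensors.  By construction both channel RMS
    and mean spectral frequency increase with speed; identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    chunks, label_chunks = [], []
    for speed, duration in profile.segments:
        n = int(round(fs * duration))
        t = np.arange(n) / fs
        env = _burst_envelope(t, speed)
        amp = config.base_amplitude * (1 + speed - SPEEDS[0])
        ch1 = amp * env * _carrier(n, speed, config, rng)
        ch2 = 0.8 * amp * env * _carrier(n, speed, config, rng)
        noise = config.noise_sd * rng.standard_normal((2, n))
        chunks.append(np.vstack([ch1, ch2]) + noise)
        label_chunks.append(np.full(n, speed, dtype=int))
    return EmgRecording(
        sampling_rate=fs,
        data=np.concatenate(chunks, axis=1),
        labels=np.concatenate(label_chunks),
    )


def _validate_emission(B: np.ndarray, n_states: int) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.shape != (n_states, n_states):
        raise ValueError(f"emission matrix must be {n_states}x{n_states}; got {B.shape}")
    if np.any(B < 0):
        raise ValueError("emission matrix entries must be non-negative")
    sums = B.sum(axis=1)
    # 0.02 absolute slack admits matrices printed to 3-4 decimals
    if np.any(np.abs(sums - 1.0) > 0.02):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"emission matrix is not row-stochastic: row {bad} sums to {sums[bad]:.4f}"
        )
    return B / sums[:, None]


def sample_observation_sequence(
    true_speeds,
    B: np.ndarray,
    seed: int | np.random.Generator = 0,
    speeds: tuple[int, ...] = SPEEDS,
) -> np.ndarray:
    """Draw per-window classifier labels for a known true-speed sequence.

    Observation t is drawn independently from row ``B[i]`` where i indexes
    the true speed at window t — i.e. the classifier is simulated by its
    confusion matrix.  Rows are renormalized internally (printed matrices
    carry rounding error).  Deterministic under a fixed seed.

    Parameters
    ----------
    true_speeds : sequence of int
        True speed per window, each in ``speeds``.
    B : ndarray (len(speeds), len(speeds))
        Row-stochastic emission matrix, rows = true speed, cols = label.
    seed : int or Generator
    speeds : state label alphabet, default the seven speeds 3..9 km/h.

    Returns
    -------
    ndarray of int — one label (km/h) per window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = _validate_emission(B, len(speeds))
    index = {s: i for i, s in enumerate(speeds)}
    true_speeds = np.asarray(true_speeds)
    bad = set(np.unique(true_speeds)) - set(speeds)
    if bad:
        raise ValueError(f"true speeds {sorted(bad)} outside the state alphabet {speeds}")
    speeds_arr = np.asarray(speeds)
    out = np.empty(len(true_speeds), dtype=int)
    for t, s in enumerate(true_speeds):
        out[t] = speeds_arr[rng.choice(len(speeds_arr), p=B[index[int(s)]])]
    return out


def write_recording_csv(recording: EmgRecording, path) -> None:
    """Write a recording as CSV with columns t, ch1, ch2, speed_kmh."""
    t = np.arange(recording.n_samples) / recording.sampling_rate
    labels = (
        recording.labels
        if recording.labels is not None
        else np.full(recording.n_samples, -1)
    )
    pd.DataFrame(
        {"t": t, "ch1": recording.data[0], "ch2": recording.data[1],
         "speed_kmh": labels}
    ).to_csv(path, index=False)


def read_recording_csv(path) -> EmgRecording:
    """Read the CSV dialect written by `write_recording_csv`.

    The sampling rate is recovered from the time column; a speed column of
    all -1 is treated as unlabeled.
    """
    df = pd.read_csv(path)
    for col in ("t", "ch1", "ch2", "speed_kmh"):
        if col not in df.columns:
            raise ValueError(f"recording CSV is missing column {col!r}")
    t = df["t"].to_numpy()
    if len(t) > 1:
        fs = 1.0 / np.median(np.diff(t))
    else:
        fs = 1000.0
    labels = df["speed_kmh"].to_numpy()
    return EmgRecording(
        sampling_rate=float(round(fs, 6)),
        data=np.vstack([df["ch1"].to_numpy(), df["ch2"].to_numpy()]),
        labels=None if np.all(labels == -1) else labels.astype(int),
    )
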