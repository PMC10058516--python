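"""Wavelet denoising and sliding-window segmentation of raw EMG.

Surface EMG is contaminated by motion artefact, mains interference and
instrumentation noise.  The standard remedy in gait work is wavelet
shrinkage: decompose with a Daubechies wavelet, soft-threshold the detail
coefficients, reconstruct.  The denoised stream is then cut into short
overlapping analysis windows (default 200 samples with 50 % overlap at
1 kHz, i.e. 200 ms windows every 100 ms) from which features are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "EmgRecording",
    "WindowSpec",
    "denoise_wavelet",
    "segment_windows",
]


@dataclass
class EmgRecording:
    """A two-channel surface-EMG record with optional per-sample speed labels.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, > 0.
    data : ndarray, shape (2, n)
        The two muscle channels (e.g. rectus femoris and vastus lateralis),
        arbitrary units.
    labels : ndarray of int, shape (n,), optional
        Treadmill speed in km/h for every sample, or None if unlabeled.
    """

    sampling_rate: float
    data: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise ValueError(
                f"EMG data must have shape (2, n); got {self.data.shape}"
            )
        if self.data.shape[1] < 1:
            raise ValueError("EMG recording must contain at least one sample")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.data.shape[1],):
                raise ValueError(
                    "labels must be one per sample: expected shape "
                    f"({self.data.shape[1]},), got {self.labels.shape}"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length and overlap.

    The step between consecutive window starts is
    ``window_samples * (1 - overlap_fraction)`` and must come out a
    positive integer.  Defaults give 200-sample windows with 50 % overlap.
    """

    window_samples: int = 200
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        step = self.window_samples * (1.0 - self.overlap_fraction)
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(
                f"window_samples * (1 - overlap_fraction) = {step} "
                "must be a positive integer"
            )

    @property
    def step(self) -> int:
        return round(self.window_samples * (1.0 - self.overlap_fraction))


def _denoise_channel(x: np.ndarray, wavelet: str, level: int, rule: str) -> np.ndarray:
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    if level > max_level:
        raise ValueError(
            f"signal of length {len(x)} supports at most decomposition "
            f"level {max_level} for wavelet '{wavelet}'; got level={level}"
        )
    coeffs = pywt.wavedec(x, w, level=level)
    # noise scale from the finest detail band: MAD / 0.6745
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    if thr == 0.0:  # noiseless estimate: shrinkage is the identity
        return x.copy()
    denoised = [coeffs[0]] + [
        pywt.threshold(c, thr, mode=rule) for c in coeffs[1:]
    ]
    return pywt.waverec(denoised, w)[: len(x)]


def denoise_wavelet(
    recording: EmgRecording,
    wavelet: str = "db5",
    level: int = 4,
    rule: str = "soft",
) -> EmgRecording:
    """Wavelet-shrinkage denoising of both EMG channels.

    Decomposes each channel with ``wavelet`` to ``level`` scales, estimates
    the noise standard deviation from the finest detail coefficients via the
    median absolute deviation, applies the universal threshold
    ``sigma * sqrt(2 ln n)`` to all detail bands with the given shrinkage
    ``rule`` ("soft" or "hard"), and reconstructs.  Labels pass through
    untouched.  With soft thresholding the output energy never exceeds the
    input energy.

    Raises
    ------
    ValueError
        If the signal is too short for the requested decomposition level.
    """
    if level < 1:
        raise ValueError("decomposition level must be >= 1")
    if rule not in ("soft", "hard"):
        raise ValueError(f"unknown threshold rule {rule!r}")
    out = np.vstack(
        [_denoise_channel(ch, wavelet, level, rule) for ch in recording.data]
    )
    labels = None if recording.labels is None else recording.labels.copy()
    return EmgRecording(recording.sampling_rate, out, labels)


def _majority_label(window_labels: np.ndarray):
    """Most frequent label; ties go to the label appearing first in the window."""
    values, first_pos, counts = np.unique(
        window_labels, return_index=True, return_counts=True
    )
    best = counts == counts.max()
    return values[best][np.argmin(first_pos[best])]


def segment_windows(
    recording: EmgRecording, spec: WindowSpec = WindowSpec()
) -> list[tuple[np.ndarray, object]]:
    """Cut the recording into overlapping windows.

    Windows are half-open ``[start, start + window_samples)`` with starts at
    multiples of ``spec.step``; a trailing partial window is discarded, so
    the count is ``floor((n - window_samples) / step) + 1``.  Each window
    carries the majority per-sample speed label (None when unlabeled).

    A recording shorter than one window yields an empty list with a warning.
    """
    n = recording.n_samples
    w, step = spec.window_samples, spec.step
    if n < w:
        warnings.warn(
            f"recording of {n} samples is shorter than one "
            f"{w}-sample window; no windows produced",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, n - w + 1, step):
        sl = slice(start, start + w)
        label = (
            None
            if recording.labels is None
            else _majority_label(recording.labels[sl])
        )
        out.append((recording.data[:, sl], label))
    return out
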