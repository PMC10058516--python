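"""End-to-end speed-recognition workflow and evaluation suite.

Offline: standardize features, train the BP network on a train split,
measure its confusion matrix on a held-out calibration split, and turn
that matrix into the HMM emission model (uniform pi, Gaussian ordinal A).
Online: run the classifier per window and smooth its labels with Viterbi
over a rolling history.  Evaluation reports a row-normalized confusion
matrix, macro accuracy (unweighted mean of per-class recall — the
headline number, matching how per-speed benchmark tables are averaged),
micro accuracy, the fraction of misclassifications within one speed step,
and the mean absolute speed deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import bpnet, speedhmm
from .features import FeatureScaler, FeatureWindow, standardize_features
from .speedhmm import SPEEDS, HmmModel
from .synth import SpeedProfile, sample_observation_sequence

__all__ = [
    "TrainedClassifier",
    "EvalReport",
    "train_offline",
    "decode_online",
    "evaluate",
    "macro_average",
    "transition_stress_test",
    "simulate_constant_blocks",
    "fusion_benchmark",
]


@dataclass
class TrainedClassifier:
    """A trained BP network with its feature scaler and class alphabet."""

    model: bpnet.BpModel
    scaler: FeatureScaler
    classes: tuple[int, ...] = SPEEDS

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict speeds (km/h) for a (n, 28) feature matrix."""
        X = np.atleast_2d(np.asarray(features, float))
        if X.shape[1] != self.model.d:
            raise ValueError(
                f"feature vectors must have length {self.model.d}; got {X.shape[1]}"
            )
        Z = np.vstack([self.scaler.transform(x) for x in X])
        return np.asarray(self.classes)[bpnet.predict_batch(self.model, Z)]


@dataclass
class EvalReport:
    """Per-class and aggregate recognition quality.

    confusion : (n, n) row-normalized matrix; rows of speeds absent from
        the truth are NaN and excluded from the macro average.
    overall_accuracy : macro average of the diagonal (per-class recall).
    micro_accuracy : plain sample-weighted accuracy.
    within_one_unit : among misclassified windows, the fraction whose
        predicted speed is within 1 km/h of the truth (1.0 if no errors).
    mean_abs_dev : mean |predicted - true| over all windows, km/h.
    """

    confusion: np.ndarray
    overall_accuracy: float
    micro_accuracy: float
    within_one_unit: float
    mean_abs_dev: float
    classes: tuple[int, ...] = SPEEDS

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "micro_accuracy": self.micro_accuracy,
            "within_one_unit": self.within_one_unit,
            "mean_abs_dev": self.mean_abs_dev,
        }

    def render_text(self) -> str:
        """Human-readable confusion table plus the summary lines."""
        header = "true\\pred " + " ".join(f"{c:>7d}" for c in self.classes)
        lines = [header]
        for i, c in enumerate(self.classes):
            row = self.confusion[i]
            cells = " ".join(
                "    nan" if not np.isfinite(v) else f"{v:7.3f}" for v in row
            )
            lines.append(f"{c:>9d} {cells}")
        lines.append(f"macro accuracy   : {self.overall_accuracy:.4f}")
        lines.append(f"micro accuracy   : {self.micro_accuracy:.4f}")
        lines.append(f"within one speed : {self.within_one_unit:.4f}")
        lines.append(f"mean abs dev km/h: {self.mean_abs_dev:.4f}")
        return "\n".join(lines)


def train_offline(
    windows: list[FeatureWindow],
    seed: int = 0,
    hidden: int = 10,
    eta: float = 0.1,
    epochs: int = 500,
    stop_tol: float = 1e-6,
    calibration_fraction: float = 0.3,
    resubstitution: bool = False,
    transition_sd: float = 1.0,
    normalize_transitions: bool = False,
    emission_floor: float = 1e-6,
    classes: tuple[int, ...] = SPEEDS,
) -> tuple[TrainedClassifier, HmmModel]:
    """Train the classifier and build the speed HMM around it.

    The labeled feature windows are split 70/30 (stratified, seeded) into
    a training split and a calibration split.  The BP network trains on
    the standardized training split; its confusion matrix on the held-out
    calibration split becomes the HMM emission matrix — held out so the
    emission probabilities are not optimistically biased.  With
    ``resubstitution`` the confusion matrix is instead measured on the
    training data itself.  A is the Gaussian ordinal kernel, pi uniform.

    Raises if any class is missing from the dataset or from either split
    (advice: resplit with a different seed or more data per class).
    """
    labeled = [fw for fw in windows if fw.label is not None]
    if not labeled:
        raise ValueError("no labeled feature windows provided")
    y = np.array([fw.label for fw in labeled])
    missing = sorted(set(classes) - set(y.tolist()))
    if missing:
        raise ValueError(f"dataset has no windows for speeds {missing} km/h")
    cls_index = {c: i for i, c in enumerate(classes)}

    if resubstitution:
        train_set = calib_set = labeled
    else:
        train_set, calib_set = train_test_split(
            labeled, test_size=calibration_fraction, random_state=seed,
            stratify=y,
        )
        for name, subset in (("training", train_set), ("calibration", calib_set)):
            present = {fw.label for fw in subset}
            gap = sorted(set(classes) - present)
            if gap:
                raise ValueError(
                    f"{name} split is missing speeds {gap} km/h; "
                    "resplit with another seed or provide more windows per class"
                )

    std_train, scaler = standardize_features(train_set)
    X_train = np.vstack([fw.values for fw in std_train])
    y_train = np.array([cls_index[fw.label] for fw in train_set])
    model = bpnet.init_model(
        d=X_train.shape[1], q=hidden, l=len(classes), eta=eta, seed=seed
    )
    model, _ = bpnet.train(model, X_train, y_train, epochs=epochs,
                           stop_tol=stop_tol, seed=seed)

    X_cal = np.vstack([scaler.transform(fw.values) for fw in calib_set])
    y_cal = np.array([cls_index[fw.label] for fw in calib_set])
    confusion = bpnet.confusion_matrix(model, X_cal, y_cal)

    hmm = HmmModel.standard(
        confusion, sd=transition_sd, normalize=normalize_transitions,
        floor=emission_floor, states=classes,
    )
    return TrainedClassifier(model=model, scaler=scaler, classes=classes), hmm


def decode_online(
    features: np.ndarray | list[FeatureWindow],
    classifier: TrainedClassifier,
    hmm: HmmModel,
    history: int = 9,
) -> np.ndarray:
    """Classify each window and smooth the label stream with the HMM.

    Returns one decoded speed (km/h) per input window; causal rolling-
    history Viterbi, emitting the last state of each decoded sub-path.
    """
    if isinstance(features, list):
        features = np.vstack([fw.values for fw in features])
    obs = classifier.predict(features)
    return speedhmm.decode_online(obs, hmm, history=history)


def macro_average(confusion: np.ndarray) -> float:
    """Unweighted mean of the confusion-matrix diagonal (per-class recall),
    ignoring NaN rows of classes absent from the truth."""
    return float(np.nanmean(np.diag(np.asarray(confusion, float))))


def evaluate(predicted, true, classes: tuple[int, ...] = SPEEDS) -> EvalReport:
    """Score a decoded speed sequence against the truth."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("predicted and true sequences must be nonempty and equal-length")
    idx = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    counts = np.zeros((n, n))
    for p, t in zip(predicted, true):
        counts[idx[int(t)], idx[int(p)]] += 1.0
    row_sums = counts.sum(axis=1)
    confusion = np.full((n, n), np.nan)
    present = row_sums > 0
    confusion[present] = counts[present] / row_sums[present, None]
    if not np.all(present):
        absent = [classes[i] for i in np.flatnonzero(~present)]
        warnings.warn(
            f"speeds {absent} km/h never occur in the truth; their confusion "
            "rows are NaN and excluded from the macro average",
            stacklevel=2,
        )
    macro = macro_average(confusion)
    micro = float(np.mean(predicted == true))
    errors = predicted != true
    if errors.any():
        within = float(np.mean(np.abs(predicted[errors] - true[errors]) <= 1))
    else:
        within = 1.0
    mad = float(np.mean(np.abs(predicted - true)))
    return EvalReport(
        confusion=confusion, overall_accuracy=macro, micro_accuracy=micro,
        within_one_unit=within, mean_abs_dev=mad, classes=classes,
    )


def _schedule_to_windows(schedule: SpeedProfile, windows_per_second: float) -> np.ndarray:
    parts = [
        np.full(max(1, int(round(duration * windows_per_second))), speed, dtype=int)
        for speed, duration in schedule.segments
    ]
    return np.concatenate(parts)


def transition_stress_test(
    hmm: HmmModel,
    schedule: SpeedProfile,
    seed: int = 0,
    emission: np.ndarray | None = None,
    windows_per_second: float = 10.0,
    history: int = 9,
    margin: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Compare raw classifier output vs HMM smoothing around speed changes.

    The schedule (>= 2 segments) is expanded to one true speed per window
    (default 10 windows/s: 200 ms windows, 50 % overlap).  Per-window
    classifier labels are drawn from ``emission`` (default: the HMM's own
    B) — the classifier-only decoder simply reports those labels, the
    hybrid decoder smooths them causally.  Misclassifications within
    ``margin`` windows of each speed change are counted for both.

    Returns (table, summary): the table has one row per window with
    columns ``window, true_kmh, bp_kmh, bphmm_kmh, near_transition``;
    the summary gives transition-window and total error counts.
    """
    if len(schedule.segments) < 2:
        raise ValueError("stress schedule needs at least 2 segments")
    rng = np.random.default_rng(seed)
    true = _schedule_to_windows(schedule, windows_per_second)
    B = hmm.B if emission is None else emission
    obs = sample_observation_sequence(true, B, seed=rng, speeds=hmm.states)
    smoothed = speedhmm.decode_online(obs, hmm, history=history)

    change_points = np.flatnonzero(np.diff(true)) + 1
    near = np.zeros(len(true), dtype=bool)
    for cp in change_points:
        near[max(0, cp - margin): cp + margin + 1] = True

    table = pd.DataFrame({
        "window": np.arange(len(true)),
        "true_kmh": true,
        "bp_kmh": obs,
        "bphmm_kmh": smoothed,
        "near_transition": near,
    })
    summary = {
        "n_windows": len(true),
        "n_transitions": len(change_points),
        "bp_transition_errors": int(np.sum((obs != true) & near)),
        "bphmm_transition_errors": int(np.sum((smoothed != true) & near)),
        "bp_total_errors": int(np.sum(obs != true)),
        "bphmm_total_errors": int(np.sum(smoothed != true)),
    }
    return table, summary


def simulate_constant_blocks(
    B: np.ndarray,
    rng: np.random.Generator,
    windows_per_speed: int = 20,
    speeds: tuple[int, ...] = SPEEDS,
) -> tuple[np.ndarray, np.ndarray, list[slice]]:
    """One constant-speed block per speed, labels drawn from B's rows.

    Emulates the standard benchmark protocol: 20 windows per speed,
    7 speeds, 140 windows total.  Returns (true, observed, block slices).
    """
    true = np.repeat(np.asarray(speeds), windows_per_speed)
    obs = sample_observation_sequence(true, B, seed=rng, speeds=speeds)
    blocks = [
        slice(i * windows_per_speed, (i + 1) * windows_per_speed)
        for i in range(len(speeds))
    ]
    return true, obs, blocks


def fusion_benchmark(
    confusion: np.ndarray,
    replicates: int = 100,
    windows_per_speed: int = 20,
    seed: int = 0,
    transition_sd: float = 1.0,
    normalize_transitions: bool = False,
    emission_floor: float = 1e-6,
    speeds: tuple[int, ...] = SPEEDS,
) -> dict:
    """Measure the benefit of HMM smoothing at the emission level.

    Per replicate: simulate one constant-speed block of
    ``windows_per_speed`` labels per speed from the confusion matrix,
    decode each block with Viterbi (Gaussian A, uniform pi, floored
    confusion as B), and score macro accuracy of the smoothed labels and
    of the raw labels.  Returns mean accuracies (fractions), the paired
    win count, and per-replicate arrays.
    """
    hmm = HmmModel.standard(
        confusion, sd=transition_sd, normalize=normalize_transitions,
        floor=emission_floor, states=speeds,
    )
    rng = np.random.default_rng(seed)
    acc_hmm = np.empty(replicates)
    acc_raw = np.empty(replicates)
    for r in range(replicates):
        true, obs, blocks = simulate_constant_blocks(
            hmm.B, rng, windows_per_speed, speeds
        )
        decoded = np.concatenate(
            [speedhmm.viterbi(obs[blk], hmm).states for blk in blocks]
        )
        acc_hmm[r] = evaluate(decoded, true, classes=speeds).overall_accuracy
        acc_raw[r] = evaluate(obs, true, classes=speeds).overall_accuracy
    return {
        "mean_macro_hmm": float(acc_hmm.mean()),
        "mean_macro_raw": float(acc_raw.mean()),
        "hmm_wins": int(np.sum(acc_hmm > acc_raw)),
        "ties": int(np.sum(acc_hmm == acc_raw)),
        "replicates": replicates,
        "per_replicate_hmm": acc_hmm,
        "per_replicate_raw": acc_raw,
    }
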