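"""Hidden Markov smoothing of per-window speed labels.

The true treadmill speed evolves slowly, so consecutive analysis windows
almost always share a speed, and a change is almost always to an adjacent
speed.  This module encodes that prior as a hidden Markov model over the
seven ordinal speed states:

* initial distribution pi: uniform, 1/M per state;
* transition matrix A: row i is the standard normal density centered on
  state i evaluated at the integer state indices, ``a_ij = phi(j - i)``
  for unit sd — a banded, symmetric kernel whose row maximum sits on the
  diagonal (stay at the current speed), with adjacent speeds next most
  likely.  The rows are *densities*, not normalized probabilities, by
  default (edge rows sum to ~0.69); pass ``normalize=True`` for proper
  row-stochastic rows.  Decoding is argmax-based, so within a row only
  relative weights matter; normalization can differ only through the
  row-dependent rescaling it introduces along a path.
* emission matrix B: the classifier's offline confusion matrix — the
  probability that the classifier emits label v_j when the true speed is
  q_i — with exact zeros floored to a small probability so every
  observation sequence has finite log-likelihood.

Decoding is the Viterbi dynamic program in the log domain:

    delta_1(i) = pi_i b_i(o_1)
    delta_t(i) = max_j [delta_{t-1}(j) a_ji] b_i(o_t)
    psi_t(i)   = argmax_j [delta_{t-1}(j) a_ji]

with P* = max_i delta_T(i) and the path read off the backpointers.
Argmax ties break toward the lowest state index.

No Baum-Welch estimation and no forward-backward posteriors here: A is
fixed analytically and B comes from the offline confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SPEEDS",
    "HmmModel",
    "DecodedPath",
    "uniform_initial",
    "gaussian_transition_matrix",
    "emission_from_confusion",
    "viterbi",
    "decode_online",
    "save_model",
    "load_model",
]

SPEEDS: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)


def uniform_initial(m: int) -> np.ndarray:
    """Uniform initial state distribution [1/m, ..., 1/m]."""
    if m < 1:
        raise ValueError("number of states must be >= 1")
    return np.full(m, 1.0 / m)


def gaussian_transition_matrix(
    n_states: int = 7, sd: float = 1.0, normalize: bool = False
) -> np.ndarray:
    """Ordinal Gaussian transition kernel over integer speed states.

    ``a_ij = phi((j - i)/sd) / sd`` with phi the standard normal density:
    for unit sd the distinct values are 0.399, 0.242, 0.054, 4.43e-3,
    1.34e-4, 1.49e-6, 6.08e-9 at offsets 0..6.  With ``normalize`` each
    row is rescaled to sum to 1 (the raw edge rows sum to ~0.69).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if not sd > 0:
        raise ValueError("sd must be positive")
    idx = np.arange(n_states)
    A = norm.pdf((idx[None, :] - idx[:, None]) / sd) / sd
    if normalize:
        A = A / A.sum(axis=1, keepdims=True)
    return A


def emission_from_confusion(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Turn a confusion matrix into a strictly positive emission matrix.

    Zero entries are replaced by ``floor`` and rows renormalized, so any
    label has positive probability under any state and Viterbi never sees
    a -inf-only column.  Input rows may carry printed/rounding slack (up
    to 0.02); output rows sum to 1 within 1e-12.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"confusion matrix must be square; got {C.shape}")
    if np.any(C < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    sums = C.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError(
            f"confusion rows {np.flatnonzero(sums == 0).tolist()} are all "
            "zero; emission rows would be undefined"
        )
    if np.any(np.abs(sums - 1.0) > 0.02):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {bad} sums to {sums[bad]:.4f}; not row-stochastic")
    if not floor > 0:
        raise ValueError("floor must be positive")
    B = np.where(C > 0, C, floor)
    return B / B.sum(axis=1, keepdims=True)


@dataclass
class HmmModel:
    """The full speed HMM: states, observation alphabet, pi, A, B.

    States and observations share the speed alphabet (default 3..9 km/h):
    hidden state = true speed, observation = per-window classifier label.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    states: tuple[int, ...] = SPEEDS

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, float)
        self.A = np.asarray(self.A, float)
        self.B = np.asarray(self.B, float)
        n = len(self.states)
        if self.pi.shape != (n,) or self.A.shape != (n, n) or self.B.shape != (n, n):
            raise ValueError("pi/A/B shapes inconsistent with the state alphabet")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be a probability distribution")
        if np.any(self.A < 0) or np.any(self.B < 0):
            raise ValueError("A and B must be non-negative")
        if np.any(np.abs(self.B.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("B rows must sum to 1 (use emission_from_confusion)")

    @classmethod
    def standard(cls, confusion: np.ndarray, sd: float = 1.0,
                 normalize: bool = False, floor: float = 1e-6,
                 states: tuple[int, ...] = SPEEDS) -> "HmmModel":
        """Uniform pi, Gaussian A, emissions from a confusion matrix."""
        n = len(states)
        return cls(
            pi=uniform_initial(n),
            A=gaussian_transition_matrix(n, sd=sd, normalize=normalize),
            B=emission_from_confusion(confusion, floor=floor),
            states=states,
        )


@dataclass
class DecodedPath:
    """Viterbi result: most probable state path and its log probability."""

    states: np.ndarray          # decoded speed labels, length T
    log_prob: float
    delta: np.ndarray | None = None   # (T, N) log trellis, if retained
    psi: np.ndarray | None = None     # (T, N) backpointers, if retained


def _safe_log(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, -np.inf, dtype=float)
    np.log(x, where=x > 0, out=out)
    return out


def viterbi(obs, model: HmmModel, keep_trellis: bool = False) -> DecodedPath:
    """Most probable hidden speed path for an observed label sequence.

    ``obs`` is a sequence of labels from the model's state alphabet.  The
    recursion runs in the log domain; ties break toward the lowest state
    index.  Rejects empty sequences and labels outside the alphabet.
    """
    obs = np.asarray(obs)
    if obs.size == 0:
        raise ValueError("observation sequence must be nonempty")
    index = {s: i for i, s in enumerate(model.states)}
    try:
        o = np.array([index[int(v)] for v in obs])
    except KeyError as exc:
        raise ValueError(
            f"observation label {exc.args[0]} outside the alphabet {model.states}"
        ) from None
    T, n = len(o), len(model.states)
    log_pi, log_A, log_B = _safe_log(model.pi), _safe_log(model.A), _safe_log(model.B)
    delta = np.empty((T, n))
    psi = np.zeros((T, n), dtype=int)
    delta[0] = log_pi + log_B[:, o[0]]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + log_A       # (from j, to i)
        psi[t] = np.argmax(scores, axis=0)
        delta[t] = scores[psi[t], np.arange(n)] + log_B[:, o[t]]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    states_arr = np.asarray(model.states)
    return DecodedPath(
        states=states_arr[path],
        log_prob=float(delta[-1, path[-1]]),
        delta=delta if keep_trellis else None,
        psi=psi if keep_trellis else None,
    )


def decode_online(obs, model: HmmModel, history: int = 9) -> np.ndarray:
    """Causal decoding: re-run Viterbi over a rolling observation history.

    At each window t the path is decoded over the last ``history``
    observations (default 9, the number of 200-sample/50 %-overlap windows
    covering a 1 s buffer) and the final state of that path is emitted as
    the current speed.  Output length equals input length.
    """
    obs = np.asarray(obs)
    if obs.size == 0:
        raise ValueError("observation sequence must be nonempty")
    if history < 1:
        raise ValueError("history must be >= 1")
    out = np.empty(len(obs), dtype=int)
    for t in range(len(obs)):
        chunk = obs[max(0, t - history + 1): t + 1]
        out[t] = viterbi(chunk, model).states[-1]
    return out


def save_model(model: HmmModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "states": list(model.states),
                "pi": model.pi.tolist(),
                "A": model.A.tolist(),
                "B": model.B.tolist(),
            },
            fh,
        )


def load_model(path) -> HmmModel:
    with open(path) as fh:
        d = json.load(fh)
    return HmmModel(
        pi=np.asarray(d["pi"], float),
        A=np.asarray(d["A"], float),
        B=np.asarray(d["B"], float),
        states=tuple(int(s) for s in d["states"]),
    )
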