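"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgspeed import bpnet, synth
from emgspeed.speedhmm import SPEEDS, HmmModel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles


def brute_force_viterbi(obs_idx, pi, A, B):
    """Exhaustive most-probable-path search; the oracle for Viterbi.

    Enumerates all N^T state paths and maximizes the product
    pi[i1] B[i1,o1] * prod_t A[i_{t-1}, i_t] B[i_t, o_t].  Ties resolve
    to the lexicographically smallest path, matching the lowest-index
    tie-break of the implementation.
    """
    n = len(pi)
    best_path, best_logp = None, -np.inf
    with np.errstate(divide="ignore"):
        log_pi, log_A, log_B = np.log(pi), np.log(A), np.log(B)
    for path in itertools.product(range(n), repeat=len(obs_idx)):
        logp = log_pi[path[0]] + log_B[path[0], obs_idx[0]]
        for t in range(1, len(path)):
            logp += log_A[path[t - 1], path[t]] + log_B[path[t], obs_idx[t]]
        if logp > best_logp:  # strict: keeps the lexicographically first max
            best_path, best_logp = path, logp
    return np.array(best_path), best_logp


def score_path(path, obs_idx, pi, A, B):
    """Log probability of one concrete state path for an observation
    sequence — the scoring half of the brute-force oracle."""
    with np.errstate(divide="ignore"):
        logp = np.log(pi[path[0]]) + np.log(B[path[0], obs_idx[0]])
        for t in range(1, len(path)):
            logp += np.log(A[path[t - 1], path[t]]) + np.log(B[path[t], obs_idx[t]])
    return logp


def numeric_gradient(model: bpnet.BpModel, x, y, h=1e-6):
    """Central finite-difference gradient of the per-sample error E_k
    with respect to every parameter; the oracle for the analytic updates."""
    grads = {}
    for name in ("v", "gamma", "w", "theta"):
        arr = getattr(model, name)
        g = np.zeros_like(arr)
        flat, gflat = arr.ravel(), g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            _, y_plus = bpnet.forward(model, x)
            flat[i] = orig - h
            _, y_minus = bpnet.forward(model, x)
            flat[i] = orig
            gflat[i] = (
                bpnet.sample_error(y_plus, y) - bpnet.sample_error(y_minus, y)
            ) / (2 * h)
        grads[name] = g
    return grads


def random_hmm_instance(rng, n_states, t_len):
    """A random strictly positive HMM instance plus an observation sequence."""
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    B = rng.dirichlet(np.ones(n_states), size=n_states)
    obs_idx = rng.integers(0, n_states, size=t_len)
    return pi, A, B, obs_idx


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def separable_feature_windows():
    """Labeled 28-D feature windows with well-separated speed clusters.

    Class means sit on distinct random directions 6 sd apart, so the BP
    network should learn an essentially perfect classifier — the fixture
    for "B is near-identity" and identity-chain decoding tests.
    """
    from emgspeed.features import FeatureWindow

    rng = np.random.default_rng(42)
    directions = rng.normal(size=(7, 28))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    windows = []
    for ci, speed in enumerate(SPEEDS):
        pts = 6.0 * directions[ci] + rng.normal(scale=1.0, size=(40, 28))
        for p in pts:
            windows.append(FeatureWindow(p, label=speed, index=len(windows)))
    return windows


@pytest.fixture(scope="session")
def reference_hmm():
    """The stock speed HMM built from the benchmark offline confusion matrix."""
    from emgspeed.reference import REFERENCE_OFFLINE_CONFUSION

    return HmmModel.standard(REFERENCE_OFFLINE_CONFUSION)


@pytest.fixture(scope="session")
def standard_fixture(reference_hmm):
    """The standard benchmark layout: 7 constant-speed blocks of 20 windows."""
    rng = np.random.default_rng(5)
    true = np.repeat(np.asarray(SPEEDS), 20)
    obs = synth.sample_observation_sequence(true, reference_hmm.B, seed=rng)
    return true, obs
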