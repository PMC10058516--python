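"""A deliberately plain three-layer sigmoid perceptron trained by
per-sample error back-propagation.

The network is the 28-10-7 classifier at the heart of the speed
recognizer: 28 EMG features in, 7 speed classes out, sigmoid activations
in both the hidden and output layers, and stochastic gradient descent on
the per-sample squared error

    E_k = 1/2 * sum_j (yhat_j - y_j)^2.

With hidden activations ``b_h = sigmoid(sum_i v_ih x_i - gamma_h)`` and
outputs ``yhat_j = sigmoid(beta_j - theta_j)``, ``beta_j = sum_h w_hj b_h``,
the gradient-descent updates are

    g_j = yhat_j (1 - yhat_j) (y_j - yhat_j)
    e_h = b_h (1 - b_h) sum_j w_hj g_j
    dw_hj = eta g_j b_h      dtheta_j = -eta g_j
    dv_ih = eta e_h x_i      dgamma_h = -eta e_h

applied simultaneously from the pre-update forward pass.  No momentum,
no regularization, no minibatching — the model's value here is as the
emission-probability source for the HMM stage, not as a state-of-the-art
classifier.

Classes are 0-based indices internally; the pipeline layer maps them to
km/h speed labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "BpModel",
    "LabeledSample",
    "init_model",
    "forward",
    "sample_error",
    "backprop_step",
    "train",
    "predict_label",
    "predict_batch",
    "confusion_matrix",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


@dataclass
class BpModel:
    """All network parameters.

    v : (d, q) input->hidden weights;  gamma : (q,) hidden thresholds
    w : (q, l) hidden->output weights; theta : (l,) output thresholds
    eta : learning rate > 0
    """

    v: np.ndarray
    gamma: np.ndarray
    w: np.ndarray
    theta: np.ndarray
    eta: float = 0.1

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, float)
        self.gamma = np.asarray(self.gamma, float)
        self.w = np.asarray(self.w, float)
        self.theta = np.asarray(self.theta, float)
        d, q = self.v.shape
        q2, l = self.w.shape
        if q2 != q or self.gamma.shape != (q,) or self.theta.shape != (l,):
            raise ValueError("inconsistent parameter shapes")
        for arr in (self.v, self.gamma, self.w, self.theta):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters must be finite")
        if not self.eta > 0:
            raise ValueError("learning rate eta must be positive")

    @property
    def d(self) -> int:
        return self.v.shape[0]

    @property
    def q(self) -> int:
        return self.v.shape[1]

    @property
    def l(self) -> int:
        return self.w.shape[1]

    def copy(self) -> "BpModel":
        return BpModel(self.v.copy(), self.gamma.copy(), self.w.copy(),
                       self.theta.copy(), self.eta)


@dataclass
class LabeledSample:
    """A feature vector with its one-hot target."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (np.sum(self.y == 1.0) == 1 and np.sum(self.y == 0.0) == len(self.y) - 1):
            raise ValueError("target must be one-hot")


def one_hot(index: int, n_classes: int) -> np.ndarray:
    y = np.zeros(n_classes)
    y[index] = 1.0
    return y


def init_model(d: int = 28, q: int = 10, l: int = 7, eta: float = 0.1,
               seed: int = 0) -> BpModel:
    """Seeded uniform(-0.5, 0.5) initialization of all parameters."""
    rng = np.random.default_rng(seed)
    return BpModel(
        v=rng.uniform(-0.5, 0.5, (d, q)),
        gamma=rng.uniform(-0.5, 0.5, q),
        w=rng.uniform(-0.5, 0.5, (q, l)),
        theta=rng.uniform(-0.5, 0.5, l),
        eta=eta,
    )


def forward(model: BpModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass; returns (hidden activations b, outputs yhat)."""
    x = np.asarray(x, float)
    if x.shape != (model.d,):
        raise ValueError(f"input must have shape ({model.d},); got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    b = expit(x @ model.v - model.gamma)
    yhat = expit(b @ model.w - model.theta)
    return b, yhat


def sample_error(yhat: np.ndarray, y: np.ndarray) -> float:
    """Half the summed squared output error of one sample."""
    yhat, y = np.asarray(yhat, float), np.asarray(y, float)
    if yhat.shape != y.shape:
        raise ValueError("output vectors must have equal length")
    return 0.5 * float(np.sum((yhat - y) ** 2))


def _step_inplace(model: BpModel, x: np.ndarray, y: np.ndarray) -> float:
    """One gradient-descent update, all parameter groups simultaneously.

    Returns the pre-update sample error.
    """
    b, yhat = forward(model, x)
    err = sample_error(yhat, y)
    g = yhat * (1.0 - yhat) * (y - yhat)
    e = b * (1.0 - b) * (model.w @ g)
    eta = model.eta
    model.w += eta * np.outer(b, g)
    model.theta += -eta * g
    model.v += eta * np.outer(x, e)
    model.gamma += -eta * e
    return err


def backprop_step(model: BpModel, sample: LabeledSample) -> BpModel:
    """One per-sample update; returns a new model, input untouched."""
    out = model.copy()
    _step_inplace(out, sample.x, np.asarray(sample.y, float))
    return out


def train(
    model: BpModel,
    X: np.ndarray,
    y_index: np.ndarray,
    epochs: int = 500,
    stop_tol: float = 1e-6,
    seed: int = 0,
) -> tuple[BpModel, list[float]]:
    """Stochastic (per-sample) training in shuffled order each epoch.

    Parameters
    ----------
    X : (n, d) feature matrix; y_index : (n,) 0-based class indices.
    epochs : maximum epochs.
    stop_tol : stop when the change in mean per-sample error between
        consecutive epochs falls below this.
    seed : controls the shuffle order (initialization is seeded separately
        in `init_model`).

    Returns the trained model and the per-epoch mean-loss history.
    """
    X = np.asarray(X, float)
    y_index = np.asarray(y_index, int)
    if len(X) == 0:
        raise ValueError("training set must be nonempty")
    if X.shape[1] != model.d:
        raise ValueError(f"features have dimension {X.shape[1]}, model expects {model.d}")
    targets = np.zeros((len(X), model.l))
    targets[np.arange(len(X)), y_index] = 1.0
    rng = np.random.default_rng(seed)
    out = model.copy()
    history: list[float] = []
    prev = None
    for _ in range(epochs):
        order = rng.permutation(len(X))
        total = 0.0
        for i in order:
            total += _step_inplace(out, X[i], targets[i])
        mean_loss = total / len(X)
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"training diverged: mean loss became {mean_loss} "
                f"(eta={model.eta}); reduce the learning rate"
            )
        history.append(mean_loss)
        if prev is not None and abs(prev - mean_loss) < stop_tol:
            break
        prev = mean_loss
    return out, history


def predict_label(model: BpModel, x: np.ndarray) -> int:
    """Argmax class index (0-based); ties break toward the lowest index."""
    _, yhat = forward(model, x)
    return int(np.argmax(yhat))


def predict_batch(model: BpModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, float)
    B = expit(X @ model.v - model.gamma)
    Y = expit(B @ model.w - model.theta)
    return np.argmax(Y, axis=1)


def confusion_matrix(model: BpModel, X: np.ndarray, y_index: np.ndarray) -> np.ndarray:
    """Row-normalized confusion matrix of the model on a labeled set.

    Entry (i, j) is the fraction of true-class-i samples predicted as j.
    Every class must be represented at least once (an empty class would
    make its emission row undefined).
    """
    y_index = np.asarray(y_index, int)
    counts = np.zeros((model.l, model.l))
    pred = predict_batch(model, X)
    np.add.at(counts, (y_index, pred), 1.0)
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = np.flatnonzero(row_sums == 0).tolist()
        raise ValueError(f"classes {empty} have no samples; confusion rows undefined")
    return counts / row_sums[:, None]


def model_to_dict(model: BpModel, scaler=None,
                  feature_names: tuple[str, ...] | None = None) -> dict:
    d = {
        "layer_sizes": [model.d, model.q, model.l],
        "eta": model.eta,
        "v": model.v.tolist(),
        "gamma": model.gamma.tolist(),
        "w": model.w.tolist(),
        "theta": model.theta.tolist(),
    }
    if scaler is not None:
        d["scaler"] = scaler.to_dict()
    if feature_names is not None:
        d["feature_order"] = list(feature_names)
    return d


def model_from_dict(d: dict) -> BpModel:
    return BpModel(
        v=np.asarray(d["v"], float),
        gamma=np.asarray(d["gamma"], float),
        w=np.asarray(d["w"], float),
        theta=np.asarray(d["theta"], float),
        eta=float(d["eta"]),
    )


def save_model(model: BpModel, path, scaler=None,
               feature_names: tuple[str, ...] | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, scaler, feature_names), fh)


def load_model(path) -> dict:
    """Load the raw JSON dict; use `model_from_dict` for the BpModel part."""
    with open(path) as fh:
        return json.load(fh)
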