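"""Three-layer backpropagation network with five classic batch trainers.

The classifier is a 4-k-3 multilayer perceptron: four normalized time-domain
features in, one tanh hidden layer of k neurons, three logistic output
neurons (one per posture).  Training minimizes the mean squared error between
the logistic outputs and one-hot targets over the full batch — the loss the
classic feed-forward toolboxes report — rather than cross-entropy.

Five trainers are implemented from scratch:

``gd``   plain steepest descent;
``gdm``  steepest descent with a momentum term;
``gda``  descent with an adaptive learning rate (grow on improvement,
         shrink and reject on worsening);
``rp``   resilient backpropagation: per-weight sign-based step sizes, here
         with a global backtracking rejection so accepted steps never
         increase the loss;
``lm``   Levenberg-Marquardt on the per-sample, per-output residual
         Jacobian, interpolating between Gauss-Newton and gradient descent
         via the damping parameter mu.

The hidden-layer width heuristic k = round(sqrt(n_in + n_out)) + slack, with
slack an integer in [1, 10], seeds the empirical width search; with 4 inputs,
3 outputs and slack 1 it gives the 4 hidden neurons used by default.

Everything is deterministic given (seed, config, data).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import POSTURES

__all__ = [
    "ALGORITHMS",
    "MlpModel",
    "TrainerConfig",
    "TrainingHistory",
    "NetworkError",
    "TrainingDivergedError",
    "hidden_neuron_heuristic",
    "toolbox_trainer_configs",
    "init_mlp",
    "forward",
    "mse_loss",
    "loss_and_gradient",
    "train",
    "predict",
    "one_hot",
]

ALGORITHMS = ("gd", "gdm", "gda", "rp", "lm")


class NetworkError(ValueError):
    """Invalid network configuration or input."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the history up to the failure."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


def hidden_neuron_heuristic(n_in: int, n_out: int, slack: int) -> int:
    """Rule-of-thumb hidden width: round(sqrt(n_in + n_out)) + slack.

    ``slack`` is an integer constant in [1, 10].  The value only seeds an
    empirical width sweep; it is not a guarantee of adequacy.
    """
    if n_in < 1 or n_out < 1:
        raise NetworkError("layer sizes must be positive")
    if not (1 <= slack <= 10):
        raise NetworkError(f"slack must lie in [1, 10], got {slack}")
    return round(math.sqrt(n_in + n_out)) + int(slack)


@dataclass
class MlpModel:
    """Weights of a 4-k-3 perceptron (tanh hidden, logistic output)."""

    w1: np.ndarray  # (k, n_in)
    b1: np.ndarray  # (k,)
    w2: np.ndarray  # (n_out, k)
    b2: np.ndarray  # (n_out,)

    def __post_init__(self):
        k, n_in = self.w1.shape
        n_out = self.w2.shape[0]
        if self.b1.shape != (k,) or self.w2.shape != (n_out, k) or self.b2.shape != (n_out,):
            raise NetworkError("inconsistent weight shapes")
        for arr in (self.w1, self.b1, self.w2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise NetworkError("weights must be finite")

    @property
    def n_in(self) -> int:
        return self.w1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_out(self) -> int:
        return self.w2.shape[0]

    @property
    def n_params(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def copy(self) -> "MlpModel":
        return MlpModel(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy())

    # flat-vector view used by the Jacobian-based and per-weight trainers
    def pack(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def unpack(self, theta: np.ndarray) -> None:
        k, n_in, n_out = self.n_hidden, self.n_in, self.n_out
        i = 0
        self.w1 = theta[i:i + k * n_in].reshape(k, n_in); i += k * n_in
        self.b1 = theta[i:i + k].copy(); i += k
        self.w2 = theta[i:i + n_out * k].reshape(n_out, k); i += n_out * k
        self.b2 = theta[i:i + n_out].copy()

    def to_json(self, path=None) -> str:
        payload = {
            "sizes": [self.n_in, self.n_hidden, self.n_out],
            "activation": {"hidden": "tanh", "output": "logistic"},
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MlpModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(np.array(payload["w1"], float), np.array(payload["b1"], float),
                   np.array(payload["w2"], float), np.array(payload["b2"], float))


def init_mlp(n_in: int = 4, n_hidden: int = 4, n_out: int = 3,
             seed: int = 0) -> MlpModel:
    """Seeded uniform [-0.5, 0.5] weight initialization."""
    if n_in < 1 or n_hidden < 1 or n_out < 1:
        raise NetworkError("layer sizes must be positive")
    rng = np.random.default_rng(seed)
    return MlpModel(
        w1=rng.uniform(-0.5, 0.5, (n_hidden, n_in)),
        b1=rng.uniform(-0.5, 0.5, n_hidden),
        w2=rng.uniform(-0.5, 0.5, (n_out, n_hidden)),
        b2=rng.uniform(-0.5, 0.5, n_out),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_full(model: MlpModel, X: np.ndarray):
    h = np.tanh(X @ model.w1.T + model.b1)
    y = _sigmoid(h @ model.w2.T + model.b2)
    return h, y


def forward(model: MlpModel, x) -> np.ndarray:
    """Class scores in (0, 1) for one feature vector or a batch.

    Hidden activations are tanh, outputs logistic; a 1-D input returns a
    length-``n_out`` score vector, a 2-D batch returns one row per sample.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.ndim != 2 or X.shape[1] != model.n_in:
        raise NetworkError(f"expected input width {model.n_in}, got shape {x.shape}")
    _, y = _forward_full(model, X)
    return y[0] if single else y


def one_hot(labels: Sequence, classes: Sequence = POSTURES) -> np.ndarray:
    """One-hot target matrix in the order of ``classes``."""
    classes = list(classes)
    idx = []
    for lbl in labels:
        try:
            idx.append(classes.index(lbl))
        except ValueError:
            raise NetworkError(f"label {lbl!r} not in classes {classes}") from None
    T = np.zeros((len(idx), len(classes)))
    T[np.arange(len(idx)), idx] = 1.0
    return T


def mse_loss(model: MlpModel, X: np.ndarray, T: np.ndarray) -> float:
    """Mean squared error over all samples and output neurons."""
    _, y = _forward_full(model, X)
    return float(np.mean((y - T) ** 2))


def loss_and_gradient(model: MlpModel, X: np.ndarray, T: np.ndarray):
    """MSE loss and its gradient as a flat vector (backpropagation).

    The gradient layout matches :meth:`MlpModel.pack`.
    """
    n, m = T.shape
    h, y = _forward_full(model, X)
    err = y - T
    loss = float(np.mean(err ** 2))
    # dL/dz2 for L = mean(err^2) over n*m entries
    dz2 = (2.0 / (n * m)) * err * y * (1.0 - y)      # (n, m)
    gw2 = dz2.T @ h                                   # (m, k)
    gb2 = dz2.sum(axis=0)
    dz1 = (dz2 @ model.w2) * (1.0 - h ** 2)           # (n, k)
    gw1 = dz1.T @ X                                   # (k, n_in)
    gb1 = dz1.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])
    return loss, grad


def residual_jacobian(model: MlpModel, X: np.ndarray, T: np.ndarray):
    """Per-sample, per-output residuals and their Jacobian.

    Residuals r = y - T flattened to length n*m; J has one row per residual
    and one column per weight (pack order).  This is the linearization the
    Levenberg-Marquardt trainer damps.
    """
    n, m = T.shape
    k, n_in = model.n_hidden, model.n_in
    h, y = _forward_full(model, X)
    r = (y - T).ravel()
    s2 = y * (1.0 - y)                                # (n, m) logistic slope
    # hidden-layer backprop factor per (sample, output, hidden unit)
    g = s2[:, :, None] * model.w2[None, :, :] * (1.0 - h ** 2)[:, None, :]  # (n,m,k)
    J = np.empty((n, m, model.n_params))
    i = 0
    J[:, :, i:i + k * n_in] = (g[:, :, :, None] * X[:, None, None, :]).reshape(n, m, k * n_in)
    i += k * n_in
    J[:, :, i:i + k] = g
    i += k
    jw2 = np.zeros((n, m, m, k))
    jw2[:, np.arange(m), np.arange(m), :] = s2[:, :, None] * h[:, None, :]
    J[:, :, i:i + m * k] = jw2.reshape(n, m, m * k)
    i += m * k
    jb2 = np.zeros((n, m, m))
    jb2[:, np.arange(m), np.arange(m)] = s2
    J[:, :, i:i + m] = jb2
    return r, J.reshape(n * m, model.n_params)


@dataclass(frozen=True)
class TrainerConfig:
    """Hyperparameters of the five batch trainers.

    The learning rate default 0.001 is shared by the gradient methods and,
    as the initial damping mu_0, by Levenberg-Marquardt.  The remaining
    internals (momentum 0.9, adaptive growth/decay 1.05 / 0.7, Rprop step
    schedule 0.07 / x1.2 / x0.5 bounded to [1e-6, 50], mu schedule x10 / x0.1
    capped at 1e10) follow the long-standing feed-forward-toolbox defaults.
    An optional validation split (fraction + patience) provides early
    stopping; set ``validation_fraction=0`` to train on everything.
    """

    algorithm: str = "lm"
    learning_rate: float = 0.001
    momentum: float = 0.9
    lr_grow: float = 1.05
    lr_shrink: float = 0.7
    rprop_delta0: float = 0.07
    rprop_grow: float = 1.2
    rprop_shrink: float = 0.5
    rprop_delta_min: float = 1e-6
    rprop_delta_max: float = 50.0
    mu0: float | None = None          # defaults to learning_rate
    mu_grow: float = 10.0
    mu_shrink: float = 0.1
    mu_max: float = 1e10
    max_epochs: int = 1000
    goal_mse: float = 0.0
    validation_fraction: float = 0.15
    patience: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise NetworkError(f"algorithm must be one of {ALGORITHMS}")
        if self.learning_rate <= 0:
            raise NetworkError("learning_rate must be > 0")
        if self.goal_mse < 0:
            raise NetworkError("goal_mse must be >= 0")
        if not (0 <= self.validation_fraction < 1):
            raise NetworkError("validation_fraction must lie in [0, 1)")

    @property
    def initial_mu(self) -> float:
        return self.learning_rate if self.mu0 is None else self.mu0


def toolbox_trainer_configs(goal_mse: float = 0.02, max_epochs: int = 20000,
                            validation_fraction: float = 0.0) -> list:
    """The five trainers at their classic toolbox defaults, in ranking order.

    The gradient methods (gd, gdm, gda) use their historical default learning
    rate 0.01; Levenberg-Marquardt keeps mu_0 = 0.001 and Rprop is
    rate-free.  A common MSE goal and epoch cap make epochs-to-stop
    comparable across algorithms.
    """
    configs = []
    for alg in ("gd", "gdm", "gda", "rp", "lm"):
        lr = 0.01 if alg in ("gd", "gdm", "gda") else 0.001
        configs.append(TrainerConfig(algorithm=alg, learning_rate=lr,
                                     goal_mse=goal_mse, max_epochs=max_epochs,
                                     validation_fraction=validation_fraction))
    return configs


@dataclass
class TrainingHistory:
    """Per-epoch record of a training run."""

    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    step_param: list = field(default_factory=list)  # lr for gradient methods, mu for lm
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs + 1),
            "train_mse": self.train_mse,
            "val_mse": self.val_mse,
            "step_param": self.step_param,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def lm_step(model: MlpModel, X: np.ndarray, T: np.ndarray, mu: float) -> np.ndarray:
    """One damped Gauss-Newton update direction: solve (J'J + mu I) d = J'r.

    With mu -> 0 this is the Gauss-Newton step of the residual linearization;
    with mu -> inf it degrades gracefully to a short steepest-descent step
    d ~ J'r / mu.  The caller subtracts d from the packed weights.
    """
    r, J = residual_jacobian(model, X, T)
    A = J.T @ J + mu * np.eye(model.n_params)
    g = J.T @ r
    return np.linalg.solve(A, g)


def _check_finite(loss: float, history: TrainingHistory):
    if not np.isfinite(loss):
        raise TrainingDivergedError("training loss became non-finite", history=history)


def train(model: MlpModel, X: np.ndarray, labels: Sequence,
          cfg: TrainerConfig | None = None,
          classes: Sequence = POSTURES):
    """Train a copy of ``model`` on normalized features; returns (model, history).

    ``X`` is the (n, n_in) matrix of normalized feature vectors and
    ``labels`` the matching posture labels (at least two classes must be
    present).  Targets are one-hot in ``classes`` order.  Optimization is
    full batch; stopping occurs on reaching ``goal_mse``, exhausting
    ``max_epochs``, mu overflow (lm), or ``patience`` consecutive epochs of
    rising validation error when a validation split is enabled.  Runs are
    reproducible given (seed, config, data).
    """
    cfg = TrainerConfig() if cfg is None else cfg
    X = np.asarray(X, dtype=float)
    T = one_hot(labels, classes)
    if len(np.unique(np.argmax(T, axis=1))) < 2:
        raise NetworkError("training data must contain at least two classes")
    if X.shape[0] != T.shape[0]:
        raise NetworkError("features and labels must have equal length")

    # optional validation split for early stopping
    if cfg.validation_fraction > 0:
        rng = np.random.default_rng(cfg.seed)
        n = X.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        n_val = min(max(n_val, 1), n - 2)
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ttr, Xval, Tval = X[tr_idx], T[tr_idx], X[val_idx], T[val_idx]
    else:
        Xtr, Ttr, Xval, Tval = X, T, None, None

    model = model.copy()
    hist = TrainingHistory()
    best_val = np.inf
    bad_epochs = 0
    best_model = model.copy()

    lr = cfg.learning_rate
    velocity = np.zeros(model.n_params)
    delta = np.full(model.n_params, cfg.rprop_delta0)
    prev_grad = np.zeros(model.n_params)
    mu = cfg.initial_mu
    loss = mse_loss(model, Xtr, Ttr)

    for _ in range(cfg.max_epochs):
        theta = model.pack()

        if cfg.algorithm == "gd":
            _, grad = loss_and_gradient(model, Xtr, Ttr)
            model.unpack(theta - lr * grad)
            loss = mse_loss(model, Xtr, Ttr)
            step = lr

        elif cfg.algorithm == "gdm":
            _, grad = loss_and_gradient(model, Xtr, Ttr)
            velocity = cfg.momentum * velocity + lr * grad
            model.unpack(theta - velocity)
            loss = mse_loss(model, Xtr, Ttr)
            step = lr

        elif cfg.algorithm == "gda":
            # accept only non-increasing steps; shrink lr on rejection so a
            # rejected configuration cannot repeat forever, grow on success
            _, grad = loss_and_gradient(model, Xtr, Ttr)
            model.unpack(theta - lr * grad)
            new_loss = mse_loss(model, Xtr, Ttr)
            if new_loss > loss:
                model.unpack(theta)          # reject
                lr *= cfg.lr_shrink
            else:
                if new_loss < loss:
                    lr *= cfg.lr_grow
                loss = new_loss
            step = lr

        elif cfg.algorithm == "rp":
            _, grad = loss_and_gradient(model, Xtr, Ttr)
            sign_change = grad * prev_grad
            delta = np.where(sign_change > 0, delta * cfg.rprop_grow, delta)
            delta = np.where(sign_change < 0, delta * cfg.rprop_shrink, delta)
            delta = np.clip(delta, cfg.rprop_delta_min, cfg.rprop_delta_max)
            candidate = theta - np.sign(grad) * delta
            model.unpack(candidate)
            new_loss = mse_loss(model, Xtr, Ttr)
            if new_loss > loss:
                model.unpack(theta)          # global backtracking rejection
                delta = np.clip(delta * cfg.rprop_shrink,
                                cfg.rprop_delta_min, cfg.rprop_delta_max)
            else:
                g = grad.copy()
                g[sign_change < 0] = 0.0     # Rprop-: forget flipped gradients
                prev_grad = g
                loss = new_loss
            step = float(delta.mean())

        elif cfg.algorithm == "lm":
            # raise mu until the damped step improves the loss (or overflows)
            while True:
                d = lm_step(model, Xtr, Ttr, mu)
                model.unpack(theta - d)
                new_loss = mse_loss(model, Xtr, Ttr)
                if new_loss < loss:
                    loss = new_loss
                    mu = max(mu * cfg.mu_shrink, np.finfo(float).tiny)
                    break
                model.unpack(theta)
                mu *= cfg.mu_grow
                if mu > cfg.mu_max:
                    break
            step = mu

        _check_finite(loss, hist)
        hist.train_mse.append(loss)
        hist.step_param.append(step)

        if Xval is not None:
            vloss = mse_loss(model, Xval, Tval)
            hist.val_mse.append(vloss)
            if vloss < best_val:
                best_val = vloss
                bad_epochs = 0
                best_model = model.copy()
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    hist.stop_reason = "patience"
                    return best_model, hist
        else:
            hist.val_mse.append(np.nan)

        if loss <= cfg.goal_mse:
            hist.stop_reason = "goal"
            return model, hist
        if cfg.algorithm == "lm" and mu > cfg.mu_max:
            hist.stop_reason = "mu_overflow"
            return model, hist

    hist.stop_reason = "max_epochs"
    return model, hist


def predict(model: MlpModel, x, classes: Sequence = POSTURES):
    """Posture label(s) by argmax score; exact ties go to the lowest index."""
    y = forward(model, np.asarray(x, dtype=float))
    classes = list(classes)
    if y.ndim == 1:
        return classes[int(np.argmax(y))]
    return np.array([classes[i] for i in np.argmax(y, axis=1)], dtype=object)
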