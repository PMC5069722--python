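"""Single-hidden-layer neural networks trained by scaled conjugate gradient.

Two variants are compared against the discriminant classifiers:

* LNN — 4 hidden units with *linear* activations.  The composition of two
  affine maps is affine, so the LNN is mathematically a linear classifier;
  it serves as the neural-network counterpart of the LDA.
* MLPANN — 7 hidden units with tanh activations, a genuinely non-linear
  model.

Both use a softmax output with cross-entropy loss, full-batch scaled
conjugate gradient (SCG) optimisation, and validation-based early stopping:
training halts once the validation classification error has failed to
improve for ``patience`` consecutive epochs (one SCG step per epoch), and
the weights of the best validation epoch are restored.  Inputs are z-scored
with training-set statistics before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainConfig", "NeuralNetModel", "fit_nn", "nn_predict"]

_HIDDEN_UNITS = {"LNN": 4, "MLPANN": 7}


@dataclass(frozen=True)
class TrainConfig:
    """SCG training hyper-parameters."""

    max_epochs: int = 300
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")


@dataclass
class NeuralNetModel:
    """Trained network with its input standardisation and training trace."""

    kind: str  # "LNN" | "MLPANN"
    classes: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    input_mean: np.ndarray
    input_std: np.ndarray
    epochs_run: int = 0
    stop_reason: str = ""
    best_val_error: float = np.nan

    @property
    def activation(self) -> str:
        return "linear" if self.kind == "LNN" else "tanh"

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def _hidden(self, Z: np.ndarray) -> np.ndarray:
        H = Z @ self.W1 + self.b1
        return H if self.kind == "LNN" else np.tanh(H)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        Z = (X - self.input_mean) / self.input_std
        return self._hidden(Z) @ self.W2 + self.b2


def nn_predict(model: NeuralNetModel, X) -> np.ndarray:
    """Class labels by maximum output; ties go to the lowest class index."""
    scores = model.decision_scores(X)
    return np.asarray(model.classes)[np.argmax(scores, axis=1)]


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    T = np.zeros((len(y), len(classes)))
    for i, label in enumerate(y):
        T[i, idx[label]] = 1.0
    return T


def _softmax(S: np.ndarray) -> np.ndarray:
    S = S - S.max(axis=1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=1, keepdims=True)


class _Net:
    """Flat-parameter view of the network for the SCG optimiser."""

    def __init__(self, d: int, h: int, K: int, tanh: bool):
        self.d, self.h, self.K, self.tanh = d, h, K, tanh
        self.sizes = [(d, h), (h,), (h, K), (K,)]

    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        d, h, K = self.d, self.h, self.K
        W1 = rng.normal(0.0, np.sqrt(1.0 / d), size=(d, h))
        W2 = rng.normal(0.0, np.sqrt(1.0 / h), size=(h, K))
        return np.concatenate([W1.ravel(), np.zeros(h), W2.ravel(), np.zeros(K)])

    def unpack(self, w: np.ndarray):
        d, h, K = self.d, self.h, self.K
        i = 0
        W1 = w[i : i + d * h].reshape(d, h)
        i += d * h
        b1 = w[i : i + h]
        i += h
        W2 = w[i : i + h * K].reshape(h, K)
        i += h * K
        b2 = w[i : i + K]
        return W1, b1, W2, b2

    def loss_grad(self, w: np.ndarray, Z: np.ndarray, T: np.ndarray):
        W1, b1, W2, b2 = self.unpack(w)
        A = Z @ W1 + b1
        H = np.tanh(A) if self.tanh else A
        P = _softmax(H @ W2 + b2)
        n = Z.shape[0]
        eps = 1e-300
        loss = -np.sum(T * np.log(P + eps)) / n
        dS = (P - T) / n
        gW2 = H.T @ dS
        gb2 = dS.sum(axis=0)
        dH = dS @ W2.T
        dA = dH * (1.0 - H**2) if self.tanh else dH
        gW1 = Z.T @ dA
        gb1 = dA.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return loss, grad


def _scg_step_generator(f_g, w0: np.ndarray):
    """Scaled conjugate gradient (Moller 1993), yielded one step at a time.

    ``f_g`` maps a weight vector to (loss, gradient).  Yields the current
    weight vector after each accepted-or-rejected step so the caller can
    interleave validation checks.
    """
    sigma0 = 1.0e-4
    lam, lam_bar = 1.0e-6, 0.0
    w = w0.copy()
    fw, grad = f_g(w)
    r = -grad
    p = r.copy()
    success = True
    n_params = len(w)
    k = 0
    delta = 0.0
    while True:
        k += 1
        p_sq = float(p @ p)
        if p_sq == 0.0:
            yield w, "gradient vanished"
            return
        if success:
            sigma = sigma0 / np.sqrt(p_sq)
            _, grad_plus = f_g(w + sigma * p)
            s = (grad_plus - grad) / sigma
            delta = float(p @ s)
        # scale the Hessian estimate
        delta += (lam - lam_bar) * p_sq
        if delta <= 0:  # make the Hessian estimate positive-definite
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        fw_new, grad_new = f_g(w + alpha * p)
        comparison = 2.0 * delta * (fw - fw_new) / mu**2
        if comparison >= 0:  # successful step
            w = w + alpha * p
            fw = fw_new
            grad = grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if k % n_params == 0:  # restart the direction periodically
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1.0e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p_sq
        if lam > 1.0e20:
            yield w, "trust region collapsed"
            return
        yield w, ""


def fit_nn(kind: str, X, y, X_val, y_val, cfg: TrainConfig | None = None) -> NeuralNetModel:
    """Train an LNN or MLPANN with SCG and validation early stopping.

    Deterministic under ``cfg.seed``.  The returned model carries the
    weights of the epoch with the lowest validation classification error.
    """
    kind = kind.upper()
    if kind not in _HIDDEN_UNITS:
        raise ValueError(f"kind must be 'LNN' or 'MLPANN', got {kind!r}")
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    Xv = np.atleast_2d(np.asarray(X_val, dtype=float))
    yv = np.asarray(y_val)
    if Xv.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    if X.shape[1] != Xv.shape[1]:
        raise ValueError("train/validation feature dimensions differ")
    classes = np.unique(y)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    Zv = (Xv - mean) / std
    T = _one_hot(y, classes)
    net = _Net(X.shape[1], _HIDDEN_UNITS[kind], len(classes), tanh=kind == "MLPANN")
    rng = np.random.default_rng(cfg.seed)
    w = net.init_params(rng)

    def f_g(wv):
        loss, grad = net.loss_grad(wv, Z, T)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        return loss, grad

    def val_error(wv) -> float:
        W1, b1, W2, b2 = net.unpack(wv)
        H = Zv @ W1 + b1
        if net.tanh:
            H = np.tanh(H)
        pred = classes[np.argmax(H @ W2 + b2, axis=1)]
        return float(np.mean(pred != yv))

    best_w = w.copy()
    best_err = val_error(w)
    fails = 0
    epochs = 0
    stop_reason = "max epochs"
    stepper = _scg_step_generator(f_g, w)
    for epochs, (w, note) in enumerate(stepper, start=1):
        err = val_error(w)
        if err < best_err:
            best_err = err
            best_w = w.copy()
            fails = 0
        else:
            fails += 1
        if note:
            stop_reason = note
            break
        if fails >= cfg.patience:
            stop_reason = "validation error stopped improving"
            break
        if epochs >= cfg.max_epochs:
            break
    W1, b1, W2, b2 = net.unpack(best_w)
    return NeuralNetModel(
        kind=kind,
        classes=classes,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        input_mean=mean,
        input_std=std,
        epochs_run=epochs,
        stop_reason=stop_reason,
        best_val_error=best_err,
    )
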