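"""Shallow MLP classifier for IDH vs. normal sessions, with confusion-matrix metrics.

Architecture: 16 inputs (upper/lower max areas for 8 nested windows), 2-5
hidden layers of 16 tanh units, 2 softmax outputs. Training is full-batch
scaled conjugate gradient (Moller 1993) on the cross-entropy loss — a
Hessian-free CG variant with no learning rate, where one iteration is one
pass over the whole training set ("epoch"). Inputs are min-max scaled to
[-1, 1] with the scaling fitted on the training split only.

Metrics follow the standard confusion-matrix definitions with IDH as the
positive class; any metric whose denominator is zero is reported as None
(undefined), never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hr_features import FeatureVector, SessionLabel

__all__ = [
    "MLPConfig",
    "ConfusionMatrix",
    "EvalReport",
    "MLPModel",
    "train",
    "predict",
    "evaluate",
    "confusion_matrix",
]

_POSITIVE = SessionLabel.IDH  # alarm-favoring: ties predict IDH


@dataclass(frozen=True)
class MLPConfig:
    n_hidden_layers: int = 2
    hidden_width: int = 16
    n_outputs: int = 2
    max_epochs: int = 20
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    early_stopping: bool = False
    patience: int = 6

    def __post_init__(self) -> None:
        if not (2 <= self.n_hidden_layers <= 5):
            raise ValueError("n_hidden_layers must be in [2, 5]")
        if self.hidden_width <= 0 or self.n_outputs != 2:
            raise ValueError("hidden_width must be > 0 and n_outputs must be 2")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be > 0")
        if len(self.split) != 3 or not math.isclose(sum(self.split), 1.0, abs_tol=1e-9):
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.split) or self.split[0] <= 0:
            raise ValueError("split fractions must be >= 0 with a non-empty train part")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with IDH as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class EvalReport:
    """ACC/TPR/PPV in percent, MCC in [-1, 1]; None where undefined."""

    acc: float | None
    tpr: float | None
    ppv: float | None
    mcc: float | None
    matrix: ConfusionMatrix
    n_layers: int

    @classmethod
    def from_matrix(cls, m: ConfusionMatrix, n_layers: int) -> "EvalReport":
        acc = _safe_div(m.tp + m.tn, m.total)
        tpr = _safe_div(m.tp, m.tp + m.fn)
        ppv = _safe_div(m.tp, m.tp + m.fp)
        den = (m.tp + m.fn) * (m.tn + m.fp) * (m.tp + m.fp) * (m.tn + m.fn)
        mcc = None if den == 0 else (m.tp * m.tn - m.fn * m.fp) / math.sqrt(den)
        return cls(
            acc=None if acc is None else 100.0 * acc,
            tpr=None if tpr is None else 100.0 * tpr,
            ppv=None if ppv is None else 100.0 * ppv,
            mcc=mcc,
            matrix=m,
            n_layers=n_layers,
        )

    def to_dict(self) -> dict:
        m = self.matrix
        return {
            "acc": self.acc,
            "tpr": self.tpr,
            "ppv": self.ppv,
            "mcc": self.mcc,
            "matrix": {"tp": m.tp, "tn": m.tn, "fp": m.fp, "fn": m.fn},
            "n_layers": self.n_layers,
        }


# ---------------------------------------------------------------------------
# network internals


def _layer_sizes(n_inputs: int, cfg: MLPConfig) -> list[int]:
    return [n_inputs] + [cfg.hidden_width] * cfg.n_hidden_layers + [cfg.n_outputs]


def _init_params(sizes: list[int], rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = math.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def _flatten(params: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    return np.concatenate([a.ravel() for W, b in params for a in (W, b)])


def _unflatten(theta: np.ndarray, sizes: list[int]) -> list[tuple[np.ndarray, np.ndarray]]:
    params, pos = [], 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = theta[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out)
        pos += fan_in * fan_out
        b = theta[pos : pos + fan_out]
        pos += fan_out
        params.append((W, b))
    return params


def _forward(X: np.ndarray, params: list[tuple[np.ndarray, np.ndarray]]):
    acts = [X]
    h = X
    for W, b in params[:-1]:
        h = np.tanh(h @ W + b)
        acts.append(h)
    W, b = params[-1]
    logits = h @ W + b
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return acts, probs


def _loss_grad(theta: np.ndarray, sizes: list[int], X: np.ndarray, Y: np.ndarray):
    """Mean cross-entropy and its gradient (flattened) by backprop."""
    params = _unflatten(theta, sizes)
    acts, probs = _forward(X, params)
    n = X.shape[0]
    loss = -float(np.mean(np.log(np.maximum(probs[np.arange(n), Y], 1e-300))))
    delta = probs.copy()
    delta[np.arange(n), Y] -= 1.0
    delta /= n
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore
    for i in range(len(params) - 1, -1, -1):
        W, _ = params[i]
        grads[i] = (acts[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ W.T) * (1.0 - acts[i] ** 2)
    return loss, _flatten(grads)


def _scg(theta0, fun, max_iters: int, callback=None) -> np.ndarray:
    """Moller's scaled conjugate gradient; fun returns (loss, grad)."""
    sigma0 = 1e-4
    lam, lam_bar = 1e-6, 0.0
    theta = theta0.copy()
    f, g = fun(theta)
    r = -g
    p = r.copy()
    success = True
    n = theta.size
    delta = 0.0
    for k in range(1, max_iters + 1):
        p2 = float(p @ p)
        if p2 == 0.0:
            break
        if success:
            sigma = sigma0 / math.sqrt(p2)
            _, g2 = fun(theta + sigma * p)
            s = (g2 - (-r)) / sigma  # -r is the current gradient
            delta = float(p @ s)
        delta += (lam - lam_bar) * p2
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun(theta + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / (mu * mu)
        if comparison >= 0:
            theta = theta + alpha * p
            f = f_new
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if k % n == 0:
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
            if callback is not None and callback(theta, f):
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p2
    return theta


@dataclass
class _Scaler:
    """Per-feature min-max map to [-1, 1]; constant features map to 0."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        span = np.where(span == 0, 1.0, span)
        return np.clip(2.0 * (X - self.lo) / span - 1.0, -3.0, 3.0)


@dataclass
class MLPModel:
    config: MLPConfig
    sizes: list[int]
    params: list[tuple[np.ndarray, np.ndarray]]
    scaler: _Scaler
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    train_loss: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.sizes[0]:
            raise ValueError(f"expected {self.sizes[0]} features, got {X.shape[1]}")
        _, probs = _forward(self.scaler.transform(X), self.params)
        return probs

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_hidden_layers": self.config.n_hidden_layers,
                "hidden_width": self.config.hidden_width,
                "n_outputs": self.config.n_outputs,
                "max_epochs": self.config.max_epochs,
                "split": list(self.config.split),
                "seed": self.config.seed,
                "early_stopping": self.config.early_stopping,
                "patience": self.config.patience,
            },
            "sizes": self.sizes,
            "weights": [[W.tolist(), b.tolist()] for W, b in self.params],
            "scaler": {"lo": self.scaler.lo.tolist(), "hi": self.scaler.hi.tolist()},
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "train_loss": self.train_loss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        cfg = MLPConfig(
            n_hidden_layers=d["config"]["n_hidden_layers"],
            hidden_width=d["config"]["hidden_width"],
            n_outputs=d["config"]["n_outputs"],
            max_epochs=d["config"]["max_epochs"],
            split=tuple(d["config"]["split"]),
            seed=d["config"]["seed"],
            early_stopping=d["config"]["early_stopping"],
            patience=d["config"]["patience"],
        )
        return cls(
            config=cfg,
            sizes=list(d["sizes"]),
            params=[(np.array(W), np.array(b)) for W, b in d["weights"]],
            scaler=_Scaler(lo=np.array(d["scaler"]["lo"]), hi=np.array(d["scaler"]["hi"])),
            train_idx=np.array(d["train_idx"], dtype=int),
            val_idx=np.array(d["val_idx"], dtype=int),
            test_idx=np.array(d["test_idx"], dtype=int),
            train_loss=float(d["train_loss"]),
        )


def _as_arrays(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    if not features:
        raise ValueError("no feature vectors given")
    width = len(features[0])
    X = np.empty((len(features), width))
    y = np.empty(len(features), dtype=int)
    for i, fv in enumerate(features):
        if len(fv) != width:
            raise ValueError(f"feature vector {i} has length {len(fv)}, expected {width}")
        if fv.label is None:
            raise ValueError(f"feature vector {i} has no label")
        X[i] = fv.values
        y[i] = 1 if fv.label == _POSITIVE else 0
    if not np.all(np.isfinite(X)):
        raise ValueError("NaN or infinite value in features")
    return X, y


def _stratified_split(y: np.ndarray, split: tuple[float, float, float], rng: np.random.Generator):
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = idx.size
        n_tr = int(round(split[0] * n))
        n_va = int(round(split[1] * n))
        n_tr = min(n_tr, n)
        n_va = min(n_va, n - n_tr)
        train.append(idx[:n_tr])
        val.append(idx[n_tr : n_tr + n_va])
        test.append(idx[n_tr + n_va :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def train(features: list[FeatureVector], cfg: MLPConfig | None = None) -> MLPModel:
    """Train the MLP on labeled feature vectors; deterministic given cfg.seed."""
    cfg = cfg or MLPConfig()
    X, y = _as_arrays(features)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        missing = SessionLabel.NORMAL if counts[0] == 0 else _POSITIVE
        raise ValueError(f"class {missing.value} absent from training data")
    rng = np.random.default_rng(cfg.seed)
    tr, va, te = _stratified_split(y, cfg.split, rng)
    scaler = _Scaler.fit(X[tr])
    Xtr, ytr = scaler.transform(X[tr]), y[tr]
    sizes = _layer_sizes(X.shape[1], cfg)
    theta0 = _flatten(_init_params(sizes, rng))

    def fun(theta: np.ndarray):
        return _loss_grad(theta, sizes, Xtr, ytr)

    callback = None
    if cfg.early_stopping and va.size:
        Xva, yva = scaler.transform(X[va]), y[va]
        state = {"best": math.inf, "bad": 0}

        def callback(theta: np.ndarray, _f: float) -> bool:
            vloss, _ = _loss_grad(theta, sizes, Xva, yva)
            if vloss < state["best"] - 1e-12:
                state["best"], state["bad"] = vloss, 0
            else:
                state["bad"] += 1
            return state["bad"] > cfg.patience

    theta = _scg(theta0, fun, cfg.max_epochs, callback=callback)
    loss, _ = fun(theta)
    return MLPModel(
        config=cfg,
        sizes=sizes,
        params=_unflatten(theta, sizes),
        scaler=scaler,
        train_idx=tr,
        val_idx=va,
        test_idx=te,
        train_loss=loss,
    )


def predict(model: MLPModel, features) -> tuple[list[SessionLabel], np.ndarray]:
    """Predicted labels and (p_normal, p_idh) rows; exact ties go to IDH."""
    if isinstance(features, FeatureVector):
        X = features.values[None, :]
    elif isinstance(features, list) and features and isinstance(features[0], FeatureVector):
        X = np.stack([fv.values for fv in features])
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    probs = model.predict_proba(X)
    labels = [
        _POSITIVE if p[1] >= p[0] else SessionLabel.NORMAL  # tie -> alarm
        for p in probs
    ]
    return labels, probs


def confusion_matrix(y_true: list[SessionLabel], y_pred: list[SessionLabel]) -> ConfusionMatrix:
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred, strict=True):
        if t == _POSITIVE:
            if p == _POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == _POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def evaluate(model: MLPModel, test_features: list[FeatureVector]) -> EvalReport:
    """Confusion matrix and ACC/TPR/PPV/MCC on a labeled evaluation set."""
    if not test_features:
        raise ValueError("empty test set")
    y_true = []
    for fv in test_features:
        if fv.label is None:
            raise ValueError("evaluation requires labeled feature vectors")
        y_true.append(fv.label)
    y_pred, _ = predict(model, test_features)
    return EvalReport.from_matrix(
        confusion_matrix(y_true, y_pred), n_layers=model.config.n_hidden_layers
    )
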