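"""Extreme learning machine: random hidden layer, closed-form output weights.

A single-hidden-layer feedforward network in which the hidden-layer input
weights ``a_j`` and biases ``b_j`` are drawn at random (uniform on [-1, 1])
and never trained; only the output weights ``beta`` are fitted, in closed
form, as the minimum-norm least-squares solution

    beta = pinv(H) @ Y,    H[i, j] = g(a_j . x_i + b_j),

with the Moore-Penrose pseudoinverse computed by SVD with a machine-
epsilon-scaled singular-value cutoff (the saturating activation can make H
rank-deficient).  The default activation is ``satlins``, the symmetric
saturating linear map clamping its argument to [-1, 1]; sigmoid and tanh
are registered for experimentation.

Because the hidden layer is random, a single fit is a noisy draw; the
repeat-and-average protocol (:func:`elm_repeat_eval`) refits with a small
number of derived seeds (< 10) and reports per-restart and mean accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .evaluation import compute_metrics


def satlins(v):
    """Symmetric saturating linear activation: clamp to [-1, 1] elementwise."""
    return np.clip(v, -1.0, 1.0)


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


ACTIVATIONS: dict[str, Callable] = {
    "satlins": satlins,
    "sigmoid": _sigmoid,
    "tanh": np.tanh,
}


@dataclass
class SampleSet:
    """Aligned training inputs X (N x n) and targets Y (N x m)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.asarray(self.Y, dtype=float)
        self.Y = Y.reshape(-1, 1) if Y.ndim == 1 else Y
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.X.shape[0] < 1:
            raise ValueError("at least one sample is required")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("training values must be finite")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.X.shape[1]


@dataclass
class ELMModel:
    """A fitted network: everything needed to reproduce its predictions."""

    L: int
    a: np.ndarray  # (L, n) hidden input weights
    b: np.ndarray  # (L,) hidden biases
    activation: str
    beta: np.ndarray  # (L, m) output weights
    seed: int

    def hidden(self, X: np.ndarray) -> np.ndarray:
        g = ACTIVATIONS[self.activation]
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.a.shape[1]:
            raise ValueError(
                f"input dimension {X.shape[1]} does not match model dimension {self.a.shape[1]}"
            )
        return g(X @ self.a.T + self.b)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        doc = json.dumps(
            {
                "L": self.L,
                "activation": self.activation,
                "seed": self.seed,
                "a": self.a.tolist(),
                "b": self.b.tolist(),
                "beta": self.beta.tolist(),
            }
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "ELMModel":
        text = Path(doc).read_text() if isinstance(doc, Path) else doc
        d = json.loads(text)
        return cls(
            L=d["L"],
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            activation=d["activation"],
            beta=np.asarray(d["beta"], dtype=float),
            seed=d["seed"],
        )


def elm_fit(train: SampleSet, L: int, activation: str = "satlins", seed: int = 0) -> ELMModel:
    """Draw the random hidden layer and solve for the output weights.

    ``a`` and ``b`` are iid uniform on [-1, 1] from ``seed``; ``beta`` is
    the minimum-norm least-squares solution of ``H beta = Y`` via the SVD
    pseudoinverse.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if activation not in ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 1.0, size=(L, train.n_inputs))
    b = rng.uniform(-1.0, 1.0, size=L)
    model = ELMModel(L=L, a=a, b=b, activation=activation, beta=np.zeros((L, 1)), seed=seed)
    H = model.hidden(train.X)
    model.beta = np.linalg.pinv(H) @ train.Y
    return model


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Network output ``sum_j beta_j g(a_j . x + b_j)`` for each row of X."""
    return model.hidden(X) @ model.beta


@dataclass
class RepeatEvaluation:
    """Repeat-and-average protocol output."""

    models: list[ELMModel]
    train_mape: list[float]
    train_rmse: list[float]
    test_mape: list[float]
    test_rmse: list[float]
    mean_train_mape: float = field(init=False)
    mean_train_rmse: float = field(init=False)
    mean_test_mape: float = field(init=False)
    mean_test_rmse: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_train_mape = float(np.mean(self.train_mape))
        self.mean_train_rmse = float(np.mean(self.train_rmse))
        self.mean_test_mape = float(np.mean(self.test_mape))
        self.mean_test_rmse = float(np.mean(self.test_rmse))


def elm_repeat_eval(
    train: SampleSet,
    test: SampleSet,
    L: int,
    activation: str = "satlins",
    n_restarts: int = 5,
    seed: int = 0,
) -> RepeatEvaluation:
    """Fit ``n_restarts`` networks from derived seeds and average accuracy.

    Restart seeds are spawned from the master seed, so the whole
    evaluation is reproducible from ``(train, test, L, activation, seed)``.
    """
    if not (1 <= n_restarts <= 10):
        raise ValueError("n_restarts must lie in 1..10")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    models, tr_mape, tr_rmse, te_mape, te_rmse = [], [], [], [], []
    for s in child_seeds:
        model = elm_fit(train, L=L, activation=activation, seed=int(s))
        models.append(model)
        m_tr = compute_metrics(train.Y.ravel(), elm_predict(model, train.X).ravel())
        m_te = compute_metrics(test.Y.ravel(), elm_predict(model, test.X).ravel())
        tr_mape.append(m_tr.mape)
        tr_rmse.append(m_tr.rmse)
        te_mape.append(m_te.mape)
        te_rmse.append(m_te.rmse)
    return RepeatEvaluation(models, tr_mape, tr_rmse, te_mape, te_rmse)
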