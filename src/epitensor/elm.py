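"""Extreme learning machine (ELM) with ridge regularization.

A single hidden layer of M neurons with *random, untrained* input weights
maps features x to h(x) = g(W x + b); only the output weights beta are
estimated, by regularized least squares against one-hot class targets:

    beta = (H^T H + E I)^-1 H^T Y      (M <= N)
    beta = H^T (H H^T + E I)^-1 Y      (M >  N)

the two forms agreeing by the push-through identity.  The ridge parameter E
is selected by exact leave-one-out (PRESS): for a linear smoother
``Yhat = HAT Y`` with ``HAT = H (H^T H + E I)^-1 H^T``, the LOO residual of
sample i is ``(y_i - yhat_i) / (1 - HAT_ii)`` without any retraining.

Labels are 1 (inter-ictal) and 2 (pre-ictal); features are standardized
with training-set statistics only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ConfigurationError

logger = logging.getLogger("epitensor")

LABELS = (1, 2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def one_hot(labels: np.ndarray) -> np.ndarray:
    """Map labels {1, 2} to rows (1,0) / (0,1)."""
    labels = np.asarray(labels)
    if not np.isin(labels, LABELS).all():
        raise ValueError("labels must be 1 (inter-ictal) or 2 (pre-ictal)")
    Y = np.zeros((labels.size, 2))
    Y[np.arange(labels.size), labels - 1] = 1.0
    return Y


@dataclass
class ElmModel:
    """A trained ELM: random hidden layer plus solved output weights."""

    W: np.ndarray  # M x d input weights (rows w_j)
    b: np.ndarray  # length M biases
    beta: np.ndarray  # M x l output weights
    train_mean: np.ndarray
    train_sd: np.ndarray
    M: int
    E: float
    seed: int
    activation: str = "sigmoid"

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.train_mean) / self.train_sd


def random_hidden_layer(d: int, M: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Input weights uniform on [-1, 1], biases uniform on [0, 1]."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(M, d))
    b = rng.uniform(0.0, 1.0, size=M)
    return W, b


def hidden_matrix(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output H with H[i, j] = g(w_j . x_i + b_j), N x M.

    ``X`` must already be on the model's standardized scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"feature dimension {X.shape[1]} != model d={model.d}")
    return _sigmoid(X @ model.W.T + model.b)


def _solve_beta(H: np.ndarray, Y: np.ndarray, E: float) -> np.ndarray:
    N, M = H.shape
    if M <= N:
        return np.linalg.solve(H.T @ H + E * np.eye(M), H.T @ Y)
    return H.T @ np.linalg.solve(H @ H.T + E * np.eye(N), Y)


def train(
    X: np.ndarray,
    labels: np.ndarray,
    M: int = 100,
    E: float = 1.0,
    seed: int = 0,
) -> ElmModel:
    """Train an ELM on features ``X`` (N x d) with labels in {1, 2}."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] < 2:
        raise ConfigurationError("need at least 2 training samples")
    if np.unique(labels).size < 2:
        raise ConfigurationError("training data must contain both classes")
    if E <= 0:
        raise ConfigurationError("regularization parameter E must be positive")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    W, b = random_hidden_layer(X.shape[1], M, seed)
    H = _sigmoid(Xs @ W.T + b)
    beta = _solve_beta(H, one_hot(labels), E)
    return ElmModel(
        W=W, b=b, beta=beta, train_mean=mean, train_sd=sd, M=M, E=E, seed=seed
    )


def decision_values(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Network outputs Yhat = H beta (N x 2) on raw-scale features."""
    H = hidden_matrix(model, model.standardize(np.atleast_2d(np.asarray(X, float))))
    return H @ model.beta


def predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels in {1, 2}; ties break toward label 1."""
    Yhat = decision_values(model, X)
    return np.where(Yhat[:, 0] >= Yhat[:, 1], 1, 2)


def press_loo_mse(H: np.ndarray, Y: np.ndarray, E: float) -> float:
    """Mean squared leave-one-out residual of the ridge fit, in closed form.

    Residuals are pooled over both output columns.  Returns ``inf`` when a
    leverage 1 - HAT_ii falls below 1e-12 (the fit interpolates sample i).
    """
    N, M = H.shape
    G = H.T @ H + E * np.eye(M)
    HG = np.linalg.solve(G.T, H.T).T  # H G^-1
    hat_diag = np.einsum("ij,ij->i", HG, H)
    denom = 1.0 - hat_diag
    if np.any(denom < 1e-12):
        logger.info("PRESS: leverage ~1 at E=%g; candidate skipped", E)
        return np.inf
    resid = Y - H @ (HG.T @ Y)  # Y - H beta
    loo = resid / denom[:, None]
    return float(np.mean(loo**2))


def select_regularization(
    X: np.ndarray,
    labels: np.ndarray,
    M: int = 100,
    E_grid=(1.0,),
    seed: int = 0,
) -> float:
    """Ridge value from ``E_grid`` minimizing the PRESS LOO error.

    The random hidden layer is drawn once from ``seed`` and shared across
    the grid so candidates differ only in E; ties break toward smaller E.
    """
    E_grid = sorted(float(e) for e in E_grid)
    if not E_grid:
        raise ConfigurationError("E_grid must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    W, b = random_hidden_layer(X.shape[1], M, seed)
    H = _sigmoid(((X - mean) / sd) @ W.T + b)
    Y = one_hot(np.asarray(labels))
    scores = [press_loo_mse(H, Y, E) for E in E_grid]
    best = int(np.argmin(scores))  # argmin takes the first = smallest E on ties
    if not np.isfinite(scores[best]):
        raise ConfigurationError("every E candidate produced leverage ~1")
    logger.info("PRESS selected E=%g (LOO MSE %.5g)", E_grid[best], scores[best])
    return E_grid[best]


# ---------------------------------------------------------------------------
# Serialization (runtime artifacts: .npz arrays + .json metadata)
# ---------------------------------------------------------------------------


def save_model(model: ElmModel, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        W=model.W,
        b=model.b,
        beta=model.beta,
        train_mean=model.train_mean,
        train_sd=model.train_sd,
    )
    meta = {"M": model.M, "E": model.E, "seed": model.seed, "activation": model.activation}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> ElmModel:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ElmModel(
        W=arrays["W"],
        b=arrays["b"],
        beta=arrays["beta"],
        train_mean=arrays["train_mean"],
        train_sd=arrays["train_sd"],
        M=int(meta["M"]),
        E=float(meta["E"]),
        seed=int(meta["seed"]),
        activation=meta["activation"],
    )
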