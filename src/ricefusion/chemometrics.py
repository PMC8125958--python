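"""PCA feature reduction, BPNN regression, metrics and run statistics.

The calibration model is a small feed-forward network trained by classic
error backpropagation: sigmoid hidden units, a linear output unit, and
per-pattern (incremental) gradient descent on the squared error — each
training pattern is propagated forward and the weights and thresholds of
every layer are adjusted along the backward pass, patterns being visited
in data order within each epoch.  Inputs and the target are min-max
scaled to [0, 1] from the training data; training stops after
``max_iterations`` epochs or once the training RMSE (on the scaled
target) falls below ``target_rmse``.

Because repeated-run protocols retrain the same network under many
initialization seeds, the trainer is vectorized across networks: the
per-pattern update of R independent networks is a batched matrix
operation, and a boolean sample mask lets disjoint cross-validation
folds share one pass over the data (a masked pattern contributes a zero
update, which is exactly "not trained on").
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PCAModel",
    "pca_fit",
    "pca_transform",
    "BPNNConfig",
    "BPNNModel",
    "bpnn_train",
    "bpnn_predict",
    "backprop_gradients",
    "pearson_r",
    "rmse",
    "MetricPair",
    "cross_validate",
    "RunStats",
    "repeat_runs",
    "derive_seeds",
    "save_bpnn",
    "load_bpnn",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    """Raised when data has no variance where variance is required."""


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAModel:
    """A fitted principal-component basis.

    ``loadings`` holds k orthonormal directions as columns, ordered by
    decreasing explained variance; ``explained_variance_ratio`` gives the
    fraction of total training variance each component carries (the
    "covariance contribution rate").
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA by SVD of the mean-centred data matrix
    (equivalent to eigendecomposition of the sample covariance).

    Components are ordered by decreasing variance; each loading's sign is
    fixed so its largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    max_k = min(n - 1, p)
    if not (1 <= k <= max_k):
        raise ValueError(f"k must be in [1, {max_k}], got {k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = Xc.var(axis=0, ddof=1).sum()
    if total_var == 0:
        raise DegenerateDataError("constant data matrix: PCA undefined")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = Vt[:k].T.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    evr = eigvals[:k] / total_var
    return PCAModel(mean=mean, loadings=loadings, explained_variance_ratio=evr)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project samples onto the fitted basis: ``(X - mean) @ loadings``."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    scores = (X - model.mean) @ model.loadings
    return scores[0] if single else scores


# ---------------------------------------------------------------------------
# BPNN


@dataclass(frozen=True)
class BPNNConfig:
    """Training configuration of the backpropagation network.

    Defaults follow the calibration protocol: 5 hidden nodes, learning
    rate 0.1, 100 iterations (epochs), minimum RMSE 4e-5 on the scaled
    target.  ``hidden_layers`` is the node count per hidden layer; the
    deeper three-layer variant ``(5, 5, 5)`` is selectable but converges
    more slowly under plain gradient descent.
    """

    hidden_layers: tuple[int, ...] = (5,)
    learning_rate: float = 0.1
    max_iterations: int = 100
    target_rmse: float = 4e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layers or any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden_layers must be positive counts")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))


@dataclass
class BPNNModel:
    """A trained network plus the min-max scalers frozen from training."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    config: BPNNConfig
    n_epochs_run: int = 0

    def __post_init__(self) -> None:
        dims = [W.shape for W in self.weights]
        for (a, b), (c, d) in zip(dims[:-1], dims[1:]):
            if b != c:
                raise ValueError(f"layer shapes do not chain: {dims}")
        if dims[-1][1] != 1:
            raise ValueError("output layer must have a single unit")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(
    layer_dims: Sequence[int], seeds: Sequence[int]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Uniform(-0.5, 0.5) weights and biases, one parameter set per seed.

    Per network, draws follow a fixed order (layer by layer, W then b)
    from that network's own generator, so single- and multi-network
    training see identical initializations for identical seeds.
    """
    R = len(seeds)
    rngs = [np.random.default_rng(s) for s in seeds]
    Ws: list[np.ndarray] = []
    bs: list[np.ndarray] = []
    draws = [[] for _ in range(R)]
    for r, rng in enumerate(rngs):
        for a, b in zip(layer_dims[:-1], layer_dims[1:]):
            W = rng.uniform(-0.5, 0.5, size=(a, b))
            bias = rng.uniform(-0.5, 0.5, size=(1, b))
            draws[r].append((W, bias))
    n_layers = len(layer_dims) - 1
    for li in range(n_layers):
        Ws.append(np.stack([draws[r][li][0] for r in range(R)]))
        bs.append(np.stack([draws[r][li][1] for r in range(R)]))
    return Ws, bs


def _forward_many(
    Xs: np.ndarray, Ws: list[np.ndarray], bs: list[np.ndarray]
) -> np.ndarray:
    """Forward pass of R networks on their own inputs.

    ``Xs`` is (R, n, d); returns scaled outputs (R, n).
    """
    a = Xs
    n_layers = len(Ws)
    for i in range(n_layers):
        z = a @ Ws[i] + bs[i]
        a = z if i == n_layers - 1 else _sigmoid(z)
    return a[..., 0]


def _train_core(
    Xs: np.ndarray,
    ys: np.ndarray,
    layer_dims: Sequence[int],
    lr: float,
    max_epochs: int,
    target_rmse: float,
    Ws: list[np.ndarray],
    bs: list[np.ndarray],
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pattern gradient descent on R networks in parallel.

    ``Xs``: (R, n, d) scaled inputs per network; ``ys``: (R, n) scaled
    targets; ``mask``: (R, n) boolean — patterns a network trains on.
    Parameters are updated in place; returns the epoch count at which
    each network stopped.
    """
    R, n, _ = Xs.shape
    if mask is None:
        mask = np.ones((R, n), dtype=bool)
    active = np.ones(R, dtype=bool)
    epochs_run = np.zeros(R, dtype=int)
    n_layers = len(Ws)
    acts: list[np.ndarray] = [np.empty(0)] * (n_layers + 1)
    for epoch in range(max_epochs):
        gate_any = active[:, None, None]
        for j in range(n):
            a = Xs[:, j, :][:, None, :]
            acts[0] = a
            for i in range(n_layers):
                z = a @ Ws[i] + bs[i]
                a = z if i == n_layers - 1 else _sigmoid(z)
                acts[i + 1] = a
            # gradient of 0.5 * e^2 for this pattern; masked nets get 0
            gate = gate_any * mask[:, j][:, None, None]
            delta = (acts[-1] - ys[:, j][:, None, None]) * gate
            for i in range(n_layers - 1, -1, -1):
                gW = np.swapaxes(acts[i], 1, 2) @ delta
                gb = delta
                if i > 0:
                    delta = (delta @ np.swapaxes(Ws[i], 1, 2)) * (
                        acts[i] * (1.0 - acts[i])
                    )
                Ws[i] -= lr * gW
                bs[i] -= lr * gb
        epochs_run[active] = epoch + 1
        if target_rmse > 0 and np.isfinite(target_rmse):
            out = _forward_many(Xs, Ws, bs)
            sq = (out - ys) ** 2
            msk_rmse = np.sqrt(
                (sq * mask).sum(axis=1) / np.maximum(mask.sum(axis=1), 1)
            )
            active &= msk_rmse > target_rmse
            if not active.any():
                break
    return epochs_run


def _minmax_scale(
    X: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    span = hi - lo
    out = np.empty_like(X, dtype=float)
    degenerate = span == 0
    safe = np.where(degenerate, 1.0, span)
    out = (X - lo) / safe
    if np.ndim(out) == 2:
        out[:, degenerate] = 0.5
    elif np.any(degenerate):
        out = np.where(degenerate, 0.5, out)
    return out


def bpnn_train(cfg: BPNNConfig, X: np.ndarray, y: np.ndarray) -> BPNNModel:
    """Train one network on (X, y) in original units.

    Min-max scales inputs and target to [0, 1] from the training data
    (a zero-range input feature maps to 0.5), initializes weights
    U(-0.5, 0.5) from ``cfg.seed``, and runs per-pattern gradient
    descent.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        raise DegenerateDataError("target has zero range")
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    Xs = _minmax_scale(X, x_min, x_max)[None, :, :]
    ys = ((y - y_min) / (y_max - y_min))[None, :]

    layer_dims = [X.shape[1], *cfg.hidden_layers, 1]
    Ws, bs = _init_params(layer_dims, [cfg.seed])
    epochs = _train_core(
        Xs, ys, layer_dims, cfg.learning_rate, cfg.max_iterations,
        cfg.target_rmse, Ws, bs,
    )
    return BPNNModel(
        weights=[W[0] for W in Ws],
        biases=[b[0] for b in bs],
        x_min=x_min,
        x_max=x_max,
        y_min=y_min,
        y_max=y_max,
        config=cfg,
        n_epochs_run=int(epochs[0]),
    )


def bpnn_predict(model: BPNNModel, X: np.ndarray) -> np.ndarray:
    """Forward pass followed by inverse target scaling (mg/100 g)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.weights[0].shape[0]})"
        )
    Xs = _minmax_scale(X, model.x_min, model.x_max)[None, :, :]
    out = _forward_many(
        Xs, [W[None] for W in model.weights], [b[None] for b in model.biases]
    )[0]
    return out * (model.y_max - model.y_min) + model.y_min


def backprop_gradients(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Loss ``E = 0.5 * sum(e^2)`` over a batch and its analytic
    gradients — the backward pass the trainer applies pattern by pattern.
    Exposed so the gradients can be checked against finite differences.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Ws = [W[None] for W in weights]
    bs = [b[None] for b in biases]
    n_layers = len(Ws)
    a = X[None, :, :]
    acts = [a]
    for i in range(n_layers):
        z = a @ Ws[i] + bs[i]
        a = z if i == n_layers - 1 else _sigmoid(z)
        acts.append(a)
    err = acts[-1][0, :, 0] - y
    loss = 0.5 * float(np.sum(err**2))
    delta = acts[-1] - y[None, :, None]
    gWs: list[np.ndarray] = [np.empty(0)] * n_layers
    gbs: list[np.ndarray] = [np.empty(0)] * n_layers
    for i in range(n_layers - 1, -1, -1):
        gWs[i] = (np.swapaxes(acts[i], 1, 2) @ delta)[0]
        gbs[i] = delta.sum(axis=1)[0]
        if i > 0:
            delta = (delta @ np.swapaxes(Ws[i], 1, 2)) * (
                acts[i] * (1.0 - acts[i])
            )
    return loss, gWs, gbs


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricPair:
    """Correlation / error pair for one evaluation set."""

    r: float
    rmse: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


def pearson_r(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation between reference and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(np.corrcoef(y, y_hat)[0, 1])


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error, in the units of y (mg/100 g)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 1:
        raise ValueError("need two equal-length vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


# ---------------------------------------------------------------------------
# cross-validation and repeated runs


def fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Random fold labels 0..folds-1, balanced to within one sample."""
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, {n}], got {folds}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % folds
    return labels[rng.permutation(n)]


def cross_validate(
    cfg: BPNNConfig,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    reducer: Callable[[np.ndarray], Callable[[np.ndarray], np.ndarray]] | None = None,
) -> MetricPair:
    """K-fold cross-validation of the BPNN.

    Folds are randomly assigned from ``seed``; metrics (R_C, RMSECV) are
    computed on the pooled out-of-fold predictions.  ``reducer``, if
    given, is fitted on each training fold only (e.g. a PCA factory) and
    returns the transform applied to both fold partitions — no test-fold
    information reaches any fitted parameter.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    labels = fold_assignment(len(y), folds, seed)
    pooled = np.empty_like(y)
    for f in range(folds):
        te = labels == f
        tr = ~te
        X_tr, X_te = X[tr], X[te]
        if reducer is not None:
            transform = reducer(X_tr)
            X_tr, X_te = transform(X_tr), transform(X_te)
        fold_seed = int(
            np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(f,)
            ).generate_state(1)[0]
            % (2**31)
        )
        model = bpnn_train(
            BPNNConfig(
                hidden_layers=cfg.hidden_layers,
                learning_rate=cfg.learning_rate,
                max_iterations=cfg.max_iterations,
                target_rmse=cfg.target_rmse,
                seed=fold_seed,
            ),
            X_tr,
            y[tr],
        )
        pooled[te] = bpnn_predict(model, X_te)
    return MetricPair(r=pearson_r(y, pooled), rmse=rmse(y, pooled))


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible 31-bit sub-seeds spawned from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass(frozen=True)
class RunStats:
    """Per-metric statistics over repeated runs.

    ``values`` holds one row per run; means, sample variances (ddof=1)
    and standard deviations are reported per metric.
    """

    values: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> pd.Series:
        return self.values.mean()

    @property
    def variance(self) -> pd.Series:
        return self.values.var(ddof=1)

    @property
    def sd(self) -> pd.Series:
        return self.values.std(ddof=1)


def repeat_runs(
    procedure: Callable[[int], Mapping[str, float]],
    n_runs: int = 50,
    master_seed: int = 0,
) -> RunStats:
    """Execute ``procedure(seed)`` under ``n_runs`` derived seeds.

    Averaging over repeated runs removes the influence of random weight
    initialization on the reported model metrics.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = derive_seeds(master_seed, n_runs)
    rows = [dict(procedure(s)) for s in seeds]
    return RunStats(values=pd.DataFrame(rows, index=seeds))


# ---------------------------------------------------------------------------
# persistence


def save_bpnn(model: BPNNModel, path: str | Path) -> None:
    """Serialize a trained network (weights, scalers, config) to JSON."""
    payload = {
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "x_min": model.x_min.tolist(),
        "x_max": model.x_max.tolist(),
        "y_min": model.y_min,
        "y_max": model.y_max,
        "n_epochs_run": model.n_epochs_run,
        "config": {
            "hidden_layers": list(model.config.hidden_layers),
            "learning_rate": model.config.learning_rate,
            "max_iterations": model.config.max_iterations,
            "target_rmse": model.config.target_rmse,
            "seed": model.config.seed,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_bpnn(path: str | Path) -> BPNNModel:
    payload = json.loads(Path(path).read_text())
    cfg = BPNNConfig(
        hidden_layers=tuple(payload["config"]["hidden_layers"]),
        learning_rate=payload["config"]["learning_rate"],
        max_iterations=payload["config"]["max_iterations"],
        target_rmse=payload["config"]["target_rmse"],
        seed=payload["config"]["seed"],
    )
    return BPNNModel(
        weights=[np.array(W) for W in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        x_min=np.array(payload["x_min"]),
        x_max=np.array(payload["x_max"]),
        y_min=payload["y_min"],
        y_max=payload["y_max"],
        config=cfg,
        n_epochs_run=payload["n_epochs_run"],
    )
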