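"""Pair classifiers: a small feedforward network plus KNN/RF baselines.

Two architectures are provided.  ``merged`` feeds the full pair
descriptor through a stack of ReLU hidden layers into a single sigmoid
output.  ``siamese`` splits the descriptor into its two protein halves,
passes each through its own twin subnetwork (independent weights),
concatenates the twin outputs and finishes with fused ReLU layers and a
sigmoid output.  Training minimises the mean binary cross-entropy with
the Adam optimiser and inverted dropout on hidden activations; all
randomness (initialisation, shuffling, dropout masks) is driven by one
seed, so training is bitwise reproducible.

The forward/backward passes are written explicitly in numpy so the
gradients can be validated against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier


@dataclass
class DNNConfig:
    architecture: str = "merged"
    hidden: tuple[int, ...] = (48, 48)
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    twin_depth: int = 1  # siamese: leading `hidden` entries used per twin

    def __post_init__(self) -> None:
        self.hidden = tuple(int(h) for h in self.hidden)
        if self.architecture not in ("merged", "siamese"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not self.hidden or any(h < 1 for h in self.hidden):
            raise ValueError("hidden widths must be >= 1, at least one layer")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid optimiser settings")
        if self.architecture == "siamese" and not (
            1 <= self.twin_depth <= len(self.hidden)
        ):
            raise ValueError("twin_depth must index into hidden")


@dataclass
class ModelState:
    """Trained weights/biases, the config that produced them, and the
    per-epoch training-loss trace.

    ``input_mean``/``input_scale`` hold the training-set centring vector
    and single global scale applied to inputs before the network; the
    scalar scale preserves the relative variances of the SVD-reduced
    components while conditioning the optimisation.
    """

    params: list[np.ndarray]
    config: DNNConfig
    input_dim: int
    loss_trace: list[float] = field(default_factory=list)
    input_mean: np.ndarray | None = None
    input_scale: float = 1.0


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _layer_dims(cfg: DNNConfig, d: int) -> list[tuple[int, int]]:
    """(fan_in, fan_out) for every weight matrix, in parameter order."""
    if cfg.architecture == "merged":
        widths = [d, *cfg.hidden, 1]
        return list(zip(widths[:-1], widths[1:]))
    half = d // 2
    twin = [half, *cfg.hidden[: cfg.twin_depth]]
    twin_dims = list(zip(twin[:-1], twin[1:]))
    fused_in = 2 * cfg.hidden[cfg.twin_depth - 1]
    fused = [fused_in, *cfg.hidden[cfg.twin_depth :], 1]
    fused_dims = list(zip(fused[:-1], fused[1:]))
    return twin_dims + twin_dims + fused_dims  # twin A, twin B, fused


def _init_params(cfg: DNNConfig, d: int, rng: np.random.Generator) -> list[np.ndarray]:
    params: list[np.ndarray] = []
    for fan_in, fan_out in _layer_dims(cfg, d):
        params.append(_glorot(rng, fan_in, fan_out))
        params.append(np.zeros(fan_out))
    return params


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _dropout_mask(
    rng: np.random.Generator | None, rate: float, shape: tuple[int, ...]
) -> np.ndarray | None:
    if rng is None or rate <= 0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


class _Forward:
    """One forward pass with everything cached for backprop."""

    def __init__(
        self,
        params: list[np.ndarray],
        cfg: DNNConfig,
        X: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.params = params
        self.cfg = cfg
        self.X = X
        self.acts: list[np.ndarray] = []  # post-activation (post-dropout) per layer
        self.pre: list[np.ndarray] = []  # pre-activation per layer
        self.masks: list[np.ndarray | None] = []
        self.scores = self._run(rng)

    def _stack(
        self,
        a: np.ndarray,
        layer_idx: range,
        rng: np.random.Generator | None,
        final_sigmoid: bool,
    ) -> np.ndarray:
        n_layers = len(layer_idx)
        for pos, li in enumerate(layer_idx):
            W, b = self.params[2 * li], self.params[2 * li + 1]
            z = a @ W + b
            self.pre.append(z)
            last = pos == n_layers - 1
            if final_sigmoid and last:
                a = _sigmoid(z)
                self.masks.append(None)
            else:
                a = _relu(z)
                mask = _dropout_mask(rng, self.cfg.dropout, a.shape)
                if mask is not None:
                    a = a * mask
                self.masks.append(mask)
            self.acts.append(a)
        return a

    def _run(self, rng: np.random.Generator | None) -> np.ndarray:
        cfg = self.cfg
        if cfg.architecture == "merged":
            n_layers = len(cfg.hidden) + 1
            self.inputs = [self.X]
            out = self._stack(self.X, range(n_layers), rng, final_sigmoid=True)
            return out.ravel()
        half = self.X.shape[1] // 2
        xa, xb = self.X[:, :half], self.X[:, half:]
        td = cfg.twin_depth
        self.inputs = [xa, xb]
        ha = self._stack(xa, range(0, td), rng, final_sigmoid=False)
        hb = self._stack(xb, range(td, 2 * td), rng, final_sigmoid=False)
        fused_in = np.concatenate([ha, hb], axis=1)
        self.fused_in = fused_in
        n_fused = len(cfg.hidden) - td + 1
        out = self._stack(
            fused_in, range(2 * td, 2 * td + n_fused), rng, final_sigmoid=True
        )
        return out.ravel()


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(scores, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _backward(fwd: _Forward, y: np.ndarray) -> list[np.ndarray]:
    """Gradients of the mean binary cross-entropy w.r.t. every parameter."""
    cfg = fwd.cfg
    n = y.size
    grads: list[np.ndarray] = [np.zeros_like(p) for p in fwd.params]
    # delta at the sigmoid output: dL/dz = (p - y)/n
    delta = ((fwd.scores - y) / n)[:, None]

    if cfg.architecture == "merged":
        for pos in reversed(range(len(cfg.hidden) + 1)):
            li = pos
            a_prev = fwd.X if pos == 0 else fwd.acts[pos - 1]
            grads[2 * li] = a_prev.T @ delta
            grads[2 * li + 1] = delta.sum(axis=0)
            if pos > 0:
                delta = delta @ fwd.params[2 * li].T
                mask = fwd.masks[pos - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (fwd.pre[pos - 1] > 0)
        return grads

    td = cfg.twin_depth
    n_fused = len(cfg.hidden) - td + 1
    # cache layout: twin A entries [0, td), twin B [td, 2td), fused [2td, 2td+n_fused)
    # fused stack backward
    for pos in reversed(range(n_fused)):
        cache_i = 2 * td + pos
        li = 2 * td + pos
        a_prev = fwd.fused_in if pos == 0 else fwd.acts[cache_i - 1]
        grads[2 * li] = a_prev.T @ delta
        grads[2 * li + 1] = delta.sum(axis=0)
        delta = delta @ fwd.params[2 * li].T
        if pos > 0:
            mask = fwd.masks[cache_i - 1]
            if mask is not None:
                delta = delta * mask
            delta = delta * (fwd.pre[cache_i - 1] > 0)
    # delta is now dL/d(fused_in); split between the twins
    width = fwd.acts[td - 1].shape[1]
    deltas = {"A": delta[:, :width], "B": delta[:, width:]}
    for twin, (base, x_in) in {"A": (0, fwd.inputs[0]), "B": (td, fwd.inputs[1])}.items():
        d_t = deltas[twin]
        for pos in reversed(range(td)):
            cache_i = base + pos
            li = base + pos
            mask = fwd.masks[cache_i]
            if mask is not None:
                d_t = d_t * mask
            d_t = d_t * (fwd.pre[cache_i] > 0)
            a_prev = x_in if pos == 0 else fwd.acts[cache_i - 1]
            grads[2 * li] = a_prev.T @ d_t
            grads[2 * li + 1] = d_t.sum(axis=0)
            if pos > 0:
                d_t = d_t @ fwd.params[2 * li].T
    return grads


def loss_and_grads(
    params: list[np.ndarray],
    cfg: DNNConfig,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Mean cross-entropy loss and its exact gradients (dropout only when
    ``rng`` is given)."""
    fwd = _Forward(params, cfg, X, rng=rng)
    return _bce(fwd.scores, y), _backward(fwd, y)


def train_dnn(X: np.ndarray, y: np.ndarray, cfg: DNNConfig) -> ModelState:
    """Train the configured network with Adam on minibatches."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x d with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if cfg.architecture == "siamese" and X.shape[1] % 2 != 0:
        raise ValueError("siamese architecture needs an even input dimension")

    input_mean = X.mean(axis=0)
    input_scale = float(X.std())
    if input_scale == 0:
        input_scale = 1.0
    X = (X - input_mean) / input_scale

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, X.shape[1], rng)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = loss_and_grads(params, cfg, X[idx], y[idx], rng=rng)
            epoch_losses.append(loss)
            t += 1
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                m_hat = m[i] / (1 - beta1**t)
                v_hat = v[i] / (1 - beta2**t)
                params[i] = params[i] - cfg.learning_rate * m_hat / (
                    np.sqrt(v_hat) + eps
                )
        trace.append(float(np.mean(epoch_losses)))
    return ModelState(
        params=params,
        config=cfg,
        input_dim=X.shape[1],
        loss_trace=trace,
        input_mean=input_mean,
        input_scale=input_scale,
    )


def predict(state: ModelState, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout disabled); scores in (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.input_dim:
        raise ValueError(
            f"X must be n x {state.input_dim}, got shape {X.shape}"
        )
    if state.input_mean is not None:
        X = (X - state.input_mean) / state.input_scale
    return _Forward(state.params, state.config, X, rng=None).scores


class BaselineModel:
    """A fitted comparator exposing the same probability-score contract."""

    def __init__(self, kind: str, estimator) -> None:
        self.kind = kind
        self._estimator = estimator

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self._estimator.predict_proba(np.asarray(X, dtype=float))
        positive = list(self._estimator.classes_).index(1)
        return proba[:, positive]


def train_baseline(
    kind: str, X: np.ndarray, y: np.ndarray, params: dict | None = None
) -> BaselineModel:
    """Fit a KNN (default k=5) or random-forest (default 500 trees)
    comparator."""
    params = dict(params or {})
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if kind == "knn":
        est = KNeighborsClassifier(n_neighbors=int(params.get("k", 5)))
    elif kind == "rf":
        est = RandomForestClassifier(
            n_estimators=int(params.get("trees", 500)),
            random_state=int(params.get("seed", 0)),
            n_jobs=1,
        )
    else:
        raise ValueError(f"unsupported baseline kind {kind!r} (use 'knn' or 'rf')")
    est.fit(X, y)
    return BaselineModel(kind, est)


def save_model(state: ModelState, path: str | Path) -> None:
    """Serialise weights, biases, config and seed to an .npz container."""
    cfg = state.config
    np.savez(
        path,
        n_params=len(state.params),
        input_dim=state.input_dim,
        loss_trace=np.array(state.loss_trace),
        architecture=cfg.architecture,
        hidden=np.array(cfg.hidden),
        dropout=cfg.dropout,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
        twin_depth=cfg.twin_depth,
        input_mean=(
            state.input_mean
            if state.input_mean is not None
            else np.zeros(state.input_dim)
        ),
        input_scale=state.input_scale,
        **{f"param_{i}": p for i, p in enumerate(state.params)},
    )


def load_model(path: str | Path) -> ModelState:
    with np.load(path, allow_pickle=False) as data:
        cfg = DNNConfig(
            architecture=str(data["architecture"]),
            hidden=tuple(int(h) for h in data["hidden"]),
            dropout=float(data["dropout"]),
            learning_rate=float(data["learning_rate"]),
            epochs=int(data["epochs"]),
            batch_size=int(data["batch_size"]),
            seed=int(data["seed"]),
            twin_depth=int(data["twin_depth"]),
        )
        params = [data[f"param_{i}"] for i in range(int(data["n_params"]))]
        return ModelState(
            params=params,
            config=cfg,
            input_dim=int(data["input_dim"]),
            loss_trace=[float(x) for x in data["loss_trace"]],
            input_mean=data["input_mean"],
            input_scale=float(data["input_scale"]),
        )
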