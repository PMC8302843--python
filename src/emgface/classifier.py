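"""The convolutional classifier mapping scaled features to class probabilities.

Architecture (default configuration):

    dense(n_features -> 64, ReLU)
      -> reshape to an 8x8 feature map
      -> 2-D convolution, 4x4 kernel, 16 filters, valid padding, ReLU  (8 -> 5)
      -> 2-D max pooling, 4x4 window, stride 1                          (5 -> 2)
      -> flatten (2*2*16 = 64)
      -> dense(64 -> k), softmax

with k = 7 for expression classification or k = 5 for intensity levels.
The dense front end re-embeds the 20 RMS/IEMG features as a small spatial
map so the convolution can pick up joint activation patterns across
channels.  Training minimises cross-entropy with Adam and backpropagation,
on a seeded stratified 2/3 train / 1/3 validation split, with early
stopping on validation loss.

Implemented directly on numpy (im2col convolution, explicit backward pass);
every forward/backward step is vectorised over the minibatch.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "NetworkConfig",
    "TrainedModel",
    "TrainingReport",
    "build_network",
    "train",
    "predict_proba",
    "predict",
]


@dataclass
class NetworkConfig:
    """Hyperparameters of the network and its training loop.

    The layer dimensions must chain: ``dense1_units == feature_map_side**2``,
    the convolution output ``side - conv_kernel + 1`` must admit the pooling
    window, and the flattened size feeds the k-way softmax layer.  With the
    defaults the chain is 20 -> 64 -> 8x8 -> 5x5x16 -> 2x2x16 -> 64 -> k.
    A 2x2 convolution kernel (8 -> 7x7) is also accepted for comparison runs.
    """

    k: int = 7
    n_features: int = 20
    dense1_units: int = 64
    feature_map_side: int = 8
    conv_kernel: int = 4
    conv_filters: int = 16
    pool_kernel: int = 4
    pool_stride: int = 1
    seed: int = 0
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    patience: int = 20
    val_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.k not in (5, 7):
            raise ValueError(f"k must be 5 (intensity) or 7 (expression), got {self.k}")
        if self.dense1_units != self.feature_map_side**2:
            raise ValueError(
                f"dense1_units ({self.dense1_units}) must equal "
                f"feature_map_side**2 ({self.feature_map_side**2})"
            )
        if self.conv_out_side < 1:
            raise ValueError("convolution kernel larger than the feature map")
        if self.pool_out_side < 1:
            raise ValueError("pooling window larger than the convolution output")
        if self.n_features < 1 or self.conv_filters < 1:
            raise ValueError("n_features and conv_filters must be positive")

    @property
    def conv_out_side(self) -> int:
        return self.feature_map_side - self.conv_kernel + 1

    @property
    def pool_out_side(self) -> int:
        return (self.conv_out_side - self.pool_kernel) // self.pool_stride + 1

    @property
    def flat_units(self) -> int:
        return self.pool_out_side**2 * self.conv_filters

    def dimension_chain(self) -> tuple:
        """The shape of the data as it flows through the network."""
        return (
            self.n_features,
            self.dense1_units,
            (self.feature_map_side, self.feature_map_side),
            (self.conv_out_side, self.conv_out_side, self.conv_filters),
            (self.pool_out_side, self.pool_out_side, self.conv_filters),
            self.flat_units,
            self.k,
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _window_indices(side: int, kernel: int, stride: int = 1) -> np.ndarray:
    """(n_windows, kernel**2) flat indices of each kernel placement on a
    side x side grid (row-major)."""
    out = side - kernel + 1
    positions = range(0, out, stride) if stride > 1 else range(out)
    rows = []
    for i in positions:
        for j in positions:
            rows.append(
                [(i + di) * side + (j + dj) for di in range(kernel) for dj in range(kernel)]
            )
    return np.array(rows, dtype=np.intp)


class FerNet:
    """The network itself: parameter store plus forward/backward passes."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        K = cfg.conv_kernel**2
        self.W1 = rng.standard_normal((cfg.n_features, cfg.dense1_units)) * np.sqrt(
            2.0 / cfg.n_features
        )
        self.b1 = np.zeros(cfg.dense1_units)
        self.Wc = rng.standard_normal((K, cfg.conv_filters)) * np.sqrt(2.0 / K)
        self.bc = np.zeros(cfg.conv_filters)
        self.W2 = rng.standard_normal((cfg.flat_units, cfg.k)) * np.sqrt(
            2.0 / cfg.flat_units
        )
        self.b2 = np.zeros(cfg.k)

        # Static index maps for im2col convolution and pooling.
        self._conv_idx = _window_indices(cfg.feature_map_side, cfg.conv_kernel)
        co = cfg.conv_out_side
        pool_rows = []
        for i in range(0, co - cfg.pool_kernel + 1, cfg.pool_stride):
            for j in range(0, co - cfg.pool_kernel + 1, cfg.pool_stride):
                pool_rows.append(
                    [
                        (i + di) * co + (j + dj)
                        for di in range(cfg.pool_kernel)
                        for dj in range(cfg.pool_kernel)
                    ]
                )
        self._pool_idx = np.array(pool_rows, dtype=np.intp)
        # Dense scatter matrix mapping im2col column gradients back to the map.
        P, K = self._conv_idx.shape
        scatter = np.zeros((P * K, cfg.dense1_units))
        scatter[np.arange(P * K), self._conv_idx.ravel()] = 1.0
        self._conv_scatter = scatter

    # -- forward ---------------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        cfg = self.cfg
        z1 = X @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        cols = a1[:, self._conv_idx]                      # (B, P, K)
        zc = cols @ self.Wc + self.bc                     # (B, P, F)
        ac = np.maximum(zc, 0.0)
        pooled_in = ac[:, self._pool_idx, :]              # (B, Q, pk*pk, F)
        arg = pooled_in.argmax(axis=2)                    # (B, Q, F)
        pooled = np.take_along_axis(pooled_in, arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(X.shape[0], cfg.flat_units)
        z2 = flat @ self.W2 + self.b2
        probs = _softmax(z2)
        if not cache:
            return probs
        return probs, (X, z1, a1, cols, zc, ac, arg, flat)

    # -- backward --------------------------------------------------------

    def gradients(self, cache, probs: np.ndarray, onehot: np.ndarray):
        X, z1, a1, cols, zc, ac, arg, flat = cache
        B = X.shape[0]
        cfg = self.cfg
        dz2 = (probs - onehot) / B                        # (B, k)
        dW2 = flat.T @ dz2
        db2 = dz2.sum(axis=0)
        dflat = dz2 @ self.W2.T
        Q = self._pool_idx.shape[0]
        dpooled = dflat.reshape(B, Q, cfg.conv_filters)
        # Scatter pooling gradient to the argmax positions of each window.
        dac = np.zeros_like(ac)                           # (B, P, F)
        b_idx = np.arange(B)[:, None, None]
        f_idx = np.arange(cfg.conv_filters)[None, None, :]
        pos = self._pool_idx[np.arange(Q)[None, :, None], arg]   # (B, Q, F)
        np.add.at(dac, (b_idx, pos, f_idx), dpooled)
        dzc = dac * (zc > 0)
        P, K = self._conv_idx.shape
        dWc = cols.reshape(B * P, K).T @ dzc.reshape(B * P, cfg.conv_filters)
        dbc = dzc.sum(axis=(0, 1))
        dcols = dzc @ self.Wc.T                           # (B, P, K)
        da1 = dcols.reshape(B, P * K) @ self._conv_scatter
        dz1 = da1 * (z1 > 0)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dWc, dbc, dW2, db2]

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.Wc, self.bc, self.W2, self.b2]

    def set_params(self, values: Sequence[np.ndarray]) -> None:
        self.W1, self.b1, self.Wc, self.bc, self.W2, self.b2 = [
            np.array(v) for v in values
        ]


@dataclass
class TrainingReport:
    """Per-epoch accuracies and losses plus the split bookkeeping."""

    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0
    best_epoch: int = 0
    seed: int = 0

    @property
    def final_train_accuracy(self) -> float:
        return self.train_accuracy[self.best_epoch]

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch]


@dataclass
class TrainedModel:
    """A fitted network with its class vocabulary and scaler policy."""

    config: NetworkConfig
    net: FerNet
    class_names: list
    scaler_scope: str = "per_batch"

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "config": asdict(self.config),
                    "weights": [w.tolist() for w in self.net.params],
                    "class_names": self.class_names,
                    "scaler_scope": self.scaler_scope,
                },
                fh,
            )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        cfg = NetworkConfig(**d["config"])
        net = FerNet(cfg)
        net.set_params([np.array(w) for w in d["weights"]])
        return cls(cfg, net, d["class_names"], d["scaler_scope"])


def build_network(cfg: NetworkConfig) -> FerNet:
    """Instantiate an untrained network with seed-deterministic weights."""
    return FerNet(cfg)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


def _encode_labels(labels: Sequence, class_names: Sequence | None, k: int):
    if class_names is None:
        class_names = sorted(set(labels))
    class_names = list(class_names)
    if len(class_names) != k:
        raise ValueError(
            f"found {len(class_names)} classes {class_names} but network has k={k}"
        )
    index = {c: i for i, c in enumerate(class_names)}
    try:
        y = np.array([index[l] for l in labels], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class_names {class_names}") from exc
    return y, class_names


def train(
    model: FerNet,
    features: np.ndarray,
    labels: Sequence,
    cfg: NetworkConfig | None = None,
    class_names: Sequence | None = None,
    scaler_scope: str = "per_batch",
) -> tuple[TrainedModel, TrainingReport]:
    """Train on a seeded stratified 2/3 train / 1/3 validation split.

    Minimises cross-entropy with Adam; early stopping restores the
    parameters of the epoch with the lowest validation loss.  Reproducible
    given (data, cfg.seed).
    """
    cfg = cfg if cfg is not None else model.cfg
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != cfg.n_features:
        raise ValueError(
            f"features must be (n, {cfg.n_features}), got {X.shape}"
        )
    y, class_names = _encode_labels(labels, class_names, cfg.k)
    counts = np.bincount(y, minlength=cfg.k)
    if (counts < 3).any():
        missing = [class_names[i] for i in np.flatnonzero(counts < 3)]
        raise ValueError(f"classes {missing} have fewer than 3 samples; cannot stratify")

    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=cfg.val_fraction, random_state=cfg.seed, stratify=y
    )
    onehot_tr = np.eye(cfg.k)[y_tr]

    rng = np.random.default_rng(cfg.seed + 1)
    # Adam state.
    m = [np.zeros_like(p) for p in model.params]
    v = [np.zeros_like(p) for p in model.params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    report = TrainingReport(n_train=len(y_tr), n_val=len(y_val), seed=cfg.seed)
    best_val = np.inf
    best_params = [p.copy() for p in model.params]
    best_epoch = 0
    since_best = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y_tr))
        # Train metrics are accumulated from the minibatch forward passes
        # (each batch scored just before its update), avoiding a second full
        # pass over the training set every epoch.
        loss_sum = 0.0
        correct = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, cache = model.forward(X_tr[idx], cache=True)
            loss_sum += -np.log(probs[np.arange(len(idx)), y_tr[idx]] + 1e-12).sum()
            correct += int((probs.argmax(axis=1) == y_tr[idx]).sum())
            grads = model.gradients(cache, probs, onehot_tr[idx])
            t += 1
            params = model.params
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        p_val = model.forward(X_val)
        report.train_loss.append(float(loss_sum / len(y_tr)))
        report.val_loss.append(_cross_entropy(p_val, y_val))
        report.train_accuracy.append(correct / len(y_tr))
        report.val_accuracy.append(float(np.mean(p_val.argmax(axis=1) == y_val)))

        if report.val_loss[-1] < best_val - 1e-6:
            best_val = report.val_loss[-1]
            best_params = [p.copy() for p in model.params]
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    model.set_params(best_params)
    report.best_epoch = best_epoch
    return TrainedModel(cfg, model, class_names, scaler_scope), report


def predict_proba(model: TrainedModel | FerNet, features: np.ndarray) -> np.ndarray:
    """Softmax class probabilities, one row per frame (rows sum to 1)."""
    net = model.net if isinstance(model, TrainedModel) else model
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != net.cfg.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match network input "
            f"{net.cfg.n_features}"
        )
    return net.forward(X)


def predict(model: TrainedModel | FerNet, features: np.ndarray) -> np.ndarray:
    """Argmax class per frame; exact ties resolve to the lowest class index."""
    probs = predict_proba(model, features)
    idx = probs.argmax(axis=1)
    if isinstance(model, TrainedModel):
        return np.array([model.class_names[i] for i in idx])
    return idx
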