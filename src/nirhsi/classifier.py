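"""Configurable fully connected classifier for sample-level features.

The network maps a standardized global-feature vector through optional
input-noise and feature-attention layers, one or more hidden blocks
(dense + optional batch norm + ReLU/ELU/GELU + dropout) and a softmax
output. Training uses class-weighted cross-entropy with label smoothing,
gradient clipping at a global norm, cosine-annealed AdamW/Adam, and early
stopping on the training-loss plateau (no validation split exists inside
a leave-one-out fold).

Feature standardization is fit on the training data inside
:func:`train_classifier` and replayed at prediction time, so
cross-validation folds cannot leak test statistics.

The attention mechanism is a single softmax gate over input features
applied multiplicatively before the first hidden layer; its normalized
weights sum to 1 and can be projected back onto the patch grid as a
spatial attention map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import _nn
from .errors import (
    AttentionDisabledError,
    ConfigError,
    ShapeMismatchError,
)
from .features import EmbeddingSet

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "train_classifier",
    "predict",
    "attention_weights",
    "attention_map",
    "hyperparameter_search",
    "sample_search_space",
]


@dataclass
class ClassifierConfig:
    """Architecture and training recipe.

    Defaults are the best configuration found by the refined search:
    single 512-neuron hidden layer, ELU, dropout 0.4, AdamW at lr 0.001
    with label smoothing and light input noise, 20 epochs with early
    stopping.
    """

    hidden_dims: list[int] = field(default_factory=lambda: [512])
    activation: str = "elu"
    dropout: float = 0.4
    use_batchnorm: bool = True
    use_attention: bool = False
    label_smoothing: float = 0.1
    input_noise_sd: float = 0.05
    learning_rate: float = 0.001
    weight_decay: float = 0.01
    optimizer: str = "adamw"
    max_epochs: int = 20
    early_stop_patience: int = 5
    grad_clip_norm: float = 1.0
    lr_schedule: str = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_dims or any(h < 1 for h in self.hidden_dims):
            raise ConfigError("hidden_dims must be non-empty with dims >= 1")
        if self.activation not in ("relu", "elu", "gelu"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if not 0 <= self.label_smoothing < 0.5:
            raise ConfigError("label_smoothing must be in [0, 0.5)")
        if self.input_noise_sd < 0 or self.learning_rate <= 0:
            raise ConfigError("invalid noise/learning-rate values")
        if self.optimizer not in ("adamw", "adam"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("cosine", "none"):
            raise ConfigError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.grad_clip_norm <= 0:
            raise ConfigError("grad_clip_norm must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


class TrainedClassifier:
    """A trained network plus its input scaler and training log."""

    def __init__(
        self,
        config: ClassifierConfig,
        net: _nn.Sequential,
        scaler: tuple[np.ndarray, np.ndarray],
        n_features: int,
        train_log: dict,
        attention_layer: _nn.AttentionGate | None,
    ) -> None:
        self.config = config
        self.net = net
        self.scaler_mean, self.scaler_sd = scaler
        self.n_features = n_features
        self.train_log = train_log
        self._attention = attention_layer

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_sd

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ShapeMismatchError(
                f"expected (n, {self.n_features}) features, got {X.shape}"
            )
        rng = np.random.default_rng(0)  # stochastic layers inactive in eval
        logits = self.net.forward(self._standardize(X), train=False, rng=rng)
        return _nn.softmax(logits)


def _build_net(
    n_features: int, config: ClassifierConfig, rng: np.random.Generator
) -> tuple[_nn.Sequential, _nn.AttentionGate | None]:
    layers: list[_nn.Layer] = [_nn.GaussianNoise(config.input_noise_sd)]
    attn = None
    if config.use_attention:
        attn = _nn.AttentionGate(n_features)
        layers.append(attn)
    prev = n_features
    for h in config.hidden_dims:
        layers.append(_nn.Dense(prev, h, rng))
        if config.use_batchnorm:
            layers.append(_nn.BatchNorm(h))
        layers.append(_nn.Activation(config.activation))
        if config.dropout > 0:
            layers.append(_nn.Dropout(config.dropout))
        prev = h
    layers.append(_nn.Dense(prev, 2, rng))
    return _nn.Sequential(layers), attn


def balanced_class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1 over classes."""
    counts = np.bincount(y, minlength=2).astype(float)
    if np.any(counts == 0):
        raise ConfigError("both classes must be present")
    w = 1.0 / counts
    return w / w.mean()


def train_classifier(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Train on global features; standardization is fit on this data only."""
    config = config or ClassifierConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ShapeMismatchError("features and labels disagree in length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ConfigError("training labels contain a single class")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC1)))
    net, attn = _build_net(X.shape[1], config, rng)
    wd = config.weight_decay if config.optimizer == "adamw" else 0.0
    opt = _nn.AdamW(net.params, lr=config.learning_rate, weight_decay=wd)
    cw = balanced_class_weights(y)

    n = X.shape[0]
    batch = min(32, n)  # small batches: several optimizer steps per epoch
    history: list[float] = []
    grad_norms: list[float] = []
    best = np.inf
    best_state = None
    wait = 0
    for epoch in range(config.max_epochs):
        if config.lr_schedule == "cosine":
            lr = _nn.cosine_lr(config.learning_rate, epoch, config.max_epochs)
        else:
            lr = config.learning_rate
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch):
            idx = order[i : i + batch]
            logits = net.forward(Xs[idx], train=True, rng=rng)
            loss, dlogits = _nn.softmax_cross_entropy(
                logits, y[idx], class_weights=cw, label_smoothing=config.label_smoothing
            )
            net.backward(dlogits)
            grad_norms.append(_nn.clip_global_norm(net.grads, config.grad_clip_norm))
            opt.step(net.grads, lr=lr)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if epoch_loss < best - 1e-5:
            best = epoch_loss
            best_state = net.state()
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    if best_state is not None:
        net.load_state(best_state)
    log = {
        "loss_history": history,
        "class_weights": cw.tolist(),
        "max_grad_norm": float(max(grad_norms)) if grad_norms else 0.0,
        "epochs_run": len(history),
        "scaler_fit_n": int(n),
    }
    return TrainedClassifier(config, net, (mean, sd), X.shape[1], log, attn)


def predict(
    model: TrainedClassifier, features: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class probabilities; 0.5 ties go to class 0."""
    proba = model.predict_proba(features)
    labels = (proba[:, 1] > proba[:, 0]).astype(int)
    return labels, proba


def attention_weights(model: TrainedClassifier) -> np.ndarray:
    """Normalized per-feature attention vector (non-negative, sums to 1)."""
    if model._attention is None:
        raise AttentionDisabledError("model was trained without attention")
    return model._attention.weights


def attention_map(
    model: TrainedClassifier,
    embeddings: EmbeddingSet,
    cube_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Project feature attention onto the patch grid as a spatial map.

    The global feature vector concatenates four statistic blocks over the
    latent dimensions, so attention on feature ``blk*d + j`` is credited
    to latent dimension ``j``. Each patch scores the attention-weighted
    L1 norm of its embedding; the patch-grid map is normalized to [0, 1]
    and, when ``cube_shape`` is given, upsampled nearest-neighbor to the
    cube's spatial size.
    """
    a = attention_weights(model)
    d = embeddings.dim
    if model.n_features % d != 0:
        raise ShapeMismatchError("feature length is not a multiple of latent dim")
    per_dim = a.reshape(-1, d).sum(axis=0)  # credit blocks back to latent dims
    scores = np.abs(embeddings.vectors) @ per_dim

    rows = np.unique(embeddings.origins[:, 0])
    cols = np.unique(embeddings.origins[:, 1])
    grid = np.full((len(rows), len(cols)), np.nan)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for (r, c), s in zip(embeddings.origins, scores):
        grid[ri[r], ci[c]] = s
    lo, hi = np.nanmin(grid), np.nanmax(grid)
    grid = np.zeros_like(grid) if hi == lo else (grid - lo) / (hi - lo)
    if cube_shape is None:
        return grid
    return _upsample_nearest(grid, embeddings.origins, cube_shape)


def _upsample_nearest(
    grid: np.ndarray, origins: np.ndarray, cube_shape: tuple[int, int]
) -> np.ndarray:
    """Paint each pixel with the value of the nearest patch origin cell."""
    rows = np.unique(origins[:, 0])
    cols = np.unique(origins[:, 1])
    H, W = cube_shape
    ridx = np.abs(np.arange(H)[:, None] - rows[None, :]).argmin(axis=1)
    cidx = np.abs(np.arange(W)[:, None] - cols[None, :]).argmin(axis=1)
    return grid[np.ix_(ridx, cidx)]


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

REFINED_HIDDEN = [[512], [640], [768], [896], [1024], [768, 384, 192]]
BROAD_HIDDEN = REFINED_HIDDEN + [[256], [128], [512, 256]]


def sample_search_space(
    mode: str, n_trials: int, seed: int, base: ClassifierConfig | None = None
) -> list[ClassifierConfig]:
    """Draw trial configs from the refined (or broad) search space.

    Refined: hidden in {512..1024 step 128} or [768, 384, 192], ELU fixed,
    dropout U[0.4, 0.6], learning rate U[5e-4, 1e-3]. Broad additionally
    varies the activation over {relu, elu, gelu} and smaller hidden sizes.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    if mode not in ("refined", "broad"):
        raise ConfigError(f"unknown search mode {mode!r}")
    base = base or ClassifierConfig()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EA)))
    hidden_pool = REFINED_HIDDEN if mode == "refined" else BROAD_HIDDEN
    configs = []
    for _ in range(n_trials):
        hidden = hidden_pool[rng.integers(len(hidden_pool))]
        act = "elu" if mode == "refined" else ("relu", "elu", "gelu")[rng.integers(3)]
        configs.append(
            replace(
                base,
                hidden_dims=list(hidden),
                activation=act,
                dropout=float(rng.uniform(0.4, 0.6)),
                learning_rate=float(rng.uniform(5e-4, 1e-3)),
            )
        )
    return configs


def hyperparameter_search(
    features: pd.DataFrame,
    labels: np.ndarray,
    mode: str = "refined",
    n_trials: int = 100,
    seed: int = 0,
    base: ClassifierConfig | None = None,
) -> tuple[pd.DataFrame, ClassifierConfig]:
    """Score sampled configs by LOOCV balanced accuracy; rank descending.

    Returns (trial table sorted by score, best config). Deterministic
    given ``seed``; ties rank by trial order.
    """
    from .evaluation import loocv  # local import to avoid a module cycle

    configs = sample_search_space(mode, n_trials, seed, base=base)
    rows = []
    for t, cfg in enumerate(configs):
        result = loocv(features, labels, replace(cfg, seed=seed + t))
        rows.append(
            {
                "trial": t,
                "hidden_dims": "x".join(map(str, cfg.hidden_dims)),
                "activation": cfg.activation,
                "dropout": cfg.dropout,
                "learning_rate": cfg.learning_rate,
                "balanced_accuracy": result.balanced_accuracy,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["balanced_accuracy", "trial"], ascending=[False, True], kind="stable"
    )
    best = configs[int(table.iloc[0]["trial"])]
    return table.reset_index(drop=True), best
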