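"""Spectral-spatial feature extraction.

Workflow: tile each preprocessed cube into overlapping 5x5 spectral
patches, train a convolutional autoencoder on a pooled patch sample by L2
reconstruction, encode every patch into a compact latent vector (default
128-D), then aggregate each sample's patch embeddings into one global
feature vector by concatenating four per-dimension statistics —
mean | max | population SD | IQR — giving 4*d features per sample.

The encoder uses valid 3x3(x3) convolutions with batch normalization and
ReLU: kernels span both spatial axes and the band axis when the cube has
at least 8 bands (3-D convolution), otherwise bands are treated as
channels of a 2-D convolution. The decoder is a dense mirror back to the
patch shape. Dropout regularizes the bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .cube_io import HyperCube
from .errors import ConfigError, EmptyInputError, ShapeMismatchError

__all__ = [
    "PatchSet",
    "EncoderModel",
    "EmbeddingSet",
    "GlobalFeature",
    "AutoencoderConfig",
    "extract_patches",
    "train_autoencoder",
    "encode_patches",
    "aggregate_features",
    "features_table",
]


@dataclass
class PatchSet:
    """Overlapping patches from one cube: (n, p, p, B) plus origins."""

    patches: np.ndarray
    origins: np.ndarray  # (n, 2) top-left (row, col), row-major order
    sample_id: str

    def __post_init__(self) -> None:
        if self.patches.ndim != 4:
            raise ShapeMismatchError("patches must be rank-4 (n, p, p, B)")
        if self.origins.shape != (self.patches.shape[0], 2):
            raise ShapeMismatchError("origins must align with patches")

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]

    def grid_shape(self, stride: int) -> tuple[int, int]:
        """Patch-grid dimensions implied by the stored origins."""
        rows = len(np.unique(self.origins[:, 0]))
        cols = len(np.unique(self.origins[:, 1]))
        return rows, cols


@dataclass
class EmbeddingSet:
    """Latent vectors for a cube's patches: (n, d) plus patch origins."""

    vectors: np.ndarray
    origins: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ShapeMismatchError("embeddings must be finite")
        if self.vectors.shape[0] != self.origins.shape[0]:
            raise ShapeMismatchError("row count must equal patch count")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class GlobalFeature:
    """Per-sample aggregated feature vector: [mean | max | SD | IQR], 4*d."""

    sample_id: str
    vector: np.ndarray

    @property
    def dim(self) -> int:
        return self.vector.shape[0] // 4

    def block(self, name: str) -> np.ndarray:
        idx = {"mean": 0, "max": 1, "sd": 2, "iqr": 3}[name]
        d = self.dim
        return self.vector[idx * d : (idx + 1) * d]


def extract_patches(
    cube: HyperCube, patch_size: int = 5, stride: int = 2
) -> PatchSet:
    """Tile the cube into overlapping full patches (no padding).

    Origins are enumerated row-major; with stride < patch_size the
    patches overlap. Patch count is ((H-p)//s + 1) * ((W-p)//s + 1).
    """
    H, W, _ = cube.data.shape
    if patch_size > min(H, W):
        raise ShapeMismatchError(
            f"patch {patch_size} exceeds image {H}x{W}"
        )
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    p = patch_size
    win = np.lib.stride_tricks.sliding_window_view(cube.data, (p, p), axis=(0, 1))
    win = win[::stride, ::stride]  # (nr, nc, B, p, p)
    nr, nc = win.shape[:2]
    patches = np.moveaxis(win, 2, -1).reshape(nr * nc, p, p, -1)
    rr, cc = np.meshgrid(
        np.arange(nr) * stride, np.arange(nc) * stride, indexing="ij"
    )
    origins = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return PatchSet(np.ascontiguousarray(patches, dtype=np.float32), origins, cube.sample_id)


@dataclass
class AutoencoderConfig:
    """Training recipe for the patch autoencoder."""

    latent_dim: int = 128
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    dropout: float = 0.1
    early_stop_patience: int = 5
    min_delta: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


class EncoderModel:
    """Trained patch autoencoder: conv encoder + dense bottleneck + mirror.

    ``descriptor`` records the architecture actually built (conv
    dimensionality, filters, latent size); ``loss_history`` the per-epoch
    mean reconstruction loss.
    """

    def __init__(self, patch_shape: tuple[int, int, int], config: AutoencoderConfig):
        self.patch_shape = tuple(patch_shape)
        self.config = config
        p, _, B = patch_shape
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xAE)))
        d = config.latent_dim
        use_3d = B >= 8
        if use_3d:
            # (p, p, B, 1) -> conv3d x2 -> (p-4, p-4, B-4, 16)
            flat = (p - 4) * (p - 4) * (B - 4) * 16
            enc_layers = [
                _nn.Reshape((p, p, B, 1)),
                _nn.Conv(3, 1, 8, 3, rng, needs_input_grad=False),
                _nn.BatchNorm(8),
                _nn.Activation("relu"),
                _nn.Conv(3, 8, 16, 3, rng),
                _nn.BatchNorm(16),
                _nn.Activation("relu"),
                _nn.Flatten(),
                _nn.Dropout(config.dropout),
                _nn.Dense(flat, d, rng),
            ]
            conv_kind = "3d"
        else:
            # bands as channels of a 2-D convolution
            flat = (p - 4) * (p - 4) * 2 * B
            enc_layers = [
                _nn.Conv(2, B, B, 3, rng, needs_input_grad=False),
                _nn.BatchNorm(B),
                _nn.Activation("relu"),
                _nn.Conv(2, B, 2 * B, 3, rng),
                _nn.BatchNorm(2 * B),
                _nn.Activation("relu"),
                _nn.Flatten(),
                _nn.Dropout(config.dropout),
                _nn.Dense(flat, d, rng),
            ]
            conv_kind = "2d"
        out_size = p * p * B
        dec_layers = [
            _nn.Activation("relu"),
            _nn.Dense(d, max(2 * d, 64), rng),
            _nn.Activation("relu"),
            _nn.Dense(max(2 * d, 64), out_size, rng),
            _nn.Reshape((p, p, B)),
        ]
        self.encoder = _nn.Sequential(enc_layers)
        self.decoder = _nn.Sequential(dec_layers)
        self.loss_history: list[float] = []
        self.descriptor = {
            "conv": conv_kind,
            "blocks": 2,
            "latent_dim": d,
            "patch_shape": list(self.patch_shape),
            "dropout": config.dropout,
        }

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def encode(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic eval-mode encoding (dropout inactive)."""
        if patches.shape[1:] != self.patch_shape:
            raise ShapeMismatchError(
                f"patch shape {patches.shape[1:]} != model {self.patch_shape}"
            )
        rng = np.random.default_rng(0)  # unused in eval mode
        out = [
            self.encoder.forward(
                patches[i : i + batch_size].astype(np.float32), train=False, rng=rng
            )
            for i in range(0, patches.shape[0], batch_size)
        ]
        return np.concatenate(out).astype(np.float32)

    def reconstruct(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        rng = np.random.default_rng(0)
        out = []
        for i in range(0, patches.shape[0], batch_size):
            z = self.encoder.forward(
                patches[i : i + batch_size].astype(np.float32), train=False, rng=rng
            )
            out.append(self.decoder.forward(z, train=False, rng=rng))
        return np.concatenate(out).astype(np.float32)

    # -- persistence (single npz archive) -----------------------------------
    def save(self, path: str | Path) -> Path:
        import json

        path = Path(path)
        state = self.encoder.state() + self.decoder.state()
        arrays = {f"arr_{i}": a for i, a in enumerate(state)}
        np.savez_compressed(
            path,
            __meta__=np.str_(
                json.dumps(
                    {
                        "descriptor": self.descriptor,
                        "config": vars(self.config),
                        "n_enc": len(self.encoder.state()),
                        "loss_history": self.loss_history,
                    }
                )
            ),
            **arrays,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        cfg = AutoencoderConfig(**meta["config"])
        model = cls(tuple(meta["descriptor"]["patch_shape"]), cfg)
        n_enc = meta["n_enc"]
        model.encoder.load_state(arrays[:n_enc])
        model.decoder.load_state(arrays[n_enc:])
        model.loss_history = list(meta["loss_history"])
        return model


def train_autoencoder(
    patches: np.ndarray | PatchSet, config: AutoencoderConfig | None = None
) -> EncoderModel:
    """Train the autoencoder by L2 reconstruction on a pooled patch set.

    Deterministic given ``config.seed``; training stops early when the
    epoch loss plateaus, and the best-epoch parameters are restored, so
    the final recorded loss never exceeds the first epoch's.
    """
    if isinstance(patches, PatchSet):
        patches = patches.patches
    if patches.shape[0] == 0:
        raise EmptyInputError("empty patch pool")
    config = config or AutoencoderConfig()
    model = EncoderModel(patches.shape[1:], config)
    x = patches.astype(np.float32)
    n = x.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xAE1)))
    params = model.encoder.params + model.decoder.params
    grads = model.encoder.grads + model.decoder.grads
    opt = _nn.AdamW(params, lr=config.learning_rate)
    best_loss = np.inf
    best_state = None
    wait = 0
    for epoch in range(config.epochs):
        lr = _nn.cosine_lr(config.learning_rate, epoch, config.epochs)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            xb = x[order[i : i + config.batch_size]]
            z = model.encoder.forward(xb, train=True, rng=rng)
            recon = model.decoder.forward(z, train=True, rng=rng)
            loss, drecon = _nn.mse_loss(recon, xb)
            gz = model.decoder.backward(drecon)
            model.encoder.backward(gz)
            _nn.clip_global_norm(grads, 5.0)
            opt.step(grads, lr=lr)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        model.loss_history.append(epoch_loss)
        if epoch_loss < best_loss - config.min_delta:
            best_loss = epoch_loss
            best_state = model.encoder.state() + model.decoder.state()
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    if best_state is not None:
        n_enc = len(model.encoder.state())
        model.encoder.load_state(best_state[:n_enc])
        model.decoder.load_state(best_state[n_enc:])
    return model


def encode_patches(model: EncoderModel, patches: PatchSet) -> EmbeddingSet:
    """Encode every patch into its latent vector (eval mode)."""
    vectors = model.encode(patches.patches)
    return EmbeddingSet(vectors, patches.origins, patches.sample_id)


def aggregate_features(embeddings: EmbeddingSet) -> GlobalFeature:
    """Concatenate mean | max | population SD | IQR over patches, per dim.

    IQR uses linear-interpolation quantiles (q75 - q25); SD is the
    population convention (ddof 0).
    """
    if len(embeddings) == 0:
        raise EmptyInputError("cannot aggregate an empty embedding set")
    v = embeddings.vectors.astype(np.float64)
    q75, q25 = np.percentile(v, [75, 25], axis=0, method="linear")
    vec = np.concatenate([v.mean(axis=0), v.max(axis=0), v.std(axis=0), q75 - q25])
    return GlobalFeature(embeddings.sample_id, vec)


def features_table(features: list[GlobalFeature]) -> pd.DataFrame:
    """Tabulate global features: rows = samples, named stat-block columns."""
    if not features:
        raise EmptyInputError("no features to tabulate")
    d = features[0].dim
    cols = [f"{blk}_{i:03d}" for blk in ("mean", "max", "sd", "iqr") for i in range(d)]
    return pd.DataFrame(
        np.stack([f.vector for f in features]),
        index=pd.Index([f.sample_id for f in features], name="sample_id"),
        columns=cols,
    )
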