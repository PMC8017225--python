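"""Unsupervised autoencoder embedding of binary spike-train epochs.

Rasters from the two conditions (baseline and post-injection), restricted to
the neurons detected in both, are cut into non-overlapping 2.5 s epochs,
binarised and flattened into neurons x frames feature vectors.  A symmetric
dense autoencoder (three SELU encoder layers down to a 100-unit code, three
decoder layers back, sigmoid output, binary cross-entropy loss, Adam) is
grid-searched over learning rate / epochs / hidden widths on held-out
reconstruction loss.  The 100-d codes are projected onto their top two
principal components for visualisation, and the silhouette of the two
condition groups in code space quantifies how separable the conditions are.

The network is implemented directly on NumPy (LeCun-normal initialisation,
hand-written Adam); at these input sizes that is fast enough and keeps the
training loop fully deterministic under a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .session import EventRaster

_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


@dataclass
class EpochMatrix:
    """Epochs x features binary matrix with condition labels."""

    X: np.ndarray                  # epochs x (neurons * frames_per_epoch)
    labels: np.ndarray             # 'baseline' | 'post' per epoch
    epoch_length_s: float
    fps: float
    n_neurons: int

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def frames_per_epoch(self) -> int:
        return self.X.shape[1] // self.n_neurons


@dataclass(frozen=True)
class EmbedderConfig:
    """Architecture and grid-search space of the autoencoder."""

    code_size: int = 100
    learning_rate_grid: tuple = (1e-3, 3e-4)
    epochs_grid: tuple = (30,)
    hidden_scale_grid: tuple = (1.0,)   # scales the geometric hidden widths
    batch_size: int = 32
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.code_size < 1:
            raise ValueError("code size must be >= 1")
        if not (self.learning_rate_grid and self.epochs_grid and self.hidden_scale_grid):
            raise ValueError("grids must be non-empty")


def make_epochs(
    raster_baseline: EventRaster,
    raster_post: EventRaster,
    matched_ids: np.ndarray,
    epoch_length_s: float = 2.5,
    fps: float | None = None,
) -> EpochMatrix:
    """Cut both rasters into binarised non-overlapping epochs.

    Counts are thresholded at >0 (the binary cross-entropy loss expects
    binary targets); the trailing partial epoch of each raster is dropped.
    """
    matched_ids = np.asarray(matched_ids)
    if matched_ids.size == 0:
        raise ValueError("no matched neurons between conditions")
    if fps is None:
        fps = raster_baseline.fps
    fpe = int(round(epoch_length_s * fps))
    blocks, labels = [], []
    for raster, label in ((raster_baseline, "baseline"), (raster_post, "post")):
        c = (raster.counts[matched_ids] > 0).astype(np.float64)
        n_ep = c.shape[1] // fpe
        if n_ep:
            trimmed = c[:, : n_ep * fpe]
            # epoch-major layout: (epochs, neurons*frames)
            eps = trimmed.reshape(matched_ids.size, n_ep, fpe).transpose(1, 0, 2)
            blocks.append(eps.reshape(n_ep, -1))
            labels.extend([label] * n_ep)
    return EpochMatrix(
        X=np.vstack(blocks),
        labels=np.array(labels),
        epoch_length_s=epoch_length_s,
        fps=fps,
        n_neurons=matched_ids.size,
    )


def _hidden_widths(input_dim: int, code: int, scale: float) -> tuple[int, int]:
    """Geometric interpolation input -> code for the two hidden layers."""
    h1 = int(round((input_dim ** (2 / 3)) * (code ** (1 / 3)) * scale))
    h2 = int(round((input_dim ** (1 / 3)) * (code ** (2 / 3)) * scale))
    return max(h1, code), max(h2, code)


def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (np.exp(z) - 1.0))


def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._adam = [np.zeros_like(p) for p in (self.W, self.b, self.W, self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out):
        self.dW = self._x.T @ grad_out
        self.db = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def adam_step(self, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
        mW, mb, vW, vb = self._adam
        for m, v, p, g in ((mW, vW, self.W, self.dW), (mb, vb, self.b, self.db)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            p -= lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)


@dataclass
class Embedder:
    """Trained encoder stack plus the selected hyperparameters."""

    layers: list = field(default_factory=list)       # full autoencoder
    n_encoder_layers: int = 3
    best_params: dict = field(default_factory=dict)
    holdout_loss: float = np.nan
    train_losses: np.ndarray | None = None

    def encode(self, X: np.ndarray) -> np.ndarray:
        h = X
        for layer in self.layers[: self.n_encoder_layers]:
            h = _selu(layer.forward(h))
        return h

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        h = X
        for i, layer in enumerate(self.layers):
            z = layer.forward(h)
            h = _sigmoid(z) if i == len(self.layers) - 1 else _selu(z)
        return h


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce(target, pred, eps=1e-7):
    p = np.clip(pred, eps, 1 - eps)
    return float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())


def _build(input_dim, code, scale, rng):
    h1, h2 = _hidden_widths(input_dim, code, scale)
    dims = [input_dim, h1, h2, code, h2, h1, input_dim]
    return [_Dense(dims[i], dims[i + 1], rng) for i in range(6)]


def _train_one(X_train, X_val, input_dim, cfg, lr, n_epochs, scale, rng):
    layers = _build(input_dim, cfg.code_size, scale, rng)
    n = X_train.shape[0]
    t = 0
    losses = []
    for _ in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            xb = X_train[order[start : start + cfg.batch_size]]
            # forward
            acts, zs = [xb], []
            h = xb
            for i, layer in enumerate(layers):
                z = layer.forward(h)
                zs.append(z)
                h = _sigmoid(z) if i == 5 else _selu(z)
                acts.append(h)
            # BCE with sigmoid output: dL/dz_out = (pred - target)/B/D
            grad = (acts[-1] - xb) / xb.size
            for i in range(5, -1, -1):
                if i != 5:
                    grad = grad * _selu_grad(zs[i])
                grad = layers[i].backward(grad)
            t += 1
            for layer in layers:
                layer.adam_step(lr, t)
        emb = Embedder(layers=layers)
        losses.append(_bce(X_train, emb.reconstruct(X_train)))
    emb = Embedder(layers=layers)
    val_loss = _bce(X_val, emb.reconstruct(X_val))
    return layers, val_loss, np.array(losses)


def fit_autoencoder(epochs: EpochMatrix, cfg: EmbedderConfig) -> Embedder:
    """Grid-search and train the autoencoder (labels are never used).

    The configuration minimising reconstruction loss on a held-out split
    (holdout_fraction of epochs, fixed by the seed) wins; the returned
    embedder keeps its training-loss trace and the selected
    hyperparameters.  Deterministic given ``cfg.seed``.
    """
    X = epochs.X
    if X.shape[0] < 10:
        raise ValueError("need at least 10 epochs to fit the autoencoder")
    if X.std() == 0:
        import warnings

        warnings.warn("all-constant epoch matrix: autoencoder may not converge")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.holdout_fraction * X.shape[0])))
    perm = rng.permutation(X.shape[0])
    X_val, X_train = X[perm[:n_val]], X[perm[n_val:]]

    best = None
    for lr, n_epochs, scale in itertools.product(
        cfg.learning_rate_grid, cfg.epochs_grid, cfg.hidden_scale_grid
    ):
        layers, val_loss, losses = _train_one(
            X_train, X_val, X.shape[1], cfg, lr, n_epochs, scale,
            np.random.default_rng(cfg.seed + 1),
        )
        if best is None or val_loss < best[1]:
            best = (layers, val_loss, losses, dict(
                learning_rate=lr, epochs=n_epochs, hidden_scale=scale
            ))
    layers, val_loss, losses, params = best
    return Embedder(
        layers=layers,
        best_params=params,
        holdout_loss=val_loss,
        train_losses=losses,
    )


def embed_and_project(embedder: Embedder, epochs: EpochMatrix):
    """100-d codes projected onto their top two principal components.

    Returns ``(coords_2d, codes)``; one row per epoch, label order
    preserved.
    """
    codes = embedder.encode(epochs.X)
    n_comp = min(2, codes.shape[0], codes.shape[1])
    coords = PCA(n_components=n_comp, random_state=0).fit_transform(codes)
    return coords, codes


def separation_score(codes: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of the two condition groups in code space, in
    [-1, 1]; ~0 means the conditions are not separable."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need both condition labels")
    return float(silhouette_score(codes, labels))


def write_embedding(path, epochs: EpochMatrix, coords: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index\tlabel\tpc1\tpc2\n")
        for i, (lab, row) in enumerate(zip(epochs.labels, coords)):
            pc2 = row[1] if row.size > 1 else 0.0
            fh.write(f"{i}\t{lab}\t{row[0]:.6g}\t{pc2:.6g}\n")
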