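"""Unsupervised encoder initialization via a stacked denoising autoencoder.

The combined (spots + cells) x genes standardized matrix Y is mapped to a
low-dimensional latent space Z by an encoder f_theta.  Each layer is first
pretrained as a denoising autoencoder: its input is a corrupted copy of the
previous layer's (uncorrupted) output with a fraction of features masked to
zero, and it learns to reconstruct the uncorrupted values under MSE.  The
encoders are then stacked (decoders in reverse order) and the whole
autoencoder is fine-tuned end-to-end on uncorrupted Y, after which the
decoder half is dropped.

Hidden activations are ReLU; the bottleneck and the final decoder layer use
tanh, since latent features and reconstructed z-scores must take both
signs.  Training is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Dense, backward_chain, forward_chain, params_of

logger = logging.getLogger(__name__)

__all__ = ["EncoderSpec", "DeconModel", "build_architecture",
           "pretrain_layerwise", "finetune_stacked"]

LATENT_DIM_DEFAULT = 64


class DivergenceError(RuntimeError):
    """Non-finite training loss."""


@dataclass
class EncoderSpec:
    """Architecture and training hyperparameters for the encoder."""

    layer_dims: list[int]          # [p, hidden..., d], strictly decreasing
    corruption_rate: float = 0.2   # fraction of features masked to zero
    pretrain_epochs: int = 100
    finetune_epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        dims = list(self.layer_dims)
        if len(dims) < 2:
            raise ValueError("need at least input and latent dimensions")
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError(f"layer dims must strictly decrease, got {dims}")
        if not (0 <= self.corruption_rate < 1):
            raise ValueError("corruption_rate must lie in [0, 1)")
        self.layer_dims = dims

    @property
    def latent_dim(self) -> int:
        return self.layer_dims[-1]


@dataclass
class DeconModel:
    """Encoder plus (after supervised training) one centroid per cell type."""

    encoder: list[Dense]
    spec: EncoderSpec
    genes: list[str] = field(default_factory=list)
    centroids: np.ndarray | None = None     # (K, d)
    cell_types: list[str] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        Z = forward_chain(self.encoder, np.asarray(X, dtype=float), cache=False)
        if not np.all(np.isfinite(Z)):
            raise DivergenceError("encoder produced non-finite embeddings")
        return Z

    @property
    def latent_dim(self) -> int:
        return self.spec.latent_dim


def build_architecture(
    n_rows: int,
    p: int,
    latent_dim: int = LATENT_DIM_DEFAULT,
    layer_dims: list[int] | None = None,
    **kwargs,
) -> EncoderSpec:
    """Deterministic architecture tiering by dataset size.

    Fewer than 10,000 rows gets two encoder layers [p, 256, d]; larger
    inputs get three [p, 512, 128, d].  An explicit ``layer_dims`` override
    is honored verbatim.
    """
    if layer_dims is not None:
        return EncoderSpec(layer_dims=list(layer_dims), **kwargs)
    if p < 32:
        raise ValueError(f"too few features ({p}); at least 32 required")
    # shrink the bottleneck for small gene panels so dims stay decreasing
    latent_dim = min(latent_dim, max(32, p // 2))
    if latent_dim >= p:
        latent_dim = p - 1
    hidden = [256] if n_rows < 10_000 else [512, 128]
    hidden = [w for w in hidden if latent_dim < w < p]
    return EncoderSpec(layer_dims=[p, *hidden, latent_dim], **kwargs)


def _corrupt(rng: np.random.Generator, x: np.ndarray, rate: float) -> np.ndarray:
    if rate == 0:
        return x
    mask = rng.random(x.shape) >= rate
    return x * mask


def _batches(rng: np.random.Generator, n: int, batch_size: int):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _decoder_activation(layer_index: int, spec: EncoderSpec) -> str:
    # decoder of the first layer reconstructs the original (z-scored) input
    return "tanh" if layer_index == 0 else "relu"


def _encoder_activation(layer_index: int, spec: EncoderSpec) -> str:
    # last encoder layer is the bottleneck
    return "tanh" if layer_index == len(spec.layer_dims) - 2 else "relu"


def pretrain_layerwise(
    Y: np.ndarray, spec: EncoderSpec
) -> tuple[list[Dense], list[Dense]]:
    """Train each (encoder, decoder) pair greedily; returns both stacks.

    Layer i maps dims[i] -> dims[i+1]; its denoising autoencoder corrupts
    the previous layer's uncorrupted output afresh each epoch and minimizes
    reconstruction MSE against the uncorrupted values.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("input matrix must be finite")
    rng = np.random.default_rng(spec.seed)
    encoders: list[Dense] = []
    decoders: list[Dense] = []
    H = Y
    for i, (n_in, n_out) in enumerate(zip(spec.layer_dims, spec.layer_dims[1:])):
        enc = Dense(n_in, n_out, _encoder_activation(i, spec), rng)
        dec = Dense(n_out, n_in, _decoder_activation(i, spec), rng)
        opt = Adam(enc.params + dec.params, lr=spec.learning_rate)
        n = H.shape[0]
        for epoch in range(spec.pretrain_epochs):
            for idx in _batches(rng, n, spec.batch_size):
                clean = H[idx]
                noisy = _corrupt(rng, clean, spec.corruption_rate)
                recon = dec.forward(enc.forward(noisy))
                diff = recon - clean
                loss = float(np.mean(diff * diff))
                if not np.isfinite(loss):
                    raise DivergenceError(f"pretraining diverged at layer {i}")
                grad = 2.0 * diff / diff.size
                g_h, g_Wd, g_bd = dec.backward(grad)
                _, g_We, g_be = enc.backward(g_h)
                opt.step([g_We, g_be, g_Wd, g_bd])
        H = enc.forward(H, cache=False)
        encoders.append(enc)
        decoders.append(dec)
        logger.debug("pretrained layer %d (%d -> %d)", i, n_in, n_out)
    return encoders, decoders


def finetune_stacked(
    Y: np.ndarray,
    encoders: list[Dense],
    decoders: list[Dense],
    spec: EncoderSpec,
) -> DeconModel:
    """Fine-tune encoders + reversed decoders end-to-end; return the encoder."""
    Y = np.asarray(Y, dtype=float)
    chain = encoders + decoders[::-1]
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(params_of(chain), lr=spec.learning_rate)
    n = Y.shape[0]
    for epoch in range(spec.finetune_epochs):
        for idx in _batches(rng, n, spec.batch_size):
            clean = Y[idx]
            recon = forward_chain(chain, clean)
            diff = recon - clean
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise DivergenceError("fine-tuning diverged")
            grads = backward_chain(chain, 2.0 * diff / diff.size)
            opt.step(grads)
    return DeconModel(encoder=encoders, spec=spec)


def reconstruction_mse(
    Y: np.ndarray, encoders: list[Dense], decoders: list[Dense]
) -> float:
    """MSE of the full stack's reconstruction of Y (no corruption)."""
    recon = forward_chain(encoders + decoders[::-1], np.asarray(Y, float), cache=False)
    return float(np.mean((recon - Y) ** 2))
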