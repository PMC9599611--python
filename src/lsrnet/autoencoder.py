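"""Stage 1: deep autoencoder over windowed-connectivity vectors.

Each D-dimensional dFC vector (D = N(N-1)/2, entries in [-1, 1] by the
Pearson construction) is compressed through fully connected layers — each
hidden affine map followed by a normalisation layer and tanh — to an
H-dimensional latent code, then mirrored back to D. The output layer ends in
tanh, so reconstructions stay in [-1, 1]. Training minimises the mean squared
reconstruction error with Adam; the pooled training windows of all training
scans are shuffled together.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dfc import DfcSequence
from .nn import Adam, BatchNorm1d, Dense, LayerNorm, Sequential, Tanh, mse_grad, mse_loss

__all__ = [
    "AutoencoderSpec",
    "Autoencoder",
    "LatentSequence",
    "reconstruction_loss",
    "train_autoencoder",
    "encode_scan",
]

reconstruction_loss = mse_loss


@dataclass
class AutoencoderSpec:
    """Architecture of the stage-1 autoencoder.

    ``encoder_dims`` must be strictly decreasing; the decoder mirrors it back
    to ``input_dim``. ``normalization`` selects batch-style (running-stat)
    or per-sample layer normalisation after each hidden affine map.
    """

    input_dim: int
    encoder_dims: tuple[int, ...] = (2048, 1024, 512)
    normalization: str = "batch"

    def __post_init__(self) -> None:
        self.encoder_dims = tuple(int(d) for d in self.encoder_dims)
        if self.input_dim < 1 or any(d < 1 for d in self.encoder_dims):
            raise ValueError("all layer dims must be >= 1")
        if list(self.encoder_dims) != sorted(set(self.encoder_dims), reverse=True):
            raise ValueError("encoder_dims must be strictly decreasing")
        if self.normalization not in ("batch", "layer", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def latent_dim(self) -> int:
        return self.encoder_dims[-1]

    @property
    def decoder_dims(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_dims[:-1])) + (self.input_dim,)


def _norm_layer(spec: AutoencoderSpec, dim: int):
    if spec.normalization == "batch":
        return BatchNorm1d(dim)
    if spec.normalization == "layer":
        return LayerNorm(dim)
    return None


def _stack(spec: AutoencoderSpec, dims_in: list[int], dims_out: list[int],
           rng: np.random.Generator, final_plain_tanh: bool) -> Sequential:
    layers = []
    last = len(dims_out) - 1
    for k, (a, b) in enumerate(zip(dims_in, dims_out)):
        layers.append(Dense(a, b, rng))
        if not (final_plain_tanh and k == last):
            norm = _norm_layer(spec, b)
            if norm is not None:
                layers.append(norm)
        layers.append(Tanh())
    return Sequential(*layers)


class Autoencoder:
    """Encoder/decoder pair; ``encode``/``decode`` default to inference mode."""

    def __init__(self, spec: AutoencoderSpec, rng: np.random.Generator):
        self.spec = spec
        enc_in = [spec.input_dim, *spec.encoder_dims[:-1]]
        self.encoder = _stack(spec, enc_in, list(spec.encoder_dims), rng,
                              final_plain_tanh=False)
        dec_in = [spec.latent_dim, *spec.decoder_dims[:-1]]
        self.decoder = _stack(spec, dec_in, list(spec.decoder_dims), rng,
                              final_plain_tanh=True)

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    @property
    def grads(self):
        return self.encoder.grads + self.decoder.grads

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} != spec input_dim {self.spec.input_dim}"
            )
        return self.encoder.forward(x, train=train)

    def decode(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        return self.decoder.forward(np.atleast_2d(np.asarray(h, float)), train=train)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.decode(self.encode(x, train=train), train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(dout))

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for side, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, layer in enumerate(net.layers):
                for j, p in enumerate(layer.params):
                    arrays[f"{side}.{i}.p{j}"] = p
                if isinstance(layer, BatchNorm1d):
                    arrays[f"{side}.{i}.rmean"] = layer.running_mean
                    arrays[f"{side}.{i}.rvar"] = layer.running_var
        return arrays

    def save(self, path: str | Path) -> None:
        arrays = {k: v for k, v in self.state_arrays().items()}
        arrays["__spec__"] = np.frombuffer(
            json.dumps(
                {
                    "input_dim": self.spec.input_dim,
                    "encoder_dims": list(self.spec.encoder_dims),
                    "normalization": self.spec.normalization,
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        data = np.load(path)
        meta = json.loads(bytes(data["__spec__"]).decode())
        spec = AutoencoderSpec(
            input_dim=meta["input_dim"],
            encoder_dims=tuple(meta["encoder_dims"]),
            normalization=meta["normalization"],
        )
        model = cls(spec, np.random.default_rng(0))
        for side, net in (("enc", model.encoder), ("dec", model.decoder)):
            for i, layer in enumerate(net.layers):
                for j, p in enumerate(layer.params):
                    p[...] = data[f"{side}.{i}.p{j}"]
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean[...] = data[f"{side}.{i}.rmean"]
                    layer.running_var[...] = data[f"{side}.{i}.rvar"]
        return model

    def digest(self) -> str:
        """Checksum of all parameters and running statistics."""
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.state_arrays()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.state_arrays()[k]).tobytes())
        return h.hexdigest()


@dataclass
class LatentSequence:
    """Per-scan M x H matrix of latent codes; stage-2 input."""

    scan_id: str
    codes: np.ndarray
    window_starts: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.codes.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.codes.shape[1]


def train_autoencoder(
    vectors: np.ndarray,
    spec: AutoencoderSpec,
    *,
    epochs: int = 100,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    seed: int = 0,
    val_vectors: np.ndarray | None = None,
    patience: int = 10,
) -> tuple[Autoencoder, dict]:
    """Train on pooled dFC vectors; deterministic given ``seed``.

    Returns the model (restored to the best validation epoch when a
    validation pool is given) and a history dict with per-epoch mean training
    loss and, if applicable, validation loss.
    """
    vectors = np.asarray(vectors, float)
    if vectors.ndim != 2 or vectors.shape[0] < 1:
        raise ValueError("need at least one training vector")
    if vectors.shape[1] != spec.input_dim:
        raise ValueError(
            f"vector dim {vectors.shape[1]} != spec input_dim {spec.input_dim}"
        )
    rng = np.random.default_rng(seed)
    model = Autoencoder(spec, rng)
    opt = Adam(model.params, model.grads, lr=learning_rate)
    n = vectors.shape[0]
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            xb = vectors[order[start : start + batch_size]]
            xhat = model.forward(xb, train=True)
            loss = mse_loss(xb, xhat)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            model.backward(mse_grad(xb, xhat))
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_vectors is not None and len(val_vectors):
            vhat = model.forward(val_vectors, train=False)
            vloss = mse_loss(val_vectors, vhat)
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-12:
                best_val, stale = vloss, 0
                best_state = [p.copy() for p in model.params] + [
                    a.copy() for a in _running_stats(model)
                ]
            else:
                stale += 1
                if stale > patience:
                    break
    if best_state is not None:
        stats = _running_stats(model)
        for p, saved in zip(model.params + stats, best_state):
            p[...] = saved
    return model, history


def _running_stats(model: Autoencoder) -> list[np.ndarray]:
    out = []
    for net in (model.encoder, model.decoder):
        for layer in net.layers:
            if isinstance(layer, BatchNorm1d):
                out.extend([layer.running_mean, layer.running_var])
    return out


def encode_scan(dfc: DfcSequence, model: Autoencoder) -> LatentSequence:
    """Encode all M windows of one scan into an M x H latent matrix."""
    codes = model.encode(dfc.vectors, train=False)
    return LatentSequence(
        scan_id=dfc.scan_id, codes=codes, window_starts=list(dfc.window_starts)
    )
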