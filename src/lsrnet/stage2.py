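"""Stage 2: multi-perspective feature extraction and fusion.

Two feature parsers read the per-scan M x H latent matrix:

* **global features (GF)** — a convolution whose kernel has the full M x H
  size, so each of the K kernels reduces the entire latent matrix to one
  scalar: ``GF_k = act(<latent, kernel_k> + b_k)``;
* **dynamic features (DF)** — a bidirectional LSTM over the M latent rows;
  by default DF concatenates the forward and backward final hidden states
  (length 2 * hidden), optionally the stacked per-step outputs.

FusionNet concatenates GF and DF, compresses through one hidden tanh layer
and classifies with softmax. All three blocks train jointly end-to-end with
cross-entropy; the stage-1 encoder stays frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    Dense,
    LSTMLayer,
    Sequential,
    Tanh,
    cross_entropy_grad,
    cross_entropy_loss,
    softmax,
)

__all__ = [
    "GlobalCnnSpec",
    "BilstmSpec",
    "FusionSpec",
    "Stage2Model",
    "global_cnn_features",
    "bilstm_features",
    "fuse_and_classify",
    "train_stage2",
    "predict_scan",
]


@dataclass(frozen=True)
class GlobalCnnSpec:
    n_windows: int      # M — kernel height equals the window count
    latent_dim: int     # H — kernel width equals the latent width
    n_kernels: int = 64

    @property
    def kernel_shape(self) -> tuple[int, int]:
        return (self.n_windows, self.latent_dim)


@dataclass(frozen=True)
class BilstmSpec:
    input_dim: int
    hidden_size: int = 32
    bidirectional: bool = True

    @property
    def feature_dim(self) -> int:
        return 2 * self.hidden_size if self.bidirectional else self.hidden_size


@dataclass(frozen=True)
class FusionSpec:
    input_dim: int
    n_classes: int
    hidden_dim: int = 32


def global_cnn_features(latent: np.ndarray, kernels: np.ndarray,
                        biases: np.ndarray, activation=np.tanh) -> np.ndarray:
    """Full-size-kernel convolution: one scalar per kernel.

    ``latent`` is M x H, ``kernels`` is K x M x H; feature k is
    ``activation(sum(latent * kernel_k) + bias_k)``.
    """
    latent = np.asarray(latent, float)
    kernels = np.asarray(kernels, float)
    if kernels.shape[1:] != latent.shape:
        raise ValueError(
            f"kernel shape {kernels.shape[1:]} != latent shape {latent.shape}"
        )
    raw = np.tensordot(kernels, latent, axes=([1, 2], [0, 1])) + biases
    return activation(raw) if activation is not None else raw


def bilstm_features(latent: np.ndarray, forward: LSTMLayer,
                    backward: LSTMLayer) -> np.ndarray:
    """Concatenated final hidden states of the two directions (length 2h)."""
    x = np.asarray(latent, float)[None]
    h_fw = forward.forward(x, train=False)[:, -1]
    h_bw = backward.forward(x[:, ::-1], train=False)[:, -1]
    return np.concatenate([h_fw, h_bw], axis=1)[0]


def fuse_and_classify(gf: np.ndarray, df: np.ndarray,
                      fusion: Sequential) -> np.ndarray:
    """concat(GF, DF) -> compression layers -> softmax probabilities."""
    feats = np.concatenate([np.atleast_1d(gf), np.atleast_1d(df)])[None]
    logits = fusion.forward(feats, train=False)
    return softmax(logits)[0]


class Stage2Model:
    """GCNN + BiLSTM + FusionNet over fixed-shape (M, F) input sequences.

    ``use_gf`` / ``use_df`` toggle the two perspectives so the same machinery
    drives the single-perspective comparison variants. The full-size global
    kernels are stored as one dense map over the flattened latent matrix,
    which is the same linear operation.
    """

    def __init__(
        self,
        n_windows: int,
        input_dim: int,
        n_classes: int,
        *,
        n_kernels: int = 64,
        lstm_hidden: int = 32,
        fusion_hidden: int = 32,
        use_gf: bool = True,
        use_df: bool = True,
        df_mode: str = "final",
        rng: np.random.Generator | None = None,
    ):
        if not (use_gf or use_df):
            raise ValueError("at least one perspective must be enabled")
        if df_mode not in ("final", "all_steps"):
            raise ValueError(f"unknown df_mode {df_mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_windows, self.input_dim, self.n_classes = n_windows, input_dim, n_classes
        self.use_gf, self.use_df, self.df_mode = use_gf, use_df, df_mode
        self.n_kernels, self.lstm_hidden = n_kernels, lstm_hidden
        feat = 0
        if use_gf:
            self.gf_dense = Dense(n_windows * input_dim, n_kernels, rng)
            self.gf_act = Tanh()
            feat += n_kernels
        if use_df:
            self.lstm_fw = LSTMLayer(input_dim, lstm_hidden, rng)
            self.lstm_bw = LSTMLayer(input_dim, lstm_hidden, rng)
            feat += (2 * lstm_hidden if df_mode == "final"
                     else 2 * lstm_hidden * n_windows)
        self.feature_dim = feat
        self.fusion = Sequential(
            Dense(feat, fusion_hidden, rng),
            Tanh(),
            Dense(fusion_hidden, n_classes, rng),
        )

    # -- parameters --------------------------------------------------------
    @property
    def params(self):
        out = []
        if self.use_gf:
            out += self.gf_dense.params
        if self.use_df:
            out += self.lstm_fw.params + self.lstm_bw.params
        return out + self.fusion.params

    @property
    def grads(self):
        out = []
        if self.use_gf:
            out += self.gf_dense.grads
        if self.use_df:
            out += self.lstm_fw.grads + self.lstm_bw.grads
        return out + self.fusion.grads

    @property
    def global_kernels(self) -> np.ndarray:
        """The K full-size kernels, shaped (K, M, F)."""
        return self.gf_dense.w.T.reshape(
            self.n_kernels, self.n_windows, self.input_dim
        )

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for a batch of sequences, x shape (B, M, F)."""
        x = np.asarray(x, float)
        if x.ndim == 2:
            x = x[None]
        b, m, f = x.shape
        if (m, f) != (self.n_windows, self.input_dim):
            raise ValueError(
                f"input shape {(m, f)} != model shape "
                f"{(self.n_windows, self.input_dim)}"
            )
        feats = []
        if self.use_gf:
            gf = self.gf_act.forward(
                self.gf_dense.forward(x.reshape(b, -1), train=train), train=train
            )
            feats.append(gf)
        if self.use_df:
            hs_fw = self.lstm_fw.forward(x, train=train)
            hs_bw = self.lstm_bw.forward(x[:, ::-1], train=train)
            if self.df_mode == "final":
                df = np.concatenate([hs_fw[:, -1], hs_bw[:, -1]], axis=1)
            else:
                df = np.concatenate(
                    [hs_fw.reshape(b, -1), hs_bw.reshape(b, -1)], axis=1
                )
            feats.append(df)
        return self.fusion.forward(np.concatenate(feats, axis=1), train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.fusion.backward(dlogits)
        pos = 0
        if self.use_gf:
            dgf = dfeat[:, pos : pos + self.n_kernels]
            pos += self.n_kernels
            self.gf_dense.backward(self.gf_act.backward(dgf))
        if self.use_df:
            b = dfeat.shape[0]
            h = self.lstm_hidden
            if self.df_mode == "final":
                dh_fw = np.zeros((b, self.n_windows, h))
                dh_bw = np.zeros((b, self.n_windows, h))
                dh_fw[:, -1] = dfeat[:, pos : pos + h]
                dh_bw[:, -1] = dfeat[:, pos + h : pos + 2 * h]
            else:
                width = self.n_windows * h
                dh_fw = dfeat[:, pos : pos + width].reshape(b, self.n_windows, h)
                dh_bw = dfeat[:, pos + width : pos + 2 * width].reshape(
                    b, self.n_windows, h
                )
            self.lstm_fw.backward(dh_fw)
            self.lstm_bw.backward(dh_bw)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def config_fingerprint(self) -> dict:
        fp = {
            "n_windows": self.n_windows,
            "input_dim": self.input_dim,
            "n_classes": self.n_classes,
            "feature_dim": self.feature_dim,
        }
        if self.use_gf:
            fp["gf_dim"] = self.n_kernels
        if self.use_df:
            fp["df_dim"] = (
                2 * self.lstm_hidden if self.df_mode == "final"
                else 2 * self.lstm_hidden * self.n_windows
            )
        return fp


def train_stage2(
    sequences: np.ndarray,
    labels: np.ndarray,
    *,
    n_classes: int,
    epochs: int = 100,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    val_sequences: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    patience: int = 10,
    class_weights: np.ndarray | None = None,
    **model_kwargs,
) -> tuple[Stage2Model, dict]:
    """Joint end-to-end training of GCNN, BiLSTM and FusionNet.

    ``sequences`` is (B, M, F); training is deterministic given ``seed``.
    Raises on a single-class training set (nothing to separate) and on
    non-finite loss.
    """
    sequences = np.asarray(sequences, float)
    labels = np.asarray(labels, int)
    if sequences.ndim != 3:
        raise ValueError("sequences must be (n_scans, n_windows, feature_dim)")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    rng = np.random.default_rng(seed)
    _, m, f = sequences.shape
    model = Stage2Model(m, f, n_classes, rng=rng, **model_kwargs)
    opt = Adam(model.params, model.grads, lr=learning_rate)
    n = len(sequences)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val, best_state, stale = np.inf, None, 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward(sequences[idx], train=True)
            loss = cross_entropy_loss(logits, labels[idx], class_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            model.backward(cross_entropy_grad(logits, labels[idx], class_weights))
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_sequences is not None and len(val_sequences):
            vlogits = model.forward(val_sequences, train=False)
            vloss = cross_entropy_loss(vlogits, np.asarray(val_labels, int))
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-12:
                best_val, stale = vloss, 0
                best_state = [p.copy() for p in model.params]
            else:
                stale += 1
                if stale > patience:
                    break
    if best_state is not None:
        for p, saved in zip(model.params, best_state):
            p[...] = saved
    return model, history


def predict_scan(latent: np.ndarray, model: Stage2Model) -> tuple[int, np.ndarray]:
    """Class id (argmax, ties to the lowest id) and probability vector."""
    probs = model.predict_proba(np.asarray(latent, float)[None])[0]
    return int(np.argmax(probs)), probs
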