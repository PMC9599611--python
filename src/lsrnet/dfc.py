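"""Dynamic functional-connectivity (dFC) construction.

The stage-1 front end: z-score each ROI's BOLD series, cut the series into
overlapping sliding windows, compute the Pearson correlation matrix of each
window and keep its strict upper triangle as a feature vector of length
D = N(N-1)/2.

Conventions
-----------
* z-scoring and Pearson correlation use the population (1/W) normalisation;
  Pearson correlation is invariant to this choice.
* Windows are 0-based and half-open: window k covers columns
  ``[k*step, k*step + window_length)`` and the window count is
  ``M = floor((T - window_length)/step) + 1``. At the published scale
  (T=137 retained timepoints, window 30, step 2) this gives M = 54.
* An ROI that is constant within a window gets correlation 0 with every
  other ROI (and 1 with itself) plus a warning, so downstream tensors stay
  finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DfcSequence",
    "normalize_series",
    "segment_windows",
    "pearson_matrix",
    "vectorize_upper",
    "devectorize_upper",
    "build_dfc",
]


@dataclass
class DfcSequence:
    """Per-scan ordered set of M windowed correlation matrices.

    ``vectors`` is the M x D matrix of row-major strict upper triangles,
    D = N(N-1)/2, in the same window order as ``matrices``.
    """

    scan_id: str
    matrices: np.ndarray      # (M, N, N)
    vectors: np.ndarray       # (M, D)
    window_starts: list[int]

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def normalize_series(signal: np.ndarray) -> np.ndarray:
    """Z-score each ROI's series: f(t) = (t - mu) / sigma, row-wise.

    Population standard deviation. A constant row has no scale; it maps to
    all zeros with a warning rather than dividing by zero.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal matrix")
    mu = signal.mean(axis=1, keepdims=True)
    sd = signal.std(axis=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant ROI row(s) mapped to zeros",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (signal - mu) / safe_sd
    out[degenerate, :] = 0.0
    return out


def segment_windows(signal: np.ndarray, window_length: int, step: int) -> list[np.ndarray]:
    """Cut an N x T matrix into M overlapping windows of width ``window_length``."""
    signal = np.asarray(signal, dtype=float)
    n, t = signal.shape
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if t < window_length:
        raise ValueError(f"series length {t} shorter than window {window_length}")
    m = (t - window_length) // step + 1
    return [signal[:, k * step : k * step + window_length] for k in range(m)]


def n_windows(t: int, window_length: int, step: int) -> int:
    """M = floor((T - w)/s) + 1, the number of valid window starts."""
    if t < window_length:
        raise ValueError(f"series length {t} shorter than window {window_length}")
    return (t - window_length) // step + 1


def pearson_matrix(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the N rows of a window.

    Symmetric with an exactly unit diagonal; entries clipped to [-1, 1]
    against round-off. Zero-variance rows correlate 0 with all others.
    """
    window = np.asarray(window, dtype=float)
    n, w = window.shape
    if w < 2:
        raise ValueError("window must span at least 2 timepoints")
    mu = window.mean(axis=1, keepdims=True)
    sd = window.std(axis=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI(s) in window; "
            "correlations set to 0",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (window - mu) / safe_sd
    r = (z @ z.T) / w
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def vectorize_upper(matrix: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Row-major strict upper triangle of a symmetric matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=atol, rtol=0):
        raise ValueError(f"matrix asymmetric beyond {atol}")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu].copy()


def devectorize_upper(vector: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` given a unit diagonal."""
    vector = np.asarray(vector, dtype=float)
    d = n * (n - 1) // 2
    if vector.shape != (d,):
        raise ValueError(f"expected vector of length {d} for n={n}")
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out


def build_dfc(recording, config) -> DfcSequence:
    """Normalize -> segment -> windowed Pearson -> vectorize, in window order."""
    signal = normalize_series(recording.signal)
    windows = segment_windows(signal, config.window_length, config.step)
    matrices = np.stack([pearson_matrix(w) for w in windows])
    vectors = np.stack([vectorize_upper(m) for m in matrices])
    starts = [k * config.step for k in range(len(windows))]
    return DfcSequence(
        scan_id=recording.scan_id,
        matrices=matrices,
        vectors=vectors,
        window_starts=starts,
    )
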