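"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the two-stage
pipeline: the sliding-window geometry of the dynamic functional-connectivity
(dFC) front end, the autoencoder architecture, the stage-2 feature extractors
(global-kernel CNN and bidirectional LSTM) and the training hyperparameters.
All randomness in the package flows from ``seed``; every stochastic routine
takes an explicit ``numpy.random.Generator`` derived from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Configuration for the full dFC -> latent -> classification pipeline.

    Defaults follow the published operating point (116-ROI parcellation,
    137 retained timepoints, window 30, step 2, encoder 2048/1024/512,
    BiLSTM hidden size 32). Tests and small synthetic cohorts override the
    architecture widths downward.
    """

    # dFC construction
    window_length: int = 30
    step: int = 2
    n_rois: int = 116

    # stage 1: autoencoder
    encoder_dims: tuple[int, ...] = (2048, 1024, 512)
    normalization: str = "batch"  # "batch" | "layer" | "none"

    # stage 2
    n_kernels: int = 64          # K, global full-size kernels
    lstm_hidden: int = 32        # BiLSTM hidden size per direction
    fusion_hidden: int = 32      # width of the FusionNet compression layer

    # training
    seed: int = 0
    ae_epochs: int = 100
    ae_batch_size: int = 64
    ae_learning_rate: float = 1e-3
    stage2_epochs: int = 100
    stage2_batch_size: int = 32
    stage2_learning_rate: float = 1e-3
    patience: int = 10
    val_fraction: float = 0.15
    class_weighting: bool = False

    @property
    def latent_dim(self) -> int:
        """H: width of the latent code (last encoder layer)."""
        return self.encoder_dims[-1]

    def __post_init__(self) -> None:
        self.encoder_dims = tuple(int(d) for d in self.encoder_dims)
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if any(d < 1 for d in self.encoder_dims):
            raise ValueError("encoder dims must be positive")
        if list(self.encoder_dims) != sorted(self.encoder_dims, reverse=True) or len(
            set(self.encoder_dims)
        ) != len(self.encoder_dims):
            raise ValueError("encoder_dims must be strictly decreasing")
        if self.normalization not in ("batch", "layer", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder_dims"] = list(self.encoder_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def small_cohort_config(n_rois: int = 20, seed: int = 0, **overrides) -> PipelineConfig:
    """A small-cohort operating point: same pipeline, narrow layers.

    Suitable for cohorts of tens of subjects with ~20 ROIs, where the
    published widths (2048/1024/512) would be severely over-parameterised.
    """
    base = dict(
        n_rois=n_rois,
        encoder_dims=(64, 32, 16),
        n_kernels=16,
        lstm_hidden=16,
        fusion_hidden=16,
        ae_epochs=40,
        stage2_epochs=80,
        seed=seed,
    )
    base.update(overrides)
    return PipelineConfig(**base)
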