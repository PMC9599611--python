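"""Model/Results interface for the two-stage pipeline.

:class:`LSRNet` is constructed from a cohort (manifest + recordings) plus a
:class:`~lsrnet.config.PipelineConfig`; :meth:`LSRNet.fit` trains stage 1
(the dFC autoencoder) and stage 2 (multi-perspective fusion classifier) on a
chosen subject set and returns an :class:`LSRNetResult` carrying the trained
components, loss histories and a ``summary()``. Cross-validated evaluation
and the comparison variants live in :mod:`lsrnet.evaluation` and are exposed
here as :meth:`LSRNet.cross_validate`.
"""

from __future__ import annotations

import numpy as np

from .autoencoder import (
    Autoencoder,
    AutoencoderSpec,
    LatentSequence,
    encode_scan,
    train_autoencoder,
)
from .bold_io import BoldRecording, CohortManifest
from .config import PipelineConfig
from .dfc import DfcSequence, build_dfc
from .stage2 import Stage2Model, predict_scan, train_stage2

__all__ = ["LSRNet", "LSRNetResult", "VARIANT_FLAGS"]

# which pipeline pieces each neural comparison variant uses
VARIANT_FLAGS: dict[str, dict[str, bool]] = {
    "LSRNet": dict(use_ae=True, use_gf=True, use_df=True),
    "LSRNet-G": dict(use_ae=True, use_gf=True, use_df=False),
    "LSRNet-B": dict(use_ae=True, use_gf=False, use_df=True),
    "dFC+GCNN": dict(use_ae=False, use_gf=True, use_df=False),
    "dFC+BiLSTM": dict(use_ae=False, use_gf=False, use_df=True),
}


class LSRNet:
    """Latent-space representation network over a BOLD cohort.

    Parameters
    ----------
    manifest
        Cohort registry; its label ordering defines the integer class ids.
    recordings
        One :class:`BoldRecording` per manifest entry (any order).
    config
        Pipeline configuration; defaults to :class:`PipelineConfig`.
    """

    def __init__(
        self,
        manifest: CohortManifest,
        recordings: list[BoldRecording],
        config: PipelineConfig | None = None,
    ):
        self.manifest = manifest
        self.config = config or PipelineConfig()
        self._recordings = {r.scan_id: r for r in recordings}
        missing = [e.scan_id for e in manifest.entries if e.scan_id not in self._recordings]
        if missing:
            raise ValueError(f"recordings missing for scan(s): {missing[:5]}")
        self._dfc_cache: dict[str, DfcSequence] = {}

    @classmethod
    def from_cohort_dir(cls, manifest_path, config: PipelineConfig | None = None) -> "LSRNet":
        from .bold_io import load_cohort

        manifest, recordings = load_cohort(manifest_path)
        return cls(manifest, recordings, config)

    # -- data access --------------------------------------------------------
    @property
    def classes(self) -> list[str]:
        return self.manifest.classes

    def recording(self, scan_id: str) -> BoldRecording:
        return self._recordings[scan_id]

    def dfc(self, scan_id: str) -> DfcSequence:
        """Windowed-connectivity sequence for one scan (cached)."""
        if scan_id not in self._dfc_cache:
            self._dfc_cache[scan_id] = build_dfc(
                self._recordings[scan_id], self.config
            )
        return self._dfc_cache[scan_id]

    def scan_label(self, scan_id: str) -> int:
        ids = self.manifest.label_ids
        for e in self.manifest.entries:
            if e.scan_id == scan_id:
                return ids[e.label]
        raise KeyError(scan_id)

    # -- fitting -------------------------------------------------------------
    def fit(
        self,
        train_subjects: list[str] | None = None,
        val_subjects: list[str] | None = None,
        seed: int | None = None,
        variant: str = "LSRNet",
    ) -> "LSRNetResult":
        """Train both stages on the given subjects and return a results object.

        With no subject lists, trains on all subjects with ``val_fraction``
        of them held out for early stopping. ``variant`` selects which
        pipeline pieces are active (see :data:`VARIANT_FLAGS`).
        """
        if variant not in VARIANT_FLAGS:
            raise ValueError(
                f"unknown variant {variant!r}; neural variants: {sorted(VARIANT_FLAGS)}"
            )
        flags = VARIANT_FLAGS[variant]
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)

        subjects = self.manifest.subjects
        if train_subjects is None:
            pool = list(subjects)
            rng.shuffle(pool)
            if val_subjects is None:
                n_val = max(1, round(cfg.val_fraction * len(pool))) if len(pool) > 1 else 0
                val_subjects = pool[:n_val]
                train_subjects = pool[n_val:]
            else:
                train_subjects = [s for s in pool if s not in set(val_subjects)]

        train_entries = self.manifest.scans_of(train_subjects)
        val_entries = self.manifest.scans_of(val_subjects or [])
        if not train_entries:
            raise ValueError("no training scans")
        ids = self.manifest.label_ids

        train_dfc = [self.dfc(e.scan_id) for e in train_entries]
        val_dfc = [self.dfc(e.scan_id) for e in val_entries]

        encoder = None
        ae_history: dict = {}
        if flags["use_ae"]:
            pooled = np.vstack([d.vectors for d in train_dfc])
            val_pool = (
                np.vstack([d.vectors for d in val_dfc]) if val_dfc else None
            )
            spec = AutoencoderSpec(
                input_dim=pooled.shape[1],
                encoder_dims=cfg.encoder_dims,
                normalization=cfg.normalization,
            )
            encoder, ae_history = train_autoencoder(
                pooled,
                spec,
                epochs=cfg.ae_epochs,
                batch_size=cfg.ae_batch_size,
                learning_rate=cfg.ae_learning_rate,
                seed=int(rng.integers(2**31 - 1)),
                val_vectors=val_pool,
                patience=cfg.patience,
            )

        def to_sequence(d: DfcSequence) -> np.ndarray:
            if encoder is not None:
                return encode_scan(d, encoder).codes
            return d.vectors

        x_train = np.stack([to_sequence(d) for d in train_dfc])
        y_train = np.array([ids[e.label] for e in train_entries])
        x_val = (
            np.stack([to_sequence(d) for d in val_dfc]) if val_dfc else None
        )
        y_val = (
            np.array([ids[e.label] for e in val_entries]) if val_dfc else None
        )

        class_weights = None
        if cfg.class_weighting:
            counts = np.bincount(y_train, minlength=len(self.classes)).astype(float)
            counts[counts == 0] = 1.0
            class_weights = counts.sum() / (len(counts) * counts)

        stage2, s2_history = train_stage2(
            x_train,
            y_train,
            n_classes=len(self.classes),
            epochs=cfg.stage2_epochs,
            batch_size=cfg.stage2_batch_size,
            learning_rate=cfg.stage2_learning_rate,
            seed=int(rng.integers(2**31 - 1)),
            val_sequences=x_val,
            val_labels=y_val,
            patience=cfg.patience,
            class_weights=class_weights,
            n_kernels=cfg.n_kernels,
            lstm_hidden=cfg.lstm_hidden,
            fusion_hidden=cfg.fusion_hidden,
            use_gf=flags["use_gf"],
            use_df=flags["use_df"],
        )
        return LSRNetResult(
            model=self,
            variant=variant,
            encoder=encoder,
            stage2=stage2,
            ae_history=ae_history,
            stage2_history=s2_history,
            train_subjects=list(train_subjects),
            val_subjects=list(val_subjects or []),
            seed=seed,
        )

    def cross_validate(self, variant: str = "LSRNet", task_classes=None,
                       k: int = 5, seed: int | None = None):
        """Subject-independent k-fold evaluation; see :mod:`lsrnet.evaluation`."""
        from .evaluation import run_variant

        return run_variant(
            variant,
            self.manifest,
            list(self._recordings.values()),
            self.config,
            seed=self.config.seed if seed is None else seed,
            task_classes=task_classes,
            k=k,
        )


class LSRNetResult:
    """Trained pipeline: encoder (optional), stage-2 classifier, histories."""

    def __init__(self, model, variant, encoder, stage2, ae_history,
                 stage2_history, train_subjects, val_subjects, seed):
        self.model = model
        self.variant = variant
        self.encoder: Autoencoder | None = encoder
        self.stage2: Stage2Model = stage2
        self.ae_history = ae_history
        self.stage2_history = stage2_history
        self.train_subjects = train_subjects
        self.val_subjects = val_subjects
        self.seed = seed

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    def latent(self, scan_id: str) -> LatentSequence:
        """The M x H latent sequence of one scan (requires the autoencoder)."""
        if self.encoder is None:
            raise ValueError(f"variant {self.variant} has no autoencoder stage")
        return encode_scan(self.model.dfc(scan_id), self.encoder)

    def _sequence(self, dfc: DfcSequence) -> np.ndarray:
        if self.encoder is not None:
            return encode_scan(dfc, self.encoder).codes
        return dfc.vectors

    def predict_recording(self, recording: BoldRecording) -> tuple[int, np.ndarray]:
        dfc = build_dfc(recording, self.model.config)
        return predict_scan(self._sequence(dfc), self.stage2)

    def predict_scan_id(self, scan_id: str) -> tuple[int, np.ndarray]:
        return predict_scan(self._sequence(self.model.dfc(scan_id)), self.stage2)

    def config_fingerprint(self) -> dict:
        fp = dict(self.model.config.to_dict())
        fp.update(self.stage2.config_fingerprint())
        fp["variant"] = self.variant
        if self.encoder is not None:
            fp["stage1_digest"] = self.encoder.digest()
        return fp

    def summary(self) -> str:
        lines = [
            f"{self.variant} — two-stage latent-space pipeline",
            f"  classes        : {', '.join(self.classes)}",
            f"  train subjects : {len(self.train_subjects)}"
            f" (+{len(self.val_subjects)} validation)",
            f"  seed           : {self.seed}",
        ]
        if self.ae_history.get("train_loss"):
            tl = self.ae_history["train_loss"]
            lines.append(
                f"  stage-1 MSE    : {tl[0]:.5f} (first epoch) -> {tl[-1]:.5f} "
                f"(last of {len(tl)})"
            )
        tl = self.stage2_history["train_loss"]
        lines.append(
            f"  stage-2 CE     : {tl[0]:.5f} (first epoch) -> {tl[-1]:.5f} "
            f"(last of {len(tl)})"
        )
        fp = self.stage2.config_fingerprint()
        dims = ", ".join(f"{k}={v}" for k, v in fp.items())
        lines.append(f"  stage-2 dims   : {dims}")
        return "\n".join(lines)
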