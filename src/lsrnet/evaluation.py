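"""Subject-independent cross-validation, comparison variants and metrics.

The evaluation protocol keeps every scan of one subject on one side of the
train/test boundary. Subjects with a baseline scan are partitioned into k
near-equal folds; fold f tests on part f and trains on the remaining parts
plus *all* subjects without a baseline scan (those never appear in a test
set). A fraction of the training subjects is moved to a validation set used
only for early stopping.

Seven pipelines run under identical folds: two static baselines
(``ROIs+SVM``, ``sFC+SVM``, linear support-vector machines on full-length
features), two ablations that skip the autoencoder (``dFC+BiLSTM``,
``dFC+GCNN``), the two single-perspective latent variants (``LSRNet-G``,
``LSRNet-B``) and the full fusion model (``LSRNet``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .autoencoder import LatentSequence
from .bold_io import BoldRecording, CohortManifest
from .config import PipelineConfig
from .dfc import normalize_series, pearson_matrix, vectorize_upper

__all__ = [
    "FoldSplit",
    "EvalReport",
    "ALL_VARIANTS",
    "SVM_VARIANTS",
    "make_subject_folds",
    "compute_metrics",
    "run_variant",
    "ablate",
    "class_mean_latent",
    "permute_subject_labels",
]

SVM_VARIANTS = ("ROIs+SVM", "sFC+SVM")
NEURAL_VARIANTS = ("dFC+BiLSTM", "dFC+GCNN", "LSRNet-G", "LSRNet-B", "LSRNet")
ALL_VARIANTS = SVM_VARIANTS + NEURAL_VARIANTS


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subjects: frozenset[str]

    def __post_init__(self):
        if (
            self.train_subjects & self.val_subjects
            or self.train_subjects & self.test_subjects
            or self.val_subjects & self.test_subjects
        ):
            raise ValueError(f"fold {self.fold}: subject sets overlap")


@dataclass
class EvalReport:
    """Overall and per-class accuracies for one task, aggregated over folds.

    Accuracies are percentages in [0, 100], computed at scan level. Both the
    pooled accuracy (all test predictions pooled over folds) and the mean of
    per-fold accuracies are reported.
    """

    task: str
    variant: str
    classes: list[str]
    scan_ids: list[str]
    subject_ids: list[str]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    fold_of_scan: np.ndarray
    config_fingerprint: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def pooled_accuracy(self) -> float:
        return 100.0 * float(np.mean(self.true_labels == self.predicted_labels))

    @property
    def fold_accuracies(self) -> list[float]:
        out = []
        for f in sorted(set(self.fold_of_scan.tolist())):
            m = self.fold_of_scan == f
            out.append(
                100.0 * float(np.mean(self.true_labels[m] == self.predicted_labels[m]))
            )
        return out

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        out = {}
        for c, name in enumerate(self.classes):
            m = self.true_labels == c
            out[f"ACC_{name}"] = (
                100.0 * float(np.mean(self.predicted_labels[m] == c)) if m.any() else float("nan")
            )
        return out

    @property
    def n_per_class(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.true_labels == c))
            for c, name in enumerate(self.classes)
        }

    @property
    def subject_accuracy(self) -> float:
        """Secondary metric: majority vote over each subject's scans."""
        correct = 0
        subjects = sorted(set(self.subject_ids))
        sid = np.array(self.subject_ids)
        for s in subjects:
            m = sid == s
            votes = np.bincount(self.predicted_labels[m], minlength=len(self.classes))
            if int(np.argmax(votes)) == int(self.true_labels[m][0]):
                correct += 1
        return 100.0 * correct / len(subjects)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "variant": self.variant,
            "classes": self.classes,
            "ACC": self.pooled_accuracy,
            "ACC_mean_over_folds": self.mean_fold_accuracy,
            "fold_accuracies": self.fold_accuracies,
            **self.per_class_accuracy,
            "n_per_class": self.n_per_class,
            "subject_level_ACC": self.subject_accuracy,
            "seed": self.seed,
            "config": self.config_fingerprint,
        }

    def summary(self) -> str:
        lines = [
            f"Task {self.task} — {self.variant} "
            f"({len(self.scan_ids)} test scans, {len(set(self.subject_ids))} subjects)",
            f"  ACC (pooled)     : {self.pooled_accuracy:5.1f}%",
            f"  ACC (fold mean)  : {self.mean_fold_accuracy:5.1f}%",
        ]
        for k, v in self.per_class_accuracy.items():
            lines.append(f"  {k:<16} : {v:5.1f}%")
        lines.append(
            "  per-fold         : "
            + ", ".join(f"{a:.1f}%" for a in self.fold_accuracies)
        )
        return "\n".join(lines)


def make_subject_folds(
    manifest: CohortManifest,
    k: int = 5,
    val_fraction: float = 0.15,
    seed: int = 0,
) -> list[FoldSplit]:
    """Partition baseline subjects into k test folds, deterministic given seed.

    Non-baseline subjects join every training set and never reach a test
    set. ``val_fraction`` of each fold's training subjects (at least 1) is
    moved to validation.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    baseline = [s for s in manifest.subjects
                if manifest.scans_of([s])[0].has_baseline]
    non_baseline = [s for s in manifest.subjects if s not in set(baseline)]
    if len(baseline) < k:
        raise ValueError(f"only {len(baseline)} baseline subjects for k={k} folds")
    order = list(baseline)
    rng.shuffle(order)
    parts = [list(p) for p in np.array_split(order, k)]
    folds = []
    for f in range(k):
        test = parts[f]
        pool = [s for g, part in enumerate(parts) if g != f for s in part]
        pool += non_baseline
        rng_f = np.random.default_rng(seed + 1000 * (f + 1))
        pool_shuffled = list(pool)
        rng_f.shuffle(pool_shuffled)
        n_val = max(1, round(val_fraction * len(pool_shuffled)))
        val = pool_shuffled[:n_val]
        train = pool_shuffled[n_val:]
        _warn_missing_classes(manifest, train, f)
        folds.append(
            FoldSplit(
                fold=f,
                train_subjects=frozenset(train),
                val_subjects=frozenset(val),
                test_subjects=frozenset(test),
            )
        )
    return folds


def _warn_missing_classes(manifest, train_subjects, fold):
    present = {e.label for e in manifest.scans_of(train_subjects)}
    missing = [c for c in manifest.classes if c not in present]
    if missing:
        warnings.warn(
            f"fold {fold}: class(es) {missing} absent from the training set",
            stacklevel=3,
        )


def compute_metrics(
    predictions,
    labels,
    class_names,
    *,
    scan_ids=None,
    subject_ids=None,
    fold_of_scan=None,
    task: str = "",
    variant: str = "",
    seed: int = 0,
    config_fingerprint: dict | None = None,
) -> EvalReport:
    """Assemble an :class:`EvalReport` from per-scan predictions."""
    predictions = np.asarray(predictions, int)
    labels = np.asarray(labels, int)
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    n = len(predictions)
    return EvalReport(
        task=task or "/".join(class_names),
        variant=variant,
        classes=list(class_names),
        scan_ids=list(scan_ids) if scan_ids is not None else [str(i) for i in range(n)],
        subject_ids=list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)],
        true_labels=labels,
        predicted_labels=predictions,
        fold_of_scan=np.asarray(fold_of_scan if fold_of_scan is not None else np.zeros(n), int),
        seed=seed,
        config_fingerprint=config_fingerprint or {},
    )


# ---------------------------------------------------------------------------
# comparison variants
# ---------------------------------------------------------------------------

def _static_features(variant: str, rec: BoldRecording) -> np.ndarray:
    if variant == "ROIs+SVM":
        return normalize_series(rec.signal).ravel()
    if variant == "sFC+SVM":
        return vectorize_upper(pearson_matrix(normalize_series(rec.signal)))
    raise ValueError(f"unknown SVM variant {variant!r}")


def run_variant(
    name: str,
    manifest: CohortManifest,
    recordings: list[BoldRecording],
    config: PipelineConfig | None = None,
    *,
    seed: int = 0,
    task_classes=None,
    k: int = 5,
    folds: list[FoldSplit] | None = None,
    _shared: dict | None = None,
) -> EvalReport:
    """Run one named pipeline under subject-independent k-fold CV.

    ``task_classes`` restricts the manifest to a binary (or any) sub-task
    before splitting. All variants run under the same folds for a given
    (manifest, k, seed).
    """
    if name not in ALL_VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {ALL_VARIANTS}")
    config = config or PipelineConfig()
    if task_classes is not None:
        manifest = manifest.subset_by_classes(task_classes)
        wanted = {e.scan_id for e in manifest.entries}
        recordings = [r for r in recordings if r.scan_id in wanted]
    if folds is None:
        folds = make_subject_folds(manifest, k=k, val_fraction=config.val_fraction,
                                   seed=seed)
    ids = manifest.label_ids
    entry_of = {e.scan_id: e for e in manifest.entries}
    rec_of = {r.scan_id: r for r in recordings}

    scan_ids, subject_ids, y_true, y_pred, fold_ids = [], [], [], [], []
    fingerprint: dict = {"variant": name, "k": k}
    neural_model = None
    if name not in SVM_VARIANTS:
        from .model import LSRNet as _LSRNet

        neural_model = _LSRNet(manifest, recordings, config)
        if _shared is not None:
            neural_model._dfc_cache = _shared.setdefault("dfc", {})
    for split in folds:
        test_entries = manifest.scans_of(sorted(split.test_subjects))
        if not test_entries:
            continue
        if name in SVM_VARIANTS:
            train_entries = manifest.scans_of(
                sorted(split.train_subjects | split.val_subjects)
            )
            x_train = np.stack(
                [_static_features(name, rec_of[e.scan_id]) for e in train_entries]
            )
            y_train = np.array([ids[e.label] for e in train_entries])
            x_test = np.stack(
                [_static_features(name, rec_of[e.scan_id]) for e in test_entries]
            )
            scaler = StandardScaler().fit(x_train)
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(scaler.transform(x_train), y_train)
            preds = clf.predict(scaler.transform(x_test))
        else:
            key = (split.fold, name)
            result = neural_model.fit(
                train_subjects=sorted(split.train_subjects),
                val_subjects=sorted(split.val_subjects),
                seed=seed + split.fold,
                variant=name,
            )
            if _shared is not None and result.encoder is not None:
                _shared.setdefault("stage1_digest", {})[key] = result.encoder.digest()
            preds = [result.predict_scan_id(e.scan_id)[0] for e in test_entries]
            fingerprint.update(result.stage2.config_fingerprint())
        for e, p in zip(test_entries, preds):
            scan_ids.append(e.scan_id)
            subject_ids.append(e.subject_id)
            y_true.append(ids[e.label])
            y_pred.append(int(p))
            fold_ids.append(split.fold)
    return compute_metrics(
        y_pred,
        y_true,
        manifest.classes,
        scan_ids=scan_ids,
        subject_ids=subject_ids,
        fold_of_scan=fold_ids,
        task="/".join(manifest.classes),
        variant=name,
        seed=seed,
        config_fingerprint=fingerprint,
    )


def ablate(
    manifest: CohortManifest,
    recordings: list[BoldRecording],
    config: PipelineConfig | None = None,
    *,
    variants=ALL_VARIANTS,
    seed: int = 0,
    task_classes=None,
    k: int = 5,
) -> dict[str, EvalReport]:
    """Run several variants under identical folds; returns name -> report."""
    shared: dict = {}
    return {
        v: run_variant(
            v, manifest, recordings, config,
            seed=seed, task_classes=task_classes, k=k, _shared=shared,
        )
        for v in variants
    }


def permute_subject_labels(manifest: CohortManifest, seed: int = 0) -> CohortManifest:
    """Null-model control: permute class labels across subjects.

    Every scan keeps its subject, but the subject-to-class assignment is a
    random permutation, destroying any real class signal while preserving the
    class balance and the scans-per-subject structure.
    """
    import dataclasses

    rng = np.random.default_rng(seed)
    subjects = manifest.subjects
    labels = [manifest.subject_label(s) for s in subjects]
    perm = rng.permutation(len(subjects))
    new_label = {s: labels[p] for s, p in zip(subjects, perm)}
    entries = [dataclasses.replace(e, label=new_label[e.subject_id])
               for e in manifest.entries]
    return CohortManifest(entries=entries, classes=list(manifest.classes))


def class_mean_latent(
    latents: list[LatentSequence] | list[np.ndarray],
    labels,
    class_names=None,
) -> dict:
    """Per-class elementwise mean of the M x H latent matrices.

    The result is heatmap-ready: rows are windows, columns latent features.
    Raises if a requested class has no scans.
    """
    mats = [l.codes if isinstance(l, LatentSequence) else np.asarray(l, float)
            for l in latents]
    labels = np.asarray(labels)
    if len(mats) != len(labels):
        raise ValueError("latents and labels differ in length")
    keys = class_names if class_names is not None else sorted(set(labels.tolist()))
    out = {}
    for c, key in enumerate(keys):
        want = c if class_names is not None else key
        sel = [m for m, l in zip(mats, labels) if l == want]
        if not sel:
            raise ValueError(f"no scans for class {key!r}")
        out[key] = np.mean(np.stack(sel), axis=0)
    return out
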