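"""Synthetic multi-subject, multi-scan BOLD cohorts.

Real resting-state cohorts of this kind are access-restricted, so the
package ships a generator that reproduces the statistical features the
pipeline depends on:

* class-specific ROI correlation structure sharing a common backbone, with
  perturbation magnitude growing along the class ordering (mimicking
  progressive disease stages);
* within-scan temporal state switching (geometric dwell times), so windowed
  correlations genuinely vary over time — the premise of dynamic FC;
* per-subject random effects, so scans of one subject are more alike than
  scans of different subjects and subject-independent splits are genuinely
  harder than scan-level splits;
* multiple scans per subject and an optional fraction of subjects without a
  baseline scan (those are routed permanently into training by the
  evaluation protocol).

The generator targets correlation structure only; it does not model
hemodynamics or physiological noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

from .bold_io import BoldRecording, CohortManifest, ManifestEntry, write_manifest, write_recording

__all__ = ["ClassConnectivitySpec", "default_spec", "generate_cohort", "write_cohort"]


class GenerationError(RuntimeError):
    pass


@dataclass
class ClassConnectivitySpec:
    """Recipe for class-specific, time-varying ROI correlation structure.

    ``backbone`` is the symmetric positive-definite correlation target shared
    by all classes; ``perturbed_edges[c]`` lists (i, j, delta) offsets applied
    for class c. ``n_states`` latent temporal states per scan switch with
    geometric dwell times of mean ``state_dwell`` timepoints.
    """

    backbone: np.ndarray
    perturbed_edges: list[list[tuple[int, int, float]]]
    n_states: int = 2
    state_dwell: float = 20.0
    noise_sd: float = 0.2
    subject_sd: float = 0.05
    state_sd: float = 0.15  # scale of state-specific correlation offsets
    class_names: list[str] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.backbone.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.perturbed_edges)

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        n = self.backbone.shape[0]
        if self.backbone.shape != (n, n):
            raise ValueError("backbone must be square")
        if not np.allclose(self.backbone, self.backbone.T):
            raise ValueError("backbone must be symmetric")
        if not np.allclose(np.diag(self.backbone), 1.0):
            raise ValueError("backbone must have unit diagonal")
        if np.linalg.eigvalsh(self.backbone).min() <= 0:
            raise ValueError("backbone must be positive definite")
        if not self.class_names:
            self.class_names = [f"class{c}" for c in range(self.n_classes)]

    def class_matrix(self, c: int) -> np.ndarray:
        """The class-c correlation matrix: backbone + offsets, repaired to a
        valid correlation matrix."""
        m = _apply_edges(self.backbone, self.perturbed_edges[c])
        return _repair(m, f"class {c}")


def _apply_edges(matrix: np.ndarray, edges) -> np.ndarray:
    out = matrix.copy()
    for i, j, delta in edges:
        v = np.clip(out[i, j] + delta, -0.99, 0.99)
        out[i, j] = out[j, i] = v
    return out


def _repair(matrix: np.ndarray, what: str) -> np.ndarray:
    """Project onto the nearest correlation matrix and verify PD-ness."""
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 1.0)
    if np.linalg.eigvalsh(matrix).min() > 1e-8:
        return matrix
    with warnings.catch_warnings():
        # the projection is good enough for sampling even when the
        # alternating scheme stops at its iteration cap
        warnings.simplefilter("ignore")
        fixed = corr_nearest(matrix, threshold=1e-6, n_fact=200)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    w = np.linalg.eigvalsh(fixed)
    if w.min() <= 0:
        # corr_nearest guarantees eigenvalues >= threshold; fall back to a
        # small ridge if numerics leave a zero mode.
        fixed = 0.99 * fixed + 0.01 * np.eye(fixed.shape[0])
        if np.linalg.eigvalsh(fixed).min() <= 0:
            raise GenerationError(f"{what}: matrix not positive definite after repair")
    return fixed


def default_spec(
    n_rois: int,
    n_classes: int,
    *,
    delta: float = 0.3,
    n_perturbed: int = 10,
    n_states: int = 2,
    noise_sd: float = 0.2,
    subject_sd: float = 0.05,
    class_names: list[str] | None = None,
) -> ClassConnectivitySpec:
    """A banded-backbone spec with perturbation magnitude increasing by class.

    Class 0 is the backbone itself; class c shifts ``n_perturbed`` fixed
    off-band edges by ``c * delta / (n_classes - 1)`` (downward, emulating
    connectivity loss as disease stage advances), so the perturbation L1 norm
    grows strictly with the class index.
    """
    if n_rois < 4:
        raise ValueError("need at least 4 ROIs")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    idx = np.arange(n_rois)
    backbone = 0.45 ** np.abs(idx[:, None] - idx[None, :])  # AR(1) Toeplitz, PD
    # fixed, well-spread set of off-band edges to perturb
    edges = []
    for k in range(n_perturbed):
        i = (3 * k) % (n_rois - 3)
        j = i + 3 + (k % 3)
        if j >= n_rois:
            j = n_rois - 1
        if i != j:
            edges.append((i, j))
    edges = list(dict.fromkeys(edges))[:n_perturbed]
    per_class = []
    for c in range(n_classes):
        mag = delta * c / (n_classes - 1)
        per_class.append([(i, j, -mag) for (i, j) in edges] if c else [])
    names = class_names or (["NC", "eMCI", "lMCI", "AD"][:n_classes]
                            if n_classes <= 4 else None)
    spec = ClassConnectivitySpec(
        backbone=backbone,
        perturbed_edges=per_class,
        n_states=n_states,
        noise_sd=noise_sd,
        subject_sd=subject_sd,
        class_names=names or [f"class{c}" for c in range(n_classes)],
    )
    for c in range(n_classes):
        spec.class_matrix(c)  # validate early
    return spec


def _state_matrices(base: np.ndarray, spec: ClassConnectivitySpec,
                    rng: np.random.Generator, what: str) -> list[np.ndarray]:
    """State 0 is the base matrix; further states add random edge offsets."""
    mats = [base]
    n = base.shape[0]
    iu = np.triu_indices(n, k=1)
    n_edges = len(iu[0])
    for s in range(1, spec.n_states):
        pick = rng.choice(n_edges, size=max(1, n_edges // 4), replace=False)
        offsets = rng.normal(0.0, spec.state_sd, size=pick.size)
        m = base.copy()
        for p, d in zip(pick, offsets):
            i, j = iu[0][p], iu[1][p]
            v = np.clip(m[i, j] + d, -0.99, 0.99)
            m[i, j] = m[j, i] = v
        mats.append(_repair(m, f"{what} state {s}"))
    return mats


def _sample_state_path(t: int, n_states: int, dwell: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Hidden state path with geometric dwell times (memoryless switching)."""
    if n_states == 1:
        return np.zeros(t, dtype=int)
    p_switch = 1.0 / max(dwell, 1.0)
    path = np.empty(t, dtype=int)
    state = int(rng.integers(n_states))
    for i in range(t):
        path[i] = state
        if rng.random() < p_switch:
            others = [s for s in range(n_states) if s != state]
            state = int(others[rng.integers(len(others))])
    return path


def generate_cohort(
    n_subjects_per_class: int,
    scans_per_subject: int,
    n_rois: int,
    n_timepoints: int,
    spec: ClassConnectivitySpec | None = None,
    seed: int = 0,
    *,
    baseline_fraction: float = 1.0,
) -> tuple[CohortManifest, list[BoldRecording]]:
    """Draw a full synthetic cohort, deterministic given ``seed``.

    Each scan samples a hidden state path, then draws timepoints from a
    zero-mean multivariate normal with the state's class- and
    subject-adjusted correlation matrix, plus independent observation noise.
    Scan paths in the manifest are relative (``scans/<scan_id>.tsv``) so the
    cohort can be written to disk with :func:`write_cohort`.
    """
    if spec is None:
        spec = default_spec(n_rois, 2)
    if spec.n_rois != n_rois:
        raise ValueError(f"spec is for {spec.n_rois} ROIs, asked for {n_rois}")
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []
    recordings: list[BoldRecording] = []
    class_mats = [spec.class_matrix(c) for c in range(spec.n_classes)]
    for c, cname in enumerate(spec.class_names):
        for s in range(n_subjects_per_class):
            subject_id = f"sub-{cname}-{s:03d}"
            has_baseline = rng.random() < baseline_fraction
            # subject random effect: shared offset on the perturbed edges
            # (or a small set of backbone edges for the unperturbed class)
            subj_edges = spec.perturbed_edges[c] or spec.perturbed_edges[-1]
            subj_offsets = [
                (i, j, float(rng.normal(0.0, spec.subject_sd)))
                for (i, j, _d) in subj_edges
            ]
            subj_base = _repair(
                _apply_edges(class_mats[c], subj_offsets), f"subject {subject_id}"
            )
            states = _state_matrices(subj_base, spec, rng, f"subject {subject_id}")
            chols = [np.linalg.cholesky(m) for m in states]
            for k in range(scans_per_subject):
                scan_id = f"{subject_id}_scan{k:02d}"
                path = _sample_state_path(
                    n_timepoints, spec.n_states, spec.state_dwell, rng
                )
                z = rng.standard_normal((n_timepoints, n_rois))
                signal = np.empty((n_rois, n_timepoints))
                for st in range(len(states)):
                    cols = np.where(path == st)[0]
                    if cols.size:
                        signal[:, cols] = chols[st] @ z[cols].T
                if spec.noise_sd > 0:
                    signal = signal + rng.normal(
                        0.0, spec.noise_sd, size=signal.shape
                    )
                entries.append(
                    ManifestEntry(
                        subject_id=subject_id,
                        scan_id=scan_id,
                        path=f"scans/{scan_id}.tsv",
                        label=cname,
                        has_baseline=has_baseline,
                    )
                )
                recordings.append(
                    BoldRecording(subject_id, scan_id, signal, label=c)
                )
    manifest = CohortManifest(entries=entries, classes=list(spec.class_names))
    return manifest, recordings


def write_cohort(out_dir: str | Path, manifest: CohortManifest,
                 recordings: list[BoldRecording]) -> Path:
    """Write per-scan TSV files plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "scans").mkdir(parents=True, exist_ok=True)
    by_id = {e.scan_id: e for e in manifest.entries}
    for rec in recordings:
        write_recording(out_dir / by_id[rec.scan_id].path, rec.signal)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest_path, manifest)
    return manifest_path
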