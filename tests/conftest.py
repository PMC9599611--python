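import numpy as np
import pytest

from lsrnet import (
    BoldRecording,
    CohortManifest,
    ManifestEntry,
    default_spec,
    generate_cohort,
    small_cohort_config,
)


@pytest.fixture(scope="session")
def tiny_config():
    """Small-cohort config with short training, for fast pipeline tests."""
    return small_cohort_config(
        n_rois=10, seed=0, ae_epochs=8, stage2_epochs=12,
        encoder_dims=(32, 16, 8), n_kernels=8, lstm_hidden=8, fusion_hidden=8,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects/class, 2 classes, 2 scans each, 10 ROIs, 70 timepoints."""
    spec = default_spec(10, 2, delta=0.6, n_perturbed=6)
    return generate_cohort(4, 2, 10, 70, spec, seed=11)


@pytest.fixture(scope="session")
def separated_cohort():
    """Strongly separated 2-class cohort (sharp connectivity perturbation)."""
    spec = default_spec(20, 2, delta=0.6)
    return generate_cohort(10, 2, 20, 137, spec, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def manifest_from_table(rows, classes=None):
    """rows: (subject, scan, label, has_baseline) tuples -> CohortManifest."""
    entries = [
        ManifestEntry(s, sc, f"scans/{sc}.tsv", lab, bool(b))
        for (s, sc, lab, b) in rows
    ]
    return CohortManifest(entries=entries, classes=classes or [])


def random_recording(rng, n=5, t=40, subject="subA", scan="scan0", label=0):
    return BoldRecording(subject, scan, rng.standard_normal((n, t)), label)
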