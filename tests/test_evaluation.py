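import numpy as np
import pytest

from lsrnet import (
    class_mean_latent,
    compute_metrics,
    make_subject_folds,
    permute_subject_labels,
)
from lsrnet.autoencoder import LatentSequence

from conftest import manifest_from_table


def simple_manifest(n_baseline, n_non_baseline=0, classes=("NC", "AD"),
                    scans_per_subject=1):
    rows = []
    for i in range(n_baseline + n_non_baseline):
        sub = f"sub{i:03d}"
        label = classes[i % len(classes)]
        baseline = i < n_baseline
        for k in range(scans_per_subject):
            rows.append((sub, f"{sub}_s{k}", label, baseline))
    return manifest_from_table(rows, classes=list(classes))


class TestMakeSubjectFolds:
    def test_ten_subjects_five_folds(self):
        man = simple_manifest(10)
        folds = make_subject_folds(man, k=5, seed=0)
        test_sets = [f.test_subjects for f in folds]
        assert all(len(t) == 2 for t in test_sets)
        union = set().union(*test_sets)
        assert union == set(man.subjects)
        assert sum(len(t) for t in test_sets) == 10

    def test_cohort_scale_partition_147(self):
        # 147 baseline + 27 non-baseline subjects: test folds of 29 or 30
        man = simple_manifest(147, 27)
        folds = make_subject_folds(man, k=5, seed=1)
        sizes = [len(f.test_subjects) for f in folds]
        assert set(sizes) <= {29, 30}
        assert sum(sizes) == 147

    def test_non_baseline_never_in_test(self):
        man = simple_manifest(20, 8)
        non_baseline = {s for s in man.subjects
                        if not man.scans_of([s])[0].has_baseline}
        for f in make_subject_folds(man, k=4, seed=2):
            assert not (f.test_subjects & non_baseline)

    def test_no_leakage_brute_force(self):
        man = simple_manifest(23, 5, scans_per_subject=2)
        for f in make_subject_folds(man, k=5, seed=3):
            assert not f.train_subjects & f.val_subjects
            assert not f.train_subjects & f.test_subjects
            assert not f.val_subjects & f.test_subjects

    def test_validation_fraction(self):
        man = simple_manifest(40)
        folds = make_subject_folds(man, k=5, val_fraction=0.15, seed=0)
        for f in folds:
            n_train_pool = len(f.train_subjects) + len(f.val_subjects)
            assert len(f.val_subjects) == max(1, round(0.15 * n_train_pool))

    def test_deterministic_given_seed(self):
        man = simple_manifest(15)
        a = make_subject_folds(man, k=3, seed=9)
        b = make_subject_folds(man, k=3, seed=9)
        assert a == b
        c = make_subject_folds(man, k=3, seed=10)
        assert a != c

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_subject_folds(simple_manifest(10), k=1)

    def test_missing_class_warns(self):
        rows = [(f"s{i}", f"s{i}_0", "NC", True) for i in range(6)]
        rows.append(("s9", "s9_0", "AD", True))
        man = manifest_from_table(rows, classes=["NC", "AD"])
        with pytest.warns(UserWarning, match="absent"):
            make_subject_folds(man, k=3, seed=0)


class TestComputeMetrics:
    def test_all_correct(self):
        rep = compute_metrics([0, 1, 0], [0, 1, 0], ["NC", "AD"])
        assert rep.pooled_accuracy == 100.0
        assert all(v == 100.0 for v in rep.per_class_accuracy.values())

    def test_degenerate_predictor(self):
        rep = compute_metrics([0, 0, 0, 0], [0, 0, 1, 1], ["NC", "AD"])
        assert rep.pooled_accuracy == 50.0
        assert rep.per_class_accuracy == {"ACC_NC": 100.0, "ACC_AD": 0.0}

    def test_hand_counted_confusion(self):
        rep = compute_metrics([0, 1, 1, 1, 0], [0, 0, 1, 1, 1], ["a", "b"])
        assert rep.pooled_accuracy == pytest.approx(60.0)
        assert rep.per_class_accuracy["ACC_a"] == pytest.approx(50.0)
        assert rep.per_class_accuracy["ACC_b"] == pytest.approx(100 * 2 / 3)

    def test_pooled_equals_weighted_mean_of_per_class(self, rng):
        y = rng.integers(0, 3, 60)
        p = rng.integers(0, 3, 60)
        rep = compute_metrics(p, y, ["x", "y", "z"])
        weighted = sum(
            rep.n_per_class[c] * rep.per_class_accuracy[f"ACC_{c}"]
            for c in ["x", "y", "z"]
        ) / 60
        assert rep.pooled_accuracy == pytest.approx(weighted)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], ["NC"])

    def test_summary_mentions_task_and_acc(self):
        rep = compute_metrics([0, 1], [0, 1], ["NC", "AD"], variant="LSRNet")
        s = rep.summary()
        assert "LSRNet" in s and "100.0%" in s


class TestClassMeanLatent:
    def test_single_scan_class_is_identity(self, rng):
        m = rng.standard_normal((4, 3))
        out = class_mean_latent([LatentSequence("a", m)], [0], ["only"])
        np.testing.assert_array_equal(out["only"], m)

    def test_two_scan_average_by_hand(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[3.0, 6.0], [5.0, 0.0]])
        out = class_mean_latent([a, b], [0, 0], ["c"])
        np.testing.assert_array_equal(out["c"], [[2.0, 4.0], [4.0, 2.0]])

    def test_shape_is_m_by_h_per_class(self, rng):
        lat = [rng.standard_normal((5, 4)) for _ in range(6)]
        out = class_mean_latent(lat, [0, 0, 1, 1, 2, 2], ["a", "b", "c"])
        assert all(v.shape == (5, 4) for v in out.values())

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError, match="b"):
            class_mean_latent([rng.standard_normal((2, 2))], [0], ["a", "b"])


class TestPermuteSubjectLabels:
    def test_preserves_balance_and_structure(self):
        man = simple_manifest(12, scans_per_subject=2)
        perm = permute_subject_labels(man, seed=1)
        assert sorted(e.label for e in perm.entries) == sorted(
            e.label for e in man.entries
        )
        for s in perm.subjects:
            labels = {e.label for e in perm.scans_of([s])}
            assert len(labels) == 1

    def test_actually_permutes(self):
        man = simple_manifest(20)
        perm = permute_subject_labels(man, seed=1)
        assert any(
            a.label != b.label for a, b in zip(man.entries, perm.entries)
        )
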