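import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from lsrnet import (
    build_dfc,
    devectorize_upper,
    normalize_series,
    pearson_matrix,
    segment_windows,
    small_cohort_config,
    vectorize_upper,
)
from lsrnet.bold_io import BoldRecording
from lsrnet.config import PipelineConfig


def brute_force_pearson(window):
    """Direct per-pair correlation: E[(x-mu_x)(y-mu_y)] / (sd_x sd_y)."""
    n, w = window.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            xi, xj = window[i], window[j]
            num = np.mean((xi - xi.mean()) * (xj - xj.mean()))
            out[i, j] = num / (xi.std() * xj.std())
    return out


def brute_force_window_starts(t, w, s):
    return [k for k in range(t) if k % s == 0 and k + w <= t]


class TestNormalize:
    def test_small_row_oracle(self):
        # (x - mean) / population-sd of [1,2,3]: sd = sqrt(2/3)
        out = normalize_series(np.array([[1.0, 2.0, 3.0]]))
        expected = np.array([-1.2247448713915890, 0.0, 1.2247448713915890])
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_rows_zero_mean_unit_sd(self, rng):
        out = normalize_series(rng.standard_normal((7, 50)) * 5 + 3)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        x = normalize_series(rng.standard_normal((4, 30)))
        np.testing.assert_allclose(normalize_series(x), x, atol=1e-12)

    def test_constant_row_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_series(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]]))
        np.testing.assert_array_equal(out[0], 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_series(np.empty((0, 0)))


class TestSegmentWindows:
    @pytest.mark.parametrize(
        "t,w,s,expected_m",
        [(137, 30, 2, 54), (30, 30, 2, 1), (36, 30, 2, 4)],
    )
    def test_window_count(self, rng, t, w, s, expected_m):
        windows = segment_windows(rng.standard_normal((3, t)), w, s)
        assert len(windows) == expected_m

    def test_single_window_is_input(self, rng):
        x = rng.standard_normal((3, 30))
        (win,) = segment_windows(x, 30, 2)
        np.testing.assert_array_equal(win, x)

    def test_starts_enumerated_brute_force(self, rng):
        x = rng.standard_normal((2, 36))
        wins = segment_windows(x, 30, 2)
        starts = brute_force_window_starts(36, 30, 2)
        assert starts == [0, 2, 4, 6]
        for k, st0 in enumerate(starts):
            np.testing.assert_array_equal(wins[k], x[:, st0 : st0 + 30])

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            segment_windows(rng.standard_normal((3, 20)), 30, 2)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        t=st.integers(2, 200),
        w=st.integers(2, 200),
        s=st.integers(1, 5),
    )
    def test_count_matches_brute_force_enumeration(self, t, w, s):
        assume(w <= t)
        x = np.zeros((2, t))
        assert len(segment_windows(x, w, s)) == len(brute_force_window_starts(t, w, s))


class TestPearsonMatrix:
    def test_identical_rows_correlate_one(self, rng):
        row = rng.standard_normal(20)
        r = pearson_matrix(np.vstack([row, row]))
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_row_correlates_minus_one(self, rng):
        row = rng.standard_normal(20)
        r = pearson_matrix(np.vstack([row, -row]))
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        window = rng.standard_normal((5, 30))
        np.testing.assert_allclose(
            pearson_matrix(window), brute_force_pearson(window), atol=1e-10
        )

    def test_unit_diagonal_bounded_symmetric(self, rng):
        r = pearson_matrix(rng.standard_normal((8, 15)))
        np.testing.assert_array_equal(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1.0)
        np.testing.assert_allclose(r, r.T, atol=1e-12)

    def test_zero_variance_row_zeroed_with_warning(self, rng):
        window = rng.standard_normal((3, 10))
        window[1] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            r = pearson_matrix(window)
        assert r[1, 0] == r[1, 2] == 0.0
        assert r[1, 1] == 1.0

    def test_too_narrow_rejected(self, rng):
        with pytest.raises(ValueError):
            pearson_matrix(rng.standard_normal((3, 1)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_invariant_to_positive_affine_rescaling(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        window = rng.standard_normal((4, 12))
        scaled = window.copy()
        scaled[2] = scale * scaled[2] + shift
        np.testing.assert_allclose(
            pearson_matrix(scaled), pearson_matrix(window), atol=1e-12
        )


class TestVectorizeUpper:
    def test_published_scale_length(self):
        a = np.eye(116)
        assert vectorize_upper(a).shape == (6670,)  # 116*115/2

    def test_smallest_case(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(vectorize_upper(a), [0.3])

    def test_row_major_order(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.1
        a[0, 2] = a[2, 0] = 0.2
        a[1, 2] = a[2, 1] = 0.3
        np.testing.assert_array_equal(vectorize_upper(a), [0.1, 0.2, 0.3])

    def test_round_trip_exact(self, rng):
        a = rng.uniform(-1, 1, size=(9, 9))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        back = devectorize_upper(vectorize_upper(a), 9)
        np.testing.assert_array_equal(back, a)

    def test_asymmetry_rejected(self, rng):
        a = rng.standard_normal((4, 4))
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_upper(a)


class TestBuildDfc:
    def test_test_scale_shapes(self, rng):
        rec = BoldRecording("s", "s0", rng.standard_normal((20, 137)), 0)
        seq = build_dfc(rec, small_cohort_config())
        assert seq.n_windows == 54
        assert seq.dim == 190  # 20*19/2
        assert seq.window_starts[:3] == [0, 2, 4]

    def test_published_scale_shapes(self, rng):
        rec = BoldRecording("s", "s0", rng.standard_normal((116, 137)), 0)
        seq = build_dfc(rec, PipelineConfig())
        assert seq.n_windows == 54
        assert seq.dim == 6670

    def test_vectors_match_matrices(self, rng):
        rec = BoldRecording("s", "s0", rng.standard_normal((6, 50)), 0)
        seq = build_dfc(rec, small_cohort_config(n_rois=6))
        for k in range(seq.n_windows):
            np.testing.assert_array_equal(
                seq.vectors[k], vectorize_upper(seq.matrices[k])
            )

    def test_roi_permutation_equivariance(self, rng):
        sig = rng.standard_normal((6, 50))
        perm = np.array([3, 1, 5, 0, 2, 4])
        cfg = small_cohort_config(n_rois=6)
        a = build_dfc(BoldRecording("s", "a", sig, 0), cfg)
        b = build_dfc(BoldRecording("s", "b", sig[perm], 0), cfg)
        for k in range(a.n_windows):
            np.testing.assert_allclose(
                b.matrices[k], a.matrices[k][np.ix_(perm, perm)], atol=1e-12
            )
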