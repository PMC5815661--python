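"""Tercile contrasts, cluster permutation, correlation analyses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

import lsaccum as L
from lsaccum.stats import (
    binomial_sign_test,
    cluster_permutation,
    compare_terciles,
    tercile_split,
    wait_w_correlation,
)


class TestTercileSplit:
    def test_exact_terciles(self):
        waits = np.arange(1, 10)
        short, long = tercile_split(waits)
        assert sorted(waits[short]) == [1, 2, 3]
        assert sorted(waits[long]) == [7, 8, 9]

    def test_all_equal_degenerate(self):
        with pytest.raises(ValueError):
            tercile_split(np.ones(9))

    def test_boundary_ties_go_inner(self):
        waits = np.array([1, 2, 2, 2, 5, 6, 7, 8, 9])
        short, long = tercile_split(waits)
        assert sorted(waits[short]) == [1, 2, 2, 2]
        assert sorted(waits[long]) == [7, 8, 9]
        assert not set(short) & set(long)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            tercile_split([1.0, 2.0])


class TestBinomialSignTest:
    def test_thirteen_of_fourteen(self):
        assert binomial_sign_test(13, 14) == pytest.approx(15 / 16384)

    def test_all_fourteen(self):
        assert binomial_sign_test(14, 14) == pytest.approx(1 / 16384)

    def test_half(self):
        # exact tail: sum_{k=7}^{14} C(14,k) / 2^14 = 9908/16384
        assert binomial_sign_test(7, 14) == pytest.approx(9908 / 16384)

    def test_invalid(self):
        with pytest.raises(ValueError):
            binomial_sign_test(15, 14)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(1, 30), k=st.integers(0, 30))
    def test_valid_probability_and_monotone(self, n, k):
        if k > n:
            return
        p = binomial_sign_test(k, n)
        assert 0.0 <= p <= 1.0
        if k > 0:
            assert p <= binomial_sign_test(k - 1, n)


class TestCompareTerciles:
    def test_identical_waveforms_no_signal(self):
        rng = np.random.default_rng(0)
        waits = rng.uniform(1, 10, 30)
        epochs = np.tile(np.sin(np.linspace(0, 3, 50)), (30, 1))
        times = np.linspace(-2, 0.5, 50)
        comp = compare_terciles(epochs, waits, times, (-1.5, -0.5))
        assert np.nanmin(comp.pointwise_p) > 0.9
        assert comp.window_p > 0.9

    def test_order_and_offset_invariance(self):
        rng = np.random.default_rng(1)
        waits = rng.uniform(1, 10, 40)
        epochs = rng.standard_normal((40, 60)) + waits[:, None] * 0.1
        times = np.linspace(-2, 0.5, 60)
        ref = compare_terciles(epochs, waits, times, (-1.5, -0.5))
        perm = rng.permutation(40)
        shuffled = compare_terciles(
            epochs[perm] + 5.0, waits[perm], times, (-1.5, -0.5)
        )
        assert shuffled.window_p == pytest.approx(ref.window_p)
        assert (shuffled.window_long - shuffled.window_short) == pytest.approx(
            ref.window_long - ref.window_short
        )

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            compare_terciles(
                np.zeros((9, 10)),
                np.arange(9),
                np.linspace(0, 1, 10),
                (5.0, 6.0),
            )

    def test_model_reversal_at_reference_parameters(self, reference_batch):
        """Long-wait trials: lower input-locked but higher output-locked
        early amplitude (the model's Prediction-1 signature)."""
        batch = reference_batch
        times = batch.epoch_times()
        window = (-1500, -500)
        comp_in = compare_terciles(
            batch.input_epochs, batch.crossing_times, times, window
        )
        comp_out = compare_terciles(
            batch.output_epochs, batch.crossing_times, times, window
        )
        assert comp_in.window_long < comp_in.window_short
        assert comp_out.window_long > comp_out.window_short


class TestClusterPermutation:
    def test_identical_groups_no_clusters(self):
        a = np.random.default_rng(2).standard_normal((10, 80))
        assert cluster_permutation(a, a.copy(), n_perm=200) == []

    def test_injected_offset_found(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((14, 120))
        b = rng.standard_normal((14, 120))
        a[:, 40:60] += 2.0
        clusters = cluster_permutation(a, b, n_perm=500, seed=1)
        sig = [c for c in clusters if c.p_corrected < 0.05]
        assert sig
        best = min(sig, key=lambda c: c.p_corrected)
        assert best.start < 60 and best.end >= 40  # overlaps the injected window

    def test_small_n_perm_warns(self):
        a = np.random.default_rng(4).standard_normal((8, 30))
        with pytest.warns(RuntimeWarning):
            cluster_permutation(a, a + 0.1, n_perm=50)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((4, 5)), np.zeros((4, 6)))


class TestWaitWCorrelation:
    def test_perfect_linear(self):
        waits = np.linspace(1, 10, 30)
        w = -0.05 * waits + 0.1
        rep = wait_w_correlation(waits, w)
        assert rep.pooled_r == pytest.approx(-1.0)
        assert rep.pooled_slope == pytest.approx(-0.05)

    def test_zero_variance_subject_excluded(self):
        waits = np.concatenate([np.linspace(1, 5, 10), np.linspace(1, 5, 10)])
        w = np.concatenate([-0.1 * np.linspace(1, 5, 10), np.zeros(10)])
        sid = np.repeat(["a", "b"], 10)
        rep = wait_w_correlation(waits, w, subject_ids=sid)
        assert rep.subjects == ["a"]
        assert rep.excluded_subjects == ["b"]

    def test_null_calibration(self):
        """Independent waits and W: pooled test at nominal level and
        sign-test counts near Binomial(n, 1/2)."""
        rng = np.random.default_rng(7)
        false_pos = 0
        neg_counts = []
        for _ in range(200):
            waits = rng.gamma(2.0, 3.0, 100)
            w = rng.normal(-0.2, 0.1, 100)
            rep = wait_w_correlation(waits, w)
            false_pos += rep.pooled_p < 0.05
            neg_counts.append(rep.pooled_r < 0)
        assert false_pos / 200 < 0.12  # ~5% nominal
        assert 0.35 < np.mean(neg_counts) < 0.65  # fair coin

    def test_model_cohort_reproduces_negative_correlation(self, reference_batch):
        """At beta = 1.4 the model's wait-W correlation is negative."""
        batch = reference_batch
        r, p = sstats.pearsonr(batch.crossing_times, batch.w_delays)
        assert r < 0
        assert p < 0.05
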