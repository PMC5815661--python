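"""Accumulator dynamics: closed forms, crossings, epochs, W delays."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sstats

import lsaccum as L
from lsaccum.accumulator import (
    AccumulatorParams,
    TrialRecord,
    compute_w_delay,
    detect_first_crossing,
    extract_epochs,
    noiseless_crossing_time,
    noiseless_trajectory,
    run_batch,
    simulate_trial,
)


def zero_noise(n=60_000):
    return L.NoiseSeries(np.zeros(n), L.NoiseParams(beta=0, n_samples=n))


class TestClosedForms:
    def test_noiseless_trajectory_matches_exponential(self):
        params = L.reference_params(c=0.0)
        rec = simulate_trial(params, zero_noise())
        t = np.arange(5000) * params.dt
        err = np.max(np.abs(rec.output[:5000] - noiseless_trajectory(params, t)))
        assert err < 1e-3  # O(dt) discretization error
        # asymptote I/k
        assert abs(rec.output[-1] - params.I / params.k) < 1e-4

    def test_noiseless_crossing_time(self):
        params = L.reference_params(c=0.0)
        rec = simulate_trial(params, zero_noise())
        t_star = noiseless_crossing_time(params)
        assert abs(t_star - 2.3347) < 1e-3  # closed form -(1/k) ln(1 - k theta / I)
        assert abs(rec.crossing_idx * params.dt - t_star) < 2 * params.dt

    def test_zero_dynamics_censored(self):
        params = AccumulatorParams(I=0.0, k=0.6, c=0.0, threshold=0.1256)
        rec = simulate_trial(params, zero_noise())
        assert rec.censored
        assert np.all(rec.output == 0)
        with pytest.raises(ValueError):
            extract_epochs(rec)


class TestFirstCrossing:
    @pytest.mark.parametrize(
        "series, level, expected",
        [
            ([0, 0.05, 0.13], 0.1256, 2),
            ([0, 0.05, 0.10], 0.1256, None),
            ([0.2, 0.05, 0.10], 0.1256, 0),
            ([0.1256], 0.1256, 0),  # closed at the threshold
        ],
    )
    def test_examples(self, series, level, expected):
        assert detect_first_crossing(series, level) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detect_first_crossing([], 0.1)

    def test_minimality_in_simulation(self):
        params = L.reference_params()
        noise = L.make_noise(L.reference_noise_params(seed=(11, 0)))
        rec = simulate_trial(params, noise)
        assert rec.crossing_idx is not None
        assert np.all(rec.output[: rec.crossing_idx] < params.threshold)
        assert rec.output[rec.crossing_idx] >= params.threshold


class TestEpochs:
    def test_window_arithmetic(self):
        params = L.reference_params(c=0.0)
        rec = simulate_trial(params, zero_noise())
        ci = rec.crossing_idx
        ep = extract_epochs(rec, pre=2000, post=300)
        assert len(ep.input_epoch) == 2301
        # time index 0 aligned to the crossing sample
        assert ep.times()[2000] == 0
        assert ep.output_epoch[2000] == rec.output[ci]
        assert np.allclose(
            ep.output_epoch, rec.output[ci - 2000 : ci + 301], equal_nan=True
        )

    def test_missing_before_trial_start(self):
        params = L.reference_params(c=0.0)
        rec = simulate_trial(params, zero_noise())
        ci = rec.crossing_idx  # ~2335 < default pre of 5000
        ep = extract_epochs(rec)
        n_missing = 5000 - ci
        assert np.all(np.isnan(ep.output_epoch[:n_missing]))
        assert np.all(np.isfinite(ep.output_epoch[n_missing:]))
        assert ep.missing[:n_missing].all()


class TestWDelay:
    def test_noiseless_two_threshold_delay(self):
        params = L.reference_params(c=0.0)
        rec = simulate_trial(params, zero_noise())
        t_hi = noiseless_crossing_time(params)
        t_lo = noiseless_crossing_time(params, 0.9 * params.threshold)
        assert abs((t_lo - t_hi) - (-0.4448)) < 1e-3
        assert abs(rec.w_delay - (t_lo - t_hi)) < 3 * params.dt
        assert rec.w_delay <= 0

    def test_steeper_drive_shortens_delay(self):
        slow = simulate_trial(L.reference_params(c=0.0), zero_noise())
        fast = simulate_trial(L.reference_params(I=0.12, c=0.0), zero_noise())
        assert abs(fast.w_delay) < abs(slow.w_delay)

    def test_single_step_jump_gives_zero_delay(self):
        params = L.reference_params()
        out = np.array([0.0, 0.05, 0.2])  # jumps from below theta_w above theta
        rec = TrialRecord(
            input=np.zeros(3), output=out, params=params, crossing_idx=2
        )
        assert compute_w_delay(rec) == 0.0

    def test_invalid_w_threshold_rejected(self):
        with pytest.raises(ValueError):
            AccumulatorParams(w_threshold=0.2, threshold=0.1)


class TestBatch:
    def test_reproducible(self):
        kwargs = dict(keep_epochs=False)
        a = run_batch(L.reference_params(), L.reference_noise_params(), 20, 7, **kwargs)
        b = run_batch(L.reference_params(), L.reference_noise_params(), 20, 7, **kwargs)
        assert np.array_equal(a.crossing_times, b.crossing_times)
        assert np.array_equal(a.w_delays, b.w_delays)

    def test_noiseless_batch_is_degenerate(self):
        batch = run_batch(
            L.reference_params(c=0.0), L.reference_noise_params(), 5, 1,
            keep_epochs=False,
        )
        t_star = noiseless_crossing_time(L.reference_params())
        assert np.allclose(batch.crossing_times, batch.crossing_times[0])
        assert abs(batch.crossing_times[0] - t_star) < 0.01

    def test_crossing_times_right_skewed(self, reference_batch):
        waits = reference_batch.crossing_times
        assert sstats.skew(waits) > 0
        assert np.median(waits) < waits.mean()  # mode/median earlier than mean

    def test_all_censored_warns(self):
        params = AccumulatorParams(I=0.0, k=0.6, c=0.0, threshold=0.1, max_samples=500)
        with pytest.warns(RuntimeWarning):
            batch = run_batch(params, L.reference_noise_params(n_samples=500), 3, 0)
        assert len(batch.crossing_times) == 0
        assert batch.n_censored == 3

    def test_sd_grows_with_mean_across_thresholds(self):
        means, sds = [], []
        for theta in (0.08, 0.10, 0.1256, 0.15):
            batch = run_batch(
                L.reference_params(threshold=theta),
                L.reference_noise_params(),
                300,
                master_seed=5,
                keep_epochs=False,
            )
            means.append(batch.crossing_times.mean())
            sds.append(batch.crossing_times.std())
        assert np.all(np.diff(means) > 0)
        assert sstats.spearmanr(means, sds).statistic > 0
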