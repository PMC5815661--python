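"""Synthetic multi-subject datasets with the structure the analyses assume.

Each subject is a leaky stochastic accumulator with pink input noise
(subject-specific exponent drawn around the group value 1.4).  Per
subject, the activation threshold is auto-calibrated by bisection so the
median simulated waiting time matches a configurable behavioral target
(default 7.1 s), and the advance-warning threshold fraction is
calibrated so the mean reported W time matches its target (default
-142 ms) after report noise, clamping and clock quantization.

The "EEG" epochs are the event-locked stochastic input of each trial:
sign-flipped to the negative-going readiness-potential convention,
low-pass filtered and decimated from the 1000 Hz simulation grid to
250 Hz, cropped to a -3.5..+1.0 s window around the crossing, and
corrupted with additive white sensor noise.  Samples that precede the
start of a trial are NaN (missing), as in short-wait empirical trials.
W reports are the model's inter-threshold delays plus Gaussian report
noise, clamped to be non-positive and quantized to a 50 ms clock tick.

The generator deliberately omits volume conduction, ocular artifacts,
and any real preprocessing chain; it emulates the statistical structure
(waiting times, W reports, spectral content, tercile contrasts) needed
to exercise the analysis pipeline end to end.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

from .accumulator import AccumulatorParams, run_batch
from .noise import NoiseParams, make_noise

__all__ = [
    "CohortConfig",
    "SubjectDataset",
    "generate_subject",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
    "concatenate_epochs",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"

_SIM_FS = 1000.0  # simulation rate implied by dt = 0.001
_PRE = 5000  # samples before the crossing kept from each trial
_POST = 1000  # samples after the crossing (covers +1.0 s)


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of the synthetic cohort.

    ``beta_sd`` is chosen so that a 14-subject group reproduces a
    standard error of ~0.14 around the group exponent 1.4
    (0.14 * sqrt(14) ~ 0.52).  ``target_median_wait`` and
    ``target_mean_w`` are the behavioral calibration targets in
    seconds.  ``w_report_noise_sd`` is a stand-in for the (unmodelled)
    trial-to-trial variability of subjective reports; 0.15 s puts the
    pooled wait-W correlation in the weak-effect regime of the
    empirical data rather than the noise-free model's strong one.
    ``amp_scale`` maps model units to microvolt-like display units
    (group-average potential ~ -7 uV at the crossing);
    ``sensor_noise_sd`` (same display units) is kept small relative to
    the in-band signal so the input's spectral exponent remains
    estimable from the short synthetic epochs.
    """

    n_subjects: int = 14
    trials_per_subject: int = 60
    beta_mean: float = 1.4
    beta_sd: float = 0.52
    beta_range: Tuple[float, float] = (0.2, 2.8)
    I: float = 0.1
    k: float = 0.6
    c: float = 0.1
    max_samples: int = 60_000
    fs_out: float = 250.0
    epoch_window: Tuple[float, float] = (-3.5, 1.0)
    amp_scale: float = 1500.0
    sensor_noise_sd: float = 0.45
    w_report_noise_sd: float = 0.15
    clock_tick: float = 0.05
    target_median_wait: float = 7.1
    target_mean_w: float = -0.142
    interruptus_fraction: float = 0.5
    n_calibration_trials: int = 96
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_subject < 3:
            raise ValueError("trials_per_subject must be >= 3")
        n_expected = int(
            round((self.epoch_window[1] - self.epoch_window[0]) * self.fs_out)
        ) + 1
        if n_expected < 2:
            raise ValueError("epoch window and fs_out give an empty epoch")

    @property
    def epoch_samples(self) -> int:
        """Samples per output epoch (1126 for -3.5..1.0 s at 250 Hz)."""
        lo, hi = self.epoch_window
        return int(round((hi - lo) * self.fs_out)) + 1


@dataclass
class SubjectDataset:
    """Synthetic per-subject trials.

    ``epochs`` is (n_trials, n_samples) at ``fs`` Hz on the
    negative-going RP convention; ``times`` the shared epoch time axis
    in seconds relative to the crossing ("button press").
    """

    subject_id: str
    epochs: np.ndarray
    times: np.ndarray
    wait_times: np.ndarray
    w_reports: np.ndarray
    task_labels: np.ndarray
    fs: float
    beta: float
    threshold: float
    w_frac: float
    w_delays: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.wait_times)
        if not (len(self.w_reports) == n == self.epochs.shape[0]):
            raise ValueError("trial-level arrays disagree on trial count")


# ---------------------------------------------------------------------------
# generation


def _calibrate_threshold(
    config: CohortConfig, beta: float, seed_key: Tuple[int, ...]
) -> float:
    """Bisect the activation threshold to hit the target median wait.

    The trajectory of the accumulator does not depend on the threshold,
    so a fixed set of calibration trajectories is simulated once and the
    crossing time of any candidate threshold is read off the running
    maximum of each trajectory.
    """
    params = AccumulatorParams(
        I=config.I, k=config.k, c=config.c, max_samples=config.max_samples
    )
    cummaxes = []
    for i in range(config.n_calibration_trials):
        noise = make_noise(
            NoiseParams(
                beta=beta,
                n_samples=config.max_samples,
                normalization="anchored",
                seed=seed_key + (i,),
            )
        )
        trial_params = dataclasses.replace(params, threshold=1e9)
        # direct integration; threshold plays no role in the dynamics
        from .accumulator import simulate_trial

        rec = simulate_trial(trial_params, noise)
        cummaxes.append(np.maximum.accumulate(rec.output))
    target_idx = config.target_median_wait / params.dt

    def median_crossing(theta: float) -> float:
        idx = [
            np.searchsorted(cm, theta, side="left") for cm in cummaxes
        ]  # == len(cm) when never crossed
        idx = [i if i < config.max_samples else np.inf for i in idx]
        return float(np.median(idx))

    lo, hi = 0.05, float(np.percentile([cm[-1] for cm in cummaxes], 40.0))
    if median_crossing(lo) > target_idx:
        return lo
    if median_crossing(hi) < target_idx:
        return hi
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if median_crossing(mid) < target_idx:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _epoch_w_delays(
    output_epochs: np.ndarray, threshold: float, frac: float, dt: float, pre: int
) -> np.ndarray:
    """W delays (s, <= 0) from output epochs for a candidate threshold
    fraction; the last upward crossing before the main crossing."""
    thw = frac * threshold
    delays = np.empty(len(output_epochs))
    for i, ep in enumerate(output_epochs):
        seg = ep[: pre + 1]
        above = np.where(np.isfinite(seg), seg, -np.inf) >= thw
        prev = np.concatenate(([False], above[:-1]))
        ups = np.nonzero(above & ~prev)[0]
        delays[i] = (ups[-1] - pre) * dt if ups.size else np.nan
    return delays


def _quantize_reports(
    delays: np.ndarray, noise: np.ndarray, tick: float
) -> np.ndarray:
    reports = np.minimum(delays + noise, 0.0)
    return np.round(reports / tick) * tick


def _calibrate_w_frac(
    output_epochs: np.ndarray,
    threshold: float,
    dt: float,
    pre: int,
    report_noise: np.ndarray,
    config: CohortConfig,
) -> float:
    """Bisect the advance-warning fraction to hit the mean-W target."""

    def mean_report(frac: float) -> float:
        delays = _epoch_w_delays(output_epochs, threshold, frac, dt, pre)
        ok = np.isfinite(delays)
        return float(
            np.mean(_quantize_reports(delays[ok], report_noise[ok], config.clock_tick))
        )

    lo, hi = 0.55, 0.995
    if mean_report(hi) < config.target_mean_w:
        return hi
    if mean_report(lo) > config.target_mean_w:
        return lo
    for _ in range(28):
        mid = 0.5 * (lo + hi)
        if mean_report(mid) < config.target_mean_w:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _decimate_epoch(
    values: np.ndarray, offsets_out: np.ndarray, pre: int, q: int, fir: np.ndarray
) -> np.ndarray:
    """Anti-aliased decimation of a NaN-padded epoch.

    ``values`` is indexed by sample offsets ``-pre .. len-pre-1`` around
    the crossing; the finite segment is zero-phase FIR filtered and
    sampled at the requested output offsets (multiples of ``q``).
    """
    finite = np.isfinite(values)
    out = np.full(len(offsets_out), np.nan)
    if not finite.any():
        return out
    f0, f1 = np.argmax(finite), len(values) - np.argmax(finite[::-1]) - 1
    seg = values[f0 : f1 + 1]
    if len(seg) > 3 * len(fir):
        seg = signal.filtfilt(fir, [1.0], seg)
    idx = offsets_out + pre  # positions in the full epoch
    ok = (idx >= f0) & (idx <= f1)
    out[ok] = seg[idx[ok] - f0]
    return out


def generate_subject(config: CohortConfig, subject_index: int) -> SubjectDataset:
    """Generate one subject's trials (see module docstring).

    Trials whose accumulator never crosses threshold are replaced by
    fresh simulations (up to 10x the requested count).
    """
    seed_key = (config.master_seed, subject_index)
    rng = np.random.default_rng(np.random.SeedSequence(seed_key + (901,)))
    beta = float(
        np.clip(
            rng.normal(config.beta_mean, config.beta_sd),
            config.beta_range[0],
            config.beta_range[1],
        )
    )
    threshold = _calibrate_threshold(config, beta, seed_key + (101,))
    acc = AccumulatorParams(
        I=config.I,
        k=config.k,
        c=config.c,
        threshold=threshold,
        max_samples=config.max_samples,
    )
    noise_params = NoiseParams(
        beta=beta, n_samples=config.max_samples, normalization="anchored"
    )
    batch = run_batch(
        acc,
        noise_params,
        config.trials_per_subject,
        master_seed=int(rng.integers(2**31)),
        keep_epochs=True,
        pre=_PRE,
        post=_POST,
        min_crossings=config.trials_per_subject,
        max_attempts_factor=10,
    )
    n = min(config.trials_per_subject, len(batch.crossing_times))
    waits = batch.crossing_times[:n]
    in_eps = batch.input_epochs[:n]
    out_eps = batch.output_epochs[:n]

    report_noise = rng.normal(0.0, config.w_report_noise_sd, n)
    w_frac = _calibrate_w_frac(
        out_eps, threshold, acc.dt, _PRE, report_noise, config
    )
    delays = _epoch_w_delays(out_eps, threshold, w_frac, acc.dt, _PRE)
    w_reports = _quantize_reports(delays, report_noise, config.clock_tick)
    w_reports = np.where(np.isfinite(w_reports), w_reports, 0.0)

    # 1000 Hz -> 250 Hz, cropped to the output window, RP sign convention
    q = int(round(_SIM_FS / config.fs_out))
    lo, hi = config.epoch_window
    offsets_out = (np.round(np.arange(lo, hi + 1e-9, 1.0 / config.fs_out) * _SIM_FS)
                   .astype(int))
    fir = signal.firwin(81, 0.8 * (config.fs_out / 2.0), fs=_SIM_FS)
    epochs = np.empty((n, len(offsets_out)))
    for i in range(n):
        dec = _decimate_epoch(in_eps[i], offsets_out, _PRE, q, fir)
        epochs[i] = -config.amp_scale * dec
    epochs += rng.normal(0.0, config.sensor_noise_sd, epochs.shape)

    labels = np.where(
        rng.random(n) < config.interruptus_fraction, "interruptus", "classic"
    )
    return SubjectDataset(
        subject_id=f"S{subject_index:02d}",
        epochs=epochs,
        times=offsets_out / _SIM_FS,
        wait_times=waits,
        w_reports=w_reports,
        task_labels=labels,
        fs=config.fs_out,
        beta=beta,
        threshold=threshold,
        w_frac=w_frac,
        w_delays=delays,
    )


def generate_cohort(config: CohortConfig) -> List[SubjectDataset]:
    """Independent subjects with seeds derived from the master seed."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def concatenate_epochs(ds: SubjectDataset) -> np.ndarray:
    """All finite epoch samples of a subject, concatenated trial by
    trial (for spectral estimation)."""
    parts = [row[np.isfinite(row)] for row in ds.epochs]
    return np.concatenate([p for p in parts if p.size])


# ---------------------------------------------------------------------------
# on-disk container: one array file + a delimited behavior table + metadata


def write_dataset(
    data: Union[SubjectDataset, Sequence[SubjectDataset]], path
) -> None:
    """Write a subject or cohort losslessly to a directory.

    Layout: ``epochs.npz`` (arrays), ``behavior.tsv`` (one row per
    trial) and ``meta.json`` (schema version, per-subject parameters).
    """
    single = isinstance(data, SubjectDataset)
    subjects = [data] if single else list(data)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    arrays = {"times": subjects[0].times}
    for ds in subjects:
        arrays[f"epochs_{ds.subject_id}"] = ds.epochs
        arrays[f"w_delays_{ds.subject_id}"] = (
            ds.w_delays if ds.w_delays is not None else np.full(len(ds.wait_times), np.nan)
        )
    np.savez(path / "epochs.npz", **arrays)

    rows = []
    for ds in subjects:
        for j in range(len(ds.wait_times)):
            rows.append(
                {
                    "subject_id": ds.subject_id,
                    "trial": j,
                    "wait_time_s": ds.wait_times[j],
                    "w_report_s": ds.w_reports[j],
                    "task_label": ds.task_labels[j],
                }
            )
    pd.DataFrame(rows).to_csv(path / "behavior.tsv", sep="\t", index=False)

    meta = {
        "schema_version": SCHEMA_VERSION,
        "single": single,
        "subjects": [
            {
                "subject_id": ds.subject_id,
                "fs": ds.fs,
                "beta": ds.beta,
                "threshold": ds.threshold,
                "w_frac": ds.w_frac,
            }
            for ds in subjects
        ],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(path) -> Union[SubjectDataset, List[SubjectDataset]]:
    """Read a dataset written by :func:`write_dataset`.

    Raises a validation error naming the missing block; a newer major
    schema version is rejected, a newer minor version warned about.
    """
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise ValueError("dataset is missing its 'meta.json' block")
    meta = json.loads(meta_file.read_text())
    version = str(meta.get("schema_version", "0"))
    major = version.split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(
            f"dataset schema version {version} is incompatible with "
            f"reader version {SCHEMA_VERSION}"
        )
    if version != SCHEMA_VERSION:
        warnings.warn(
            f"dataset schema version {version} differs from reader "
            f"version {SCHEMA_VERSION}; reading anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    if not (path / "behavior.tsv").exists():
        raise ValueError("dataset is missing its 'behavior.tsv' block")
    if not (path / "epochs.npz").exists():
        raise ValueError("dataset is missing its 'epochs.npz' block")

    behavior = pd.read_csv(
        path / "behavior.tsv", sep="\t", float_precision="round_trip"
    )
    with np.load(path / "epochs.npz") as arrays:
        times = arrays["times"]
        subjects = []
        for info in meta["subjects"]:
            sid = info["subject_id"]
            rows = behavior[behavior["subject_id"] == sid].sort_values("trial")
            if rows.empty:
                raise ValueError(
                    f"behavior table has no rows for subject {sid}"
                )
            subjects.append(
                SubjectDataset(
                    subject_id=sid,
                    epochs=arrays[f"epochs_{sid}"],
                    times=times,
                    wait_times=rows["wait_time_s"].to_numpy(),
                    w_reports=rows["w_report_s"].to_numpy(),
                    task_labels=rows["task_label"].to_numpy(),
                    fs=info["fs"],
                    beta=info["beta"],
                    threshold=info["threshold"],
                    w_frac=info["w_frac"],
                    w_delays=arrays[f"w_delays_{sid}"],
                )
            )
    return subjects[0] if meta.get("single") else subjects
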