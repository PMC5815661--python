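"""Leaky stochastic accumulator with autocorrelated input noise.

The decision variable ``x`` integrates a constant imperative ``I`` minus
a leak ``k * x`` plus scaled stochastic input, by the per-sample update

    x[t+1] = x[t] + (I - k * x[t]) * dt + c * sqrt(dt) * xi[t]

with ``dt`` simulation time units per sample (default 0.001, i.e. 1000
samples per time unit).  Movement is triggered at the first sample where
``x >= threshold``; a second, slightly lower "advance warning" threshold
models the subjectively reported awareness time W as the (negative)
delay between the crossings of the two thresholds.

In the noiseless limit (``c = 0``) the trajectory follows
``(I/k) * (1 - exp(-k t))`` and the first crossing of a threshold
``theta < I/k`` happens at ``t* = -(1/k) * log(1 - k*theta/I)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy import signal

from .noise import NoiseParams, NoiseSeries, make_noise

__all__ = [
    "AccumulatorParams",
    "TrialRecord",
    "EpochPair",
    "BatchResult",
    "reference_params",
    "reference_noise_params",
    "simulate_trial",
    "detect_first_crossing",
    "extract_epochs",
    "compute_w_delay",
    "run_batch",
    "noiseless_trajectory",
    "noiseless_crossing_time",
]

#: best-fit exponent of the stochastic input (used as packaged default)
REFERENCE_BETA = 1.4

#: default epoch window around the threshold crossing, in samples
EPOCH_PRE = 5000
EPOCH_POST = 500


@dataclass(frozen=True)
class AccumulatorParams:
    """Parameters of the accumulator.

    ``I`` (imperative / drift), ``k`` (leak) and the noise scale ``c``
    are rates per simulation time unit; ``dt`` is the integration step
    in time units per sample.  ``w_threshold`` defaults to
    ``0.9 * threshold`` when not given.  ``w_rule`` selects which upward
    crossing of the lower threshold defines W: the last one before the
    main crossing (``"last"``, the final approach) or the first ever
    (``"first"``).
    """

    I: float = 0.1
    k: float = 0.6
    c: float = 0.1
    threshold: float = 0.1256
    w_threshold: Optional[float] = None
    dt: float = 0.001
    max_samples: int = 60_000
    x0: float = 0.0
    w_rule: str = "last"

    def __post_init__(self) -> None:
        for name in ("I", "k", "c", "threshold", "dt", "x0"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v}")
        if self.k <= 0:
            raise ValueError("leak k must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.c < 0:
            raise ValueError("noise scale c must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_samples < 1:
            raise ValueError("max_samples must be >= 1")
        if self.w_threshold is not None:
            if not np.isfinite(self.w_threshold):
                raise ValueError("w_threshold must be finite")
            if not (0.0 < self.w_threshold < self.threshold):
                raise ValueError(
                    "w_threshold must satisfy 0 < w_threshold < threshold"
                )
        if self.w_rule not in ("last", "first"):
            raise ValueError(f"unknown w_rule {self.w_rule!r}")

    @property
    def w_thresh(self) -> float:
        """Advance-warning threshold (defaults to 0.9 * threshold)."""
        if self.w_threshold is not None:
            return self.w_threshold
        return 0.9 * self.threshold


def reference_params(**overrides) -> AccumulatorParams:
    """The best-fit reference configuration (I=0.1, k=0.6, theta=0.1256)."""
    return AccumulatorParams(**overrides)


def reference_noise_params(
    beta: float = REFERENCE_BETA,
    n_samples: int = 60_000,
    seed=None,
    **overrides,
) -> NoiseParams:
    """Noise configuration used as the accumulator's stochastic input.

    Amplitude-anchored spectral shaping (see :mod:`lsaccum.noise`), so
    that ``beta = 0`` coincides with unit-variance white noise.
    """
    return NoiseParams(
        beta=beta,
        n_samples=n_samples,
        seed=seed,
        normalization="anchored",
        **overrides,
    )


@dataclass
class TrialRecord:
    """One simulation run.

    ``input`` is the scaled stochastic input ``c * xi`` (one value per
    integration step); ``output`` is the decision-variable trajectory,
    with ``output[0] = x0`` and ``output[t]`` the state after ``t``
    updates, so input sample ``t`` drives the step from ``output[t]`` to
    ``output[t+1]``.  ``crossing_idx`` is the first sample index with
    ``output >= threshold`` (None if censored).  Times are in
    simulation time units (samples * dt).
    """

    input: np.ndarray
    output: np.ndarray
    params: AccumulatorParams
    crossing_idx: Optional[int]
    w_crossing_idx: Optional[int] = None
    w_delay: Optional[float] = None

    @property
    def censored(self) -> bool:
        return self.crossing_idx is None

    @property
    def wait_time(self) -> Optional[float]:
        if self.crossing_idx is None:
            return None
        return self.crossing_idx * self.params.dt


@dataclass
class EpochPair:
    """Input- and output-locked epochs around the threshold crossing.

    Both windows span ``pre`` samples before to ``post`` samples after
    the crossing (length ``pre + post + 1``); time index 0 is the
    crossing sample.  Samples outside the simulated trial (before trial
    start, or beyond its end) are NaN and are reflected in ``missing``.
    """

    input_epoch: np.ndarray
    output_epoch: np.ndarray
    wait_time: float
    pre: int = EPOCH_PRE
    post: int = EPOCH_POST
    dt: float = 0.001

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.output_epoch)

    def times(self, seconds: bool = False) -> np.ndarray:
        """Sample offsets relative to the crossing (optionally scaled)."""
        offs = np.arange(-self.pre, self.post + 1)
        return offs * self.dt if seconds else offs


def detect_first_crossing(series, level: float) -> Optional[int]:
    """Smallest index with ``series[i] >= level``; None if absent."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot detect crossings in an empty series")
    hits = np.nonzero(arr >= level)[0]
    if hits.size == 0:
        return None
    return int(hits[0])


def simulate_trial(
    params: AccumulatorParams, noise: Union[NoiseSeries, np.ndarray]
) -> TrialRecord:
    """Integrate the accumulator over a supplied noise series.

    The noise must provide at least ``params.max_samples`` samples.  A
    trial with no threshold crossing within ``max_samples`` updates is
    flagged censored (``crossing_idx is None``), not an error.
    """
    xi = noise.values if isinstance(noise, NoiseSeries) else np.asarray(noise, float)
    n = params.max_samples
    if len(xi) < n:
        raise ValueError(
            f"noise series has {len(xi)} samples; need >= max_samples = {n}"
        )
    xi = xi[:n]
    a = 1.0 - params.k * params.dt
    drive = params.I * params.dt + params.c * np.sqrt(params.dt) * xi
    # linear recurrence x[t+1] = a x[t] + drive[t] via an IIR filter
    body, _ = signal.lfilter([1.0], [1.0, -a], drive, zi=np.array([a * params.x0]))
    x = np.concatenate(([params.x0], body))
    ci = detect_first_crossing(x, params.threshold)
    rec = TrialRecord(
        input=params.c * xi,
        output=x,
        params=params,
        crossing_idx=ci,
    )
    if ci is not None:
        rec.w_crossing_idx, rec.w_delay = _w_crossing(x, ci, params)
    return rec


def _w_crossing(x: np.ndarray, crossing_idx: int, params: AccumulatorParams):
    """Index of the advance-warning crossing and the (<= 0) W delay."""
    thw = params.w_thresh
    above = x[: crossing_idx + 1] >= thw
    prev = np.concatenate(([False], above[:-1]))
    ups = np.nonzero(above & ~prev)[0]
    if ups.size == 0:  # x0 already above threshold handled by ups[0] == 0
        return None, None
    j = int(ups[-1] if params.w_rule == "last" else ups[0])
    return j, (j - crossing_idx) * params.dt


def compute_w_delay(trial: TrialRecord, params: Optional[AccumulatorParams] = None):
    """W delay of a trial: t(lower-threshold crossing) - t(main crossing).

    Uses the crossing selected by ``params.w_rule`` (default: the last
    upward crossing of the lower threshold before the main crossing,
    i.e. the final approach).  Always <= 0.
    """
    if params is None:
        params = trial.params
    if params.w_thresh >= params.threshold:
        raise ValueError("w_threshold must be below threshold")
    if trial.censored:
        raise ValueError("cannot compute W delay for a censored trial")
    _, delay = _w_crossing(trial.output, trial.crossing_idx, params)
    return delay


def extract_epochs(
    trial: TrialRecord, pre: int = EPOCH_PRE, post: int = EPOCH_POST
) -> EpochPair:
    """Fixed-length windows of input and output aligned at the crossing."""
    if trial.censored:
        raise ValueError("cannot extract epochs from a censored trial")
    ci = trial.crossing_idx
    length = pre + post + 1
    inp = np.full(length, np.nan)
    out = np.full(length, np.nan)
    for src, dst in ((trial.input, inp), (trial.output, out)):
        lo = max(0, ci - pre)
        hi = min(len(src), ci + post + 1)
        dst[lo - (ci - pre) : lo - (ci - pre) + (hi - lo)] = src[lo:hi]
    return EpochPair(
        input_epoch=inp,
        output_epoch=out,
        wait_time=trial.wait_time,
        pre=pre,
        post=post,
        dt=trial.params.dt,
    )


@dataclass
class BatchResult:
    """Trial ensemble summary: crossing times, W delays and epochs.

    Censored trials are excluded from ``crossing_times``, ``w_delays``
    and the epoch stacks, mirroring the conditioning on movement
    occurrence; ``n_censored`` counts them.
    """

    crossing_times: np.ndarray
    w_delays: np.ndarray
    input_epochs: Optional[np.ndarray]
    output_epochs: Optional[np.ndarray]
    n_trials: int
    n_censored: int
    params: AccumulatorParams
    noise_params: NoiseParams
    pre: int = EPOCH_PRE
    post: int = EPOCH_POST

    def epoch_times(self, seconds: bool = False) -> np.ndarray:
        offs = np.arange(-self.pre, self.post + 1)
        return offs * self.params.dt if seconds else offs


def run_batch(
    params: AccumulatorParams,
    noise_params: NoiseParams,
    n_trials: int,
    master_seed: int,
    keep_epochs: bool = True,
    pre: int = EPOCH_PRE,
    post: int = EPOCH_POST,
    min_crossings: Optional[int] = None,
    max_attempts_factor: int = 4,
) -> BatchResult:
    """Simulate ``n_trials`` independent trials.

    Each trial gets its own noise realization with a seed derived from
    ``(master_seed, trial_index)``, so a batch is reproducible and
    trials are independent.  When ``min_crossings`` is given, extra
    trials are simulated (up to ``max_attempts_factor * n_trials``)
    until that many crossings are collected.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base = dataclasses.replace(
        noise_params, n_samples=max(noise_params.n_samples, params.max_samples)
    )
    waits: List[float] = []
    delays: List[float] = []
    in_eps: List[np.ndarray] = []
    out_eps: List[np.ndarray] = []
    n_censored = 0
    target = min_crossings if min_crossings is not None else n_trials
    limit = n_trials if min_crossings is None else max_attempts_factor * n_trials
    i = 0
    while i < limit:
        if min_crossings is not None and len(waits) >= target:
            break
        trial_params = dataclasses.replace(base, seed=(master_seed, i))
        trial = simulate_trial(params, make_noise(trial_params))
        i += 1
        if trial.censored:
            n_censored += 1
            continue
        if trial.w_delay is None:
            n_censored += 1
            continue
        waits.append(trial.wait_time)
        delays.append(trial.w_delay)
        if keep_epochs:
            ep = extract_epochs(trial, pre=pre, post=post)
            in_eps.append(ep.input_epoch)
            out_eps.append(ep.output_epoch)
    if not waits:
        warnings.warn(
            "all trials censored: empty crossing-time distribution",
            RuntimeWarning,
            stacklevel=2,
        )
    return BatchResult(
        crossing_times=np.asarray(waits),
        w_delays=np.asarray(delays),
        input_epochs=np.asarray(in_eps) if keep_epochs else None,
        output_epochs=np.asarray(out_eps) if keep_epochs else None,
        n_trials=i,
        n_censored=n_censored,
        params=params,
        noise_params=base,
        pre=pre,
        post=post,
    )


def noiseless_trajectory(params: AccumulatorParams, t) -> np.ndarray:
    """Closed-form deterministic solution ``(I/k)(1 - exp(-k t))``.

    ``t`` is in simulation time units; assumes ``x0 = 0``.
    """
    t = np.asarray(t, dtype=float)
    return (params.I / params.k) * (1.0 - np.exp(-params.k * t))


def noiseless_crossing_time(params: AccumulatorParams, level: Optional[float] = None):
    """Closed-form first-passage time of the noiseless accumulator.

    Returns ``-(1/k) * log(1 - k*level/I)`` or None when the asymptote
    ``I/k`` never reaches ``level``.
    """
    if level is None:
        level = params.threshold
    arg = 1.0 - params.k * level / params.I if params.I != 0 else -np.inf
    if arg <= 0:
        return None
    return -np.log(arg) / params.k
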