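"""Exponent sweeps for the model's two predictions.

Prediction 1: when epochs are time-locked to the threshold crossing,
the long-wait tercile shows a *lower* early amplitude than the
short-wait tercile on the input-locked average but a *higher* one on
the output-locked average.  :func:`scan_prediction1` measures both
tercile differences over the early window (samples -1500..-500 before
the crossing) across a grid of noise exponents and reports the smallest
exponent from which the opposite ordering holds stably up the grid.

Prediction 2: the first-crossing (waiting) time correlates negatively
with the model's W delay (the inter-threshold interval).
:func:`scan_prediction2` computes the Pearson correlation per exponent
and reports the smallest exponent from which it is significantly
negative (two-tailed p < 0.05) for that exponent and all larger ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .accumulator import AccumulatorParams, reference_noise_params, reference_params, run_batch
from .stats import tercile_split

__all__ = [
    "Prediction1Row",
    "Prediction2Row",
    "scan_prediction1",
    "scan_prediction2",
    "stable_onset",
]

EARLY_WINDOW = (-1500, -500)  # samples relative to the crossing


@dataclass
class Prediction1Row:
    beta: float
    d_input: float  # long-wait minus short-wait, input-locked
    d_output: float  # long-wait minus short-wait, output-locked
    reversed_ordering: bool
    n: int


@dataclass
class Prediction2Row:
    beta: float
    r: float
    p: float
    significantly_negative: bool
    n: int


def stable_onset(betas: Sequence[float], flags: Sequence[bool]) -> Optional[float]:
    """Smallest beta from which the flag holds for all larger betas."""
    for i in range(len(betas)):
        if all(flags[i:]):
            return float(betas[i])
    return None


def _batch(beta: float, n_trials: int, seed: int, params: AccumulatorParams,
           keep_epochs: bool):
    noise = reference_noise_params(beta=float(beta))
    return run_batch(
        params, noise, n_trials, master_seed=seed,
        keep_epochs=keep_epochs, min_crossings=n_trials,
    )


def scan_prediction1(
    betas: Sequence[float],
    n_trials: int = 2000,
    seed: int = 0,
    params: Optional[AccumulatorParams] = None,
    window: Tuple[int, int] = EARLY_WINDOW,
) -> Tuple[Optional[float], List[Prediction1Row]]:
    """Tercile amplitude orderings across noise exponents.

    Returns ``(onset, rows)`` where ``onset`` is the smallest exponent
    from which the input-locked difference (long minus short) is
    negative while the output-locked difference is positive, stably for
    all larger grid values.
    """
    params = params or reference_params()
    rows = []
    for beta in betas:
        batch = _batch(beta, n_trials, seed, params, keep_epochs=True)
        waits = batch.crossing_times
        short, long = tercile_split(waits)
        t = batch.epoch_times()
        win = (t >= window[0]) & (t <= window[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d_in = float(
                np.nanmean(batch.input_epochs[long][:, win])
                - np.nanmean(batch.input_epochs[short][:, win])
            )
            d_out = float(
                np.nanmean(batch.output_epochs[long][:, win])
                - np.nanmean(batch.output_epochs[short][:, win])
            )
        rows.append(
            Prediction1Row(
                beta=float(beta),
                d_input=d_in,
                d_output=d_out,
                reversed_ordering=bool(d_in < 0 and d_out > 0),
                n=len(waits),
            )
        )
    onset = stable_onset([r.beta for r in rows], [r.reversed_ordering for r in rows])
    return onset, rows


def scan_prediction2(
    betas: Sequence[float],
    n_trials: int = 2000,
    seed: int = 0,
    params: Optional[AccumulatorParams] = None,
    alpha: float = 0.05,
) -> Tuple[Optional[float], List[Prediction2Row]]:
    """Wait-W correlation across noise exponents.

    Returns ``(onset, rows)`` where ``onset`` is the smallest exponent
    from which the Pearson correlation between first-crossing time and
    W delay is significantly negative for that exponent and all larger
    grid values.
    """
    params = params or reference_params()
    rows = []
    for beta in betas:
        batch = _batch(beta, n_trials, seed, params, keep_epochs=False)
        waits = batch.crossing_times[:n_trials]
        delays = batch.w_delays[:n_trials]
        res = sstats.pearsonr(waits, delays)
        r, p = float(res.statistic), float(res.pvalue)
        rows.append(
            Prediction2Row(
                beta=float(beta),
                r=r,
                p=p,
                significantly_negative=bool(r < 0 and p < alpha),
                n=len(waits),
            )
        )
    onset = stable_onset(
        [r.beta for r in rows], [r.significantly_negative for r in rows]
    )
    return onset, rows
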