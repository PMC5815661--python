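"""Statistical procedures for the two model predictions.

Prediction 1 (shape of the event-preceding potential versus waiting
time): trials are split into the lower and upper thirds of the
waiting-time distribution, group-average waveforms are compared
point-by-point with two-tailed rank tests, and contiguous runs of
suprathreshold time points are corrected for multiple comparisons with a
cluster-based sign-flip permutation test.  A single window test on the
mean amplitude over a declared interval (canonically the early -1.5 to
-0.5 s window) accompanies the pointwise map.

Prediction 2 (waiting time versus reported awareness time W): Pearson
correlation on pooled trials, per-subject correlations summarized with a
Wilcoxon signed-rank test, and an exact one-sided binomial sign test on
the number of subjects with a negative correlation.

Sign conventions: "amplitude" comparisons are expressed on the
sign-reversed (positive-going) scale of the model, i.e. callers should
flip negative-going potentials before comparing, to avoid
double-negation mistakes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

__all__ = [
    "TercileComparison",
    "CorrelationReport",
    "Cluster",
    "tercile_split",
    "compare_terciles",
    "cluster_permutation",
    "wait_w_correlation",
    "binomial_sign_test",
]


# ---------------------------------------------------------------------------
# tercile machinery


def tercile_split(wait_times) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of the lower-33rd and upper-33rd percentile trials.

    Nearest-rank percentiles; ties at a boundary are assigned to the
    inner (short / long) group.  Raises on fewer than 3 trials or when
    the two groups would overlap (degenerate split).
    """
    waits = np.asarray(wait_times, dtype=float)
    if waits.ndim != 1:
        raise ValueError("wait_times must be one-dimensional")
    n = len(waits)
    if n < 3:
        raise ValueError("need at least 3 trials for a tercile split")
    ordered = np.sort(waits)
    lo_cut = ordered[int(np.ceil(0.33 * n)) - 1]
    hi_cut = ordered[int(np.ceil(0.67 * n)) - 1]
    short = np.nonzero(waits <= lo_cut)[0]
    long = np.nonzero(waits >= hi_cut)[0]
    if np.intersect1d(short, long).size:
        raise ValueError(
            "degenerate tercile split: short and long groups overlap "
            "(too many tied waiting times)"
        )
    return short, long


@dataclass
class Cluster:
    """A contiguous suprathreshold run of time points."""

    start: int
    end: int  # inclusive
    statistic: float
    p_corrected: float


@dataclass
class TercileComparison:
    short_mean: np.ndarray
    long_mean: np.ndarray
    pointwise_p: np.ndarray
    window: Tuple[float, float]
    window_short: float
    window_long: float
    window_stat: float
    window_p: float
    clusters: Optional[List[Cluster]] = None


def _signed_rank_z(diffs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized Wilcoxon signed-rank z per column of an (n, T) array.

    The statistic is S = sum(sign * rank(|d|)), which has mean 0 and
    variance sum(rank^2) under random sign flips; this is exactly the
    statistic permuted by the cluster test.
    """
    absd = np.abs(diffs)
    ranks = sstats.rankdata(absd, axis=0)
    s = np.sum(np.sign(diffs) * ranks, axis=0)
    denom = np.sqrt(np.sum(ranks**2, axis=0))
    denom[denom == 0] = np.inf
    z = s / denom
    p = 2.0 * sstats.norm.sf(np.abs(z))
    return z, p


def _ranksum_z(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample rank-sum z per column, NaN-aware."""
    combined = np.vstack([a, b])
    ranks = sstats.rankdata(combined, axis=0, nan_policy="omit")
    n1 = np.sum(np.isfinite(a), axis=0).astype(float)
    n2 = np.sum(np.isfinite(b), axis=0).astype(float)
    r1 = np.nansum(np.where(np.isfinite(a), ranks[: len(a)], 0.0), axis=0)
    mean = n1 * (n1 + n2 + 1) / 2.0
    var = n1 * n2 * (n1 + n2 + 1) / 12.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (r1 - mean) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    p = 2.0 * sstats.norm.sf(np.abs(z))
    return z, p


def compare_terciles(
    epochs,
    wait_times,
    times,
    window: Tuple[float, float],
    subject_ids=None,
    n_perm: int = 0,
    cluster_alpha: float = 0.05,
    seed: Optional[int] = 0,
) -> TercileComparison:
    """Compare short- versus long-wait average waveforms.

    Parameters
    ----------
    epochs : (n_trials, T) array
        Event-locked waveforms; NaN marks missing samples.
    wait_times : (n_trials,) array
    times : (T,) array
        Time axis of the epochs (same units as ``window``).
    window : (t1, t2)
        Interval for the single mean-amplitude test.
    subject_ids : optional (n_trials,) array
        When given, the tercile split is performed within each subject,
        per-subject tercile-mean waveforms form the paired units, and
        pointwise/window tests are paired signed-rank tests across
        subjects (group-level inference).  Otherwise tests are
        independent rank-sum tests across trials.
    n_perm : int
        When > 0 (and in subject mode), additionally run the
        cluster-based permutation correction.
    """
    epochs = np.asarray(epochs, dtype=float)
    waits = np.asarray(wait_times, dtype=float)
    times = np.asarray(times, dtype=float)
    if epochs.shape[0] != len(waits):
        raise ValueError("epochs and wait_times disagree on trial count")
    if epochs.shape[1] != len(times):
        raise ValueError("epochs and times disagree on sample count")
    t1, t2 = window
    win_mask = (times >= t1) & (times <= t2)
    if not win_mask.any():
        raise ValueError(f"window [{t1}, {t2}] lies outside the epoch")

    clusters = None
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        subjects = np.unique(subject_ids)
        short_stack, long_stack = [], []
        for s in subjects:
            m = subject_ids == s
            si, li = tercile_split(waits[m])
            sub = epochs[m]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                short_stack.append(np.nanmean(sub[si], axis=0))
                long_stack.append(np.nanmean(sub[li], axis=0))
        short_stack = np.asarray(short_stack)
        long_stack = np.asarray(long_stack)
        short_mean = np.nanmean(short_stack, axis=0)
        long_mean = np.nanmean(long_stack, axis=0)
        d = long_stack - short_stack
        d = np.where(np.isfinite(d), d, 0.0)
        _, pointwise_p = _signed_rank_z(d)
        short_win = np.nanmean(short_stack[:, win_mask], axis=1)
        long_win = np.nanmean(long_stack[:, win_mask], axis=1)
        res = sstats.wilcoxon(long_win, short_win, alternative="two-sided")
        window_stat, window_p = float(res.statistic), float(res.pvalue)
        if n_perm > 0:
            clusters = cluster_permutation(
                long_stack, short_stack, n_perm=n_perm,
                cluster_alpha=cluster_alpha, seed=seed,
            )
    else:
        si, li = tercile_split(waits)
        short_grp, long_grp = epochs[si], epochs[li]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            short_mean = np.nanmean(short_grp, axis=0)
            long_mean = np.nanmean(long_grp, axis=0)
            _, pointwise_p = _ranksum_z(long_grp, short_grp)
            short_win = np.nanmean(short_grp[:, win_mask], axis=1)
            long_win = np.nanmean(long_grp[:, win_mask], axis=1)
        short_win = short_win[np.isfinite(short_win)]
        long_win = long_win[np.isfinite(long_win)]
        res = sstats.ranksums(long_win, short_win)
        window_stat, window_p = float(res.statistic), float(res.pvalue)

    return TercileComparison(
        short_mean=short_mean,
        long_mean=long_mean,
        pointwise_p=pointwise_p,
        window=(float(t1), float(t2)),
        window_short=float(np.nanmean(short_win)),
        window_long=float(np.nanmean(long_win)),
        window_stat=window_stat,
        window_p=window_p,
        clusters=clusters,
    )


# ---------------------------------------------------------------------------
# cluster-based permutation correction


def _find_clusters(z: np.ndarray, z_crit: float) -> List[Tuple[int, int, float]]:
    """Contiguous runs where |z| exceeds z_crit, per sign; stat = sum z."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * z > z_crit
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0])
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(z) - 1)
        for s, e in zip(starts, ends):
            out.append((s, e, float(np.sum(z[s : e + 1]))))
    return out


def cluster_permutation(
    group_a,
    group_b,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: Optional[int] = 0,
) -> List[Cluster]:
    """Cluster-corrected comparison of paired waveform sets.

    ``group_a`` and ``group_b`` are (n_units, T) arrays with matched
    rows (e.g. per-subject condition means).  Pointwise statistics are
    Wilcoxon signed-rank z values; clusters are contiguous runs with
    uncorrected two-tailed p below ``cluster_alpha`` (positive and
    negative runs handled separately); the cluster statistic is the sum
    of z within the run.  The null distribution is the maximum absolute
    cluster statistic over random within-unit sign flips, and corrected
    p-values use the add-one permutation estimate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired groups must have identical shapes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse p-value resolution "
            f"(minimum {1.0 / (n_perm + 1):.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    d = a - b
    d = np.where(np.isfinite(d), d, 0.0)
    n_units, n_t = d.shape
    ranks = sstats.rankdata(np.abs(d), axis=0)
    signed = np.sign(d) * ranks
    denom = np.sqrt(np.sum(ranks**2, axis=0))
    denom[denom == 0] = np.inf
    z_obs = np.sum(signed, axis=0) / denom
    z_crit = sstats.norm.isf(cluster_alpha / 2.0)

    observed = _find_clusters(z_obs, z_crit)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_units))
    z_perm = (flips @ signed) / denom  # (n_perm, T)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _find_clusters(z_perm[i], z_crit)
        if cl:
            null_max[i] = max(abs(c[2]) for c in cl)
    out = []
    for s, e, stat in observed:
        p = (1.0 + np.sum(null_max >= abs(stat))) / (n_perm + 1.0)
        out.append(Cluster(start=int(s), end=int(e), statistic=stat, p_corrected=float(p)))
    out.sort(key=lambda c: c.p_corrected)
    return out


# ---------------------------------------------------------------------------
# waiting time versus W time


@dataclass
class CorrelationReport:
    pooled_r: float
    pooled_p: float
    pooled_slope: float
    per_subject_r: List[float]
    per_subject_p: List[float]
    subjects: List
    excluded_subjects: List
    signed_rank_p: float
    n_negative: int
    binomial_p: float


def binomial_sign_test(n_successes: int, n_total: int) -> float:
    """One-sided tail P(X >= n_successes) for X ~ Binomial(n_total, 1/2)."""
    if not (0 <= n_successes <= n_total):
        raise ValueError("need 0 <= n_successes <= n_total")
    return float(sstats.binom.sf(n_successes - 1, n_total, 0.5))


def wait_w_correlation(
    wait_times, w_times, subject_ids=None
) -> CorrelationReport:
    """Pooled and per-subject Pearson correlation of waits and W times.

    Subjects with fewer than 3 trials or zero variance in either
    variable are excluded from the per-subject summary and reported in
    ``excluded_subjects``.
    """
    waits = np.asarray(wait_times, dtype=float)
    w = np.asarray(w_times, dtype=float)
    if waits.shape != w.shape:
        raise ValueError("wait_times and w_times must have equal length")
    if len(waits) < 3:
        raise ValueError("need at least 3 trials")
    pooled = sstats.pearsonr(waits, w)
    slope = float(np.polyfit(waits, w, 1)[0])

    rs: List[float] = []
    ps: List[float] = []
    used, excluded = [], []
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        for s in np.unique(subject_ids):
            m = subject_ids == s
            if m.sum() < 3 or waits[m].std() == 0 or w[m].std() == 0:
                excluded.append(s)
                continue
            r = sstats.pearsonr(waits[m], w[m])
            rs.append(float(r.statistic))
            ps.append(float(r.pvalue))
            used.append(s)
    if rs:
        signed_rank_p = float(
            sstats.wilcoxon(rs, alternative="two-sided").pvalue
        )
        n_negative = int(np.sum(np.asarray(rs) < 0))
        binomial_p = binomial_sign_test(n_negative, len(rs))
    else:
        signed_rank_p = np.nan
        n_negative = 0
        binomial_p = np.nan
    return CorrelationReport(
        pooled_r=float(pooled.statistic),
        pooled_p=float(pooled.pvalue),
        pooled_slope=slope,
        per_subject_r=rs,
        per_subject_p=ps,
        subjects=used,
        excluded_subjects=excluded,
        signed_rank_p=signed_rank_p,
        n_negative=n_negative,
        binomial_p=binomial_p,
    )
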