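"""Aperiodic (1/f) exponent estimation via IRASA.

The 1/f exponent of a time series is estimated as the sign-reversed
slope of an ordinary-least-squares line fit, in log-log coordinates, to
the *fractal* component of its power spectrum.  The fractal component is
obtained by irregular-resampling auto-spectral analysis (IRASA): for a
set of non-integer factors ``h``, the series is resampled by ``h`` and
``1/h``, Welch spectra of the two resampled copies are multiplied
geometrically bin-by-bin, and the median over the ``h`` set is taken.
A pure power law ``f**-beta`` is invariant under this operation
(``(h f)**(-b/2) * (f/h)**(-b/2) = f**-b``) whereas narrow-band
oscillatory peaks are displaced in opposite directions and suppressed by
the median, so the residual (original PSD minus fractal) isolates the
oscillatory component.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

__all__ = [
    "SpectralEstimate",
    "irasa",
    "fit_loglog_slope",
    "estimate_beta",
    "DEFAULT_HSET",
    "DEFAULT_FIT_BAND",
]

#: IRASA resampling factors (the reference set 1.1 ... 1.9, step 0.05)
DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.9001, 0.05), 2))

#: default log-log fit band in Hz (avoids DC and Nyquist-adjacent bins)
DEFAULT_FIT_BAND = (0.1, 25.0)

#: Welch segment length in samples (Hann taper, 50% overlap)
DEFAULT_NPERSEG = 4096


@dataclass
class SpectralEstimate:
    """IRASA decomposition plus the fitted aperiodic exponent."""

    freqs: np.ndarray
    fractal_psd: np.ndarray
    oscillatory_psd: np.ndarray
    beta_hat: float
    fit_band: Tuple[float, float]
    n_segments: int = 0


def irasa(
    series,
    fs: float,
    hset: Sequence[float] = DEFAULT_HSET,
    nperseg: int = DEFAULT_NPERSEG,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a power spectrum into fractal and oscillatory components.

    Returns ``(freqs, fractal_psd, oscillatory_psd)`` where the
    oscillatory part is the raw Welch PSD minus the fractal component.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    hmax = max(hset)
    if len(x) < nperseg * hmax:
        raise ValueError(
            f"series too short for IRASA: need >= nperseg * max(h) = "
            f"{int(np.ceil(nperseg * hmax))} samples, got {len(x)}"
        )
    nper = min(nperseg, len(x))
    freqs, psd = signal.welch(x, fs, nperseg=nper)
    resampled = np.empty((len(hset), len(freqs)))
    for i, h in enumerate(hset):
        frac = Fraction(str(round(h, 2))).limit_denominator(100)
        up, down = frac.numerator, frac.denominator
        x_up = signal.resample_poly(x, up, down)
        x_down = signal.resample_poly(x, down, up)
        _, psd_up = signal.welch(x_up, fs * h, nperseg=nper)
        _, psd_down = signal.welch(x_down, fs / h, nperseg=nper)
        # geometric mean pairs PSD values at (h f) and (f / h)
        resampled[i] = np.sqrt(psd_up * psd_down)
    fractal = np.median(resampled, axis=0)
    return freqs, fractal, psd - fractal


def fit_loglog_slope(
    freqs, psd, band: Tuple[float, float] = DEFAULT_FIT_BAND
) -> float:
    """Sign-reversed OLS slope of log10(psd) against log10(f) on a band."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi) & (freqs > 0) & (psd > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable points in fit band [{lo}, {hi}] Hz"
        )
    slope, _ = np.polyfit(np.log10(freqs[mask]), np.log10(psd[mask]), 1)
    return float(-slope)


def estimate_beta(
    series,
    fs: float,
    band: Tuple[float, float] = DEFAULT_FIT_BAND,
    hset: Sequence[float] = DEFAULT_HSET,
    nperseg: int = DEFAULT_NPERSEG,
) -> SpectralEstimate:
    """Estimate the 1/f exponent of a series (IRASA + log-log OLS)."""
    freqs, fractal, osc = irasa(series, fs, hset=hset, nperseg=nperseg)
    beta_hat = fit_loglog_slope(freqs, fractal, band)
    nper = min(nperseg, len(np.asarray(series)))
    n_segments = max(1, int(np.floor((len(series) - nper // 2) / (nper // 2))))
    return SpectralEstimate(
        freqs=freqs,
        fractal_psd=fractal,
        oscillatory_psd=osc,
        beta_hat=beta_hat,
        fit_band=(float(band[0]), float(band[1])),
        n_segments=n_segments,
    )
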