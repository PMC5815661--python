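"""Temporally autocorrelated (1/f^beta) noise via FFT spectral shaping.

The generator produces Gaussian white noise and imposes a power-law
spectrum on it by multiplying the positive-frequency FFT amplitudes with
``(f / f0)**(-beta/2)`` (so power scales as ``f**-beta``), zeroing the DC
bin, and inverting the transform.  Phases are untouched, so ``beta = 0``
returns the input unchanged (up to mean removal / standardization).

Two normalization modes are supported:

``"unit"``
    The shaped series is re-standardized to zero mean and unit variance.
    This keeps the noise-scale parameter ``c`` comparable across beta.

``"anchored"``
    The series keeps the variance implied by the shaping multiplier,
    whose amplitude is anchored at the reference frequency ``anchor_hz``
    (default 0.1 Hz).  Raising beta then tilts power from fast into slow
    fluctuations while the slow-fluctuation amplitude scale stays fixed;
    total variance is *not* conserved.  This mirrors FFT shaping with a
    fixed log-linear multiplier intercept and is the mode used for the
    accumulator's stochastic input.

A first-order Butterworth low-pass applied to white noise is provided as
the comparison input family.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal

__all__ = [
    "NoiseParams",
    "NoiseSeries",
    "generate_white",
    "shape_spectrum",
    "lowpass_white",
    "make_noise",
]

SeedLike = Union[int, Sequence[int], None]

#: admissible exponent range: 0 (white) up to, but excluding, 3
BETA_RANGE = (0.0, 3.0)


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, tuple):
        return np.random.default_rng(np.random.SeedSequence(seed))
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NoiseParams:
    """Configuration of one noise series.

    Parameters
    ----------
    beta : float
        1/f exponent; power scales as ``f**-beta``.  Must satisfy
        ``0 <= beta < 3``.
    n_samples : int
        Series length (>= 2).
    c : float
        Noise scaling factor applied by the consumer (the accumulator);
        kept here so a series carries its intended scale.  Default 0.1.
    kind : str
        ``"powerlaw"`` (spectrally shaped) or ``"lowpass_white"``
        (Butterworth-filtered white noise).
    cutoff_hz : float, optional
        Low-pass cutoff; required for ``kind="lowpass_white"``.
    filter_order : int
        Butterworth order (default 1, a single-pole roll-off).
    fs : float
        Nominal sampling rate in Hz (default 1000).
    seed : int or tuple of int, optional
        RNG seed; tuples are fed to :class:`numpy.random.SeedSequence`.
    normalization : str
        ``"unit"`` or ``"anchored"`` (see module docstring).
    anchor_hz : float
        Reference frequency of the shaping multiplier (anchored mode).
    """

    beta: float
    n_samples: int
    c: float = 0.1
    kind: str = "powerlaw"
    cutoff_hz: Optional[float] = None
    filter_order: int = 1
    fs: float = 1000.0
    seed: SeedLike = None
    normalization: str = "unit"
    anchor_hz: float = 0.1

    def __post_init__(self) -> None:
        if not (BETA_RANGE[0] <= self.beta < BETA_RANGE[1]):
            raise ValueError(f"beta must be in [0, 3), got {self.beta}")
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.kind not in ("powerlaw", "lowpass_white"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "lowpass_white":
            if self.cutoff_hz is None:
                raise ValueError("lowpass_white requires cutoff_hz")
            if not (0.0 < self.cutoff_hz < self.fs / 2.0):
                raise ValueError(
                    f"cutoff_hz must lie in (0, fs/2) = (0, {self.fs / 2}), "
                    f"got {self.cutoff_hz}"
                )
        if self.normalization not in ("unit", "anchored"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.anchor_hz <= 0:
            raise ValueError("anchor_hz must be positive")


@dataclass
class NoiseSeries:
    """A realized noise series together with its generating parameters."""

    values: np.ndarray
    params: NoiseParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("noise series must be one-dimensional")
        if len(self.values) != self.params.n_samples:
            raise ValueError(
                f"series length {len(self.values)} != n_samples "
                f"{self.params.n_samples}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def standardized(self) -> "NoiseSeries":
        """Return a copy standardized to zero mean, unit variance."""
        return NoiseSeries(_standardize(self.values), self.params)


def _standardize(values: np.ndarray) -> np.ndarray:
    out = values - values.mean()
    sd = out.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant series")
    return out / sd


def generate_white(params: NoiseParams) -> NoiseSeries:
    """Independent Gaussian draws, reproducible for a fixed seed."""
    rng = _rng(params.seed)
    return NoiseSeries(rng.standard_normal(params.n_samples), params)


def shape_spectrum(series: NoiseSeries, beta: Optional[float] = None) -> NoiseSeries:
    """Impose a 1/f^beta power spectrum on ``series`` by FFT shaping.

    The positive-frequency FFT amplitudes are multiplied by
    ``(f/f0)**(-beta/2)``; the DC bin is zeroed (the multiplier diverges
    there), which makes the output mean-zero by construction.  Phases are
    preserved.  The normalization mode of ``series.params`` decides
    whether the output is re-standardized to unit variance.
    """
    if beta is None:
        beta = series.params.beta
    if not (BETA_RANGE[0] <= beta < BETA_RANGE[1]):
        raise ValueError(f"beta must be in [0, 3), got {beta}")
    x = series.values
    if not np.all(np.isfinite(x)):
        raise ValueError("input series contains non-finite values")
    p = series.params
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / p.fs)
    mult = np.zeros(len(freqs))
    mult[1:] = (freqs[1:] / p.anchor_hz) ** (-beta / 2.0)
    shaped = np.fft.irfft(spec * mult, n)
    if p.normalization == "unit":
        shaped = _standardize(shaped)
    else:
        shaped = shaped - shaped.mean()
    out_params = dataclasses.replace(p, beta=beta, kind="powerlaw")
    return NoiseSeries(shaped, out_params)


def lowpass_white(params: NoiseParams) -> NoiseSeries:
    """White noise through a causal Butterworth low-pass filter.

    With ``filter_order=1`` the squared magnitude response is
    ``1 / (1 + (f/fc)**2)``: flat (unit gain) well below the cutoff and a
    single-pole ``f**-2`` power roll-off above it.  The output is
    re-standardized to zero mean and unit variance ("unit" mode) or mean
    zero only ("anchored" mode).
    """
    if params.kind != "lowpass_white":
        raise ValueError("params.kind must be 'lowpass_white'")
    white = generate_white(params)
    b, a = signal.butter(
        params.filter_order, params.cutoff_hz, btype="low", fs=params.fs
    )
    filtered = signal.lfilter(b, a, white.values)
    if params.normalization == "unit":
        filtered = _standardize(filtered)
    else:
        filtered = filtered - filtered.mean()
    return NoiseSeries(filtered, params)


def make_noise(params: NoiseParams) -> NoiseSeries:
    """Generate a noise series according to ``params.kind``."""
    if params.kind == "powerlaw":
        return shape_spectrum(generate_white(params))
    return lowpass_white(params)
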