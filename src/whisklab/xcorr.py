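"""Normalized cross-correlograms between firing rates and behaviour.

Spike trains and behavioural traces are binned at 10 ms, z-scored (mean 0,
SD 1), and correlated over a symmetric lag grid.  The correlogram is
normalized by the full series length, so any autocorrelogram equals
exactly 1 at zero lag.  Positive lag means the second series follows the
first (e.g. ``cross_correlate(whisking, pupil)`` peaking at +0.88 s means
the pupil lags whisking by 0.88 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .containers import CrossCorrelation, SpikeTrain
from .state_activity import paired_test

__all__ = [
    "bin_and_zscore", "cross_correlate", "peak_lag", "compare_at_peak",
    "PeakComparison",
]


def _bin_trace(x: np.ndarray, frame_rate: float, bin_width: float,
               n_bins: int) -> np.ndarray:
    """Mean of the trace's frames falling in each bin."""
    idx = np.minimum((np.arange(x.size) / frame_rate / bin_width).astype(int),
                     n_bins - 1)
    sums = np.bincount(idx, weights=x, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    out = np.zeros(n_bins)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if not nz.all():  # empty bins (coarser trace than bins): interpolate
        out[~nz] = np.interp(np.flatnonzero(~nz), np.flatnonzero(nz), out[nz])
    return out


def bin_and_zscore(data, bin_width: float = 0.010,
                   duration: Optional[float] = None,
                   frame_rate: Optional[float] = None) -> np.ndarray:
    """Bin a spike train or a uniformly sampled trace and z-score it.

    Spike trains (:class:`SpikeTrain` or a 1-D array of spike times with
    ``duration`` given) become counts per bin; continuous traces (with
    ``frame_rate`` given) become the per-bin mean of their frames.  The
    binned series is normalized to mean 0, SD 1.
    """
    if isinstance(data, SpikeTrain):
        times = data.times
        if duration is None:
            raise ValueError("spike binning requires the session duration")
        if duration <= 10.0:
            raise ValueError("series span must exceed 10 s")
        n_bins = int(round(duration / bin_width))
        v, _ = np.histogram(times, bins=n_bins, range=(0.0, duration))
        v = v.astype(float)
    else:
        x = np.asarray(data, dtype=float).ravel()
        if frame_rate is None:
            raise ValueError("trace binning requires the frame rate")
        duration = x.size / frame_rate if duration is None else duration
        if duration <= 10.0:
            raise ValueError("series span must exceed 10 s")
        n_bins = int(round(duration / bin_width))
        v = _bin_trace(x, frame_rate, bin_width, n_bins)
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (v - v.mean()) / sd


def cross_correlate(x: np.ndarray, y: np.ndarray, bin_width: float = 0.010,
                    max_lag: float = 2.0) -> CrossCorrelation:
    """Normalized cross-correlogram of two z-scored binned series.

    ``value(k) = (1/N) Σ_t x(t)·y(t+k)`` over the valid overlap, with N the
    full series length (biased normalization: with z-scored input the
    autocorrelation at zero lag is exactly 1 and edge lags are damped).
    Positive lag means y follows x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    k = int(round(max_lag / bin_width))
    if k >= n / 2:
        raise ValueError("max_lag must be shorter than half the span")
    full = signal.correlate(y, x, mode="full", method="fft")
    values = full[n - 1 - k:n + k] / n
    lags = np.arange(-k, k + 1) * bin_width
    return CrossCorrelation(lags=lags, values=values, bin_width=bin_width,
                            n_bins_used=n)


def peak_lag(xc: CrossCorrelation) -> Tuple[float, float]:
    """Lag and value of the correlogram maximum.

    Ties are broken toward lag 0 first, then toward the negative lag.
    """
    v = np.asarray(xc.values)
    if v.size == 0:
        raise ValueError("empty correlogram")
    best = np.flatnonzero(v == v.max())
    if best.size > 1:
        warnings.warn("tied correlogram maximum; tie-break applied")
        lags = xc.lags[best]
        order = np.lexsort((lags, np.abs(lags)))
        i = best[order[0]]
    else:
        i = best[0]
    return float(xc.lags[i]), float(v[i])


@dataclass
class PeakComparison:
    """Paired comparison of two correlogram cohorts at their peak lags."""

    lag_a: float
    lag_b: float
    t_at_lag_a: float
    p_at_lag_a: float
    t_at_lag_b: float
    p_at_lag_b: float


def _mean_correlogram(xcorrs: Sequence[CrossCorrelation]) -> CrossCorrelation:
    values = np.mean([xc.values for xc in xcorrs], axis=0)
    return CrossCorrelation(lags=xcorrs[0].lags, values=values,
                            bin_width=xcorrs[0].bin_width,
                            n_bins_used=xcorrs[0].n_bins_used)


def compare_at_peak(xcorrs_a: Sequence[CrossCorrelation],
                    xcorrs_b: Sequence[CrossCorrelation]) -> PeakComparison:
    """Compare two conditions at the peak lag of each cohort-mean correlogram.

    For each condition the peak lag of the across-cell mean correlogram is
    found; each cell's correlation value at that lag is extracted from both
    conditions and compared with a paired t-test.  Both per-condition peak
    lags (and the test at each) are reported.
    """
    if len(xcorrs_a) != len(xcorrs_b):
        raise ValueError("conditions must contain the same cells")
    if len(xcorrs_a) < 3:
        raise ValueError("need at least 3 cells")
    lags = xcorrs_a[0].lags
    lag_a, _ = peak_lag(_mean_correlogram(xcorrs_a))
    lag_b, _ = peak_lag(_mean_correlogram(xcorrs_b))
    out = {}
    for name, lag in (("a", lag_a), ("b", lag_b)):
        i = int(np.argmin(np.abs(lags - lag)))
        va = [xc.values[i] for xc in xcorrs_a]
        vb = [xc.values[i] for xc in xcorrs_b]
        out[name] = paired_test(va, vb)
    return PeakComparison(lag_a=lag_a, lag_b=lag_b,
                          t_at_lag_a=out["a"][0], p_at_lag_a=out["a"][1],
                          t_at_lag_b=out["b"][0], p_at_lag_b=out["b"][1])
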