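"""Multitaper spectra, spike–field coherence, and the circular-shift null.

Spectra use discrete prolate spheroidal (Slepian) tapers averaged over
50 %-overlapping windows.  Spike trains enter as binned counts at the
video frame rate, so spike–field coherence is the magnitude-squared
coherence |S_xy|²/(S_xx·S_yy) between the count series and the raw angle.
Significance comes from a shuffle null built by circularly rotating the
spike vector by a random offset and recomputing coherence (50 shuffles by
default).
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.signal.windows import dpss

from .containers import SpectralResult, SpikeTrain

__all__ = [
    "multitaper_psd", "spike_field_coherence", "shuffle_null_coherence",
    "band_average", "bin_spikes_at_frame_rate",
]


def _windows(n: int, win_len: int, overlap: float) -> np.ndarray:
    step = max(int(round(win_len * (1.0 - overlap))), 1)
    starts = np.arange(0, n - win_len + 1, step)
    if starts.size == 0:
        raise ValueError("window longer than the trace")
    return starts


def _taper_ffts(x: np.ndarray, starts: np.ndarray, win_len: int,
                tapers: np.ndarray) -> np.ndarray:
    """rFFTs of every (window, taper) segment: shape (n_win, K, n_freq)."""
    segs = np.stack([x[s:s + win_len] for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    return np.fft.rfft(segs[:, None, :] * tapers[None, :, :], axis=2)


def multitaper_psd(x: np.ndarray, fs: float, nw: float = 3.0, k: int = 5,
                   window: float = 10.0, overlap: float = 0.5
                   ) -> SpectralResult:
    """Multitaper power spectral density of a uniformly sampled trace.

    DPSS tapers (time–bandwidth ``nw``, ``k`` tapers) on windows of
    ``window`` seconds with the given overlap; each window is demeaned.
    One-sided density: the integral over frequency approximates the signal
    variance.
    """
    x = np.asarray(x, dtype=float)
    win_len = int(round(window * fs))
    starts = _windows(x.size, win_len, overlap)
    tapers = dpss(win_len, nw, Kmax=k)
    F = _taper_ffts(x, starts, win_len, tapers)
    psd = np.mean(np.abs(F) ** 2, axis=(0, 1)) / fs
    psd[1:-1 if win_len % 2 == 0 else None] *= 2.0
    freqs = np.fft.rfftfreq(win_len, 1.0 / fs)
    return SpectralResult(freqs=freqs, psd=psd, taper_params=(nw, k))


def bin_spikes_at_frame_rate(spikes: SpikeTrain, n_frames: int,
                             frame_rate: float) -> np.ndarray:
    """Spike counts per video frame."""
    return np.histogram(spikes.times, bins=n_frames,
                        range=(0.0, n_frames / frame_rate))[0].astype(float)


def _coherence_from_series(x: np.ndarray, y: np.ndarray, fs: float,
                           nw: float, k: int, window: float,
                           overlap: float) -> Tuple[np.ndarray, np.ndarray]:
    win_len = int(round(window * fs))
    starts = _windows(min(x.size, y.size), win_len, overlap)
    tapers = dpss(win_len, nw, Kmax=k)
    Fx = _taper_ffts(x, starts, win_len, tapers)
    Fy = _taper_ffts(y, starts, win_len, tapers)
    sxy = np.sum(Fx * np.conj(Fy), axis=(0, 1))
    sxx = np.sum(np.abs(Fx) ** 2, axis=(0, 1))
    syy = np.sum(np.abs(Fy) ** 2, axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / (sxx * syy)
    freqs = np.fft.rfftfreq(win_len, 1.0 / fs)
    return freqs, np.clip(np.nan_to_num(coh), 0.0, 1.0)


def spike_field_coherence(spikes, angle: np.ndarray, fs: float,
                          nw: float = 3.0, k: int = 5, window: float = 10.0,
                          overlap: float = 0.5,
                          min_spikes: int = 50) -> SpectralResult:
    """Magnitude-squared coherence between a unit's spiking and the angle.

    ``spikes`` may be a :class:`SpikeTrain` (binned internally at the frame
    rate) or an already-binned count series; ``angle`` is the raw
    (unfiltered) trace.  Estimates from fewer than ``min_spikes`` spikes
    are flagged unreliable.
    """
    angle = np.asarray(angle, dtype=float)
    if isinstance(spikes, SpikeTrain):
        counts = bin_spikes_at_frame_rate(spikes, angle.size, fs)
        n_spk = spikes.n_spikes
    else:
        counts = np.asarray(spikes, dtype=float)
        n_spk = int(counts.sum())
    if angle.size / fs < 60.0:
        raise ValueError("need at least 60 s of overlapping data")
    reliable = n_spk >= min_spikes
    if not reliable:
        warnings.warn(f"only {n_spk} spikes: coherence flagged unreliable")
    freqs, coh = _coherence_from_series(counts, angle, fs, nw, k, window,
                                        overlap)
    return SpectralResult(freqs=freqs, coherence=coh, taper_params=(nw, k),
                          reliable=reliable)


def shuffle_null_coherence(spikes, angle: np.ndarray, fs: float,
                           n_shuffles: int = 50, seed: int = 0,
                           margin: float = 10.0, nw: float = 3.0, k: int = 5,
                           window: float = 10.0, overlap: float = 0.5
                           ) -> SpectralResult:
    """Coherence null from circular shifts of the spike vector.

    Each shuffle rotates the binned spike series by a uniform random
    offset in [``margin``, span − ``margin``] seconds and recomputes the
    coherence; the null curve is the mean across shuffles and the full
    shuffle distribution is retained for percentile bands.
    """
    angle = np.asarray(angle, dtype=float)
    span = angle.size / fs
    if span <= 2 * margin:
        raise ValueError("trace too short for the shuffle offset margin")
    if isinstance(spikes, SpikeTrain):
        counts = bin_spikes_at_frame_rate(spikes, angle.size, fs)
    else:
        counts = np.asarray(spikes, dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, 0))
    curves = []
    for _ in range(n_shuffles):
        offset = rng.uniform(margin, span - margin)
        rolled = np.roll(counts, int(round(offset * fs)))
        freqs, coh = _coherence_from_series(rolled, angle, fs, nw, k,
                                            window, overlap)
        curves.append(coh)
    null = np.stack(curves)
    return SpectralResult(freqs=freqs, null_coherence=null.mean(axis=0),
                          null_distribution=null, taper_params=(nw, k))


def band_average(freqs: np.ndarray, values: np.ndarray,
                 band: Tuple[float, float]) -> float:
    """Mean of a spectral curve over frequency bins inside [lo, hi]."""
    freqs = np.asarray(freqs, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(values[mask].mean())
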