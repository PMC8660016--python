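"""Whisker-angle decomposition: phase, envelopes, amplitude, bout labels.

The median whisker angle is band-pass filtered (4–30 Hz, zero-phase),
passed through a Hilbert transform for instantaneous phase (0 = most
protracted, ±π = most retracted), and the unfiltered angle is sampled at
the phase-0 / ±π anchors to form protraction and retraction envelopes;
whisking amplitude is their difference.  Frames where amplitude exceeds
20 % of its maximum for at least 250 ms are whisking, shorter
supra-threshold runs are ambiguous, and everything else is quiescent.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (AMBIGUOUS, QUIESCENT, WHISKING, AngleTrace,
                         WhiskDecomposition)

__all__ = [
    "median_angle", "bandpass_angle", "compute_phase", "compute_amplitude",
    "segment_bouts", "whisking_fraction", "motion_energy", "decompose",
    "WhiskerKinematics",
]


def median_angle(per_whisker: np.ndarray, frame_rate: float,
                 max_gap: float = 0.08) -> AngleTrace:
    """Per-frame median across tracked whiskers, NaN entries ignored.

    Frames with no tracked whisker form gaps; gaps shorter than
    ``max_gap`` seconds are linearly interpolated, longer gaps raise.
    """
    mat = np.asarray(per_whisker, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        med = np.nanmedian(mat, axis=1)
    missing = ~np.isfinite(med)
    if missing.any():
        runs = _runs(missing)
        max_frames = int(round(max_gap * frame_rate))
        for i0, i1 in runs:
            if i1 - i0 >= max_frames or i0 == 0 or i1 == med.size:
                raise ValueError(
                    f"untracked gap of {(i1 - i0) / frame_rate * 1e3:.0f} ms "
                    f"exceeds {max_gap * 1e3:.0f} ms")
        good = np.flatnonzero(~missing)
        med[missing] = np.interp(np.flatnonzero(missing), good, med[good])
    return AngleTrace(med, frame_rate)


def _runs(mask: np.ndarray) -> list:
    """[start, stop) index pairs of True runs."""
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(edges[::2], edges[1::2]))


def bandpass_angle(samples: np.ndarray, frame_rate: float,
                   lo: float = 4.0, hi: float = 30.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward–backward) Butterworth band-pass of the angle."""
    x = np.asarray(samples, dtype=float)
    if not frame_rate > 2 * hi:
        raise ValueError("frame rate must exceed twice the upper band edge")
    ntaps = 2 * order + 1
    if x.size <= 3 * 3 * ntaps:
        raise ValueError("trace too short to band-pass filter")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=frame_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, x - x.mean())


def compute_phase(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the band-passed angle via the analytic signal.

    Phase is 0 at local maxima of the filtered angle (most protracted) and
    ±π at minima (most retracted), taking angle to increase with
    protraction.  An all-zero input has no defined phase and returns NaN.
    """
    x = np.asarray(filtered, dtype=float)
    if np.allclose(x, 0.0):
        return np.full(x.size, np.nan)
    return np.angle(signal.hilbert(x))


def _zero_crossings(phase: np.ndarray) -> np.ndarray:
    """Frame indices nearest to upward crossings of phase through 0."""
    d = np.diff(phase)
    cross = np.flatnonzero((phase[:-1] < 0) & (phase[1:] >= 0) & (d < np.pi))
    if cross.size == 0:
        return cross
    pick_right = np.abs(phase[cross + 1]) < np.abs(phase[cross])
    return cross + pick_right.astype(int)


def _pi_crossings(phase: np.ndarray) -> np.ndarray:
    """Frame indices nearest to the ±π wrap (most retracted)."""
    d = np.diff(phase)
    cross = np.flatnonzero((phase[:-1] > 0) & (phase[1:] < 0) & (d < -np.pi))
    if cross.size == 0:
        return cross
    pick_right = (np.pi + phase[cross + 1]) < (np.pi - phase[cross])
    return cross + pick_right.astype(int)


def compute_amplitude(angle: np.ndarray, phase: np.ndarray
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Protraction/retraction envelopes of the *unfiltered* angle.

    The unfiltered angle is sampled at phase-0 crossings (upper anchors)
    and ±π crossings (lower anchors); envelopes interpolate linearly
    between consecutive anchors and hold the nearest anchor value beyond
    the first/last.  Amplitude is upper − lower, clipped at zero.  With
    fewer than two anchors of either kind there are no whisk cycles and
    amplitude is zero throughout.
    """
    angle = np.asarray(angle, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if angle.size != phase.size:
        raise ValueError("angle and phase must have equal length")
    n = angle.size
    idx = np.arange(n)
    up_i = _zero_crossings(phase)
    lo_i = _pi_crossings(phase)
    if up_i.size < 2 or lo_i.size < 2:
        nanv = np.full(n, np.nan)
        return nanv, nanv.copy(), np.zeros(n)
    upper = np.interp(idx, up_i, angle[up_i])
    lower = np.interp(idx, lo_i, angle[lo_i])
    amplitude = np.clip(upper - lower, 0.0, None)
    return upper, lower, amplitude


def segment_bouts(amplitude: np.ndarray, frame_rate: float,
                  threshold_frac: float = 0.2, min_dur: float = 0.25,
                  threshold_mode: str = "max") -> np.ndarray:
    """Label frames whisking / ambiguous / quiescent by the bout rule.

    The threshold is ``threshold_frac`` times the maximum amplitude over
    the recording (``threshold_mode='p99'`` substitutes the 99th percentile
    for robustness to tracker glitches).  Supra-threshold runs of at least
    ``min_dur`` seconds are whisking; shorter supra-threshold runs are
    ambiguous and excluded from state analyses; everything below threshold
    is quiescent.
    """
    amp = np.asarray(amplitude, dtype=float)
    if threshold_mode == "max":
        ref = np.nanmax(amp) if amp.size else 0.0
    elif threshold_mode == "p99":
        ref = np.nanpercentile(amp, 99) if amp.size else 0.0
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    thr = threshold_frac * ref
    state = np.full(amp.size, QUIESCENT, dtype=np.int8)
    if ref <= 0:
        return state
    min_frames = int(np.ceil(min_dur * frame_rate))
    for i0, i1 in _runs(amp > thr):
        state[i0:i1] = WHISKING if (i1 - i0) >= min_frames else AMBIGUOUS
    return state


def whisking_fraction(state: np.ndarray) -> float:
    """Percent of unambiguous frames labelled whisking."""
    state = np.asarray(state)
    n_w = int(np.sum(state == WHISKING))
    n_q = int(np.sum(state == QUIESCENT))
    if n_w + n_q == 0:
        raise ValueError("no unambiguous frames")
    return 100.0 * n_w / (n_w + n_q)


def motion_energy(frames: np.ndarray) -> Tuple[np.ndarray, float]:
    """Mean absolute successive-frame difference: per-pixel map and mean."""
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("motion energy needs at least two frames")
    emap = np.mean(np.abs(np.diff(stack, axis=0)), axis=0)
    return emap, float(emap.mean())


class WhiskerKinematics(BaseEstimator, TransformerMixin):
    """Transformer from an angle trace to its kinematic decomposition.

    ``fit`` runs the full decomposition and stores the results as fitted
    attributes (``filtered_``, ``phase_``, ``amplitude_``, ``state_`` ...);
    ``transform`` returns them stacked as columns
    (filtered, phase, amplitude, state).

    Parameters
    ----------
    frame_rate : float
        Sampling rate in Hz of the angle trace passed to :meth:`fit`.
    lowcut, highcut : float
        Band-pass edges in Hz (defaults 4 and 30).
    threshold_frac : float
        Whisking threshold as a fraction of the maximum amplitude.
    min_dur : float
        Minimum whisking-bout duration in seconds.
    threshold_mode : {'max', 'p99'}
        Amplitude reference for the threshold.
    """

    def __init__(self, frame_rate: float = 125.0, lowcut: float = 4.0,
                 highcut: float = 30.0, threshold_frac: float = 0.2,
                 min_dur: float = 0.25, threshold_mode: str = "max"):
        self.frame_rate = frame_rate
        self.lowcut = lowcut
        self.highcut = highcut
        self.threshold_frac = threshold_frac
        self.min_dur = min_dur
        self.threshold_mode = threshold_mode

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        self.filtered_ = bandpass_angle(x, self.frame_rate,
                                        self.lowcut, self.highcut)
        self.phase_ = compute_phase(self.filtered_)
        self.upper_env_, self.lower_env_, self.amplitude_ = \
            compute_amplitude(x, self.phase_)
        self.state_ = segment_bouts(self.amplitude_, self.frame_rate,
                                    self.threshold_frac, self.min_dur,
                                    self.threshold_mode)
        ref = np.nanmax(self.amplitude_) if self.amplitude_.size else 0.0
        if self.threshold_mode == "p99":
            ref = np.nanpercentile(self.amplitude_, 99)
        self.threshold_ = self.threshold_frac * ref
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        if not hasattr(self, "state_"):
            self.fit(X)
        return np.column_stack([self.filtered_, self.phase_,
                                self.amplitude_, self.state_])


def decompose(angle: AngleTrace, **params) -> WhiskDecomposition:
    """Convenience wrapper: full decomposition of an :class:`AngleTrace`."""
    est = WhiskerKinematics(frame_rate=angle.frame_rate, **params).fit(
        angle.samples)
    return WhiskDecomposition(
        filtered=est.filtered_, phase=est.phase_, upper_env=est.upper_env_,
        lower_env=est.lower_env_, amplitude=est.amplitude_, state=est.state_,
        frame_rate=angle.frame_rate, threshold=est.threshold_)
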