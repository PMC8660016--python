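"""State-conditioned firing rates and the two-group tests built on them.

Spikes are assigned to video frames (floor of time × frame rate); frames
labelled ambiguous are excluded from both the spike counts and the time
denominators, so each rate is exactly count / labelled time.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
from scipy import stats

from .containers import QUIESCENT, WHISKING, SpikeTrain, StateRates

__all__ = [
    "spike_frames", "state_firing_rates", "percent_change",
    "paired_test", "variance_ratio_test", "rank_sum_test",
]


def spike_frames(spikes: SpikeTrain, n_frames: int,
                 frame_rate: float) -> np.ndarray:
    """0-based frame index of each spike; spikes outside the trace dropped."""
    frames = np.floor(spikes.times * frame_rate).astype(int)
    keep = (frames >= 0) & (frames < n_frames)
    if not keep.all():
        warnings.warn(f"dropped {np.sum(~keep)} spikes outside the trace")
    return frames[keep]


def state_firing_rates(spikes: SpikeTrain, state: np.ndarray,
                       frame_rate: float) -> StateRates:
    """Mean firing rate during whisking and quiescence for one unit.

    A state with zero labelled time has an undefined (NaN) rate rather
    than a zero rate.
    """
    state = np.asarray(state)
    frames = spike_frames(spikes, state.size, frame_rate)
    spike_state = state[frames]
    n_w = int(np.sum(spike_state == WHISKING))
    n_q = int(np.sum(spike_state == QUIESCENT))
    t_w = float(np.sum(state == WHISKING)) / frame_rate
    t_q = float(np.sum(state == QUIESCENT)) / frame_rate
    r_w = n_w / t_w if t_w > 0 else np.nan
    r_q = n_q / t_q if t_q > 0 else np.nan
    return StateRates(rate_quiescent=r_q, rate_whisking=r_w,
                      time_quiescent=t_q, time_whisking=t_w,
                      n_spikes_q=n_q, n_spikes_w=n_w,
                      unit_id=spikes.unit_id)


def percent_change(rate_quiescent: float, rate_whisking: float) -> float:
    """Percent change from quiescent to whisking rate; NaN if r_Q is 0."""
    if not rate_quiescent > 0:
        return np.nan
    return 100.0 * (rate_whisking - rate_quiescent) / rate_quiescent


def paired_test(a, b) -> Tuple[float, float]:
    """Two-sided paired t-test (df = n − 1) between per-cell value pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("paired t-test needs at least 3 pairs")
    d = b - a
    if np.all(d == d[0]):
        # degenerate: zero variance of the differences
        if d[0] == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance differences; p degenerate")
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(b, a)
    return float(t), float(p)


def variance_ratio_test(a, b) -> Tuple[float, float]:
    """Two-sided two-sample F-test on variances: F = var(a)/var(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("variance-ratio test needs n >= 2 per group")
    vb = np.var(b, ddof=1)
    if vb == 0:
        raise ValueError("zero variance in the denominator group")
    F = float(np.var(a, ddof=1) / vb)
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(p, 1.0))


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value, ties mid-ranked."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test needs non-empty groups")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
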