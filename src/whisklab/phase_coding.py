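"""Spike-phase tuning: binned rate-vs-phase curves, sinusoid fits,
modulation depth, and Kuiper-test significance with Bonferroni correction.

Each spike fired while the animal is whisking is assigned the whisking
phase of its video frame.  The spike-phase histogram (32 equal bins over
(−π, π]) is normalized by phase occupancy (time the whiskers spend at each
phase) to give firing rate as a function of phase; a period-2π sinusoid is
fit by linear least squares; modulation depth is the fitted amplitude
divided by the mean firing rate.  Significance compares the unbinned spike
phases against the whisking-frame phase distribution with a two-sample
Kuiper test, Bonferroni-corrected across cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .containers import WHISKING, PhaseTuning, SpikeTrain
from .state_activity import spike_frames

__all__ = [
    "spike_phases", "phase_occupancy", "tuning_curve", "fit_sinusoid",
    "modulation_depth", "kuiper_two_sample", "kuiper_statistic",
    "kuiper_p_asymptotic", "bonferroni", "KuiperResult", "PhaseTuningModel",
    "phase_tuning",
]


def phase_bin_edges(n_bins: int = 32) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def spike_phases(spikes: SpikeTrain, phase: np.ndarray, state: np.ndarray,
                 frame_rate: float) -> np.ndarray:
    """Whisking phase of each spike fired in a whisking frame."""
    phase = np.asarray(phase, dtype=float)
    frames = spike_frames(spikes, phase.size, frame_rate)
    frames = frames[np.asarray(state)[frames] == WHISKING]
    return phase[frames]


def phase_occupancy(phase: np.ndarray, state: np.ndarray, frame_rate: float,
                    n_bins: int = 32) -> np.ndarray:
    """Seconds spent at each phase bin while whisking."""
    phase = np.asarray(phase, dtype=float)
    whisk = np.asarray(state) == WHISKING
    if not whisk.any():
        raise ValueError("no whisking frames: phase occupancy undefined")
    counts, _ = np.histogram(phase[whisk], bins=phase_bin_edges(n_bins))
    return counts / frame_rate


def tuning_curve(spike_phase: np.ndarray, occupancy: np.ndarray,
                 frame_rate: float = 125.0) -> Tuple[np.ndarray, np.ndarray]:
    """Firing rate per phase bin: spike counts / occupancy.

    Bins occupied for less than one frame are undefined (NaN rate).
    Returns ``(counts, rate)``.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if not np.any(occupancy > 0):
        raise ValueError("all-zero occupancy")
    counts, _ = np.histogram(spike_phase, bins=phase_bin_edges(occupancy.size))
    rate = np.full(occupancy.size, np.nan)
    ok = occupancy >= 1.0 / frame_rate
    rate[ok] = counts[ok] / occupancy[ok]
    return counts, rate


def fit_sinusoid(rate: np.ndarray,
                 bin_centers: Optional[np.ndarray] = None
                 ) -> Tuple[float, float, float]:
    """Least-squares fit of ``a + b·cos(φ − φ0)`` to the binned rate curve.

    Linear in (a, c, d) with rate ≈ a + c·cosφ + d·sinφ, so
    b = √(c² + d²) ≥ 0 and φ0 = atan2(d, c).  Undefined (NaN) bins are
    omitted; at least three defined bins are required.  A flat curve has
    b = 0 and an undefined (NaN) preferred phase.
    """
    rate = np.asarray(rate, dtype=float)
    if bin_centers is None:
        edges = phase_bin_edges(rate.size)
        bin_centers = 0.5 * (edges[:-1] + edges[1:])
    ok = np.isfinite(rate)
    if np.sum(ok) < 3:
        raise ValueError("need at least 3 defined bins to fit a sinusoid")
    phi = bin_centers[ok]
    X = np.column_stack([np.ones(phi.size), np.cos(phi), np.sin(phi)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: too few distinct bins")
    a, c, d = np.linalg.lstsq(X, rate[ok], rcond=None)[0]
    b = math.hypot(c, d)
    # flat curve: amplitude at rounding level, preferred phase undefined
    if b <= 1e-9 * max(1.0, abs(a)):
        return float(a), float(b), float("nan")
    return float(a), float(b), float(math.atan2(d, c))


def modulation_depth(fit_amplitude: float, mean_rate: float,
                     peak_trough: bool = False) -> float:
    """Fitted sinusoid amplitude over mean firing rate (dimensionless).

    ``peak_trough=True`` reports the peak-to-trough variant (2b / mean).
    """
    if not mean_rate > 0:
        return np.nan
    depth = fit_amplitude / mean_rate
    return 2.0 * depth if peak_trough else depth


@dataclass
class KuiperResult:
    V: float
    p: float
    n_effective: float


def kuiper_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kuiper statistic V = sup(F−G) + sup(G−F).

    Rotation-invariant analogue of the two-sample KS statistic for
    circular data.  Ties between the samples are handled by evaluating the
    CDF difference only after all jumps at a tied value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Kuiper test needs non-empty samples")
    data = np.concatenate([a, b])
    step = np.concatenate([np.full(a.size, 1.0 / a.size),
                           np.full(b.size, -1.0 / b.size)])
    order = np.argsort(data, kind="mergesort")
    data, step = data[order], np.cumsum(step[order])
    # evaluate only at the last jump of each distinct value
    last = np.r_[data[1:] != data[:-1], True]
    d = step[last]
    return float(max(d.max(), 0.0) - min(d.min(), 0.0))


def kuiper_p_asymptotic(V: float, n: int, m: int) -> float:
    """Asymptotic two-sample Kuiper tail probability.

    Uses the effective size N_e = nm/(n+m) with the small-sample
    correction λ = (√N_e + 0.155 + 0.24/√N_e)·V and the standard tail
    series  p = 2·Σ_j (4j²λ² − 1)·exp(−2j²λ²).
    """
    ne = n * m / (n + m)
    lam = (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne)) * V
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101)
    p = 2.0 * np.sum((4.0 * j ** 2 * lam ** 2 - 1.0)
                     * np.exp(-2.0 * j ** 2 * lam ** 2))
    return float(min(max(p, 0.0), 1.0))


def kuiper_two_sample(a, b, n_permutations: int = 0,
                      rng: Optional[np.random.Generator] = None
                      ) -> KuiperResult:
    """Two-sample Kuiper test for circular samples on (−π, π].

    By default the p-value is asymptotic; with ``n_permutations > 0`` it is
    estimated by pooling and relabelling instead (preferred for small
    samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    V = kuiper_statistic(a, b)
    ne = a.size * b.size / (a.size + b.size)
    if n_permutations > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled.size)
            if kuiper_statistic(pooled[perm[:a.size]],
                                pooled[perm[a.size:]]) >= V:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        p = kuiper_p_asymptotic(V, a.size, b.size)
    return KuiperResult(V=V, p=float(p), n_effective=ne)


def bonferroni(p_values, n: Optional[int] = None) -> np.ndarray:
    """Bonferroni correction: min(1, p × n); n defaults to len(p_values)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size if n is None else int(n)
    return np.minimum(1.0, p * n)


class PhaseTuningModel(BaseEstimator):
    """Estimator of a unit's spike-phase tuning.

    ``fit(spike_phases, frame_phases)`` takes the phases of spikes fired
    during whisking and the phases of all whisking video frames, and
    estimates the occupancy-normalized tuning curve, its sinusoid fit,
    modulation depth, and Kuiper significance.

    Parameters
    ----------
    n_bins : int
        Number of equal phase bins over (−π, π] (default 32).
    frame_rate : float
        Video frame rate in Hz; converts frame counts to occupancy time.
    peak_trough_depth : bool
        If True report modulation depth as peak-to-trough over mean
        (2b/r̄) instead of the sinusoid amplitude over mean (b/r̄).
    bonferroni_n : int or None
        Number of comparisons for the corrected p-value (defaults to 1).
    n_permutations : int
        If > 0, use a permutation Kuiper p-value instead of asymptotics.
    occupancy_cap : int
        Subsample the frame-phase sample to at most this many frames when
        running permutations (keeps the permutation cost bounded).

    Attributes
    ----------
    rate_ : ndarray of shape (n_bins,)
        Occupancy-normalized firing rate per phase bin (Hz).
    offset_, amplitude_ : float
        Fitted sinusoid offset a and amplitude b (Hz).
    preferred_phase_ : float
        Phase of peak firing, radians in (−π, π].
    modulation_depth_ : float
        Dimensionless depth (see ``peak_trough_depth``).
    kuiper_V_, p_raw_, p_corrected_ : float
        Kuiper statistic and raw / Bonferroni-corrected p-values.
    """

    def __init__(self, n_bins: int = 32, frame_rate: float = 125.0,
                 peak_trough_depth: bool = False,
                 bonferroni_n: Optional[int] = None,
                 n_permutations: int = 0, occupancy_cap: int = 100_000,
                 random_state: int = 0):
        self.n_bins = n_bins
        self.frame_rate = frame_rate
        self.peak_trough_depth = peak_trough_depth
        self.bonferroni_n = bonferroni_n
        self.n_permutations = n_permutations
        self.occupancy_cap = occupancy_cap
        self.random_state = random_state

    def fit(self, X, frame_phases):
        sp = np.asarray(X, dtype=float).ravel()
        fp = np.asarray(frame_phases, dtype=float).ravel()
        if fp.size == 0:
            raise ValueError("no whisking frames")
        counts, _ = np.histogram(fp, bins=phase_bin_edges(self.n_bins))
        self.occupancy_ = counts / self.frame_rate
        self.spike_counts_, self.rate_ = tuning_curve(
            sp, self.occupancy_, self.frame_rate)
        self.offset_, self.amplitude_, self.preferred_phase_ = \
            fit_sinusoid(self.rate_)
        whisk_time = fp.size / self.frame_rate
        self.mean_rate_ = sp.size / whisk_time
        self.modulation_depth_ = modulation_depth(
            self.amplitude_, self.mean_rate_, self.peak_trough_depth)
        rng = np.random.default_rng(self.random_state)
        occ_sample = fp
        if self.n_permutations > 0 and fp.size > self.occupancy_cap:
            occ_sample = rng.choice(fp, self.occupancy_cap, replace=False)
        res = kuiper_two_sample(sp, occ_sample,
                                n_permutations=self.n_permutations, rng=rng)
        self.kuiper_V_ = res.V
        self.p_raw_ = res.p
        self.p_corrected_ = float(bonferroni([res.p], self.bonferroni_n)[0])
        self.n_features_in_ = 1
        return self

    def to_tuning(self, unit_id: int = 0) -> PhaseTuning:
        return PhaseTuning(
            bin_edges=phase_bin_edges(self.n_bins), occupancy=self.occupancy_,
            spike_counts=self.spike_counts_, rate=self.rate_,
            fit_offset=self.offset_, fit_amplitude=self.amplitude_,
            preferred_phase=self.preferred_phase_,
            modulation_depth=self.modulation_depth_, kuiper_v=self.kuiper_V_,
            p_raw=self.p_raw_, p_corrected=self.p_corrected_,
            unit_id=unit_id)


def phase_tuning(spikes: SpikeTrain, phase: np.ndarray, state: np.ndarray,
                 frame_rate: float, **model_params) -> PhaseTuning:
    """Full per-unit phase analysis from spikes + decomposition."""
    sp = spike_phases(spikes, phase, state, frame_rate)
    fp = np.asarray(phase)[np.asarray(state) == WHISKING]
    model = PhaseTuningModel(frame_rate=frame_rate, **model_params)
    model.fit(sp, fp)
    return model.to_tuning(unit_id=spikes.unit_id)
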