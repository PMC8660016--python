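"""Core in-memory containers shared across the analysis stages.

All traces are uniformly sampled at a session frame rate (video frames are
the master clock); spike times are in seconds on the same time base, with
t = 0 at the first video frame.  Per-frame behavioural state uses the
integer codes :data:`QUIESCENT`, :data:`WHISKING`, :data:`AMBIGUOUS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Per-frame behavioural state codes.
QUIESCENT: int = 0
WHISKING: int = 1
AMBIGUOUS: int = 2


@dataclass
class AngleTrace:
    """Uniformly sampled median whisker angle.

    Parameters
    ----------
    samples : array of float
        Angle in degrees, one value per video frame.
    frame_rate : float
        Sampling rate in Hz (video frame rate, nominally 125).
    t0 : float
        Time of the first frame in seconds.
    """

    samples: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("angle trace must be one-dimensional")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit, optionally with its mean waveform."""

    times: np.ndarray
    unit_id: int = 0
    waveform: Optional[np.ndarray] = None
    waveform_fs: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted ascending")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class PupilTrace:
    """Per-frame pupil diameter with validity flags.

    Diameter units are pixels when measured from video and arbitrary units
    when synthesised; every downstream statistic z-scores the trace, so the
    absolute scale never enters an analysis.
    """

    diameter: np.ndarray
    frame_rate: float
    center: Optional[np.ndarray] = None  # (n, 2) of (x, y)
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.diameter)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class WhiskDecomposition:
    """Output of the kinematic decomposition of an angle trace.

    ``amplitude`` is the difference between the protraction (upper) and
    retraction (lower) envelopes of the unfiltered angle, sampled at phase 0
    and ±π of the 4–30 Hz band-passed trace; ``state`` labels each frame
    whisking / quiescent / ambiguous by the amplitude-threshold bout rule.
    """

    filtered: np.ndarray
    phase: np.ndarray
    upper_env: np.ndarray
    lower_env: np.ndarray
    amplitude: np.ndarray
    state: np.ndarray
    frame_rate: float
    threshold: float = np.nan


@dataclass
class StateRates:
    """State-conditioned firing rates for one unit (rate = count / time)."""

    rate_quiescent: float
    rate_whisking: float
    time_quiescent: float
    time_whisking: float
    n_spikes_q: int
    n_spikes_w: int
    unit_id: int = 0


@dataclass
class PhaseTuning:
    """Firing rate versus whisking phase, with sinusoid fit and Kuiper test."""

    bin_edges: np.ndarray
    occupancy: np.ndarray       # seconds per bin
    spike_counts: np.ndarray
    rate: np.ndarray            # Hz per bin; NaN where occupancy undefined
    fit_offset: float
    fit_amplitude: float
    preferred_phase: float
    modulation_depth: float
    kuiper_v: float
    p_raw: float
    p_corrected: float
    unit_id: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def significant(self) -> bool:
        return bool(self.p_corrected < 0.05)


@dataclass
class CrossCorrelation:
    """Normalized cross-correlogram on a symmetric lag grid.

    Positive lag means the second series follows (is delayed relative to)
    the first.  With z-scored inputs the autocorrelation at zero lag is
    exactly one.
    """

    lags: np.ndarray
    values: np.ndarray
    bin_width: float
    n_bins_used: int


@dataclass
class SpectralResult:
    """Multitaper spectrum / coherence on a common frequency grid."""

    freqs: np.ndarray
    psd: Optional[np.ndarray] = None
    coherence: Optional[np.ndarray] = None
    null_coherence: Optional[np.ndarray] = None
    null_distribution: Optional[np.ndarray] = None  # (n_shuffles, n_freqs)
    taper_params: tuple = (3.0, 5)
    band_low: tuple = (0.5, 5.0)
    band_high: tuple = (8.0, 13.0)
    reliable: bool = True


@dataclass
class SessionContainer:
    """One recording session: angle trace, spike trains, optional pupil."""

    angle: AngleTrace
    units: list = field(default_factory=list)
    pupil: Optional[PupilTrace] = None
    condition_epochs: list = field(default_factory=list)  # (label, t0, t1)
    metadata: dict = field(default_factory=dict)

    def epochs_for(self, label: str) -> list:
        out = [(t0, t1) for (lab, t0, t1) in self.condition_epochs if lab == label]
        for (a0, a1), (b0, b1) in zip(out, out[1:]):
            if b0 < a1:
                raise ValueError(f"epochs for label {label!r} overlap")
        return out
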