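"""Synthetic whisking sessions with known ground truth.

Generates the statistical structure the downstream analysis assumes:
alternating whisking/quiescent bouts, an angle trace built from a slow
envelope times a fast 8–13 Hz carrier, a pupil trace that is a delayed,
smoothed, noisy copy of the whisking envelope, inhomogeneous-Poisson spike
trains with state-dependent rate and optional phase locking, and eye-image
stacks with a dark pupil disk of known diameter.  Every generated quantity
is returned as ground truth so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal

from .containers import (AMBIGUOUS, QUIESCENT, WHISKING, AngleTrace,
                         PupilTrace, SpikeTrain)

__all__ = [
    "SessionParams", "EyeImageParams", "SyntheticSession",
    "generate_bout_process", "generate_whisker_angle", "generate_pupil",
    "generate_spikes", "generate_eye_frames", "generate_session",
]


@dataclass
class SessionParams:
    """Parameters of one synthetic session.

    Defaults follow the study conditions the analysis is built for: 125
    frames/s video, an 8–13 Hz whisk carrier, quiescent/whisking mean rates
    of 7.8 and 12.4 Hz (secondary somatosensory thalamus cohort means), and
    a pupil that lags the whisking envelope by 0.88 s.  Bout-duration means
    (2 s whisking / 4 s quiescence, whisking fraction 1/3) are a realistic
    choice for head-fixed mice and are exposed as configuration.
    """

    duration: float = 600.0          # s
    frame_rate: float = 125.0        # Hz
    mean_bout_dur: float = 2.0       # s, whisking
    mean_quiet_dur: float = 4.0      # s, quiescence
    min_bout_dur: float = 0.25       # s, truncation floor for whisk bouts
    carrier_band: tuple = (8.0, 13.0)  # Hz
    peak_amplitude: float = 20.0     # degrees, peak-to-trough of envelope
    baseline_angle: float = 90.0     # degrees
    setpoint_gain: float = 0.5       # degrees of setpoint shift per degree
                                     # of envelope (whiskers protract
                                     # overall during whisking bouts)
    angle_drift_sd: float = 0.5      # degrees, slow (<1 Hz) setpoint drift
    angle_noise_sd: float = 0.1      # degrees, per-frame tracker noise
    ramp_dur: float = 0.15           # s, raised-cosine envelope ramps
    pupil_lag: float = 0.88          # s, pupil dilation after whisking
    pupil_smooth_tau: float = 0.2    # s, causal low-pass time constant
    pupil_noise_sd: float = 0.05     # fraction of pupil-signal SD
    rate_quiet: float = 7.8          # Hz
    rate_whisk: float = 12.4         # Hz
    phase_mod_depth: float = 0.3     # m >= 0, multiplicative phase locking
    preferred_phase: float = 0.0     # radians in (-pi, pi]
    seed: int = 0

    def validate(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.mean_bout_dur <= 0 or self.mean_quiet_dur <= 0:
            raise ValueError("mean bout/quiet durations must be positive")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.frame_rate / 2):
            raise ValueError("carrier band must lie inside (0, frame_rate/2)")
        if self.rate_quiet < 0 or self.rate_whisk < 0:
            raise ValueError("firing rates must be non-negative")
        if self.phase_mod_depth < 0:
            raise ValueError("phase modulation depth must be >= 0")
        if self.pupil_noise_sd < 0:
            raise ValueError("pupil noise SD must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class EyeImageParams:
    """Geometry and noise of synthetic eye frames (pixel units)."""

    shape: tuple = (120, 160)        # (rows, cols)
    center: tuple = (60.0, 80.0)     # (row, col) of the iris
    iris_radius: float = 45.0
    bg_level: float = 0.55
    iris_level: float = 0.85
    pupil_level: float = 0.10
    center_jitter: float = 1.0       # px SD of pupil-center jitter
    noise_sd: float = 0.02           # grey-level units


@dataclass
class SyntheticSession:
    """A generated session together with all of its ground truth."""

    angle: AngleTrace
    true_envelope: np.ndarray
    true_phase: np.ndarray
    true_state: np.ndarray
    pupil: PupilTrace
    spikes: SpikeTrain
    params: SessionParams


def generate_bout_process(params: SessionParams,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Alternating whisking/quiescence indicator, one value per frame.

    Quiescent durations are exponential with mean ``mean_quiet_dur``; whisk
    bout durations are exponential truncated below at ``min_bout_dur``
    (drawn as ``min + Exp(mean - min)``), so every generated bout satisfies
    the downstream 250 ms bout rule by construction.  The long-run whisking
    fraction is ``mean_bout_dur / (mean_bout_dur + mean_quiet_dur)``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = params.n_frames
    state = np.zeros(n, dtype=np.int8)
    if np.isinf(params.mean_quiet_dur):
        return state
    bout_scale = max(params.mean_bout_dur - params.min_bout_dur, 1e-6)
    t = 0.0
    whisking = False
    while t < params.duration:
        if whisking:
            dur = params.min_bout_dur + rng.exponential(bout_scale)
        else:
            dur = rng.exponential(params.mean_quiet_dur)
        i0 = int(round(t * params.frame_rate))
        i1 = min(int(round((t + dur) * params.frame_rate)), n)
        if whisking:
            state[i0:i1] = WHISKING
        t += dur
        whisking = not whisking
    return state


def _raised_cosine_envelope(state: np.ndarray, params: SessionParams) -> np.ndarray:
    """Smooth 0/1 indicator into a per-frame envelope, ramps inside bouts.

    Each whisking segment ramps up and down with a raised cosine of duration
    min(ramp_dur, L/3); the envelope is exactly zero on quiescent frames, so
    the ground-truth state stays consistent with a 20 %-of-max threshold.
    """
    fs = params.frame_rate
    env = np.zeros(state.size, dtype=float)
    edges = np.flatnonzero(np.diff(np.r_[0, state == WHISKING, 0].astype(int)))
    for s0, s1 in zip(edges[::2], edges[1::2]):
        length = s1 - s0
        ramp = min(int(round(params.ramp_dur * fs)), max(length // 3, 1))
        seg = np.ones(length)
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        seg[:ramp] = up
        seg[length - ramp:] = up[::-1]
        env[s0:s1] = seg
    return params.peak_amplitude * env


def _carrier_phase(n: int, params: SessionParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Carrier phase advancing at a slowly wandering frequency in-band.

    The instantaneous frequency follows a mean-reverting (OU-like) walk
    clipped to the carrier band, giving a broad spectral peak rather than a
    line, as real whisking shows.
    """
    lo, hi = params.carrier_band
    dt = 1.0 / params.frame_rate
    mu = 0.5 * (lo + hi)
    theta = 1.0                      # 1/s mean reversion
    sd = (hi - lo) / 4.0             # stationary SD of the walk
    sigma = sd * math.sqrt(2 * theta)
    steps = rng.standard_normal(n)
    f = np.empty(n)
    f[0] = mu
    for i in range(1, n):
        f[i] = f[i - 1] + theta * (mu - f[i - 1]) * dt \
            + sigma * math.sqrt(dt) * steps[i]
        if f[i] < lo:
            f[i] = lo
        elif f[i] > hi:
            f[i] = hi
    phase = 2 * np.pi * np.cumsum(f) * dt
    return np.angle(np.exp(1j * phase))


def _slow_drift(n: int, params: SessionParams,
                rng: np.random.Generator) -> np.ndarray:
    """Sub-1-Hz setpoint drift that survives neither bandpass nor envelope."""
    if params.angle_drift_sd <= 0 or n < 100:
        return np.zeros(n)
    pad = int(2 * params.frame_rate)
    white = rng.standard_normal(n + 2 * pad)
    b, a = signal.butter(2, 1.0, btype="low", fs=params.frame_rate)
    slow = signal.filtfilt(b, a, white)[pad:pad + n]  # trim edge transients
    sd = slow.std()
    if sd > 0:
        slow *= params.angle_drift_sd / sd
    return slow


def generate_whisker_angle(state: np.ndarray, params: SessionParams,
                           rng: Optional[np.random.Generator] = None):
    """Angle = baseline + setpoint(E) + (E/2)·cos(carrier) + drift + noise.

    Returns ``(AngleTrace, true_envelope, true_phase)``.  ``true_envelope``
    is the peak-to-trough excursion E(t) (degrees), so the cosine term has
    amplitude E/2 and the within-bout angle range is ≈ E.  The setpoint
    term shifts the mean angle protracted in proportion to the envelope,
    reproducing the dominant low-frequency (< 5 Hz) power of real whisker
    traces; it is removed by the 4–30 Hz bandpass and cancels in the
    upper − lower envelope difference, so amplitude and phase ground truth
    are unaffected.
    """
    params.validate()
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    n = state.size
    env = _raised_cosine_envelope(state, params)
    phase = _carrier_phase(n, params, rng)
    drift = _slow_drift(n, params, rng)
    noise = params.angle_noise_sd * rng.standard_normal(n)
    # the setpoint tracks the envelope but more sluggishly (< ~1 Hz), so
    # its bout-onset transients stay below the 4 Hz analysis band
    if params.setpoint_gain != 0 and n > 300:
        b, a = signal.butter(2, 1.0, btype="low", fs=params.frame_rate)
        setpoint = params.setpoint_gain * signal.filtfilt(b, a, env)
    else:
        setpoint = params.setpoint_gain * env
    samples = params.baseline_angle + setpoint \
        + 0.5 * env * np.cos(phase) + drift + noise
    return AngleTrace(samples, params.frame_rate), env, phase


def generate_pupil(envelope: np.ndarray, frame_rate: float, lag: float,
                   tau: float = 0.0, noise_sd: float = 0.0,
                   rng: Optional[np.random.Generator] = None,
                   out_range: tuple = (1.0, 2.5)) -> PupilTrace:
    """Pupil trace: delayed, causally smoothed, rescaled, noisy envelope.

    The envelope is shifted later by ``lag`` seconds (edges held at the
    first value), low-pass filtered with a causal single-pole filter of
    time constant ``tau`` (a causal filter adds roughly ``tau`` of extra
    apparent delay), affinely mapped onto ``out_range`` (arbitrary units),
    and corrupted with Gaussian noise of SD ``noise_sd`` × signal SD.
    """
    env = np.asarray(envelope, dtype=float)
    n = env.size
    shift = int(round(lag * frame_rate))
    if abs(shift) >= n:
        raise ValueError("pupil lag must be shorter than the trace")
    shifted = np.empty(n)
    if shift >= 0:
        shifted[:shift] = env[0]
        shifted[shift:] = env[:n - shift]
    else:
        shifted[:n + shift] = env[-shift:]
        shifted[n + shift:] = env[-1]
    if tau > 0:
        alpha = 1.0 - math.exp(-1.0 / (tau * frame_rate))
        smoothed = signal.lfilter([alpha], [1.0, alpha - 1.0], shifted,
                                  zi=[(1 - alpha) * shifted[0]])[0]
    else:
        smoothed = shifted
    lo, hi = out_range
    span = smoothed.max() - smoothed.min()
    if span > 0:
        sig = lo + (hi - lo) * (smoothed - smoothed.min()) / span
    else:
        sig = np.full(n, lo)
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        scale = sig.std() if sig.std() > 0 else 1.0
        sig = sig + noise_sd * scale * rng.standard_normal(n)
    return PupilTrace(sig, frame_rate)


def frame_rates(state: np.ndarray, true_phase: np.ndarray,
                params: SessionParams, coupling: str = "state",
                envelope: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame target firing rate (Hz) for the spike generator.

    ``coupling='state'``: rate_quiet / rate_whisk by state, multiplied
    during whisking by ``1 + m·cos(phase − φ0)`` (clipped at zero).
    ``coupling='envelope'``: rate tracks the envelope instantaneously,
    ``rate_quiet + (rate_whisk − rate_quiet) · E(t)/peak_amplitude``.
    """
    whisking = state == WHISKING
    if coupling == "envelope":
        if envelope is None:
            raise ValueError("envelope coupling requires the envelope")
        rate = params.rate_quiet + (params.rate_whisk - params.rate_quiet) \
            * envelope / params.peak_amplitude
    elif coupling == "state":
        rate = np.where(whisking, params.rate_whisk, params.rate_quiet).astype(float)
        if params.phase_mod_depth > 0:
            mod = 1.0 + params.phase_mod_depth * np.cos(
                true_phase - params.preferred_phase)
            rate = rate * np.where(whisking, mod, 1.0)
    else:
        raise ValueError(f"unknown coupling {coupling!r}")
    return np.clip(rate, 0.0, None)


def generate_spikes(state: np.ndarray, true_phase: np.ndarray,
                    params: SessionParams,
                    rng: Optional[np.random.Generator] = None,
                    coupling: str = "state",
                    envelope: Optional[np.ndarray] = None,
                    unit_id: int = 0) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning at frame resolution."""
    params.validate()
    rng = np.random.default_rng(params.seed + 2) if rng is None else rng
    rate = frame_rates(state, true_phase, params, coupling, envelope)
    rmax = float(rate.max())
    duration = state.size / params.frame_rate
    if rmax <= 0:
        return SpikeTrain(np.empty(0), unit_id=unit_id)
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0, duration, n_cand))
    frames = np.minimum((cand * params.frame_rate).astype(int), state.size - 1)
    keep = rng.uniform(0, rmax, n_cand) < rate[frames]
    return SpikeTrain(cand[keep], unit_id=unit_id)


def generate_eye_frames(diameter_trace: np.ndarray,
                        image_params: Optional[EyeImageParams] = None,
                        rng: Optional[np.random.Generator] = None,
                        seed: int = 0):
    """Synthetic eye video: bright iris disk, dark pupil disk, pixel noise.

    Returns ``(frames, centers, diameters)`` where ``centers`` holds the
    jittered ground-truth pupil centers as (row, col) and ``diameters`` the
    planted diameters in pixels.
    """
    ip = EyeImageParams() if image_params is None else image_params
    rng = np.random.default_rng(seed) if rng is None else rng
    diam = np.asarray(diameter_trace, dtype=float)
    if np.any(diam / 2 + ip.center_jitter * 3 > ip.iris_radius):
        raise ValueError("pupil diameter exceeds the iris")
    h, w = ip.shape
    rr, cc = np.mgrid[0:h, 0:w]
    frames = np.empty((diam.size, h, w))
    centers = np.empty((diam.size, 2))
    iris = (rr - ip.center[0]) ** 2 + (cc - ip.center[1]) ** 2 \
        <= ip.iris_radius ** 2
    for i, d in enumerate(diam):
        cy = ip.center[0] + ip.center_jitter * rng.standard_normal()
        cx = ip.center[1] + ip.center_jitter * rng.standard_normal()
        frame = np.full((h, w), ip.bg_level)
        frame[iris] = ip.iris_level
        pupil = (rr - cy) ** 2 + (cc - cx) ** 2 <= (d / 2) ** 2
        frame[pupil] = ip.pupil_level
        if ip.noise_sd > 0:
            frame = frame + ip.noise_sd * rng.standard_normal((h, w))
        frames[i] = frame
        centers[i] = (cy, cx)
    return frames, centers, diam.copy()


def generate_session(params: Optional[SessionParams] = None,
                     **overrides) -> SyntheticSession:
    """Compose a full synthetic session, fully seed-reproducible."""
    if params is None:
        params = SessionParams(**overrides)
    elif overrides:
        params = SessionParams(**{**asdict(params), **overrides})
    params.validate()
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=4)
    state = generate_bout_process(params, np.random.default_rng(seeds[0]))
    angle, env, phase = generate_whisker_angle(
        state, params, np.random.default_rng(seeds[1]))
    pupil = generate_pupil(env, params.frame_rate, params.pupil_lag,
                           params.pupil_smooth_tau, params.pupil_noise_sd,
                           np.random.default_rng(seeds[2]))
    spikes = generate_spikes(state, phase, params,
                             np.random.default_rng(seeds[3]))
    return SyntheticSession(angle=angle, true_envelope=env, true_phase=phase,
                            true_state=state, pupil=pupil, spikes=spikes,
                            params=params)
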