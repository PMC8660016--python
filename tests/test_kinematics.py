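"""Kinematic decomposition: filters, phase convention, envelopes, bouts."""

import numpy as np
import pytest
from scipy import signal

from whisklab import AMBIGUOUS, QUIESCENT, WHISKING
from whisklab.kinematics import (WhiskerKinematics, bandpass_angle,
                                 compute_amplitude, compute_phase, decompose,
                                 median_angle, motion_energy, segment_bouts,
                                 whisking_fraction)

FS = 125.0


def test_median_angle_matches_naive_per_frame_median(rng):
    mat = rng.normal(90, 10, size=(200, 5))
    tr = median_angle(mat, FS)
    naive = np.array([sorted(row)[2] for row in mat])
    np.testing.assert_allclose(tr.samples, naive)


def test_median_angle_single_whisker_is_identity(rng):
    col = rng.normal(90, 5, 100)
    np.testing.assert_allclose(median_angle(col, FS).samples, col)


def test_median_angle_interpolates_short_gaps_and_rejects_long():
    mat = np.full((100, 2), 80.0)
    mat[50:55] = np.nan  # 40 ms gap
    tr = median_angle(mat, FS)
    assert np.all(np.isfinite(tr.samples))
    mat[50:70] = np.nan  # 160 ms gap
    with pytest.raises(ValueError):
        median_angle(mat, FS)


@pytest.mark.parametrize("freq, lo_gain, hi_gain", [
    (8.0, 0.9, 1.0),    # in-band: near-unit amplitude
    (0.5, 0.0, 0.1),    # below band: strongly attenuated
])
def test_bandpass_gain_matches_filter_response(freq, lo_gain, hi_gain):
    t = np.arange(0, 60, 1 / FS)
    out = bandpass_angle(np.sin(2 * np.pi * freq * t), FS)
    amp = np.ptp(out[200:-200]) / 2
    assert lo_gain <= amp <= hi_gain
    # oracle: squared magnitude response of the forward-backward filter
    sos = signal.butter(4, [4, 30], btype="bandpass", fs=FS, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=FS)
    assert amp == pytest.approx(np.abs(h[0]) ** 2, abs=0.03)


def test_bandpass_constant_trace_is_zero():
    out = bandpass_angle(np.full(1000, 93.0), FS)
    assert np.abs(out).max() < 1e-8


def test_bandpass_rejects_short_trace():
    with pytest.raises(ValueError):
        bandpass_angle(np.zeros(50), FS)


def test_phase_convention_zero_at_peak_pi_at_trough():
    # 6.25 Hz divides the frame rate, so peaks fall exactly on samples
    t = np.arange(0, 20, 1 / FS)
    x = np.cos(2 * np.pi * 6.25 * t)
    phase = compute_phase(x)
    peaks = signal.argrelmax(x[100:-100])[0] + 100
    troughs = signal.argrelmin(x[100:-100])[0] + 100
    assert np.abs(phase[peaks]).max() < 0.05
    assert (np.pi - np.abs(phase[troughs])).max() < 0.05


def test_unwrapped_phase_slope_is_carrier_frequency():
    t = np.arange(0, 20, 1 / FS)
    phase = compute_phase(np.cos(2 * np.pi * 8 * t))
    slope = np.mean(np.diff(np.unwrap(phase))[100:-100]) * FS
    assert slope == pytest.approx(2 * np.pi * 8, rel=0.01)


def test_phase_of_all_zero_input_is_flagged_nan():
    assert np.all(np.isnan(compute_phase(np.zeros(500))))


def test_amplitude_of_pure_sinusoid_is_peak_to_trough():
    t = np.arange(0, 20, 1 / FS)
    angle = 90 + 10 * np.sin(2 * np.pi * 8 * t)
    phase = compute_phase(bandpass_angle(angle, FS))
    upper, lower, amp = compute_amplitude(angle, phase)
    interior = slice(200, -200)
    assert np.median(amp[interior]) == pytest.approx(20.0, rel=0.02)
    assert np.all(upper[interior] >= lower[interior])


def test_amplitude_of_constant_angle_is_zero():
    _, _, amp = compute_amplitude(np.full(1000, 90.0), np.full(1000, np.nan))
    assert np.all(amp == 0)


def test_amplitude_tracks_true_envelope_inside_bouts(long_session,
                                                     long_decomposition):
    s, dec = long_session, long_decomposition
    inside = (s.true_state == WHISKING) & (
        s.true_envelope > 0.5 * s.params.peak_amplitude)
    rel = np.abs(dec.amplitude[inside] - s.true_envelope[inside]) \
        / s.true_envelope[inside]
    assert np.median(rel) < 0.05
    assert np.percentile(rel, 90) < 0.10


def test_segment_bouts_rule_and_ambiguous_label():
    amp = np.zeros(1000)
    amp[100:225] = 10.0   # 1 s supra-threshold -> whisking
    amp[600:625] = 10.0   # 200 ms -> ambiguous
    state = segment_bouts(amp, FS)
    assert np.all(state[100:225] == WHISKING)
    assert np.all(state[600:625] == AMBIGUOUS)
    assert np.all(state[:100] == QUIESCENT)
    # no whisking run shorter than 250 ms in the output
    runs = np.diff(np.flatnonzero(np.diff(
        np.r_[0, (state == WHISKING).view(np.int8), 0])))[::2]
    assert runs.min() >= int(np.ceil(0.25 * FS))


def test_segment_bouts_matches_naive_run_length_scan(rng):
    amp = np.abs(rng.normal(0, 5, 4000)) * (rng.random(4000) < 0.4)
    state = segment_bouts(amp, FS)
    thr = 0.2 * amp.max()
    min_frames = int(np.ceil(0.25 * FS))
    naive = np.zeros(amp.size, dtype=int)
    i = 0
    while i < amp.size:
        if amp[i] > thr:
            j = i
            while j < amp.size and amp[j] > thr:
                j += 1
            naive[i:j] = WHISKING if (j - i) >= min_frames else AMBIGUOUS
            i = j
        else:
            i += 1
    np.testing.assert_array_equal(state, naive)


def test_all_zero_amplitude_is_all_quiescent():
    assert np.all(segment_bouts(np.zeros(500), FS) == QUIESCENT)


def test_whisking_fraction_definition():
    state = np.array([WHISKING] * 3 + [QUIESCENT] * 3 + [AMBIGUOUS] * 4)
    assert whisking_fraction(state) == pytest.approx(50.0)
    assert whisking_fraction(np.full(10, WHISKING)) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        whisking_fraction(np.full(10, AMBIGUOUS))


def test_estimated_whisking_fraction_matches_truth(long_session,
                                                   long_decomposition):
    est = whisking_fraction(long_decomposition.state)
    true = 100.0 * (long_session.true_state == WHISKING).mean()
    assert abs(est - true) < 3.0


def test_phase_zero_frames_are_most_protracted(long_decomposition):
    dec = long_decomposition
    near0 = np.abs(dec.phase) < 0.1
    nearpi = np.abs(dec.phase) > np.pi - 0.1
    assert dec.filtered[near0].mean() > dec.filtered[nearpi].mean()


def test_time_shift_equivariance():
    t = np.arange(0, 40, 1 / FS)
    angle = 90 + 8 * np.sin(2 * np.pi * 9 * t) * (np.sin(2 * np.pi * 0.2 * t) > 0)
    k = 250
    d0 = decompose_like(angle)
    d1 = decompose_like(np.r_[angle[k:], angle[:k]])
    sl = slice(400, angle.size - k - 400)
    np.testing.assert_allclose(d1["amplitude"][sl],
                               d0["amplitude"][sl.start + k:sl.stop + k],
                               atol=0.5)
    assert np.mean(d1["state"][sl] == d0["state"][sl.start + k:sl.stop + k]) \
        > 0.98


def decompose_like(samples):
    est = WhiskerKinematics(frame_rate=FS).fit(samples)
    return {"amplitude": est.amplitude_, "state": est.state_}


def test_motion_energy_matches_naive_loop(rng):
    stack = rng.random((6, 8, 9))
    emap, scalar = motion_energy(stack)
    naive = np.zeros((8, 9))
    for i in range(5):
        for r in range(8):
            for c in range(9):
                naive[r, c] += abs(stack[i + 1, r, c] - stack[i, r, c])
    naive /= 5
    np.testing.assert_allclose(emap, naive, atol=1e-12)
    assert scalar == pytest.approx(naive.mean())


def test_motion_energy_trivial_cases():
    same = np.ones((4, 5, 5))
    emap, scalar = motion_energy(same)
    assert np.all(emap == 0) and scalar == 0
    alt = np.zeros((4, 2, 2))
    alt[1::2, 0, 0] = 1.0
    emap, _ = motion_energy(alt)
    assert emap[0, 0] == pytest.approx(1.0)
    assert emap[1, 1] == 0
    with pytest.raises(ValueError):
        motion_energy(np.ones((1, 5, 5)))


def test_transformer_interface_roundtrip(short_session):
    est = WhiskerKinematics(frame_rate=FS)
    cols = est.fit_transform(short_session.angle.samples)
    assert cols.shape == (short_session.angle.n_frames, 4)
    assert set(est.get_params()) >= {"frame_rate", "threshold_frac",
                                     "min_dur", "lowcut", "highcut"}
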