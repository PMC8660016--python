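"""Phase tuning curves, sinusoid fits, modulation depth, Kuiper test."""

import numpy as np
import pytest

from whisklab import QUIESCENT, WHISKING, SpikeTrain
from whisklab.phase_coding import (PhaseTuningModel, bonferroni, fit_sinusoid,
                                   kuiper_statistic, kuiper_two_sample,
                                   modulation_depth, phase_bin_edges,
                                   phase_occupancy, phase_tuning,
                                   spike_phases, tuning_curve)

FS = 125.0


def _centers(n=32):
    e = phase_bin_edges(n)
    return 0.5 * (e[:-1] + e[1:])


def test_spike_phase_assignment_and_state_filter():
    phase = np.linspace(-np.pi, np.pi, 1000, endpoint=False)
    state = np.full(1000, WHISKING, dtype=np.int8)
    state[500:] = QUIESCENT
    spikes = SpikeTrain(np.array([100.4 / FS, 600.2 / FS]))
    out = spike_phases(spikes, phase, state, FS)
    assert out.size == 1  # quiescent-frame spike excluded
    assert out[0] == phase[100]


def test_occupancy_conserves_whisking_time():
    phase = np.random.default_rng(0).uniform(-np.pi, np.pi, 5000)
    state = np.full(5000, WHISKING, dtype=np.int8)
    state[::3] = QUIESCENT
    occ = phase_occupancy(phase, state, FS)
    assert occ.sum() == pytest.approx((state == WHISKING).sum() / FS)
    with pytest.raises(ValueError):
        phase_occupancy(phase, np.zeros(5000, dtype=np.int8), FS)


def test_occupancy_of_constant_frequency_rotation_is_uniform():
    """A linearly advancing phase spends equal time in every bin."""
    n = 125_000
    phase = np.angle(np.exp(1j * 2 * np.pi * 9.7 * np.arange(n) / FS))
    occ = phase_occupancy(phase, np.full(n, WHISKING, dtype=np.int8), FS)
    assert np.ptp(occ) / occ.mean() < 0.05


def test_tuning_curve_scale_invariance_and_flat_case(rng):
    occ = np.full(32, 2.0)
    sp = rng.uniform(-np.pi, np.pi, 2000)
    _, r1 = tuning_curve(sp, occ, FS)
    _, r2 = tuning_curve(np.r_[sp, sp], 2 * occ, FS)
    np.testing.assert_allclose(r1, r2)
    # homogeneous spikes over uniform occupancy: flat at the mean rate
    assert r1.mean() == pytest.approx(2000 / 64.0, rel=0.1)
    assert np.isnan(tuning_curve(sp, np.r_[np.zeros(31), [2.0]], FS)[1][:31]).all()
    with pytest.raises(ValueError):
        tuning_curve(sp, np.zeros(32), FS)


def test_planted_rate_function_recovered_within_binomial_error(rng):
    """r(phi) = 10(1 + 0.5 cos(phi - 1)) from occupancy-weighted draws."""
    n_frames = 500_000
    phase = rng.uniform(-np.pi, np.pi, n_frames)
    rate = 10 * (1 + 0.5 * np.cos(phase - 1.0))
    spikes = phase[rng.random(n_frames) < rate / FS]
    occ = phase_occupancy(phase, np.full(n_frames, WHISKING, np.int8), FS)
    _, curve = tuning_curve(spikes, occ, FS)
    expected = 10 * (1 + 0.5 * np.cos(_centers() - 1.0))
    # ~4000 s of data: every bin within 4 binomial SEs
    se = np.sqrt(expected / occ)
    assert np.all(np.abs(curve - expected) < 4 * se)


def test_sinusoid_fit_exact_on_noiseless_curve():
    rate = 5 + 2 * np.cos(_centers() - 1.0)
    a, b, phi0 = fit_sinusoid(rate)
    assert a == pytest.approx(5.0, abs=1e-12)
    assert b == pytest.approx(2.0, abs=1e-12)
    assert phi0 == pytest.approx(1.0, abs=1e-12)


def test_sinusoid_fit_matches_closed_form_normal_equations(rng):
    rate = rng.normal(8, 2, 32)
    a, b, phi0 = fit_sinusoid(rate)
    # oracle: solve the 3x3 normal equations explicitly
    phi = _centers()
    X = np.column_stack([np.ones(32), np.cos(phi), np.sin(phi)])
    beta = np.linalg.solve(X.T @ X, X.T @ rate)
    assert a == pytest.approx(beta[0], abs=1e-10)
    assert b == pytest.approx(np.hypot(beta[1], beta[2]), abs=1e-10)
    assert phi0 == pytest.approx(np.arctan2(beta[2], beta[1]), abs=1e-10)


def test_sinusoid_fit_rotation_equivariance():
    base = 5 + 2 * np.cos(_centers() - 0.4)
    a0, b0, p0 = fit_sinusoid(base)
    delta = 2 * np.pi * 4 / 32  # rotate by 4 bins
    rotated = np.roll(base, 4)
    a1, b1, p1 = fit_sinusoid(rotated)
    assert (a1, b1) == pytest.approx((a0, b0))
    assert np.angle(np.exp(1j * (p1 - p0 - delta))) == pytest.approx(0, abs=1e-9)


def test_sinusoid_fit_flat_and_degenerate_cases():
    a, b, phi0 = fit_sinusoid(np.full(32, 7.0))
    assert b == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(phi0)
    with pytest.raises(ValueError):
        fit_sinusoid(np.r_[[1.0, 2.0], np.full(30, np.nan)])


def test_modulation_depth_definitions():
    assert modulation_depth(0.0, 10.0) == 0.0
    assert modulation_depth(3.0, 10.0) == pytest.approx(0.3)
    assert modulation_depth(3.0, 10.0, peak_trough=True) == pytest.approx(0.6)
    assert modulation_depth(3.0, 20.0) == modulation_depth(1.5, 10.0)
    assert np.isnan(modulation_depth(1.0, 0.0))


def test_kuiper_statistic_trivials_and_rotation_invariance(rng):
    a = rng.uniform(-np.pi, np.pi, 200)
    res = kuiper_two_sample(a, a.copy())
    assert res.V == 0.0 and res.p == 1.0
    b = rng.uniform(-np.pi, np.pi, 150)
    v0 = kuiper_statistic(a, b)
    for delta in (0.7, -2.1):
        ar = np.angle(np.exp(1j * (a + delta)))
        br = np.angle(np.exp(1j * (b + delta)))
        assert kuiper_statistic(ar, br) == pytest.approx(v0, abs=1e-12)
    with pytest.raises(ValueError):
        kuiper_statistic(a, np.array([]))


def test_kuiper_asymptotic_agrees_with_permutation(rng):
    """Same-uniform samples, n=m=100: |p_asym - p_perm| small on average."""
    diffs = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = r.uniform(-np.pi, np.pi, 100)
        b = r.uniform(-np.pi, np.pi, 100)
        p_asym = kuiper_two_sample(a, b).p
        p_perm = kuiper_two_sample(a, b, n_permutations=500,
                                   rng=np.random.default_rng(seed + 1)).p
        diffs.append(abs(p_asym - p_perm))
    assert np.mean(diffs) < 0.03


def test_bonferroni_correction():
    np.testing.assert_allclose(bonferroni([0.01]), [0.01])
    assert bonferroni([0.002], n=22)[0] == pytest.approx(0.044)
    p = np.array([0.001, 0.2, 0.9])
    assert np.all(bonferroni(p) >= p)
    assert np.all(bonferroni(p) <= 1.0)
    with pytest.raises(ValueError):
        bonferroni([1.5])


def test_planted_modulation_recovered_end_to_end(long_session):
    """Generator at m=0.3 (default): depth and preferred phase recovered."""
    from whisklab import decompose
    s = long_session
    dec = decompose(s.angle)
    tun = phase_tuning(s.spikes, dec.phase, dec.state, FS)
    assert tun.modulation_depth == pytest.approx(s.params.phase_mod_depth,
                                                 abs=0.05)
    err = np.angle(np.exp(1j * (tun.preferred_phase
                                - s.params.preferred_phase)))
    assert abs(err) < 0.2
    assert tun.p_raw < 0.01


def test_estimator_attributes_and_conservation(long_session,
                                               long_decomposition):
    s, dec = long_session, long_decomposition
    sp = spike_phases(s.spikes, dec.phase, dec.state, FS)
    fp = dec.phase[dec.state == WHISKING]
    model = PhaseTuningModel(frame_rate=FS, bonferroni_n=22).fit(sp, fp)
    assert model.spike_counts_.sum() == sp.size
    assert model.occupancy_.sum() == pytest.approx(fp.size / FS)
    assert model.p_corrected_ >= model.p_raw_
    tun = model.to_tuning()
    defined = ~np.isnan(tun.rate)
    np.testing.assert_allclose(
        tun.rate[defined],
        tun.spike_counts[defined] / tun.occupancy[defined])
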