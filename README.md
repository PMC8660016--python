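# whisklab

Analysis toolkit for asking how thalamic (or any) spiking relates to
whisking behaviour and arousal in head-fixed rodents.  It implements the
standard chain used in systems-neuroscience studies of secondary thalamus
(POm, LP): decompose a median-whisker-angle trace into instantaneous
phase and a slow amplitude envelope, segment whisking bouts, compare
firing rates between whisking and quiescence, quantify spike-phase tuning
with circular (Kuiper) statistics, correlate binned firing with
behavioural traces and pupil diameter, estimate multitaper spike–field
coherence against a circular-shuffle null, and measure pupil diameter
from eye video.  A synthetic-session generator with complete ground truth
(bout times, envelope, carrier phase, planted lags and coupling
strengths) closes the loop, so every estimator is validated by parameter
recovery.

## The core quantities

- **Whisking amplitude and phase.**  The median whisker angle θ(t)
  (125 frames/s) is band-passed 4–30 Hz (zero-phase Butterworth) and
  Hilbert-transformed; phase φ = 0 at peak protraction, ±π at peak
  retraction.  Protraction/retraction envelopes sample the unfiltered θ
  at the φ = 0 / ±π anchors; amplitude = upper − lower envelope.
  Whisking = amplitude > 20 % of max for ≥ 250 ms; shorter excursions are
  ambiguous and excluded.
- **State-conditioned rates.**  r_Q, r_W = spike count / labelled time per
  state; percent change = 100·(r_W − r_Q)/r_Q.
- **Phase tuning.**  Firing rate vs φ in 32 bins, occupancy-normalized;
  sinusoid fit r(φ) ≈ a + b·cos(φ − φ0); modulation depth = b / mean
  rate; significance by a two-sample Kuiper test (spike phases vs
  whisking-frame phases), Bonferroni-corrected.
- **Cross-correlograms.**  10-ms binned, z-scored series;
  c(k) = (1/N)Σ x(t)y(t+k), so every autocorrelogram is exactly 1 at zero
  lag; positive lag means the second series follows the first.
- **Coherence.**  Magnitude-squared multitaper coherence (DPSS, NW = 3,
  K = 5, 10-s windows) between binned spiking and the raw angle, tested
  against 50 circular spike-vector shifts; contrast of a 0.5–5 Hz band
  (slow envelope) vs 8–13 Hz (whisk cycle).
- **Pupillometry.**  Percentile contrast normalization, automatic
  threshold, circular-Hough detection → per-frame diameter in pixels.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import whisklab as wl
from whisklab.kinematics import whisking_fraction
from whisklab.state_activity import state_firing_rates, percent_change
from whisklab.phase_coding import phase_tuning
from whisklab.xcorr import bin_and_zscore, cross_correlate, peak_lag

session = wl.generate_session(wl.SessionParams(duration=600.0, seed=1))
dec = wl.decompose(session.angle)
print(f"whisking fraction: {whisking_fraction(dec.state):.1f}%")

rates = state_firing_rates(session.spikes, dec.state, 125.0)
print(f"rate quiescent: {rates.rate_quiescent:.2f} Hz, "
      f"whisking: {rates.rate_whisking:.2f} Hz "
      f"({percent_change(rates.rate_quiescent, rates.rate_whisking):.0f}% change)")

tuning = phase_tuning(session.spikes, dec.phase, dec.state, 125.0)
print(f"modulation depth: {tuning.modulation_depth:.3f}, "
      f"preferred phase: {tuning.preferred_phase:+.2f} rad, "
      f"Kuiper p: {tuning.p_raw:.2e}")

amp_z = bin_and_zscore(dec.amplitude, frame_rate=125.0)
pup_z = bin_and_zscore(session.pupil.diameter, frame_rate=125.0)
lag, peak = peak_lag(cross_correlate(amp_z, pup_z))
print(f"pupil lags whisking by {lag*1000:.0f} ms (peak correlation {peak:.2f})")
```

Output:

```
whisking fraction: 30.5%
rate quiescent: 7.92 Hz, whisking: 12.68 Hz (60% change)
modulation depth: 0.346, preferred phase: +0.04 rad, Kuiper p: 4.40e-24
pupil lags whisking by 1020 ms (peak correlation 0.99)
```

The session was generated with quiescent/whisking rates of 7.8/12.4 Hz,
phase modulation m = 0.3 at φ0 = 0, and a pupil delayed 880 ms behind the
envelope and then causally smoothed (τ = 0.2 s, which adds ≈ τ of
apparent delay — hence the measured ~1.0 s lag); the pipeline recovers
all of it from the raw traces alone.

There is also a CLI (`whisklab simulate | kinematics | rates | phase |
xcorr | coherence | pupil | run-all`), e.g.

```sh
whisklab simulate --seed 1 --duration 300 --out session.h5
whisklab run-all --session session.h5 --out results/
```

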