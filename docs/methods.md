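# Methods

`whisklab` implements the analysis chain used to relate spiking in
secondary thalamic nuclei (e.g. POm, LP) to whisking behaviour and
arousal in head-fixed mice: whisker-angle decomposition, whisking-bout
segmentation, state-conditioned firing rates, spike-phase coding,
normalized cross-correlograms, multitaper spike–field coherence with a
shuffle null, and video pupillometry.  A synthetic-session generator with
full ground truth makes every stage testable without recorded data.

## Whisker kinematics

The master clock is the whisker video (default 125 frames/s).  The
per-frame median angle across tracked whiskers is the root input; frames
with no tracked whisker are linearly interpolated when the gap is shorter
than 80 ms and rejected otherwise.

The median angle is band-pass filtered 4–30 Hz with a 4th-order
Butterworth applied forward–backward.  Zero-phase filtering matters
because the instantaneous phase extracted downstream must not be delayed;
a causal filter would bias every spike-phase assignment by the group
delay.  Phase is the angle of the analytic signal (Hilbert transform) of
the filtered trace, with the convention that phase 0 is the most
protracted point of the whisk cycle and ±π the most retracted (whisker
angle increases with protraction).

Protraction and retraction envelopes sample the *unfiltered* angle at the
phase-0 and ±π crossings respectively, interpolate linearly between
consecutive anchors, and hold the nearest anchor value before the first
and after the last anchor.  Whisking amplitude is the difference of the
two envelopes, clipped at zero.  Linear interpolation between anchors and
end-holding are our choices where the procedure is otherwise
underdetermined; with fewer than two anchors of either kind there are no
whisk cycles and amplitude is zero throughout.

Bout segmentation: frames where amplitude exceeds 20 % of its maximum
over the recording for at least 250 ms are *whisking*; shorter
supra-threshold runs are *ambiguous* and excluded from all state-
conditioned statistics; everything below threshold is *quiescent*.  The
threshold reference is the recording maximum by default; a `p99` option
substitutes the 99th percentile for robustness against single-frame
tracker glitches.  No minimum duration is imposed on quiescent runs.

## State-conditioned rates and group tests

Spikes are assigned to frames by `floor(t × frame_rate)`.  Each state's
rate is exactly spike count over labelled time; a state with zero
labelled time has an undefined (NaN) rate rather than zero.  Percent
change is `100·(r_W − r_Q)/r_Q`.  Cohort comparisons use the standard
two-sided paired t-test, two-sample F-test on variances, and Wilcoxon
rank-sum (Mann–Whitney) test, all delegated to scipy behind the module
surface.

## Spike-phase coding

Spikes fired during whisking frames receive the phase of their frame.
Spike-phase counts in 32 equal bins over (−π, π] are divided by phase
*occupancy* (time the whiskers spend at each phase while whisking) to
give firing rate versus phase; bins occupied for less than one frame are
undefined.  A period-2π sinusoid `a + b·cos(φ − φ0)` is fit by linear
least squares at the bin centers (the problem is linear in
`a, b·cosφ0, b·sinφ0`).  Modulation depth is `b` divided by the mean
whisking-period firing rate; a configuration flag switches to the
peak-to-trough variant `2b/r̄`, and the amplitude-over-mean form is the
default because it is the operational definition used with this kind of
tuning fit.  Under the generator's multiplicative rate model
`r(φ) = R(1 + m·cos(φ − φ0))`, depth estimates `m` directly.

Significance compares the unbinned spike phases against the whisking-
frame phase sample with a two-sample Kuiper test — the rotation-invariant
analogue of Kolmogorov–Smirnov appropriate for circular data.  The
statistic is `V = sup(F−G) + sup(G−F)`; ties (every spike phase ties a
frame phase by construction) are handled by evaluating the CDF difference
only after all jumps at a tied value.  The asymptotic p-value uses the
effective size `N_e = nm/(n+m)` and the tail series with the standard
small-sample correction `λ = (√N_e + 0.155 + 0.24/√N_e)·V`; a permutation
option re-labels the pooled sample and is preferred for small samples
(and doubles as an independent oracle in the tests; the two agree to
within ~0.03 at n = m = 100).  The frame-phase sample is autocorrelated
over a few frames, which makes the test mildly conservative-to-nominal
when the spike count is much smaller than the frame count — the regime in
which it is used.  Bonferroni correction multiplies by the number of
cells analysed (configurable).

## Cross-correlograms

Spike trains and behavioural traces are binned at 10 ms (counts and
per-bin means respectively) and z-scored.  The correlogram
`c(k) = (1/N)·Σ x(t)·y(t+k)` sums over the valid overlap but normalizes
by the full length N (biased estimator): with z-scored inputs this makes
any autocorrelogram exactly 1 at zero lag and damps extreme lags.  The
sign convention is that positive lag means the second series follows the
first.  Peak-lag ties break toward zero lag, then toward negative lag.
Condition comparisons find the peak lag of the across-cell *mean*
correlogram per condition and run a paired t-test across cells on the
values at each condition's peak lag; the across-cell-mean choice yields
one lag per condition (per-cell peaks are available as an option).
Ambiguous epochs are not excised before correlation by default.
Default maximum lag is ±2 s.

## Multitaper spectra and coherence

Spectra use discrete prolate spheroidal (Slepian) tapers from scipy with
time–bandwidth NW = 3 and K = 5 tapers on 10-s windows with 50 % overlap
(≈ 0.3 Hz bandwidth at 125 Hz sampling); windows are demeaned.  Spike
trains enter as binned counts at the frame rate — at 8 ms bins this is
indistinguishable from a point-process estimator for rates below
~50 Hz — and coherence is the magnitude-squared form
`|S_xy|²/(S_xx·S_yy)` accumulated over windows × tapers, bounded in
[0, 1].  The shuffle null circularly rotates the spike vector by a
uniform random offset in [10 s, span − 10 s] (the margin keeps shuffles
away from near-identity offsets) and recomputes coherence; 50 shuffles
per cell, retaining both the mean null curve and the full distribution
for percentile bands.  Band contrasts use a low band of 0.5–5 Hz (the
lower edge is our choice; the upper edge is where slow whisking power
ends) and a high band of 8–13 Hz (the whisk-cycle band).

## Pupillometry

Eye frames are contrast-normalized (1st/99th intensity percentiles to
[0, 1], making the pipeline invariant to global illumination scaling),
binarized with an automatic between-class-variance (Otsu) threshold by
default (manual override available, since contrast is often hand-tuned in
practice), and the dark-region boundary is fed to a circular Hough
accumulator over a configured radius range.  The strongest circle gives
center and diameter (pixels; no mm calibration); frames whose best
accumulator score falls below a confidence floor are invalid.  Invalid
runs shorter than 400 ms (blinks, dropouts) are linearly interpolated but
stay flagged; longer runs remain NaN.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
with every generated quantity stored as ground truth:

- **Bouts.** Alternating quiescence (exponential, mean 4 s) and whisking
  bouts (exponential truncated below at 0.25 s, drawn as
  `0.25 + Exp(mean − 0.25)`, mean 2 s), giving a whisking fraction of 1/3.
  Bout-duration statistics are not constrained by recorded data, so these
  are realistic defaults exposed as configuration; every generated bout
  satisfies the 250 ms rule by construction.
- **Envelope.** Peak-to-trough excursion E(t) = 20° × a smoothed bout
  indicator with raised-cosine ramps of min(150 ms, L/3) placed strictly
  inside each bout, so quiescent frames have exactly zero envelope.
- **Carrier.** Instantaneous frequency follows a mean-reverting random
  walk clipped to 8–13 Hz (a broad spectral peak, not a line); phase is
  its integral and keeps advancing through quiescence.
- **Angle.** `baseline + setpoint + (E/2)·cos(phase) + drift + noise`,
  with a setpoint that tracks the envelope through a 1 Hz low-pass
  (gain 0.5°/°): whiskers protract overall during whisking, which is what
  gives real angle traces their dominant sub-5 Hz power.  Keeping the
  setpoint slower than 1 Hz also keeps its bout-onset transients out of
  the 4–30 Hz phase-estimation band.  Drift is sub-1-Hz noise of 0.5° SD;
  tracker noise is 0.1° per frame.
- **Spikes.** Inhomogeneous Poisson by thinning at frame resolution.
  State coupling: `r = r_Q` or `r_W` by state (defaults 7.8 and 12.4 Hz,
  the secondary-somatosensory cohort means), multiplied during whisking
  by `1 + m·cos(phase − φ0)` (default m = 0.3, clipped at zero); phase
  modulation is multiplicative and active only during whisking because
  phase coding is only defined there.  Envelope coupling:
  `r = r_Q + (r_W − r_Q)·E/E_max`, a rate that follows the envelope
  instantaneously.
- **Pupil.** The envelope shifted later by 0.88 s (the mean lag of pupil
  dilation behind whisking), causally low-pass smoothed (single pole,
  default τ = 0.2 s), affinely mapped to [1, 2.5] arbitrary units, plus
  Gaussian noise scaled to the signal SD.  Absolute pupil units never
  enter a statistic (everything is z-scored downstream).  A causal
  smoother adds roughly τ of apparent delay, so lag-recovery analyses
  that target the planted delay itself are run with τ = 0.
- **Eye frames.** Bright iris disk, dark pupil disk of planted diameter
  at a jittered center, Gaussian pixel noise.

What the generator does *not* emulate: non-Poisson spiking (bursting,
refractoriness), whisker-by-whisker kinematics, setpoint changes
independent of amplitude, eye-lid occlusion, and slow electrode drift.
Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed statistical structure, not robustness to
every artefact of recorded data.

## Numerical choices and degenerate inputs

- Zero-variance series cannot be z-scored and raise; a paired test on
  identical vectors returns (t = 0, p = 1); zero-variance differences
  with non-zero mean are flagged degenerate.
- The zero-lag autocorrelation equals 1 exactly in exact arithmetic; the
  FFT evaluation reproduces it to ~1e-16 and tests assert at 1e-12.
- A flat tuning curve has fit amplitude at rounding level; its preferred
  phase is reported NaN (threshold 1e-9 relative to the offset).
- Unit QC: waveform half-width is the time from maximum negativity back
  to baseline, with the crossing interpolated between samples; units
  strictly below 0.25 ms are narrow-spiking (putative inhibitory) and
  excluded by default; exactly 0.25 ms is broad.
- Simulation sizes in the test suite (600-s sessions for parameter
  recovery, 300-s for cohort contrasts, 200 null cells for calibration)
  are chosen so Monte-Carlo error is comfortably inside the documented
  tolerances.

## Known limitations

The Kuiper asymptotic p-value treats the frame-phase sample as i.i.d.;
for very high firing rates (spike counts approaching the frame count) the
permutation option should be preferred.  Peak-lag estimation by argmax on
a broad correlogram has bin-level jitter at realistic spike counts
(±1–3 bins at 600 s for the default rates); it is unbiased but not
sub-bin accurate.  The Hough pupil detector quantizes radius at one
pixel, so diameters are accurate to ±2 px.  Two-way repeated-measures
ANOVA (condition × state designs) is intentionally delegated to standard
statistical software rather than re-implemented here.
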