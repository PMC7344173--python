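# Methods

`fmtheta` implements a closed-loop frontal-midline theta (FMθ)
neurofeedback engine: a simulated responsive subject, the causal
streaming preprocessing chain, artifact subspace reconstruction (ASR),
the adaptive dynamic-range feedback controller, the 8-day sham-controlled
protocol, and the offline statistical battery. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## The feedback signal

Every 250 ms, a sliding 1 s window (75% overlap) of the cleaned Fz signal
at 256 Hz is Hamming-tapered and Fourier-transformed; with 256 samples
the bin spacing is exactly 1 Hz. The instantaneous theta log power is

    p = mean_{k in {4,5,6}} 10 log10 |X(k)|^2

i.e. the average of the squared-magnitude FFT at 4, 5 and 6 Hz on a dB
scale. Alpha (8–12 Hz) and beta (12–18 Hz) log powers are logged from the
same FFT for the offline specificity analyses.

## The adaptive dynamic-range controller

The displayed value is f = (p − l)/(h − l) for an adaptive range [l, h].
Per 250 ms tick, with r = h − l evaluated *before* the update:

- f < 0: display 0 and expand the lower edge, l ← l − r/30;
  otherwise idle-contract, l ← l + r/100.
- f > 1: display 1 and expand the upper edge, h ← h + r/30;
  otherwise idle-contract, h ← h − r/100.

Saturation therefore widens the range 100/30 ≈ 3.3× faster per tick than
idle updates shrink it, so the range tracks slow drifts in the subject's
theta while staying snug around its recent excursion span. The displayed
value may change by at most 0.05 per tick (the "5%" slew cap, read as an
absolute step on the [0,1] scale: a relative reading would deadlock at
f = 0) and is rendered as a black→blue square, B = round(255·f)
(0 → #000000, 0.5 → #000080, 1 → #0000FF).

Numerical choices:

- **Initialization.** Before any update, l = p₀ − δ, h = p₀ + δ with
  δ = 1 dB. The 1-minute baseline then runs the full update law with the
  display disabled, which is what actually establishes the working range;
  the returned state starts each block with the displayed value reset to
  0 (black square).
- **Simultaneous edge updates.** Both edge increments use the pre-update
  range, so a single tick cannot compound its own edge movement.
- **Ties.** f exactly 0 or 1 counts as non-saturated; only strict
  overshoot expands.
- **Minimum range.** ε = 1e−6 dB is enforced after each update so that a
  pathological constant input cannot collapse the range to zero width.
- The range carries unchanged across blocks and breaks, and the end
  baseline keeps updating it (display off).

## Streaming chain

Quarter-second chunks at the native rate (2048 Hz by default) are
decimated to 256 Hz (polyphase-style FIR anti-alias low-pass at 80% of
the output Nyquist, then phase-tracked subsampling) and high-passed at
0.5 Hz with a minimum-phase FIR, then average-referenced. Both filters
carry their delay lines across chunks, and chunked output equals
whole-signal output to floating-point rounding — streaming equivalence is
a hard guarantee, tested at 1e−8 relative.

The high-pass is a Kaiser-window linear-phase prototype converted to
minimum phase (homomorphic method) with the tap mean subtracted, which
places an exact spectral null at DC. The default order (513-tap
prototype, 257 final taps) keeps the passband flat within 1% from 4 Hz up
— the feedback band is what matters — while remaining cheap enough for
the 4 Hz real-time loop; attenuation of sub-quarter-Hz drift rises
steeply toward the DC null. A longer prototype (config-exposed) buys a
sharper shoulder below 1 Hz at proportional cost.

## ASR

Calibration on the day's 1-minute start baseline: the covariance (mean of
per-10-sample-block sample covariances) is eigendecomposed into
orthonormal component axes; each component's rejection threshold is
median + cutoff·1.4826·MAD of its windowed RMS (500 ms windows, 330 ms
overlap; cutoff 5). Robust z-scoring replaces the truncated-Gaussian fit
of the original ASR formulation — simpler, monotone in the cutoff, and
sufficient for the clip-style cleaning used here; a distribution-fit
variant is left as a config hook.

Processing: sliding 500 ms windows at 50% overlap are projected onto the
calibration axes; any component whose windowed RMS exceeds its threshold
is scaled down *to* the threshold (clipping, not zeroing — this preserves
continuity and never increases window power); windows are blended with a
periodic Hann taper, which at 50% overlap sums exactly to one, so
sub-threshold data are reconstructed identically and chunk boundaries are
seamless by construction. The processor is primed with half a window of
zeros so that output length always equals input length at a fixed 250 ms
latency (`delay_samples`). State (input tail, partial overlap-add
accumulators) carries across chunks; boundary first-differences are
statistically indistinguishable from interior ones (KS test in the
suite).

Average referencing precedes ASR (the processing order is
config-switchable); the common-mode null direction this introduces is
recognized and tolerated during calibration, while any other rank
deficiency (constant or duplicated channels) is an error.

## The simulated subject

The subject is phenomenological, not biophysical: 8-channel (Fpz, Fz, F7,
F8, Cz, P7, P8, Oz) spatially correlated 1/f noise (spectral shaping,
exponent 1.0, nearest-neighbour channel correlation ~0.5 via a fixed
mixing matrix) carrying three sinusoidal components with fixed scalp
topographies — theta 5 Hz maximal at Fz, alpha 10 Hz posterior, beta
15 Hz diffuse. The theta amplitude at Fz is exactly

    A(t) = baseline_theta_amp + theta_gain · attention(t)    [µV]

where attention(t) ∈ [0,1] follows an Ornstein–Uhlenbeck drift (time
constant 20 s, diffusion 0.05 /√s) around a set-point. Two couplings
close the loop:

- **feedback_coupling** (default 0.002 per update): each displayed value
  nudges attention by coupling·(f − 0.5) — the subject "follows" the
  square.
- **session_learning_rate** (default 0.05 per session): the set-point
  rises between days, modelling consolidation of the strategy; sham-like
  subjects have 0.

Defaults (baseline theta 4 µV, gain 4 µV, noise 10 µV RMS, blinks
4/min at 150 µV, muscle bursts 1/min) produce a session-level theta
increase of a few percent per day — a deliberately modest, realistic
effect size. Blinks are 300 ms smooth bumps dominant on Fpz (≥5× the
background RMS); muscle bursts are 500 ms 20–40 Hz band-limited
transients sized to exceed the offline 10 dB rejection threshold. Ground
truth (attention trace, artifact intervals) is returned for testing.

What the generator does *not* emulate: volume conduction from dipolar
sources, line noise, electrode drift/impedance changes, non-stationary
spectra, or any physiological link between theta and task performance.
Passing tests therefore demonstrate that the *pipeline* recovers planted
effects under its stated noise model — not that real subjects behave this
way.

## Protocol and sham

One day = 60 s start baseline (display off; calibrates ASR and warms up
the range) → six 5-minute blocks with 150 s breaks (clock gaps only) → 60 s
end baseline. Eight days; the subject's learning state persists across
days. In sham mode the yoked partner's displayed sequence is replayed
while the sham subject's own EEG still runs through the whole chain, so
their p and hypothetical f are logged — this maximizes analyzable output
and makes the "non-specific effects" comparison possible. The displayed
histogram of a sham run equals its source's exactly.

## Offline battery

- Channel rejection: kurtosis z-scored against the channel ensemble,
  |z| > 5. Note a 5-SD criterion needs a large montage — with n channels
  the largest attainable |z| is (n−1)/√n, so the rule only bites for the
  64-channel recordings, which is where it is applied.
- Segment rejection: per-0.5 s window 20–40 Hz power vs. the recording
  mean; runs of ≥4 contiguous windows above 10 dB are rejected.
- Training curves: block amplitude = mean of 10^(p/20) (the amplitude
  implied by the logged dB values, in µV); session amplitude = mean over
  blocks; percent change relative to session 1; the baseline series uses
  the mean of start and end baselines. Band edges default to theta 4–6,
  alpha 8–12, beta 12–18 Hz.
- Per-subject OLS slope over sessions 1–8; one-tailed Welch t-test on
  group slopes; Pearson correlation of the group-mean curve vs. session
  index with df = n_sessions − 2.
- Non-responder exclusion: single pass, |power − mean| > 3 SD using the
  population SD (with ~12 subjects an outlier inflates the spread it is
  judged against; the sample-SD variant would make the rule nearly
  unattainable). "Total power" is the whole-protocol mean theta power
  (config-exposed; which band/sessions was an open choice).
- Spectral permutation test: per-frequency difference of mean log
  periodograms, null by label permutation, Benjamini–Hochberg across
  frequencies restricted to 1–40 Hz. FDR control admits occasional false
  discoveries by construction; localization claims in the tests allow at
  most one spurious high-band bin.
- RM-ANOVA (session × group, Greenhouse–Geisser) is delegated to
  pingouin's `mixed_anova`; the battery GLM is an OLS fit with
  sum-coded factors, explicit subject-within-group deviation columns
  (keeping the group main effect estimable), and Type-II F-tests —
  Statistica's exact sums-of-squares convention is unknown, so this is a
  documented approximation.

## Task battery

n-back (280 letters from {A,B,C,D} per load; target = match `load` back;
unconstrained uniform sampling, so the load-1 target rate is ~25% — an
optional constrained generator can fix the rate), SART (250 digits, no
immediate repeats, withhold on 3), local-global (200 trials, 4 sessions
of 50, instruction global/local/global/local; congruent iff the large
letter equals its constituents). Scoring is signal-detection style; a
no-response on a non-target is a correct rejection, on a target a miss;
RT statistics cover correct response trials only. The simulated responder
draws evidence from an equal-variance Gaussian model (d′, criterion 0)
with log-normal RTs, giving the GLM planted, recoverable effects.

## Desk-scale problem sizes

The statistical acceptance runs use reduced problem sizes chosen so a
full 50-replicate matched-cohort experiment (12 feedback + 12 yoked sham,
8 sessions each) completes on a single CPU: 8 s baselines, two 12 s
blocks per session, 256 Hz native rate (no decimation stage in that
particular test — decimation has its own equivalence tests). The
controller, ASR, logging and statistics are identical to the full-scale
plan; only durations shrink, which raises the variance of per-session
amplitude estimates and makes the recovery test conservative rather than
optimistic.

## Known limitations

- The ASR threshold statistic deliberately diverges from the original
  truncated-Gaussian calibration; cutoff values are therefore not
  numerically interchangeable with other ASR implementations.
- The minimum-phase high-pass trades sub-Hz shoulder sharpness for
  real-time cost; it is not a brick wall at 0.5 Hz.
- The EDF writer emits plain continuous 16-bit EDF (no annotations,
  single data-record duration); it targets round-trip fidelity with
  standard readers, not the full EDF+ feature set.
- The subject model's couplings are free parameters of a synthetic
  organism; nothing here estimates how quickly real subjects respond to
  feedback.
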