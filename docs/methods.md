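# Methods

This note documents the models implemented in `voicecue`, the parameters
that matter, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Voice manipulation and stimuli

Voice differences are parameterized in semitones: a shift of `s` st is a
frequency ratio `2^(s/12)`. An f0 shift multiplies the fundamental by this
ratio; a VTL shift of `+s` st lengthens the vocal tract by the same factor,
which *divides* every formant frequency by it (longer tract → lower
resonances). The canonical male-like counterpart of a 225 Hz female
reference voice is `df0 = −12 st` (112.5 Hz) and `dvtl = +3.8 st`.

Syllables are a parametric source–filter stand-in for recorded
consonant–vowel tokens: a glottal pulse train at the (flat) shifted f0,
filtered through second-order resonators at the shifted formants of a small
female /a, i, u/ inventory, with a 60 ms cosine fade-out and RMS
normalization. The formant table and resonator bandwidths
(`80 + 0.05·f` Hz) are configuration defaults, not claims about a talker.
A 3AFC trial concatenates three triplets of three 200 ms syllables with
50 ms intra-triplet and 950 ms inter-triplet silences — 4.0 s in total —
with the deviant voice in one of the three positions. Within one trial each
(voice, syllable) token is rendered once and reused, the way a recorded
item would be replayed; "fixed" item variability repeats one syllable
sequence across the three triplets, "variable" draws an independent
sequence per triplet.

The noise vocoder spaces `n+1` band edges between 150 and 7000 Hz at equal
cochlear positions by inverting the Greenwood map `F(x) = A(10^(a·x) − k)`
with the standard human constants `A = 165.4`, `a = 2.1`, `k = 0.88`
(config-exposed). Per band the signal is band-pass filtered, half-wave
rectified, low-pass filtered at 300 Hz (2nd-order Butterworth, zero-phase),
and the resulting envelope modulates a fresh white-noise carrier that is
re-filtered with the same band-pass; bands are summed and the output RMS is
matched to the input. The "12th-order zero-phase" band-pass is realized as
a forward–backward pass of a 6th-order Butterworth band-pass, so the
effective magnitude response is 12th order and the phase exactly zero.
Half-wave rectification (not a Hilbert envelope) is used deliberately, to
stay literal to the procedure being modelled.

## Adaptive staircase

2-down-1-up, 3AFC: the run starts at 12 st with a 2 st step; two
consecutive correct responses at a level move the difference down one step,
one error moves it up. The level in force when the movement direction flips
is logged as a reversal; the initial descent contributes none. The step is
divided by √2 (floor 0.1 st) when the 15th trial is reached with no prior
division, and each time the condition `diff < 2·step` becomes **newly**
true after a move (it re-arms once the difference climbs back above
`2·step`). Runs converge at 12 reversals, stop at 150 trials, and fail if
the last 15 or more responses were all incorrect; the JND is the mean of
the last 10 reversal levels. The difference is clamped at 0 st. A
`single_division` switch restricts the schedule to one division in total,
for comparison.

An alternative reading of the schedule — divide repeatedly until
`diff ≥ 2·step` — was evaluated and rejected: because divisions then
coincide with downward excursions, the walk ratchets low and the procedure
converges near 66.5% correct instead of 70.7% for a moderate-slope oracle.

Simulated listeners follow `P(correct|Δ) = γ + (1−γ−λ)·F(Δ)` with
`γ = 1/3`. The Weibull family is parameterized directly by its
70.7%-correct threshold; its shape defaults to 1.5, a shallow-moderate
psychometric typical of voice-cue discrimination under spectral
degradation. This matters because the finite-step schedule carries a small
steepness-dependent bias: measured over 5000 runs at threshold 3 st, the
convergence level is 70.5% at shape 1.5, 69.2% at shape 2 and about 68% at
shape 3 (all within 0.3 st of the threshold). A logistic-on-log2 family and
a step-function listener are provided for property tests.

## Pupil preprocessing

Order of operations (fixed): eye selection → blink detection →
blink-fraction exclusion → interpolation (pupil **and** gaze channels) →
gaze-bounds exclusion → smoothing → baseline correction → metrics. Gaze is
screened *after* interpolation so that the (0, 0) gaze a tracker reports
during a blink cannot masquerade as a saccade.

* Eye selection: most valid (nonzero) samples across a subject's trials;
  ties go left.
* Blinks: maximal zero runs intersecting the [−1, 6.5] s window. A trial is
  excluded when blink samples are ≥ 20% of the window.
* Interpolation: a straight line from 10 samples before to 16 samples after
  each blink; valid samples inside those guard bands are replaced too.
  Anchors are clipped to the nearest valid sample; a side with no valid
  sample yields a constant fill; no valid side at all marks the trial
  unrecoverable.
* Smoothing: 11-point moving average with a symmetrically shrinking window
  at the edges (no out-of-window data is invented).
* Baseline: mean over [−1, 0) s (the sample at exactly t = 0 belongs to the
  metrics window); subtracted pointwise.
* Metrics over [0, 6.5] s: MPD = mean, PPD = max, PPDL = time of the first
  maximum in ms.
* Condition averages: pointwise means of kept corrected traces per subject
  × condition; PPD/MPD/PPDL are recomputed from the averaged trace and the
  reported baseline is the mean of per-trial baselines.
* Downsampling for time-course export: block means of 4 samples
  (120 → 30 Hz), timestamps at block centers.

Screen bounds are a configurable rectangle (default 1920 × 1080 gaze
units); no claim is made about any particular tracker's coordinate system.
Missing-data sentinels other than exact zero should be mapped to zero on
ingest.

## Synthetic experiments

The generator defines the study conditions: 16 subjects, 8 within-subject
conditions (training × vocoder × variability). Per-condition true JNDs are
log-normal with moment-matched means/SDs equal to the bundled
`jnd_condition_targets.tsv` table, so condition means are unbiased for
those targets. Behavioral data are produced by running the real staircase
against a Weibull oracle whose 70.7% point equals the subject's true JND.

Pupil trials are 120 Hz two-eye traces over [−3, +6.5] s: a tonic level
(default 3.03 mm; +0.04 mm applied tonically in variable-item conditions,
reflecting an anticipatory baseline shift), an event-related gamma-density
kernel (shape 4, scale 0.5 s → mode at 1.5 s; peak-normalized) scaled by a
per-condition amplitude (defaults 0.20 mm non-vocoded vs 0.40 mm vocoded,
subject SD 0.05 mm), and AR(1) noise (ρ = 0.95, stationary SD 0.03 mm)
shared between the eyes plus 0.01 mm eye-specific noise. The kernel shape
and the latency are generator choices, not physiological claims. Artifacts:
shared blinks (Poisson, ~200 ms), eye-specific tracking dropouts (the right
eye noisier by default, so eye selection is exercised), a 4% chance of a
trial-killing long blink, and a 4% chance of a conjugate off-screen gaze
excursion placed clear of every zero run and interpolation guard band. Each
trial's intended keep/exclude disposition is recorded for the eye that eye
selection will pick, and the test suite requires 100% agreement with the
preprocessing pipeline.

What the generator does **not** emulate: pupil foreshortening, slow drift
and light-reflex components, blink-duration/amplitude covariation,
staircase-coupled trial timing (audio rendering and pupil trials are
decoupled), and training-duration effects. Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the stated
noise model, not robustness to every property of real recordings.

## Statistics

JNDs are natural-log transformed before the ANOVA (the base affects neither
F nor η²g). The fully within-subject 2×2×2 ANOVA tests each of the seven
effects against its own subject-interaction error term,
`F(1, n−1) = MS_E / MS_(E×S)`, which for two-level factors equals the
squared one-sample t on per-subject contrast scores — the test suite checks
agreement with that brute-force route to 1e−8 and with
`statsmodels.AnovaRM`. Generalized eta-squared uses
`η²g = SS_E / (SS_E + SS_subjects + Σ all error SS)`, the standard form for
fully within designs. Missing cells abort the ANOVA; no imputation is done.
Zero-variance contrasts report F = ∞ (or 0/NaN when the effect SS is also
zero). Pairwise follow-ups are paired t-tests with Benjamini–Hochberg
adjustment across the contrasts requested in one call; degenerate
zero-variance pairs report t = 0, p = 1 (or t = ∞ when the shared
difference is nonzero). Marginal means are unweighted averages of condition
cells, printed with decimal half-up rounding to 2 decimals (a 12
significant-digit pre-quantization absorbs float artifacts).

Under a pure-noise null the suite verifies the empirical type-I error of
every effect stays within [0.035, 0.065] at α = 0.05 over 2000 simulated
16-subject datasets.

The GAMM export pools item-variability conditions, yielding a 4-level
condition factor (training × vocoder) and one averaged 30 Hz curve per
subject × condition (`Event`), restricted to [−1, 6.5] s. The optional R
stage (`scripts/gamm_fit.R`, mgcv only) fits
`Pupil ~ Condition + s(Time, by=Condition, k=15) + s(Event, bs="re") +
s(Time, Event, bs="re")` with an AR(1) correction whose ρ is the lag-1
residual autocorrelation of an uncorrected pilot fit, and writes fitted and
pairwise difference curves with pointwise 95% intervals. The primary
pipeline and its tests do not depend on this stage.

## Problem sizes and numerical choices

Simulation-based checks use deliberately modest sizes chosen for stable
statistics: 500 staircase runs for convergence (batch SE ≈ 0.4 percentage
points), 300-run probes in unit tests, 2000 replicates for type-I
calibration, 4–16 subjects and 2–10 pupil trials per condition for
end-to-end checks, and 16 kHz audio for filtering tests (the Nyquist
frequency still clears the 7 kHz vocoder edge). Audio defaults remain
44.1 kHz. Ties are broken deterministically everywhere (first maximum for
PPDL, left eye on selection ties), and all randomness flows from explicit
`numpy` generators seeded per run.
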