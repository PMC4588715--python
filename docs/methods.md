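# Methods

This note documents the models, estimators, parameter choices, and known
limitations of the package. Everything quantitative stated here is
computed by the test suite or the analysis scripts.

## Synthetic sessions

A session is 4 blocks × 96 trials; each block holds 48 match trials
(Δθ = 0) and 12 non-match trials per rotation (3/5/10/20°), shuffled
within the block. A trial spans 500 ms fixation, 300 ms target, 1000 ms
delay (fixed by default; an optional uniform 800–1200 ms jitter is
supported), 300 ms test, plus 100 ms of trailing trace. All signals are
sampled at 1 kHz.

**LFP.** Each channel is the sum of a band-limited oscillation and
1/f^α Gaussian background noise (α = 1, RMS 0.5 by default; the
background spectrum of the emulated recordings is not characterized
anywhere, so this is a generic cortical-noise choice). The oscillation is
a cosine at the coupling band's center frequency (6 Hz for theta 4–8 Hz)
with amplitude 1.0 and an independent uniform phase per trial, shared
across channels: it models a local population rhythm coherent over the
electrode array, which is what makes unit-to-channel coherence
well-defined for every pair and makes coupling distance-independent by
construction.

**Spikes.** Units fire as inhomogeneous Poisson processes with
`r(t) = r₀ · exp(κ·cos(φ(t) − φ₀)) / I₀(κ)`: a von Mises modulation of
the rate by the oscillator phase. The I₀ normalization keeps the expected
rate equal to `r₀` (15 spikes/s by default, a typical V4 rate) for every
κ, so coupling strength and firing rate are independent dials. φ(t) is
the generator's ground-truth oscillator phase stored with each trace —
identical to the band-filtered Hilbert phase of the noiseless oscillation
— which keeps κ exactly interpretable; for bare traces without ground
truth the generator falls back to the band-filtered Hilbert phase of the
samples. By default the modulation acts only during the two stimulus
epochs (the regime in which block-wise coupling changes are confined to
stimulus processing and the delay period stays flat); `coupling="uniform"`
applies it throughout the trial. Spikes are drawn by thinning at the peak
rate.

**Observer.** Responses are Bernoulli draws from
`P(report different | Δθ) = 1 − (1 − FA)·exp(−(Δθ/a)^b)`; at Δθ = 0 the
error probability is exactly FA. Condition presets pin the block-wise 75%
thresholds by inverting the closed form (FA = 0.1, b = 1.3): "novel"
steps 18.9° → 8/5.5/4.5° with theta κ stepping 0.3 → 0.8/0.7/0.65;
"familiar" is flat (κ 0.65, threshold 4.5°); "no_learning"/"passive" are
flat with weak coupling (κ 0.3, threshold 19°). The 18.9° → 4.5°
trajectory and the <5° familiar regime are the study conditions being
emulated; the κ values are the generator's own ground truth chosen to put
block-1 theta SFC near its noise floor and the learned blocks an order of
magnitude above it.

**Eye traces.** Slow smoothed drift (RMS 0.02°) plus Poisson-injected
microsaccades (1/s, amplitudes 0.05–0.2° as 10 ms linear ramps in random
directions), returned together with the ground-truth event list.

**Seeding.** Every random draw derives from the single session seed via
`default_rng([seed, stream_tag, trial, entity])`, so any trial/channel/
unit is reproducible in isolation.

## Signal conditioning

LFPs are band-passed 0.5–100 Hz with a 4th-order Butterworth (the design
order; forward-backward application makes the effective order 8 and the
phase zero) and notched at 60 Hz with a 4th-order elliptic band-stop
(0.1 dB ripple, 40 dB stopband, edges 57/63 Hz chosen so one pass meets
40 dB at 60 Hz while 55/65 Hz lose < 3 dB). Because the 0.5 Hz corner has
multi-second transients, `filtfilt` is given reflect padding of
3/low seconds rather than scipy's short default. Artifact rejection
discards a trace iff more than 3 samples leave its own mean ± 4 SD; the
statistics are per trial and channel since muscle artifacts are
trial-local events.

Multitaper spectra of the 300 ms windows use unit-energy Slepian tapers
with TW = 4, K = 2·TW − 1 = 7 for frequencies strictly above 30 Hz and a
single Hanning taper at and below 30 Hz, where the Slepian main lobe
(±TW/T ≈ 13 Hz) would smear the low bands. The PSD is scaled so that its
integral over the one-sided grid equals the windowed variance. Power
statistics live on the native FFT grid of the window (≈ 3.32 Hz spacing);
no zero padding is used for statistics, avoiding interpolation artifacts.
Band powers are grid means over theta 5–7, alpha 8–13, beta 15–30, gamma
35–80 Hz; block-wise powers are normalized to the fixation-period
spectrum and then to each channel/band's block-1 mean (block 1 ≡ 1 by
construction).

Two theta definitions coexist deliberately: the power bands use 5–7 Hz
while all coherence statistics use 4–8 Hz; both are named presets
(`POWER_BANDS["theta"]`, `SFC_THETA`) so neither silently stands in for
the other.

## Spike-field coherence

Segments are ±150 ms around each spike — 301 samples, center sample
included; the spectral code accepts 300 or 301 so STA and segment spectra
always share a grid. Spikes whose window crosses the trace edge are
excluded rather than zero-padded (padding would bias segment spectra
low). SFC = STA power / mean segment power per frequency; by Jensen's
inequality this ratio cannot leave [0, 1], and it is exactly invariant to
scaling the LFP. Sliding maps use 10 ms steps with windows fully inside
the trace. Block statistics pool the 150–350 ms post-onset windows of
target and test (skipping the onset transient), equalize spike counts
across blocks by sampling without replacement down to the minimum block
count, and are reproducible from the analysis seed.

**z-transform.** `z = β(−(V − 2)·ln(1 − SFC) − β)`, β = 1.15, applied
with the SFC in the role of magnitude-squared coherence (the quantity
`|C|²` of the transform; a "coherence magnitude of 0.5" therefore enters
as SFC = 0.25). V defaults to `n_spikes × n_tapers`; the conventional
`2 × n_spikes × n_tapers` is available via `dof_convention`. The package's
null-calibration study (`spikefield.calibration.null_z_samples`:
independent Poisson trains of ~1,000 spikes on white-noise LFP, z read at
a theta grid frequency where a single Hanning taper is in effect)
measures a variance near 1 under the default convention — analytically
the asymptotic independent-segment value is β² ≈ 1.32, and mild segment
overlap pulls the measured value down into the 0.9–1.3 range — whereas
the 2× convention gives ≈ 4–5. The default convention is therefore the
one the calibration supports; the transform is a variance *assessment*,
not an exact standard-normalizer, and tests treat it as such.

**Shuffle surrogate.** Trial-to-LFP assignments are permuted (each trial
used exactly once; plain permutations by default — a `derangement` flag
forbids fixed points, which changes nothing detectable at 96 trials), one
SFC per permutation, median over 100 permutations. Coupled data collapse
to the null under shuffling; uncoupled data are unchanged.

**Cross-check.** A direct multitaper point-process coherence estimator
(tapered spike spectra, mean-rate corrected, cross/auto spectra averaged
over trials and tapers) is implemented as an independent route. On
spike-centered windows with single-taper (theta-grid) spectra the two
estimators coincide algebraically, and the test suite verifies < 2% RMS
disagreement over 20 coupled fixtures. With fixed (non-spike-centered)
windows and many spikes per window the two measure genuinely different
quantities — the point-process coherence grows with spikes-per-window —
so the equivalence is only asserted in the matched regime.

## Phase locking

Band filters are equiripple FIRs (remez) with edges theta 3.5/4–8/8.5,
alpha 7/8–14/15, beta 13/14–30/31.5, gamma 28/30–80/82 Hz, 40 dB
stopband, 1 dB passband ripple. The narrow 0.5 Hz transitions at 1 kHz force long filters
(~4,000 taps for theta); they are applied once as centered convolutions
(linear phase → exact group-delay compensation) over reflect-padded
traces. Phases come from the analytic signal; spike phases use
nearest-sample lookup (worst-case error at 8 Hz and 1 kHz is < 0.026 rad,
negligible against the effects measured).

Circular statistics are implemented directly (no circular-statistics
dependency exists in the environment): Rayleigh `Z = |Σe^{iθ}|²/n` with
the standard exponential p-approximation, the Hodges–Ajne omnibus test
(exact half-circle count formula) as the "omnibus" variant since no
specific one is named, Fisher's nonparametric common-median test across
blocks (the `circ_cmtest` semantics), and a two-sample Kuiper test with
Stephens' asymptotic tail (p clamped to 1 below the series' validity;
adequate for n ≳ 20 per sample). Golden tests pin their behavior on
constructed fixtures (identical samples, antipodal pairs, uniform nulls,
rotation invariance).

## Behavior

Psychometric curves report the proportion of "different" reports per Δθ —
at Δθ = 0 this is the false-alarm rate. Weibull fits hold FA fixed at the
observed rate (the formula treats FA as data, not a parameter) and
estimate (a, b) by bounded least squares on the per-Δθ proportions;
binomial likelihood weighting is available as an option and agrees on
clean data. A fit is flagged unconverged when the optimizer fails with a
non-trivial residual, the fitted curve has no usable dynamic range, or a
parameter sits on its bound; saturated-accuracy plateaus that merely
exhaust the optimizer's budget at a near-zero residual still count as
converged, because b is then unidentified but the threshold is not.
Thresholds use the exact closed-form inversion (P(T) = 0.75 identically).
Learning curves: per-96-trial-block fits, and a 64-trial window slid in
10-trial steps with an exponential fit `y∞ + (y0 − y∞)e^{−t/τ}` (the
simplest saturating form). Block-1-style thresholds near or beyond the
largest tested rotation (20°) are extrapolations and unstable at 96
trials — the cohort driver censors fits beyond 40° rather than trusting
them. Microsaccade detection thresholds the 10 ms vector velocity at
≥ 10 deg/s (inclusive: 0.1° per 10 ms sits exactly at threshold and
counts), merges contiguous intervals, and flags a trial for abort iff an
event's net amplitude exceeds 0.25°.

## Session pipeline

Blocks are consecutive 96-trial groups (trailing remainder dropped).
`d′ = |μ_A − μ_B| / sqrt((σ²_A + σ²_B)/2)` per test-rotation pair from
test-window firing rates. Pairs are every unit × channel combination with
their electrode distance (near < 2 mm ≤ far; default geometry 0, 1.0,
3.2 mm puts same-electrode, near, and far pairs in every session).
Block-change statistics: per pair, mean of blocks 2–4 vs block 1 —
paired Wilcoxon signed-rank, Kruskal–Wallis omnibus across blocks, and
relative change (block_k − block_1)/block_1 computed per pair before
averaging. Per-band tests are reported uncorrected (matching the emulated
analysis; a Holm option exists), and with fewer than 10 pairs only
descriptive summaries are produced. The delay is split into three equal
windows (boundaries 0/333/667/1000 ms after target offset). Error trials
are included in neural analyses by default (a correct-only switch
exists); the emulated protocol does not state the exclusion. The
cross-session report correlates each session's threshold change (blocks
2–4 mean vs block 1) with its mean theta-SFC change, Pearson r with
per-band breakdown.

## Problem sizes

Defaults are desk-scale by design: 2 units × 3 channels (6 pairs) per
synthetic session rather than hundreds, 384 trials, 100 shuffle
permutations, 400 null-calibration replicates of ~1,000 spikes. These
sizes make every block-1 coherence estimate sit close to its noise floor
(1/n_spikes), which is faithful to the small-sample behavior of the
estimator but makes *relative* SFC changes unstable when the baseline is
near zero — absolute changes are the robust summary at this scale, and
the statistics tables report both.

## Known limitations

- The common-oscillator LFP model makes coupling distance-independent and
  gives every pair the same rhythm; spatial falloff of coherence cannot
  be studied with it.
- The von Mises rate modulation is periodic in the oscillator phase, so
  strong theta locking carries harmonics (12, 18 Hz …) and spectral
  leakage of the 6 Hz peak into neighboring bands; with the generator's
  modest noise this produces small but systematic alpha/beta/gamma SFC
  residuals that real broadband recordings would swamp. Passing tests
  constrain these to be an order of magnitude below the theta effect, not
  to be zero.
- The z-transform's stated unit null variance is only approximately
  attained (see above); comparisons between z values are safe, absolute
  normal-theory p-values from z are not.
- The Kuiper and Rayleigh p-values are asymptotic approximations;
  simulations in the tests bound their type-I error near the nominal 5%
  but small samples (< ~20 angles) should rely on the omnibus test's
  exact formula.
- The generator emulates neither attention/reward dynamics, receptive
  field structure, spike sorting, nor recording hardware; condition flags
  ("familiar", "no_learning", "passive") reproduce the study's contrasts
  only at the level of coupling and observer parameters.
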