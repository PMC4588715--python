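# spikefield

Analysis of spike–LFP synchronization during rapid perceptual learning,
with a synthetic-session generator that carries known ground truth.

During a single discrimination session, a subject compares a 300 ms target
image with a 300 ms test image flashed after a 1 s delay and reports
whether the test was rotated (0/3/5/10/20°). Behavior and simultaneously
recorded spikes and local field potentials (LFPs) are analyzed in blocks
of 96 trials to ask whether learning within the session is accompanied by
a tightening of spike timing relative to the local theta (4–8 Hz) rhythm.
The package implements the full analysis chain and, because no public
recordings accompany this paradigm, a generator that emulates entire
sessions (LFPs, phase-coupled spike trains, a Weibull observer, eye
traces) so that every stage has a parameter-recovery test.

## Core quantities

**Spike-field coherence (SFC).** With LFP segments `s_i` of ±150 ms around
each spike, the spike-triggered average is `STA = mean_i(s_i)` and

    SFC(f) = P_STA(f) / mean_i P_{s_i}(f)

where `P` is a multitaper power spectrum (Slepian tapers, `K = 2·TW − 1`,
`TW = 4` above 30 Hz; a single Hanning taper below). SFC lies in [0, 1]
(1 = every spike at the same phase of that frequency) and is invariant to
LFP rescaling and, in expectation, to firing rate. Block-wise statistics
equalize spike counts across blocks by random subsampling, use the
150–350 ms window after each stimulus onset, and are checked against a
100-permutation trial-shuffle surrogate. Coherence is variance-assessed
through `z = β(−(V − 2)·ln(1 − SFC) − β)` with `β = 1.15` and
`V = n_spikes × n_tapers`.

**Phase locking.** The LFP is band-passed with zero-phase equiripple FIR
filters (theta edges 3.5/4–8/8.5 Hz, 40 dB stopband), Hilbert transformed,
and the phase at each spike time is tested for non-uniformity (Rayleigh
`Z = |Σ e^{iθ}|²/n`, Hodges–Ajne omnibus) and compared across blocks
(common-median test, pairwise Kuiper tests).

**Psychometrics.** Accuracy follows the Weibull form
`P(Δθ) = 1 − (1 − FA)·exp(−(Δθ/a)^b)` with FA the observed false-alarm
rate; the discrimination threshold is the rotation at which accuracy is
75%, `T = a·(ln((1 − FA)/0.25))^{1/b}`.

## Worked example

```python
import spikefield as sk
from spikefield.session_pipeline import AnalysisConfig

cfg, profiles, observer = sk.make_condition("novel", seed=2)
session = sk.generate_session(cfg, profiles, observer)
result = sk.run_session(session, AnalysisConfig(n_shuffles=100))

print(result.thresholds[["block", "threshold"]])
print(result.pair_results.query("band == 'theta'")
      .groupby("block")[["sfc", "sfc_shuffled"]].mean())
```

prints (seed 2)

```
 block  threshold        block     sfc  sfc_shuffled
     1      18.81            1  0.0022        0.0018
     2       6.19            2  0.0692        0.0030
     3       6.77            3  0.0689        0.0032
     4       3.34            4  0.0466        0.0024
```

i.e. the behavioral threshold collapses after the first 96-trial block
(18.8° → ~3–7°) while theta SFC rises from its block-1 level and the
trial-shuffled surrogate stays at the null — the coupling is carried by
spike timing, not by stimulus-locked components. The numbered scripts in
`analysis/` walk through the full study: session generation, behavioral
learning curves, block-wise SFC with near/far electrode splits,
delay-period windows and phase statistics, and the cross-session
correlation between threshold change and theta-SFC change (negative: more
synchronization, better learning).

The same machinery runs from the shell:

```sh
spikefield simulate --condition novel --seed 2 --out session.h5
spikefield analyze --in session.h5 --out results/
spikefield cohort --sessions results/ --out cohort.json
```

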