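"""Synthetic discrimination sessions with known ground truth.

Emulates one recording session of the delayed match-to-sample orientation
discrimination task: a 300 ms target, a 1000 ms blank delay, and a 300 ms
test image rotated by 0/3/5/10/20 degrees, organized in blocks of 96 trials
(48 match trials and 12 non-match trials per non-zero rotation).  For each
trial the generator produces

* an LFP per channel: 1/f^α Gaussian background plus a band-limited
  oscillation (common oscillator across channels, random phase per trial),
* spike trains whose instantaneous rate is modulated by the oscillator
  phase through a von Mises factor with block-dependent concentration κ
  (κ = 0 reduces to a homogeneous Poisson train at the base rate),
* a behavioral outcome drawn from a Weibull observer
  P(Δθ) = 1 − (1 − FA)·exp(−(Δθ/a)^b) with block-dependent parameters,
* eye-position traces with drift and injected microsaccades.

All randomness derives from the single session seed through named
SeedSequence streams (one per trial and signal kind), so any single trial
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0

from .signal_conditioning import LfpTrace

# stream tags for seed splitting: default_rng([seed, TAG, trial, entity])
_TAG_LFP, _TAG_SPIKES, _TAG_BEHAVIOR, _TAG_EYE, _TAG_PLAN, _TAG_PHASE = range(6)


@dataclass(frozen=True)
class TrialTiming:
    """Trial epoch durations (ms).  Times are referenced to target onset."""

    fixation_ms: float = 500.0
    target_ms: float = 300.0
    delay_ms: float = 1000.0
    test_ms: float = 300.0
    post_ms: float = 100.0
    delay_jitter_ms: tuple[float, float] | None = None  # e.g. (800, 1200)

    def __post_init__(self) -> None:
        for name in ("fixation_ms", "target_ms", "delay_ms", "test_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def delay_for_trial(self, rng: np.random.Generator | None) -> float:
        if self.delay_jitter_ms is None or rng is None:
            return self.delay_ms
        lo, hi = self.delay_jitter_ms
        return float(rng.uniform(lo, hi))

    def test_onset(self, delay_ms: float | None = None) -> float:
        d = self.delay_ms if delay_ms is None else delay_ms
        return (self.target_ms + d) / 1000.0

    def trial_span(self, delay_ms: float | None = None) -> tuple[float, float]:
        """(t_start, t_end) in seconds relative to target onset."""
        d = self.delay_ms if delay_ms is None else delay_ms
        t_end = (self.target_ms + d + self.test_ms + self.post_ms) / 1000.0
        return -self.fixation_ms / 1000.0, t_end


@dataclass(frozen=True)
class SessionConfig:
    n_blocks: int = 4
    trials_per_block: int = 96
    orientations: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0, 20.0)
    timing: TrialTiming = field(default_factory=TrialTiming)
    lfp_rate: float = 1000.0
    seed: int = 0
    n_channels: int = 3
    n_units: int = 2
    #: electrode position (mm along the array) of each LFP channel / unit
    channel_positions_mm: tuple[float, ...] = (0.0, 1.0, 3.2)
    unit_positions_mm: tuple[float, ...] = (0.0, 1.0)

    def __post_init__(self) -> None:
        nz = [o for o in self.orientations if o > 0]
        if 0.0 not in self.orientations or not nz:
            raise ValueError("orientations must include 0 and >=1 rotation")
        if self.trials_per_block % 2 or (self.trials_per_block // 2) % len(nz):
            raise ValueError("trials_per_block must split into half match "
                             "trials and equal non-match counts per rotation")
        if len(self.channel_positions_mm) != self.n_channels:
            raise ValueError("one position per channel required")
        if len(self.unit_positions_mm) != self.n_units:
            raise ValueError("one position per unit required")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def match_per_block(self) -> int:
        return self.trials_per_block // 2

    @property
    def nonmatch_per_orientation(self) -> int:
        nz = [o for o in self.orientations if o > 0]
        return self.trials_per_block // 2 // len(nz)


@dataclass(frozen=True)
class CouplingProfile:
    """Ground-truth spike/LFP coupling for one block.

    ``kappa`` is the von Mises concentration of the phase modulation of the
    firing rate (0 = no coupling); ``coupling`` restricts the modulation to
    the stimulus epochs ("stimulus") or applies it throughout ("uniform").
    """

    band: tuple[str, float, float] = ("theta", 4.0, 8.0)
    kappa: float = 0.0
    preferred_phase: float = 0.0
    base_rate: float = 15.0
    oscillation_amplitude: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 0.5
    coupling: str = "stimulus"

    def __post_init__(self) -> None:
        name, low, high = self.band
        if low >= high:
            raise ValueError(f"band {name}: low must be < high")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.coupling not in ("stimulus", "uniform"):
            raise ValueError("coupling must be 'stimulus' or 'uniform'")

    @property
    def oscillation_freq(self) -> float:
        return 0.5 * (self.band[1] + self.band[2])


@dataclass(frozen=True)
class ObserverModel:
    """Weibull observer parameters for one block."""

    fa: float = 0.10
    a: float = 8.0
    b: float = 1.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa < 1.0:
            raise ValueError("false-alarm rate must be in [0, 1)")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Weibull offset and slope must be positive")


def weibull_p(delta_theta: float | np.ndarray, fa: float, a: float, b: float):
    """P(report 'different') = 1 − (1 − FA)·exp(−(Δθ/a)^b); P(0) = FA."""
    d = np.asarray(delta_theta, float)
    return 1.0 - (1.0 - fa) * np.exp(-np.power(d / a, b, where=d > 0,
                                               out=np.zeros_like(d)))


@dataclass
class Session:
    """One complete synthetic session with embedded ground truth."""

    config: SessionConfig
    trials: pd.DataFrame
    lfp: np.ndarray          # (n_channels, n_trials, n_samples)
    spikes: list             # [unit][trial] -> array of times (s)
    eye: np.ndarray          # (n_trials, n_samples, 2) degrees
    eye_events: list         # [trial] -> DataFrame of injected events
    oscillation_phase0: np.ndarray  # per-trial oscillator phase offset (rad)
    profiles: tuple[CouplingProfile, ...]
    observer: tuple[ObserverModel, ...]
    condition: str = "novel"
    t0: float = -0.5

    @property
    def rate(self) -> float:
        return self.config.lfp_rate

    def lfp_trace(self, channel: int, trial: int) -> LfpTrace:
        prof = self.profiles[int(self.trials.iloc[trial]["block"]) - 1]
        phase = self._phase_series(trial, prof)
        return LfpTrace(self.lfp[channel, trial], self.rate, self.t0,
                        oscillation_phase=phase)

    def _phase_series(self, trial: int, prof: CouplingProfile) -> np.ndarray:
        n = self.lfp.shape[2]
        t = self.t0 + np.arange(n) / self.rate
        ph = 2 * np.pi * prof.oscillation_freq * t + self.oscillation_phase0[trial]
        return np.angle(np.exp(1j * ph))

    def pair_distance_mm(self, unit: int, channel: int) -> float:
        return abs(self.config.unit_positions_mm[unit]
                   - self.config.channel_positions_mm[channel])


def _trial_rng(seed: int, tag: int, trial: int, entity: int = 0
               ) -> np.random.Generator:
    return np.random.default_rng([seed, tag, trial, entity])


def _one_over_f(n: int, rate: float, exponent: float, scale: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^α Gaussian noise with RMS ≈ scale."""
    if scale == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n)
    rms = x.std()
    return x * (scale / rms) if rms > 0 else x


def generate_lfp(config: SessionConfig, profile: CouplingProfile,
                 trial_index: int, channel: int = 0,
                 oscillation_phase0: float | None = None,
                 delay_ms: float | None = None) -> LfpTrace:
    """One trial's LFP: band oscillation plus 1/f^α background.

    The trace spans fixation onset through ``post_ms`` after test offset.
    The ground-truth oscillator phase is attached to the returned trace.
    """
    t_start, t_end = config.timing.trial_span(delay_ms)
    n = int(round((t_end - t_start) * config.lfp_rate)) + 1
    t = t_start + np.arange(n) / config.lfp_rate
    rng = _trial_rng(config.seed, _TAG_LFP, trial_index, channel)
    if oscillation_phase0 is None:
        oscillation_phase0 = float(
            _trial_rng(config.seed, _TAG_PHASE, trial_index).uniform(
                0, 2 * np.pi))
    phase = 2 * np.pi * profile.oscillation_freq * t + oscillation_phase0
    osc = profile.oscillation_amplitude * np.cos(phase)
    noise = _one_over_f(n, config.lfp_rate, profile.noise_exponent,
                        profile.noise_scale, rng)
    return LfpTrace(osc + noise, config.lfp_rate, t_start,
                    oscillation_phase=np.angle(np.exp(1j * phase)))


def _coupling_mask(times: np.ndarray, timing: TrialTiming,
                   delay_ms: float | None = None) -> np.ndarray:
    test_on = timing.test_onset(delay_ms)
    tgt = (times >= 0) & (times < timing.target_ms / 1000.0)
    tst = (times >= test_on) & (times < test_on + timing.test_ms / 1000.0)
    return tgt | tst


def generate_spikes(lfp: LfpTrace, profile: CouplingProfile,
                    rng: np.random.Generator | None = None,
                    timing: TrialTiming | None = None,
                    delay_ms: float | None = None):
    """Phase-coupled inhomogeneous Poisson spike train on one trial.

    Rate r(t) = base_rate·exp(κ·cos(φ(t) − φ₀))/I₀(κ): the expected rate
    equals base_rate over a uniform phase distribution for any κ.  φ(t) is
    the trace's ground-truth oscillator phase when available, otherwise the
    band-filtered Hilbert phase of the samples.  Spikes are drawn by
    thinning a homogeneous Poisson train at the peak rate.
    """
    from .spike_field import SpikeTrain

    if profile.kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    n = lfp.samples.size
    t = lfp.times
    if profile.base_rate == 0:
        return SpikeTrain(np.array([]))
    if lfp.oscillation_phase is not None:
        phi = lfp.oscillation_phase
    else:
        from .phase_locking import band_filter, instantaneous_phase
        name, low, high = profile.band
        spec_band = {"theta": "theta", "alpha": "alpha", "beta": "beta",
                     "gamma": "gamma"}.get(name, "theta")
        phi = instantaneous_phase(band_filter(lfp, spec_band))
    kappa = profile.kappa
    mod = np.exp(kappa * np.cos(phi - profile.preferred_phase)) / i0(kappa)
    if profile.coupling == "stimulus" and timing is not None:
        mask = _coupling_mask(t, timing, delay_ms)
        mod = np.where(mask, mod, 1.0)
    r_max = profile.base_rate * np.exp(kappa) / i0(kappa)
    span = t[-1] - t[0]
    n_cand = rng.poisson(r_max * span)
    cand = np.sort(t[0] + rng.uniform(0, span, size=n_cand))
    idx = np.clip(np.round((cand - lfp.t0) * lfp.rate).astype(int), 0, n - 1)
    rate_at = profile.base_rate * mod[idx]
    keep = rng.uniform(0, r_max, size=n_cand) < rate_at
    return SpikeTrain(cand[keep])


def generate_behavior(config: SessionConfig, observer: ObserverModel,
                      trial_index: int, delta_theta: float | None = None,
                      block: int | None = None) -> dict:
    """One trial's behavioral record as a dict (TrialRecord fields).

    The correct/incorrect flag is Bernoulli with P('different' report)
    given by the observer's Weibull; a match trial (Δθ = 0) is an error
    ('hold') with probability FA.
    """
    rng = _trial_rng(config.seed, _TAG_BEHAVIOR, trial_index)
    if delta_theta is None:
        delta_theta = float(rng.choice(config.orientations))
    if delta_theta not in config.orientations:
        raise ValueError(f"delta_theta {delta_theta} not in configured set")
    p_diff = float(weibull_p(delta_theta, observer.fa, observer.a, observer.b))
    says_different = bool(rng.uniform() < p_diff)
    is_match = delta_theta == 0.0
    response = "hold" if says_different else "release"
    correct = says_different != is_match
    return {"trial": trial_index, "block": block,
            "delta_theta": delta_theta, "is_match": is_match,
            "response": response, "correct": correct}


def generate_eye_trace(config: SessionConfig, microsaccade_rate: float = 1.0,
                       amplitudes: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20),
                       trial_index: int = 0, duration: float | None = None,
                       drift_rms: float = 0.02):
    """Eye x/y positions (degrees, 1 kHz) with injected microsaccades.

    Returns (positions (n, 2), events DataFrame with the ground-truth
    injection times/amplitudes).  Steps ramp linearly over 10 ms.
    """
    if microsaccade_rate < 0:
        raise ValueError("microsaccade rate must be >= 0")
    if np.any(np.asarray(amplitudes) < 0):
        raise ValueError("amplitudes must be >= 0")
    rng = _trial_rng(config.seed, _TAG_EYE, trial_index)
    if duration is None:
        t_start, t_end = config.timing.trial_span()
        duration = t_end - t_start
    n = int(round(duration * config.lfp_rate)) + 1
    # slow smooth drift: heavily low-passed white noise, zero mean
    pos = np.zeros((n, 2))
    if drift_rms > 0:
        from scipy.ndimage import uniform_filter1d
        for k in range(2):
            w = rng.standard_normal(n)
            d = uniform_filter1d(uniform_filter1d(w, 201), 201)
            sd = d.std()
            pos[:, k] = d * (drift_rms / sd) if sd > 0 else 0.0
    n_ev = rng.poisson(microsaccade_rate * duration)
    step_len = int(0.010 * config.lfp_rate)
    events = []
    starts = np.sort(rng.integers(0, max(n - step_len - 1, 1), size=n_ev))
    for s in starts:
        amp = float(rng.choice(amplitudes))
        ang = rng.uniform(0, 2 * np.pi)
        vec = amp * np.array([np.cos(ang), np.sin(ang)])
        ramp = np.linspace(0, 1, step_len + 1)
        pos[s:s + step_len + 1] += ramp[:, None] * vec[None, :]
        pos[s + step_len + 1:] += vec[None, :]
        events.append({"t": s / config.lfp_rate, "amplitude": amp,
                       "angle": ang})
    return pos, pd.DataFrame(events, columns=["t", "amplitude", "angle"])


def _block_plan(config: SessionConfig, block: int) -> np.ndarray:
    """Shuffled Δθ sequence for one block honoring the trial composition."""
    nz = [o for o in config.orientations if o > 0]
    plan = ([0.0] * config.match_per_block
            + [o for o in nz for _ in range(config.nonmatch_per_orientation)])
    rng = _trial_rng(config.seed, _TAG_PLAN, block)
    plan = np.array(plan)
    rng.shuffle(plan)
    return plan


def generate_session(config: SessionConfig,
                     profiles: list[CouplingProfile],
                     observer: list[ObserverModel],
                     condition: str = "novel",
                     microsaccade_rate: float = 1.0) -> Session:
    """Full synthetic session: trials, LFPs, spikes, behavior, eye traces."""
    if len(profiles) != config.n_blocks or len(observer) != config.n_blocks:
        raise ValueError("need one CouplingProfile and one ObserverModel "
                         "per block")
    t_start, t_end = config.timing.trial_span()
    n_samples = int(round((t_end - t_start) * config.lfp_rate)) + 1

    records = []
    lfp = np.empty((config.n_channels, config.n_trials, n_samples))
    spikes = [[None] * config.n_trials for _ in range(config.n_units)]
    eye = np.empty((config.n_trials, n_samples, 2))
    eye_events = []
    phase0 = np.empty(config.n_trials)

    trial = 0
    for b in range(config.n_blocks):
        prof, obs = profiles[b], observer[b]
        plan = _block_plan(config, b)
        for dtheta in plan:
            phase0[trial] = float(_trial_rng(config.seed, _TAG_PHASE,
                                             trial).uniform(0, 2 * np.pi))
            ref = None
            for ch in range(config.n_channels):
                tr = generate_lfp(config, prof, trial, channel=ch,
                                  oscillation_phase0=phase0[trial])
                lfp[ch, trial] = tr.samples
                if ref is None:
                    ref = tr
            for u in range(config.n_units):
                rng_u = _trial_rng(config.seed, _TAG_SPIKES, trial, u)
                spikes[u][trial] = generate_spikes(
                    ref, prof, rng=rng_u, timing=config.timing).times
            rec = generate_behavior(config, obs, trial, delta_theta=dtheta,
                                    block=b + 1)
            records.append(rec)
            pos, ev = generate_eye_trace(config, microsaccade_rate,
                                         trial_index=trial)
            eye[trial] = pos[:n_samples]
            eye_events.append(ev)
            trial += 1

    trials = pd.DataFrame(records)
    return Session(config=config, trials=trials, lfp=lfp, spikes=spikes,
                   eye=eye, eye_events=eye_events, oscillation_phase0=phase0,
                   profiles=tuple(profiles), observer=tuple(observer),
                   condition=condition, t0=t_start)


# ------------------------------------------------------- condition presets

def _observer_for_thresholds(thresholds, fa: float = 0.10, b: float = 1.3):
    """Observers whose exact 75% thresholds equal ``thresholds``."""
    scale = np.log((1 - fa) / 0.25) ** (1.0 / b)
    return [ObserverModel(fa=fa, a=float(t) / scale, b=b) for t in thresholds]


def make_condition(condition: str, seed: int = 0,
                   config: SessionConfig | None = None
                   ) -> tuple[SessionConfig, list[CouplingProfile],
                              list[ObserverModel]]:
    """Generator presets for the four session types.

    novel: theta coupling steps up after block 1 while the behavioral
    threshold falls 18.9° → 4.5°; familiar: flat coupling, low flat
    threshold; no_learning / passive: flat weak coupling, high flat
    threshold.
    """
    from dataclasses import replace as _replace
    if config is None:
        config = SessionConfig(seed=seed)
    elif config.seed != seed:
        config = _replace(config, seed=seed)
    nb = config.n_blocks

    def profs(kappas):
        return [CouplingProfile(kappa=k) for k in kappas]

    if condition == "novel":
        kappas = [0.3, 0.8, 0.7, 0.65][:nb]
        thresholds = [18.9, 8.0, 5.5, 4.5][:nb]
    elif condition == "familiar":
        kappas, thresholds = [0.65] * nb, [4.5] * nb
    elif condition == "no_learning":
        kappas, thresholds = [0.3] * nb, [19.0] * nb
    elif condition == "passive":
        kappas, thresholds = [0.3] * nb, [19.0] * nb
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return config, profs(kappas), _observer_for_thresholds(thresholds)
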