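"""Spike-triggered averages and spike-field coherence (SFC).

The STA is the mean LFP segment in a ±150 ms window centered on each spike;
the SFC at each frequency is the power spectrum of the STA divided by the
average power spectrum of the contributing segments, so it lies in [0, 1]
(1 = every spike at the same phase of that frequency) and is invariant to
LFP rescaling and, in expectation, to firing-rate changes.  Supporting
machinery: sliding-window SFC maps, spike-count equalization across blocks,
the z-transform of coherence with its degrees-of-freedom bookkeeping, a
trial-shuffle surrogate, and a direct multitaper point-process coherence
estimator used as an independent cross-check of the STA route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_conditioning import (BandDefinition, LfpTrace, MultitaperConfig,
                                  _segment_psd)

logger = logging.getLogger(__name__)

#: constant of the coherence z-transform
Z_BETA = 1.15


class NoUsableSpikesError(ValueError):
    """Raised when no spike has a full ±window segment inside the trace."""


@dataclass
class SpikeTrain:
    """Event times (s) of one unit in one trial, relative to target onset."""

    times: np.ndarray
    unit_id: str = "u0"
    channel_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class SpikeTriggeredAverage:
    trace: np.ndarray
    rate: float
    n_spikes: int
    window_half: float = 0.150

    def __post_init__(self) -> None:
        if self.n_spikes < 1:
            raise ValueError("an STA needs at least one spike")


@dataclass
class CoherenceEstimate:
    frequencies: np.ndarray
    sfc: np.ndarray               # nan where undefined (zero segment power)
    n_spikes: int
    n_tapers: np.ndarray          # tapers per frequency

    def __post_init__(self) -> None:
        ok = np.isfinite(self.sfc)
        if np.any(self.sfc[ok] < -1e-9) or np.any(self.sfc[ok] > 1 + 1e-9):
            raise ValueError("SFC must lie in [0, 1]")


@dataclass
class ZScoredCoherence:
    frequencies: np.ndarray
    z: np.ndarray
    beta: float = Z_BETA
    dof: np.ndarray | None = None


def _usable_spike_indices(spikes: SpikeTrain, lfp: LfpTrace,
                          analysis_window, half_n: int) -> np.ndarray:
    times = spikes.times
    if analysis_window is not None:
        t0, t1 = analysis_window
        times = times[(times >= t0) & (times <= t1)]
    idx = np.round((times - lfp.t0) * lfp.rate).astype(int)
    ok = (idx - half_n >= 0) & (idx + half_n < lfp.samples.size)
    return idx[ok]


def _segments(spikes: SpikeTrain, lfp: LfpTrace, analysis_window,
              window_half: float) -> np.ndarray:
    """(n_spikes, 2·half+1) LFP segments centered on each usable spike."""
    half_n = int(round(window_half * lfp.rate))
    idx = _usable_spike_indices(spikes, lfp, analysis_window, half_n)
    if idx.size == 0:
        raise NoUsableSpikesError("no spike has a full window inside the trace")
    offs = np.arange(-half_n, half_n + 1)
    return lfp.samples[idx[:, None] + offs[None, :]]


def compute_sta(spikes: SpikeTrain, lfp: LfpTrace,
                analysis_window: tuple[float, float] | None = None,
                window_half: float = 0.150) -> SpikeTriggeredAverage:
    """Mean ±window LFP segment over usable spikes.

    Spikes whose window crosses the trace edge are excluded (zero-padding
    would bias the segment spectra); none usable raises
    :class:`NoUsableSpikesError`.
    """
    segs = _segments(spikes, lfp, analysis_window, window_half)
    return SpikeTriggeredAverage(segs.mean(axis=0), lfp.rate, segs.shape[0],
                                 window_half)


def _sfc_from_segments(segs: np.ndarray, rate: float, cfg: MultitaperConfig
                       ) -> CoherenceEstimate:
    freqs, psd_segs, n_tapers = _segment_psd(segs, rate, cfg)
    _, psd_sta, _ = _segment_psd(segs.mean(axis=0)[None, :], rate, cfg)
    denom = psd_segs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sfc = np.where(denom > 0, psd_sta[0] / denom, np.nan)
    if np.any(denom == 0):
        logger.info("SFC: %d frequencies with zero segment power masked",
                    int(np.sum(denom == 0)))
    return CoherenceEstimate(freqs, np.clip(sfc, 0.0, 1.0), segs.shape[0],
                             n_tapers)


def compute_sfc(spikes: SpikeTrain, lfp: LfpTrace,
                analysis_window: tuple[float, float] | None = None,
                cfg: MultitaperConfig | None = None) -> CoherenceEstimate:
    """STA-power over mean segment-power, per frequency.

    Both spectra use the same taper configuration.  Frequencies where the
    mean segment power is zero are undefined and returned as NaN (logged).
    """
    cfg = cfg or MultitaperConfig()
    segs = _segments(spikes, lfp, analysis_window, cfg.window_half)
    return _sfc_from_segments(segs, lfp.rate, cfg)


def pooled_sfc(spikes_per_trial: list[SpikeTrain],
               lfps_per_trial: list[LfpTrace],
               analysis_window: tuple[float, float] | None = None,
               cfg: MultitaperConfig | None = None) -> CoherenceEstimate:
    """One SFC from spike-centered segments pooled across trials."""
    cfg = cfg or MultitaperConfig()
    segs = []
    for spk, lfp in zip(spikes_per_trial, lfps_per_trial):
        try:
            segs.append(_segments(spk, lfp, analysis_window, cfg.window_half))
        except NoUsableSpikesError:
            continue
    if not segs:
        raise NoUsableSpikesError("no usable spikes in any trial")
    return _sfc_from_segments(np.concatenate(segs, axis=0),
                              lfps_per_trial[0].rate, cfg)


def sliding_sfc(spikes: SpikeTrain, lfp: LfpTrace,
                cfg: MultitaperConfig | None = None,
                t_start: float = -0.100, t_end: float = 1.700
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SFC in ±150 ms windows stepped every 10 ms over [t_start, t_end].

    Returns (window centers, frequencies, sfc[time, freq]); windows without
    usable spikes are NaN rows.
    """
    cfg = cfg or MultitaperConfig()
    half = cfg.window_half
    centers = np.arange(t_start + half, t_end - half + 1e-9, cfg.step)
    freqs = np.fft.rfftfreq(int(round(2 * half * lfp.rate)) + 1,
                            1.0 / lfp.rate)
    out = np.full((centers.size, freqs.size), np.nan)
    for i, c in enumerate(centers):
        try:
            est = compute_sfc(spikes, lfp, (c - half, c + half), cfg)
        except NoUsableSpikesError:
            continue
        out[i] = est.sfc
    return centers, freqs, out


def subsample_spikes(spikes_by_block: dict[int, SpikeTrain],
                     seed: int | np.random.Generator = 0
                     ) -> dict[int, SpikeTrain]:
    """Equalize spike counts across blocks by sampling without replacement.

    Every returned train has exactly the minimum block count; blocks with
    zero spikes invalidate the pair and raise.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    counts = {b: tr.n for b, tr in spikes_by_block.items()}
    if any(c == 0 for c in counts.values()):
        empty = [b for b, c in counts.items() if c == 0]
        raise NoUsableSpikesError(f"blocks {empty} have no spikes")
    m = min(counts.values())
    out = {}
    for b in sorted(spikes_by_block):
        tr = spikes_by_block[b]
        keep = np.sort(rng.choice(tr.n, size=m, replace=False))
        out[b] = SpikeTrain(tr.times[keep], tr.unit_id, tr.channel_id)
    return out


def z_transform_sfc(est: CoherenceEstimate,
                    dof_convention: str = "spikes_x_tapers"
                    ) -> ZScoredCoherence:
    """z = β·(−(V−2)·ln(1−SFC) − β), β = 1.15.

    The SFC (a power ratio) plays the role of magnitude-squared coherence
    in the transform.  V is the degrees of freedom: n_spikes·n_tapers by
    default, with the conventional 2·n_spikes·n_tapers as an option.
    Frequencies with SFC = 1 are masked (infinite z); V ≤ 2 is rejected.
    """
    if dof_convention == "spikes_x_tapers":
        V = est.n_spikes * est.n_tapers.astype(float)
    elif dof_convention == "2_spikes_x_tapers":
        V = 2.0 * est.n_spikes * est.n_tapers.astype(float)
    else:
        raise ValueError(f"unknown dof convention {dof_convention!r}")
    if np.any(V <= 2):
        raise ValueError("degrees of freedom must exceed 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = Z_BETA * (-(V - 2) * np.log(1.0 - est.sfc) - Z_BETA)
    z = np.where(est.sfc >= 1.0, np.nan, z)
    return ZScoredCoherence(est.frequencies, z, Z_BETA, dof=V)


def shuffle_control_sfc(spikes_per_trial: list[SpikeTrain],
                        lfps_per_trial: list[LfpTrace],
                        analysis_window: tuple[float, float] | None = None,
                        cfg: MultitaperConfig | None = None,
                        n_shuffles: int = 100,
                        seed: int | np.random.Generator = 0,
                        derangement: bool = False) -> CoherenceEstimate:
    """Trial-shuffled surrogate SFC: median over permutations.

    Each shuffle permutes the trial-to-LFP assignment (each trial sampled
    once — a plain permutation by default; ``derangement`` forbids fixed
    points), pools all spike-centered segments, and computes one SFC; the
    per-frequency median across shuffles is returned.
    """
    cfg = cfg or MultitaperConfig()
    n_trials = len(spikes_per_trial)
    if n_trials < 2 or len(lfps_per_trial) != n_trials:
        raise ValueError("need >= 2 trials with matching spike/LFP lists")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    freqs = None
    all_sfc, n_used = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_trials)
        if derangement:
            while np.any(perm == np.arange(n_trials)):
                perm = rng.permutation(n_trials)
        segs = []
        for i, j in enumerate(perm):
            try:
                segs.append(_segments(spikes_per_trial[i], lfps_per_trial[j],
                                      analysis_window, cfg.window_half))
            except NoUsableSpikesError:
                continue
        if not segs:
            continue
        est = _sfc_from_segments(np.concatenate(segs, axis=0),
                                 lfps_per_trial[0].rate, cfg)
        freqs, n_tapers = est.frequencies, est.n_tapers
        all_sfc.append(est.sfc)
        n_used.append(est.n_spikes)
    if not all_sfc:
        raise NoUsableSpikesError("no usable spikes in any shuffle")
    med = np.clip(np.nanmedian(np.stack(all_sfc), axis=0), 0.0, 1.0)
    return CoherenceEstimate(freqs, med, int(np.median(n_used)), n_tapers)


def band_average_sfc(est: CoherenceEstimate, band: BandDefinition) -> float:
    """Mean SFC over grid frequencies inside [band.low, band.high]."""
    sel = (est.frequencies >= band.low) & (est.frequencies <= band.high)
    if not np.any(sel):
        raise ValueError(f"band {band.name} overlaps no grid frequency")
    return float(np.nanmean(est.sfc[sel]))


def point_process_coherence(spikes_per_trial: list[SpikeTrain],
                            lfps_per_trial: list[LfpTrace],
                            window: tuple[float, float],
                            cfg: MultitaperConfig | None = None
                            ) -> CoherenceEstimate:
    """Direct multitaper coherence between spikes (point process) and LFP.

    Per trial and taper, the LFP spectrum of the analysis window and the
    tapered point-process spectrum (sum of taper-weighted complex
    exponentials at spike times, mean-rate corrected) form cross and auto
    spectra averaged over trials and tapers; the magnitude-squared
    coherence is returned on the same grid as the STA-based SFC.  This is
    the estimator of the Chronux ``coherencycpt`` family and serves as an
    independent check of the STA route.
    """
    from .signal_conditioning import _hanning, _tapers

    cfg = cfg or MultitaperConfig()
    rate = lfps_per_trial[0].rate
    n = int(round(2 * cfg.window_half * rate)) + 1
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    low = freqs <= cfg.crossover if cfg.low_freq_taper else np.zeros_like(
        freqs, bool)
    slep = _tapers(n, cfg.TW, cfg.K)
    han = _hanning(n)[None, :]

    def accumulate(tapers):
        K = tapers.shape[0]
        sxx = np.zeros(freqs.size)
        syy = np.zeros(freqs.size)
        sxy = np.zeros(freqs.size, complex)
        count = 0
        for spk, lfp in zip(spikes_per_trial, lfps_per_trial):
            i0 = lfp.index_of(window[0])
            if i0 < 0 or i0 + n > lfp.samples.size:
                continue
            x = lfp.samples[i0:i0 + n]
            t_rel = spk.times - (lfp.t0 + i0 / rate)
            sel = (t_rel >= 0) & (t_rel < n / rate)
            samp = np.round(t_rel[sel] * rate).astype(int)
            samp = samp[samp < n]
            Jx = np.fft.rfft(tapers * x[None, :], axis=1)
            # tapered point-process spectrum, mean-rate contribution removed
            if samp.size:
                e = np.exp(-2j * np.pi * np.outer(samp / rate, freqs))
                Jy = tapers[:, samp] @ e  # (K, freqs)
                Jy = Jy - (samp.size / n) * np.fft.rfft(tapers, axis=1)
            else:
                Jy = np.zeros((K, freqs.size), complex)
            sxx += np.sum(np.abs(Jx) ** 2, axis=0)
            syy += np.sum(np.abs(Jy) ** 2, axis=0)
            sxy += np.sum(Jx * np.conj(Jy), axis=0)
            count += samp.size
        with np.errstate(divide="ignore", invalid="ignore"):
            c2 = np.abs(sxy) ** 2 / (sxx * syy)
        return np.where((sxx > 0) & (syy > 0), c2, np.nan), count

    c2_s, count = accumulate(slep)
    if cfg.low_freq_taper:
        c2_h, _ = accumulate(han)
        c2 = np.where(low, c2_h, c2_s)
    else:
        c2 = c2_s
    n_tapers = np.where(low, 1, cfg.K)
    return CoherenceEstimate(freqs, np.clip(c2, 0, 1), count, n_tapers)
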