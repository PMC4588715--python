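"""Session-level orchestration: blocks, pairs, statistics, cross-session.

Runs the full analysis of one session — LFP conditioning, block
segmentation, per-pair spike-field coherence with spike-count equalization,
z-scores and phase statistics, band-power trends, behavioral fits, delay
period windows — and pools sessions for the coherence/behavior correlation
(change in theta SFC, blocks 2–4 vs block 1, against the change in
discrimination threshold).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as beh
from . import phase_locking as pl
from . import signal_conditioning as sc
from . import spike_field as sf
from .synthetic_data import Session

logger = logging.getLogger(__name__)

#: SFC statistics are computed in this window after each stimulus onset,
#: skipping the onset transient
STIM_WINDOW = (0.150, 0.350)
NEAR_FAR_MM = 2.0


@dataclass(frozen=True)
class AnalysisConfig:
    mt: sc.MultitaperConfig = field(default_factory=sc.MultitaperConfig)
    #: SFC bands: theta uses the wide 4–8 Hz definition
    sfc_bands: tuple = (
        sc.BandDefinition("theta", *sc.SFC_THETA),
        sc.BandDefinition("alpha", 8.0, 13.0),
        sc.BandDefinition("beta", 15.0, 30.0),
        sc.BandDefinition("gamma", 35.0, 80.0),
    )
    block_size: int = 96
    n_shuffles: int = 100
    dof_convention: str = "spikes_x_tapers"
    include_same_electrode: bool = True
    seed: int = 0


@dataclass
class SessionResult:
    condition: str
    thresholds: pd.DataFrame          # per-block behavioral fits
    pair_results: pd.DataFrame        # pair × block × band SFC (+z)
    phase_stats: pd.DataFrame
    band_stats: pd.DataFrame
    delay_sfc: pd.DataFrame
    neuron_metrics: pd.DataFrame
    qc: pd.DataFrame

    @property
    def delta_threshold(self) -> float:
        t = self.thresholds.sort_values("block")["threshold"].to_numpy()
        if np.isnan(t[0]):
            return np.nan
        return float(np.nanmean(t[1:]) - t[0])

    def delta_sfc(self, band: str = "theta") -> float:
        df = self.pair_results[self.pair_results["band"] == band]
        b1 = df[df["block"] == 1].set_index("pair")["sfc"]
        rest = (df[df["block"] > 1].groupby("pair")["sfc"].mean())
        common = b1.index.intersection(rest.index)
        if len(common) == 0:
            return np.nan
        return float((rest[common] - b1[common]).mean())


def segment_blocks(trials: pd.DataFrame, block_size: int = 96) -> pd.DataFrame:
    """Label consecutive ``block_size``-trial blocks; drop the remainder."""
    n = len(trials)
    if n < block_size:
        raise ValueError(f"need >= {block_size} trials, got {n}")
    n_blocks = n // block_size
    dropped = n - n_blocks * block_size
    if dropped:
        logger.info("segment_blocks: dropping %d trailing trials", dropped)
    out = trials.iloc[:n_blocks * block_size].copy()
    out["block"] = np.repeat(np.arange(1, n_blocks + 1), block_size)
    return out


def compute_dprime(rates_a: np.ndarray, rates_b: np.ndarray) -> float:
    """d' = |mean_A − mean_B| / sqrt((var_A + var_B)/2)."""
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 trials per condition")
    pooled = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    diff = abs(a.mean() - b.mean())
    if pooled == 0:
        if diff == 0:
            return 0.0
        logger.warning("compute_dprime: zero pooled variance with unequal "
                       "means -> inf")
        return float("inf")
    return float(diff / np.sqrt(pooled))


def _condition_lfp(session: Session, cfg: AnalysisConfig
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Band-pass + notch every trace; artifact partition per channel."""
    n_ch, n_tr, _ = session.lfp.shape
    cond = np.empty_like(session.lfp)
    qc_rows = []
    for ch in range(n_ch):
        traces = []
        for tr in range(n_tr):
            t = sc.LfpTrace(session.lfp[ch, tr], session.rate, session.t0)
            t = sc.notch_filter(sc.bandpass_filter(t))
            cond[ch, tr] = t.samples
            traces.append(t)
        kept, discarded = sc.reject_artifacts(traces)
        qc_rows.append({"channel": ch, "kept": len(kept),
                        "discarded": len(discarded),
                        "discarded_trials": discarded})
    return cond, pd.DataFrame(qc_rows)


def _trace(session: Session, cond: np.ndarray, ch: int, tr: int) -> sc.LfpTrace:
    return sc.LfpTrace(cond[ch, tr], session.rate, session.t0)


def _stim_windows(session: Session) -> list[tuple[float, float]]:
    test_on = session.config.timing.test_onset()
    return [STIM_WINDOW, (test_on + STIM_WINDOW[0], test_on + STIM_WINDOW[1])]


def _spikes_in_windows(times: np.ndarray, windows) -> np.ndarray:
    keep = np.zeros(times.size, bool)
    for lo, hi in windows:
        keep |= (times >= lo) & (times <= hi)
    return times[keep]


def _block_spike_trains(session: Session, unit: int, trials: pd.DataFrame,
                        windows) -> dict[int, dict[int, np.ndarray]]:
    """block -> {trial index -> in-window spike times}."""
    out: dict[int, dict[int, np.ndarray]] = {}
    for block, grp in trials.groupby("block"):
        d = {}
        for tr in grp.index:
            t = _spikes_in_windows(np.asarray(session.spikes[unit][tr]),
                                   windows)
            if t.size:
                d[tr] = t
        out[int(block)] = d
    return out


def _pooled_sfc(session: Session, cond: np.ndarray, ch: int,
                spike_times_by_trial: dict[int, np.ndarray],
                cfg: AnalysisConfig) -> sf.CoherenceEstimate:
    """One SFC from segments pooled over the trials of a block."""
    trials = sorted(spike_times_by_trial)
    return sf.pooled_sfc(
        [sf.SpikeTrain(spike_times_by_trial[t]) for t in trials],
        [_trace(session, cond, ch, t) for t in trials], None, cfg.mt)


def _equalize_counts(blocks: dict[int, dict[int, np.ndarray]],
                     rng: np.random.Generator
                     ) -> dict[int, dict[int, np.ndarray]]:
    """Subsample each block's pooled spikes to the min block count."""
    counts = {b: sum(t.size for t in d.values()) for b, d in blocks.items()}
    if any(c == 0 for c in counts.values()):
        raise sf.NoUsableSpikesError("a block has no in-window spikes")
    m = min(counts.values())
    out = {}
    for b, d in blocks.items():
        trials = sorted(d)
        lengths = [d[t].size for t in trials]
        total = sum(lengths)
        pick = np.sort(rng.choice(total, size=m, replace=False))
        edges = np.cumsum([0] + lengths)
        sub = {}
        for t, lo, hi in zip(trials, edges[:-1], edges[1:]):
            sel = pick[(pick >= lo) & (pick < hi)] - lo
            if sel.size:
                sub[t] = d[t][sel]
        out[b] = sub
    return out


def pair_sfc_table(session: Session, cond: np.ndarray, trials: pd.DataFrame,
                   cfg: AnalysisConfig) -> pd.DataFrame:
    """Per unit×channel pair and block: band SFC, z, shuffle surrogate."""
    rng = np.random.default_rng([cfg.seed, 7])
    windows = _stim_windows(session)
    rows = []
    for u in range(session.config.n_units):
        blocks_all = _block_spike_trains(session, u, trials, windows)
        for ch in range(session.config.n_channels):
            dist = session.pair_distance_mm(u, ch)
            if not cfg.include_same_electrode and dist == 0.0:
                continue
            try:
                eq = _equalize_counts(blocks_all, rng)
            except sf.NoUsableSpikesError as err:
                logger.warning("pair u%d-ch%d excluded: %s", u, ch, err)
                continue
            for b, spk in sorted(eq.items()):
                try:
                    est = _pooled_sfc(session, cond, ch, spk, cfg)
                except sf.NoUsableSpikesError:
                    continue
                zsc = sf.z_transform_sfc(est, cfg.dof_convention)
                shuffled = None
                if cfg.n_shuffles > 0:
                    tr_ids = sorted(spk)
                    if len(tr_ids) >= 2:
                        sp_trains = [sf.SpikeTrain(spk[t]) for t in tr_ids]
                        lfps = [_trace(session, cond, ch, t) for t in tr_ids]
                        shuffled = sf.shuffle_control_sfc(
                            sp_trains, lfps, None, cfg.mt,
                            n_shuffles=cfg.n_shuffles, seed=rng)
                for band in cfg.sfc_bands:
                    sel = ((est.frequencies >= band.low)
                           & (est.frequencies <= band.high))
                    row = {"pair": f"u{u}-ch{ch}", "unit": u, "channel": ch,
                           "distance_mm": dist,
                           "near": dist < NEAR_FAR_MM,
                           "same_electrode": dist == 0.0,
                           "block": b, "band": band.name,
                           "n_spikes": est.n_spikes,
                           "sfc": sf.band_average_sfc(est, band),
                           "z": float(np.nanmean(zsc.z[sel]))}
                    row["sfc_shuffled"] = (
                        sf.band_average_sfc(shuffled, band)
                        if shuffled is not None else np.nan)
                    rows.append(row)
    return pd.DataFrame(rows)


def phase_locking_table(session: Session, cond: np.ndarray,
                        trials: pd.DataFrame, cfg: AnalysisConfig,
                        band: str = "theta") -> pd.DataFrame:
    """Per pair and block: spike-phase circular statistics in the band."""
    windows = _stim_windows(session)
    rows = []
    for u in range(session.config.n_units):
        blocks = _block_spike_trains(session, u, trials, windows)
        for ch in range(session.config.n_channels):
            dists_by_block = {}
            for b, d in blocks.items():
                angles = []
                for tr, times in d.items():
                    filt = pl.band_filter(_trace(session, cond, ch, tr), band)
                    phi = pl.instantaneous_phase(filt)
                    for lo, hi in windows:
                        dist = pl.spike_phases(times, phi, session.rate,
                                               session.t0, (lo, hi))
                        angles.append(dist.angles)
                pooled = (np.concatenate(angles) if angles
                          else np.array([]))
                dists_by_block[b] = pl.PhaseDistribution(pooled,
                                                         window=STIM_WINDOW)
            for b, dist in sorted(dists_by_block.items()):
                rep = pl.uniformity_tests(dist)
                rows.append({"pair": f"u{u}-ch{ch}", "block": b, "band": band,
                             "n": rep["n"],
                             "rayleigh_z": rep["rayleigh_z"],
                             "rayleigh_p": rep["rayleigh_p"],
                             "omnibus_p": rep["omnibus_p"],
                             "mean_phase": (pl.circular_mean(dist.angles)
                                            if dist.n else np.nan),
                             "resultant": (pl.resultant_length(dist.angles)
                                           if dist.n else np.nan)})
    return pd.DataFrame(rows)


def delay_windows(timing) -> dict[str, tuple[float, float]]:
    """Early/middle/late thirds of the delay, seconds from target onset."""
    delay_s = timing.delay_ms / 1000.0
    if delay_s < 0.999:
        logger.warning("delay period %.0f ms < 1000 ms: windows rescaled",
                       timing.delay_ms)
    t_off = timing.target_ms / 1000.0
    w = delay_s / 3.0
    return {name: (t_off + i * w, t_off + (i + 1) * w)
            for i, name in enumerate(("early", "middle", "late"))}


def delay_period_sfc(session: Session, cond: np.ndarray, trials: pd.DataFrame,
                     cfg: AnalysisConfig) -> pd.DataFrame:
    """Band SFC in three equal delay windows (early/middle/late) per block."""
    windows = delay_windows(session.config.timing)
    rng = np.random.default_rng([cfg.seed, 11])
    rows = []
    for name, win in windows.items():
        for u in range(session.config.n_units):
            blocks = _block_spike_trains(session, u, trials, [win])
            for ch in range(session.config.n_channels):
                try:
                    eq = _equalize_counts(blocks, rng)
                except sf.NoUsableSpikesError:
                    continue
                for b, spk in sorted(eq.items()):
                    try:
                        est = _pooled_sfc(session, cond, ch, spk, cfg)
                    except sf.NoUsableSpikesError:
                        continue
                    for band in cfg.sfc_bands:
                        rows.append({"window": name, "pair": f"u{u}-ch{ch}",
                                     "block": b, "band": band.name,
                                     "sfc": sf.band_average_sfc(est, band)})
    return pd.DataFrame(rows)


def block_change_statistics(pair_values: pd.DataFrame,
                            value_col: str = "sfc",
                            min_pairs: int = 10) -> pd.DataFrame:
    """Blocks 2–4 vs block 1 statistics per band.

    Paired Wilcoxon signed-rank on per-pair (mean of blocks ≥ 2) vs block 1,
    Kruskal–Wallis across blocks, and relative-change summaries
    (block_k − block_1)/block_1 computed per pair then averaged.
    """
    rows = []
    for band, df in pair_values.groupby("band"):
        piv = df.pivot_table(index="pair", columns="block", values=value_col)
        piv = piv.dropna()
        blocks = sorted(c for c in piv.columns)
        n_pairs = len(piv)
        row = {"band": band, "n_pairs": n_pairs}
        if 1 in blocks:
            b1 = piv[1]
            later = piv[[b for b in blocks if b > 1]].mean(axis=1)
            rel = (later - b1) / b1.replace(0, np.nan)
            row["median_rel_change"] = float(rel.median())
            row["mean_rel_change"] = float(rel.mean())
            row["sem_rel_change"] = float(rel.sem())
        if n_pairs < min_pairs:
            row.update({"wilcoxon_p": np.nan, "kruskal_p": np.nan,
                        "descriptive_only": True})
            rows.append(row)
            continue
        row["descriptive_only"] = False
        try:
            diff = later - b1
            if np.allclose(diff, 0):
                row.update({"wilcoxon_p": np.nan, "degenerate": True})
            else:
                row["wilcoxon_p"] = float(
                    stats.wilcoxon(later, b1).pvalue)
        except ValueError:
            row["wilcoxon_p"] = np.nan
        try:
            row["kruskal_p"] = float(
                stats.kruskal(*[piv[b] for b in blocks]).pvalue)
        except ValueError:
            row["kruskal_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def neuron_block_metrics(session: Session, trials: pd.DataFrame,
                         window: tuple[float, float] | None = None
                         ) -> pd.DataFrame:
    """Per-unit, per-block mean firing rate and d' between test rotations."""
    timing = session.config.timing
    if window is None:
        on = timing.test_onset()
        window = (on, on + timing.test_ms / 1000.0)
    dur = window[1] - window[0]
    rows = []
    for u in range(session.config.n_units):
        for block, grp in trials.groupby("block"):
            rates = {}
            for tr in grp.index:
                t = np.asarray(session.spikes[u][tr])
                cnt = np.sum((t >= window[0]) & (t <= window[1]))
                rates.setdefault(grp.loc[tr, "delta_theta"], []).append(
                    cnt / dur)
            mean_rate = float(np.mean([r for v in rates.values() for r in v]))
            oris = sorted(rates)
            dps = []
            for i, oa in enumerate(oris):
                for ob in oris[i + 1:]:
                    if len(rates[oa]) >= 2 and len(rates[ob]) >= 2:
                        dps.append(compute_dprime(rates[oa], rates[ob]))
            rows.append({"unit": u, "block": int(block),
                         "mean_rate": mean_rate,
                         "dprime": float(np.mean(dps)) if dps else np.nan})
    return pd.DataFrame(rows)


def run_session(session: Session, cfg: AnalysisConfig | None = None,
                out_dir: str | Path | None = None) -> SessionResult:
    """Full per-session analysis; optionally writes result tables."""
    cfg = cfg or AnalysisConfig()
    trials = segment_blocks(session.trials, cfg.block_size)
    cond, qc = _condition_lfp(session, cfg)
    thresholds = beh.block_thresholds(trials)
    pairs = pair_sfc_table(session, cond, trials, cfg)
    phases = phase_locking_table(session, cond, trials, cfg)
    delay = delay_period_sfc(session, cond, trials, cfg)
    stats_tab = block_change_statistics(pairs)
    metrics = neuron_block_metrics(session, trials)
    result = SessionResult(session.condition, thresholds, pairs, phases,
                           stats_tab, delay, metrics, qc)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        thresholds.to_csv(out / "thresholds.csv", index=False)
        pairs.to_csv(out / "pair_sfc.csv", index=False)
        phases.to_csv(out / "phase_stats.csv", index=False)
        stats_tab.to_csv(out / "band_stats.csv", index=False)
        delay.to_csv(out / "delay_sfc.csv", index=False)
        metrics.to_csv(out / "neuron_metrics.csv", index=False)
        qc.drop(columns=["discarded_trials"]).to_csv(out / "qc.csv",
                                                     index=False)
    return result


def sfc_behavior_correlation(results: list[SessionResult],
                             bands: tuple[str, ...] = ("theta", "alpha",
                                                       "beta", "gamma")
                             ) -> pd.DataFrame:
    """Pearson correlation of Δthreshold with ΔSFC per band across sessions.

    ΔSFC is the mean change (blocks 2–4 vs block 1) across a session's
    pairs; Δthreshold is the block 2–4 mean minus block 1 threshold.
    """
    dthr = np.array([r.delta_threshold for r in results])
    rows = []
    for band in bands:
        dsfc = np.array([r.delta_sfc(band) for r in results])
        ok = np.isfinite(dthr) & np.isfinite(dsfc)
        if ok.sum() < 5:
            raise ValueError("need >= 5 sessions with valid changes")
        if np.std(dthr[ok]) == 0 or np.std(dsfc[ok]) == 0:
            rows.append({"band": band, "r": np.nan, "p": np.nan,
                         "n_sessions": int(ok.sum()), "degenerate": True})
            continue
        r, p = stats.pearsonr(dthr[ok], dsfc[ok])
        rows.append({"band": band, "r": float(r), "p": float(p),
                     "n_sessions": int(ok.sum()), "degenerate": False})
    return pd.DataFrame(rows)


def save_cohort_report(results: list[SessionResult], path: str | Path
                       ) -> dict:
    corr = sfc_behavior_correlation(results)
    report = {
        "n_sessions": len(results),
        "delta_threshold": [r.delta_threshold for r in results],
        "delta_theta_sfc": [r.delta_sfc("theta") for r in results],
        "correlations": corr.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(report, indent=2))
    return report
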