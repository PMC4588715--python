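#!/usr/bin/env python
"""Delay-period SFC windows and spike-phase circular statistics.

Splits the 1000 ms delay into early/middle/late thirds and asks whether
theta SFC changes across blocks there (with stimulus-locked coupling it
should not), then summarizes theta spike-phase locking per block: Rayleigh
Z and p, omnibus test, and the across-block common-median / pairwise
Kuiper comparisons.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import spikefield as sk
from spikefield.session_pipeline import (AnalysisConfig, _condition_lfp,
                                         delay_period_sfc,
                                         phase_locking_table)
from spikefield.phase_locking import PhaseDistribution, compare_phase_distributions

from importlib import import_module
get_session = import_module("02_behavioral_learning").get_session

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    session = get_session("novel")
    cfg = AnalysisConfig(n_shuffles=0)
    trials = sk.segment_blocks(session.trials)
    cond, _ = _condition_lfp(session, cfg)

    delay = delay_period_sfc(session, cond, trials, cfg)
    delay.to_csv(OUT / "delay_sfc.csv", index=False)
    th = delay.query("band == 'theta'")
    print("delay-period theta SFC (mean over pairs), block 1 vs 2-4:")
    for name, grp in th.groupby("window"):
        b1 = grp.query("block == 1")["sfc"].mean()
        rest = grp.query("block > 1")["sfc"].mean()
        print(f"  {name:6s}: block1 {b1:.4f}  blocks2-4 {rest:.4f}")

    phases = phase_locking_table(session, cond, trials, cfg)
    phases.to_csv(OUT / "phase_stats.csv", index=False)
    summary = phases.groupby("block")[["rayleigh_z", "resultant"]].mean()
    print("\ntheta spike-phase locking by block (stimulus windows):")
    print(summary.round(3).to_string())

    # block-wise phase-distribution comparison on one example pair
    dists = {}
    from spikefield.phase_locking import band_filter, instantaneous_phase, spike_phases
    from spikefield.session_pipeline import _stim_windows, _trace
    windows = _stim_windows(session)
    for b, grp in trials.groupby("block"):
        angles = []
        for tr in grp.index:
            filt = band_filter(_trace(session, cond, 1, tr), "theta")
            phi = instantaneous_phase(filt)
            for w in windows:
                angles.append(spike_phases(session.spikes[0][tr], phi,
                                           session.rate, session.t0,
                                           w).angles)
        dists[int(b)] = PhaseDistribution(np.concatenate(angles))
    rep = compare_phase_distributions(dists)
    print(f"\nexample pair u0-ch1: common-median test across blocks "
          f"p = {rep['cm_p']:.4g}")
    pw = pd.DataFrame([{"blocks": k, **v} for k, v in rep["pairwise"].items()])
    pw.to_csv(OUT / "kuiper_pairwise.csv", index=False)
    print(pw.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
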