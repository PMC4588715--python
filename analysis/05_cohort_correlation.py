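#!/usr/bin/env python
"""Cross-session correlation between learning and theta synchronization.

Simulates a cohort in which a per-session coupling gain drives both the
block 2-4 rise in theta coupling and the behavioral threshold improvement,
then correlates the session's threshold change with its mean theta SFC
change (blocks 2-4 vs block 1) per band.  Expected: a significant negative
Pearson r in theta and nothing in the higher bands.
"""

from pathlib import Path

import numpy as np

import spikefield as sk
from spikefield.session_pipeline import (AnalysisConfig, run_session,
                                         save_cohort_report,
                                         sfc_behavior_correlation)
from spikefield.synthetic_data import (CouplingProfile, SessionConfig,
                                       _observer_for_thresholds)

OUT = Path(__file__).resolve().parents[1] / "results"
N_SESSIONS = 16
SEED = 7
#: thresholds extrapolated far beyond the largest tested rotation (20 deg)
#: are unreliable; such sessions are censored from the correlation
MAX_THRESHOLD = 40.0


def gained_session(seed: int, gain: float) -> sk.Session:
    """Session whose learning magnitude scales with ``gain`` in [0, 1]."""
    rng = np.random.default_rng(seed)
    cfg = SessionConfig(seed=seed)
    kappas = [0.3] + [0.3 + 0.5 * gain + 0.05 * rng.standard_normal()] * 3
    t1 = 18.9
    t_rest = t1 - 14.4 * gain + 1.5 * rng.standard_normal()
    thresholds = [t1] + [max(t_rest, 2.0)] * 3
    profiles = [CouplingProfile(kappa=max(k, 0.0)) for k in kappas]
    observer = _observer_for_thresholds(thresholds)
    return sk.generate_session(cfg, profiles, observer, condition="novel")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    gains = np.linspace(0.05, 0.95, N_SESSIONS)
    results = []
    for i, g in enumerate(gains):
        s = gained_session(SEED + i, float(g))
        res = run_session(s, AnalysisConfig(n_shuffles=0))
        thr = res.thresholds["threshold"]
        if thr.isna().any() or (thr > MAX_THRESHOLD).any():
            print(f"session {i}: gain {g:.2f}  censored "
                  f"(threshold fit outside tested range)")
            continue
        results.append(res)
        print(f"session {i}: gain {g:.2f}  dThr {res.delta_threshold:+6.1f} deg  "
              f"dTheta-SFC {res.delta_sfc('theta'):+.4f}")
    corr = sfc_behavior_correlation(results)
    mags = {b: float(np.mean([r.delta_sfc(b) for r in results]))
            for b in ("theta", "alpha", "beta", "gamma")}
    corr["mean_delta_sfc"] = corr["band"].map(mags)
    save_cohort_report(results, OUT / "cohort.json")
    print("\nsession-by-session correlation of threshold change vs SFC change:")
    print(corr.round(4).to_string(index=False))
    print("\nnote: only theta carries a sizable SFC change; the non-zero "
          "r in other bands rides\non changes one to two orders of "
          "magnitude smaller (harmonics and spectral leakage\nof the 6 Hz "
          "locking), which real broadband noise would swamp.")


if __name__ == "__main__":
    main()
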