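"""Estimator calibration studies run on synthetic null/ideal inputs.

These are the package's own validation experiments: the null distribution
of the z-transformed SFC under independent spikes and LFP (which also pins
the degrees-of-freedom convention), and the perfect-synchronization bound.
"""

from __future__ import annotations

import numpy as np

from .signal_conditioning import LfpTrace, MultitaperConfig
from .spike_field import SpikeTrain, compute_sfc, z_transform_sfc


def null_z_samples(n_replicates: int = 200, n_spikes: int = 1000,
                   spike_rate: float = 1.0, frequency: float = 6.5,
                   seed: int = 0,
                   cfg: MultitaperConfig | None = None) -> dict:
    """z-transformed SFC at one frequency under the no-coupling null.

    Each replicate draws an independent white-noise LFP at 1 kHz and a
    homogeneous Poisson spike train (``n_spikes`` expected events at
    ``spike_rate`` spikes/s, so segments overlap little), computes the
    STA-based SFC and the z-transform under both degrees-of-freedom
    conventions, and records z at the grid frequency nearest ``frequency``.

    Returns {"frequency", "z": {convention: array}, "variance": {...}}.
    """
    cfg = cfg or MultitaperConfig()
    rng = np.random.default_rng(seed)
    fs = 1000.0
    duration = n_spikes / spike_rate
    n = int(duration * fs)
    zs = {"spikes_x_tapers": [], "2_spikes_x_tapers": []}
    freq_used = None
    for _ in range(n_replicates):
        x = rng.standard_normal(n)
        n_sp = rng.poisson(n_spikes)
        times = np.sort(rng.uniform(0.151, duration - 0.151, size=n_sp))
        times = np.unique(times)
        est = compute_sfc(SpikeTrain(times), LfpTrace(x, fs, 0.0), None, cfg)
        fi = int(np.argmin(np.abs(est.frequencies - frequency)))
        freq_used = float(est.frequencies[fi])
        for conv in zs:
            zs[conv].append(float(z_transform_sfc(est, conv).z[fi]))
    zs = {k: np.asarray(v) for k, v in zs.items()}
    return {"frequency": freq_used,
            "z": zs,
            "variance": {k: float(np.var(v, ddof=1)) for k, v in zs.items()}}


def perfect_sync_sfc(frequency: float = 6.0, n_spikes: int = 200,
                     cfg: MultitaperConfig | None = None) -> float:
    """SFC at ``frequency`` for spikes placed at successive sinusoid peaks.

    A noiseless sinusoid with every spike at the same phase is the
    perfect-synchronization limit: the value approaches 1 up to the
    sub-sample jitter of placing continuous-time peaks on the 1 kHz grid.
    """
    fs = 1000.0
    duration = (n_spikes + 2) / frequency
    t = np.arange(int(duration * fs)) / fs
    lfp = LfpTrace(np.cos(2 * np.pi * frequency * t), fs, 0.0)
    peaks = (np.arange(n_spikes) + 1) / frequency
    est = compute_sfc(SpikeTrain(peaks), lfp, None, cfg)
    fi = int(np.argmin(np.abs(est.frequencies - frequency)))
    return float(est.sfc[fi])
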