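"""Shared fixtures: sinusoid traces and small coupled spike/LFP fixtures."""

import numpy as np
import pytest

from spikefield import SpikeTrain
from spikefield.signal_conditioning import LfpTrace


def sinusoid_trace(freq: float, duration: float = 2.0, rate: float = 1000.0,
                   amplitude: float = 1.0, phase: float = 0.0,
                   t0: float = 0.0) -> LfpTrace:
    t = t0 + np.arange(int(round(duration * rate))) / rate
    return LfpTrace(amplitude * np.cos(2 * np.pi * freq * t + phase),
                    rate, t0)


@pytest.fixture(scope="session")
def peak_locked_spikes():
    """Pure 6 Hz sinusoid with 200 spikes at successive peaks."""
    trace = sinusoid_trace(6.0, duration=34.0)
    peaks = (np.arange(200) + 1) / 6.0
    return SpikeTrain(peaks), trace


def coupled_fixture(seed: int, kappa: float = 2.0, n_trials: int = 60,
                    freq: float = 6.0, noise: float = 0.05,
                    rate: float = 1000.0):
    """Trials of a noisy sinusoid with one von Mises-locked spike each.

    Returns (spike trains, traces); each spike sits at a random cycle near
    mid-trial with phase drawn from a von Mises around 0 (the cosine peak).
    """
    rng = np.random.default_rng(seed)
    spikes, lfps = [], []
    while len(spikes) < n_trials:
        t = np.arange(0, 1.0, 1.0 / rate)
        ph0 = rng.uniform(0, 2 * np.pi)
        x = np.cos(2 * np.pi * freq * t + ph0)
        x = x + noise * rng.standard_normal(t.size)
        phi = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi,
                                                                     np.pi)
        k = round((2 * np.pi * freq * 0.5 + ph0) / (2 * np.pi))
        t_spk = (2 * np.pi * k - ph0 + phi) / (2 * np.pi * freq)
        if not 0.2 < t_spk < 0.8:
            continue
        spikes.append(SpikeTrain(np.array([t_spk])))
        lfps.append(LfpTrace(x, rate, 0.0))
    return spikes, lfps
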