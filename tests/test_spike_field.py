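"""STA, spike-field coherence, z-transform, subsampling, shuffle surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikefield as sk
from spikefield.signal_conditioning import BandDefinition, LfpTrace
from spikefield.spike_field import NoUsableSpikesError
from .conftest import coupled_fixture, sinusoid_trace


class TestSta:
    def test_constant_lfp_gives_constant_sta(self):
        tr = LfpTrace(np.full(2000, 2.5), 1000.0)
        sta = sk.compute_sta(sk.SpikeTrain(np.array([0.5, 0.9, 1.4])), tr)
        assert np.allclose(sta.trace, 2.5)
        assert sta.n_spikes == 3

    def test_sta_length_convention(self):
        tr = LfpTrace(np.zeros(2000), 1000.0)
        sta = sk.compute_sta(sk.SpikeTrain(np.array([1.0])), tr)
        assert sta.trace.size == 301  # 0.300 s × rate + 1

    def test_peak_locked_spikes_give_peak_at_lag_zero(self, peak_locked_spikes):
        spikes, tr = peak_locked_spikes
        sta = sk.compute_sta(spikes, tr)
        assert np.argmax(sta.trace) == 150

    def test_sta_shrinks_with_sqrt_n_on_noise(self):
        rng = np.random.default_rng(0)
        tr = LfpTrace(rng.standard_normal(400_000), 1000.0)
        amps = {}
        for n in (50, 800):
            t = np.sort(rng.choice(np.arange(1.0, 399.0, 0.25), n,
                                   replace=False))
            sta = sk.compute_sta(sk.SpikeTrain(t), tr)
            amps[n] = np.sqrt(np.mean(sta.trace ** 2))
        # amplitude ratio ≈ sqrt(800/50) = 4
        assert amps[50] / amps[800] == pytest.approx(4.0, rel=0.5)

    def test_no_usable_spikes_raises(self):
        tr = LfpTrace(np.zeros(200), 1000.0)
        with pytest.raises(NoUsableSpikesError):
            sk.compute_sta(sk.SpikeTrain(np.array([0.01])), tr)


class TestSfc:
    def test_perfect_synchronization(self, peak_locked_spikes):
        spikes, tr = peak_locked_spikes
        est = sk.compute_sfc(spikes, tr)
        fi = np.argmin(np.abs(est.frequencies - 6.0))
        assert est.sfc[fi] >= 0.99

    def test_uncoupled_sfc_near_zero_and_decreasing_with_n(self):
        rng = np.random.default_rng(1)
        tr = LfpTrace(rng.standard_normal(300_000), 1000.0)
        vals = {}
        for n in (100, 2000):
            t = np.sort(rng.choice(np.arange(1.0, 299.0, 0.05), n,
                                   replace=False))
            est = sk.compute_sfc(sk.SpikeTrain(t), tr)
            vals[n] = np.nanmean(est.sfc)
        assert vals[2000] < vals[100] < 0.15

    def test_scale_invariance_exact(self, peak_locked_spikes):
        spikes, tr = peak_locked_spikes
        ref = sk.compute_sfc(spikes, tr).sfc
        for alpha in (0.1, 10.0):
            scaled = LfpTrace(alpha * tr.samples, tr.rate, tr.t0)
            got = sk.compute_sfc(spikes, scaled).sfc
            assert np.allclose(np.nan_to_num(got), np.nan_to_num(ref))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_sfc_bounded_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        tr = LfpTrace(rng.standard_normal(4000), 1000.0)
        t = np.sort(rng.choice(np.arange(0.2, 3.8, 0.01), n, replace=False))
        est = sk.compute_sfc(sk.SpikeTrain(t), tr)
        ok = np.isfinite(est.sfc)
        assert np.all(est.sfc[ok] >= 0.0) and np.all(est.sfc[ok] <= 1.0)


class TestSlidingSfc:
    def test_window_center_count(self):
        # trial spanning −0.1 to 1.7 s: floor((1.8 − 0.3)/0.01) + 1 windows
        tr = LfpTrace(np.zeros(2200), 1000.0, t0=-0.4)
        centers, _, _ = sk.sliding_sfc(sk.SpikeTrain(np.array([0.5])), tr)
        assert centers.size == 151

    def test_empty_windows_masked(self):
        rng = np.random.default_rng(0)
        tr = LfpTrace(rng.standard_normal(2200), 1000.0, t0=-0.4)
        spikes = sk.SpikeTrain(np.sort(rng.uniform(0.9, 1.1, 40)))
        centers, _, sfc_map = sk.sliding_sfc(spikes, tr)
        early = centers < 0.5
        assert np.all(np.isnan(sfc_map[early]))
        assert np.any(np.isfinite(sfc_map[~early]))


class TestSubsample:
    def _trains(self, counts):
        rng = np.random.default_rng(0)
        return {b + 1: sk.SpikeTrain(np.sort(rng.uniform(0, 10, c)))
                for b, c in enumerate(counts)}

    def test_min_rule(self):
        out = sk.subsample_spikes(self._trains([100, 80, 90, 85]), seed=0)
        assert all(tr.n == 80 for tr in out.values())

    def test_equal_counts_preserved_size(self):
        out = sk.subsample_spikes(self._trains([50, 50]), seed=0)
        assert all(tr.n == 50 for tr in out.values())

    def test_seeds_give_different_subsets_same_sizes(self):
        trains = self._trains([100, 80])
        a = sk.subsample_spikes(trains, seed=0)
        b = sk.subsample_spikes(trains, seed=1)
        assert a[1].n == b[1].n == 80
        assert not np.array_equal(a[1].times, b[1].times)

    def test_zero_spike_block_rejected(self):
        trains = self._trains([50, 50])
        trains[3] = sk.SpikeTrain(np.array([]))
        with pytest.raises(NoUsableSpikesError):
            sk.subsample_spikes(trains, seed=0)


class TestZTransform:
    def _est(self, sfc_value, n_spikes, n_tapers=1):
        freqs = np.array([6.0])
        return sk.CoherenceEstimate(freqs, np.array([sfc_value]), n_spikes,
                                    np.array([n_tapers]))

    def test_zero_coherence_gives_minus_beta_squared(self):
        z = sk.z_transform_sfc(self._est(0.0, 100)).z[0]
        assert z == pytest.approx(-1.3225, abs=1e-12)

    def test_worked_example_magnitude_half(self):
        # coherence magnitude 0.5 (SFC = 0.25), V = 50:
        # z = 1.15·(−48·ln(0.75) − 1.15) — high-precision direct evaluation
        want = 1.15 * (-48.0 * np.log(0.75) - 1.15)
        z = sk.z_transform_sfc(self._est(0.25, 50)).z[0]
        assert z == pytest.approx(want, rel=1e-12)
        assert z == pytest.approx(14.558, abs=0.01)

    def test_sfc_one_masked(self):
        z = sk.z_transform_sfc(self._est(1.0, 100)).z[0]
        assert np.isnan(z)

    def test_low_dof_rejected(self):
        with pytest.raises(ValueError):
            sk.z_transform_sfc(self._est(0.2, 2))

    def test_conventional_dof_doubles_v(self):
        a = sk.z_transform_sfc(self._est(0.1, 50), "spikes_x_tapers")
        b = sk.z_transform_sfc(self._est(0.1, 50), "2_spikes_x_tapers")
        assert b.dof[0] == 2 * a.dof[0]


class TestShuffleControl:
    def test_identical_lfps_reproduce_unshuffled(self):
        # every permutation is the identity when all trial LFPs are equal
        tr = sinusoid_trace(6.0, duration=1.0)
        spikes = [sk.SpikeTrain(np.array([0.4])),
                  sk.SpikeTrain(np.array([0.5, 0.6]))]
        lfps = [tr, LfpTrace(tr.samples.copy(), tr.rate, tr.t0)]
        shuffled = sk.shuffle_control_sfc(spikes, lfps, n_shuffles=5, seed=0)
        segs = np.concatenate([np.stack([tr.samples[250:551]]),
                               np.stack([tr.samples[350:651],
                                         tr.samples[450:751]])])
        from spikefield.signal_conditioning import (MultitaperConfig,
                                                    _segment_psd)
        cfg = MultitaperConfig()
        _, psd, _ = _segment_psd(segs, 1000.0, cfg)
        _, psta, _ = _segment_psd(segs.mean(0)[None, :], 1000.0, cfg)
        want = np.clip(psta[0] / psd.mean(0), 0, 1)
        assert np.allclose(shuffled.sfc, want, atol=1e-12)

    def test_shuffling_destroys_coupling(self):
        spikes, lfps = coupled_fixture(0, kappa=3.0, n_trials=50)
        theta = BandDefinition("theta", 4, 8)
        unshuffled = sk.pooled_sfc(spikes, lfps)
        shuffled = sk.shuffle_control_sfc(spikes, lfps, n_shuffles=30, seed=1)
        assert sk.band_average_sfc(shuffled, theta) < \
            0.3 * sk.band_average_sfc(unshuffled, theta)

    def test_uncoupled_shuffle_matches_unshuffled(self):
        spikes, lfps = coupled_fixture(2, kappa=0.0, n_trials=60)
        theta = BandDefinition("theta", 4, 8)
        shuffled = sk.shuffle_control_sfc(spikes, lfps, n_shuffles=30, seed=2)
        unshuffled = sk.band_average_sfc(sk.pooled_sfc(spikes, lfps), theta)
        assert abs(sk.band_average_sfc(shuffled, theta) - unshuffled) < 0.25

    def test_single_trial_rejected(self):
        tr = sinusoid_trace(6.0, duration=1.0)
        with pytest.raises(ValueError):
            sk.shuffle_control_sfc([sk.SpikeTrain(np.array([0.5]))], [tr])


class TestBandAverage:
    def test_flat_sfc(self):
        freqs = np.arange(0, 101, 1.0)
        est = sk.CoherenceEstimate(freqs, np.full(freqs.size, 0.4), 10,
                                   np.ones(freqs.size))
        assert sk.band_average_sfc(est, BandDefinition("theta", 4, 8)) == \
            pytest.approx(0.4)

    def test_single_frequency_band_isolation(self):
        freqs = np.arange(0, 101, 1.0)
        sfc = np.zeros(freqs.size)
        sfc[6] = 0.8
        est = sk.CoherenceEstimate(freqs, sfc, 10, np.ones(freqs.size))
        assert sk.band_average_sfc(est, BandDefinition("theta", 4, 8)) > 0
        assert sk.band_average_sfc(est, BandDefinition("gamma", 35, 80)) == 0

    def test_hand_table(self):
        freqs = np.array([4.0, 6.0, 8.0, 40.0])
        est = sk.CoherenceEstimate(freqs, np.array([0.1, 0.2, 0.6, 0.9]), 10,
                                   np.ones(4))
        assert sk.band_average_sfc(est, BandDefinition("theta", 4, 8)) == \
            pytest.approx(0.3)

    def test_empty_overlap_rejected(self):
        freqs = np.array([4.0, 6.0])
        est = sk.CoherenceEstimate(freqs, np.array([0.1, 0.2]), 10,
                                   np.ones(2))
        with pytest.raises(ValueError):
            sk.band_average_sfc(est, BandDefinition("gamma", 35, 80))
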