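"""Psychometric curves, Weibull fits, thresholds, eye screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikefield as sk
from spikefield.behavior import threshold_from_params
from spikefield.synthetic_data import (ObserverModel, SessionConfig,
                                       _block_plan, generate_behavior,
                                       weibull_p)


def make_trials(n_per_level=100, fa=0.0, a=8.0, b=2.0, seed=0,
                orientations=(0, 3, 5, 10, 20), blocks=1):
    """Deterministic-probability trials from a Weibull observer."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for blk in range(1, blocks + 1):
        for d in orientations:
            p_diff = weibull_p(d, fa, a, b)
            for _ in range(n_per_level):
                says_diff = rng.uniform() < p_diff
                rows.append({"trial": i, "block": blk,
                             "delta_theta": float(d), "is_match": d == 0,
                             "response": "hold" if says_diff else "release",
                             "correct": says_diff != (d == 0)})
                i += 1
    return pd.DataFrame(rows)


class TestPsychometricCurve:
    def test_all_correct(self):
        trials = make_trials(50, fa=0.0, a=1e-6, b=2.0)  # saturated observer
        trials["correct"] = True
        curve = sk.psychometric_curve(trials)
        assert np.allclose(
            curve.loc[curve["delta_theta"] > 0, "p_different"], 1.0)
        assert curve.loc[curve["delta_theta"] == 0, "p_different"].iloc[0] == 0

    def test_fa_definition_at_zero(self):
        trials = make_trials(2000, fa=0.10, seed=1)
        curve = sk.psychometric_curve(trials)
        fa = curve.loc[curve["delta_theta"] == 0, "p_different"].iloc[0]
        assert fa == pytest.approx(0.10, abs=0.02)

    def test_curve_tracks_observer_within_binomial_error(self):
        trials = make_trials(192, fa=0.1, a=8.0, b=2.0, seed=2)
        curve = sk.psychometric_curve(trials)
        for _, row in curve.iterrows():
            p = weibull_p(row["delta_theta"], 0.1, 8.0, 2.0)
            se = np.sqrt(p * (1 - p) / row["n_trials"])
            assert abs(row["p_different"] - p) < 4 * se + 1e-9


class TestWeibullFit:
    def test_exact_data_recovered(self):
        d = np.array([0.0, 3.0, 5.0, 10.0, 20.0])
        curve = pd.DataFrame({"delta_theta": d,
                              "p_different": weibull_p(d, 0.1, 8.0, 2.0),
                              "n_trials": 100})
        fit = sk.fit_weibull(curve)
        assert fit.converged
        assert fit.a == pytest.approx(8.0, rel=1e-4)
        assert fit.b == pytest.approx(2.0, rel=1e-4)

    def test_binomial_loss_agrees_on_clean_data(self):
        trials = make_trials(500, fa=0.1, a=8.0, b=1.5, seed=3)
        curve = sk.psychometric_curve(trials)
        f1 = sk.fit_weibull(curve, loss="least_squares")
        f2 = sk.fit_weibull(curve, loss="binomial")
        assert f1.a == pytest.approx(f2.a, rel=0.1)
        assert f1.b == pytest.approx(f2.b, rel=0.2)

    def test_flat_curve_flagged(self):
        d = np.array([0.0, 3.0, 5.0, 10.0, 20.0])
        curve = pd.DataFrame({"delta_theta": d,
                              "p_different": [0.5] * 5, "n_trials": 100})
        fit = sk.fit_weibull(curve)
        assert not fit.converged
        assert np.isnan(fit.threshold75)

    def test_too_few_levels_rejected(self):
        curve = pd.DataFrame({"delta_theta": [0.0, 5.0],
                              "p_different": [0.1, 0.9], "n_trials": 10})
        with pytest.raises(ValueError):
            sk.fit_weibull(curve)


class TestThreshold:
    @pytest.mark.parametrize("fa,a,b,want", [
        (0.0, 5.0, 1.0, 5.0 * np.log(4.0)),          # ≈ 6.931
        (0.25, 10.0, 1.0, 10.0 * np.log(3.0)),       # ≈ 10.986
        (0.1, 8.0, 2.0, 8.0 * np.sqrt(np.log(3.6))),  # ≈ 9.054
    ])
    def test_closed_forms(self, fa, a, b, want):
        assert threshold_from_params(fa, a, b) == pytest.approx(want,
                                                                rel=1e-12)

    def test_fa_above_075_undefined(self):
        with pytest.raises(ValueError):
            threshold_from_params(0.8, 5.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.0, 0.6), st.floats(0.5, 50.0), st.floats(0.3, 5.0))
    def test_threshold_inverts_to_075_exactly(self, fa, a, b):
        thr = threshold_from_params(fa, a, b)
        assert weibull_p(thr, fa, a, b) == pytest.approx(0.75, abs=1e-9)


class TestBlockAndSlidingThresholds:
    def test_decreasing_observer_recovered(self):
        rows = []
        cfg = SessionConfig(seed=4)
        observers = [ObserverModel(fa=0.1, a=15.0, b=1.5),
                     ObserverModel(fa=0.1, a=4.0, b=1.5)]
        i = 0
        for blk, obs in enumerate(observers, 1):
            for rep in range(3):
                for d in _block_plan(cfg, blk * 10 + rep):
                    rows.append(generate_behavior(cfg, obs, i,
                                                  delta_theta=float(d),
                                                  block=blk))
                    i += 1
        res = sk.block_thresholds(pd.DataFrame(rows))
        t = res.sort_values("block")["threshold"].to_numpy()
        assert t[1] < t[0]

    def test_relative_decrease_arithmetic(self):
        t1, t4 = 18.9, 4.5
        assert (t1 - t4) / t1 * 100 == pytest.approx(76.2, abs=0.05)

    def test_sliding_window_count(self):
        trials = make_trials(n_per_level=77, seed=5)  # 385 trials
        trials = trials.sample(frac=1.0, random_state=0,
                               ignore_index=True).iloc[:384]
        curve, _ = sk.sliding_threshold(trials, window=64, step=10)
        assert len(curve) == (384 - 64) // 10 + 1 == 33

    def test_step_change_gives_decreasing_fit(self):
        parts = [make_trials(40, fa=0.1, a=15.0, b=1.5, seed=6),
                 make_trials(40, fa=0.1, a=3.0, b=1.5, seed=7)]
        parts = [p.sample(frac=1.0, random_state=1, ignore_index=True)
                 for p in parts]
        trials = pd.concat(parts, ignore_index=True)
        curve, fit = sk.sliding_threshold(trials)
        assert fit["converged"]
        assert fit["y0"] > fit["y_inf"]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            sk.sliding_threshold(make_trials(2), window=64)


class TestMatchRate:
    def test_all_match_correct(self):
        trials = make_trials(50, fa=0.0, seed=8, blocks=4)
        trials.loc[trials["is_match"], "correct"] = True
        rates, test = sk.match_rate_by_block(trials)
        assert np.allclose(rates["match_accuracy"], 1.0)

    def test_hold_bias_collapses_match_accuracy(self):
        trials = make_trials(50, fa=0.05, seed=9, blocks=4)
        late = (trials["block"] > 1) & trials["is_match"]
        trials.loc[late, "correct"] = False  # strategy: always hold
        rates, test = sk.match_rate_by_block(trials)
        assert rates["match_accuracy"].iloc[0] > 0.8
        assert test["p"] < 1e-6

    def test_honest_observer_no_trend(self):
        trials = make_trials(100, fa=0.1, seed=10, blocks=4)
        _, test = sk.match_rate_by_block(trials)
        assert test["p"] > 0.01


class TestMicrosaccades:
    def _step_trace(self, amp, n=2000, at=1000, over_ms=10):
        x = np.zeros(n)
        x[at + over_ms:] = amp
        x[at:at + over_ms + 1] = np.linspace(0, amp, over_ms + 1)
        return sk.EyeTrace(x, np.zeros(n))

    def test_threshold_displacement_detected(self):
        # 0.1 deg over 10 ms = exactly 10 deg/s -> inclusive threshold
        events, abort = sk.detect_microsaccades(self._step_trace(0.10))
        assert len(events) == 1
        assert events["peak_velocity"].iloc[0] == pytest.approx(10.0,
                                                                rel=0.05)
        assert not abort

    def test_large_saccade_aborts(self):
        events, abort = sk.detect_microsaccades(self._step_trace(0.30))
        assert abort

    def test_smooth_drift_not_detected(self):
        t = np.arange(3000) / 1000.0
        eye = sk.EyeTrace(2.0 * t, np.zeros_like(t))  # 2 deg/s drift
        events, abort = sk.detect_microsaccades(eye)
        assert len(events) == 0 and not abort

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sk.detect_microsaccades(sk.EyeTrace(np.zeros(15), np.zeros(15)))


class TestEyeTrends:
    def test_injected_amplitude_trend_detected(self):
        rng = np.random.default_rng(11)
        events = {b: pd.DataFrame({
            "amplitude": 0.05 * b + 0.002 * rng.standard_normal(40)})
            for b in range(1, 5)}
        rep = sk.eye_trend_check(events)
        amp = rep[rep["measure"] == "amplitude"].iloc[0]
        assert amp["r"] > 0.9 and amp["p"] < 0.05

    def test_stationary_events_no_strong_trend(self):
        rng = np.random.default_rng(12)
        events = {b: pd.DataFrame({
            "amplitude": 0.1 + 0.01 * rng.standard_normal(40)})
            for b in range(1, 5)}
        rep = sk.eye_trend_check(events)
        assert abs(rep[rep["measure"] == "amplitude"]["r"].iloc[0]) < 0.999

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            sk.eye_trend_check({1: pd.DataFrame({"amplitude": [0.1]})})
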