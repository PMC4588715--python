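"""Psychometric analysis and eye-movement screening.

The psychometric curve plots, per rotation Δθ, the proportion of
'different' (bar-hold) reports: at Δθ = 0 this is the false-alarm rate FA,
and for Δθ > 0 it equals the accuracy on non-match trials.  The curve is
fitted with the Weibull form

    P(Δθ) = 1 − (1 − FA)·exp(−(Δθ/a)^b)

with FA fixed to the observed false-alarm rate and (a, b) estimated; the
discrimination threshold is the rotation at which P = 0.75,

    T = a·(ln((1 − FA)/0.25))^(1/b),

so P(T) = 0.75 exactly.  Learning curves use 96-trial blocks or a 64-trial
sliding window with an exponential fit.  Microsaccades are detected from
10 ms vector velocities (≥ 10 deg/s) and a fixation-instability abort rule
(amplitude > 0.25 deg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_data import weibull_p

logger = logging.getLogger(__name__)


@dataclass
class PsychometricFit:
    fa: float
    a: float
    b: float
    threshold75: float
    converged: bool
    residual: float
    n_levels: int

    def p(self, delta_theta):
        return weibull_p(delta_theta, self.fa, self.a, self.b)


@dataclass
class EyeTrace:
    """Eye x/y positions in degrees sampled at ``rate`` Hz."""

    x: np.ndarray
    y: np.ndarray
    rate: float = 1000.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")


def psychometric_curve(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-Δθ proportion of 'different' reports (accuracy for Δθ > 0, FA at 0).

    Missing Δθ = 0 trials leave the FA row absent (flagged in the log).
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    rows = []
    for dtheta, grp in trials.groupby("delta_theta"):
        n = len(grp)
        if dtheta == 0:
            value = 1.0 - grp["correct"].mean()  # error rate = FA
        else:
            value = grp["correct"].mean()
        rows.append({"delta_theta": float(dtheta), "n_trials": n,
                     "p_different": float(value)})
    curve = pd.DataFrame(rows).sort_values("delta_theta", ignore_index=True)
    if 0.0 not in curve["delta_theta"].values:
        logger.warning("psychometric_curve: no zero-rotation trials; "
                       "false-alarm rate unavailable")
    return curve


def fit_weibull(curve: pd.DataFrame, loss: str = "least_squares"
                ) -> PsychometricFit:
    """Fit (a, b) with FA fixed to the observed false-alarm rate.

    ``loss`` is "least_squares" on per-Δθ proportions (default) or
    "binomial" (negative log-likelihood weighted by trial counts).
    Degenerate curves (no usable dynamic range) are flagged unconverged
    and the threshold withheld.
    """
    zero = curve[curve["delta_theta"] == 0.0]
    if len(zero) == 0:
        raise ValueError("curve lacks the zero-rotation (FA) point")
    fa = float(zero["p_different"].iloc[0])
    pts = curve[curve["delta_theta"] > 0]
    if len(pts) < 3:
        raise ValueError("need >= 3 non-zero rotation levels")
    d = pts["delta_theta"].to_numpy()
    y = pts["p_different"].to_numpy()
    w = pts["n_trials"].to_numpy().astype(float)
    x0 = np.array([np.median(d), 1.0])
    bounds = ([1e-3, 1e-2], [1e3, 1e2])

    if loss == "least_squares":
        res = optimize.least_squares(
            lambda p: weibull_p(d, fa, p[0], p[1]) - y, x0, bounds=bounds,
            max_nfev=2000)
        a, b = res.x
        cost = float(np.sqrt(2 * res.cost / len(d)))
        # a flat cost plateau in b can exhaust evaluations at an excellent
        # fit (e.g. saturated accuracies); small residual still counts
        ok = res.success or cost < 0.05
    elif loss == "binomial":
        eps = 1e-9
        def nll(p):
            q = np.clip(weibull_p(d, fa, p[0], p[1]), eps, 1 - eps)
            return -np.sum(w * (y * np.log(q) + (1 - y) * np.log(1 - q)))
        res = optimize.minimize(nll, x0, bounds=list(zip(*bounds)),
                                method="L-BFGS-B")
        a, b = res.x
        cost = float(res.fun)
        ok = res.success
    else:
        raise ValueError(f"unknown loss {loss!r}")

    fitted = weibull_p(d, fa, a, b)
    informative = float(np.ptp(fitted)) > 0.05 and y.max() > fa + 0.05
    at_bound = bool(np.any(np.isclose([a, b], bounds[0]))
                    or np.any(np.isclose([a, b], bounds[1])))
    converged = bool(ok and informative and not at_bound)
    thr = np.nan
    if converged and fa < 0.75:
        thr = threshold_from_params(fa, a, b)
    return PsychometricFit(fa, float(a), float(b), float(thr), converged,
                           cost, len(d))


def threshold_from_params(fa: float, a: float, b: float) -> float:
    if fa >= 0.75:
        raise ValueError("threshold undefined for FA >= 0.75")
    return float(a * np.log((1.0 - fa) / 0.25) ** (1.0 / b))


def threshold_from_fit(fit: PsychometricFit) -> float:
    """Closed-form 75% threshold: a·(ln((1−FA)/0.25))^(1/b)."""
    return threshold_from_params(fit.fa, fit.a, fit.b)


def block_thresholds(trials: pd.DataFrame, loss: str = "least_squares"
                     ) -> pd.DataFrame:
    """One Weibull fit and threshold per block (blocks labeled in trials)."""
    if "block" not in trials:
        raise ValueError("trials need a 'block' column")
    rows = []
    for block, grp in trials.groupby("block"):
        try:
            fit = fit_weibull(psychometric_curve(grp), loss=loss)
            rows.append({"block": block, "fa": fit.fa, "a": fit.a,
                         "b": fit.b, "threshold": fit.threshold75,
                         "converged": fit.converged})
        except ValueError as err:
            logger.warning("block %s fit failed: %s", block, err)
            rows.append({"block": block, "fa": np.nan, "a": np.nan,
                         "b": np.nan, "threshold": np.nan,
                         "converged": False})
    return pd.DataFrame(rows)


def _exp_decay(t, y_inf, y0, tau):
    return y_inf + (y0 - y_inf) * np.exp(-t / tau)


def sliding_threshold(trials: pd.DataFrame, window: int = 64, step: int = 10
                      ) -> tuple[pd.DataFrame, dict]:
    """Threshold vs trial index in a sliding window, plus exponential fit.

    Returns (curve with one row per window center, exponential-decay
    parameters y(t) = y∞ + (y0 − y∞)·e^(−t/τ) fitted to the valid points).
    Windows whose Weibull fit fails are masked (NaN threshold).
    """
    n = len(trials)
    if n < window:
        raise ValueError(f"need >= {window} trials")
    starts = np.arange(0, n - window + 1, step)
    rows = []
    for s in starts:
        sub = trials.iloc[s:s + window]
        thr = np.nan
        try:
            fit = fit_weibull(psychometric_curve(sub))
            if fit.converged:
                thr = fit.threshold75
        except ValueError:
            pass
        rows.append({"start": int(s), "center": s + window / 2.0,
                     "threshold": thr})
    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["threshold"])
    fitp = {"y_inf": np.nan, "y0": np.nan, "tau": np.nan, "converged": False}
    if len(valid) >= 4 and valid["threshold"].std() > 0:
        t = valid["center"].to_numpy()
        y = valid["threshold"].to_numpy()
        try:
            popt, _ = optimize.curve_fit(
                _exp_decay, t - t[0], y,
                p0=[y[-1], y[0], max((t[-1] - t[0]) / 3.0, 1.0)],
                bounds=([0, 0, 1e-2], [np.inf, np.inf, 1e6]), maxfev=20000)
            fitp = {"y_inf": float(popt[0]), "y0": float(popt[1]),
                    "tau": float(popt[2]), "converged": True}
        except RuntimeError:
            pass
    return curve, fitp


def match_rate_by_block(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Accuracy on match (bar-release) trials per block + equality test.

    A hold-forever strategy would collapse match accuracy after block 1;
    the across-block test is a chi-square on correct/incorrect counts.
    """
    match = trials[trials["is_match"]]
    if match.empty or match.groupby("block").size().min() < 1:
        raise ValueError("need >= 1 match trial per block")
    tab = match.groupby("block")["correct"].agg(["sum", "size"])
    tab["match_accuracy"] = tab["sum"] / tab["size"]
    table = np.c_[tab["sum"], tab["size"] - tab["sum"]]
    if np.all(table[:, 0] == 0) or np.all(table[:, 1] == 0):
        test = {"chi2": 0.0, "p": 1.0, "degenerate": True}
    else:
        chi2, p, _, _ = stats.chi2_contingency(table)
        test = {"chi2": float(chi2), "p": float(p), "degenerate": False}
    out = tab.reset_index()[["block", "match_accuracy", "size"]]
    return out, test


def detect_microsaccades(eye: EyeTrace, velocity_threshold: float = 10.0,
                         abort_amplitude: float = 0.25,
                         interval_s: float = 0.010
                         ) -> tuple[pd.DataFrame, bool]:
    """Velocity-threshold microsaccade detector with an abort rule.

    Vector velocity is evaluated every 10 ms from the displacement across
    consecutive 10 ms interval endpoints; intervals at or above
    10 deg/s (0.1 deg per 10 ms sits exactly at threshold and counts)
    form events, merged when contiguous.  The abort flag is set iff any
    event's net amplitude exceeds 0.25 deg.
    """
    stride = int(round(interval_s * eye.rate))
    if eye.x.size < 2 * stride + 1:
        raise ValueError("trace shorter than two velocity intervals")
    xs = eye.x[::stride]
    ys = eye.y[::stride]
    disp = np.hypot(np.diff(xs), np.diff(ys))
    vel = disp / interval_s
    above = vel >= velocity_threshold
    events = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            amp = float(np.hypot(xs[j + 1] - xs[i], ys[j + 1] - ys[i]))
            events.append({"t_start": i * interval_s,
                           "duration": (j - i + 1) * interval_s,
                           "amplitude": amp,
                           "peak_velocity": float(vel[i:j + 1].max())})
            i = j + 1
        else:
            i += 1
    ev = pd.DataFrame(events,
                      columns=["t_start", "duration", "amplitude",
                               "peak_velocity"])
    abort = bool((ev["amplitude"] > abort_amplitude).any()) if len(ev) else False
    return ev, abort


def eye_trend_check(events_by_block: dict[int, pd.DataFrame],
                    block_duration_s: float | None = None) -> pd.DataFrame:
    """Correlation of per-block microsaccade amplitude and rate with block.

    Returns one row per measure (amplitude, frequency) with Pearson r and p.
    """
    blocks = sorted(b for b, ev in events_by_block.items() if len(ev) > 0)
    if len(blocks) < 2:
        raise ValueError("need >= 2 blocks with events")
    amp = [events_by_block[b]["amplitude"].mean() for b in blocks]
    freq = [len(events_by_block[b]) / (block_duration_s or 1.0)
            for b in blocks]
    rows = []
    for name, vals in (("amplitude", amp), ("frequency", freq)):
        if np.std(vals) == 0:
            rows.append({"measure": name, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(blocks, vals)
        rows.append({"measure": name, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
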