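"""Comparison models: the lagged-linear activity fit and a circadian sine.

Two reference models against which the state-space model is benchmarked:

* The Weinert–Waterhouse (WW) model — a static ordinary-least-squares fit of
  CBT on a rolling sum of the preceding ``tau`` minutes of activity,
  ``y_hat[t] = m * S[t] + b``.  The lag window ``tau`` is selected per animal
  as the window length maximising Pearson correlation between the rolling sum
  and CBT.  The rolling window is *backward* (samples ``t-tau+1 .. t``): a
  "lag" must be causal, so the forward summation sometimes written for this
  model is interpreted as looking back in time.
* A circadian sinusoid at a fixed (default 24 h) period, fit by the standard
  linearised sine+cosine regression, reported as mesor/amplitude/acrophase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_preprocess import MINUTES_PER_DAY, MinuteSeries

__all__ = [
    "WWParams", "CircadianParams",
    "rolling_sum", "select_tau", "ww_fit", "ww_predict",
    "circadian_fit", "circadian_predict",
]


@dataclass(frozen=True)
class WWParams:
    m: float  # °C per summed count
    b: float  # °C
    tau: int  # minutes

    def __post_init__(self) -> None:
        if self.tau < 1 or self.tau != int(self.tau):
            raise ValueError("tau must be a positive integer number of minutes")


@dataclass(frozen=True)
class CircadianParams:
    mesor: float  # °C
    amplitude: float  # °C, nonnegative
    phase: float  # minutes, acrophase offset in [0, period)
    period: float = float(MINUTES_PER_DAY)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, MinuteSeries) else np.asarray(x, dtype=float)


def rolling_sum(la, tau: int) -> np.ndarray:
    """Backward rolling sum S[t] = sum of la[t-tau+1 .. t].

    The first ``tau - 1`` entries sum the shorter available history, so the
    output has the same length as the input.
    """
    v = _values(la)
    c = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(1, v.size + 1)
    return c[idx] - c[np.maximum(idx - tau, 0)]


def select_tau(cbt, la, tau_range=(1, 120)) -> int:
    """Lag-window length maximising |corr(rolling-sum LA, CBT)|.

    Ties break toward the smaller window.  A warning is raised when even the
    best correlation is weak (|r| < 0.1), which signals that the activity
    signal carries little information about temperature.
    """
    c = _values(cbt)
    a = _values(la)
    if c.size != a.size:
        raise ValueError("cbt and la lengths differ")
    if np.std(c) == 0 or np.std(a) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    lo, hi = int(tau_range[0]), int(tau_range[1])
    if lo < 1:
        raise ValueError("tau_range must start at >= 1")
    best_tau, best_r = lo, -np.inf
    for tau in range(lo, hi + 1):
        s = rolling_sum(a, tau)
        sd = np.std(s)
        if sd == 0:
            continue
        r = abs(float(np.corrcoef(s, c)[0, 1]))
        if r > best_r + 1e-15:
            best_tau, best_r = tau, r
    if best_r < 0.1:
        warnings.warn(
            f"best LA-CBT correlation is weak (|r|={best_r:.3f}); "
            "the selected lag is unlikely to be meaningful", stacklevel=2,
        )
    return best_tau


def ww_fit(cbt, la, tau: int) -> WWParams:
    """OLS of CBT on the tau-minute rolling activity sum."""
    c = _values(cbt)
    a = _values(la)
    if c.size <= tau:
        raise ValueError("series must be longer than tau")
    s = rolling_sum(a, tau)
    if np.std(s) == 0:
        raise ValueError("rolling activity sum has zero variance; slope undefined")
    res = stats.linregress(s, c)
    return WWParams(m=float(res.slope), b=float(res.intercept), tau=int(tau))


def ww_predict(params: WWParams, la) -> np.ndarray:
    return params.m * rolling_sum(la, params.tau) + params.b


def circadian_fit(cbt, period: float = float(MINUTES_PER_DAY)) -> CircadianParams:
    """Least-squares sinusoid at a fixed period.

    Fits ``mesor + A*cos(w t) + B*sin(w t)`` by linear regression and converts
    to mesor/amplitude/acrophase; requires at least two full periods so that
    amplitude and mesor are well separated.
    """
    c = _values(cbt)
    if c.size < 2 * period:
        raise ValueError("need at least two full periods of data")
    t = np.arange(c.size)
    w = 2 * np.pi / period
    X = np.column_stack([np.ones(c.size), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, c, rcond=None)
    mesor, ca, sa = beta
    amplitude = float(np.hypot(ca, sa))
    phase = float(np.arctan2(sa, ca) / w % period)
    return CircadianParams(float(mesor), amplitude, phase, float(period))


def circadian_predict(params: CircadianParams, n: int) -> np.ndarray:
    t = np.arange(n)
    w = 2 * np.pi / params.period
    return params.mesor + params.amplitude * np.cos(w * (t - params.phase))
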