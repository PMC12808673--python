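"""Sequential-residual diagnostics: median days, window sums, Durbin–Watson.

The sequential residual ``r[t] = T[t] - y_hat[t]`` is what remains of the
temperature signal after the modelled activity heating and innate cooling
have been differenced out.  If the model captured all deterministic
structure, the residuals are white; leftover time-of-day structure (e.g. an
endogenous circadian rhythm, or an estrous-related morning elevation) shows
up as

* a non-flat lights-off-aligned *median day* — the pointwise median residual
  at each of the 1440 minutes of the day,
* non-zero *window sums* of the median day over stated post-lights-off /
  post-lights-on windows, and
* first-order serial correlation, summarised by the Durbin–Watson statistic
  (≈2 for white residuals, →0 under positive serial correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .io_preprocess import MINUTES_PER_DAY, DaySlice, MinuteSeries

__all__ = [
    "MedianDayResiduals", "sequential_residuals", "median_day",
    "group_median_day", "window_sum", "durbin_watson",
]


@dataclass
class MedianDayResiduals:
    """Per-mouse and group-combined lights-off-aligned median residual days."""

    group: str  # "M", "NE" or "E"
    per_mouse: dict[str, np.ndarray]  # mouse_id -> 1440-vector (°C)
    group_median: np.ndarray  # pointwise median across mice

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "minute_from_lights_off": np.arange(MINUTES_PER_DAY),
            "group": self.group,
            "value": self.group_median,
        })


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, MinuteSeries) else np.asarray(x, dtype=float)


def sequential_residuals(observed, predicted) -> np.ndarray:
    """r[t] = T[t] - y_hat[t]; positive where the model underestimated."""
    obs, pred = _values(observed), _values(predicted)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    return obs - pred


def median_day(residuals, day_slices: list[DaySlice], day_subset=None) -> np.ndarray:
    """Pointwise median residual over selected complete aligned days.

    ``residuals`` must be indexed like the record the slices were cut from.
    ``day_subset`` restricts to the given day indices (e.g. a female's
    non-estrous days); None uses every complete day.
    """
    r = _values(residuals)
    days = [s for s in day_slices if s.complete
            and (day_subset is None or s.day_index in day_subset)]
    if not days:
        raise ValueError("no complete days in the requested subset")
    stack = np.stack([r[s.start:s.stop] for s in days])
    return np.median(stack, axis=0)


def group_median_day(group: str, per_mouse: dict[str, np.ndarray]) -> MedianDayResiduals:
    """Combine per-mouse median days into a group profile.

    Per-mouse median days are computed first; the group curve is then the
    pointwise across-mouse median, so no animal dominates through extra days.
    """
    if not per_mouse:
        raise ValueError("empty group")
    mats = np.stack(list(per_mouse.values()))
    return MedianDayResiduals(group, dict(per_mouse), np.median(mats, axis=0))


def window_sum(day_vector, window: tuple[float, float], anchor: str = "lights_off") -> float:
    """Sum of a 1440-minute day vector over [start, end) hours past an anchor.

    The vector is lights-off-aligned, so ``anchor="lights_on"`` offsets by
    12 h (minute 720).  Units: °C·min.
    """
    v = _values(day_vector)
    if v.size != MINUTES_PER_DAY:
        raise ValueError("day vector must have 1440 samples")
    start_h, end_h = window
    if not (0 <= start_h < end_h <= 24):
        raise ValueError("window must satisfy 0 <= start < end <= 24 hours")
    offset = 0 if anchor == "lights_off" else MINUTES_PER_DAY // 2
    if anchor not in ("lights_off", "lights_on"):
        raise ValueError("anchor must be 'lights_off' or 'lights_on'")
    i0 = offset + int(round(start_h * 60))
    i1 = offset + int(round(end_h * 60))
    idx = np.arange(i0, i1) % MINUTES_PER_DAY
    return float(v[idx].sum())


def durbin_watson(residuals) -> float:
    """Durbin–Watson statistic sum(diff(r)^2)/sum(r^2), in [0, 4].

    ≈2 for serially uncorrelated residuals; <2 indicates positive first-order
    serial correlation (deterministic structure the model missed).
    """
    r = _values(residuals)
    if r.size < 2:
        raise ValueError("need at least 2 residuals")
    if np.sum(r**2) == 0:
        raise ValueError("all-zero residuals: DW undefined")
    return float(_sm_dw(r))
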