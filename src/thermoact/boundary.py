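"""Boundary-condition characterisation of the (CBT, LA) state space.

The minute-to-minute temperature change ``dT[t] = T[t+1] - T[t]`` is paired
with the *current* state ``(T[t], A[t])``.  If the dynamics are linear in
each state variable, then restricting to a boundary where one variable's
effect is negligible isolates the other's linear effect:

* at ``LA = 0`` (no activity), ``dT ≈ a2*T + C`` with ``C = -a2*T_min`` —
  OLS of dT on T over that subset estimates the cooling coefficient and the
  steady-state temperature;
* at low CBT (below ~35.25 °C, near the population steady state, where the
  cooling term is negligible), ``dT ≈ a1*LA + C`` — OLS of dT on LA
  estimates the activity heating coefficient.

A degree-2 polynomial refit on the same subsets quantifies whether any
curvature is present (on linear dynamics it is not), and a 2-D binned mean-dT
map shows where in the state space heating and cooling balance (cells with
``|mean dT| < 0.0025`` °C/min are flagged negligible — the empirical
nullcline ``a1*A = -a2*(T - T_min)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_preprocess import MinuteSeries

__all__ = [
    "BoundaryFit", "DeltaTGrid", "delta_t", "pool_states",
    "boundary_ols_la_zero", "boundary_ols_low_cbt", "boundary_poly2",
    "delta_t_grid", "NEGLIGIBLE_DT",
]

NEGLIGIBLE_DT = 0.0025  # °C/min


@dataclass
class BoundaryFit:
    variable: str  # "CBT" or "LA"
    slope: float
    intercept: float
    p_values: tuple[float, float]  # (intercept, slope)
    ci95: tuple[tuple[float, float], tuple[float, float]]  # (intercept, slope)
    n: int
    degree2_coeffs: tuple[float, float, float] | None = None

    @property
    def equilibrium(self) -> float:
        """Implied steady state -intercept/slope (meaningful for the CBT fit)."""
        return -self.intercept / self.slope


@dataclass
class DeltaTGrid:
    cbt_bin_edges: np.ndarray
    la_bin_edges: np.ndarray
    mean_dt: np.ndarray  # NaN where empty
    counts: np.ndarray
    negligible_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per populated cell."""
        rows = []
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                if self.counts[i, j] > 0:
                    rows.append({
                        "cbt_bin": 0.5 * (self.cbt_bin_edges[i] + self.cbt_bin_edges[i + 1]),
                        "la_bin": 0.5 * (self.la_bin_edges[j] + self.la_bin_edges[j + 1]),
                        "mean_dT": self.mean_dt[i, j],
                        "n": int(self.counts[i, j]),
                        "negligible": bool(self.negligible_mask[i, j]),
                    })
        return pd.DataFrame(rows)


def delta_t(cbt) -> np.ndarray:
    """Forward difference dT[t] = T[t+1] - T[t]; length N-1."""
    v = cbt.values if isinstance(cbt, MinuteSeries) else np.asarray(cbt, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples for a difference")
    return np.diff(v)


def pool_states(records_or_pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (dT, T, A) triples across animals.

    Accepts either MouseRecord objects or plain ``(cbt, la)`` pairs.  Within
    each animal, dT[t] is paired with the state (T[t], A[t]); the last sample
    has no forward difference and is dropped.
    """
    dts, ts, as_ = [], [], []
    for item in records_or_pairs:
        if hasattr(item, "cbt"):
            c, a = item.cbt.values, item.la.values
        else:
            c, a = (np.asarray(x, dtype=float) for x in item)
        dts.append(np.diff(c))
        ts.append(c[:-1])
        as_.append(a[:-1])
    return np.concatenate(dts), np.concatenate(ts), np.concatenate(as_)


def _ols(y: np.ndarray, x: np.ndarray, variable: str) -> BoundaryFit:
    if y.size < 3:
        raise ValueError(f"too few boundary samples ({y.size}) for the {variable} fit")
    if np.std(x) == 0:
        raise ValueError("zero-variance regressor at the boundary")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return BoundaryFit(
        variable=variable,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_values=(float(model.pvalues[0]), float(model.pvalues[1])),
        ci95=((float(ci[0][0]), float(ci[0][1])), (float(ci[1][0]), float(ci[1][1]))),
        n=int(y.size),
    )


def boundary_ols_la_zero(pooled) -> BoundaryFit:
    """OLS of dT on CBT over the LA = 0 subset.

    On linear dynamics the slope estimates the cooling coefficient a2 and the
    intercept estimates -a2*T_min.
    """
    dt, t, a = pooled
    sel = a == 0
    return _ols(dt[sel], t[sel], "CBT")


def boundary_ols_low_cbt(pooled, threshold: float = 35.25, inclusive: bool = True) -> BoundaryFit:
    """OLS of dT on LA over the low-CBT subset (default CBT <= 35.25 °C).

    On linear dynamics the slope estimates the heating coefficient a1.  The
    comparison operator is configurable (``inclusive=False`` for strict <).
    """
    dt, t, a = pooled
    sel = t <= threshold if inclusive else t < threshold
    return _ols(dt[sel], a[sel], "LA")


def boundary_poly2(pooled, which: str = "la_zero", threshold: float = 35.25,
                   inclusive: bool = True) -> dict:
    """Quadratic refit of a boundary subset, with the linear fit's RMSE delta.

    Returns the degree-2 coefficients (quadratic, linear, intercept) plus the
    in-sample RMSE of both fits: on genuinely linear dynamics the quadratic
    coefficient is ~0 and ``rmse_linear - rmse_quadratic`` is ~0.
    """
    dt, t, a = pooled
    if which == "la_zero":
        sel = a == 0
        x, y = t[sel], dt[sel]
    elif which == "low_cbt":
        sel = t <= threshold if inclusive else t < threshold
        x, y = a[sel], dt[sel]
    else:
        raise ValueError("which must be 'la_zero' or 'low_cbt'")
    if y.size < 4:
        raise ValueError("too few boundary samples for a quadratic fit")
    lin = np.polyfit(x, y, 1)
    quad = np.polyfit(x, y, 2)
    rmse_lin = float(np.sqrt(np.mean((y - np.polyval(lin, x)) ** 2)))
    rmse_quad = float(np.sqrt(np.mean((y - np.polyval(quad, x)) ** 2)))
    return {
        "degree2_coeffs": tuple(float(c) for c in quad),
        "rmse_linear": rmse_lin,
        "rmse_quadratic": rmse_quad,
        "delta_rmse": rmse_lin - rmse_quad,
        "n": int(y.size),
    }


def delta_t_grid(pooled, cbt_bins=None, la_bins=None,
                 negligible: float = NEGLIGIBLE_DT) -> DeltaTGrid:
    """Binned 2-D map of mean dT over the (CBT, LA) state space.

    Empty cells stay NaN (undefined, not zero).  Populated cells with
    ``|mean dT| < negligible`` are flagged: together they trace the nullcline
    where activity heating balances innate cooling.
    """
    dt, t, a = pooled
    if dt.size == 0:
        raise ValueError("empty pooled data")
    if cbt_bins is None:
        lo = np.floor(t.min() / 0.25) * 0.25
        hi = np.ceil(t.max() / 0.25) * 0.25
        cbt_bins = np.arange(lo, hi + 0.25, 0.25)  # 0.25 °C cells
    if la_bins is None:
        la_bins = np.arange(0.0, np.ceil(a.max()) + 2.0, 2.0)
    cbt_bins = np.asarray(cbt_bins, dtype=float)
    la_bins = np.asarray(la_bins, dtype=float)
    counts, _, _ = np.histogram2d(t, a, bins=[cbt_bins, la_bins])
    sums, _, _ = np.histogram2d(t, a, bins=[cbt_bins, la_bins], weights=dt)
    with np.errstate(invalid="ignore"):
        mean_dt = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mask = (counts > 0) & (np.abs(mean_dt) < negligible)
    return DeltaTGrid(cbt_bins, la_bins, mean_dt, counts.astype(int), mask)
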