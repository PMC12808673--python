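"""Welch periodograms of residuals and the shuffle-based white-noise null.

Residual rhythm detection: the Welch power spectral density of each animal's
residual series is computed over 48 h (2880-sample) windows with 24 h
(1440-sample) overlap, each window linearly detrended.  The null hypothesis —
the residuals are Gaussian white noise — is represented empirically by
randomly permuting the pooled per-group residuals many times (default 1000)
and taking the per-frequency 95th percentile of the resulting periodograms.
Group-mean observed power exceeding that envelope within a frequency band
(circadian: 20–28 h periods; ultradian: 1–12 h) rejects the null for that
band.

No taper is applied beyond the per-window linear detrend (``window="boxcar"``
by default); a taper can be requested through the ``window`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io_preprocess import MinuteSeries

__all__ = [
    "PeriodogramWithNull", "DEFAULT_BANDS",
    "welch", "shuffle_null", "band_exceedance",
]

#: Band definitions as (min period, max period) in minutes.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "circadian": (20 * 60.0, 28 * 60.0),
    "ultradian": (1 * 60.0, 12 * 60.0),
}


@dataclass
class PeriodogramWithNull:
    frequencies: np.ndarray  # cycles/min
    power: dict[str, np.ndarray]  # mouse_id -> PSD
    mean_power: np.ndarray
    sd_power: np.ndarray
    null_p95: np.ndarray
    n_shuffles: int

    def to_frame(self, group: str = "") -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            period = np.where(self.frequencies > 0, 1.0 / self.frequencies, np.inf)
        return pd.DataFrame({
            "frequency_cpm": self.frequencies,
            "period_min": period,
            "group": group,
            "mean_power": self.mean_power,
            "sd_power": self.sd_power,
            "null_p95": self.null_p95,
        })


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, MinuteSeries) else np.asarray(x, dtype=float)


def welch(series, window: int = 2880, overlap: int = 1440,
          taper: str = "boxcar") -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with per-window linear detrend; sampling rate 1/min.

    Returns (frequencies in cycles/min, power spectral density).
    """
    v = _values(series)
    if v.size < window:
        raise ValueError(f"series length {v.size} shorter than one {window}-sample window")
    freqs, power = signal.welch(
        v, fs=1.0, window=taper, nperseg=window, noverlap=overlap,
        detrend="linear", scaling="density",
    )
    return freqs, power


def shuffle_null(pooled_residuals, n_shuffles: int = 1000, seed: int = 0, *,
                 length: int | None = None, window: int = 2880, overlap: int = 1440,
                 taper: str = "boxcar", percentile: float = 95.0) -> np.ndarray:
    """Per-frequency percentile envelope of permuted-residual periodograms.

    Each shuffle permutes the pooled per-group residual samples (destroying
    any temporal structure while keeping the marginal distribution), takes
    the first ``length`` samples (default: the pooled length) and computes
    the same Welch periodogram as the observed data.  The default 95th
    percentile over 1000 shuffles is the white-noise rejection boundary.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    pooled = _values(pooled_residuals)
    length = pooled.size if length is None else int(length)
    if length < window:
        raise ValueError("null series length shorter than one window")
    rng = np.random.default_rng(seed)
    spectra = np.empty((n_shuffles, window // 2 + 1))
    for i in range(n_shuffles):
        perm = rng.permutation(pooled)[:length]
        _, spectra[i] = welch(perm, window=window, overlap=overlap, taper=taper)
    return np.percentile(spectra, percentile, axis=0)


def group_periodogram(residuals_by_mouse: dict[str, np.ndarray],
                      n_shuffles: int = 1000, seed: int = 0,
                      window: int = 2880, overlap: int = 1440,
                      taper: str = "boxcar") -> PeriodogramWithNull:
    """Per-mouse Welch periodograms + group mean/SD + pooled shuffle null.

    The null is built from the pooled per-group residual vector; its Welch
    computation uses a null series as long as one mouse's series so the
    window count matches the observed per-mouse periodograms.
    """
    freqs = None
    power: dict[str, np.ndarray] = {}
    lengths = []
    for mouse_id, r in residuals_by_mouse.items():
        f, p = welch(r, window=window, overlap=overlap, taper=taper)
        freqs = f if freqs is None else freqs
        power[mouse_id] = p
        lengths.append(_values(r).size)
    pooled = np.concatenate([_values(r) for r in residuals_by_mouse.values()])
    null = shuffle_null(pooled, n_shuffles=n_shuffles, seed=seed,
                        length=min(lengths), window=window, overlap=overlap,
                        taper=taper)
    mat = np.stack(list(power.values()))
    return PeriodogramWithNull(
        frequencies=freqs, power=power,
        mean_power=mat.mean(axis=0), sd_power=mat.std(axis=0, ddof=0),
        null_p95=null, n_shuffles=n_shuffles,
    )


def band_exceedance(result: PeriodogramWithNull,
                    bands: dict[str, tuple[float, float]] | None = None) -> dict[str, bool]:
    """Whether group-mean power exceeds the null envelope anywhere in a band.

    Bands are (min period, max period) in minutes; zero frequency is never
    part of a band.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    out: dict[str, bool] = {}
    for name, (pmin, pmax) in bands.items():
        if pmin <= 0 or pmax <= pmin:
            raise ValueError(f"band {name!r} has an invalid period interval")
        f = result.frequencies
        sel = (f > 0) & (f >= 1.0 / pmax) & (f <= 1.0 / pmin)
        if not sel.any():
            raise ValueError(f"band {name!r} contains no frequency-grid points")
        out[name] = bool(np.any(result.mean_power[sel] > result.null_p95[sel]))
    return out
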