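"""End-to-end orchestration: cohort → per-mouse fits → residual diagnostics
→ spectra → group statistics.

This module glues the analysis stages together for the CLI and the
reproduction script.  Fits are organised by *day group*:

* ``M`` — each male mouse, all complete days, one model;
* ``NE`` / ``E`` — each female mouse, separate models on her labeled
  non-estrous and estrous day subsets.  Each maximal run of consecutive
  selected days forms one forecast segment started from its own first
  observed temperature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import baselines, residuals as res_mod, spectral, stats as stats_mod
from .io_preprocess import MINUTES_PER_DAY, DaySlice, MouseRecord, complete_days
from .state_space import FitConfig, FitResult, SSParams, fit, rmse

__all__ = [
    "segments_for_days", "fit_record_group", "fit_cohort", "CohortFits",
    "baseline_rmses", "group_residual_series", "group_median_days",
    "spectral_report", "stats_report",
]


@dataclass
class GroupFit:
    mouse_id: str
    sex: str
    group: str  # "M", "NE" or "E"
    result: FitResult
    day_indices: tuple[int, ...]

    def to_json(self, lambda_: float) -> dict:
        p = self.result.params
        return {
            "mouse_id": self.mouse_id, "group": self.group,
            "a1": p.a1, "a2": p.a2, "T_min": p.t_min,
            "rmse": self.result.rmse, "converged": self.result.converged,
            "lambda": lambda_,
        }


@dataclass
class CohortFits:
    fits: list[GroupFit]
    config: FitConfig

    def by_group(self, group: str) -> dict[str, GroupFit]:
        return {f.mouse_id: f for f in self.fits if f.group == group}

    def params_by_group(self) -> dict[str, dict[str, SSParams]]:
        return {g: {m: f.result.params for m, f in self.by_group(g).items()}
                for g in ("M", "NE", "E")}


def _consecutive_runs(days: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for d in sorted(days):
        if runs and d == runs[-1][-1] + 1:
            runs[-1].append(d)
        else:
            runs.append([d])
    return runs


def segments_for_days(record: MouseRecord, day_indices) -> list[tuple[np.ndarray, np.ndarray]]:
    """(cbt, la) segments for maximal runs of consecutive selected days."""
    slices = {s.day_index: s for s in complete_days(record)}
    missing = [d for d in day_indices if d not in slices]
    if missing:
        raise ValueError(f"days {missing} are not complete days of {record.mouse_id}")
    segments = []
    for run in _consecutive_runs(list(day_indices)):
        start, stop = slices[run[0]].start, slices[run[-1]].stop
        segments.append((record.cbt.values[start:stop], record.la.values[start:stop]))
    return segments


def fit_record_group(record: MouseRecord, group: str,
                     config: FitConfig | None = None) -> GroupFit:
    n_days = len(complete_days(record))
    if group in ("M", "F"):  # full record (all complete days)
        days = tuple(range(n_days))
    elif group == "NE":
        days = tuple(sorted(record.nonestrous_days(n_days)))
    elif group == "E":
        days = tuple(sorted(d for d in record.estrous_days if d < n_days))
    else:
        raise ValueError(f"unknown group {group!r}")
    if not days:
        raise ValueError(f"no days in group {group} for mouse {record.mouse_id}")
    result = fit(segments_for_days(record, days), config)
    return GroupFit(record.mouse_id, record.sex, group, result, days)


def fit_cohort(records: list[MouseRecord], config: FitConfig | None = None) -> CohortFits:
    """State-space fits per mouse.

    Males get one full-record fit (group M).  Females get a full-record fit
    (group F, used for whole-animal model comparison against the baselines)
    plus separate fits on their non-estrous (NE) and estrous (E) day subsets.
    """
    config = config or FitConfig()
    fits = []
    for rec in records:
        if rec.sex == "M":
            fits.append(fit_record_group(rec, "M", config))
        else:
            fits.append(fit_record_group(rec, "F", config))
            fits.append(fit_record_group(rec, "NE", config))
            fits.append(fit_record_group(rec, "E", config))
    return CohortFits(fits, config)


def baseline_rmses(records: list[MouseRecord], tau_range=(1, 120)):
    """Per-mouse RMSE of the WW and circadian baselines on the full record.

    Returns (ww_rmse, circ_rmse, tau) dicts keyed by mouse_id.
    """
    ww_rmse, circ_rmse, taus = {}, {}, {}
    for rec in records:
        tau = baselines.select_tau(rec.cbt, rec.la, tau_range)
        ww = baselines.ww_fit(rec.cbt, rec.la, tau)
        ww_rmse[rec.mouse_id] = rmse(rec.cbt.values, baselines.ww_predict(ww, rec.la))
        circ = baselines.circadian_fit(rec.cbt)
        circ_rmse[rec.mouse_id] = rmse(
            rec.cbt.values, baselines.circadian_predict(circ, rec.n_minutes))
        taus[rec.mouse_id] = tau
    return ww_rmse, circ_rmse, taus


def _record_by_id(records) -> dict[str, MouseRecord]:
    return {r.mouse_id: r for r in records}


def group_residual_series(records, fits: CohortFits) -> dict[str, dict[str, np.ndarray]]:
    """Per-group, per-mouse concatenated residual series (model day subsets)."""
    out: dict[str, dict[str, np.ndarray]] = {"M": {}, "NE": {}, "E": {}}
    for f in fits.fits:
        if f.group in out:
            out[f.group][f.mouse_id] = f.result.residuals.values
    return out


def group_median_days(records, fits: CohortFits) -> dict[str, res_mod.MedianDayResiduals]:
    """Lights-off-aligned median residual days per group.

    Residuals are taken from each group's own fit; a mouse's median day is
    computed over that group's days, then the group curve is the pointwise
    across-mouse median.
    """
    recs = _record_by_id(records)
    out = {}
    for group in ("M", "NE", "E"):
        per_mouse = {}
        for mouse_id, gf in fits.by_group(group).items():
            rec = recs[mouse_id]
            # residuals are concatenated over the group's days in day order,
            # so reshape directly into aligned days
            r = gf.result.residuals.values
            days = r.reshape(-1, MINUTES_PER_DAY)
            per_mouse[mouse_id] = np.median(days, axis=0)
        if per_mouse:
            out[group] = res_mod.group_median_day(group, per_mouse)
    return out


def spectral_report(records, fits: CohortFits, n_shuffles: int = 1000,
                    seed: int = 0, window: int = 2880, overlap: int = 1440):
    """Welch periodograms + shuffle nulls + band verdicts per group."""
    series = group_residual_series(records, fits)
    report = {}
    for group, by_mouse in series.items():
        usable = {m: r for m, r in by_mouse.items() if r.size >= window}
        if not usable:
            continue
        pg = spectral.group_periodogram(usable, n_shuffles=n_shuffles,
                                        seed=seed, window=window, overlap=overlap)
        report[group] = {
            "periodogram": pg,
            "exceedance": spectral.band_exceedance(pg),
        }
    return report


def stats_report(records, fits: CohortFits, ww_rmse: dict, circ_rmse: dict) -> dict:
    """Model-comparison and parameter-comparison statistics.

    Per sex: Kruskal–Wallis across circadian/WW/state-space RMSEs with Dunn
    + BH post-hocs, and paired Cohen's d of WW-vs-state-space RMSE.  Across
    day groups: Mann–Whitney / Wilcoxon comparisons of each parameter, plus
    quadratic-surface sex separability (female NE fits).
    """
    recs = _record_by_id(records)
    report: dict = {"models": {}, "params": {}, "separability": None}
    # one full-record fit per animal for whole-animal model comparison
    ss_rmse = {f.mouse_id: f.result.rmse for f in fits.fits
               if f.group in ("M", "F")}
    for sex in ("M", "F"):
        ids = [m for m, r in recs.items() if r.sex == sex]
        by_model = {
            "circadian": np.array([circ_rmse[m] for m in ids]),
            "ww": np.array([ww_rmse[m] for m in ids]),
            "ss_linear": np.array([ss_rmse[m] for m in ids]),
        }
        comp = stats_mod.compare_model_errors(by_model)
        d = stats_mod.paired_cohens_d([ww_rmse[m] for m in ids],
                                      [ss_rmse[m] for m in ids])
        report["models"][sex] = {
            "omnibus_p": comp.omnibus_p,
            "pairwise": comp.to_report(),
            "paired_cohens_d_ww_minus_ss": d,
            "ss_beats_ww_per_mouse": bool(
                all(ss_rmse[m] < ww_rmse[m] for m in ids)),
        }

    params = fits.params_by_group()
    male_fits = fits.by_group("M")
    quantities = {
        "T_min": lambda p: p.t_min, "a1": lambda p: p.a1, "a2": lambda p: p.a2,
    }
    for name, get in quantities.items():
        comp = stats_mod.compare_params_by_state({
            "M": np.array([get(f.result.params) for f in male_fits.values()]),
            "NE": {m: get(p) for m, p in params["NE"].items()},
            "E": {m: get(p) for m, p in params["E"].items()},
        })
        report["params"][name] = comp.to_report()
    comp = stats_mod.compare_params_by_state({
        "M": np.array([f.result.rmse for f in male_fits.values()]),
        "NE": {m: f.result.rmse for m, f in fits.by_group("NE").items()},
        "E": {m: f.result.rmse for m, f in fits.by_group("E").items()},
    })
    report["params"]["rmse"] = comp.to_report()

    points = [(f.result.params, "M") for f in male_fits.values()]
    points += [(f.result.params, "F") for f in fits.by_group("NE").values()]
    report["separability"] = stats_mod.parameter_separability(points)
    return report
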