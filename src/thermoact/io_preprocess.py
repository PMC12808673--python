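"""Reading, writing and preprocessing of minute-resolution telemetry.

The telemetry model is deliberately rigid: paired core body temperature
(CBT, °C) and locomotor activity (LA, counts/min) sampled once per minute
from intraperitoneal transmitters, with the animal housed under a 12:12
light:dark cycle (lights on 06:00, lights off 18:00 by default).  Days are
always aligned to the start of the dark phase (lights off), which is when
mice become active.

CSV schemas
-----------
Telemetry: header ``mouse_id,minute_index,cbt_c,la_counts``; ``minute_index``
is 0-based from the start of the recording.  Missing minutes may simply be
absent rows; they are flagged in ``gap_mask`` and repaired by
:func:`fill_gaps_linear`.

Labels: header ``mouse_id,sex,estrous_days`` where ``estrous_days`` is a
semicolon-separated list of 0-based day indices (empty for males).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MinuteSeries",
    "MouseRecord",
    "DaySlice",
    "MINUTES_PER_DAY",
    "read_telemetry",
    "write_telemetry",
    "fill_gaps_linear",
    "slice_days",
]

MINUTES_PER_DAY = 1440


@dataclass
class MinuteSeries:
    """A uniformly sampled 1-minute-resolution series.

    Parameters
    ----------
    values : ndarray of float
        The samples.  Entries at masked positions are placeholders until
        :func:`fill_gaps_linear` has been applied.
    gap_mask : ndarray of bool, optional
        True where the sample was originally missing.  Defaults to all-False.
    start_minute : int
        Clock minute-of-day of the first sample (0 = midnight).
    """

    values: np.ndarray
    gap_mask: np.ndarray | None = None
    start_minute: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("MinuteSeries requires a non-empty 1-D array")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != self.values.shape:
                raise ValueError("gap_mask shape must match values")
        self.start_minute = int(self.start_minute) % MINUTES_PER_DAY

    def __len__(self) -> int:
        return self.values.size

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(self.values.copy(), self.gap_mask.copy(), self.start_minute)


@dataclass
class MouseRecord:
    """One animal's paired CBT/LA telemetry plus schedule and labels."""

    mouse_id: str
    sex: str  # "M" or "F"
    cbt: MinuteSeries  # °C
    la: MinuteSeries  # counts/min, nonnegative
    lights_on: int = 360  # 06:00
    lights_off: int = 1080  # 18:00
    estrous_days: frozenset[int] = field(default_factory=frozenset)
    unlabeled_days: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex code {self.sex!r} for mouse {self.mouse_id}")
        if len(self.cbt) != len(self.la):
            raise ValueError("cbt and la must have equal length")
        observed_la = self.la.values[~self.la.gap_mask]
        if observed_la.size and observed_la.min() < 0:
            raise ValueError("LA counts must be nonnegative")
        self.estrous_days = frozenset(int(d) for d in self.estrous_days)
        self.unlabeled_days = frozenset(int(d) for d in self.unlabeled_days)
        if self.sex == "M" and self.estrous_days:
            raise ValueError("male record cannot carry estrous day labels")

    @property
    def n_minutes(self) -> int:
        return len(self.cbt)

    def nonestrous_days(self, n_days: int) -> frozenset[int]:
        """Day indices labeled non-estrous: all complete days not estrous
        and not explicitly unlabeled."""
        return frozenset(
            d for d in range(n_days)
            if d not in self.estrous_days and d not in self.unlabeled_days
        )


@dataclass(frozen=True)
class DaySlice:
    """A complete lights-off-anchored day: samples ``[start, stop)``."""

    day_index: int
    start: int
    stop: int
    complete: bool = True

    def __post_init__(self) -> None:
        if self.complete and self.stop - self.start != MINUTES_PER_DAY:
            raise ValueError("complete DaySlice must span exactly 1440 samples")


# ---------------------------------------------------------------------------
# CSV I/O


def read_telemetry(telemetry_path, labels_path, schema: dict | None = None) -> list[MouseRecord]:
    """Read paired telemetry + labels CSVs into :class:`MouseRecord` objects.

    Rows may be missing for individual minutes; those samples are flagged in
    ``gap_mask`` (CBT placeholder NaN, LA placeholder 0) and must be repaired
    with :func:`fill_gaps_linear` before modelling.

    ``schema`` optionally remaps column names, e.g. ``{"cbt_c": "temp"}``
    maps the canonical name onto the name found in the file.
    """
    cols = {"mouse_id": "mouse_id", "minute_index": "minute_index",
            "cbt_c": "cbt_c", "la_counts": "la_counts"}
    if schema:
        cols.update(schema)
    df = pd.read_csv(telemetry_path, float_precision="round_trip")
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"telemetry file missing columns: {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})

    labels = pd.read_csv(labels_path, dtype={"mouse_id": str}, keep_default_na=False)
    for col in ("mouse_id", "sex"):
        if col not in labels.columns:
            raise ValueError(f"labels file missing column {col!r}")
    labels = labels.set_index("mouse_id")

    records: list[MouseRecord] = []
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        mouse_id = str(mouse_id)
        idx = grp["minute_index"].to_numpy(dtype=int)
        order = np.argsort(idx, kind="stable")
        idx = idx[order]
        if np.any(np.diff(idx) == 0):
            raise ValueError(f"duplicate (mouse, minute) rows for mouse {mouse_id}")
        n = int(idx[-1]) - int(idx[0]) + 1
        cbt = np.full(n, np.nan)
        la = np.zeros(n)
        gap = np.ones(n, dtype=bool)
        pos = idx - idx[0]
        cbt[pos] = grp["cbt_c"].to_numpy(dtype=float)[order]
        la[pos] = grp["la_counts"].to_numpy(dtype=float)[order]
        gap[pos] = False
        # rows present but holding NaN also count as gaps
        gap |= np.isnan(cbt)
        la[gap] = 0.0

        if mouse_id not in labels.index:
            raise ValueError(f"mouse {mouse_id} absent from labels file")
        row = labels.loc[mouse_id]
        sex = str(row["sex"]).strip()
        est_raw = str(row.get("estrous_days", "") or "").strip()
        estrous = frozenset(int(tok) for tok in est_raw.split(";") if tok != "")
        records.append(
            MouseRecord(
                mouse_id=mouse_id,
                sex=sex,
                cbt=MinuteSeries(cbt, gap.copy()),
                la=MinuteSeries(la, gap.copy()),
                estrous_days=estrous,
            )
        )
    return records


def write_telemetry(records: list[MouseRecord], telemetry_path, labels_path) -> None:
    """Write records back to the canonical two-CSV layout.

    Samples that are still flagged as gaps are written as absent rows, so a
    read→write cycle on unrepaired data is an identity on the CSV body.
    """
    frames = []
    label_rows = []
    for rec in sorted(records, key=lambda r: r.mouse_id):  # canonical order
        n = rec.n_minutes
        keep = ~rec.cbt.gap_mask
        frames.append(pd.DataFrame({
            "mouse_id": rec.mouse_id,
            "minute_index": np.arange(n)[keep],
            "cbt_c": rec.cbt.values[keep],
            "la_counts": rec.la.values[keep],
        }))
        label_rows.append({
            "mouse_id": rec.mouse_id,
            "sex": rec.sex,
            "estrous_days": ";".join(str(d) for d in sorted(rec.estrous_days)),
        })
    pd.concat(frames, ignore_index=True).to_csv(telemetry_path, index=False)
    pd.DataFrame(label_rows).to_csv(labels_path, index=False)


# ---------------------------------------------------------------------------
# Gap repair


def fill_gaps_linear(series: MinuteSeries) -> MinuteSeries:
    """Repair flagged gaps by linear interpolation between the nearest
    flanking observed samples.

    Leading/trailing gaps, which have only one flanking observation, are held
    at that nearest observed value.  Observed samples are never modified, and
    the operation is idempotent (the returned series has an all-False mask).
    """
    observed = ~series.gap_mask
    if not observed.any():
        raise ValueError("cannot repair an all-gap series")
    if not series.gap_mask.any():
        return series.copy()
    x = np.arange(len(series))
    filled = series.values.copy()
    filled[series.gap_mask] = np.interp(
        x[series.gap_mask], x[observed], series.values[observed]
    )
    return MinuteSeries(filled, np.zeros(len(series), dtype=bool), series.start_minute)


# ---------------------------------------------------------------------------
# Day alignment


def slice_days(record: MouseRecord) -> list[DaySlice]:
    """Partition a record into complete 1440-sample days anchored at lights-off.

    Day ``d`` covers samples ``[first_off + d*1440, first_off + (d+1)*1440)``
    where ``first_off`` is the first sample at the lights-off clock minute.
    Partial leading/trailing segments are returned as incomplete slices
    (``complete=False``) so nothing is silently dropped; callers that need
    whole days filter on ``complete``.

    A record spanning less than one complete day yields no complete slices
    and a warning.
    """
    n = record.n_minutes
    first_off = (record.lights_off - record.cbt.start_minute) % MINUTES_PER_DAY
    slices: list[DaySlice] = []
    if first_off > 0:
        slices.append(DaySlice(-1, 0, min(first_off, n), complete=False))
    n_complete = max(0, (n - first_off) // MINUTES_PER_DAY)
    if n_complete == 0:
        warnings.warn(
            f"record {record.mouse_id} spans less than one complete "
            "lights-off-aligned day", stacklevel=2,
        )
    for d in range(n_complete):
        start = first_off + d * MINUTES_PER_DAY
        slices.append(DaySlice(d, start, start + MINUTES_PER_DAY))
    tail_start = first_off + n_complete * MINUTES_PER_DAY
    if tail_start < n:
        slices.append(DaySlice(n_complete, tail_start, n, complete=False))
    return slices


def complete_days(record: MouseRecord) -> list[DaySlice]:
    """The complete lights-off-anchored days of a record."""
    return [s for s in slice_days(record) if s.complete]
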