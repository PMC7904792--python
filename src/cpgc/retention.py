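"""Linear temperature-programmed retention indices (LTPRI).

Under a linear oven ramp the retention index of an analyte is obtained by
linear interpolation between the bracketing n-alkanes,

    RI = (Rt_i - Rt_x) / (Rt_{x+1} - Rt_x) * 100 + RI_x,

where an n-alkane's index is 100 times its carbon number. Standards that
produce several peaks (diastereomers, isomeric impurities) are summarised
by the peak-area-weighted mean RI, and polar-column retention is expressed
as dRI = RI(column) - RI(nonpolar reference column).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import LadderError, OutOfRangeError

__all__ = [
    "AlkaneLadder",
    "PeakTable",
    "RIRecord",
    "ltpri",
    "inverse_ltpri",
    "weighted_mean_ri",
    "delta_ri",
    "compute_ri_table",
]


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of the n-alkane reference series on one column.

    ``retention_times`` are in minutes for measured ladders; the same
    container is reused with kelvin entries when interpolation is carried
    out in the elution-temperature domain (time and temperature are affine
    during a linear ramp).
    """

    carbon_numbers: tuple[int, ...]
    retention_times: tuple[float, ...]
    column_id: str = ""

    def __post_init__(self) -> None:
        ns = tuple(int(n) for n in self.carbon_numbers)
        ts = tuple(float(t) for t in self.retention_times)
        if len(ns) != len(ts):
            raise LadderError("carbon_numbers and retention_times differ in length")
        if len(ns) < 2:
            raise LadderError("an alkane ladder needs at least 2 entries")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise LadderError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise LadderError("retention times must be strictly increasing")
        object.__setattr__(self, "carbon_numbers", ns)
        object.__setattr__(self, "retention_times", ts)

    @classmethod
    def from_csv(cls, path: str | Path, column_id: str = "") -> "AlkaneLadder":
        """Read a ladder CSV with columns ``n_carbons, rt_min``."""
        df = pd.read_csv(path).sort_values("n_carbons")
        return cls(
            tuple(df["n_carbons"].astype(int)),
            tuple(df["rt_min"].astype(float)),
            column_id=column_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_carbons": self.carbon_numbers, "rt_min": self.retention_times}
        )


def _segment(ladder: AlkaneLadder, rt: float, extrapolate: bool) -> int:
    ts = ladder.retention_times
    # tolerate float round-off at the span boundaries (e.g. values
    # reconstructed through an inverse transform landing 1 ulp outside)
    tol = 1e-9 * max(abs(ts[0]), abs(ts[-1]))
    if not extrapolate and (rt < ts[0] - tol or rt > ts[-1] + tol):
        raise OutOfRangeError(
            f"retention value {rt:g} outside the ladder span "
            f"[{ts[0]:g}, {ts[-1]:g}] (C{ladder.carbon_numbers[0]}..C"
            f"{ladder.carbon_numbers[-1]}); enable extrapolation to extend "
            "the terminal segment"
        )
    # index of the segment [ts[i], ts[i+1]] used for interpolation
    i = int(np.searchsorted(ts, rt, side="right")) - 1
    return min(max(i, 0), len(ts) - 2)


def ltpri(rt: float, ladder: AlkaneLadder, extrapolate: bool = False) -> float:
    """Retention index of a peak at ``rt`` against the ladder.

    Exact at the knots: ``rt`` equal to an alkane's retention time returns
    exactly 100 times its carbon number. Strictly increasing and piecewise
    linear in ``rt`` between knots. Outside the ladder span the terminal
    segment's slope is extended only when ``extrapolate`` is true.
    """
    rt = float(rt)
    ts, ns = ladder.retention_times, ladder.carbon_numbers
    # bit-exact at ladder alkanes, no interpolation arithmetic
    for n, t in zip(ns, ts):
        if rt == t:
            return 100.0 * n
    i = _segment(ladder, rt, extrapolate)
    frac = (rt - ts[i]) / (ts[i + 1] - ts[i])
    return 100.0 * (ns[i] + frac * (ns[i + 1] - ns[i]))


def inverse_ltpri(ri: float, ladder: AlkaneLadder, extrapolate: bool = False) -> float:
    """Retention time at which :func:`ltpri` returns ``ri`` (exact inverse)."""
    ri = float(ri)
    ts, ns = ladder.retention_times, ladder.carbon_numbers
    ris = [100.0 * n for n in ns]
    for r, t in zip(ris, ts):
        if ri == r:
            return t
    if not extrapolate and (ri < ris[0] or ri > ris[-1]):
        raise OutOfRangeError(
            f"RI {ri:g} outside the ladder span [{ris[0]:g}, {ris[-1]:g}]"
        )
    i = int(np.searchsorted(ris, ri, side="right")) - 1
    i = min(max(i, 0), len(ts) - 2)
    frac = (ri - ris[i]) / (ris[i + 1] - ris[i])
    return ts[i] + frac * (ts[i + 1] - ts[i])


@dataclass(frozen=True)
class PeakTable:
    """Measured peaks for one column run.

    ``data`` columns: ``compound_id, peak_id, rt_min, area``. Retention
    times must be positive and areas non-negative; filtering of impurity
    peaks is the caller's responsibility (via ``peak_id``).
    """

    data: pd.DataFrame
    column_id: str = ""

    _REQUIRED = ("compound_id", "peak_id", "rt_min", "area")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")
        if (self.data["rt_min"] <= 0).any():
            raise ValueError("retention times must be positive")
        if (self.data["area"] < 0).any():
            raise ValueError("peak areas must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path, column_id: str = "") -> "PeakTable":
        return cls(pd.read_csv(path), column_id=column_id)

    def rows_for(self, compound_id: str) -> pd.DataFrame:
        rows = self.data[self.data["compound_id"] == compound_id]
        if rows.empty:
            raise KeyError(f"no peaks for compound {compound_id!r}")
        return rows

    @property
    def compound_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["compound_id"]))


@dataclass(frozen=True)
class RIRecord:
    """Per-compound RI summary on one column."""

    compound_id: str
    column_id: str
    ri_values: tuple[float, ...]
    areas: tuple[float, ...]
    weighted_mean_ri: float
    ri_range: float

    def __post_init__(self) -> None:
        lo, hi = min(self.ri_values), max(self.ri_values)
        if not (lo - 1e-9 <= self.weighted_mean_ri <= hi + 1e-9):
            raise ValueError("weighted mean RI outside the per-peak RI range")


def weighted_mean_ri(
    peaks: PeakTable | pd.DataFrame,
    ladder: AlkaneLadder,
    compound_id: str | None = None,
    extrapolate: bool = False,
) -> RIRecord:
    """Area-weighted mean RI of one compound's peaks.

    Multi-peak standards (diastereomers) are summarised by
    ``sum(area_i * RI_i) / sum(area_i)``; ``ri_range`` is max - min, zero
    for a single peak. The mean is invariant under uniform area rescaling.
    """
    if isinstance(peaks, PeakTable):
        column_id = peaks.column_id
        rows = peaks.rows_for(compound_id) if compound_id is not None else peaks.data
        if compound_id is None:
            ids = rows["compound_id"].unique()
            if len(ids) != 1:
                raise ValueError("pass compound_id when the table holds several compounds")
            compound_id = ids[0]
    else:
        rows = peaks
        column_id = ladder.column_id
        ids = rows["compound_id"].unique()
        if len(ids) != 1:
            raise ValueError("peak rows must belong to a single compound")
        compound_id = ids[0]
    if rows.empty:
        raise ValueError(f"no peaks for {compound_id!r}")
    areas = rows["area"].to_numpy(dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError(f"total peak area for {compound_id!r} must be positive")
    ris = np.array(
        [ltpri(rt, ladder, extrapolate=extrapolate) for rt in rows["rt_min"]]
    )
    mean = float((areas * ris).sum() / total)
    return RIRecord(
        compound_id=str(compound_id),
        column_id=column_id,
        ri_values=tuple(ris),
        areas=tuple(areas),
        weighted_mean_ri=mean,
        ri_range=float(ris.max() - ris.min()),
    )


def delta_ri(record: RIRecord, reference: RIRecord) -> float:
    """dRI: weighted-mean RI on a column minus that on the nonpolar reference.

    Both records must describe the same compound; a record against itself
    gives exactly 0.
    """
    if record.compound_id != reference.compound_id:
        raise ValueError(
            f"compound mismatch: {record.compound_id!r} vs {reference.compound_id!r}"
        )
    return record.weighted_mean_ri - reference.weighted_mean_ri


def compute_ri_table(
    peaks: PeakTable,
    ladder: AlkaneLadder,
    reference: dict[str, RIRecord] | None = None,
    extrapolate: bool = False,
) -> pd.DataFrame:
    """Summarise every compound of a peak table; optionally append dRI.

    Returns columns ``compound_id, column_id, n_peaks, ri_min, ri_max,
    ri_weighted_mean`` (plus ``delta_ri`` when reference records are given).
    """
    rows = []
    for cid in peaks.compound_ids:
        rec = weighted_mean_ri(peaks, ladder, cid, extrapolate=extrapolate)
        row = {
            "compound_id": cid,
            "column_id": peaks.column_id,
            "n_peaks": len(rec.ri_values),
            "ri_min": min(rec.ri_values),
            "ri_max": max(rec.ri_values),
            "ri_weighted_mean": rec.weighted_mean_ri,
        }
        if reference is not None:
            row["delta_ri"] = (
                delta_ri(rec, reference[cid]) if cid in reference else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
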