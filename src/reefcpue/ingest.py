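"""Swipe/logbook ingestion, outlier filtering, weight and effort assignment.

A "swipe" is one abalone passed through a GPS-enabled measuring board:
diver, instant, position and maximum shell length.  Two artefact filters are
applied before any spatial analysis: a speed filter (gaps implying vessel
transit between sites) and a reef-mismatch filter (records too far from
mapped reef to be plausible dive positions given the ~100 m umbilical).
Retained records get an allometric catch weight and an even share of the
diver-day's logbook hours.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import Raster

#: Allometric length->whole-weight coefficients for blacklip abalone:
#: W[kg] = A * (SL[mm] / 10)^B
ALLOMETRIC_A = 0.000412
ALLOMETRIC_B = 2.76


@dataclass
class FilterReport:
    """Bookkeeping for the ingest filters; counts always reconcile."""

    n_input: int = 0
    n_transit_removed: int = 0
    n_reef_mismatch_removed: int = 0
    n_retained: int = 0
    removal_reasons: dict[int, str] = field(default_factory=dict)  # row index -> reason
    warnings: list[str] = field(default_factory=list)

    def check(self) -> None:
        removed = self.n_transit_removed + self.n_reef_mismatch_removed
        if self.n_input != self.n_retained + removed:
            raise AssertionError("filter report counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        self.check()
        doc = {
            "n_input": self.n_input,
            "n_transit_removed": self.n_transit_removed,
            "n_reef_mismatch_removed": self.n_reef_mismatch_removed,
            "n_retained": self.n_retained,
            "removal_reasons": {str(k): v for k, v in self.removal_reasons.items()},
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def estimate_weight(shell_length_mm):
    """Whole weight (kg) from maximum shell length (mm).

    Uses the allometric power law W = 0.000412 (SL/10)^2.76, the standard
    length-weight relationship for blacklip abalone.  Strictly increasing
    in SL; SL = 10 mm maps to exactly 0.000412 kg.
    """
    sl = np.asarray(shell_length_mm, dtype=float)
    if np.any(~(sl > 0)):
        raise ValueError("shell length must be positive")
    w = ALLOMETRIC_A * (sl / 10.0) ** ALLOMETRIC_B
    return float(w) if np.isscalar(shell_length_mm) else w


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_swipes(path: str | Path) -> pd.DataFrame:
    """Read a swipe CSV (diver_id, timestamp, x_m, y_m, shell_length_mm)."""
    df = pd.read_csv(path)
    required = {"diver_id", "timestamp", "x_m", "y_m", "shell_length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"swipe file missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df


def load_logbook(path: str | Path) -> pd.DataFrame:
    """Read a logbook CSV (diver_id, date, hours)."""
    df = pd.read_csv(path)
    required = {"diver_id", "date", "hours"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"logbook file missing columns: {sorted(missing)}")
    if np.any(~(df["hours"] > 0)):
        raise ValueError("logbook hours must be positive")
    df["date"] = pd.to_datetime(df["date"]).dt.date.astype(str)
    return df


def _ensure_parsed(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if not np.issubdtype(df["timestamp"].dtype, np.datetime64):
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["date"] = df["timestamp"].dt.date.astype(str)
    df["year"] = df["timestamp"].dt.year
    return df


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def flag_transit_outliers(records: pd.DataFrame, speed_threshold_m_s: float = 2.0
                          ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove records implying vessel-transit speeds.

    Within each diver-day ordered by time, a record whose straight-line
    speed from the previous *retained* record exceeds the threshold is
    removed (streaming removal: one transit leg does not cascade into
    removing the next legitimate swipe).
    """
    if speed_threshold_m_s <= 0:
        raise ValueError("speed threshold must be positive")
    df = _ensure_parsed(records)
    dup = df.duplicated(subset=["diver_id", "timestamp"], keep=False)
    if dup.any():
        d = df.loc[dup]
        if (d.groupby(["diver_id", "timestamp"])[["x_m", "y_m"]]
                .nunique().to_numpy() > 1).any():
            raise ValueError("malformed input: duplicate (diver, timestamp) "
                             "with different positions")

    report = FilterReport(n_input=len(df))
    keep = np.ones(len(df), dtype=bool)
    order = df.sort_values(["diver_id", "timestamp"], kind="mergesort")
    for (_, _), grp in order.groupby(["diver_id", "date"], sort=False):
        idx = grp.index.to_numpy()
        xs = grp["x_m"].to_numpy()
        ys = grp["y_m"].to_numpy()
        ts = grp["timestamp"].astype("int64").to_numpy() / 1e9
        last = 0
        for k in range(1, len(idx)):
            dt = ts[k] - ts[last]
            dist = float(np.hypot(xs[k] - xs[last], ys[k] - ys[last]))
            if dt <= 0:
                speed = 0.0 if dist == 0 else np.inf
            else:
                speed = dist / dt
            loc = df.index.get_loc(idx[k])
            if speed > speed_threshold_m_s:
                keep[loc] = False
                report.removal_reasons[int(idx[k])] = "transit"
            else:
                last = k
    retained = df.loc[keep].copy()
    report.n_transit_removed = int((~keep).sum())
    report.n_retained = len(retained)
    report.check()
    return retained, report


def flag_reef_mismatch(records: pd.DataFrame, reef_mask: Raster,
                       buffer_m: float = 100.0
                       ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove records farther than ``buffer_m`` from any reef cell.

    Distance is measured to the nearest reef pixel centre; the 100 m default
    mirrors the umbilical length that tethers a diver to the vessel.
    """
    df = _ensure_parsed(records)
    report = FilterReport(n_input=len(df))
    mask = reef_mask.data.astype(bool)
    if not mask.any():
        report.warnings.append("reef mask is empty: all records removed")
        report.n_reef_mismatch_removed = len(df)
        report.n_retained = 0
        for i in df.index:
            report.removal_reasons[int(i)] = "reef_mismatch"
        report.check()
        return df.iloc[0:0].copy(), report

    rows, cols = np.nonzero(mask)
    res = reef_mask.resolution
    px = reef_mask.x0 + (cols + 0.5) * res
    py = reef_mask.y0 + (rows + 0.5) * res
    tree = cKDTree(np.column_stack([px, py]))
    dist, _ = tree.query(df[["x_m", "y_m"]].to_numpy(), k=1)
    keep = dist <= buffer_m
    for i in df.index[~keep]:
        report.removal_reasons[int(i)] = "reef_mismatch"
    retained = df.loc[keep].copy()
    report.n_reef_mismatch_removed = int((~keep).sum())
    report.n_retained = len(retained)
    report.check()
    return retained, report


def apportion_effort(records: pd.DataFrame, effort: pd.DataFrame
                     ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Divide each diver-day's logbook hours evenly over its retained swipes.

    Every retained (diver, date) must have a logbook row; logbook rows with
    no swipes are returned as unapportioned.  Per-day sums of
    ``apportioned_hours`` equal logbook hours exactly.
    """
    df = _ensure_parsed(records)
    eff = effort.copy()
    eff["date"] = pd.to_datetime(eff["date"]).dt.date.astype(str)
    eff_key = eff.set_index(["diver_id", "date"])["hours"]
    if eff_key.index.has_duplicates:
        eff_key = eff_key.groupby(level=[0, 1]).sum()

    counts = df.groupby(["diver_id", "date"]).size()
    missing = counts.index.difference(eff_key.index)
    if len(missing):
        raise ValueError(f"diver-days with swipes but no logbook row: "
                         f"{list(missing)[:5]}{'...' if len(missing) > 5 else ''}")
    per_swipe = eff_key / counts.reindex(eff_key.index)
    key = pd.MultiIndex.from_frame(df[["diver_id", "date"]])
    df["apportioned_hours"] = per_swipe.reindex(key).to_numpy()
    unmatched = [tuple(k) for k in eff_key.index.difference(counts.index)]
    return df, unmatched


def ingest(records: pd.DataFrame, effort: pd.DataFrame, reef_mask: Raster,
           speed_threshold_m_s: float = 2.0, buffer_m: float = 100.0
           ) -> tuple[pd.DataFrame, FilterReport]:
    """Full ingest: transit filter, reef-mismatch filter, weight, effort.

    Returns the retained records (with ``weight_kg``, ``apportioned_hours``,
    ``year``) and a combined :class:`FilterReport`.
    """
    after_transit, rep_t = flag_transit_outliers(records, speed_threshold_m_s)
    retained, rep_m = flag_reef_mismatch(after_transit, reef_mask, buffer_m)
    report = FilterReport(
        n_input=rep_t.n_input,
        n_transit_removed=rep_t.n_transit_removed,
        n_reef_mismatch_removed=rep_m.n_reef_mismatch_removed,
        n_retained=rep_m.n_retained,
        removal_reasons={**rep_t.removal_reasons, **rep_m.removal_reasons},
        warnings=rep_t.warnings + rep_m.warnings,
    )
    report.check()
    retained["weight_kg"] = estimate_weight(retained["shell_length_mm"].to_numpy())
    retained, unmatched = apportion_effort(retained, effort)
    if unmatched:
        report.warnings.append(
            f"{len(unmatched)} logbook rows had no retained swipes")
    return retained, report
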