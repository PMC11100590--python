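"""CSV input/output for all tabular dataset kinds.

Canonical units: concentrations in nM, times in seconds, energies in
kcal/mol.  A ``time_units`` column (``s``, ``min`` or ``h``) overrides
the time unit row-wise.  All readers validate fractions to [0, 1] and
report offending rows by file line number (header = line 1).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import AssociationDataset, TitrationDataset
from .fitting import SlicingSeries, SlicingTimeCourse
from .footprint import ReactivityProfile
from .thermo import ThermoPoint

__all__ = [
    "SchemaError",
    "RowValidationError",
    "read_timecourse_table",
    "read_slicing_csv",
    "write_slicing_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_association_csv",
    "write_association_csv",
    "read_thermo_csv",
    "write_thermo_csv",
    "read_lane_table",
    "read_sample_sheet",
    "write_lane_table",
]

_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "second": 1.0, "seconds": 1.0,
                 "min": 60.0, "minute": 60.0, "minutes": 60.0,
                 "h": 3600.0, "hr": 3600.0, "hour": 3600.0, "hours": 3600.0}


class SchemaError(ValueError):
    """A required column is missing."""


class RowValidationError(ValueError):
    """A row holds an out-of-range value; the message cites the line."""


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )


def _check_fraction(df: pd.DataFrame, column: str, path) -> None:
    bad = df.index[(df[column] < 0) | (df[column] > 1) | df[column].isna()]
    if len(bad):
        line = int(bad[0]) + 2  # +1 header, +1 1-based
        raise RowValidationError(
            f"{path}, line {line}: {column} = {df.loc[bad[0], column]!r} "
            "outside [0, 1]"
        )


def _times_seconds(df: pd.DataFrame) -> np.ndarray:
    t = df["time"].to_numpy(dtype=float)
    if "time_units" in df.columns:
        factors = (
            df["time_units"].astype(str).str.strip().str.lower()
            .map(_TIME_FACTORS)
        )
        if factors.isna().any():
            bad = df.index[factors.isna()][0]
            raise RowValidationError(
                f"line {int(bad) + 2}: unknown time unit "
                f"{df.loc[bad, 'time_units']!r}"
            )
        t = t * factors.to_numpy(dtype=float)
    return t


def read_slicing_csv(path) -> SlicingTimeCourse:
    """Read a slicing time-course table.

    Required columns: ``e_all`` (nM), ``s0`` (nM), ``time`` (s unless
    ``time_units`` says otherwise), ``fraction_sliced``.  Optional:
    ``guide_id``, ``target_id``, ``time_units``.  Rows are grouped into
    one series per (e_all, s0) pair, preserving row order within groups.
    """
    df = pd.read_csv(path)
    _require(df, ["e_all", "s0", "time", "fraction_sliced"], path)
    _check_fraction(df, "fraction_sliced", path)
    df = df.assign(_t=_times_seconds(df))
    guide = str(df["guide_id"].iloc[0]) if "guide_id" in df.columns else "guide"
    target = str(df["target_id"].iloc[0]) if "target_id" in df.columns else "target"
    series = []
    for (e_all, s0), grp in df.groupby(["e_all", "s0"], sort=True):
        grp = grp.sort_values("_t")
        series.append(
            SlicingSeries(
                e_all=float(e_all),
                s0=float(s0),
                times=grp["_t"].to_numpy(),
                fractions=grp["fraction_sliced"].to_numpy(dtype=float),
            )
        )
    return SlicingTimeCourse(guide_id=guide, target_id=target, series=series)


def write_slicing_csv(data: SlicingTimeCourse, path) -> None:
    rows = []
    for s in data.series:
        for t, f in zip(s.times, s.fractions):
            rows.append(
                {
                    "guide_id": data.guide_id,
                    "target_id": data.target_id,
                    "e_all": s.e_all,
                    "s0": s.s0,
                    "time": t,
                    "fraction_sliced": f,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration_csv(path, target_total: float = 1.0) -> TitrationDataset:
    """Columns: ``dilution_factor``, ``fraction_bound``; optional
    ``target_total`` column (nM) overrides the argument."""
    df = pd.read_csv(path)
    _require(df, ["dilution_factor", "fraction_bound"], path)
    _check_fraction(df, "fraction_bound", path)
    if "target_total" in df.columns:
        target_total = float(df["target_total"].iloc[0])
    return TitrationDataset(
        target_total=target_total,
        dilution_factors=df["dilution_factor"].to_numpy(dtype=float),
        fractions_bound=df["fraction_bound"].to_numpy(dtype=float),
    )


def write_titration_csv(data: TitrationDataset, path) -> None:
    pd.DataFrame(
        {
            "dilution_factor": data.dilution_factors,
            "fraction_bound": data.fractions_bound,
            "target_total": data.target_total,
        }
    ).to_csv(path, index=False)


def read_association_csv(path, risc_total: float | None = None
                         ) -> AssociationDataset:
    """Columns: ``time``, ``fraction_bound``; optional ``time_units`` and
    ``risc_total`` (nM) columns."""
    df = pd.read_csv(path)
    _require(df, ["time", "fraction_bound"], path)
    _check_fraction(df, "fraction_bound", path)
    if "risc_total" in df.columns:
        risc_total = float(df["risc_total"].iloc[0])
    if risc_total is None:
        raise SchemaError(
            f"{path}: risc_total must be given as an argument or column"
        )
    t = _times_seconds(df)
    order = np.argsort(t)
    return AssociationDataset(
        risc_total=risc_total,
        times=t[order],
        fractions_bound=df["fraction_bound"].to_numpy(dtype=float)[order],
    )


def write_association_csv(data: AssociationDataset, path) -> None:
    pd.DataFrame(
        {
            "time": data.times,
            "fraction_bound": data.fractions_bound,
            "risc_total": data.risc_total,
        }
    ).to_csv(path, index=False)


def read_thermo_csv(path) -> list[ThermoPoint]:
    """Columns: ``dG_9_12`` (kcal/mol), ``ratio``."""
    df = pd.read_csv(path)
    _require(df, ["dG_9_12", "ratio"], path)
    bad = df.index[(df["ratio"] <= 0) | (df["ratio"] > 1) | df["ratio"].isna()]
    if len(bad):
        raise RowValidationError(
            f"{path}, line {int(bad[0]) + 2}: ratio outside (0, 1]"
        )
    return [
        ThermoPoint(float(g), float(r))
        for g, r in zip(df["dG_9_12"], df["ratio"])
    ]


def write_thermo_csv(points, path) -> None:
    pd.DataFrame(
        {"dG_9_12": [p.dG_9_12 for p in points],
         "ratio": [p.ratio for p in points]}
    ).to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Lane metadata: columns ``lane``, ``condition``, ``replicate``,
    optional ``guide_id``."""
    df = pd.read_csv(path)
    _require(df, ["lane", "condition", "replicate"], path)
    return df


def read_lane_table(path, sample_sheet: pd.DataFrame,
                    masked_positions=()) -> list[ReactivityProfile]:
    """Long-format lane intensities: columns ``lane``, ``position``,
    ``intensity``.  Positions must form a contiguous 1..L range within
    each lane.  Lanes are labeled via the sample sheet."""
    df = pd.read_csv(path)
    _require(df, ["lane", "position", "intensity"], path)
    meta = sample_sheet.set_index("lane")
    profiles = []
    for lane, grp in df.groupby("lane", sort=True):
        if lane not in meta.index:
            warnings.warn(f"lane {lane!r} absent from sample sheet; skipped",
                          stacklevel=2)
            continue
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy(dtype=int)
        if not np.array_equal(pos, np.arange(1, pos.size + 1)):
            raise RowValidationError(
                f"{path}: lane {lane!r} positions are not contiguous 1..L"
            )
        mask = np.zeros(pos.size, dtype=bool)
        for p in masked_positions:
            mask[int(p) - 1] = True
        row = meta.loc[lane]
        profiles.append(
            ReactivityProfile(
                guide_id=str(row.get("guide_id", "guide")),
                condition=str(row["condition"]),
                replicate_id=str(row["replicate"]),
                values=grp["intensity"].to_numpy(dtype=float),
                mask=mask,
            )
        )
    return profiles


def write_lane_table(profiles, lanes_path, sheet_path) -> None:
    rows, sheet = [], []
    for i, p in enumerate(profiles, start=1):
        lane = f"L{i:02d}"
        sheet.append(
            {"lane": lane, "condition": p.condition,
             "replicate": p.replicate_id, "guide_id": p.guide_id}
        )
        for pos, v in zip(p.positions, p.values):
            rows.append({"lane": lane, "position": int(pos), "intensity": v})
    pd.DataFrame(rows).to_csv(lanes_path, index=False)
    pd.DataFrame(sheet).to_csv(sheet_path, index=False)


def read_timecourse_table(path, kind: str = "auto"):
    """Dispatch a CSV to the matching dataset reader.

    ``kind`` in {"auto", "slicing", "titration", "association"}; "auto"
    inspects the header.
    """
    if kind == "slicing":
        return read_slicing_csv(path)
    if kind == "titration":
        return read_titration_csv(path)
    if kind == "association":
        return read_association_csv(path)
    if kind != "auto":
        raise ValueError(f"unknown kind {kind!r}")
    cols = set(pd.read_csv(path, nrows=0).columns)
    if "fraction_sliced" in cols:
        return read_slicing_csv(path)
    if "dilution_factor" in cols:
        return read_titration_csv(path)
    if "fraction_bound" in cols:
        return read_association_csv(path)
    raise SchemaError(f"{path}: cannot infer dataset kind from columns {cols}")
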