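"""Reading, validation and writing of specimen, sample-level and isotope tables.

The package exchanges three plain CSV tables (comma-separated, UTF-8, ``.``
decimal separator, mandatory header row):

``specimens.csv``
    one row per shell occurrence:
    ``specimen_id,sample_id,strat_height,taxon,clade,valve,dim_a,dim_b,measured``
    ``dim_a`` is shell length L; ``dim_b`` is width W for brachiopods and
    height H for bivalves, both in mm.  After size computation/imputation the
    columns ``size_log2`` and ``provenance`` are appended on write.
``isotopes.csv``
    one row per isotope measurement:
    ``sample_id,substrate,d18O,d13C,mn_ca,fe_ca`` (element/Ca ratios in
    mmol/mol, optional), plus an ``accepted`` column after screening.
``levels.csv``
    one row per sampled level:
    ``sample_id,strat_height,label,in_event`` where ``in_event`` flags the
    chemostratigraphically defined excursion interval.

Tables are held as :class:`pandas.DataFrame` with a validated schema; each
specimen row represents one individual (valve-pairing is assumed to have been
resolved during data entry).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLADES",
    "ANALYSIS_CLADES",
    "VALVES",
    "SchemaError",
    "RowError",
    "read_specimens",
    "write_specimens",
    "read_isotopes",
    "write_isotopes",
    "read_levels",
    "write_levels",
    "levels_from_specimens",
    "drop_rare_groups",
]

#: Clades accepted in specimen tables.
CLADES = frozenset({"bivalve", "brachiopod", "gastropod", "coral"})
#: Clades retained for quantitative analysis (gastropods and corals are rare
#: and fragmented in this kind of assemblage and are excluded).
ANALYSIS_CLADES = frozenset({"bivalve", "brachiopod"})
#: Accepted valve states.
VALVES = frozenset({"left", "right", "dorsal", "ventral", "articulated", "unknown"})

SPECIMEN_COLUMNS = [
    "specimen_id",
    "sample_id",
    "strat_height",
    "taxon",
    "clade",
    "valve",
    "dim_a",
    "dim_b",
    "measured",
]
ISOTOPE_COLUMNS = ["sample_id", "substrate", "d18O", "d13C", "mn_ca", "fe_ca"]
ISOTOPE_REQUIRED = ["sample_id", "substrate", "d18O", "d13C"]
LEVEL_COLUMNS = ["sample_id", "strat_height", "label", "in_event"]

SUBSTRATES = frozenset({"rhynchonellid", "oyster"})


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable layout."""


class RowError(ValueError):
    """A single row violates an invariant; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing mandatory column(s): {', '.join(missing)}")


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = int(series.index[out.isna()][0])
        raise RowError(bad, f"cannot interpret {series[bad]!r} as a boolean")
    return out.astype(bool)


def read_specimens(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a specimen occurrence table.

    Parameters
    ----------
    path
        CSV file with the ``specimens.csv`` schema.
    column_map
        Optional ``{csv_column: schema_column}`` renaming, for mapping
        externally deposited files onto the expected schema.

    Returns
    -------
    pandas.DataFrame
        Typed table in file order.  Measured rows are guaranteed to carry
        strictly positive ``dim_a`` and ``dim_b``.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "sample_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, SPECIMEN_COLUMNS, "specimen")
    return validate_specimens(df)


def validate_specimens(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory specimen table (same checks as :func:`read_specimens`)."""
    _require_columns(df, SPECIMEN_COLUMNS, "specimen")
    df = df.copy()
    df["specimen_id"] = df["specimen_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df["taxon"] = df["taxon"].astype(str)
    df["clade"] = df["clade"].astype(str).str.strip().str.lower()
    df["valve"] = df["valve"].astype(str).str.strip().str.lower()
    df["measured"] = _to_bool(df["measured"])

    unknown = ~df["clade"].isin(CLADES)
    if unknown.any():
        row = int(df.index[unknown][0])
        raise RowError(row, f"unknown clade {df.loc[row, 'clade']!r}")
    bad_valve = ~df["valve"].isin(VALVES)
    if bad_valve.any():
        row = int(df.index[bad_valve][0])
        raise RowError(row, f"unknown valve state {df.loc[row, 'valve']!r}")

    for col in ("strat_height", "dim_a", "dim_b"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            row = int(df.index[newly_bad][0])
            raise RowError(row, f"non-numeric value {df.loc[row, col]!r} in column {col!r}")
        df[col] = coerced.astype(float)

    if df["strat_height"].isna().any():
        row = int(df.index[df["strat_height"].isna()][0])
        raise RowError(row, "missing strat_height")

    measured = df["measured"]
    bad_dims = measured & ~((df["dim_a"] > 0) & (df["dim_b"] > 0))
    if bad_dims.any():
        row = int(df.index[bad_dims][0])
        raise RowError(row, "measured specimen must have positive dim_a and dim_b")

    heights = df.groupby("sample_id")["strat_height"].nunique()
    if (heights > 1).any():
        sid = heights.index[heights > 1][0]
        raise SchemaError(f"sample {sid!r} has inconsistent strat_height values")
    per_height = df.drop_duplicates("sample_id").groupby("strat_height")["sample_id"].nunique()
    if (per_height > 1).any():
        h = per_height.index[per_height > 1][0]
        raise SchemaError(f"distinct samples share strat_height {h}; series order is ambiguous")
    return df


def write_specimens(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in SPECIMEN_COLUMNS + ["size_log2", "provenance"] if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def read_isotopes(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a per-specimen isotope/element table."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    _require_columns(df, ISOTOPE_REQUIRED, "isotope")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["substrate"] = df["substrate"].astype(str).str.strip().str.lower()
    for col in ("d18O", "d13C", "mn_ca", "fe_ca"):
        if col not in df.columns:
            df[col] = np.nan
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            row = int(df.index[newly_bad][0])
            raise RowError(row, f"non-numeric value {df.loc[row, col]!r} in column {col!r}")
        df[col] = coerced.astype(float)
    if df["d18O"].isna().any():
        row = int(df.index[df["d18O"].isna()][0])
        raise RowError(row, "missing d18O value")
    if "accepted" in df.columns:
        df["accepted"] = _to_bool(df["accepted"])
    return df


def write_isotopes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in ISOTOPE_COLUMNS + ["accepted"] if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def read_levels(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sampled-level table and order it by stratigraphic height."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "strat_height"], "level")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["strat_height"] = pd.to_numeric(df["strat_height"])
    if "label" not in df.columns:
        df["label"] = ""
    if "in_event" not in df.columns:
        df["in_event"] = False
    else:
        df["in_event"] = _to_bool(df["in_event"])
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicated sample_id in level table")
    if df["strat_height"].duplicated().any():
        raise SchemaError("tied strat_height across distinct samples; series order is ambiguous")
    return df.sort_values("strat_height", ignore_index=True)


def write_levels(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in LEVEL_COLUMNS + ["temperature_true", "d18O_true"] if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def levels_from_specimens(specimens: pd.DataFrame) -> pd.DataFrame:
    """Derive an ordered level table from the (sample_id, strat_height) pairs."""
    lv = (
        specimens[["sample_id", "strat_height"]]
        .drop_duplicates()
        .sort_values("strat_height", ignore_index=True)
    )
    lv["label"] = ""
    lv["in_event"] = False
    return lv


def drop_rare_groups(specimens: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Restrict the table to bivalves and brachiopods.

    Gastropod and coral occurrences are removed; returns the filtered table
    and the number of rows dropped.
    """
    keep = specimens["clade"].isin(ANALYSIS_CLADES)
    removed = int((~keep).sum())
    return specimens.loc[keep].reset_index(drop=True), removed
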