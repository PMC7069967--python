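"""Per-sample community statistics.

Mean shell-size trajectories with interquartile ranges, the common-species
filter, classification of common species into larger- and smaller-sized
around the global mean of species means, the percentage of larger-sized
individuals per sample, and a display-only three-point moving average.

Series tables share the layout ``sample_id, strat_height, value, q1, q3, n``
ordered by stratigraphic height; ``df.attrs["statistic"]`` names the
statistic (``mean_size_log2`` or ``pct_larger``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .size import retained

__all__ = [
    "GROUPS",
    "select_group",
    "sample_mean_size",
    "moving_average_3",
    "common_species",
    "classify_species_size",
    "percent_larger",
]

GROUPS = ("all", "bivalves", "brachiopods")


def select_group(specimens: pd.DataFrame, group: str) -> pd.DataFrame:
    """Restrict to a faunal group.

    ``brachiopods`` means articulate brachiopods: if the table carries a
    boolean ``articulate`` column it is honoured, otherwise all brachiopod
    records are taken as articulate (inarticulates are marginal in these
    assemblages and would normally be flagged during data entry).
    """
    if group == "all":
        return specimens
    if group == "bivalves":
        return specimens[specimens["clade"] == "bivalve"]
    if group == "brachiopods":
        out = specimens[specimens["clade"] == "brachiopod"]
        if "articulate" in out.columns:
            out = out[out["articulate"].astype(bool)]
        return out
    raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")


def _series_frame(rows: pd.DataFrame, statistic: str) -> pd.DataFrame:
    rows = rows.sort_values("strat_height", ignore_index=True)
    rows.attrs["statistic"] = statistic
    return rows


def sample_mean_size(specimens: pd.DataFrame, group: str = "all") -> pd.DataFrame:
    """Mean shell size (log2 mm) per sample with quartiles and counts.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention).  Samples without qualifying specimens are omitted.
    """
    sub = select_group(retained(specimens), group)
    if len(sub) == 0:
        raise ValueError(f"no specimens with sizes for group {group!r}")
    agg = (
        sub.groupby("sample_id")
        .agg(
            strat_height=("strat_height", "first"),
            value=("size_log2", "mean"),
            q1=("size_log2", lambda s: float(np.quantile(s, 0.25))),
            q3=("size_log2", lambda s: float(np.quantile(s, 0.75))),
            n=("size_log2", "size"),
        )
        .reset_index()
    )
    return _series_frame(agg, "mean_size_log2")


def moving_average_3(series: pd.DataFrame) -> pd.DataFrame:
    """Centered three-point moving average of ``value``.

    Endpoints average the available points (a shrinking window), so the
    series keeps its length.  Intended for display only.
    """
    out = series.copy()
    out["value"] = (
        series["value"].rolling(window=3, center=True, min_periods=1).mean().to_numpy()
    )
    out.attrs = dict(series.attrs)
    return out


def common_species(
    specimens: pd.DataFrame,
    min_per_level: int = 3,
    min_levels: int = 3,
    rule: str = "per_level",
) -> list[str]:
    """Species abundant enough to enter the size-class analysis.

    rule="per_level" (default)
        a level counts toward ``min_levels`` only if it holds at least
        ``min_per_level`` specimens of the species; the species is common
        when at least ``min_levels`` levels qualify.
    rule="any_level"
        the species must occur at ``min_levels`` levels (any abundance) and
        reach ``min_per_level`` specimens in at least one of them.

    Both readings of the filter are kept because occurrence datasets differ
    in how sparse levels were tallied; the stricter per-level reading is the
    default.  Only retained (sized) specimens are counted.
    """
    sub = retained(specimens)
    tab = sub.groupby(["taxon", "sample_id"]).size().rename("n").reset_index()
    out = []
    for taxon, g in tab.groupby("taxon"):
        if rule == "per_level":
            ok = int((g["n"] >= min_per_level).sum()) >= min_levels
        elif rule == "any_level":
            ok = len(g) >= min_levels and int(g["n"].max()) >= min_per_level
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if ok:
            out.append(taxon)
    return sorted(out)


def classify_species_size(
    specimens: pd.DataFrame, species: list[str]
) -> pd.DataFrame:
    """Split common species into larger- and smaller-sized.

    Each species' mean ``size_log2`` over all its retained specimens is
    compared against the cutoff, the unweighted mean of those species means.
    A species is ``larger`` iff its mean strictly exceeds the cutoff (an
    exact tie classifies as ``smaller``).  The cutoff is stored in
    ``df.attrs["cutoff"]``.
    """
    if len(species) < 2:
        raise ValueError("need at least two common species to define a size cutoff")
    sub = retained(specimens)
    sub = sub[sub["taxon"].isin(species)]
    means = (
        sub.groupby("taxon")
        .agg(clade=("clade", "first"), mean_size=("size_log2", "mean"))
        .reindex(species)
        .reset_index()
    )
    if means["mean_size"].isna().any():
        missing = means.loc[means["mean_size"].isna(), "taxon"].tolist()
        raise ValueError(f"no sized specimens for species: {missing}")
    cutoff = float(means["mean_size"].mean())
    means["size_class"] = np.where(means["mean_size"] > cutoff, "larger", "smaller")
    means.attrs["cutoff"] = cutoff
    return means


def percent_larger(
    specimens: pd.DataFrame, size_classes: pd.DataFrame, group: str = "all"
) -> pd.DataFrame:
    """Percentage of larger-sized individuals per sample.

    100 x (individuals of larger-class common species) / (individuals of all
    common species in the sample); samples without common-species
    individuals are omitted.  ``q1``/``q3`` are not defined for a percentage
    and are reported as NaN.
    """
    sub = select_group(retained(specimens), group)
    sub = sub[sub["taxon"].isin(size_classes["taxon"])]
    larger = set(size_classes.loc[size_classes["size_class"] == "larger", "taxon"])
    if len(sub) == 0:
        raise ValueError(f"no common-species individuals for group {group!r}")
    agg = (
        sub.assign(is_larger=sub["taxon"].isin(larger))
        .groupby("sample_id")
        .agg(
            strat_height=("strat_height", "first"),
            n_larger=("is_larger", "sum"),
            n=("is_larger", "size"),
        )
        .reset_index()
    )
    agg["value"] = 100.0 * agg["n_larger"] / agg["n"]
    agg["q1"] = np.nan
    agg["q3"] = np.nan
    agg = agg[["sample_id", "strat_height", "value", "q1", "q3", "n"]]
    return _series_frame(agg, "pct_larger")
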