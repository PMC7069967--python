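"""Shell-size computation and hierarchical imputation of unmeasured specimens.

Shell size is the base-2 logarithm of the geometric mean of two linear
dimensions: length x width for brachiopods and length x height for bivalves.
Specimens without direct measurements receive a size by a two-step fallback
(mean of measured conspecifics in the same sample, else the mean of the
per-sample species means in the nearest sampled levels below and above);
species that were never measured anywhere are dropped from analysis.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

__all__ = [
    "PROVENANCES",
    "geometric_mean_size",
    "log2_size",
    "compute_measured_sizes",
    "impute_sizes",
    "imputed_fraction",
    "retained",
]

#: Provenance labels, in imputation priority order.
PROVENANCES = ("measured", "imputed_same_sample", "imputed_adjacent", "dropped")


def geometric_mean_size(dim_a, dim_b):
    """Geometric mean of two shell dimensions in mm, ``sqrt(dim_a * dim_b)``.

    Accepts scalars or arrays; every dimension must be strictly positive.
    The result always lies between ``min(dim_a, dim_b)`` and
    ``max(dim_a, dim_b)``.
    """
    a = np.asarray(dim_a, dtype=float)
    b = np.asarray(dim_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("shell dimensions must be strictly positive")
    out = np.sqrt(a * b)
    return float(out) if out.ndim == 0 else out


def log2_size(geomean):
    """log2 of a geometric-mean size in mm; the analysis scale for shell size."""
    g = np.asarray(geomean, dtype=float)
    if np.any(g <= 0):
        raise ValueError("geometric-mean size must be strictly positive")
    out = np.log2(g)
    return float(out) if out.ndim == 0 else out


def compute_measured_sizes(specimens: pd.DataFrame) -> pd.DataFrame:
    """Attach ``size_log2`` and ``provenance`` for measured specimens.

    Unmeasured rows get ``size_log2 = NaN`` and an empty provenance; run
    :func:`impute_sizes` afterwards to fill them.
    """
    df = specimens.copy()
    df["size_log2"] = np.nan
    df["provenance"] = ""
    m = df["measured"].to_numpy(bool)
    if m.any():
        sizes = log2_size(
            geometric_mean_size(df.loc[m, "dim_a"].to_numpy(), df.loc[m, "dim_b"].to_numpy())
        )
        df.loc[m, "size_log2"] = sizes
        df.loc[m, "provenance"] = "measured"
    return df


def impute_sizes(specimens: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill sizes of unmeasured specimens by the species-mean hierarchy.

    For each unmeasured specimen of species *s* in sample *v*:

    1. if measured conspecifics exist in *v*, use their mean ``size_log2``
       (``imputed_same_sample``);
    2. else find the nearest sampled level below and the nearest above that
       contain measured conspecifics and average the two per-sample species
       means — or use one side alone if only one exists
       (``imputed_adjacent``);
    3. else mark the record ``dropped``; it is excluded downstream.

    Means are arithmetic means on the log2 scale.  Measured values are never
    altered.  Returns the augmented table and a count per provenance.
    """
    df = specimens.copy()
    if "size_log2" not in df.columns or "provenance" not in df.columns:
        df = compute_measured_sizes(df)

    # per (taxon, sample) mean of measured sizes, with the sample's height
    measured = df[df["provenance"] == "measured"]
    sp_means = (
        measured.groupby(["taxon", "sample_id"])
        .agg(mean_size=("size_log2", "mean"), strat_height=("strat_height", "first"))
        .reset_index()
    )
    by_taxon: dict[str, pd.DataFrame] = {
        t: g.sort_values("strat_height") for t, g in sp_means.groupby("taxon")
    }
    same_sample = {
        (r.taxon, r.sample_id): r.mean_size for r in sp_means.itertuples()
    }

    todo = df.index[df["provenance"] == ""]
    for i in todo:
        taxon = df.at[i, "taxon"]
        sid = df.at[i, "sample_id"]
        key = (taxon, sid)
        if key in same_sample:
            df.at[i, "size_log2"] = same_sample[key]
            df.at[i, "provenance"] = "imputed_same_sample"
            continue
        g = by_taxon.get(taxon)
        if g is None:
            df.at[i, "provenance"] = "dropped"
            continue
        h = df.at[i, "strat_height"]
        below = g[g["strat_height"] < h]
        above = g[g["strat_height"] > h]
        sides = []
        if len(below):
            sides.append(below["mean_size"].iloc[-1])  # nearest below
        if len(above):
            sides.append(above["mean_size"].iloc[0])  # nearest above
        if sides:
            df.at[i, "size_log2"] = float(np.mean(sides))
            df.at[i, "provenance"] = "imputed_adjacent"
        else:
            df.at[i, "provenance"] = "dropped"

    counts = Counter(df["provenance"])
    return df, {p: int(counts.get(p, 0)) for p in PROVENANCES}


def retained(specimens: pd.DataFrame) -> pd.DataFrame:
    """Rows carrying a usable size (everything not ``dropped``)."""
    if "provenance" not in specimens.columns:
        raise ValueError("run impute_sizes first")
    return specimens[specimens["provenance"].isin(PROVENANCES[:3])]


def imputed_fraction(specimens: pd.DataFrame) -> float:
    """Proportion of retained specimens whose size was imputed (either step)."""
    kept = retained(specimens)
    if len(kept) == 0:
        raise ValueError("no retained specimens; imputed fraction is undefined")
    n_imp = int(kept["provenance"].isin(PROVENANCES[1:3]).sum())
    return n_imp / len(kept)
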