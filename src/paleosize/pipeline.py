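"""End-to-end analysis orchestration.

Ties the modules together in the order of the study design: load (or take)
specimen, isotope and level tables; keep bivalves and brachiopods; compute
and impute shell sizes; build per-group mean-size trajectories and the
percent-larger-individuals series; screen and aggregate the isotope data
into a temperature series; then run the lag-aware GLS correlation procedure
to produce two report tables — size against percent-larger (composition
report) and size / percent-larger against d18O at lag 0 and lag 1
(temperature report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, io, size, thermometry
from .simulate import SyntheticDataset
from .timeseries import PipelineConfig, run_correlation_pipeline

__all__ = ["AnalysisOptions", "AnalysisResult", "analyze", "write_results", "summarize"]

logger = logging.getLogger("paleosize")


@dataclass(frozen=True)
class AnalysisOptions:
    """Run-level switches: groups, lags, filter and statistical thresholds."""

    groups: tuple[str, ...] = ("all", "bivalves", "brachiopods")
    lags: tuple[int, ...] = (0, 1)
    min_per_level: int = 3
    min_levels: int = 3
    common_rule: str = "per_level"
    thermometer: thermometry.ThermometerParams = field(
        default_factory=thermometry.ThermometerParams
    )
    stats: PipelineConfig = field(default_factory=PipelineConfig)


@dataclass
class AnalysisResult:
    """All tables produced by one analysis run."""

    size_series: dict[str, pd.DataFrame]
    pct_series: dict[str, pd.DataFrame]
    isotope_series: pd.DataFrame
    size_classes: pd.DataFrame
    composition_report: pd.DataFrame  # size ~ percent-larger, per group
    temperature_report: pd.DataFrame  # size / pct ~ d18O, per group and lag
    counts: dict[str, int]
    levels: pd.DataFrame


def _level_series(series_df: pd.DataFrame, order: pd.Index) -> pd.Series:
    s = series_df.set_index("sample_id")["value"]
    return s.reindex(order)


def analyze(
    specimens: pd.DataFrame,
    isotopes: pd.DataFrame,
    levels: pd.DataFrame,
    options: AnalysisOptions = AnalysisOptions(),
) -> AnalysisResult:
    """Run the complete analysis on validated tables."""
    levels = levels.sort_values("strat_height", ignore_index=True)
    order = pd.Index(levels["sample_id"])

    specimens, n_rare = io.drop_rare_groups(specimens)
    sized, prov_counts = size.impute_sizes(size.compute_measured_sizes(specimens))
    counts = {"dropped_rare_clades": n_rare, **prov_counts}
    counts["retained"] = len(size.retained(sized))
    counts["imputed_fraction"] = (
        size.imputed_fraction(sized) if counts["retained"] else float("nan")
    )
    logger.info("specimens: %s", counts)

    size_series = {g: community.sample_mean_size(sized, g) for g in options.groups}
    common = community.common_species(
        sized, options.min_per_level, options.min_levels, options.common_rule
    )
    classes = community.classify_species_size(sized, common)
    counts["common_species"] = len(common)
    counts["larger_species"] = int((classes["size_class"] == "larger").sum())
    counts["smaller_species"] = int((classes["size_class"] == "smaller").sum())
    pct_series = {g: community.percent_larger(sized, classes, g) for g in options.groups}

    screened = thermometry.screen_measurements(isotopes)
    counts["isotopes_rejected"] = int((~screened["accepted"]).sum())
    iso_series = thermometry.aggregate_isotopes(screened, levels, options.thermometer)
    d18o = iso_series.set_index("sample_id")["d18O_mean"].reindex(order)

    comp_rows = []
    for g in options.groups:
        resp = _level_series(size_series[g], order)
        pred = _level_series(pct_series[g], order)
        res = run_correlation_pipeline(
            resp, pred, lag=0, config=options.stats, label=f"size~pct_larger {g}"
        )
        comp_rows.append(res.as_row())
    composition_report = pd.DataFrame(comp_rows)

    temp_rows = []
    for resp_kind, series_by_group in (("size", size_series), ("pct_larger", pct_series)):
        for g in options.groups:
            resp = _level_series(series_by_group[g], order)
            for lag in options.lags:
                res = run_correlation_pipeline(
                    resp, d18o, lag=lag, config=options.stats,
                    label=f"{resp_kind} {g}",
                )
                row = res.as_row()
                row["response"] = resp_kind
                temp_rows.append(row)
    temperature_report = pd.DataFrame(temp_rows)

    return AnalysisResult(
        size_series=size_series,
        pct_series=pct_series,
        isotope_series=iso_series,
        size_classes=classes,
        composition_report=composition_report,
        temperature_report=temperature_report,
        counts=counts,
        levels=levels,
    )


def analyze_paths(
    specimens_path, isotopes_path, levels_path=None,
    options: AnalysisOptions = AnalysisOptions(),
    column_map=None,
) -> AnalysisResult:
    """Read the input CSVs and run :func:`analyze`."""
    specimens = io.read_specimens(specimens_path, column_map=column_map)
    isotopes = io.read_isotopes(isotopes_path)
    if levels_path is not None:
        levels = io.read_levels(levels_path)
    else:
        levels = io.levels_from_specimens(specimens)
    return analyze(specimens, isotopes, levels, options)


def analyze_dataset(
    dataset: SyntheticDataset, options: AnalysisOptions = AnalysisOptions()
) -> AnalysisResult:
    """Run the analysis on an in-memory synthetic dataset."""
    specimens = io.validate_specimens(dataset.specimens)
    return analyze(specimens, dataset.isotopes, dataset.levels, options)


# ---------------------------------------------------------------------------
# persistence and reporting

_SERIES_COLS = ["sample_id", "strat_height", "value", "q1", "q3", "n"]


def write_results(result: AnalysisResult, outdir: str | os.PathLike) -> list[Path]:
    """Write every result table as CSV plus a JSON counts file; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, columns=None):
        p = out / name
        df.to_csv(p, index=False, columns=columns)
        written.append(p)

    for g, df in result.size_series.items():
        smoothed = community.moving_average_3(df)
        df = df.assign(ma3=smoothed["value"])
        _write(df, f"size_series_{g}.csv")
    for g, df in result.pct_series.items():
        smoothed = community.moving_average_3(df)
        df = df.assign(ma3=smoothed["value"])
        _write(df, f"pct_larger_series_{g}.csv")
    _write(result.isotope_series, "isotope_series.csv")
    classes = result.size_classes.copy()
    classes["cutoff"] = result.size_classes.attrs.get("cutoff", np.nan)
    _write(classes, "size_classes.csv")
    _write(result.composition_report, "composition_report.csv")
    _write(result.temperature_report, "temperature_report.csv")
    _write(result.levels, "levels.csv")
    p = out / "counts.json"
    p.write_text(json.dumps(result.counts, indent=2, default=float))
    written.append(p)
    return written


def checksum_manifest(paths: list[Path], extra: dict | None = None) -> dict:
    """SHA-256 checksums of written files, for reproducibility manifests."""
    manifest = {"files": {}}
    for p in paths:
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    if extra:
        manifest.update(extra)
    return manifest


def summarize(outdir: str | os.PathLike) -> str:
    """Build a human-readable markdown summary from a written results directory.

    Every number is re-read from the CSVs produced by :func:`write_results`;
    nothing is recomputed from raw data.
    """
    out = Path(outdir)
    required = ["levels.csv", "size_classes.csv", "counts.json", "temperature_report.csv"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"analysis outputs missing from {out}: {missing}")

    levels = pd.read_csv(out / "levels.csv")
    counts = json.loads((out / "counts.json").read_text())
    classes = pd.read_csv(out / "size_classes.csv")
    comp = pd.read_csv(out / "composition_report.csv")
    temp = pd.read_csv(out / "temperature_report.csv")

    lines = ["# Analysis summary", ""]
    lines.append(
        f"Specimens retained: {counts.get('retained')} "
        f"(imputed fraction {counts.get('imputed_fraction', float('nan')):.3f}); "
        f"{counts.get('dropped_rare_clades')} rare-clade records excluded."
    )
    n_larger = int((classes["size_class"] == "larger").sum())
    n_smaller = int((classes["size_class"] == "smaller").sum())
    lines.append(
        f"Common species: {len(classes)} ({n_larger} larger-sized / "
        f"{n_smaller} smaller-sized; cutoff "
        f"{classes['cutoff'].iloc[0]:.3f} log2 mm)."
    )
    lines.append("")

    in_event_ids = set(levels.loc[levels["in_event"].astype(bool), "sample_id"].astype(str))
    if in_event_ids:
        lines.append("## Mean shell size inside vs. outside the event interval")
        for f in sorted(out.glob("size_series_*.csv")):
            s = pd.read_csv(f, dtype={"sample_id": str})
            inside = s[s["sample_id"].isin(in_event_ids)]["value"]
            outside = s[~s["sample_id"].isin(in_event_ids)]["value"]
            if len(inside) and len(outside):
                group = f.stem.replace("size_series_", "")
                lines.append(
                    f"- {group}: {inside.mean():.3f} (event) vs "
                    f"{outside.mean():.3f} (outside); change "
                    f"{inside.mean() - outside.mean():+.3f} log2 mm"
                )
        lines.append("")

    def _table(df: pd.DataFrame, title: str) -> list[str]:
        rows = [f"## {title}", "",
                "| group | lag | ARIMA(p,d,q) | p-value | correlation | resid. SE | differenced |",
                "|---|---|---|---|---|---|---|"]
        for r in df.itertuples():
            resp = getattr(r, "response", None)
            label = f"{resp} {r.group}" if resp else r.group
            rows.append(
                f"| {label} | {r.lag} | ({r.p},{r.d},{r.q}) | {r.p_value:.3f} "
                f"| {r.correlation:.3f} | {r.residual_std_error:.3f} | {r.differenced} |"
            )
        rows.append("")
        return rows

    lines += _table(comp, "GLS: shell size ~ percent larger-sized individuals")
    lines += _table(temp, "GLS: faunal series ~ d18O")
    return "\n".join(lines)
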