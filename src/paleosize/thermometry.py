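"""Oxygen-isotope palaeothermometry of shell calcite.

Measurements are first screened for diagenetic alteration using trace-element
thresholds (Mn/Ca > 0.1 mmol/mol or Fe/Ca > 1 mmol/mol rejects a sample),
then aggregated per sampled level, and converted to temperature with the
brachiopod calcite thermometer

    T (degC) = 16.192 - 3.468 * (d18O_calcite - d18O_seawater - Mg_calcite)

with d18O_calcite in permil V-PDB and the ambient seawater composition
assumed constant at -1 permil V-SMOW.  The Mg term is a pass-through permil
offset (default 0: at the ~0.4 wt% MgCO3 typical of these shells its effect
on temperature is negligible, and it cancels entirely from temperature
*change*).  Relative warming/cooling (``delta_T`` against the lowermost
sample of the profile) is the analysis quantity and is invariant to both
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThermometerParams",
    "screen_measurement",
    "screen_measurements",
    "calcite_temperature",
    "aggregate_isotopes",
]


@dataclass(frozen=True)
class ThermometerParams:
    """Calibration constants of the calcite oxygen-isotope thermometer.

    ``intercept`` (degC) and ``slope`` (degC per permil) are the published
    calibration and should normally not be overridden; ``d18O_seawater``
    (permil V-SMOW) and ``mg_term`` (permil-equivalent offset for shell Mg
    content) are setting-specific assumptions.
    """

    d18O_seawater: float = -1.0
    mg_term: float = 0.0
    intercept: float = 16.192
    slope: float = -3.468


#: Screening thresholds (mmol/mol) above which calcite is taken as altered.
MN_CA_MAX = 0.1
FE_CA_MAX = 1.0


def screen_measurement(
    mn_ca: float | None,
    fe_ca: float | None,
    mn_max: float = MN_CA_MAX,
    fe_max: float = FE_CA_MAX,
    missing_passes: bool = True,
) -> bool:
    """Accept or reject one measurement on its element/Ca ratios.

    Rejection requires *exceeding* a threshold: a ratio exactly at the
    threshold passes.  Ratios that were not determined pass by default
    (``missing_passes=False`` rejects them instead).
    """
    accepted = True
    for value, limit in ((mn_ca, mn_max), (fe_ca, fe_max)):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if not missing_passes:
                accepted = False
            continue
        if value < 0:
            raise ValueError("element/Ca ratios cannot be negative")
        if value > limit:
            accepted = False
    return accepted


def screen_measurements(
    isotopes: pd.DataFrame,
    mn_max: float = MN_CA_MAX,
    fe_max: float = FE_CA_MAX,
    missing_passes: bool = True,
) -> pd.DataFrame:
    """Vectorised screening; adds/overwrites the boolean ``accepted`` column."""
    df = isotopes.copy()
    mn = df.get("mn_ca", pd.Series(np.nan, index=df.index)).astype(float)
    fe = df.get("fe_ca", pd.Series(np.nan, index=df.index)).astype(float)
    if (mn.dropna() < 0).any() or (fe.dropna() < 0).any():
        raise ValueError("element/Ca ratios cannot be negative")
    ok = pd.Series(True, index=df.index)
    ok &= ~(mn > mn_max)
    ok &= ~(fe > fe_max)
    if not missing_passes:
        ok &= mn.notna() & fe.notna()
    df["accepted"] = ok
    return df


def calcite_temperature(d18O_calcite, params: ThermometerParams = ThermometerParams()):
    """Seawater temperature (degC) recorded by shell calcite d18O (permil V-PDB)."""
    d = np.asarray(d18O_calcite, dtype=float)
    out = params.intercept + params.slope * (d - params.d18O_seawater - params.mg_term)
    return float(out) if out.ndim == 0 else out


def aggregate_isotopes(
    isotopes: pd.DataFrame,
    levels: pd.DataFrame,
    params: ThermometerParams = ThermometerParams(),
) -> pd.DataFrame:
    """Per-level isotope means, uncertainties and derived temperatures.

    Only ``accepted`` measurements enter (run :func:`screen_measurements`
    first; a missing ``accepted`` column takes every row).  For each level:
    mean d18O and d13C, their double standard errors (2 * sd/sqrt(n), with
    the n-1 sd denominator; absent when n = 1), the specimen count, the
    temperature implied by the mean d18O, and ``delta_T`` relative to the
    lowermost sample of the profile.  Levels without accepted measurements
    are omitted; an entirely empty result is an error.
    """
    df = isotopes
    if "accepted" in df.columns:
        df = df[df["accepted"]]
    if len(df) == 0:
        raise ValueError("no accepted isotope measurements")

    def _two_se(s: pd.Series) -> float:
        n = s.notna().sum()
        if n < 2:
            return np.nan
        return 2.0 * s.std(ddof=1) / np.sqrt(n)

    agg = (
        df.groupby("sample_id")
        .agg(
            d18O_mean=("d18O", "mean"),
            d18O_2se=("d18O", _two_se),
            d13C_mean=("d13C", "mean"),
            d13C_2se=("d13C", _two_se),
            n=("d18O", "size"),
        )
        .reset_index()
    )
    out = levels[["sample_id", "strat_height"]].merge(agg, on="sample_id", how="inner")
    out = out.sort_values("strat_height", ignore_index=True)
    if len(out) == 0:
        raise ValueError("no isotope measurements match the level table")
    out["temperature"] = calcite_temperature(out["d18O_mean"].to_numpy(), params)
    out["delta_T"] = out["temperature"] - out["temperature"].iloc[0]
    return out
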