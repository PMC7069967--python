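"""Synthetic fossil-community and isotope series generator.

Emulates the statistical structure the analysis assumes: an ordered
stratigraphic section of ~30 sampled levels whose d18O series carries a
negative excursion interval (warmer bottom water), a two-clade species pool
with species-specific mean shell sizes, per-level multinomial abundances
whose weights shift against larger species as temperature rises
(composition effect, ``beta_abund``), optional within-species size
plasticity (``beta_size``), lognormal within-species dimension noise, and a
configurable fraction of specimens without direct measurements.

The two mechanisms are separable: a ``beta_size``-only run shrinks sizes
within species while the larger-species share stays flat, a
``beta_abund``-only run shifts the larger-species share while within-species
sizes stay put.  Regeneration with the same config and seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .thermometry import ThermometerParams, calcite_temperature

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_isotopes",
    "simulate_community",
    "apply_missingness",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    The defaults describe a section comparable in scope to a bed-by-bed
    sampled epicontinental TOAE record: 30 levels 1 m apart, an excursion
    spanning levels 10-19, a -1 permil d18O excursion over a -1 permil
    baseline (~3.5 degC of warming), ~115 individuals and 4 isotope
    specimens per level, a 20-species pool, and 30% of specimens left
    unmeasured.
    """

    n_levels: int = 30
    level_spacing: float = 1.0  # m
    excursion_start: int = 10  # first level index inside the excursion
    excursion_end: int = 20  # one past the last level inside
    d18o_baseline: float = -1.0  # permil V-PDB
    d18o_amplitude: float = -1.0  # permil, negative = warming
    d18o_level_sd: float = 0.1  # smooth level-to-level geological noise, permil
    d18o_obs_sd: float = 0.15  # per-specimen observation noise, permil
    isotope_specimens_per_level: int = 4
    n_bivalve_species: int = 13
    n_brachiopod_species: int = 7
    species_mean_log2: float = 3.5  # pool mean of species mean sizes, log2 mm
    species_sd_log2: float = 1.0  # spread of species mean sizes
    within_species_sd: float = 0.45  # within-species size sd, log2 mm
    individuals_per_level: int = 115
    beta_abund: float = -0.25  # log-weight change per degC per log2-size deviation
    beta_size: float = -0.03  # within-species log2-size change per degC
    missing_fraction: float = 0.3
    exact_missing: bool = True
    thermometer: ThermometerParams = field(default_factory=ThermometerParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 4:
            raise ValueError("n_levels must be at least 4")
        if not (0 <= self.excursion_start < self.excursion_end <= self.n_levels):
            raise ValueError("excursion window must lie inside the section")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        for name in ("d18o_level_sd", "d18o_obs_sd", "species_sd_log2", "within_species_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_bivalve_species + self.n_brachiopod_species < 1:
            raise ValueError("species pool is empty")


@dataclass
class SyntheticDataset:
    """A generated dataset plus the generating truth."""

    specimens: pd.DataFrame
    isotopes: pd.DataFrame
    levels: pd.DataFrame  # includes d18O_true, temperature_true, in_event
    species: pd.DataFrame  # taxon, clade, mean_log2, base_logw, aspect
    config: SimulationConfig


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:02d}" for i in range(n)]


def simulate_isotopes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-specimen isotope measurements and the true level table.

    The true per-level d18O is baseline + amplitude inside the excursion
    window plus smoothed (AR(1), lag weight 0.5) level noise; each of the
    per-level specimens observes it with independent Gaussian noise.  True
    temperature follows the thermometer equation.  Returns
    ``(isotopes, levels)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_levels
    ids = _sample_ids(n)
    heights = np.arange(n, dtype=float) * config.level_spacing
    in_event = np.zeros(n, dtype=bool)
    in_event[config.excursion_start: config.excursion_end] = True

    noise = np.zeros(n)
    if config.d18o_level_sd > 0:
        e = rng.normal(0.0, 1.0, size=n)
        for t in range(1, n):
            noise[t] = 0.5 * noise[t - 1] + e[t]
        noise = noise * config.d18o_level_sd / np.sqrt(1.0 / (1.0 - 0.25))
        noise[0] = e[0] * config.d18o_level_sd
    d18o_true = config.d18o_baseline + config.d18o_amplitude * in_event + noise
    temp_true = calcite_temperature(d18o_true, config.thermometer)

    rows = []
    substrates = ("rhynchonellid", "oyster")
    for i, sid in enumerate(ids):
        for j in range(config.isotope_specimens_per_level):
            rows.append(
                {
                    "sample_id": sid,
                    "substrate": substrates[int(rng.integers(0, 2))],
                    "d18O": d18o_true[i] + rng.normal(0.0, config.d18o_obs_sd),
                    "d13C": rng.normal(1.0, 0.2) - 3.0 * in_event[i],
                    "mn_ca": float(rng.uniform(0.0, 0.08)),
                    "fe_ca": float(rng.uniform(0.0, 0.8)),
                }
            )
    isotopes = pd.DataFrame(rows)
    levels = pd.DataFrame(
        {
            "sample_id": ids,
            "strat_height": heights,
            "label": "",
            "in_event": in_event,
            "d18O_true": d18o_true,
            "temperature_true": temp_true,
        }
    )
    return isotopes, levels


def _species_pool(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_bi, n_br = config.n_bivalve_species, config.n_brachiopod_species
    taxa = [f"Bivalvia sp. {i + 1}" for i in range(n_bi)] + [
        f"Brachiopoda sp. {i + 1}" for i in range(n_br)
    ]
    clades = ["bivalve"] * n_bi + ["brachiopod"] * n_br
    mean_log2 = rng.normal(config.species_mean_log2, config.species_sd_log2, len(taxa))
    base_logw = rng.normal(0.0, 0.5, len(taxa))  # uneven base abundances
    aspect = np.exp(rng.normal(0.3, 0.15, len(taxa)))  # dim_a : dim_b ratio
    return pd.DataFrame(
        {
            "taxon": taxa,
            "clade": clades,
            "mean_log2": mean_log2,
            "base_logw": base_logw,
            "aspect": aspect,
        }
    )


def simulate_community(
    config: SimulationConfig,
    levels: pd.DataFrame,
    rng: np.random.Generator | None = None,
    species: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw specimen records given per-level true temperatures.

    Species weights per level are softmax of
    ``base + beta_abund * (T - T_ref) * (species mean size - pool mean)``
    with ``T_ref`` the temperature at the baseline d18O, so warming
    depresses large species when ``beta_abund < 0`` while the per-level
    total stays fixed.  Individual log2 sizes are Gaussian around
    ``species mean + beta_size * (T - T_ref)``; the two shell dimensions
    realise that geometric-mean size at a species-specific aspect ratio.
    Returns ``(specimens, species)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if species is None:
        species = _species_pool(config, rng)
    if len(species) == 0:
        raise ValueError("species pool is empty")

    t_ref = calcite_temperature(config.d18o_baseline, config.thermometer)
    pool_mean = float(species["mean_log2"].mean())
    dev = species["mean_log2"].to_numpy() - pool_mean

    rows = []
    counter = 0
    for lvl in levels.itertuples():
        dT = lvl.temperature_true - t_ref
        logw = species["base_logw"].to_numpy() + config.beta_abund * dT * dev
        w = np.exp(logw - logw.max())
        w /= w.sum()
        counts = rng.multinomial(config.individuals_per_level, w)
        for s_idx, c in enumerate(counts):
            if c == 0:
                continue
            sp = species.iloc[s_idx]
            mu = sp["mean_log2"] + config.beta_size * dT
            sizes = rng.normal(mu, config.within_species_sd, size=c)
            geomean = np.exp2(sizes)
            dim_a = geomean * np.sqrt(sp["aspect"])
            dim_b = geomean / np.sqrt(sp["aspect"])
            if sp["clade"] == "bivalve":
                valves = rng.choice(["left", "right", "articulated"], size=c)
            else:
                valves = rng.choice(["dorsal", "ventral", "articulated"], size=c)
            for k in range(c):
                rows.append(
                    {
                        "specimen_id": f"SP{counter:05d}",
                        "sample_id": lvl.sample_id,
                        "strat_height": lvl.strat_height,
                        "taxon": sp["taxon"],
                        "clade": sp["clade"],
                        "valve": valves[k],
                        "dim_a": dim_a[k],
                        "dim_b": dim_b[k],
                        "measured": True,
                    }
                )
                counter += 1
    return pd.DataFrame(rows), species


def apply_missingness(
    specimens: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator | None = None,
    exact: bool = True,
    protect_species: bool = True,
) -> pd.DataFrame:
    """Hide the dimensions of a random subset of specimens.

    Chosen rows get ``measured = False`` and NaN dimensions.  ``exact``
    masks exactly ``round(fraction * n)`` rows (deterministic count);
    otherwise each row is masked independently with probability
    ``fraction``.  With ``protect_species`` (default) one specimen per
    species is kept measured whenever the species has any specimen at all,
    so no species loses every direct measurement.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    df = specimens.reset_index(drop=True).copy()
    n = len(df)
    if n == 0 or fraction == 0.0:
        return df

    protected = np.zeros(n, dtype=bool)
    if protect_species:
        keep_idx = df.groupby("taxon", sort=True).apply(
            lambda g: g.index[rng.integers(0, len(g))], include_groups=False
        )
        protected[np.asarray(keep_idx, dtype=int)] = True

    eligible = np.flatnonzero(~protected)
    if exact:
        k = min(int(round(fraction * n)), len(eligible))
        mask_idx = rng.choice(eligible, size=k, replace=False)
    else:
        draw = rng.random(n) < fraction
        mask_idx = np.flatnonzero(draw & ~protected)
    df.loc[mask_idx, "measured"] = False
    df.loc[mask_idx, ["dim_a", "dim_b"]] = np.nan
    return df


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete dataset (isotopes, community, missingness, truth)."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    isotopes, levels = simulate_isotopes(config, rng)
    specimens, species = simulate_community(config, levels, rng)
    specimens = apply_missingness(
        specimens, config.missing_fraction, rng, exact=config.exact_missing
    )
    return SyntheticDataset(
        specimens=specimens,
        isotopes=isotopes,
        levels=levels,
        species=species,
        config=config,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a config (incl. thermometer) to plain scalars for serialisation."""
    d = asdict(config)
    d["thermometer"] = asdict(config.thermometer)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    thermo = d.pop("thermometer", None)
    cfg = SimulationConfig(**d)
    if thermo:
        cfg = replace(cfg, thermometer=ThermometerParams(**thermo))
    return cfg
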