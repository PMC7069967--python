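import numpy as np
import pandas as pd
import pytest

from paleosize.simulate import SimulationConfig, simulate_dataset


def make_specimens(rows):
    """Build a specimen table from compact tuples.

    Each row: (sample_id, strat_height, taxon, clade, dim_a, dim_b) with
    dims None for unmeasured specimens.
    """
    recs = []
    for i, (sid, h, taxon, clade, a, b) in enumerate(rows):
        recs.append(
            {
                "specimen_id": f"sp{i}",
                "sample_id": sid,
                "strat_height": float(h),
                "taxon": taxon,
                "clade": clade,
                "valve": "articulated",
                "dim_a": np.nan if a is None else float(a),
                "dim_b": np.nan if b is None else float(b),
                "measured": a is not None,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study conditions (seed 0)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size configuration for fast I/O and CLI round trips."""
    return SimulationConfig(
        n_levels=16,
        excursion_start=5,
        excursion_end=11,
        individuals_per_level=40,
        isotope_specimens_per_level=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
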