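import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleosize import community, size
from paleosize.simulate import (
    SimulationConfig,
    apply_missingness,
    simulate_community,
    simulate_dataset,
    simulate_isotopes,
)


def _event_change(cfg, column="size_log2"):
    """In-event minus out-of-event mean of per-level community means."""
    ds = simulate_dataset(cfg)
    sized, _ = size.impute_sizes(size.compute_measured_sizes(ds.specimens))
    series = community.sample_mean_size(sized, "all")
    in_ids = set(ds.levels.loc[ds.levels["in_event"], "sample_id"])
    inside = series[series["sample_id"].isin(in_ids)]["value"]
    outside = series[~series["sample_id"].isin(in_ids)]["value"]
    return inside.mean() - outside.mean(), ds, sized


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_levels": 3},
            {"excursion_start": 25, "excursion_end": 20},
            {"excursion_end": 99},
            {"missing_fraction": 1.0},
            {"within_species_sd": -0.1},
            {"n_bivalve_species": 0, "n_brachiopod_species": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateIsotopes:
    def test_no_amplitude_no_noise_is_constant(self):
        cfg = SimulationConfig(
            d18o_amplitude=0.0, d18o_level_sd=0.0, d18o_obs_sd=0.0, seed=1
        )
        iso, levels = simulate_isotopes(cfg)
        assert np.allclose(iso["d18O"], cfg.d18o_baseline)
        assert np.allclose(levels["d18O_true"], cfg.d18o_baseline)

    def test_excursion_amplitude_recovered(self):
        cfg = SimulationConfig(seed=2)
        iso, levels = simulate_isotopes(cfg)
        per_level = iso.groupby("sample_id")["d18O"].mean()
        in_ids = levels.loc[levels["in_event"], "sample_id"]
        out_ids = levels.loc[~levels["in_event"], "sample_id"]
        shift = per_level[in_ids].mean() - per_level[out_ids].mean()
        # 2 SE of the contrast, dominated by the smoothed level noise
        assert shift == pytest.approx(cfg.d18o_amplitude, abs=0.2)

    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(seed=3)
        a_iso, a_lv = simulate_isotopes(cfg)
        b_iso, b_lv = simulate_isotopes(cfg)
        pd.testing.assert_frame_equal(a_iso, b_iso)
        pd.testing.assert_frame_equal(a_lv, b_lv)


class TestSimulateCommunity:
    def test_individuals_per_level_exact(self, small_dataset, small_config):
        counts = small_dataset.specimens.groupby("sample_id").size()
        assert (counts == small_config.individuals_per_level).all()

    def test_null_generator_sizes_equal_across_event(self):
        """With both effects off, in/out-of-event sizes differ only by chance."""
        cfg0 = dict(
            n_levels=20, excursion_start=7, excursion_end=13,
            individuals_per_level=40, beta_abund=0.0, beta_size=0.0,
            missing_fraction=0.0,
        )
        nonsig = 0
        reps = 100
        for s in range(reps):
            ds = simulate_dataset(SimulationConfig(seed=s, **cfg0))
            sized = size.compute_measured_sizes(ds.specimens)
            means = sized.groupby("sample_id")["size_log2"].mean()
            in_ids = set(ds.levels.loc[ds.levels["in_event"], "sample_id"])
            a = means[means.index.isin(in_ids)]
            b = means[~means.index.isin(in_ids)]
            nonsig += stats.ttest_ind(a, b).pvalue > 0.05
        assert nonsig >= 0.9 * reps

    def test_negative_abundance_effect_shrinks_event_sizes(self):
        change, _, _ = _event_change(SimulationConfig(seed=5))
        assert change < 0

    def test_empty_pool_is_error(self):
        cfg = SimulationConfig(seed=0)
        _, levels = simulate_isotopes(cfg)
        with pytest.raises(ValueError, match="pool"):
            simulate_community(cfg, levels, species=pd.DataFrame(
                columns=["taxon", "clade", "mean_log2", "base_logw", "aspect"]))


class TestMechanismSeparability:
    def _summaries(self, cfg):
        change, ds, sized = _event_change(cfg)
        common = community.common_species(sized)
        classes = community.classify_species_size(sized, common)
        pct = community.percent_larger(sized, classes)
        in_ids = set(ds.levels.loc[ds.levels["in_event"], "sample_id"])
        pct_change = (
            pct[pct["sample_id"].isin(in_ids)]["value"].mean()
            - pct[~pct["sample_id"].isin(in_ids)]["value"].mean()
        )
        # within-species size change, averaged over species present both in
        # and out of the event window
        sub = sized[sized["provenance"] == "measured"]
        per = sub.assign(inside=sub["sample_id"].isin(in_ids)).groupby(
            ["taxon", "inside"])["size_log2"].mean().unstack()
        per = per.dropna()
        within_change = float((per[True] - per[False]).mean())
        return pct_change, within_change

    def test_abundance_only_shifts_composition_not_within_species(self):
        pct_change, within = self._summaries(
            SimulationConfig(beta_size=0.0, seed=21)
        )
        assert pct_change < -10.0
        assert abs(within) < 0.06

    def test_plasticity_only_shifts_within_species_not_composition(self):
        pct_change, within = self._summaries(
            SimulationConfig(beta_abund=0.0, seed=22)
        )
        assert abs(pct_change) < 6.0
        assert within < -0.05


class TestApplyMissingness:
    def test_fraction_zero_is_identity(self, small_dataset):
        df = small_dataset.specimens
        out = apply_missingness(df, 0.0, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, df.reset_index(drop=True))

    def test_exact_count_masked(self):
        cfg = SimulationConfig(missing_fraction=0.0, seed=4)
        ds = simulate_dataset(cfg)
        n = len(ds.specimens)
        out = apply_missingness(ds.specimens, 0.3, np.random.default_rng(1))
        assert int((~out["measured"]).sum()) == round(0.3 * n)
        assert out.loc[~out["measured"], "dim_a"].isna().all()

    def test_binomial_count_near_fraction(self):
        cfg = SimulationConfig(missing_fraction=0.0, seed=4)
        ds = simulate_dataset(cfg)
        n = len(ds.specimens)
        out = apply_missingness(
            ds.specimens, 0.3, np.random.default_rng(2), exact=False
        )
        hidden = int((~out["measured"]).sum())
        assert abs(hidden - 0.3 * n) < 4 * np.sqrt(n * 0.3 * 0.7)

    def test_same_seed_same_mask(self, small_dataset):
        a = apply_missingness(small_dataset.specimens, 0.3, np.random.default_rng(9))
        b = apply_missingness(small_dataset.specimens, 0.3, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_every_species_keeps_one_measurement(self):
        cfg = SimulationConfig(missing_fraction=0.0, seed=4)
        ds = simulate_dataset(cfg)
        out = apply_missingness(ds.specimens, 0.9, np.random.default_rng(3))
        assert out.groupby("taxon")["measured"].any().all()


def test_dataset_regeneration_is_bit_identical(small_config):
    a = simulate_dataset(small_config)
    b = simulate_dataset(small_config)
    pd.testing.assert_frame_equal(a.specimens, b.specimens)
    pd.testing.assert_frame_equal(a.isotopes, b.isotopes)
    pd.testing.assert_frame_equal(a.levels, b.levels)
    pd.testing.assert_frame_equal(a.species, b.species)
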