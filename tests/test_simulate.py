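"""Synthetic-data generator: design, genetic architecture and round trips."""

import numpy as np
import pandas as pd
import pytest

from nutrieff.pedigree import additive_relationship
from nutrieff.phenotypes import derive_phenotypes
from nutrieff.simulate import (
    ConfigError,
    SimulationConfig,
    TraitSpec,
    back_generate_observables,
    default_config,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
    simulate_phenotypes,
)


def tiny_config(**kw):
    defaults = dict(
        seed=0, n_sires=1, n_dams=1, n_series=2,
        dams_per_litter_count=(1, 0, 0), litter_size_mean=2.0,
        n_grandsires=0, n_granddams=0,
        traits=(TraitSpec("pe", 0.39, 5.2e-4, 5.8e-6, 4.342e-4),),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPedigreeDesign:
    def test_single_litter_full_sibs(self):
        cfg = tiny_config(litter_size_mean=3.0)
        ped, litters = simulate_pedigree(cfg, np.random.default_rng(5))
        assert len(litters) >= 2
        A = additive_relationship(ped)
        a, b = litters["animal_id"].iloc[:2]
        assert A.loc(a, b) == pytest.approx(0.5)
        assert A.loc(a, a) == pytest.approx(1.0)

    def test_default_scale(self):
        cfg = default_config(1)
        ped, litters = simulate_pedigree(cfg)
        # ~118 litters with mean size 9.08 -> about 1071 offspring
        assert abs(len(litters) - 1071) < 140
        assert len(ped) <= 1600
        assert ped.depth == 3
        assert litters["series"].nunique() == 14

    def test_litter_count_distribution(self):
        cfg = default_config(2)
        _, litters = simulate_pedigree(cfg)
        per_dam = litters.groupby("dam")["litter_id"].nunique().value_counts()
        assert per_dam.get(1, 0) == 48
        assert per_dam.get(2, 0) == 23
        assert per_dam.get(3, 0) == 8

    def test_determinism(self):
        ds1 = simulate_dataset(seed=7)
        ds2 = simulate_dataset(seed=7)
        assert ds1.pedigree.ids == ds2.pedigree.ids
        pd.testing.assert_frame_equal(ds1.records, ds2.records)
        pd.testing.assert_frame_equal(ds1.sensory, ds2.sensory)

    def test_infeasible_design_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_dams=5, dams_per_litter_count=(1, 1, 1))


class TestBreedingValues:
    def test_zero_genetic_variance(self, trio):
        bv = simulate_breeding_values(trio, np.zeros((1, 1)),
                                      np.random.default_rng(0))
        assert np.allclose(bv.to_numpy(), 0.0)

    def test_mendelian_sampling_variance(self):
        """Offspring of fixed non-inbred parents: deviation variance = V_A/2."""
        from nutrieff.pedigree import Pedigree, PedigreeRecord

        n_off = 10_000
        recs = [PedigreeRecord("s"), PedigreeRecord("d")]
        recs += [PedigreeRecord(f"o{i}", "s", "d") for i in range(n_off)]
        ped = Pedigree(recs)
        v_a = 2.5
        bv = simulate_breeding_values(ped, [[v_a]], np.random.default_rng(3))
        dev = bv.iloc[2:, 0].to_numpy() - 0.5 * (bv.iloc[0, 0] + bv.iloc[1, 0])
        assert dev.var() == pytest.approx(0.5 * v_a, rel=0.03)

    def test_founder_covariance_matches_G(self):
        from nutrieff.pedigree import Pedigree, PedigreeRecord

        n = 2000
        ped = Pedigree([PedigreeRecord(f"f{i}") for i in range(n)])
        G = np.array([[1.0, 0.6], [0.6, 2.0]])
        bv = simulate_breeding_values(ped, G, np.random.default_rng(4))
        emp = np.cov(bv.to_numpy().T)
        assert np.max(np.abs(emp - G)) < 0.15

    def test_non_psd_rejected(self, trio):
        with pytest.raises(ConfigError):
            simulate_breeding_values(trio, [[1.0, 2.0], [2.0, 1.0]],
                                     np.random.default_rng(0))


class TestPhenotypes:
    def test_pure_residual_variance(self):
        cfg = tiny_config(
            n_sires=5, n_dams=10, dams_per_litter_count=(10, 0, 0),
            litter_size_mean=20.0,
            traits=(TraitSpec("pe", 0.0, 0.0, 0.0, 1.0),),
        )
        rng = np.random.default_rng(6)
        ped, litters = simulate_pedigree(cfg, rng)
        bv = simulate_breeding_values(ped, cfg.covariance("a"), rng, ["pe"])
        ph = simulate_phenotypes(ped, litters, bv, cfg, rng)
        assert ph["pe"].var() == pytest.approx(1.0, rel=0.2)

    def test_full_sib_covariance(self):
        """Within-litter phenotypic covariance approximates V_A/2 + V_CE."""
        cfg = SimulationConfig(
            seed=0, n_sires=20, n_dams=40, n_series=4,
            dams_per_litter_count=(40, 0, 0), litter_size_mean=8.0,
            n_grandsires=0, n_granddams=0,
            traits=(TraitSpec("t", 0.0, 0.4, 0.2, 0.4, v_fixed=0.0),),
        )
        covs = []
        rng = np.random.default_rng(10)
        for _ in range(6):
            ped, litters = simulate_pedigree(cfg, rng)
            bv = simulate_breeding_values(ped, cfg.covariance("a"), rng, ["t"])
            ph = simulate_phenotypes(ped, litters, bv, cfg, rng)
            y = ph["t"] - ph["t"].mean()
            for _, grp in ph.assign(y=y).groupby("litter_id"):
                v = grp["y"].to_numpy()
                if v.size >= 2:
                    covs.append((np.sum(np.outer(v, v)) - np.sum(v * v))
                                / (v.size * (v.size - 1)))
        assert np.mean(covs) == pytest.approx(0.5 * 0.4 + 0.2, rel=0.2)

    def test_offspring_midparent_regression(self):
        """Slope of offspring on mid-parent phenotype approximates h2 (no litter)."""
        rng = np.random.default_rng(11)
        v_a, v_r = 0.5, 0.5
        h2 = v_a / (v_a + v_r)
        slopes = []
        from nutrieff.pedigree import Pedigree, PedigreeRecord

        for _ in range(30):
            n_fam = 150
            recs = ([PedigreeRecord(f"s{i}") for i in range(n_fam)]
                    + [PedigreeRecord(f"d{i}") for i in range(n_fam)]
                    + [PedigreeRecord(f"o{i}", f"s{i}", f"d{i}")
                       for i in range(n_fam)])
            ped = Pedigree(recs)
            bv = simulate_breeding_values(ped, [[v_a]], rng).to_numpy()[:, 0]
            y = bv + rng.normal(0, np.sqrt(v_r), bv.size)
            mid = 0.5 * (y[:n_fam] + y[n_fam:2 * n_fam])
            off = y[2 * n_fam:]
            slopes.append(np.polyfit(mid, off, 1)[0])
        assert np.mean(slopes) == pytest.approx(h2, abs=0.03)

    def test_missing_trait_config_rejected(self):
        cfg = tiny_config(traits=())
        rng = np.random.default_rng(0)
        ped, litters = simulate_pedigree(cfg, rng)
        with pytest.raises(ConfigError):
            simulate_phenotypes(ped, litters, pd.DataFrame(index=ped.ids), cfg, rng)


class TestAnimalModelRecovery:
    def test_univariate_heritability_recovered(self):
        """Fitting the animal model to generator output recovers the true h2."""
        from nutrieff.validation import recover_heritability

        truth, est = recover_heritability("adg", n_replicates=20, seed=303)
        mean = np.mean(est)
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert truth == pytest.approx(1.3e-3 / 2.9e-3)
        assert abs(mean - truth) <= max(2 * se, 0.03)


class TestBackGeneration:
    def test_round_trip_identity(self):
        """Deriving phenotypes from back-generated records reproduces the traits."""
        ds = simulate_dataset(seed=5)
        derived, qc = derive_phenotypes(
            ds.records.drop(columns=["flagged"]), ds.config.baseline
        )
        for col in ("pe", "phe", "adg", "adfi"):
            assert np.max(np.abs(derived[col].to_numpy()
                                 - ds.traits[col].to_numpy())) < 1e-8
        # fcr in derived output is the exact ratio identity
        assert np.allclose(derived["fcr"], derived["adfi"] / derived["adg"])

    def test_zero_pe_target_gives_equal_protein(self):
        ds = simulate_dataset(seed=2)
        traits = ds.traits.head(5).copy()
        traits["pe"] = 0.0
        rec = back_generate_observables(traits, ds.config, np.random.default_rng(0))
        derived, _ = derive_phenotypes(rec.drop(columns=["flagged"]),
                                       ds.config.baseline)
        assert np.allclose(derived["pe"], 0.0, atol=1e-12)

    def test_lean_mass_inversion(self):
        """Solving the protein equation: CP 4117.255 g at P=0.5 needs 40 kg lean."""
        ds = simulate_dataset(seed=2)
        rec = ds.records
        half_prop = rec["left_half_weight"] / rec["total_carcass_weight"]
        cp = -482.745 + 0.23 * rec["dxa_lean"] * half_prop
        lean_back = (cp + 482.745) / (0.23 * half_prop)
        assert np.allclose(lean_back, rec["dxa_lean"])
        assert (4117.255 + 482.745) / (0.23 * 0.5) == pytest.approx(40_000.0)


class TestCalibration:
    def test_default_pe_targets(self):
        """Default generator hits the configured PE mean and spread."""
        ds = simulate_dataset(seed=11)
        assert ds.traits["pe"].mean() == pytest.approx(0.39, abs=0.012)
        assert 0.03 < ds.traits["pe"].std() < 0.05

    def test_all_trait_means(self):
        ds = simulate_dataset(seed=13)
        for spec in ds.config.traits:
            mean = ds.traits[spec.name].mean()
            assert mean == pytest.approx(spec.mean, abs=4 * spec.sd_total / 10)

    def test_correlation_structure_propagates(self):
        ds = simulate_dataset(seed=17)
        r = np.corrcoef(ds.traits["pe"], ds.traits["phe"])[0, 1]
        assert 0.3 < r < 0.7  # target phenotypic correlation 0.53
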