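"""Simulator: founders, phenotypes, contributions, mating, full runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adaptscan.containers import GenotypeMatrix
from adaptscan.exceptions import ConfigurationError, ExtinctionError
from adaptscan.synthetic_experiment import (
    DEFAULT_NE,
    ExperimentConfig,
    GeneticArchitecture,
    Locus,
    TraitModel,
    contributions,
    make_transplant_phenotypes,
    residual_sd_for_h2,
    run_experiment,
    select_and_mate,
    simulate_blup_panel,
    simulate_founders,
    simulate_neutral_panel,
    simulate_phenotype,
    standard_architecture,
)


def one_locus_arch(freq=0.5, s_lime=0.0, s_tuff=0.0, beta=0.0, cls="NEUTRAL"):
    return GeneticArchitecture(
        [Locus("A01", 1000, freq, cls, {"limestone": s_lime, "tuff": s_tuff}, beta)]
    )


class TestConfig:
    def test_default_design_has_784_plants_per_generation(self, default_config):
        assert len(default_config.treatments) == 8
        assert default_config.plants_per_generation == 8 * 2 * 49

    def test_printed_effective_sizes_cover_all_treatments(self, default_config):
        assert set(DEFAULT_NE) == {t.label for t in default_config.treatments}
        assert all(21 <= ne <= 28 for ne in DEFAULT_NE.values())

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_plants=1), dict(n_replicates=0), dict(ne_per_treatment={"LHB": 1})],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ExperimentConfig(**kwargs)

    def test_architecture_invariants_enforced(self):
        with pytest.raises(ConfigurationError):  # AP needs opposite signs
            one_locus_arch(s_lime=0.3, s_tuff=0.3, cls="AP")
        with pytest.raises(ConfigurationError):  # neutral must be unselected
            one_locus_arch(s_lime=0.3, cls="NEUTRAL")
        with pytest.raises(ConfigurationError):  # founder freq in open interval
            one_locus_arch(freq=1.0)


class TestFounders:
    def test_sample_table_has_784_rows_for_generation_one(self, default_config):
        geno, samples = simulate_founders(
            default_config, standard_architecture(n_neutral=10)
        )
        assert len(samples) == 784
        assert (samples["generation"] == 1).all()
        assert geno.n_samples == 784

    def test_degenerate_founder_frequency_fixes_genotypes(self, default_config):
        geno, _ = simulate_founders(default_config, one_locus_arch(freq=1 - 1e-12))
        assert (geno.dosages == 2.0).all()

    def test_founder_frequency_matches_binomial_sampling(self):
        cfg = ExperimentConfig(
            soils=("limestone", "tuff"),
            herbivory_levels=(True,),
            pollination_modes=("bee",),
            n_plants=5000,
            ne_per_treatment={"LHB": 22, "THB": 21},
            rng_seed=11,
        )
        geno, _ = simulate_founders(cfg, one_locus_arch(freq=0.5))
        p_hat = geno.dosages.mean() / 2
        assert abs(p_hat - 0.5) < 0.02


class TestPhenotype:
    def test_zero_effects_give_intercept_exactly(self, default_config, rng):
        arch = one_locus_arch()
        geno, samples = simulate_founders(default_config, arch)
        trait = TraitModel(intercept=30.0, soil_main_effect={"limestone": 0, "tuff": 0},
                           residual_sd=0.0)
        out = simulate_phenotype(geno, samples, arch, trait, rng)
        assert np.allclose(out["open_flowers"], 30.0)

    def test_additive_effect_separates_dosage_classes_by_two(self, default_config, rng):
        arch = one_locus_arch(beta=1.0)
        geno, samples = simulate_founders(default_config, arch)
        trait = TraitModel(soil_main_effect={"limestone": 0, "tuff": 0},
                           residual_sd=0.0)
        out = simulate_phenotype(geno, samples, arch, trait, rng)
        by_dosage = out.groupby(geno.dosages[:, 0])["open_flowers"].mean()
        assert by_dosage[2.0] - by_dosage[0.0] == pytest.approx(2.0)

    def test_configured_heritability_is_realized(self):
        dosages, trait, beta = simulate_blup_panel(
            n_samples=2000, n_markers=100, h2=0.5, rng=np.random.default_rng(42)
        )
        genetic = (dosages - 1.0) @ beta
        ratio = genetic.var() / trait.var()
        assert 0.42 <= ratio <= 0.58

    def test_residual_sd_for_h2_reproduces_target(self):
        arch = standard_architecture()
        sd = residual_sd_for_h2(arch, 0.5)
        p = arch.founder_freqs
        var_g = np.sum(2 * p * (1 - p) * arch.trait_effects**2)
        assert sd**2 == pytest.approx(var_g)

    def test_missing_soil_label_is_an_error(self, default_config, rng):
        arch = one_locus_arch()
        geno, samples = simulate_founders(default_config, arch)
        trait = TraitModel(soil_main_effect={"limestone": 0.0})
        with pytest.raises(ConfigurationError):
            simulate_phenotype(geno, samples, arch, trait, rng)


class TestContributions:
    def test_quota_follows_seed_share(self):
        seeds = [10] + [88 / 10] * 10  # replicate total 98
        plan = contributions(seeds, 49)
        assert plan.contribution_quota[0] == pytest.approx(5.0)

    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=120).filter(
        lambda s: sum(s) > 0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation_for_any_seed_sets(self, seeds):
        plan = contributions(seeds, 49)
        assert plan.contribution_quota.sum() == pytest.approx(49.0)
        assert plan.offspring_count.sum() == 49
        assert not np.any((plan.seed_set == 0) & (plan.offspring_count > 0))

    def test_equal_seeds_round_by_largest_remainder(self):
        plan = contributions([1, 1, 1], 49)
        assert sorted(plan.offspring_count) == [16, 16, 17]

    def test_extinction_on_all_zero_seed_sets(self):
        with pytest.raises(ExtinctionError):
            contributions([0.0, 0.0], 49)


class TestSelectAndMate:
    def test_neutral_transmission_shows_only_binomial_drift(self, default_config):
        rng = np.random.default_rng(1)
        n_loci = 1000
        p0 = np.full(n_loci, 0.5)
        dosages = rng.binomial(2, p0, size=(49, n_loci)).astype(float)
        kids = select_and_mate(dosages, np.zeros(n_loci), "bee", default_config,
                               ne=49, rng=rng)
        dp = np.abs(kids.mean(0) / 2 - dosages.mean(0) / 2)
        assert dp.mean() < 0.05

    def test_neutral_mean_delta_is_centred_on_zero(self, default_config):
        rng = np.random.default_rng(2)
        deltas = []
        for _ in range(500):
            dosages = rng.binomial(2, 0.5, size=(49, 20)).astype(float)
            kids = select_and_mate(dosages, np.zeros(20), "hand", default_config,
                                   ne=49, rng=rng)
            deltas.append(kids.mean(0) / 2 - dosages.mean(0) / 2)
        deltas = np.concatenate(deltas)
        sem = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * sem

    def test_overwhelming_selection_forces_fixation(self, default_config):
        rng = np.random.default_rng(3)
        dosages = rng.binomial(2, 0.7, size=(49, 1)).astype(float)
        kids = select_and_mate(dosages, np.array([50.0]), "bee", default_config,
                               ne=49, rng=rng)
        assert kids.mean() / 2 == 1.0

    def test_antagonistic_locus_moves_oppositely_in_the_two_soils(
            self, default_config):
        s = 0.3
        means = {}
        for soil_sign in (+1, -1):
            final = []
            for seed in range(200):
                rng = np.random.default_rng(10_000 + seed)
                dosages = rng.binomial(2, 0.5, size=(49, 1)).astype(float)
                p_start = dosages.mean() / 2
                for _ in range(9):
                    dosages = select_and_mate(
                        dosages, np.array([soil_sign * s]), "bee",
                        default_config, ne=22, rng=rng)
                final.append(dosages.mean() / 2 - p_start)
            means[soil_sign] = np.mean(final)
        assert means[+1] > 0 and means[-1] < 0

    def test_no_selfing(self, default_config):
        rng = np.random.default_rng(4)
        dosages = rng.binomial(2, 0.5, size=(49, 5)).astype(float)
        _, mothers, fathers = select_and_mate(
            dosages, np.zeros(5), "bee", default_config, ne=22, rng=rng,
            return_parents=True)
        assert np.all(mothers != fathers)

    def test_extinction_when_nothing_sets_seed(self, default_config):
        dosages = np.zeros((1, 3))
        with pytest.raises(ExtinctionError):
            select_and_mate(dosages, np.zeros(3), "bee", default_config, ne=22,
                            rng=np.random.default_rng(0))


class TestRunExperiment:
    def test_all_sixteen_populations_present(self, experiment_result):
        res = experiment_result
        labels = {t.label for t in res.config.treatments}
        assert len(labels) == 8
        for label in labels:
            for rep in "AB":
                assert res.dosages(label, rep, 1).shape == (49, len(res.markers))
                assert res.dosages(label, rep, 10).shape == (49, len(res.markers))

    def test_no_evolution_leaves_genotypes_unchanged(self, small_architecture):
        cfg = ExperimentConfig(rng_seed=5, n_selection_generations=0,
                               n_neutral_generations=0)
        res = run_experiment(cfg, small_architecture)
        for label in {t.label for t in cfg.treatments}:
            for rep in "AB":
                # the final sampled generation IS generation 1
                assert {g for (t, r, g) in res.genotypes
                        if t == label and r == rep} == {1}
        assert set(res.samples["generation"]) == {1}

    def test_same_seed_reproduces_bit_identical_outputs(self, small_architecture):
        cfg = ExperimentConfig(rng_seed=9)
        r1 = run_experiment(cfg, small_architecture)
        r2 = run_experiment(cfg, small_architecture)
        for key in r1.genotypes:
            np.testing.assert_array_equal(r1.genotypes[key], r2.genotypes[key])
        pd.testing.assert_frame_equal(r1.transplant, r2.transplant)

    def test_dosages_and_frequencies_stay_in_range(self, experiment_result):
        for dos in experiment_result.genotypes.values():
            assert np.isin(dos, (0.0, 1.0, 2.0)).all()

    def test_transplant_table_covers_both_soils(self, experiment_result):
        tab = experiment_result.transplant
        counts = tab.groupby(["treatment", "replicate", "generation"])[
            "soil_grown"].nunique()
        assert (counts == 2).all()


class TestAuxiliaryGenerators:
    def test_neutral_panel_shapes_and_margins(self):
        tables = simulate_neutral_panel(100, rng=np.random.default_rng(0))
        assert tables.shape == (100, 2, 2, 2)
        assert (tables.sum(axis=-1) == 98).all()

    def test_transplant_generator_balance(self):
        df = make_transplant_phenotypes(30, rng=np.random.default_rng(0))
        assert len(df) == 30 * 4
        assert df.groupby(["soil_line", "soil_grown"]).size().eq(30).all()
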