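"""G x E local-adaptation model, contrasts, fitness-proxy and trait evolution."""

import numpy as np
import pandas as pd
import pytest

from adaptscan import phenotype_adaptation as pa
from adaptscan.exceptions import ConfigurationError
from adaptscan.synthetic_experiment import make_transplant_phenotypes


def verdict_for(df, alpha=0.05):
    model = pa.fit_gxe(df)
    cons = pa.contrasts(model)
    return model, cons, pa.assess_local_adaptation(model, cons, alpha)


class TestFitGxE:
    def test_null_interaction_is_rarely_significant(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            df = make_transplant_phenotypes(50, local_advantage=0.0,
                                            rng=np.random.default_rng(seed))
            m = pa.fit_gxe(df)
            hits += m.terms["soil_lines_x_soil"]["p_value"] > 0.05
        assert hits / n_runs >= 0.90

    def test_crossing_interaction_detected_with_high_power(self):
        hits = 0
        for seed in range(30):
            df = make_transplant_phenotypes(50, local_advantage=1.0,
                                            rng=np.random.default_rng(500 + seed))
            m = pa.fit_gxe(df)
            hits += m.terms["soil_lines_x_soil"]["p_value"] < 0.001
        assert hits / 30 >= 0.95

    def test_zero_replicate_variance_recovered_at_boundary(self):
        df = make_transplant_phenotypes(40, replicate_sd=0.0,
                                        rng=np.random.default_rng(5))
        m = pa.fit_gxe(df)
        assert m.replicate_var <= 1e-3

    def test_empty_cell_is_a_named_error(self):
        df = make_transplant_phenotypes(10, rng=np.random.default_rng(0))
        df = df[~((df.soil_line == "tuff") & (df.soil_grown == "tuff"))]
        with pytest.raises(ConfigurationError, match="soil_line=tuff"):
            pa.fit_gxe(df)

    def test_fit_invariant_to_row_order(self):
        df = make_transplant_phenotypes(30, local_advantage=0.4,
                                        rng=np.random.default_rng(2))
        m1 = pa.fit_gxe(df)
        m2 = pa.fit_gxe(df.sample(frac=1.0, random_state=1))
        for cell in m1.cell_means:
            assert m1.cell_means[cell] == pytest.approx(m2.cell_means[cell],
                                                        abs=1e-6)

    def test_soil_relabel_flips_estimates_consistently(self):
        df = make_transplant_phenotypes(40, soil_main=1.0,
                                        rng=np.random.default_rng(3))
        swap = {"limestone": "tuff", "tuff": "limestone"}
        df2 = df.assign(soil_line=df.soil_line.map(swap),
                        soil_grown=df.soil_grown.map(swap))
        m1, m2 = pa.fit_gxe(df), pa.fit_gxe(df2)
        assert m1.cell_means[("limestone", "limestone")] == pytest.approx(
            m2.cell_means[("tuff", "tuff")], abs=1e-6)
        # the local-vs-foreign contrast is label-symmetric
        c1 = pa.contrasts(m1)["local_vs_foreign"].estimate
        c2 = pa.contrasts(m2)["local_vs_foreign"].estimate
        assert c1 == pytest.approx(c2, abs=1e-6)


class TestContrasts:
    def manual_model(self, means, se=1.0, df=100):
        cells = list(means)
        return pa.GxEModelResult(
            terms={"soil_lines_x_soil": {"chi2": 0.0, "p_value": 1.0}},
            cell_means=means, cell_cov=np.eye(4) * se**2,
            replicate_var=0.0, resid_df=df, n_obs=df + 4)

    def test_local_minus_foreign_arithmetic(self):
        means = {("limestone", "limestone"): 30.0, ("limestone", "tuff"): 20.0,
                 ("tuff", "limestone"): 20.0, ("tuff", "tuff"): 30.0}
        cons = pa.contrasts(self.manual_model(means))
        assert cons["local_vs_foreign"].estimate == pytest.approx(10.0)
        assert cons["home_vs_away"].estimate == pytest.approx(10.0)

    def test_symmetric_means_give_null_contrast(self):
        means = {c: 25.0 for c in [("limestone", "limestone"),
                                   ("limestone", "tuff"),
                                   ("tuff", "limestone"), ("tuff", "tuff")]}
        cons = pa.contrasts(self.manual_model(means))
        assert cons["local_vs_foreign"].estimate == pytest.approx(0.0)

    def test_local_advantage_detected_with_power(self):
        hits = 0
        for seed in range(30):
            df = make_transplant_phenotypes(75, local_advantage=0.5,
                                            residual_sd=1.0,
                                            rng=np.random.default_rng(seed))
            _, _, verdict = verdict_for(df)
            hits += verdict.adapted
        assert hits / 30 >= 0.8


class TestVerdict:
    def make_verdict(self, inter_p, contrast_p, estimate):
        model = pa.GxEModelResult(
            terms={"soil_lines_x_soil": {"chi2": 1.0, "p_value": inter_p}},
            cell_means={}, cell_cov=np.eye(4), replicate_var=0.0,
            resid_df=100, n_obs=104)
        cons = {"local_vs_foreign": pa.ContrastResult(
            "local_vs_foreign", estimate, 1.0, estimate, contrast_p, 100)}
        return pa.assess_local_adaptation(model, cons)

    def test_joint_significance_with_positive_contrast_is_adapted(self):
        assert self.make_verdict(6.96e-4, 7.9e-4, 3.39).adapted

    def test_nonsignificant_interaction_blocks_verdict(self):
        assert not self.make_verdict(0.59, 1e-5, 2.0).adapted

    def test_foreign_advantage_blocks_verdict(self):
        assert not self.make_verdict(1e-4, 1e-4, -2.0).adapted

    def test_null_verdict_rate_is_near_one_sided_alpha(self):
        # interaction and local-vs-foreign are collinear in a balanced 2x2,
        # so the conjunction behaves like a one-sided test at alpha/2
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            df = make_transplant_phenotypes(50, local_advantage=0.0,
                                            rng=np.random.default_rng(seed))
            _, _, verdict = verdict_for(df)
            hits += verdict.adapted
        assert hits / n_runs <= 0.05


class TestFitnessProxies:
    def make_data(self, seed, n=150, effect=0.0):
        rng = np.random.default_rng(seed)
        trait = rng.normal(0, 1, n)
        produced = rng.random(n) < 0.5
        seeds = np.where(produced, rng.gamma(2, 5, n) * np.exp(effect * trait),
                         0.0)
        return pd.DataFrame({
            "open_flowers": trait, "seed_set": seeds,
            "first_choices": rng.poisson(1.0, n),
            "visits": rng.poisson(1.5, n)})

    def test_null_rejection_rates_are_nominal(self):
        rej_bin, rej_trunc = [], []
        for seed in range(400):
            rep = pa.fitness_proxy_models(self.make_data(seed))
            rej_bin.append(rep.binary["p_value"].iloc[0] < 0.05)
            rej_trunc.append(rep.truncated["p_value"].iloc[0] < 0.05)
        assert 0.03 <= np.mean(rej_bin) <= 0.07
        assert 0.03 <= np.mean(rej_trunc) <= 0.07

    def test_deterministic_association_found(self):
        rng = np.random.default_rng(0)
        trait = rng.normal(0, 1, 100)
        df = pd.DataFrame({"open_flowers": trait, "seed_set": np.exp(trait)})
        rep = pa.fitness_proxy_models(df)
        row = rep.truncated.iloc[0]
        assert row["coef"] > 0 and row["p_value"] < 1e-6

    def test_universal_seed_production_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"open_flowers": rng.normal(0, 1, 50),
                           "seed_set": rng.gamma(2, 5, 50) + 1})
        rep = pa.fitness_proxy_models(df)
        assert rep.binary_degenerate and rep.binary is None

    def test_visits_seeds_correlation_reported(self):
        rng = np.random.default_rng(1)
        visits = rng.poisson(3, 200).astype(float)
        df = pd.DataFrame({"open_flowers": rng.normal(0, 1, 200),
                           "seed_set": 2 * visits + rng.normal(0, 1, 200),
                           "visits": visits})
        rep = pa.fitness_proxy_models(df)
        assert rep.visits_seeds_r > 0.8 and rep.visits_seeds_p < 1e-10


class TestTraitEvolution:
    def make_data(self, shift, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for trt in ("LHB", "THB"):
            soil = "limestone" if trt.startswith("L") else "tuff"
            for gen, mean in ((1, 30.0), (10, 30.0 + shift)):
                for rep in "AB":
                    rows.append(pd.DataFrame({
                        "treatment": trt, "soil_line": soil,
                        "soil_grown": soil, "replicate": rep,
                        "generation": gen,
                        "open_flowers": rng.normal(mean, 1.0, n // 2)}))
        return pd.concat(rows, ignore_index=True)

    def test_identical_generations_give_null_contrast(self):
        out = pa.trait_evolution(self.make_data(0.0, seed=4))
        assert (out["p_value"] > 0.01).all()

    def test_evolved_shift_detected_with_power(self):
        hits = 0
        for seed in range(20):
            out = pa.trait_evolution(self.make_data(1.0, seed=seed))
            hits += (out["p_value"] < 0.05).all() and (out["estimate"] > 0).all()
        assert hits / 20 >= 0.9

    def test_foreign_soil_plants_are_excluded(self):
        df = self.make_data(0.0, seed=8)
        foreign = df.assign(soil_grown=df.soil_grown.map(
            {"limestone": "tuff", "tuff": "limestone"}),
            open_flowers=df.open_flowers + 100)
        out_clean = pa.trait_evolution(df)
        out_mixed = pa.trait_evolution(pd.concat([df, foreign],
                                                 ignore_index=True))
        pd.testing.assert_frame_equal(
            out_clean.sort_values("treatment").reset_index(drop=True),
            out_mixed.sort_values("treatment").reset_index(drop=True))

    def test_missing_generation_is_an_error(self):
        df = self.make_data(0.0)
        with pytest.raises(ConfigurationError):
            pa.trait_evolution(df[df.generation == 1])
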