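"""Two-stage LMM: BLUEs, variance components, Wald/LRT, h², correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import supergs as sg
from supergs.pheno import VarCompModel, _dummy


def _plot_table(values, genotypes, site="s1"):
    rows = []
    for r, (vals, genos) in enumerate(zip(values, genotypes), start=1):
        for c, (v, g) in enumerate(zip(vals, genos), start=1):
            rows.append((g, site, r, r, c, "t", v))
    return sg.PhenotypeTable(
        data=pd.DataFrame(
            rows, columns=["genotype", "site", "rep", "row", "col", "trait", "value"]
        )
    )


class TestSiteLmm:
    def test_balanced_two_genotype_difference_exact(self):
        pt = _plot_table([[10.0, 20.0], [12.0, 22.0]], [["a", "b"], ["a", "b"]])
        _, blues = sg.fit_site_lmm(pt, "s1", "t")
        b = blues.set_index("genotype")["blue"]
        assert b["b"] - b["a"] == pytest.approx(10.0, abs=1e-8)

    def test_no_spatial_variance_gives_raw_means(self, small_panel):
        # complete-block layout: on balanced data the GLS genotype estimates
        # equal the raw plot means exactly, whatever the variance estimates
        pheno, _ = sg.simulate_trait(
            small_panel, n_qtl=10, h2_plot=0.5, n_sites=1, n_reps=3,
            spatial_sd=0.0, seed=3, randomize_layout=False,
        )
        _, blues = sg.fit_site_lmm(pheno, "site1", "trait")
        raw = pheno.data.groupby("genotype")["value"].mean()
        merged = blues.set_index("genotype")["blue"]
        np.testing.assert_allclose(
            merged.to_numpy(), raw.reindex(merged.index).to_numpy(), atol=1e-6
        )

    def test_spatial_adjustment_beats_raw_means(self):
        # strong row gradient: BLUEs should be closer to the truth than raw means
        gm, _, _ = sg.simulate_genotypes(n=30, m=100, K=1, seed=8)
        wins = 0
        n_sims = 60
        for s in range(n_sims):
            pheno, truth = sg.simulate_trait(
                gm, n_qtl=10, h2_plot=0.45, n_sites=1, n_reps=3,
                spatial_sd=0.7, seed=500 + s,
            )
            _, blues = sg.fit_site_lmm(pheno, "site1", "trait")
            b = blues.set_index("genotype")["blue"].reindex(gm.samples).to_numpy()
            raw = (
                pheno.data.groupby("genotype")["value"].mean()
                .reindex(gm.samples).to_numpy()
            )
            g = truth.genetic_values + truth.mu
            if np.mean((b - g) ** 2) < np.mean((raw - g) ** 2):
                wins += 1
        assert wins > n_sims / 2

    def test_single_genotype_rejected(self):
        pt = _plot_table([[10.0], [11.0]], [["a"], ["a"]])
        with pytest.raises(ValueError, match="2 genotypes"):
            sg.fit_site_lmm(pt, "s1", "t")


class TestMultiEnv:
    def test_identical_environments_no_noise(self):
        rows = []
        vals = {"a": 10.0, "b": 12.0, "c": 15.0}
        for env in ("e1", "e2"):
            for rep in (1, 2):
                for g, v in vals.items():
                    rows.append((g, env, rep, v))
        df = pd.DataFrame(rows, columns=["genotype", "env", "rep", "value"])
        fit = sg.fit_multienv_lmm(df, mode="genotype_random")
        assert fit.varcomps["gxe"] == pytest.approx(0.0, abs=1e-8)
        assert fit.sigma2_e == pytest.approx(0.0, abs=1e-8)
        assert fit.varcomps["genotype"] > 1.0

    def test_combined_blues_equal_site_average_when_balanced(self):
        rng = np.random.default_rng(0)
        genos = [f"g{i}" for i in range(12)]
        vals = {(g, e): rng.normal() for g in genos for e in ("e1", "e2", "e3")}
        df = pd.DataFrame(
            [(g, e, v) for (g, e), v in vals.items()],
            columns=["genotype", "env", "value"],
        )
        fit = sg.fit_multienv_lmm(df, mode="genotype_fixed")
        site_means = df.groupby("genotype")["value"].mean()
        diff = fit.beta - site_means.reindex(fit.beta.index)
        # equality up to a common shift is exact on balanced data
        np.testing.assert_allclose(diff - diff.mean(), 0.0, atol=1e-8)

    def test_variance_component_recovery(self):
        # truth (σ²g, σ²ge, σ²e) = (1.0, 0.5, 2.0): h2_plot = 1/3.5
        gm, _, _ = sg.simulate_genotypes(n=200, m=300, K=1, seed=10)
        est = []
        for s in range(10):
            pheno, _ = sg.simulate_trait(
                gm, n_qtl=40, h2_plot=1 / 3.5, prop_ge=0.5, spatial_sd=0.0,
                n_sites=3, n_reps=3, seed=900 + s,
            )
            fit = sg.fit_multienv_lmm(
                pheno.data.rename(columns={"site": "env"}), mode="genotype_random"
            )
            vc = sg.VarianceComponents.from_fit(fit)
            est.append([vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e])
        mean = np.mean(est, axis=0)
        np.testing.assert_allclose(mean, [1.0, 0.5, 2.0], rtol=0.15)

    def test_single_environment_random_mode_refused(self):
        df = pd.DataFrame(
            {"genotype": ["a", "b", "a", "b"], "env": ["e1"] * 4,
             "value": [1.0, 2.0, 1.5, 2.5]}
        )
        with pytest.raises(ValueError, match="single environment"):
            sg.fit_multienv_lmm(df, mode="genotype_random")

    def test_reml_nesting_never_decreases_loglik(self):
        rng = np.random.default_rng(4)
        n_g, n_r = 15, 4
        rows = []
        for g in range(n_g):
            for r in range(n_r):
                rows.append((f"g{g}", r, rng.normal(g * 0.1, 1.0)))
        df = pd.DataFrame(rows, columns=["geno", "grp", "y"])
        X = np.ones((len(df), 1))
        Zg, _ = _dummy(df["geno"])
        Zr, _ = _dummy(df["grp"])
        full = VarCompModel(df["y"].to_numpy(), X, [Zg, Zr], ["g", "r"]).fit()
        reduced = VarCompModel(df["y"].to_numpy(), X, [Zg], ["g"]).fit()
        assert full.loglik >= reduced.loglik - 1e-6


class TestWald:
    def test_single_contrast_equals_squared_z(self):
        pt = _plot_table(
            [[10.0, 13.2], [11.4, 14.1], [9.5, 12.0]],
            [["a", "b"]] * 3,
        )
        fit, _ = sg.fit_site_lmm(pt, "s1", "t")
        stat, df, p = sg.wald_test_genotype(fit)
        d = fit.beta["b"] - fit.beta["a"]
        var = fit.cov_beta[0, 0] + fit.cov_beta[1, 1] - 2 * fit.cov_beta[0, 1]
        z2 = d**2 / var
        assert df == 1
        assert stat == pytest.approx(z2, rel=1e-8)

    def test_power_under_strong_genotype_effect(self, small_panel):
        hits = 0
        for s in range(10):
            pheno, _ = sg.simulate_trait(
                small_panel, n_qtl=10, h2_plot=0.8, n_sites=1, n_reps=3, seed=200 + s,
            )
            fit, _ = sg.fit_site_lmm(pheno, "site1", "trait")
            _, _, p = sg.wald_test_genotype(fit)
            hits += p < 0.001
        assert hits >= 9


class TestLrt:
    def test_identical_models_give_p_one(self):
        fit = sg.LmmFit(
            beta=pd.Series([1.0]), cov_beta=np.eye(1), varcomps={"a": 0.5},
            sigma2_e=1.0, loglik=-10.0, n_obs=20, terms=["a"],
        )
        stat, p = sg.lrt_random_term(fit, fit)
        assert stat == 0.0
        assert p == 1.0

    def test_optimizer_failure_detected(self):
        good = sg.LmmFit(
            beta=pd.Series([1.0]), cov_beta=np.eye(1), varcomps={},
            sigma2_e=1.0, loglik=-10.0, n_obs=20, terms=[],
        )
        bad = sg.LmmFit(
            beta=pd.Series([1.0]), cov_beta=np.eye(1), varcomps={"a": 0.5},
            sigma2_e=1.0, loglik=-12.0, n_obs=20, terms=["a"],
        )
        with pytest.raises(RuntimeError, match="optimiser"):
            sg.lrt_random_term(bad, good)

    def test_power_under_large_component(self):
        rng = np.random.default_rng(6)
        pvals = []
        for s in range(10):
            groups = np.repeat(np.arange(10), 8)
            y = rng.normal(0, 1, 80) + 2.0 * rng.standard_normal(10)[groups]
            X = np.ones((80, 1))
            Zg, _ = _dummy(groups)
            full = VarCompModel(y, X, [Zg], ["grp"]).fit()
            reduced = VarCompModel(y, X, [], []).fit()
            _, p = sg.lrt_random_term(full, reduced)
            pvals.append(p)
        assert np.median(pvals) < 1e-4


class TestHeritability:
    def test_direct_arithmetic(self):
        vc = sg.VarianceComponents(sigma2_g=1, sigma2_ge=1, sigma2_e=1, t=3, r=3)
        assert sg.broad_sense_h2(vc) == pytest.approx(1 / (1 + 1 / 3 + 1 / 9))

    def test_pure_genetic_variance_gives_one(self):
        vc = sg.VarianceComponents(sigma2_g=2, sigma2_ge=0, sigma2_e=0, t=2, r=3)
        assert sg.broad_sense_h2(vc) == 1.0

    def test_all_zero_rejected(self):
        vc = sg.VarianceComponents(sigma2_g=0, sigma2_ge=0, sigma2_e=0, t=2, r=2)
        with pytest.raises(ValueError, match="undefined"):
            sg.broad_sense_h2(vc)

    def test_monotonicity_in_each_component(self):
        base = dict(sigma2_g=1.0, sigma2_ge=0.5, sigma2_e=1.0, t=3, r=3)
        h0 = sg.broad_sense_h2(sg.VarianceComponents(**base))
        up_g = sg.broad_sense_h2(sg.VarianceComponents(**{**base, "sigma2_g": 1.5}))
        up_ge = sg.broad_sense_h2(sg.VarianceComponents(**{**base, "sigma2_ge": 1.0}))
        up_e = sg.broad_sense_h2(sg.VarianceComponents(**{**base, "sigma2_e": 2.0}))
        assert up_g > h0 and up_ge < h0 and up_e < h0


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        blues = pd.DataFrame({"a": x, "b": -x})
        r, p, stars = sg.trait_correlations(blues)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert stars.loc["a", "b"] == "***"

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        blues = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        r, _, _ = sg.trait_correlations(blues)
        for i, c1 in enumerate("abcdef"):
            for c2 in "abcdef"[i + 1:]:
                x, y = blues[c1].to_numpy(), blues[c2].to_numpy()
                expected = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert r.loc[c1, c2] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_trait_reported_missing(self):
        blues = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        r, p, _ = sg.trait_correlations(blues)
        assert np.isnan(r.loc["a", "b"])
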