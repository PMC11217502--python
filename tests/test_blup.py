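"""Variance components, BLUP shrinkage, genetic statistics, WAASB, quadrants."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from metstab import (BLUP, SimConfig, anova_from_mean_squares, cell_means,
                     genetic_stats, pooled_anova, quadrant_classify,
                     simulate_met, variance_components, waasb_scores)
from metstab.blup import blup_predicted_means, blup_shrinkage
from metstab.exceptions import ContractError

from conftest import make_table


def _vc_from_ms(ms_g, ms_ge, ms_e, design=(6, 3, 3), mu=50.0):
    anova = anova_from_mean_squares(
        {"GEN": design[0] - 1, "ENV:GEN": (design[0] - 1) * (design[1] - 1),
         "Residuals": design[1] * (design[0] - 1) * (design[2] - 1)},
        {"GEN": ms_g, "ENV:GEN": ms_ge, "Residuals": ms_e})
    return variance_components(anova, design, mu)


class TestVarianceComponents:
    def test_equal_mean_squares_give_zero_components(self):
        vc = _vc_from_ms(2.0, 2.0, 2.0)
        assert vc.sigma2_g == 0.0
        assert vc.sigma2_ge == 0.0
        assert vc.sigma2_e == 2.0
        assert vc.clamped == ()

    def test_negative_estimates_clamped_and_flagged(self):
        vc = _vc_from_ms(1.0, 3.0, 5.0)
        assert vc.sigma2_g == 0.0 and vc.sigma2_ge == 0.0
        assert set(vc.clamped) == {"sigma2_g", "sigma2_ge"}

    def test_parameter_recovery(self):
        """Mean EMS estimates across seeds land near the generating values."""
        truth = {"sigma2_g": 16.0, "sigma2_ge": 1.0, "sigma2_e": 1.0}
        est = []
        for seed in range(200):
            cfg = SimConfig(n_genotypes=30, n_envs=3, n_reps=3, sigma_g=4.0,
                            sigma_ge_noise=1.0, sigma_e=1.0,
                            interaction_rank=1, lambdas=(0.0,),
                            env_effects=(1.0, 0.0, -1.0), seed=seed)
            tbl, _ = simulate_met(cfg)
            anova = pooled_anova(tbl, "yield")
            vc = variance_components(anova, (30, 3, 3), 70.0)
            est.append((vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e))
        means = np.mean(est, axis=0)
        for got, want in zip(means, truth.values()):
            assert got == pytest.approx(want, rel=0.15)

    def test_matches_reml_oracle_on_balanced_data(self, rng):
        """EMS components equal the REML maximizer on balanced data.

        Oracle: direct restricted log-likelihood of the two-variance-
        component mixed model, maximized numerically from a perturbed start.
        """
        cfg = SimConfig(n_genotypes=6, n_envs=3, n_reps=3, sigma_g=3.0,
                        sigma_ge_noise=1.5, sigma_e=1.0, interaction_rank=1,
                        lambdas=(0.0,), env_effects=(1.0, 0.0, -1.0), seed=42)
        tbl, _ = simulate_met(cfg)
        anova = pooled_anova(tbl, "yield")
        means = cell_means(tbl, "yield")
        vc = variance_components(anova, (6, 3, 3), float(means.mean().mean()))

        frame = tbl.frame
        y = frame["value"].to_numpy()
        X = pd.get_dummies(frame["env"].astype(str) + "/" +
                           frame["rep"].astype(str)).to_numpy(float)  # env+rep(env) fixed
        Zg = pd.get_dummies(frame["genotype"]).to_numpy(float)
        Zge = pd.get_dummies(frame["genotype"].astype(str) + ":" +
                             frame["env"].astype(str)).to_numpy(float)

        def neg_restricted_ll(log_s2):
            s2g, s2ge, s2e = np.exp(log_s2)
            V = s2g * Zg @ Zg.T + s2ge * Zge @ Zge.T + s2e * np.eye(len(y))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            sign, ld_v = np.linalg.slogdet(V)
            _, ld_x = np.linalg.slogdet(XtViX)
            return 0.5 * (ld_v + ld_x + r @ Vi @ r)

        start = np.log([vc.sigma2_g * 1.7, vc.sigma2_ge * 0.6, vc.sigma2_e * 1.4])
        opt = optimize.minimize(neg_restricted_ll, start, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-12,
                                         "maxiter": 4000})
        reml = np.exp(opt.x)
        np.testing.assert_allclose(
            [vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e], reml, atol=1e-6)


class TestBLUPMeans:
    def test_zero_genetic_variance_total_shrinkage(self, rng):
        vc = _vc_from_ms(2.0, 2.0, 2.0, mu=50.0)
        means = pd.DataFrame(rng.normal(50, 3, size=(6, 3)))
        pred = blup_predicted_means(vc, means, (6, 3, 3))
        np.testing.assert_allclose(pred, 50.0)

    def test_no_error_no_shrinkage(self, rng):
        vc = _vc_from_ms(10.0, 0.0, 0.0, mu=50.0)
        means = pd.DataFrame(rng.normal(50, 3, size=(6, 3)))
        pred = blup_predicted_means(vc, means, (6, 3, 3))
        np.testing.assert_allclose(pred, means.mean(axis=1), rtol=1e-12)

    def test_matches_mixed_model_equations_oracle(self):
        """Predicted means equal mu + g from Henderson's equations solved
        directly on the replicate-level data."""
        cfg = SimConfig(n_genotypes=8, n_envs=3, n_reps=3, sigma_g=4.0,
                        sigma_ge_noise=1.0, sigma_e=2.0, interaction_rank=1,
                        lambdas=(0.0,), env_effects=(2.0, -1.0, -1.0), seed=3)
        tbl, _ = simulate_met(cfg)
        res = BLUP(tbl, "yield").fit()
        vc = res.variance_components

        frame = tbl.frame.sort_values(["genotype", "env", "rep"])
        y = frame["value"].to_numpy()
        X = np.ones((len(y), 1))  # intercept; env/rep effects average out in balance
        X = np.hstack([X, pd.get_dummies(frame["env"]).to_numpy(float)[:, 1:],
                       pd.get_dummies(frame["env"].astype(str) + "/" +
                                      frame["rep"].astype(str)).to_numpy(float)[:, 1:]])
        Zg = pd.get_dummies(frame["genotype"]).to_numpy(float)
        Zge = pd.get_dummies(frame["genotype"].astype(str) + ":" +
                             frame["env"].astype(str)).to_numpy(float)
        Z = np.hstack([Zg, Zge])
        lam = np.concatenate([
            np.full(Zg.shape[1], vc.sigma2_e / vc.sigma2_g),
            np.full(Zge.shape[1], vc.sigma2_e / vc.sigma2_ge)])
        top = np.hstack([X.T @ X, X.T @ Z])
        bottom = np.hstack([Z.T @ X, Z.T @ Z + np.diag(lam)])
        lhs = np.vstack([top, bottom])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        g_hat = sol[X.shape[1]: X.shape[1] + Zg.shape[1]]
        fixed_mean = (X @ sol[: X.shape[1]]).mean()  # balanced: = grand mean
        oracle = fixed_mean + g_hat
        np.testing.assert_allclose(res.predicted_means.to_numpy(), oracle,
                                   atol=1e-6)

    def test_shrinkage_keeps_order_and_convexity(self):
        tbl, _ = simulate_met(SimConfig(seed=11), seed=11)
        res = BLUP(tbl, "yield").fit()
        assert 0.0 <= res.shrinkage <= 1.0
        obs = res.observed_means
        pred = res.predicted_means
        rho = stats.spearmanr(obs, pred).statistic
        assert rho == pytest.approx(1.0)
        mu = res.variance_components.grand_mean
        between = ((pred - mu) * (obs - mu) >= -1e-12) & \
                  ((pred - mu).abs() <= (obs - mu).abs() + 1e-12)
        assert between.all()


class TestGeneticStats:
    def test_perfect_heritability(self):
        vc = _vc_from_ms(10.0, 0.0, 0.0)
        h2, acc, _ = genetic_stats(vc, (6, 3, 3))
        assert h2 == pytest.approx(1.0)
        assert acc == pytest.approx(1.0)

    def test_cv_arithmetic(self):
        vc = _vc_from_ms(10.0, 6.0, 4.0, mu=20.0)
        _, _, cv = genetic_stats(vc, (6, 3, 3))
        assert cv == pytest.approx(100 * 2.0 / 20.0)

    def test_high_heritability_regime(self):
        """Strong genotype signal gives near-unit selection accuracy, the
        regime reported for dormancy intensity."""
        accs = []
        for seed in range(20):
            cfg = SimConfig(sigma_g=25.0, sigma_e=4.0, seed=seed)
            tbl, _ = simulate_met(cfg)
            accs.append(BLUP(tbl, "yield").fit().accuracy)
        assert np.mean(accs) >= 0.95

    def test_h2_recovery(self):
        """Entry-mean H2 estimate within +-0.1 of planted truth on average."""
        errs = []
        for seed in range(200):
            cfg = SimConfig(seed=seed)
            tbl, truth = simulate_met(cfg)
            errs.append(BLUP(tbl, "yield").fit().heritability
                        - truth.heritability)
        assert abs(np.mean(errs)) <= 0.1


class TestWAASB:
    def test_additive_data_zero_waasb(self, additive_table):
        res = BLUP(additive_table, "trait").fit()
        np.testing.assert_allclose(res.waasb, 0.0, atol=1e-10)

    def test_single_axis_equals_absolute_score(self):
        """With E=2 there is a single interaction axis, so WAASB reduces to
        the absolute IPCA1 score of the shrunken interaction."""
        rng = np.random.default_rng(8)
        vals = rng.normal(40, 6, size=(6, 2, 3))
        tbl = make_table(vals)
        res = BLUP(tbl, "trait").fit()
        from metstab.ammi import svd_interaction
        from metstab.blup import interaction_blup_matrix
        blup_ge = interaction_blup_matrix(res.means, res.variance_components, 3)
        u, s, v = svd_interaction(blup_ge)
        np.testing.assert_allclose(res.waasb, np.abs(u[:, 0] * np.sqrt(s[0])),
                                   atol=1e-12)

    def test_matches_weighted_sum_oracle(self, rng):
        vals = rng.normal(40, 6, size=(7, 4, 2))
        tbl = make_table(vals)
        res = BLUP(tbl, "trait").fit()
        from metstab.ammi import svd_interaction
        from metstab.blup import interaction_blup_matrix
        blup_ge = interaction_blup_matrix(res.means, res.variance_components, 2)
        u, s, v = svd_interaction(blup_ge)
        lam = s ** 2
        w = lam / lam.sum()
        oracle = np.abs(u * np.sqrt(s)) @ w
        np.testing.assert_allclose(res.waasb, oracle, atol=1e-12)

    def test_invariant_to_genotype_relabeling(self, rng):
        vals = rng.normal(40, 6, size=(6, 3, 3))
        base = BLUP(make_table(vals), "trait").fit().waasb
        perm = rng.permutation(6)
        shuffled = BLUP(make_table(vals[perm]), "trait").fit().waasb
        np.testing.assert_allclose(shuffled.to_numpy(),
                                   base.to_numpy()[perm], atol=1e-10)


class TestQuadrants:
    def test_quadrant_semantics(self):
        means = pd.Series({"a": 60.0, "b": 60.0, "c": 40.0, "d": 40.0})
        waasb = pd.Series({"a": 0.1, "b": 2.0, "c": 0.1, "d": 2.0})
        out = quadrant_classify(means, waasb)
        assert out.to_dict() == {"a": "IV", "b": "II", "c": "III", "d": "I"}

    def test_boundary_goes_to_favourable_quadrant(self):
        means = pd.Series({"a": 50.0, "b": 50.0})
        waasb = pd.Series({"a": 1.0, "b": 1.0})
        out = quadrant_classify(means, waasb)
        assert (out == "IV").all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        means = pd.Series(rng.normal(50, 5, size=10))
        waasb = pd.Series(rng.uniform(0, 2, size=10))
        base = quadrant_classify(means, waasb)
        scaled = quadrant_classify(3.0 * means + 7.0, waasb)
        pd.testing.assert_series_equal(base, scaled)
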