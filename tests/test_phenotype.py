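"""Descriptors, PCA fitness proxy, Box-Cox, response models, partition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermalgarden as tg
from thermalgarden import phenotype as ph
from conftest import toy_panel


class TestPanelValidation:
    def test_off_grid_value_rejected(self):
        panel = toy_panel({"c1": [0, 12, 20]})
        panel.loc[1, "necrosis_pct"] = 12.0
        with pytest.raises(ValueError, match="5% grid"):
            ph.validate_panel(panel)

    def test_decreasing_trajectory_rejected(self):
        panel = toy_panel({"c1": [0, 20, 10]})
        with pytest.raises(ValueError, match="decreases"):
            ph.validate_panel(panel)

    def test_inclusion_rule_drops_single_year_colonies(self):
        a = toy_panel({"c1": [0, 5]}, year=2015)
        b = toy_panel({"c1": [0, 10]}, year=2016)
        c = toy_panel({"c2": [0, 0]}, year=2015)
        panel = pd.concat([a, b, c])
        kept = ph.apply_inclusion_rule(panel)
        assert set(kept["colony_id"]) == {"c1"}


class TestDailyDescriptors:
    def test_all_zero_panel(self):
        panel = toy_panel({f"c{i}": [0] * 12 for i in range(3)})
        d = ph.compute_daily_descriptors(panel)
        assert (d[["mean_extent", "pct_affected", "pct_dead"]] == 0).all().all()

    def test_hand_computed_three_colony_day(self):
        """Colonies at 0, 15 and 100%: mean 38.33, affected 66.7, dead 33.3."""
        panel = toy_panel({"a": [0, 0], "b": [15, 15], "c": [100, 100]})
        d = ph.compute_daily_descriptors(panel)
        row = d[d["day"] == 2].iloc[0]
        assert row["mean_extent"] == pytest.approx(115 / 3)
        assert row["pct_affected"] == pytest.approx(200 / 3)
        assert row["pct_dead"] == pytest.approx(100 / 3)
        assert row["se_extent"] == pytest.approx(
            np.std([0, 15, 100], ddof=1) / np.sqrt(3))

    def test_dead_is_subset_of_affected(self, default_panel):
        d = ph.compute_daily_descriptors(default_panel)
        assert (d["pct_dead"] <= d["pct_affected"] + 1e-12).all()


class TestImpactClass:
    @pytest.mark.parametrize("value,expected", [
        (0, "none"), (5, "none"), (9.9, "none"),
        (10, "low"), (30, "low"),
        (30.1, "moderate"), (60, "moderate"),
        (60.1, "severe"), (100, "severe"),
    ])
    def test_boundaries(self, value, expected):
        assert ph.classify_impact(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ph.classify_impact(101)


class TestFitnessPca:
    def test_rank_one_panel_recovers_multiples(self):
        """Trajectories proportional to one template: PC1 captures ~all
        variance and scores are affine in the multiples, matching a
        brute-force eigendecomposition of the correlation matrix."""
        template = np.array([0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95])
        mult = {"c1": 0.2, "c2": 0.4, "c3": 0.6, "c4": 1.0}
        trajs = {c: 5 * np.round(m * template / 5) for c, m in mult.items()}
        panel = toy_panel(trajs)
        res = tg.fit_fitness_pca(panel, trim_before_day=1)
        # 5%-grid rounding perturbs exact proportionality a little
        assert res.variance_explained[0] > 90.0
        # oracle: eigendecomposition of the standardized data covariance
        mat = np.array([trajs[c] for c in mult])
        keep = mat.std(axis=0) > 0
        z = (mat[:, keep] - mat[:, keep].mean(0)) / mat[:, keep].std(0)
        w, v = np.linalg.eigh(np.cov(z.T, ddof=0) * (1 if True else 1))
        assert res.variance_explained[0] == pytest.approx(
            100 * w[-1] / w.sum(), abs=1e-6)
        r = np.corrcoef(res.scores["pc1_score"],
                        [mult[c] for c in res.scores["colony_id"]])[0, 1]
        assert r > 0.99

    def test_case_order_invariance(self, default_panel):
        shuffled = default_panel.sample(frac=1, random_state=0)
        a = tg.fit_fitness_pca(default_panel).scores.set_index(
            ["colony_id", "year"])["pc1_score"].sort_index()
        b = tg.fit_fitness_pca(shuffled).scores.set_index(
            ["colony_id", "year"])["pc1_score"].sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_pc1_positively_tracks_final_necrosis(self, default_panel):
        res = tg.fit_fitness_pca(default_panel)
        final = (default_panel[default_panel["day"] == 28]
                 .set_index(["colony_id", "year"])["necrosis_pct"])
        merged = res.scores.set_index(["colony_id", "year"]).join(final)
        assert merged["pc1_score"].corr(merged["necrosis_pct"]) > 0

    def test_too_few_cases_rejected(self):
        panel = toy_panel({"c1": [0] * 10 + [5, 10]})
        with pytest.raises(ValueError, match="cases"):
            tg.fit_fitness_pca(panel)


class TestBoxCox:
    def test_normal_scores_lambda_near_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "colony_id": [f"c{i}" for i in range(200)],
            "population": np.repeat(["A", "B"], 100),
            "year": np.tile([2015, 2016], 100),
            "pc1_score": rng.normal(10, 1, 200),
        })
        res = tg.boxcox_transform(df)
        # profile-ML lambda is weakly identified far from zero, so it
        # scatters around 1; the transform must stay near-affine
        assert 0.2 < res.lmbda < 2.5
        a = stats.zscore(df["pc1_score"])
        b = stats.zscore(res.scores["transformed"])
        assert np.max(np.abs(np.sort(a) - np.sort(b))) < 0.15

    def test_lognormal_scores_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "colony_id": [f"c{i}" for i in range(300)],
            "population": np.repeat(["A", "B"], 150),
            "year": np.tile([2015, 2016], 150),
            "pc1_score": np.exp(rng.normal(0, 1, 300)),
        })
        res = tg.boxcox_transform(df)
        assert abs(res.lmbda) < 0.15

    def test_constant_scores_rejected(self):
        df = pd.DataFrame({"colony_id": list("abcd"), "population": "A",
                           "year": 2015, "pc1_score": 1.0})
        with pytest.raises(ValueError, match="constant"):
            tg.boxcox_transform(df)


def _sim_scores(seed, **kw):
    cfg = tg.SimConfig(seed=seed, **kw)
    panel = ph.apply_inclusion_rule(
        ph.validate_panel(tg.simulate_necrosis_panel(cfg).panel))
    return tg.boxcox_transform(tg.fit_fitness_pca(panel).scores).scores


class TestResponseModels:
    def test_aic_identity_and_preference(self, default_panel):
        scores = tg.boxcox_transform(tg.fit_fitness_pca(default_panel).scores).scores
        comp, nec_int = tg.fit_response_models(scores)
        for _, row in comp.models.iterrows():
            assert row["aic"] == pytest.approx(2 * row["df"] - 2 * row["loglik"])
        assert comp.lrt_df == 1
        assert nec_int.abs().mean() > 0          # non-degenerate intercepts
        assert abs(nec_int.mean()) < 0.2 * nec_int.std()

    def test_only_year_significant_under_default_conditions(self, default_panel):
        """Year-dominated generator: the year deviance test rejects, the
        population and interaction tests do not."""
        scores = tg.boxcox_transform(tg.fit_fitness_pca(default_panel).scores).scores
        comp, _ = tg.fit_response_models(scores)
        tests = comp.fixed_factor_tests.set_index("factor")["p"]
        assert tests["year"] < 1e-6
        assert tests["population"] > 0.05
        assert tests["population:year"] > 0.05
        # Tukey: the lethal year differs from both ordinary years
        tuk = comp.tukey_year
        vs17 = tuk[(tuk["year_b"] == 2017)]
        assert (vs17["p_tukey"] < 1e-6).all()

    def test_null_random_intercept_lrt_calibration(self):
        """sigma_individual = 0: the random-intercept LRT rejects at no
        more than ~nominal rate (chi2(1) reference is conservative at the
        boundary)."""
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            scores = _sim_scores(1000 + s, sigma_individual=0.0,
                                 n_colonies_per_pop=10,
                                 missing_year_fraction=0.0)
            comp, _ = tg.fit_response_models(scores)
            hits += comp.lrt_p < 0.05
        assert hits / n_rep <= 0.125

    def test_single_year_colony_rejected(self):
        df = pd.DataFrame({
            "colony_id": ["a", "a", "b"],
            "population": ["A", "A", "B"],
            "year": [2015, 2016, 2015],
            "transformed": [0.1, 0.2, 0.3],
        })
        with pytest.raises(ValueError, match="inclusion"):
            tg.fit_response_models(df)


def _gaussian_loglik(y, X):
    """Exact ML log-likelihood of a fixed-effect Gaussian linear model."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    s2 = resid @ resid / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)


def _mixed_loglik_bruteforce(y, X, groups):
    """ML log-likelihood of a random-intercept model by direct 1-D search.

    Profiles beta and sigma^2 out via GLS for each variance ratio
    gamma = var_intercept / var_resid and maximizes over gamma >= 0
    numerically -- independent of statsmodels.
    """
    from scipy.optimize import minimize_scalar
    n = len(y)
    codes = pd.factorize(groups)[0]
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0

    def nll(log_gamma):
        gamma = np.exp(log_gamma)
        V = np.eye(n) + gamma * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        beta = np.linalg.solve(XtVi @ X, XtVi @ y)
        r = y - X @ beta
        s2 = r @ Vi @ r / n
        _, logdet = np.linalg.slogdet(V)
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    best = min(nll(lg) for lg in np.linspace(-12, 4, 33))
    res = minimize_scalar(nll, bounds=(-12, 4), method="bounded")
    return -min(best, res.fun)


class TestVariancePartition:
    def test_matches_analytic_two_factor_oracle(self):
        """Fixed-factor contributions agree with a brute-force oracle that
        enumerates the reduced models and computes exact Gaussian ML
        log-likelihoods (no-random-intercept limit, large residual)."""
        rng = np.random.default_rng(5)
        pops = np.repeat(["A", "B", "C"], 30)
        years = np.tile([2015, 2016, 2017], 30)
        colonies = [f"c{i // 3}-{p}" for i, p in enumerate(pops)]
        y = (np.where(years == 2017, 3.0, 0.0)
             + np.where(pops == "B", 0.3, 0.0) + rng.normal(0, 1.5, 90))
        df = pd.DataFrame({"colony_id": colonies, "population": pops,
                           "year": years, "transformed": y})
        res = tg.variance_partition(df)

        import patsy

        def ll_mixed(formula):
            X = np.asarray(patsy.dmatrix(formula, df))
            return (_mixed_loglik_bruteforce(y, X, df["colony_id"]),
                    X.shape[1] + 2)

        def ll_fixed(formula):
            X = np.asarray(patsy.dmatrix(formula, df))
            return _gaussian_loglik(y, X), X.shape[1] + 1

        ll_full, df_full = ll_mixed("C(population) * C(year)")
        expected = {}
        for factor, fml in [("year", "C(population)"),
                            ("population", "C(year)"),
                            ("population:year", "C(population) + C(year)")]:
            l, d = ll_mixed(fml)
            expected[factor] = max(0.0, (ll_full - l) / (df_full - d))
        l, d = ll_fixed("C(population) * C(year)")
        expected["individual"] = max(0.0, (ll_full - l) / (df_full - d))
        got = res.contributions.set_index("factor")
        for factor, exp_raw in expected.items():
            assert got.loc[factor, "raw"] == pytest.approx(exp_raw, abs=0.02)

    def test_percentages_sum_to_100(self, default_panel):
        scores = tg.boxcox_transform(tg.fit_fitness_pca(default_panel).scores).scores
        res = tg.variance_partition(scores)
        assert res.contributions["contribution_pct"].sum() == pytest.approx(100, abs=0.01)
        assert (res.contributions["contribution_pct"] >= 0).all()

    def test_year_only_signal_gives_dominant_year_share(self):
        """Response driven by year effects alone: year share > 95%."""
        shares = []
        for s in range(5):
            scores = _sim_scores(2000 + s, sigma_individual=0.0,
                                 sigma_residual=0.35, n_colonies_per_pop=10,
                                 missing_year_fraction=0.0)
            vp = tg.variance_partition(scores)
            shares.append(vp.contributions.set_index("factor")
                          .loc["year", "contribution_pct"])
        assert np.median(shares) > 95

    def test_null_panel_has_small_raw_contributions(self):
        """No simulated effects at all: every factor's raw per-df
        contribution stays near zero (the partition fabricates no signal)."""
        raws = []
        for s in range(5):
            scores = _sim_scores(3000 + s, sigma_individual=0.0,
                                 year_effects=(0, 0, 0), n_colonies_per_pop=10,
                                 missing_year_fraction=0.0)
            vp = tg.variance_partition(scores)
            raws.append(vp.contributions["raw"].max())
        assert np.median(raws) < 2.0


class TestRandomInterceptRecovery:
    def test_sigma_u_recovered_from_known_mixture(self):
        """Data generated directly from the random-intercept model: the
        fitted sigma_u matches a brute-force profiled-GLS ML oracle on the
        same data and tracks the true value within Monte-Carlo tolerance."""
        import patsy
        from scipy.optimize import minimize_scalar
        rng = np.random.default_rng(11)
        sigma_u, sigma_e = 0.8, 0.5
        n_col = 90      # study-sized panel: 3 populations x 30 colonies
        n_obs = 3 * n_col
        pkg_ests, oracle_ests = [], []
        for _ in range(10):
            pops = np.repeat(["A", "B", "C"], n_col)
            years = np.tile([2015, 2016, 2017], n_col)
            colonies = np.repeat([f"c{i}" for i in range(n_col)], 3)
            u = np.repeat(rng.normal(0, sigma_u, n_col), 3)
            y = (np.where(years == 2017, 2.0, 0.0) + u
                 + rng.normal(0, sigma_e, n_obs))
            df = pd.DataFrame({"colony_id": colonies, "population": pops,
                               "year": years, "transformed": y})
            comp, _ = tg.fit_response_models(df)
            pkg_ests.append(comp.sigma_u)

            # oracle: 1-D profiled GLS over gamma = var_u / var_e
            X = np.asarray(patsy.dmatrix("C(population) * C(year)", df))
            codes = pd.factorize(colonies)[0]
            Z = np.zeros((n_obs, n_col))
            Z[np.arange(n_obs), codes] = 1.0

            def nll(log_gamma):
                g = np.exp(log_gamma)
                V = np.eye(n_obs) + g * Z @ Z.T
                Vi = np.linalg.inv(V)
                beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
                r = y - X @ beta
                s2 = r @ Vi @ r / n_obs
                _, logdet = np.linalg.slogdet(V)
                return 0.5 * (n_obs * np.log(2 * np.pi * s2) + logdet + n_obs)

            res = minimize_scalar(nll, bounds=(-10, 6), method="bounded")
            g = np.exp(res.x)
            V = np.eye(n_obs) + g * Z @ Z.T
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ beta
            s2 = float(r @ Vi @ r / n_obs)
            oracle_ests.append(np.sqrt(g * s2))
        assert np.mean(pkg_ests) == pytest.approx(np.mean(oracle_ests),
                                                  rel=0.02)
        # the true sigma_u sits inside the estimator's Monte-Carlo spread
        # (ML at 30 groups carries a known downward small-sample bias)
        lo = np.mean(oracle_ests) - 2 * np.std(oracle_ests, ddof=1)
        hi = np.mean(oracle_ests) + 2 * np.std(oracle_ests, ddof=1)
        assert lo < sigma_u < hi


class TestSurveyAnova:
    def test_hand_computed_f(self):
        """Three integer groups: F from hand-computed mean squares."""
        survey = pd.DataFrame({
            "colony_id": list("abcdefghi"),
            "population": list("AAABBBCCC"),
            "necrosis_pct": [1, 2, 3, 4, 5, 6, 10, 11, 12],
        })
        res = tg.survey_anova(survey)
        # group means 2,5,11; grand 6; SSB=3*(16+1+25)=126; SSW=2+2+2=6
        f_hand = (126 / 2) / (6 / 6)
        assert res.f_stat == pytest.approx(f_hand)
        assert len(res.tukey) == 3

    def test_single_group_rejected(self):
        survey = pd.DataFrame({"colony_id": list("ab"), "population": "A",
                               "necrosis_pct": [0.0, 5.0]})
        with pytest.raises(ValueError, match="populations"):
            tg.survey_anova(survey)


class TestNecIntProperties:
    def test_location_invariance(self, default_panel):
        """Adding a constant to every score leaves nec-int unchanged."""
        scores = tg.boxcox_transform(tg.fit_fitness_pca(default_panel).scores).scores
        _, a = tg.fit_response_models(scores)
        shifted = scores.copy()
        shifted["transformed"] = shifted["transformed"] + 7.5
        _, b = tg.fit_response_models(shifted)
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-4)
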