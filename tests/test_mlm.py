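import numpy as np
import pandas as pd
import pytest
from scipy import stats

import burstrti as b
from burstrti.mlm import (MLMSpec, VarianceComponents, _PreparedData,
                          marginal_loglik)


# ---------------------------------------------------------------------------
# dense oracle: assemble the joint covariance of ALL observations
# elementwise from the model definition, independent of the per-person
# block implementation


def dense_cov(df, vc):
    n = len(df)
    V = np.zeros((n, n))
    pid = df["person_id"].to_numpy()
    yr = df["year0"].to_numpy(float)
    wk = df["week"].to_numpy(float)
    for a in range(n):
        for c in range(n):
            if pid[a] != pid[c]:
                continue
            za = np.array([1.0, yr[a], wk[a]])
            zc = np.array([1.0, yr[c], wk[c]])
            V[a, c] += za @ vc.level3_cov @ zc
            if yr[a] == yr[c]:
                V[a, c] += vc.level2_vars[0] + vc.level2_vars[1] * wk[a] * wk[c]
                if a == c:
                    V[a, c] += vc.resid_var
    return V


def dense_loglik(df, spec, fixef, vc):
    X = design_matrix(df, spec)
    V = dense_cov(df, vc)
    return stats.multivariate_normal(mean=X @ fixef, cov=V).logpdf(
        df[spec.outcome].to_numpy())


def design_matrix(df, spec):
    cols = {"intercept": np.ones(len(df)),
            "week": df["week"].to_numpy(float),
            "year": df["year0"].to_numpy(float),
            "age": df.get("age_c", pd.Series(0.0, index=df.index)).to_numpy(float),
            "sex": df.get("sex", pd.Series(0.0, index=df.index)).to_numpy(float)}
    cols["age:year"] = cols["age"] * cols["year"]
    cols["sex:year"] = cols["sex"] * cols["year"]
    return np.column_stack([cols[t] for t in spec.fixed])


@pytest.fixture(scope="module")
def toy_data(tiny_design):
    p = b.GeneratingParams.crt_like()
    df = b.simulate_rti(tiny_design, p, np.random.default_rng(0))
    return df.sort_values(["person_id", "year0", "week"]).reset_index(drop=True)


@pytest.fixture(scope="module")
def toy_vc():
    g3 = np.array([[4.0, 0.3, 0.1], [0.3, 0.5, 0.05], [0.1, 0.05, 0.2]])
    return VarianceComponents(g3, np.array([1.5, 0.1]), 2.0)


class TestMarginalLoglik:
    def test_matches_dense_oracle(self, toy_data, toy_vc):
        spec = MLMSpec()
        fixef = np.array([7.0, -0.05, 0.2, 0.2, -0.3])
        mine = marginal_loglik(toy_data, spec, fixef, toy_vc)
        oracle = dense_loglik(toy_data, spec, fixef, toy_vc)
        assert abs(mine - oracle) < 1e-8

    def test_reduces_to_iid_ols_loglik(self, toy_data):
        spec = MLMSpec()
        vc = VarianceComponents(np.zeros((3, 3)), np.array([0.0, 0.0]), 3.0)
        X = design_matrix(toy_data, spec)
        y = toy_data["t_score"].to_numpy()
        fixef, *_ = np.linalg.lstsq(X, y, rcond=None)
        mine = marginal_loglik(toy_data, spec, fixef, vc)
        iid = stats.norm(loc=X @ fixef, scale=np.sqrt(3.0)).logpdf(y).sum()
        assert abs(mine - iid) < 1e-8

    def test_row_order_invariance(self, toy_data, toy_vc):
        spec = MLMSpec()
        fixef = np.array([7.0, -0.05, 0.2, 0.2, -0.3])
        shuffled = toy_data.sample(frac=1.0, random_state=4)
        a = marginal_loglik(toy_data, spec, fixef, toy_vc)
        c = marginal_loglik(shuffled, spec, fixef, toy_vc)
        assert abs(a - c) < 1e-8


class TestConditionalFit:
    def test_zero_noise_exact_recovery(self, default_design):
        p = b.GeneratingParams.crt_like(level3_cov=np.zeros((3, 3)),
                                        level2_vars=(0.0, 0.0),
                                        level1_var=0.0)
        rti = b.simulate_rti(default_design, p, np.random.default_rng(3))
        m = b.fit_conditional(rti)
        got = m.gamma_.set_index("term")["estimate"]
        want = {"intercept": 7.44, "week": -0.02, "year": 0.15,
                "age": 0.21, "sex": -0.24}
        for term, val in want.items():
            assert abs(got[term] - val) < 1e-6

    def test_ols_reduction_with_zero_variances(self, toy_data):
        """Fixed effects at zero random variances equal OLS exactly."""
        spec = MLMSpec()
        vc = VarianceComponents(np.zeros((3, 3)), np.array([0.0, 0.0]), 1.0)
        from burstrti.mlm import _profiled_nll
        prep = _PreparedData(toy_data, spec)
        _, gamma, _ = _profiled_nll(vc, prep)
        X = design_matrix(toy_data, spec)
        y = toy_data["t_score"].to_numpy()
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(gamma, ols, atol=1e-8)

    def test_likelihood_ascent(self, default_design):
        """The optimum is at least as good as the generating parameters."""
        p = b.GeneratingParams.crt_like()
        spec = MLMSpec()
        true_fe = np.array([p.gamma000, p.gamma100, p.gamma010,
                            p.gamma001, p.gamma002])
        true_vc = VarianceComponents(p.level3_cov,
                                     np.array(p.level2_vars), p.level1_var)
        for seed in (0, 1, 2):
            small = b.BurstDesign(n_persons=60)
            rti = b.simulate_rti(small, p, np.random.default_rng(seed))
            m = b.fit_conditional(rti)
            at_truth = marginal_loglik(rti, spec, true_fe, true_vc)
            assert m.loglik_ >= at_truth - 1e-6

    def test_slope_recovery_small_mc(self, default_design):
        """Mean estimated weekly and yearly slopes track the generating
        values across replicates."""
        p = b.GeneratingParams.crt_like()
        week, year = [], []
        for seed in range(6):
            rti = b.simulate_rti(default_design, p,
                                 np.random.default_rng(200 + seed))
            m = b.fit_conditional(rti)
            g = m.gamma_.set_index("term")["estimate"]
            week.append(g["week"])
            year.append(g["year"])
        for est, true in ((week, -0.02), (year, 0.15)):
            mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - true) < 4 * mc_se + 1e-3


class TestUnconditional:
    def test_zero_within_variance_all_between(self, default_design):
        p = b.GeneratingParams.unconditional(25.0, 0.0, 0.0,
                                             level1_var=1e-4)
        rti = b.simulate_rti(default_design, p, np.random.default_rng(5))
        dec, _ = b.fit_unconditional(rti)
        assert dec.shares["between_person"] > 99.0

    def test_equal_variances_equal_shares(self, default_design):
        p = b.GeneratingParams.unconditional(1.0, 1.0, 1.0)
        shares = []
        for seed in range(3):
            rti = b.simulate_rti(default_design, p,
                                 np.random.default_rng(50 + seed))
            dec, _ = b.fit_unconditional(rti)
            shares.append([dec.shares[k] for k in
                           ("between_person", "within_person_year",
                            "within_person_week")])
        mean_shares = np.mean(shares, axis=0)
        assert np.allclose(mean_shares, 100.0 / 3, atol=4.0)

    def test_shares_sum_to_100(self, default_design):
        p = b.GeneratingParams.unconditional(34.0, 3.0, 13.0)
        rti = b.simulate_rti(default_design, p, np.random.default_rng(6))
        dec, fit = b.fit_unconditional(rti)
        assert np.isclose(sum(dec.shares.values()), 100.0)
        assert fit.converged
        assert np.isfinite(fit.loglik)


class TestRandomEffects:
    def test_blups_match_dense_posterior_mean(self, toy_data):
        """EB estimates equal the Gaussian conditional means computed from
        the dense joint covariance."""
        m = b.fit_conditional(toy_data)
        vc = m.varcomp_
        spec = m.spec
        gamma = m.gamma_["estimate"].to_numpy()
        df = toy_data.dropna(subset=["t_score"]).sort_values(
            ["person_id", "year0", "week"]).reset_index(drop=True)
        V = dense_cov(df, vc)
        X = design_matrix(df, spec)
        r = df["t_score"].to_numpy() - X @ gamma
        Vinv_r = np.linalg.solve(V, r)

        eb = m.random_effects()
        pid = df["person_id"].to_numpy()
        yr = df["year0"].to_numpy(float)
        wk = df["week"].to_numpy(float)
        for _, row in eb["person"].iterrows():
            sel = pid == row["person_id"]
            Z = np.column_stack([np.ones(sel.sum()), yr[sel], wk[sel]])
            u_oracle = vc.level3_cov @ Z.T @ Vinv_r[sel]
            assert np.allclose([row["u00"], row["u01"], row["u10"]],
                               u_oracle, atol=1e-8)
        for _, row in eb["person_year"].iterrows():
            sel = (pid == row["person_id"]) & (yr == row["year0"])
            Z2 = np.column_stack([np.ones(sel.sum()), wk[sel]])
            G2 = np.diag(vc.level2_vars)
            mu_oracle = G2 @ Z2.T @ Vinv_r[sel]
            assert np.allclose([row["mu0"], row["mu1"]], mu_oracle,
                               atol=1e-8)

    def test_zero_level3_variance_zero_blups(self, toy_data):
        spec = MLMSpec(random_level3="intercept", random_level2="intercept")
        m = b.ThreeLevelModel(spec).fit(toy_data)
        # force the level-3 variance to ~0 and recompute
        m.varcomp_.level3_cov[:] = 0.0
        eb = m.random_effects()
        assert np.allclose(eb["person"][["u00", "u01", "u10"]], 0.0)

    def test_shrinkage(self, default_design):
        """Sample variance of EB year-slope estimates does not exceed the
        generating random-slope variance."""
        p = b.GeneratingParams.crt_like()
        rti = b.simulate_rti(default_design, p, np.random.default_rng(7))
        m = b.fit_conditional(rti)
        eb = m.random_effects()
        assert eb["person"]["u01"].var() <= p.level3_cov[1, 1] * 1.15
        for col in ("u00", "u01", "u10"):
            assert abs(eb["person"][col].mean()) < 0.5

    def test_fallback_ladder_on_degenerate_structure(self, toy_data):
        """With a tiny dataset the unstructured fit may fail; the ladder
        must still deliver a converged fit with a recorded structure."""
        m = b.ThreeLevelModel(MLMSpec()).fit(toy_data)
        assert m.result_.structure_level3 in ("unstructured", "diagonal",
                                              "intercept")
        assert np.isfinite(m.loglik_)
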