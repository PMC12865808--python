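"""Hierarchical Gaussian models, diagnostics, Bayes factors, sequential design."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadsync import bayes as B


# ---------------------------------------------------------------------------
# formula grammar and design matrix
# ---------------------------------------------------------------------------

def test_parse_formula_factorial_expansion():
    resp, terms, group = B.parse_formula("y ~ A*B*C + x + (1|dyad)")
    assert resp == "y"
    assert ("A",) in terms and ("A", "B") in terms and ("A", "B", "C") in terms
    assert ("x",) in terms
    assert len(terms) == 8  # 2^3 - 1 factorial terms + x
    assert group == "dyad"


def test_parse_formula_interaction_token():
    _, terms, group = B.parse_formula("y ~ A + B + A:B")
    assert terms == [("A",), ("B",), ("A", "B")]
    assert group is None


def test_effect_coding_two_level():
    df = pd.DataFrame({"y": [1.0, 2, 3, 4],
                       "A": [True, True, False, False],
                       "B": ["ctrl", "treat", "ctrl", "treat"]})
    m = B.HierarchicalGaussianModel(df, "y ~ A*B")
    assert m.param_names == ["intercept", "A", "B", "A:B"]
    np.testing.assert_allclose(m.X[:, 1], [0.5, 0.5, -0.5, -0.5])
    np.testing.assert_allclose(m.X[:, 2], [-0.5, 0.5, -0.5, 0.5])
    np.testing.assert_allclose(m.X[:, 3], m.X[:, 1] * m.X[:, 2])


# ---------------------------------------------------------------------------
# conjugate agreement
# ---------------------------------------------------------------------------

def _conjugate_case(seed=0, n=100, sigma=0.5):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 1.0 + 0.7 * x + sigma * rng.standard_normal(n)
    df = pd.DataFrame({"y": y, "x": x})
    priors = B.PriorSpec(intercept_mean=0.0, intercept_sd=2.0, beta_sd=1.0)
    model = B.HierarchicalGaussianModel(df, "y ~ x", priors=priors, sigma=sigma)
    prior_prec = np.diag([1 / 2.0**2, 1 / 1.0**2])
    vn = np.linalg.inv(model.X.T @ model.X / sigma**2 + prior_prec)
    mn = vn @ (model.X.T @ y / sigma**2)
    return model, mn, vn


def test_conjugate_posterior_matches_closed_form():
    """Known sigma, no random term: MCMC matches the normal-normal update
    within 3 Monte Carlo standard errors."""
    model, mn, vn = _conjugate_case()
    res = model.fit(draws=1500, warmup=500, chains=4, seed=1)
    s = res.summary()
    for j, name in enumerate(["b_intercept", "b_x"]):
        mcse = s.loc[name, "sd"] / np.sqrt(s.loc[name, "ess"])
        assert abs(s.loc[name, "mean"] - mn[j]) < 3 * mcse
        assert abs(s.loc[name, "sd"] - np.sqrt(vn[j, j])) < 0.1 * np.sqrt(vn[j, j])


def test_likelihood_invariance_under_response_shift():
    """Adding a constant to the response shifts only the intercept posterior."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(150)
    y = 0.4 * x + 0.3 * rng.standard_normal(150)
    pri = B.PriorSpec(intercept_mean=0.0, intercept_sd=50.0, beta_sd=50.0,
                      sigma_scale=5.0)
    r1 = B.fit_hierarchical(pd.DataFrame({"y": y, "x": x}), "y ~ x",
                            chains=2, iterations=1200, seed=4, priors=pri)
    r2 = B.fit_hierarchical(pd.DataFrame({"y": y + 10.0, "x": x}), "y ~ x",
                            chains=2, iterations=1200, seed=4, priors=pri)
    s1, s2 = r1.summary(), r2.summary()
    assert s2.loc["b_intercept", "mean"] - s1.loc["b_intercept", "mean"] == \
        pytest.approx(10.0, abs=0.1)
    assert s2.loc["b_x", "mean"] == pytest.approx(s1.loc["b_x", "mean"], abs=0.05)


def test_random_intercept_recovery():
    rng = np.random.default_rng(5)
    G = 150
    g = np.repeat(np.arange(G), 2)
    u = 0.2 * rng.standard_normal(G)
    x = rng.standard_normal(2 * G)
    y = 0.5 - 0.3 * x + u[g] + 0.1 * rng.standard_normal(2 * G)
    df = pd.DataFrame({"y": y, "x": x, "dyad": g})
    res = B.fit_hierarchical(df, "y ~ x + (1|dyad)", chains=2, iterations=1000, seed=6)
    s = res.summary()
    assert s.loc["b_x", "eti_low"] < -0.3 < s.loc["b_x", "eti_high"]
    assert s.loc["tau", "mean"] == pytest.approx(0.2, abs=0.05)
    assert s.loc["sigma", "mean"] == pytest.approx(0.1, abs=0.04)


def test_zero_tau_concentrates_near_zero():
    rng = np.random.default_rng(6)
    G = 200
    g = np.repeat(np.arange(G), 2)
    y = 0.3 + 0.1 * rng.standard_normal(2 * G)
    df = pd.DataFrame({"y": y, "dyad": g})
    res = B.fit_hierarchical(df, "y ~ (1|dyad)", chains=2, iterations=1000, seed=7)
    assert res.summary().loc["tau", "eti_high"] < 0.1


def test_complete_case_drops_missing():
    df = pd.DataFrame({"y": [1.0, np.nan, 3.0, 4.0], "x": [0.0, 1, np.nan, 2]})
    m = B.HierarchicalGaussianModel(df, "y ~ x")
    assert m.n_dropped == 2 and len(m.y) == 2


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_rhat_well_mixed_chains(rng):
    chains = rng.standard_normal((4, 1000))
    assert B.rhat(chains) < 1.01


def test_rhat_separated_chains(rng):
    chains = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 5.0])
    assert B.rhat(chains) > 1.5


def test_rhat_constant_chains_not_applicable():
    assert np.isnan(B.rhat(np.ones((2, 100))))


def test_rhat_agrees_with_arviz(rng):
    az = pytest.importorskip("arviz")
    chains = np.cumsum(rng.standard_normal((4, 800)), axis=1) * 0.01 \
        + rng.standard_normal((4, 800))
    ours = B.rhat(chains)
    theirs = float(az.rhat(az.convert_to_dataset(chains))["x"])
    assert ours == pytest.approx(theirs, abs=0.01)


def test_ess_agrees_with_arviz_order(rng):
    az = pytest.importorskip("arviz")
    chains = rng.standard_normal((4, 800))
    ours = B.ess(chains)
    theirs = float(az.ess(az.convert_to_dataset(chains))["x"])
    assert 0.5 * theirs < ours < 2.0 * theirs


# ---------------------------------------------------------------------------
# predictive checks
# ---------------------------------------------------------------------------

def test_prior_predictive_mean_centered_on_intercept_prior():
    df = pd.DataFrame({"y": np.full(50, 0.3)})
    pri = B.PriorSpec(intercept_mean=0.3, intercept_sd=0.1, sigma_scale=0.01)
    m = B.HierarchicalGaussianModel(df, "y ~ 1", priors=pri)
    pp = B.prior_predictive(m, n_draws=10_000, seed=0)
    assert pp["rep_means"].mean() == pytest.approx(0.3, abs=0.02)


def test_prior_predictive_degenerate_priors():
    df = pd.DataFrame({"y": np.zeros(20)})
    pri = B.PriorSpec(intercept_mean=1.5, intercept_sd=1e-12, sigma_scale=1e-12)
    m = B.HierarchicalGaussianModel(df, "y ~ 1", priors=pri)
    pp = B.prior_predictive(m, n_draws=50, seed=0)
    assert np.allclose(pp["y_rep"], 1.5, atol=1e-6)


def test_prior_predictive_seeded():
    df = pd.DataFrame({"y": np.arange(10.0)})
    m = B.HierarchicalGaussianModel(df, "y ~ 1")
    a = B.prior_predictive(m, 100, seed=5)["y_rep"]
    b = B.prior_predictive(m, 100, seed=5)["y_rep"]
    assert np.array_equal(a, b)


def test_posterior_predictive_well_specified_and_misfit(rng):
    y = 0.5 + 0.2 * rng.standard_normal(200)
    df = pd.DataFrame({"y": y})
    res = B.fit_hierarchical(df, "y ~ 1", chains=2, iterations=800, seed=8)
    pp = B.posterior_predictive(res, seed=0)
    assert 0.05 < pp["observed_mean_percentile"] < 0.95
    # mean-shifted data against the same fitted model
    res.model.y = res.model.y + 1.0
    pp2 = B.posterior_predictive(res, seed=0)
    assert pp2["observed_mean_percentile"] > 0.99


def test_posterior_predictive_deterministic_given_draws(rng):
    y = rng.standard_normal(50)
    res = B.fit_hierarchical(pd.DataFrame({"y": y}), "y ~ 1",
                             chains=2, iterations=400, seed=9)
    a = B.posterior_predictive(res, seed=1)["y_rep"]
    b = B.posterior_predictive(res, seed=1)["y_rep"]
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def test_bf_model_vs_itself_is_one():
    df = pd.DataFrame({"y": np.random.default_rng(0).standard_normal(30)})
    m = B.HierarchicalGaussianModel(df, "y ~ 1")
    bf = B.bayes_factor(m, m)
    assert bf.bf10 == pytest.approx(1.0, abs=bf.mc_error + 1e-12)


def test_savage_dickey_matches_analytic():
    """Single-coefficient normal-prior model with known sigma: the
    Savage-Dickey ratio has a closed form."""
    model, mn, vn = _conjugate_case(seed=2, n=60, sigma=1.0)
    null = B.HierarchicalGaussianModel(model.data, "y ~ 1",
                                       priors=B.PriorSpec(intercept_mean=0.0,
                                                          intercept_sd=2.0,
                                                          beta_sd=1.0),
                                       sigma=1.0)
    bf = B.bayes_factor(model, null, draws=2000, chains=4, seed=10)
    analytic = stats.norm.pdf(0, 0, 1.0) / stats.norm.pdf(0, mn[1], np.sqrt(vn[1, 1]))
    assert abs(bf.bf10 - analytic) < 3 * bf.mc_error


def test_bridge_matches_savage_dickey():
    model, _, _ = _conjugate_case(seed=4, n=60, sigma=1.0)
    pri = B.PriorSpec(intercept_mean=0.0, intercept_sd=2.0, beta_sd=1.0)
    null = B.HierarchicalGaussianModel(model.data, "y ~ 1", priors=pri, sigma=1.0)
    sd = B.bayes_factor(model, null, method="savage_dickey", draws=2000, seed=11)
    br = B.bayes_factor(model, null, method="bridge", draws=2000, seed=11)
    assert br.bf10 == pytest.approx(sd.bf10, rel=0.15)


def test_bf_reciprocity():
    rng = np.random.default_rng(12)
    df = pd.DataFrame({"y": rng.standard_normal(80), "x": rng.standard_normal(80)})
    pri = B.PriorSpec(intercept_mean=0.0, intercept_sd=2.0, beta_sd=1.0, sigma_scale=2.0)
    full = B.HierarchicalGaussianModel(df, "y ~ x", priors=pri)
    null = B.HierarchicalGaussianModel(df, "y ~ 1", priors=pri)
    ab = B.bayes_factor(full, null, method="bridge", draws=1500, seed=13)
    ba = B.bayes_factor(null, full, method="bridge", draws=1500, seed=14)
    assert ab.bf10 * ba.bf10 == pytest.approx(
        1.0, abs=3 * (ab.mc_error * ba.bf10 + ba.mc_error * ab.bf10) + 0.05)


def test_savage_dickey_requires_nesting():
    rng = np.random.default_rng(15)
    df = pd.DataFrame({"y": rng.standard_normal(30), "x": rng.standard_normal(30),
                       "z": rng.standard_normal(30)})
    m1 = B.HierarchicalGaussianModel(df, "y ~ x")
    m2 = B.HierarchicalGaussianModel(df, "y ~ z")
    with pytest.raises(ValueError):
        B.bayes_factor(m1, m2, method="savage_dickey")


# ---------------------------------------------------------------------------
# sequential design
# ---------------------------------------------------------------------------

def test_stopping_decision_support_full():
    bfs = [1.0, 2.0, 6.0, 8.0]
    d = B.stopping_decision(bfs, [20, 25, 30, 35])
    assert d.decision == "support-full" and d.stop_n == 30


def test_stopping_decision_support_null():
    d = B.stopping_decision([1.0, 0.5, 0.1], [20, 25, 30])
    assert d.decision == "support-null" and d.stop_n == 30


def test_stopping_decision_resources_exhausted():
    d = B.stopping_decision([1.0, 0.5, 2.0], [20, 25, 30])
    assert d.decision == "resources-exhausted" and d.stop_n is None


def test_sequential_monitor_stops_on_strong_effect():
    rng = np.random.default_rng(16)
    n = 120
    laughter = np.tile([True, False], n // 2)
    social = np.tile([True, True, False, False], n // 4)
    y = 0.8 * np.where(laughter, 0.5, -0.5) + 0.2 * rng.standard_normal(n)
    df = pd.DataFrame({"y": y, "laughter": laughter, "social": social})
    pri = B.PriorSpec(intercept_mean=0.0, intercept_sd=1.0, beta_sd=1.0)
    d = B.sequential_monitor(df, "y ~ laughter", "y ~ 1",
                             condition_cols=("laughter", "social"),
                             start_n_per_condition=10, step=8, priors=pri,
                             iterations=500, seed=17)
    assert d.decision == "support-full"
    assert d.stop_n is not None and d.stop_n <= n


# ---------------------------------------------------------------------------
# Bayesian ANOVA
# ---------------------------------------------------------------------------

def _anova_data(shift, seed=0, n_per_cell=24, sd=5.0):
    rng = np.random.default_rng(seed)
    rows = []
    for laughter in (True, False):
        for social in (True, False):
            mu = 50.0 + (shift if laughter else 0.0)
            for _ in range(n_per_cell):
                rows.append({"laughter": laughter, "social": social,
                             "y": mu + sd * rng.standard_normal()})
    return pd.DataFrame(rows)


def test_bayesian_anova_null_covers_zero():
    df = _anova_data(shift=0.0, seed=1)
    res = B.bayesian_anova(df, "y", ["laughter", "social"], chains=2,
                           iterations=800, seed=18)
    s = res.summary()
    for term in ("b_laughter", "b_social", "b_laughter:social"):
        assert s.loc[term, "eti_low"] < 0 < s.loc[term, "eti_high"]


def test_bayesian_anova_detects_large_shift():
    df = _anova_data(shift=50.0, seed=2)
    res = B.bayesian_anova(df, "y", ["laughter", "social"], chains=2,
                           iterations=800, seed=19)
    assert res.summary().loc["b_laughter", "eti_low"] > 0


def test_bayesian_anova_label_swap_flips_sign():
    df = _anova_data(shift=30.0, seed=3)
    res1 = B.bayesian_anova(df, "y", ["laughter", "social"], chains=2,
                            iterations=800, seed=20)
    df2 = df.assign(laughter=~df["laughter"])
    res2 = B.bayesian_anova(df2, "y", ["laughter", "social"], chains=2,
                            iterations=800, seed=20)
    m1 = res1.summary().loc["b_laughter", "mean"]
    m2 = res2.summary().loc["b_laughter", "mean"]
    assert m1 == pytest.approx(-m2, abs=0.15 * abs(m1) + 0.5)
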