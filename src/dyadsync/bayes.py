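"""Bayesian Gaussian (hierarchical) linear models with Bayes-factor comparison.

The modelling surface follows the Model/Results convention:
:class:`HierarchicalGaussianModel` is built from a data frame and a compact
formula grammar (``y ~ A*B + x + (1|dyad)``); ``fit()`` runs an in-package
MCMC sampler (conjugate Gibbs updates for coefficients and random intercepts,
slice sampling for the scale parameters under half-normal priors) and returns
a :class:`PosteriorResults` carrying draws, posterior summaries,
rank-normalised split R-hat, effective sample sizes, predictive checks, and a
``summary()`` table.

Two-level factors are effect-coded +/-0.5 so main effects are means of simple
effects under the full factorial expansion.  Bayes factors for nested
comparisons use a Rao-Blackwellised Savage-Dickey density ratio; non-nested
comparisons use bridge sampling of the (random-intercept-marginalised)
unnormalised posterior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, ndtri

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "HierarchicalGaussianModel",
    "PosteriorResults",
    "BFResult",
    "fit_hierarchical",
    "bayes_factor",
    "bayesian_anova",
    "sequential_monitor",
    "stopping_decision",
    "prior_predictive",
    "posterior_predictive",
    "rhat",
    "ess",
]


# ---------------------------------------------------------------------------
# priors and formula grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Priors: normal for the intercept and coefficients, half-normal scales.

    Unset entries are resolved from the response at fit time: coefficient SD
    and the half-normal scales default to 5 * sd(y) ("noninformative"); the
    intercept prior defaults to normal(mean(y), 5 * sd(y)).  The synchrony
    pipeline passes an explicit pilot-informed intercept prior instead
    (normal(0.3, 0.2) by default in the shipped config).
    """

    intercept_mean: float | None = None
    intercept_sd: float | None = None
    beta_sd: float | None = None
    sigma_scale: float | None = None
    tau_scale: float | None = None

    def resolve(self, y: np.ndarray) -> "PriorSpec":
        sd = float(np.std(y)) or 1.0
        return PriorSpec(
            intercept_mean=self.intercept_mean if self.intercept_mean is not None else float(np.mean(y)),
            intercept_sd=self.intercept_sd if self.intercept_sd is not None else 5.0 * sd,
            beta_sd=self.beta_sd if self.beta_sd is not None else 5.0 * sd,
            sigma_scale=self.sigma_scale if self.sigma_scale is not None else 5.0 * sd,
            tau_scale=self.tau_scale if self.tau_scale is not None else 5.0 * sd,
        )


def parse_formula(formula: str) -> tuple[str, list[tuple[str, ...]], str | None]:
    """Parse ``y ~ A*B + x + (1|group)``.

    '*' expands to all non-empty interaction subsets, ':' denotes a single
    interaction.  Returns (response, term list as variable tuples, random
    intercept group or None).  The intercept is implicit.
    """
    lhs, _, rhs = formula.partition("~")
    response = lhs.strip()
    if not response:
        raise ValueError("formula needs a response left of '~'")
    terms: list[tuple[str, ...]] = []
    random_group = None
    for raw in rhs.split("+"):
        tok = raw.strip()
        if not tok or tok == "1":
            continue
        if tok.startswith("(") and tok.endswith(")"):
            inner = tok[1:-1]
            one, _, grp = inner.partition("|")
            if one.strip() != "1" or not grp.strip():
                raise ValueError(f"unsupported random term {tok!r}; only (1|group)")
            random_group = grp.strip()
            continue
        if "*" in tok:
            vars_ = [v.strip() for v in tok.split("*")]
            for r in range(1, len(vars_) + 1):
                for combo in itertools.combinations(vars_, r):
                    if combo not in terms:
                        terms.append(combo)
        else:
            combo = tuple(v.strip() for v in tok.split(":"))
            if combo not in terms:
                terms.append(combo)
    return response, terms, random_group


def _code_variable(col: pd.Series, name: str) -> np.ndarray:
    """Effect-code two-level factors +/-0.5; numeric columns pass through."""
    if col.dtype == bool:
        return np.where(col.to_numpy(), 0.5, -0.5)
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(col.dropna()))
        if len(levels) != 2:
            raise ValueError(f"factor {name!r} must have exactly 2 levels, got {levels}")
        return np.where(col.to_numpy() == levels[1], 0.5, -0.5)
    return col.to_numpy(dtype=float)


@dataclass
class ModelSpec:
    """Response, fixed terms (tuples of variable names), optional random
    intercept group, and priors."""

    response: str
    terms: list
    random_intercept: str | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)

    @classmethod
    def from_formula(cls, formula: str, priors: PriorSpec | None = None) -> "ModelSpec":
        response, terms, group = parse_formula(formula)
        return cls(response, terms, group, priors or PriorSpec())

    @property
    def term_names(self) -> list[str]:
        return [":".join(t) for t in self.terms]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class HierarchicalGaussianModel:
    """Gaussian linear model y = X beta + u_group + eps with normal priors.

    ``sigma`` may be fixed to a known value (conjugate special case used for
    analytic cross-checks); otherwise it carries a half-normal prior and is
    sampled.  Rows with missing values in any referenced column are dropped
    (complete-case) and counted in ``n_dropped``.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | str,
                 priors: PriorSpec | None = None, sigma: float | None = None):
        if isinstance(spec, str):
            spec = ModelSpec.from_formula(spec, priors)
        elif priors is not None:
            spec = ModelSpec(spec.response, spec.terms, spec.random_intercept, priors)
        self.spec = spec
        cols = [spec.response] + sorted({v for t in spec.terms for v in t})
        if spec.random_intercept:
            cols.append(spec.random_intercept)
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"columns not in data: {missing}")
        sub = data[cols].dropna()
        self.n_dropped = len(data) - len(sub)
        self.data = sub.reset_index(drop=True)
        self.y = self.data[spec.response].to_numpy(dtype=float)
        coded = {v: _code_variable(self.data[v], v)
                 for v in {v for t in spec.terms for v in t}}
        columns = [np.ones(len(self.y))]
        self.param_names = ["intercept"]
        for t in spec.terms:
            x = np.ones(len(self.y))
            for v in t:
                x = x * coded[v]
            columns.append(x)
            self.param_names.append(":".join(t))
        self.X = np.column_stack(columns)
        if spec.random_intercept:
            codes, self.group_levels = pd.factorize(self.data[spec.random_intercept])
            self.groups = codes
            self.n_groups = len(self.group_levels)
        else:
            self.groups = None
            self.n_groups = 0
        self.sigma_fixed = sigma
        self.priors = spec.priors.resolve(self.y)
        p = self.X.shape[1]
        self.prior_mean = np.zeros(p)
        self.prior_mean[0] = self.priors.intercept_mean
        self.prior_sd = np.full(p, self.priors.beta_sd)
        self.prior_sd[0] = self.priors.intercept_sd

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     priors: PriorSpec | None = None, sigma: float | None = None):
        return cls(data, formula, priors=priors, sigma=sigma)

    # -- sampling ----------------------------------------------------------

    def fit(self, draws: int = 1000, warmup: int = 500, chains: int = 4,
            seed: int = 0) -> "PosteriorResults":
        if chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")
        store = {"beta": [], "sigma": [], "tau": [], "u": []}
        for c in range(chains):
            rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
            out = self._run_chain(rng, draws, warmup)
            for k in store:
                store[k].append(out[k])
        draws_dict = {k: np.array(v) for k, v in store.items() if v[0] is not None}
        return PosteriorResults(self, draws_dict)

    def _run_chain(self, rng, draws, warmup):
        X, y = self.X, self.y
        n, p = X.shape
        XtX = X.T @ X
        prior_prec = 1.0 / self.prior_sd**2
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma = self.sigma_fixed if self.sigma_fixed is not None else max(resid.std(), 1e-3)
        has_group = self.groups is not None
        u = np.zeros(self.n_groups) if has_group else None
        tau = 0.5 * sigma if has_group else None
        ngroup = np.bincount(self.groups, minlength=self.n_groups) if has_group else None

        b_out = np.empty((draws, p))
        s_out = np.empty(draws)
        t_out = np.empty(draws) if has_group else None
        u_out = np.empty((draws, self.n_groups)) if has_group else None

        for it in range(warmup + draws):
            r = y - (u[self.groups] if has_group else 0.0)
            prec = XtX / sigma**2 + np.diag(prior_prec)
            chol = np.linalg.cholesky(prec)
            rhs = X.T @ r / sigma**2 + prior_prec * self.prior_mean
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)

            fitted = X @ beta
            if has_group:
                res_sum = np.bincount(self.groups, weights=y - fitted,
                                      minlength=self.n_groups)
                prec_u = ngroup / sigma**2 + 1.0 / tau**2
                mean_u = (res_sum / sigma**2) / prec_u
                u = mean_u + rng.standard_normal(self.n_groups) / np.sqrt(prec_u)
                tau = _slice_scale(u, self.priors.tau_scale, tau, rng)
                resid = y - fitted - u[self.groups]
            else:
                resid = y - fitted
            if self.sigma_fixed is None:
                sigma = _slice_scale(resid, self.priors.sigma_scale, sigma, rng)

            if it >= warmup:
                k = it - warmup
                b_out[k] = beta
                s_out[k] = sigma
                if has_group:
                    t_out[k] = tau
                    u_out[k] = u
        return {"beta": b_out, "sigma": s_out, "tau": t_out, "u": u_out}

    # -- log densities used by bridge sampling ----------------------------

    def log_unnormalised_posterior(self, beta, sigma, tau=None) -> float:
        """Log posterior (up to the marginal likelihood) with random intercepts
        integrated out analytically per group."""
        r = self.y - self.X @ beta
        if self.groups is None:
            ll = float(np.sum(stats.norm.logpdf(r, scale=sigma)))
        else:
            ll = 0.0
            s2, t2 = sigma**2, (tau or 0.0) ** 2
            for g in range(self.n_groups):
                rg = r[self.groups == g]
                ng = rg.size
                ss = float(rg @ rg)
                tot = float(rg.sum())
                quad = (ss - t2 / (s2 + ng * t2) * tot**2) / s2
                logdet = (ng - 1) * math.log(s2) + math.log(s2 + ng * t2)
                ll += -0.5 * (ng * math.log(2 * math.pi) + logdet + quad)
        lp = float(np.sum(stats.norm.logpdf(beta, self.prior_mean, self.prior_sd)))
        if self.sigma_fixed is None:
            lp += _halfnormal_logpdf(sigma, self.priors.sigma_scale)
        if self.groups is not None:
            lp += _halfnormal_logpdf(tau, self.priors.tau_scale)
        return ll + lp


def _halfnormal_logpdf(x, scale):
    if x <= 0:
        return -np.inf
    return math.log(2.0) + stats.norm.logpdf(x, scale=scale)


def _slice_scale(values, prior_scale, current, rng, w=0.5, max_steps=50):
    """Slice-sample a scale parameter (SD) with a half-normal prior on the
    log scale; ``values`` are the zero-mean normals it governs."""
    n = values.size
    ss = float(values @ values)

    def logf(t):
        s2 = math.exp(2.0 * t)
        return -n * t - ss / (2.0 * s2) - s2 / (2.0 * prior_scale**2) + t

    t0 = math.log(max(current, 1e-12))
    y0 = logf(t0) + math.log(rng.uniform(1e-300, 1.0))
    lo, hi = t0 - w * rng.uniform(), t0 + w
    for _ in range(max_steps):
        if logf(lo) < y0:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) < y0:
            break
        hi += w
    for _ in range(100):
        t = rng.uniform(lo, hi)
        if logf(t) >= y0:
            return math.exp(t)
        if t < t0:
            lo = t
        else:
            hi = t
    return current


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def rhat(chains_matrix: np.ndarray) -> float:
    """Rank-normalised split R-hat (potential scale reduction factor).

    chains_matrix: (n_chains, n_draws).  Returns NaN when the within-chain
    variance is zero (diagnostic not applicable to constant chains).
    """
    x = np.asarray(chains_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) matrix")
    half = x.shape[1] // 2
    split = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    ranks = stats.rankdata(split, axis=None).reshape(split.shape)
    z = ndtri((ranks - 0.375) / (split.size + 0.25))
    m, n = z.shape
    chain_means = z.mean(axis=1)
    w = z.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess(chains_matrix: np.ndarray) -> float:
    """Bulk effective sample size from rank-normalised split chains, using
    FFT autocorrelations with Geyer's initial monotone positive sequence."""
    x = np.asarray(chains_matrix, dtype=float)
    half = x.shape[1] // 2
    split = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    ranks = stats.rankdata(split, axis=None).reshape(split.shape)
    z = ndtri((ranks - 0.375) / (split.size + 0.25))
    m, n = z.shape
    if n < 4:
        return float(m * n)
    acov = np.empty((m, n))
    for c in range(m):
        d = z[c] - z[c].mean()
        f = np.fft.rfft(d, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n].real / n
        acov[c] = ac
    w = acov[:, 0].mean() * n / (n - 1)
    mean_acov = acov.mean(axis=0)
    var_plus = (w * (n - 1) / n) + (z.mean(axis=1).var(ddof=1) if m > 1 else 0.0)
    if var_plus <= 0:
        return float(m * n)
    rho = 1.0 - (w - mean_acov) / var_plus
    # Geyer initial monotone positive sequence over paired autocorrelations
    tau_int, prev, t = -1.0, np.inf, 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau_int += 2.0 * pair
        prev = pair
        t += 2
    return float(m * n / max(tau_int, 1e-3))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class PosteriorResults:
    """Posterior draws and summaries for a fitted hierarchical Gaussian model."""

    RHAT_GATE = 1.01
    ESS_GATE = 400.0

    def __init__(self, model: HierarchicalGaussianModel, draws: dict):
        self.model = model
        self.draws = draws
        self._summary = None

    # flattened draws, shape (chains*draws,) or (chains*draws, p)
    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def _scalar_chains(self):
        out = {}
        beta = self.draws["beta"]
        for j, name in enumerate(self.model.param_names):
            out[f"b_{name}"] = beta[:, :, j]
        if self.model.sigma_fixed is None:
            out["sigma"] = self.draws["sigma"]
        if "tau" in self.draws:
            out["tau"] = self.draws["tau"]
        return out

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            rows = []
            for name, ch in self._scalar_chains().items():
                flat = ch.reshape(-1)
                lo, hi = np.quantile(flat, [0.025, 0.975])
                rows.append({
                    "param": name, "mean": flat.mean(), "sd": flat.std(ddof=1),
                    "eti_low": lo, "eti_high": hi,
                    "rhat": rhat(ch), "ess": ess(ch),
                })
            self._summary = pd.DataFrame(rows).set_index("param")
        return self._summary

    @property
    def converged(self) -> bool:
        s = self.summary()
        r = s["rhat"].dropna()
        return bool((r <= self.RHAT_GATE).all())

    @property
    def ess_ok(self) -> bool:
        return bool((self.summary()["ess"] >= self.ESS_GATE).all())

    def coef(self, term: str) -> np.ndarray:
        """Flattened posterior draws of one coefficient."""
        j = self.model.param_names.index(term)
        return self.flat("beta")[:, j]

    def posterior_predictive(self, seed: int = 0, max_draws: int = 500):
        return posterior_predictive(self, seed=seed, max_draws=max_draws)


# ---------------------------------------------------------------------------
# predictive checks
# ---------------------------------------------------------------------------

def prior_predictive(model: HierarchicalGaussianModel, n_draws: int = 1000,
                     seed: int = 0) -> dict:
    """Responses simulated from the prior; returns draws and their means."""
    rng = np.random.default_rng(seed)
    n = model.y.size
    reps = np.empty((n_draws, n))
    for i in range(n_draws):
        beta = rng.normal(model.prior_mean, model.prior_sd)
        sigma = model.sigma_fixed if model.sigma_fixed is not None else \
            abs(rng.normal(0.0, model.priors.sigma_scale))
        mu = model.X @ beta
        if model.groups is not None:
            tau = abs(rng.normal(0.0, model.priors.tau_scale))
            u = rng.normal(0.0, tau, model.n_groups)
            mu = mu + u[model.groups]
        reps[i] = mu + rng.normal(0.0, sigma, n)
    return {"y_rep": reps, "rep_means": reps.mean(axis=1),
            "observed_mean": float(model.y.mean())}


def posterior_predictive(results: PosteriorResults, seed: int = 0,
                         max_draws: int = 500) -> dict:
    """Replicated responses per posterior draw plus the observed-mean percentile."""
    rng = np.random.default_rng(seed)
    model = results.model
    beta = results.flat("beta")
    sigma = results.flat("sigma") if "sigma" in results.draws else \
        np.full(beta.shape[0], model.sigma_fixed)
    idx = np.arange(beta.shape[0])
    if idx.size > max_draws:
        idx = np.linspace(0, idx.size - 1, max_draws).astype(int)
    n = model.y.size
    reps = np.empty((idx.size, n))
    u = results.flat("u") if "u" in results.draws else None
    for k, i in enumerate(idx):
        mu = model.X @ beta[i]
        if u is not None:
            mu = mu + u[i][model.groups]
        reps[k] = mu + rng.normal(0.0, sigma[i], n)
    rep_means = reps.mean(axis=1)
    obs = float(model.y.mean())
    pct = float((np.sum(rep_means < obs) + 0.5 * np.sum(rep_means == obs)) / rep_means.size)
    return {"y_rep": reps, "rep_means": rep_means, "observed_mean": obs,
            "observed_mean_percentile": pct}


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

@dataclass
class BFResult:
    bf10: float
    method: str
    mc_error: float
    log_bf10: float = 0.0
    converged: bool = True

    def __post_init__(self):
        if self.bf10 <= 0:
            raise ValueError("BF10 must be positive")


def bayes_factor(full: HierarchicalGaussianModel, null: HierarchicalGaussianModel,
                 method: str = "auto", draws: int = 1000, warmup: int = 500,
                 chains: int = 4, seed: int = 0,
                 full_fit: PosteriorResults | None = None) -> BFResult:
    """BF10 in favour of the full model.

    Nested comparisons (the null's terms are a subset of the full's) use the
    Savage-Dickey density ratio, Rao-Blackwellised: the conditional posterior
    of the dropped coefficient block given each draw of the remaining
    parameters is Gaussian in closed form, so the posterior density at zero is
    the average of those conditional densities.  Non-nested comparisons use
    bridge sampling of each model's marginal likelihood.
    """
    full_terms, null_terms = set(full.param_names), set(null.param_names)
    nested = null_terms <= full_terms and full.spec.random_intercept == null.spec.random_intercept
    if full_terms == null_terms:
        return BFResult(1.0, "analytic", 0.0, 0.0)
    if method == "auto":
        method = "savage_dickey" if nested else "bridge"
    if method == "savage_dickey":
        if not nested:
            raise ValueError("Savage-Dickey requires the null nested in the full model")
        return _savage_dickey(full, sorted(full_terms - null_terms, key=full.param_names.index),
                              draws, warmup, chains, seed, full_fit)
    if method == "bridge":
        lf, ef, cf = _bridge_logml(full, draws, warmup, chains, seed)
        ln, en, cn = _bridge_logml(null, draws, warmup, chains, seed + 1)
        log_bf = lf - ln
        err = math.hypot(ef, en)
        with np.errstate(over="ignore"):
            bf = float(np.exp(log_bf))
        return BFResult(bf, "bridge", bf * err, log_bf, converged=cf and cn)
    raise ValueError(f"unknown method {method!r}")


def _savage_dickey(full, dropped, draws, warmup, chains, seed, full_fit):
    res = full_fit or full.fit(draws=draws, warmup=warmup, chains=chains, seed=seed)
    jdx = np.array([full.param_names.index(t) for t in dropped])
    kdx = np.array([j for j in range(len(full.param_names)) if j not in jdx])
    X, y = full.X, full.y
    Xd, Xk = X[:, jdx], X[:, kdx]
    XdtXd = Xd.T @ Xd
    prior_prec_d = np.diag(1.0 / full.prior_sd[jdx] ** 2)
    prior_mean_d = full.prior_mean[jdx]

    beta = res.flat("beta")
    sigma = res.flat("sigma") if "sigma" in res.draws else \
        np.full(beta.shape[0], full.sigma_fixed)
    u = res.flat("u") if "u" in res.draws else None
    n_draws_tot = beta.shape[0]
    logpdf0 = np.empty(n_draws_tot)
    for i in range(n_draws_tot):
        r = y - Xk @ beta[i, kdx]
        if u is not None:
            r = r - u[i][full.groups]
        prec = XdtXd / sigma[i] ** 2 + prior_prec_d
        mean = np.linalg.solve(prec, Xd.T @ r / sigma[i] ** 2 + prior_prec_d @ prior_mean_d)
        # multivariate normal density at 0
        chol = np.linalg.cholesky(prec)
        logdet_prec = 2.0 * np.log(np.diag(chol)).sum()
        quad = mean @ prec @ mean
        logpdf0[i] = 0.5 * (logdet_prec - len(jdx) * math.log(2 * math.pi) - quad)

    log_post0 = logsumexp(logpdf0) - math.log(n_draws_tot)
    # MC error from batch means (4 batches per chain), robust to autocorrelation
    n_chains = res.draws["beta"].shape[0]
    per_chain = np.exp(logpdf0.reshape(n_chains, -1) - log_post0)
    nb = 4
    width = per_chain.shape[1] // nb
    blocks = per_chain[:, : nb * width].reshape(n_chains * nb, width).mean(axis=1)
    rel_err = blocks.std(ddof=1) / math.sqrt(blocks.size) if blocks.size > 1 else 0.0
    log_prior0 = float(np.sum(stats.norm.logpdf(0.0, prior_mean_d, full.prior_sd[jdx])))
    log_bf = log_prior0 - log_post0
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))  # may be inf for overwhelming evidence
    return BFResult(bf, "savage_dickey", bf * rel_err, log_bf, converged=res.converged)


def _bridge_logml(model, draws, warmup, chains, seed, iterations=200, tol=1e-8):
    """Bridge-sampling estimate of the log marginal likelihood.

    Parameters are mapped to an unconstrained space (log scales); the proposal
    is a Gaussian fitted to the posterior draws; the Meng-Wong fixed point is
    iterated on the log scale.  Returns (log_ml, se_estimate, converged).
    """
    res = model.fit(draws=draws, warmup=warmup, chains=chains, seed=seed)
    beta = res.flat("beta")
    cols = [beta]
    if model.sigma_fixed is None:
        cols.append(np.log(res.flat("sigma"))[:, None])
    if "tau" in res.draws:
        cols.append(np.log(res.flat("tau"))[:, None])
    theta = np.concatenate(cols, axis=1)
    n_post, d = theta.shape
    mu = theta.mean(axis=0)
    cov = np.cov(theta.T) + 1e-10 * np.eye(d)
    prop = stats.multivariate_normal(mu, cov, allow_singular=True)
    rng = np.random.default_rng(seed + 77)
    n_prop = n_post
    theta_prop = prop.rvs(size=n_prop, random_state=rng).reshape(n_prop, d)

    def log_q(th):
        p = len(model.param_names)
        b = th[:p]
        k = p
        if model.sigma_fixed is None:
            sig = math.exp(th[k]); jac = th[k]; k += 1
        else:
            sig = model.sigma_fixed; jac = 0.0
        tau = None
        if model.groups is not None:
            tau = math.exp(th[k]); jac += th[k]
        return model.log_unnormalised_posterior(b, sig, tau) + jac

    lq_post = np.array([log_q(t) for t in theta])
    lq_prop = np.array([log_q(t) for t in theta_prop])
    lg_post = prop.logpdf(theta)
    lg_prop = prop.logpdf(theta_prop)

    l1 = lq_post - lg_post   # at posterior draws
    l2 = lq_prop - lg_prop   # at proposal draws
    s1 = n_post / (n_post + n_prop)
    s2 = n_prop / (n_post + n_prop)
    logml = (np.median(l2) if np.isfinite(np.median(l2)) else np.median(l1))
    for _ in range(iterations):
        num = logsumexp(l2 - np.logaddexp(np.log(s1) + l2 - logml, np.log(s2))) - math.log(n_prop)
        den = logsumexp(-np.logaddexp(np.log(s1) + l1 - logml, np.log(s2))) - math.log(n_post)
        new = num - den
        if abs(new - logml) < tol:
            logml = new
            break
        logml = new
    # crude error: split-half spread
    h = n_post // 2
    def _estimate(i1, i2):
        lm = logml
        for _ in range(50):
            num = logsumexp(l2[i2] - np.logaddexp(np.log(s1) + l2[i2] - lm, np.log(s2))) - math.log(len(i2))
            den = logsumexp(-np.logaddexp(np.log(s1) + l1[i1] - lm, np.log(s2))) - math.log(len(i1))
            lm = num - den
        return lm
    a = _estimate(np.arange(h), np.arange(h))
    b = _estimate(np.arange(h, n_post), np.arange(h, min(2 * h, n_prop)))
    se = abs(a - b) / 2.0 + 1e-12
    return float(logml), float(se), res.converged


# ---------------------------------------------------------------------------
# convenience surfaces
# ---------------------------------------------------------------------------

def fit_hierarchical(data: pd.DataFrame, spec: ModelSpec | str,
                     chains: int = 4, iterations: int = 1000, warmup: int | None = None,
                     seed: int = 0, priors: PriorSpec | None = None,
                     sigma: float | None = None) -> PosteriorResults:
    """Functional wrapper: build and fit a hierarchical Gaussian model."""
    model = HierarchicalGaussianModel(data, spec, priors=priors, sigma=sigma)
    return model.fit(draws=iterations, warmup=warmup if warmup is not None else max(iterations // 2, 200),
                     chains=chains, seed=seed)


def bayesian_anova(data: pd.DataFrame, response: str, factors,
                   priors: PriorSpec | None = None, chains: int = 4,
                   iterations: int = 1000, seed: int = 0) -> PosteriorResults:
    """Factorial Bayesian ANOVA: effect-coded factors, full interaction, no
    random term (a special case of the hierarchical model)."""
    formula = f"{response} ~ {'*'.join(factors)}"
    return fit_hierarchical(data, formula, chains=chains, iterations=iterations,
                            seed=seed, priors=priors)


@dataclass
class SequentialDecision:
    decision: str           # 'support-full' | 'support-null' | 'resources-exhausted'
    stop_n: int | None
    trajectory: pd.DataFrame


def stopping_decision(bf_values, ns, upper: float = 5.0, lower: float = 0.20) -> SequentialDecision:
    """Apply the sequential stopping rule to a BF trajectory."""
    traj = pd.DataFrame({"n": list(ns), "bf10": list(bf_values)})
    for n, bf in zip(ns, bf_values):
        if bf > upper:
            return SequentialDecision("support-full", int(n), traj)
        if bf < lower:
            return SequentialDecision("support-null", int(n), traj)
    return SequentialDecision("resources-exhausted", None, traj)


def sequential_monitor(dyad_stream: pd.DataFrame, full_formula: str, null_formula: str,
                       condition_cols=("laughter", "social"),
                       start_n_per_condition: int = 20, upper: float = 5.0,
                       lower: float = 0.20, step: int = 1,
                       priors: PriorSpec | None = None, chains: int = 2,
                       iterations: int = 600, seed: int = 0) -> SequentialDecision:
    """Sequential Bayes-factor design: accrue dyads in stream order, compute
    BF10(full vs null) at each step once every condition cell holds the
    starting quota, and stop at the first threshold crossing."""
    bfs, ns = [], []
    n_total = len(dyad_stream)
    for n in range(1, n_total + 1, step):
        sub = dyad_stream.iloc[:n]
        if condition_cols:
            counts = sub.groupby(list(condition_cols)).size()
            if len(counts) < 2 ** len(condition_cols) or counts.min() < start_n_per_condition:
                continue
        full = HierarchicalGaussianModel(sub, full_formula, priors=priors)
        null = HierarchicalGaussianModel(sub, null_formula, priors=priors)
        bf = bayes_factor(full, null, draws=iterations, warmup=max(iterations // 2, 200),
                          chains=chains, seed=seed + n)
        bfs.append(bf.bf10)
        ns.append(n)
        if bf.bf10 > upper or bf.bf10 < lower:
            break
    return stopping_decision(bfs, ns, upper, lower)
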