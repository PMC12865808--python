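"""Bayesian mediation at the dyad level: treatment -> mediator -> outcome.

Two Gaussian linear equations are sampled jointly (their parameter blocks are
a priori and a posteriori independent, so index-paired draws from the two
posteriors are draws from the joint posterior):

    M = alpha0 + a * T + gamma' C + eps1
    Y = beta0  + c' * T + b * M + delta' C + eps2

Per posterior draw the average causal mediation effect is ACME = a * b, the
average direct effect ADE = c', the total effect c' + a * b (so
total = ADE + ACME holds exactly per draw in this linear, no-interaction
model), and the proportion mediated ACME / total (draws with |total| below a
tolerance are excluded from the ratio and counted).  Intervals are 95%
equal-tailed posterior quantiles (ETI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import HierarchicalGaussianModel, PriorSpec

__all__ = ["MediationModel", "MediationResult", "fit_mediation", "eti", "mediation_grid"]


def eti(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval: linear-interpolation quantiles."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("no draws")
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [q, 1.0 - q], method="linear")
    return (float(lo), float(hi))


@dataclass
class MediationResult:
    """Posterior summaries of the mediation decomposition."""

    treatment: str
    mediator: str
    outcome: str
    n_dyads: int
    acme: dict
    ade: dict
    total: dict
    prop_mediated: dict
    paths: dict          # 'a', 'b', 'c_prime' -> {mean, eti}
    prop_excluded_frac: float
    draws: dict = field(repr=False, default_factory=dict)
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in [("ACME", self.acme), ("ADE", self.ade), ("total", self.total),
                        ("prop_mediated", self.prop_mediated),
                        ("a (T->M)", self.paths["a"]), ("b (M->Y)", self.paths["b"]),
                        ("c' (T->Y direct)", self.paths["c_prime"])]:
            rows.append({"effect": name, "mean": d["mean"],
                         "eti_low": d["eti"][0], "eti_high": d["eti"][1]})
        return pd.DataFrame(rows).set_index("effect")


class MediationModel:
    """Dyad-level Bayesian mediation model (Model/Results interface)."""

    def __init__(self, data: pd.DataFrame, treatment: str, mediator: str,
                 outcome: str, covariates=(), priors: PriorSpec | None = None):
        cols = [treatment, mediator, outcome, *covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"columns not in data: {missing}")
        sub = data[cols].dropna()
        if len(sub) < 10:
            raise ValueError(
                f"only {len(sub)} complete dyads; mediation needs at least 10 — "
                "collect more dyads or check for missing synchrony values"
            )
        if np.asarray(sub[mediator], dtype=float).std() == 0:
            raise ValueError("mediator is constant; the a and b paths are unidentified")
        self.data = sub.reset_index(drop=True)
        self.treatment, self.mediator, self.outcome = treatment, mediator, outcome
        self.covariates = list(covariates)
        self.priors = priors or PriorSpec()

    def fit(self, draws: int = 1000, warmup: int = 500, chains: int = 4,
            seed: int = 0, zero_total_tol: float = 1e-8,
            keep_draws: bool = True) -> MediationResult:
        cov = " + ".join(self.covariates)
        f_m = f"{self.mediator} ~ {self.treatment}" + (f" + {cov}" if cov else "")
        f_y = (f"{self.outcome} ~ {self.treatment} + {self.mediator}"
               + (f" + {cov}" if cov else ""))
        m_fit = HierarchicalGaussianModel(self.data, f_m, priors=self.priors).fit(
            draws=draws, warmup=warmup, chains=chains, seed=seed)
        y_fit = HierarchicalGaussianModel(self.data, f_y, priors=self.priors).fit(
            draws=draws, warmup=warmup, chains=chains, seed=seed + 1)

        a = m_fit.coef(self.treatment)
        c_prime = y_fit.coef(self.treatment)
        b = y_fit.coef(self.mediator)
        acme = a * b
        ade = c_prime
        total = ade + acme
        keep = np.abs(total) > zero_total_tol
        prop = acme[keep] / total[keep]
        excl = 1.0 - keep.mean()

        def _sumr(d):
            return {"mean": float(np.mean(d)), "eti": eti(d)}

        return MediationResult(
            treatment=self.treatment, mediator=self.mediator, outcome=self.outcome,
            n_dyads=len(self.data),
            acme=_sumr(acme), ade=_sumr(ade), total=_sumr(total),
            prop_mediated=_sumr(prop) if prop.size else {"mean": float("nan"),
                                                         "eti": (float("nan"), float("nan"))},
            paths={"a": _sumr(a), "b": _sumr(b), "c_prime": _sumr(c_prime)},
            prop_excluded_frac=float(excl),
            draws={"a": a, "b": b, "c_prime": c_prime, "acme": acme,
                   "ade": ade, "total": total} if keep_draws else {},
            converged=m_fit.converged and y_fit.converged,
        )


def fit_mediation(dyad_data: pd.DataFrame, treatment: str, mediator: str,
                  outcome: str, covariates=(), priors: PriorSpec | None = None,
                  seed: int = 0, draws: int = 1000, warmup: int = 500,
                  chains: int = 4) -> MediationResult:
    """Functional wrapper over :class:`MediationModel`."""
    return MediationModel(dyad_data, treatment, mediator, outcome,
                          covariates, priors).fit(draws=draws, warmup=warmup,
                                                  chains=chains, seed=seed)


def mediation_grid(dyad_data: pd.DataFrame, treatments, mediator_columns, outcomes,
                   covariates=(), priors: PriorSpec | None = None, seed: int = 0,
                   draws: int = 600, warmup: int = 300, chains: int = 2) -> pd.DataFrame:
    """One mediation model per (treatment x mediator x outcome) cell.

    Returns a flat table with the ACME/ADE/total/b-path summaries and flags
    for cells whose ACME, ADE, or mediator->outcome path ETI excludes zero;
    per-cell failures are recorded, not raised.
    """
    rows = []
    k = 0
    for t in treatments:
        for m in mediator_columns:
            for y in outcomes:
                k += 1
                row = {"treatment": t, "mediator": m, "outcome": y}
                try:
                    res = fit_mediation(dyad_data, t, m, y, covariates=covariates,
                                        priors=priors, seed=seed + k, draws=draws,
                                        warmup=warmup, chains=chains)
                    for eff in ("acme", "ade", "total"):
                        d = getattr(res, eff)
                        row[f"{eff}_mean"] = d["mean"]
                        row[f"{eff}_low"], row[f"{eff}_high"] = d["eti"]
                        row[f"{eff}_excludes_zero"] = d["eti"][0] > 0 or d["eti"][1] < 0
                    bp = res.paths["b"]
                    row["b_mean"] = bp["mean"]
                    row["b_low"], row["b_high"] = bp["eti"]
                    row["b_excludes_zero"] = bp["eti"][0] > 0 or bp["eti"][1] < 0
                    row["n_dyads"] = res.n_dyads
                    row["error"] = None
                except Exception as err:  # noqa: BLE001 — grid continues per spec
                    row["error"] = str(err)
                rows.append(row)
    return pd.DataFrame(rows)
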