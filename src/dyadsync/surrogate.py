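"""Pseudo-dyad surrogate null for interbrain synchrony.

Chance-level synchrony is estimated by pairing each participant with randomly
selected non-partners, averaging the resulting coherence matrices elementwise
(matrix first, scalar second), and comparing real-dyad synchrony against the
pseudo-dyad sample with a Bayesian group comparison per ROI pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import HierarchicalGaussianModel, PriorSpec
from .wtc import (CWTResult, adaptive_period_range, compute_wtc, mask_and_average,
                  morlet_cwt, period_grid, roi_signals)

__all__ = [
    "SurrogatePlan",
    "sample_partners",
    "pseudo_dyad_value",
    "real_vs_surrogate",
    "cohort_surrogate_table",
]


@dataclass(frozen=True)
class SurrogatePlan:
    """How to build the surrogate pool.

    The pool excludes the participant and their true partner; when fewer
    eligible partners than ``n_surrogates`` exist, sampling is with
    replacement (recorded on the plan's log).  Unequal segment lengths are
    truncated to the shorter series before the transform.
    """

    n_surrogates: int = 100
    seed: int = 0
    exclude_self: bool = True
    exclude_partner: bool = True
    length_policy: str = "truncate-to-shorter"

    def __post_init__(self):
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


def sample_partners(participant_id, pool, true_partner, plan: SurrogatePlan,
                    rng: np.random.Generator | None = None,
                    log: list | None = None) -> list:
    """Seeded random surrogate partners, never self or the true partner."""
    eligible = [p for p in pool
                if not (plan.exclude_self and p == participant_id)
                and not (plan.exclude_partner and p == true_partner)]
    if not eligible:
        raise ValueError(f"no eligible surrogate partners for {participant_id!r}")
    rng = rng or np.random.default_rng(plan.seed)
    replace = len(eligible) < plan.n_surrogates
    if replace and log is not None:
        log.append(f"{participant_id}: pool of {len(eligible)} < {plan.n_surrogates}, "
                   "sampling with replacement")
    idx = rng.choice(len(eligible), size=plan.n_surrogates, replace=replace)
    return [eligible[i] for i in idx]


def pseudo_dyad_value(cwt_self: CWTResult, cwt_partners: list[CWTResult],
                      band: tuple[float, float]) -> tuple[float, int]:
    """Average the WTC matrices over all surrogate pairings, then reduce.

    Matrices are averaged elementwise on the common grid before the band/COI
    mask and scalar average are applied (matrix-then-scalar order).  Signals
    of unequal length must already be truncated to a common grid.
    """
    if not cwt_partners:
        raise ValueError("need at least one surrogate partner")
    acc = None
    mask = None
    for cp in cwt_partners:
        w = compute_wtc(cwt_self, cp)
        if acc is None:
            acc = w.coherence.copy()
            mask = w.coi_mask
            template = w
        else:
            acc += w.coherence
    acc /= len(cwt_partners)
    template.coherence = acc
    return mask_and_average(template, band)


class SurrogateComparison:
    """Posterior of the real-minus-pseudo synchrony difference.

    Mimics the fitted-results surface (``summary()`` with a ``b_is_real``
    row) so downstream reporting is uniform.
    """

    def __init__(self, diff_chains: np.ndarray, degenerate_variance: bool):
        from .bayes import ess, rhat

        self.draws = {"b_is_real": diff_chains}
        flat = diff_chains.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        self._summary = pd.DataFrame([{
            "param": "b_is_real", "mean": flat.mean(), "sd": flat.std(ddof=1),
            "eti_low": lo, "eti_high": hi,
            "rhat": rhat(diff_chains), "ess": ess(diff_chains),
        }]).set_index("param")
        self.degenerate_variance = degenerate_variance

    def summary(self) -> pd.DataFrame:
        return self._summary


def real_vs_surrogate(real_values, surrogate_values,
                      priors: PriorSpec | None = None, chains: int = 4,
                      iterations: int = 800, seed: int = 0) -> SurrogateComparison:
    """Bayesian comparison of real vs pseudo-dyad synchrony (one ROI pair).

    Each group's mean is fitted with its own residual SD (intercept-only
    Gaussian models via :func:`~dyadsync.bayes.fit_hierarchical`), because
    pseudo-dyad values are matrix averages over many pairings and are
    systematically less variable than real-dyad values; a common-variance
    model would understate the uncertainty of the difference.  The reported
    ``b_is_real`` posterior is the index-paired difference of the two group
    means (the groups' posteriors are independent).  A degenerate-variance
    input sets a diagnostic flag.
    """
    real_values = np.asarray(real_values, dtype=float)
    surrogate_values = np.asarray(surrogate_values, dtype=float)
    if real_values.size < 2 or surrogate_values.size < 2:
        raise ValueError("need at least 2 values per group")
    fits = []
    for i, vals in enumerate((real_values, surrogate_values)):
        df = pd.DataFrame({"wtc": vals})
        model = HierarchicalGaussianModel(df, "wtc ~ 1", priors=priors)
        fits.append(model.fit(draws=iterations, warmup=max(iterations // 2, 200),
                              chains=chains, seed=seed + i))
    diff = fits[0].draws["beta"][:, :, 0] - fits[1].draws["beta"][:, :, 0]
    degenerate = (real_values.var(ddof=1) <= 1e-14
                  or surrogate_values.var(ddof=1) <= 1e-14)
    return SurrogateComparison(diff, degenerate)


def cohort_surrogate_table(recordings, plan: SurrogatePlan, roi_pairs,
                           phase: str, interval_index: int = 0,
                           min_period_s: float = 8.0, voices_per_octave: int = 12,
                           n_intervals: int = 2) -> pd.DataFrame:
    """Pseudo-dyad synchrony values for a cohort of recordings.

    Participants are pooled across all dyads of the phase (condition- and
    gender-unrestricted pool); each participant is paired with
    ``plan.n_surrogates`` sampled non-partners.  Returns a long table
    mirroring the real synchrony table with ``is_surrogate=True``.

    CWTs are computed once per participant/ROI and reused across pairings.
    """
    rng = np.random.default_rng(plan.seed)
    # participant registry: (dyad_index, member) with truncated common length
    n_common = min(r.phases[phase].shape[2] for r in recordings)
    edges = np.linspace(0, n_common, n_intervals + 1).astype(int)
    sl = slice(edges[interval_index], edges[interval_index + 1])
    fs = recordings[0].sampling_rate_hz
    duration = (sl.stop - sl.start) / fs
    band = adaptive_period_range(duration, min_period_s)
    periods = period_grid(*band, voices_per_octave)

    needed = {r for p in roi_pairs for r in p.split("_")}
    participants = []
    cwts = {}
    for di, rec in enumerate(recordings):
        for member in (0, 1):
            pid = (rec.dyad_id, member)
            participants.append(pid)
            sigs = roi_signals(rec.phases[phase][member][:, sl], rec.channel_rois)
            cwts[pid] = {roi: (morlet_cwt(s, fs, periods) if s is not None else None)
                         for roi, s in sigs.items() if roi in needed}

    rows = []
    for rec in recordings:
        for member in (0, 1):
            pid = (rec.dyad_id, member)
            partner = (rec.dyad_id, 1 - member)
            chosen = sample_partners(pid, participants, partner, plan, rng=rng)
            for pair in roi_pairs:
                a, b = pair.split("_")
                combos = [(a, b)] if a == b else [(a, b), (b, a)]
                vals = []
                for ra, rb in combos:
                    cs = cwts[pid][ra]
                    partners_cwt = [cwts[q][rb] for q in chosen]
                    v, _ = pseudo_dyad_value(cs, partners_cwt, band)
                    if not np.isnan(v):
                        vals.append(v)
                rows.append({
                    "dyad_id": rec.dyad_id, "participant": member, "roi_pair": pair,
                    "phase": phase, "interval": interval_index,
                    "wtc_value": float(np.mean(vals)) if vals else np.nan,
                    "is_surrogate": True,
                })
    return pd.DataFrame(rows)
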