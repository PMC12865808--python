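"""Questionnaire-derived outcome variables and the dyad-level analysis table.

Liking is the mean of three 0-8 items (internal consistency checked with
Cronbach's alpha); bonding is the single-item 1-7 Inclusion-of-Other-in-Self
(IOS) score; prosociality is expressed as two capped ratios (money given to
the other relative to money spent on a friend, and helping willingness toward
the other relative to general helping willingness).  Dyad-level aggregation
follows composite-then-sum: outcomes are summed across the two dyad members,
synchrony is averaged across the two intervals per ROI pair and phase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "composite_liking",
    "cronbach_alpha",
    "money_ratio",
    "helping_ratio",
    "grand_mean_center",
    "build_dyad_dataset",
]


def composite_liking(items) -> float:
    """Arithmetic mean of the three 0-8 liking items."""
    items = np.asarray(items, dtype=float)
    if items.shape != (3,):
        raise ValueError("expected exactly 3 liking items")
    if np.any(items < 0) or np.any(items > 8):
        raise ValueError("liking items must lie on the 0-8 scale")
    return float(items.mean())


def cronbach_alpha(item_matrix, ci: bool = False, level: float = 0.95):
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances) / variance(sum)).

    Sample variances use denominator n-1.  With ``ci=True`` a Feldt-type
    confidence interval based on the F distribution with (n-1) and
    (n-1)(k-1) degrees of freedom is returned as (alpha, (low, high)).
    Zero total-score variance makes alpha undefined (returns NaN).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 respondents, k >= 2 items")
    n, k = x.shape
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return (float("nan"), (float("nan"), float("nan"))) if ci else float("nan")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    if not ci:
        return float(alpha)
    q = 1.0 - level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    low = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - q / 2.0, df1, df2)
    high = 1.0 - (1.0 - alpha) * stats.f.ppf(q / 2.0, df1, df2)
    return float(alpha), (float(low), float(high))


def money_ratio(other_eur: float, friend_eur: float, cap: bool = True) -> float:
    """Money given to the other relative to money spent on a friend, capped at 1.

    friend = 0 edge cases: both zero -> 0; other > 0 with friend = 0 -> 1 (cap).
    """
    if other_eur < 0 or friend_eur < 0:
        raise ValueError("money amounts must be nonnegative")
    if friend_eur == 0:
        return 0.0 if other_eur == 0 else 1.0
    r = other_eur / friend_eur
    return min(r, 1.0) if cap else r


def helping_ratio(help_other: float, help_general: float, cap: bool = True) -> float:
    """Helping willingness toward the other relative to general willingness."""
    for v in (help_other, help_general):
        if not 1 <= v <= 4:
            raise ValueError("helping items must lie on the 1-4 scale")
    r = help_other / help_general
    return min(r, 1.0) if cap else r


def grand_mean_center(values) -> np.ndarray:
    """Subtract the sample grand mean (used for the baseline-liking covariate)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot center an empty vector")
    return values - values.mean()


def participant_scores(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Compute per-participant composites and ratios from raw questionnaire items."""
    df = outcomes.copy()
    df["liking1"] = [
        composite_liking(r) for r in df[[f"liking1_item{j}" for j in (1, 2, 3)]].to_numpy()
    ]
    df["liking2"] = [
        composite_liking(r) for r in df[[f"liking2_item{j}" for j in (1, 2, 3)]].to_numpy()
    ]
    df["money_ratio"] = [
        money_ratio(o, f) for o, f in zip(df["money_other_eur"], df["money_friend_eur"])
    ]
    df["helping_ratio"] = [
        helping_ratio(o, g) for o, g in zip(df["help_other"], df["help_general"])
    ]
    return df


def build_dyad_dataset(outcomes: pd.DataFrame, synchrony: pd.DataFrame,
                       behavior: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per dyad: interval-averaged synchrony per ROI pair and phase,
    member-summed outcomes, and the laughter behavior covariates.

    outcomes: per-participant raw item table (two rows per dyad) — composites
    and ratios are computed here; synchrony: long table from
    :func:`dyadsync.wtc.dyad_synchrony`; behavior: optional per-dyad LBMP/LBFI
    table.  Dyads missing a member or all synchrony values are dropped with a
    reason recorded in ``result.attrs['dropped']``.
    """
    scored = participant_scores(outcomes)
    dropped = {}
    rows = {}
    for dyad_id, grp in scored.groupby("dyad_id"):
        if len(grp) != 2:
            dropped[dyad_id] = f"expected 2 members, found {len(grp)}"
            continue
        row = {"dyad_id": dyad_id}
        for col in ("laughter", "social"):
            if col in grp.columns:
                row[col] = grp[col].iloc[0]
        row["liking1_sum"] = grp["liking1"].sum()
        row["liking2_sum"] = grp["liking2"].sum()
        row["ios_sum"] = grp["ios"].sum()
        row["money_ratio_sum"] = grp["money_ratio"].sum()
        row["helping_ratio_sum"] = grp["helping_ratio"].sum()
        rows[dyad_id] = row

    sync_mean = (
        synchrony.dropna(subset=["wtc_value"])
        .groupby(["dyad_id", "roi_pair", "phase"])["wtc_value"]
        .mean()
    )
    for (dyad_id, roi_pair, phase), v in sync_mean.items():
        if dyad_id in rows:
            rows[dyad_id][f"sync_{roi_pair}_{phase}"] = v

    if behavior is not None:
        for _, b in behavior.iterrows():
            if b["dyad_id"] in rows:
                rows[b["dyad_id"]]["lbmp"] = b["lbmp"]
                rows[b["dyad_id"]]["lbfi"] = b["lbfi"]

    out = pd.DataFrame(list(rows.values()))
    if not out.empty and "liking1_sum" in out:
        out["liking1_centered"] = grand_mean_center(out["liking1_sum"].to_numpy())
    out.attrs["dropped"] = dropped
    return out
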