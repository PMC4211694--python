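"""Relative quantification from qPCR Ct tables and exact rank-sum testing.

Expression of each target miRNA is normalized to two endogenous controls
(U6 snRNA and 5S rRNA): dCt = Ct_target - mean(Ct_U6, Ct_5S), the arithmetic
mean of the reference Cts being equivalent to geometric-mean normalization
in expression space.  Between conditions, ddCt = mean(dCt_treated) -
mean(dCt_control) and fold change = 2**(-ddCt), so ddCt = -1 is a two-fold
induction.  Group differences are assessed with the Wilcoxon-Mann-Whitney
test: the U statistic counts pairwise wins with half credit for ties, and
the two-sided p-value is exact (full enumeration of rank assignments by
dynamic programming) up to a combined sample size of 25, switching to the
tie-corrected normal approximation beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GroupComparison",
    "delta_ct",
    "fold_change",
    "mann_whitney_u",
    "mann_whitney_exact",
    "compare_groups",
    "analyze_ct_table",
]

EXACT_LIMIT = 25  # combined sample size up to which the exact null is enumerated


@dataclass(frozen=True)
class GroupComparison:
    """ddCt comparison of one target between control and treated groups."""

    ddct: float
    fold_change: float
    u: float
    p_two_sided: float
    n_control: int
    n_treated: int
    mean_dct_control: float
    mean_dct_treated: float


def delta_ct(ct_target: float, ct_u6: float, ct_5s: float) -> float:
    """dCt against the mean of the two endogenous controls."""
    for name, v in (("target", ct_target), ("U6", ct_u6), ("5S", ct_5s)):
        if v is None or not (0 < v < 45) or math.isnan(v):
            raise ValueError(f"Ct value for {name} outside (0, 45): {v!r}")
    return ct_target - (ct_u6 + ct_5s) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic: pairs where x beats y, with 0.5 credit for ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


@lru_cache(maxsize=64)
def _null_u_distribution(ranks2: tuple[int, ...], n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact permutation distribution of U for group sizes (n1, N-n1).

    ``ranks2`` holds doubled midranks (integers even with 0.5-ties).  Returns
    (u_values, counts) where u = (ranksum2 - n1*(n1+1)) / 2 carries the
    0.5 tie credit automatically.  Counts stay exact in int64 for N <= 25.
    """
    n_total = len(ranks2)
    max_sum = sum(sorted(ranks2)[-n1:]) if n1 else 0
    # dp[k, s] = number of k-subsets of processed items with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in ranks2:
        for k in range(min(n1, n_total), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    sums = np.nonzero(dp[n1])[0]
    counts = dp[n1][sums]
    u_values = (sums - n1 * (n1 + 1)) / 2.0
    return u_values, counts


def _exact_p(x: Sequence[float], y: Sequence[float], u_obs: float) -> float:
    n1, n2 = len(x), len(y)
    combined = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    # sorted so the cache key depends only on the rank multiset
    ranks2 = tuple(sorted(int(round(2 * r)) for r in rankdata(combined)))
    u_values, counts = _null_u_distribution(ranks2, n1)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    mask = np.abs(u_values - mu) >= dev - 1e-9
    return float(counts[mask].sum() / counts.sum())


def _normal_p(x: Sequence[float], y: Sequence[float], u_obs: float) -> float:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return float(math.erfc(z / math.sqrt(2.0)))


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """(U, two-sided p); exact for n_x + n_y <= 25, else normal approximation.

    The two-sided p is P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) under the
    permutation null; with every observation identical across both groups
    the statistic is degenerate and p = 1.
    """
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    u_obs = mann_whitney_u(x, y)
    if len(set(x) | set(y)) == 1:
        return u_obs, 1.0
    if len(x) + len(y) <= EXACT_LIMIT:
        return u_obs, _exact_p(x, y, u_obs)
    return u_obs, _normal_p(x, y, u_obs)


def fold_change(
    control_dcts: Sequence[float], treated_dcts: Sequence[float]
) -> GroupComparison:
    """ddCt / fold change plus the exact rank-sum comparison of dCt groups."""
    if len(control_dcts) < 1 or len(treated_dcts) < 1:
        raise ValueError("both groups must be non-empty")
    mean_c = float(np.mean(control_dcts))
    mean_t = float(np.mean(treated_dcts))
    ddct = mean_t - mean_c
    u, p = mann_whitney_exact(control_dcts, treated_dcts)
    return GroupComparison(
        ddct=ddct,
        fold_change=2.0 ** (-ddct),
        u=u,
        p_two_sided=p,
        n_control=len(control_dcts),
        n_treated=len(treated_dcts),
        mean_dct_control=mean_c,
        mean_dct_treated=mean_t,
    )


compare_groups = fold_change


def analyze_ct_table(
    ct: pd.DataFrame,
    control_group: str = "normoxia",
    treated_group: str = "hypoxia",
) -> pd.DataFrame:
    """Per-(target, tissue, sex) ddCt comparisons from a Ct table.

    Expected columns: sample_id, target, ct_target, ct_u6, ct_5s, group,
    tissue, sex.  Technical replicate rows of one biological sample are
    averaged to a single Ct per (sample_id, target) before any statistics.
    """
    required = {"sample_id", "target", "ct_target", "ct_u6", "ct_5s", "group",
                "tissue", "sex"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    keys = ["target", "tissue", "sex", "group", "sample_id"]
    averaged = ct.groupby(keys, as_index=False)[["ct_target", "ct_u6", "ct_5s"]].mean()
    averaged["dct"] = [
        delta_ct(r.ct_target, r.ct_u6, r.ct_5s)
        for r in averaged.itertuples(index=False)
    ]
    rows = []
    for (target, tissue, sex), sub in averaged.groupby(["target", "tissue", "sex"]):
        control = sub.loc[sub["group"] == control_group, "dct"].tolist()
        treated = sub.loc[sub["group"] == treated_group, "dct"].tolist()
        if not control or not treated:
            continue
        cmp = fold_change(control, treated)
        rows.append(
            {
                "target": target,
                "tissue": tissue,
                "sex": sex,
                "n_control": cmp.n_control,
                "n_treated": cmp.n_treated,
                "ddct": cmp.ddct,
                "fold_change": cmp.fold_change,
                "u": cmp.u,
                "p_two_sided": cmp.p_two_sided,
            }
        )
    return pd.DataFrame(rows).sort_values(["target", "tissue", "sex"]).reset_index(
        drop=True
    )
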