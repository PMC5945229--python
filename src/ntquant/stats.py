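"""Group comparisons with exact small-sample behavior.

Two-group comparisons use a two-sided two-sample Student t test (pooled
variance by default, Welch optional) for means, or a two-sided Mann-Whitney
U test for medians — exact when the combined sample is small (full
enumeration of the null distribution of U; with combined n <= 20 this is at
most C(20, 10) = 184,756 assignments), and the tie-corrected normal
approximation otherwise.  Three or more groups use one-way ANOVA with Tukey
HSD pairwise comparisons, or Kruskal-Wallis with Dunn's rank-based pairwise
z tests under a Bonferroni-family adjustment (the convention of common
point-and-click statistics packages).

Significance stars follow the usual figure-legend convention: ns p > 0.05,
* p < 0.05, ** p < 0.01, *** p < 0.001, with boundary values mapped to the
less significant label.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "compare_two",
    "compare_many",
    "mannwhitney_exact",
    "dunn_posthoc",
    "star_code",
    "EXACT_ENUMERATION_LIMIT",
]

EXACT_ENUMERATION_LIMIT = 20  # combined n at or below which the U null is enumerated


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two- or multi-group comparison."""

    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    pairwise: pd.DataFrame | None = None  # columns: group_a, group_b, statistic, p, p_adj, stars
    stars: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value!r} outside [0, 1]")


def star_code(p: float) -> str:
    """Significance stars; boundary p-values get the less significant label."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mannwhitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by full enumeration.

    Enumerates every assignment of the pooled midranks to the two groups and
    doubles the smaller tail of the U null distribution (capped at 1).
    Handles ties exactly, since the enumeration is over the realized
    midranks.  Intended for combined n <= ``EXACT_ENUMERATION_LIMIT``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    total = comb(n_a + n_b, n_a)
    n_le = 0
    n_ge = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = _u_statistic(ranks[list(idx)], n_a, n_b)
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    n = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    if n <= EXACT_ENUMERATION_LIMIT:
        if has_ties:
            u, p = mannwhitney_exact(a, b)
            return u, p, "Mann-Whitney U (exact, ties)"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "Mann-Whitney U (exact)"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "Mann-Whitney U (asymptotic)"


def compare_two(a, b, mode: str = "nonparametric",
                welch: bool = False) -> ComparisonResult:
    """Two-sided two-group comparison.

    ``mode="parametric"`` runs a Student t test (pooled variance unless
    ``welch``); ``mode="nonparametric"`` a Mann-Whitney U test, exact for
    combined n <= 20.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if mode == "parametric":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("zero variance in both groups: t test undefined")
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        name = "Welch t" if welch else "Student t"
        return ComparisonResult(name, float(t), float(p), (len(a), len(b)),
                                stars=star_code(float(p)))
    if mode != "nonparametric":
        raise ValueError("mode must be 'parametric' or 'nonparametric'")
    u, p, name = _mannwhitney(a, b)
    return ComparisonResult(name, u, p, (len(a), len(b)), stars=star_code(p))


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    For groups i, j the statistic is z = (Rbar_i - Rbar_j) / SE with
    SE = sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) and the tie correction
    T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values are adjusted
    over all pairs by Bonferroni (default) or Holm.
    """
    if adjust not in ("bonferroni", "holm"):
        raise ValueError("adjust must be 'bonferroni' or 'holm'")
    labels = labels or [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + len(g)].mean()))
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "statistic": float(z), "p": p})
    table = pd.DataFrame(rows)
    k = len(table)
    if adjust == "bonferroni":
        table["p_adj"] = np.minimum(1.0, table["p"] * k)
    else:  # holm step-down
        order = np.argsort(table["p"].to_numpy())
        adj = np.empty(k)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * table["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adj"] = adj
    table["stars"] = [star_code(p) for p in table["p_adj"]]
    return table


def compare_many(groups: list, mode: str = "nonparametric",
                 labels: list[str] | None = None,
                 adjust: str = "bonferroni") -> ComparisonResult:
    """Omnibus comparison of three or more groups with pairwise follow-up.

    Parametric: one-way ANOVA with Tukey HSD pairwise comparisons.
    Nonparametric: Kruskal-Wallis with Dunn's pairwise tests.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("compare_many needs at least 3 groups (use compare_two)")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    labels = labels or [str(i) for i in range(len(groups))]
    sizes = tuple(len(g) for g in groups)

    if mode == "parametric":
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = (float(x) for x in sps.f_oneway(*groups))
        hsd = sps.tukey_hsd(*groups)
        rows = []
        for i, j in combinations(range(len(groups)), 2):
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "statistic": float(hsd.statistic[i, j]),
                         "p": float(hsd.pvalue[i, j]),
                         "p_adj": float(hsd.pvalue[i, j]),  # Tukey p is family-adjusted
                         "stars": star_code(float(hsd.pvalue[i, j]))})
        pairwise = pd.DataFrame(rows)
        return ComparisonResult("one-way ANOVA + Tukey HSD", stat, p, sizes,
                                pairwise=pairwise, stars=star_code(p))
    if mode != "nonparametric":
        raise ValueError("mode must be 'parametric' or 'nonparametric'")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = (float(x) for x in sps.kruskal(*groups))
    pairwise = dunn_posthoc(groups, labels=labels, adjust=adjust)
    return ComparisonResult("Kruskal-Wallis + Dunn", stat, p, sizes,
                            pairwise=pairwise, stars=star_code(p))
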