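"""Statistical comparisons used throughout the pipeline's figures.

Two-group comparisons (Mann–Whitney U with exact enumeration for small
samples, Welch's t, paired t), factorial layouts (one- and two-way
ANOVA with Šídák / Holm-Šídák / Dunn / Dunnett-T3 post-hoc
corrections), Shapiro–Wilk normality, all reported in a uniform
:class:`ComparisonResult` record carrying medians + IQR and
means ± SEM per group.

The exact Mann–Whitney p-value enumerates all C(n1+n2, n1) group
assignments whenever min(n1, n2) ≤ 8 (ties included); larger samples
use the normal approximation with midranks, tie correction and
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import scipy.stats

__all__ = [
    "ComparisonResult",
    "compare_two",
    "compare_factorial",
    "normality",
    "mann_whitney_exact",
    "sidak_adjust",
    "holm_sidak_adjust",
]

_EXACT_U_MAX_N = 8


@dataclass(frozen=True)
class ComparisonResult:
    """Uniform report record for one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    group_sizes: tuple = ()
    effect_summary: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def _summary(groups: dict) -> dict:
    out = {}
    for name, g in groups.items():
        g = np.asarray(g, dtype=float)
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        out[name] = {
            "n": int(g.size),
            "mean": float(g.mean()),
            "sem": float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan"),
            "median": float(med),
            "iqr": (float(q1), float(q3)),
        }
    return out


# ---------------------------------------------------------------------------
# two-group comparisons
# ---------------------------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a vs b via midranks (handles ties)."""
    n1, n2 = len(a), len(b)
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by full enumeration of all
    C(n1+n2, n1) assignments of the pooled observations.

    Two-sided p: fraction of assignments whose U is at least as far from
    the null mean n1·n2/2 as the observed U.  Valid with ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu) - 1e-12
    n_total = n1 + n2
    hits = 0
    for idx in combinations(range(n_total), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
        if abs(u - mu) >= dev:
            hits += 1
    return u_obs, hits / comb(n_total, n1)


def compare_two(a, b, paired: bool = False, method: str = "mannwhitney") -> ComparisonResult:
    """Compare two samples.

    ``method``: ``"mannwhitney"`` (exact enumeration when
    min(n1, n2) ≤ 8, normal approximation with continuity correction
    otherwise), ``"welch"``, or ``"ttest"``/``"paired"`` with
    ``paired=True`` for the paired Student's t-test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired or method in ("paired", "ttest_paired"):
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = scipy.stats.ttest_rel(a, b)
        name = "paired t-test"
    elif method == "welch":
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        name = "Welch's t-test"
    elif method == "mannwhitney":
        if min(len(a), len(b)) <= _EXACT_U_MAX_N:
            stat, p = mann_whitney_exact(a, b)
            name = "Mann-Whitney U (exact)"
        else:
            res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
            name = "Mann-Whitney U (asymptotic)"
    else:
        raise ValueError(f"unknown method: {method!r}")
    return ComparisonResult(
        name,
        float(stat),
        float(min(p, 1.0)),
        group_sizes=(len(a), len(b)),
        effect_summary=_summary({"a": a, "b": b}),
    )


# ---------------------------------------------------------------------------
# multiple-comparison adjustments
# ---------------------------------------------------------------------------


def sidak_adjust(pvals) -> np.ndarray:
    """Šídák adjustment: p_adj = 1 − (1 − p)^m."""
    p = np.asarray(pvals, dtype=float)
    return np.clip(1.0 - (1.0 - p) ** len(p), 0.0, 1.0)


def holm_sidak_adjust(pvals) -> np.ndarray:
    """Holm-Šídák step-down adjustment, monotone in the raw-p ranking."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for rank, i in enumerate(order):
        val = 1.0 - (1.0 - p[i]) ** (m - rank)
        running_max = max(running_max, val)
        adj[i] = min(running_max, 1.0)
    return adj


# ---------------------------------------------------------------------------
# factorial comparisons
# ---------------------------------------------------------------------------


def _pairwise_posthoc(groups: dict, correction: str) -> list[ComparisonResult]:
    names = list(groups.keys())
    raw: list[tuple] = []
    if correction == "dunn":
        # rank-based Dunn test on the pooled midranks
        pooled = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
        ranks = scipy.stats.rankdata(pooled)
        sizes = [len(groups[n]) for n in names]
        splits = np.cumsum(sizes)[:-1]
        rank_groups = dict(zip(names, np.split(ranks, splits)))
        n_tot = len(pooled)
        # tie correction for the rank variance
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (12.0 * (n_tot - 1))
        for g1, g2 in combinations(names, 2):
            r1, r2 = rank_groups[g1], rank_groups[g2]
            se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term) * (1 / len(r1) + 1 / len(r2)))
            z = (r1.mean() - r2.mean()) / se
            p = 2 * scipy.stats.norm.sf(abs(z))
            raw.append((g1, g2, float(z), float(p), "Dunn"))
    else:
        # Welch-type pairwise t (also the basis of the Dunnett-T3 variant,
        # whose studentised-maximum-modulus bound is approximated by Sidak)
        for g1, g2 in combinations(names, 2):
            stat, p = scipy.stats.ttest_ind(groups[g1], groups[g2], equal_var=False)
            label = "Dunnett T3 (Welch/Sidak bound)" if correction == "dunnett-t3" else "Welch pairwise"
            raw.append((g1, g2, float(stat), float(p), label))

    pvals = [r[3] for r in raw]
    if correction in ("sidak", "dunn", "dunnett-t3"):
        adj = sidak_adjust(pvals)
    elif correction == "holm-sidak":
        adj = holm_sidak_adjust(pvals)
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    out = []
    for (g1, g2, stat, p, label), pa in zip(raw, adj):
        out.append(
            ComparisonResult(
                f"{label}: {g1} vs {g2}",
                stat,
                p,
                adjusted_p=float(pa),
                group_sizes=(len(groups[g1]), len(groups[g2])),
                effect_summary=_summary({g1: groups[g1], g2: groups[g2]}),
            )
        )
    return out


def compare_factorial(
    values,
    factor1,
    factor2=None,
    correction: str = "holm-sidak",
) -> list[ComparisonResult]:
    """Omnibus ANOVA plus pairwise post-hoc comparisons.

    One factor → one-way ANOVA with post-hoc over factor-1 levels.  Two
    factors → two-way ANOVA (type-II sums of squares, with interaction)
    with post-hoc over the factor-1 levels within each factor-2 level.
    ``correction``: ``"sidak"``, ``"holm-sidak"``, ``"dunn"`` or
    ``"dunnett-t3"``.  The omnibus result(s) come first in the returned
    list.
    """
    values = np.asarray(values, dtype=float)
    factor1 = np.asarray(factor1)
    if factor2 is not None:
        factor2 = np.asarray(factor2)
        if len(factor2) != len(values):
            raise ValueError("factor2 length mismatch")
    if len(factor1) != len(values):
        raise ValueError("factor1 length mismatch")

    results: list[ComparisonResult] = []
    if factor2 is None:
        groups = {str(l): values[factor1 == l] for l in np.unique(factor1)}
        if len(groups) < 2:
            raise ValueError("need at least 2 levels")
        for g in groups.values():
            if len(g) < 2:
                raise ValueError("every cell needs at least 2 observations")
        f, p = scipy.stats.f_oneway(*groups.values())
        results.append(
            ComparisonResult(
                "one-way ANOVA",
                float(f),
                float(p),
                group_sizes=tuple(len(g) for g in groups.values()),
                effect_summary=_summary(groups),
            )
        )
        results.extend(_pairwise_posthoc(groups, correction))
        return results

    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": values, "f1": factor1.astype(str), "f2": factor2.astype(str)})
    for (_, _), cell in df.groupby(["f1", "f2"]):
        if len(cell) < 2:
            raise ValueError("every cell needs at least 2 observations")
    model = smf.ols("value ~ C(f1) * C(f2)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    for term in ("C(f1)", "C(f2)", "C(f1):C(f2)"):
        results.append(
            ComparisonResult(
                f"two-way ANOVA (type II): {term.replace('C(f1)', 'factor1').replace('C(f2)', 'factor2')}",
                float(table.loc[term, "F"]),
                float(table.loc[term, "PR(>F)"]),
                group_sizes=tuple(df.groupby(["f1", "f2"]).size()),
            )
        )
    for lvl2, sub in df.groupby("f2"):
        groups = {f"{l}|{lvl2}": sub.loc[sub.f1 == l, "value"].to_numpy() for l in sub.f1.unique()}
        if len(groups) >= 2:
            results.extend(_pairwise_posthoc(groups, correction))
    return results


def normality(sample) -> ComparisonResult:
    """Shapiro–Wilk normality test (3 ≤ n ≤ 5000)."""
    sample = np.asarray(sample, dtype=float)
    if not 3 <= len(sample) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = scipy.stats.shapiro(sample)
    return ComparisonResult(
        "Shapiro-Wilk",
        float(w),
        float(p),
        group_sizes=(len(sample),),
        effect_summary=_summary({"sample": sample}),
    )
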