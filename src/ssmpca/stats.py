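"""Group-comparison statistics for pattern-expression scores.

The decision logic mirrors common practice for score tables: normality of
each group (Lilliefors) and homogeneity of variance (Levene) gate the
choice between one-way ANOVA with pooled-t post-hocs and Kruskal-Wallis
with Mann-Whitney post-hocs; pairwise post-hoc p-values are Holm-adjusted
as one family. A chlorpromazine-equivalent utility converts antipsychotic
doses to a common scale via user-supplied drug ratios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatValidationError(ValueError):
    pass


class DegeneracyError(ValueError):
    """Sample has no variation where the test requires some."""


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatValidationError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo null, seeded for reproducibility)

_LILLIEFORS_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_statistic(sample: np.ndarray) -> float:
    """Sup distance between the sample ECDF and N(mean, sd) fitted to it."""
    x = np.sort(sample)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_NULL_CACHE:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_mc, n))
        draws.sort(axis=1)
        z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf(z)
        i = np.arange(1, n + 1)
        stat = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
        _LILLIEFORS_NULL_CACHE[key] = stat
    return _LILLIEFORS_NULL_CACHE[key]


def lilliefors_test(sample: Sequence[float], n_mc: int = 10_000, seed: int = 0,
                    alpha: float = 0.05) -> StatResult:
    """Normality test with estimated mean/sd and a seeded Monte-Carlo null.

    The p-value is ``(1 + #{null stats >= observed}) / (n_mc + 1)`` over
    ``n_mc`` standard-normal samples of the same size; identical seeds give
    identical p-values. The null distribution is location/scale-free, so
    standard-normal draws suffice.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 4:
        raise StatValidationError(f"need n >= 4, got {x.size}")
    if x.std(ddof=1) == 0:
        raise DegeneracyError("sample is constant; normality test undefined")
    stat = _lilliefors_statistic(x)
    null = _lilliefors_null(x.size, n_mc, seed)
    p = (1 + int((null >= stat - 1e-15).sum())) / (n_mc + 1)
    return StatResult("lilliefors", stat, p, df=x.size, alpha=alpha)


def levene_test(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> StatResult:
    """Levene's test on absolute deviations from group means."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise StatValidationError("need >= 2 groups with >= 2 observations each")
    k, n = len(groups), sum(g.size for g in groups)
    if all(np.allclose(g, g.mean()) for g in groups):
        # zero spread in every group: no evidence of unequal variances
        return StatResult("levene", 0.0, 1.0, df=(k - 1, n - k), alpha=alpha)
    stat, p = sps.levene(*groups, center="mean")
    return StatResult("levene", float(stat), float(p), df=(k - 1, n - k), alpha=alpha)


def oneway_anova(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> StatResult:
    """One-way fixed-effects ANOVA F-test."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise StatValidationError("need >= 2 groups with >= 2 observations each")
    if all(g.std() == 0 for g in groups):
        raise DegeneracyError("zero within-group variance in every group")
    stat, p = sps.f_oneway(*groups)
    k, n = len(groups), sum(g.size for g in groups)
    return StatResult("anova", float(stat), float(p), df=(k - 1, n - k), alpha=alpha)


def kruskal_wallis(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> StatResult:
    """Kruskal-Wallis H with tie correction, chi-square null."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups) or sum(g.size for g in groups) < 3:
        raise StatValidationError("need >= 2 non-empty groups, total n >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise DegeneracyError("all observations identical")
    stat, p = sps.kruskal(*groups)
    return StatResult("kruskal-wallis", float(stat), float(p), df=len(groups) - 1, alpha=alpha)


def mann_whitney(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> StatResult:
    """Mann-Whitney U: exact two-sided p by enumeration when n_a+n_b <= 12,
    tie-corrected normal approximation otherwise.

    U counts pairs where an ``a`` observation exceeds a ``b`` one (ties
    count one half). The exact null enumerates every assignment of the
    pooled ranks to the two samples, so it remains valid under ties.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise StatValidationError("both samples must be non-empty")
    na, nb = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u = float(ranks[:na].sum() - na * (na + 1) / 2)
    if na + nb <= 12:
        p = _mwu_exact_p(ranks, na, u)
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StatResult("mann-whitney", u, float(p), df=None, alpha=alpha)


def _mwu_exact_p(ranks: np.ndarray, na: int, u_obs: float) -> float:
    """Two-sided exact p over all C(n, na) rank assignments (tie-safe)."""
    n = ranks.size
    mu = na * (n - na) / 2.0
    null_u = np.array([
        sum(combo) - na * (na + 1) / 2
        for combo in itertools.combinations(ranks, na)
    ])
    # two-sided: as or more extreme in distance from the null mean
    p = float(np.mean(np.abs(null_u - mu) >= abs(u_obs - mu) - 1e-12))
    return min(1.0, p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, monotone, capped at 1, in input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise StatValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def spearman_corr(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> StatResult:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise StatValidationError("need equal-length samples with n >= 3")
    if sps.rankdata(x).std() == 0 or sps.rankdata(y).std() == 0:
        raise DegeneracyError("zero rank variance")
    r, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(r), float(p), df=x.size - 2, alpha=alpha)


def compare_groups(scores: pd.DataFrame, alpha: float = 0.05, fwer: float = 0.05,
                   value_column: str = "z_score", n_mc: int = 10_000,
                   seed: int = 0) -> dict:
    """Full decision-trail comparison of scores across groups.

    Gate tests: Lilliefors per group and Levene across groups. If every
    group passes normality (p > 0.05) and variances are homogeneous
    (p > 0.05), the parametric branch runs one-way ANOVA with pairwise
    pooled-t post-hocs; otherwise Kruskal-Wallis with pairwise
    Mann-Whitney post-hocs. Post-hoc p-values are Holm-adjusted as one
    family (the omnibus test is not in the family).
    """
    if "group" not in scores.columns or value_column not in scores.columns:
        raise StatValidationError(f"score table needs 'group' and {value_column!r} columns")
    labels = list(dict.fromkeys(scores["group"]))  # preserve first-appearance order
    if len(labels) < 2:
        raise StatValidationError("need >= 2 groups to compare")
    samples = {g: scores.loc[scores["group"] == g, value_column].to_numpy(dtype=np.float64)
               for g in labels}

    normality = {g: lilliefors_test(s, n_mc=n_mc, seed=seed) for g, s in samples.items()}
    variance = levene_test(list(samples.values()))
    parametric = all(r.p_value > 0.05 for r in normality.values()) and variance.p_value > 0.05

    if parametric:
        omnibus = oneway_anova(list(samples.values()), alpha=alpha)
        def pairwise(a, b):
            t, p = sps.ttest_ind(a, b, equal_var=True)
            return float(t), float(p)
        posthoc_name = "pooled-t"
    else:
        omnibus = kruskal_wallis(list(samples.values()), alpha=alpha)
        def pairwise(a, b):
            r = mann_whitney(a, b)
            return r.statistic, r.p_value
        posthoc_name = "mann-whitney"

    pairs = list(itertools.combinations(labels, 2))
    raw = []
    stats_ = []
    for ga, gb in pairs:
        s, p = pairwise(samples[ga], samples[gb])
        stats_.append(s)
        raw.append(p)
    adjusted = holm_adjust(raw)

    return {
        "groups": labels,
        "group_means": {g: float(np.mean(s)) for g, s in samples.items()},
        "normality": {g: {"statistic": r.statistic, "p": r.p_value} for g, r in normality.items()},
        "levene": {"statistic": variance.statistic, "p": variance.p_value},
        "branch": "parametric" if parametric else "nonparametric",
        "omnibus": {"test": omnibus.test_name, "statistic": omnibus.statistic,
                    "p": omnibus.p_value, "significant": bool(omnibus.p_value < alpha)},
        "posthoc": [
            {"pair": f"{ga} vs {gb}", "test": posthoc_name, "statistic": float(s),
             "p_raw": float(p), "p_holm": float(q), "significant": bool(q < fwer)}
            for (ga, gb), s, p, q in zip(pairs, stats_, raw, adjusted)
        ],
    }


# ---------------------------------------------------------------------------
# Chlorpromazine equivalents

@dataclass(frozen=True)
class DoseRecord:
    drug: str
    dose_mg: float


def read_ratio_table(path: str | Path) -> dict[str, float]:
    """Read a ``drug,multiplier,source`` CSV into a drug -> multiplier map."""
    df = pd.read_csv(path)
    if df["drug"].duplicated().any():
        raise StatValidationError(f"duplicate drugs: {df.loc[df['drug'].duplicated(), 'drug'].tolist()}")
    if (df["multiplier"] <= 0).any():
        raise StatValidationError("multipliers must be positive")
    return dict(zip(df["drug"], df["multiplier"].astype(float)))


def cpz_equivalent(doses: Sequence[DoseRecord], table: dict[str, float]) -> float:
    """Total chlorpromazine-equivalent dose: sum of dose x drug multiplier."""
    total = 0.0
    for rec in doses:
        if rec.drug not in table:
            raise KeyError(f"drug {rec.drug!r} not in ratio table")
        total += rec.dose_mg * table[rec.drug]
    return total
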