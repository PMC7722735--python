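"""Group-level statistics: rank tests, effect sizes, split-plot ANOVA,
and two-sample power analysis.

Rank tests use exact enumeration of the permutation null when both
samples have at most 10 observations (average ranks under ties), and the
normal approximation with tie and continuity corrections otherwise.
The 2 (prior) x 2 (likelihood) x group ANOVA is computed through
orthogonal within-participant contrasts, which for two-level factors is
exactly the classical split-plot (mixed-design) decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "TestResult",
    "PowerSpec",
    "rank_sum_test",
    "signed_rank_test",
    "cohens_d",
    "mixed_anova_2x2xG",
    "stress_effect_check",
    "power_two_sample_t",
    "solve_detectable_d",
]

EXACT_MAX_N = 10  # exact permutation enumeration threshold (per sample)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    n1: int | None = None
    n2: int | None = None
    tails: int = 2


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sample t-test power calculation."""

    n1: int
    n2: int
    d: float
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")

    def power(self) -> float:
        return power_two_sample_t(self.n1, self.n2, self.d, self.alpha, self.tails)


def cohens_d(x, y) -> float:
    """Standardised mean difference with the (n-1)-weighted pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per sample")
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided p by full enumeration of rank-subset assignments.

    The permutation distribution of the rank sum is symmetric about
    n1 (N + 1) / 2 even under ties, so the two-sided p-value is the
    probability of a rank sum at least as far from that centre.
    """
    n = len(ranks)
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9  # tolerance against float rank sums
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            count += 1
    return count / total


def rank_sum_test(x, y) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test; W = sum of ranks of `x`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    if np.all(pooled == pooled[0]):
        p = 1.0
    elif len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        p = _exact_rank_sum_p(ranks, len(x), w)
    else:
        # asymptotic path: tie-corrected normal approximation with
        # continuity correction, via the Mann-Whitney U equivalence
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    d = cohens_d(x, y) if len(x) > 1 and len(y) > 1 else None
    return TestResult("wilcoxon_rank_sum", w, p, effect_size=d, n1=len(x), n2=len(y))


def signed_rank_test(x, y=None) -> TestResult:
    """Wilcoxon signed-rank test on differences (or x - y if y given).

    Reports T = sum of ranks of the positive differences; zero
    differences are dropped.  With no non-zero differences the test is
    undefined and NaN statistics are returned.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult("wilcoxon_signed_rank", math.nan, math.nan, n1=0)
    ranks = stats.rankdata(np.abs(nz))
    t_plus = float(ranks[nz > 0].sum())
    p = float(stats.wilcoxon(nz, alternative="two-sided", method="auto").pvalue)
    return TestResult("wilcoxon_signed_rank", t_plus, p, n1=len(nz))


def _f_p(num_t: float, df: int) -> tuple[float, float]:
    f = num_t**2
    return f, float(stats.f.sf(f, 1, df))


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    diff = np.mean(a) - np.mean(b)
    if sp2 == 0:
        return (0.0 if diff == 0 else math.inf * np.sign(diff)), df
    return float(diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))), df


def _grand_mean_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """t for the unweighted grand mean of a contrast across two groups."""
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    mu = (np.mean(a) + np.mean(b)) / 2.0
    if sp2 == 0:
        return (0.0 if mu == 0 else math.inf * np.sign(mu)), df
    se = np.sqrt(sp2) / 2.0 * np.sqrt(1 / n1 + 1 / n2)
    return float(mu / se), df


def mixed_anova_2x2xG(table: pd.DataFrame) -> pd.DataFrame:
    """Split-plot ANOVA: 2 within (prior, likelihood) x 1 between (group).

    Expects one row per participant with columns ``group`` and
    ``weight_pl``, ``weight_pL``, ``weight_Pl``, ``weight_PL``.  Within
    effects and their group interactions are tested on orthogonal
    participant contrasts (exact for two-level factors, Type-III /
    unweighted-means convention for unequal group sizes); the group main
    effect is tested on participant means.
    """
    required = {"group", "weight_pl", "weight_pL", "weight_Pl", "weight_PL"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if table[list(required)].isna().any().any():
        raise ValueError("missing cells in the condition-weight table")
    groups = list(pd.unique(table["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    w = {c: table[f"weight_{c}"].to_numpy(dtype=float) for c in ("pl", "pL", "Pl", "PL")}
    contrasts = {
        "prior": (w["Pl"] + w["PL"]) / 2 - (w["pl"] + w["pL"]) / 2,
        "likelihood": (w["pl"] + w["Pl"]) / 2 - (w["pL"] + w["PL"]) / 2,
        "prior_x_likelihood": ((w["pl"] - w["pL"]) - (w["Pl"] - w["PL"])) / 2,
    }
    mean_w = (w["pl"] + w["pL"] + w["Pl"] + w["PL"]) / 4
    g1 = (table["group"] == groups[0]).to_numpy()
    rows = []
    for name, c in contrasts.items():
        t, df = _grand_mean_t(c[g1], c[~g1])
        f, p = _f_p(t, df)
        rows.append({"effect": name, "F": f, "df1": 1, "df2": df, "p": p})
        t, df = _two_sample_t(c[g1], c[~g1])
        f, p = _f_p(t, df)
        rows.append({"effect": f"{name}_x_group", "F": f, "df1": 1, "df2": df, "p": p})
    t, df = _two_sample_t(mean_w[g1], mean_w[~g1])
    f, p = _f_p(t, df)
    rows.append({"effect": "group", "F": f, "df1": 1, "df2": df, "p": p})
    order = [
        "prior",
        "likelihood",
        "prior_x_likelihood",
        "group",
        "prior_x_group",
        "likelihood_x_group",
        "prior_x_likelihood_x_group",
    ]
    frame = pd.DataFrame(rows).set_index("effect").loc[order].reset_index()
    return frame


def stress_effect_check(table: pd.DataFrame, outcome: str) -> dict[str, TestResult]:
    """Two-stage group-effect check on a per-participant summary column.

    Stage one is the per-participant summary (the table row); stage two
    compares it across groups.  Returns the intercept test (pooled mean
    different from zero, one-sample t) and the group coefficient
    (stressed minus control difference, pooled-variance two-sample t).
    """
    if outcome not in table.columns:
        raise ValueError(f"unknown outcome column {outcome!r}")
    y = table[outcome].to_numpy(dtype=float)
    stressed = (table["group"] == "stressed").to_numpy()
    if stressed.all() or (~stressed).all():
        raise ValueError("need both control and stressed participants")
    t_int, p_int = stats.ttest_1samp(y, 0.0)
    a, b = y[stressed], y[~stressed]
    t_grp, df = _two_sample_t(a, b)
    p_grp = float(2 * stats.t.sf(abs(t_grp), df)) if math.isfinite(t_grp) else 0.0
    return {
        "intercept": TestResult("one_sample_t", float(t_int), float(p_int), n1=len(y)),
        "group": TestResult(
            "two_sample_t",
            t_grp,
            p_grp,
            effect_size=cohens_d(a, b),
            n1=len(a),
            n2=len(b),
        ),
    }


def _safe_nct_tail(tc: float, df: int, ncp: float) -> float:
    """Two-sided rejection probability under the noncentral t; falls back
    to the normal approximation where scipy's nct is numerically unstable
    at large noncentrality."""
    p = float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    if math.isnan(p):
        p = float(stats.norm.sf(tc - ncp) + stats.norm.cdf(-tc - ncp))
    return min(max(p, 0.0), 1.0)


def power_two_sample_t(n1: int, n2: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the pooled two-sample t-test at standardised effect d.

    Uses the noncentral t with df = n1 + n2 - 2 and noncentrality
    d * sqrt(n1 n2 / (n1 + n2)).
    """
    spec_check = PowerSpec(n1, n2, abs(d), alpha, tails)  # validates inputs
    df = n1 + n2 - 2
    ncp = abs(d) * math.sqrt(n1 * n2 / (n1 + n2))
    tc = float(stats.t.ppf(1 - alpha / spec_check.tails, df))
    if tails == 2:
        return _safe_nct_tail(tc, df, ncp)
    p = float(stats.nct.sf(tc, df, ncp))
    if math.isnan(p):
        p = float(stats.norm.sf(tc - ncp))
    return min(max(p, 0.0), 1.0)


def solve_detectable_d(
    n1: int, n2: int, alpha: float = 0.05, target_power: float = 0.8, tails: int = 2
) -> float:
    """Smallest standardised effect detectable at the target power.

    Solves power(d) = target_power by bracketing bisection to 1e-6; the
    power function is strictly increasing in d.
    """
    if not alpha <= target_power < 1:
        raise ValueError("target_power must be in [alpha, 1)")
    if target_power == alpha:
        return 0.0
    lo, hi = 0.0, 1.0
    while power_two_sample_t(n1, n2, hi, alpha, tails) < target_power:
        hi *= 2
        if hi > 100:
            raise RuntimeError("no detectable effect below d = 100")
    return float(
        brentq(
            lambda d: power_two_sample_t(n1, n2, d, alpha, tails) - target_power,
            lo,
            hi,
            xtol=1e-6,
        )
    )
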