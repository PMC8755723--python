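"""Statistical layer: depth-trend correlations, group tests, TOST equivalence
with power-derived bounds, genome-quality gating, and p-value adjustment.

All tests are two-sided. The t-test default is Welch (unequal variances).
No multiple-testing correction is applied by default — an optional
Benjamini-Hochberg adjustment is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as _sps
from statsmodels.stats.weightstats import ttost_ind


@dataclass(frozen=True)
class TrendResult:
    r: float
    p: float
    n: int
    scope: str

    def summary(self) -> str:
        return f"Depth trend ({self.scope}): r = {self.r:.4f}, p = {self.p:.3g}, n = {self.n}"


@dataclass(frozen=True)
class EquivalenceResult:
    """Two one-sided tests against symmetric power-derived bounds.

    ``lower``/``upper`` are the equivalence bounds in Cohen's-d units
    (lower = -upper); ``verdict`` is "equivalent" when both one-sided
    p-values fall below alpha, else "not shown".
    """

    lower: float
    upper: float
    p_lower: float
    p_upper: float
    verdict: str
    alpha: float
    power_for_bound: float

    def summary(self) -> str:
        return (f"TOST: bounds d* = [{self.lower:.4f}, {self.upper:.4f}] "
                f"(power {self.power_for_bound:.0%}); "
                f"p_lower = {self.p_lower:.4g}, p_upper = {self.p_upper:.4g} "
                f"-> {self.verdict}")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one margin")
    res = _sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def depth_trend(
    values: pd.DataFrame,
    scope: str = "per_value",
    value_col: str = "value",
    depth_col: str = "depth_m",
    site_col: str = "site_id",
    exclude: pd.Series | np.ndarray | None = None,
) -> TrendResult:
    """Correlate per-genome values (e.g. replication indices) with site depth.

    ``scope="per_value"`` correlates every genome value with its site depth;
    ``scope="per_ecosystem_median"`` correlates per-site medians with site
    depth. An optional boolean ``exclude`` mask (e.g. high-CO2 sites) removes
    rows before correlating.
    """
    if scope not in ("per_value", "per_ecosystem_median"):
        raise ValueError("scope must be 'per_value' or 'per_ecosystem_median'")
    df = values
    if exclude is not None:
        df = df.loc[~np.asarray(exclude, dtype=bool)]
    if scope == "per_value":
        x, y = df[depth_col], df[value_col]
    else:
        med = df.groupby(site_col).agg({value_col: "median", depth_col: "first"})
        if len(med) < 3:
            raise ValueError("per-ecosystem scope needs >= 3 sites")
        x, y = med[depth_col], med[value_col]
    r, p = pearson(x, y)
    return TrendResult(r=r, p=p, n=len(x), scope=scope)


def group_tests(a, b=None, kind: str = "welch_t", *groups):
    """Two-sided group-difference tests.

    ``welch_t``: unequal-variance t-test; ``mann_whitney_u``: two-sided
    Mann-Whitney U (exact method for small tie-free samples via scipy's
    auto rule, asymptotic with tie correction otherwise);
    ``kruskal_wallis``: accepts two or more groups (pass extras positionally).
    Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    if kind == "kruskal_wallis":
        gs = [a] + ([np.asarray(b, dtype=float)] if b is not None else []) \
             + [np.asarray(g, dtype=float) for g in groups]
        if len(gs) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        if np.ptp(np.concatenate(gs)) == 0:
            return 0.0, 1.0  # every observation tied: no evidence of difference
        stat, p = _sps.kruskal(*gs)
        return float(stat), float(p)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if kind == "welch_t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
        stat, p = _sps.ttest_ind(a, b, equal_var=False)
    elif kind == "mann_whitney_u":
        if np.ptp(np.concatenate([a, b])) == 0:
            # ties-only degenerate input: U at its null mean, no evidence
            return float(a.size * b.size / 2.0), 1.0
        stat, p = _sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test kind: {kind}")
    return float(stat), float(min(p, 1.0))


def power_welch_two_sided(d: float, n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at standardized effect d
    (noncentral-t formula, pooled df)."""
    df = n_a + n_b - 2
    nc = d * np.sqrt(n_a * n_b / (n_a + n_b))
    tcrit = _sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(_sps.nct.sf(tcrit, df, nc) + _sps.nct.cdf(-tcrit, df, nc))


def detectable_effect(n_a: int, n_b: int, power: float = 0.33,
                      alpha: float = 0.05) -> float:
    """Standardized effect size d* at which the two-sample t-test has the
    requested power — used as the symmetric TOST equivalence bound."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    base = power_welch_two_sided(0.0, n_a, n_b, alpha)
    if power <= base:
        raise ValueError(
            f"requested power {power} not above the type-I floor {base:.3f}")
    # power is monotone increasing in d; grow the bracket just past the target
    # (large noncentralities are numerically fragile in the nct tail)
    hi = 0.5
    while power_welch_two_sided(hi, n_a, n_b, alpha) < power:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - diagnostics path
            raise ValueError(
                f"equivalence-bound search failed for n=({n_a},{n_b}), "
                f"alpha={alpha}, power={power}: no bracket found")
    return float(optimize.brentq(
        lambda d: power_welch_two_sided(d, n_a, n_b, alpha) - power,
        1e-9, hi, xtol=1e-10))


def tost_equivalence(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    power_for_bound: float = 0.33,
    bound_n_a: int | None = None,
    bound_n_b: int | None = None,
) -> EquivalenceResult:
    """Equivalence of two groups by TOST against power-derived bounds.

    The symmetric bound is the Cohen's-d effect a reference design had
    ``power_for_bound`` power to detect with a two-sided t-test; the two
    one-sided tests run against +/- d* (converted to raw units with the
    pooled sd) and equivalence is declared when both p-values are below
    alpha.

    ``bound_n_a``/``bound_n_b`` set the reference group sizes for the power
    computation (e.g. a previously studied CO2-poor group); they default to
    the tested groups' own sizes. Note that with the default, the 33%-power
    noncentrality sits below the one-sided critical value for every n, so
    equivalence can only be declared when the bound derives from a design
    smaller than the tested one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    d_star = detectable_effect(bound_n_a or a.size, bound_n_b or b.size,
                               power=power_for_bound, alpha=alpha)
    sd_pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if sd_pooled == 0:
        sd_pooled = 1.0  # degenerate constant groups: bounds in raw units of 1
    _, t1, t2 = ttost_ind(a, b, -d_star * sd_pooled, d_star * sd_pooled,
                          usevar="pooled")
    p_lower, p_upper = float(t1[1]), float(t2[1])
    verdict = "equivalent" if max(p_lower, p_upper) < alpha else "not shown"
    return EquivalenceResult(lower=-d_star, upper=d_star, p_lower=p_lower,
                             p_upper=p_upper, verdict=verdict, alpha=alpha,
                             power_for_bound=power_for_bound)


def quality_gate(
    table: pd.DataFrame,
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> pd.DataFrame:
    """Keep genome bins with completeness >= 70% and contamination <= 10%
    (boundaries inclusive)."""
    for col in ("completeness", "contamination"):
        if col not in table.columns:
            raise ValueError(f"quality table lacks column '{col}'")
        vals = table[col]
        if vals.isna().any() or (vals < 0).any() or (vals > 100).any():
            raise ValueError(f"column '{col}' must be within [0, 100] with no gaps")
    keep = ((table["completeness"] >= min_completeness)
            & (table["contamination"] <= max_contamination))
    return table.loc[keep].copy()


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing adjustment (Benjamini-Hochberg by default)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]
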