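"""Descriptive and inferential statistics for phase-length tables.

Covers the downstream statistical surface of the protocol: median/quartile
summaries (linear-interpolation quartile convention), normality-gated
two-group tests with significance stars, pairwise phase regressions,
Cohen's d, a-priori sample size (noncentral-t iteration, with a
rank-test variant via the normal-parent asymptotic relative efficiency
3/pi), and percent-change summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

PHASES = ("G1", "S", "G2M", "total")


@dataclass
class PowerSpec:
    """Parameters of an a-priori sample-size calculation."""
    effect_size: float
    alpha: float = 0.05
    power: float = 0.95
    test_family: str = "t"   # "t" or "wmw"
    tails: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be > 0")
        if self.test_family not in ("t", "wmw"):
            raise ValueError("test_family must be 't' or 'wmw'")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def describe_phases(lengths: dict[str, np.ndarray] | pd.DataFrame
                    ) -> pd.DataFrame:
    """Median and [Q1, Q3] per phase, hours.

    Quartiles use the linear-interpolation convention
    (``numpy.percentile`` default).
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = {c: lengths[c].dropna().to_numpy() for c in lengths.columns}
    rows = []
    for phase, vals in lengths.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 1:
            raise ValueError(f"phase {phase} has no values")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"phase": phase, "median_h": med, "q1_h": q1,
                     "q3_h": q3, "n": len(vals)})
    return pd.DataFrame(rows, columns=["phase", "median_h", "q1_h", "q3_h", "n"])


def significance_stars(p: float) -> str:
    """Star annotation: * P<0.05, ** P<0.005, *** P<0.0005."""
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
                   welch: bool = False) -> dict:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group at ``alpha``; if both pass, a two-sample
    (pooled, or Welch if requested) t test, otherwise a two-tailed
    Wilcoxon-Mann-Whitney. Returns normality p-values, chosen test,
    statistic, p and stars.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3 for the normality gate")
    p_a = float(sps.shapiro(a).pvalue)
    p_b = float(sps.shapiro(b).pvalue)
    if p_a > alpha and p_b > alpha:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        test = "t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon-mann-whitney"
    p = float(res.pvalue)
    return {
        "normality_p_a": p_a, "normality_p_b": p_b, "test": test,
        "statistic": float(res.statistic), "p": p,
        "stars": significance_stars(p),
    }


def phase_regressions(per_cell: pd.DataFrame,
                      phases: tuple[str, ...] = ("G1", "S", "G2M")
                      ) -> pd.DataFrame:
    """OLS fit for each unordered phase pair; p is for slope != 0.

    ``per_cell`` holds one row per cell with one column per phase (hours).
    """
    complete = per_cell[list(phases)].dropna()
    if len(complete) < 3:
        raise ValueError("need >= 3 cells with all phases called")
    rows = []
    for i in range(len(phases)):
        for j in range(i + 1, len(phases)):
            x = complete[phases[i]].to_numpy()
            y = complete[phases[j]].to_numpy()
            fit = sps.linregress(x, y)
            rows.append({
                "x_phase": phases[i], "y_phase": phases[j],
                "slope": float(fit.slope), "intercept": float(fit.intercept),
                "r_squared": float(fit.rvalue) ** 2,
                "p_slope": float(fit.pvalue), "n": len(complete),
            })
    return pd.DataFrame(rows)


def cohens_d(mean1: float, mean2: float, sd: float) -> float:
    """|mean1 - mean2| / sd for a common within-group standard deviation."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return abs(mean1 - mean2) / sd


def _t_power(n: int, d: float, alpha: float, tails: int) -> float:
    """Power of a two-sample t test with n per group at effect size d."""
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2.0)
    crit = sps.t.ppf(1 - alpha / tails, df)
    power = 1 - sps.nct.cdf(crit, df, nc)
    if tails == 2:
        power += sps.nct.cdf(-crit, df, nc)
    return float(power)


def a_priori_n(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n per group achieving the target power.

    t family: direct noncentral-t power iteration over n. Rank-test family
    ("wmw"): the t-family n divided by the asymptotic relative efficiency
    for a normal parent (3/pi), rounded up.
    """
    n = 2
    while n <= n_max:
        if _t_power(n, spec.effect_size, spec.alpha, spec.tails) >= spec.power:
            break
        n += 1
    else:
        raise ValueError("no n under the cap reaches the requested power")
    if spec.test_family == "wmw":
        are = 3.0 / math.pi
        return math.ceil(n / are)
    return n


def percent_change(control: float, treated: float) -> float:
    """100 * (treated - control) / control (unrounded; reports round to int)."""
    if control <= 0:
        raise ValueError("control value must be > 0")
    return 100.0 * (treated - control) / control


def percentage_point_change(control_percent: float,
                            treated_percent: float) -> float:
    """Difference of two already-percent-scaled fractions, in points."""
    return treated_percent - control_percent


def group_comparison_table(control: pd.DataFrame, treated: pd.DataFrame,
                           phases: tuple[str, ...] = ("G1", "S", "G2M",
                                                      "total"),
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-phase group comparison of two per-cell phase-length tables."""
    rows = []
    for phase in phases:
        a = control[phase].dropna().to_numpy()
        b = treated[phase].dropna().to_numpy()
        res = compare_groups(a, b, alpha=alpha)
        rows.append({
            "phase": phase,
            "control_median_h": float(np.median(a)),
            "treated_median_h": float(np.median(b)),
            "percent_change": round(percent_change(float(np.median(a)),
                                                   float(np.median(b)))),
            **res,
        })
    return pd.DataFrame(rows)
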