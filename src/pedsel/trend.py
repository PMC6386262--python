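"""Ordered-trend and association statistics.

The Jonckheere-Terpstra test detects a monotone shift in a response across
ordered groups (here: hip-score distributions across generation classes).
It accumulates pairwise Mann-Whitney counts between every earlier/later
group pair; under the null its normal approximation uses a tie-corrected
variance, and for small samples the exact permutation distribution is
enumerated instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

__all__ = ["jonckheere_terpstra", "JTResult", "lm_anova", "pearson_with_ci"]

#: total sample size at or below which the exact permutation p is used
EXACT_N = 12


@dataclass
class JTResult:
    statistic: float      # JT: sum of pairwise Mann-Whitney counts
    z: float              # normal-approximation standard score
    pvalue: float
    n: int
    alternative: str
    exact: bool           # p from exhaustive permutation enumeration


def _jt_statistic(values: np.ndarray, group_codes: np.ndarray, k: int) -> float:
    jt = 0.0
    groups = [values[group_codes == g] for g in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = groups[i], groups[j]
            # U_ij: pairs with x_i < x_j, ties counted half
            less = np.sum(xi[:, None] < xj[None, :])
            ties = np.sum(xi[:, None] == xj[None, :])
            jt += less + 0.5 * ties
    return float(jt)


def _jt_null_moments(values: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """Tie-corrected mean and variance of JT under the null."""
    n = values.size
    mean = (n * n - np.sum(sizes**2)) / 4.0
    _, tie_counts = np.unique(values, return_counts=True)
    t = tie_counts.astype(float)
    u = sizes.astype(float)
    v1 = (n * (n - 1) * (2 * n + 5)
          - np.sum(t * (t - 1) * (2 * t + 5))
          - np.sum(u * (u - 1) * (2 * u + 5))) / 72.0
    v2 = (np.sum(t * (t - 1) * (t - 2)) * np.sum(u * (u - 1) * (u - 2))
          / (36.0 * n * (n - 1) * (n - 2)))
    v3 = (np.sum(t * (t - 1)) * np.sum(u * (u - 1))) / (8.0 * n * (n - 1))
    return mean, v1 + v2 + v3


def jonckheere_terpstra(
    values,
    groups,
    alternative: str = "increasing",
    exact: bool | None = None,
) -> JTResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    Parameters
    ----------
    values : array-like
        Observations (real or ordinal codes).
    groups : array-like
        Group label per observation.  Groups are ordered by sorted label;
        pass integer codes to control the order explicitly.
    alternative : {"increasing", "decreasing", "two-sided"}
        Direction of the shift under the alternative.  Default tests for
        values shifting upward in later groups.
    exact : bool, optional
        Force (or suppress) exhaustive permutation enumeration; by default
        it is used automatically when the total n is at most 12.
    """
    values = np.asarray(values, dtype=float)
    labels = pd.Series(groups)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("Jonckheere-Terpstra needs at least 2 ordered groups")
    codes = labels.map({g: i for i, g in enumerate(uniq)}).to_numpy()
    k, n = len(uniq), values.size
    sizes = np.bincount(codes, minlength=k)
    if np.any(sizes == 0):
        raise ValueError("every ordered group must be non-empty")
    jt = _jt_statistic(values, codes, k)
    mean, var = _jt_null_moments(values, sizes)
    z = (jt - mean) / math.sqrt(var) if var > 0 else 0.0
    use_exact = exact if exact is not None else n <= EXACT_N
    if use_exact:
        null = np.array(
            [_jt_statistic(values, np.asarray(perm), k)
             for perm in multiset_permutations(list(codes))]
        )
        eps = 1e-9
        p_up = np.mean(null >= jt - eps)
        p_dn = np.mean(null <= jt + eps)
        if alternative == "increasing":
            p = p_up
        elif alternative == "decreasing":
            p = p_dn
        else:
            p = min(1.0, 2.0 * min(p_up, p_dn))
    else:
        if alternative == "increasing":
            p = stats.norm.sf(z)
        elif alternative == "decreasing":
            p = stats.norm.cdf(z)
        elif alternative == "two-sided":
            p = 2.0 * stats.norm.sf(abs(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return JTResult(jt, z, float(p), n, alternative, bool(use_exact))


def lm_anova(
    data: pd.DataFrame,
    response: str,
    class_effects: list[str] | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of a linear model with class effects and covariates.

    Returns the statsmodels ``anova_lm`` table (sum_sq, df, F, PR(>F) per
    term, fitted in the order given: class effects first, then covariates).
    Raises on a rank-deficient design, naming the aliased terms.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    class_effects = class_effects or []
    covariates = covariates or []
    terms = [f"C(Q('{c}'))" for c in class_effects] + [f"Q('{c}')" for c in covariates]
    if not terms:
        raise ValueError("need at least one explanatory term")
    formula = f"Q('{response}') ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    X = fit.model.exog
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix rank-deficient; aliased among terms {class_effects + covariates}"
        )
    return sm.stats.anova_lm(fit, typ=1)


def pearson_with_ci(x, y, conf: float = 0.95) -> tuple[float, float, float]:
    """Pearson correlation with a Fisher-z confidence interval.

    CI = tanh(atanh(r) +/- z_(alpha/2) / sqrt(n - 3)); requires n >= 4 and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    zr = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r)))
    half = zcrit / math.sqrt(x.size - 3)
    return r, math.tanh(zr - half), math.tanh(zr + half)
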