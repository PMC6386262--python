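"""Correlated-response prediction and selection-differential analysis.

Direct selection on trait X changes a genetically correlated trait Y by

    CR_Y = i * h_X * r_A * sigma_A(Y)     (per generation)

where ``i`` is the selection intensity on X (selection differential in
phenotypic SD units), ``h_X`` the square root of X's heritability, ``r_A``
the genetic correlation, and ``sigma_A(Y)`` the additive genetic SD of Y.
Realized selection pressure is summarised per generation class by the
selection differential S = mean(parents) - mean(population).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "correlated_response",
    "response_grid",
    "selection_differential",
    "selection_intensity",
    "intensity_from_proportion",
    "response_table",
]


def correlated_response(i: float, h2_x: float, r_a: float, var_a_y: float) -> float:
    """Expected per-generation change in trait Y from selection on trait X."""
    if not 0.0 < h2_x < 1.0:
        raise ValueError(f"h2_x must be in (0, 1), got {h2_x}")
    if not -1.0 <= r_a <= 1.0:
        raise ValueError(f"r_a must be in [-1, 1], got {r_a}")
    if var_a_y <= 0.0:
        raise ValueError(f"var_a_y must be positive, got {var_a_y}")
    return i * np.sqrt(h2_x) * r_a * np.sqrt(var_a_y)


def response_grid(
    params: pd.DataFrame, intensities: tuple[float, ...] = (1.0, 0.5, 0.1)
) -> pd.DataFrame:
    """Correlated-response grid over parameter rows x selection intensities.

    ``params`` needs columns ``h2_x``, ``r_a``, ``var_a_y`` (any other
    columns, e.g. breed/method labels, are carried through).  Adds one
    column ``cr_i_<i>`` per intensity, rounded to 3 decimals.
    """
    out = params.copy()
    for i in intensities:
        out[f"cr_i_{i:g}"] = [
            round(correlated_response(i, r.h2_x, r.r_a, r.var_a_y), 3)
            for r in params.itertuples()
        ]
    return out


def selection_differential(parent_values, population_values) -> float:
    """S = mean of selected parents minus mean of their whole cohort."""
    p = np.asarray(parent_values, dtype=float)
    pop = np.asarray(population_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty parent set")
    if pop.size == 0:
        raise ValueError("empty population")
    return float(p.mean() - pop.mean())


def selection_intensity(s: float, sigma_p: float) -> float:
    """Selection intensity i = S / sigma_P."""
    if sigma_p <= 0:
        raise ValueError(f"sigma_p must be positive, got {sigma_p}")
    return s / sigma_p


def intensity_from_proportion(p: float) -> float:
    """Expected intensity of truncation selection keeping the top fraction p
    of a normal distribution: i = phi(z) / p with z the truncation point."""
    from scipy import stats

    if not 0.0 < p <= 1.0:
        raise ValueError(f"selected proportion must be in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def response_table(
    values: pd.Series,
    gen_class: pd.Series,
    is_parent: pd.Series,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-generation-class selection differentials (retrospective).

    "Parents" of class k are the measured dogs of class k that were later
    used for breeding; they are compared against all measured dogs of the
    class.  Classes without any parent get a missing S.  Means and S are
    rounded to ``decimals`` for reporting.
    """
    df = pd.DataFrame({
        "value": pd.Series(values).astype(float),
        "gen": gen_class,
        "parent": pd.Series(is_parent).astype(bool),
    }).dropna(subset=["value", "gen"])
    rows = []
    for cls in sorted(df["gen"].unique()):
        sub = df[df["gen"] == cls]
        par = sub[sub["parent"]]
        pop_mean = sub["value"].mean()
        row = {
            "gen_class": cls,
            "parent_mean": round(par["value"].mean(), decimals) if len(par) else np.nan,
            "parent_n": int(len(par)),
            "pop_mean": round(pop_mean, decimals),
            "pop_n": int(len(sub)),
        }
        if len(par):
            row["S"] = round(par["value"].mean() - pop_mean, decimals)
        else:
            row["S"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
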