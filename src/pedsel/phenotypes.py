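"""Hip-phenotype preparation: score scales, contemporary groups, summaries.

Two measures of canine hip quality are handled:

* **HES** — the hip-extended score, an ordinal radiographic grade from 1
  (worst) to 8 (best), analysed downstream as a linear 1-8 variable;
* **DI** — the PennHIP distraction index, a unitless joint-laxity ratio
  (lower is better; values at or below 0.30 indicate minimal
  osteoarthritis risk).

For summary reporting HES is collapsed to seven ordered classes (HESC),
merging the two worst grades; "normal" hips are Fair, Good or Excellent.
Phenotypes are adjusted by expressing each record as a deviation from its
contemporary-group mean, where a contemporary group is all dogs of one
breed evaluated in the same calendar quarter.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HESC_LABELS",
    "NORMAL_CLASSES",
    "collapse_hesc",
    "contemporary_groups",
    "deviate_from_group_mean",
    "generation_summary",
    "hesc_generation_table",
    "combine_class_counts",
]

#: HESC classes from worst to best; index = ordinal rank
HESC_LABELS = ("Severe", "Moderate", "Mild", "Borderline", "Fair", "Good", "Excellent")

#: classes counted as CHD-normal
NORMAL_CLASSES = frozenset({"Fair", "Good", "Excellent"})

# HES 1 and 2 merge into Severe; 3..8 map one-to-one upward
_HES_TO_HESC = {1: "Severe", 2: "Severe", 3: "Moderate", 4: "Mild",
                5: "Borderline", 6: "Fair", 7: "Good", 8: "Excellent"}


def collapse_hesc(hes: int | Iterable[int]) -> str | pd.Categorical:
    """Collapse a 1-8 hip-extended score into the 7-class ordinal HESC."""
    if np.isscalar(hes):
        h = int(hes)
        if h not in _HES_TO_HESC:
            raise ValueError(f"HES must be in 1..8, got {hes}")
        return _HES_TO_HESC[h]
    arr = np.asarray(list(hes), dtype=int)
    if arr.size and (arr.min() < 1 or arr.max() > 8):
        bad = arr[(arr < 1) | (arr > 8)][0]
        raise ValueError(f"HES must be in 1..8, got {bad}")
    return pd.Categorical(
        [_HES_TO_HESC[h] for h in arr], categories=list(HESC_LABELS), ordered=True
    )


def hesc_rank(labels: Iterable[str]) -> np.ndarray:
    """Ordinal rank (0 = Severe .. 6 = Excellent) of HESC labels."""
    order = {lab: i for i, lab in enumerate(HESC_LABELS)}
    return np.array([order[l] for l in labels], dtype=int)


def contemporary_groups(
    eval_dates: pd.Series, breeds: pd.Series | str
) -> pd.Series:
    """Contemporary-group keys ``"<breed>:<year>Q<q>"`` per record.

    Quarters are Jan-Mar, Apr-Jun, Jul-Sep, Oct-Dec.  Records with a
    missing evaluation date get a missing key (flagged, excluded from any
    grouping downstream).
    """
    dates = pd.to_datetime(eval_dates, errors="coerce")
    if isinstance(breeds, str):
        breeds = pd.Series(breeds, index=dates.index)
    quarter = ((dates.dt.month - 1) // 3 + 1).astype("Int64")
    key = breeds.astype(str) + ":" + dates.dt.year.astype("Int64").astype(str) + "Q" + quarter.astype(str)
    key[dates.isna()] = pd.NA
    n_missing = int(dates.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} record(s) lack an evaluation date and were not grouped")
    return key


def deviate_from_group_mean(values: pd.Series, groups: pd.Series) -> pd.Series:
    """Express each value as a deviation from its contemporary-group mean.

    The within-group mean of the output is exactly zero; the operation is
    idempotent.  Missing values are ignored in the group means and stay
    missing in the output.
    """
    values = pd.Series(values).astype(float)
    means = values.groupby(groups, dropna=True).transform("mean")
    return values - means


def _quartiles(x: np.ndarray, method: str = "linear") -> tuple[float, float, float]:
    return tuple(np.quantile(x, [0.25, 0.5, 0.75], method=method))  # type: ignore[return-value]


def generation_summary(
    values: pd.Series,
    gen_class: pd.Series,
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Per-generation-class summary of a continuous trait.

    One row per class: N, min, quartiles, mean, max, SEM (= SD/sqrt(N),
    sample SD).  Classes with no non-missing value are omitted with a
    warning.  ``quantile_method`` is any method accepted by
    :func:`numpy.quantile` (default the linearly interpolated empirical
    CDF, "type 7").
    """
    df = pd.DataFrame({"value": pd.Series(values).astype(float), "gen": gen_class})
    rows = []
    for cls in sorted(df["gen"].dropna().unique()):
        x = df.loc[df["gen"] == cls, "value"].dropna().to_numpy()
        if x.size == 0:
            warnings.warn(f"generation class {cls}: no observations, row omitted")
            continue
        q1, med, q3 = _quartiles(x, quantile_method)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else np.nan
        rows.append({
            "gen_class": cls, "n": int(x.size), "min": float(x.min()),
            "q1": q1, "median": med, "mean": float(x.mean()), "q3": q3,
            "max": float(x.max()), "sem": sd / np.sqrt(x.size) if x.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def hesc_generation_table(hes: pd.Series, gen_class: pd.Series) -> pd.DataFrame:
    """Percent of dogs in each HESC class, by generation class.

    Mirrors the classic selection-program report: one row per generation
    class with the percentage (1 decimal) falling in each of the seven
    HESC classes, total N, and the percent with any CHD vs normal hips.
    """
    hesc = collapse_hesc(pd.Series(hes).dropna().astype(int))
    gen = pd.Series(gen_class).loc[pd.Series(hes).dropna().index]
    rows = []
    for cls in sorted(pd.unique(gen)):
        sub = pd.Series(hesc[(gen == cls).to_numpy()])
        n = len(sub)
        counts = sub.value_counts().reindex(HESC_LABELS, fill_value=0)
        pct = (100.0 * counts / n).round(1)
        normal = float(pct[list(NORMAL_CLASSES)].sum())
        row = {"gen_class": cls, **{lab: pct[lab] for lab in HESC_LABELS},
               "n": n, "pct_chd": round(100.0 - normal, 1), "pct_normal": round(normal, 1)}
        rows.append(row)
    return pd.DataFrame(rows)


def combine_class_counts(percents: Iterable[float], ns: Iterable[int]) -> tuple[int, int, float]:
    """Pool rounded per-class percentages back into combined counts.

    Given printed percentages (one per generation class) and class sizes,
    reconstruct per-class counts as round(pct * N / 100), pool them, and
    return ``(count, total_n, combined_percent)`` with the percent at one
    decimal.  Used to check pooled claims derived from rounded per-class
    report tables.
    """
    counts = [int(round(p * n / 100.0)) for p, n in zip(percents, ns, strict=True)]
    total = int(sum(ns))
    pooled = int(sum(counts))
    return pooled, total, round(100.0 * pooled / total, 1)
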