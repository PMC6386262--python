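"""Classical selection-index EBVs from up to four information sources.

Before animal-model BLUP became routine, breeding values for a candidate
were predicted as a weighted sum of contemporary-group-deviated phenotypic
means from up to four sources: the candidate's own record, the mean of its
paternal half-sibs, the mean of its maternal half-sibs, and the mean of
its progeny.  The weights b solve the index equations P b = g, where P is
the (co)variance matrix of the sources and g their covariance with the
candidate's additive genetic merit.

With phenotypic variance sigma2_P, heritability h2 (so sigma2_A = h2 *
sigma2_P) and intraclass correlation t = 0.25 h2 among half-sibs:

* var(own record)          = sigma2_P
* var(mean of n half-sibs) = sigma2_P (1 + (n-1) t) / n
* var(mean of n progeny)   = sigma2_P (1 + (n-1) t') / n, t' = 0.25 h2
  when progeny are from distinct mates (half-sibs of each other; a
  full-sib family uses t' = 0.5 h2)
* cov(own, A)      = sigma2_A       cov(half-sib mean, A) = 0.25 sigma2_A
* cov(progeny, A)  = 0.5 sigma2_A
* off-diagonals: own-half-sib 0.25 sigma2_A, own-progeny 0.5 sigma2_A,
  paternal-maternal half-sib 0, half-sib-progeny 0.125 sigma2_A.

Index theory assumes the sources are unselected; no adjustment for
selected parents is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IndexSources", "index_weights", "index_ebv", "index_accuracy", "index_ebvs_for"]

SOURCE_NAMES = ("own", "phs", "mhs", "prog")


@dataclass
class IndexSources:
    """Deviated phenotypic information available on one candidate."""

    own: float | None = None
    phs_mean: float | None = None
    n_phs: int = 0
    mhs_mean: float | None = None
    n_mhs: int = 0
    prog_mean: float | None = None
    n_prog: int = 0

    def present(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.own is not None,
            self.n_phs > 0 and self.phs_mean is not None,
            self.n_mhs > 0 and self.mhs_mean is not None,
            self.n_prog > 0 and self.prog_mean is not None,
        )

    def vector(self) -> np.ndarray:
        vals = (self.own, self.phs_mean, self.mhs_mean, self.prog_mean)
        return np.array([v for v, p in zip(vals, self.present()) if p], dtype=float)


def _index_system(
    present: tuple[bool, bool, bool, bool],
    n_phs: int,
    n_mhs: int,
    n_prog: int,
    h2: float,
    sigma2_p: float,
    progeny_full_sibs: bool,
) -> tuple[np.ndarray, np.ndarray]:
    s2a = h2 * sigma2_p
    t_hs = 0.25 * h2
    t_prog = 0.5 * h2 if progeny_full_sibs else 0.25 * h2

    def mean_var(n: int, t: float) -> float:
        return sigma2_p * (1.0 + (n - 1) * t) / n

    var = {
        "own": sigma2_p,
        "phs": mean_var(n_phs, t_hs) if n_phs else np.nan,
        "mhs": mean_var(n_mhs, t_hs) if n_mhs else np.nan,
        "prog": mean_var(n_prog, t_prog) if n_prog else np.nan,
    }
    cov = {
        ("own", "phs"): 0.25 * s2a, ("own", "mhs"): 0.25 * s2a,
        ("own", "prog"): 0.5 * s2a, ("phs", "mhs"): 0.0,
        ("phs", "prog"): 0.125 * s2a, ("mhs", "prog"): 0.125 * s2a,
    }
    g_full = {"own": s2a, "phs": 0.25 * s2a, "mhs": 0.25 * s2a, "prog": 0.5 * s2a}

    names = [nm for nm, p in zip(SOURCE_NAMES, present) if p]
    k = len(names)
    P = np.empty((k, k))
    for a, na in enumerate(names):
        P[a, a] = var[na]
        for b in range(a + 1, k):
            nb = names[b]
            key = (na, nb) if (na, nb) in cov else (nb, na)
            P[a, b] = P[b, a] = cov[key]
    g = np.array([g_full[nm] for nm in names])
    return P, g


def index_weights(
    present: tuple[bool, bool, bool, bool],
    n_phs: int = 0,
    n_mhs: int = 0,
    n_prog: int = 0,
    h2: float = 0.3,
    sigma2_p: float = 1.0,
    progeny_full_sibs: bool = False,
) -> np.ndarray:
    """Solve the selection-index equations P b = g for the present sources.

    ``present`` flags (own, paternal half-sib mean, maternal half-sib mean,
    progeny mean) in that fixed order; the returned weights match the
    present sources in the same order.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    if sigma2_p <= 0:
        raise ValueError(f"sigma2_p must be positive, got {sigma2_p}")
    if not any(present):
        raise ValueError("at least one information source must be present")
    P, g = _index_system(present, n_phs, n_mhs, n_prog, h2, sigma2_p, progeny_full_sibs)
    try:
        b = np.linalg.solve(P, g)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular index equations (degenerate source configuration)") from exc
    return b


def index_ebv(sources: IndexSources, b: np.ndarray) -> float:
    """EBV = b . (deviated source values); missing sources contribute nothing."""
    x = sources.vector()
    if x.size != np.asarray(b).size:
        raise ValueError(f"weight vector length {np.size(b)} != {x.size} present sources")
    return float(np.dot(b, x))


def index_accuracy(
    present: tuple[bool, bool, bool, bool],
    n_phs: int = 0,
    n_mhs: int = 0,
    n_prog: int = 0,
    h2: float = 0.3,
    sigma2_p: float = 1.0,
    progeny_full_sibs: bool = False,
) -> float:
    """Accuracy r_TI = sqrt(b'g) / sigma_A of the index for this configuration."""
    P, g = _index_system(present, n_phs, n_mhs, n_prog, h2, sigma2_p, progeny_full_sibs)
    b = np.linalg.solve(P, g)
    s2a = h2 * sigma2_p
    return float(np.sqrt(b @ g / s2a))


def _collect_sources(ped, deviated: pd.Series) -> list[IndexSources]:
    """Per-animal index sources from a pedigree and deviated records.

    Half-sib sets exclude the candidate itself; progeny of the candidate
    are excluded from its half-sib means.
    """
    n = len(ped)
    dev = np.full(n, np.nan)
    for aid, v in deviated.items():
        if aid in ped._index and pd.notna(v):
            dev[ped.index(aid)] = v
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                children[p].append(i)
    out = []
    for i in range(n):
        own = None if np.isnan(dev[i]) else float(dev[i])
        prog = [c for c in children[i] if not np.isnan(dev[c])]

        def hs_mean(parent: int) -> tuple[float | None, int]:
            if parent < 0:
                return None, 0
            sibs = [c for c in children[parent]
                    if c != i and c not in children[i] and not np.isnan(dev[c])]
            if not sibs:
                return None, 0
            return float(np.mean(dev[sibs])), len(sibs)

        phs_m, n_phs = hs_mean(ped.sire[i])
        mhs_m, n_mhs = hs_mean(ped.dam[i])
        prog_m = float(np.mean(dev[prog])) if prog else None
        out.append(IndexSources(own, phs_m, n_phs, mhs_m, n_mhs, prog_m, len(prog)))
    return out


def index_ebvs_for(ped, deviated: pd.Series, h2: float, sigma2_p: float) -> pd.DataFrame:
    """Selection-index EBVs for every pedigree animal with any information.

    ``deviated`` maps animal_id -> contemporary-group-deviated phenotype.
    Returns a frame with columns ``animal_id, ebv, accuracy`` (animals with
    no information get a missing EBV).
    """
    sources = _collect_sources(ped, deviated)
    rows = []
    for i, src in enumerate(sources):
        pres = src.present()
        if not any(pres):
            rows.append({"animal_id": ped.ids[i], "ebv": np.nan, "accuracy": np.nan})
            continue
        b = index_weights(pres, src.n_phs, src.n_mhs, src.n_prog, h2, sigma2_p)
        rows.append({
            "animal_id": ped.ids[i],
            "ebv": index_ebv(src, b),
            "accuracy": index_accuracy(pres, src.n_phs, src.n_mhs, src.n_prog, h2, sigma2_p),
        })
    return pd.DataFrame(rows)
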