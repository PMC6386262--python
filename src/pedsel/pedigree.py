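"""Pedigree representation and relationship algebra.

A :class:`Pedigree` stores animals in parents-before-offspring order and
provides the quantities every downstream analysis needs:

* per-animal inbreeding coefficients ``F`` (Meuwissen & Luo tabular
  recursion, exact);
* the numerator relationship matrix ``A`` (dense, small pedigrees only)
  and its sparse inverse assembled directly from Henderson's rules with
  full accounting for parental inbreeding;
* approximate generation coefficients ``g`` (1 + mean of parents' values,
  founders anchored at 0) and their rounding into whole generation classes,
  which accommodate overlapping generations.

Unknown parents are encoded as ``None`` internally; on file input the empty
string and the literal ``"0"`` are both accepted and normalised.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import numpy as np
import numpy.typing as npt
from numba import njit
from scipy import sparse

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "topo_sort",
    "UNKNOWN_CODES",
]

#: strings accepted as "parent unknown" on input
UNKNOWN_CODES = frozenset({"", "0", "NA", "na", ".", "unknown"})

_SEXES = {"male", "female", "unknown"}


def normalize_parent(pid: object) -> str | None:
    """Map the various unknown-parent encodings onto ``None``."""
    if pid is None:
        return None
    s = str(pid).strip()
    return None if s in UNKNOWN_CODES else s


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identity, parent links, sex, breed, birth date."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"
    breed: str = ""
    birth_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {sorted(_SEXES)}, got {self.sex!r}")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, dangling parent, duplicate id)."""


def topo_sort(records: list[PedigreeRecord]) -> "Pedigree":
    """Reorder records so every parent precedes its offspring.

    Raises :class:`PedigreeError` on a duplicated animal id, a parent id not
    present in the record list, or a cycle (an animal that is its own
    ancestor); the cycle error names one animal on the cycle.
    """
    by_id: dict[str, PedigreeRecord] = {}
    for rec in records:
        if rec.animal_id in by_id:
            raise PedigreeError(f"duplicate animal_id {rec.animal_id!r}")
        by_id[rec.animal_id] = rec
    ts: TopologicalSorter[str] = TopologicalSorter()
    for rec in records:
        parents = []
        for pid, role in ((rec.sire_id, "sire"), (rec.dam_id, "dam")):
            if pid is None:
                continue
            if pid not in by_id:
                raise PedigreeError(
                    f"animal {rec.animal_id!r}: {role} {pid!r} not in pedigree"
                )
            parent = by_id[pid]
            if role == "sire" and parent.sex == "female":
                raise PedigreeError(f"sire {pid!r} of {rec.animal_id!r} is recorded female")
            if role == "dam" and parent.sex == "male":
                raise PedigreeError(f"dam {pid!r} of {rec.animal_id!r} is recorded male")
            parents.append(pid)
        ts.add(rec.animal_id, *parents)
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        cyc = exc.args[1]
        raise PedigreeError(
            f"pedigree cycle detected involving animal {cyc[0]!r}"
        ) from exc
    return Pedigree([by_id[a] for a in order])


@njit(cache=True)
def _ml_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Meuwissen-Luo single-pass inbreeding on a sorted pedigree."""
    n = sire.shape[0]
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian-sampling variance coefficient of each animal
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            D[i] = 0.75 - 0.25 * F[p]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0  # at least one parent unknown -> assumed unrelated
            continue
        # a_ii = sum_j L_ij^2 D_j over ancestors j (including i); F_i = a_ii - 1
        for j in range(i + 1):
            L[j] = 0.0
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            aii += lj * lj * D[j]
            if sire[j] >= 0:
                L[sire[j]] += 0.5 * lj
            if dam[j] >= 0:
                L[dam[j]] += 0.5 * lj
        F[i] = aii - 1.0
    return F


@njit(cache=True)
def _tabular_nrm(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:  # pragma: no cover
    """Dense numerator relationship matrix by the tabular recursion."""
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a_js = A[j, s] if s >= 0 else 0.0
            a_jd = A[j, d] if d >= 0 else 0.0
            aij = 0.5 * (a_js + a_jd)
            A[i, j] = aij
            A[j, i] = aij
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return A


class Pedigree:
    """A topologically sorted pedigree with cached relationship quantities.

    Build via :func:`topo_sort` (arbitrary record order) or directly from a
    record list already in parents-before-offspring order.
    """

    #: animals above this size must use the sparse inverse, never dense A
    DENSE_CAP = 5000

    def __init__(self, records: list[PedigreeRecord]):
        self.records = list(records)
        self.ids = [r.animal_id for r in self.records]
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal_id in pedigree")
        n = len(self.records)
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        for i, rec in enumerate(self.records):
            for arr, pid in ((self.sire, rec.sire_id), (self.dam, rec.dam_id)):
                if pid is not None:
                    j = self._index.get(pid)
                    if j is None:
                        raise PedigreeError(
                            f"animal {rec.animal_id!r}: parent {pid!r} not in pedigree"
                        )
                    if j >= i:
                        raise PedigreeError(
                            f"pedigree not sorted: parent {pid!r} does not precede "
                            f"offspring {rec.animal_id!r}"
                        )
                    arr[i] = j
        self._F: np.ndarray | None = None
        self._g: np.ndarray | None = None
        self._gen_class: np.ndarray | None = None

    # -- basics ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def index(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire < 0) & (self.dam < 0)))

    # -- inbreeding and relationships ----------------------------------

    @property
    def F(self) -> npt.NDArray[np.float64]:
        """Per-animal inbreeding coefficient, F = 0.5 a(sire, dam)."""
        if self._F is None:
            self._F = _ml_inbreeding(self.sire, self.dam)
        return self._F

    def inbreeding(self) -> npt.NDArray[np.float64]:
        return self.F

    def nrm(self) -> npt.NDArray[np.float64]:
        """Dense numerator relationship matrix A (a_ii = 1 + F_i).

        Guarded by :attr:`DENSE_CAP`; large pedigrees should use
        :meth:`nrm_inverse`, which is sparse and never forms A.
        """
        if len(self) > self.DENSE_CAP:
            raise PedigreeError(
                f"pedigree has {len(self)} animals > dense cap {self.DENSE_CAP}; "
                "use nrm_inverse() instead"
            )
        return _tabular_nrm(self.sire, self.dam)

    def mendelian_variance(self) -> npt.NDArray[np.float64]:
        """d_i: within-family (Mendelian-sampling) variance coefficients."""
        F, s, d = self.F, self.sire, self.dam
        Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
        Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
        both = (s >= 0) & (d >= 0)
        one = (s >= 0) ^ (d >= 0)
        dcoef = np.ones(len(self))
        dcoef[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
        dcoef[one] = 0.75 - 0.25 * (Fs + Fd)[one]  # the known parent's F
        return dcoef

    def nrm_inverse(self) -> sparse.csr_matrix:
        """Sparse A^-1 by Henderson's rules with inbreeding.

        Per animal i with alpha_i = 1/d_i: add alpha at (i,i), -alpha/2 at
        (i, parent) and (parent, i), alpha/4 at all known-parent pairs.
        """
        n = len(self)
        alpha = 1.0 / self.mendelian_variance()
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        i = np.arange(n)
        rows.append(i), cols.append(i), vals.append(alpha)
        for p in (self.sire, self.dam):
            k = p >= 0
            rows.append(i[k]), cols.append(p[k]), vals.append(-0.5 * alpha[k])
            rows.append(p[k]), cols.append(i[k]), vals.append(-0.5 * alpha[k])
            rows.append(p[k]), cols.append(p[k]), vals.append(0.25 * alpha[k])
        both = (self.sire >= 0) & (self.dam >= 0)
        s, d = self.sire[both], self.dam[both]
        a4 = 0.25 * alpha[both]
        rows.append(s), cols.append(d), vals.append(a4)
        rows.append(d), cols.append(s), vals.append(a4)
        Ainv = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return Ainv.tocsr()

    def relationship(self, a: str, b: str) -> float:
        """Additive relationship between two animals (dense path)."""
        A = self.nrm()
        return float(A[self.index(a), self.index(b)])

    # -- generation coefficients ---------------------------------------

    def generation_coefficients(
        self, rounding: str = "half_up"
    ) -> tuple[npt.NDArray[np.float64], npt.NDArray[np.int64]]:
        """Approximate generation coefficient g and whole generation class.

        g = 1 + (g_sire + g_dam)/2 with founders at 0; an unknown parent is
        treated as a phantom founder contributing g = 0.  ``rounding`` is
        ``"half_up"`` (default: 2.5 -> 3) or ``"half_even"`` (banker's).
        """
        n = len(self)
        g = np.zeros(n)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s < 0 and d < 0:
                continue  # founder
            gs = g[s] if s >= 0 else 0.0
            gd = g[d] if d >= 0 else 0.0
            g[i] = 1.0 + 0.5 * (gs + gd)
        if rounding == "half_up":
            gen_class = np.floor(g + 0.5).astype(np.int64)
        elif rounding == "half_even":
            gen_class = np.rint(g).astype(np.int64)
        else:
            raise ValueError(f"unknown rounding policy {rounding!r}")
        self._g, self._gen_class = g, gen_class
        return g, gen_class

    @property
    def g(self) -> npt.NDArray[np.float64]:
        if self._g is None:
            self.generation_coefficients()
        return self._g

    @property
    def gen_class(self) -> npt.NDArray[np.int64]:
        if self._gen_class is None:
            self.generation_coefficients()
        return self._gen_class
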