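"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import functools
import itertools

import numpy as np
import pytest

from pedsel.pedigree import Pedigree, PedigreeRecord


# ---------------------------------------------------------------------------
# random pedigree generation
# ---------------------------------------------------------------------------

def random_pedigree(rng: np.random.Generator, n: int, n_founders: int = 6,
                    shuffle: bool = False) -> list[PedigreeRecord]:
    """A random valid pedigree: later animals draw parents from earlier ones.

    Produces inbreeding by reusing popular parents.  Returned in sorted
    order unless ``shuffle``.
    """
    records: list[PedigreeRecord] = []
    sexes: list[str] = []
    for i in range(n):
        aid = f"a{i}"
        sex = "male" if rng.random() < 0.5 else "female"
        if i < n_founders:
            records.append(PedigreeRecord(aid, None, None, sex))
        else:
            males = [j for j in range(i) if sexes[j] == "male"]
            females = [j for j in range(i) if sexes[j] == "female"]
            sire = f"a{rng.choice(males)}" if males and rng.random() < 0.9 else None
            dam = f"a{rng.choice(females)}" if females and rng.random() < 0.9 else None
            records.append(PedigreeRecord(aid, sire, dam, sex))
        sexes.append(sex)
    if shuffle:
        order = rng.permutation(n)
        records = [records[i] for i in order]
    return records


# ---------------------------------------------------------------------------
# Wright's path-counting inbreeding oracle (independent of the package)
# ---------------------------------------------------------------------------

def path_counting_inbreeding(records: list[PedigreeRecord]) -> dict[str, float]:
    """F by enumerating ancestor paths: F_x = sum over common ancestors A and
    non-overlapping path pairs of (1/2)^(n1+n2+1) (1 + F_A)."""
    parents = {r.animal_id: (r.sire_id, r.dam_id) for r in records}

    def paths_up(node: str) -> list[list[str]]:
        out = [[node]]
        for p in parents[node]:
            if p is not None:
                out.extend([[node] + path for path in paths_up(p)])
        return out

    @functools.lru_cache(maxsize=None)
    def F(x: str) -> float:
        s, d = parents[x]
        if s is None or d is None:
            return 0.0
        total = 0.0
        for p1 in paths_up(s):
            for p2 in paths_up(d):
                if p1[-1] != p2[-1]:
                    continue  # must meet at a common ancestor
                if set(p1) & set(p2) != {p1[-1]}:
                    continue  # paths may share only that ancestor
                n1, n2 = len(p1) - 1, len(p2) - 1
                total += 0.5 ** (n1 + n2 + 1) * (1.0 + F(p1[-1]))
        return total

    return {r.animal_id: F(r.animal_id) for r in records}


# ---------------------------------------------------------------------------
# exhaustive Jonckheere-Terpstra permutation oracle
# ---------------------------------------------------------------------------

def jt_brute_force(values, codes, k: int) -> tuple[float, float]:
    """(JT, one-sided increasing permutation p) by enumerating all distinct
    assignments of observations to groups via index combinations."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sizes = [int(np.sum(np.asarray(codes) == g)) for g in range(k)]

    def stat(assign: np.ndarray) -> float:
        jt = 0.0
        gs = [values[assign == g] for g in range(k)]
        for i in range(k):
            for j in range(i + 1, k):
                jt += np.sum(gs[i][:, None] < gs[j][None, :])
                jt += 0.5 * np.sum(gs[i][:, None] == gs[j][None, :])
        return jt

    observed = stat(np.asarray(codes))
    null = []

    def enumerate_assignments(remaining: tuple[int, ...], group: int,
                              assign: np.ndarray):
        if group == k - 1:
            a = assign.copy()
            a[list(remaining)] = group
            null.append(stat(a))
            return
        for combo in itertools.combinations(remaining, sizes[group]):
            a = assign.copy()
            a[list(combo)] = group
            rest = tuple(i for i in remaining if i not in combo)
            enumerate_assignments(rest, group + 1, a)

    enumerate_assignments(tuple(range(n)), 0, np.full(n, -1))
    null = np.asarray(null)
    p = float(np.mean(null >= observed - 1e-9))
    return observed, p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
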