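"""Two-trait pedigree-based linear mixed model ("animal model").

For traits y_1, y_2 observed once per animal (either may be missing):

    y_t = X_t b_t + Z u_t + e_t,   var([u_1; u_2]) = G0 (x) A,
                                   var(e_i) = R0 restricted to the traits
                                              observed on record i,

where A is the numerator relationship matrix, G0 / R0 the 2x2 additive and
residual (co)variance matrices, X_t trait-specific fixed effects (class
effects dummy-coded with the first level dropped, covariates centred) and
Z the record-to-animal incidence.  Breeding values are defined for every
pedigree member, phenotyped or not.

Fitting:

* **EM-REML** — expectation-maximisation on the mixed-model equations,
  iterated to a relative-change tolerance; standard errors from the
  inverse average-information matrix evaluated at the optimum, with
  delta-method SEs for heritability and the genetic correlation.
* **Gibbs sampling** — single-site updates of all location effects,
  inverse-Wishart full conditionals for G0 and R0, and data augmentation
  of trait-wise missing records.  Priors are proper but near-flat
  inverse-Wishart (scale = prior_scale * I with a tiny default scale so a
  trait with variance far below 1 is not dragged toward the prior, df =
  dim + 2) and flat on fixed effects.

The usage pattern follows statsmodels: build an :class:`AnimalModel` from
a DataFrame + :class:`~pedsel.pedigree.Pedigree`, call ``fit()``, inspect
the returned results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.linalg import lapack
from scipy.sparse.linalg import splu
from scipy.stats import invwishart, norm

from pedsel.pedigree import Pedigree

__all__ = [
    "TraitSpec",
    "ChainConfig",
    "AnimalModel",
    "REMLResults",
    "GibbsResults",
    "MMESystem",
    "solve_mme",
    "heritability",
    "genetic_correlation",
    "hpd_interval",
    "nearest_pd",
]


# ---------------------------------------------------------------------------
# small free functions (ratio statistics and intervals)
# ---------------------------------------------------------------------------

def heritability(var_a: float, var_e: float) -> float:
    """h2 = sigma2_A / (sigma2_A + sigma2_E)."""
    tot = var_a + var_e
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return var_a / tot


def genetic_correlation(cov_a: float, var_a_x: float, var_a_y: float) -> float:
    """r_A = cov_A(x,y) / sqrt(var_A(x) var_A(y)), clamped to [-1, 1]."""
    if var_a_x <= 0 or var_a_y <= 0:
        raise ValueError("both genetic variances must be positive")
    r = cov_a / math.sqrt(var_a_x * var_a_y)
    return min(1.0, max(-1.0, r))


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 50:
        raise ValueError(f"need at least 50 draws for an HPD interval, got {n}")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def nearest_pd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the positive-definite cone."""
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    floor = eps * max(1.0, float(w.max()))
    if w.min() > 0:
        return sym
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """Fixed-effect structure for one trait.

    ``response`` names the data column; ``class_effects`` are dummy-coded
    with the first level dropped; ``covariates`` enter linearly, centred
    on the observed-record mean.  The inbreeding covariate is expected in
    percent (0-100).
    """

    name: str
    response: str
    class_effects: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()


@dataclass
class ChainConfig:
    """Gibbs chain geometry; retained draws = (iterations - burn_in)/thin."""

    iterations: int = 50_000
    burn_in: int = 5_000
    thin: int = 50

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def paper_scale(cls) -> "ChainConfig":
        return cls(iterations=500_000, burn_in=50_000, thin=500)


@dataclass
class MMESystem:
    """Assembled mixed-model equations C theta = rhs with coordinate layout."""

    C: sparse.csr_matrix
    rhs: np.ndarray
    off_b: list[int]
    off_u: list[int]
    n_animals: int
    fixed_names: list[list[str]]


def solve_mme(system: MMESystem, rtol: float = 1e-8) -> np.ndarray:
    """Solve the MME by sparse LU; verify the relative residual."""
    lu = splu(system.C.tocsc())
    theta = lu.solve(system.rhs)
    rhs_norm = np.linalg.norm(system.rhs)
    resid = np.linalg.norm(system.C @ theta - system.rhs)
    if rhs_norm > 0 and resid > rtol * rhs_norm:
        raise RuntimeError(
            f"MME solve did not reach tolerance: relative residual {resid / rhs_norm:.3e}"
        )
    return theta


@njit(cache=True)
def _gibbs_sweep(indptr, indices, data, theta, rhs, z):  # pragma: no cover
    """One single-site Gibbs pass over all location effects (CSR walk)."""
    n = theta.shape[0]
    for i in range(n):
        s = 0.0
        d = 1.0
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if j == i:
                d = data[p]
            else:
                s += data[p] * theta[j]
        mu = (rhs[i] - s) / d
        theta[i] = mu + z[i] / math.sqrt(d)


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class AnimalModel:
    """Pedigree-based mixed model for one or two traits.

    Parameters
    ----------
    data : DataFrame
        One row per phenotyped animal.  Must contain ``animal_col`` plus
        every column named by the trait specs.  A missing response means
        the animal was not measured for that trait (trait-wise missing;
        rows missing every trait are dropped).
    pedigree : Pedigree
        Sorted pedigree covering (at least) all phenotyped animals;
        breeding values are predicted for every pedigree member.
    traits : sequence of TraitSpec
        One or two traits.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree: Pedigree,
        traits: list[TraitSpec] | tuple[TraitSpec, ...],
        animal_col: str = "animal_id",
        drop_aliased: bool = False,
    ):
        self.ped = pedigree
        self.traits = list(traits)
        self.T = len(self.traits)
        if self.T not in (1, 2):
            raise ValueError("AnimalModel supports one or two traits")
        q = len(pedigree)

        data = data.copy()
        resp = [t.response for t in self.traits]
        keep = data[resp].notna().any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"dropped {n_drop} record(s) missing every trait")
        data = data.loc[keep].reset_index(drop=True)
        missing_ped = set(data[animal_col]) - set(pedigree.ids)
        if missing_ped:
            raise ValueError(f"animals not in pedigree: {sorted(missing_ped)[:5]} ...")
        self.data = data
        self.N = len(data)
        self.animal_idx = np.array([pedigree.index(a) for a in data[animal_col]])

        self.y = np.zeros((self.T, self.N))
        self.mask = np.zeros((self.T, self.N), dtype=bool)
        for t, spec in enumerate(self.traits):
            col = pd.to_numeric(data[spec.response], errors="coerce")
            self.mask[t] = col.notna().to_numpy()
            self.y[t] = col.fillna(0.0).to_numpy()

        # fixed-effect design per trait (drop-first dummies, centred covariates)
        self.X: list[np.ndarray] = []
        self.fixed_names: list[list[str]] = []
        for t, spec in enumerate(self.traits):
            cols = [np.ones(self.N)]
            names = ["intercept"]
            for ce in spec.class_effects:
                cat = pd.Categorical(data[ce].astype(str))
                dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
                for lev in dummies.columns:
                    cols.append(dummies[lev].to_numpy())
                    names.append(f"{ce}[{lev}]")
            for cv in spec.covariates:
                v = pd.to_numeric(data[cv], errors="coerce").to_numpy(dtype=float)
                obs = self.mask[t] & ~np.isnan(v)
                center = v[obs].mean() if obs.any() else 0.0
                v = np.where(np.isnan(v), center, v) - center
                cols.append(v)
                names.append(cv)
            X = np.column_stack(cols)
            Xobs = X[self.mask[t]]
            if Xobs.shape[0] == 0:
                # no records: the trait's fixed effects are inestimable and are
                # dropped; its breeding values stay, tied in through G0
                warnings.warn(
                    f"trait {spec.name!r}: no observed records; fixed effects "
                    "dropped, EBVs informed only through the genetic covariance"
                )
                self.X.append(np.zeros((self.N, 0)))
                self.fixed_names.append([])
                continue
            rank = np.linalg.matrix_rank(Xobs)
            if rank < X.shape[1]:
                if not drop_aliased:
                    raise ValueError(
                        f"trait {spec.name!r}: fixed-effect design singular after "
                        f"drop-first constraints ({rank} < {X.shape[1]}); confounded "
                        f"among {names}"
                    )
                # pivoted QR keeps a maximal independent column subset
                from scipy.linalg import qr

                _, R, piv = qr(Xobs, mode="economic", pivoting=True)
                dr = np.abs(np.diag(R))
                keep = np.sort(piv[dr > dr.max() * 1e-10 * max(Xobs.shape)])
                dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep)]
                warnings.warn(
                    f"trait {spec.name!r}: dropped aliased fixed-effect "
                    f"column(s) {dropped}"
                )
                X = X[:, keep]
                names = [names[i] for i in keep]
            self.X.append(X)
            self.fixed_names.append(names)

        self.p = [X.shape[1] for X in self.X]
        self.off_b = list(np.cumsum([0] + self.p[:-1]))
        p_tot = sum(self.p)
        self.off_u = [p_tot + t * q for t in range(self.T)]
        self.dim = p_tot + self.T * q
        self.q = q
        self.Ainv = pedigree.nrm_inverse()

        # global row-design S_t: X_t in its b-block, 1 at the animal's u_t slot
        self.S: list[sparse.csr_matrix] = []
        rows = np.arange(self.N)
        for t in range(self.T):
            Xs = sparse.csr_matrix(self.X[t])
            Zt = sparse.coo_matrix(
                (np.ones(self.N), (rows, self.off_u[t] + self.animal_idx)),
                shape=(self.N, self.dim),
            )
            Xpad = sparse.hstack(
                [sparse.csr_matrix((self.N, self.off_b[t])), Xs,
                 sparse.csr_matrix((self.N, self.dim - self.off_b[t] - self.p[t]))],
                format="csr",
            )
            self.S.append((Xpad + Zt).tocsr())

        # observation patterns (which traits present on each record)
        self.patterns: dict[tuple[bool, ...], np.ndarray] = {}
        keys = [tuple(self.mask[:, i]) for i in range(self.N)]
        for pat in sorted(set(keys), reverse=True):
            self.patterns[pat] = np.array([i for i, k in enumerate(keys) if k == pat])

        # per-pattern normal-equation pieces M = S_j' S_k, w = S_j' y_k
        self._M: dict[tuple[bool, ...], dict[tuple[int, int], sparse.csr_matrix]] = {}
        self._w: dict[tuple[bool, ...], dict[tuple[int, int], np.ndarray]] = {}
        for pat, idx in self.patterns.items():
            obs = [t for t in range(self.T) if pat[t]]
            Mp, wp = {}, {}
            for j in obs:
                Sj = self.S[j][idx]
                for k in obs:
                    Sk = self.S[k][idx]
                    Mp[(j, k)] = (Sj.T @ Sk).tocsr()
                    wp[(j, k)] = np.asarray(Sj.T @ self.y[k][idx]).ravel()
            self._M[pat] = Mp
            self._w[pat] = wp

    # -- assembly -------------------------------------------------------

    def _rinv_pattern(self, R0: np.ndarray, pat: tuple[bool, ...]) -> np.ndarray:
        obs = [t for t in range(self.T) if pat[t]]
        sub = R0[np.ix_(obs, obs)]
        inv = np.linalg.inv(sub)
        full = np.zeros_like(R0)
        full[np.ix_(obs, obs)] = inv
        return full

    def _gpart(self, G0: np.ndarray) -> sparse.coo_matrix:
        Ginv = np.linalg.inv(G0)
        gp = sparse.kron(sparse.csr_matrix(Ginv), self.Ainv).tocoo()
        off = self.off_u[0]
        return sparse.coo_matrix(
            (gp.data, (gp.row + off, gp.col + off)), shape=(self.dim, self.dim)
        )

    def build_mme(self, G0: np.ndarray, R0: np.ndarray) -> MMESystem:
        """Assemble the sparse mixed-model equations for given (G0, R0)."""
        G0 = np.atleast_2d(np.asarray(G0, dtype=float))
        R0 = np.atleast_2d(np.asarray(R0, dtype=float))
        if np.any(np.linalg.eigvalsh(G0) <= 0) or np.any(np.linalg.eigvalsh(R0) <= 0):
            raise ValueError("G0 and R0 must be positive definite")
        C = sparse.csr_matrix((self.dim, self.dim))
        rhs = np.zeros(self.dim)
        for pat in self.patterns:
            rinv = self._rinv_pattern(R0, pat)
            for (j, k), M in self._M[pat].items():
                if rinv[j, k] != 0.0:
                    C = C + rinv[j, k] * M
                    rhs += rinv[j, k] * self._w[pat][(j, k)]
        C = (C + self._gpart(G0)).tocsr()
        return MMESystem(C, rhs, self.off_b, self.off_u, self.q, self.fixed_names)

    def _theta_to_tables(self, theta: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
        fixed_rows = []
        for t, spec in enumerate(self.traits):
            for m, name in enumerate(self.fixed_names[t]):
                fixed_rows.append(
                    {"trait": spec.name, "effect": name,
                     "estimate": theta[self.off_b[t] + m]}
                )
        ebv_rows = {"animal_id": self.ped.ids}
        for t, spec in enumerate(self.traits):
            ebv_rows[f"ebv_{spec.name}"] = theta[self.off_u[t]: self.off_u[t] + self.q]
        return pd.DataFrame(fixed_rows), pd.DataFrame(ebv_rows)

    # -- fitting --------------------------------------------------------

    def fit(self, method: str = "reml", **kwargs):
        """Fit by ``"reml"`` (EM-REML) or ``"gibbs"`` (MCMC)."""
        if method == "reml":
            return self.fit_reml(**kwargs)
        if method == "gibbs":
            return self.fit_gibbs(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def _start_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Half the phenotypic (co)variance to each of G0 and R0."""
        P = np.eye(self.T)
        for j in range(self.T):
            for k in range(j, self.T):
                both = self.mask[j] & self.mask[k]
                if both.sum() > 2:
                    c = np.cov(self.y[j][both], self.y[k][both])[0, 1] if j != k else np.var(
                        self.y[j][both], ddof=1
                    )
                else:
                    c = 1.0 if j == k else 0.0
                P[j, k] = P[k, j] = c
        P = nearest_pd(P)
        return 0.5 * P, 0.5 * P

    def fit_reml(
        self,
        tol: float = 1e-9,
        max_rounds: int = 300,
        start: tuple[np.ndarray, np.ndarray] | None = None,
        compute_se: bool = True,
        accelerate: bool = True,
        verbose: bool = False,
    ) -> "REMLResults":
        """EM-REML for (G0, R0), SEs from the average-information matrix.

        Iterates the expectation-maximisation updates on the mixed-model
        equations until the maximum relative parameter change drops below
        ``tol``.  Raises if ``max_rounds`` is reached first (the trajectory
        is attached to the exception).  ``accelerate`` applies safeguarded
        component-wise Aitken extrapolation to shorten EM's linear tail;
        extrapolated points are only accepted while both matrices stay
        positive definite.
        """
        for t in range(self.T):
            if self.mask[t].sum() < 2:
                raise ValueError(f"trait {self.traits[t].name!r}: fewer than 2 records")
        G0, R0 = start if start is not None else self._start_values()
        G0, R0 = np.atleast_2d(np.asarray(G0, float)), np.atleast_2d(np.asarray(R0, float))
        history = []
        converged = False
        bent = False
        theta = np.zeros(self.dim)
        Cinv = None
        prev_step: np.ndarray | None = None
        for rnd in range(1, max_rounds + 1):
            theta, Cinv = self._solve_dense(G0, R0)
            G_new, R_new = self._em_update(theta, Cinv, G0, R0)
            for name, m in (("G0", G_new), ("R0", R_new)):
                if np.any(np.linalg.eigvalsh(m) <= 0):
                    warnings.warn(f"{name} left the positive-definite cone; bent back")
                    bent = True
            G_new, R_new = nearest_pd(G_new), nearest_pd(R_new)
            old = np.concatenate([G0.ravel(), R0.ravel()])
            new = np.concatenate([G_new.ravel(), R_new.ravel()])
            step = new - old
            delta = float(np.max(np.abs(step) / (np.abs(old) + 1e-12)))
            history.append({"round": rnd, "delta": delta,
                            "G0": G_new.copy(), "R0": R_new.copy()})
            G0, R0 = G_new, R_new
            if verbose:
                print(f"round {rnd}: delta={delta:.3e}")
            if delta < tol:
                converged = True
                break
            if accelerate and prev_step is not None and rnd % 3 == 0:
                # Aitken jump along each component's geometric tail
                with np.errstate(divide="ignore", invalid="ignore"):
                    rate = np.where(np.abs(prev_step) > 0, step / prev_step, 0.0)
                rate = np.clip(rate, 0.0, 0.98)
                ext = new + rate / (1.0 - rate) * step
                k = self.T
                G_ext = ext[: k * k].reshape(k, k)
                R_ext = ext[k * k:].reshape(k, k)
                if (np.all(np.linalg.eigvalsh(0.5 * (G_ext + G_ext.T)) > 0)
                        and np.all(np.linalg.eigvalsh(0.5 * (R_ext + R_ext.T)) > 0)):
                    G0 = 0.5 * (G_ext + G_ext.T)
                    R0 = 0.5 * (R_ext + R_ext.T)
                    prev_step = None
                    continue
            prev_step = step
        if not converged:
            err = RuntimeError(
                f"EM-REML did not converge in {max_rounds} rounds "
                f"(last relative change {history[-1]['delta']:.3e})"
            )
            err.history = history  # type: ignore[attr-defined]
            raise err
        theta, Cinv = self._solve_dense(G0, R0)
        vc_cov = self._ai_covariance(theta, Cinv, G0, R0) if compute_se else None
        fixed, ebv = self._theta_to_tables(theta)
        return REMLResults(
            model=self, G0=G0, R0=R0, vc_cov=vc_cov, n_rounds=len(history),
            converged=converged, pd_bent=bent, history=history,
            fixed_effects=fixed, ebv_table=ebv,
        )

    def _solve_dense(self, G0, R0) -> tuple[np.ndarray, np.ndarray]:
        """Solve the MME and return (theta, dense inverse of C)."""
        sys_ = self.build_mme(G0, R0)
        Cd = sys_.C.toarray()
        cf, info = lapack.dpotrf(Cd, lower=1, overwrite_a=1)
        if info != 0:
            raise RuntimeError(f"MME coefficient matrix not PD (dpotrf info={info})")
        theta = lapack.dpotrs(cf, sys_.rhs, lower=1)[0]
        Cinv, info = lapack.dpotri(cf, lower=1)
        if info != 0:
            raise RuntimeError(f"dpotri failed (info={info})")
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        return theta, Cinv

    def _trace_ainv_block(self, Cinv: np.ndarray, j: int, k: int) -> float:
        A = self.Ainv.tocoo()
        block = Cinv[self.off_u[j]: self.off_u[j] + self.q,
                     self.off_u[k]: self.off_u[k] + self.q]
        return float(np.sum(A.data * block[A.col, A.row]))

    def _diag_svs(self, Cinv: np.ndarray, j: int, k: int) -> np.ndarray:
        """diag(S_j Cinv S_k') — per-record estimation-error covariance."""
        a = self.animal_idx
        bj = slice(self.off_b[j], self.off_b[j] + self.p[j])
        bk = slice(self.off_b[k], self.off_b[k] + self.p[k])
        uj = slice(self.off_u[j], self.off_u[j] + self.q)
        uk = slice(self.off_u[k], self.off_u[k] + self.q)
        Xj, Xk = self.X[j], self.X[k]
        v = np.einsum("ip,pq,iq->i", Xj, Cinv[bj, bk], Xk)
        v += np.einsum("ip,ip->i", Xj, Cinv[bj, uk][:, a].T)
        v += np.einsum("iq,iq->i", Xk, Cinv[uj, bk][:, :][a, :])
        v += Cinv[uj, uk][a, a]
        return v

    def _em_update(self, theta, Cinv, G0, R0) -> tuple[np.ndarray, np.ndarray]:
        T, q, N = self.T, self.q, self.N
        # genetic block
        G_new = np.zeros((T, T))
        u = [theta[self.off_u[t]: self.off_u[t] + q] for t in range(T)]
        for j in range(T):
            for k in range(j, T):
                val = float(u[j] @ (self.Ainv @ u[k])) + self._trace_ainv_block(Cinv, j, k)
                G_new[j, k] = G_new[k, j] = val / q
        # residual block: expected residual cross-products, pattern-wise
        resid = np.zeros((T, N))
        for t in range(T):
            resid[t] = self.y[t] - self.S[t] @ theta
        vdiag = {}
        for j in range(T):
            for k in range(T):
                vdiag[(j, k)] = self._diag_svs(Cinv, j, k)
        R_acc = np.zeros((T, T))
        for pat, idx in self.patterns.items():
            obs = [t for t in range(T) if pat[t]]
            mis = [t for t in range(T) if not pat[t]]
            E = np.zeros((T, T, idx.size))
            for j in obs:
                for k in obs:
                    E[j, k] = resid[j][idx] * resid[k][idx] + vdiag[(j, k)][idx]
            if mis:
                m, o = mis[0], obs[0]  # at most one missing trait when T == 2
                b = R0[m, o] / R0[o, o]
                schur = R0[m, m] - R0[m, o] ** 2 / R0[o, o]
                E[o, m] = E[m, o] = b * E[o, o]
                E[m, m] = b * b * E[o, o] + schur
            R_acc += E.sum(axis=2)
        return G_new, R_acc / N

    # -- average information at the optimum ----------------------------

    def _py(self, theta: np.ndarray, R0: np.ndarray) -> np.ndarray:
        """P y = Rinv (y - W theta) on observed coordinates ((T, N), zeros elsewhere)."""
        T, N = self.T, self.N
        resid = np.zeros((T, N))
        for t in range(T):
            resid[t] = np.where(self.mask[t], self.y[t] - self.S[t] @ theta, 0.0)
        out = np.zeros((T, N))
        for pat, idx in self.patterns.items():
            rinv = self._rinv_pattern(R0, pat)
            for j in range(T):
                if not pat[j]:
                    continue
                for k in range(T):
                    if pat[k] and rinv[j, k] != 0.0:
                        out[j, idx] += rinv[j, k] * resid[k][idx]
        return out

    def _apply_p(self, f: np.ndarray, Cinv: np.ndarray, R0: np.ndarray) -> np.ndarray:
        """P f = Rinv f - Rinv W Cinv W' Rinv f (observed coordinates)."""
        T, N = self.T, self.N

        def rinv_apply(v: np.ndarray) -> np.ndarray:
            out = np.zeros_like(v)
            for pat, idx in self.patterns.items():
                rinv = self._rinv_pattern(R0, pat)
                for j in range(T):
                    if not pat[j]:
                        continue
                    for k in range(T):
                        if pat[k] and rinv[j, k] != 0.0:
                            out[j, idx] += rinv[j, k] * v[k][idx]
            return out

        t1 = rinv_apply(f)
        h = np.zeros(self.dim)
        for t in range(T):
            h += self.S[t].T @ (t1[t] * self.mask[t])
        s = Cinv @ h
        ws = np.zeros((T, N))
        for t in range(T):
            ws[t] = np.where(self.mask[t], self.S[t] @ s, 0.0)
        return t1 - rinv_apply(ws)

    def _vc_param_list(self) -> list[tuple[str, int, int]]:
        out = [("G", j, k) for j in range(self.T) for k in range(j, self.T)]
        out += [("R", j, k) for j in range(self.T) for k in range(j, self.T)]
        return out

    def _ai_covariance(self, theta, Cinv, G0, R0) -> np.ndarray:
        """Inverse average-information matrix over (G0, R0) free parameters."""
        T, N = self.T, self.N
        py = self._py(theta, R0)
        lu = splu(self.Ainv.tocsc())
        params = self._vc_param_list()
        fs = []
        for kind, j, k in params:
            f = np.zeros((T, N))
            if kind == "G":
                for a, b in ((j, k), (k, j)) if j != k else ((j, k),):
                    tq = np.zeros(self.q)
                    np.add.at(tq, self.animal_idx[self.mask[b]], py[b][self.mask[b]])
                    x = lu.solve(tq)  # A @ tq  via  Ainv x = tq
                    f[a][self.mask[a]] += x[self.animal_idx[self.mask[a]]]
            else:
                both = self.mask[j] & self.mask[k]
                for a, b in ((j, k), (k, j)) if j != k else ((j, k),):
                    f[a][both] += py[b][both]
            fs.append(f)
        npar = len(params)
        AI = np.zeros((npar, npar))
        pfs = [self._apply_p(f, Cinv, R0) for f in fs]
        for a in range(npar):
            for b in range(a, npar):
                AI[a, b] = AI[b, a] = 0.5 * float(np.sum(fs[a] * pfs[b]))
        try:
            return np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            warnings.warn("average-information matrix singular; SEs unavailable")
            return np.full((npar, npar), np.nan)

    # -- Gibbs ----------------------------------------------------------

    def fit_gibbs(
        self,
        chain: ChainConfig | None = None,
        seed: int = 0,
        prior_scale: float = 1e-6,
        start: tuple[np.ndarray, np.ndarray] | None = None,
        keep_location_mean: bool = True,
    ) -> "GibbsResults":
        """Blocked Gibbs sampler for (G0, R0) and all location effects.

        Location effects are refreshed coordinate-wise from their univariate
        normal full conditionals; G0 and R0 from inverse-Wishart full
        conditionals; trait-wise missing phenotypes are imputed from their
        residual conditional each round (data augmentation).  Identical
        seeds give identical retained draws.
        """
        chain = chain or ChainConfig()
        rng = np.random.default_rng(seed)
        T, q, N, dim = self.T, self.q, self.N, self.dim

        G0, R0 = start if start is not None else self._start_values()
        G0 = np.atleast_2d(np.asarray(G0, float)).copy()
        R0 = np.atleast_2d(np.asarray(R0, float)).copy()
        nu = T + 2
        S_prior = prior_scale * np.eye(T)

        # complete-data design pieces over all records
        M_all = {
            (j, k): (self.S[j].T @ self.S[k]).tocsr()
            for j in range(T) for k in range(T)
        }
        y_aug = self.y.copy()
        for t in range(T):
            obs_mean = self.y[t][self.mask[t]].mean() if self.mask[t].any() else 0.0
            y_aug[t][~self.mask[t]] = obs_mean

        theta = np.zeros(dim)
        draws_G = np.zeros((chain.n_retained, T, T))
        draws_R = np.zeros((chain.n_retained, T, T))
        theta_sum = np.zeros(dim)
        kept = 0
        for it in range(1, chain.iterations + 1):
            Rinv = np.linalg.inv(R0)
            C = sparse.csr_matrix((dim, dim))
            for (j, k), M in M_all.items():
                if Rinv[j, k] != 0.0:
                    C = C + Rinv[j, k] * M
            C = (C + self._gpart(G0)).tocsr()
            rhs = np.zeros(dim)
            for j in range(T):
                sy = np.zeros(dim)
                for k in range(T):
                    if Rinv[j, k] != 0.0:
                        sy += Rinv[j, k] * (self.S[j].T @ y_aug[k])
                rhs += sy
            z = rng.standard_normal(dim)
            _gibbs_sweep(C.indptr, C.indices, C.data, theta, rhs, z)

            # residual covariance | locations
            resid = np.empty((T, N))
            for t in range(T):
                resid[t] = y_aug[t] - self.S[t] @ theta
            Se = resid @ resid.T
            R0 = invwishart.rvs(df=nu + N, scale=S_prior + Se, random_state=rng)
            R0 = np.atleast_2d(R0)

            # genetic covariance | breeding values
            u = [theta[self.off_u[t]: self.off_u[t] + q] for t in range(T)]
            Su = np.empty((T, T))
            for j in range(T):
                for k in range(j, T):
                    Su[j, k] = Su[k, j] = float(u[j] @ (self.Ainv @ u[k]))
            G0 = np.atleast_2d(invwishart.rvs(df=nu + q, scale=S_prior + Su, random_state=rng))

            # impute missing trait values (only relevant when T == 2)
            if T == 2:
                for pat, idx in self.patterns.items():
                    if all(pat):
                        continue
                    m = pat.index(False)
                    o = 1 - m
                    fit_m = self.S[m][idx] @ theta
                    e_o = y_aug[o][idx] - self.S[o][idx] @ theta
                    b = R0[m, o] / R0[o, o]
                    sd = math.sqrt(max(R0[m, m] - R0[m, o] ** 2 / R0[o, o], 1e-30))
                    y_aug[m][idx] = fit_m + b * e_o + sd * rng.standard_normal(idx.size)

            if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
                draws_G[kept] = G0
                draws_R[kept] = R0
                theta_sum += theta
                kept += 1

        fixed, ebv = self._theta_to_tables(theta_sum / max(kept, 1))
        return GibbsResults(
            model=self, draws_G=draws_G[:kept], draws_R=draws_R[:kept],
            chain=chain, seed=seed, fixed_effects=fixed, ebv_table=ebv,
        )


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------

@dataclass
class REMLResults:
    """EM-REML estimates with average-information standard errors."""

    model: AnimalModel
    G0: np.ndarray
    R0: np.ndarray
    vc_cov: np.ndarray | None
    n_rounds: int
    converged: bool
    pd_bent: bool
    history: list
    fixed_effects: pd.DataFrame
    ebv_table: pd.DataFrame

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.model.traits]

    @property
    def h2(self) -> np.ndarray:
        return np.array([
            heritability(self.G0[t, t], self.R0[t, t]) for t in range(self.model.T)
        ])

    def _param_index(self, kind: str, j: int, k: int) -> int:
        return self.model._vc_param_list().index((kind, min(j, k), max(j, k)))

    @property
    def h2_se(self) -> np.ndarray:
        if self.vc_cov is None:
            return np.full(self.model.T, np.nan)
        out = np.empty(self.model.T)
        for t in range(self.model.T):
            g, r = self.G0[t, t], self.R0[t, t]
            tot = g + r
            grad = np.zeros(len(self.model._vc_param_list()))
            grad[self._param_index("G", t, t)] = r / tot**2
            grad[self._param_index("R", t, t)] = -g / tot**2
            out[t] = math.sqrt(max(grad @ self.vc_cov @ grad, 0.0))
        return out

    @property
    def r_a(self) -> float:
        if self.model.T < 2:
            raise ValueError("genetic correlation needs two traits")
        return genetic_correlation(self.G0[0, 1], self.G0[0, 0], self.G0[1, 1])

    @property
    def r_a_se(self) -> float:
        if self.vc_cov is None or self.model.T < 2:
            return float("nan")
        g11, g12, g22 = self.G0[0, 0], self.G0[0, 1], self.G0[1, 1]
        s = math.sqrt(g11 * g22)
        grad = np.zeros(len(self.model._vc_param_list()))
        grad[self._param_index("G", 0, 0)] = -0.5 * g12 / (g11 * s)
        grad[self._param_index("G", 0, 1)] = 1.0 / s
        grad[self._param_index("G", 1, 1)] = -0.5 * g12 / (g22 * s)
        return math.sqrt(max(grad @ self.vc_cov @ grad, 0.0))

    def h2_interval(self, t: int = 0, conf: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + conf / 2)
        return self.h2[t] - z * self.h2_se[t], self.h2[t] + z * self.h2_se[t]

    def r_a_interval(self, conf: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + conf / 2)
        return self.r_a - z * self.r_a_se, self.r_a + z * self.r_a_se

    def to_report(self) -> dict:
        """JSON-ready variance-component report."""
        rep = {
            "method": "EM-REML",
            "converged": self.converged,
            "rounds": self.n_rounds,
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "traits": self.trait_names,
            "h2": self.h2.tolist(),
            "h2_se": self.h2_se.tolist(),
        }
        if self.model.T == 2:
            rep["r_a"] = self.r_a
            rep["r_a_se"] = self.r_a_se
        return rep

    def summary(self) -> str:
        lines = ["EM-REML animal model", "=" * 52,
                 f"records: {self.model.N}   pedigree animals: {self.model.q}",
                 f"converged in {self.n_rounds} rounds", ""]
        for t, name in enumerate(self.trait_names):
            lines.append(
                f"{name}: sigma2_A={self.G0[t, t]:.4g}  sigma2_E={self.R0[t, t]:.4g}  "
                f"h2={self.h2[t]:.3f} (SE {self.h2_se[t]:.3f})"
            )
        if self.model.T == 2:
            lines.append(
                f"genetic correlation rA={self.r_a:.3f} (SE {self.r_a_se:.3f})"
            )
        return "\n".join(lines)


@dataclass
class GibbsResults:
    """Posterior draws of (G0, R0) with derived heritabilities/correlation."""

    model: AnimalModel
    draws_G: np.ndarray  # (S, T, T)
    draws_R: np.ndarray
    chain: ChainConfig
    seed: int
    fixed_effects: pd.DataFrame
    ebv_table: pd.DataFrame

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.model.traits]

    @property
    def n_draws(self) -> int:
        return self.draws_G.shape[0]

    @property
    def G0(self) -> np.ndarray:
        return self.draws_G.mean(axis=0)

    @property
    def R0(self) -> np.ndarray:
        return self.draws_R.mean(axis=0)

    @property
    def h2(self) -> np.ndarray:
        """Ratio of posterior means (report-table convention)."""
        G, R = self.G0, self.R0
        return np.array([G[t, t] / (G[t, t] + R[t, t]) for t in range(self.model.T)])

    def h2_draws(self, t: int = 0) -> np.ndarray:
        return self.draws_G[:, t, t] / (self.draws_G[:, t, t] + self.draws_R[:, t, t])

    @property
    def h2_posterior_mean(self) -> np.ndarray:
        """Posterior mean of the per-draw ratio."""
        return np.array([self.h2_draws(t).mean() for t in range(self.model.T)])

    @property
    def r_a(self) -> float:
        G = self.G0
        return genetic_correlation(G[0, 1], G[0, 0], G[1, 1])

    def r_a_draws(self) -> np.ndarray:
        g11 = self.draws_G[:, 0, 0]
        g22 = self.draws_G[:, 1, 1]
        return np.clip(self.draws_G[:, 0, 1] / np.sqrt(g11 * g22), -1, 1)

    def h2_interval(self, t: int = 0, mass: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.h2_draws(t), mass)

    def r_a_interval(self, mass: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.r_a_draws(), mass)

    def to_report(self) -> dict:
        rep = {
            "method": "Gibbs",
            "chain": {"iterations": self.chain.iterations, "burn_in": self.chain.burn_in,
                      "thin": self.chain.thin, "retained": self.n_draws, "seed": self.seed},
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "traits": self.trait_names,
            "h2": self.h2.tolist(),
            "h2_hpd": [list(self.h2_interval(t)) for t in range(self.model.T)],
        }
        if self.model.T == 2:
            rep["r_a"] = self.r_a
            rep["r_a_hpd"] = list(self.r_a_interval())
        return rep

    def summary(self) -> str:
        lines = ["Gibbs-sampler animal model", "=" * 52,
                 f"records: {self.model.N}   pedigree animals: {self.model.q}",
                 f"chain: {self.chain.iterations} iters, burn-in {self.chain.burn_in}, "
                 f"thin {self.chain.thin} -> {self.n_draws} retained draws", ""]
        for t, name in enumerate(self.trait_names):
            lo, hi = self.h2_interval(t)
            lines.append(
                f"{name}: sigma2_A={self.G0[t, t]:.4g}  sigma2_E={self.R0[t, t]:.4g}  "
                f"h2={self.h2[t]:.3f} (95% HPD {lo:.3f}..{hi:.3f})"
            )
        if self.model.T == 2:
            lo, hi = self.r_a_interval()
            lines.append(f"genetic correlation rA={self.r_a:.3f} (95% HPD {lo:.3f}..{hi:.3f})")
        return "\n".join(lines)
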