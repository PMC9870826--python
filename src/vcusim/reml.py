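"""REML estimation for crossed variance-component models.

Model class: y = X tau + sum_f Z_f u_f + e, with X an intercept plus up to two
uncentered numeric covariates (calendar year of testing ``t`` and year of
first testing ``r``), each u_f ~ N(0, sigma2_f I) for an independent crossed
grouping factor f, and e ~ N(0, sigma2_e I).  This covers the single-mean
analysis model (year, location, genotype, year-by-location, trial,
genotype-by-location, genotype-by-year + residual) and its extension with a
separate genotype-by-year-by-location term, as well as the small within-cycle
selection models.

Estimation maximises the restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = sum_f sigma2_f Z_f Z_f' + sigma2_e I

over nonnegative variances by average-information (AI) updates with
step-halving, falling back on EM steps when an AI step is not acceptable,
and projecting variances onto a small nonnegative floor.  All per-iteration
quantities come from the mixed-model equations

    C = W' W / sigma2_e + diag(0_p, sigma2_1^-1 I, ..., sigma2_q^-1 I),
    W = [X, Z_1, ..., Z_q]

using the identities  log|V| + log|X'V^-1X| = log|R| + log|G| + log|C|,
y'Py = (y'y - b' W'y)/sigma2_e  with C b = W'y / sigma2_e, and
tr(P Z_f Z_f') = (q_f - tr(C^ff)/sigma2_f)/sigma2_f  where C^ff is factor
f's diagonal block of C^-1.  A dense Cholesky path is used for moderate
numbers of levels; larger problems fall back on a sparse LU factorisation
with chunked solves for the inverse-diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ModelSpec",
    "ModelFit",
    "Design",
    "build_design",
    "reml_fit",
    "blup_H",
    "solve_mme",
    "MODEL5_RANDOM",
    "MODEL2_RANDOM",
]

#: named grouping factors -> dataset key columns
FACTOR_KEYS: dict[str, tuple[str, ...]] = {
    "year": ("year",),
    "location": ("location",),
    "year_location": ("year", "location"),
    "trial": ("trial",),
    "genotype": ("genotype",),
    "genotype_location": ("genotype", "location"),
    "genotype_year": ("genotype", "year"),
    "genotype_year_location": ("genotype", "year", "location"),
}

MODEL5_RANDOM = (
    "year",
    "location",
    "year_location",
    "trial",
    "genotype",
    "genotype_location",
    "genotype_year",
)
MODEL2_RANDOM = MODEL5_RANDOM + ("genotype_year_location",)


class DesignError(ValueError):
    """Unresolvable grouping key or duplicate factor in a model spec."""


class EstimabilityError(ValueError):
    """Singular fixed-effect design (e.g. r collinear with t)."""


def factor_keys(name: str) -> tuple[str, ...]:
    if name in FACTOR_KEYS:
        return FACTOR_KEYS[name]
    if "*" in name:
        return tuple(k.strip() for k in name.split("*"))
    return (name,)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed covariates (subset of t, r; intercept implicit) and random
    grouping factors; an i.i.d. residual is always present."""

    fixed: tuple[str, ...] = ("t", "r")
    random: tuple[str, ...] = MODEL5_RANDOM

    def __post_init__(self):
        if len(set(self.random)) != len(self.random):
            raise DesignError("duplicate random factors")

    def resolve(self, dataset: pd.DataFrame) -> "ModelSpec":
        """Drop a three-way genotype-by-year-by-location factor when the data
        carry no duplicated (genotype, year, location) rows: the term is then
        completely confounded with the residual (the separation rests on
        check varieties occurring in parallel series)."""
        random = self.random
        if "genotype_year_location" in random:
            keys = list(FACTOR_KEYS["genotype_year_location"])
            if not dataset.duplicated(keys).any():
                random = tuple(f for f in random if f != "genotype_year_location")
        return ModelSpec(self.fixed, random)


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]  # includes "intercept"
    Z: dict[str, sp.csc_matrix]
    levels: dict[str, pd.Index]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q_levels(self) -> dict[str, int]:
        return {f: Z.shape[1] for f, Z in self.Z.items()}


def build_design(dataset: pd.DataFrame, spec: ModelSpec) -> Design:
    """Response vector, fixed design and one sparse indicator per factor.

    Indicator columns exist only for level combinations observed in the data.
    """
    n = len(dataset)
    y = dataset["y"].to_numpy(dtype=float)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in spec.fixed:
        if c not in dataset.columns:
            raise DesignError(f"fixed covariate {c!r} not in dataset")
        cols.append(dataset[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        raise EstimabilityError("fixed-effect design is singular")

    Z: dict[str, sp.csc_matrix] = {}
    levels: dict[str, pd.Index] = {}
    for f in spec.random:
        keys = factor_keys(f)
        for k in keys:
            if k not in dataset.columns:
                raise DesignError(f"grouping key {k!r} for factor {f!r} not in dataset")
        if len(keys) == 1:
            codes, idx = pd.factorize(dataset[keys[0]], sort=True)
            levels[f] = pd.Index(idx)
        else:
            mi = pd.MultiIndex.from_frame(dataset[list(keys)])
            codes, idx = pd.factorize(mi, sort=True)
            levels[f] = idx
        q = len(levels[f])
        Z[f] = sp.csc_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, q)
        )
    return Design(y=y, X=X, fixed_names=names, Z=Z, levels=levels)


@dataclass
class ModelFit:
    """REML fit: variance components, fixed slopes with standard errors,
    genotype BLUPs, restricted log-likelihood and convergence diagnostics."""

    spec: ModelSpec
    vc: dict[str, float]  # per factor, plus "residual"
    fixed: dict[str, float]
    fixed_se: dict[str, float]
    blups: dict[str, pd.Series]
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    notes: list[str] = field(default_factory=list)

    @property
    def beta_hat(self) -> float:
        return self.fixed.get("r", np.nan)

    @property
    def gamma_hat(self) -> float:
        return self.fixed.get("t", np.nan)

    def vc_table(self) -> pd.Series:
        return pd.Series(self.vc)


class _MME:
    """Workspace for the mixed-model equations of one design.

    Offers factorisation-backed solves, the log-determinant, and the
    diagonal of C^-1, on a dense (Cholesky) or sparse (LU) path.
    """

    def __init__(self, design: Design, dense_limit: int = 3500):
        self.d = design
        X = sp.csc_matrix(design.X)
        self.W = sp.hstack([X] + [design.Z[f] for f in design.Z], format="csc")
        self.r = self.W.shape[1]
        self.p = design.p
        self.Wty = self.W.T @ design.y
        self.yty = float(design.y @ design.y)
        self.q = design.q_levels
        # slices of each factor's block in the MME solution vector
        self.slices: dict[str, slice] = {}
        off = design.p
        for f, qf in self.q.items():
            self.slices[f] = slice(off, off + qf)
            off += qf
        self.dense = self.r <= dense_limit
        self.M = (self.W.T @ self.W).tocsc()
        if self.dense:
            self.M_dense = self.M.toarray()
        self._chol = None
        self._lu = None
        self._logdet = None

    def factorize(self, lam: dict[str, float], lam_e: float) -> None:
        dvec = np.zeros(self.r)
        for f, s in self.slices.items():
            dvec[s] = 1.0 / lam[f]
        if self.dense:
            C = self.M_dense / lam_e + np.diag(dvec)
            self._chol = sla.cholesky(C, lower=True, check_finite=False)
            self._logdet = 2.0 * float(np.sum(np.log(np.diag(self._chol))))
            self._lu = None
        else:
            C = (self.M / lam_e + sp.diags(dvec)).tocsc()
            self._lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
            diagU = self._lu.U.diagonal()
            self._logdet = float(np.sum(np.log(np.abs(diagU))))
            self._chol = None

    @property
    def logdet(self) -> float:
        return self._logdet

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self._chol is not None:
            return sla.cho_solve((self._chol, True), rhs, check_finite=False)
        if rhs.ndim == 1:
            return self._lu.solve(rhs)
        return np.column_stack([self._lu.solve(rhs[:, j]) for j in range(rhs.shape[1])])

    def inv_diag(self, chunk: int = 1024) -> np.ndarray:
        """diag(C^-1)."""
        if self._chol is not None:
            # diag(C^-1) = squared column norms of L^-1
            Linv = sla.solve_triangular(
                self._chol, np.eye(self.r), lower=True, check_finite=False
            )
            return np.einsum("ij,ij->j", Linv, Linv)
        out = np.empty(self.r)
        for start in range(0, self.r, chunk):
            stop = min(start + chunk, self.r)
            E = np.zeros((self.r, stop - start))
            E[np.arange(start, stop), np.arange(stop - start)] = 1.0
            S = self.solve(E)
            out[start:stop] = S[np.arange(start, stop), np.arange(stop - start)]
        return out

    def fixed_cov(self) -> np.ndarray:
        """(X' V^-1 X)^-1: the leading p x p block of C^-1."""
        E = np.zeros((self.r, self.p))
        E[: self.p, : self.p] = np.eye(self.p)
        return self.solve(E)[: self.p, :]


def _restricted_ll(
    mme: _MME, lam: dict[str, float], lam_e: float, b: np.ndarray
) -> float:
    d = mme.d
    yPy = (mme.yty - float(mme.Wty @ b)) / lam_e
    ql = sum(qf * np.log(lam[f]) for f, qf in mme.q.items())
    return -0.5 * (d.n * np.log(lam_e) + ql + mme.logdet + yPy)


def _start_values(design: Design) -> tuple[dict[str, float], float]:
    """Equal split of the OLS residual variance across all factors."""
    X, y = design.X, design.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tot = float(resid @ resid) / max(len(y) - design.p, 1)
    k = len(design.Z) + 1
    lam = {f: tot / k for f in design.Z}
    return lam, tot / k


def reml_fit(
    dataset: pd.DataFrame,
    spec: ModelSpec | None = None,
    start: dict[str, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    dense_limit: int = 3500,
) -> ModelFit:
    """Fit a crossed variance-component model by AI-REML with EM fallback.

    Convergence requires a relative restricted-log-likelihood change below
    ``tol`` and a relative variance change below 1e-6.  Variances are kept on
    or above a small positive floor (1e-8 of the phenotypic variance);
    estimates at the floor are reported as 0.
    """
    if spec is None:
        spec = ModelSpec()
    spec = spec.resolve(dataset)
    design = build_design(dataset, spec)
    n, p = design.n, design.p
    if n <= p:
        raise EstimabilityError("need more observations than fixed effects")
    mme = _MME(design, dense_limit=dense_limit)

    var_y = float(np.var(design.y)) or 1.0
    floor = 1e-8 * var_y
    if start is None:
        lam, lam_e = _start_values(design)
    else:
        lam = {f: max(float(start[f]), floor) for f in design.Z}
        lam_e = max(float(start.get("residual", var_y / 2)), floor)
    lam = {f: max(v, floor) for f, v in lam.items()}
    factors = list(design.Z)

    def evaluate(lam, lam_e):
        mme.factorize(lam, lam_e)
        b = mme.solve(mme.Wty / lam_e)
        ll = _restricted_ll(mme, lam, lam_e, b)
        return b, ll

    b, ll = evaluate(lam, lam_e)
    converged = False
    notes: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        # gradient pieces at the current factorisation
        cdiag = mme.inv_diag()
        traces = {f: float(cdiag[mme.slices[f]].sum()) for f in factors}
        u = {f: b[mme.slices[f]] for f in factors}
        resid = design.y - mme.W @ b
        sse = float(resid @ resid)

        grad = np.empty(len(factors) + 1)
        trPZZ = {}
        for i, f in enumerate(factors):
            trPZZ[f] = (mme.q[f] - traces[f] / lam[f]) / lam[f]
            grad[i] = -0.5 * (trPZZ[f] - float(u[f] @ u[f]) / lam[f] ** 2)
        trP = (n - p - sum(mme.q[f] - traces[f] / lam[f] for f in factors)) / lam_e
        grad[-1] = -0.5 * (trP - sse / lam_e**2)

        # average-information matrix from working vectors Z_f u_f / lam_f, Py
        cols = [design.Z[f] @ (u[f] / lam[f]) for f in factors]
        cols.append(resid / lam_e)
        Wk = np.column_stack(cols)
        B = mme.solve(mme.W.T @ Wk / lam_e)
        PWk = (Wk - mme.W @ B) / lam_e
        AI = 0.5 * (Wk.T @ PWk)
        AI = (AI + AI.T) / 2

        theta = np.array([lam[f] for f in factors] + [lam_e])
        # active set: variances pinned at the floor with a downhill gradient
        # are held there and excluded from the update (boundary REML maximum)
        active = np.array(
            [not (theta[i] <= 2 * floor and grad[i] < 0) for i in range(len(theta))]
        )
        if not active[-1]:
            active[-1] = True  # never pin the residual
        took_step = False
        ll_new = ll
        ia = np.flatnonzero(active)
        try:
            delta_a = np.linalg.solve(
                AI[np.ix_(ia, ia)] + 1e-12 * np.eye(len(ia)), grad[ia]
            )
            delta = np.zeros(len(theta))
            delta[ia] = delta_a
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None and np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(12):
                cand = np.maximum(theta + step * delta, floor)
                lam_c = dict(zip(factors, cand[:-1]))
                lam_ec = float(cand[-1])
                try:
                    b_c, ll_c = evaluate(lam_c, lam_ec)
                except (sla.LinAlgError, np.linalg.LinAlgError, RuntimeError):
                    step /= 2
                    continue
                if ll_c > ll:
                    lam, lam_e, b, ll_new = lam_c, lam_ec, b_c, ll_c
                    took_step = True
                    break
                step /= 2
        if not took_step:
            # EM step on the active variances: guaranteed uphill
            denom = n - p - sum(mme.q[f] - traces[f] / lam[f] for f in factors)
            lam_c = {
                f: (
                    max((float(u[f] @ u[f]) + traces[f]) / mme.q[f], floor)
                    if active[i]
                    else lam[f]
                )
                for i, f in enumerate(factors)
            }
            lam_ec = max(sse / max(denom, 1e-8), floor)
            b_c, ll_c = evaluate(lam_c, lam_ec)
            if ll_c < ll - 1e-6 * (1 + abs(ll)):
                notes.append(f"iteration {it}: EM step decreased l_R by {ll - ll_c:.3g}")
            lam, lam_e, b, ll_new = lam_c, lam_ec, b_c, ll_c

        theta_new = np.array([lam[f] for f in factors] + [lam_e])
        rel_par = float(
            np.max(np.abs(theta_new - theta)[ia] / (np.abs(theta)[ia] + floor))
        )
        rel_ll = abs(ll_new - ll) / (1 + abs(ll_new))
        ll = ll_new
        if rel_ll < tol and rel_par < 1e-6:
            converged = True
            break
    if not converged:
        notes.append(f"no convergence in {max_iter} iterations")
        warnings.warn("REML did not converge; see fit.notes", RuntimeWarning)

    # final quantities at the converged factorisation
    b = mme.solve(mme.Wty / lam_e)
    cov_fixed = mme.fixed_cov()
    fixed = dict(zip(design.fixed_names, b[:p]))
    fixed_se = dict(zip(design.fixed_names, np.sqrt(np.maximum(np.diag(cov_fixed), 0))))
    blups = {
        f: pd.Series(b[mme.slices[f]], index=design.levels[f])
        for f in factors
    }
    vc = {f: (0.0 if lam[f] <= 2 * floor else float(lam[f])) for f in factors}
    vc["residual"] = float(lam_e)
    return ModelFit(
        spec=spec,
        vc=vc,
        fixed=fixed,
        fixed_se=fixed_se,
        blups=blups,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        n_obs=n,
        notes=notes,
    )


def blup_H(fit: ModelFit, genotype_factor: str = "genotype") -> pd.Series:
    """BLUPs of the genotype deviations from the genetic trend line, indexed
    by genotype id.  All-zero under full shrinkage (genotype variance 0)."""
    if genotype_factor not in fit.blups:
        raise KeyError(f"fit has no {genotype_factor!r} factor")
    s = fit.blups[genotype_factor].copy()
    if isinstance(s.index, pd.MultiIndex):
        s.index = [k[0] for k in s.index]
    return s


def solve_mme(
    design: Design, variances: dict[str, float], resid_var: float
) -> tuple[np.ndarray, dict[str, pd.Series]]:
    """BLUE/BLUP solve at known variances (no estimation).

    Returns the fixed-effect estimates and per-factor BLUP series.  Used by
    the within-cycle selection models, where ranking uses the true simulation
    variances mapped onto the confounded factors.
    """
    mme = _MME(design)
    lam = {f: max(float(variances[f]), 1e-12) for f in design.Z}
    mme.factorize(lam, resid_var)
    b = mme.solve(mme.Wty / resid_var)
    blups = {
        f: pd.Series(b[mme.slices[f]], index=design.levels[f]) for f in design.Z
    }
    return b[: design.p], blups
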