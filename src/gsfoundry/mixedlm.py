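"""Linear mixed models with independent crossed random effects, fit by REML.

This is the numerical core behind the multi-environment trial models

    y = X b + sum_k Z_k u_k + e,     u_k ~ N(0, s2_k I),  e ~ N(0, s2_e I)

used for genetic-value estimation (genotype random -> BLUPs, genotype
fixed -> marginal means via GLS) and for the gene-by-region interaction
model.  The fitting algorithm is EM-REML with average-information (AI)
Newton steps once the expectation-maximization phase has stabilized; the
AI step is guarded by a restricted-likelihood monotonicity check and falls
back to EM whenever it would leave the feasible region or decrease the
restricted likelihood.

All computations run through Henderson's mixed-model equations.  With
C = [[X'X, X'Z], [Z'X, Z'Z + D]], D_k = (s2_e / s2_k) I, the inverse of C
(times s2_e) carries the prediction-error (co)variances of the random
effects and the sampling covariance of the fixed effects, both of which
downstream code consumes (Cullis heritability, Tukey contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = ["RandomTerm", "MixedModelFit", "indicator_matrix", "fit_mixed_model"]

_LOG2PI = np.log(2.0 * np.pi)


def indicator_matrix(labels) -> tuple[sp.csr_matrix, np.ndarray]:
    """0/1 incidence matrix mapping observations to factor levels.

    Returns the (n_obs x n_levels) sparse matrix and the ordered level array.
    """
    codes, levels = pd_factorize(labels)
    n = len(codes)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return Z, levels


def pd_factorize(labels):
    import pandas as pd

    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    if (codes < 0).any():
        raise ValueError("missing factor level in random-term labels")
    return codes, np.asarray(levels)


@dataclass
class RandomTerm:
    """One independent random effect: name, incidence matrix, level labels."""

    name: str
    Z: sp.csr_matrix
    levels: np.ndarray

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class MixedModelFit:
    beta: np.ndarray
    u: dict[str, np.ndarray]
    varcomp: dict[str, float]          # includes "residual"
    loglik_restricted: float
    n_obs: int
    n_fixed: int
    converged: bool
    n_iter: int
    # s2_e * Cinv; leading block = cov(beta_hat), term blocks = PEV(u_k)
    cov_blocks: dict[str, np.ndarray] = field(default_factory=dict)
    beta_cov: np.ndarray | None = None
    term_levels: dict[str, np.ndarray] = field(default_factory=dict)

    def pev(self, term: str) -> np.ndarray:
        """Prediction-error covariance matrix of the BLUPs of ``term``."""
        return self.cov_blocks[term]


def _assemble(X: np.ndarray, terms: list[RandomTerm]):
    Z = sp.hstack([t.Z for t in terms], format="csr")
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = (Z.T @ Z).toarray()
    return Z, XtX, np.asarray(XtZ), ZtZ


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    start: dict[str, float] | None = None,
    max_iter: int = 200,
    n_em_warmup: int = 5,
    rtol_loglik: float = 1e-8,
    rtol_varcomp: float = 1e-6,
) -> MixedModelFit:
    """REML fit of a mixed model with independent crossed random terms.

    Parameters
    ----------
    y
        Response vector, length n.
    X
        Dense fixed-effect design, full column rank (n x p).
    terms
        Random terms; each contributes one variance component.
    start
        Optional starting variance components keyed by term name plus
        ``"residual"``; defaults to an equal split of var(y).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError("more fixed-effect parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effect design")
    K = len(terms)
    if K == 0:
        raise ValueError("at least one random term is required")

    Z, XtX, XtZ, ZtZ = _assemble(X, terms)
    qs = [t.q for t in terms]
    offsets = np.concatenate([[0], np.cumsum(qs)])
    qtot = offsets[-1]
    Xty = X.T @ y
    Zty = np.asarray(Z.T @ y).ravel()
    yty = float(y @ y)
    vary = float(np.var(y))
    if vary == 0.0:
        vary = 1.0
    floor = 1e-10 * vary

    names = [t.name for t in terms]
    if start is None:
        s2 = {nm: vary / (K + 1) for nm in names}
        s2e = vary / (K + 1)
    else:
        s2 = {nm: max(float(start.get(nm, vary / (K + 1))), floor) for nm in names}
        s2e = max(float(start.get("residual", vary / (K + 1))), floor)

    dim = p + qtot
    C = np.empty((dim, dim))
    rhs = np.concatenate([Xty, Zty])

    def build_and_solve(s2_vec, s2e_val):
        """Return (beta, u, Cinv, neg2_loglik, yPy)."""
        C[:p, :p] = XtX
        C[:p, p:] = XtZ
        C[p:, :p] = XtZ.T
        C[p:, p:] = ZtZ
        for k in range(K):
            lo, hi = p + offsets[k], p + offsets[k + 1]
            idx = np.arange(lo, hi)
            C[idx, idx] += s2e_val / s2_vec[k]
        try:
            cf = scipy.linalg.cho_factor(C, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "mixed-model equations are singular"
            ) from exc
        sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = (yty - rhs @ sol) / s2e_val
        # -2 restricted loglik (Searle et al.):
        #   log|R| + log|G| + log|M| + y'Py, M = C / s2e
        neg2 = (
            n * np.log(s2e_val)
            + sum(qs[k] * np.log(s2_vec[k]) for k in range(K))
            + logdetC
            - dim * np.log(s2e_val)
            + yPy
            + (n - p) * _LOG2PI
        )
        # dpotri turns the Cholesky factor into the inverse in ~n^3/3
        Cinv, info = scipy.linalg.lapack.dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed on the MME matrix")
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        return sol, Cinv, neg2, yPy

    s2_vec = np.array([s2[nm] for nm in names])
    sol, Cinv, neg2, _ = build_and_solve(s2_vec, s2e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta = sol[:p]
        u = sol[p:]
        resid = y - X @ beta - Z @ u
        # per-term quantities from the current factorization
        uu = np.empty(K)
        trT = np.empty(K)        # tr of s2e * Cinv block for term k
        for k in range(K):
            lo, hi = p + offsets[k], p + offsets[k + 1]
            uu[k] = sol[lo:hi] @ sol[lo:hi]
            trT[k] = s2e * np.trace(Cinv[lo:hi, lo:hi])
        ee = float(resid @ resid)

        # EM-REML updates
        s2_new = np.maximum((uu + trT) / np.array(qs), floor)
        yey = yty - rhs @ sol
        s2e_new = max(yey / (n - p), floor)

        if it > n_em_warmup:
            stepped = _ai_step(
                y, X, Z, terms, sol, resid, s2_vec, s2e, Cinv, p, offsets,
                qs, uu, trT, ee, rhs, floor,
            )
            if stepped is not None:
                s2_try, s2e_try = stepped
                try:
                    sol_try, Cinv_try, neg2_try, _ = build_and_solve(
                        s2_try, s2e_try
                    )
                except np.linalg.LinAlgError:
                    neg2_try = np.inf
                if neg2_try <= neg2 + 1e-10:
                    s2_new, s2e_new = s2_try, s2e_try
                    sol_new, Cinv_new, neg2_new = sol_try, Cinv_try, neg2_try
                    delta_ll = abs(neg2 - neg2_new)
                    rel = _rel_change(s2_vec, s2e, s2_new, s2e_new, floor)
                    s2_vec, s2e = s2_new, s2e_new
                    sol, Cinv, neg2 = sol_new, Cinv_new, neg2_new
                    if delta_ll < rtol_loglik * (1 + abs(neg2)) and rel < rtol_varcomp:
                        converged = True
                        break
                    continue

        sol_new, Cinv_new, neg2_new, _ = build_and_solve(s2_new, s2e_new)
        delta_ll = abs(neg2 - neg2_new)
        rel = _rel_change(s2_vec, s2e, s2_new, s2e_new, floor)
        s2_vec, s2e = s2_new, s2e_new
        sol, Cinv, neg2 = sol_new, Cinv_new, neg2_new
        if delta_ll < rtol_loglik * (1 + abs(neg2)) and rel < rtol_varcomp:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations; "
            "returning last iterate",
            RuntimeWarning,
        )

    beta = sol[:p]
    u_dict = {}
    cov_blocks = {}
    levels = {}
    for k, t in enumerate(terms):
        lo, hi = p + offsets[k], p + offsets[k + 1]
        u_dict[t.name] = sol[lo:hi].copy()
        cov_blocks[t.name] = s2e * Cinv[lo:hi, lo:hi]
        levels[t.name] = t.levels
    varcomp = {nm: float(s2_vec[k]) for k, nm in enumerate(names)}
    varcomp["residual"] = float(s2e)
    return MixedModelFit(
        beta=beta,
        u=u_dict,
        varcomp=varcomp,
        loglik_restricted=-0.5 * neg2,
        n_obs=n,
        n_fixed=p,
        converged=converged,
        n_iter=it,
        cov_blocks=cov_blocks,
        beta_cov=s2e * Cinv[:p, :p],
        term_levels=levels,
    )


def _rel_change(s2_vec, s2e, s2_new, s2e_new, floor):
    old = np.concatenate([s2_vec, [s2e]])
    new = np.concatenate([s2_new, [s2e_new]])
    return float(np.max(np.abs(new - old) / np.maximum(old, 100 * floor)))


def _ai_step(
    y, X, Z, terms, sol, resid, s2_vec, s2e, Cinv, p, offsets, qs,
    uu, trT, ee, rhs, floor,
):
    """One average-information Newton step on the variance components.

    Returns proposed (s2_vec, s2e) or None when the AI matrix is unusable.
    """
    K = len(terms)
    n = len(y)
    # working vectors f_k = Z_k u_k / s2_k (= Z_k Z_k' P y); f_e = e / s2e = P y
    F = np.empty((n, K + 1))
    for k, t in enumerate(terms):
        lo, hi = p + offsets[k], p + offsets[k + 1]
        F[:, k] = t.Z @ (sol[lo:hi] / s2_vec[k])
    F[:, K] = resid / s2e

    # f' P g = (f'g - rhs(f)' Cinv rhs(g)) / s2e
    XtF = X.T @ F
    ZtF = np.asarray(Z.T @ F)
    RF = np.vstack([XtF, ZtF])
    FPF = (F.T @ F - RF.T @ (Cinv @ RF)) / s2e
    AI = 0.5 * (FPF + FPF.T) / 2.0 + 1e-12 * np.eye(K + 1)
    # AI_ij = f_i' P f_j / 2 -> the /2 above; symmetrize for safety

    # gradient of restricted loglik wrt each variance component
    trPZZ = (np.array(qs) - trT / s2_vec) / s2_vec
    grad = np.empty(K + 1)
    grad[:K] = -0.5 * (trPZZ - uu / s2_vec**2)
    trP = (n - p - np.sum(np.array(qs) - trT / s2_vec)) / s2e
    grad[K] = -0.5 * (trP - ee / s2e**2)

    try:
        step = np.linalg.solve(AI, grad)
    except np.linalg.LinAlgError:
        return None
    theta = np.concatenate([s2_vec, [s2e]])
    new = theta + step
    # damp steps that would go non-positive
    bad = new <= floor
    if bad.any():
        scale = np.min(0.5 * theta[bad] / np.maximum(theta[bad] - new[bad], 1e-300))
        new = theta + min(1.0, scale) * step
        new = np.maximum(new, floor)
    if not np.all(np.isfinite(new)):
        return None
    return new[:-1], float(new[-1])
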