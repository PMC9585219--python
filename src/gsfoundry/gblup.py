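"""GBLUP / ridge-regression BLUP genomic prediction.

Fits the genomic mixed model

    y = X b + Z u + e,   u ~ N(0, s2_u K),   e ~ N(0, s2_e I)

by REML, where y holds one genetic value (EMM or BLUP) per genotyped line
and K is either the VanRaden relationship matrix W W'/c or is implied by
the marker matrix.  The restricted likelihood is reduced, via the
spectral decomposition of K projected onto the fixed-effect complement,
to a one-dimensional function of lambda = s2_e / s2_u which is maximized
by bounded derivative-free search on log lambda.

Two parameterizations are exposed and are algebraically identical (the
test suite verifies this numerically): line genetic values from the
kinship form and marker effects m = (s2_u / c) W' V^-1 (y - X b), with
GEBV = b0 + W_new m for untested lines.  Predictions are anchored at the
fitted intercept so GEBVs live on the trait scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar

from gsfoundry.genotype import MarkerMatrix, RelationshipMatrix

__all__ = ["GBLUPFit", "fit_gblup", "predict_gebv", "rank_select"]


@dataclass
class GBLUPFit:
    beta: np.ndarray                  # intercept (trait units)
    var_u: float
    var_e: float
    lam: float                        # var_e / var_u
    u_hat: pd.Series                  # line genetic-value deviations
    loglik_restricted: float
    train_ids: np.ndarray
    marker_effects: pd.Series | None = None
    train_allele_means: pd.Series | None = None    # per-marker mean code
    alpha: np.ndarray | None = field(default=None, repr=False)  # V^-1 (y - Xb)
    degenerate: bool = False
    # centered training codes and VanRaden scale, for kinship-form prediction
    train_W: np.ndarray | None = field(default=None, repr=False)
    scale_c: float | None = None

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    def fitted(self) -> pd.Series:
        """GEBVs of the training lines, intercept-anchored."""
        return self.u_hat + self.mu


def _reml_lambda(y, X, K, bracket=(-10.0, 10.0), tol=1e-8):
    """Profile REML of the single-kinship model over log lambda."""
    n, p = X.shape
    # orthonormal basis of the complement of col(X)
    Q = scipy.linalg.null_space(X.T)
    yt = Q.T @ y
    Kt = Q.T @ K @ Q
    theta, U = scipy.linalg.eigh(Kt)
    theta = np.clip(theta, 0.0, None)
    z2 = (U.T @ yt) ** 2
    m = n - p

    def neg2_profile(loglam):
        # -2 l_R up to a constant: V = s2u (K~ + lam I) in the projected
        # space, log|V| = m log s2u + sum log d, and y'V^-1 y = m at the
        # profiled s2u = sum(z^2/d)/m.
        lam = np.exp(loglam)
        d = theta + lam
        s2u = float(np.sum(z2 / d)) / m
        if s2u <= 0:
            return np.inf
        return m * np.log(s2u) + float(np.sum(np.log(d)))

    res = minimize_scalar(neg2_profile, bounds=bracket, method="bounded",
                          options={"xatol": tol})
    loglam = float(res.x)
    lam = float(np.exp(loglam))
    d = theta + lam
    s2u = float(np.sum(z2 / d)) / m
    s2e = lam * s2u
    neg2 = m * np.log(s2u) + float(np.sum(np.log(d))) \
        + m + m * np.log(2 * np.pi)
    return lam, s2u, s2e, -0.5 * neg2, neg2_profile


def fit_gblup(
    y,
    geno: MarkerMatrix | None = None,
    K: RelationshipMatrix | None = None,
    min_lines_warn: int = 30,
) -> GBLUPFit:
    """REML fit of the genomic mixed model with an intercept.

    ``y`` is a pandas Series indexed by line id (or a DataFrame with
    ``line_id`` plus one value column).  Provide markers (``geno``) for
    the ridge / marker-effect parameterization — required to predict
    untested lines — or a precomputed relationship matrix ``K``.
    """
    y = _as_series(y)
    if geno is None and K is None:
        raise ValueError("provide geno or K")
    if geno is not None:
        if np.isnan(geno.codes).any():
            raise ValueError("impute genotype codes before GBLUP")
        pos = pd.Series(np.arange(geno.n_lines), index=geno.line_ids)
        ids = [i for i in y.index if i in pos.index]
    else:
        pos = pd.Series(np.arange(len(K.line_ids)), index=K.line_ids)
        ids = [i for i in y.index if i in pos.index]
    if len(ids) < 2:
        raise ValueError("fewer than 2 phenotyped lines with genotype data")
    if len(ids) < min_lines_warn:
        warnings.warn(
            f"only {len(ids)} training lines; genomic prediction will be "
            "unstable", UserWarning,
        )
    yv = y.reindex(ids).to_numpy(dtype=float)
    idx = pos.reindex(ids).to_numpy(dtype=int)

    marker_effects = None
    train_means = None
    if geno is not None:
        codes = geno.codes[idx]
        pbar = codes.mean(axis=0) / 2.0
        W = codes - 2.0 * pbar
        c = float(np.sum(2.0 * pbar * (1.0 - pbar)))
        if c <= 0:
            raise ValueError("all markers monomorphic in the training set")
        Kmat = (W @ W.T) / c
        train_means = pd.Series(2.0 * pbar, index=geno.marker_ids)
    else:
        Kmat = K.values[np.ix_(idx, idx)]
        ev_min = scipy.linalg.eigvalsh(Kmat, subset_by_index=[0, 0])[0]
        if ev_min < -1e-6 * max(1.0, abs(Kmat).max()):
            raise ValueError("relationship matrix is not positive semidefinite")
    Kmat = 0.5 * (Kmat + Kmat.T)

    n = len(ids)
    X = np.ones((n, 1))
    if np.allclose(yv, yv[0]):
        warnings.warn("constant response: var_u = 0 degenerate fit",
                      UserWarning)
        return GBLUPFit(
            beta=np.array([yv[0]]), var_u=0.0, var_e=0.0, lam=np.inf,
            u_hat=pd.Series(np.zeros(n), index=ids),
            loglik_restricted=np.nan, train_ids=np.array(ids),
            marker_effects=(pd.Series(np.zeros(geno.n_markers),
                                      index=geno.marker_ids)
                            if geno is not None else None),
            train_allele_means=train_means, degenerate=True,
        )

    lam, s2u, s2e, ll, _ = _reml_lambda(yv, X, Kmat)
    Vi = np.linalg.inv(s2u * Kmat + s2e * np.eye(n))
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ yv)
    alpha = Vi @ (yv - X @ beta)
    u_hat = s2u * (Kmat @ alpha)
    train_W, scale_c = None, None
    if geno is not None:
        m_hat = (s2u / c) * (W.T @ alpha)
        marker_effects = pd.Series(m_hat, index=geno.marker_ids)
        train_W, scale_c = W, c
    return GBLUPFit(
        beta=beta, var_u=s2u, var_e=s2e, lam=lam,
        u_hat=pd.Series(u_hat, index=ids),
        loglik_restricted=ll, train_ids=np.array(ids),
        marker_effects=marker_effects, train_allele_means=train_means,
        alpha=alpha, train_W=train_W, scale_c=c if geno is not None else None,
    )


def predict_gebv(
    fit: GBLUPFit,
    geno_new: MarkerMatrix,
    method: str = "marker",
) -> pd.DataFrame:
    """Predict intercept-anchored GEBVs for (possibly untested) lines.

    Markers are intersected by id with the training panel (error when
    under half the panel remains); new-line codes are centered at the
    training allele means, so predictions are invariant to allele-coding
    flips.  ``method="marker"`` uses the marker-effect back-solution,
    ``method="kinship"`` the cross-relationship block; the two agree to
    numerical precision.
    """
    if fit.marker_effects is None:
        raise ValueError("fit has no marker effects; refit with geno=")
    panel = fit.marker_effects.index
    common = panel.intersection(pd.Index(geno_new.marker_ids))
    if len(common) < 0.5 * len(panel):
        raise ValueError(
            f"only {len(common)}/{len(panel)} training markers present in "
            "the new genotypes; marker panels are incompatible"
        )
    col = pd.Series(np.arange(geno_new.n_markers), index=geno_new.marker_ids)
    codes = geno_new.codes[:, col.reindex(common).to_numpy(dtype=int)]
    means = fit.train_allele_means.reindex(common).to_numpy()
    codes = np.where(np.isnan(codes), means, codes)
    Wn = codes - means
    if method == "marker":
        g = Wn @ fit.marker_effects.reindex(common).to_numpy()
    elif method == "kinship":
        if fit.alpha is None or fit.train_W is None:
            raise ValueError("fit cannot predict via kinship (degenerate "
                             "or markerless fit)")
        keep = pd.Index(panel).get_indexer(common)
        K_cross = (Wn @ fit.train_W[:, keep].T) / fit.scale_c
        g = fit.var_u * (K_cross @ fit.alpha)
    else:
        raise ValueError(f"unknown prediction method {method!r}")
    trained = pd.Index(geno_new.line_ids).isin(fit.train_ids)
    return pd.DataFrame({
        "line_id": geno_new.line_ids,
        "gebv": g + fit.mu,
        "trained": trained,
    })


def rank_select(
    gebvs: pd.DataFrame,
    n_top: int,
    n_bottom: int,
    value_col: str = "gebv",
    companion: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Top and bottom selections by GEBV, ties broken by line id.

    ``companion`` (indexed by line id) is joined onto the selections so
    correlated traits of the chosen lines travel with them.
    """
    if n_top + n_bottom > len(gebvs):
        raise ValueError("n_top + n_bottom exceeds the number of lines")
    d = gebvs.copy()
    if d[value_col].nunique() == 1 and len(d) > 1:
        warnings.warn("all GEBVs equal; selection falls back to id order",
                      UserWarning)
    d = d.sort_values([value_col, "line_id"],
                      ascending=[False, True], kind="stable")
    top = d.head(n_top).reset_index(drop=True)
    bottom = d.sort_values([value_col, "line_id"],
                           ascending=[True, True], kind="stable") \
        .head(n_bottom).reset_index(drop=True)
    if companion is not None:
        top = top.join(companion, on="line_id")
        bottom = bottom.join(companion, on="line_id")
    return {"top": top, "bottom": bottom}


def _as_series(y) -> pd.Series:
    if isinstance(y, pd.Series):
        return y.dropna()
    if isinstance(y, pd.DataFrame):
        if "line_id" not in y.columns:
            raise ValueError("DataFrame y needs a line_id column")
        value_cols = [c for c in y.columns if c != "line_id"
                      and np.issubdtype(y[c].dtype, np.number)]
        if not value_cols:
            raise ValueError("no numeric value column in y")
        return y.set_index("line_id")[value_cols[0]].dropna()
    raise TypeError("y must be a Series (line_id index) or DataFrame")
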