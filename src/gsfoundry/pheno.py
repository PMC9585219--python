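"""Multi-environment trial models: REML genetic values and Cullis heritability.

Fits the standard unbalanced multi-environment model

    Y_ijk = mu + G_i + E_j + R_k(j) + GE_ij + e_ijk

with environment defined as a location-year combination.  Two fits are
offered, mirroring how plant-breeding analyses extract genetic values:

* genotype random -> variance components and BLUPs (shrunken line values),
  from which broad-sense heritability on an entry-mean basis is computed
  by the Cullis method, H2 = 1 - mean pairwise BLUP-difference
  prediction-error variance / (2 sigma2_G);
* genotype fixed -> estimated marginal means (EMMs) by generalized least
  squares at REML estimates of the remaining components.

Terms degenerate gracefully: with a single environment the model reduces
to the one-way genotype model (no E, GE or R terms), which is what the
closed-form ANOVA oracles in the test suite exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gsfoundry.mixedlm import MixedModelFit, RandomTerm, fit_mixed_model, indicator_matrix

__all__ = [
    "VarianceComponents",
    "RandomGenotypeFit",
    "FixedGenotypeFit",
    "fit_random_genotype",
    "fit_fixed_genotype",
    "cullis_h2",
    "subset_trials",
]

REQUIRED_COLUMNS = ("line_id", "location", "year", "rep", "trait", "value")


@dataclass
class VarianceComponents:
    var_G: float
    var_E: float
    var_R: float
    var_GE: float
    var_eps: float
    loglik_restricted: float
    n_obs: int
    n_lines: int
    n_envs: int
    converged: bool

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RandomGenotypeFit:
    """BLUP fit: variance components, per-line values, and the MME solution."""

    varcomp: VarianceComponents
    values: pd.DataFrame      # line_id, blup (deviation), blup_plus_mu, n_obs
    mu: float
    mme: MixedModelFit

    @property
    def blups(self) -> pd.Series:
        return self.values.set_index("line_id")["blup"]


@dataclass
class FixedGenotypeFit:
    """GLS marginal means with their sampling covariance."""

    values: pd.DataFrame      # line_id, emm, se, n_obs, large_se_flag
    mu: float
    varcomp: dict[str, float]
    emm_cov: np.ndarray
    mme: MixedModelFit

    @property
    def emms(self) -> pd.Series:
        return self.values.set_index("line_id")["emm"]


def _prepare(t: pd.DataFrame, trait: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"trial table lacks column(s) {missing}")
    d = t[t["trait"] == trait].copy()
    if d.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if not np.isfinite(d["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite trait values present")
    d["env"] = d["location"].astype(str) + "_" + d["year"].astype(str)
    dup = d.duplicated(["line_id", "env", "rep"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (line, environment, rep) record(s)"
        )
    return d


def _check_connectivity(d: pd.DataFrame) -> None:
    """Warn when the line-environment incidence graph is disconnected."""
    lines = pd.factorize(d["line_id"])[0]
    envs = pd.factorize(d["env"])[0]
    n_l, n_e = lines.max() + 1, envs.max() + 1
    parent = np.arange(n_l + n_e)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for li, ej in zip(lines, envs):
        ra, rb = find(li), find(n_l + ej)
        if ra != rb:
            parent[rb] = ra
    roots = {find(i) for i in range(n_l + n_e)}
    if len(roots) > 1:
        warnings.warn(
            f"design is disconnected ({len(roots)} components); genetic "
            "values are only comparable within components",
            UserWarning,
        )


def _random_terms(d: pd.DataFrame, include_genotype: bool) -> list[RandomTerm]:
    n_envs = d["env"].nunique()
    terms = []
    if include_genotype:
        Zg, lg = indicator_matrix(d["line_id"].to_numpy())
        terms.append(RandomTerm("G", Zg, lg))
    if n_envs >= 2:
        Ze, le = indicator_matrix(d["env"].to_numpy())
        terms.append(RandomTerm("E", Ze, le))
        rep_labels = d["env"].astype(str) + ":" + d["rep"].astype(str)
        if d.groupby("env")["rep"].nunique().max() > 1:
            Zr, lr = indicator_matrix(rep_labels.to_numpy())
            terms.append(RandomTerm("R", Zr, lr))
        ge_labels = d["line_id"].astype(str) + ":" + d["env"].astype(str)
        # GE is only identifiable when some lines are replicated within envs
        if len(d) > ge_labels.nunique():
            Zge, lge = indicator_matrix(ge_labels.to_numpy())
            terms.append(RandomTerm("GE", Zge, lge))
    return terms


def fit_random_genotype(
    t: pd.DataFrame,
    trait: str,
    **reml_kwargs,
) -> RandomGenotypeFit:
    """Fit the trial model with genotype random; return BLUPs and components.

    Environment, replicate-within-environment and genotype-by-environment
    terms enter when the design supports them (>= 2 environments; GE needs
    within-environment replication); absent terms report variance 0.
    """
    d = _prepare(t, trait)
    if d["line_id"].nunique() < 2:
        raise ValueError("need >= 2 lines")
    _check_connectivity(d)
    y = d["value"].to_numpy(dtype=float)
    X = np.ones((len(d), 1))
    terms = _random_terms(d, include_genotype=True)
    fit = fit_mixed_model(y, X, terms, **reml_kwargs)

    vc = {t_.name: fit.varcomp[t_.name] for t_ in terms}
    varcomp = VarianceComponents(
        var_G=vc.get("G", 0.0),
        var_E=vc.get("E", 0.0),
        var_R=vc.get("R", 0.0),
        var_GE=vc.get("GE", 0.0),
        var_eps=fit.varcomp["residual"],
        loglik_restricted=fit.loglik_restricted,
        n_obs=fit.n_obs,
        n_lines=int(d["line_id"].nunique()),
        n_envs=int(d["env"].nunique()),
        converged=fit.converged,
    )
    mu = float(fit.beta[0])
    blup = pd.Series(fit.u["G"], index=fit.term_levels["G"])
    n_obs = d.groupby("line_id").size()
    values = pd.DataFrame({
        "line_id": blup.index,
        "blup": blup.to_numpy(),
        "blup_plus_mu": blup.to_numpy() + mu,
        "n_obs": n_obs.reindex(blup.index).to_numpy(),
    }).reset_index(drop=True)
    return RandomGenotypeFit(varcomp=varcomp, values=values, mu=mu, mme=fit)


def fit_fixed_genotype(
    t: pd.DataFrame,
    trait: str,
    **reml_kwargs,
) -> FixedGenotypeFit:
    """Fit the trial model with genotype fixed; return GLS marginal means.

    A cell-means parameterization is used, so EMM_i is the genotype-i
    fixed coefficient with all random effects at their zero expectation.
    Lines observed in a single environment-replicate are flagged
    ``large_se_flag`` (their EMM rests on one plot).
    """
    d = _prepare(t, trait)
    _check_connectivity(d)
    y = d["value"].to_numpy(dtype=float)
    codes, line_levels = pd.factorize(d["line_id"].to_numpy(), sort=True)
    X = np.zeros((len(d), len(line_levels)))
    X[np.arange(len(d)), codes] = 1.0
    terms = _random_terms(d, include_genotype=False)
    if not terms:
        # single environment, single rep: plain OLS cell means
        fit = None
        emm = np.array([y[codes == i].mean() for i in range(len(line_levels))])
        resid = y - emm[codes]
        dfree = max(len(d) - len(line_levels), 1)
        s2 = float(resid @ resid) / dfree
        counts = np.bincount(codes, minlength=len(line_levels))
        cov = np.diag(s2 / counts)
        varcomp = {"residual": s2}
        mme = None
    else:
        mme = fit_mixed_model(y, X, terms, **reml_kwargs)
        emm = mme.beta
        cov = mme.beta_cov
        varcomp = dict(mme.varcomp)
    n_obs = d.groupby("line_id").size().reindex(line_levels)
    env_count = d.groupby("line_id")["env"].nunique().reindex(line_levels)
    flag = (n_obs.to_numpy() == 1) & (env_count.to_numpy() == 1)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    values = pd.DataFrame({
        "line_id": line_levels,
        "emm": emm,
        "se": se,
        "n_obs": n_obs.to_numpy(),
        "large_se_flag": flag,
    })
    return FixedGenotypeFit(
        values=values,
        mu=float(np.mean(emm)),
        varcomp=varcomp,
        emm_cov=cov,
        mme=mme,
    )


def cullis_h2(fit: RandomGenotypeFit) -> float:
    """Cullis broad-sense heritability for unbalanced trials.

    H2 = 1 - Vbar_Delta / (2 sigma2_G), with Vbar_Delta the mean over line
    pairs of the prediction-error variance of BLUP differences, computed
    exactly from the genotype block of the inverted mixed-model-equation
    coefficient matrix:

        mean_{i != j} (T_ii + T_jj - 2 T_ij)
            = 2 (g * tr(T) - 1'T1) / (g (g - 1)).
    """
    s2g = fit.varcomp.var_G
    if s2g <= 0:
        warnings.warn("var_G = 0: heritability degenerate, returning 0",
                      UserWarning)
        return 0.0
    T = fit.mme.pev("G")
    g = T.shape[0]
    if g < 2:
        raise ValueError("need >= 2 lines for heritability")
    vbar = 2.0 * (g * np.trace(T) - float(T.sum())) / (g * (g - 1))
    h2 = 1.0 - vbar / (2.0 * s2g)
    if h2 < 0 or h2 > 1:
        warnings.warn(f"Cullis H2 = {h2:.3f} outside [0, 1]; clipping",
                      UserWarning)
    return float(np.clip(h2, 0.0, 1.0))


def subset_trials(
    t: pd.DataFrame,
    env_group: list[str],
    min_obs: int = 30,
) -> pd.DataFrame:
    """Restrict a trial table to a group of environments (or locations).

    ``env_group`` entries may be environment labels (``location_year``) or
    bare location names, in which case all years at that location are
    taken.  Groups supplying fewer than ``min_obs`` records are rejected:
    genetic values estimated from a handful of plots are not worth
    carrying forward.
    """
    if not env_group:
        raise ValueError("empty environment group")
    d = t.copy()
    env = d["location"].astype(str) + "_" + d["year"].astype(str)
    group = set(map(str, env_group))
    mask = env.isin(group) | d["location"].astype(str).isin(group)
    out = d[mask]
    if out.empty:
        raise ValueError(f"no records match environment group {sorted(group)}")
    if len(out) < min_obs:
        raise ValueError(
            f"group {sorted(group)} has only {len(out)} observations "
            f"(minimum {min_obs}); too few for genetic-value estimation"
        )
    return out.reset_index(drop=True)
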