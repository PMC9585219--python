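"""Clustering trial environments by similarity of line performance.

A line x environment table of replicate means feeds two complementary
views of environment relatedness:

* a GGE decomposition — SVD of the environment-centered two-way table —
  whose environment loadings (right singular vectors scaled by singular
  values) approximate environment correlations through vector cosines;
* PCA of the pairwise-complete Pearson correlation matrix of environment
  columns.

Environments are then grouped by average-linkage hierarchical clustering
on the distance 1 - r.  This replaces the visual biplot inspection a
breeder would do with an explicit, reproducible rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

__all__ = [
    "TwoWayTable",
    "GGEResult",
    "CorrelationPCA",
    "EnvClustering",
    "build_two_way",
    "gge_decompose",
    "correlation_pca",
    "cluster_environments",
]


@dataclass
class TwoWayTable:
    """Line x environment replicate-mean table with missingness mask."""

    values: pd.DataFrame        # lines x environments, NaN = unobserved

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_masked(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class GGEResult:
    env_loadings: pd.DataFrame      # environments x axes, scaled by singular values
    line_scores: pd.DataFrame
    explained_fraction: np.ndarray

    def env_correlations(self) -> pd.DataFrame:
        """Cosine similarities between environment vectors (all axes)."""
        L = self.env_loadings.to_numpy()
        norms = np.linalg.norm(L, axis=1)
        norms[norms == 0] = 1.0
        C = (L @ L.T) / np.outer(norms, norms)
        return pd.DataFrame(C, index=self.env_loadings.index,
                            columns=self.env_loadings.index)


@dataclass
class CorrelationPCA:
    correlations: pd.DataFrame
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    no_structure: bool = False


@dataclass
class EnvClustering:
    labels: pd.Series                  # environment -> group id (1-based)
    groups: dict[int, list[str]]
    linkage: np.ndarray
    cut_height: float
    note: str = ""


def build_two_way(
    t: pd.DataFrame,
    trait: str,
    min_lines_per_env: int = 3,
) -> TwoWayTable:
    """Average replicates into a line x environment mean table."""
    d = t[t["trait"] == trait].copy()
    if d.empty:
        raise ValueError(f"no records for trait {trait!r}")
    d["env"] = d["location"].astype(str) + "_" + d["year"].astype(str)
    if d["env"].nunique() < 2:
        raise ValueError("need >= 2 environments")
    w = d.pivot_table(index="line_id", columns="env", values="value",
                      aggfunc="mean")
    n_lines = w.notna().sum(axis=0)
    drop = n_lines[n_lines < min_lines_per_env].index
    if len(drop):
        warnings.warn(
            f"dropping {len(drop)} environment(s) with < "
            f"{min_lines_per_env} lines: {sorted(drop)}",
            UserWarning,
        )
        w = w.drop(columns=drop)
    if w.shape[1] < 2:
        raise ValueError("fewer than 2 environments after minimum-line filter")
    return TwoWayTable(values=w)


def _svd_impute(M: np.ndarray, rank: int = 2, max_iter: int = 50,
                tol: float = 1e-6) -> np.ndarray:
    """Iterative low-rank imputation of masked cells.

    Missing cells start at their environment (column) mean and are
    refreshed from a rank-``rank`` SVD reconstruction until the filled
    values stabilize.
    """
    mask = np.isnan(M)
    if not mask.any():
        return M.copy()
    X = M.copy()
    col_means = np.nanmean(M, axis=0)
    col_means = np.where(np.isnan(col_means), np.nanmean(M), col_means)
    X[mask] = np.take(col_means, np.nonzero(mask)[1])
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        r = min(rank, len(s))
        recon = (U[:, :r] * s[:r]) @ Vt[:r]
        delta = np.max(np.abs(X[mask] - recon[mask])) if mask.any() else 0.0
        X[mask] = recon[mask]
        scale = max(np.nanstd(M), 1e-12)
        if delta < tol * scale:
            break
    return X


def gge_decompose(w: TwoWayTable, impute_rank: int = 2) -> GGEResult:
    """Genotype + genotype-by-environment SVD of the two-way table.

    The table is environment-centered (column means removed), so the
    decomposition carries G and GE signal only; environment loadings are
    right singular vectors scaled by singular values.
    """
    M = _svd_impute(w.values.to_numpy(dtype=float), rank=impute_rank)
    M = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("two-way table is constant after centering")
    frac = s**2 / total
    eff_rank = int(np.sum(s > s[0] * 1e-9))
    if eff_rank < 2:
        warnings.warn(
            "environment-centered table has rank < 2: all environment "
            "vectors are collinear (single-cluster structure)",
            UserWarning,
        )
    axes = [f"axis{i + 1}" for i in range(len(s))]
    return GGEResult(
        env_loadings=pd.DataFrame((Vt.T * s), index=w.values.columns,
                                  columns=axes),
        line_scores=pd.DataFrame(U, index=w.values.index, columns=axes),
        explained_fraction=frac,
    )


def correlation_pca(
    w: TwoWayTable,
    min_overlap: int = 3,
) -> CorrelationPCA:
    """PCA of the pairwise-complete Pearson correlations of environments."""
    vals = w.values
    C = vals.corr(min_periods=min_overlap)
    if C.isna().any().any():
        n_bad = int(C.isna().to_numpy().sum() - np.isnan(np.diag(C)).sum())
        warnings.warn(
            f"{n_bad // 2} environment pair(s) share < {min_overlap} lines; "
            "their correlation is imputed to 0",
            UserWarning,
        )
        C = C.fillna(0.0)
        np.fill_diagonal(C.values, 1.0)
    evals, evecs = np.linalg.eigh(C.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    no_structure = bool(np.allclose(evals, evals[0]))
    if no_structure:
        warnings.warn(
            "correlation matrix has no structure (all eigenvalues equal); "
            "PC rotation is arbitrary",
            UserWarning,
        )
    scores = evecs * np.sqrt(np.clip(evals, 0, None))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return CorrelationPCA(
        correlations=C,
        scores=pd.DataFrame(scores, index=C.index, columns=cols),
        eigenvalues=evals,
        no_structure=no_structure,
    )


def cluster_environments(
    similarity,
    n_groups: int | None = None,
    height: float | None = None,
) -> EnvClustering:
    """Average-linkage clustering of environments on distance 1 - r.

    ``similarity`` is either a square environment correlation matrix
    (DataFrame) or a :class:`GGEResult`, whose environment-vector cosines
    are used.  Cut the dendrogram to ``n_groups`` clusters or at
    ``height``; exactly one of the two must be given.
    """
    if isinstance(similarity, GGEResult):
        R = similarity.env_correlations()
    else:
        R = similarity
    envs = list(R.index)
    n = len(envs)
    if (n_groups is None) == (height is None):
        raise ValueError("give exactly one of n_groups or height")
    if n_groups is not None and n_groups > n:
        raise ValueError(f"requested {n_groups} groups for {n} environments")
    D = 1.0 - R.to_numpy()
    D = np.clip(0.5 * (D + D.T), 0.0, None)
    np.fill_diagonal(D, 0.0)
    # condensed form, stable ordering
    iu = np.triu_indices(n, k=1)
    Z = sch.linkage(D[iu], method="average")
    if n_groups is not None:
        flat = sch.fcluster(Z, t=n_groups, criterion="maxclust")
        cut = float(Z[-(n_groups - 1), 2]) if n_groups > 1 else float("inf")
    else:
        flat = sch.fcluster(Z, t=height, criterion="distance")
        cut = float(height)
    # renumber groups deterministically by first environment appearance
    remap, labels = {}, []
    for f in flat:
        if f not in remap:
            remap[f] = len(remap) + 1
        labels.append(remap[f])
    labels = pd.Series(labels, index=envs, name="group")
    groups = {g: sorted(labels.index[labels == g]) for g in sorted(set(labels))}
    return EnvClustering(labels=labels, groups=groups, linkage=Z,
                         cut_height=cut)
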