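"""Predictive-ability assessment: five-fold CV, external validation, quadrants.

Accuracy is the Pearson correlation between observed genetic values
(EMMs or BLUPs) and GEBVs, matching common usage in applied genomic
selection; Spearman rank correlation is carried as a secondary column.
The four-quadrant summary splits the observed/predicted plane at the two
means: quadrants A (both high) and B (both low) are correct
classifications, C (predicted high, observed low) and D (the reverse)
are errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gsfoundry.genotype import MarkerMatrix
from gsfoundry.gblup import fit_gblup, predict_gebv, _as_series

__all__ = [
    "CVResult",
    "QuadrantSummary",
    "five_fold_cv",
    "external_validate",
    "accuracy_matrix",
]


@dataclass
class CVResult:
    fold_assignments: pd.Series      # line_id -> fold (0-based)
    fold_accuracies: list[float]
    mean_accuracy: float
    mean_rank_accuracy: float
    trait: str | None
    value_type: str | None
    seed: int
    n_repeats: int


@dataclass
class QuadrantSummary:
    quadrants: pd.Series              # line_id -> A/B/C/D
    percentages: dict[str, float]
    pct_correct: float                # A + B


def _folds(ids: np.ndarray, n_folds: int, rng) -> list[np.ndarray]:
    perm = rng.permutation(len(ids))
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def five_fold_cv(
    tp_pheno,
    tp_geno: MarkerMatrix,
    trait: str | None = None,
    seed: int = 0,
    n_folds: int = 5,
    n_repeats: int = 1,
    value_type: str | None = None,
) -> CVResult:
    """K-fold cross-validated prediction accuracy of GBLUP on a TP.

    Lines are shuffled into ``n_folds`` groups of near-equal size
    (differing by at most one); each fold is masked in turn, GBLUP is
    refit on the rest and the masked lines' observed values are
    correlated with their GEBVs.  The reported accuracy averages the
    fold correlations, optionally over ``n_repeats`` reshuffles.
    """
    y = _as_series(tp_pheno)
    # sorted so fold membership depends on the line set, not input order
    common = sorted(i for i in y.index if i in set(tp_geno.line_ids))
    if len(common) < 2 * n_folds:
        raise ValueError(
            f"TP of {len(common)} genotyped lines is too small for "
            f"{n_folds}-fold CV"
        )
    y = y.reindex(common)
    ids = np.array(common)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))

    all_acc, all_rank = [], []
    assign = pd.Series(index=ids, dtype=int)
    for rep in range(n_repeats):
        folds = _folds(ids, n_folds, rng)
        if rep == 0:
            for f, members in enumerate(folds):
                assign.loc[ids[members]] = f
        for members in folds:
            mask_ids = ids[members]
            train_ids = np.setdiff1d(ids, mask_ids)
            fit = fit_gblup(y.reindex(train_ids), geno=tp_geno,
                            min_lines_warn=0)
            pred = predict_gebv(fit, tp_geno).set_index("line_id")["gebv"]
            obs = y.reindex(mask_ids).to_numpy()
            est = pred.reindex(mask_ids).to_numpy()
            if np.std(obs) == 0 or np.std(est) == 0:
                warnings.warn("zero-variance fold excluded from accuracy",
                              UserWarning)
                continue
            all_acc.append(float(np.corrcoef(obs, est)[0, 1]))
            all_rank.append(float(stats.spearmanr(obs, est).statistic))
    if not all_acc:
        raise ValueError("no fold produced a defined correlation")
    return CVResult(
        fold_assignments=assign,
        fold_accuracies=all_acc,
        mean_accuracy=float(np.mean(all_acc)),
        mean_rank_accuracy=float(np.mean(all_rank)),
        trait=trait,
        value_type=value_type,
        seed=seed,
        n_repeats=n_repeats,
    )


def quadrant_classify(observed: pd.Series, predicted: pd.Series) -> QuadrantSummary:
    """Mean-split four-quadrant classification of observed vs predicted."""
    obs, pred = observed.align(predicted, join="inner")
    ox = obs.to_numpy() - obs.mean()
    px = pred.to_numpy() - pred.mean()
    quad = np.where((ox >= 0) & (px >= 0), "A",
                    np.where((ox < 0) & (px < 0), "B",
                             np.where((ox < 0) & (px >= 0), "C", "D")))
    s = pd.Series(quad, index=obs.index, name="quadrant")
    pct = {q: 100.0 * float((s == q).mean()) for q in "ABCD"}
    return QuadrantSummary(
        quadrants=s,
        percentages=pct,
        pct_correct=pct["A"] + pct["B"],
    )


def external_validate(
    gebvs,
    observed,
    min_overlap: int = 5,
) -> tuple[float, QuadrantSummary]:
    """Accuracy of GEBVs against independently observed genetic values.

    Both inputs are Series indexed by line id (or DataFrames with a
    ``line_id`` column); the Pearson r over the intersection and the
    quadrant summary are returned.
    """
    pred = _coerce(gebvs, "gebv")
    obs = _coerce(observed, "emm")
    obs, pred = obs.align(pred, join="inner")
    if len(obs) < min_overlap:
        raise ValueError(
            f"only {len(obs)} lines shared between predictions and "
            f"observations (minimum {min_overlap})"
        )
    r = float(np.corrcoef(obs.to_numpy(), pred.to_numpy())[0, 1])
    return r, quadrant_classify(obs, pred)


def _coerce(x, prefer: str) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.dropna()
    if isinstance(x, pd.DataFrame):
        d = x.set_index("line_id") if "line_id" in x.columns else x
        if prefer in d.columns:
            return d[prefer].dropna()
        num = [c for c in d.columns if np.issubdtype(d[c].dtype, np.number)]
        if not num:
            raise ValueError("no numeric column found")
        return d[num[0]].dropna()
    raise TypeError("expected Series or DataFrame")


def accuracy_matrix(
    tp_values: dict[str, pd.DataFrame],
    geno: MarkerMatrix,
    seed: int = 0,
    value_types: tuple[str, ...] = ("emm", "blup"),
    trait: str | None = None,
    n_folds: int = 5,
) -> pd.DataFrame:
    """Five-fold CV accuracy for several TPs and observed-value types.

    ``tp_values`` maps a TP name to a DataFrame with ``line_id`` plus one
    column per value type (``emm``, ``blup``).  Returns a tidy table with
    one row per TP, one column per value type, and a final ``Average``
    row; combinations whose value column is absent stay empty (NaN).
    """
    rows = {}
    for tp_name, df in tp_values.items():
        row = {}
        for vt in value_types:
            if vt not in df.columns:
                warnings.warn(f"{tp_name}: no {vt!r} column; cell left empty",
                              UserWarning)
                row[vt] = np.nan
                continue
            series = df.set_index("line_id")[vt]
            cv = five_fold_cv(series, geno, trait=trait, seed=seed,
                              n_folds=n_folds, value_type=vt)
            row[vt] = cv.mean_accuracy
        rows[tp_name] = row
    out = pd.DataFrame(rows).T
    out.loc["Average"] = out.mean(axis=0)
    return out
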