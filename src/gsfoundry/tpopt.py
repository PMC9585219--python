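"""Training-population optimization by mean prediction-error variance.

Given genotype principal-component scores for a candidate pool and a
target (prediction) set, the criterion scored for a candidate subset T is

    PEVmean(T) = mean diag( X_P (X_T' X_T + eps I)^-1 X_P' )

where X_T / X_P are the PC scores of the training / target lines with an
intercept column and eps is a small trace-scaled ridge for conditioning.
Smaller is better: it is the average variance of the target lines' fitted
values under the PC regression the training set supports.

The search is a genetic algorithm over fixed-size subsets (elitism,
tournament selection, uniform subset crossover, member-swap mutation)
with several independent replications; an exhaustive enumerator is
provided as an oracle for small instances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from gsfoundry.genotype import GenotypePCs

__all__ = [
    "TPSearchConfig",
    "TrainingSet",
    "pev_mean",
    "ga_select",
    "exhaustive_select",
    "summarize_tp_composition",
]


@dataclass
class TPSearchConfig:
    tp_size: int = 400
    n_elite: int = 10
    ga_population: int = 100
    n_iterations: int = 300
    n_replications: int = 10
    n_pcs: int = 100
    ridge_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.n_elite > self.ga_population:
            raise ValueError("n_elite cannot exceed ga_population")
        if self.tp_size < 1:
            raise ValueError("tp_size must be positive")


@dataclass
class TrainingSet:
    members: list[str]
    pevmean: float
    replication_scores: list[float]
    trace: list[float]                 # best score per iteration (winning rep)
    config: TPSearchConfig
    note: str = ""
    program_summary: pd.DataFrame | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "members": list(self.members),
            "pevmean": self.pevmean,
            "replication_scores": list(self.replication_scores),
            "trace": list(self.trace),
            "tp_size": self.config.tp_size,
            "seed": self.config.seed,
            "note": self.note,
        }


def _design(pcs: GenotypePCs, ids, n_pcs: int) -> np.ndarray:
    pos = pd.Series(np.arange(len(pcs.line_ids)), index=pcs.line_ids)
    missing = [i for i in ids if i not in pos.index]
    if missing:
        raise KeyError(f"lines without PC scores: {missing[:5]}")
    S = pcs.scores[pos.reindex(ids).to_numpy(dtype=int), :n_pcs]
    return np.column_stack([np.ones(len(ids)), S])


def pev_mean(
    train_ids,
    target_ids,
    pcs: GenotypePCs,
    n_pcs: int | None = None,
    ridge_epsilon: float = 1e-8,
) -> float:
    """Mean prediction-error variance of the target set given a training set."""
    k = pcs.scores.shape[1] if n_pcs is None else min(n_pcs, pcs.scores.shape[1])
    XT = _design(pcs, list(train_ids), k)
    XP = _design(pcs, list(target_ids), k)
    A = XT.T @ XT
    eps = ridge_epsilon * np.trace(A) / A.shape[0]
    if eps > 0:
        A = A + eps * np.eye(A.shape[0])
    try:
        cf = scipy.linalg.cho_factor(A, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular training normal equations; increase ridge_epsilon or "
            "reduce n_pcs below the training-set size"
        ) from exc
    B = scipy.linalg.cho_solve(cf, XP.T, check_finite=False)
    return float(np.mean(np.sum(XP.T * B, axis=0)))


def exhaustive_select(
    candidates,
    targets,
    pcs: GenotypePCs,
    tp_size: int,
    n_pcs: int | None = None,
    ridge_epsilon: float = 1e-8,
    max_combinations: int = 2_000_000,
) -> tuple[list[str], float]:
    """Enumerate every subset; the oracle for small instances."""
    candidates = sorted(candidates)
    from math import comb

    if comb(len(candidates), tp_size) > max_combinations:
        raise ValueError("instance too large for exhaustive enumeration")
    best, best_score = None, np.inf
    for subset in itertools.combinations(candidates, tp_size):
        s = pev_mean(subset, targets, pcs, n_pcs, ridge_epsilon)
        if s < best_score:
            best, best_score = list(subset), s
    return best, best_score


def ga_select(
    candidates,
    targets,
    pcs: GenotypePCs,
    cfg: TPSearchConfig,
) -> TrainingSet:
    """Genetic-algorithm subset search minimizing PEVmean.

    Runs ``cfg.n_replications`` independent searches and returns the best.
    Each search keeps a population of ``ga_population`` subsets of size
    ``tp_size``; the ``n_elite`` best pass unchanged, the rest come from
    size-2 tournaments, uniform subset crossover (child sampled from the
    parents' union) and per-slot member-swap mutation at rate 1/tp_size.
    Deterministic under ``cfg.seed``.
    """
    pool = sorted(set(map(str, candidates)))
    targets = list(map(str, targets))
    note = ""
    tp_size = cfg.tp_size
    if tp_size > len(pool):
        tp_size = int(np.floor(0.875 * len(pool)))
        note = (f"candidate pool ({len(pool)}) smaller than requested "
                f"tp_size ({cfg.tp_size}); reduced to {tp_size}")
        warnings.warn(note, UserWarning)
    if tp_size == len(pool):
        score = pev_mean(pool, targets, pcs, cfg.n_pcs, cfg.ridge_epsilon)
        return TrainingSet(
            members=pool, pevmean=score, replication_scores=[score],
            trace=[score], config=cfg,
            note="tp_size equals pool size; nothing to optimize",
        )

    pool_arr = np.array(pool)
    n = len(pool_arr)

    # pre-extract design rows once; subset scoring is the GA's hot loop
    k_pcs = min(cfg.n_pcs, pcs.scores.shape[1])
    Xpool = _design(pcs, list(pool_arr), k_pcs)
    XP = _design(pcs, targets, k_pcs)
    eye = np.eye(Xpool.shape[1])

    def score_subset(idx) -> float:
        XT = Xpool[idx]
        A = XT.T @ XT
        eps = cfg.ridge_epsilon * np.trace(A) / A.shape[0]
        try:
            cf = scipy.linalg.cho_factor(A + eps * eye, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular training normal equations; increase ridge_epsilon"
            ) from exc
        B = scipy.linalg.cho_solve(cf, XP.T, check_finite=False)
        return float(np.mean(np.sum(XP.T * B, axis=0)))

    master = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    rep_seeds = master.integers(0, 2**31 - 1, size=cfg.n_replications)

    best_overall = None
    rep_scores, best_trace = [], None
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(int(rep_seed))
        popn = [np.sort(rng.choice(n, tp_size, replace=False))
                for _ in range(cfg.ga_population)]
        fitness = np.array([score_subset(s) for s in popn])
        trace = []
        for _ in range(cfg.n_iterations):
            order = np.argsort(fitness, kind="stable")
            popn = [popn[i] for i in order]
            fitness = fitness[order]
            trace.append(float(fitness[0]))
            nxt = popn[:cfg.n_elite]
            while len(nxt) < cfg.ga_population:
                pa = _tournament(rng, fitness)
                pb = _tournament(rng, fitness)
                child = _crossover(rng, popn[pa], popn[pb], tp_size)
                child = _mutate(rng, child, n, tp_size)
                nxt.append(np.sort(child))
            popn = nxt
            fitness = np.concatenate([
                fitness[:cfg.n_elite],
                [score_subset(s) for s in popn[cfg.n_elite:]],
            ])
        order = np.argsort(fitness, kind="stable")
        best_idx, best_score = popn[order[0]], float(fitness[order[0]])
        trace.append(best_score)
        rep_scores.append(best_score)
        if best_overall is None or best_score < best_overall[1]:
            best_overall = (best_idx, best_score)
            best_trace = trace
    members = sorted(pool_arr[best_overall[0]])
    return TrainingSet(
        members=members,
        pevmean=best_overall[1],
        replication_scores=rep_scores,
        trace=[float(min(best_trace[: i + 1])) for i in range(len(best_trace))],
        config=cfg,
        note=note,
    )


def _tournament(rng, fitness) -> int:
    a, b = rng.integers(0, len(fitness), size=2)
    return int(a if fitness[a] <= fitness[b] else b)


def _crossover(rng, pa, pb, tp_size) -> np.ndarray:
    union = np.union1d(pa, pb)
    return rng.choice(union, tp_size, replace=False)


def _mutate(rng, child, n, tp_size) -> np.ndarray:
    flips = rng.random(tp_size) < 1.0 / tp_size
    if not flips.any():
        return child
    members = set(child.tolist())
    child = child.copy()
    for slot in np.flatnonzero(flips):
        repl = int(rng.integers(0, n))
        while repl in members:
            repl = int(rng.integers(0, n))
        members.discard(int(child[slot]))
        members.add(repl)
        child[slot] = repl
    return child


def summarize_tp_composition(
    tp: TrainingSet,
    program_labels: dict | pd.Series,
) -> pd.DataFrame:
    """Per-program counts, raw % of the TP, and normalized % (selected/available).

    ``program_labels`` maps every candidate-pool line to its breeding
    program; members without a label are counted under ``"unknown"``.
    """
    labels = pd.Series(program_labels)
    member_prog = labels.reindex(tp.members).fillna("unknown")
    counts = member_prog.value_counts().sort_index()
    available = labels.value_counts().sort_index()
    progs = sorted(set(counts.index) | set(available.index))
    rows = []
    for p in progs:
        sel = int(counts.get(p, 0))
        avail = int(available.get(p, 0))
        rows.append({
            "program": p,
            "selected": sel,
            "available": avail,
            "raw_pct": 100.0 * sel / len(tp.members),
            "normalized_pct": 100.0 * sel / avail if avail else np.nan,
        })
    return pd.DataFrame(rows).set_index("program")
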