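"""Simulated-annealing selection of AAindex accessions.

A subset of amino-acid property indices is searched by simulated annealing
with a linear-SVM objective: the score of a candidate subset is the mean
validation AUC of a linear SVM over a seeded stratified 3-fold split of the
residues, using only the subset's columns. One SA run is performed per
(window length, subset size) combination; the final feature set is the
frequency consensus (top 54 by membership count) across all runs.

Schedule: geometric cooling from T0=100 down to T1=0.1 at rate 0.95 (135
temperature plateaus), a configurable number of swap moves per plateau, and
Metropolis acceptance exp(dScore/T) for worsening moves.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .features import WindowSpec, map_aaindex, window_average
from .io_formats import AAindexTable, ProteinRecord


@dataclass
class SAConfig:
    """Annealing schedule and objective seeds (defaults: T0=100, T1=0.1, a=0.95)."""

    T0: float = 100.0
    T1: float = 0.1
    alpha: float = 0.95
    subset_size: int = 10
    moves_per_temp: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.T0 > self.T1 > 0):
            raise ValueError("need T0 > T1 > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.subset_size < 1 or self.moves_per_temp < 1:
            raise ValueError("subset_size and moves_per_temp must be positive")

    @property
    def n_cooling_steps(self) -> int:
        """Number of temperature plateaus before T drops below T1."""
        n, T = 0, self.T0
        while T >= self.T1:
            n += 1
            T *= self.alpha
        return n


@dataclass
class SAResult:
    best_subset: list[str]
    best_score: float
    score_trace: list[float]  # best-so-far at the end of each plateau
    accepted_moves: int
    evaluations: int = 0


@dataclass
class FrequencyTally:
    counts: dict[str, int]
    selected: list[str]


def evaluate_subset(
    subset: Sequence[str],
    features: pd.DataFrame,
    labels: np.ndarray,
    evaluator_seed: int = 0,
) -> float:
    """Linear-SVM objective: mean 3-fold stratified validation AUC.

    Deterministic for fixed inputs and seed (primal liblinear solver, seeded
    fold shuffling).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain both classes")
    if counts.min() < 3:
        raise ValueError("need at least 3 residues per class for 3-fold CV")
    X = features.loc[:, list(subset)].to_numpy()
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=evaluator_seed)
    aucs = []
    for tr, va in skf.split(X, labels):
        clf = LinearSVC(C=1.0, dual=False, tol=1e-3, max_iter=5000)
        clf.fit(X[tr], labels[tr])
        aucs.append(roc_auc_score(labels[va], clf.decision_function(X[va])))
    return float(np.mean(aucs))


def sa_select(
    pool: Sequence[str],
    features: pd.DataFrame,
    labels: np.ndarray,
    config: SAConfig,
    score_fn: Callable[[tuple[str, ...]], float] | None = None,
) -> SAResult:
    """Anneal a fixed-size accession subset toward maximal SVM AUC.

    The neighbour move swaps one in-subset accession for one outside it;
    improving moves are always accepted, worsening ones with probability
    ``exp(dScore/T)``. ``score_fn`` may replace the default SVM objective
    (it receives a sorted accession tuple); scores are memoized, so only
    novel subsets cost an evaluation.
    """
    pool = list(pool)
    if config.subset_size > len(pool):
        raise ValueError(
            f"subset_size {config.subset_size} exceeds pool size {len(pool)}"
        )
    cache: dict[tuple[str, ...], float] = {}
    evals = 0

    def score(subset: list[str]) -> float:
        nonlocal evals
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = (
                score_fn(key)
                if score_fn is not None
                else evaluate_subset(key, features, labels, evaluator_seed=config.seed)
            )
            evals += 1
        return cache[key]

    rng = np.random.default_rng(config.seed)
    current = sorted(rng.choice(pool, size=config.subset_size, replace=False))
    cur_score = score(current)
    best, best_score = list(current), cur_score

    if config.subset_size == len(pool):  # no neighbours to move to
        return SAResult(best, best_score, [best_score], 0, evals)

    trace: list[float] = []
    accepted = 0
    T = config.T0
    while T >= config.T1:
        for _ in range(config.moves_per_temp):
            out_pool = [a for a in pool if a not in current]
            drop = int(rng.integers(len(current)))
            add = int(rng.integers(len(out_pool)))
            candidate = sorted(current[:drop] + current[drop + 1 :] + [out_pool[add]])
            cand_score = score(candidate)
            delta = cand_score - cur_score
            if delta >= 0 or rng.random() < math.exp(delta / T):
                current, cur_score = candidate, cand_score
                accepted += 1
                if cur_score > best_score:
                    best, best_score = list(current), cur_score
        trace.append(best_score)
        T *= config.alpha
    return SAResult(best, best_score, trace, accepted, evals)


def consensus_features(results: list[SAResult], top_k: int = 54) -> FrequencyTally:
    """Frequency consensus over SA runs: top-k by membership count.

    Ties are broken by lexicographic accession order.
    """
    if not results:
        raise ValueError("no SA results given")
    counts: Counter[str] = Counter()
    for res in results:
        counts.update(res.best_subset)
    if top_k > len(counts):
        raise ValueError(
            f"top_k={top_k} exceeds the {len(counts)} distinct accessions seen"
        )
    ranked = sorted(counts, key=lambda a: (-counts[a], a))
    return FrequencyTally(dict(counts), ranked[:top_k])


def run_window_sweep(
    records: list[ProteinRecord],
    table: AAindexTable,
    windows: Sequence[int] = (5, 7, 9, 11, 21, 41),
    subset_sizes: Sequence[int] = (10, 20),
    config: SAConfig | None = None,
    top_k: int = 54,
    max_residues: int = 2000,
    scale: bool = True,
) -> tuple[dict[tuple[int, int], SAResult], FrequencyTally]:
    """One SA run per (window, subset size) pair, then frequency consensus.

    For each window length the full accession pool is mapped onto every
    sequence, smoothed twice, and pooled residue-wise; a seeded sample of at
    most ``max_residues`` residues (shared across windows) keeps the SVM
    objective desk-scale.
    """
    if config is None:
        config = SAConfig()
    pool = table.accessions
    src = table.scaled() if scale else table
    labels = np.concatenate([r.labels for r in records])
    if labels.min() == labels.max():
        raise ValueError("records must contain both motif and background residues")

    mapped = [map_aaindex(r.seq, src, pool) for r in records]
    rng = np.random.default_rng(config.seed)
    n = len(labels)
    sample = (
        np.sort(rng.choice(n, size=max_residues, replace=False))
        if n > max_residues
        else np.arange(n)
    )

    results: dict[tuple[int, int], SAResult] = {}
    run_idx = 0
    for N in windows:
        spec = WindowSpec(N=N, passes=2)
        X = np.vstack([window_average(m, spec) for m in mapped])[sample]
        df = pd.DataFrame(X, columns=pool)
        y = labels[sample]
        for size in subset_sizes:
            cfg = replace(config, subset_size=size, seed=config.seed + run_idx)
            results[(N, size)] = sa_select(pool, df, y, cfg)
            run_idx += 1
    all_results = list(results.values())
    seen = len(set().union(*(set(r.best_subset) for r in all_results)))
    tally = consensus_features(all_results, top_k=min(top_k, seen))
    return results, tally


def write_accessions(accessions: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for acc in accessions:
            fh.write(acc + "\n")


def read_accessions(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
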