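"""Maximally-informative-next-experiment scoring and genotype selection.

From the ensemble of fitted models, the predicted trait value of candidate
accession k is G_k(beta) = x_k' beta.  Ensemble moments of the predictions
give the K x K prediction covariance matrix

    D_kj = E[G_k G_j] - E[G_k] E[G_j]

or its correlation form E_kj = D_kj / sqrt(D_kk D_jj).  The determinant of D
(or E), computed from its eigenvalues, measures the prediction-uncertainty
ellipsoid volume: the panel maximizing it is the most informative next
experiment.  Determinants are handled on the log scale (a raw product of
eigenvalues under/overflows near K = 80), with a small eigenvalue floor to
tolerate positive-semidefinite rank deficiency.

Four selectors are provided: exhaustive tuple ranking ("suboptimal"),
Metropolis swap search ("monte_carlo"), one top triple followed by top
doublets ("nc3plus2"), and a one-at-a-time greedy grower seeded with the top
triple.  Exact score ties are broken by accession-label lexicographic order so
every selector is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from minegwas.genomatrix import DesignMatrix
from minegwas.mcmc import Ensemble
from minegwas.models import _as_array

EIG_FLOOR_REL = 1e-12
DEFAULT_TUPLE_BUDGET = 2_000_000


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CandidatePool:
    """Selectable accessions with their design-matrix rows."""

    accession_ids: list[str]
    X_cand: np.ndarray

    def __post_init__(self) -> None:
        self.X_cand = _as_array(self.X_cand)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession labels in pool")
        if self.X_cand.shape[0] != len(self.accession_ids):
            raise ValueError("X_cand rows must align with labels")

    @classmethod
    def from_design(cls, dm: DesignMatrix) -> "CandidatePool":
        return cls(list(dm.row_ids), dm.values)

    @property
    def size(self) -> int:
        return len(self.accession_ids)

    def index_of(self, labels) -> list[int]:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return [lookup[l] for l in labels]
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not in candidate pool")


@dataclass
class MineScore:
    """Prediction covariance (D) or correlation (E) matrix and its log-det."""

    criterion: str               # {"covariance", "correlation"}
    matrix: np.ndarray
    log_det: float
    eigenvalues: np.ndarray


@dataclass
class SelectionResult:
    """Ordered selected accessions with the per-step score trace."""

    selected: list[str]
    score_trace: list[float]
    algorithm: str
    seed: int | None = None
    final_score: float = float("nan")


# ---------------------------------------------------------------------------
# scoring


def prediction_moments(e: Ensemble, pool: CandidatePool, subset):
    """Ensemble first and second moments of predictions for a label subset."""
    idx = pool.index_of(subset)
    if e.n_samples == 0:
        raise ValueError("empty ensemble")
    preds = e.beta @ pool.X_cand[idx].T           # (N, K)
    first = preds.mean(axis=0)
    second = preds.T @ preds / e.n_samples
    return first, second


def _logdet_psd(mat: np.ndarray) -> tuple[float, np.ndarray]:
    eig = np.linalg.eigvalsh(mat)
    floor = EIG_FLOOR_REL * max(float(eig.max(initial=0.0)), 1.0)
    return float(np.log(np.maximum(eig, floor)).sum()), eig


def score_subset(e: Ensemble, pool: CandidatePool, subset,
                 criterion: str = "covariance") -> MineScore:
    """Assemble D (or E) for the subset and return it with its log-det."""
    first, second = prediction_moments(e, pool, subset)
    D = second - np.outer(first, first)
    D = 0.5 * (D + D.T)
    if criterion == "covariance":
        mat = D
    elif criterion == "correlation":
        d = np.diag(D)
        if np.any(d <= 0):
            bad = [s for s, v in zip(subset, d) if v <= 0]
            raise ValueError(
                f"zero-variance candidate(s) under correlation criterion: {bad}"
            )
        mat = D / np.sqrt(np.outer(d, d))
        np.fill_diagonal(mat, 1.0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    log_det, eig = _logdet_psd(mat)
    return MineScore(criterion, mat, log_det, eig)


class _Scorer:
    """Caches the full N x pool prediction matrix so subset scores are cheap."""

    def __init__(self, e: Ensemble, pool: CandidatePool, criterion: str):
        self.pool = pool
        self.criterion = criterion
        self.preds = e.beta @ pool.X_cand.T        # (N, n_pool)
        self.N = self.preds.shape[0]
        self.mean = self.preds.mean(axis=0)

    def logdet(self, idx: list[int]) -> float:
        P = self.preds[:, idx]
        m = self.mean[idx]
        D = P.T @ P / self.N - np.outer(m, m)
        D = 0.5 * (D + D.T)
        if self.criterion == "correlation":
            d = np.diag(D).copy()
            d[d <= 0] = np.nan
            D = D / np.sqrt(np.outer(d, d))
            np.fill_diagonal(D, 1.0)
            D = np.nan_to_num(D, nan=0.0)
        val, _ = _logdet_psd(D)
        return val


def _labels_sorted(pool: CandidatePool) -> list[int]:
    """Pool indices in label-lexicographic order (deterministic tie-break)."""
    return sorted(range(pool.size), key=lambda i: pool.accession_ids[i])


def _best_tuple(scorer: _Scorer, pool_idx: list[int], p_t: int,
                base: list[int] | None = None) -> tuple[list[int], float]:
    """Top p_t-tuple among pool_idx; when ``base`` is given each tuple is
    scored jointly with the already-selected accessions."""
    best, best_score = None, -np.inf
    order = sorted(pool_idx, key=lambda i: scorer.pool.accession_ids[i])
    for tup in combinations(order, p_t):
        idx = (base or []) + list(tup)
        s = scorer.logdet(idx)
        if s > best_score:
            best, best_score = list(tup), s
    return best, best_score


# ---------------------------------------------------------------------------
# selectors


def select_suboptimal(e: Ensemble, pool: CandidatePool, p_t: int, p_a: int,
                      criterion: str = "covariance",
                      tuple_budget: int = DEFAULT_TUPLE_BUDGET) -> SelectionResult:
    """Score every p_t-tuple, sort descending, harvest individual accessions
    from the top tuples (input order within a tuple, duplicates skipped)
    until p_a are collected."""
    n_tuples = comb(pool.size, p_t)
    if n_tuples > tuple_budget:
        raise ValueError(
            f"{n_tuples} tuples exceed the enumeration budget {tuple_budget}; "
            "consider the monte-carlo, nc3plus2 or greedy selectors"
        )
    if p_a > pool.size:
        raise ValueError("p_a exceeds pool size")
    scorer = _Scorer(e, pool, criterion)
    order = _labels_sorted(pool)
    scored = []
    for tup in combinations(order, p_t):
        scored.append((scorer.logdet(list(tup)), tup))
    # stable sort on -score keeps label-lexicographic order among exact ties
    scored.sort(key=lambda t: -t[0])
    selected: list[int] = []
    trace: list[float] = []
    seen = set()
    for s, tup in scored:
        for i in tup:
            if i not in seen:
                seen.add(i)
                selected.append(i)
                trace.append(s)
                if len(selected) == p_a:
                    break
        if len(selected) == p_a:
            break
    labels = [pool.accession_ids[i] for i in selected]
    final = scorer.logdet(selected)
    return SelectionResult(labels, trace, "suboptimal", final_score=final)


def select_monte_carlo(e: Ensemble, pool: CandidatePool, p_a: int, m: int,
                       temperature: float = 1.0, seed: int = 0,
                       criterion: str = "covariance") -> SelectionResult:
    """Metropolis swap search: start from a random panel, propose m single
    accession swaps with the pool, accept with the Boltzmann probability
    min(1, exp(delta_logdet / temperature)) (Hamiltonian = -log_det), and
    return the best panel seen."""
    if not (1 <= p_a < pool.size):
        raise ValueError("need 1 <= p_a < pool size")
    rng = np.random.default_rng(seed)
    scorer = _Scorer(e, pool, criterion)
    current = list(rng.choice(pool.size, size=p_a, replace=False))
    outside = [i for i in range(pool.size) if i not in set(current)]
    score = scorer.logdet(current)
    best, best_score = list(current), score
    trace = [score]
    for _ in range(m):
        a = int(rng.integers(p_a))
        b = int(rng.integers(len(outside)))
        proposal = list(current)
        proposal[a] = outside[b]
        new_score = scorer.logdet(proposal)
        d = new_score - score
        if d >= 0 or rng.random() < np.exp(d / temperature):
            outside[b] = current[a]
            current = proposal
            score = new_score
            if score > best_score:
                best, best_score = list(current), score
        trace.append(score)
    labels = sorted(
        (pool.accession_ids[i] for i in best)
    )  # stable presentation order
    return SelectionResult(labels, trace, "monte_carlo", seed=seed,
                           final_score=best_score)


def select_nc3plus2(e: Ensemble, pool: CandidatePool, p_a: int,
                    p_t1: int = 3, p_t2: int = 2,
                    criterion: str = "covariance",
                    cycle: bool = False) -> SelectionResult:
    """One top p_t1-tuple, then top p_t2-tuples (joint scoring with what is
    already selected), removing chosen accessions each round.

    With ``cycle=True`` rounds alternate p_t1 and p_t2 tuples instead.
    """
    if p_a > pool.size:
        raise ValueError("panel larger than pool")
    scorer = _Scorer(e, pool, criterion)
    remaining = _labels_sorted(pool)
    selected: list[int] = []
    trace: list[float] = []

    def take(p_t: int) -> None:
        nonlocal remaining
        k = min(p_t, p_a - len(selected), len(remaining))
        if k == 0:
            return
        tup, s = _best_tuple(scorer, remaining, k, base=selected)
        selected.extend(tup)
        trace.append(s)
        remaining = [i for i in remaining if i not in set(tup)]

    take(p_t1)
    use_t1 = False
    while len(selected) < p_a:
        if not remaining:
            raise ValueError("pool exhausted before reaching the panel size")
        take(p_t1 if (cycle and use_t1) else p_t2)
        use_t1 = not use_t1
    labels = [pool.accession_ids[i] for i in selected]
    return SelectionResult(labels, trace, "nc3plus2",
                           final_score=scorer.logdet(selected))


def select_greedy(e: Ensemble, pool: CandidatePool, p_a: int, p_t: int = 3,
                  criterion: str = "covariance") -> SelectionResult:
    """Seed with the top p_t-tuple, then repeatedly add the single accession
    that maximizes the score of the augmented panel."""
    if p_a > pool.size:
        raise ValueError("panel larger than pool")
    scorer = _Scorer(e, pool, criterion)
    remaining = _labels_sorted(pool)
    k0 = min(p_t, p_a)
    selected, s = _best_tuple(scorer, remaining, k0)
    trace = [s]
    remaining = [i for i in remaining if i not in set(selected)]
    while len(selected) < p_a:
        best_i, best_s = None, -np.inf
        for i in remaining:
            s = scorer.logdet(selected + [i])
            if s > best_s:
                best_i, best_s = i, s
        selected.append(best_i)
        trace.append(best_s)
        remaining.remove(best_i)
    labels = [pool.accession_ids[i] for i in selected]
    return SelectionResult(labels, trace, "greedy",
                           final_score=scorer.logdet(selected))


# ---------------------------------------------------------------------------
# comparison harness


def compare_selectors(e: Ensemble, pool: CandidatePool, p_a: int,
                      n_repeats: int = 10, seeds=None,
                      selectors: dict | None = None,
                      criterion: str = "covariance") -> pd.DataFrame:
    """Final log MINE score per selector across repeated seeded runs.

    ``selectors`` maps name -> callable(seed) -> SelectionResult; by default
    the monte-carlo and greedy selectors are compared (deterministic selectors
    simply repeat their score).
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    if selectors is None:
        selectors = {
            "monte_carlo": lambda s: select_monte_carlo(
                e, pool, p_a, m=500, seed=s, criterion=criterion
            ),
            "greedy": lambda s: select_greedy(e, pool, p_a, criterion=criterion),
        }
    if len(selectors) < 2:
        raise ValueError("need at least two selectors to compare")
    rows = []
    for name, fn in selectors.items():
        for s in seeds:
            res = fn(s)
            rows.append({"selector": name, "seed": s, "log_det": res.final_score})
    return pd.DataFrame(rows)
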