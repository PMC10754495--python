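"""Combinatorial maximum-likelihood estimation of the contributing individuals.

For a candidate set C of individuals, each haplotype contributes a factor

    p_h(C) = (sum of match values over members of C) / |C|,

the fraction of the candidate set that carries the haplotype (missing match
indicators enter through their mean-imputed values). The likelihood of C is
the product of these factors over all retained haplotypes; a haplotype
carried by nobody in C annihilates the product, and superfluous members
dilute every factor's denominator, so the likelihood penalizes both
under- and over-sized sets. The best set of each size n = 1..n_max is found
by exhaustive enumeration when the combination count is affordable, and by
beam search (flagged approximate) otherwise. The estimated number of
contributors is the smallest n attaining the overall maximum; a likelihood
still strictly increasing at n_max yields the open bound ">= n_max".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .matching import MatchMatrix

logger = logging.getLogger(__name__)

_CHUNK = 16384  # combinations scored per vectorized block


@dataclass(frozen=True)
class CombinationLikelihood:
    combination: tuple[str, ...]  # individual identifiers, sorted
    likelihood: float
    log_likelihood: float
    n_unexplained: int  # haplotypes with zero probability under the set


@dataclass
class ContributorProfile:
    """Best combination per candidate-set size, and the resulting estimate."""

    per_n: dict[int, CombinationLikelihood]
    n_estimate: int
    is_lower_bound: bool  # True when the likelihood still increases at n_max
    search_mode: str  # "exhaustive" | "beam" (approximate)
    field_note: str = field(default="", repr=False)

    @property
    def estimate_label(self) -> str:
        return f">= {self.n_estimate}" if self.is_lower_bound else str(self.n_estimate)


def _as_array(matrix: MatchMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, MatchMatrix):
        return matrix.imputed, list(matrix.individuals)
    X = np.asarray(matrix, dtype=float)
    return X, [f"ind{i}" for i in range(X.shape[1])]


def per_haplotype_probability(row: np.ndarray, members: np.ndarray) -> float:
    """Fraction of the candidate set carrying the haplotype (imputed values)."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("candidate combination must be non-empty")
    return float(np.asarray(row, dtype=float)[members].sum() / members.size)


def _combo_logliks(X: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Log-likelihood for each combination (rows of ``combos``, indices)."""
    n = combos.shape[1]
    S = X[:, combos].sum(axis=2) / n  # (J, m) per-haplotype probabilities
    with np.errstate(divide="ignore"):
        logs = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), -np.inf)
    return logs.sum(axis=0)


def combination_likelihood(
    matrix: MatchMatrix | np.ndarray, combination: tuple[str, ...] | np.ndarray
) -> CombinationLikelihood:
    """Product over haplotypes of per-haplotype probability, via log space."""
    X, ids = _as_array(matrix)
    if isinstance(combination, np.ndarray) or (combination and isinstance(combination[0], (int, np.integer))):
        members = np.asarray(combination, dtype=int)
    else:
        lookup = {name: i for i, name in enumerate(ids)}
        members = np.asarray([lookup[name] for name in combination], dtype=int)
    if members.size == 0:
        raise ValueError("candidate combination must be non-empty")
    S = X[:, members].sum(axis=1) / members.size
    unexplained = int((S <= 0).sum())
    with np.errstate(divide="ignore"):
        ll = float(np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), -np.inf).sum())
    names = tuple(sorted(ids[i] for i in members))
    return CombinationLikelihood(names, float(np.exp(ll)), ll, unexplained)


def _best_of(X: np.ndarray, order: np.ndarray, combos_iter, n: int) -> tuple[np.ndarray, float]:
    """Scan combinations (index tuples over ``order``) for the max log-likelihood.

    Combinations are generated in lexicographic order of sorted identifiers,
    and only strict improvements replace the incumbent, so ties resolve to
    the lexicographically smallest identifier set.
    """
    best_ll = -np.inf
    best: np.ndarray | None = None
    while True:
        chunk = np.array(list(itertools.islice(combos_iter, _CHUNK)), dtype=int)
        if chunk.size == 0:
            break
        lls = _combo_logliks(X, order[chunk])
        k = int(np.argmax(lls))
        if lls[k] > best_ll:
            best_ll = float(lls[k])
            best = order[chunk[k]]
        if best is None:  # all -inf so far: keep the lexicographically first
            best = order[chunk[0]]
    assert best is not None
    return best, best_ll


def mle_over_combinations(
    matrix: MatchMatrix | np.ndarray,
    n: int,
    strategy: str = "auto",
    budget: int = 10**6,
    beam_width: int = 50,
) -> CombinationLikelihood:
    """Best individual set of size ``n`` under the product likelihood.

    ``strategy='auto'`` enumerates all C(I, n) sets when that count is within
    ``budget`` and otherwise falls back to beam search (greedy forward
    selection keeping the ``beam_width`` best partial sets per level), whose
    result is approximate.
    """
    X, ids = _as_array(matrix)
    I = X.shape[1]
    if not (1 <= n <= I):
        raise ValueError(f"candidate-set size n={n} outside 1..{I}")
    order = np.asarray(sorted(range(I), key=lambda i: ids[i]), dtype=int)

    n_comb = _n_combinations(I, n)
    if strategy == "auto":
        strategy = "exhaustive" if n_comb <= budget else "beam"
    if strategy == "exhaustive":
        combos_iter = itertools.combinations(range(I), n)
        best, _ = _best_of(X, order, combos_iter, n)
        return combination_likelihood(matrix, best)
    if strategy == "beam":
        best = _beam_search(X, ids, order, n, beam_width)
        return combination_likelihood(matrix, best)
    raise ValueError(f"unknown strategy {strategy!r}")


def _n_combinations(I: int, n: int) -> int:
    import math

    return math.comb(I, n)


def _beam_search(X: np.ndarray, ids: list[str], order: np.ndarray, n: int,
                 beam_width: int) -> np.ndarray:
    """Greedy forward selection keeping the best ``beam_width`` partial sets."""
    frontier: list[tuple[int, ...]] = [(int(i),) for i in order]
    for level in range(1, n + 1):
        if level > 1:
            extended: set[tuple[int, ...]] = set()
            for combo in frontier:
                present = set(combo)
                for i in order:
                    if int(i) not in present:
                        extended.add(tuple(sorted(present | {int(i)})))
            frontier = list(extended)
        combos = np.asarray(frontier, dtype=int)
        lls = _combo_logliks(X, combos)
        # rank by log-likelihood, identifier-lexicographic on ties
        keys = sorted(
            range(len(frontier)),
            key=lambda k: (-lls[k], tuple(ids[i] for i in sorted(frontier[k], key=lambda j: ids[j]))),
        )
        frontier = [frontier[k] for k in keys[:beam_width]]
    return np.asarray(frontier[0], dtype=int)


def contributor_profile(
    matrix: MatchMatrix | np.ndarray,
    n_max: int = 6,
    strategy: str = "auto",
    budget: int = 10**6,
    beam_width: int = 50,
) -> ContributorProfile:
    """MLE of which and how many individuals contributed, for n = 1..n_max.

    The point estimate is the smallest n whose best combination attains the
    overall maximum likelihood. A likelihood strictly increasing all the way
    to ``n_max`` is reported as the open bound ``>= n_max`` — the data favor
    more contributors than were searched.
    """
    X, ids = _as_array(matrix)
    if n_max > X.shape[1]:
        raise ValueError(f"n_max={n_max} exceeds panel size {X.shape[1]}")
    per_n: dict[int, CombinationLikelihood] = {}
    modes = set()
    for n in range(1, n_max + 1):
        mode = strategy
        if strategy == "auto":
            mode = "exhaustive" if _n_combinations(X.shape[1], n) <= budget else "beam"
        per_n[n] = mle_over_combinations(matrix, n, strategy=mode, budget=budget,
                                         beam_width=beam_width)
        modes.add(mode)
    lls = np.asarray([per_n[n].log_likelihood for n in range(1, n_max + 1)])
    finite = np.where(np.isfinite(lls), lls, -np.inf)
    with np.errstate(invalid="ignore"):
        diffs = np.diff(finite)
    increasing = bool(np.all(diffs > 0)) and bool(np.isfinite(finite[-1]))
    if increasing:
        n_hat, lower = n_max, True
    else:
        n_hat, lower = int(np.argmax(finite)) + 1, False  # argmax -> smallest on ties
    search_mode = "beam" if "beam" in modes else "exhaustive"
    if search_mode == "beam":
        logger.info("contributor profile used approximate beam search")
    return ContributorProfile(per_n=per_n, n_estimate=n_hat, is_lower_bound=lower,
                              search_mode=search_mode)


class ContributorMLE(BaseEstimator):
    """Estimator interface to the combinatorial contributor analysis.

    ``fit(X)`` accepts a :class:`MatchMatrix` or an imputed J x I array and
    exposes ``profile_``, ``n_contributors_``, ``is_lower_bound_`` and
    ``best_combination_``.
    """

    def __init__(self, n_max: int = 6, strategy: str = "auto", budget: int = 10**6,
                 beam_width: int = 50):
        self.n_max = n_max
        self.strategy = strategy
        self.budget = budget
        self.beam_width = beam_width

    def fit(self, X, y=None) -> "ContributorMLE":
        arr, ids = _as_array(X)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("X must be a non-empty J x I matrix")
        self.individuals_ = ids
        self.profile_ = contributor_profile(X, n_max=min(self.n_max, arr.shape[1]),
                                            strategy=self.strategy, budget=self.budget,
                                            beam_width=self.beam_width)
        self.n_contributors_ = self.profile_.n_estimate
        self.is_lower_bound_ = self.profile_.is_lower_bound
        self.best_combination_ = self.profile_.per_n[self.n_contributors_].combination
        self.n_features_in_ = arr.shape[1]
        return self
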