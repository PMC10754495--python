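"""Bayesian mixture estimation of individual contributions.

Each retained haplotype is treated as one observation drawn from a mixture
over the panel's individuals — the genetic-stock-identification model with
every individual acting as a reference collection of size one. With mixing
proportions pi on the I-simplex and a fixed likelihood matrix L (J x I,
derived from the mean-imputed match matrix), the generative model is

    z_j | pi ~ Categorical(pi),        j = 1..J
    x_j | z_j = i  with likelihood L_ji,
    pi ~ Dirichlet(alpha, ..., alpha)   (alpha = 1: uniform prior)

and the collapsed conditionals are conjugate, so a two-block Gibbs sampler
alternates z | pi and pi | z. Posterior means of pi are the reported mixing
proportions; the per-haplotype posterior assignment matrix records how often
each haplotype was attributed to each individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matching import MatchMatrix


@dataclass
class MixtureResult:
    """Posterior summaries of a fitted mixture."""

    individuals: list[str]
    proportions: pd.Series  # posterior mean mixing proportions, sums to 1
    assignment: pd.DataFrame  # J x I posterior assignment probabilities
    individual_means: pd.Series  # column means of `assignment`
    trace: np.ndarray  # retained post-burn-in samples of pi, (n_retained, I)


def likelihood_matrix(matrix: MatchMatrix | np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """L = imputed match matrix + eps; the floor keeps every entry positive.

    A hard zero would make an individual an absorbing non-option for a
    haplotype; the small floor preserves ranking while keeping the sampler
    ergodic. ``eps=0`` disables the floor (used for exact conjugacy checks).
    """
    X = matrix.imputed if isinstance(matrix, MatchMatrix) else np.asarray(matrix, dtype=float)
    if eps < 0 or eps > 0.01:
        raise ValueError("eps must lie in [0, 0.01]")
    return X + eps


class DirichletMixture(BaseEstimator):
    """Gibbs-sampled Dirichlet-categorical mixture over panel individuals.

    Parameters
    ----------
    n_iter : int, default 2000
        Total Gibbs sweeps.
    burn_in : int, default 100
        Sweeps discarded before posterior summaries are accumulated.
    alpha : float, default 1.0
        Symmetric Dirichlet concentration; 1 is the uniform prior.
    eps : float, default 1e-6
        Likelihood floor added to the (imputed) match matrix.
    random_state : int or None
        Seed; identical seeds give bit-identical traces.

    Attributes
    ----------
    proportions_ : ndarray (I,)
        Posterior mean mixing proportions (sum to 1).
    assignment_ : ndarray (J, I)
        Posterior probability that haplotype j originated from individual i.
    individual_means_ : ndarray (I,)
        Column means of ``assignment_``.
    trace_ : ndarray (n_iter - burn_in, I)
        Retained samples of pi.
    """

    def __init__(self, n_iter: int = 2000, burn_in: int = 100, alpha: float = 1.0,
                 eps: float = 1e-6, random_state: int | None = None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.alpha = alpha
        self.eps = eps
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, MatchMatrix):
            self.individuals_ = list(X.individuals)
            X = X.imputed
        else:
            X = np.asarray(X, dtype=float)
            self.individuals_ = getattr(self, "individuals_", None)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("X must be a non-empty J x I matrix")
        if not np.isfinite(X).all():
            raise ValueError("likelihoods must be finite (impute missing values first)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        L = likelihood_matrix(X, self.eps)
        if (L < 0).any() or (L.sum(axis=1) <= 0).any():
            raise ValueError("every haplotype needs positive total likelihood")
        return L

    @staticmethod
    def _sample_rows(rng: np.random.Generator, W: np.ndarray) -> np.ndarray:
        """Draw one categorical index per row of the nonnegative weight matrix W."""
        c = W.cumsum(axis=1)
        u = rng.random(W.shape[0]) * c[:, -1]
        return np.minimum((c < u[:, None]).sum(axis=1), W.shape[1] - 1)

    def fit(self, X, y=None) -> "DirichletMixture":
        L = self._validate(X)
        J, I = L.shape
        rng = np.random.default_rng(self.random_state)

        pi = np.full(I, 1.0 / I)
        n_retained = self.n_iter - self.burn_in
        trace = np.empty((n_retained, I))
        assign_counts = np.zeros((J, I))
        for sweep in range(self.n_iter):
            z = self._sample_rows(rng, pi[None, :] * L)
            counts = np.bincount(z, minlength=I)
            if I == 1:  # degenerate simplex: pi is exactly [1.0]
                pi = np.ones(1)
            else:
                pi = rng.dirichlet(self.alpha + counts)
            if sweep >= self.burn_in:
                trace[sweep - self.burn_in] = pi
                assign_counts[np.arange(J), z] += 1.0

        self.trace_ = trace
        self.proportions_ = trace.mean(axis=0)
        self.assignment_ = assign_counts / n_retained
        self.individual_means_ = self.assignment_.mean(axis=0)
        self.n_features_in_ = I
        return self

    def result(self) -> MixtureResult:
        """Package fitted attributes with individual identifiers."""
        ids = self.individuals_ or [f"ind{i}" for i in range(self.n_features_in_)]
        return MixtureResult(
            individuals=list(ids),
            proportions=pd.Series(self.proportions_, index=ids, name="proportion"),
            assignment=pd.DataFrame(self.assignment_, columns=ids),
            individual_means=pd.Series(self.individual_means_, index=ids, name="posterior_mean"),
            trace=self.trace_,
        )


def gibbs_mixture(matrix: MatchMatrix | np.ndarray, n_iter: int = 2000, burn_in: int = 100,
                  alpha: float = 1.0, eps: float = 1e-6,
                  random_state: int | None = None) -> MixtureResult:
    """Fit the Dirichlet-categorical mixture and return posterior summaries."""
    model = DirichletMixture(n_iter=n_iter, burn_in=burn_in, alpha=alpha, eps=eps,
                             random_state=random_state)
    model.fit(matrix)
    return model.result()


def summarize_mixture(result: MixtureResult, top_k: int = 2,
                      exclude: tuple[str, ...] = ()) -> dict:
    """Ranked view of mixing proportions: best hit, runner-up, rest.

    ``exclude`` removes named individuals before ranking (useful when one
    individual's signal saturates every sample and the question is who else
    contributed). Ties are broken by identifier order and flagged.
    """
    props = result.proportions.drop(list(exclude), errors="ignore")
    if top_k > len(props):
        top_k = len(props)
    # sort by proportion descending, identifier ascending on ties
    ranked = props.iloc[np.lexsort((props.index, -props.to_numpy()))]
    top = ranked.iloc[:top_k]
    remaining = ranked.iloc[top_k:]
    tie = bool(len(ranked) > 1 and np.isclose(ranked.iloc[0], ranked.iloc[1]))
    return {
        "ranking": [(str(i), float(p)) for i, p in ranked.items()],
        "best": str(ranked.index[0]),
        "best_proportion": float(ranked.iloc[0]),
        "second": str(ranked.index[1]) if len(ranked) > 1 else None,
        "second_proportion": float(ranked.iloc[1]) if len(ranked) > 1 else None,
        "top": [(str(i), float(p)) for i, p in top.items()],
        "remaining_mean": float(remaining.mean()) if len(remaining) else None,
        "excluded": list(exclude),
        "tie": tie,
    }
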