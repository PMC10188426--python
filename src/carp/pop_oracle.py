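"""Exact population computations for a logistic latent-trait bank.

Full enumeration of the ``2^J`` response patterns with probabilities

    P(x) = integral  prod_i P(X_i = x_i | theta)  dPhi_D(theta)

approximated by tensor-product Gauss-Hermite quadrature (probabilists'
weighting, 64 nodes per dimension by default; at that count doubling the
nodes moves no pattern probability by more than 1e-8 even for the steepest
supported loadings).  The resulting pattern
probability mass function is the independent oracle behind simulator
checks, population regression weights, and exact conditional correlations
in quantile groups of any conditioning score.

Quantile groups of a *discrete* population score need a tie rule: patterns
are sorted by score value, group boundaries sit at cumulative probability
``s/m``, and a score value whose mass straddles a boundary is assigned
wholly to the straddled group nearer the center of the distribution.  The
outermost groups therefore contain only values whose entire tail mass fits
within ``1/m`` -- a conservative convention for extreme-group conditioning.
See ``docs/methods.md`` for discussion of this rule's sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import (
    EnumerationBoundError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .irt_sim import ItemBank
from .pair_test import PairWeights

__all__ = [
    "PatternPMF",
    "pattern_distribution",
    "population_weights",
    "score_groups",
    "conditional_correlation",
    "predicted_difference_correlation",
    "carp_population_covariances",
    "rest_score_conditional_covariances",
]

_MAX_ITEMS = 20


def _patterns(n_items: int) -> np.ndarray:
    """All binary patterns, shape (2^J, J); item 0 is the least-significant bit."""
    idx = np.arange(2**n_items, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n_items)) & 1).astype(np.int8)


@dataclass(frozen=True)
class PatternPMF:
    """Exact pattern probabilities under an :class:`~carp.irt_sim.ItemBank`."""

    probabilities: np.ndarray
    bank: ItemBank
    quadrature_nodes: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 1 or probs.size != 2**self.bank.n_items:
            raise InvalidParameterError("probabilities must have length 2^J")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise InvalidParameterError("probabilities must be a distribution")
        probs.setflags(write=False)
        object.__setattr__(self, "probabilities", probs)

    @property
    def n_items(self) -> int:
        return self.bank.n_items

    @property
    def patterns(self) -> np.ndarray:
        return _patterns(self.n_items)

    def item_means(self) -> np.ndarray:
        """Population marginal P(X_i = 1) for every item."""
        return self.probabilities @ self.patterns

    def second_moments(self) -> np.ndarray:
        """Population matrix E[X X^T] (diagonal holds the marginals)."""
        pats = self.patterns.astype(float)
        return (pats * self.probabilities[:, None]).T @ pats


def pattern_distribution(bank: ItemBank, nodes: int = 64) -> PatternPMF:
    """Enumerate all ``2^J`` pattern probabilities by Gauss-Hermite quadrature.

    Only loading columns with a nonzero entry consume quadrature dimensions;
    an all-zero bank needs no integration at all.  Deterministic.
    """
    if bank.n_items > _MAX_ITEMS:
        raise EnumerationBoundError(
            f"pattern enumeration supports at most {_MAX_ITEMS} items"
        )
    if nodes < 10:
        raise InvalidParameterError("use at least 10 quadrature nodes per dimension")
    j = bank.n_items
    active = np.any(bank.loadings != 0, axis=0)
    loadings = bank.loadings[:, active]
    d = loadings.shape[1]
    if d == 0:
        theta = np.zeros((1, 0))
        weights = np.ones(1)
    else:
        x, w = np.polynomial.hermite_e.hermegauss(nodes)
        w = w / np.sqrt(2.0 * np.pi)
        grids = np.meshgrid(*([x] * d), indexing="ij")
        theta = np.column_stack([g.ravel() for g in grids])
        wgrids = np.meshgrid(*([w] * d), indexing="ij")
        weights = np.prod(np.column_stack([g.ravel() for g in wgrids]), axis=1)
    prob_items = expit(theta @ loadings.T + bank.intercepts)  # (K, J)
    prob_items = np.clip(prob_items, 1e-300, 1.0 - 1e-16)
    log_p = np.log(prob_items)
    log_q = np.log1p(-prob_items)
    pats = _patterns(j).astype(float)
    # chunk quadrature nodes to bound the (2^J x K) intermediate
    chunk = max(1, (1 << 22) // pats.shape[0])
    probs = np.zeros(pats.shape[0])
    for start in range(0, theta.shape[0], chunk):
        sl = slice(start, start + chunk)
        logpat = pats @ log_p[sl].T + (1.0 - pats) @ log_q[sl].T
        probs += np.exp(logpat) @ weights[sl]
    probs /= probs.sum()  # remove residual quadrature error (< 1e-12 relative)
    return PatternPMF(probabilities=probs, bank=bank, quadrature_nodes=nodes)


def population_weights(pmf: PatternPMF, i: int, j: int) -> PairWeights:
    """Population least-squares weights for a focal pair.

    Solves the population normal equations built from the exact second
    moments of the pattern distribution; coefficients of the focal items are
    exactly zero.  A singular moment matrix resolves to the minimum-norm
    solution, the same convention as the sample-level fit.
    """
    n_items = pmf.n_items
    if i == j or not (0 <= i < n_items and 0 <= j < n_items):
        raise InvalidParameterError("focal items must be two distinct column indices")
    pats = pmf.patterns.astype(float)
    mask = np.ones(n_items, dtype=bool)
    mask[[i, j]] = False
    design = np.column_stack([np.ones(pats.shape[0]), pats[:, mask]])
    weighted = design * pmf.probabilities[:, None]
    moment = weighted.T @ design

    def solve(target: int) -> np.ndarray:
        rhs = weighted.T @ pats[:, target]
        sol, *_ = np.linalg.lstsq(moment, rhs, rcond=None)
        out = np.zeros(n_items + 1)
        out[0] = sol[0]
        out[1:][mask] = sol[1:]
        return out

    return PairWeights(a_i=solve(i), a_j=solve(j), focal=(i, j))


def score_groups(score_by_pattern, pmf: PatternPMF, m: int) -> np.ndarray:
    """Partition patterns into ``m`` near-equal-probability groups of a score.

    Patterns sharing a score value always share a group.  Distinct values
    are sorted; boundaries sit at cumulative probability ``s/m``.  A value
    whose mass lies within a single interval ``((s-1)/m, s/m]`` gets group
    ``s``; a value whose mass straddles one or more boundaries is assigned
    wholly to whichever straddled group lies nearer the center of the
    distribution (ties resolve to the lower group).  Group ``1`` (resp.
    ``m``) therefore contains exactly the values whose entire lower (resp.
    upper) tail mass is at most ``1/m``.  Returns a 1-based group label per
    pattern (labels in ``1..m``).
    """
    if m < 2:
        raise InvalidParameterError("m must be at least 2")
    score = np.asarray(score_by_pattern, dtype=float)
    if score.shape != pmf.probabilities.shape:
        raise InvalidParameterError("need one score per pattern")
    # cluster values that differ only by floating-point noise, so ties in
    # the population score are grouped as one value
    order = np.argsort(score, kind="stable")
    srt = score[order]
    tol = 1e-9 * max(1.0, np.ptp(srt))
    new_cluster = np.empty(srt.size, dtype=bool)
    new_cluster[0] = True
    new_cluster[1:] = np.diff(srt) > tol
    cluster_sorted = np.cumsum(new_cluster) - 1
    inverse = np.empty(score.size, dtype=int)
    inverse[order] = cluster_sorted
    mass = np.bincount(inverse, weights=pmf.probabilities)
    cum_after = np.cumsum(mass)
    cum_before = cum_after - mass
    g_start = np.clip(np.floor(cum_before * m + 1e-9).astype(int) + 1, 1, m)
    g_end = np.clip(np.ceil(cum_after * m - 1e-9).astype(int), 1, m)
    center = (m + 1) / 2.0
    inward = np.where(
        np.abs(g_start - center) <= np.abs(g_end - center), g_start, g_end
    )
    return inward[inverse]


def conditional_correlation(pmf: PatternPMF, i: int, j: int, groups, keep) -> float:
    """Exact Pearson correlation of the focal pair within a union of groups.

    ``groups`` assigns a group label to every pattern (as from
    :func:`score_groups`); ``keep`` is the set of labels forming the
    subpopulation.  Raises :class:`UndefinedCorrelationError` when the
    subpopulation has zero probability or a degenerate focal marginal.
    """
    groups = np.asarray(groups)
    mask = np.isin(groups, np.asarray(list(keep)))
    mass = pmf.probabilities[mask].sum()
    if mass <= 0:
        raise UndefinedCorrelationError("subpopulation has zero probability")
    pats = pmf.patterns
    w = pmf.probabilities[mask] / mass
    xi = pats[mask, i].astype(float)
    xj = pats[mask, j].astype(float)
    ei, ej = w @ xi, w @ xj
    eij = w @ (xi * xj)
    var_i = ei * (1 - ei)
    var_j = ej * (1 - ej)
    if var_i <= 0 or var_j <= 0:
        raise UndefinedCorrelationError("degenerate focal marginal in subpopulation")
    return float((eij - ei * ej) / np.sqrt(var_i * var_j))


def predicted_difference_correlation(
    pmf: PatternPMF,
    i: int,
    j: int,
    m: int = 20,
    keep=(1, 20),
) -> float:
    """Correlation of the focal pair in extreme quantile groups of ``Xhat_ij - Xhat_ji``.

    The conditioning score is the *difference* of the population predicted
    scores of the two focal items (not the CARP sum); with ``m = 20`` and
    ``keep = (1, 20)`` this is the extreme-vigintile construction whose
    population value is strongly negative for two independent blocks.
    """
    w = population_weights(pmf, i, j)
    pats = pmf.patterns.astype(float)
    diff = (w.a_i[0] - w.a_j[0]) + pats @ (w.a_i[1:] - w.a_j[1:])
    groups = score_groups(diff, pmf, m)
    return conditional_correlation(pmf, i, j, groups, keep)


def carp_population_covariances(
    pmf: PatternPMF, i: int, j: int, m: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group population CARP covariances and group masses.

    Groups are ``m``-quantile groups of the population conditioning score
    ``Xhat_ij + Xhat_ji``.  Returns ``(covariances, masses)`` over the
    groups that carry positive probability.
    """
    w = population_weights(pmf, i, j)
    pats = pmf.patterns.astype(float)
    score = (w.a_i[0] + w.a_j[0]) + pats @ (w.a_i[1:] + w.a_j[1:])
    groups = score_groups(score, pmf, m)
    return _groupwise_covariances(pmf, i, j, groups)


def rest_score_conditional_covariances(
    pmf: PatternPMF, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Population covariances of the focal pair given the unweighted rest score."""
    pats = pmf.patterns
    rest = pats.sum(axis=1) - pats[:, i] - pats[:, j]
    return _groupwise_covariances(pmf, i, j, rest)


def _groupwise_covariances(pmf, i, j, groups):
    groups = np.asarray(groups)
    pats = pmf.patterns.astype(float)
    covs, masses = [], []
    for g in np.unique(groups):
        mask = groups == g
        mass = pmf.probabilities[mask].sum()
        if mass <= 0:
            continue
        w = pmf.probabilities[mask] / mass
        xi, xj = pats[mask, i], pats[mask, j]
        covs.append(w @ (xi * xj) - (w @ xi) * (w @ xj))
        masses.append(mass)
    return np.asarray(covs), np.asarray(masses)
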