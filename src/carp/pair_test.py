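"""The CARP test for a single focal item pair, and the CRS comparator.

The CARP (conditioning on added regression predictions) test asks whether a
focal pair of binary items ``(i, j)`` has nonnegative covariance given a
*weighted* rest score.  Conditional association -- a consequence of the
unidimensional monotone homogeneity model -- implies the covariance is
nonnegative given any function of the remaining items, so a significantly
negative conditional covariance rejects every unidimensional monotone model.

The procedure:

1.  split the ``N`` subjects into a training sample of ``L = round(ell*N)``
    subjects and a test sample of the remaining ``M``;
2.  on the training sample, regress ``X_i`` and ``X_j`` each on all other
    items by ordinary least squares (coefficients of the focal items fixed
    at zero), giving predicted scores ``Xhat_ij`` and ``Xhat_ji``;
3.  take empirical ``m``-quantile separators of ``Xhat_ij + Xhat_ji`` on the
    training sample;
4.  assign each *test* subject to a layer via those separators (intervals
    right-closed: a score equal to a separator falls in the lower layer);
5.  apply the one-sided Mantel-Haenszel test of :mod:`carp.mh_core` to the
    layered 2x2 tables of the focal pair in the test sample.

Because the layering is estimated on an independent training sample with
the focal coefficients forced to zero, the asymptotic type-I error rate is
controlled under any conditionally associated population, however poor the
regression estimates are.

The CRS (conditioning on rest scores) comparator conditions on the raw
unweighted rest score of the pair on the full sample, with no splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateScoresError,
    DegenerateTableError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from .mh_core import LayerCounts, MHResult, mantel_haenszel_one_sided, tabulate_layers

__all__ = [
    "SampleSplit",
    "PairWeights",
    "QuantileSeparators",
    "CarpResult",
    "split_sample",
    "fit_pair_regressions",
    "predicted_sum",
    "quantile_separators",
    "assign_layers",
    "carp_pair_test",
    "crs_pair_test",
    "default_ell",
]


@dataclass(frozen=True)
class SampleSplit:
    """A disjoint, exhaustive train/test partition of subject indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ell: float

    @property
    def n_train(self) -> int:
        return self.train_indices.size

    @property
    def n_test(self) -> int:
        return self.test_indices.size

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test


@dataclass(frozen=True)
class PairWeights:
    """Estimated regression weights for a focal pair.

    ``a_i[0]`` and ``a_j[0]`` are intercepts; ``a_i[1 + k]`` is the
    coefficient of item ``k`` (0-based) in the prediction of the first focal
    item, and symmetrically for ``a_j``.  Both coefficient vectors are
    exactly zero at the two focal positions.
    """

    a_i: np.ndarray
    a_j: np.ndarray
    focal: tuple[int, int]

    @property
    def conditioning_weights(self) -> np.ndarray:
        """Length-(J+1) weights of the conditioning score ``Xhat_ij + Xhat_ji``."""
        return self.a_i + self.a_j


@dataclass(frozen=True)
class QuantileSeparators:
    """Strictly increasing separators defining up to ``m_requested`` layers."""

    q: np.ndarray
    m_requested: int

    @property
    def m_effective(self) -> int:
        return self.q.size + 1


@dataclass(frozen=True)
class CarpResult:
    """Outcome of a CARP (or CRS) pair test.

    ``mh`` is ``None`` for a *no-decision* outcome, in which case ``failure``
    names the degeneracy (constant conditioning scores or an entirely
    degenerate layer table).  No-decision outcomes should be counted as
    non-rejections in rejection-rate studies.
    """

    mh: MHResult | None
    weights: PairWeights | None
    separators: QuantileSeparators | None
    split: SampleSplit | None
    focal: tuple[int, int]
    conditioning: np.ndarray | None
    table: LayerCounts | None = None
    failure: str | None = None

    @property
    def z(self) -> float:
        return np.nan if self.mh is None else self.mh.z

    @property
    def p_value(self) -> float:
        return np.nan if self.mh is None else self.mh.p_value

    def rejects(self, alpha: float = 0.05) -> bool:
        """One-sided decision ``p < alpha``; False for no-decision outcomes."""
        return self.mh is not None and self.mh.p_value < alpha


def default_ell(n_subjects: int) -> float:
    """Recommended training fraction: .5 for N <= 500, else .3."""
    return 0.5 if n_subjects <= 500 else 0.3


def split_sample(n_subjects: int, ell: float, seed) -> SampleSplit:
    """Uniformly random train/test partition with ``L = round(ell * N)``.

    Rounding ties (``ell * N`` ending in .5) resolve downward.
    """
    if not 0.0 < ell < 1.0:
        raise InvalidParameterError("ell must lie strictly between 0 and 1")
    if n_subjects < 2:
        raise InvalidParameterError("need at least two subjects to split")
    n_train = int(np.ceil(ell * n_subjects - 0.5))
    if n_train < 1 or n_train >= n_subjects:
        raise InvalidParameterError(
            f"ell={ell} with N={n_subjects} leaves an empty training or test sample"
        )
    perm = np.random.default_rng(seed).permutation(n_subjects)
    return SampleSplit(
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
        ell=ell,
    )


def _binary_matrix(x) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise InvalidInputError("response matrix must be 2-D (subjects x items)")
    if not np.isin(x, (0, 1)).all():
        raise InvalidInputError("response matrix entries must be 0 or 1")
    return x


def _ols_excluding(x: np.ndarray, target: int, excluded: tuple[int, int]) -> np.ndarray:
    """Least-squares weights predicting column ``target`` from the others.

    Returns a length-(J+1) vector (intercept first) with exact zeros at both
    excluded positions.  The design is centered before solving and
    exactly-constant predictor columns are dropped (their effect is absorbed
    by the intercept); remaining collinearity resolves to the minimum-norm
    solution, which fixes a unique answer in degenerate training samples.
    """
    n, j = x.shape
    y = x[:, target].astype(float)
    mask = np.ones(j, dtype=bool)
    mask[list(excluded)] = False
    z = x[:, mask].astype(float)
    zmean = z.mean(axis=0)
    ymean = y.mean()
    zc = z - zmean
    varying = np.ptp(z, axis=0) > 0
    coef_sub = np.zeros(mask.sum())
    if varying.any():
        sol, *_ = np.linalg.lstsq(zc[:, varying], y - ymean, rcond=None)
        coef_sub[varying] = sol
    weights = np.zeros(j + 1)
    weights[1:][mask] = coef_sub
    weights[0] = ymean - coef_sub @ zmean
    return weights


def fit_pair_regressions(train, i: int, j: int) -> PairWeights:
    """OLS weights predicting each focal item from the other ``J - 2`` items."""
    x = _binary_matrix(train)
    n_items = x.shape[1]
    if i == j or not (0 <= i < n_items and 0 <= j < n_items):
        raise InvalidParameterError("focal items must be two distinct column indices")
    if n_items < 3:
        raise InvalidParameterError("need at least three items (one non-focal)")
    if x.shape[0] < 2:
        raise InsufficientDataError("need at least two training rows")
    return PairWeights(
        a_i=_ols_excluding(x, i, (i, j)),
        a_j=_ols_excluding(x, j, (i, j)),
        focal=(i, j),
    )


def predicted_sum(x, w: PairWeights) -> np.ndarray:
    """Per-subject conditioning score ``Xhat_ij + Xhat_ji``."""
    x = np.asarray(x)
    c = w.conditioning_weights
    if x.ndim != 2 or x.shape[1] != c.size - 1:
        raise InvalidInputError("response matrix columns must match weight length")
    return c[0] + x @ c[1:]


def quantile_separators(train_scores, m: int) -> QuantileSeparators:
    """Empirical quantile separators at probabilities ``s/m``, ``s = 1..m-1``.

    Uses the left-continuous inverse of the empirical distribution function
    (type-1 quantiles): the ``s/m`` separator is the ``ceil(L*s/m)``-th order
    statistic.  Duplicate separators are collapsed, so the effective number
    of layers may be smaller than ``m``.
    """
    scores = np.asarray(train_scores, dtype=float)
    if m < 2:
        raise InvalidParameterError("m must be at least 2")
    if scores.ndim != 1 or scores.size < m:
        raise InvalidParameterError("need at least m training scores")
    if np.ptp(scores) == 0:
        raise DegenerateScoresError("all conditioning scores identical")
    srt = np.sort(scores)
    idx = np.ceil(np.arange(1, m) * scores.size / m).astype(int) - 1
    q = np.unique(srt[idx])
    # a separator at the training maximum would leave an empty top layer;
    # dropping it caps the effective layer count at the number of distinct values
    q = q[q < srt[-1]]
    q.setflags(write=False)
    return QuantileSeparators(q=q, m_requested=m)


def assign_layers(test_scores, seps: QuantileSeparators) -> np.ndarray:
    """Layer labels in ``1..m_effective``; intervals are right-closed.

    A score exactly equal to separator ``q_s`` is assigned to layer ``s``;
    the outer intervals extend to minus/plus infinity, so every score
    receives a layer.
    """
    scores = np.asarray(test_scores, dtype=float)
    return np.searchsorted(seps.q, scores, side="left") + 1


def carp_pair_test(
    x,
    i: int,
    j: int,
    ell: float | None = None,
    m: int = 10,
    seed=0,
) -> CarpResult:
    """Run the full CARP procedure for focal pair ``(i, j)`` (0-based).

    ``ell`` defaults to the recommended training fraction (.5 for
    ``N <= 500``, else .3).  The result is deterministic given ``seed``,
    which drives only the train/test split.  Degenerate conditioning scores
    or an entirely degenerate layer table yield a flagged no-decision
    result rather than an error.
    """
    x = _binary_matrix(x)
    n, n_items = x.shape
    if ell is None:
        ell = default_ell(n)
    split = split_sample(n, ell, seed)
    if split.n_train < n_items + 2:
        raise InsufficientDataError(
            f"training sample of {split.n_train} subjects is too small for J={n_items}"
        )
    train = x[split.train_indices]
    test = x[split.test_indices]
    weights = fit_pair_regressions(train, i, j)
    try:
        seps = quantile_separators(predicted_sum(train, weights), m)
    except DegenerateScoresError:
        return CarpResult(
            mh=None, weights=weights, separators=None, split=split,
            focal=(i, j), conditioning=None, failure="degenerate-scores",
        )
    layers = assign_layers(predicted_sum(test, weights), seps)
    tab = tabulate_layers(test[:, i], test[:, j], layers, seps.m_effective)
    try:
        mh = mantel_haenszel_one_sided(tab)
    except DegenerateTableError:
        return CarpResult(
            mh=None, weights=weights, separators=seps, split=split,
            focal=(i, j), conditioning=layers, table=tab, failure="degenerate-table",
        )
    return CarpResult(
        mh=mh, weights=weights, separators=seps, split=split,
        focal=(i, j), conditioning=layers, table=tab,
    )


def crs_pair_test(x, i: int, j: int) -> CarpResult:
    """Rosenbaum-style comparator: condition on the raw unweighted rest score.

    Layers are the observed values ``0..J-2`` of the rest score of the pair,
    computed on the full sample with no train/test split.
    """
    x = _binary_matrix(x)
    n_items = x.shape[1]
    if i == j or not (0 <= i < n_items and 0 <= j < n_items):
        raise InvalidParameterError("focal items must be two distinct column indices")
    if n_items < 3:
        raise InvalidParameterError("need at least three items (one non-focal)")
    rest = x.sum(axis=1) - x[:, i] - x[:, j]
    layers = rest.astype(np.int64) + 1
    tab = tabulate_layers(x[:, i], x[:, j], layers, n_items - 1)
    try:
        mh = mantel_haenszel_one_sided(tab)
    except DegenerateTableError:
        return CarpResult(
            mh=None, weights=None, separators=None, split=None,
            focal=(i, j), conditioning=layers, table=tab, failure="degenerate-table",
        )
    return CarpResult(
        mh=mh, weights=None, separators=None, split=None,
        focal=(i, j), conditioning=layers, table=tab,
    )
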