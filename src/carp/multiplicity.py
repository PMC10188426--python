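"""Screening and Bonferroni aggregation of CARP tests across item pairs.

Testing all ``J(J-1)/2`` pairs with a blanket multiple-testing correction
wastes power when most conditional covariances are positive.  Instead the
*training* sample screens for candidate pairs: the set ``S`` collects the
pairs ``(i, j)``, ``i > j``, whose CARP-layered Mantel-Haenszel numerator
``n_11+ - e+`` (no continuity correction) is negative on the training
subjects.  Because ``S`` is a function of the training sample alone, it is
independent of the test-sample p-values, and rejecting pair ``(i, j)`` iff
``(i, j) in S`` and ``p_ij <= alpha / |S|`` keeps the family-wise error
rate at or below ``alpha``.

Weights and quantile separators for each pair are estimated on the full
training sample and the screening numerator is evaluated on those same
training subjects; the error-rate argument only requires screening to be
independent of the *test* sample, so no inner split is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateScoresError,
    DegenerateTableError,
    InvalidInputError,
    InvalidParameterError,
)
from .mh_core import mantel_haenszel_one_sided, tabulate_layers
from .pair_test import (
    CarpResult,
    assign_layers,
    default_ell,
    fit_pair_regressions,
    predicted_sum,
    quantile_separators,
    split_sample,
)

__all__ = ["ScreeningResult", "ScanResult", "screen_negative_pairs", "bonferroni_decisions", "carp_scan"]


@dataclass(frozen=True)
class ScreeningResult:
    """Training-sample screening outcome.

    ``pairs`` is the screened set ``S`` of ``(i, j)`` with ``i > j`` whose
    training-sample MH numerator is negative; ``statistics`` maps every
    evaluable pair to that numerator; ``degenerate`` lists pairs that could
    not be evaluated (constant scores or fully degenerate table).
    """

    pairs: tuple[tuple[int, int], ...]
    statistics: dict[tuple[int, int], float]
    degenerate: tuple[tuple[int, int], ...] = ()

    @property
    def size(self) -> int:
        return len(self.pairs)


def _pair_numerator(train: np.ndarray, i: int, j: int, m: int) -> float:
    weights = fit_pair_regressions(train, i, j)
    scores = predicted_sum(train, weights)
    seps = quantile_separators(scores, m)
    layers = assign_layers(scores, seps)
    tab = tabulate_layers(train[:, i], train[:, j], layers, seps.m_effective)
    mh = mantel_haenszel_one_sided(tab)
    return mh.n11_plus - mh.e_plus


def screen_negative_pairs(train, m: int = 10) -> ScreeningResult:
    """Collect pairs with a negative training-sample conditional covariance.

    The screening statistic for pair ``(i, j)`` is the Mantel-Haenszel
    numerator ``n_11+ - e+`` (no continuity correction) of the CARP-layered
    table built entirely from the training sample.
    """
    train = np.asarray(train)
    if train.ndim != 2 or train.shape[1] < 3:
        raise InvalidInputError("training matrix must have at least three items")
    n_items = train.shape[1]
    if train.shape[0] < 2 * (n_items + 2):
        raise InvalidParameterError(
            "training sample too small to screen all pairs reliably"
        )
    pairs: list[tuple[int, int]] = []
    stats: dict[tuple[int, int], float] = {}
    degenerate: list[tuple[int, int]] = []
    for i in range(1, n_items):
        for j in range(i):
            try:
                stat = _pair_numerator(train, i, j, m)
            except (DegenerateScoresError, DegenerateTableError):
                degenerate.append((i, j))
                continue
            stats[(i, j)] = stat
            if stat < 0:
                pairs.append((i, j))
    return ScreeningResult(
        pairs=tuple(pairs), statistics=stats, degenerate=tuple(degenerate)
    )


def bonferroni_decisions(
    p_values: dict[tuple[int, int], float],
    screening: ScreeningResult,
    alpha: float,
) -> dict[tuple[int, int], bool]:
    """Reject pair ``(i, j)`` iff it was screened and ``p_ij <= alpha / S``.

    Pairs outside the screened set are never rejected; with an empty
    screened set nothing is rejected.  A screened pair missing from
    ``p_values`` is an error.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    missing = [p for p in screening.pairs if p not in p_values]
    if missing:
        raise InvalidInputError(f"missing p-values for screened pairs: {missing}")
    s = screening.size
    decisions = {pair: False for pair in p_values}
    for pair in screening.pairs:
        decisions[pair] = p_values[pair] <= alpha / s
    return decisions


@dataclass(frozen=True)
class ScanResult:
    """Full-scale scan: screening plus Bonferroni-corrected pair tests."""

    screening: ScreeningResult
    results: dict[tuple[int, int], CarpResult]
    p_values: dict[tuple[int, int], float]
    decisions: dict[tuple[int, int], bool]
    alpha: float
    no_decision: tuple[tuple[int, int], ...] = field(default=())

    @property
    def any_rejection(self) -> bool:
        return any(self.decisions.values())


def carp_scan(x, ell: float | None = None, m: int = 10, alpha: float = 0.05, seed=0) -> ScanResult:
    """Screen all item pairs on the training half and test the screened set.

    One train/test split serves every pair.  Screened pairs are tested on
    the test sample with the training-estimated weights and separators, and
    the Bonferroni rule ``p <= alpha / S`` is applied.  Screened pairs whose
    test-sample table is degenerate are flagged as no-decisions and counted
    as non-rejections.
    """
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InvalidInputError("response matrix must have at least three items")
    n = x.shape[0]
    if ell is None:
        ell = default_ell(n)
    split = split_sample(n, ell, seed)
    train = x[split.train_indices]
    test = x[split.test_indices]
    screening = screen_negative_pairs(train, m=m)
    results: dict[tuple[int, int], CarpResult] = {}
    p_values: dict[tuple[int, int], float] = {}
    no_decision: list[tuple[int, int]] = []
    for (i, j) in screening.pairs:
        weights = fit_pair_regressions(train, i, j)
        try:
            seps = quantile_separators(predicted_sum(train, weights), m)
            layers = assign_layers(predicted_sum(test, weights), seps)
            tab = tabulate_layers(test[:, i], test[:, j], layers, seps.m_effective)
            mh = mantel_haenszel_one_sided(tab)
        except (DegenerateScoresError, DegenerateTableError):
            results[(i, j)] = CarpResult(
                mh=None, weights=weights, separators=None, split=split,
                focal=(i, j), conditioning=None, failure="degenerate",
            )
            p_values[(i, j)] = 1.0  # conservative placeholder; flagged below
            no_decision.append((i, j))
            continue
        results[(i, j)] = CarpResult(
            mh=mh, weights=weights, separators=seps, split=split,
            focal=(i, j), conditioning=layers, table=tab,
        )
        p_values[(i, j)] = mh.p_value
    decisions = bonferroni_decisions(p_values, screening, alpha)
    for pair in no_decision:
        decisions[pair] = False
    return ScanResult(
        screening=screening,
        results=results,
        p_values=p_values,
        decisions=decisions,
        alpha=alpha,
        no_decision=tuple(no_decision),
    )
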