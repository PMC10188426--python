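"""Simulation of binary item scores under multidimensional logistic latent-trait models.

The data-generating model is the compensatory multidimensional logistic model

    P(X_i = 1 | Theta) = logistic(sum_d alpha_id Theta_d + beta_i),

with ``Theta`` a vector of independent standard-normal latent dimensions,
nonnegative loadings ``alpha_id`` and intercepts ``beta_i`` in logit units.
Item scores are conditionally independent Bernoulli draws given ``Theta``.

Three generators are provided:

* :func:`standard_case_bank` -- the "standard" simple-structure design with
  unit loadings and zero intercepts, in one to three blocks of items;
* :func:`sample_parameter_set` -- randomly drawn parameter sets
  (``beta_i ~ U(-1.5, 1.5)``, nonzero loadings ``~ U(0.5, 2.5)``) for the
  zero-dimensional, unidimensional and two-block designs used in the
  type-I-error and power studies;
* :func:`simulate_responses` -- seeded response matrices for any bank.

The *zero-dimensional* case (all loadings zero, so items are mutually
independent) is the least favorable null for type-I-error studies because
every conditional covariance is exactly zero rather than positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import InvalidParameterError

__all__ = [
    "ItemBank",
    "simulate_responses",
    "standard_case_bank",
    "sample_parameter_set",
]

_MAX_DIMS = 3


@dataclass(frozen=True)
class ItemBank:
    """Item parameters of a multidimensional logistic bank.

    Parameters
    ----------
    loadings
        ``(J, D)`` matrix of nonnegative discrimination parameters
        ``alpha_id``.  A column that is entirely zero does not count as a
        dimension; the zero-dimensional case is represented by an all-zero
        loading matrix.
    intercepts
        Length-``J`` vector of intercepts ``beta_i`` (logit units).
    dim_assignment
        Optional length-``J`` vector of 1-based dimension labels for
        simple-structure banks; when given, each item may load only on its
        assigned dimension.
    """

    loadings: np.ndarray
    intercepts: np.ndarray
    dim_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        loadings = np.array(self.loadings, dtype=float)
        intercepts = np.array(self.intercepts, dtype=float)
        if loadings.ndim != 2:
            raise InvalidParameterError("loadings must be a 2-D (J x D) matrix")
        j, d = loadings.shape
        if j < 1:
            raise InvalidParameterError("bank must contain at least one item")
        if d > _MAX_DIMS:
            raise InvalidParameterError(f"at most {_MAX_DIMS} latent dimensions supported")
        if intercepts.shape != (j,):
            raise InvalidParameterError("intercepts must have one entry per item")
        if not np.all(np.isfinite(loadings)) or not np.all(np.isfinite(intercepts)):
            raise InvalidParameterError("item parameters must be finite")
        if np.any(loadings < 0):
            raise InvalidParameterError("loadings must be nonnegative")
        assignment = self.dim_assignment
        if assignment is not None:
            assignment = np.array(assignment, dtype=int)
            if assignment.shape != (j,):
                raise InvalidParameterError("dim_assignment must have one label per item")
            if np.any((assignment < 1) | (assignment > max(d, 1))):
                raise InvalidParameterError("dim_assignment labels must lie in 1..D")
            off = loadings.copy()
            off[np.arange(j), assignment - 1] = 0.0
            if np.any(off != 0):
                raise InvalidParameterError(
                    "simple-structure bank has loadings outside assigned dimensions"
                )
            assignment.setflags(write=False)
        loadings.setflags(write=False)
        intercepts.setflags(write=False)
        object.__setattr__(self, "loadings", loadings)
        object.__setattr__(self, "intercepts", intercepts)
        object.__setattr__(self, "dim_assignment", assignment)

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_dims(self) -> int:
        """Number of dimensions with at least one nonzero loading."""
        return int(np.sum(np.any(self.loadings != 0, axis=0)))

    def to_json(self) -> str:
        payload = {
            "loadings": self.loadings.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        if self.dim_assignment is not None:
            payload["dim_assignment"] = self.dim_assignment.tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ItemBank":
        payload = json.loads(text)
        return cls(
            loadings=np.asarray(payload["loadings"], dtype=float),
            intercepts=np.asarray(payload["intercepts"], dtype=float),
            dim_assignment=payload.get("dim_assignment"),
        )


def simulate_responses(bank: ItemBank, n_subjects: int, seed) -> np.ndarray:
    """Draw an ``(n_subjects, J)`` binary response matrix from ``bank``.

    Per subject a latent vector is drawn from independent standard normals
    (one component per stored loading column) and item scores are
    conditionally independent Bernoulli draws with logistic probabilities.
    The generator consumes latent draws first, then item draws, in
    subject-major order, so identical ``(bank, n_subjects, seed)`` yield
    bit-identical matrices.
    """
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be at least 1")
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal((n_subjects, bank.loadings.shape[1]))
    prob = expit(theta @ bank.loadings.T + bank.intercepts)
    return (rng.random((n_subjects, bank.n_items)) < prob).astype(np.int8)


def standard_case_bank(j1: int, j2: int, j3: int = 0) -> ItemBank:
    """Simple-structure bank with unit loadings and zero intercepts.

    The first ``j1`` items load 1.0 on dimension 1, the next ``j2`` on
    dimension 2 and the last ``j3`` on dimension 3 (zero-size blocks are
    skipped).  With ``j1 == j2`` and ``j3 == 0`` this is the standard
    two-dimensional case used as the reference design in the power studies.
    """
    counts = (j1, j2, j3)
    if any(c < 0 for c in counts):
        raise InvalidParameterError("block sizes must be nonnegative")
    if sum(counts) < 3:
        raise InvalidParameterError("need at least three items in total")
    nonzero = [c for c in counts if c > 0]
    d = len(nonzero)
    j = sum(counts)
    loadings = np.zeros((j, d))
    assignment = np.empty(j, dtype=int)
    row = 0
    for dim, count in enumerate(nonzero, start=1):
        loadings[row : row + count, dim - 1] = 1.0
        assignment[row : row + count] = dim
        row += count
    return ItemBank(loadings=loadings, intercepts=np.zeros(j), dim_assignment=assignment)


_DESIGN_ALIASES = {
    "zero": "zero",
    "zero-dimensional": "zero",
    "uni": "uni",
    "unidimensional": "uni",
    "two_block": "two_block",
    "two-block": "two_block",
}


def sample_parameter_set(j: int, design: str, seed, j1: int | None = None) -> ItemBank:
    """Randomly drawn item parameters for the Monte-Carlo study designs.

    Intercepts are drawn ``beta_i ~ Uniform(-1.5, 1.5)``; structurally
    nonzero loadings ``~ Uniform(0.5, 2.5)``; structural zeros are exact.

    ``design`` is one of

    * ``"zero"`` -- all loadings zero (mutually independent items);
    * ``"uni"``  -- one dimension, all items loading on it;
    * ``"two_block"`` -- items ``1..j1`` load on dimension 1 only, items
      ``j1+1..J`` on dimension 2 only (``j1`` defaults to ``J // 2``).
    """
    if j < 3:
        raise InvalidParameterError("need at least three items")
    try:
        kind = _DESIGN_ALIASES[design]
    except KeyError:
        raise InvalidParameterError(f"unknown design {design!r}") from None
    rng = np.random.default_rng(seed)
    beta = rng.uniform(-1.5, 1.5, size=j)
    if kind == "zero":
        return ItemBank(loadings=np.zeros((j, 1)), intercepts=beta)
    if kind == "uni":
        alpha = rng.uniform(0.5, 2.5, size=j)
        return ItemBank(
            loadings=alpha[:, None],
            intercepts=beta,
            dim_assignment=np.ones(j, dtype=int),
        )
    j1 = j // 2 if j1 is None else j1
    if not 1 <= j1 < j:
        raise InvalidParameterError("two-block design needs 1 <= j1 < J")
    alpha = rng.uniform(0.5, 2.5, size=j)
    loadings = np.zeros((j, 2))
    loadings[:j1, 0] = alpha[:j1]
    loadings[j1:, 1] = alpha[j1:]
    assignment = np.where(np.arange(j) < j1, 1, 2)
    return ItemBank(loadings=loadings, intercepts=beta, dim_assignment=assignment)
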