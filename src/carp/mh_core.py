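"""Layered 2x2 tables and the one-sided Mantel-Haenszel statistic.

For a focal item pair the test sample is cross-tabulated into a 2x2xm
table ``n_abs`` (``a`` = score on item i, ``b`` = score on item j,
``s`` = conditioning layer).  The null hypothesis is that the covariance
of the pair is nonnegative within every layer; under the least favorable
case (all layer covariances zero) ``n_11+`` has expectation and variance

    e+ = sum_s n_1+s n_+1s / n_++s,
    v+ = sum_s n_1+s n_0+s n_+1s n_+0s / (n_++s^2 (n_++s - 1)),

and the continuity-corrected statistic is

    Z = (n_11+ - e+ + 0.5) / sqrt(v+).

The numerator equals ``sum_s n_++s * cov_hat_s`` (a weighted sum of the
per-layer sample covariances) plus the correction, so very negative ``Z``
signals negative conditional covariance; the one-sided p-value is the
lower tail of the standard normal at ``Z``.

Layers with ``n_++s <= 1`` or with a zero row or column margin contribute
``0/0`` or exactly zero to both the numerator and the variance; they carry
no information about the layer covariance and are excluded from all three
sums (``layers_used`` records what remains).  Keeping zero-margin layers
with ``n_++s >= 2`` would change none of the sums.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import DegenerateTableError, InvalidInputError

__all__ = ["LayerCounts", "MHResult", "tabulate_layers", "mantel_haenszel_one_sided"]


@dataclass(frozen=True)
class LayerCounts:
    """A 2x2xm table of subject counts; ``counts[a, b, s-1] = n_abs``."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.array(self.counts, dtype=np.int64)
        if counts.ndim != 3 or counts.shape[:2] != (2, 2) or counts.shape[2] < 1:
            raise InvalidInputError("counts must have shape (2, 2, m) with m >= 1")
        if np.any(counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def m(self) -> int:
        return self.counts.shape[2]

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def swap_focal(self) -> "LayerCounts":
        """Transpose the roles of the two focal items in every layer."""
        return LayerCounts(self.counts.transpose(1, 0, 2))

    def to_long_frame(self) -> pd.DataFrame:
        a, b, s = np.meshgrid(range(2), range(2), range(1, self.m + 1), indexing="ij")
        return pd.DataFrame(
            {
                "a": a.ravel(),
                "b": b.ravel(),
                "s": s.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass(frozen=True)
class MHResult:
    """One-sided Mantel-Haenszel test result for a layered 2x2 table.

    ``layer_covariances[s-1]`` is the sample covariance of the focal pair
    inside layer ``s`` (NaN for empty layers); ``layers_used`` counts the
    non-degenerate layers entering ``e_plus``, ``v_plus`` and ``n11_plus``.
    """

    z: float
    p_value: float
    e_plus: float
    v_plus: float
    n11_plus: int
    layer_covariances: np.ndarray
    layers_used: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "z": self.z,
                "p_value": self.p_value,
                "e_plus": self.e_plus,
                "v_plus": self.v_plus,
                "n11_plus": self.n11_plus,
                "layer_covariances": self.layer_covariances.tolist(),
                "layers_used": self.layers_used,
            }
        )


def tabulate_layers(x_i, x_j, layer, m: int) -> LayerCounts:
    """Cross-tabulate two binary vectors within layers ``1..m``."""
    x_i = np.asarray(x_i)
    x_j = np.asarray(x_j)
    layer = np.asarray(layer)
    if not (x_i.shape == x_j.shape == layer.shape) or x_i.ndim != 1:
        raise InvalidInputError("x_i, x_j and layer must be equal-length vectors")
    if m < 1:
        raise InvalidInputError("m must be at least 1")
    for name, v in (("x_i", x_i), ("x_j", x_j)):
        if not np.isin(v, (0, 1)).all():
            raise InvalidInputError(f"{name} must be binary")
    if x_i.size and (layer.min() < 1 or layer.max() > m):
        raise InvalidInputError("layer labels must lie in 1..m")
    code = (x_i.astype(np.int64) * 2 + x_j) * m + (layer - 1)
    counts = np.bincount(code, minlength=4 * m).reshape(2, 2, m)
    return LayerCounts(counts)


def mantel_haenszel_one_sided(tab: LayerCounts) -> MHResult:
    """One-sided Mantel-Haenszel test of nonnegative covariance in every layer.

    Raises
    ------
    DegenerateTableError
        If every layer is degenerate (``v_plus`` would be zero).
    """
    n = tab.counts.astype(float)
    n11 = n[1, 1]
    n1p = n[1, 0] + n[1, 1]
    np1 = n[0, 1] + n[1, 1]
    npp = n.sum(axis=(0, 1))
    n0p = npp - n1p
    np0 = npp - np1

    with np.errstate(divide="ignore", invalid="ignore"):
        covs = np.where(npp > 0, n11 / npp - (n1p / npp) * (np1 / npp), np.nan)
    covs = np.asarray(covs)
    covs.setflags(write=False)

    used = (npp >= 2) & (n1p > 0) & (n0p > 0) & (np1 > 0) & (np0 > 0)
    layers_used = int(used.sum())
    if layers_used == 0:
        raise DegenerateTableError(layers_used=0)

    e_plus = float(np.sum(n1p[used] * np1[used] / npp[used]))
    v_plus = float(
        np.sum(
            n1p[used] * n0p[used] * np1[used] * np0[used]
            / (npp[used] ** 2 * (npp[used] - 1.0))
        )
    )
    n11_plus = int(n11[used].sum())
    z = (n11_plus - e_plus + 0.5) / np.sqrt(v_plus)
    return MHResult(
        z=float(z),
        p_value=float(norm.cdf(z)),
        e_plus=e_plus,
        v_plus=v_plus,
        n11_plus=n11_plus,
        layer_covariances=covs,
        layers_used=layers_used,
    )
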