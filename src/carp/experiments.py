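"""Seeded Monte-Carlo harness for type-I-error, power and training-fraction studies.

Each study draws per-replicate seeds from one root generator up front, so
results are reproducible and independent of execution order.  Rejection is
``p < alpha`` one-sided; no-decision outcomes count as non-rejections and
are tallied separately.  Monte-Carlo standard errors use the binomial
formula ``sqrt(r (1 - r) / R)``.

Default scales are scaled-down presets of the full study grids (hundreds of
replicates and tens of parameter sets rather than thousands); the printed
standard errors quantify the resulting Monte-Carlo uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, NoMaximumError
from .irt_sim import ItemBank, sample_parameter_set, simulate_responses, standard_case_bank
from .pair_test import carp_pair_test, crs_pair_test

__all__ = [
    "StudyConfig",
    "RejectionTable",
    "type1_study",
    "randomized_type1_study",
    "power_study",
    "ell_sweep",
    "optimal_ell",
]

_SEED_CAP = 2**31


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one Monte-Carlo study.

    ``design`` is ``"zero"`` or ``"uni"`` for type-I studies (with ``j``
    items) or ``"standard"`` for power studies (with ``blocks`` giving the
    simple-structure block sizes).  ``focal`` defaults to items (0, 1) for
    type-I designs and to the first items of blocks 1 and 2 for power
    designs.
    """

    design: str
    n: int
    replicates: int
    j: int | None = None
    blocks: tuple[int, int, int] | None = None
    ell: float | None = None
    m: int = 10
    parameter_sets: int = 1
    alpha: float = 0.05
    seed: int = 0
    focal: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be at least 1")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.design in ("zero", "uni"):
            if self.j is None:
                raise InvalidParameterError("type-I designs need j")
        elif self.design == "standard":
            if self.blocks is None:
                raise InvalidParameterError("power designs need block sizes")
        else:
            raise InvalidParameterError(f"unknown design {self.design!r}")


@dataclass(frozen=True)
class RejectionTable:
    """Per-configuration rejection rates with Monte-Carlo standard errors."""

    per_config: pd.DataFrame
    alpha: float

    def summary(self, column: str = "rate") -> dict[str, float]:
        """Mean and five-number summary of a rate column across configurations."""
        r = self.per_config[column]
        q = r.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        return {
            "mean": float(r.mean()),
            "min": float(q.iloc[0]),
            "q1": float(q.iloc[1]),
            "median": float(q.iloc[2]),
            "q3": float(q.iloc[3]),
            "max": float(q.iloc[4]),
        }


def _mc_se(rate: float, n: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / n))


def _replicate_rates(bank: ItemBank, cfg: StudyConfig, focal, seeds, crs: bool):
    """Rejection tallies for one parameter set; returns dict of counters."""
    i, j = focal
    carp_rej = crs_rej = no_dec = 0
    for sim_seed, split_seed in seeds:
        x = simulate_responses(bank, cfg.n, int(sim_seed))
        res = carp_pair_test(x, i, j, ell=cfg.ell, m=cfg.m, seed=int(split_seed))
        if res.mh is None:
            no_dec += 1
        elif res.mh.p_value < cfg.alpha:
            carp_rej += 1
        if crs:
            cres = crs_pair_test(x, i, j)
            if cres.mh is not None and cres.mh.p_value < cfg.alpha:
                crs_rej += 1
    return carp_rej, crs_rej, no_dec


def type1_study(cfg: StudyConfig) -> RejectionTable:
    """Rejection rates under zero- or unidimensional (MH-satisfying) designs.

    Draws ``cfg.parameter_sets`` random parameter sets, runs
    ``cfg.replicates`` simulated samples each through the CARP test on a
    fixed focal pair, and reports one row per parameter set.
    """
    if cfg.design not in ("zero", "uni"):
        raise InvalidParameterError("type1_study needs a zero or uni design")
    focal = cfg.focal or (0, 1)
    root = np.random.default_rng(cfg.seed)
    rows = []
    for s in range(cfg.parameter_sets):
        bank_seed = int(root.integers(_SEED_CAP))
        seeds = root.integers(_SEED_CAP, size=(cfg.replicates, 2))
        bank = sample_parameter_set(cfg.j, cfg.design, bank_seed)
        rej, _, no_dec = _replicate_rates(bank, cfg, focal, seeds, crs=False)
        rate = rej / cfg.replicates
        rows.append(
            {
                "design": cfg.design,
                "j": cfg.j,
                "n": cfg.n,
                "ell": cfg.ell,
                "parameter_set": s,
                "replicates": cfg.replicates,
                "rate": rate,
                "se": _mc_se(rate, cfg.replicates),
                "no_decision": no_dec,
            }
        )
    return RejectionTable(per_config=pd.DataFrame(rows), alpha=cfg.alpha)


def randomized_type1_study(
    n_configs: int,
    replicates: int,
    seed: int = 0,
    ell_range: tuple[float, float] = (0.2, 0.5),
    n_range: tuple[int, int] = (500, 1000),
    j_range: tuple[int, int] = (10, 50),
    design: str = "zero",
    alpha: float = 0.05,
    m: int = 10,
) -> RejectionTable:
    """Type-I study with ``ell``, ``N`` and ``J`` themselves drawn uniformly.

    Each configuration draws ``ell ~ U(ell_range)``, integer ``N`` and ``J``
    uniformly on their ranges, one random parameter set, and
    ``replicates`` simulated samples.
    """
    root = np.random.default_rng(seed)
    rows = []
    for c in range(n_configs):
        ell = float(root.uniform(*ell_range))
        n = int(root.integers(n_range[0], n_range[1] + 1))
        j = int(root.integers(j_range[0], j_range[1] + 1))
        bank_seed = int(root.integers(_SEED_CAP))
        seeds = root.integers(_SEED_CAP, size=(replicates, 2))
        cfg = StudyConfig(
            design=design, n=n, j=j, ell=ell, m=m,
            replicates=replicates, alpha=alpha, seed=0,
        )
        bank = sample_parameter_set(j, design, bank_seed)
        rej, _, no_dec = _replicate_rates(bank, cfg, (0, 1), seeds, crs=False)
        rate = rej / replicates
        rows.append(
            {
                "design": design, "j": j, "n": n, "ell": ell,
                "parameter_set": c, "replicates": replicates,
                "rate": rate, "se": _mc_se(rate, replicates),
                "no_decision": no_dec,
            }
        )
    return RejectionTable(per_config=pd.DataFrame(rows), alpha=alpha)


def power_study(cfg: StudyConfig) -> RejectionTable:
    """CARP and CRS rejection rates under a standard multi-block design.

    The focal pair defaults to the first item of block 1 and the first item
    of block 2 (items within a block are exchangeable in these designs).
    """
    if cfg.design != "standard":
        raise InvalidParameterError("power_study needs the standard design")
    j1, j2, j3 = cfg.blocks
    bank = standard_case_bank(j1, j2, j3)
    focal = cfg.focal or (0, j1)
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(_SEED_CAP, size=(cfg.replicates, 2))
    carp_rej, crs_rej, no_dec = _replicate_rates(bank, cfg, focal, seeds, crs=True)
    carp_rate = carp_rej / cfg.replicates
    crs_rate = crs_rej / cfg.replicates
    row = {
        "blocks": [cfg.blocks],
        "j": bank.n_items,
        "n": cfg.n,
        "ell": cfg.ell,
        "replicates": cfg.replicates,
        "rate": carp_rate,
        "se": _mc_se(carp_rate, cfg.replicates),
        "crs_rate": crs_rate,
        "crs_se": _mc_se(crs_rate, cfg.replicates),
        "no_decision": no_dec,
    }
    return RejectionTable(per_config=pd.DataFrame(row), alpha=cfg.alpha)


def ell_sweep(
    blocks: tuple[int, int, int],
    n: int,
    ells,
    replicates: int,
    seed: int = 0,
    m: int = 10,
    alpha: float = 0.05,
) -> dict[float, float]:
    """CARP power across a grid of training fractions (input to :func:`optimal_ell`)."""
    powers = {}
    for k, ell in enumerate(ells):
        cfg = StudyConfig(
            design="standard", blocks=blocks, n=n, ell=float(ell), m=m,
            replicates=replicates, alpha=alpha, seed=seed + k,
        )
        powers[float(ell)] = float(power_study(cfg).per_config["rate"].iloc[0])
    return powers


def optimal_ell(power_by_ell: dict[float, float]) -> float:
    """Vertex of a quadratic fit of power on the training fraction.

    Fits ``power = a + b*ell + c*ell^2`` by least squares over at least
    three distinct ``ell`` values and returns ``-b / (2c)``.  Raises
    :class:`NoMaximumError` for a convex (or flat) fit or a vertex outside
    ``(0, 1)`` rather than silently clipping.
    """
    ells = np.asarray(list(power_by_ell.keys()), dtype=float)
    powers = np.asarray(list(power_by_ell.values()), dtype=float)
    if np.unique(ells).size < 3:
        raise InvalidParameterError("need at least three distinct ell values")
    c2, c1, _ = np.polyfit(ells, powers, 2)
    if c2 >= 0:
        raise NoMaximumError("quadratic fit is convex; no interior maximum")
    vertex = -c1 / (2.0 * c2)
    if not 0.0 < vertex < 1.0:
        raise NoMaximumError(f"vertex {vertex:.3f} lies outside (0, 1)")
    return float(vertex)
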