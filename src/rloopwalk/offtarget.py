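"""Off-target prediction surfaces from the random-walk model.

Given a fitted parameter set, the model predicts the mean locked-R-loop
formation time for any mismatch configuration and torque.  This module
produces the derived quantities used to reason about off-targeting:

* single-mismatch position scans of the relative formation time
  ``T_MM / T_WT``,
* the torque-dependent seed length (PAM-proximal extent over which a
  single mismatch slows formation at least 10-fold),
* double-mismatch matrices comparing the full random-walk prediction with
  a penalty-addition comparator that composes single-mismatch
  fold-changes multiplicatively (adding apparent free-energy penalties),
* the torque corresponding to physiological supercoiling densities in
  *E. coli*, from the twist-partitioned supercoiling of a semiflexible
  polymer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .first_passage import formation_time
from .landscape import (
    DEFAULT_EXCLUDED_POSITIONS,
    ModelParams,
    PhysicalConstants,
    TargetSpec,
)

__all__ = [
    "SupercoilingContext",
    "PredictionGrid",
    "position_scan",
    "seed_length",
    "double_mismatch_matrix",
    "ecoli_torque",
]


@dataclass(frozen=True)
class SupercoilingContext:
    """Supercoiling state of genomic DNA.

    ``sigma`` is the superhelical density; only the fraction
    ``twist_fraction`` (default 0.2, the twist share of plasmid
    supercoiling) stresses the helix as twist.  ``p_tor`` is the torsional
    persistence length (nm) and ``h`` the helical pitch of B-DNA (nm).
    """

    sigma: float
    twist_fraction: float = 0.2
    p_tor: float = 100.0
    h: float = 3.5

    def __post_init__(self) -> None:
        if not 0 < self.twist_fraction <= 1:
            raise ValueError("twist_fraction must be in (0, 1]")
        if self.p_tor <= 0 or self.h <= 0:
            raise ValueError("p_tor and h must be positive")


@dataclass
class PredictionGrid:
    """Relative formation times ``T_MM / T_WT`` over positions/torques."""

    values: pd.DataFrame
    model: str  # "random-walk" | "penalty-addition"
    torque: float | None = None
    penalty: float | None = None

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def position_scan(penalty: float, params: ModelParams, torques,
                  hybrid_length: int = 32,
                  excluded=DEFAULT_EXCLUDED_POSITIONS) -> PredictionGrid:
    """Relative formation time of a single mismatch at every position.

    Rows are positions 1..hybrid_length, columns the requested torques.
    Excluded positions carry no penalty and get ratio 1 exactly.
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    torques = list(np.atleast_1d(torques).astype(float))
    wt = TargetSpec.wild_type(hybrid_length=hybrid_length,
                              excluded_positions=excluded)
    out = pd.DataFrame(index=pd.Index(range(1, hybrid_length + 1),
                                      name="position"),
                       columns=pd.Index(torques, name="torque"),
                       dtype=float)
    for tau in torques:
        t_wt = formation_time(wt, params, tau)
        for pos in range(1, hybrid_length + 1):
            if pos in excluded or penalty == 0.0:
                out.loc[pos, tau] = 1.0
                continue
            t = TargetSpec.single_mismatch(pos, penalty,
                                           hybrid_length=hybrid_length,
                                           excluded_positions=excluded)
            out.loc[pos, tau] = formation_time(t, params, tau) / t_wt
    return PredictionGrid(values=out, model="random-walk", penalty=penalty)


def seed_length(ratios: pd.Series, threshold: float = 10.0,
                excluded=DEFAULT_EXCLUDED_POSITIONS) -> int:
    """Seed extent from a single-torque position scan.

    The largest position p such that every penalized position <= p slows
    formation at least ``threshold``-fold; excluded positions do not break
    the contiguity.  Returns 0 when even the first penalized position is
    below threshold.
    """
    seed = 0
    for pos in sorted(ratios.index):
        if pos in excluded:
            seed = pos if seed == pos - 1 else seed
            continue
        if ratios.loc[pos] >= threshold:
            seed = pos
        else:
            break
    return int(seed)


def count_seed_positions(ratios: pd.Series, threshold: float = 10.0,
                         excluded=DEFAULT_EXCLUDED_POSITIONS) -> int:
    """Alternative readout: total count of penalized positions at or above
    the threshold (sensitivity check for the contiguity rule)."""
    n = 0
    for pos in sorted(ratios.index):
        if pos in excluded:
            continue
        if ratios.loc[pos] >= threshold:
            n += 1
    return n


def double_mismatch_matrix(penalty: float, params: ModelParams, torque: float,
                           model: str = "random-walk",
                           hybrid_length: int = 32,
                           excluded=DEFAULT_EXCLUDED_POSITIONS) -> PredictionGrid:
    """Relative formation time for every ordered pair of mismatch positions.

    ``"random-walk"`` solves the first-passage problem on the
    two-mismatch chain; ``"penalty-addition"`` composes the two
    single-mismatch fold-changes multiplicatively (equivalent to adding
    apparent free-energy penalties), which by construction carries no
    proximity dependence.  Pairs with one excluded position reduce exactly
    to the single-mismatch value; the diagonal is the single-mismatch
    case.
    """
    if model not in ("random-walk", "penalty-addition"):
        raise ValueError(f"unknown model {model!r}")
    positions = range(1, hybrid_length + 1)
    single = position_scan(penalty, params, [torque],
                           hybrid_length=hybrid_length,
                           excluded=excluded).values[float(torque)]
    out = pd.DataFrame(index=pd.Index(positions, name="first"),
                       columns=pd.Index(positions, name="second"), dtype=float)
    if model == "penalty-addition":
        for i in positions:
            for j in positions:
                out.loc[i, j] = single[i] if i == j else single[i] * single[j]
        return PredictionGrid(values=out, model=model, torque=torque,
                              penalty=penalty)
    wt = TargetSpec.wild_type(hybrid_length=hybrid_length,
                              excluded_positions=excluded)
    t_wt = formation_time(wt, params, torque)
    cache: dict = {}
    for i in positions:
        for j in positions:
            key = frozenset((i, j)) - frozenset(excluded)
            if key not in cache:
                mms = tuple((p, penalty) for p in sorted(key))
                if not mms:
                    cache[key] = 1.0
                else:
                    t = TargetSpec(hybrid_length=hybrid_length, mismatches=mms,
                                   excluded_positions=excluded)
                    cache[key] = formation_time(t, params, torque) / t_wt
            out.loc[i, j] = cache[key]
    return PredictionGrid(values=out, model=model, torque=torque,
                          penalty=penalty)


def ecoli_torque(ctx: SupercoilingContext,
                 constants: PhysicalConstants | None = None) -> float:
    """Torque (pN nm) on chromosomal DNA at superhelical density sigma.

    Only the twist share of the supercoiling stresses the helix:
    ``tau = (kBT p_tor / h) 2 pi (twist_fraction * sigma)``.  With the
    defaults, physiological sigma between -0.06 and -0.029 maps to
    torques between about -8.9 and -4.3 pN nm.
    """
    constants = constants or PhysicalConstants()
    sigma_tw = ctx.twist_fraction * ctx.sigma
    return (constants.kBT_pNnm * ctx.p_tor / ctx.h) * 2.0 * np.pi * sigma_tw
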