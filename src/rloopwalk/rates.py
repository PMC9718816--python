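"""Detailed-balance rate chains over the R-loop length coordinate.

A :class:`RateChain` is the birth-death chain of single-bp stepping rates
obtained from a free-energy landscape.  The construction rules are:

* all transitions share one unbiased stepping rate ``k_step`` (no sequence
  dependence of the kinetic barriers),
* initiation 0 -> 1 is slowed by the full concentration-adjusted
  initiation penalty (``k+ = k_step * exp(-dG_ini)``),
* at a penalized mismatch the forward step keeps the plain stepping rate
  (the rate-limiting event is DNA base-pair disruption) and detailed
  balance puts the whole penalty on the backward rate
  (``k- = k_step * exp(+dG_MM)``),
* the per-bp bias (intrinsic + torque work) is split half onto the forward
  and half onto the backward rate of every step, the transition barrier
  being centered between adjacent R-loop positions.

Detailed balance ``k+[n] / k-[n+1] = exp(-(G_{n+1} - G_n))`` holds at every
step by construction, in every mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import (
    Landscape,
    ModelParams,
    TargetSpec,
    concentration_adjusted_dG_ini,
    total_bias_per_bp,
)

__all__ = ["RateChain", "landscape_to_rates", "verify_detailed_balance"]


class ChainStructureError(ValueError):
    """Landscape / target / chain shapes are inconsistent."""


@dataclass(frozen=True)
class RateChain:
    """Forward/backward rate arrays of the R-loop birth-death chain.

    ``up[n]`` is the rate of the step ``n -> n+1`` and ``down[n]`` the rate
    of ``n+1 -> n``, both for ``n = 0..N_eff-1`` (step-aligned storage).
    ``k_plus`` / ``k_minus`` expose the position-indexed view used in the
    text export: ``k_plus[n] = up[n]`` and ``k_minus[n] = down[n-1]``.
    """

    up: np.ndarray
    down: np.ndarray
    torque: float
    absorbing_top: bool

    def __post_init__(self) -> None:
        if len(self.up) != len(self.down):
            raise ChainStructureError("up/down arrays must have equal length")
        if not (np.all(np.isfinite(self.up)) and np.all(self.up > 0)
                and np.all(np.isfinite(self.down)) and np.all(self.down > 0)):
            raise ChainStructureError("all rates must be positive and finite")

    @property
    def n_states(self) -> int:
        """Number of microstates 0..N_eff."""
        return len(self.up) + 1

    @property
    def n_top(self) -> int:
        return len(self.up)

    def k_plus(self, n: int) -> float:
        """Rate of the step ``n -> n+1``."""
        return float(self.up[n])

    def k_minus(self, n: int) -> float:
        """Rate of the step ``n -> n-1`` (defined for n >= 1)."""
        return float(self.down[n - 1])

    def to_text(self, path) -> None:
        """Write as three-column text (n, k_plus, k_minus); nan where a
        rate does not exist (k_plus at the top, k_minus at 0)."""
        n = np.arange(self.n_states)
        kp = np.append(self.up, np.nan)
        km = np.insert(self.down, 0, np.nan)
        np.savetxt(path, np.column_stack([n, kp, km]),
                   header="n k_plus_per_s k_minus_per_s",
                   fmt=["%d", "%.10g", "%.10g"])


def landscape_to_rates(landscape: Landscape, target: TargetSpec,
                       params: ModelParams, *,
                       torque_on_initiation: bool = True) -> RateChain:
    """Convert a landscape into the forward/backward stepping rates.

    Parameters
    ----------
    torque_on_initiation : bool
        If True (default), the half-bias factor multiplies the initiation
        rate like any other forward rate.  If False, initiation is
        bias-free and the full bias factor moves onto the collapse rate
        1 -> 0, preserving detailed balance.
    """
    n_eff = target.n_eff
    if landscape.n_eff != n_eff or len(landscape.energies) != n_eff + 1:
        raise ChainStructureError(
            f"landscape has {landscape.n_eff + 1} states but target implies "
            f"{n_eff + 1}"
        )
    k = params.k_step
    bias = total_bias_per_bp(params, landscape.torque)
    fwd_half = np.exp(-bias / 2.0)
    bwd_half = np.exp(+bias / 2.0)

    up = np.full(n_eff, k * fwd_half)
    down = np.full(n_eff, k * bwd_half)

    dG_ini = concentration_adjusted_dG_ini(params)
    if torque_on_initiation:
        up[0] = k * np.exp(-dG_ini) * fwd_half
    else:
        up[0] = k * np.exp(-dG_ini)
        down[0] = k * np.exp(+bias)

    for p, g in target.penalized_mismatches():
        # backward rate of the step p -> p-1 carries the whole penalty
        down[p - 1] *= np.exp(g)

    return RateChain(up=up, down=down, torque=landscape.torque,
                     absorbing_top=target.lock_competent)


def verify_detailed_balance(chain: RateChain, landscape: Landscape,
                            rtol: float = 1e-10):
    """Check ``k+[n]/k-[n+1] = exp(-(G_{n+1} - G_n))`` at every step.

    Returns ``(ok, max_deviation, worst_step)`` where the deviation is the
    relative error of the identity and ``worst_step`` the offending ``n``.
    """
    if chain.n_states != landscape.n_eff + 1:
        raise ChainStructureError("chain and landscape lengths differ")
    dG = np.diff(landscape.energies)
    ratio = chain.up / chain.down
    dev = np.abs(ratio * np.exp(dG) - 1.0)
    worst = int(np.argmax(dev))
    return bool(dev[worst] <= rtol), float(dev[worst]), worst
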