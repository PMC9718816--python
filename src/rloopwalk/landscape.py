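"""Free-energy landscapes for R-loop formation.

The R-loop length ``n`` (number of formed crRNA-DNA hybrid base pairs,
counted from the PAM) is the one-dimensional reaction coordinate.  A
landscape assigns a free energy ``G_n`` (in units of k_BT) to every
microstate ``n = 0..N_eff``, built from four ingredients:

* an initiation penalty ``dG_ini`` paid at the first base pair, shifted by
  the chemical potential of the effector complex concentration,
* a uniform per-bp bias composed of an intrinsic (zero-torque) term and the
  mechanical work ``tau * dphi_bp`` done against the applied torque,
* local mismatch penalties that raise every state at and beyond the
  mismatched position,
* an optional locked state below the full-length R-loop (treated as
  absorbing by the rate chain; its depth never enters any rate).

Targets with a continuous PAM-distal mismatch stretch are cut off at the
first mismatch of the stretch (infinite free energy there), which removes
the locked state and caps the chain at ``N_eff = distal_cutoff - 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "PhysicalConstants",
    "TargetSpec",
    "ModelParams",
    "Landscape",
    "total_bias_per_bp",
    "concentration_adjusted_dG_ini",
    "build_landscape",
    "DEFAULT_EXCLUDED_POSITIONS",
    "CASCADE_HYBRID_LENGTH",
]

#: Positions along the 32-bp Cascade hybrid where base pairing is disrupted
#: every 6th bp by the Cas7 backbone; mismatches there carry no penalty.
DEFAULT_EXCLUDED_POSITIONS = frozenset({6, 12, 18, 24, 30})

#: Full protospacer length of the Cascade crRNA-DNA hybrid.
CASCADE_HYBRID_LENGTH = 32


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraints."""


class InvalidTargetError(ValueError):
    """A target specification is internally inconsistent."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermal energy and DNA untwisting geometry.

    Parameters
    ----------
    kBT_pNnm : float
        Thermal energy in pN nm.  Default 4.114 pN nm (25 degC).
    dphi_bp : float
        Untwisting angle of the DNA per bp of R-loop, radians.  Fixed model
        constant 0.515 rad (29.5 deg).
    """

    kBT_pNnm: float = 4.114
    dphi_bp: float = 0.515

    def __post_init__(self) -> None:
        if not self.kBT_pNnm > 0:
            raise InvalidParameterError("kBT_pNnm must be positive")
        if not self.dphi_bp > 0:
            raise InvalidParameterError("dphi_bp must be positive")


@dataclass(frozen=True)
class TargetSpec:
    """A DNA target as seen by the model.

    Parameters
    ----------
    hybrid_length : int
        Full protospacer length (32 bp for Cascade).
    mismatches : tuple of (position, penalty)
        1-based positions counted from the PAM with mismatch penalties in
        k_BT.  A mismatch at an excluded position contributes zero penalty.
    distal_cutoff : int or None
        1-based position of the first base of a continuous PAM-distal
        mismatch stretch.  If set, the chain ends at ``distal_cutoff - 1``
        and the target cannot lock.
    lock_competent : bool
        Whether full-length R-loop formation triggers the locking
        transition (state F).  Forced False when ``distal_cutoff`` is set.
    excluded_positions : frozenset of int
        Positions with forced zero penalty (disrupted hybrid base pairing).
    """

    hybrid_length: int = CASCADE_HYBRID_LENGTH
    mismatches: tuple[tuple[int, float], ...] = ()
    distal_cutoff: int | None = None
    lock_competent: bool = True
    excluded_positions: frozenset[int] = DEFAULT_EXCLUDED_POSITIONS

    def __post_init__(self) -> None:
        if self.hybrid_length < 1:
            raise InvalidTargetError("hybrid_length must be >= 1")
        mms = tuple((int(p), float(g)) for p, g in self.mismatches)
        object.__setattr__(self, "mismatches", mms)
        positions = [p for p, _ in mms]
        if len(set(positions)) != len(positions):
            raise InvalidTargetError("mismatch positions must be unique")
        for p, _ in mms:
            if not 1 <= p <= self.hybrid_length:
                raise InvalidTargetError(
                    f"mismatch position {p} outside 1..{self.hybrid_length}"
                )
        if self.distal_cutoff is not None:
            if self.distal_cutoff <= 1:
                raise InvalidTargetError("distal_cutoff must be > 1")
            if self.distal_cutoff > self.hybrid_length + 1:
                raise InvalidTargetError("distal_cutoff beyond hybrid length")
            # a cut-off target can never reach the locked state
            object.__setattr__(self, "lock_competent", False)
        object.__setattr__(
            self, "excluded_positions", frozenset(self.excluded_positions)
        )

    @property
    def n_eff(self) -> int:
        """Last reachable microstate of the chain."""
        if self.distal_cutoff is not None:
            return self.distal_cutoff - 1
        return self.hybrid_length

    def penalized_mismatches(self) -> tuple[tuple[int, float], ...]:
        """Mismatches that actually contribute a penalty, sorted by position.

        Excluded positions and positions beyond the cut-off are dropped
        (the latter with a warning: they are unreachable).
        """
        out = []
        for p, g in sorted(self.mismatches):
            if p > self.n_eff:
                warnings.warn(
                    f"mismatch at position {p} lies beyond the effective chain "
                    f"end {self.n_eff} and is ignored",
                    stacklevel=2,
                )
                continue
            if p in self.excluded_positions or g == 0.0:
                continue
            out.append((p, g))
        return tuple(out)

    # -- convenience constructors ------------------------------------------

    @classmethod
    def matched(cls, length: int, hybrid_length: int = CASCADE_HYBRID_LENGTH,
                **kw) -> "TargetSpec":
        """Intermediate-only target: ``length`` matching PAM-proximal bases
        followed by a continuous mismatch stretch (no locking)."""
        return cls(hybrid_length=hybrid_length, distal_cutoff=length + 1, **kw)

    @classmethod
    def single_mismatch(cls, position: int, penalty: float,
                        distal_cutoff: int | None = None, **kw) -> "TargetSpec":
        """Target with one internal mismatch (and optionally a PAM-distal
        mismatch stretch that prevents locking)."""
        return cls(mismatches=((position, penalty),),
                   distal_cutoff=distal_cutoff, **kw)

    @classmethod
    def wild_type(cls, **kw) -> "TargetSpec":
        """Fully matching, lock-competent target."""
        return cls(**kw)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hybrid_length": self.hybrid_length,
            "mismatches": [[p, g] for p, g in self.mismatches],
            "distal_cutoff": self.distal_cutoff,
            "lock_competent": self.lock_competent,
            "excluded_positions": sorted(self.excluded_positions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSpec":
        d = dict(d)
        d["mismatches"] = tuple((p, g) for p, g in d.get("mismatches", ()))
        d["excluded_positions"] = frozenset(
            d.get("excluded_positions", DEFAULT_EXCLUDED_POSITIONS)
        )
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TargetSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and thermodynamic parameters of the random-walk model.

    Defaults correspond to the global fit of locked-R-loop formation times
    on single-mismatch targets (initiation penalty 8.5 k_BT at the
    reference concentration, stepping rate 2000 /s, intrinsic upward bias
    0.14 k_BT per bp).

    ``dG_lock`` is the free-energy drop of the locking transition; it makes
    the locked state effectively absorbing on the experimental timescale
    and never enters any rate.
    """

    k_step: float = 2000.0
    dG_ini: float = 8.5
    dG_bias_intrinsic: float = 0.14
    dG_lock: float = 10.0
    concentration: float = 0.5e-9
    c0: float = 0.5e-9
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if not self.k_step > 0:
            raise InvalidParameterError("k_step must be positive")
        if self.dG_lock < 0:
            raise InvalidParameterError("dG_lock must be non-negative")
        if not self.concentration > 0 or not self.c0 > 0:
            raise InvalidParameterError("concentrations must be positive")

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "k_step": self.k_step,
            "dG_ini": self.dG_ini,
            "dG_bias_intrinsic": self.dG_bias_intrinsic,
            "dG_lock": self.dG_lock,
            "concentration": self.concentration,
            "c0": self.c0,
            "kBT_pNnm": self.constants.kBT_pNnm,
            "dphi_bp": self.constants.dphi_bp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        const = PhysicalConstants(
            kBT_pNnm=d.pop("kBT_pNnm", 4.114),
            dphi_bp=d.pop("dphi_bp", 0.515),
        )
        return cls(constants=const, **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class Landscape:
    """Free energies ``G_n`` (k_BT) for ``n = 0..N_eff`` with ``G_0 = 0``."""

    energies: np.ndarray
    n_eff: int
    mismatch_steps: tuple[int, ...]
    torque: float
    locked_energy: float | None = None

    @property
    def G(self) -> np.ndarray:
        return self.energies

    def to_text(self, path) -> None:
        """Write as two-column text (n, G_n in k_BT)."""
        np.savetxt(path, np.column_stack([np.arange(self.n_eff + 1),
                                          self.energies]),
                   header="n G_kBT", fmt=["%d", "%.10g"])


def total_bias_per_bp(params: ModelParams, torque: float) -> float:
    """Net free-energy bias per bp of R-loop expansion, in k_BT.

    Sum of the intrinsic (zero-torque) bias and the work done against the
    applied torque, ``tau * dphi_bp / kBT``.  Negative torque (negative
    supercoiling) gives a negative, i.e. downhill, contribution.
    """
    c = params.constants
    return params.dG_bias_intrinsic + torque * c.dphi_bp / c.kBT_pNnm


def concentration_adjusted_dG_ini(params: ModelParams) -> float:
    """Initiation penalty at the working concentration, in k_BT.

    The chemical potential of the effector complexes shifts the standard
    initiation penalty by ``-ln(c / c0)``.
    """
    if not params.concentration > 0:
        raise InvalidParameterError("concentration must be positive")
    return params.dG_ini - math.log(params.concentration / params.c0)


def build_landscape(target: TargetSpec, params: ModelParams,
                    torque: float = 0.0) -> Landscape:
    """Construct the free-energy landscape for a target at a given torque.

    ``G_0 = 0``; the first step carries the concentration-adjusted
    initiation penalty plus the per-bp bias; every further step carries the
    bias plus, at penalized mismatch positions, the mismatch penalty, so a
    mismatch raises all states at and beyond its position equally.
    """
    n_eff = target.n_eff
    bias = total_bias_per_bp(params, torque)
    steps = np.full(n_eff + 1, bias)
    steps[0] = 0.0
    steps[1] = concentration_adjusted_dG_ini(params) + bias
    penalized = target.penalized_mismatches()
    for p, g in penalized:
        steps[p] += g
    energies = np.cumsum(steps)
    locked = None
    if target.lock_competent:
        locked = float(energies[-1]) - params.dG_lock
    return Landscape(
        energies=energies,
        n_eff=n_eff,
        mismatch_steps=tuple(p for p, _ in penalized),
        torque=float(torque),
        locked_energy=locked,
    )
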