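"""Exact first-passage computations on the R-loop rate chain.

Everything the single-molecule experiment measures is, in the model, a
first-passage or equilibrium quantity of the birth-death chain:

* mean first-passage times (MFPT) between microstates give formation and
  collapse times,
* splitting probabilities partition the exits of a coarse basin,
* Boltzmann weights give the predicted occupancies of the coarse states,
* MFPTs and splitting probabilities combine into the coarse transition
  rates (k1..k4 for three-state targets, six rates for four-state ones).

Three MFPT backends are provided and agree to numerical precision: a
linear solve over transient microstates (default), the closed-form nested
sum for birth-death chains, and a steady-state single-particle flux
formulation with transmissive boundaries that instantly reinject the
particle at the start state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape, ModelParams, TargetSpec, build_landscape
from .rates import ChainStructureError, RateChain, landscape_to_rates

__all__ = [
    "Basin",
    "CoarseStates",
    "CoarseRates",
    "mfpt",
    "splitting_probability",
    "partition_basins",
    "coarse_rates",
    "occupancies",
    "formation_time",
]


@dataclass(frozen=True)
class Basin:
    """A coarse state: a contiguous interval of microstates."""

    label: str
    start: int
    stop: int  # inclusive
    representative: int

    @property
    def states(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass(frozen=True)
class CoarseStates:
    """Partition of the chain into U / I / I* / F* (or F) basins.

    The unbound basin is exactly {0}; penalized mismatch positions are the
    basin boundaries, the microstate at the top of a barrier (position m,
    after paying the penalty) starting the next basin.  The representative
    of a basin is its lowest-free-energy microstate (the PAM-proximal one
    on ties).
    """

    basins: tuple[Basin, ...]
    boundaries: tuple[int, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.basins)

    @property
    def representatives(self) -> tuple[int, ...]:
        return tuple(b.representative for b in self.basins)

    def label_of(self, microstate: int) -> str:
        for b in self.basins:
            if b.start <= microstate <= b.stop:
                return b.label
        raise ValueError(f"microstate {microstate} outside chain")

    def index_path(self, microstates: np.ndarray) -> np.ndarray:
        """Map an array of microstates to basin indices (0 = U)."""
        edges = np.array([b.start for b in self.basins[1:]])
        return np.searchsorted(edges, microstates, side="right")


@dataclass(frozen=True)
class CoarseRates:
    """Inter-basin rates in chain order.

    ``rates[(a, b)]`` is the rate (1/s) from basin label ``a`` to adjacent
    basin label ``b``.  ``labeled()`` returns the conventional numbering
    k1 = U->I, k2 = I->U, k3 = I->next, k4 = next->I, ... .
    """

    labels: tuple[str, ...]
    rates: dict

    def labeled(self) -> dict:
        out = {}
        for i in range(len(self.labels) - 1):
            a, b = self.labels[i], self.labels[i + 1]
            out[f"k{2 * i + 1}"] = self.rates[(a, b)]
            out[f"k{2 * i + 2}"] = self.rates[(b, a)]
        return out

    def __getitem__(self, key: str) -> float:
        if key in self.rates:
            return self.rates[key]
        return self.labeled()[key]


def _check_chain(chain: RateChain) -> None:
    if chain.n_states < 2:
        raise ChainStructureError("chain needs at least two microstates")


def mfpt(chain: RateChain, start: int, absorb, method: str = "linear") -> float:
    """Mean first-passage time (s) from ``start`` to any state in ``absorb``.

    Ends of the chain that are not absorbing are reflecting.

    ``method`` selects the backend: ``"linear"`` (solve the first-passage
    linear system; default), ``"sum"`` (closed-form nested sum, single
    absorbing boundary only), or ``"flux"`` (steady-state single-particle
    flux with a transmissive boundary reinjecting at ``start``).
    """
    _check_chain(chain)
    absorb = frozenset(int(a) for a in (absorb if np.iterable(absorb) else [absorb]))
    if not absorb:
        raise ChainStructureError("absorb set must be non-empty")
    n = chain.n_states
    for a in absorb:
        if not 0 <= a < n:
            raise ChainStructureError(f"absorbing state {a} outside chain")
    if start in absorb:
        raise ChainStructureError("start state must not be absorbing")
    if method == "linear":
        return _mfpt_linear(chain, start, absorb)
    if method == "sum":
        return _mfpt_sum(chain, start, absorb)
    if method == "flux":
        return _mfpt_flux(chain, start, absorb)
    raise ValueError(f"unknown method {method!r}")


def _mfpt_linear(chain: RateChain, start: int, absorb: frozenset) -> float:
    n = chain.n_states
    transient = [i for i in range(n) if i not in absorb]
    idx = {s: j for j, s in enumerate(transient)}
    m = len(transient)
    A = np.zeros((m, m))
    b = -np.ones(m)
    for j, s in enumerate(transient):
        out = 0.0
        if s < n - 1:  # up step exists
            out += chain.up[s]
            if s + 1 in idx:
                A[j, idx[s + 1]] += chain.up[s]
        if s > 0:  # down step exists
            out += chain.down[s - 1]
            if s - 1 in idx:
                A[j, idx[s - 1]] += chain.down[s - 1]
        A[j, j] -= out
    T = np.linalg.solve(A, b)
    return float(T[idx[start]])


def _mfpt_sum(chain: RateChain, start: int, absorb: frozenset) -> float:
    """Closed-form nested sum; requires a single absorbing boundary with the
    walk confined to one side of it (the other end reflecting)."""
    if len(absorb) != 1:
        raise ChainStructureError("sum backend needs a single absorbing state")
    a = next(iter(absorb))
    if start < a:
        # reflecting at 0, absorbing at a: T = sum_{j=start}^{a-1} phi_j
        return float(sum(_phi_up(chain.up, chain.down, j)
                         for j in range(start, a)))
    # reflecting at the top, absorbing at a
    return float(sum(_phi_down(chain, j) for j in range(a, start)))


def _phi_up(up: np.ndarray, down: np.ndarray, j: int) -> float:
    """Expected crossing time of level j -> j+1 for upward passage with a
    reflecting boundary at 0:
    phi_j = sum_{i=0}^{j} (1/up[i]) prod_{l=i+1}^{j} down[l-1]/up[l]."""
    phi = 0.0
    prod = 1.0
    for i in range(j, -1, -1):
        phi += prod / up[i]
        if i > 0:
            prod *= down[i - 1] / up[i]
    return phi


def _phi_down(chain: RateChain, j: int) -> float:
    """Mirror of :func:`_phi_up` for downward passage with a reflecting
    boundary at the top of the chain."""
    up, down = chain.up, chain.down
    top = chain.n_states - 1
    phi = 0.0
    prod = 1.0
    for i in range(j, top):
        phi += prod / down[i]
        if i < top - 1:
            prod *= up[i + 1] / down[i]
    return phi


def _mfpt_flux(chain: RateChain, start: int, absorb: frozenset) -> float:
    """Steady-state single-particle flux with transmissive boundaries: the
    particle is reinjected at ``start`` upon arrival at an absorbing state;
    the MFPT is the inverse stationary flux into the boundaries."""
    n = chain.n_states
    transient = [i for i in range(n) if i not in absorb]
    idx = {s: j for j, s in enumerate(transient)}
    m = len(transient)
    Q = np.zeros((m, m))  # generator of the recycled chain, Q[i, j] rate i->j
    for j, s in enumerate(transient):
        if s < n - 1:
            dest = s + 1
            tgt = idx[dest] if dest in idx else idx[start]
            Q[j, tgt] += chain.up[s]
            Q[j, j] -= chain.up[s]
        if s > 0:
            dest = s - 1
            tgt = idx[dest] if dest in idx else idx[start]
            Q[j, tgt] += chain.down[s - 1]
            Q[j, j] -= chain.down[s - 1]
    # stationary distribution: pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(m)])
    b = np.append(np.zeros(m), 1.0)
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    flux = 0.0
    for j, s in enumerate(transient):
        if s < n - 1 and (s + 1) in absorb:
            flux += pi[j] * chain.up[s]
        if s > 0 and (s - 1) in absorb:
            flux += pi[j] * chain.down[s - 1]
    return float(1.0 / flux)


def splitting_probability(chain: RateChain, start: int, absorbA: int,
                          absorbB: int) -> float:
    """Probability of reaching ``absorbA`` before ``absorbB`` from ``start``.

    Requires ``absorbA < start < absorbB`` (degenerate starts at a boundary
    return 1 or 0).  The complement is the probability of reaching B first.
    """
    _check_chain(chain)
    if start == absorbA:
        return 1.0
    if start == absorbB:
        return 0.0
    if not absorbA < start < absorbB:
        raise ChainStructureError("need absorbA < start < absorbB")
    # harmonic function h with h(A) = 1, h(B) = 0:
    # h(s) = sum_{j=s}^{B-1} rho_j / sum_{j=A}^{B-1} rho_j,
    # rho_j = prod_{i=A+1}^{j} down[i-1]/up[i]   (rho_A = 1)
    up, down = chain.up, chain.down
    log_rho = np.zeros(absorbB - absorbA)  # index j-A
    for j in range(absorbA + 1, absorbB):
        log_rho[j - absorbA] = (log_rho[j - absorbA - 1]
                                + np.log(down[j - 1]) - np.log(up[j]))
    rho = np.exp(log_rho - log_rho.max())
    total = rho.sum()
    tail = rho[start - absorbA:].sum()
    return float(tail / total)


def partition_basins(landscape: Landscape, target: TargetSpec) -> CoarseStates:
    """Partition the chain into coarse basins at penalized mismatches.

    The unbound basin U is {0}.  With no internal mismatch the single bound
    basin is the intermediate I (cut-off targets) or the full R-loop F.
    With internal mismatches the bound basins are I, I*, ... and the last
    one F* (cut-off) or F (lock-competent).
    """
    boundaries = tuple(p for p, _ in target.penalized_mismatches())
    edges = [1, *boundaries, landscape.n_eff + 1]
    n_bound = len(edges) - 1
    if n_bound == 1:
        bound_labels = ["F" if target.lock_competent else "I"]
    else:
        inner = ["I"] + [f"I{'*' * i}" for i in range(1, n_bound - 1)]
        bound_labels = inner + ["F" if target.lock_competent else "F*"]
    basins = [Basin("U", 0, 0, 0)]
    G = landscape.energies
    for lab, lo, hi in zip(bound_labels, edges[:-1], edges[1:]):
        seg = G[lo:hi]
        rep = lo + int(np.argmin(seg))
        basins.append(Basin(lab, lo, hi - 1, rep))
    return CoarseStates(basins=tuple(basins), boundaries=boundaries)


def coarse_rates(chain: RateChain, basins: CoarseStates) -> CoarseRates:
    """Inter-basin transition rates from MFPTs and splitting probabilities.

    For an interior basin with representative r flanked by neighbor
    representatives a < r < b, the dwell is tau = MFPT(r -> {a, b}) and the
    exit rates are the splitting probabilities divided by tau.  Terminal
    basins use the single-boundary MFPT.
    """
    reps = basins.representatives
    if len(reps) < 2:
        raise ChainStructureError("need at least two basins")
    labels = basins.labels
    rates: dict = {}
    for i, r in enumerate(reps):
        if i == 0:
            rates[(labels[0], labels[1])] = 1.0 / mfpt(chain, r, {reps[1]})
        elif i == len(reps) - 1:
            rates[(labels[i], labels[i - 1])] = 1.0 / mfpt(chain, r, {reps[i - 1]})
        else:
            a, b = reps[i - 1], reps[i + 1]
            tau = mfpt(chain, r, {a, b})
            p_left = splitting_probability(chain, r, a, b)
            rates[(labels[i], labels[i - 1])] = p_left / tau
            rates[(labels[i], labels[i + 1])] = (1.0 - p_left) / tau
    return CoarseRates(labels=labels, rates=rates)


def occupancies(landscape: Landscape, basins: CoarseStates) -> dict:
    """Equilibrium occupancy of each basin from Boltzmann weights.

    Weights ``exp(-G_n)`` are summed per basin and normalized over all
    microstates; the minimum energy is subtracted before exponentiation to
    guard against overflow.  Basins with weight below 1e-12 of the total
    are reported as 0.
    """
    G = landscape.energies
    w = np.exp(-(G - G.min()))
    total = w.sum()
    out = {}
    for b in basins.basins:
        p = w[b.start:b.stop + 1].sum() / total
        out[b.label] = 0.0 if p < 1e-12 else float(p)
    return out


def formation_time(target: TargetSpec, params: ModelParams, torque: float,
                   *, torque_on_initiation: bool = True) -> float:
    """Mean time (s) to locked full R-loop formation: MFPT from the unbound
    state to the full hybrid length on a lock-competent chain."""
    if not target.lock_competent:
        raise ChainStructureError(
            "formation time requires a lock-competent target (no distal cut-off)"
        )
    ls = build_landscape(target, params, torque)
    chain = landscape_to_rates(ls, target, params,
                               torque_on_initiation=torque_on_initiation)
    return mfpt(chain, 0, {chain.n_states - 1})
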