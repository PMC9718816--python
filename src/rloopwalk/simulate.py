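"""Stochastic simulation of R-loop dynamics and the tweezers readout.

Two tiers mirror the measurement physics:

1. the R-loop length itself is a jump process on the rate chain, simulated
   either with exact (Gillespie) event sampling or with a fixed-step
   scheme taking a +-1 bp step per ``dt`` with probability ``k * dt``;
2. the observable is the axial position of a magnetic bead tethered by
   supercoiled DNA.  R-loop unwinding absorbs ``n * dphi_bp / 2pi`` turns
   of supercoiling, moving the equilibrium DNA extension by the local
   slope of the supercoiling curve; the bead relaxes toward that
   equilibrium with overdamped Ornstein-Uhlenbeck dynamics
   (spring ``kappa``, Stokes drag ``gamma``) and is sampled at the camera
   rate (120 Hz by default) by block averaging.

All kernels run under numba with a single seeded generator per call;
seeded runs are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .landscape import PhysicalConstants
from .rates import RateChain

__all__ = [
    "SimConfig",
    "BeadModel",
    "Trajectory",
    "simulate_rloop",
    "sample_first_passage",
    "rloop_to_extension",
    "simulate_bead",
    "virtual_instrument",
    "detection_resolution",
    "write_trajectory_csv",
    "read_trajectory_csv",
]


class SimulationConfigError(ValueError):
    """Simulation settings violate a stability/validity constraint."""


@dataclass(frozen=True)
class SimConfig:
    """Integrator settings for KMC and Brownian-dynamics runs.

    ``dt`` is the fixed step of the fixed-step KMC scheme and of the bead
    integrator, and the sampling grid spacing of exact-event runs.
    """

    dt: float
    duration: float
    seed: int = 0
    method: str = "exact-event"  # or "fixed-step"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise SimulationConfigError("dt and duration must be positive")
        if self.method not in ("exact-event", "fixed-step"):
            raise SimulationConfigError(f"unknown method {self.method!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt)) + 1


@dataclass(frozen=True)
class BeadModel:
    """Mechanics of the bead-on-supercoiled-DNA readout.

    ``kappa`` is the stretch stiffness of the supercoiled DNA (pN/nm),
    ``gamma`` the axial drag of the bead (pN s/nm; derived from the Stokes
    formula ``6 pi eta R`` when not given), ``slope_nm_per_turn`` the
    extension gained per turn of supercoiling absorbed by the R-loop.
    """

    kappa: float = 0.01
    radius_nm: float = 800.0
    viscosity_Pa_s: float = 1.0e-3
    gamma: float | None = None
    slope_nm_per_turn: float = 55.0
    sample_rate: float = 120.0
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if self.gamma is None:
            # Stokes drag 6 pi eta R; 1 N s/m = 1e3 pN s/nm, R in m = 1e-9 R_nm
            g = 6.0 * math.pi * self.viscosity_Pa_s * self.radius_nm * 1.0e-6
            object.__setattr__(self, "gamma", g)
        if self.kappa <= 0 or self.gamma <= 0:
            raise SimulationConfigError("kappa and gamma must be positive")

    @property
    def relaxation_time(self) -> float:
        """Bead relaxation time gamma/kappa in seconds."""
        return self.gamma / self.kappa

    @property
    def equilibrium_variance(self) -> float:
        """Equipartition variance kBT/kappa of the bead position, nm^2."""
        return self.constants.kBT_pNnm / self.kappa


@dataclass
class Trajectory:
    """Time series of the (latent) R-loop length and observed extension."""

    time: np.ndarray
    rloop_length: np.ndarray
    extension: np.ndarray | None
    sample_rate: float
    true_state_path: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.time) != len(self.rloop_length):
            raise ValueError("time and rloop_length must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


# ---------------------------------------------------------------------------
# numba kernels

@njit
def _kmc_fixed(up, down, dt, n_samples, start, absorbing_top, seed):
    np.random.seed(seed)
    N = up.shape[0]
    out = np.empty(n_samples, np.int16)
    pos = start
    for i in range(n_samples):
        out[i] = pos
        if absorbing_top and pos == N:
            continue
        pu = up[pos] * dt if pos < N else 0.0
        pd = down[pos - 1] * dt if pos > 0 else 0.0
        r = np.random.random()
        if r < pu:
            pos += 1
        elif r < pu + pd:
            pos -= 1
    return out


@njit
def _gillespie_sampled(up, down, dt, n_samples, start, absorbing_top, seed):
    np.random.seed(seed)
    N = up.shape[0]
    out = np.empty(n_samples, np.int16)
    pos = start
    t = 0.0
    i = 0
    while i < n_samples:
        frozen = (absorbing_top and pos == N)
        ku = up[pos] if (pos < N and not frozen) else 0.0
        kd = down[pos - 1] if (pos > 0 and not frozen) else 0.0
        ktot = ku + kd
        if ktot == 0.0:
            for j in range(i, n_samples):
                out[j] = pos
            break
        t_new = t + np.random.exponential(1.0 / ktot)
        while i < n_samples and i * dt < t_new:
            out[i] = pos
            i += 1
        if np.random.random() * ktot < ku:
            pos += 1
        else:
            pos -= 1
        t = t_new
    return out


@njit
def _gillespie_fpt(up, down, start, absorb_lo, absorb_hi, n_walks, seed):
    np.random.seed(seed)
    N = up.shape[0]
    times = np.empty(n_walks)
    hit_hi = np.empty(n_walks, np.uint8)
    for w in range(n_walks):
        pos = start
        t = 0.0
        while True:
            if pos == absorb_lo:
                hit_hi[w] = 0
                break
            if pos == absorb_hi:
                hit_hi[w] = 1
                break
            ku = up[pos] if pos < N else 0.0
            kd = down[pos - 1] if pos > 0 else 0.0
            ktot = ku + kd
            t += np.random.exponential(1.0 / ktot)
            if np.random.random() * ktot < ku:
                pos += 1
            else:
                pos -= 1
        times[w] = t
    return times, hit_hi


@njit
def _bead_bd(z_dna, dt, kappa, gamma, kBT, seed):
    np.random.seed(seed)
    n = z_dna.shape[0]
    out = np.empty(n)
    z = z_dna[0]
    sig = np.sqrt(2.0 * kBT / gamma * dt)
    for i in range(n):
        out[i] = z
        z += dt * (-kappa * (z - z_dna[i])) / gamma + sig * np.random.normal()
    return out


# ---------------------------------------------------------------------------


def simulate_rloop(chain: RateChain, config: SimConfig, start: int = 0) -> Trajectory:
    """Simulate the R-loop length process on a regular time grid.

    ``fixed-step`` takes a +-1 bp step per ``dt`` with probability
    ``k * dt`` (requires ``dt * max(rate) <= 0.1``); ``exact-event`` draws
    exponential waiting times (Gillespie) and samples the path on the
    grid.  Lock-competent chains absorb at the top state.
    """
    up = np.asarray(chain.up, dtype=np.float64)
    down = np.asarray(chain.down, dtype=np.float64)
    if config.method == "fixed-step":
        kmax = max(up.max(), down.max())
        if config.dt * kmax > 0.1:
            raise SimulationConfigError(
                f"dt={config.dt} too large for fixed-step: fastest rate "
                f"{kmax:.4g}/s gives stepping probability {config.dt * kmax:.3g} > 0.1"
            )
        path = _kmc_fixed(up, down, config.dt, config.n_samples, start,
                          chain.absorbing_top, config.seed)
    else:
        path = _gillespie_sampled(up, down, config.dt, config.n_samples,
                                  start, chain.absorbing_top, config.seed)
    time = np.arange(config.n_samples) * config.dt
    return Trajectory(time=time, rloop_length=path.astype(np.int16),
                      extension=None, sample_rate=1.0 / config.dt,
                      meta={"seed": config.seed, "method": config.method})


def sample_first_passage(chain: RateChain, start: int, absorb, n_walks: int,
                         seed: int = 0):
    """Sample first-passage times by exact-event simulation.

    ``absorb`` may be one microstate or a pair (lo, hi).  Returns
    ``(times, hit_hi)`` where ``hit_hi`` flags walks absorbed at the upper
    boundary (all 1 or all 0 for a single boundary).
    """
    up = np.asarray(chain.up, dtype=np.float64)
    down = np.asarray(chain.down, dtype=np.float64)
    absorb = sorted({int(a) for a in (absorb if np.iterable(absorb) else [absorb])})
    if len(absorb) == 1:
        lo, hi = -1, absorb[0]
        if absorb[0] < start:
            lo, hi = absorb[0], -1
    elif len(absorb) == 2:
        lo, hi = absorb
    else:
        raise SimulationConfigError("at most two absorbing boundaries supported")
    return _gillespie_fpt(up, down, start, lo, hi, n_walks, seed)


def rloop_to_extension(rloop_length, bead: BeadModel) -> np.ndarray:
    """Equilibrium DNA extension offset (nm) for a given R-loop length.

    An n-bp R-loop unwinds the duplex by ``n * dphi_bp`` radians, i.e.
    absorbs ``n * dphi_bp / 2pi`` turns of the applied supercoiling; each
    absorbed turn lengthens the DNA by the slope of the supercoiling
    curve.
    """
    n = np.asarray(rloop_length, dtype=np.float64)
    turns = n * bead.constants.dphi_bp / (2.0 * math.pi)
    return bead.slope_nm_per_turn * turns


def simulate_bead(z_dna: np.ndarray, bead: BeadModel, config: SimConfig) -> np.ndarray:
    """Brownian dynamics of the bead about the DNA equilibrium extension.

    ``z_dna`` must be given on the integrator grid (spacing ``config.dt``).
    Per step the bead drifts by ``dt * (-kappa (z - z_dna)) / gamma`` and
    diffuses with variance ``2 (kBT/gamma) dt``.  The output is resampled
    to ``bead.sample_rate`` by block averaging (camera integration).
    """
    if config.dt > 0.1 * bead.relaxation_time:
        raise SimulationConfigError(
            f"dt={config.dt} exceeds 0.1 * gamma/kappa = "
            f"{0.1 * bead.relaxation_time:.3g} s"
        )
    z = _bead_bd(np.asarray(z_dna, dtype=np.float64), config.dt, bead.kappa,
                 bead.gamma, bead.constants.kBT_pNnm, config.seed)
    return _block_average(z, config.dt, bead.sample_rate)


def _block_average(x: np.ndarray, dt: float, sample_rate: float) -> np.ndarray:
    m = max(1, int(round(1.0 / (sample_rate * dt))))
    n = (len(x) // m) * m
    return x[:n].reshape(-1, m).mean(axis=1)


def virtual_instrument(chain: RateChain, bead: BeadModel, config: SimConfig,
                       basins=None, start: int = 0) -> Trajectory:
    """Full measurement emulation: KMC -> extension -> bead BD -> camera.

    Returns a trajectory sampled at ``bead.sample_rate`` whose
    ``extension`` is the block-averaged bead position and whose
    ``rloop_length`` / ``true_state_path`` keep the latent ground truth at
    the camera sample times (state at the end of each camera block).
    """
    latent = simulate_rloop(chain, config, start=start)
    z_dna = rloop_to_extension(latent.rloop_length, bead)
    bead_config = SimConfig(config.dt, config.duration, config.seed + 1,
                            config.method)
    z_cam = simulate_bead(z_dna, bead, bead_config)
    m = max(1, int(round(1.0 / (bead.sample_rate * config.dt))))
    n = (len(latent.rloop_length) // m) * m
    rl = latent.rloop_length[:n].reshape(-1, m)[:, -1]
    time = (np.arange(len(z_cam)) + 1) * (m * config.dt)
    states = None
    if basins is not None:
        states = np.asarray(basins.labels)[basins.index_path(rl)]
    return Trajectory(time=time, rloop_length=rl, extension=z_cam,
                      sample_rate=bead.sample_rate, true_state_path=states,
                      meta={"seed": config.seed, "method": config.method,
                            "dt": config.dt})


def detection_resolution(snr: float = 3.0, dz: float = 50.0,
                         kappa: float = 1.25e-3, gamma: float = 1.5e-5,
                         kBT_pNnm: float = 4.114) -> float:
    """Temporal resolution (s) of the nanomechanical detection system.

    ``tau = SNR^2 kBT gamma / (kappa dz)^2``.  Defaults reproduce the
    instrument characterization (SNR 3, 50 nm signal, kappa 1.25e-3 pN/nm,
    gamma 1.5e-5 pN s/nm), about 0.14 s, i.e. ~7 Hz bandwidth.
    """
    if min(snr, dz, kappa, gamma, kBT_pNnm) <= 0:
        raise SimulationConfigError("all resolution inputs must be positive")
    return snr**2 * kBT_pNnm * gamma / (kappa * dz) ** 2


# ---------------------------------------------------------------------------
# trajectory CSV dialect: '#'-prefixed JSON metadata, then CSV columns


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write time_s, extension_nm[, rloop_bp, true_state] with a sidecar
    metadata block (seed, parameters) in '#'-prefixed header lines."""
    cols = {"time_s": traj.time}
    if traj.extension is not None:
        cols["extension_nm"] = traj.extension
    cols["rloop_bp"] = traj.rloop_length
    if traj.true_state_path is not None:
        cols["true_state"] = traj.true_state_path
    df = pd.DataFrame(cols)
    meta = dict(traj.meta, sample_rate=traj.sample_rate)
    with open(path, "w") as fh:
        fh.write("# rloopwalk trajectory\n")
        fh.write("# " + json.dumps(meta, default=float) + "\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            text = line[1:].strip()
            if text.startswith("{"):
                meta = json.loads(text)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return Trajectory(
        time=df["time_s"].to_numpy(),
        rloop_length=df["rloop_bp"].to_numpy() if "rloop_bp" in df else
        np.zeros(len(df), dtype=np.int16),
        extension=df["extension_nm"].to_numpy() if "extension_nm" in df else None,
        sample_rate=float(meta.get("sample_rate", 120.0)),
        true_state_path=df["true_state"].to_numpy() if "true_state" in df else None,
        meta=meta,
    )
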