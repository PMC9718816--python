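"""Synthetic experiment generator with the model's statistical structure.

Emulates the three data products the analysis consumes, so the entire
pipeline is testable without instrument data:

* **rate/time tables** — model coarse rates or formation times per
  (target, torque) condition, perturbed by the sampling error of a finite
  number of exponential dwells (the SEM structure of the measurements:
  mean of n events, error = mean / sqrt(n));
* **extension trajectories** — the full virtual instrument: exact-event
  kinetic Monte Carlo of the R-loop length, conversion to DNA extension,
  bead Brownian dynamics, camera sampling at 120 Hz, with the latent basin
  path stored as ground truth;
* **fluorescence traces** — zero-torque population kinetics: first-passage
  times to the locked state sampled per molecule, cumulative fraction
  formed over time plus Gaussian noise, and a matching no-protein control.

Every artifact carries its generating parameters and seed; regeneration
with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .first_passage import coarse_rates, mfpt, partition_basins
from .landscape import ModelParams, TargetSpec, build_landscape
from .rates import landscape_to_rates
from .simulate import (
    BeadModel,
    SimConfig,
    Trajectory,
    sample_first_passage,
    virtual_instrument,
)

__all__ = [
    "ExperimentDesign",
    "make_rate_tables",
    "make_trajectories",
    "make_fluorescence",
]


@dataclass
class ExperimentDesign:
    """Layout of a synthetic experiment campaign.

    ``events_per_condition`` defaults to 27, the scale of the locked
    R-loop formation statistics (means over >27 events per condition).
    """

    targets: dict[str, TargetSpec]
    torques: tuple[float, ...] = (-6.7, -5.6, -4.7, -3.4)
    events_per_condition: int = 27
    trajectory_duration: float = 3000.0
    bead: BeadModel = field(default_factory=BeadModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_condition < 1:
            raise ValueError("events_per_condition must be >= 1")
        self.torques = tuple(float(t) for t in self.torques)


def _model_observables(target: TargetSpec, truth: ModelParams, torque: float):
    """True model values per observable label for one condition."""
    ls = build_landscape(target, truth, torque)
    chain = landscape_to_rates(ls, target, truth)
    if target.lock_competent:
        return {"formation_time": mfpt(chain, 0, {chain.n_states - 1})}
    return coarse_rates(chain, partition_basins(ls, target)).labeled()


def make_rate_tables(design: ExperimentDesign, truth: ModelParams,
                     seed: int | None = None) -> pd.DataFrame:
    """Observation table emulating the rate/time-vs-torque measurements.

    For each condition the model value is computed exactly, then replaced
    by the mean of ``events_per_condition`` exponential dwells drawn at
    that mean (rates: dwell mean 1/k, observed rate = 1/mean), with
    ``sem = value / sqrt(n)``.  The exact model value is kept in the
    ``truth`` column.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.events_per_condition
    rows = []
    for tid, target in design.targets.items():
        for tau in design.torques:
            for label, v in _model_observables(target, truth, tau).items():
                if label == "formation_time":
                    sampled = rng.exponential(v, size=n).mean()
                else:
                    sampled = 1.0 / rng.exponential(1.0 / v, size=n).mean()
                rows.append({
                    "target_id": tid, "torque": tau, "observable": label,
                    "value": sampled, "sem": sampled / np.sqrt(n),
                    "n_events": n, "truth": v,
                })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = design.seed if seed is None else seed
    df.attrs["truth_params"] = truth.to_dict()
    return df


def make_trajectories(design: ExperimentDesign, truth: ModelParams,
                      dt: float = 1e-4, seed: int | None = None
                      ) -> dict[str, dict[float, Trajectory]]:
    """Virtual-instrument extension trajectories with ground-truth states.

    Returns ``{target_id: {torque: Trajectory}}``; each trajectory carries
    the 120 Hz extension signal, the latent R-loop length and the basin
    label path for detection benchmarking.
    """
    base_seed = design.seed if seed is None else seed
    out: dict[str, dict[float, Trajectory]] = {}
    k = 0
    for tid, target in design.targets.items():
        out[tid] = {}
        for tau in design.torques:
            ls = build_landscape(target, truth, tau)
            chain = landscape_to_rates(ls, target, truth)
            basins = partition_basins(ls, target)
            config = SimConfig(dt=dt, duration=design.trajectory_duration,
                               seed=base_seed + 1000 * k, method="exact-event")
            traj = virtual_instrument(chain, design.bead, config, basins=basins)
            traj.meta.update(target_id=tid, torque=tau,
                             truth_params=truth.to_dict())
            out[tid][tau] = traj
            k += 1
    return out


def make_fluorescence(design: ExperimentDesign, truth: ModelParams,
                      n_molecules: int = 200, duration: float | None = None,
                      n_points: int = 400, noise: float = 0.02,
                      amplitude: float = 1.0, seed: int | None = None
                      ) -> dict[str, pd.DataFrame]:
    """Zero-torque bulk fluorescence traces per lock-competent target.

    Per molecule a first-passage time to the locked state is sampled by
    exact-event simulation; the signal is the cumulative fraction formed
    scaled to ``amplitude`` plus Gaussian noise.  A no-protein ``control``
    trace (flat noisy baseline) is included under its own key.
    """
    base_seed = design.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    out: dict[str, pd.DataFrame] = {}
    fpt_by_target = {}
    for i, (tid, target) in enumerate(design.targets.items()):
        if not target.lock_competent:
            continue
        ls = build_landscape(target, truth, 0.0)
        chain = landscape_to_rates(ls, target, truth)
        times, _ = sample_first_passage(chain, 0, chain.n_states - 1,
                                        n_molecules, seed=base_seed + 17 * i + 1)
        fpt_by_target[tid] = times
    if not fpt_by_target:
        raise ValueError("no lock-competent target in the design")
    # each target gets its own grid spanning 3x its mean formation time, as
    # a real assay would be recorded until saturation
    last_grid = None
    for tid, times in fpt_by_target.items():
        dur = duration if duration is not None else 3.0 * float(np.mean(times))
        grid = np.linspace(0.0, dur, n_points)
        last_grid = grid
        frac = np.searchsorted(np.sort(times), grid, side="right") / len(times)
        signal = amplitude * frac + rng.normal(0.0, noise, size=n_points)
        df = pd.DataFrame({"time_s": grid, "signal": signal})
        df.attrs.update(seed=base_seed, target_id=tid, n_molecules=n_molecules,
                        mean_fpt=float(np.mean(times)))
        out[tid] = df
    control = pd.DataFrame({
        "time_s": last_grid,
        "signal": rng.normal(0.0, noise, size=n_points),
    })
    control.attrs.update(seed=base_seed, target_id="control")
    out["control"] = control
    return out
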