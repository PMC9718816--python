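"""Global fitting of the random-walk model to rate/time-vs-torque tables.

The model object is built from a tidy observation table (one row per
measured quantity: target, torque, observable label, value, SEM) plus the
target specifications, and exposes a statsmodels-like interface::

    model = RLoopGlobalFit.from_dataframe(obs, targets, free=("k_step",))
    res = model.fit(seed=0)
    res.params, res.bse, res.conf_int(), res.summary()

Observables are the coarse transition rates ("k1".."k6") predicted by the
first-passage solver on each target's chain, or "formation_time" (mean
time to the locked full R-loop).  The default objective is weighted least
squares on log10 of the values — measured rates span three orders of
magnitude, and log-scale weighting keeps fast conditions from dominating —
with SEMs propagated to the log scale; a linear-scale objective is
selectable.  Optimization is multi-start trust-region least squares
(deterministic given the seed); uncertainties come from the Jacobian
(Wald) or from profile likelihood at one-sigma (67%) level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .first_passage import coarse_rates, mfpt, partition_basins
from .landscape import ModelParams, TargetSpec, build_landscape
from .rates import landscape_to_rates

__all__ = ["RLoopGlobalFit", "RLoopFitResults"]

_LN10 = np.log(10.0)

#: optimizer bounds in internal coordinates (k_step handled as log10)
_BOUNDS = {
    "k_step": (2.0, 5.0),  # log10 of 1e2..1e5 /s
    "dG_ini": (0.0, 15.0),
    "dG_MM": (0.0, 15.0),
    "dG_bias": (-1.0, 1.0),
}
_PARAM_ORDER = ("k_step", "dG_ini", "dG_MM", "dG_bias")


class RLoopGlobalFit:
    """Weighted global fit of kinetic parameters to observation tables.

    Parameters
    ----------
    observations : DataFrame
        Columns ``target_id, torque, observable, value, sem``.
    targets : dict
        Maps each target_id to its :class:`TargetSpec`.
    base_params : ModelParams
        Values for parameters that are not free (and physical constants).
    free : sequence of str
        Subset of ``{"k_step", "dG_ini", "dG_MM", "dG_bias"}``.  When
        ``dG_MM`` is free (or fixed explicitly), it replaces the penalty of
        every penalized mismatch of every target.
    fixed : dict, optional
        Explicit fixed values overriding ``base_params``.
    scale : str
        ``"log10"`` (default) or ``"linear"`` residual scale.
    """

    def __init__(self, observations: pd.DataFrame, targets: dict,
                 base_params: ModelParams | None = None,
                 free=("k_step",), fixed: dict | None = None,
                 scale: str = "log10", torque_on_initiation: bool = True):
        obs = observations.reset_index(drop=True).copy()
        required = {"target_id", "torque", "observable", "value", "sem"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if not np.all(obs["sem"] > 0):
            raise ValueError("all SEMs must be positive")
        if not np.all(obs["value"] > 0):
            raise ValueError("rates and times must be positive")
        unknown = set(obs["target_id"]) - set(targets)
        if unknown:
            raise ValueError(f"no TargetSpec for target ids {sorted(unknown)}")
        self.observations = obs
        self.targets = dict(targets)
        self.base_params = base_params or ModelParams()
        self.free = tuple(p for p in _PARAM_ORDER if p in free)
        if len(self.free) != len(set(free)):
            bad = set(free) - set(_PARAM_ORDER)
            raise ValueError(f"unknown free parameters {sorted(bad)}")
        if len(obs) < len(self.free):
            raise ValueError("need at least as many observations as free parameters")
        self.fixed = dict(fixed or {})
        self.scale = scale
        self.torque_on_initiation = torque_on_initiation
        self._override_penalty = ("dG_MM" in self.free) or ("dG_MM" in self.fixed)
        # evaluation plan: one chain build per (target, torque) condition
        self._groups = []
        for (tid, tau), grp in obs.groupby(["target_id", "torque"], sort=False):
            self._groups.append((tid, float(tau), grp.index.to_numpy(),
                                 grp["observable"].tolist()))

    @classmethod
    def from_dataframe(cls, observations: pd.DataFrame, targets: dict,
                       **kw) -> "RLoopGlobalFit":
        """Build the model from a tidy observation table."""
        return cls(observations, targets, **kw)

    # -- parameter bookkeeping ---------------------------------------------

    def _param_dict(self, theta: np.ndarray) -> dict:
        d = {}
        d.update(self.fixed)
        for name, v in zip(self.free, theta):
            d[name] = 10.0**v if name == "k_step" else v
        return d

    def _theta0(self) -> np.ndarray:
        defaults = {
            "k_step": self.base_params.k_step,
            "dG_ini": self.base_params.dG_ini,
            "dG_MM": 6.0,
            "dG_bias": self.base_params.dG_bias_intrinsic,
        }
        defaults.update(self.fixed)
        out = []
        for name in self.free:
            v = defaults[name]
            v = np.log10(v) if name == "k_step" else v
            lo, hi = _BOUNDS[name]
            out.append(np.clip(v, lo + 1e-6, hi - 1e-6))
        return np.array(out)

    def _bounds(self):
        lo = np.array([_BOUNDS[n][0] for n in self.free])
        hi = np.array([_BOUNDS[n][1] for n in self.free])
        return lo, hi

    # -- model evaluation ---------------------------------------------------

    def _materialize(self, p: dict):
        params = self.base_params.with_(
            k_step=p.get("k_step", self.base_params.k_step),
            dG_ini=p.get("dG_ini", self.base_params.dG_ini),
            dG_bias_intrinsic=p.get("dG_bias",
                                    self.base_params.dG_bias_intrinsic),
        )
        return params

    def _target_for(self, tid: str, p: dict) -> TargetSpec:
        t = self.targets[tid]
        if self._override_penalty and t.mismatches:
            mms = tuple(
                (pos, p["dG_MM"] if pos not in t.excluded_positions else pen)
                for pos, pen in t.mismatches
            )
            return TargetSpec(hybrid_length=t.hybrid_length, mismatches=mms,
                              distal_cutoff=t.distal_cutoff,
                              lock_competent=t.lock_competent,
                              excluded_positions=t.excluded_positions)
        return t

    def predict(self, param_values: dict) -> np.ndarray:
        """Model predictions aligned with the observation rows."""
        params = self._materialize(param_values)
        out = np.empty(len(self.observations))
        for tid, tau, rows, obs_labels in self._groups:
            target = self._target_for(tid, param_values)
            ls = build_landscape(target, params, tau)
            chain = landscape_to_rates(
                ls, target, params,
                torque_on_initiation=self.torque_on_initiation)
            need_rates = any(lbl != "formation_time" for lbl in obs_labels)
            rates = None
            if need_rates:
                rates = coarse_rates(chain, partition_basins(ls, target)).labeled()
            for row, lbl in zip(rows, obs_labels):
                if lbl == "formation_time":
                    out[row] = mfpt(chain, 0, {chain.n_states - 1})
                else:
                    out[row] = rates[lbl]
        return out

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        pred = self.predict(self._param_dict(theta))
        val = self.observations["value"].to_numpy()
        sem = self.observations["sem"].to_numpy()
        if self.scale == "log10":
            sigma = sem / (val * _LN10)
            return (np.log10(pred) - np.log10(val)) / sigma
        return (pred - val) / sem

    def objective(self, theta: np.ndarray) -> float:
        r = self._residuals(theta)
        return float(r @ r)

    # -- fitting ------------------------------------------------------------

    def fit(self, n_starts: int = 10, seed: int = 0) -> "RLoopFitResults":
        """Multi-start weighted least squares over the free parameters.

        The first start is the base-parameter point; the remaining
        ``n_starts - 1`` are drawn uniformly in the internal bounds
        (log-uniform for ``k_step``), deterministically from ``seed``.
        """
        lo, hi = self._bounds()
        rng = np.random.default_rng(seed)
        starts = [self._theta0()]
        for _ in range(max(n_starts - 1, 0)):
            starts.append(rng.uniform(lo + 1e-6, hi - 1e-6))
        best = None
        for x0 in starts:
            try:
                sol = optimize.least_squares(self._residuals, x0,
                                             bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("optimization failed from every start")
        return RLoopFitResults(self, best)


class RLoopFitResults:
    """Estimates, uncertainties and diagnostics of a global fit."""

    def __init__(self, model: RLoopGlobalFit, solution):
        self.model = model
        self._sol = solution
        self.theta = solution.x
        self.objective = float(2.0 * solution.cost)  # sum of squared residuals
        self.success = bool(solution.status > 0)
        self.nfev = int(solution.nfev)
        self.params = model._param_dict(solution.x)
        self.n_obs = len(model.observations)
        self.df_resid = self.n_obs - len(model.free)
        self._cov = self._covariance()
        self.flags: dict = {}

    # -- uncertainties ------------------------------------------------------

    def _covariance(self) -> np.ndarray:
        J = self._sol.jac
        try:
            cov = np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov = np.full((len(self.theta),) * 2, np.nan)
        return cov

    @property
    def bse(self) -> dict:
        """Standard errors on the natural parameter scale (Wald)."""
        out = {}
        for i, name in enumerate(self.model.free):
            se = np.sqrt(self._cov[i, i]) if np.isfinite(self._cov[i, i]) else np.nan
            if name == "k_step":
                se = se * _LN10 * self.params["k_step"]
            out[name] = float(se)
        return out

    def conf_int(self, method: str = "profile", sigma: float = 1.0) -> dict:
        """Per-parameter intervals at ``sigma`` standard deviations (the
        default 1.0 is the single/67% confidence interval).

        ``"profile"`` re-optimizes the remaining parameters along each
        profile and locates the chi-square increase of ``sigma^2``;
        ``"wald"`` uses the Jacobian covariance.  Open-ended profiles are
        returned one-sided (nan on the open side) and flagged.
        """
        out = {}
        if method == "wald":
            for name, se in self.bse.items():
                v = self.params[name]
                out[name] = (v - sigma * se, v + sigma * se)
            return out
        for i, name in enumerate(self.model.free):
            lo = self._profile_bound(i, -1, sigma)
            hi = self._profile_bound(i, +1, sigma)
            if np.isnan(lo) or np.isnan(hi):
                self.flags[name] = "open-ended profile; one-sided interval"
            pair = []
            for v in (lo, hi):
                if name == "k_step" and np.isfinite(v):
                    v = 10.0**v
                pair.append(v)
            out[name] = tuple(pair)
        return out

    def _chi2_fixed(self, i: int, value: float) -> float:
        free_idx = [j for j in range(len(self.theta)) if j != i]
        if not free_idx:
            theta = np.array([value])
            return self.model.objective(theta)
        lo, hi = self.model._bounds()

        def resid(sub):
            theta = np.empty(len(self.theta))
            theta[i] = value
            theta[free_idx] = sub
            return self.model._residuals(theta)

        sol = optimize.least_squares(resid, self.theta[free_idx],
                                     bounds=(lo[free_idx], hi[free_idx]),
                                     method="trf")
        return float(2.0 * sol.cost)

    def _profile_bound(self, i: int, direction: int, sigma: float) -> float:
        target = self.objective + sigma**2
        lo_b, hi_b = self.model._bounds()
        x0 = self.theta[i]
        step = np.sqrt(max(self._cov[i, i], 1e-8))
        step = min(max(step, 1e-3), 0.5 * (hi_b[i] - lo_b[i]))
        prev = x0
        for k in range(1, 30):
            x = x0 + direction * step * 2.0 ** (k - 1)
            x = np.clip(x, lo_b[i], hi_b[i])
            chi2 = self._chi2_fixed(i, x)
            if chi2 >= target:
                f = lambda v: self._chi2_fixed(i, v) - target
                a, b = (prev, x) if prev < x else (x, prev)
                try:
                    return float(optimize.brentq(f, a, b, xtol=1e-4))
                except ValueError:
                    return float(x)
            prev = x
            if x in (lo_b[i], hi_b[i]):
                return float("nan")  # open-ended within bounds
        return float("nan")

    # -- presentation -------------------------------------------------------

    def predict(self) -> pd.DataFrame:
        """Observation table with the best-fit model column appended."""
        df = self.model.observations.copy()
        df["model"] = self.model.predict(self.params)
        return df

    def summary(self) -> str:
        lines = []
        lines.append("Random-walk model global fit")
        lines.append("=" * 64)
        lines.append(f"observations: {self.n_obs}    free parameters: "
                     f"{len(self.model.free)}    scale: {self.model.scale}")
        lines.append(f"objective (chi2): {self.objective:.4g}    "
                     f"nfev: {self.nfev}    converged: {self.success}")
        lines.append("-" * 64)
        lines.append(f"{'parameter':<12}{'estimate':>14}{'std err':>14}")
        bse = self.bse
        units = {"k_step": "1/s", "dG_ini": "kBT", "dG_MM": "kBT",
                 "dG_bias": "kBT/bp"}
        for name in self.model.free:
            lines.append(f"{name:<12}{self.params[name]:>14.4g}"
                         f"{bse[name]:>14.3g}  {units[name]}")
        for name, value in self.model.fixed.items():
            lines.append(f"{name:<12}{value:>14.4g}{'(fixed)':>14}")
        if self.flags:
            lines.append("-" * 64)
            for k, v in self.flags.items():
                lines.append(f"flag: {k}: {v}")
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<RLoopFitResults {pars}, chi2={self.objective:.4g}>"
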