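"""Global model fitting: recovery, uncertainties, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from rloopwalk import (
    ExperimentDesign,
    ModelParams,
    RLoopGlobalFit,
    TargetSpec,
    make_rate_tables,
)


def collapse_rate_design(lengths=(8, 12, 16, 20), torques=(-3.5, -5.0, -6.5)):
    targets = {f"L{L}": TargetSpec.matched(L) for L in lengths}
    return ExperimentDesign(targets=targets, torques=torques,
                            events_per_condition=100, seed=0), targets


class TestFitGlobal:
    def test_zero_noise_objective_vanishes_at_truth(self):
        truth = ModelParams(k_step=1500.0)
        design, targets = collapse_rate_design()
        obs = make_rate_tables(design, truth, seed=1)
        obs = obs[obs.observable == "k2"].copy()
        obs["value"] = obs["truth"]  # noise-free observations
        model = RLoopGlobalFit(obs, targets, base_params=truth,
                               free=("k_step",))
        res = model.fit(n_starts=3, seed=0)
        assert res.objective < 1e-10
        assert res.params["k_step"] == pytest.approx(1500.0, rel=1e-4)

    def test_stepping_rate_recovery_within_uncertainty(self):
        truth = ModelParams(k_step=1900.0)
        design, targets = collapse_rate_design()
        obs = make_rate_tables(design, truth, seed=7)
        obs = obs[obs.observable == "k2"].reset_index(drop=True)
        model = RLoopGlobalFit(obs, targets,
                               base_params=truth.with_(k_step=300.0),
                               free=("k_step",))
        res = model.fit(n_starts=4, seed=0)
        assert abs(res.params["k_step"] - 1900.0) < 3 * res.bse["k_step"]

    def test_multi_parameter_recovery(self):
        truth = ModelParams(k_step=2000.0, dG_ini=8.5, dG_bias_intrinsic=0.14)
        targets = {"WT": TargetSpec.wild_type()}
        for pos in (5, 9, 14, 17, 21):
            targets[f"M{pos}"] = TargetSpec.single_mismatch(pos, 6.9)
        design = ExperimentDesign(targets=targets,
                                  torques=(-3.0, -4.0, -5.0, -6.0, -7.0),
                                  events_per_condition=27, seed=0)
        obs = make_rate_tables(design, truth, seed=11)
        model = RLoopGlobalFit(obs, targets,
                               base_params=truth.with_(k_step=500.0,
                                                       dG_bias_intrinsic=0.0),
                               free=("k_step", "dG_MM", "dG_bias"),
                               fixed={"dG_ini": 8.5})
        res = model.fit(n_starts=4, seed=0)
        assert abs(res.params["dG_MM"] - 6.9) < 3 * res.bse["dG_MM"]
        assert abs(res.params["dG_bias"] - 0.14) < 3 * res.bse["dG_bias"]
        assert abs(res.params["k_step"] - 2000) < 3 * res.bse["k_step"]

    def test_linear_scale_objective_selectable(self):
        truth = ModelParams(k_step=1500.0)
        design, targets = collapse_rate_design(lengths=(8, 12))
        obs = make_rate_tables(design, truth, seed=3)
        obs = obs[obs.observable == "k2"].reset_index(drop=True)
        model = RLoopGlobalFit(obs, targets, base_params=truth,
                               free=("k_step",), scale="linear")
        res = model.fit(n_starts=3, seed=0)
        assert res.params["k_step"] == pytest.approx(1500.0, rel=0.1)

    def test_input_validation(self):
        obs = pd.DataFrame({"target_id": ["a"], "torque": [-5.0],
                            "observable": ["k2"], "value": [1.0],
                            "sem": [-0.1]})
        with pytest.raises(ValueError, match="SEM"):
            RLoopGlobalFit(obs, {"a": TargetSpec.matched(8)})
        obs2 = obs.assign(sem=[0.1])
        with pytest.raises(ValueError, match="target ids"):
            RLoopGlobalFit(obs2, {"b": TargetSpec.matched(8)})
        with pytest.raises(ValueError, match="observations"):
            RLoopGlobalFit(obs2, {"a": TargetSpec.matched(8)},
                           free=("k_step", "dG_bias"))


class TestConfidenceIntervals:
    @pytest.fixture(scope="class")
    def one_param_fit(self):
        truth = ModelParams(k_step=1700.0)
        design, targets = collapse_rate_design()
        obs = make_rate_tables(design, truth, seed=5)
        obs = obs[obs.observable == "k2"].reset_index(drop=True)
        model = RLoopGlobalFit(obs, targets, base_params=truth,
                               free=("k_step",))
        return model, model.fit(n_starts=3, seed=0)

    def test_profile_matches_wald_in_quadratic_regime(self, one_param_fit):
        model, res = one_param_fit
        prof = res.conf_int(method="profile")["k_step"]
        wald = res.conf_int(method="wald")["k_step"]
        assert prof[0] == pytest.approx(wald[0], rel=0.01)
        assert prof[1] == pytest.approx(wald[1], rel=0.01)
        assert prof[0] < res.params["k_step"] < prof[1]

    def test_duplicated_observations_shrink_interval_sqrt2(self, one_param_fit):
        model, res = one_param_fit
        doubled = pd.concat([model.observations, model.observations],
                            ignore_index=True)
        model2 = RLoopGlobalFit(doubled, model.targets,
                                base_params=model.base_params,
                                free=("k_step",))
        res2 = model2.fit(n_starts=3, seed=0)
        assert res2.bse["k_step"] == pytest.approx(
            res.bse["k_step"] / np.sqrt(2), rel=0.05)

    def test_unidentifiable_pair_flagged_wide(self):
        """k_step and dG_ini are exchangeable for formation times at a
        single torque: the profile opens up and gets flagged."""
        truth = ModelParams(k_step=2000.0)
        targets = {"WT": TargetSpec.wild_type()}
        design = ExperimentDesign(targets=targets, torques=(-5.0,),
                                  events_per_condition=200, seed=0)
        obs = make_rate_tables(design, truth, seed=2)
        obs = pd.concat([obs, obs], ignore_index=True)  # two replicates
        model = RLoopGlobalFit(obs, targets, base_params=truth,
                               free=("k_step", "dG_ini"))
        res = model.fit(n_starts=4, seed=0)
        ci = res.conf_int(method="profile")
        lo, hi = ci["k_step"]
        open_ended = np.isnan(lo) or np.isnan(hi)
        wide = (not open_ended) and (hi / max(lo, 1e-12) > 5)
        assert open_ended or wide
        if open_ended:
            assert "k_step" in res.flags


class TestUncertaintyCalibration:
    def test_recovery_median_and_interval_coverage(self):
        """Across 50 replicate campaigns of the formation-time design
        (27 events per condition), the median recovered parameters sit
        within one reported sigma of the generating values and the
        1-sigma (67%) intervals cover the truth between 50% and 85% of
        the time."""
        truth = ModelParams(k_step=2000.0, dG_ini=8.5, dG_bias_intrinsic=0.14)
        targets = {"WT": TargetSpec.wild_type()}
        for pos in (7, 11, 14, 17):
            targets[f"M{pos}"] = TargetSpec.single_mismatch(pos, 6.9)
        design = ExperimentDesign(targets=targets,
                                  torques=(-3.5, -4.5, -5.5, -6.5),
                                  events_per_condition=27, seed=0)
        truths = {"k_step": 2000.0, "dG_MM": 6.9, "dG_bias": 0.14}
        recovered = {k: [] for k in truths}
        covered = {k: 0 for k in truths}
        sigmas = {k: [] for k in truths}
        n_rep = 50
        for rep in range(n_rep):
            obs = make_rate_tables(design, truth, seed=100 + rep)
            model = RLoopGlobalFit(
                obs, targets,
                base_params=truth.with_(k_step=800.0, dG_bias_intrinsic=0.05),
                free=("k_step", "dG_MM", "dG_bias"), fixed={"dG_ini": 8.5})
            res = model.fit(n_starts=2, seed=rep)
            ci = res.conf_int(method="wald")
            for k, v in truths.items():
                recovered[k].append(res.params[k])
                sigmas[k].append(res.bse[k])
                lo, hi = ci[k]
                covered[k] += int(lo <= v <= hi)
        for k, v in truths.items():
            med = np.median(recovered[k])
            assert abs(med - v) <= np.median(sigmas[k]), k
            assert 0.5 <= covered[k] / n_rep <= 0.85, (k, covered[k] / n_rep)


class TestResultsApi:
    def test_summary_and_predict(self):
        truth = ModelParams(k_step=1500.0)
        design, targets = collapse_rate_design(lengths=(8, 12))
        obs = make_rate_tables(design, truth, seed=9)
        obs = obs[obs.observable == "k2"].reset_index(drop=True)
        model = RLoopGlobalFit(obs, targets, base_params=truth,
                               free=("k_step",), fixed={"dG_ini": 8.5})
        res = model.fit(n_starts=2, seed=0)
        text = res.summary()
        assert "k_step" in text and "chi2" in text and "(fixed)" in text
        df = res.predict()
        assert "model" in df.columns
        # log-scale residuals should scatter around zero
        assert np.abs(np.log10(df["model"] / df["value"])).mean() < 0.1
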