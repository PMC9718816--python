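"""First-passage solvers: MFPT, splitting, occupancies, coarse rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopwalk import (
    ModelParams,
    RateChain,
    TargetSpec,
    build_landscape,
    coarse_rates,
    formation_time,
    landscape_to_rates,
    mfpt,
    occupancies,
    partition_basins,
    splitting_probability,
)
from rloopwalk.rates import ChainStructureError


def uniform_chain(n, k_up, k_down, absorbing_top=False):
    return RateChain(up=np.full(n, float(k_up)), down=np.full(n, float(k_down)),
                     torque=0.0, absorbing_top=absorbing_top)


class TestMfpt:
    def test_pure_forward_chain_sums_step_times(self):
        # backward rates negligible: sequential Poisson steps, T = N/k
        ch = uniform_chain(10, 500.0, 1e-9)
        assert mfpt(ch, 0, {10}) == pytest.approx(10 / 500.0, rel=1e-6)

    def test_three_state_symmetric_hand_solution(self):
        # k = 1000/s on {0,1,2}, reflecting at 2, absorb {0}, start 2: 3 ms
        ch = uniform_chain(2, 1000.0, 1000.0)
        for method in ("linear", "sum", "flux"):
            assert mfpt(ch, 2, {0}, method=method) == pytest.approx(3.0e-3)

    def test_unbiased_walk_closed_form(self):
        # reflecting at 0, absorbing at N: T = N(N+1)/(2 k)
        n, k = 12, 700.0
        ch = uniform_chain(n, k, k)
        assert mfpt(ch, 0, {n}) == pytest.approx(n * (n + 1) / (2 * k))

    @pytest.mark.parametrize("seed", range(4))
    def test_backends_agree_on_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        up = rng.uniform(1.0, 3000.0, 9)
        down = rng.uniform(1.0, 3000.0, 9)
        ch = RateChain(up=up, down=down, torque=0.0, absorbing_top=False)
        ref = mfpt(ch, 2, {9}, method="linear")
        assert mfpt(ch, 2, {9}, method="sum") == pytest.approx(ref, rel=1e-9)
        assert mfpt(ch, 2, {9}, method="flux") == pytest.approx(ref, rel=1e-7)
        ref_down = mfpt(ch, 7, {1}, method="linear")
        assert mfpt(ch, 7, {1}, method="sum") == pytest.approx(ref_down, rel=1e-9)
        assert mfpt(ch, 7, {1}, method="flux") == pytest.approx(ref_down, rel=1e-7)

    def test_two_boundary_absorption(self):
        ch = uniform_chain(6, 800.0, 800.0)
        t_both = mfpt(ch, 3, {0, 6})
        assert t_both < mfpt(ch, 3, {0})
        assert t_both < mfpt(ch, 3, {6})

    def test_invalid_inputs(self):
        ch = uniform_chain(4, 1.0, 1.0)
        with pytest.raises(ChainStructureError):
            mfpt(ch, 2, set())
        with pytest.raises(ChainStructureError):
            mfpt(ch, 2, {2})
        with pytest.raises(ChainStructureError):
            mfpt(ch, 0, {9})


class TestSplitting:
    def test_symmetric_midpoint(self):
        ch = uniform_chain(8, 100.0, 100.0)
        assert splitting_probability(ch, 4, 0, 8) == pytest.approx(0.5)

    def test_complements_sum_to_one(self):
        rng = np.random.default_rng(3)
        ch = RateChain(up=rng.uniform(1, 100, 8), down=rng.uniform(1, 100, 8),
                       torque=0.0, absorbing_top=False)
        p_a = splitting_probability(ch, 3, 0, 8)
        # complement: probability of reaching 8 before 0
        ratios = [ch.down[j - 1] / ch.up[j] for j in range(1, 8)]
        rho = np.concatenate([[1.0], np.cumprod(ratios)])
        p_b_closed = rho[:3].sum() / rho.sum()  # product-formula oracle
        assert p_a + p_b_closed == pytest.approx(1.0, abs=1e-12)

    def test_biased_walk_against_product_formula(self):
        # every forward/backward ratio = e
        ch = RateChain(up=np.full(10, np.e * 100), down=np.full(10, 100.0),
                       torque=0.0, absorbing_top=False)
        # P(reach B=10 before A=0 from 5) by the product formula
        rho = np.exp(-np.arange(10))  # down/up products
        p_b = rho[:5].sum() / rho.sum()
        assert 1.0 - splitting_probability(ch, 5, 0, 10) == pytest.approx(p_b)

    def test_degenerate_start_at_boundary(self):
        ch = uniform_chain(4, 1.0, 1.0)
        assert splitting_probability(ch, 0, 0, 4) == 1.0
        assert splitting_probability(ch, 4, 0, 4) == 0.0

    def test_strong_downhill_near_boundary(self):
        ch = RateChain(up=np.full(6, 1e-3), down=np.full(6, 1e3),
                       torque=0.0, absorbing_top=False)
        assert splitting_probability(ch, 1, 0, 6) == pytest.approx(1.0, abs=1e-5)


class TestBasins:
    def test_partition_intermediate_only_target(self, params):
        t = TargetSpec.matched(12)
        ls = build_landscape(t, params, -4.7)
        basins = partition_basins(ls, t)
        assert basins.labels == ("U", "I")
        assert basins.basins[0].states == range(0, 1)
        # under net negative bias the representative sits at the far end
        assert basins.basins[1].representative == 12

    def test_partition_single_mismatch_cutoff(self, params):
        t = TargetSpec.single_mismatch(17, 6.9, distal_cutoff=27)
        ls = build_landscape(t, params, -4.2)
        basins = partition_basins(ls, t)
        assert basins.labels == ("U", "I", "F*")
        # representative of the basin ending just before the mismatch
        assert basins.basins[1].representative == 16
        assert basins.basins[2].states == range(17, 27)

    def test_partition_double_mismatch(self, params):
        t = TargetSpec(mismatches=((11, 6.9), (17, 6.9)), distal_cutoff=27)
        ls = build_landscape(t, params, -6.7)
        basins = partition_basins(ls, t)
        assert basins.labels == ("U", "I", "I*", "F*")

    def test_lock_competent_labels(self, params):
        t = TargetSpec(mismatches=((17, 6.9),))
        ls = build_landscape(t, params, -6.7)
        assert partition_basins(ls, t).labels == ("U", "I", "F")


class TestOccupancies:
    def test_two_level_boltzmann(self):
        p = ModelParams(dG_ini=-1.0, dG_bias_intrinsic=0.0)
        t = TargetSpec(hybrid_length=1, excluded_positions=frozenset())
        ls = build_landscape(t, p, 0.0)
        occ = occupancies(ls, partition_basins(ls, t))
        assert occ["F"] == pytest.approx(np.e / (1 + np.e))

    def test_flat_landscape_ratio(self):
        p = ModelParams(dG_ini=8.5, dG_bias_intrinsic=0.0)
        t = TargetSpec.matched(12)
        ls = build_landscape(t, p, 0.0)
        occ = occupancies(ls, partition_basins(ls, t))
        assert occ["I"] / occ["U"] == pytest.approx(12 * np.exp(-8.5))

    def test_normalization(self, params):
        t = TargetSpec(mismatches=((11, 4.0), (17, 6.9)), distal_cutoff=27)
        ls = build_landscape(t, params, -5.0)
        occ = occupancies(ls, partition_basins(ls, t))
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_deep_state_population_grows_with_torque(self, params):
        t = TargetSpec.single_mismatch(17, 6.9, distal_cutoff=27)
        prev = 0.0
        for tau in (-3.0, -4.0, -5.0, -6.0, -7.0):
            ls = build_landscape(t, params, tau)
            occ = occupancies(ls, partition_basins(ls, t))
            assert occ["F*"] > prev
            prev = occ["F*"]


class TestCoarseRates:
    def test_two_basin_reduction(self, params):
        t = TargetSpec.matched(12)
        ls = build_landscape(t, params, -4.7)
        ch = landscape_to_rates(ls, t, params)
        basins = partition_basins(ls, t)
        cr = coarse_rates(ch, basins)
        r = basins.basins[1].representative
        assert cr["k1"] == pytest.approx(1.0 / mfpt(ch, 0, {r}))
        assert cr["k2"] == pytest.approx(1.0 / mfpt(ch, r, {0}))

    def test_longer_intermediates_collapse_slower(self, params):
        k2 = {}
        for L in (12, 22):
            t = TargetSpec.matched(L)
            ls = build_landscape(t, params, -4.7)
            ch = landscape_to_rates(ls, t, params)
            k2[L] = coarse_rates(ch, partition_basins(ls, t))["k2"]
        assert k2[22] < k2[12]

    def test_torque_pushes_expansion_rates_up_collapse_down(self, params):
        t = TargetSpec.single_mismatch(17, 6.9, distal_cutoff=27)
        out = {}
        for tau in (-4.0, -6.0):
            ls = build_landscape(t, params, tau)
            ch = landscape_to_rates(ls, t, params)
            out[tau] = coarse_rates(ch, partition_basins(ls, t)).labeled()
        assert out[-6.0]["k3"] > out[-4.0]["k3"]
        assert out[-6.0]["k4"] < out[-4.0]["k4"]
        assert out[-6.0]["k1"] > out[-4.0]["k1"]
        assert out[-6.0]["k2"] < out[-4.0]["k2"]

    def test_rate_ratios_match_basin_free_energies(self, params):
        """Coarse detailed balance: k_ab / k_ba ~ basin partition functions."""
        t = TargetSpec.single_mismatch(17, 6.9, distal_cutoff=27)
        ls = build_landscape(t, params, -4.7)
        ch = landscape_to_rates(ls, t, params)
        basins = partition_basins(ls, t)
        cr = coarse_rates(ch, basins)
        G = ls.energies
        w = np.exp(-(G - G.min()))
        Z = {b.label: w[b.start:b.stop + 1].sum() for b in basins.basins}
        for a, b in (("U", "I"), ("I", "F*")):
            lhs = cr.rates[(a, b)] / cr.rates[(b, a)]
            assert lhs == pytest.approx(Z[b] / Z[a], rel=0.15)


class TestFormationTime:
    def test_initiation_limited_at_extreme_torque(self, params):
        """As torque grows strongly negative the downhill walk never
        returns and the formation time approaches 1/k+_0."""
        t = TargetSpec()
        ratios = []
        for tau in (-10.0, -20.0, -30.0):
            ls = build_landscape(t, params, tau)
            ch = landscape_to_rates(ls, t, params)
            ratios.append(formation_time(t, params, tau) * ch.up[0])
        assert np.all(np.diff(ratios) < 0)  # converging from above
        assert ratios[-1] == pytest.approx(1.0, rel=0.05)

    def test_mismatch_never_accelerates(self, params):
        wt = TargetSpec()
        mm = TargetSpec.single_mismatch(17, 6.9)
        for tau in (-3.0, -5.0, -7.0):
            assert formation_time(mm, params, tau) > formation_time(
                wt, params, tau)

    def test_plateau_at_wild_type_level(self, params):
        """Mismatch formation time decreases monotonically with negative
        torque and approaches the matched-target level."""
        mm = TargetSpec.single_mismatch(17, 6.9)
        wt = TargetSpec()
        taus = np.linspace(-2.0, -9.0, 8)
        times = [formation_time(mm, params, tau) for tau in taus]
        assert np.all(np.diff(times) < 0)
        assert times[-1] / formation_time(wt, params, taus[-1]) < 1.5
        assert times[0] / formation_time(wt, params, taus[0]) > 50

    def test_cutoff_target_rejected(self, params):
        with pytest.raises(ChainStructureError):
            formation_time(TargetSpec.matched(12), params, -5.0)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_mfpt_linear_vs_sum_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 12))
    up = rng.uniform(0.1, 5000.0, n)
    down = rng.uniform(0.1, 5000.0, n)
    ch = RateChain(up=up, down=down, torque=0.0, absorbing_top=False)
    start = int(rng.integers(0, n))
    ref = mfpt(ch, start, {n}, method="linear")
    assert mfpt(ch, start, {n}, method="sum") == pytest.approx(ref, rel=1e-9)
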