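"""Denaturation fitting, stability curves, linkage, and phase space."""

import math

import numpy as np
import pytest

from aggkin import (
    GAS_CONSTANT_KCAL,
    GibbsHelmholtzParams,
    InvalidParameterError,
    anchored_gibbs_helmholtz,
    default_linkage,
    dg_of_temperature,
    fit_denaturation,
    fit_linkage,
    nonnative_fraction,
    phase_space,
    preset_truth,
    simulate_denaturation,
)
from aggkin.mechanism import ArrheniusParam, ParameterSet


UREA = np.linspace(0.0, 9.5, 25)


class TestFitDenaturation:
    def test_noise_free_two_state_recovery(self):
        curve = simulate_denaturation(UREA, 4.0, 1.0)
        fit = fit_denaturation(curve, "2state")
        assert fit.dG_d == pytest.approx(4.0, rel=1e-6)
        assert fit.m_value == pytest.approx(1.0, rel=1e-6)

    def test_midpoint_identity(self):
        curve = simulate_denaturation(UREA, 6.0, 1.5,
                                      baselines={"sN": 0.01, "sD": -0.02})
        fit = fit_denaturation(curve, "2state")
        assert fit.midpoints[0] == pytest.approx(fit.dG_d / fit.m_value)
        assert fit.midpoints[0] == pytest.approx(4.0, rel=1e-4)

    def test_three_state_first_transition(self):
        # well-separated midpoints at 2 M and 6 M
        curve = simulate_denaturation(UREA, 4.0, 2.0,
                                      second_transition=(12.0, 2.0))
        fit = fit_denaturation(curve, "3state")
        assert fit.dG_d == pytest.approx(4.0, rel=0.05)
        assert fit.midpoints[0] == pytest.approx(2.0, rel=0.05)
        assert fit.midpoints[1] == pytest.approx(6.0, rel=0.05)

    def test_noisy_recovery_at_high_snr(self):
        """At SNR = 50 on a dense titration the estimator is unbiased and
        its RMS error stays below 5 % for both dG_d and m (seeded)."""
        rng = np.random.default_rng(7)
        dense = np.linspace(0.0, 9.5, 96)
        est = []
        for _ in range(40):
            curve = simulate_denaturation(dense, 4.0, 1.0, noise_sd=0.02,
                                          rng=rng)
            fit = fit_denaturation(curve, "2state")
            est.append((fit.dG_d, fit.m_value))
        est = np.array(est)
        assert est[:, 0].mean() == pytest.approx(4.0, rel=0.05)
        assert est[:, 1].mean() == pytest.approx(1.0, rel=0.05)
        assert np.sqrt(np.mean((est[:, 0] - 4.0) ** 2)) / 4.0 < 0.05
        assert np.sqrt(np.mean((est[:, 1] - 1.0) ** 2)) < 0.05

    def test_baseline_only_data_rejected(self):
        flat = simulate_denaturation(UREA, 4.0, 1.0,
                                     baselines={"bD": 1.0})  # no amplitude
        with pytest.raises(InvalidParameterError):
            fit_denaturation(flat, "2state")


class TestGibbsHelmholtz:
    def test_zero_at_melting_temperature(self):
        gh = GibbsHelmholtzParams()
        assert dg_of_temperature(gh, gh.T_m) == 0.0

    def test_closed_form_without_heat_capacity(self):
        gh = GibbsHelmholtzParams(70.0, 100.0, 0.0)
        expected = 100.0 * (1.0 - 278.15 / 343.15)
        assert dg_of_temperature(gh, 5.0) == pytest.approx(expected, rel=1e-12)

    def test_concave_with_maximum_below_tm(self):
        gh = GibbsHelmholtzParams(70.0, 150.0, 2.0)
        temps = np.linspace(0.0, 70.0, 71)
        vals = np.array([dg_of_temperature(gh, t) for t in temps])
        i_max = int(np.argmax(vals))
        assert 0 < i_max < 70
        d2 = np.diff(vals, 2)
        assert np.all(d2 < 1e-9)

    def test_anchoring_solves_melting_temperature(self):
        gh = GibbsHelmholtzParams()
        for dg25 in (0.5, 3.0, 8.0):
            anchored = anchored_gibbs_helmholtz(gh, dg25)
            assert dg_of_temperature(anchored, 25.0) == pytest.approx(
                dg25, abs=1e-6)
        # stability and melting temperature move together
        tms = [anchored_gibbs_helmholtz(gh, g).T_m for g in (1.0, 4.0, 9.0)]
        assert tms[0] < tms[1] < tms[2]


class TestNonnativeFraction:
    def test_zero_stability_is_half(self):
        assert nonnative_fraction(0.0, 25.0) == pytest.approx(0.5)

    def test_large_stability_vanishes(self):
        assert nonnative_fraction(50.0, 25.0) < 1e-30

    def test_closed_form_at_3_kcal(self):
        k = math.exp(-3.0 / (GAS_CONSTANT_KCAL * 298.15))
        assert nonnative_fraction(3.0, 25.0) == pytest.approx(k / (1 + k))
        assert nonnative_fraction(3.0, 25.0) == pytest.approx(6.3e-3, rel=0.01)


class TestLinkage:
    def test_exact_line_recovered(self):
        pairs = [(g, math.exp(-13.0 - 0.4 * g)) for g in (1.0, 3.0, 5.0, 8.0)]
        lm = fit_linkage(pairs)
        assert lm.intercept == pytest.approx(-13.0, abs=1e-9)
        assert lm.slope == pytest.approx(-0.4, abs=1e-9)
        assert lm.r_squared == pytest.approx(1.0)

    def test_noisy_slope_sign_and_permutation_null(self):
        rng = np.random.default_rng(11)
        dg = np.linspace(1.0, 9.0, 12)
        ln_k = -13.0 - 0.4 * dg + rng.normal(0.0, 0.3, dg.size)
        lm = fit_linkage(list(zip(dg, np.exp(ln_k))))
        assert lm.slope < 0
        assert lm.slope == pytest.approx(-0.4, abs=3 * lm.stderr_slope)
        # permuting the pairing destroys the correlation
        slopes = []
        for _ in range(30):
            perm = rng.permutation(dg.size)
            slopes.append(fit_linkage(list(zip(dg, np.exp(ln_k[perm])))).slope)
        assert abs(np.mean(slopes)) < abs(lm.slope) / 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_linkage([(1.0, 1e-6), (2.0, 1e-7)])


class TestPhaseSpace:
    @pytest.fixture(scope="class")
    def mab1_params(self):
        return preset_truth("mab1like").params

    def test_no_lt_initiation_means_zero_lt_share(self, mab1_params):
        params = ParameterSet(mab1_params)
        params["r_I"] = ArrheniusParam(0.0, params["r_I"].E_a)
        grid = phase_space([30.0, 50.0], [1.0, 5.0], params,
                           use_linkage=False)
        defined = ~np.isnan(grid.lt_share)
        assert defined.any()
        assert np.all(grid.lt_share[defined] == pytest.approx(0.0, abs=1e-9))

    def test_no_ht_pathway_means_full_lt_share(self, mab1_params):
        from aggkin.mechanism import knockout

        params = knockout(mab1_params, ["r_D", "r_D2", "r_Dn"])
        grid = phase_space([30.0, 50.0], [2.0, 6.0], params)
        defined = ~np.isnan(grid.lt_share)
        assert defined.any()
        assert np.all(grid.lt_share[defined] == pytest.approx(1.0, abs=1e-9))

    def test_boundary_temperature_rises_with_stability(self, mab1_params):
        """The LT->HT switch temperature (share crossing 0.5) is
        nondecreasing in dG_25."""
        temps = np.array([20.0, 27.5, 35.0, 42.5, 50.0, 57.5])
        dgs = np.array([1.0, 3.0, 5.0, 8.0])
        grid = phase_space(temps, dgs, mab1_params)
        boundary = []
        for j in range(len(dgs)):
            share = grid.lt_share[:, j]
            below = np.where(share < 0.5)[0]
            boundary.append(temps[below[0]] if below.size else temps[-1] + 5)
        assert all(b2 >= b1 for b1, b2 in zip(boundary, boundary[1:]))

    def test_stability_dependence_steep_below_3_and_shallow_above(
            self, mab1_params):
        """At a moderate temperature the apparent rate drops steeply with
        stability below ~3 kcal/mol (non-native seeding) and gently above
        (k_I linkage); disabling each mechanism removes its regime."""
        t_row = [30.0]
        low, high = [0.5, 1.5, 2.5], [5.0, 7.0, 9.0]
        full = phase_space(t_row, low + high, mab1_params)
        ka = full.k_app[0]
        slope_low = (math.log(ka[0]) - math.log(ka[2])) / 2.0
        slope_high = (math.log(ka[3]) - math.log(ka[5])) / 4.0
        assert slope_low > 2.0 * slope_high > 0.0

        no_seed = phase_space(t_row, low, mab1_params, seed_nonnative=False)
        ks = no_seed.k_app[0]
        slope_low_ns = (math.log(ks[0]) - math.log(ks[2])) / 2.0
        assert slope_low_ns < slope_low / 2.0

        no_link = phase_space(t_row, high, mab1_params, use_linkage=False)
        kl = no_link.k_app[0]
        slope_high_nl = abs(math.log(kl[0]) - math.log(kl[2])) / 4.0
        assert slope_high_nl < slope_high / 2.0

    def test_undefined_cells_are_nan_not_errors(self, mab1_params):
        # a very stable molecule at refrigerator temperature never reaches
        # 1 % dimers within the ten-year cap
        grid = phase_space([5.0], [9.0], mab1_params)
        assert np.isnan(grid.lt_share[0, 0])
        assert np.isnan(grid.t_1pct[0, 0])

    def test_axis_validation(self, mab1_params):
        with pytest.raises(InvalidParameterError):
            phase_space([100.0], [5.0], mab1_params)
        with pytest.raises(InvalidParameterError):
            phase_space([50.0], [12.0], mab1_params)
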