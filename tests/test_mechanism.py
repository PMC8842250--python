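"""Mechanism construction, Arrhenius rates, and integrator behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggkin import (
    ArrheniusParam,
    Condition,
    GAS_CONSTANT_KCAL,
    InvalidParameterError,
    ParameterSet,
    StiffnessError,
    T_REF_K,
    arrhenius_rate,
    build_scheme,
    fraction_map,
    simulate,
)
from aggkin.mechanism import zero_params


def closed_form_rate(k_ref, e_a, t_c):
    """Independent closed-form Arrhenius evaluation."""
    return k_ref * math.exp(
        -(e_a / GAS_CONSTANT_KCAL) * (1.0 / (t_c + 273.15) - 1.0 / T_REF_K)
    )


class TestArrheniusRate:
    @pytest.mark.parametrize(
        "k_ref,e_a,t_c",
        [
            (1e-6, 18.0, 5.0),     # at the reference temperature
            (1e-6, 0.0, 75.0),     # zero activation energy
            (1e-6, 18.0, 40.0),    # generic evaluation
            (0.05, 20.0, 65.0),
        ],
    )
    def test_matches_closed_form(self, k_ref, e_a, t_c):
        got = arrhenius_rate(ArrheniusParam(k_ref, e_a), t_c)
        assert got == pytest.approx(closed_form_rate(k_ref, e_a, t_c), rel=1e-12)

    def test_reference_temperature_returns_k_ref(self):
        assert arrhenius_rate(ArrheniusParam(1e-6, 18.0), 5.0) == pytest.approx(1e-6)

    def test_example_value_at_40C(self):
        # frozen from the closed form: 1e-6 * exp(3.639816...) = 3.8083e-5
        got = arrhenius_rate(ArrheniusParam(1e-6, 18.0), 40.0)
        assert got == pytest.approx(3.8083e-5, rel=1e-4)

    @given(st.floats(min_value=-20.0, max_value=90.0),
           st.floats(min_value=-20.0, max_value=90.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_temperature(self, t1, t2):
        p = ArrheniusParam(1e-4, 25.0)
        k1, k2 = arrhenius_rate(p, t1), arrhenius_rate(p, t2)
        if t1 + 1e-6 < t2:
            assert k1 < k2
        elif t1 > t2 + 1e-6:
            assert k1 > k2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            arrhenius_rate(ArrheniusParam(1e-6, 18.0), -300.0)
        with pytest.raises(InvalidParameterError):
            ArrheniusParam(float("nan"), 18.0)
        with pytest.raises(InvalidParameterError):
            ArrheniusParam(1e-6, -1.0)


class TestBuildScheme:
    def test_trimer_capped_scheme(self):
        s = build_scheme(3)
        assert len(s.reactions) == 5
        assert len(s.species) == 6
        assert "HMW" not in s.species_names

    def test_hmw_scheme_shares_growth_parameter(self):
        s = build_scheme(4)
        assert len(s.reactions) == 6
        assert len(s.species) == 7
        growth = [r for r in s.reactions if r.param_label == "r_Dn"]
        assert len(growth) == 2
        assert len(s.param_labels) == 5

    @pytest.mark.parametrize("n", [3, 4])
    def test_every_reaction_mass_balanced(self, n):
        s = build_scheme(n)
        sizes = {sp.name: sp.stoichiometric_size for sp in s.species}
        for r in s.reactions:
            lhs = sum(sizes[nm] * c for nm, c in r.reactants)
            rhs = sum(sizes[nm] * c for nm, c in r.products)
            assert lhs == rhs

    def test_unsupported_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_scheme(5)


class TestFractionMap:
    def test_pure_native_is_all_monomer(self, scheme):
        f = fraction_map(scheme, {"N": 1e-4})
        assert f.as_array() == pytest.approx([100.0, 0.0, 0.0, 0.0])

    def test_mass_weighting_of_dimers(self, scheme):
        # equimolar N and D2: dimer carries twice the mass
        f = fraction_map(scheme, {"N": 1e-4, "D2": 1e-4})
        assert f.f_monomer == pytest.approx(100.0 / 3.0, abs=1e-9)
        assert f.f_dimer == pytest.approx(200.0 / 3.0, abs=1e-9)

    def test_intermediates_elute_as_monomer(self, scheme):
        f = fraction_map(scheme, {"N": 5e-5, "I": 3e-5, "D": 2e-5})
        assert f.f_monomer == pytest.approx(100.0)

    def test_zero_mass_rejected(self, scheme):
        with pytest.raises(InvalidParameterError):
            fraction_map(scheme, {"N": 0.0})


class TestSimulate:
    def test_no_reactions_means_constant_state(self, scheme, cond50):
        tc = simulate(scheme, zero_params(scheme), cond50, 1000.0)
        assert all(o.f_monomer == pytest.approx(100.0) for o in tc.observed)
        assert np.allclose(tc.state, tc.state[0])

    def test_lt_intermediate_alone_keeps_monomer_peak(self, scheme, cond50):
        params = zero_params(scheme)
        params["r_I"] = ArrheniusParam(1e-4, 18.0)
        tc = simulate(scheme, params, cond50, 1000.0)
        i_col = tc.species.index("I")
        assert tc.state[-1, i_col] > 0
        assert all(o.f_monomer == pytest.approx(100.0, abs=1e-9)
                   for o in tc.observed)

    @pytest.mark.parametrize("preset", ["mab1like", "mab3like", "lowstab"])
    @pytest.mark.parametrize("temperature", [40.0, 55.0, 65.0, 75.0])
    def test_linear_propagation_matches_reference(self, scheme, preset,
                                                  temperature):
        """Euler at 3000 steps vs adaptive oracle: within 1e-3 proportion
        on every SEC fraction up to roughly the 1 %-dimer horizon."""
        from aggkin import preset_truth

        params = preset_truth(preset).params
        cond = Condition(temperature, 50.0)
        t_end = {40.0: 2190.0, 55.0: 500.0, 65.0: 40.0, 75.0: 3.0}[temperature]
        times = np.linspace(0.0, t_end, 13)
        euler = simulate(scheme, params, cond, t_end, 3000,
                         "linear_propagation", times).observed_array()
        ref = simulate(scheme, params, cond, t_end, method="reference",
                       eval_times=times).observed_array()
        assert np.max(np.abs(euler - ref)) / 100.0 < 1e-3

    def test_first_order_convergence(self, scheme, mab1):
        """Halving the step size roughly halves the integration error."""
        cond = Condition(65.0, 50.0)
        times = np.linspace(0.0, 40.0, 9)
        ref = simulate(scheme, mab1.params, cond, 40.0, method="reference",
                       eval_times=times).observed_array()
        errs = []
        for n in (750, 1500, 3000, 6000):
            e = simulate(scheme, mab1.params, cond, 40.0, n,
                         eval_times=times).observed_array()
            errs.append(np.max(np.abs(e - ref)))
        assert errs[0] > errs[1] > errs[2] > errs[3]
        ratios = [errs[i] / errs[i + 1] for i in range(3)]
        assert all(1.5 < r < 2.5 for r in ratios)

    def test_mass_conservation_reference(self, scheme, mab1):
        for t_c, t_end in ((40.0, 4380.0), (75.0, 6.0)):
            cond = Condition(t_c, 50.0)
            tc = simulate(scheme, mab1.params, cond, t_end, method="reference")
            mass = tc.state @ scheme.sizes
            assert np.max(np.abs(mass - mass[0])) / mass[0] < 1e-9

    def test_fractions_always_sum_to_100(self, scheme, mab1):
        tc = simulate(scheme, mab1.params, Condition(65.0, 100.0), 72.0)
        sums = tc.observed_array().sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_aggregation_nondecreasing_in_temperature(self, scheme, mab1):
        """With all activation energies positive, more heat means more
        aggregate at a fixed time and concentration."""
        aggs = []
        for t_c in (40.0, 50.0, 60.0, 70.0):
            tc = simulate(scheme, mab1.params, Condition(t_c, 50.0), 500.0)
            aggs.append(tc.total_aggregate()[-1])
        assert all(a2 >= a1 for a1, a2 in zip(aggs, aggs[1:]))

    def test_aggregation_nondecreasing_in_concentration(self, scheme, mab1):
        aggs = []
        for c in (10.0, 50.0, 150.0):
            tc = simulate(scheme, mab1.params, Condition(55.0, c), 500.0)
            aggs.append(tc.total_aggregate()[-1])
        assert all(a2 >= a1 for a1, a2 in zip(aggs, aggs[1:]))

    def test_stiff_system_raises_actionable_error(self, scheme, cond50):
        params = zero_params(scheme)
        # absurdly fast dimerisation makes the Euler grid overshoot
        params["r_D"] = ArrheniusParam(1e2, 0.0)
        params["r_D2"] = ArrheniusParam(1e12, 0.0)
        with pytest.raises(StiffnessError, match="n_steps"):
            simulate(scheme, params, cond50, 1000.0, n_steps=10)

    def test_eval_times_validation(self, scheme, mab1, cond50):
        with pytest.raises(InvalidParameterError):
            simulate(scheme, mab1.params, cond50, 10.0, eval_times=[0.0, 20.0])
        with pytest.raises(InvalidParameterError):
            simulate(scheme, mab1.params, cond50, -1.0)
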