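"""Structural model: micro-constants, closed forms vs the ODE oracle,
mass balance and superposition."""

import numpy as np
import pytest

from lactopk.model import (DoseEvent, PKParams, micro_constants,
                           milk_cumulative_closed, milk_fraction_of_dose,
                           plasma_conc_closed, solve_ode, terminal_halflife)

SINGLE = [DoseEvent(0.0, 2.2e8)]
TWO = [DoseEvent(0.0, 2.2e8), DoseEvent(168.0, 2.2e8)]


def random_params(rng):
    return PKParams(V=rng.uniform(1e4, 1e6), Cl=rng.uniform(1e3, 1e5),
                    V2=rng.uniform(1e4, 2e6), Cl2=rng.uniform(0.0, 5e4),
                    CLmilk=rng.uniform(0.0, 5e3), Ka=rng.uniform(0.01, 5.0))


class TestMicroConstants:
    def test_reference_values(self, theta_ref):
        mc = micro_constants(theta_ref)
        assert mc.k10 == pytest.approx(0.06733, rel=1e-3)
        assert mc.k21 == pytest.approx(0.018545, rel=1e-3)
        assert mc.beta == pytest.approx(0.011023, rel=1e-3)

    def test_decoupled_limit(self):
        p = PKParams(V=1e5, Cl=5e3, V2=2e5, Cl2=0.0, CLmilk=0.0, Ka=1.0)
        mc = micro_constants(p)
        assert mc.k12 == 0.0
        assert mc.alpha == pytest.approx(max(mc.k10, mc.k21))
        assert mc.beta == pytest.approx(min(mc.k10, mc.k21))

    def test_symmetric_function_identities(self, rng):
        for _ in range(20):
            p = random_params(rng)
            mc = micro_constants(p)
            assert mc.alpha + mc.beta == pytest.approx(mc.k10 + mc.k12 + mc.k21,
                                                       rel=1e-12)
            assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21,
                                                       rel=1e-10, abs=1e-18)
            assert mc.alpha >= mc.beta >= 0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            PKParams(V=-1.0, Cl=1.0, V2=1.0, Cl2=1.0, CLmilk=0.0, Ka=1.0)


class TestPlasmaClosedForm:
    def test_no_doses_is_zero(self, theta_ref):
        t = np.linspace(0, 100, 11)
        assert np.all(plasma_conc_closed(theta_ref, [], t) == 0.0)

    def test_zero_at_dose_time(self, theta_ref):
        # A + B + G = 0, so each dose contributes nothing at tau = 0
        c = plasma_conc_closed(theta_ref, SINGLE, np.array([0.0]))
        assert abs(c[0]) < 1e-9

    def test_against_ode_at_reference(self, theta_ref):
        t = np.array([360.0])
        c = plasma_conc_closed(theta_ref, SINGLE, t)
        sol = solve_ode(theta_ref, SINGLE, np.array([0.0, 360.0]))
        assert c[0] == pytest.approx(sol["C_plasma"][-1], rel=1e-8)

    def test_negative_time_rejected(self, theta_ref):
        with pytest.raises(ValueError):
            plasma_conc_closed(theta_ref, SINGLE, np.array([-1.0]))

    def test_superposition(self, theta_ref):
        t = np.linspace(0, 1000, 201)
        both = plasma_conc_closed(theta_ref, TWO, t)
        first = plasma_conc_closed(theta_ref, [TWO[0]], t)
        second = plasma_conc_closed(theta_ref, [TWO[1]], t)
        assert both == pytest.approx(first + second, rel=1e-12)


class TestMilkClosedForm:
    def test_no_milk_clearance(self):
        p = PKParams(V=1e5, Cl=1e4, V2=1e5, Cl2=1e3, CLmilk=0.0, Ka=0.3)
        t = np.linspace(0, 500, 21)
        assert np.all(milk_cumulative_closed(p, SINGLE, t) == 0.0)

    def test_infinite_time_limit(self, theta_ref):
        # total excreted fraction = CLmilk / (Cl + CLmilk)
        limit = 2.2e8 * theta_ref.CLmilk / (theta_ref.Cl + theta_ref.CLmilk)
        assert limit == pytest.approx(8.828e6, rel=1e-3)
        got = milk_cumulative_closed(theta_ref, SINGLE, np.array([5e6]))
        assert got[0] == pytest.approx(limit, rel=1e-6)

    def test_monotone_and_bounded(self, theta_ref):
        t = np.linspace(0, 3000, 301)
        m = milk_cumulative_closed(theta_ref, SINGLE, t)
        limit = 2.2e8 * milk_fraction_of_dose(theta_ref)
        assert np.all(np.diff(m) > 0)
        assert np.all(m < limit)


class TestOdeOracle:
    def test_closed_forms_match_ode_random_params(self, rng):
        # grid starts after the dose: at t=0 both forms are identically zero
        # up to floating cancellation
        t = np.linspace(0.5, 1536, 129)
        for _ in range(20):
            p = random_params(rng)
            sol = solve_ode(p, TWO, t)
            c = plasma_conc_closed(p, TWO, t)
            m = milk_cumulative_closed(p, TWO, t)
            cref = np.maximum(np.abs(sol["C_plasma"]), 1e-9 * sol["C_plasma"].max())
            assert np.max(np.abs(c - sol["C_plasma"]) / cref) < 1e-6
            if p.CLmilk > 0:
                mref = np.maximum(sol["Amilk"], 1e-9 * sol["Amilk"].max())
                assert np.max(np.abs(m - sol["Amilk"]) / mref) < 1e-6

    def test_mass_balance(self, theta_ref, rng):
        t = np.linspace(0, 1536, 65)
        for params in [theta_ref] + [random_params(rng) for _ in range(5)]:
            sol = solve_ode(params, TWO, t)
            total = (sol["Aa"] + sol["A1"] + sol["A2"] + sol["Amilk"]
                     + sol["Aelim"])
            dosed = np.array([sum(d.amount_ng for d in TWO if d.time_h <= tt)
                              for tt in t])
            assert total[1:] == pytest.approx(dosed[1:], rel=1e-6)

    def test_bolus_limit_fast_absorption(self, theta_ref):
        from dataclasses import replace
        fast = replace(theta_ref, Ka=1e4)
        sol = solve_ode(fast, SINGLE, np.array([0.0, 0.01]))
        assert sol["A1"][-1] == pytest.approx(2.2e8, rel=0.01)

    def test_two_dose_prefix_equals_single_dose(self, theta_ref):
        t = np.linspace(0, 167.9, 64)
        one = solve_ode(theta_ref, SINGLE, t)
        two = solve_ode(theta_ref, TWO, t)
        assert two["C_plasma"] == pytest.approx(one["C_plasma"], rel=1e-9)


class TestTerminalHalflife:
    def test_reference_value(self, theta_ref):
        assert terminal_halflife(theta_ref) == pytest.approx(62.9, rel=0.005)

    def test_one_compartment_limit(self):
        p = PKParams(V=1e5, Cl=1e4, V2=1.0, Cl2=0.0, CLmilk=0.0, Ka=100.0)
        assert terminal_halflife(p) == pytest.approx(np.log(2) * 1e5 / 1e4, rel=1e-9)

    def test_flip_flop(self, theta_ref):
        from dataclasses import replace
        slow = replace(theta_ref, Ka=0.001)
        assert terminal_halflife(slow) == pytest.approx(np.log(2) / 0.001, rel=1e-12)


class TestVariants:
    def test_one_compartment_closed_form_matches_ode(self):
        p = PKParams(V=2e5, Cl=2e4, V2=1.0, Cl2=0.0, CLmilk=900.0, Ka=0.3)
        t = np.linspace(0, 720, 61)
        sol = solve_ode(p, SINGLE, t)
        c = plasma_conc_closed(p, SINGLE, t)
        m = milk_cumulative_closed(p, SINGLE, t)
        assert c[1:] == pytest.approx(sol["C_plasma"][1:], rel=1e-7)
        assert m[1:] == pytest.approx(sol["Amilk"][1:], rel=1e-7)

    def test_three_compartment_eigen_matches_ode(self):
        p = PKParams(V=2e5, Cl=2e4, V2=4e5, Cl2=1e4, CLmilk=900.0, Ka=0.3,
                     V3=1e5, Cl3=3e3)
        t = np.linspace(0, 720, 61)
        sol = solve_ode(p, SINGLE, t)
        c = plasma_conc_closed(p, SINGLE, t)
        m = milk_cumulative_closed(p, SINGLE, t)
        assert c[1:] == pytest.approx(sol["C_plasma"][1:], rel=1e-6)
        assert m[1:] == pytest.approx(sol["Amilk"][1:], rel=1e-6)

    def test_ka_coincident_with_alpha_is_finite(self):
        p = PKParams(V=1e5, Cl=1e4, V2=1e5, Cl2=0.0, CLmilk=0.0, Ka=0.1)
        # k10 = 0.1 exactly equals Ka: the nudge must keep values finite
        c = plasma_conc_closed(p, SINGLE, np.linspace(0, 100, 11))
        assert np.all(np.isfinite(c))
        sol = solve_ode(p, SINGLE, np.linspace(0, 100, 11))
        assert c[1:] == pytest.approx(sol["C_plasma"][1:], rel=1e-5)
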