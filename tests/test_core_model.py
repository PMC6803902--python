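"""Unit and property tests for the multi-phase equilibrium solvers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdspme.core_model import (CDSpecies, CompoundParams, Spike, VialConfig,
                               headspace_fraction, phase_ratio,
                               solve_closed_system, solve_with_cd)
from cdspme.units import (mass_conc_to_molar, molar_conc_to_mass,
                          molar_mass_from_formula)

GUAIACOL_K = 2.2e4


def make_compound(name="guest", k1=GUAIACOL_K, k2=1e-3, kb=None, **kw):
    return CompoundParams(name=name, molar_mass=124.14, k1=k1, k2=k2,
                          kb=kb or {}, **kw)


class TestPhaseRatio:
    @pytest.mark.parametrize("v_h, v_liq, expected", [
        (13.5, 0.5, 27.0),    # 0.5 mL ampoule in a 20-mL vial with 6 mL sample
        (13.5, 6.0, 2.25),    # the sample phase of the same vial
        (12.0, 2.0, 6.0),     # largest ampoule volume studied
        (13.9, 0.1, 139.0),   # smallest ampoule volume studied
        (5.0, 5.0, 1.0),
    ])
    def test_known_ratios(self, v_h, v_liq, expected):
        assert phase_ratio(v_h, v_liq) == pytest.approx(expected, rel=1e-12)

    def test_vial_config_derives_both_ratios(self):
        vial = VialConfig(v_total=20.0, v_sample=6.0, v_istd=0.5)
        assert vial.v_headspace == pytest.approx(13.5)
        assert vial.beta_istd == pytest.approx(27.0)
        assert vial.beta_sample == pytest.approx(2.25)

    def test_rejects_nonpositive_liquid_volume(self):
        with pytest.raises(ValueError):
            phase_ratio(10.0, 0.0)

    def test_rejects_vanishing_headspace(self):
        with pytest.raises(ValueError):
            VialConfig(v_total=20.0, v_sample=19.0, v_istd=1.5)


class TestHeadspaceFraction:
    def test_fully_volatile_equal_volumes(self):
        assert headspace_fraction(1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_guaiacol_at_sample_phase_ratio(self):
        # C_0/(K + beta) with the literature water/air K for guaiacol
        assert headspace_fraction(1.0, GUAIACOL_K, 2.25) == \
            pytest.approx(4.5449e-5, rel=1e-4)

    def test_insensitive_to_istd_phase_ratio(self):
        # the ampoule's beta (6..139) is negligible against K = 2.2e4, which
        # is why the ISTD volume barely moves its headspace concentration
        lo = headspace_fraction(1.0, GUAIACOL_K, 139.0)
        hi = headspace_fraction(1.0, GUAIACOL_K, 6.0)
        assert 0 < (hi - lo) / hi < 0.0061

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            headspace_fraction(1.0, 0.0, 0.0)


class TestUnits:
    def test_guaiacol_millimolar(self):
        m = molar_mass_from_formula("C7H8O2")
        assert m == pytest.approx(124.14, abs=0.01)
        assert mass_conc_to_molar(124.14, 124.14) == pytest.approx(1e-3, rel=1e-12)

    def test_beta_cd_molarity_at_25_g_per_l(self):
        m = molar_mass_from_formula("C42H70O35")
        assert m == pytest.approx(1134.98, abs=0.02)
        assert CDSpecies("beta", m, 25.0).total_molar == \
            pytest.approx(2.2026e-2, rel=1e-3)

    @given(st.floats(1e-6, 1e6), st.floats(1.0, 2000.0))
    def test_round_trip_identity(self, value, molar_mass):
        back = molar_conc_to_mass(mass_conc_to_molar(value, molar_mass), molar_mass)
        assert back == pytest.approx(value, rel=1e-12)

    def test_rejects_unparseable_formula(self):
        with pytest.raises(ValueError):
            molar_mass_from_formula("C7X8")


class TestClosedSystem:
    def test_reduces_to_two_phase_limit(self):
        # with no fiber and no ampoule the closed form is C_0/(K1 + beta_s)
        vial = VialConfig(v_total=20.0, v_sample=6.0, v_istd=0.0, v_fiber=0.0)
        c = make_compound()
        state = solve_closed_system([Spike(c, 1e-5)], vial,
                                    "four_phase_short_extraction")
        expected = headspace_fraction(1e-5, c.k1, vial.beta_sample)
        assert state.c_h("guest") == pytest.approx(expected, rel=1e-12)

    @given(st.floats(1e-2, 1e6), st.floats(1e-4, 10.0), st.floats(1e-8, 1e-2),
           st.sampled_from(["three_phase", "four_phase_equilibrium",
                            "four_phase_short_extraction"]))
    def test_mass_conservation(self, k1, k2, c0, mode):
        vial = VialConfig(v_total=20.0, v_sample=6.0, v_istd=0.5)
        c = make_compound(k1=k1, k2=k2)
        state = solve_closed_system([Spike(c, c0)], vial, mode)
        assert state.max_residual <= 1e-12

    def test_ampoule_compound_short_extraction(self, vial):
        # an ISTD isolated in the ampoule equilibrates with headspace and
        # fiber only: C_s = 0 and C_h follows the two-phase closed form
        c = make_compound("istd")
        state = solve_closed_system([Spike(c, 1e-4, phase="istd")], vial,
                                    "four_phase_short_extraction")
        assert state["istd"]["c_s"] == 0.0
        # brute-force two-phase oracle: distribute n0 over ampoule+headspace
        # +fiber by scanning C_h and taking the best mass balance
        n0 = 1e-4 * vial.v_istd
        grid = np.linspace(0, n0 / vial.v_headspace, 2_000_001)
        imbalance = np.abs(
            grid / c.k3_resolved * vial.v_istd + grid * vial.v_headspace
            + grid / c.k2 * vial.v_fiber - n0)
        oracle = grid[np.argmin(imbalance)]
        assert state.c_h("istd") == pytest.approx(oracle, rel=1e-5)
        assert state.max_residual <= 1e-12

    def test_unknown_mode_rejected(self, vial):
        with pytest.raises(ValueError):
            solve_closed_system([Spike(make_compound(), 1e-5)], vial, "dynamic")


def quadratic_free_host(kb, n0, h_total, vial, params,
                        mode="four_phase_short_extraction"):
    """Closed-form positive root of the 1:1 single-guest host balance."""
    d0 = (params.k1 * vial.v_sample + vial.v_headspace
          + vial.v_fiber / params.k2)
    a = params.k1 * vial.v_sample
    qa = a * kb
    qb = d0 + kb * params.k1 * n0 - a * kb * h_total
    qc = -h_total * d0
    return (-qb + np.sqrt(qb * qb - 4 * qa * qc)) / (2 * qa)


class TestCDBinding:
    def test_zero_binding_identical_to_closed_form(self, vial):
        c = make_compound(kb={"beta": 0.0})
        cd = CDSpecies("beta", 1134.98, 25.0)
        spikes = [Spike(c, 1e-5)]
        plain = solve_closed_system(spikes, vial)
        bound = solve_with_cd(spikes, cd, vial)
        for col in ("c_s", "c_h", "c_i", "c_f", "c_x"):
            assert bound["guest"][col] == pytest.approx(
                plain["guest"][col], abs=1e-12)

    def test_single_guest_matches_quadratic_oracle(self, vial):
        kb, c0 = 500.0, 8e-6
        c = make_compound(kb={"beta": kb})
        cd = CDSpecies("beta", 1134.98, 25.0)
        state = solve_with_cd([Spike(c, c0)], cd, vial)
        oracle = quadratic_free_host(kb, c0 * vial.v_sample, cd.total_molar,
                                     vial, c)
        assert state.free_host == pytest.approx(oracle, rel=1e-10)
        assert state.max_residual <= 1e-9

    @given(kb=st.floats(1.0, 1e5), c0=st.floats(1e-7, 1e-4))
    def test_quadratic_oracle_property(self, kb, c0, vial):
        c = make_compound(kb={"beta": kb})
        cd = CDSpecies("beta", 1134.98, 25.0)
        state = solve_with_cd([Spike(c, c0)], cd, vial)
        oracle = quadratic_free_host(kb, c0 * vial.v_sample, cd.total_molar,
                                     vial, c)
        assert state.free_host == pytest.approx(oracle, rel=1e-10)

    def test_huge_dose_empties_headspace(self, vial):
        c = make_compound(kb={"beta": 500.0})
        spikes = [Spike(c, 8e-6)]
        doses = [0.0, 1.0, 25.0, 2500.0]
        chs = []
        for dose in doses:
            cd = CDSpecies("beta", 1134.98, dose)
            chs.append(solve_with_cd(spikes, cd, vial).c_h("guest"))
        assert all(a > b for a, b in zip(chs, chs[1:]))
        assert chs[-1] < 1e-2 * chs[0]

    def test_c_h_monotone_in_kb_dose_and_k1(self, vial):
        base = dict(c0=8e-6, dose=25.0, kb=100.0, k1=GUAIACOL_K)

        def ch(c0, dose, kb, k1):
            c = make_compound(k1=k1, kb={"beta": kb})
            return solve_with_cd([Spike(c, c0)],
                                 CDSpecies("beta", 1134.98, dose), vial).c_h("guest")

        for key, factor in (("kb", 3.0), ("dose", 3.0), ("k1", 3.0)):
            lo = ch(**base)
            hi = ch(**{**base, key: base[key] * factor})
            assert hi < lo

    def test_temperature_scaled_k1_raises_headspace(self, vial):
        # a 100-fold K1 drop (the 35->80 degC change reported for guaiacol)
        # must strictly increase the headspace concentration
        cold = make_compound(k1=GUAIACOL_K)
        hot = make_compound(k1=GUAIACOL_K / 100.0)
        spikes_cold, spikes_hot = [Spike(cold, 1e-5)], [Spike(hot, 1e-5)]
        assert solve_closed_system(spikes_hot, vial).c_h("guest") > \
            solve_closed_system(spikes_cold, vial).c_h("guest")

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            CDSpecies("beta", 1134.98, -1.0)


class TestCompoundParams:
    def test_isotopologue_inherits_parent_constants(self):
        parent = make_compound("guaiacol", kb={"beta": 13.0})
        iso = CompoundParams.isotopologue(parent, "d3-guaiacol", 127.16)
        assert iso.k1 == parent.k1 and iso.k2 == parent.k2
        assert dict(iso.kb) == {"beta": 13.0}
        assert iso.isotopologue_of == "guaiacol"

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_compound(k1=0.0)
        with pytest.raises(ValueError):
            make_compound(kb={"beta": -1.0})
        with pytest.raises(ValueError):
            CompoundParams(name="x", molar_mass=-5.0, k1=1.0)
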