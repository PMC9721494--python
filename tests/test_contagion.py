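"""SIS contagion core: reproduction numbers, equilibria, rare-mutant limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sociality import (
    ContagionParams,
    DimorphicParams,
    dimorphic_equilibrium,
    dimorphic_rhs,
    mono_equilibrium,
    mono_rhs,
    mutant_rare_equilibrium,
    mutant_rare_sensitivities,
    net_reproduction_number,
    reproduction_numbers,
    simulate_mono,
)
from sociality.contagion import _dimorphic_ode_equilibrium


class TestReproductionNumbers:
    @pytest.mark.parametrize("rates, want_Rg, want_c, want_Rb", [
        ((2, 0.5, 0.25, 1, 1), 1.0, 0.5, 0.5),
        ((0, 0.5, 0.25, 1, 1), 0.0, 0.5, 0.0),
        ((3, 0.4, 0.4, 2, 2), 0.6, 1.0, 0.6),
    ])
    def test_rate_conversion(self, rates, want_Rg, want_c, want_Rb):
        p = reproduction_numbers(*rates)
        assert p.R_g == pytest.approx(want_Rg)
        assert p.c == pytest.approx(want_c)
        assert p.R_b == pytest.approx(want_Rb)

    @pytest.mark.parametrize("rates", [
        (2, 0.5, 0.25, 0, 1),    # zero recovery rate
        (2, 0.0, 0.25, 1, 1),    # p_g = 0 leaves c undefined
        (-1, 0.5, 0.25, 1, 1),   # negative interaction rate
        (2, 1.5, 0.25, 1, 1),    # probability outside [0, 1]
    ])
    def test_domain_errors(self, rates):
        with pytest.raises(ValueError):
            reproduction_numbers(*rates)

    def test_inconsistent_raw_rates_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ContagionParams(R_g=2.0, c=0.5, sigma=2, p_g=0.5, p_b=0.25,
                            gamma_g=1, gamma_b=1)


class TestMonoDynamics:
    @pytest.mark.parametrize("R, I_g, want", [
        (2.0, 0.0, 0.0),      # contagion-free is an equilibrium
        (2.0, 0.5, 0.0),      # endemic equilibrium 1 - 1/R
        (2.0, 0.25, 0.125),   # 2 * 0.75 * 0.25 - 0.25
    ])
    def test_rhs(self, R, I_g, want):
        dI_g, _ = mono_rhs(I_g, 0.0, ContagionParams(R_g=R, c=1.0))
        assert dI_g == pytest.approx(want)

    def test_rhs_domain_error(self):
        with pytest.raises(ValueError):
            mono_rhs(1.5, 0.0, ContagionParams(R_g=2, c=1))

    @pytest.mark.parametrize("R, c, want_Ig, want_Ib", [
        (4.0, 0.25, 0.75, 0.0),          # c*R = 1 exactly: at-threshold extinct
        (7.0, 0.25, 6 / 7, 1 - 1 / 1.75),
        (0.5, 1.0, 0.0, 0.0),
        (1.0, 1.0, 0.0, 0.0),            # threshold convention R <= 1
    ])
    def test_equilibrium(self, R, c, want_Ig, want_Ib):
        eq = mono_equilibrium(ContagionParams(R_g=R, c=c))
        assert eq.I_g == pytest.approx(want_Ig)
        assert eq.I_b == pytest.approx(want_Ib)
        assert eq.S_b == pytest.approx(1 - want_Ib)

    def test_simulation_reaches_closed_form(self):
        p = ContagionParams(R_g=4, c=0.2)
        t = np.linspace(0, 100, 201)
        traj = simulate_mono(p, (0.01, 0.01), t)
        assert traj.I_g[-1] == pytest.approx(0.75, abs=1e-6)
        # c R = 0.8 < 1: the bad contagion dies out exponentially
        assert traj.I_b[-1] == pytest.approx(0.0, abs=1e-6)

    def test_equilibrium_is_fixed_point_and_zero_absorbing(self):
        p = ContagionParams(R_g=3, c=2.0)
        eq = mono_equilibrium(p)
        t = np.linspace(0, 20, 21)
        traj = simulate_mono(p, (eq.I_g, eq.I_b), t)
        assert np.allclose(traj.I_g, eq.I_g, atol=1e-8)
        assert np.allclose(traj.I_b, eq.I_b, atol=1e-8)
        traj0 = simulate_mono(p, (0.0, 0.0), t)
        assert np.all(traj0.I_g == 0) and np.all(traj0.I_b == 0)


class TestNetReproductionNumber:
    def test_limits_and_arithmetic(self):
        assert net_reproduction_number(4.0, 5.0, 0.0) == pytest.approx(4.0)
        assert net_reproduction_number(3.0, 3.0, 0.7) == pytest.approx(3.0)
        assert net_reproduction_number(4.0, 5.0, 0.5) == pytest.approx(20.5 / 4.5)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            net_reproduction_number(0.0, 5.0, 0.0)


class TestDimorphic:
    def test_rhs_zero_state(self):
        dp = DimorphicParams(R_r=4, R_m=5, f=0.5, c=0.25)
        assert np.all(dimorphic_rhs([0, 0, 0, 0], dp) == 0)

    def test_rhs_collapses_to_mono_for_equal_strategies(self, rng):
        dp = DimorphicParams(R_r=3.0, R_m=3.0, f=0.4, c=0.7)
        p = ContagionParams(R_g=3.0, c=0.7)
        for _ in range(10):
            I_g, I_b = rng.uniform(0, 1, 2)
            d = dimorphic_rhs([I_g, I_g, I_b, I_b], dp)
            mg, mb = mono_rhs(I_g, I_b, p)
            assert d[0] == pytest.approx(mg) and d[1] == pytest.approx(mg)
            assert d[2] == pytest.approx(mb) and d[3] == pytest.approx(mb)

    def test_rhs_rare_mutant_limit(self):
        # f = 0: resident terms follow the monomorphic equation; the mutant
        # term is driven by the resident prevalence only
        dp = DimorphicParams(R_r=4.0, R_m=6.0, f=0.0, c=0.5)
        I_r, I_m = 0.6, 0.3
        d = dimorphic_rhs([I_r, I_m, 0, 0], dp)
        assert d[0] == pytest.approx(4 * (1 - I_r) * I_r - I_r)
        assert d[1] == pytest.approx(6 * (1 - I_m) * I_r - I_m)

    def test_equilibrium_threshold_zeros(self):
        dp = DimorphicParams(R_r=0.8, R_m=1.2, f=0.5, c=0.5)
        eq = dimorphic_equilibrium(dp)
        # R_net = (0.5*1.44 + 0.5*0.64) / (0.5*2.0) = 1.04 > 1: good endemic
        assert eq.I_r_g > 0 and eq.I_m_g > 0
        assert eq.I_r_b == 0 and eq.I_m_b == 0  # c*R_net = 0.52 <= 1

    def test_equilibrium_rare_mutant_consistency(self):
        dp = DimorphicParams(R_r=4.0, R_m=7.0, f=0.0, c=0.25)
        eq = dimorphic_equilibrium(dp)
        mono = mono_equilibrium(ContagionParams(R_g=4.0, c=0.25))
        I_m_g, S_m_b = mutant_rare_equilibrium(7.0, 4.0, 0.25)
        assert eq.I_r_g == pytest.approx(mono.I_g, abs=1e-10)
        assert eq.I_m_g == pytest.approx(I_m_g, abs=1e-10)
        assert eq.S_m_b == pytest.approx(S_m_b, abs=1e-10)

    def test_equilibrium_matches_ode_oracle(self):
        dp = DimorphicParams(R_r=4.0, R_m=5.0, f=0.5, c=0.25)
        eq = dimorphic_equilibrium(dp)
        ode = _dimorphic_ode_equilibrium(dp)
        got = [eq.I_r_g, eq.I_m_g, eq.I_r_b, eq.I_m_b]
        assert np.allclose(got, ode, atol=1e-6)

    def test_higher_contact_means_higher_prevalence(self):
        eq = dimorphic_equilibrium(DimorphicParams(R_r=4, R_m=5, f=0.3, c=0.5))
        assert eq.I_m_g > eq.I_r_g
        assert eq.I_m_b > eq.I_r_b

    @given(R_r=st.floats(0.1, 8), R_m=st.floats(0.1, 8),
           f=st.floats(0.0, 1.0), c=st.floats(0.1, 4.0))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_threshold_property(self, R_r, R_m, f, c):
        """A contagion is endemic in the mixed population iff its net
        reproduction number exceeds 1."""
        dp = DimorphicParams(R_r=R_r, R_m=R_m, f=f, c=c)
        eq = dimorphic_equilibrium(dp)
        R_net = net_reproduction_number(R_r, R_m, f)
        good = (eq.I_r_g, eq.I_m_g)
        bad = (eq.I_r_b, eq.I_m_b)
        if R_net <= 1:
            assert good == (0.0, 0.0)
        else:
            assert all(I > 0 for I in good)
        if c * R_net <= 1:
            assert bad == (0.0, 0.0)
        else:
            assert all(I > 0 for I in bad)


class TestMutantRare:
    @pytest.mark.parametrize("R_m, R_r, c, want_I, want_S", [
        (4.0, 3.0, 4.0, 8 / 11, 3 / 47),
        (7.0, 4.0, 0.25, 21 / 25, 1.0),   # c R_r = 1: threshold branch
        (5.0, 0.9, 0.5, 0.0, 1.0),        # resident cannot sustain either
    ])
    def test_closed_form(self, R_m, R_r, c, want_I, want_S):
        I_m_g, S_m_b = mutant_rare_equilibrium(R_m, R_r, c)
        assert I_m_g == pytest.approx(want_I)
        assert S_m_b == pytest.approx(want_S)

    def test_collapses_to_mono_at_equal_strategies(self):
        for R, c in [(4, 0.25), (7, 0.5), (2, 3.0)]:
            I_m_g, S_m_b = mutant_rare_equilibrium(R, R, c)
            eq = mono_equilibrium(ContagionParams(R_g=R, c=c))
            assert I_m_g == pytest.approx(eq.I_g)
            assert S_m_b == pytest.approx(eq.S_b)

    def test_local_sensitivities(self):
        dI, dS = mutant_rare_sensitivities(4.0, 4.0, 0.2)
        assert dI == pytest.approx(3 / 64)
        assert dS == 0.0  # c R_r = 0.8 <= 1: bad contagion absent
        dI, dS = mutant_rare_sensitivities(4.0, 4.0, 0.5)
        assert dS == pytest.approx(-(0.5 * 4 - 1) / (0.5**2 * 4**3))

    def test_sensitivities_match_finite_differences(self):
        h = 1e-6
        for R_m, R_r, c in [(4, 3, 4.0), (2, 5, 0.5), (6, 2, 1.0)]:
            dI, dS = mutant_rare_sensitivities(R_m, R_r, c)
            Ip, Sp = mutant_rare_equilibrium(R_m + h, R_r, c)
            Im, Sm = mutant_rare_equilibrium(R_m - h, R_r, c)
            assert dI == pytest.approx((Ip - Im) / (2 * h), abs=1e-6)
            assert dS == pytest.approx((Sp - Sm) / (2 * h), abs=1e-6)

    def test_requires_endemic_resident(self):
        with pytest.raises(ValueError):
            mutant_rare_sensitivities(2.0, 1.0, 0.5)

    @given(R_r=st.floats(1.05, 8), c=st.floats(0.1, 4.0),
           R_lo=st.floats(0.5, 8), R_hi=st.floats(0.5, 8))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_in_mutant_strategy(self, R_r, c, R_lo, R_hi):
        """Exposure to both contagions increases with mutant sociality."""
        if R_lo == R_hi:
            return
        lo, hi = sorted((R_lo, R_hi))
        I_lo, S_lo = mutant_rare_equilibrium(lo, R_r, c)
        I_hi, S_hi = mutant_rare_equilibrium(hi, R_r, c)
        assert I_hi > I_lo  # R_r > 1 so the good contagion is endemic
        if c * R_r > 1:
            assert S_hi < S_lo
        else:
            assert S_hi == S_lo == 1.0
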