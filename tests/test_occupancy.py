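"""Occupancy solver: hijacking, dimensionless groups, closed forms vs the
ODE oracle, and profile classification."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bindkin as bk
from bindkin.occupancy import _hyp2f1_1b, SingularParameters
from conftest import make_problem


class TestEffectiveKoff:
    @pytest.mark.parametrize("koff, kmi, expected, hijacked", [
        (3.64e-4, 2.3e-3, 2.3e-3, True),   # D374Y PCSK9 vs clearance
        (1.0, 1e-3, 1.0, False),
        (1e-5, 1e-2, 1e-2, True),
    ])
    def test_hijack_rule(self, koff, kmi, expected, hijacked):
        eff = bk.effective_koff(bk.BindingKinetics(1e5, koff), kmi)
        assert eff.koff_prime == expected
        assert eff.hijacked is hijacked

    def test_rejects_nonpositive_site_decay(self):
        with pytest.raises(ValueError):
            bk.effective_koff(bk.BindingKinetics(1e5, 1e-3), 0.0)

    @given(koff=st.floats(1e-8, 1e2), kmi=st.floats(1e-8, 1e2),
           kon=st.floats(1e1, 1e9))
    @settings(max_examples=200, deadline=None)
    def test_hijack_monotonicity(self, koff, kmi, kon):
        """Kd' >= Kd always; the effective off-rate exceeds the intrinsic
        one exactly when koff sits strictly below the site decay rate."""
        kin = bk.BindingKinetics(kon, koff)
        eff = bk.effective_koff(kin, kmi)
        assert eff.Kd_prime >= kin.Kd
        assert (eff.koff_prime > koff) == (koff < kmi)


class TestKonSS:
    def test_values(self):
        assert bk.kon_ss(1e-4, 1e-9) == pytest.approx(1e6)
        assert bk.kon_ss(1e-2, 1e-9) == pytest.approx(1e8)
        assert bk.kon_ss(2e-3, 1e-9) == pytest.approx(2 * bk.kon_ss(1e-3, 1e-9))

    def test_zero_ligand_rejected(self):
        with pytest.raises(ValueError):
            bk.kon_ss(1e-3, 0.0)


class TestDimensionless:
    def test_balanced_groups(self):
        kin, eff, dose, to = make_problem(1e5, 1e-4, 1e-4, 1e-4, 1e-9)
        sys = bk.dimensionless(kin, eff, dose, to)
        assert sys.alpha == pytest.approx(1.0)
        assert sys.beta == pytest.approx(1.0)
        assert sys.c_inf == pytest.approx(0.5)
        assert (sys.lambda1, sys.lambda2, sys.lambda3) == (-2.0, -1.0, 0.0)

    def test_tenfold_ligand_raises_alpha_only(self):
        kin, eff, dose, to = make_problem(1e5, 1e-4, 1e-4, 1e-4, 1e-8)
        sys = bk.dimensionless(kin, eff, dose, to)
        assert sys.alpha == pytest.approx(10.0)
        assert sys.beta == pytest.approx(1.0)


class TestEquilibrium:
    def test_limits(self):
        assert bk.c_equilibrium(bk.DimensionlessSystem(3.0, 3.0, 1.0)) == 0.5
        assert bk.c_equilibrium(bk.DimensionlessSystem(19.0, 1.0, 1.0)) == \
            pytest.approx(0.95)
        assert bk.c_equilibrium(bk.DimensionlessSystem(2.0, 0.0, 1.0)) == 1.0
        with pytest.raises(ValueError):
            bk.c_equilibrium(bk.DimensionlessSystem(0.0, 0.0, 1.0))


class TestClosedFormScenario1:
    def test_wild_type_occupancy_at_settling(self):
        # measured endosomal-pH kinetics: ~82% at the site peak
        sys = bk.DimensionlessSystem(alpha=1.91565, beta=0.197, gamma=1.0)
        assert bk.c_closed_scenario1(sys, 3.0) == pytest.approx(0.822, abs=0.005)

    def test_saturating_balanced_groups_hold_half_fractional_occupancy(self):
        # alpha = beta >> 10: constant 50% of the available site, at
        # every time point (the steady-state profile)
        sys = bk.DimensionlessSystem(alpha=100.0, beta=100.0, gamma=1.0)
        for tau in (0.3, 1.5, 2.9):
            b = -math.expm1(-tau)
            frac = bk.c_closed_scenario1(sys, tau) / b
            assert frac == pytest.approx(0.5, abs=0.01)

    def test_singularity_raises(self):
        with pytest.raises(SingularParameters):
            bk.c_closed_scenario1(bk.DimensionlessSystem(0.6, 0.4, 2.0), 1.0)
        with pytest.raises(SingularParameters):  # alpha+beta == gamma
            bk.c_closed_scenario1(bk.DimensionlessSystem(1.0, 1.0, 2.0), 1.0)

    def test_paper_literal_decay_restarts_at_truncated_plateau(self):
        sys = bk.DimensionlessSystem(alpha=2.73, beta=0.23, gamma=1.0)
        c_lit = bk.c_closed_scenario1(sys, 3.0, continuity="paper_literal")
        assert c_lit == pytest.approx(0.95 * sys.c_inf, rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.05, 0.5, 2.0, 10.0, 50.0])
    @pytest.mark.parametrize("beta", [0.05, 0.3, 8.0, 40.0])
    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
    def test_matches_ode_integration(self, alpha, beta, gamma, tau_grid):
        """Closed form agrees with adaptive integration to 1e-6 on the
        full window (continuous decay initial condition)."""
        ki = 1e-3
        kon = alpha * ki / 1e-9
        kin = bk.BindingKinetics(kon, beta * gamma * ki)
        eff = bk.EffectiveKinetics(kon=kon, koff_prime=beta * gamma * ki,
                                   hijacked=False)
        to = bk.SiteTurnover(ki, gamma * ki)
        num = bk.solve_numeric(kin, eff, bk.LigandDose(1e-9), to, tau_grid)
        ana = bk.c_closed_scenario1(
            bk.DimensionlessSystem(alpha, beta, gamma), tau_grid)
        assert float(np.max(np.abs(num.c - ana))) < 1e-6


class TestClosedFormScenario2:
    def make_sys(self, kon=1e5, koff=1e-4, ki=1e-4, L0=1e-9):
        kin, eff, dose, to = make_problem(kon, koff, ki, ki, L0,
                                          bk.Scenario.LOGISTIC_STATE)
        return bk.dimensionless(kin, eff, dose, to), (kin, eff, dose, to)

    def test_initial_complex_respects_five_percent_site(self):
        sys, _ = self.make_sys()
        assert bk.c_closed_scenario2(sys, 0.0) <= 0.05 * sys.c_inf + 1e-3

    def test_buildup_approaches_equilibrium_fraction_of_site(self):
        # fast binding rides the site curve at the equilibrium fraction,
        # so by the settling time c ~ c_inf * b_total
        sys, (kin, eff, dose, to) = self.make_sys(kon=1e6)
        from bindkin.site_dynamics import XI_BAR_SCENARIO2
        tau = XI_BAR_SCENARIO2 - 1e-6
        c_near_peak = bk.c_closed_scenario2(sys, tau)
        expected = bk.c_equilibrium(sys) * bk.btotal_scenario2(to, tau)
        assert c_near_peak == pytest.approx(expected, rel=0.01)

    def test_equilibrium_regime_constant_fraction(self, tau_grid):
        # very slow turnover: the bound fraction rides at 50% throughout
        sys, (kin, eff, dose, to) = self.make_sys(ki=1e-7)
        traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
        frac = traj.fractional[1:]
        assert np.nanmax(np.abs(frac - 0.5)) < 0.005

    def test_unequal_rates_demand_numeric_fallback(self):
        sys = bk.DimensionlessSystem(2.0, 1.0, 0.16)
        with pytest.raises(SingularParameters):
            bk.c_closed_scenario2(sys, 1.0)

    @pytest.mark.parametrize("kon", [1e4, 1e5, 3e6])
    def test_matches_ode_integration(self, kon, tau_grid):
        sys, (kin, eff, dose, to) = self.make_sys(kon=kon)
        num = bk.solve_numeric(kin, eff, dose, to, tau_grid)
        ana = bk.c_closed_scenario2(sys, tau_grid)
        assert float(np.max(np.abs(num.c - ana))) < 1e-6


@pytest.mark.parametrize("b", [0.7, 3.2, 41.0, 2001.0])
@pytest.mark.parametrize("x", [-1e-5, -0.9, -7.0, -8600.0])
def test_hypergeometric_kernel_matches_arbitrary_precision(b, x):
    """The Pfaff-transformed 2F1(1, b; b+1; x) agrees with mpmath."""
    ref = float(mpmath.hyp2f1(1, b, b + 1, x))
    assert float(_hyp2f1_1b(b, x)) == pytest.approx(ref, rel=1e-11)


class TestNumericSolver:
    def test_conservation_and_bounds(self, tau_grid):
        kin, eff, dose, to = make_problem(1e6, 1e-3, 1e-4, 1e-4, 5e-9)
        traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
        np.testing.assert_allclose(traj.b_free + traj.c, traj.b_total,
                                   atol=1e-9)
        assert np.all(traj.c >= 0.0)
        assert np.all(traj.c <= traj.b_total + 1e-6)

    def test_equilibrium_regime_holds_95_percent(self, tau_grid):
        """Slow turnover at L0 = 19*Kd: bound fraction pinned at 95%."""
        kin, eff, dose, to = make_problem(1e5, 1e-4, 1e-8, 1e-8, 19e-9)
        traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
        frac = traj.fractional[1:]  # fraction undefined at tau = 0
        assert np.nanmax(np.abs(frac - 0.95)) < 0.01 * 0.95

    def test_bad_grid_rejected(self):
        kin, eff, dose, to = make_problem(1e5, 1e-4, 1e-3, 1e-3, 1e-9)
        with pytest.raises(ValueError):
            bk.solve_numeric(kin, eff, dose, to, np.array([0.0, 0.0, 1.0]))

    def test_peak_monotone_in_kon(self, tau_grid):
        """Holding Kd fixed, peak occupancy never drops as kon speeds."""
        peaks = []
        for kon in np.logspace(5, 7, 10):
            kin, eff, dose, to = make_problem(kon, kon * 1e-9, 1e-4, 1e-4, 1e-9)
            traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
            peaks.append(bk.peak_occupancy(traj)[0])
        assert np.all(np.diff(peaks) >= -1e-9)

    def test_residence_time_futility_below_site_decay(self, tau_grid):
        """With kon < kon_ss, slowing koff 1e5-fold below the site decay
        rate leaves the trajectory unchanged: dissociation is hijacked."""
        base = None
        for koff in [1e-2, 1e-4, 1e-7]:
            kin, eff, dose, to = make_problem(5e5, koff, 1e-2, 1e-2, 1e-9)
            traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
            if base is None:
                base = traj.c
            else:
                assert float(np.max(np.abs(traj.c - base))) < 0.01


class TestClassification:
    def run(self, kon, koff, ki, kmi, L0, scenario=bk.Scenario.EXP_SPECIES):
        kin, eff, dose, to = make_problem(kon, koff, ki, kmi, L0, scenario)
        tau = np.linspace(0, 12, 1201)
        traj = bk.solve_numeric(kin, eff, dose, to, tau)
        sys = bk.dimensionless(kin, eff, dose, to)
        return bk.classify_profile(traj, sys, turnover=to, dose=dose)

    def test_slow_turnover_is_steady_state_at_half_occupancy(self):
        rep = self.run(1e5, 1e-4, 1e-8, 1e-8, 1e-9)
        assert rep.label is bk.Profile.SSO
        assert rep.c_inf == pytest.approx(0.5)
        assert rep.max_relative_deviation < 0.01

    def test_fast_turnover_slow_kon_is_non_steady_state(self):
        # kon 1000-fold below kon_ss: occupancy cannot keep up
        rep = self.run(1e5, 1e-4, 1e-2, 1e-2, 1e-9)
        assert rep.label is bk.Profile.NSSO
        assert rep.c_peak < 0.01
        assert not rep.meets_kon_ss

    def test_saturating_ligand_reaches_quasi_steady_state(self):
        rep = self.run(1e4, 1e-5, 1e-3, 1e-3, 1e-6)
        assert rep.label in (bk.Profile.QSSO, bk.Profile.SSO)
        assert rep.occupancy_multiple >= 10.0

    def test_kon_at_threshold_is_steady_state(self):
        rep = self.run(1e4, 1e-5, 1e-6, 1e-6, 1e-9)
        assert rep.label is bk.Profile.SSO
        assert rep.meets_kon_ss

    def test_equilibrium_limit_recovers_hill_occupancy(self):
        """As turnover slows with kinetics fixed, the profile becomes SSO
        and the fraction matches the static Hill value within 1%."""
        kon, koff, L0 = 1e6, 1e-3, 2e-9
        rep = self.run(kon, koff, 1e-8, 1e-8, L0)
        hill = bk.hill_occupancy(L0, koff / kon)
        assert rep.label is bk.Profile.SSO
        assert rep.c_inf == pytest.approx(hill, rel=0.01)


class TestPeakOccupancy:
    def test_steady_state_peak_equals_equilibrium_fraction(self, tau_grid):
        kin, eff, dose, to = make_problem(1e5, 1e-4, 1e-8, 1e-8, 1e-9)
        traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
        c_peak, _ = bk.peak_occupancy(traj)
        sys = bk.dimensionless(kin, eff, dose, to)
        assert c_peak == pytest.approx(sys.c_inf, rel=0.06)

    def test_buildup_only_grid_peaks_at_last_point(self):
        kin, eff, dose, to = make_problem(1e6, 1e-4, 1e-4, 1e-4, 1e-9)
        tau = np.linspace(0.0, 2.5, 251)  # ends before settling
        traj = bk.solve_numeric(kin, eff, dose, to, tau)
        _, tau_peak = bk.peak_occupancy(traj)
        assert tau_peak == tau[-1]

    def test_pcsk9_wild_type_peak(self, pcsk9_wt_acidic, tau_grid):
        kin, eff, dose, to = pcsk9_wt_acidic
        traj = bk.solve_numeric(kin, eff, dose, to, tau_grid)
        c_peak, tau_peak = bk.peak_occupancy(traj)
        assert c_peak == pytest.approx(0.83, abs=0.005)
        assert 3.0 < tau_peak < 3.2
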