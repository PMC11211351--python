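"""Structural model: covariate submodels, PK superposition, Hill inhibition
and the transit-chain INR dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from warfinr.model_core import (
    DEFAULT_THETA,
    PatientRecord,
    ThetaVector,
    clearance_for,
    concentration_profile,
    individual_ec50,
    inhibition,
    inr_trajectory,
    transit_deficit,
    typical_ec50,
)

TH = DEFAULT_THETA


class TestClearance:
    @pytest.mark.parametrize("diplo, expected", [
        ("*1/*1", 0.348),     # 0.174 + 0.174
        ("*1/*3", 0.2162),    # 0.174 + 0.0422
        ("*2/*3", 0.1301),    # 0.0879 + 0.0422
    ])
    def test_additive_allele_model_at_reference_age(self, diplo, expected):
        assert clearance_for(diplo, TH.age_ref) == pytest.approx(expected)

    def test_age_slope_is_minus_0p571_percent_per_year(self):
        cl60 = clearance_for("*1/*1", 60.0)
        cl70 = clearance_for("*1/*1", 70.0)
        assert cl70 / cl60 == pytest.approx(1.0 - 0.00571 * 10.0)

    def test_six_genotype_ordering(self):
        order = ["*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3"]
        for age in (30.0, 60.0, 80.0):
            cls = [clearance_for(g, age) for g in order]
            assert all(a > b for a, b in zip(cls, cls[1:]))

    def test_unknown_allele_named_in_error(self):
        with pytest.raises(ValueError, match=r"\*4"):
            clearance_for("*1/*4", 60.0)

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            clearance_for("*1/*1", 0.5)


class TestTypicalEc50:
    def test_reference_values(self):
        assert typical_ec50("AA", 60.0, 0) == pytest.approx(1.14)
        assert typical_ec50("GG", 60.0, 0) == pytest.approx(4.3)
        assert typical_ec50("AA", 60.0, 1) == pytest.approx(1.14 - 0.602)

    def test_weight_effect_is_22p9_percent_per_10kg(self):
        ratio = typical_ec50("AA", 70.0, 0) / typical_ec50("AA", 60.0, 0)
        assert round((ratio - 1.0) * 100.0, 1) == 22.9

    def test_ga_strictly_between_homozygotes(self):
        for wt in (45.0, 60.0, 90.0):
            for cm1 in (0, 1):
                aa = typical_ec50("AA", wt, cm1)
                ga = typical_ec50("GA", wt, cm1)
                gg = typical_ec50("GG", wt, cm1)
                assert aa < ga < gg

    # weights kept high enough that the amiodarone-shifted EC50 stays above
    # the positivity floor (the identity only holds above it)
    @given(wt=st.floats(45.0, 120.0),
           g=st.sampled_from(["AA", "GA", "GG"]))
    @settings(max_examples=50, deadline=None)
    def test_amiodarone_flag_shifts_by_exactly_0p602(self, wt, g):
        off = typical_ec50(g, wt, 0)
        on = typical_ec50(g, wt, 1)
        assert off - on == pytest.approx(0.602, abs=1e-12)

    @given(w1=st.floats(30.0, 119.0), dw=st.floats(0.5, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_weight(self, w1, dw):
        assert typical_ec50("AA", w1 + dw, 0) > typical_ec50("AA", w1, 0)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="AG"):
            typical_ec50("AG", 60.0, 0)

    def test_individual_ec50_lognormal(self):
        assert individual_ec50(1.14, 0.0) == pytest.approx(1.14)
        assert individual_ec50(1.14, np.log(2.0)) == pytest.approx(2.28)


class TestConcentration:
    times = np.linspace(0.0, 240.0, 241)

    def test_no_doses_gives_zero(self):
        c = concentration_profile([], 0.348, TH, self.times)
        assert np.all(c == 0.0)

    def test_washout_to_zero(self):
        c = concentration_profile([(0.0, 5.0)], 0.348, TH,
                                  np.array([0.0, 5000.0]))
        assert c[-1] < 1e-10

    def test_superposition_equals_sum_of_single_doses(self):
        doses = [(24.0 * k, 2.5) for k in range(7)]
        c_all = concentration_profile(doses, 0.3, TH, self.times)
        c_sum = sum(concentration_profile([d], 0.3, TH, self.times)
                    for d in doses)
        np.testing.assert_allclose(c_all, c_sum, rtol=1e-14)

    def test_steady_state_average_is_dose_over_cl_tau(self):
        cl, dose = 0.3, 2.5
        n_days = 100
        doses = [(24.0 * k, dose) for k in range(n_days)]
        t = np.linspace(24.0 * (n_days - 1), 24.0 * n_days, 2001)
        c = concentration_profile(doses, cl, TH, t)
        css_avg = np.trapezoid(c, t) / 24.0
        assert css_avg == pytest.approx(dose / (cl * 24.0), rel=1e-4)

    def test_ka_equal_ke_limit_is_continuous(self):
        ke = TH.ka  # force cl so that ke == ka
        cl = ke * TH.v_f
        t = np.linspace(0.0, 48.0, 100)
        c_limit = concentration_profile([(0.0, 5.0)], cl, TH, t)
        c_near = concentration_profile([(0.0, 5.0)], cl * (1 + 1e-9), TH, t)
        np.testing.assert_allclose(c_limit, c_near, rtol=1e-6, atol=1e-12)
        assert np.all(c_limit[1:] > 0)


class TestInhibition:
    def test_zero_concentration(self):
        assert inhibition(0.0, 1.14, TH) == 0.0

    def test_hill_midpoint(self):
        assert inhibition(1.14, 1.14, TH) == pytest.approx(TH.emax / 2)

    def test_monotone_and_bounded(self):
        c = np.linspace(0.0, 500.0, 200)
        e = inhibition(c, 1.14, TH)
        assert np.all(np.diff(e) > 0)
        assert np.all(e < TH.emax)
        assert inhibition(1e9, 1.14, TH) == pytest.approx(TH.emax, rel=1e-4)


class TestTransitChains:
    def test_constant_eff_fixed_point(self):
        # constant inhibition e: both chain outputs -> 1 - e, so the combined
        # deficit -> e and INR -> base + INRmax * e
        e = 0.05
        dt = 0.5
        nt = int(12 * TH.mtt2 / dt)
        d = transit_deficit(np.full(nt, e), dt, TH)
        assert d[-1] == pytest.approx(e, rel=1e-6)
        inr = 1.0 + TH.inr_max * d[-1]
        assert inr == pytest.approx(2.0, rel=1e-6)

    def test_fast_kernel_matches_generic_filter_path(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0.0, 0.15, size=(5, 400))
        d_fast = transit_deficit(u, 1.0, TH)
        d_ref, _ = transit_deficit(u, 1.0, TH, return_chains=True)
        np.testing.assert_allclose(d_fast, d_ref, atol=1e-12)

    def test_matches_ode_solver_oracle(self, patient):
        times = np.linspace(0.0, 800.0, 81)
        traj = inr_trajectory(patient, 0.1, TH, times, dt=0.5)
        cl_ = clearance_for(patient.cyp2c9, patient.age, TH)
        ec = individual_ec50(
            typical_ec50(patient.vkorc1, patient.weight, patient.cm1, TH), 0.1)
        k1, k2 = TH.n1 / TH.mtt1, TH.n2 / TH.mtt2

        def rhs(t, A):
            c = concentration_profile(patient.doses, cl_, TH, np.array([t]))[0]
            eff = inhibition(c, ec, TH)
            return [k1 * (1 - eff) - k1 * A[0], k1 * (A[0] - A[1]),
                    k2 * (1 - eff) - k2 * A[2], k2 * (A[2] - A[3])]

        sol = solve_ivp(rhs, (0.0, 800.0), [1.0] * 4, t_eval=times,
                        rtol=1e-8, atol=1e-10, max_step=4.0)
        inr_ref = patient.inr_base + TH.inr_max * (1 - (sol.y[1] + sol.y[3]) / 2)
        np.testing.assert_allclose(traj.inr, inr_ref, atol=5e-3)

    def test_zero_doses_inr_flat_at_baseline(self, patient):
        times = np.linspace(0.0, 500.0, 50)
        traj = inr_trajectory(patient, 0.0, TH, times, doses=[])
        np.testing.assert_allclose(traj.inr, patient.inr_base, atol=1e-12)

    def test_washout_returns_to_baseline(self, patient):
        t_end = patient.doses[-1][0] + 15.0 * TH.mtt2
        traj = inr_trajectory(patient, 0.0, TH, np.array([0.0, t_end]))
        assert traj.inr[-1] == pytest.approx(patient.inr_base, abs=2e-3)

    def test_trajectory_invariants(self, patient):
        times = np.linspace(0.0, 400.0, 100)
        traj = inr_trajectory(patient, -0.3, TH, times)
        assert np.all(traj.inr >= patient.inr_base - 1e-9)
        assert np.all(traj.inr <= patient.inr_base + TH.inr_max)
        assert np.all(traj.eff >= 0.0) and np.all(traj.eff < TH.emax)
        assert traj.chain1[0, 0] == pytest.approx(1.0)


class TestThetaVector:
    def test_mtt_composition(self):
        # MTT2 equals MTT1 plus the published inter-chain difference
        assert TH.mtt1 + 83.7 == pytest.approx(TH.mtt2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ThetaVector(mtt1=100.0, mtt2=50.0)
        with pytest.raises(ValueError):
            ThetaVector(emax=0.0)
        with pytest.raises(ValueError):
            ThetaVector.from_dict({"not_a_param": 1.0})

    def test_patient_record_validation(self):
        with pytest.raises(ValueError):
            PatientRecord("x", 60, 60, "*1/*1", "AA", 0, 1.0,
                          doses=[(0.0, 25.0)])
        with pytest.raises(ValueError):
            PatientRecord("x", 60, -5, "*1/*1", "AA", 0, 1.0)
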