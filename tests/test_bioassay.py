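"""Assay arithmetic: inhibition, IC50, degree of hydrolysis, yields."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snailpep import (
    AssayMeasurement,
    DoseResponseCurve,
    TitrationRecord,
    degree_of_hydrolysis,
    enzyme_substrate_ratio,
    fit_ic50,
    percent_inhibition,
    percent_yield,
    protein_from_nitrogen,
    round_mass,
)
from snailpep.synthetic_data import simulate_dose_response


class TestPercentInhibition:
    @pytest.mark.parametrize("control,sample,expected",
                             [(1.0, 1.0, 0.0), (1.0, 0.0, 100.0), (0.80, 0.20, 75.0)])
    def test_direct_arithmetic(self, control, sample, expected):
        m = AssayMeasurement(activity_control=control, activity_sample=sample)
        assert percent_inhibition(m) == pytest.approx(expected)

    def test_sample_above_control_is_negative(self):
        m = AssayMeasurement(activity_control=0.5, activity_sample=0.6)
        assert percent_inhibition(m) < 0

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="activity_control"):
            AssayMeasurement(activity_control=0.0, activity_sample=0.1)

    @given(
        control=st.floats(0.01, 10.0),
        s1=st.floats(0.0, 10.0),
        s2=st.floats(0.0, 10.0),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_scale_invariant(self, control, s1, s2, c):
        lo, hi = sorted((s1, s2))
        a = percent_inhibition(AssayMeasurement(control, lo))
        b = percent_inhibition(AssayMeasurement(control, hi))
        assert a >= b  # strictly decreasing in sample absorbance
        scaled = percent_inhibition(AssayMeasurement(control * c, lo * c))
        assert scaled == pytest.approx(a, abs=1e-8)


class TestFitIC50:
    def test_noiseless_recovery(self):
        doses = np.logspace(-2, 1, 8) * 0.3
        curve = simulate_dose_response(0.3, 1.0, doses, noise_sd=0.0, seed=0)
        fit = fit_ic50(curve)
        assert fit.method == "loglogistic"
        assert fit.ic50 == pytest.approx(0.3, rel=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-6)

    def test_midpoint_identity_of_fit(self):
        doses = np.logspace(-1.5, 1.5, 9) * 0.5
        curve = simulate_dose_response(0.5, 1.4, doses, noise_sd=0.0, seed=0)
        fit = fit_ic50(curve)
        # predicted inhibition at the fitted IC50 is the midpoint of the asymptotes
        pred = fit.bottom + (fit.top - fit.bottom) / (1 + (fit.ic50 / fit.ic50) ** 1)
        assert pred == pytest.approx((fit.top + fit.bottom) / 2)

    def test_two_point_log_linear_interpolation(self):
        curve = DoseResponseCurve(points=[(0.1, 20.0), (1.0, 80.0)])
        fit = fit_ic50(curve)
        assert fit.method == "interpolation"
        assert fit.ic50 == pytest.approx(10 ** -0.5, rel=1e-9)

    def test_all_below_50_unidentifiable(self):
        curve = DoseResponseCurve(points=[(0.1, 5.0), (0.3, 12.0), (1.0, 28.0)])
        with pytest.raises(ValueError, match="not identifiable"):
            fit_ic50(curve)

    def test_single_concentration_rejected(self):
        curve = DoseResponseCurve(points=[(0.5, 40.0), (0.5, 60.0)])
        with pytest.raises(ValueError, match="distinct"):
            fit_ic50(curve)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DoseResponseCurve(points=[(0.0, 10.0), (1.0, 60.0)])

    def test_recovery_under_noise(self):
        # median relative error over seeded noisy curves stays under 10%
        rng = np.random.default_rng(2024)
        errors = []
        for i in range(50):
            true_ic50 = 10 ** rng.uniform(np.log10(0.05), 0.0)
            hill = rng.uniform(0.8, 2.0)
            doses = np.logspace(-1.5, 1.5, 8) * true_ic50
            curve = simulate_dose_response(true_ic50, hill, doses, noise_sd=2.0,
                                           seed=10_000 + i)
            fit = fit_ic50(curve)
            errors.append(abs(fit.ic50 - true_ic50) / true_ic50)
        assert float(np.median(errors)) < 0.10


class TestDegreeOfHydrolysis:
    def test_direct_substitution(self):
        t = TitrationRecord(B=5.0, N_B=1.0, alpha_inv=1.2, M_P=10.0, h_tot=8.0)
        assert degree_of_hydrolysis(t) == pytest.approx(7.5)

    def test_no_base_no_hydrolysis(self):
        t = TitrationRecord(B=0.0, N_B=0.1, alpha_inv=1.2, M_P=10.0, h_tot=8.0)
        assert degree_of_hydrolysis(t) == 0.0

    @given(b=st.floats(0.0, 50.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_linear_homogeneous_in_B_and_NB(self, b, scale):
        base = TitrationRecord(B=b, N_B=0.1, alpha_inv=1.2, M_P=10.0, h_tot=8.0)
        doubled_b = TitrationRecord(B=b * scale, N_B=0.1, alpha_inv=1.2, M_P=10.0, h_tot=8.0)
        scaled_nb = TitrationRecord(B=b, N_B=0.1 * scale, alpha_inv=1.2, M_P=10.0, h_tot=8.0)
        assert degree_of_hydrolysis(doubled_b) == pytest.approx(
            scale * degree_of_hydrolysis(base), abs=1e-9)
        assert degree_of_hydrolysis(scaled_nb) == pytest.approx(
            scale * degree_of_hydrolysis(base), abs=1e-9)

    def test_invalid_template_rejected(self):
        with pytest.raises(ValueError, match="M_P"):
            TitrationRecord(B=1.0, N_B=0.1, alpha_inv=1.2, M_P=0.0, h_tot=8.0)


class TestYieldArithmetic:
    @pytest.mark.parametrize("recovered,total,printed",
                             [(3.98, 44.0, 9.05), (7.98, 44.0, 18.13), (0.0, 44.0, 0.0)])
    def test_recovery_percent(self, recovered, total, printed):
        # 7.98/44 is 18.136..., printed as 18.13: the source truncated, so
        # agreement is asserted to printed precision under either convention
        assert abs(percent_yield(recovered, total) - printed) <= 0.011

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            percent_yield(1.0, 0.0)

    @pytest.mark.parametrize("vol,mass,expected", [(1.76, 44.0, 4.0), (0.0, 44.0, 0.0),
                                                   (0.44, 44.0, 1.0)])
    def test_enzyme_substrate_ratio(self, vol, mass, expected):
        assert enzyme_substrate_ratio(vol, mass) == pytest.approx(expected)

    @pytest.mark.parametrize("n,expected", [(10.4784, 65.49), (0.0, 0.0), (16.0, 100.0)])
    def test_protein_from_nitrogen(self, n, expected):
        assert protein_from_nitrogen(n) == pytest.approx(expected)

    def test_nitrogen_out_of_range(self):
        with pytest.raises(ValueError):
            protein_from_nitrogen(17.0)
        with pytest.raises(ValueError):
            protein_from_nitrogen(-1.0)
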