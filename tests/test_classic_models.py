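"""Classic D12 models: hydrodynamic equations, the 2-parameter correlation,
and the hybrid Lennard-Jones model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracerdiff.classic_models import (
    MagalhaesFit,
    MagalhaesFitError,
    ZhuState,
    association_factor,
    combine_lj,
    magalhaes_fit,
    magalhaes_predict,
    tyn_calus,
    wilke_chang,
    zhu_d12,
    zhu_state,
)
from tracerdiff.compounds import CompoundProperties

positive = st.floats(min_value=1e-2, max_value=1e3)


class TestWilkeChang:
    def test_hand_evaluation(self):
        # ethanol solvent (phi = 1.5), Vbp2 = 96.42 cm3/mol
        d = wilke_chang(300.0, 1.0, 46.07, 96.42, phi=1.5)
        assert d == pytest.approx(1.190e-5, rel=5e-3)

    def test_linear_in_temperature(self):
        base = wilke_chang(300.0, 1.0, 100.0, 100.0)
        assert wilke_chang(600.0, 1.0, 100.0, 100.0) == pytest.approx(2 * base)

    @pytest.mark.parametrize(
        "solvent, phi",
        [("methanol", 1.9), ("67-56-1", 1.9), ("ethanol", 1.5), ("64-17-5", 1.5),
         ("n-hexane", 1.0), (None, 1.0)],
    )
    def test_association_factor(self, solvent, phi):
        assert association_factor(solvent) == phi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilke_chang(300.0, 0.0, 100.0, 100.0)
        with pytest.raises(ValueError):
            wilke_chang(-1.0, 1.0, 100.0, 100.0)

    @given(positive, positive, st.floats(min_value=1.1, max_value=10))
    def test_homogeneity(self, T, mu, k):
        """Degree +1 in T, degree -1 in viscosity."""
        base = wilke_chang(T, mu, 80.0, 120.0)
        assert wilke_chang(k * T, mu, 80.0, 120.0) == pytest.approx(k * base, rel=1e-9)
        assert wilke_chang(T, k * mu, 80.0, 120.0) == pytest.approx(base / k, rel=1e-9)


class TestTynCalus:
    def test_hand_evaluation(self):
        d = tyn_calus(300.0, 1.0, 100.0, 100.0)
        assert d == pytest.approx(8.93e-8 * 100.0 ** (-0.166) * 300.0, rel=5e-3)

    def test_decreasing_in_solute_volume(self):
        assert tyn_calus(300, 1, 100, 200) < tyn_calus(300, 1, 100, 100)

    @given(positive, positive, st.floats(min_value=1.1, max_value=10))
    def test_homogeneity(self, T, mu, k):
        base = tyn_calus(T, mu, 90.0, 150.0)
        assert tyn_calus(k * T, mu, 90.0, 150.0) == pytest.approx(k * base, rel=1e-9)
        assert tyn_calus(T, k * mu, 90.0, 150.0) == pytest.approx(base / k, rel=1e-9)


class TestMagalhaes:
    def test_exact_line_recovered(self):
        a_true, b_true = 2e-9, 1e-6
        records = [(T, mu, a_true * T / mu + b_true)
                   for T, mu in [(300, 1.0), (320, 0.8), (340, 0.6), (360, 0.5)]]
        fit = magalhaes_fit(records)
        assert fit.a == pytest.approx(a_true, rel=1e-10)
        assert fit.b == pytest.approx(b_true, rel=1e-6)
        assert fit.n_points == 4

    def test_three_point_least_squares(self):
        # x = T/mu = {1,2,3}, D12 = {1,2,2}; expected values from an
        # independent closed-form least-squares evaluation (np.polyfit).
        fit = magalhaes_fit([(1, 1, 1), (2, 1, 2), (3, 1, 2)])
        a_ref, b_ref = np.polyfit([1.0, 2.0, 3.0], [1.0, 2.0, 2.0], 1)
        assert (a_ref, b_ref) == pytest.approx((0.5, 2.0 / 3.0))
        assert fit.a == pytest.approx(a_ref)
        assert fit.b == pytest.approx(b_ref)

    def test_too_few_points(self):
        with pytest.raises(MagalhaesFitError):
            magalhaes_fit([(300, 1, 1e-5), (310, 1, 1.1e-5)])

    def test_degenerate_regressor(self):
        with pytest.raises(MagalhaesFitError):
            magalhaes_fit([(300, 1, 1e-5), (300, 1, 1.1e-5), (300, 1, 0.9e-5)])

    def test_predict_constant_fit(self):
        fit = MagalhaesFit(a=0.0, b=3e-6, n_points=3)
        assert magalhaes_predict(fit, 300.0, 1.0) == 3e-6
        assert magalhaes_predict(fit, 500.0, 0.1) == 3e-6

    def test_predict_plug_in_and_viscous_limit(self):
        fit = MagalhaesFit(a=2e-9, b=1e-6, n_points=3)
        assert magalhaes_predict(fit, 4.0, 1.0) == pytest.approx(8e-9 + 1e-6)
        assert magalhaes_predict(fit, 300.0, 1e12) == pytest.approx(1e-6, rel=1e-6)

    def test_negative_extrapolation_warns(self):
        fit = MagalhaesFit(a=1e-9, b=-1e-3, n_points=3)
        with pytest.warns(RuntimeWarning):
            assert magalhaes_predict(fit, 300.0, 1.0) < 0

    @given(
        st.floats(min_value=1e-10, max_value=1e-7),
        st.floats(min_value=-1e-6, max_value=1e-6),
    )
    def test_fit_predict_roundtrip_noiseless(self, a, b):
        """Noiseless affine data reproduce with AARD below 1e-10 %."""
        pts = [(280.0 + 20 * i, 1.2 - 0.1 * i, 0.0) for i in range(5)]
        pts = [(T, mu, a * T / mu + b) for T, mu, _ in pts]
        if any(d <= 0 for _, _, d in pts):
            return  # stay in the physical regime
        fit = magalhaes_fit(pts)
        rel = [abs(magalhaes_predict(fit, T, mu) - d) / d for T, mu, d in pts]
        assert 100 * max(rel) < 1e-10


def _compound(name, cas, M, Tc, Vc, Pc):
    return CompoundProperties(
        name=name, cas=cas, formula="X", M=M, Tc=Tc, Tb=0.65 * Tc, Pc=Pc, Vc=Vc,
        w=0.3, sigma_lj=5.0, eps_lj_over_kB=400.0,
    )


HEXANE_LIKE = _compound("hexane-like", "90000-00-1", 86.18, 507.5, 370.0, 30.1)
BENZENE_LIKE = _compound("benzene-like", "90000-00-2", 78.11, 562.2, 259.0, 48.9)


class TestZhuState:
    def test_combining_rule_arithmetic(self):
        sigma12, eps12, k12d = combine_lj(3.0, 400.0, 5.0, 400.0)
        assert k12d == pytest.approx(0.7926 * 0.25)
        assert sigma12 == pytest.approx((1 - 0.19815) * 4.0)
        assert eps12 == pytest.approx(400.0)

    def test_equal_diameters_no_correction(self):
        sigma12, eps12, k12d = combine_lj(4.2, 300.0, 4.2, 500.0)
        assert k12d == 0.0
        assert sigma12 == pytest.approx(4.2)
        assert eps12 == pytest.approx(math.sqrt(300.0 * 500.0))

    def test_identical_inputs_swap_invariant(self):
        """With identical solvent/solute LJ inputs the binary parameters
        reduce to the pure-component ones, so a swap changes nothing."""
        s_ab, e_ab, k = combine_lj(4.1, 320.0, 4.1, 320.0)
        assert (s_ab, e_ab, k) == (pytest.approx(4.1), pytest.approx(320.0), 0.0)
        # the energy combination is swap-symmetric in general
        _, e1, _ = combine_lj(3.5, 250.0, 4.5, 350.0)
        _, e2, _ = combine_lj(4.5, 350.0, 3.5, 250.0)
        assert e1 == pytest.approx(e2)

    def test_state_bookkeeping(self):
        st_ = zhu_state(300.0, 0.7, HEXANE_LIKE, BENZENE_LIKE)
        na = 6.02214076e23
        assert st_.rho_n1 == pytest.approx(0.7 * na / 86.18)
        assert st_.m1 == pytest.approx(86.18 / na)
        assert st_.rho12_star == pytest.approx(
            st_.rho_n1 * (st_.sigma12 * 1e-8) ** 3
        )
        assert st_.T12_star == pytest.approx(300.0 / st_.eps12_over_kB)

    def test_invalid_state_inputs(self):
        with pytest.raises(ValueError):
            zhu_state(-300.0, 0.7, HEXANE_LIKE, BENZENE_LIKE)
        with pytest.raises(ValueError):
            zhu_state(300.0, 0.0, HEXANE_LIKE, BENZENE_LIKE)


def _state(rho_star, t_star, sigma12=5.0, eps12=400.0, m1=1.4e-22):
    sigma_cm = sigma12 * 1e-8
    rho_n1 = max(rho_star, 1e-30) / sigma_cm**3 if rho_star > 0 else 1e20
    return ZhuState(
        sigma12=sigma12, eps12_over_kB=eps12, k12d=0.0,
        T12_star=t_star, rho12_star=rho_star,
        rho_n1=rho_n1 if rho_star > 0 else 1e20, m1=m1,
    )


class TestZhuD12:
    def test_zero_density_kinetic_limit(self):
        """At rho* = 0 the model collapses to the dilute-gas prefactor."""
        s = _state(0.0, 1.5)
        T = s.T12_star * s.eps12_over_kB
        d_kin = (
            (3 / 8) * math.sqrt(1.380649e-16 * T / (math.pi * s.m1))
            / (s.rho_n1 * (s.sigma12 * 1e-8) ** 2)
        )
        assert zhu_d12(s) == pytest.approx(d_kin, rel=1e-10)

    def test_inverse_sqrt_mass_scaling(self):
        d1 = zhu_d12(_state(0.5, 1.5, m1=1.0e-22))
        d4 = zhu_d12(_state(0.5, 1.5, m1=4.0e-22))
        assert d1 == pytest.approx(2 * d4, rel=1e-10)

    def test_monotone_decreasing_in_reduced_density(self):
        import warnings

        for t_star in [0.6, 1.0, 2.0, 4.0]:
            with warnings.catch_warnings():
                # the cold end of the grid leaves the validity domain; only
                # monotonicity is under test here
                warnings.simplefilter("ignore", RuntimeWarning)
                values = [
                    zhu_d12(_state(r, t_star)) for r in np.linspace(0.05, 1.0, 20)
                ]
            assert all(a > b for a, b in zip(values, values[1:]))

    def test_outside_validity_warns_but_returns(self):
        # dense, cold state drives the free-volume factor negative
        s = _state(1.4, 0.5)
        with pytest.warns(RuntimeWarning):
            assert isinstance(zhu_d12(s), float)

    def test_regression_pin_full_evaluation(self):
        """Hexane-like solvent / benzene-like solute at 300 K, 0.7 g/cm3;
        value frozen from an independent script evaluation."""
        s = zhu_state(300.0, 0.7, HEXANE_LIKE, BENZENE_LIKE)
        assert zhu_d12(s) == pytest.approx(4.481337574310756e-05, rel=1e-9)
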