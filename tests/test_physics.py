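"""Unit and property tests for the closed-form SLP physics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magslp
from magslp import (
    CoatingParams,
    FieldParams,
    InvalidParameterError,
    InvalidStateError,
    MaterialParams,
    MediumParams,
    ParticleParams,
)
from magslp.physics import (
    brown_time,
    effective_time,
    hydrodynamic_diameter,
    initial_susceptibility,
    langevin,
    langevin_argument,
    langevin_factor,
    magnetization,
    neel_time,
    slp_dispersed,
    slp_immobilized,
    slp_values,
)

from conftest import oracle_slp

NM = 1e-9
TABLE1 = MaterialParams(Ms=425e3, K=200e3, rho=5.29e3)
SALINE = MediumParams(eta=7e-4, T=300.0)
SHELL = CoatingParams(d=1.6 * NM)


class TestGeometry:
    @pytest.mark.parametrize(
        "D, d, expected",
        [(13.6 * NM, 1.6 * NM, 16.8 * NM), (22.8 * NM, 1.6 * NM, 26.0 * NM), (10 * NM, 0.0, 10 * NM)],
    )
    def test_hydrodynamic_diameter(self, D, d, expected):
        assert hydrodynamic_diameter(D, d) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_core_rejected(self):
        with pytest.raises(InvalidParameterError):
            hydrodynamic_diameter(0.0, 1.6 * NM)


class TestLangevin:
    @pytest.mark.parametrize(
        "Ms, D, H, expected",
        [(425e3, 13.6 * NM, 10e3, 1.6982812), (425e3, 22.8 * NM, 5e3, 4.0009896)],
    )
    def test_argument(self, Ms, D, H, expected):
        assert langevin_argument(Ms, D, H, 300.0) == pytest.approx(expected, rel=1e-6)

    def test_argument_zero_field(self):
        assert langevin_argument(425e3, 10 * NM, 0.0, 300.0) == 0.0

    def test_argument_bad_temperature(self):
        with pytest.raises(InvalidParameterError):
            langevin_argument(425e3, 10 * NM, 10e3, 0.0)

    def test_langevin_values(self):
        assert langevin(1.6983) == pytest.approx(0.4804702, rel=1e-6)
        assert langevin(0.0) == 0.0
        assert langevin(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_small_argument_series_matches_taylor(self):
        xi = np.logspace(-8, -2, 50)
        assert np.allclose(langevin(xi), xi / 3, rtol=1e-5)
        # relative error of L ~ xi/3 below 1e-6 for xi < 1e-2 per the Taylor remainder
        assert np.all(np.abs(langevin(1e-3) - 1e-3 / 3) / (1e-3 / 3) < 1e-6)

    @pytest.mark.parametrize(
        "xi, expected", [(0.0, 1.0), (1.6983, 0.8487373), (4.0011, 0.5628990)]
    )
    def test_saturation_factor(self, xi, expected):
        assert langevin_factor(xi) == pytest.approx(expected, rel=1e-6)

    @given(st.floats(min_value=1e-6, max_value=50.0))
    @settings(derandomize=True, max_examples=200)
    def test_langevin_monotone_and_bounded(self, xi):
        L = langevin(xi)
        assert 0 < L < 1
        assert langevin(xi * 1.01) > L
        fac = langevin_factor(xi)
        assert 0 < fac <= 1
        assert langevin_factor(xi * 1.01) < fac

    def test_magnetization_saturates(self):
        assert magnetization(425e3, 0.0) == 0.0
        assert magnetization(425e3, 1e4) == pytest.approx(425e3, rel=1e-3)
        assert magnetization(425e3, 1.6983) == pytest.approx(204199.8, rel=1e-5)


class TestSusceptibility:
    @pytest.mark.parametrize(
        "eps, D, expected",
        [(0.024, 13.6 * NM, 0.5774156), (0.15, 22.8 * NM, 17.004206), (0.0, 10 * NM, 0.0)],
    )
    def test_values(self, eps, D, expected):
        assert initial_susceptibility(eps, 425e3, D, 300.0) == pytest.approx(expected, rel=1e-6)

    def test_bad_epsilon(self):
        with pytest.raises(InvalidParameterError):
            initial_susceptibility(1.5, 425e3, 10 * NM, 300.0)


class TestRelaxationTimes:
    def test_neel_time_value(self):
        assert neel_time(1e-9, 200e3, 6.1 * NM, 300.0) == pytest.approx(3.1066e-7, rel=1e-4)

    def test_neel_zero_barrier_limit(self):
        assert neel_time(1e-9, 200e3, 0.1 * NM, 300.0) == pytest.approx(1e-9, rel=1e-4)

    def test_neel_overflow_guard(self):
        # 25 nm core: exponent ~395 < clamp, still finite but astronomically large
        assert math.isfinite(neel_time(1e-9, 200e3, 25 * NM, 300.0))
        # past the clamp the time is flagged effectively infinite
        t = neel_time(1e-9, 200e3, 40 * NM, 300.0)
        assert math.isinf(t) and 1.0 / t == 0.0

    @pytest.mark.parametrize(
        "Dh, expected", [(16.8 * NM, 1.25876e-6), (26.0 * NM, 4.66588e-6)]
    )
    def test_brown_time_value(self, Dh, expected):
        assert brown_time(7e-4, Dh, 300.0) == pytest.approx(expected, rel=1e-4)

    def test_brown_cubic_scaling(self):
        assert brown_time(7e-4, 20 * NM, 300.0) == pytest.approx(
            8 * brown_time(7e-4, 10 * NM, 300.0), rel=1e-12
        )

    def test_effective_time(self):
        assert effective_time(2e-7, 2e-7) == pytest.approx(1e-7, rel=1e-12)
        assert effective_time(math.inf, 3e-6) == pytest.approx(3e-6, rel=1e-12)
        assert effective_time(3.11e-7, 2.14e-7) == pytest.approx(1.26770e-7, rel=1e-4)

    def test_effective_time_both_infinite(self):
        with pytest.raises(InvalidStateError):
            effective_time(math.inf, math.inf)

    @given(
        st.floats(min_value=1e-9, max_value=1e-3),
        st.floats(min_value=1e-9, max_value=1e-3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_effective_below_either_channel(self, a, b):
        assert effective_time(a, b) <= min(a, b) * (1 + 1e-12)


class TestSLP:
    def test_immobilized_reference_point(self):
        bd = slp_immobilized(
            TABLE1, ParticleParams(D=6.2 * NM, epsilon=0.024), FieldParams(H=10e3, f=500e3), T=300.0
        )
        assert bd.Ps == pytest.approx(0.98479, rel=1e-4)
        assert bd.tau_B is None and bd.tau_eff == bd.tau_N

    def test_zero_field_dissipates_nothing(self):
        for fn, args in [
            (slp_immobilized, (TABLE1, ParticleParams(D=10 * NM, epsilon=0.024), FieldParams(H=0.0, f=500e3))),
            (slp_dispersed, (TABLE1, SHELL, SALINE, ParticleParams(D=10 * NM, epsilon=0.024), FieldParams(H=0.0, f=500e3))),
        ]:
            assert fn(*args).Ps == 0.0

    def test_dispersed_high_packing_point(self):
        # 22.8 nm core at 5 kA/m, 50 kHz, packing 0.15: printed reference 4.16 W/g
        bd = slp_dispersed(
            TABLE1, SHELL, MediumParams(eta=7e-4, T=300.0),
            ParticleParams(D=22.8 * NM, epsilon=0.15), FieldParams(H=5e3, f=50e3),
        )
        assert bd.Ps == pytest.approx(4.16, rel=0.01)

    def test_dispersed_brown_dominated_point(self):
        # 9.9 nm core at 30 kA/m, 1000 kHz: printed reference 30.16 W/g
        bd = slp_dispersed(
            TABLE1, SHELL, SALINE,
            ParticleParams(D=9.9 * NM, epsilon=0.024), FieldParams(H=30e3, f=1000e3),
        )
        assert bd.Ps == pytest.approx(30.16, rel=0.03)
        assert bd.tau_B < bd.tau_N

    def test_breakdown_invariants(self):
        bd = slp_dispersed(
            TABLE1, SHELL, SALINE,
            ParticleParams(D=12 * NM, epsilon=0.024), FieldParams(H=20e3, f=300e3),
        )
        assert bd.Ps >= 0 and bd.chi_i >= 0
        assert 0 <= bd.L < 1 and 0 < bd.langevin_factor <= 1
        assert bd.tau_eff <= min(bd.tau_N, bd.tau_B)


class TestModelProperties:
    """Structural invariants of the dissipation model."""

    @given(
        D=st.floats(min_value=2e-9, max_value=20e-9),
        H=st.floats(min_value=1e3, max_value=100e3),
        f=st.floats(min_value=5e4, max_value=2e6),
        eps=st.floats(min_value=0.005, max_value=0.3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_oracle_equivalence(self, D, H, f, eps):
        """Every breakdown field matches the independent one-pass evaluation."""
        ob = oracle_slp(D, H, f, eps)
        bd = slp_dispersed(
            TABLE1, SHELL, SALINE, ParticleParams(D=D, epsilon=eps), FieldParams(H=H, f=f)
        )
        for name in ("chi_i", "xi", "langevin_factor", "tau_N", "tau_B", "tau_eff", "Ps"):
            a, b = getattr(bd, name), getattr(ob, name)
            assert a == pytest.approx(b, rel=1e-12), name

    def test_linear_response_limit(self):
        # for vanishing field the saturation factor drops out exactly
        D, f, eps = 12e-9, 300e3, 0.024
        H = 1e-3  # xi ~ 2e-10
        bd = slp_dispersed(TABLE1, SHELL, SALINE, ParticleParams(D=D, epsilon=eps), FieldParams(H=H, f=f))
        wt = 2 * math.pi * f * bd.tau_eff
        expected = math.pi * magslp.MU0 * f * H**2 * bd.chi_i * wt / (1 + wt**2) / TABLE1.rho / 1000
        assert bd.Ps == pytest.approx(expected, rel=1e-5)

    def test_immobile_limit_of_dispersed_model(self):
        # in a glassy carrier the Brown channel freezes out and Eq. for the
        # dispersed case collapses onto the Néel-only expression
        D, eps = 5e-9, 0.024
        field = FieldParams(H=10e3, f=500e3)
        ref = slp_immobilized(TABLE1, ParticleParams(D=D, epsilon=eps), field, T=300.0)
        thick = MediumParams(eta=1e6, T=300.0)  # tau_B >> 1e6 tau_N at 5 nm
        bd = slp_dispersed(TABLE1, SHELL, thick, ParticleParams(D=D, epsilon=eps), field)
        assert bd.tau_B > 1e6 * bd.tau_N
        assert bd.Ps == pytest.approx(ref.Ps, rel=1e-6)

    @given(
        f=st.floats(min_value=1e4, max_value=5e6),
        tau=st.floats(min_value=1e-10, max_value=1e-3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_lorentzian_bound(self, f, tau):
        wt = 2 * math.pi * f * tau
        assert wt / (1 + wt * wt) <= 0.5 + 1e-15

    def test_lorentzian_peak_at_matched_frequency(self):
        # equality holds exactly when the drive period matches the relaxation time
        wt = 1.0
        assert wt / (1 + wt * wt) == 0.5

    def test_epsilon_linearity(self):
        field = FieldParams(H=30e3, f=500e3)
        lo = slp_dispersed(TABLE1, SHELL, SALINE, ParticleParams(D=11e-9, epsilon=0.075), field)
        hi = slp_dispersed(TABLE1, SHELL, SALINE, ParticleParams(D=11e-9, epsilon=0.15), field)
        assert hi.Ps == pytest.approx(2 * lo.Ps, rel=1e-12)

    def test_monotone_in_field_amplitude(self):
        H = np.linspace(5e3, 100e3, 40)
        ps = [
            slp_dispersed(TABLE1, SHELL, SALINE, ParticleParams(D=12e-9, epsilon=0.024), FieldParams(H=h, f=500e3)).Ps
            for h in H
        ]
        assert np.all(np.diff(ps) > 0)

    def test_coating_off_single_diameter(self):
        # with no shell the dispersed model sees exactly one diameter
        bare = CoatingParams(d=0.0)
        bd = slp_dispersed(TABLE1, bare, SALINE, ParticleParams(D=10e-9, epsilon=0.024), FieldParams(H=10e3, f=500e3))
        assert bd.Dh == pytest.approx(10e-9, rel=1e-15)
        assert bd.tau_B == pytest.approx(brown_time(7e-4, 10e-9, 300.0), rel=1e-12)

    def test_vectorized_kernel_matches_scalar_path(self):
        D = np.array([5e-9, 10e-9, 15e-9])
        vec = slp_values(
            D, material=TABLE1, epsilon=0.024, f=500e3, H=10e3, coating=SHELL, medium=SALINE
        )
        scal = [
            slp_dispersed(TABLE1, SHELL, SALINE, ParticleParams(D=d, epsilon=0.024), FieldParams(H=10e3, f=500e3)).Ps
            for d in D
        ]
        assert np.allclose(vec, scal, rtol=1e-14)
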