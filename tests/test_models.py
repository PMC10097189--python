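"""Closed-form model evaluators: frozen-value examples and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronoamp import (
    CONSTANTS,
    AnalyteSpec,
    BiexpParams,
    ButlerVolmerParams,
    CottrellParams,
    ElectrodeSpec,
    biexp_current,
    butler_volmer_density,
    cottrell_amplitude,
    cottrell_current,
    diffusion_length,
    hemispherical_limit_current,
    microdisk_array_current,
    microdisk_current,
    shoup_szabo_f,
    tau_of,
)
from chronoamp.models import A_per_m2_to_uA_per_cm2, uA_per_cm2_to_A_per_m2

F = CONSTANTS["F"]
R = CONSTANTS["R"]


class TestCottrell:
    @pytest.mark.parametrize(
        "t, expected",
        [(1.0, 0.00633), (4.0, 0.003165)],  # sqrt(1)=1; current halves at 4x time
    )
    def test_decay_values(self, t, expected):
        assert cottrell_current(t, CottrellParams(B0=0.00633)) == pytest.approx(expected)

    def test_vanishes_at_long_times(self):
        assert cottrell_current(1e18, CottrellParams(B0=0.00633)) < 1e-11

    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            cottrell_current(0.0, CottrellParams(B0=1.0))
        with pytest.raises(ValueError):
            cottrell_current(-1.0, CottrellParams(B0=1.0))

    @given(
        b0=st.floats(1e-6, 1e2),
        t1=st.floats(1e-3, 1e4),
        t2=st.floats(1e-3, 1e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_i_sqrt_t_invariant(self, b0, t1, t2):
        p = CottrellParams(B0=b0)
        lhs = cottrell_current(t1, p) * np.sqrt(t1)
        rhs = cottrell_current(t2, p) * np.sqrt(t2)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_amplitude_lumping(self, glucose):
        """B0 = n F A c sqrt(D/pi), frozen against direct arithmetic."""
        elec = ElectrodeSpec(A=1e-4, r=1e-6)
        assert cottrell_amplitude(glucose, elec).B0 == pytest.approx(
            2.818082786820404e-3, rel=1e-12
        )

    def test_amplitude_linear_in_concentration(self, glucose):
        elec = ElectrodeSpec(A=1e-4, r=1e-6)
        zero = AnalyteSpec(n=2, D=glucose.D, c=0.0)
        double = AnalyteSpec(n=2, D=glucose.D, c=2 * glucose.c)
        assert cottrell_amplitude(zero, elec).B0 == 0.0
        assert cottrell_amplitude(double, elec).B0 == pytest.approx(
            2 * cottrell_amplitude(glucose, elec).B0, rel=1e-12
        )


class TestConvergentDiffusion:
    def test_hemispherical_limit_value(self, glucose):
        # 2 pi r n F D c at r = 1 um
        assert hemispherical_limit_current(glucose, 1e-6) == pytest.approx(
            8.123551784712607e-9, rel=1e-12
        )

    def test_hemispherical_scalings(self, glucose):
        i1 = hemispherical_limit_current(glucose, 1e-6)
        assert hemispherical_limit_current(glucose, 3e-6) == pytest.approx(3 * i1)
        zero_c = AnalyteSpec(n=2, D=glucose.D, c=0.0)
        assert hemispherical_limit_current(zero_c, 1e-6) == 0.0
        with pytest.raises(ValueError):
            hemispherical_limit_current(glucose, -1e-6)

    def test_shoup_szabo_at_unit_tau(self):
        expected = 0.7854 + 0.8862 + 0.2146 * np.exp(-0.7823)
        assert shoup_szabo_f(1.0) == pytest.approx(expected, rel=1e-12)

    def test_shoup_szabo_steady_state_limit(self):
        assert abs(shoup_szabo_f(1.0000001e6) - 1.0) < 1e-3
        assert abs(shoup_szabo_f(1e12) - 1.0) < 1e-5

    def test_shoup_szabo_short_time_divergence(self):
        tau = 1e-8
        assert shoup_szabo_f(tau) == pytest.approx(0.8862 * tau**-0.5, rel=1e-3)

    @given(st.floats(1e-6, 1e9), st.floats(1.0001, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_shoup_szabo_strictly_decreasing(self, tau, factor):
        assert shoup_szabo_f(tau * factor) < shoup_szabo_f(tau)

    def test_tau_definition(self, glucose):
        assert tau_of(1.0, glucose, 1e-6) == pytest.approx(2680.0, rel=1e-12)
        assert tau_of(0.0, glucose, 1e-6) == 0.0
        # halving the radius quadruples tau
        assert tau_of(1.0, glucose, 0.5e-6) == pytest.approx(4 * 2680.0, rel=1e-12)

    def test_microdisk_steady_state(self, glucose):
        r = 1e-6
        i_inf = 4 * glucose.n * F * r * glucose.D * glucose.c
        assert i_inf == pytest.approx(5.171613688e-9, rel=1e-9)
        # tau > 1e6: within 0.1% of the convergent-diffusion plateau
        t_late = 1.0001e6 * r**2 / (4 * glucose.D)
        assert microdisk_current(t_late, glucose, r) == pytest.approx(i_inf, rel=1e-3)

    def test_microdisk_shape_factorization(self, glucose):
        r, t = 2e-6, 0.5
        i_inf = 4 * glucose.n * F * r * glucose.D * glucose.c
        ratio = microdisk_current(t, glucose, r) / i_inf
        assert ratio == pytest.approx(shoup_szabo_f(tau_of(t, glucose, r)), rel=1e-12)

    def test_microdisk_zero_concentration(self, glucose):
        zero_c = AnalyteSpec(n=2, D=glucose.D, c=0.0)
        t = np.array([0.1, 1.0, 10.0])
        assert np.all(microdisk_current(t, zero_c, 1e-6) == 0.0)

    def test_array_reduces_to_prefactor_times_shape(self, glucose):
        elec = ElectrodeSpec(A=1e-4, r=1e-7, N=1)
        t = 2.0
        pref = 4 * glucose.n * F * elec.A * glucose.D * glucose.c / (np.pi * elec.r)
        expected = pref * shoup_szabo_f(tau_of(t, glucose, elec.r))
        assert microdisk_array_current(t, glucose, elec) == pytest.approx(
            expected, rel=1e-12
        )

    def test_array_linear_in_disk_count(self, glucose):
        e1 = ElectrodeSpec(A=1e-4, r=1e-7, N=7)
        e2 = ElectrodeSpec(A=1e-4, r=1e-7, N=14)
        t = np.array([0.1, 1.0, 100.0])
        np.testing.assert_allclose(
            microdisk_array_current(t, glucose, e2),
            2 * microdisk_array_current(t, glucose, e1),
            rtol=1e-12,
        )

    def test_array_steady_state_prefactor(self, glucose):
        # N 4 n F A D c / (pi r), frozen by direct arithmetic
        elec = ElectrodeSpec(A=1e-4, r=1e-7, N=int(1e10))
        pref = elec.N * 4 * glucose.n * F * elec.A * glucose.D * glucose.c / (np.pi * elec.r)
        assert pref == pytest.approx(1.6461757644138138e10, rel=1e-9)
        t_late = 1e6 * elec.r**2 / (4 * glucose.D)
        assert microdisk_array_current(t_late, glucose, elec) == pytest.approx(
            pref, rel=1e-3
        )


class TestBiexp:
    def test_endpoint_currents(self, nanoporous_biexp):
        p = nanoporous_biexp
        # sum of amplitudes: 6.74e-4 + 0.00339 + 0.00333
        assert biexp_current(0.0, p) == pytest.approx(7.394e-3, rel=1e-12)
        assert biexp_current(1e6, p) == pytest.approx(p.a1, rel=1e-12)
        # frozen: a1 + a2 e^-3.63 + a3 e^-0.625
        assert biexp_current(10.0, p) == pytest.approx(
            2.546310422114389e-3, rel=1e-12
        )

    def test_amplitude_sum_identity(self, nanoporous_biexp):
        p = nanoporous_biexp
        assert biexp_current(0.0, p) - p.a1 == pytest.approx(p.a2 + p.a3, abs=1e-18)

    @given(
        a1=st.floats(0, 1e-2),
        a2=st.floats(1e-5, 1e-2),
        a3=st.floats(1e-5, 1e-2),
        k2=st.floats(1e-3, 1.0),
        dk=st.floats(1e-3, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_convex_decreasing(self, a1, a2, a3, k2, dk):
        p = BiexpParams(a1=a1, a2=a2, a3=a3, k1=k2 + dk, k2=k2)
        t = np.linspace(0, 100, 201)
        i = biexp_current(t, p)
        assert np.all(np.diff(i) <= 0)
        # convexity up to float rounding on ~1e-2-magnitude currents
        assert np.all(np.diff(i, 2) >= -1e-15)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            BiexpParams(a1=1e-4, a2=1e-3, a3=1e-3, k1=0.05, k2=0.5)


class TestButlerVolmer:
    def test_formal_potential_anchor(self, glucose):
        p = ButlerVolmerParams(k0=1e-5, alpha_a=0.5, Ef0=0.2, T=295.15)
        assert butler_volmer_density(0.2, glucose, p) == pytest.approx(
            p.k0 * F * glucose.c, rel=1e-12
        )

    def test_unit_exponent_step(self, glucose):
        p = ButlerVolmerParams(k0=1e-5, alpha_a=0.5, Ef0=0.0, T=295.15)
        e_step = R * p.T / (p.alpha_a * F)
        j0 = butler_volmer_density(0.0, glucose, p)
        assert butler_volmer_density(e_step, glucose, p) == pytest.approx(
            np.e * j0, rel=1e-12
        )

    def test_frozen_overpotential_value(self, glucose):
        p = ButlerVolmerParams(k0=1e-5, alpha_a=0.5, Ef0=0.0, T=295.15)
        assert butler_volmer_density(0.1, glucose, p) == pytest.approx(
            68.9087462727872, rel=1e-12
        )

    def test_log_current_affine_in_potential(self, glucose):
        p = ButlerVolmerParams(k0=1e-5, alpha_a=0.45, Ef0=0.1, T=300.0)
        E = np.linspace(-0.2, 0.5, 50)
        logj = np.log(butler_volmer_density(E, glucose, p))
        slope = np.polyfit(E, logj, 1)[0]
        assert slope == pytest.approx(p.alpha_a * F / (R * p.T), rel=1e-10)


class TestDiffusionLength:
    def test_one_second_value(self, glucose):
        assert diffusion_length(1.0, glucose) == pytest.approx(
            3.660601043544625e-5, rel=1e-12
        )

    def test_zero_and_scaling(self, glucose):
        assert diffusion_length(0.0, glucose) == 0.0
        assert diffusion_length(4.0, glucose) == pytest.approx(
            2 * diffusion_length(1.0, glucose), rel=1e-12
        )
        with pytest.raises(ValueError):
            diffusion_length(-1.0, glucose)


def test_spec_validation():
    with pytest.raises(ValueError):
        AnalyteSpec(n=0, D=1e-10, c=1.0)
    with pytest.raises(ValueError):
        AnalyteSpec(n=2, D=-1e-10, c=1.0)
    with pytest.raises(ValueError):
        ElectrodeSpec(A=0.0, r=1e-6)
    with pytest.raises(ValueError):
        ElectrodeSpec(A=1e-4, r=1e-6, N=0)
    with pytest.raises(ValueError):
        ButlerVolmerParams(k0=1e-5, alpha_a=1.5, Ef0=0.0)


def test_current_density_unit_roundtrip():
    x = np.array([0.5, 95.49, 652.39])
    assert uA_per_cm2_to_A_per_m2(100.0) == pytest.approx(1.0)
    np.testing.assert_allclose(A_per_m2_to_uA_per_cm2(uA_per_cm2_to_A_per_m2(x)), x)
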