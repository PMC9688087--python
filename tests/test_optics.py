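import cmath
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import nanoptt as nt
from nanoptt.optics import OpticsDomainError

EPS_GOLD_808 = complex(-24.718, 3.6581)  # size-corrected study value
EPS_HOST = complex(1.767, 0.0)


def depolarization_quadrature(a, b):
    """Independent oracle: spheroid depolarization integral by quadrature."""

    def integrand(s, axis2):
        return 1.0 / ((s + axis2) * math.sqrt((s + a * a) * (s + b * b) * (s + b * b)))

    p1 = a * b * b / 2.0 * quad(integrand, 0, np.inf, args=(a * a,), limit=200)[0]
    p2 = a * b * b / 2.0 * quad(integrand, 0, np.inf, args=(b * b,), limit=200)[0]
    return p1, p2


def mie_dipole_absorption(radius_nm, wavelength_nm, eps, eps_m):
    """Independent oracle: exact n=1 Mie term (Riccati-Bessel with complex
    argument), C_abs = C_ext - C_sca."""
    m = cmath.sqrt(eps) / cmath.sqrt(eps_m)
    if m.imag < 0:
        m = -m
    k = 2.0 * math.pi * math.sqrt(eps_m.real) / wavelength_nm
    x = k * radius_nm
    mx = m * x

    def psi1(z):
        return cmath.sin(z) / z - cmath.cos(z)

    def dpsi1(z):
        return cmath.cos(z) / z - cmath.sin(z) / z**2 + cmath.sin(z)

    def chi1(z):
        return cmath.cos(z) / z + cmath.sin(z)

    def dchi1(z):
        return -cmath.sin(z) / z - cmath.cos(z) / z**2 + cmath.cos(z)

    def xi1(z):
        return psi1(z) - 1j * chi1(z)

    def dxi1(z):
        return dpsi1(z) - 1j * dchi1(z)

    a1 = (m * psi1(mx) * dpsi1(x) - psi1(x) * dpsi1(mx)) / (
        m * psi1(mx) * dxi1(x) - xi1(x) * dpsi1(mx)
    )
    c_ext = 2.0 * math.pi / k**2 * 3.0 * a1.real
    c_sca = 2.0 * math.pi / k**2 * 3.0 * abs(a1) ** 2
    return c_ext - c_sca


class TestDepolarization:
    def test_sphere_limit(self):
        assert nt.depolarization_factors(10.0, 10.0) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_study_rod_values(self):
        p = nt.depolarization_factors(10.0, 41.0)
        assert p[0] == pytest.approx(0.0730, abs=5e-4)
        assert p[1] == pytest.approx(0.4635, abs=5e-4)
        assert p[1] == p[2]

    def test_against_quadrature_oracle(self):
        for d, l in [(10.0, 41.0), (10.0, 15.0), (5.0, 40.0)]:
            p = nt.depolarization_factors(d, l)
            q1, q2 = depolarization_quadrature(l / 2.0, d / 2.0)
            assert p[0] == pytest.approx(q1, rel=1e-6)
            assert p[1] == pytest.approx(q2, rel=1e-6)

    def test_longitudinal_factor_decreases_with_aspect_ratio(self):
        p1s = [nt.depolarization_factors(10.0, 10.0 * ar)[0] for ar in (1.5, 2.0, 4.1, 8.0)]
        assert all(a > b for a, b in zip(p1s, p1s[1:]))

    def test_oblate_rejected(self):
        with pytest.raises(OpticsDomainError):
            nt.depolarization_factors(41.0, 10.0)

    @given(
        d=st.floats(min_value=1.0, max_value=50.0),
        ar=st.floats(min_value=1.0, max_value=20.0),
    )
    def test_invariants(self, d, ar):
        p = nt.depolarization_factors(d, d * ar)
        assert sum(p) == pytest.approx(1.0, abs=1e-9)
        assert all(0 < v < 1 for v in p)
        if ar > 1.001:
            assert p[0] < 1 / 3 < p[1]


class TestGeometry:
    def test_equivalent_radius_sphere_limit(self):
        assert nt.equivalent_radius(10.0, 10.0) == pytest.approx(5.0)

    def test_equivalent_radius_study_rod(self):
        assert nt.equivalent_radius(10.0, 41.0) == pytest.approx(8.91, abs=0.02)

    @given(
        d=st.floats(min_value=1.0, max_value=50.0),
        ar=st.floats(min_value=1.0, max_value=20.0),
    )
    def test_equivalent_radius_bounds(self, d, ar):
        l = d * ar
        r = nt.equivalent_radius(d, l)
        r_cyl = (3.0 * math.pi * (d / 2) ** 2 * l / (4.0 * math.pi)) ** (1 / 3)
        assert d / 2 - 1e-9 <= r <= r_cyl + 1e-9

    def test_particle_volume(self):
        # b = 5, a = 15.5: V = 2 pi a b^2 + 4/3 pi b^3 = 2958 nm^3
        assert nt.particle_volume(nt.GNRSpec()) == pytest.approx(2958.3, abs=0.5)
        sphere = nt.GNRSpec(diameter_nm=10.0, length_nm=10.0)
        assert nt.particle_volume(sphere) == pytest.approx(4 / 3 * math.pi * 125.0)

    def test_volume_monotone_in_length(self):
        vols = [
            nt.particle_volume(nt.GNRSpec(diameter_nm=10.0, length_nm=l))
            for l in (10.0, 20.0, 41.0, 80.0)
        ]
        assert all(a < b for a, b in zip(vols, vols[1:]))


class TestSizeCorrection:
    def test_no_surface_scattering_no_correction(self):
        drude = nt.DrudeParams(surface_scattering=0.0)
        eps = nt.size_corrected_permittivity(8.9, 808.0, drude, eps_bulk=EPS_GOLD_808)
        assert eps == pytest.approx(EPS_GOLD_808)

    def test_large_particle_limit(self):
        eps = nt.size_corrected_permittivity(1e9, 808.0, eps_bulk=EPS_GOLD_808)
        assert eps.real == pytest.approx(EPS_GOLD_808.real, abs=1e-6)
        assert eps.imag == pytest.approx(EPS_GOLD_808.imag, abs=1e-6)

    def test_correction_value_against_direct_arithmetic(self):
        # independent evaluation of the two Drude terms
        drude = nt.DrudeParams()
        a_nm, lam = 8.91, 808.0
        omega = 2 * math.pi * 2.99792458e8 / (lam * 1e-9)
        gb = drude.gamma_bulk
        ga = gb + drude.fermi_velocity / (a_nm * 1e-9)
        wp2 = drude.plasma_frequency**2
        delta = wp2 / (omega * complex(omega, gb)) - wp2 / (omega * complex(omega, ga))
        got = nt.size_corrected_permittivity(a_nm, lam, drude, eps_bulk=0j)
        assert got.real == pytest.approx(delta.real, rel=1e-12)
        assert got.imag == pytest.approx(delta.imag, rel=1e-12)
        # surface scattering only adds loss, barely perturbs the real part
        assert delta.imag > 0
        assert abs(delta.real) < 1.0

    def test_invalid_radius(self):
        with pytest.raises(OpticsDomainError):
            nt.size_corrected_permittivity(-1.0, 808.0, eps_bulk=0j)


class TestPolarizability:
    def test_index_matched_vanishes(self):
        alphas = nt.gans_polarizability(EPS_HOST, EPS_HOST, 10.0, 41.0)
        assert all(a == 0 for a in alphas)

    def test_sphere_reduces_to_clausius_mossotti(self):
        r = 5.0
        alphas = nt.gans_polarizability(EPS_GOLD_808, EPS_HOST, 2 * r, 2 * r)
        cm = (
            4.0
            * math.pi
            * r**3
            * (EPS_GOLD_808 - EPS_HOST)
            / (EPS_GOLD_808 + 2 * EPS_HOST)
        )
        for a in alphas:
            assert abs(a - cm) / abs(cm) < 1e-12

    def test_longitudinal_dominance(self):
        a1, a2, a3 = nt.gans_polarizability(EPS_GOLD_808, EPS_HOST, 10.0, 41.0)
        assert a1.imag / a2.imag > 100
        assert a2 == a3


class TestCrossSection:
    def test_study_value(self):
        c = nt.absorption_cross_section(nt.GNRSpec(), EPS_GOLD_808, EPS_HOST, 808.0)
        assert c == pytest.approx(476.0, rel=0.05)

    def test_index_matched_zero(self):
        assert nt.absorption_cross_section(nt.GNRSpec(), EPS_HOST, EPS_HOST, 808.0) == 0.0

    def test_sphere_limit_matches_mie_dipole(self):
        r = 5.0
        spec = nt.GNRSpec(diameter_nm=2 * r, length_nm=2 * r)
        gans = nt.absorption_cross_section(spec, EPS_GOLD_808, EPS_HOST, 808.0)
        mie = mie_dipole_absorption(r, 808.0, EPS_GOLD_808, EPS_HOST)
        assert gans == pytest.approx(mie, rel=0.01)

    def test_absorptive_host_rejected(self):
        with pytest.raises(OpticsDomainError):
            nt.absorption_cross_section(nt.GNRSpec(), EPS_GOLD_808, complex(1.767, 0.1), 808.0)

    def test_resonance_near_operating_wavelength(self):
        lam = np.arange(650.0, 1000.0, 2.0)
        c = nt.cross_section_spectrum(nt.GNRSpec(), lam, EPS_HOST)
        peak = lam[np.argmax(c)]
        assert abs(peak - 808.0) <= 20.0

    def test_resonance_cross_section_grows_with_volume(self):
        # same aspect ratio, increasing volume
        peaks = []
        for d in (8.0, 10.0, 12.0):
            spec = nt.GNRSpec(diameter_nm=d, length_nm=4.1 * d)
            lam = np.arange(700.0, 900.0, 2.0)
            peaks.append(nt.cross_section_spectrum(spec, lam, EPS_HOST).max())
        assert peaks[0] < peaks[1] < peaks[2]


class TestLoading:
    def test_volume_fraction_study_value(self):
        assert nt.volume_fraction(12.5, 19.3) == pytest.approx(6.48e-7, rel=0.01)
        assert nt.volume_fraction(0.0, 19.3) == 0.0
        assert nt.volume_fraction(25.0, 19.3) == pytest.approx(
            2 * nt.volume_fraction(12.5, 19.3)
        )

    def test_number_density(self):
        n = nt.number_density(12.5, nt.GNRSpec())
        assert n == pytest.approx(2.19e17, rel=0.01)
        assert nt.number_density(0.0, nt.GNRSpec()) == 0.0
        # inverse scaling with particle volume at fixed concentration
        big = nt.GNRSpec(diameter_nm=20.0, length_nm=82.0)
        ratio = nt.number_density(12.5, nt.GNRSpec()) / nt.number_density(12.5, big)
        assert ratio == pytest.approx(nt.particle_volume(big) / nt.particle_volume(nt.GNRSpec()))

    def test_nano_absorption(self):
        mu, la = nt.nano_absorption(2.2e17, 476.0)
        assert mu == pytest.approx(1.047, rel=0.01)
        assert la == pytest.approx(0.955, rel=0.01)
        mu0, la0 = nt.nano_absorption(0.0, 476.0)
        assert mu0 == 0.0 and math.isinf(la0)
        assert nt.nano_absorption(4.4e17, 476.0)[0] == pytest.approx(2 * mu)

    def test_invalid_density(self):
        with pytest.raises(OpticsDomainError):
            nt.volume_fraction(12.5, 0.0)
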