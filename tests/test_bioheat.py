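import math

import numpy as np
import pytest

import nanoptt as nt
from nanoptt.bioheat import TemperatureField, ThermalModel

PITCH = 0.25


def impulse_field(n=48, value=1.0):
    f = np.zeros((n, n, n))
    f[n // 2, n // 2, n // 2] = value
    return TemperatureField(f, 26.0, 0.0, PITCH, np.full(3, -n * PITCH / 2))


def fd_diffuse(field, alpha, t, pitch, n_steps):
    """Independent oracle: explicit finite-difference heat equation with
    zero-Dirichlet boundaries."""
    dt = t / n_steps
    lam = alpha * dt / pitch**2
    assert lam <= 1.0 / 6.0 + 1e-12, "stability limit"
    u = field.copy()
    for _ in range(n_steps):
        lap = -6.0 * u
        lap[:-1] += u[1:]
        lap[1:] += u[:-1]
        lap[:, :-1] += u[:, 1:]
        lap[:, 1:] += u[:, :-1]
        lap[:, :, :-1] += u[:, :, 1:]
        lap[:, :, 1:] += u[:, :, :-1]
        u = u + lam * lap
    return u


class TestConversion:
    def test_pancreas_voxel_factor(self):
        # rho = 1040, pitch 0.25 mm -> m = 1.625e-8 kg; Cp = 3554.6
        m = 1040.0 * (0.25e-3) ** 3
        f = nt.conversion_factor(3554.6, m)
        assert f == pytest.approx(2.77e-15, rel=0.005)

    def test_doubling_mass_halves_factor(self):
        assert nt.conversion_factor(3554.6, 2e-8) == pytest.approx(
            nt.conversion_factor(3554.6, 1e-8) / 2
        )

    def test_dimensional_identity(self):
        m, cp = 3.2e-8, 4100.0
        assert nt.conversion_factor(cp, m) * (m * cp) == pytest.approx(1.602176634e-19)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            nt.conversion_factor(3554.6, 0.0)

    def test_energy_to_deltaT_product(self):
        em = nt.EnergyMap(
            energy=np.zeros((4, 4, 4)),
            counts=np.zeros((4, 4, 4), dtype=np.int64),
            nano_counts=np.zeros((4, 4, 4), dtype=np.int64),
            pitch=PITCH,
            origin=np.zeros(3),
            e0_ev=1.5345,
            n_histories=1,
            seed=0,
            n_absorbed=0,
            n_escaped=1,
            n_terminated=0,
        )
        em.energy[1, 2, 3] = 1e12
        field = nt.energy_to_deltaT(em, 2.77e-15, 6e13)
        assert field.deltaT[1, 2, 3] == pytest.approx(1e12 * 2.77e-15 * 6e13)
        assert np.count_nonzero(field.deltaT) == 1
        doubled = nt.energy_to_deltaT(em, 2.77e-15, 1.2e14)
        assert np.allclose(doubled.deltaT, 2 * field.deltaT)

    def test_zero_map_zero_field(self):
        em = nt.EnergyMap(
            energy=np.zeros((2, 2, 2)),
            counts=np.zeros((2, 2, 2), dtype=np.int64),
            nano_counts=np.zeros((2, 2, 2), dtype=np.int64),
            pitch=PITCH,
            origin=np.zeros(3),
            e0_ev=1.5345,
            n_histories=1,
            seed=0,
            n_absorbed=0,
            n_escaped=1,
            n_terminated=0,
        )
        assert not nt.energy_to_deltaT(em, 2.77e-15, 6e13).deltaT.any()


class TestSteadyStateConversion:
    def test_voxel_irradiance(self):
        # 1e18 eV over 30 s through a (0.25 mm)^2 face
        i = nt.voxel_irradiance(1e18, 30.0, (0.25e-3) ** 2)
        assert i == pytest.approx(8.54e4, rel=0.005)
        assert nt.voxel_irradiance(0.0, 30.0, 1e-8) == 0.0
        assert nt.voxel_irradiance(1e18, 60.0, (0.25e-3) ** 2) == pytest.approx(i / 2)

    def test_gnr_deltaT_direct_arithmetic(self):
        got = nt.gnr_deltaT(2.2e17, 1.25e-4, 476e-18, 1e5, 0.59)
        assert got == pytest.approx(2.2e17 * 1.25e-4**2 * 476e-18 * 1e5 / (2 * 0.59))
        assert got == pytest.approx(0.1386, rel=0.01)
        assert nt.gnr_deltaT(0.0, 1.25e-4, 476e-18, 1e5, 0.59) == 0.0
        assert nt.gnr_deltaT(2.2e17, 1.25e-4, 476e-18, 2e5, 0.59) == pytest.approx(2 * got)

    def test_invalid_conductivity(self):
        with pytest.raises(ValueError):
            nt.gnr_deltaT(1e17, 1e-4, 1e-16, 1e5, 0.0)


class TestHeatKernel:
    def test_delta_at_t0(self):
        k = nt.heat_kernel(0.14, 0.0, PITCH)
        assert k.shape == (1, 1, 1) and k[0, 0, 0] == 1.0

    def test_sigma(self):
        # sqrt(2 * 0.14 * 10) = 1.673 mm
        k = nt.heat_kernel(0.14, 10.0, PITCH)
        ax = (np.arange(k.shape[0]) - k.shape[0] // 2) * PITCH
        marginal = k.sum(axis=(1, 2))
        sigma = math.sqrt((marginal * ax**2).sum())
        assert sigma == pytest.approx(1.673, abs=0.005)

    def test_normalized(self):
        assert nt.heat_kernel(0.16, 30.0, PITCH).sum() == pytest.approx(1.0, abs=1e-6)


class TestDiffuse:
    def test_identity_at_t0(self):
        f = impulse_field()
        out = nt.diffuse(f, ThermalModel(alpha_mm2_s=0.16), 0.0)
        assert (out.deltaT == f.deltaT).all()

    def test_impulse_matches_closed_form(self):
        n = 48
        f = impulse_field(n)
        model = ThermalModel(alpha_mm2_s=0.16)
        out = nt.diffuse(f, model, 2.0)
        xs = (np.arange(n) + 0.5) * PITCH - n * PITCH / 2
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        c = xs[n // 2]
        r2 = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2
        exact = PITCH**3 / (4 * math.pi * 0.16 * 2.0) ** 1.5 * np.exp(-r2 / (4 * 0.16 * 2.0))
        assert np.abs(out.deltaT - exact).max() / exact.max() < 1e-6

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(5)
        n = 48
        # random smooth blobs: superposed impulses lightly diffused
        raw = np.zeros((n, n, n))
        idx = rng.integers(8, n - 8, size=(30, 3))
        raw[idx[:, 0], idx[:, 1], idx[:, 2]] = rng.random(30) + 0.5
        f = TemperatureField(raw, 26.0, 0.0, PITCH, np.full(3, -n * PITCH / 2))
        f = nt.diffuse(f, ThermalModel(alpha_mm2_s=0.16), 0.5)
        out = nt.diffuse(f, ThermalModel(alpha_mm2_s=0.16), 1.5)
        oracle = fd_diffuse(f.deltaT, 0.16, 1.5, PITCH, n_steps=100)
        assert np.abs(out.deltaT - oracle).max() / oracle.max() <= 0.02

    def test_conservation_without_perfusion(self):
        n = 64
        f = impulse_field(n, value=10.0)
        out = nt.diffuse(f, ThermalModel(alpha_mm2_s=0.16), 3.0)  # sigma ~ 1 mm << box
        assert out.deltaT.sum() == pytest.approx(10.0, rel=1e-4)

    def test_perfusion_decay_exact_factor(self):
        f = impulse_field()
        model0 = ThermalModel(alpha_mm2_s=0.16)
        modelq = ThermalModel(alpha_mm2_s=0.16, q_b=0.02)
        t = 4.0
        ratio = nt.diffuse(f, modelq, t).deltaT.sum() / nt.diffuse(f, model0, t).deltaT.sum()
        assert ratio == pytest.approx(math.exp(-0.02 * t), rel=1e-12)


class TestIrradiate:
    def test_zero_rate_stays_zero(self):
        rate = np.zeros((16, 16, 16))
        fields = nt.irradiate(
            rate, ThermalModel(alpha_mm2_s=0.16), [5.0, 10.0], PITCH, np.zeros(3), 10.0
        )
        assert all(not f.deltaT.any() for f in fields)
        assert [f.time_s for f in fields] == [5.0, 10.0]

    def test_linearity_in_rate(self):
        rng = np.random.default_rng(3)
        rate = rng.random((16, 16, 16))
        model = ThermalModel(alpha_mm2_s=0.16)
        f1 = nt.irradiate(rate, model, [8.0], PITCH, np.zeros(3), 8.0)[0]
        f2 = nt.irradiate(3.0 * rate, model, [8.0], PITCH, np.zeros(3), 8.0)[0]
        assert np.allclose(f2.deltaT, 3.0 * f1.deltaT, rtol=1e-12)

    def test_time_step_self_convergence(self):
        n = 48
        rate = np.zeros((n, n, n))
        rate[n // 2, n // 2, n // 2] = 1.0
        org = np.full(3, -n * PITCH / 2)
        model = ThermalModel(alpha_mm2_s=0.16)
        probe = (n // 2, n // 2 + 8, n // 2)  # 2 mm off-axis
        f1 = nt.irradiate(rate, model, [30.0], PITCH, org, 30.0, dt_s=1.0)[0]
        f05 = nt.irradiate(rate, model, [30.0], PITCH, org, 30.0, dt_s=0.5)[0]
        assert abs(f1.deltaT[probe] - f05.deltaT[probe]) / f05.deltaT[probe] < 0.02

    def test_heating_stops_at_duration(self):
        n = 48
        rate = np.zeros((n, n, n))
        rate[n // 2, n // 2, n // 2] = 1.0
        model = ThermalModel(alpha_mm2_s=0.16)
        fields = nt.irradiate(rate, model, [3.0, 6.0], PITCH, np.full(3, -n * PITCH / 2), 3.0)
        # after the laser stops, total heat is conserved (no perfusion)
        assert fields[0].deltaT.sum() == pytest.approx(3.0, rel=1e-3)
        assert fields[1].deltaT.sum() == pytest.approx(3.0, rel=1e-3)

    def test_non_increasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            nt.irradiate(
                np.zeros((4, 4, 4)), ThermalModel(alpha_mm2_s=0.16), [5.0, 5.0], PITCH,
                np.zeros(3), 10.0,
            )
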