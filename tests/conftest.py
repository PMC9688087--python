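import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanoptt as nt

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def material_table():
    return nt.default_material_table()


@pytest.fixture(scope="session")
def pancreas(material_table):
    return material_table["pancreas"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def pure_absorber(mu_a=2.0, name="absorber"):
    """Scattering-free test medium (mu_a in 1/cm)."""
    return nt.Material(
        name=name,
        density=1000.0,
        refractive_index=1.4,
        mu_a=mu_a,
        mu_s=0.0,
        g_hg=0.0,
        heat_capacity=4000.0,
        thermal_diffusivity=0.14,
    )


def turbid(mu_a=1.0, mu_n=0.0, mu_s=2.0, g=0.5, name="turbid"):
    return nt.Material(
        name=name,
        density=1000.0,
        refractive_index=1.4,
        mu_a=mu_a,
        mu_s=mu_s,
        g_hg=g,
        heat_capacity=4000.0,
        thermal_diffusivity=0.14,
    )


@pytest.fixture(scope="session")
def slab_beam():
    """Pencil-ish beam entering a 2 cm slab from its -z face."""
    return nt.LaserBeam(
        power_w=2.1,
        tip_diameter_mm=0.3,
        tip_position_mm=(0.0, 0.0, -9.999),
        direction=(0.0, 0.0, 1.0),
        duration_s=30.0,
    )


@pytest.fixture(scope="session")
def gnr_run_small():
    """Shared scaled-down run of the packaged tumor scenario (2e5 histories)."""
    return nt.run_scenario(
        "pancreas_ptt", seed=11, overrides={"transport.n_histories": 200_000}
    )


@pytest.fixture(scope="session")
def plain_run_small():
    """Matched nanorod-free control at the same seed and problem size."""
    return nt.run_scenario(
        "pancreas_no_gnr", seed=11, overrides={"transport.n_histories": 200_000}
    )
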