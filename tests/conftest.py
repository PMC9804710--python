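import math

import numpy as np
import pytest

from beamlab import dose, geometry, nuclear, source, transport


@pytest.fixture(scope="session")
def library():
    return nuclear.default_library()


@pytest.fixture(scope="session")
def weights():
    return dose.WeightingConfig.from_yaml()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def narrow_source():
    """Mono-energetic (anchor-energy) pencil beam on the axis."""
    spec = source.EnergySpectrum(
        np.array([0.0253 * (1 - 1e-8), 0.0253 * (1 + 1e-8)]), np.array([1.0]))
    return source.SourceModel(
        neutron_spectrum=spec, gamma_spectrum=None, disc_radius=1e-6,
        plane_z=-0.5, angular_exponent=math.inf)


@pytest.fixture(scope="session")
def pure_absorber(library):
    """Inject a scatter-free 1/v test nuclide and an absorber material."""
    nuclear.NUCLIDES["XAbs"] = nuclear.Nuclide(
        name="XAbs", atomic_mass=10.0, Z=5, sigma0_capture=500.0,
        sigma_scatter=0.0, has_1v_capture=True, capture_channel="XAbs(n,g)",
        q_local_mev=0.0)
    library["absorber"] = nuclear.Material(
        "absorber", density=1.0, number_densities={"XAbs": 0.004})
    yield library["absorber"]
    nuclear.NUCLIDES.pop("XAbs", None)
    library.pop("absorber", None)


@pytest.fixture(scope="session")
def water_run(library):
    """Analog water-phantom run shared by conservation/estimator tests."""
    src = source.make_epithermal_source(disc_radius=7.0, gamma_params=[])
    scene = geometry.build_scene(geometry.FilterDesign("none"))
    mesh = transport.MeshSpec.phantom_default(bin_cm=0.5)
    rs = transport.RunSpec(n_particles=100_000, seed=42, implicit_capture=False,
                           photon_transport=True, mesh=mesh)
    result = transport.run_transport(src, scene, rs, library)
    return {"result": result, "scene": scene, "runspec": rs, "source": src}


@pytest.fixture(scope="session")
def brain_run(library):
    """Implicit-capture ICRP-brain run shared by dose/metric tests."""
    src = source.make_epithermal_source(disc_radius=7.0)
    scene = geometry.build_scene(geometry.FilterDesign("none"),
                                 phantom_material="brain")
    mesh = transport.MeshSpec.phantom_default(bin_cm=0.4)
    rs = transport.RunSpec(n_particles=80_000, seed=7, implicit_capture=True,
                           photon_transport=True, mesh=mesh)
    result = transport.run_transport(src, scene, rs, library)
    dose.set_result_strength(result, src.strength)
    return {"result": result, "scene": scene, "source": src}
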