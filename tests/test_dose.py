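import numpy as np
import pytest

from beamlab import dose, geometry, nuclear, transport
from beamlab.dose import (
    DoseComponents,
    WeightingConfig,
    compute_dose_components,
    tumor_dose_profile,
    weight_dose,
)
from beamlab.transport import MeshSpec, TallyGrid, TransportResult


def make_fake_result(mesh, one_v=0.0, recoil=0.0, gamma=0.0):
    """Hand-built transport result with uniform auxiliary tallies."""
    shape = tuple(mesh.shape)
    z3 = np.zeros((3,) + shape)

    def grid(v):
        return TallyGrid(mesh, np.full(shape, float(v)), np.zeros(shape), 1)

    return TransportResult(
        neutron=TallyGrid(mesh, z3, np.zeros_like(z3), 1),
        photon=grid(0.0),
        aux={
            "one_v_tot": grid(one_v),
            "one_v_sub": grid(one_v),
            "recoil_mev": grid(recoil),
            "gamma_edep_mev": grid(gamma),
        },
        absorbed=0, escaped=1, n_source=1, channels=[], seed=0,
    )


@pytest.fixture
def brain_box(library):
    scene = geometry.Scene(
        regions=[geometry.Region("box", (-5, 5, -5, 5, 0, 10), "brain", 1)],
        bbox=((-5, 5), (-5, 5), (0, 10)),
    )
    mesh = MeshSpec(origin=(-5, -5, 0), spacing=(2.5, 2.5, 2.5), shape=(4, 4, 4))
    return scene, mesh


class TestComputeDoseComponents:
    def test_zero_fluence_all_zero(self, brain_box, library):
        scene, mesh = brain_box
        res = make_fake_result(mesh)
        dose.set_result_strength(res, 1e12)
        c = compute_dose_components(res, scene, 25.0, library)
        assert np.all(c.total == 0.0)

    def test_boron_single_voxel_hand_calculation(self, brain_box, library):
        scene, mesh = brain_box
        phi_1v = 1e-4  # cm^-2 per source, 1/v folded
        res = make_fake_result(mesh, one_v=phi_1v)
        strength = 1e12
        dose.set_result_strength(res, strength)
        c = compute_dose_components(res, scene, 25.0, library)
        rho = 1.04
        n_b = 25e-6 * rho * nuclear.AVOGADRO / 10.0129 * 1e-24
        mev_per_cm3_s = n_b * 3837.0 * phi_1v * 2.34 * strength
        expected = mev_per_cm3_s / rho * 1.602176634e-10 * 3600.0
        assert c.boron[0, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_boron_linearity_in_concentration(self, brain_box, library):
        scene, mesh = brain_box
        res = make_fake_result(mesh, one_v=1e-4, recoil=1e-6, gamma=1e-6)
        dose.set_result_strength(res, 1e12)
        c1 = compute_dose_components(res, scene, 25.0, library)
        c2 = compute_dose_components(res, scene, 50.0, library)
        np.testing.assert_allclose(c2.boron, 2 * c1.boron, rtol=1e-12)
        np.testing.assert_allclose(c2.hydrogen, c1.hydrogen, rtol=1e-12)
        np.testing.assert_allclose(c2.gamma, c1.gamma, rtol=1e-12)
        np.testing.assert_allclose(c2.nitrogen, c1.nitrogen, rtol=1e-12)

    def test_shape_mismatch_rejected(self, brain_box, library):
        scene, mesh = brain_box
        res = make_fake_result(mesh, one_v=1e-4)
        dose.set_result_strength(res, 1e12)
        with pytest.raises(ValueError):
            compute_dose_components(res, scene, np.ones((2, 2, 2)), library)


class TestWeightDose:
    def _unit_components(self, mesh):
        ones = np.ones(mesh.shape)
        return DoseComponents(boron=ones.copy(), nitrogen=ones.copy(),
                              hydrogen=ones.copy(), gamma=ones.copy(),
                              mesh=mesh, boron_ppm=25.0)

    def test_zero_components(self, brain_box, weights):
        _, mesh = brain_box
        z = np.zeros(mesh.shape)
        c = DoseComponents(z, z, z, z, mesh, 25.0)
        assert np.all(weight_dose(c, weights, "tumor") == 0.0)

    def test_pure_boron_tumor_cbe(self, brain_box):
        _, mesh = brain_box
        z = np.zeros(mesh.shape)
        b = np.ones(mesh.shape)
        # boron map evaluated at the tumor concentration itself
        c = DoseComponents(b, z.copy(), z.copy(), z.copy(), mesh, 25.0)
        w = WeightingConfig(tumor_to_blood=1.0)
        out = weight_dose(c, w, "tumor")
        np.testing.assert_allclose(out, 3.8)

    def test_unit_components_normal_role(self, brain_box, weights):
        _, mesh = brain_box
        c = self._unit_components(mesh)
        out = weight_dose(c, weights, "normal")
        expected = 1.0 * 1 + 3.0 * 1 + 3.0 * 1 + 1.34 * 1
        np.testing.assert_allclose(out, expected)

    def test_identity_config_gives_physical_total(self, brain_box, weights):
        _, mesh = brain_box
        c = self._unit_components(mesh)
        ident = weights.identity()
        for role in ("tumor", "normal", "skin"):
            np.testing.assert_allclose(weight_dose(c, ident, role), c.total)

    def test_unknown_role(self, brain_box, weights):
        _, mesh = brain_box
        c = self._unit_components(mesh)
        with pytest.raises(ValueError):
            weight_dose(c, weights, "bone_marrow")

    def test_tumor_normal_ratio_bounds(self, brain_box, weights):
        _, mesh = brain_box
        # boron-dominated limit: ratio -> cbe_tumor*ratio/cbe_normal
        z = np.zeros(mesh.shape)
        big_b = np.full(mesh.shape, 1e9)
        c = DoseComponents(big_b, z + 1, z + 1, z + 1, mesh, 25.0)
        t = weight_dose(c, weights, "tumor")
        n = weight_dose(c, weights, "normal")
        ratio = t / n
        upper = weights.cbe_tumor * weights.tumor_to_blood / weights.cbe_normal
        assert np.all(ratio >= 1.0)
        assert np.all(ratio <= upper * (1 + 1e-9))
        np.testing.assert_allclose(ratio, upper, rtol=1e-6)


class TestTumorProfile:
    def test_degenerate_equality(self, brain_box):
        _, mesh = brain_box
        rng = np.random.default_rng(3)
        comps = DoseComponents(
            boron=rng.random(mesh.shape), nitrogen=rng.random(mesh.shape),
            hydrogen=rng.random(mesh.shape), gamma=rng.random(mesh.shape),
            mesh=mesh, boron_ppm=25.0)
        w = WeightingConfig(tumor_to_blood=1.0 + 1e-12, cbe_tumor=1.34)
        t, nt = tumor_dose_profile(comps, w, radius_cm=3.0)
        np.testing.assert_allclose(t.value, nt.value, rtol=1e-9)

    def test_dominance_on_synthetic_beam(self, brain_run, weights, library):
        comps = compute_dose_components(
            brain_run["result"], brain_run["scene"], weights.blood_boron, library)
        t, nt = tumor_dose_profile(comps, weights)
        has_boron = comps.boron.mean(axis=(0, 1)) > 0
        assert np.all(t.value[has_boron] > nt.value[has_boron])

    def test_boron_share_over_therapeutic_range(self, brain_run, weights, library):
        """Boron carries >90% of the weighted tumor dose at depth."""
        comps = compute_dose_components(
            brain_run["result"], brain_run["scene"], weights.blood_boron, library)
        profs = dose.axial_component_profiles(comps, radius_cm=2.0)
        t, _ = tumor_dose_profile(comps, weights, radius_cm=2.0)
        z = t.depth
        band = (z >= 2.0) & (z <= 8.0)
        share = (weights.cbe_tumor * weights.tumor_to_blood
                 * profs["boron"].value[band]) / t.value[band]
        assert np.all(share > 0.9)

    def test_linearity_in_time_and_fluence(self, brain_box, weights):
        _, mesh = brain_box
        rng = np.random.default_rng(5)
        arrs = [rng.random(mesh.shape) for _ in range(4)]
        c1 = DoseComponents(*arrs, mesh=mesh, boron_ppm=25.0)
        c2 = DoseComponents(*[2 * a for a in arrs], mesh=mesh, boron_ppm=25.0)
        np.testing.assert_allclose(
            weight_dose(c2, weights, "normal"),
            2 * weight_dose(c1, weights, "normal"), rtol=1e-12)


class TestWeightingConfig:
    def test_paper_defaults(self, weights):
        assert weights.rbe_nitrogen == 3.0
        assert weights.rbe_hydrogen == 3.0
        assert weights.rbe_gamma == 1.0
        assert weights.cbe_tumor == 3.8
        assert weights.cbe_skin == 2.5
        assert weights.cbe_normal == 1.34
        assert weights.blood_boron == 25.0
        assert weights.tumor_to_blood == 3.5
        assert weights.skin_to_blood == 1.0
        assert weights.brain_dose_limit == 12.5

    def test_positive_validation(self):
        with pytest.raises(ValueError):
            WeightingConfig(rbe_gamma=0.0)
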