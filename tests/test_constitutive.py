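"""Hyperelastic material laws: parameter conversions, energies, stresses
and consistent tangents against independent finite-difference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import breastfem as bf
from breastfem.constitutive import (ADIPOSE_MR, DeformationPoint,
                                    IncompressibleLimitError, _invariants)


def random_F(rng, scale=0.2):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    return F


def fd_pk1(model, F, h=1e-6):
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (bf.strain_energy(model, Fp)
                       - bf.strain_energy(model, Fm)) / (2 * h)
    return P


class TestConversion:
    def test_soft_tissue_values(self):
        mu, d = bf.convert_E_nu(10.0, 0.49)
        assert mu == pytest.approx(3.3557, abs=1e-4)
        assert d == pytest.approx(0.012, abs=1e-12)

    def test_skin_value(self):
        mu, _ = bf.convert_E_nu(500.0, 0.49)
        assert mu == pytest.approx(167.79, abs=0.01)

    @given(v=st.floats(0.01, 0.49))
    @settings(max_examples=25, deadline=None)
    def test_identity_scaling(self, v):
        mu, _ = bf.convert_E_nu(2.0 * (1.0 + v), v)
        assert mu == pytest.approx(1.0, rel=1e-12)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(IncompressibleLimitError):
            bf.convert_E_nu(10.0, 0.5)

    @pytest.mark.parametrize("E,v", [(-1.0, 0.3), (10.0, 0.6), (10.0, 0.0)])
    def test_invalid_parameters(self, E, v):
        with pytest.raises(ValueError):
            bf.convert_E_nu(E, v)


class TestEnergyAndStress:
    @pytest.mark.parametrize("model", [bf.neo_hookean(10.0),
                                       bf.mooney_rivlin5()],
                             ids=["neo_hookean", "mooney_rivlin"])
    def test_undeformed_state(self, model):
        assert bf.strain_energy(model, np.eye(3)) == 0.0
        assert np.allclose(bf.cauchy_stress(model, np.eye(3)), 0.0)

    def test_neo_hookean_isochoric_uniaxial_energy(self):
        lam = 1.1
        model = bf.neo_hookean(10.0)
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        expected = 0.5 * model.mu * (lam ** 2 + 2.0 / lam - 3.0)
        assert bf.strain_energy(model, F) == pytest.approx(expected, rel=1e-12)

    def test_mooney_rivlin_small_shear_limit(self):
        """W -> (C10 + C01) gamma^2 as gamma -> 0 for isochoric shear."""
        model = bf.mooney_rivlin5()
        c = ADIPOSE_MR["C10"] + ADIPOSE_MR["C01"]
        for gamma in (1e-3, 1e-4):
            F = np.eye(3)
            F[0, 1] = gamma
            assert bf.strain_energy(model, F) == pytest.approx(
                c * gamma ** 2, rel=1e-3)

    def test_incompressible_uniaxial_cauchy_closed_form(self):
        """Axial-minus-lateral Cauchy stress equals mu (lam^2 - 1/lam) for
        an isochoric uniaxial deformation (pressure eliminated)."""
        model = bf.neo_hookean(10.0)
        for lam in (0.9, 1.1, 1.3):
            F = np.diag([lam, lam ** -0.5, lam ** -0.5])
            sig = bf.cauchy_stress(model, F)
            assert sig[0, 0] - sig[1, 1] == pytest.approx(
                model.mu * (lam ** 2 - 1.0 / lam), rel=1e-10)

    @pytest.mark.parametrize("model", [bf.neo_hookean(10.0),
                                       bf.mooney_rivlin5()],
                             ids=["neo_hookean", "mooney_rivlin"])
    def test_stress_symmetry(self, model, rng):
        for _ in range(5):
            sig = bf.cauchy_stress(model, random_F(rng))
            assert np.abs(sig - sig.T).max() < 1e-10

    def test_inverted_deformation_rejected(self):
        with pytest.raises(bf.InvertedElementError):
            bf.strain_energy(bf.neo_hookean(10.0), -np.eye(3))


class TestConsistency:
    """Stress = dW/dF and tangent = dP/dF against finite differences."""

    @pytest.mark.parametrize("model", [bf.neo_hookean(10.0),
                                       bf.mooney_rivlin5()],
                             ids=["neo_hookean", "mooney_rivlin"])
    def test_pk1_matches_fd_of_energy(self, model, rng):
        for _ in range(5):
            F = random_F(rng)
            P = bf.pk1_stress(model, F)
            Pfd = fd_pk1(model, F)
            assert np.abs(P - Pfd).max() <= 1e-5 * np.abs(Pfd).max()

    @pytest.mark.parametrize("model", [bf.neo_hookean(10.0),
                                       bf.mooney_rivlin5()],
                             ids=["neo_hookean", "mooney_rivlin"])
    def test_tangent_matches_fd_of_stress(self, model, rng):
        h = 1e-6
        for _ in range(3):
            F = random_F(rng)
            A = bf.pk1_tangent(model, F)
            Afd = np.zeros((3, 3, 3, 3))
            for k in range(3):
                for L in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[k, L] += h
                    Fm[k, L] -= h
                    Afd[:, :, k, L] = (bf.pk1_stress(model, Fp)
                                       - bf.pk1_stress(model, Fm)) / (2 * h)
            assert np.abs(A - Afd).max() <= 1e-4 * np.abs(Afd).max()

    @pytest.mark.parametrize("model", [bf.neo_hookean(10.0),
                                       bf.mooney_rivlin5()],
                             ids=["neo_hookean", "mooney_rivlin"])
    def test_analytic_local_tangent_matches_complex_step(self, model, rng):
        """The closed-form assembly tangent agrees with the complex-step
        derivative of the same frozen-pressure stress to round-off."""
        from breastfem.constitutive import (pk1_local_tangent,
                                            pk1_local_tangent_analytic)
        F = np.stack([random_F(rng) for _ in range(6)])
        p = rng.standard_normal(6) * 5.0
        A_cs = pk1_local_tangent(model, F, p)
        A_an = pk1_local_tangent_analytic(model, F, p)
        assert np.abs(A_cs - A_an).max() <= 1e-12 * np.abs(A_cs).max()

    def test_mooney_rivlin_reduces_to_neo_hookean(self, rng):
        nh = bf.neo_hookean(10.0)
        mr = bf.mooney_rivlin5({"C10": nh.mu / 2.0, "C01": 0.0, "C11": 0.0,
                                "C20": 0.0, "C02": 0.0}, v=nh.v)
        for _ in range(5):
            F = random_F(rng)
            assert bf.strain_energy(mr, F) == pytest.approx(
                bf.strain_energy(nh, F), abs=1e-12 + 1e-12 * abs(
                    bf.strain_energy(nh, F)))


class TestDeformationPoint:
    def test_isochoric_invariants(self, rng):
        for _ in range(5):
            p = DeformationPoint.from_F(random_F(rng))
            assert p.J > 0
            assert np.linalg.det(p.B_bar) == pytest.approx(1.0, abs=1e-8)
            assert p.I1_bar >= 3.0 - 1e-9
            assert p.I2_bar >= 3.0 - 1e-9


class TestMaterialTable:
    def test_component_moduli(self, materials):
        assert materials["ligament"].E == 100.0
        assert materials["skin"].E == 500.0
        assert materials["gland"].E == 10.0
        assert materials["soft_layer"].E == 10.0
        assert materials["pectoralis"].E == 10.0
        assert materials["adipose"].kind == "mooney_rivlin_5"
        assert materials["adipose"].coefficients == ADIPOSE_MR

    def test_densities_kg_m3(self, materials):
        to_kgm3 = 1e9
        assert materials["gland"].density * to_kgm3 == pytest.approx(1070.0)
        assert materials["adipose"].density * to_kgm3 == pytest.approx(950.0)
        assert materials["ligament"].density * to_kgm3 == pytest.approx(1040.0)
        assert materials["pectoralis"].density * to_kgm3 == pytest.approx(1050.0)

    def test_poisson_ratio_everywhere(self, materials):
        assert all(m.v == 0.49 for m in materials.values())

    def test_small_strain_modulus_round_trip(self):
        assert bf.small_strain_modulus(bf.neo_hookean(42.0)) == pytest.approx(42.0)

    def test_adipose_effective_modulus(self, materials):
        assert round(bf.small_strain_modulus(materials["adipose"]), 1) == 3.6
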