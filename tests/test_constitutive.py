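"""Constitutive laws: invariants, energies, stresses, curves, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v2g import constitutive as cst
from v2g.errors import (InvalidDeformationError, ParameterRangeError)


def random_spd(rng):
    A = rng.normal(size=(3, 3))
    return A @ A.T + 0.5 * np.eye(3)


def random_incompressible_F(rng, scale=0.15):
    """Unimodular F with moderate distortion."""
    A = np.eye(3) + scale * rng.normal(size=(3, 3))
    return A / np.linalg.det(A) ** (1.0 / 3.0)


class TestInvariants:
    def test_identity(self):
        I1, I2, I4 = cst.strain_invariants(np.eye(3), [1, 0, 0])
        assert (I1, I2, I4) == (3.0, 3.0, 1.0)

    @pytest.mark.parametrize("lam", [1.05, 1.2, 1.4])
    def test_equibiaxial_closed_form(self, lam):
        C = np.diag([lam ** 2, lam ** 2, lam ** -4])
        I1, I2, I4 = cst.strain_invariants(C, [1, 0, 0])
        assert I1 == pytest.approx(2 * lam ** 2 + lam ** -4)
        assert I4 == pytest.approx(lam ** 2)

    def test_matches_index_summation_oracle(self, rng):
        for _ in range(20):
            C = random_spd(rng)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            I1, I2, I4 = cst.strain_invariants(C, n)
            # brute-force index contraction
            i1 = sum(C[i, i] for i in range(3))
            i2 = 0.5 * (i1 ** 2 - sum(C[i, j] * C[i, j]
                                      for i in range(3) for j in range(3)))
            i4 = sum(C[i, j] * n[i] * n[j] for i in range(3) for j in range(3))
            assert I1 == pytest.approx(i1, rel=1e-12)
            assert I2 == pytest.approx(i2, rel=1e-12)
            assert I4 == pytest.approx(i4, rel=1e-12)

    def test_rejects_non_spd(self):
        with pytest.raises(InvalidDeformationError):
            cst.strain_invariants(np.diag([1.0, 1.0, -0.5]), [1, 0, 0])
        with pytest.raises(InvalidDeformationError):
            cst.strain_invariants(np.eye(3) + np.triu(np.ones((3, 3)), 1),
                                  [1, 0, 0])


class TestEnergies:
    def test_reference_state_zero(self):
        p = cst.IsoMRParams(1.0, 0.5, 2.0, 3.0)
        assert cst.energy_iso(p, 3.0, 3.0) == 0.0
        pa = cst.AnisoMRParams(iso=p, K1=2.0, K2=1.0)
        assert cst.energy_aniso(pa, 3.0, 3.0, 1.0) == 0.0
        f = cst.FungParams(2.0, 1.0, 1.0, 1.0)
        assert cst.energy_fung(f, np.zeros((3, 3))) == 0.0

    def test_iso_linear_term(self):
        assert cst.energy_iso(cst.IsoMRParams(1, 0, 0, 0), 4.0, 3.0) == 1.0

    def test_iso_exponential_term(self):
        p = cst.IsoMRParams(0, 0, 2.0, 3.0)
        assert cst.energy_iso(p, 3.1, 3.0) == pytest.approx(
            2.0 * (np.exp(0.3) - 1.0), rel=1e-12)

    def test_literal_grouping_is_nonzero_at_identity(self):
        p = cst.IsoMRParams(0, 0, 2.0, 3.0)
        assert cst.energy_iso(p, 3.0, 3.0, literal_grouping=True) == \
            pytest.approx(2.0 * np.exp(-1.0))

    def test_aniso_term(self):
        pa = cst.AnisoMRParams(iso=cst.IsoMRParams(0, 0, 0, 0), K1=2.0, K2=1.0)
        assert cst.energy_aniso(pa, 3.0, 3.0, 2.0) == pytest.approx(
            np.e - 1.0, rel=1e-12)

    @pytest.mark.parametrize("d", [0.1, 0.3, 0.6])
    def test_aniso_term_symmetric_about_I4_1(self, d):
        pa = cst.AnisoMRParams(iso=cst.IsoMRParams(0, 0, 0, 0), K1=2.0, K2=1.5)
        assert cst.energy_aniso(pa, 3, 3, 1 + d) == pytest.approx(
            cst.energy_aniso(pa, 3, 3, 1 - d), rel=1e-12)

    def test_K2_zero_limit(self):
        pa0 = cst.AnisoMRParams(iso=cst.IsoMRParams(0, 0, 0, 0), K1=2.0, K2=0.0)
        pa_eps = cst.AnisoMRParams(iso=cst.IsoMRParams(0, 0, 0, 0), K1=2.0,
                                   K2=1e-8)
        assert cst.energy_aniso(pa0, 3, 3, 1.3) == pytest.approx(
            cst.energy_aniso(pa_eps, 3, 3, 1.3), rel=1e-6)
        assert cst.energy_aniso(pa0, 3, 3, 1.3) == pytest.approx(
            0.5 * 2.0 * 0.3 ** 2)

    def test_fung_single_component(self):
        f = cst.FungParams(2.0, 1.0, 0.0, 0.0)
        E = np.zeros((3, 3))
        E[0, 0] = 1.0
        assert cst.energy_fung(f, E) == pytest.approx(np.e - 1.0, rel=1e-12)

    def test_fung_shear_symmetry(self, rng):
        f = cst.FungParams(2.0, 1.0, 0.7, 0.4)
        E = rng.normal(size=(3, 3)) * 0.1
        E_sw = E.copy()
        E_sw[1, 2], E_sw[2, 1] = E[2, 1], E[1, 2]
        assert cst.fung_Q(f, E) == pytest.approx(cst.fung_Q(f, E_sw), rel=1e-12)

    def test_overflow_reported(self):
        p = cst.IsoMRParams(0, 0, 1.0, 100.0)
        with pytest.raises(ParameterRangeError):
            cst.energy_iso(p, 13.0, 3.0)


class TestCauchyStress:
    def test_zero_at_identity(self, dia_material):
        st_id = cst.DeformationState(np.eye(3))
        sig = cst.cauchy_stress(dia_material, st_id)
        assert np.allclose(sig, 0.0, atol=1e-12)

    @pytest.mark.parametrize("lam", [1.1, 1.3])
    def test_neo_hookean_uniaxial(self, lam):
        c1 = 2.0
        p = cst.IsoMRParams(c1, 0, 0, 0)
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        sig = cst.cauchy_stress(p, cst.DeformationState(F),
                                traction_free_dir="y")
        assert sig[0, 0] == pytest.approx(2 * c1 * (lam ** 2 - 1 / lam),
                                          rel=1e-12)
        assert abs(sig[1, 1]) < 1e-12 and abs(sig[2, 2]) < 1e-10

    @pytest.mark.parametrize("law", ["iso", "aniso", "fung"])
    def test_matches_finite_difference_gradient(self, law, rng):
        from tests_support_fd import fd_cauchy_stress

        mats = {
            "iso": cst.IsoMRParams(2.0, 0.8, 0.5, 1.5),
            "aniso": cst.AnisoMRParams(iso=cst.IsoMRParams(2.0, 0.8, 0.5, 1.5),
                                       K1=3.0, K2=1.2),
            "fung": cst.FungParams(5.0, 2.0, 1.0, 0.5),
        }
        m = mats[law]
        for _ in range(5):
            F = random_incompressible_F(rng)
            state = cst.DeformationState(F)
            sig = cst.cauchy_stress(m, state, traction_free_dir="z")
            sig_fd = fd_cauchy_stress(m, F, state.fiber_dir, [0, 0, 1])
            scale = max(np.abs(sig).max(), 1e-6)
            assert np.max(np.abs(sig - sig_fd)) / scale < 1e-5

    def test_frame_indifference(self, dia_material, rng):
        from scipy.spatial.transform import Rotation

        F = random_incompressible_F(rng)
        w0 = cst.energy(dia_material, cst.DeformationState(F))
        for q in Rotation.random(5, random_state=7):
            w = cst.energy(dia_material,
                           cst.DeformationState(q.as_matrix() @ F))
            assert w == pytest.approx(w0, rel=1e-10)

    def test_rejects_compressible_state(self, dia_material):
        with pytest.raises(InvalidDeformationError):
            cst.cauchy_stress(dia_material,
                              cst.DeformationState(1.1 * np.eye(3)))


class TestStressStretchCurves:
    def test_zero_at_unit_stretch(self, dia_material):
        c = cst.stress_stretch_curve(dia_material, "equibiaxial", [1.0])
        assert c.T_ff[0] == pytest.approx(0.0, abs=1e-12)
        assert c.T_cc[0] == pytest.approx(0.0, abs=1e-12)

    def test_fiber_stiffer_than_crossfiber(self, dia_material):
        lams = np.linspace(1.02, 1.3, 10)
        c = cst.stress_stretch_curve(dia_material, "equibiaxial", lams)
        assert np.all(c.T_ff > c.T_cc)
        assert np.all(np.diff(c.T_ff) > 0)

    def test_isotropic_curves_coincide(self):
        p = cst.AnisoMRParams(iso=cst.IsoMRParams(2.0, 0.5, 0.5, 1.5),
                              K1=0.0, K2=1.0)
        c = cst.stress_stretch_curve(p, "equibiaxial",
                                     np.linspace(1.0, 1.3, 8))
        assert np.allclose(c.T_ff, c.T_cc, rtol=1e-10, atol=1e-12)

    def test_uniaxial_crossfiber_traction_free_fiber(self, dia_material):
        c = cst.stress_stretch_curve(dia_material, "uniaxial-crossfiber",
                                     np.linspace(1.05, 1.25, 4))
        assert np.all(np.abs(c.T_ff) < 1e-7 * np.abs(c.T_cc).max())

    def test_rejects_bad_grid(self, dia_material):
        with pytest.raises(ValueError):
            cst.stress_stretch_curve(dia_material, "equibiaxial", [1.2, 1.1])
        with pytest.raises(ValueError):
            cst.stress_stretch_curve(dia_material, "equibiaxial", [0.9, 1.1])


class TestFitAnisoToFung:
    def test_self_fit_recovers_curves(self):
        target = cst.AnisoMRParams(iso=cst.IsoMRParams(2.0, 1.0, 0.5, 1.2),
                                   K1=3.0, K2=1.5)
        _, rms = cst.fit_aniso_to_fung(target, (1.0, 1.3))
        assert rms < 1e-6

    def test_fung_round_trip_under_5pct(self):
        f = cst.FungParams(10.0, 3.0, 1.5, 0.8)
        fit, _ = cst.fit_aniso_to_fung(f, (1.0, 1.3))
        lams = np.linspace(1.0, 1.3, 25)
        cf = cst.stress_stretch_curve(f, "equibiaxial", lams)
        cm = cst.stress_stretch_curve(fit, "equibiaxial", lams)
        num = np.sqrt(np.mean(np.r_[cm.T_ff - cf.T_ff,
                                    cm.T_cc - cf.T_cc] ** 2))
        assert num / np.abs(cf.T_ff).max() < 0.05

    def test_zero_stiffness_target(self):
        fit, rms = cst.fit_aniso_to_fung(cst.FungParams(0.0, 3.0, 1.5, 0.8))
        c = cst.stress_stretch_curve(fit, "equibiaxial",
                                     np.linspace(1.0, 1.3, 10))
        assert np.abs(c.T_ff).max() < 1e-8
        assert rms < 1e-8


class TestMaterialIO:
    @pytest.mark.parametrize("name", list(cst.DEFAULT_MATERIALS))
    def test_json_round_trip(self, name, tmp_path):
        path = tmp_path / "mats.json"
        cst.save_materials(cst.DEFAULT_MATERIALS, path)
        loaded = cst.load_materials(path)
        assert loaded[name] == cst.DEFAULT_MATERIALS[name]

    def test_scaled_multiplies_stress_like_parameters_only(self, dia_material):
        s = dia_material.scaled(2.5)
        assert s.iso.c1 == 2.5 * dia_material.iso.c1
        assert s.K1 == 2.5 * dia_material.K1
        assert s.iso.D2 == dia_material.iso.D2
        assert s.K2 == dia_material.K2


@given(lam=st.floats(1.0, 1.35), c1=st.floats(0.1, 5.0), k1=st.floats(0.0, 5.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_equibiaxial_energy_and_stress_nonnegative(lam, c1, k1):
    """Admissible parameters give non-negative energy and tensile stresses."""
    p = cst.AnisoMRParams(iso=cst.IsoMRParams(c1, 0.2, 0.1, 1.0), K1=k1, K2=1.0)
    F = np.diag([lam, lam, lam ** -2])
    state = cst.DeformationState(F)
    assert cst.energy(p, state) >= -1e-12
    sig = cst.cauchy_stress(p, state, traction_free_dir="z")
    assert sig[0, 0] >= -1e-9 and sig[1, 1] >= -1e-9
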