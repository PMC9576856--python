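"""Constitutive-model checks against independent oracles.

Stress and tangent are validated against central finite differences of
the energy; the energy itself against a high-precision symbolic
evaluation of the strain-energy function; the fitter against parameter
recovery on self-generated data.
"""

import numpy as np
import pytest

from tonosim.errors import (FitFailureError, InvalidDeformationError,
                            NumericRangeError)
from tonosim.materials import (FiberFrame, HGOMaterial, HGOParams,
                               LinearElasticParams, NeoHookeanParams,
                               StVenantKirchhoffMaterial, cauchy_stress,
                               compute_kinematics, consistent_tangent,
                               fit_hgo_uniaxial, strain_energy,
                               uniaxial_stress)

M0 = np.array([1.0, 0.0, 0.0])
N0 = np.array([0.0, 0.0, 1.0])
FRAME = FiberFrame(m=M0, n=N0)
CORNEA = HGOParams()
SCLERA = NeoHookeanParams()


def random_F(rng, scale=0.15):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return F


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

class TestKinematics:
    def test_identity(self):
        st = compute_kinematics(np.eye(3), FRAME)
        assert st.J == pytest.approx(1.0)
        assert st.I1bar == pytest.approx(3.0)
        assert st.I4bar == pytest.approx(1.0)
        assert st.I6bar == pytest.approx(1.0)

    def test_isochoric_uniaxial_stretch(self):
        lam = 1.2
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        st = compute_kinematics(F, FRAME)
        assert st.J == pytest.approx(1.0, abs=1e-12)
        assert st.I4bar == pytest.approx(lam ** 2)

    def test_simple_shear(self):
        F = np.eye(3)
        F[0, 2] = 0.5                      # shear in the m-n plane
        st = compute_kinematics(F, FRAME)
        assert st.I1bar == pytest.approx(3.25)
        assert abs(np.linalg.det(st.Cbar) - 1.0) < 1e-10

    def test_negative_determinant_rejected(self):
        with pytest.raises(InvalidDeformationError):
            compute_kinematics(-np.eye(3), FRAME)

    def test_invariant_floor(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            st = compute_kinematics(random_F(rng), FRAME)
            assert st.J > 0
            assert st.I1bar >= 3.0 - 1e-9


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

class TestStrainEnergy:
    def test_zero_at_identity(self):
        st = compute_kinematics(np.eye(3), FRAME)
        for p in (CORNEA, SCLERA, LinearElasticParams(E=0.35)):
            assert strain_energy(st, p) == 0.0

    def test_zero_for_rotations(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = rng.standard_normal((3, 3))
            Q, _ = np.linalg.qr(A)
            Q *= np.sign(np.linalg.det(Q))
            st = compute_kinematics(Q, FRAME)
            assert strain_energy(st, CORNEA) == pytest.approx(0.0, abs=1e-12)

    def test_compressed_fibres_contribute_nothing(self):
        # both families shortened (I4bar = 0.81, I6bar ~ 0.90): the
        # tension-only switch reduces the energy to the matrix response
        F = np.diag([0.9, 1.0 / (0.9 * 0.95), 0.95])
        st = compute_kinematics(F, FRAME)
        assert st.I4bar == pytest.approx(0.81)
        assert st.I6bar < 1.0
        psi_full = strain_energy(st, CORNEA)
        psi_matrix = strain_energy(
            st, NeoHookeanParams(C10=CORNEA.C10, kappa=CORNEA.kappa))
        assert psi_full == pytest.approx(psi_matrix, rel=1e-14)

    def test_symbolic_oracle_uniaxial(self):
        """Energy matches a high-precision symbolic evaluation."""
        sympy = pytest.importorskip("sympy")
        lam = 1.05
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        st = compute_kinematics(F, FRAME)
        psi = strain_energy(st, CORNEA)

        lam_s = sympy.Rational(105, 100)
        J = sympy.Integer(1)
        I1b = lam_s ** 2 + 2 / lam_s
        I4b = lam_s ** 2            # m along the stretch
        I6b = 1 / lam_s             # n transverse, compressed -> inactive
        C10, k1, k2 = (sympy.Rational(5, 100), sympy.Rational(1, 100),
                       sympy.Integer(100))
        psi_sym = C10 * (I1b - 3) \
            + k1 / (2 * k2) * (sympy.exp(k2 * (I4b - 1) ** 2) - 1)
        assert psi == pytest.approx(float(psi_sym.evalf(30)), rel=1e-10)

    def test_monotone_in_material_constants(self):
        lam = 1.06
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        st = compute_kinematics(F, FRAME)
        base = strain_energy(st, CORNEA)
        for kw in ({"C10": 0.06}, {"k1": 0.012}, {"k2": 120.0}):
            assert strain_energy(st, HGOParams(**{**dict(
                C10=0.05, k1=0.010, k2=100.0), **kw})) > base

    def test_overflow_raises(self):
        lam = 4.0
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        st = compute_kinematics(F, FRAME)
        with pytest.raises(NumericRangeError):
            strain_energy(st, CORNEA)


# ---------------------------------------------------------------------------
# stress and tangent vs finite-difference oracles
# ---------------------------------------------------------------------------

def fd_cauchy(F, params, frame=FRAME, h=1e-7):
    """Cauchy stress via central differences of Psi and push-forward."""
    def psi(Fx):
        return strain_energy(compute_kinematics(Fx, frame), params)
    P = np.zeros((3, 3))
    for i in range(3):
        for a in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, a] += h
            Fm[i, a] -= h
            P[i, a] = (psi(Fp) - psi(Fm)) / (2 * h)
    sig = P @ F.T / np.linalg.det(F)
    return 0.5 * (sig + sig.T)


class TestStress:
    def test_zero_at_identity(self):
        st = compute_kinematics(np.eye(3), FRAME)
        for p in (CORNEA, SCLERA, LinearElasticParams(E=0.35)):
            assert np.abs(cauchy_stress(st, p)).max() == pytest.approx(
                0.0, abs=1e-14)

    def test_neo_hookean_simple_shear(self):
        F = np.eye(3)
        F[0, 1] = 0.1
        st = compute_kinematics(F, FRAME)
        sig = cauchy_stress(st, SCLERA)
        assert sig[0, 1] == pytest.approx(2 * 0.8 * 0.1, rel=1e-10)

    def test_fibre_stretch_matches_fd(self):
        lam = 1.1
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        st = compute_kinematics(F, FRAME)
        sig = cauchy_stress(st, CORNEA)
        ref = fd_cauchy(F, CORNEA)
        assert np.abs(sig - ref).max() < 1e-6 * max(np.abs(ref).max(), 1)

    @pytest.mark.parametrize("params", [CORNEA, SCLERA,
                                        LinearElasticParams(E=0.35)],
                             ids=["hgo", "neo_hookean", "stvk"])
    def test_random_states_match_fd(self, params):
        rng = np.random.default_rng(11)
        for _ in range(100):
            F = random_F(rng)
            st = compute_kinematics(F, FRAME)
            try:
                sig = cauchy_stress(st, params)
            except NumericRangeError:
                continue
            ref = fd_cauchy(F, params)
            scale = max(np.abs(ref).max(), 1e-6)
            assert np.abs(sig - ref).max() < 1e-5 * scale

    def test_objectivity(self):
        """Psi(Q F) = Psi(F) and sigma rotates with Q."""
        rng = np.random.default_rng(5)
        F = random_F(rng)
        st = compute_kinematics(F, FRAME)
        psi0 = strain_energy(st, CORNEA)
        sig0 = cauchy_stress(st, CORNEA)
        for _ in range(20):
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            Q *= np.sign(np.linalg.det(Q))
            stq = compute_kinematics(Q @ F, FRAME)
            assert strain_energy(stq, CORNEA) == pytest.approx(
                psi0, rel=1e-10, abs=1e-12)
            assert np.allclose(cauchy_stress(stq, CORNEA),
                               Q @ sig0 @ Q.T, atol=1e-10)


class TestTangent:
    def test_small_strain_limit_neo_hookean(self):
        st = compute_kinematics(np.eye(3), FRAME)
        A = consistent_tangent(st, SCLERA)
        mu = 2 * SCLERA.C10
        lam = SCLERA.kappa - 2 * mu / 3
        d = np.eye(3)
        expected = (lam * np.einsum('ia,jb->iajb', d, d)
                    + mu * (np.einsum('ij,ab->iajb', d, d)
                            + np.einsum('ib,aj->iajb', d, d)))
        assert np.abs(A - expected).max() < 1e-10

    def test_major_symmetry_and_fd(self):
        rng = np.random.default_rng(2)
        h = 1e-6
        for _ in range(20):
            F = random_F(rng, scale=0.1)
            st = compute_kinematics(F, FRAME)
            A = consistent_tangent(st, CORNEA)
            assert np.abs(A - A.transpose(2, 3, 0, 1)).max() < 1e-8
            # directional FD of the stress (first Piola via energy FD)
            for _ in range(3):
                dF = rng.standard_normal((3, 3))
                dF /= np.linalg.norm(dF)
                Pp = _pk1(F + h * dF, CORNEA)
                Pm = _pk1(F - h * dF, CORNEA)
                dP_fd = (Pp - Pm) / (2 * h)
                dP = np.einsum('iajb,jb->ia', A, dF)
                assert np.abs(dP - dP_fd).max() < 1e-5 * max(
                    np.abs(dP_fd).max(), 1e-3)

    def test_compressed_fibre_no_tangent_contribution(self):
        F = np.diag([0.9, 1.0 / (0.9 * 0.95), 0.95])
        st = compute_kinematics(F, FRAME)
        assert st.I4bar < 1 and st.I6bar < 1
        A_full = consistent_tangent(st, CORNEA)
        A_matrix = consistent_tangent(st, NeoHookeanParams(
            C10=CORNEA.C10, kappa=CORNEA.kappa))
        assert np.abs(A_full - A_matrix).max() < 1e-14


def _pk1(F, params):
    mat = HGOMaterial(params)
    P, _ = mat.stress_tangent(F[None], M0[None], N0[None],
                              want_tangent=False)
    return P[0]


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

class TestPropertyBased:
    """Hypothesis-driven invariants over random deformation gradients."""

    hypothesis = pytest.importorskip("hypothesis")

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-0.2, 0.2), min_size=9, max_size=9))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_kinematic_invariants(self, entries):
        F = np.eye(3) + np.array(entries).reshape(3, 3)
        if np.linalg.det(F) < 0.3:
            return
        st_ = compute_kinematics(F, FRAME)
        assert st_.J > 0
        assert st_.I1bar >= 3.0 - 1e-9
        assert abs(np.linalg.det(st_.Cbar) - 1.0) < 1e-10

    @given(st.lists(st.floats(-0.15, 0.15), min_size=9, max_size=9),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_nonnegative_and_objective(self, entries, qseed):
        F = np.eye(3) + np.array(entries).reshape(3, 3)
        if np.linalg.det(F) < 0.3:
            return
        st_ = compute_kinematics(F, FRAME)
        psi = strain_energy(st_, CORNEA)
        assert psi >= -1e-14
        Q, _ = np.linalg.qr(
            np.random.default_rng(qseed).standard_normal((3, 3)))
        Q *= np.sign(np.linalg.det(Q))
        assert strain_energy(compute_kinematics(Q @ F, FRAME), CORNEA) \
            == pytest.approx(psi, rel=1e-10, abs=1e-13)


class TestFitting:
    lam = np.linspace(1.005, 1.08, 12)

    def _curves(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for o in (0.0, 90.0):
            s = uniaxial_stress(self.lam, CORNEA, o)
            if noise:
                s = s * (1 + noise * rng.standard_normal(len(s)))
            out.append((self.lam, s, o))
        return out

    def test_noise_free_recovery(self):
        fit = fit_hgo_uniaxial(self._curves())
        assert fit.fiber_identifiable
        assert fit.params.C10 == pytest.approx(CORNEA.C10, rel=0.01)
        assert fit.params.k1 == pytest.approx(CORNEA.k1, rel=0.01)
        assert fit.params.k2 == pytest.approx(CORNEA.k2, rel=0.01)

    def test_noisy_recovery(self):
        for seed in range(5):
            fit = fit_hgo_uniaxial(self._curves(noise=0.02, seed=seed))
            assert fit.params.C10 == pytest.approx(CORNEA.C10, rel=0.15)
            assert fit.params.k1 == pytest.approx(CORNEA.k1, rel=0.15)
            assert fit.params.k2 == pytest.approx(CORNEA.k2, rel=0.15)

    def test_off_fibre_only_flags_unidentifiable(self):
        s = uniaxial_stress(self.lam, CORNEA, 90.0)
        fit = fit_hgo_uniaxial([(self.lam, s, 90.0)])
        assert not fit.fiber_identifiable
        assert fit.params.C10 == pytest.approx(CORNEA.C10, rel=0.02)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(FitFailureError):
            fit_hgo_uniaxial([(self.lam, np.ones_like(self.lam), 0.0)])
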