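"""Constitutive models for the ocular tissues.

The cornea and limbus are anisotropic, nearly-incompressible hyperelastic
solids described by a Holzapfel--Gasser--Ogden (HGO) strain energy with two
collagen-fibre families:

    Psi = C10 (I1bar - 3)
        + k1/(2 k2) * sum_{i=4,6} [ exp(k2 (Ibar_i - 1)^2) - 1 ]
        + U(J)

where ``I1bar = tr(Cbar)`` is the first isochoric invariant and ``Ibar_4 =
m . Cbar m``, ``Ibar_6 = n . Cbar n`` are the squared isochoric fibre
stretches of the two families with reference directions ``m`` and ``n``.
Collagen fibres buckle rather than carry compressive load, so each fibre
term is active only while its invariant exceeds one (tension-only switch).
The volumetric part defaults to the quadratic penalty
``U(J) = kappa/2 (J - 1)^2``; the inverse-compressibility convention
``U(J) = (1/kappa) (J - 1)^2`` is available as a configuration switch.

The sclera uses the isotropic specialization (no fibre terms, i.e. a
nearly-incompressible neo-Hookean matrix), and the soft internal structures
(crystalline lens, ciliary zonule, vitreous membrane) use a Saint
Venant--Kirchhoff linear-elastic law, objective under finite rotation.

All stress kernels work on stacked arrays ``F`` of shape ``(N, 3, 3)`` so
the finite-element assembly can evaluate every quadrature point of a part
in a single call.  The scalar convenience API (:func:`compute_kinematics`,
:func:`strain_energy`, :func:`cauchy_stress`, :func:`consistent_tangent`)
wraps the same kernels for a single material point.

Units: stresses in MPa, densities in g/mm^3 (the package-wide mm-g-ms
system, see :mod:`tonosim.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import FitFailureError, InvalidDeformationError, NumericRangeError

_EYE3 = np.eye(3)
# Largest admissible exponent of the fibre term before we refuse to continue.
_EXP_CAP = 250.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberFrame:
    """Reference directions of the two collagen-fibre families.

    ``m`` is the nasal-temporal family, ``n`` the superior-inferior family
    (circumferential single family in the limbus, where ``n`` is ignored).
    """

    m: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float)
        n = np.asarray(self.n, dtype=float)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "n", n)
        if abs(np.linalg.norm(m) - 1.0) > 1e-12 or abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise ValueError("fibre directions must be unit vectors")


@dataclass(frozen=True)
class HGOParams:
    """HGO constants; defaults are the corneal/limbal reference values."""

    C10: float = 0.05      # matrix stiffness [MPa]
    k1: float = 0.010      # fibre stiffness [MPa]
    k2: float = 100.0      # fibre nonlinearity [-]
    kappa: float = None    # volumetric penalty [MPa]; default 1e3 * C10
    rho: float = 0.0011    # density [g/mm^3]
    volumetric_convention: Literal["penalty", "inverse"] = "penalty"

    def __post_init__(self):
        if self.kappa is None:
            object.__setattr__(self, "kappa", 1e3 * self.C10)
        for name in ("C10", "k1", "k2", "kappa", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class NeoHookeanParams:
    """Isotropic nearly-incompressible matrix; default is the sclera."""

    C10: float = 0.8
    kappa: float = None
    rho: float = 0.0011
    volumetric_convention: Literal["penalty", "inverse"] = "penalty"

    def __post_init__(self):
        if self.kappa is None:
            object.__setattr__(self, "kappa", 1e3 * self.C10)
        for name in ("C10", "kappa", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class LinearElasticParams:
    """Saint Venant-Kirchhoff law for the soft internal structures.

    The default Poisson ratio is nearly incompressible: the hydrated
    lens/zonule tissues conserve volume, and with the very soft lens
    nucleus (E = 0.0003 MPa) any appreciable compressibility would let
    the physiological IOP (0.002 MPa) collapse it.
    """

    E: float
    nu: float = 0.4999
    rho: float = 0.0011

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def lam(self) -> float:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def mu(self) -> float:
        return self.E / (2 * (1 + self.nu))


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities at a material point (all dimensionless)."""

    F: np.ndarray
    C: np.ndarray
    Cbar: np.ndarray
    J: float
    I1bar: float
    I4bar: float
    I6bar: float
    frame: FiberFrame


# ---------------------------------------------------------------------------
# small vectorized linear algebra helpers
# ---------------------------------------------------------------------------

def _det33(A):
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def _inv33(A, det=None):
    if det is None:
        det = _det33(A)
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    inv[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    inv[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    inv[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    inv[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    inv[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    inv[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    inv[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    inv[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return inv / det[..., None, None]


def _outer(a, b):
    """Batched tensor (dyadic) product of two (N,3,3) tensors -> (N,3,3,3,3)."""
    return a[:, :, :, None, None] * b[:, None, None, :, :]


def _sym_outer(a):
    """Batched (a (.) a)_{ABCD} = 1/2 (a_AC a_BD + a_AD a_BC)."""
    t1 = a[:, :, None, :, None] * a[:, None, :, None, :]
    t2 = a[:, :, None, None, :] * a[:, None, :, :, None]
    return 0.5 * (t1 + t2)


def _fiber_psi(k1, k2, x, context="", overflow="raise"):
    """Per-invariant fibre response psi_i = dPsi/dIbar_i and its derivative.

    ``x = Ibar_i - 1``; both vanish for fibres in compression (x <= 0).
    Raises :class:`NumericRangeError` when exp(k2 x^2) would overflow,
    unless ``overflow="clip"`` (used inside nested root solves whose trial
    iterates may wander far before converging).
    """
    x = np.where(x > 0.0, x, 0.0)
    arg = k2 * x * x
    if np.any(arg > _EXP_CAP):
        if overflow == "clip":
            arg = np.minimum(arg, _EXP_CAP)
            x = np.sqrt(arg / k2)
        else:
            idx = np.flatnonzero(np.atleast_1d(arg) > _EXP_CAP)
            raise NumericRangeError(
                f"fibre exponential overflow (k2*(Ibar-1)^2 > {_EXP_CAP:g}) "
                f"at point(s) {idx[:10].tolist()}{' ' + context if context else ''}")
    e = np.exp(arg)
    psi = k1 * x * e
    dpsi = k1 * (1.0 + 2.0 * k2 * x * x) * e
    dpsi = np.where(x > 0.0, dpsi, 0.0)
    return psi, dpsi


def _volumetric(J, kappa, convention):
    """U(J), U'(J), U''(J) for the configured volumetric convention."""
    if convention == "penalty":
        c = 0.5 * kappa
    elif convention == "inverse":
        c = 1.0 / kappa
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown volumetric convention {convention!r}")
    x = J - 1.0
    return c * x * x, 2.0 * c * x, 2.0 * c * np.ones_like(J)


# ---------------------------------------------------------------------------
# vectorized stress / tangent kernels (reference configuration, S and CC)
# ---------------------------------------------------------------------------

def hgo_energy(F, m0=None, n0=None, C10=0.05, k1=0.01, k2=100.0, kappa=50.0,
               convention="penalty", context="", split=None):
    """Strain-energy density (MPa) of the (possibly fibre-free) HGO law.

    ``split`` selects a part: ``"iso"``/``"vol"``/``None`` (total).
    """
    F = np.asarray(F, float)
    J = _det33(F)
    if np.any(J <= 0):
        raise InvalidDeformationError("non-positive det(F)")
    C = np.einsum('...ki,...kj->...ij', F, F)
    I1b = np.einsum('...ii', C) * J ** (-2.0 / 3.0)
    psi_iso = C10 * (I1b - 3.0)
    for a0 in (m0, n0):
        if a0 is None:
            continue
        a0 = np.asarray(a0, float)
        I4b = J ** (-2.0 / 3.0) * np.einsum('...i,...ij,...j->...', a0, C, a0)
        x = np.maximum(I4b - 1.0, 0.0)
        arg = k2 * x * x
        if np.any(arg > _EXP_CAP):
            idx = np.flatnonzero(np.atleast_1d(arg) > _EXP_CAP)
            raise NumericRangeError(
                f"fibre exponential overflow at point(s) {idx[:10].tolist()}"
                f"{' ' + context if context else ''}")
        psi_iso = psi_iso + k1 / (2.0 * k2) * (np.exp(arg) - 1.0)
    U, _, _ = _volumetric(J, kappa, convention)
    if split == "iso":
        return psi_iso
    if split == "vol":
        return U
    return psi_iso + U


def hgo_pk2_tangent(F, m0=None, n0=None, C10=0.05, k1=0.01, k2=100.0,
                    kappa=50.0, convention="penalty", part="total",
                    want_tangent=True, context="", overflow="raise"):
    """Second Piola-Kirchhoff stress S and material tangent CC = 2 dS/dC.

    ``part`` selects ``"iso"``, ``"vol"`` or ``"total"`` so the selective
    reduced integration scheme can evaluate the two contributions on
    different quadrature rules.  Shapes: F (N,3,3) -> S (N,3,3),
    CC (N,3,3,3,3).
    """
    F = np.asarray(F, float)
    single = F.ndim == 2
    if single:
        F = F[None]
    N = F.shape[0]
    with np.errstate(over="ignore", invalid="ignore"):
        J = _det33(F)
    bad_mask = ~np.isfinite(J) | (J <= 0)
    if np.any(bad_mask):
        bad = np.flatnonzero(bad_mask)
        raise InvalidDeformationError(
            f"non-positive or non-finite det(F) at point(s) "
            f"{bad[:10].tolist()}{' ' + context if context else ''}")
    C = np.einsum('nki,nkj->nij', F, F)
    Ci = _inv33(C, det=J * J)
    Jm23 = J ** (-2.0 / 3.0)

    S = np.zeros((N, 3, 3))
    CC = np.zeros((N, 3, 3, 3, 3)) if want_tangent else None

    if part in ("iso", "total"):
        # fictitious stress Sbar = 2 dPsi/dCbar evaluated at Cbar
        Sbar = 2.0 * C10 * np.broadcast_to(_EYE3, (N, 3, 3)).copy()
        SbarC = 2.0 * C10 * np.einsum('nii->n', C)  # Sbar : C
        fib_terms = []
        for a0 in (m0, n0):
            if a0 is None:
                continue
            a0 = np.asarray(a0, float)
            if a0.ndim == 1:
                a0 = np.broadcast_to(a0, (N, 3))
            M = np.einsum('ni,nj->nij', a0, a0)
            I4 = np.einsum('nij,nij->n', M, C)          # unbarred m.C m
            I4b = Jm23 * I4
            psi, dpsi = _fiber_psi(k1, k2, I4b - 1.0, context, overflow)
            Sbar += 2.0 * psi[:, None, None] * M
            SbarC += 2.0 * psi * I4
            fib_terms.append((M, I4, dpsi))
        dev = Sbar - (SbarC / 3.0)[:, None, None] * Ci
        S_iso = Jm23[:, None, None] * dev
        S += S_iso
        if want_tangent:
            CiCi = _sym_outer(Ci)
            CioCi = _outer(Ci, Ci)
            Ptil = CiCi - CioCi / 3.0
            CC += (2.0 / 3.0) * (Jm23 * SbarC)[:, None, None, None, None] * Ptil
            CC -= (2.0 / 3.0) * (_outer(Ci, S_iso) + _outer(S_iso, Ci))
            for M, I4, dpsi in fib_terms:
                DevM = M - (I4 / 3.0)[:, None, None] * Ci
                CC += 4.0 * (Jm23 * Jm23 * dpsi)[:, None, None, None, None] \
                    * _outer(DevM, DevM)

    if part in ("vol", "total"):
        _, Up, Upp = _volumetric(J, kappa, convention)
        S += (J * Up)[:, None, None] * Ci
        if want_tangent:
            CC += ((J * Up + J * J * Upp)[:, None, None, None, None] * _outer(Ci, Ci)
                   - 2.0 * (J * Up)[:, None, None, None, None] * _sym_outer(Ci))

    if single:
        S = S[0]
        if want_tangent:
            CC = CC[0]
    return (S, CC) if want_tangent else (S, None)


def stvk_pk2_tangent(F, lam, mu, want_tangent=True):
    """Saint Venant-Kirchhoff S = lam tr(E) I + 2 mu E and constant tangent."""
    F = np.asarray(F, float)
    single = F.ndim == 2
    if single:
        F = F[None]
    N = F.shape[0]
    if not np.all(np.isfinite(F)):
        from .errors import InvalidDeformationError
        raise InvalidDeformationError("non-finite deformation gradient")
    C = np.einsum('nki,nkj->nij', F, F)
    E = 0.5 * (C - _EYE3)
    trE = np.einsum('nii->n', E)
    S = lam * trE[:, None, None] * _EYE3 + 2.0 * mu * E
    CC = None
    if want_tangent:
        I = np.broadcast_to(_EYE3, (N, 3, 3)).copy()
        CC = lam * _outer(I, I) + 2.0 * mu * _sym_outer(I)
    if single:
        S = S[0]
        CC = CC[0] if want_tangent else None
    return S, CC


def pk2_to_pk1(F, S, CC=None):
    """Convert (S, CC) to first Piola-Kirchhoff P and tangent A = dP/dF."""
    single = F.ndim == 2
    if single:
        F, S = F[None], S[None]
        CC = None if CC is None else CC[None]
    P = np.einsum('niC,nCA->niA', F, S)
    A = None
    if CC is not None:
        A = np.einsum('ij,nAB->niAjB', _EYE3, S) \
            + np.einsum('niC,njE,nCABE->niAjB', F, F, CC, optimize=True)
    if single:
        P = P[0]
        A = None if A is None else A[0]
    return P, A


# ---------------------------------------------------------------------------
# material objects used by the finite-element engine
# ---------------------------------------------------------------------------

class HGOMaterial:
    """Vectorized HGO material bound to per-point fibre directions.

    ``split = True`` signals the assembly to integrate the isochoric part on
    the full quadrature rule and the volumetric part at the element centroid
    (selective reduced integration against volumetric locking).
    """

    split = True

    def __init__(self, params: HGOParams, context: str = ""):
        self.params = params
        self.rho = params.rho
        self.context = context

    def _kw(self):
        p = self.params
        return dict(C10=p.C10, k1=p.k1, k2=p.k2, kappa=p.kappa,
                    convention=p.volumetric_convention, context=self.context)

    def energy(self, F, m0=None, n0=None, split=None):
        return hgo_energy(F, m0, n0, split=split, **self._kw())

    def stress_tangent(self, F, m0=None, n0=None, part="total", want_tangent=True):
        S, CC = hgo_pk2_tangent(F, m0, n0, part=part,
                                want_tangent=want_tangent, **self._kw())
        return pk2_to_pk1(F, S, CC)


class NeoHookeanMaterial(HGOMaterial):
    """Isotropic specialization (fibre-free) used for the sclera."""

    def __init__(self, params: NeoHookeanParams, context: str = ""):
        self.params = params
        self.rho = params.rho
        self.context = context

    def _kw(self):
        p = self.params
        return dict(C10=p.C10, k1=0.0, k2=1.0, kappa=p.kappa,
                    convention=p.volumetric_convention, context=self.context)

    def energy(self, F, m0=None, n0=None, split=None):
        return hgo_energy(F, None, None, split=split, **self._kw())

    def stress_tangent(self, F, m0=None, n0=None, part="total", want_tangent=True):
        S, CC = hgo_pk2_tangent(F, None, None, part=part,
                                want_tangent=want_tangent, **self._kw())
        return pk2_to_pk1(F, S, CC)


class StVenantKirchhoffMaterial:
    """Linear-elastic (finite rotation safe) law; full integration."""

    split = False

    def __init__(self, params: LinearElasticParams, context: str = ""):
        self.params = params
        self.rho = params.rho
        self.context = context

    def energy(self, F, m0=None, n0=None, split=None):
        F = np.asarray(F, float)
        C = np.einsum('...ki,...kj->...ij', F, F)
        E = 0.5 * (C - _EYE3)
        trE = np.einsum('...ii', E)
        return 0.5 * self.params.lam * trE ** 2 \
            + self.params.mu * np.einsum('...ij,...ij', E, E)

    def stress_tangent(self, F, m0=None, n0=None, part="total", want_tangent=True):
        S, CC = stvk_pk2_tangent(F, self.params.lam, self.params.mu,
                                 want_tangent=want_tangent)
        return pk2_to_pk1(F, S, CC)


# ---------------------------------------------------------------------------
# scalar (single material point) API
# ---------------------------------------------------------------------------

_DEFAULT_FRAME = FiberFrame(m=np.array([1.0, 0, 0]), n=np.array([0, 0, 1.0]))


def compute_kinematics(F, frame: FiberFrame = _DEFAULT_FRAME) -> DeformationState:
    """Kinematic invariants of a deformation gradient at one material point."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det(F) = {J:g} <= 0")
    C = F.T @ F
    Cbar = J ** (-2.0 / 3.0) * C
    return DeformationState(
        F=F, C=C, Cbar=Cbar, J=J,
        I1bar=float(np.trace(Cbar)),
        I4bar=float(frame.m @ Cbar @ frame.m),
        I6bar=float(frame.n @ Cbar @ frame.n),
        frame=frame,
    )


def _material_for(params):
    if isinstance(params, HGOParams):
        return HGOMaterial(params)
    if isinstance(params, NeoHookeanParams):
        return NeoHookeanMaterial(params)
    if isinstance(params, LinearElasticParams):
        return StVenantKirchhoffMaterial(params)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def _frames_for(state, params):
    if isinstance(params, HGOParams):
        return state.frame.m[None], state.frame.n[None]
    return None, None


def strain_energy(state: DeformationState, params) -> float:
    """Strain-energy density Psi (MPa) at a material point."""
    mat = _material_for(params)
    m0, n0 = _frames_for(state, params)
    return float(mat.energy(state.F[None], m0, n0)[0])


def cauchy_stress(state: DeformationState, params) -> np.ndarray:
    """Cauchy stress sigma = J^-1 P F^T (MPa), symmetric 3x3."""
    mat = _material_for(params)
    m0, n0 = _frames_for(state, params)
    P, _ = mat.stress_tangent(state.F[None], m0, n0, want_tangent=False)
    sig = P[0] @ state.F.T / state.J
    return 0.5 * (sig + sig.T)


def consistent_tangent(state: DeformationState, params) -> np.ndarray:
    """First-elasticity tensor A = d^2 Psi / dF dF, shape (3,3,3,3).

    Index convention A[i, A, j, B] = dP_iA / dF_jB; possesses major symmetry
    A[i, A, j, B] = A[j, B, i, A].
    """
    mat = _material_for(params)
    m0, n0 = _frames_for(state, params)
    _, A = mat.stress_tangent(state.F[None], m0, n0)
    return A[0]


# ---------------------------------------------------------------------------
# uniaxial response and parameter fitting
# ---------------------------------------------------------------------------

def uniaxial_stress(stretch, params: HGOParams, orientation_deg: float = 0.0):
    """Closed-form(-to-quadrature) uniaxial Cauchy stress of an HGO strip.

    The strip is cut from the fibre plane; ``orientation_deg`` is the angle
    between the loading axis and the ``m`` fibre family, rotating the axis
    out of the fibre plane toward the sheet normal.  0 deg loads along a
    fibre family; 90 deg loads through the thickness where both families go
    into compression and only the matrix responds.  Lateral faces are
    traction free; the two lateral stretches are found by a nested
    incompressible root solve.

    Returns the axial Cauchy stress array (MPa) matching ``stretch``.
    """
    stretch = np.atleast_1d(np.asarray(stretch, dtype=float))
    a = np.deg2rad(orientation_deg)
    e = np.array([np.cos(a), np.sin(a), 0.0])    # loading axis
    g1 = np.array([-np.sin(a), np.cos(a), 0.0])  # lateral, in m-h plane
    g2 = np.array([0.0, 0.0, 1.0])               # lateral, along n
    m0 = np.array([1.0, 0.0, 0.0])
    n0 = np.array([0.0, 0.0, 1.0])
    mat = HGOMaterial(params)

    def sigma(lam, a1, a2):
        F = lam * np.outer(e, e) + a1 * np.outer(g1, g1) + a2 * np.outer(g2, g2)
        S, _ = hgo_pk2_tangent(F[None], m0[None], n0[None],
                               want_tangent=False, overflow="clip",
                               **mat._kw())
        s = F @ S[0] @ F.T / np.linalg.det(F)
        return s

    out = np.empty_like(stretch)
    for k, lam in enumerate(stretch):
        # incompressible split a1 = sqrt(r/lam), a2 = sqrt(1/(r lam));
        # solve the single transverse-stress balance for r.
        def balance(logr):
            r = np.exp(logr)
            a1 = np.sqrt(r / lam)
            a2 = np.sqrt(1.0 / (r * lam))
            s = sigma(lam, a1, a2)
            return g1 @ s @ g1 - g2 @ s @ g2
        logr = brentq(balance, -2.0, 2.0, xtol=1e-12)
        r = np.exp(logr)
        a1, a2 = np.sqrt(r / lam), np.sqrt(1.0 / (r * lam))
        s = sigma(lam, a1, a2)
        # hydrostatic part set by the (equal) lateral traction-free faces
        p_lat = 0.5 * (g1 @ s @ g1 + g2 @ s @ g2)
        out[k] = e @ s @ e - p_lat
    return out


@dataclass
class HGOFitResult:
    params: HGOParams
    residual: float
    fiber_identifiable: bool
    message: str = ""


def fit_hgo_uniaxial(curves: Sequence[tuple], rho: float = 0.0011,
                     kappa_factor: float = 1e3) -> HGOFitResult:
    """Least-squares fit of (C10, k1, k2) to uniaxial stress-stretch curves.

    ``curves`` is a sequence of ``(stretch, stress_MPa, orientation_deg)``
    triples.  At least one curve should load the fibres (orientation well
    below 90 deg); if no supplied data point ever stretches a fibre family,
    only the matrix stiffness is identifiable and the fibre parameters are
    returned at their defaults with ``fiber_identifiable = False``.
    """
    curves = [(np.asarray(s, float), np.asarray(t, float), float(o))
              for s, t, o in curves]
    if not curves:
        raise FitFailureError("no curves supplied")
    for s, t, _ in curves:
        if np.ptp(t) < 1e-12 or np.ptp(s) < 1e-12:
            raise FitFailureError("degenerate (constant) stress-stretch curve")
        if np.any(s <= 1.0):
            raise FitFailureError("stretches must exceed 1")

    def fiber_active(orientation_deg, stretches):
        # fibre stretch along m for the trial kinematics (incompressible,
        # equal laterals as a screening approximation)
        a = np.deg2rad(orientation_deg)
        lam = stretches
        lam_t2 = 1.0 / lam
        I4 = lam ** 2 * np.cos(a) ** 2 + lam_t2 * np.sin(a) ** 2
        return np.any(I4 > 1.0 + 1e-9)

    any_fiber = any(fiber_active(o, s) for s, _, o in curves)

    def model(theta):
        C10, k1, k2 = np.exp(theta)
        p = HGOParams(C10=C10, k1=max(k1, 1e-12), k2=max(k2, 1e-6),
                      kappa=kappa_factor * C10, rho=rho)
        res = []
        for s, t, o in curves:
            res.append(uniaxial_stress(s, p, o) - t)
        return np.concatenate(res)

    if not any_fiber:
        # matrix-only identification from the (fibre-free) curves
        def model_iso(logc):
            p = HGOParams(C10=np.exp(logc[0]), k1=1e-9, k2=100.0,
                          kappa=kappa_factor * np.exp(logc[0]), rho=rho)
            return np.concatenate([uniaxial_stress(s, p, o) - t
                                   for s, t, o in curves])
        sol = least_squares(model_iso, [np.log(0.05)], method="lm")
        C10 = float(np.exp(sol.x[0]))
        return HGOFitResult(
            params=HGOParams(C10=C10, k1=0.010, k2=100.0,
                             kappa=kappa_factor * C10, rho=rho),
            residual=float(np.sqrt(np.mean(sol.fun ** 2))),
            fiber_identifiable=False,
            message="no fibre family in tension anywhere in the data; "
                    "k1 and k2 left at their defaults")

    # crude initial matrix stiffness from the small-strain slope of the
    # most off-fibre curve (sigma ~ 6 C10 eps for an incompressible matrix)
    s0, t0, _ = max(curves, key=lambda c: c[2])
    slope = (t0[-1] - t0[0]) / (s0[-1] - s0[0])
    c10_0 = max(slope / 6.0, 1e-4)
    x0 = np.log([c10_0, 0.01, 100.0])
    sol = least_squares(model, x0, method="trf",
                        bounds=(np.log([1e-6, 1e-8, 1e-2]),
                                np.log([1e2, 1e2, 1e5])),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    C10, k1, k2 = np.exp(sol.x)
    return HGOFitResult(
        params=HGOParams(C10=float(C10), k1=float(k1), k2=float(k2),
                         kappa=kappa_factor * float(C10), rho=rho),
        residual=float(np.sqrt(np.mean(sol.fun ** 2))),
        fiber_identifiable=True)
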