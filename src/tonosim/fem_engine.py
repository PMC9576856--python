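"""Total-Lagrangian finite-element machinery.

Hexahedral solids with selective reduced integration (isochoric terms on
the full 2x2x2 Gauss rule, volumetric penalty at the element centroid, to
avoid locking of the nearly-incompressible tissues), 4-node membrane
elements for the thin internal structures, follower pressure loads, humor
cavities as single-pressure enclosed volumes, implicit Newmark dynamics
with mass-weighted damping, and incremental-iterative quasi-statics.

Unit system mm-g-ms-MPa throughout (1 mm/ms = 1 m/s).

Sign conventions.  The enclosed-volume function V(x) of an oriented facet
set is the potential of the follower pressure load: a cavity at pressure
p exerts the nodal force p dV/dx on the structure (facets oriented out of
the cavity).  The public :func:`apply_pressure_load` uses the opposite,
compressive convention (positive pressure pushes against the oriented
normal), matching an air jet impinging on the anterior surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import (ConvergenceError, GeometryError,
                     InvalidDeformationError, NumericRangeError,
                     OrientationError)
from .eye_model import (EyeMesh, _faces_to_tris, facet_volume,
                        facet_volume_gradient)
from .materials import (HGOMaterial, HGOParams, LinearElasticParams,
                        NeoHookeanMaterial, NeoHookeanParams,
                        StVenantKirchhoffMaterial)
from .units import MMHG_TO_MPA, MPA_TO_MMHG

# ---------------------------------------------------------------------------
# quadrature tables for the trilinear hex
# ---------------------------------------------------------------------------

_XI_NODES = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                     dtype=float)


def _hex_dN(xi):
    """Shape-function gradients dN/dxi at one natural point, shape (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI_NODES[a]
        g[a, 0] = xa * (1 + ya * xi[1]) * (1 + za * xi[2]) / 8.0
        g[a, 1] = ya * (1 + xa * xi[0]) * (1 + za * xi[2]) / 8.0
        g[a, 2] = za * (1 + xa * xi[0]) * (1 + ya * xi[1]) / 8.0
    return g


_GP = np.array([[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)],
               dtype=float) / np.sqrt(3.0)
_DN_GP = np.stack([_hex_dN(p) for p in _GP])       # (8, 8, 3)
_DN_C = _hex_dN(np.zeros(3))[None]                 # (1, 8, 3), centroid


def _grad_ops(X_e, dN):
    """Per-element, per-gp gradient operators.

    Returns G (ne, ng, 8, 3) with G[e,g,n,:] = dN_n/dX, and the Jacobian
    determinants detJ (ne, ng).
    """
    Jm = np.einsum('eni,gnj->egij', X_e, dN)
    det = (Jm[..., 0, 0] * (Jm[..., 1, 1] * Jm[..., 2, 2] - Jm[..., 1, 2] * Jm[..., 2, 1])
           - Jm[..., 0, 1] * (Jm[..., 1, 0] * Jm[..., 2, 2] - Jm[..., 1, 2] * Jm[..., 2, 0])
           + Jm[..., 0, 2] * (Jm[..., 1, 0] * Jm[..., 2, 1] - Jm[..., 1, 1] * Jm[..., 2, 0]))
    from .materials import _inv33
    invJ = _inv33(Jm, det=det)
    G = np.einsum('gnj,egji->egni', dN, invJ)
    return G, det


def hex_volumes(nodes, hexes):
    """Element volumes by full quadrature."""
    X_e = nodes[hexes]
    _, det = _grad_ops(X_e, _DN_GP)
    return det.sum(axis=1)


# ---------------------------------------------------------------------------
# configuration / state containers
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    dt: float = 0.25                 # time step [ms]
    beta: float = 0.3025             # Newmark beta (mild dissipation pair)
    gamma: float = 0.6               # Newmark gamma
    mass_damping: float = 0.1        # c [1/ms], damping force = c M v
    newton_rtol: float = 1e-6
    newton_atol: float = 1e-10
    newton_maxit: int = 30
    max_halvings: int = 4
    full_integration: bool = False   # disable SRI (verification only)
    stabilization: float = 1e-6      # grounding springs on floating internals
    track_energy: bool = True        # maintain the energy ledger per step

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 < self.beta <= 0.5 and 0.5 <= self.gamma <= 1.0):
            raise ValueError("Newmark parameters out of range")
        if self.mass_damping < 0:
            raise ValueError("damping constant must be non-negative")


@dataclass
class CavityState:
    """Closed/inflow/constant-pressure humor cavity.

    Volumes are quarter-model values (mm^3); pressures are stored in MPa
    and reported in mmHg (1 mmHg = 1.33322e-4 MPa).
    """

    name: str
    mode: str = "constant"           # 'constant' | 'inflow' | 'closed'
    V0: float = 0.0                  # reference (build) volume
    V: float = 0.0                   # current volume
    p: float = 0.0                   # pressure [MPa]
    V_closed: float = 0.0            # conserved volume in closed mode
    inflow_rate: float = 0.0         # [mm^3/ms], drives V_target
    V_target: float = 0.0            # tracked volume in inflow mode
    target_pressure: float = 0.0     # [MPa]
    Kc: float = 1e-2                 # inflow penalty [MPa/mm^3]

    @property
    def p_mmhg(self):
        return self.p * MPA_TO_MMHG


def cavity_pressure_update(cavity: CavityState, V_new: float,
                           stiffness: float = None) -> CavityState:
    """Pressure-volume update rule of one cavity (augmented-Lagrange form).

    closed: p <- p + K (V_closed - V); inflow: p = Kc (V_target - V);
    constant: p unchanged.  The monolithic solver enforces the closed-mode
    constraint exactly via a Lagrange multiplier; this op expresses the
    same physics as an explicit update (and is what an operator-split
    coupling would iterate).
    """
    if V_new <= 0:
        raise GeometryError(f"cavity {cavity.name}: non-positive volume")
    c = replace(cavity, V=V_new)
    K = stiffness if stiffness is not None else cavity.Kc
    if cavity.mode == "closed":
        c.p = cavity.p + K * (cavity.V_closed - V_new)
    elif cavity.mode == "inflow":
        c.p = cavity.Kc * (cavity.V_target - V_new)
    elif cavity.mode != "constant":
        raise ValueError(f"unknown cavity mode {cavity.mode!r}")
    return c


@dataclass
class EnergyLedger:
    strain: float = 0.0
    kinetic: float = 0.0
    damping: float = 0.0
    external_work: float = 0.0
    peak_external_work: float = 0.0

    @property
    def balance_residual(self):
        return self.external_work - (self.strain + self.kinetic + self.damping)


@dataclass
class SystemState:
    u: np.ndarray                    # nodal displacements (Nn, 3) [mm]
    v: np.ndarray                    # velocities [mm/ms]
    a: np.ndarray                    # accelerations [mm/ms^2]
    time: float = 0.0                # [ms]
    cavities: dict = field(default_factory=dict)
    energy: EnergyLedger = field(default_factory=EnergyLedger)

    def copy(self):
        return SystemState(self.u.copy(), self.v.copy(), self.a.copy(),
                           self.time,
                           {k: replace(v) for k, v in self.cavities.items()},
                           replace(self.energy))


# ---------------------------------------------------------------------------
# element groups
# ---------------------------------------------------------------------------

class _HexGroup:
    def __init__(self, name, conn, material, m0=None, n0=None,
                 full_integration=False):
        self.name = name
        self.conn = conn                          # (ne, 8)
        self.material = material
        self.m0 = m0
        self.n0 = n0
        self.split = material.split and not full_integration
        self.dofs = (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), 24)

    def set_reference(self, X):
        X_e = X[self.conn]
        self.G, det = _grad_ops(X_e, _DN_GP)
        self.w = det                              # gauss weights are 1
        self.G0, det0 = _grad_ops(X_e, _DN_C)
        self.w0 = 8.0 * det0[:, 0]
        if np.any(det <= 0) or np.any(det0 <= 0):
            raise GeometryError(f"inverted element in group {self.name}")
        self.volume = self.w.sum()

    def _deformation(self, u):
        u_e = u[self.conn]
        F = np.einsum('eni,egnj->egij', u_e, self.G)
        F += np.eye(3)
        F0 = np.einsum('eni,egnj->egij', u_e, self.G0)
        F0 += np.eye(3)
        return F, F0

    def _fib(self, n_rep):
        m0 = None if self.m0 is None else np.repeat(self.m0, n_rep, axis=0)
        n0 = None if self.n0 is None else np.repeat(self.n0, n_rep, axis=0)
        return m0, n0

    def force_stiffness(self, u, want_K=True, want_energy=False):
        ne = len(self.conn)
        F, F0 = self._deformation(u)
        Ff = F.reshape(-1, 3, 3)
        m8, n8 = self._fib(8)
        m1, n1 = self._fib(1)
        mat = self.material
        if self.split:
            P_i, A_i = mat.stress_tangent(Ff, m8, n8, part="iso",
                                          want_tangent=want_K)
            P_v, A_v = mat.stress_tangent(F0.reshape(-1, 3, 3), m1, n1,
                                          part="vol", want_tangent=want_K)
            P_i = P_i.reshape(ne, 8, 3, 3)
            P_v = P_v.reshape(ne, 1, 3, 3)
            f = np.einsum('eg,egij,egnj->eni', self.w, P_i, self.G)
            f += np.einsum('e,eij,egnj->eni', self.w0, P_v[:, 0], self.G0)
            k = None
            if want_K:
                A_i = A_i.reshape(ne, 8, 3, 3, 3, 3)
                A_v = A_v.reshape(ne, 1, 3, 3, 3, 3)
                t1 = np.einsum('egna,egiajb->egnijb', self.G, A_i)
                k = np.einsum('eg,egnijb,egmb->enimj', self.w, t1, self.G,
                              optimize=True)
                t2 = np.einsum('egna,egiajb->egnijb', self.G0, A_v)
                k += np.einsum('e,egnijb,egmb->enimj', self.w0, t2, self.G0,
                               optimize=True)
            energy = None
            if want_energy:
                e_i = mat.energy(Ff, m8, n8, split="iso").reshape(ne, 8)
                e_v = mat.energy(F0.reshape(-1, 3, 3), m1, n1,
                                 split="vol").reshape(ne)
                energy = float((self.w * e_i).sum() + (self.w0 * e_v).sum())
        else:
            P, A = mat.stress_tangent(Ff, m8, n8, want_tangent=want_K)
            P = P.reshape(ne, 8, 3, 3)
            f = np.einsum('eg,egij,egnj->eni', self.w, P, self.G)
            k = None
            if want_K:
                A = A.reshape(ne, 8, 3, 3, 3, 3)
                t1 = np.einsum('egna,egiajb->egnijb', self.G, A)
                k = np.einsum('eg,egnijb,egmb->enimj', self.w, t1, self.G,
                              optimize=True)
            energy = None
            if want_energy:
                energy = float((self.w * mat.energy(Ff, m8, n8)
                                .reshape(ne, 8)).sum())
        if want_K:
            k = k.reshape(ne, 24, 24)
        return f, k, energy


class _MembraneGroup:
    """4-node total-Lagrangian membranes, plane-stress StVK material."""

    _gp2 = np.array([[a, b] for a in (-1, 1) for b in (-1, 1)]) / np.sqrt(3.0)

    def __init__(self, name, conn, params: LinearElasticParams, thickness):
        self.name = name
        self.conn = conn
        self.params = params
        self.t = thickness
        self.dofs = (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), 12)
        dN = np.empty((4, 4, 2))
        corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
        for g, (xi, eta) in enumerate(self._gp2):
            for a, (xa, ya) in enumerate(corners):
                dN[g, a, 0] = xa * (1 + ya * eta) / 4.0
                dN[g, a, 1] = ya * (1 + xa * xi) / 4.0
        self.dN = dN                                # (gp, node, alpha)
        E, nu = params.E, params.nu
        Eb = E / (1.0 - nu * nu)
        I2 = np.eye(2)
        self.D = Eb * (nu * np.einsum('ij,pq->ijpq', I2, I2)
                       + 0.5 * (1 - nu) * (np.einsum('ip,jq->ijpq', I2, I2)
                                           + np.einsum('iq,jp->ijpq', I2, I2)))

    def set_reference(self, X):
        X_e = X[self.conn]
        A = np.einsum('gna,eni->egai', self.dN, X_e)   # covariant base (2,3)
        self.Aref = A
        self.Amet = np.einsum('egai,egbi->egab', A, A)
        n = np.cross(A[:, :, 0], A[:, :, 1])
        self.jw = np.linalg.norm(n, axis=-1)           # area jacobian
        e1 = A[:, :, 0] / np.linalg.norm(A[:, :, 0], axis=-1, keepdims=True)
        a2 = A[:, :, 1] - np.einsum('egi,egi->eg', A[:, :, 1], e1)[..., None] * e1
        e2 = a2 / np.linalg.norm(a2, axis=-1, keepdims=True)
        Q = np.stack([np.einsum('egai,egi->ega', A, e1),
                      np.einsum('egai,egi->ega', A, e2)], axis=-2)  # (e,g,i,a)
        det = Q[..., 0, 0] * Q[..., 1, 1] - Q[..., 0, 1] * Q[..., 1, 0]
        Qi = np.empty_like(Q)                           # Qi[a, i]
        Qi[..., 0, 0] = Q[..., 1, 1]
        Qi[..., 0, 1] = -Q[..., 0, 1]
        Qi[..., 1, 0] = -Q[..., 1, 0]
        Qi[..., 1, 1] = Q[..., 0, 0]
        self.Qi = Qi / det[..., None, None]
        self.area = self.jw.sum()
        self.volume = self.area * self.t

    def assemble(self, X, u, want_K=True, want_energy=False):
        x_e = (X + u)[self.conn]
        a = np.einsum('gna,eni->egai', self.dN, x_e)
        Ecov = 0.5 * (np.einsum('egai,egbi->egab', a, a) - self.Amet)
        Qi = self.Qi
        Eloc = np.einsum('egai,egab,egbj->egij', Qi, Ecov, Qi)
        Sloc = np.einsum('ijpq,egpq->egij', self.D, Eloc)
        Scon = np.einsum('egai,egij,egbj->egab', Qi, Sloc, Qi)
        wt = self.jw * self.t
        f = np.einsum('eg,egab,gna,egbi->eni', wt, Scon, self.dN, a)
        k = None
        if want_K:
            # B[e,g,i,j,n,k]: cartesian strain rate per unit nodal velocity
            t1 = np.einsum('gna,egbk->egabnk', self.dN, a)
            Bcov = 0.5 * (t1 + np.einsum('egabnk->egbank', t1))
            B = np.einsum('egai,egbj,egabnk->egijnk', Qi, Qi, Bcov)
            k = np.einsum('eg,egijnk,ijpq,egpqml->enkml', wt, B, self.D, B,
                          optimize=True)
            kg = np.einsum('eg,egab,gna,gmb->enm', wt, Scon, self.dN, self.dN)
            k += kg[:, :, None, :, None] * np.eye(3)[None, None, :, None, :]
            k = k.reshape(len(self.conn), 12, 12)
        energy = None
        if want_energy:
            e = 0.5 * np.einsum('egij,ijpq,egpq->eg', Eloc, self.D, Eloc)
            energy = float((wt * e).sum())
        return f, k, energy


# ---------------------------------------------------------------------------
# pressure loads
# ---------------------------------------------------------------------------

def _skew(v):
    z = np.zeros(v.shape[:-1])
    return np.stack([
        np.stack([z, -v[..., 2], v[..., 1]], axis=-1),
        np.stack([v[..., 2], z, -v[..., 0]], axis=-1),
        np.stack([-v[..., 1], v[..., 0], z], axis=-1)], axis=-2)


def volume_load(x, faces, p):
    """Force p dV/dx of (possibly per-face) pressure on oriented facets."""
    faces = np.asarray(faces)
    p = np.broadcast_to(np.atleast_1d(p), (len(faces),))
    tris = _faces_to_tris(faces)
    pt = np.concatenate([p, p])
    p1, p2, p3 = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    f = np.zeros_like(x)
    np.add.at(f, tris[:, 0], pt[:, None] * np.cross(p2, p3) / 6.0)
    np.add.at(f, tris[:, 1], pt[:, None] * np.cross(p3, p1) / 6.0)
    np.add.at(f, tris[:, 2], pt[:, None] * np.cross(p1, p2) / 6.0)
    return f


def volume_load_hessian_triplets(x, faces, p):
    """COO triplets of p d2V/dx2 (symmetric follower-load stiffness)."""
    faces = np.asarray(faces)
    p = np.broadcast_to(np.atleast_1d(p), (len(faces),))
    tris = _faces_to_tris(faces)
    pt = np.concatenate([p, p])
    i1, i2, i3 = tris[:, 0], tris[:, 1], tris[:, 2]
    x1, x2, x3 = x[i1], x[i2], x[i3]
    rows, cols, vals = [], [], []

    def add_block(ia, ib, M):
        r = (3 * ia[:, None, None] + np.arange(3)[None, :, None])
        c = (3 * ib[:, None, None] + np.arange(3)[None, None, :])
        rows.append(np.broadcast_to(r, M.shape).ravel())
        cols.append(np.broadcast_to(c, M.shape).ravel())
        vals.append(M.ravel())

    s1, s2, s3 = _skew(x1), _skew(x2), _skew(x3)
    w = pt[:, None, None] / 6.0
    add_block(i1, i2, -w * s3)
    add_block(i2, i1, w * s3)
    add_block(i1, i3, w * s2)
    add_block(i3, i1, -w * s2)
    add_block(i2, i3, -w * s1)
    add_block(i3, i2, w * s1)
    return (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))


def surface_pressure_force(x, faces, p):
    """Consistent follower force of per-face pressure on an open facet set.

    Each triangle distributes ``p A n / 3`` to its nodes, with ``n`` the
    current unit normal; positive ``p`` pushes along the oriented normal.
    Unlike :func:`volume_load` this is exact for open patches with
    non-uniform pressure (the air-jet footprint).
    """
    faces = np.asarray(faces)
    p = np.broadcast_to(np.atleast_1d(p), (len(faces),))
    tris = _faces_to_tris(faces)
    pt = np.concatenate([p, p])
    p1, p2, p3 = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    An = 0.5 * np.cross(p2 - p1, p3 - p1)          # area-weighted normal
    fn = (pt[:, None] / 3.0) * An
    f = np.zeros_like(x)
    for k in range(3):
        np.add.at(f, tris[:, k], fn)
    return f


def surface_pressure_stiffness_triplets(x, faces, p):
    """COO triplets of d(surface_pressure_force)/dx (follower stiffness)."""
    faces = np.asarray(faces)
    p = np.broadcast_to(np.atleast_1d(p), (len(faces),))
    tris = _faces_to_tris(faces)
    pt = np.concatenate([p, p])
    i1, i2, i3 = tris[:, 0], tris[:, 1], tris[:, 2]
    x1, x2, x3 = x[i1], x[i2], x[i3]
    # d(A n)/dx_k = 1/2 skew(x_{k+2} - x_{k+1})  (cyclic)
    dn = {0: 0.5 * _skew(x3 - x2), 1: 0.5 * _skew(x1 - x3),
          2: 0.5 * _skew(x2 - x1)}
    rows, cols, vals = [], [], []
    idx = {0: i1, 1: i2, 2: i3}
    for i in range(3):           # receiving node
        for j in range(3):       # moving node
            M = (pt[:, None, None] / 3.0) * dn[j]
            r = (3 * idx[i][:, None, None] + np.arange(3)[None, :, None])
            c = (3 * idx[j][:, None, None] + np.arange(3)[None, None, :])
            rows.append(np.broadcast_to(r, M.shape).ravel())
            cols.append(np.broadcast_to(c, M.shape).ravel())
            vals.append(M.ravel())
    return (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))


def apply_pressure_load(x, faces, p):
    """External force of a compressive pressure on an oriented facet set.

    Positive ``p`` pushes against the oriented facet normals (a jet blowing
    onto an outward-oriented surface); for a closed surface the net force
    is exactly zero.
    """
    faces = np.asarray(faces)
    n = np.cross(x[faces[:, 2]] - x[faces[:, 0]],
                 x[faces[:, 3]] - x[faces[:, 1]])
    if np.any(np.linalg.norm(n, axis=1) == 0):
        raise OrientationError("degenerate facet in pressure load")
    return -surface_pressure_force(x, faces, p)


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

class Model:
    """A meshed eye (or verification body) with materials and constraints."""

    def __init__(self, mesh: EyeMesh, materials: dict,
                 solver: SolverConfig = None,
                 membrane_thickness: float = 0.05,
                 extra_fixed_dofs=None):
        self.mesh = mesh
        self.materials = materials
        self.solver = solver or SolverConfig()
        self.X = mesh.nodes.copy()
        self.n_nodes = len(self.X)
        self.ndof = 3 * self.n_nodes

        self.groups = []
        for part in mesh.part_names:
            elems = mesh.part_elements(part)
            if len(elems) == 0 or part not in materials:
                continue
            mat = materials[part]
            m0 = mesh.fiber_m[elems]
            n0 = mesh.fiber_n[elems]
            m0 = m0 if np.isfinite(m0).all() else None
            n0 = n0 if np.isfinite(n0).all() else None
            if not isinstance(mat, (HGOMaterial, NeoHookeanMaterial)):
                m0 = n0 = None
            if isinstance(mat, NeoHookeanMaterial):
                m0 = n0 = None
            self.groups.append(_HexGroup(part, mesh.hexes[elems], mat,
                                         m0, n0,
                                         self.solver.full_integration))
        self.membranes = []
        for part in mesh.part_names:
            shells = mesh.part_shells(part)
            if len(shells) == 0 or part not in materials:
                continue
            self.membranes.append(_MembraneGroup(
                part, mesh.shells[shells], materials[part].params
                if hasattr(materials[part], "params") else materials[part],
                membrane_thickness))

        # fixed dofs from symmetry planes and the equatorial cut
        fixed = np.zeros(self.ndof, dtype=bool)
        fixed[3 * mesh.node_sets["symmetry_x"] + 0] = True
        fixed[3 * mesh.node_sets["symmetry_z"] + 2] = True
        bottom_bc = mesh.config.bottom_bc if mesh.config else "symmetry"
        if bottom_bc == "clamped":
            for c in range(3):
                fixed[3 * mesh.node_sets["bottom"] + c] = True
        else:
            fixed[3 * mesh.node_sets["bottom"] + 1] = True
        if extra_fixed_dofs is not None:
            fixed[np.asarray(extra_fixed_dofs)] = True
        self.fixed = fixed
        self.free = np.flatnonzero(~fixed)

        # grounding springs on nodes not attached to the corneo-scleral shell
        shell_nodes = set()
        for g in self.groups:
            if g.name in ("cornea", "limbus", "sclera", "block"):
                shell_nodes.update(np.unique(g.conn).tolist())
        float_nodes = sorted(set(range(self.n_nodes)) - shell_nodes)
        internal = np.array([n for n in float_nodes], dtype=np.int64)
        self.spring_nodes = internal if len(shell_nodes) else np.array([], np.int64)
        self.k_spring = self.solver.stabilization

        self.set_reference(self.X)

    # -- reference-dependent precomputations ---------------------------
    def set_reference(self, X):
        self.X = np.asarray(X, float).copy()
        for g in self.groups:
            g.set_reference(self.X)
        for m in self.membranes:
            m.set_reference(self.X)
        rows = []
        for g in self.groups:
            d = g.dofs
            rows.append((np.repeat(d, 24, axis=1).ravel(),
                         np.tile(d, (1, 24)).ravel()))
        for m in self.membranes:
            d = m.dofs
            rows.append((np.repeat(d, 12, axis=1).ravel(),
                         np.tile(d, (1, 12)).ravel()))
        self._krows = np.concatenate([r for r, _ in rows]) if rows else np.array([], int)
        self._kcols = np.concatenate([c for _, c in rows]) if rows else np.array([], int)
        self._mass = self._lumped_mass()

    def _lumped_mass(self):
        m = np.zeros(self.n_nodes)
        for g in self.groups:
            vol = g.w.sum(axis=1)
            np.add.at(m, g.conn, (g.material.rho * vol / 8.0)[:, None])
        for mem in self.membranes:
            area = mem.jw.sum(axis=1)
            rho = mem.params.rho
            np.add.at(m, mem.conn, (rho * mem.t * area / 4.0)[:, None])
        return m

    @property
    def mass_node(self):
        return self._mass

    def make_cavities(self, mode="constant", p_mmhg=0.0):
        cavs = {}
        for name, faces in self.mesh.cavity_faces.items():
            V = facet_volume(self.X, faces)
            cavs[name] = CavityState(name=name, mode=mode, V0=V, V=V,
                                     p=p_mmhg * MMHG_TO_MPA, V_closed=V,
                                     V_target=V)
        return cavs

    # -- assembly -------------------------------------------------------
    def internal(self, u, want_K=True, want_energy=False):
        """Internal force (Nn,3), stiffness triplet values, strain energy."""
        f = np.zeros((self.n_nodes, 3))
        vals = []
        energy = 0.0
        for g in self.groups:
            fe, ke, ee = g.force_stiffness(u, want_K, want_energy)
            np.add.at(f, g.conn, fe)
            if want_K:
                vals.append(ke.ravel())
            if want_energy:
                energy += ee
        for m in self.membranes:
            fe, ke, ee = m.assemble(self.X, u, want_K, want_energy)
            np.add.at(f, m.conn, fe)
            if want_K:
                vals.append(ke.ravel())
            if want_energy:
                energy += ee
        if len(self.spring_nodes):
            f[self.spring_nodes] += self.k_spring * u[self.spring_nodes]
            if want_energy:
                energy += 0.5 * self.k_spring * float(
                    (u[self.spring_nodes] ** 2).sum())
        kv = np.concatenate(vals) if (want_K and vals) else None
        return f, kv, energy

    def stiffness_matrix(self, kvals, extra=None):
        rows, cols, vals = self._krows, self._kcols, kvals
        if len(self.spring_nodes):
            sd = (3 * self.spring_nodes[:, None] + np.arange(3)).ravel()
            rows = np.concatenate([rows, sd])
            cols = np.concatenate([cols, sd])
            vals = np.concatenate([vals, np.full(len(sd), self.k_spring)])
        if extra is not None:
            er, ec, ev = extra
            rows = np.concatenate([rows, er])
            cols = np.concatenate([cols, ec])
            vals = np.concatenate([vals, ev])
        K = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        return K

    def quadrature_stress(self, u, part):
        """Cauchy stress at the Gauss points of one part, (ne, 8, 3, 3)."""
        for g in self.groups:
            if g.name == part:
                break
        else:
            raise KeyError(part)
        F, F0 = g._deformation(u)
        ne = len(g.conn)
        m8, n8 = g._fib(8)
        Ff = F.reshape(-1, 3, 3)
        P, _ = g.material.stress_tangent(Ff, m8, n8, want_tangent=False)
        J = np.linalg.det(Ff)
        sig = np.einsum('nij,nkj->nik', P, Ff) / J[:, None, None]
        return sig.reshape(ne, 8, 3, 3)


# ---------------------------------------------------------------------------
# nonlinear solves
# ---------------------------------------------------------------------------

def _solve_newton(model: Model, u, cavities: dict, jet=None, dyn=None,
                  rtol=None, maxit=None, lu_cache=None):
    """One Newton solve of the (possibly dynamic) bordered system.

    ``jet`` = (faces, per-face pressures) with compressive convention.
    ``dyn`` = dict(u_n, v_n, a_n, dt) for a Newmark step, else quasi-static.

    Globalization: a residual-norm backtracking line search (an update
    that grows the residual or inverts elements is halved before being
    accepted), plus modified-Newton reuse of the tangent factorization --
    optionally carried across solves through ``lu_cache`` -- with
    automatic refactorization when the frozen tangent stops contracting.
    Mutates nothing; returns (u, cavities, info dict).
    """
    cfg = model.solver
    rtol = rtol or cfg.newton_rtol
    maxit = maxit or cfg.newton_maxit
    free = model.free
    nfree = len(free)
    cav_names = [n for n, c in cavities.items()
                 if c.mode in ("closed", "inflow")]
    ncav = len(cav_names)
    cavs = {n: replace(c) for n, c in cavities.items()}
    u = u.copy()
    mvec = np.repeat(model.mass_node, 3)

    if dyn is not None:
        dt = dyn["dt"]
        beta, gamma = cfg.beta, cfg.gamma
        c1 = 1.0 / (beta * dt * dt)
        u_pred = dyn["u_n"] + dt * dyn["v_n"] \
            + dt * dt * (0.5 - beta) * dyn["a_n"]
        v_base = dyn["v_n"] + dt * (1 - gamma) * dyn["a_n"]
        dyn_coeff = c1 + cfg.mass_damping * gamma / (beta * dt)

    # frozen-tangent reuse pays off in dynamics (many similar solves);
    # quasi-statics with large load steps converges best with full Newton
    allow_frozen = dyn is not None or lu_cache is not None
    lu = lu_cache.get("lu") if lu_cache is not None else None
    lu_frozen = lu is not None            # factored at some other state

    def residual(u_c, cavs_c, want_K=False):
        """(R_free, cres, fnorm, scale, grads, kvals_or_None, extras)."""
        x = model.X + u_c
        f_int, kvals, _ = model.internal(u_c, want_K=want_K)
        R = f_int.copy()
        extra_r, extra_c, extra_v = [], [], []
        grads = {}
        for name in cavities:
            c = cavs_c[name]
            faces = model.mesh.cavity_faces[name]
            c.V = facet_volume(x, faces)
            g = facet_volume_gradient(x, faces)
            grads[name] = g
            R -= c.p * g
            if want_K:
                hr, hc, hv = volume_load_hessian_triplets(x, faces, 1.0)
                extra_r.append(hr)
                extra_c.append(hc)
                extra_v.append(-c.p * hv)
        if jet is not None:
            faces_j, p_j = jet
            if np.any(np.atleast_1d(p_j) != 0.0):
                R -= -surface_pressure_force(x, faces_j, p_j)
                if want_K:
                    hr, hc, hv = surface_pressure_stiffness_triplets(
                        x, faces_j, p_j)
                    extra_r.append(hr)
                    extra_c.append(hc)
                    extra_v.append(hv)
        if dyn is not None:
            a = c1 * (u_c - u_pred)
            v = v_base + gamma * dt * a
            R += (mvec * (a + cfg.mass_damping * v).ravel()).reshape(-1, 3)
        Rf = R.reshape(-1)[free]
        scale = max(np.linalg.norm(f_int.reshape(-1)[free]),
                    np.linalg.norm((R - f_int).reshape(-1)[free]), 1e-8)
        cres = []
        for name in cav_names:
            c = cavs_c[name]
            if c.mode == "closed":
                cres.append(c.V - c.V_closed)
            else:
                cres.append(c.p - c.Kc * (c.V_target - c.V))
        extras = (np.concatenate(extra_r), np.concatenate(extra_c),
                  np.concatenate(extra_v)) if extra_r else None
        return Rf, cres, float(np.linalg.norm(Rf)), scale, grads, kvals, \
            extras

    scale_ref = [1e-8]

    def merit(fn, cr, sc):
        """Dimensionless combined residual: force + cavity constraints.

        Forces are normalized by the largest load scale seen so far in
        this solve (a zero-load starting state must not make ordinary
        intermediate residuals look enormous); closed-cavity constraint
        residuals by the cavity volume, inflow ones by a physiological
        pressure scale.
        """
        scale_ref[0] = max(scale_ref[0], sc)
        cterm = 0.0
        for r, name in zip(cr, cav_names):
            c = cavs[name]
            ref = c.V0 if c.mode == "closed" else 2e-3
            cterm += abs(r) / max(ref, 1e-12)
        return fn / scale_ref[0] + cterm

    try:
        Rf, cres, fnorm, scale, grads, kvals, extras = residual(u, cavs)
    except (InvalidDeformationError, NumericRangeError) as exc:
        raise ConvergenceError(f"invalid initial state: {exc}")

    solves = 0
    for it in range(maxit):
        cnorm = max((abs(r) for r in cres), default=0.0)
        if fnorm <= rtol * scale + cfg.newton_atol and \
                cnorm <= 1e-9 * max(1.0, max((cavs[n].V for n in cav_names),
                                             default=1.0)):
            return u, cavs, {"iterations": it, "residual": fnorm}

        if lu is None:
            if kvals is None:
                Rf, cres, fnorm, scale, grads, kvals, extras = \
                    residual(u, cavs, want_K=True)
            K = model.stiffness_matrix(kvals, extras)
            if dyn is not None:
                K = K + sp.diags(mvec * dyn_coeff)
            Kff = K[free][:, free]
            if ncav:
                Bcols, Crows = [], []
                for name in cav_names:
                    g = grads[name].reshape(-1)[free]
                    c = cavs[name]
                    Bcols.append(-g[:, None])
                    if c.mode == "closed":
                        Crows.append((g[None, :], 0.0))
                    else:
                        Crows.append((c.Kc * g[None, :], 1.0))
                B = sp.csr_matrix(np.hstack(Bcols))
                C = sp.csr_matrix(np.vstack([r for r, _ in Crows]))
                D = sp.diags([d for _, d in Crows])
                A = sp.bmat([[Kff, B], [C, D]], format="csc")
            else:
                A = Kff.tocsc()
            lu = splu(A)
            lu_frozen = False
            if lu_cache is not None:
                lu_cache["lu"] = lu

        rhs = np.concatenate([-Rf, -np.asarray(cres)]) if ncav else -Rf
        if lu.shape[0] != len(rhs):
            lu = None
            continue
        sol = lu.solve(rhs)
        du = np.zeros(model.ndof)
        du[free] = sol[:nfree]
        dp = dict(zip(cav_names, sol[nfree:])) if ncav else {}

        # backtracking line search on the combined residual merit
        m_cur = merit(fnorm, cres, scale)
        accepted = False
        alpha = 1.0
        out = None
        for _ in range(5):
            u_try = u + alpha * du.reshape(-1, 3)
            cavs_try = {n: replace(c) for n, c in cavs.items()}
            for name, dpi in dp.items():
                cavs_try[name].p += alpha * dpi
            try:
                out = residual(u_try, cavs_try)
            except (InvalidDeformationError, NumericRangeError):
                alpha *= 0.5
                continue
            # accept a step that reduces the merit, or any full fresh
            # step that does not blow it up badly
            m_try = merit(out[2], out[1], out[3])
            if m_try <= (0.99 if lu_frozen else 1.5) * m_cur:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if lu_frozen:
                lu = None              # refactor at the current state
                continue
            if out is not None and m_try < 10 * m_cur:
                accepted = True        # accept a mild uphill step
            else:
                raise ConvergenceError(
                    f"Newton line search failed (|R| = {fnorm:.3e}, "
                    f"ref = {scale:.3e})")
        u, cavs = u_try, cavs_try
        Rf, cres, fnorm, scale, grads, kvals, extras = out
        # after a step the factorization is stale; keep it only while it
        # still contracts well (and never in plain quasi-statics)
        if not allow_frozen or alpha < 1.0 or \
                merit(fnorm, cres, scale) > 0.3 * m_cur:
            lu = None
        else:
            lu_frozen = True

    raise ConvergenceError(
        f"Newton failed after {maxit} iterations (|R| = {fnorm:.3e}, "
        f"ref = {scale:.3e})")


def solve_quasi_static(model: Model, cavity_targets=None, jet=None,
                       n_steps=4, u0=None, cavities=None,
                       closed_cavities=False):
    """Incremental-iterative static solve with adaptive load cutback.

    ``cavity_targets``: target pressure per cavity in MPa (ramped from the
    initial cavity pressures); ``jet``: (faces, per-face pressures), ramped
    likewise.  Returns a :class:`SystemState` at equilibrium.
    """
    u = np.zeros((model.n_nodes, 3)) if u0 is None else u0.copy()
    if cavities is None:
        cavities = model.make_cavities(mode="constant")
    cavs = {n: replace(c) for n, c in cavities.items()}
    p_start = {n: c.p for n, c in cavs.items()}
    lam0, lam, dlam = 0.0, 0.0, 1.0 / n_steps
    halvings = 0
    while lam < 1.0 - 1e-12:
        lam_try = min(1.0, lam + dlam)
        for n, c in cavs.items():
            if c.mode == "constant" and cavity_targets and n in cavity_targets:
                c.p = p_start[n] + lam_try * (cavity_targets[n] - p_start[n])
        jet_try = None
        if jet is not None:
            jet_try = (jet[0], lam_try * np.asarray(jet[1]))
        try:
            u_new, cavs_new, info = _solve_newton(model, u, cavs, jet=jet_try)
        except ConvergenceError:
            halvings += 1
            if halvings > model.solver.max_halvings + 2:
                raise
            dlam *= 0.5
            continue
        u, cavs = u_new, cavs_new
        lam = lam_try
    state = SystemState(u=u, v=np.zeros_like(u), a=np.zeros_like(u),
                        time=0.0, cavities=cavs)
    _, _, es = model.internal(u, want_K=False, want_energy=True)
    state.energy.strain = es
    return state


def newmark_step(model: Model, state: SystemState, dt, jet=None,
                 u_guess=None, lu_cache=None, jet_prev=None):
    """Advance one implicit Newmark step with mass-weighted damping.

    Returns the new :class:`SystemState`; on Newton failure the step is
    halved (up to ``max_halvings`` times) and sub-stepped.
    """
    cfg = model.solver
    mvec = np.repeat(model.mass_node, 3)

    def advance(st, h):
        dyn = {"u_n": st.u, "v_n": st.v, "a_n": st.a, "dt": h}
        u_start = u_guess if (u_guess is not None and h == dt) \
            else st.u + h * st.v
        u1, cavs1, info = _solve_newton(model, u_start, st.cavities,
                                        jet=jet, dyn=dyn, lu_cache=lu_cache)
        c1 = 1.0 / (cfg.beta * h * h)
        a1 = c1 * (u1 - st.u - h * st.v - h * h * (0.5 - cfg.beta) * st.a)
        v1 = st.v + h * ((1 - cfg.gamma) * st.a + cfg.gamma * a1)
        new = SystemState(u=u1, v=v1, a=a1, time=st.time + h,
                          cavities=cavs1, energy=replace(st.energy))
        if cfg.track_energy:
            _update_energy(model, st, new, mvec, jet, jet_prev)
        return new

    try:
        return advance(state, dt)
    except ConvergenceError:
        pass
    n_sub, h = 2, dt / 2
    for _ in range(cfg.max_halvings):
        if lu_cache is not None:
            lu_cache.pop("lu", None)   # stale dt makes the tangent useless
        try:
            st = state
            for _ in range(n_sub):
                st = advance(st, h)
            if lu_cache is not None:
                lu_cache.pop("lu", None)
            return st
        except ConvergenceError:
            n_sub *= 2
            h /= 2
    raise ConvergenceError(f"Newmark step failed at t = {state.time:.3f} ms "
                           f"even with dt = {h * 2:.4f} ms")


def _update_energy(model, old, new, mvec, jet, jet_prev=None):
    du = (new.u - old.u).reshape(-1)
    # external work: cavity pressures (trapezoidal) + jet load (trapezoidal
    # in both the deforming surface and the evolving pressure field)
    W = 0.0
    for name, c0 in old.cavities.items():
        c1 = new.cavities[name]
        W += 0.5 * (c0.p + c1.p) * (c1.V - c0.V)
    if jet is not None:
        faces, p = jet
        p0 = jet_prev[1] if jet_prev is not None else p
        f0 = -surface_pressure_force(model.X + old.u, faces, p0)
        f1 = -surface_pressure_force(model.X + new.u, faces, p)
        W += 0.5 * float((f0 + f1).reshape(-1) @ du)
    new.energy.external_work = old.energy.external_work + W
    new.energy.peak_external_work = max(old.energy.peak_external_work,
                                        abs(new.energy.external_work))
    fd0 = model.solver.mass_damping * mvec * old.v.reshape(-1)
    fd1 = model.solver.mass_damping * mvec * new.v.reshape(-1)
    new.energy.damping = old.energy.damping + 0.5 * float((fd0 + fd1) @ du)
    new.energy.kinetic = 0.5 * float(new.v.reshape(-1) @ (mvec * new.v.reshape(-1)))
    _, _, es = model.internal(new.u, want_K=False, want_energy=True)
    new.energy.strain = es


def assemble_internal_force(model: Model, u):
    """Internal nodal force vector (public verification surface)."""
    f, _, _ = model.internal(u, want_K=False)
    return f
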