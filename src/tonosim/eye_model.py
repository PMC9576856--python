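"""Parametric idealized quarter-eye geometry and structured hex meshing.

Coordinate convention: ``y`` is the optical (anterior-posterior) axis with
the corneal apex at maximal ``y``; ``x`` is nasal-temporal and ``z``
superior-inferior.  The model is the anterior half-globe cut at the
equatorial plane ``y = 0``, reduced to a quarter by the two symmetry
planes ``x = 0`` and ``z = 0``.

The corneo-scleral shell is swept from a two-block structured surface
grid: an elliptically-mapped quarter-square cap around the apex (which
avoids a degenerate pole) joined to a polar annulus whose rings are
placed exactly on the part boundaries (cornea | limbus | sclera) and on
the zonule attachment circle.  The wall is extruded radially with a
configurable number of through-thickness element layers.

The crystalline lens is an independent solid block (nucleus + cortex)
connected to the shell only through the ciliary zonule membrane; the
vitreous membrane lines the posterior lens surface.  The aqueous and
vitreous humors are not meshed: they are closed cavities whose volumes
are evaluated with the divergence theorem over oriented facet lists
(virtual caps on the three symmetry planes pass through the origin and
contribute nothing to the flux integral).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, WatertightError

_PRESETS = {
    # n_cap, (cornea, limbus, cornea->zonule, zonule->equator) ring counts
    "ultra": (4, (3, 1, 1, 3)),
    "coarse": (5, (4, 2, 2, 4)),
    "medium": (7, (5, 2, 3, 6)),
}


@dataclass(frozen=True)
class EyeGeometryConfig:
    """Idealized eye dimensions (mm).  Literature-typical defaults."""

    cornea_anterior_radius: float = 7.8
    central_corneal_thickness: float = 0.55
    sclera_outer_radius: float = 12.0
    sclera_thickness: float = 0.8
    limbus_radius: float = 5.9          # lateral radius of the limbus circle
    limbus_half_width_deg: float = 3.0  # half angular width of the blend band
    lens_radius: float = 4.5
    lens_thickness: float = 3.6
    lens_edge_thickness: float = 0.5
    lens_center_y: float = 8.0
    nucleus_radius: float = 2.5
    nucleus_half_thickness: float = 1.0
    zonule_theta_deg: float = 38.0      # polar angle of the zonule attachment
    membrane_thickness: float = 0.05    # zonule / vitreous membrane shells
    include_internals: bool = True
    bottom_bc: str = "symmetry"         # "symmetry" (mirrored globe) | "clamped"

    def __post_init__(self):
        for name in ("cornea_anterior_radius", "central_corneal_thickness",
                     "sclera_outer_radius", "sclera_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.central_corneal_thickness >= self.cornea_anterior_radius:
            raise GeometryError("corneal thickness must be below its radius")
        if self.sclera_thickness >= self.sclera_outer_radius:
            raise GeometryError("scleral thickness must be below its radius")
        if self.limbus_radius >= min(self.cornea_anterior_radius,
                                     self.sclera_outer_radius) \
                and not self._is_sphere():
            raise GeometryError("limbus radius incompatible with the spheres")

    def _is_sphere(self) -> bool:
        return abs(self.cornea_anterior_radius - self.sclera_outer_radius) < 1e-12

    @classmethod
    def sphere(cls, radius: float = 12.0, thickness: float = 0.8,
               bottom_bc: str = "symmetry") -> "EyeGeometryConfig":
        """Degenerate sclera-only spherical shell (verification geometry)."""
        return cls(cornea_anterior_radius=radius, sclera_outer_radius=radius,
                   sclera_thickness=thickness,
                   central_corneal_thickness=thickness,
                   limbus_radius=0.1 * radius, include_internals=False,
                   bottom_bc=bottom_bc)

    # derived quantities -----------------------------------------------
    @property
    def cornea_center_offset(self) -> float:
        """y-offset of the corneal sphere centre from the globe centre."""
        if self._is_sphere():
            return 0.0
        rl = self.limbus_radius
        y_lim = np.sqrt(self.sclera_outer_radius ** 2 - rl ** 2)
        return y_lim - np.sqrt(self.cornea_anterior_radius ** 2 - rl ** 2)

    @property
    def theta_limbus(self) -> float:
        """Polar angle (rad) of the cornea-sclera intersection circle."""
        if self._is_sphere():
            return 0.0
        y_lim = np.sqrt(self.sclera_outer_radius ** 2 - self.limbus_radius ** 2)
        return float(np.arctan2(self.limbus_radius, y_lim))

    @property
    def apex_y(self) -> float:
        return self.cornea_center_offset + self.cornea_anterior_radius


@dataclass
class EyeMesh:
    """Quarter-eye hexahedral mesh with part labels and cavity surfaces."""

    nodes: np.ndarray                 # (Nn, 3) reference coordinates [mm]
    hexes: np.ndarray                 # (Ne, 8) connectivity
    hex_part: np.ndarray              # (Ne,) index into part_names
    part_names: list
    shells: np.ndarray                # (Ns, 4) membrane connectivity
    shell_part: np.ndarray            # (Ns,) index into part_names
    fiber_m: np.ndarray               # (Ne, 3); NaN where no fibres
    fiber_n: np.ndarray               # (Ne, 3); NaN where single/no family
    cavity_faces: dict                # name -> (nf, 4) outward-from-cavity
    outer_faces: np.ndarray           # anterior/outer shell surface quads
    outer_face_part: np.ndarray
    node_sets: dict                   # 'symmetry_x'|'symmetry_z'|'bottom'
    apex_node: int
    meridian_nodes: np.ndarray        # anterior-surface chain along z = 0
    config: EyeGeometryConfig = None
    n_thickness: int = 0

    @property
    def n_nodes(self):
        return len(self.nodes)

    def part_elements(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.hex_part == self.part_names.index(name))

    def part_shells(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.shell_part == self.part_names.index(name))


# ---------------------------------------------------------------------------
# facet geometry: volumes, gradients, orientation
# ---------------------------------------------------------------------------

def _faces_to_tris(faces):
    faces = np.asarray(faces)
    return np.concatenate([faces[:, [0, 1, 2]], faces[:, [0, 2, 3]]], axis=0)


def facet_volume(x, faces):
    """Signed enclosed volume of an oriented facet set by the divergence
    theorem, ``V = 1/6 sum x1 . (x2 x x3)`` over the triangulated facets.

    Facets whose virtual closing caps lie on planes through the origin
    (the three symmetry planes) need no explicit caps.
    """
    t = _faces_to_tris(faces)
    p1, p2, p3 = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
    return float(np.einsum('ij,ij->', p1, np.cross(p2, p3)) / 6.0)


def facet_volume_gradient(x, faces, out=None):
    """dV/dx as a dense (Nn, 3) array (zero off the facet nodes)."""
    t = _faces_to_tris(faces)
    p1, p2, p3 = x[t[:, 0]], x[t[:, 1]], x[t[:, 2]]
    g = np.zeros_like(x) if out is None else out
    np.add.at(g, t[:, 0], np.cross(p2, p3) / 6.0)
    np.add.at(g, t[:, 1], np.cross(p3, p1) / 6.0)
    np.add.at(g, t[:, 2], np.cross(p1, p2) / 6.0)
    return g


def facet_area_normals(x, faces):
    """Per-facet area-weighted normal (sum of its two triangles)."""
    faces = np.asarray(faces)
    p0, p1, p2, p3 = (x[faces[:, k]] for k in range(4))
    n = 0.5 * (np.cross(p1 - p0, p2 - p0) + np.cross(p2 - p0, p3 - p0))
    return n


def check_watertight(x, faces, plane_tol=1e-6):
    """Verify the facet set is closed up to the three symmetry planes.

    Every boundary edge (an edge used by exactly one facet) must lie in a
    coordinate plane through the origin; otherwise a
    :class:`WatertightError` listing offending edges is raised.
    """
    faces = np.asarray(faces)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                            faces[:, [2, 3]], faces[:, [3, 0]]], axis=0)
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    bad = []
    for a, b in boundary:
        pa, pb = x[a], x[b]
        on_plane = any(abs(pa[k]) < plane_tol and abs(pb[k]) < plane_tol
                       for k in range(3))
        if not on_plane:
            bad.append((int(a), int(b)))
    if bad:
        raise WatertightError(
            f"cavity surface has {len(bad)} open boundary edges off the "
            f"symmetry planes (first few: {bad[:5]})", boundary_edges=bad)


def _orient_away_from(x, faces, interior_point):
    """Flip facets so normals point away from an interior reference point."""
    faces = np.asarray(faces).copy()
    n = facet_area_normals(x, faces)
    c = x[faces].mean(axis=1)
    flip = np.einsum('ij,ij->i', n, c - np.asarray(interior_point)) < 0
    faces[flip] = faces[flip][:, ::-1]
    return faces


def _orient_toward(x, faces, interior_point):
    """Flip facets so normals point toward a reference point (into a body)."""
    faces = np.asarray(faces).copy()
    n = facet_area_normals(x, faces)
    c = x[faces].mean(axis=1)
    flip = np.einsum('ij,ij->i', n, np.asarray(interior_point) - c) < 0
    faces[flip] = faces[flip][:, ::-1]
    return faces


def hex_scaled_jacobians(nodes, hexes):
    """Minimum scaled corner Jacobian per hex (1 = perfect cube)."""
    # corner triads in VTK ordering
    corner_edges = [(0, 1, 3, 4), (1, 2, 0, 5), (2, 3, 1, 6), (3, 0, 2, 7),
                    (4, 7, 5, 0), (5, 4, 6, 1), (6, 5, 7, 2), (7, 6, 4, 3)]
    X = nodes[hexes]                       # (ne, 8, 3)
    out = np.full(len(hexes), np.inf)
    for c, e1, e2, e3 in corner_edges:
        a = X[:, e1] - X[:, c]
        b = X[:, e2] - X[:, c]
        d = X[:, e3] - X[:, c]
        det = np.einsum('ij,ij->i', a, np.cross(b, d))
        scale = (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
                 * np.linalg.norm(d, axis=1))
        out = np.minimum(out, det / scale)
    return out


# ---------------------------------------------------------------------------
# structured surface grids
# ---------------------------------------------------------------------------

def _disc_mesh(n, rho0=0.55, corner=0.8):
    """Butterfly quad mesh of the unit quarter disc.

    A bilinear inner square block (outer corner pulled to the diagonal)
    plus a transition ring to the arc avoids the degenerate corner of
    single-block square-to-disc maps; worst cell scaled Jacobian ~0.86.

    Returns ``(xy, quads, arc_ids, axis_ids)``: parametric node
    coordinates (Nc, 2), CCW quad connectivity, the ordered node ids on
    the unit arc (2n + 1 nodes at uniform azimuth), and the ordered chain
    of nodes along the b = 0 axis from the centre to the arc.
    """
    m = max(1, n // 2)
    q = rho0 * corner
    P = [np.array([0.0, 0.0]), np.array([rho0, 0.0]),
         np.array([q, q]), np.array([0.0, rho0])]
    nodes = []
    grid = np.zeros((n + 1, n + 1), dtype=int)
    for i in range(n + 1):
        for j in range(n + 1):
            u, v = i / n, j / n
            p = ((1 - u) * (1 - v) * P[0] + u * (1 - v) * P[1]
                 + u * v * P[2] + (1 - u) * v * P[3])
            grid[i, j] = len(nodes)
            nodes.append(p)
    quads = [[grid[i, j], grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1]]
             for i in range(n) for j in range(n)]
    sq_bnd = [grid[n, j] for j in range(n + 1)] \
        + [grid[i, n] for i in range(n - 1, -1, -1)]
    phi = np.linspace(0.0, np.pi / 2.0, 2 * n + 1)
    layers = [sq_bnd]
    for l in range(1, m + 1):
        t = l / m
        ids = []
        for k in range(2 * n + 1):
            p = (1 - t) * nodes[sq_bnd[k]] \
                + t * np.array([np.cos(phi[k]), np.sin(phi[k])])
            ids.append(len(nodes))
            nodes.append(p)
        layers.append(ids)
    for l in range(m):
        lo, hi = layers[l], layers[l + 1]
        for k in range(2 * n):
            quads.append([lo[k], hi[k], hi[k + 1], lo[k + 1]])
    xy = np.asarray(nodes)
    xy[np.abs(xy) < 1e-14] = 0.0
    arc = np.asarray(layers[-1], dtype=int)
    xy[arc[-1], 0] = 0.0   # exact symmetry at phi = pi/2
    axis = [grid[i, 0] for i in range(n + 1)] \
        + [layers[l][0] for l in range(1, m + 1)]
    return xy, np.asarray(quads, dtype=np.int64), arc, np.asarray(axis, int)


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# main mesh builder
# ---------------------------------------------------------------------------

def build_eye_mesh(config: EyeGeometryConfig, n_thickness: int = 5,
                   surface_res="coarse") -> EyeMesh:
    """Build the quarter-eye hexahedral mesh.

    ``n_thickness`` is the number of element layers through the
    corneo-scleral wall (2..8).  ``surface_res`` selects the in-surface
    grid density: one of ``"ultra" | "coarse" | "medium"`` or an explicit
    ``(n_cap, (n1, n2, n3, n4))`` tuple.
    """
    if not 2 <= n_thickness <= 8:
        raise GeometryError("n_thickness must lie in [2, 8]")
    if isinstance(surface_res, str):
        try:
            n_cap, seg_counts = _PRESETS[surface_res]
        except KeyError:
            raise GeometryError(f"unknown surface resolution {surface_res!r}")
    else:
        n_cap, seg_counts = surface_res

    cfg = config
    Rs = cfg.sclera_outer_radius
    yc = cfg.cornea_center_offset
    th_lim = cfg.theta_limbus
    dlim = np.deg2rad(cfg.limbus_half_width_deg)
    th_zon = np.deg2rad(cfg.zonule_theta_deg)
    sphere = cfg._is_sphere()

    # --- angular layout -------------------------------------------------
    if sphere:
        th_cap = np.pi / 12.0
        n_total = sum(seg_counts)
        rows = np.linspace(th_cap, np.pi / 2.0, n_total + 1)[1:]
        row_part = ["sclera"] * len(rows)
        zonule_row = None
    else:
        th1, th2 = th_lim - dlim, th_lim + dlim
        # the cap spans most of the central cornea so the meridian chain
        # samples the bending-peak region (2.5-4 mm) densely
        th_cap = 0.62 * th1
        if not th_cap < th1 < th2 < th_zon < np.pi / 2:
            raise GeometryError("angular part boundaries out of order")
        n1, n2, n3, n4 = seg_counts
        rows = np.concatenate([
            np.linspace(th_cap, th1, n1 + 1)[1:],
            np.linspace(th1, th2, n2 + 1)[1:],
            np.linspace(th2, th_zon, n3 + 1)[1:],
            np.linspace(th_zon, np.pi / 2.0, n4 + 1)[1:],
        ])
        zonule_row = n1 + n2 + n3  # 1-based ring index of the zonule circle

    # --- surface parameterization ---------------------------------------
    cap_xy, cap_quads, cap_arc, cap_axis = _disc_mesh(n_cap)
    cap_rho = np.hypot(cap_xy[:, 0], cap_xy[:, 1])          # 0..1
    cap_phi = np.arctan2(cap_xy[:, 1], cap_xy[:, 0])
    cap_theta = cap_rho * th_cap

    n_arc = 2 * n_cap + 1
    arc_phi = np.linspace(0.0, np.pi / 2.0, n_arc)

    n_cap_nodes = len(cap_xy)
    n_rows = len(rows)
    Ns = n_cap_nodes + n_rows * n_arc             # nodes per radial layer

    theta_s = np.empty(Ns)
    phi_s = np.empty(Ns)
    theta_s[:n_cap_nodes] = cap_theta
    phi_s[:n_cap_nodes] = cap_phi
    for r in range(n_rows):
        sl = slice(n_cap_nodes + r * n_arc, n_cap_nodes + (r + 1) * n_arc)
        theta_s[sl] = rows[r]
        phi_s[sl] = arc_phi

    def ring_ids(r):
        """Surface ids of ring r (r = 0 is the cap boundary arc)."""
        if r == 0:
            return cap_arc
        return np.arange(n_cap_nodes + (r - 1) * n_arc,
                         n_cap_nodes + r * n_arc)

    # anterior radius and thickness profile
    def anterior_radius(theta):
        if sphere:
            return np.full_like(theta, Rs)
        Rc = cfg.cornea_anterior_radius
        dc = yc * np.cos(theta)
        disc = np.maximum(dc * dc - yc * yc + Rc * Rc, 0.0)
        r_cor = dc + np.sqrt(disc)
        w = _smoothstep((theta - (th_lim - dlim)) / (2.0 * dlim))
        return (1.0 - w) * r_cor + w * Rs

    def wall_thickness(theta):
        if sphere:
            return np.full_like(theta, cfg.sclera_thickness)
        w = _smoothstep((theta - (th_lim - dlim)) / (2.0 * dlim))
        return (1.0 - w) * cfg.central_corneal_thickness \
            + w * cfg.sclera_thickness

    r_a = anterior_radius(theta_s)
    t_w = wall_thickness(theta_s)
    d = np.stack([np.sin(theta_s) * np.cos(phi_s),
                  np.cos(theta_s),
                  np.sin(theta_s) * np.sin(phi_s)], axis=1)
    # exact symmetry-plane coordinates
    d[np.isclose(phi_s, 0.0, atol=1e-14), 2] = 0.0
    d[np.isclose(phi_s, np.pi / 2, atol=1e-12), 0] = 0.0
    d[np.isclose(theta_s, np.pi / 2, atol=1e-12), 1] = 0.0

    nt = n_thickness
    shell_nodes = np.concatenate([
        d * (r_a - t_w * (1.0 - l / nt))[:, None] for l in range(nt + 1)
    ], axis=0)                                     # layer-major: l * Ns + s

    # --- surface quads (CCW seen from outside, +radial normal) ----------
    quads = [list(q) for q in cap_quads]
    quad_theta = [cap_theta[q].mean() for q in cap_quads]
    for r in range(1, n_rows + 1):
        inner = ring_ids(r - 1)
        outer = ring_ids(r)
        th_mid = 0.5 * (rows[r - 1] + (rows[r - 2] if r >= 2 else th_cap))
        for k in range(n_arc - 1):
            quads.append([inner[k], outer[k], outer[k + 1], inner[k + 1]])
            quad_theta.append(th_mid)
    quads = np.asarray(quads, dtype=np.int64)
    quad_theta = np.asarray(quad_theta)

    # fix orientation: CCW from outside means normal . radial > 0
    x_surf = shell_nodes[nt * Ns:(nt + 1) * Ns]   # outer layer
    nrm = facet_area_normals(x_surf, quads)
    ctr = x_surf[quads].mean(axis=1)
    flip = np.einsum('ij,ij->i', nrm, ctr) < 0
    quads[flip] = quads[flip][:, ::-1]

    # --- hexes -----------------------------------------------------------
    part_names = ["cornea", "limbus", "sclera", "lens_nucleus", "lens_cortex",
                  "zonule", "vitreous_membrane"]
    if sphere:
        q_part = np.full(len(quads), part_names.index("sclera"))
    else:
        q_part = np.where(
            quad_theta < th_lim - dlim - 1e-12, part_names.index("cornea"),
            np.where(quad_theta < th_lim + dlim + 1e-12,
                     part_names.index("limbus"), part_names.index("sclera")))

    hexes = []
    hex_part = []
    for l in range(nt):
        lo, hi = l * Ns, (l + 1) * Ns
        for q, pt in zip(quads, q_part):
            hexes.append([q[0] + lo, q[1] + lo, q[2] + lo, q[3] + lo,
                          q[0] + hi, q[1] + hi, q[2] + hi, q[3] + hi])
            hex_part.append(pt)
    hexes = np.asarray(hexes, dtype=np.int64)
    hex_part = np.asarray(hex_part)

    nodes = shell_nodes
    n_shell_nodes = len(nodes)

    shells = np.zeros((0, 4), dtype=np.int64)
    shell_part = np.zeros(0, dtype=np.int64)
    inner_quads = quads.copy()                    # layer-0 face ids == surface ids
    outer_quads = quads + nt * Ns

    cavity_faces = {}
    if cfg.include_internals and not sphere:
        (nodes, lens_hexes, lens_part, lens_surf, shells, shell_part,
         lens_arc_top, lens_arc_layers) = _build_lens(cfg, n_cap, nodes,
                                                      part_names)
        hexes = np.concatenate([hexes, lens_hexes], axis=0)
        hex_part = np.concatenate([hex_part, lens_part])

        ring_zon = ring_ids(zonule_row)           # inner-surface node ids
        zon_quads = []
        for k in range(n_arc - 1):
            zon_quads.append([lens_arc_top[k], lens_arc_top[k + 1],
                              ring_zon[k + 1], ring_zon[k]])
        zon_quads = np.asarray(zon_quads, dtype=np.int64)
        shells = np.concatenate([shells, zon_quads], axis=0)
        shell_part = np.concatenate([
            shell_part,
            np.full(len(zon_quads), part_names.index("zonule"))])

        # cavity facet lists ------------------------------------------------
        aq_shell = inner_quads[quad_theta < rows[zonule_row - 1] - 1e-12]
        vi_shell = inner_quads[quad_theta > rows[zonule_row - 1] + 1e-12]
        aq_pt = np.array([0.0, 0.5 * (cfg.apex_y - cfg.central_corneal_thickness
                                      + cfg.lens_center_y
                                      + 0.5 * cfg.lens_thickness), 0.0])
        vi_pt = np.array([0.0, 0.45 * cfg.lens_center_y, 0.0])
        x0 = nodes
        # lens-boundary facets point into the lens (out of either cavity)
        lens_pt = np.array([0.0, cfg.lens_center_y, 0.0])
        aq = [aq_shell, _orient_away_from(x0, zon_quads, aq_pt),
              _orient_toward(x0, lens_surf["anterior"], lens_pt),
              _orient_toward(x0, lens_surf["lateral_upper"], lens_pt)]
        vi = [vi_shell, _orient_away_from(x0, zon_quads, vi_pt),
              _orient_toward(x0, lens_surf["posterior"], lens_pt),
              _orient_toward(x0, lens_surf["lateral_lower"], lens_pt)]
        cavity_faces["aqueous"] = np.concatenate(aq, axis=0)
        cavity_faces["vitreous"] = np.concatenate(vi, axis=0)
    else:
        cavity_faces["humor"] = inner_quads

    # --- node sets, apex, meridian --------------------------------------
    node_sets = {
        "symmetry_x": np.flatnonzero(np.abs(nodes[:, 0]) < 1e-9),
        "symmetry_z": np.flatnonzero(np.abs(nodes[:, 2]) < 1e-9),
        "bottom": np.flatnonzero(np.abs(nodes[:, 1]) < 1e-9),
    }

    apex_node = int(nt * Ns + cap_axis[0])
    # anterior chain along z = 0: cap axis chain, then ring k = 0 nodes
    chain = [nt * Ns + s for s in cap_axis]
    chain += [nt * Ns + ring_ids(r)[0] for r in range(1, n_rows + 1)]
    meridian = np.asarray(chain, dtype=np.int64)

    mesh = EyeMesh(
        nodes=nodes, hexes=hexes, hex_part=hex_part, part_names=part_names,
        shells=shells, shell_part=shell_part,
        fiber_m=np.full((len(hexes), 3), np.nan),
        fiber_n=np.full((len(hexes), 3), np.nan),
        cavity_faces=cavity_faces,
        outer_faces=outer_quads, outer_face_part=q_part.copy(),
        node_sets=node_sets, apex_node=apex_node, meridian_nodes=meridian,
        config=cfg, n_thickness=nt)

    # ensure positive hex volumes
    from .fem_engine import hex_volumes  # local import to avoid cycle
    vols = hex_volumes(mesh.nodes, mesh.hexes)
    if np.any(vols <= 0):
        raise GeometryError(f"{int(np.sum(vols <= 0))} inverted hexahedra")

    for faces in mesh.cavity_faces.values():
        check_watertight(mesh.nodes, faces)
        if facet_volume(mesh.nodes, faces) <= 0:
            raise GeometryError("negative cavity volume (orientation)")

    return assign_fiber_frames(mesh)


def _build_lens(cfg, n_cap, nodes, part_names):
    """Mesh the crystalline lens block and its lining membranes.

    Returns the grown node array, lens hexes/parts, named surface facet
    groups, membrane shells, the equatorial arc node ring used for the
    zonule attachment, and all lateral arc rings.
    """
    disc_xy, disc_quads, disc_arc, _ = _disc_mesh(n_cap)
    rho = np.hypot(disc_xy[:, 0], disc_xy[:, 1]) * cfg.lens_radius
    RL, tL, te = cfg.lens_radius, cfg.lens_thickness, cfg.lens_edge_thickness
    h = 0.5 * (te + (tL - te) * np.sqrt(np.maximum(
        0.0, 1.0 - (rho / RL) ** 2)))
    n_lz = 2                                        # layers: posterior->anterior
    base = len(nodes)
    npts = len(disc_xy)
    lx = disc_xy[:, 0] * cfg.lens_radius
    lz = disc_xy[:, 1] * cfg.lens_radius
    layers = []
    for l in range(n_lz + 1):
        y = cfg.lens_center_y - h + (l / n_lz) * 2.0 * h
        layers.append(np.stack([lx, y, lz], axis=1))
    lens_nodes = np.concatenate(layers, axis=0)
    nodes = np.concatenate([nodes, lens_nodes], axis=0)

    def lid(l, s):
        return base + l * npts + s

    hexes, parts = [], []
    inuc, icor = part_names.index("lens_nucleus"), part_names.index("lens_cortex")
    for l in range(n_lz):
        for q in disc_quads:
            # reversed winding: disc quads are CCW in the x-z plane, which
            # gives a -y bottom normal; flip for a positive hex Jacobian
            hx = [lid(l, q[0]), lid(l, q[3]), lid(l, q[2]), lid(l, q[1]),
                  lid(l + 1, q[0]), lid(l + 1, q[3]), lid(l + 1, q[2]),
                  lid(l + 1, q[1])]
            c = nodes[hx].mean(axis=0)
            rr = np.hypot(c[0], c[2])
            in_nuc = (rr / cfg.nucleus_radius) ** 2 + \
                ((c[1] - cfg.lens_center_y) / cfg.nucleus_half_thickness) ** 2 <= 1.0
            hexes.append(hx)
            parts.append(inuc if in_nuc else icor)
    hexes = np.asarray(hexes, dtype=np.int64)
    parts = np.asarray(parts)

    arcs = [np.array([lid(l, s) for s in disc_arc]) for l in range(n_lz + 1)]

    ant, post, lat_up, lat_lo = [], [], [], []
    for q in disc_quads:
        ant.append([lid(n_lz, s) for s in q])
        post.append([lid(0, s) for s in q])
    mid = n_lz // 2 + n_lz % 2                      # zonule attaches here
    for l in range(n_lz):
        tgt = lat_up if l >= mid else lat_lo
        lo, hi = arcs[l], arcs[l + 1]
        for k in range(len(disc_arc) - 1):
            tgt.append([lo[k], lo[k + 1], hi[k + 1], hi[k]])
    surf = {"anterior": np.asarray(ant, dtype=np.int64),
            "posterior": np.asarray(post, dtype=np.int64),
            "lateral_upper": np.asarray(lat_up, dtype=np.int64).reshape(-1, 4),
            "lateral_lower": np.asarray(lat_lo, dtype=np.int64).reshape(-1, 4)}

    # vitreous membrane lines the posterior lens surface and the lower band
    vm = np.concatenate([surf["posterior"], surf["lateral_lower"]], axis=0)
    shells = vm
    shell_part = np.full(len(vm), part_names.index("vitreous_membrane"))

    return (nodes, hexes, parts, surf, shells, shell_part,
            arcs[mid], arcs)


# ---------------------------------------------------------------------------
# fibre frames
# ---------------------------------------------------------------------------

def assign_fiber_frames(mesh: EyeMesh) -> EyeMesh:
    """Assign per-element collagen fibre frames.

    Cornea: the two families are the projections of the global x
    (nasal-temporal) and z (superior-inferior) axes onto the local tangent
    plane, re-orthonormalized.  Limbus: one circumferential family.
    """
    X = mesh.nodes
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    for part, two_families in (("cornea", True), ("limbus", False)):
        for e in mesh.part_elements(part):
            hx = mesh.hexes[e]
            inner = X[hx[:4]].mean(axis=0)
            outer = X[hx[4:]].mean(axis=0)
            r = outer - inner
            r /= np.linalg.norm(r)                 # local surface normal
            if two_families:
                m = ex - (ex @ r) * r
                nm = np.linalg.norm(m)
                if nm < 1e-8:                      # pathological: propagate x
                    m = ex.copy()
                    nm = 1.0
                m /= nm
                n = np.cross(r, m)
                if n[2] < 0:
                    n = -n
                mesh.fiber_m[e] = m
                mesh.fiber_n[e] = n
            else:
                c = np.cross(ey, r)
                c /= np.linalg.norm(c)
                mesh.fiber_m[e] = c
    return mesh


# ---------------------------------------------------------------------------
# cavity volume (public op)
# ---------------------------------------------------------------------------

def cavity_volume(mesh: EyeMesh, displacements=None, cavity=None,
                  whole_eye=False) -> float:
    """Enclosed volume (mm^3) of a cavity in the (possibly displaced) mesh.

    ``cavity`` names one of ``mesh.cavity_faces``; by default the volumes
    of all cavities are summed.  With ``whole_eye=True`` the quarter-model
    value is multiplied by 4.
    """
    x = mesh.nodes if displacements is None else mesh.nodes + displacements
    names = [cavity] if cavity else list(mesh.cavity_faces)
    v = 0.0
    for name in names:
        faces = mesh.cavity_faces[name]
        check_watertight(x, faces)
        v += facet_volume(x, faces)
    return 4.0 * v if whole_eye else v


# ---------------------------------------------------------------------------
# simple meshes for verification
# ---------------------------------------------------------------------------

def box_mesh(nx=1, ny=1, nz=1, lengths=(1.0, 1.0, 1.0)):
    """Structured unit-ish box of hex8 elements (verification problems)."""
    lx, ly, lz = lengths
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append([nid[i, j, k], nid[i + 1, j, k],
                              nid[i + 1, j + 1, k], nid[i, j + 1, k],
                              nid[i, j, k + 1], nid[i + 1, j, k + 1],
                              nid[i + 1, j + 1, k + 1], nid[i, j + 1, k + 1]])
    return nodes, np.asarray(hexes, dtype=np.int64)


def simple_mesh(nodes, hexes, part="block", cavity_faces=None,
                shells=None, shell_part_name=None, config=None):
    """Wrap bare node/hex arrays into an :class:`EyeMesh` (verification)."""
    part_names = [part]
    shell_conn = np.zeros((0, 4), dtype=np.int64)
    shell_part = np.zeros(0, dtype=np.int64)
    if shells is not None:
        part_names.append(shell_part_name or "membrane")
        shell_conn = np.asarray(shells, dtype=np.int64)
        shell_part = np.full(len(shell_conn), part_names.index(
            shell_part_name or "membrane"))
    empty = np.zeros(0, dtype=np.int64)
    return EyeMesh(
        nodes=np.asarray(nodes, float), hexes=np.asarray(hexes, np.int64),
        hex_part=np.zeros(len(hexes), dtype=np.int64), part_names=part_names,
        shells=shell_conn, shell_part=shell_part,
        fiber_m=np.full((len(hexes), 3), np.nan),
        fiber_n=np.full((len(hexes), 3), np.nan),
        cavity_faces=cavity_faces or {},
        outer_faces=np.zeros((0, 4), dtype=np.int64),
        outer_face_part=empty,
        node_sets={"symmetry_x": empty, "symmetry_z": empty, "bottom": empty},
        apex_node=0, meridian_nodes=empty, config=config)


def unit_cube_faces():
    """Oriented (outward) facet list of the unit cube, for volume tests."""
    nodes, _ = box_mesh(1, 1, 1)
    # node index = 4 i + 2 j + k for corner (i, j, k) in {0,1}^3
    n = lambda i, j, k: i * 4 + j * 2 + k
    faces = np.array([
        [n(0, 0, 0), n(0, 0, 1), n(0, 1, 1), n(0, 1, 0)],   # x=0, -x
        [n(1, 0, 0), n(1, 1, 0), n(1, 1, 1), n(1, 0, 1)],   # x=1, +x
        [n(0, 0, 0), n(1, 0, 0), n(1, 0, 1), n(0, 0, 1)],   # y=0, -y
        [n(0, 1, 0), n(0, 1, 1), n(1, 1, 1), n(1, 1, 0)],   # y=1, +y
        [n(0, 0, 0), n(0, 1, 0), n(1, 1, 0), n(1, 0, 0)],   # z=0, -z
        [n(0, 0, 1), n(1, 0, 1), n(1, 1, 1), n(0, 1, 1)],   # z=1, +z
    ])
    return nodes, faces
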