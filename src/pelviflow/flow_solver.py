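"""Steady incompressible Stokes / Navier–Stokes solver on tetrahedral meshes.

Discretization: Taylor–Hood mixed finite elements — continuous piecewise
quadratic (P2) velocity and piecewise linear (P1) pressure — which is
inf-sup stable, so no pressure stabilization is needed.  The governing
equations are the continuity equation ``div U = 0`` and steady momentum
balance ``rho (U.grad) U = -grad P + mu lap U`` for an incompressible
Newtonian fluid (urine: rho = 1050 kg/m^3, mu = 0.001 Pa.s).

Boundary conditions follow the virtual pressure-flow study protocol:

* plug inflow of prescribed total volumetric rate Q on the papillary inlet
  patch(es), split area-weighted across patches;
* zero traction with reference (gauge) pressure at the ureteral outlet
  (default 0 Pa), which fixes the pressure datum;
* homogeneous no-slip velocity on rigid walls.

The Stokes problem is one sparse direct solve; Navier–Stokes is solved by
Picard (fixed-point) iteration on the convective term, initialized from the
Stokes solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .meshing import INLET, OUTLET, VolumeMesh

STOKES = "stokes"
NAVIER_STOKES = "navier_stokes"

#: convergence tolerance on the relative momentum residual (Picard)
NS_TOLERANCE = 1e-8
NS_MAX_ITERATIONS = 50


class SolverError(RuntimeError):
    """Singular system, missing boundary groups or non-convergence."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density (kg/m^3) and dynamic viscosity (Pa.s)."""

    density: float = 1050.0
    dynamic_viscosity: float = 0.001

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and dynamic_viscosity must be positive")


@dataclass(frozen=True)
class FlowCase:
    """Imposed flow rate and boundary assignments for one solve.

    ``inlet_tags`` maps inlet tag -> flux share; None distributes the total
    rate area-weighted over all tags starting with ``inlet``.
    """

    flow_rate: float  # m^3/s
    inlet_tags: dict | None = None
    outlet_tag: str = OUTLET
    outlet_pressure: float = 0.0
    model: str = STOKES

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if not np.isfinite(self.outlet_pressure):
            raise ValueError("outlet_pressure must be finite")
        if self.model not in (STOKES, NAVIER_STOKES):
            raise ValueError(f"unknown model {self.model!r}")
        if self.inlet_tags is not None:
            total = sum(self.inlet_tags.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("inlet flux shares must sum to 1")


@dataclass
class FlowSolution:
    """Discrete velocity/pressure fields and solve diagnostics.

    Velocity lives on P2 nodes (mesh vertices followed by edge midpoints);
    pressure on mesh vertices.  Pressures are gauge pressures relative to
    the outlet datum.
    """

    mesh: VolumeMesh
    velocity: np.ndarray           # (n_p2, 3) m/s
    pressure: np.ndarray           # (n_vertices,) Pa
    residual: float
    iterations: int
    model: str
    case: FlowCase
    fluid: FluidProperties
    _space: "_TaylorHood" = field(repr=False, default=None)

    # -- field evaluation ---------------------------------------------------

    def vertex_velocity(self) -> np.ndarray:
        return self.velocity[: len(self.mesh.vertices)]

    def pressure_at(self, points: np.ndarray) -> np.ndarray:
        """P1-interpolated pressure at interior points."""
        cells, bary = _locate(self.mesh, np.atleast_2d(points))
        return np.einsum("pi,pi->p", bary,
                         self.pressure[self.mesh.tets[cells]])

    def velocity_at(self, points: np.ndarray) -> np.ndarray:
        cells, bary = _locate(self.mesh, np.atleast_2d(points))
        phi = _p2_values(bary)  # (p, 10)
        dofs = self._space.cell_nodes[cells]  # (p, 10)
        return np.einsum("pa,pad->pd", phi, self.velocity[dofs])

    def mean_outlet_pressure(self) -> float:
        return _facet_mean_p1(self.mesh, self.pressure, self.case.outlet_tag)

    def max_wall_speed(self) -> float:
        wall_nodes = self._space.tag_nodes.get("wall", np.array([], int))
        if len(wall_nodes) == 0:
            return 0.0
        return float(np.linalg.norm(self.velocity[wall_nodes], axis=1).max())


# ---------------------------------------------------------------------------
# Reference-element machinery
# ---------------------------------------------------------------------------

# local edges of a tet: P2 dofs are 4 vertices then these 6 midpoints
_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])

# degree-2 Keast rule (4 points), barycentric, weights sum to 1
_QA = 0.5854101966249685
_QB = 0.1381966011250105
_QP2 = np.array([
    [_QA, _QB, _QB, _QB],
    [_QB, _QA, _QB, _QB],
    [_QB, _QB, _QA, _QB],
    [_QB, _QB, _QB, _QA],
])
_QW2 = np.full(4, 0.25)

# degree-3 rule (5 points: centroid + 4)
_QP3 = np.vstack([
    np.full((1, 4), 0.25),
    np.array([
        [0.5, 1 / 6, 1 / 6, 1 / 6],
        [1 / 6, 0.5, 1 / 6, 1 / 6],
        [1 / 6, 1 / 6, 0.5, 1 / 6],
        [1 / 6, 1 / 6, 1 / 6, 0.5],
    ]),
])
_QW3 = np.concatenate([[-0.8], np.full(4, 0.45)])


def _p2_values(lam: np.ndarray) -> np.ndarray:
    """P2 basis values at barycentric points lam (n, 4) -> (n, 10)."""
    lam = np.atleast_2d(lam)
    out = np.empty((len(lam), 10))
    out[:, :4] = lam * (2.0 * lam - 1.0)
    for k, (i, j) in enumerate(_EDGES):
        out[:, 4 + k] = 4.0 * lam[:, i] * lam[:, j]
    return out


def _p2_gradients(lam: np.ndarray, grad_lam: np.ndarray) -> np.ndarray:
    """P2 basis gradients: (cells, nq, 10, 3).

    ``grad_lam``: (cells, 4, 3) constant barycentric gradients per cell.
    """
    nq = len(lam)
    nc = len(grad_lam)
    g = np.empty((nc, nq, 10, 3))
    for i in range(4):
        g[:, :, i, :] = (4.0 * lam[None, :, i, None] - 1.0) \
            * grad_lam[:, None, i, :]
    for k, (i, j) in enumerate(_EDGES):
        g[:, :, 4 + k, :] = 4.0 * (
            lam[None, :, i, None] * grad_lam[:, None, j, :]
            + lam[None, :, j, None] * grad_lam[:, None, i, :]
        )
    return g


class _TaylorHood:
    """P2/P1 dof layout and assembled constant operators on a mesh."""

    def __init__(self, mesh: VolumeMesh):
        self.mesh = mesh
        tets = mesh.tets
        nv = len(mesh.vertices)

        # global edge numbering
        edges = tets[:, _EDGES].reshape(-1, 2)
        edges.sort(axis=1)
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        self.edges = uniq
        self.n_vertices = nv
        self.n_p2 = nv + len(uniq)
        self.cell_nodes = np.hstack([
            tets, nv + inv.reshape(len(tets), 6)
        ]).astype(np.int64)

        # P2 node coordinates (vertices + edge midpoints)
        self.node_xyz = np.vstack([
            mesh.vertices,
            0.5 * (mesh.vertices[uniq[:, 0]] + mesh.vertices[uniq[:, 1]]),
        ])

        # geometry: barycentric gradients and volumes
        v = mesh.vertices[tets]
        J = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0],
                      v[:, 3] - v[:, 0]], axis=2)  # (c, 3, 3) columns
        detJ = np.linalg.det(J)
        self.volumes = detJ / 6.0
        Jinv = np.linalg.inv(J)  # lambda_i = Jinv[i-1, :] . (x - x0)
        gl = np.empty((len(tets), 4, 3))
        gl[:, 1:, :] = Jinv
        gl[:, 0, :] = -Jinv.sum(axis=1)
        self.grad_lam = gl

        # boundary facet -> P2 nodes (3 vertices + 3 edge midpoints)
        self.facet_nodes = self._facet_p2_nodes(mesh.boundary_faces)

        # nodes per boundary tag
        self.tag_nodes: dict[str, np.ndarray] = {}
        for tag in np.unique(mesh.boundary_tags):
            faces = mesh.boundary_tags == tag
            self.tag_nodes[str(tag)] = np.unique(self.facet_nodes[faces])

        self._L = None
        self._Bd = None
        self._mp = None
        self._gp3 = None

    def _facet_p2_nodes(self, faces: np.ndarray) -> np.ndarray:
        out = np.empty((len(faces), 6), dtype=np.int64)
        out[:, :3] = faces
        # locate facet edges in the sorted unique-edge table
        keys = self.edges[:, 0] * (self.edges.max() + 1) + self.edges[:, 1]
        order = np.argsort(keys)
        for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
            pairs = np.sort(faces[:, [i, j]], axis=1)
            pk = pairs[:, 0] * (self.edges.max() + 1) + pairs[:, 1]
            pos = order[np.searchsorted(keys[order], pk)]
            out[:, 3 + k] = self.n_vertices + pos
        return out

    # -- operators -----------------------------------------------------------
    #
    # The velocity operator (viscous + linearized convection) acts
    # component-wise with ONE scalar matrix, which the solver factorizes
    # once and reuses for all three components.

    def scalar_laplacian(self) -> sp.csr_matrix:
        """(grad phi_a, grad phi_b) — unscaled scalar stiffness matrix."""
        if self._L is None:
            gp = _p2_gradients(_QP2, self.grad_lam)
            K = np.einsum("q,cqad,cqbd->cab", _QW2, gp, gp)
            K *= self.volumes[:, None, None]
            self._L = self._assemble(K)
        return self._L

    def divergence_components(self) -> list[sp.csr_matrix]:
        """B_d[c, a] = integral psi_c d(phi_a)/dx_d, one matrix per axis."""
        if self._Bd is None:
            gp = _p2_gradients(_QP2, self.grad_lam)
            Bl = np.einsum("q,qi,cqad->ciad", _QW2, _QP2, gp)
            Bl *= self.volumes[:, None, None, None]
            nc = len(self.mesh.tets)
            rows = np.repeat(self.mesh.tets, 10).reshape(nc, 4, 10)
            cols = np.broadcast_to(self.cell_nodes[:, None, :], rows.shape)
            self._Bd = [
                sp.coo_matrix(
                    (Bl[..., d].ravel(), (rows.ravel(), cols.ravel())),
                    shape=(self.n_vertices, self.n_p2),
                ).tocsr()
                for d in range(3)
            ]
        return self._Bd

    def scalar_convection(self, rho: float, u: np.ndarray) -> sp.csr_matrix:
        """rho * ((w . grad) phi_b, phi_a) linearized around w = u."""
        phi = _p2_values(_QP3)                       # (q, 10)
        if self._gp3 is None:
            self._gp3 = _p2_gradients(_QP3, self.grad_lam)
        gp = self._gp3                               # (c, q, 10, 3)
        uloc = u[self.cell_nodes]                    # (c, 10, 3)
        wq = np.einsum("qa,cad->cqd", phi, uloc)     # (c, q, 3)
        wdotg = np.einsum("cqd,cqbd->cqb", wq, gp)   # (c, q, 10)
        N = np.einsum("q,qa,cqb->cab", _QW3, phi, wdotg)
        N *= rho * self.volumes[:, None, None]
        return self._assemble(N)

    def pressure_lumped_mass(self) -> np.ndarray:
        """Row-lumped P1 mass matrix diagonal (Schur preconditioner)."""
        if self._mp is None:
            m = np.zeros(self.n_vertices)
            np.add.at(m, self.mesh.tets.ravel(),
                      np.repeat(self.volumes / 4.0, 4))
            self._mp = m
        return self._mp

    def _assemble(self, local: np.ndarray) -> sp.csr_matrix:
        dofs = self.cell_nodes
        rows = np.repeat(dofs, 10, axis=1)
        cols = np.tile(dofs, (1, 10))
        return sp.coo_matrix(
            (local.ravel(), (rows.ravel(), cols.ravel())),
            shape=(self.n_p2, self.n_p2),
        ).tocsr()


# ---------------------------------------------------------------------------
# Boundary data
# ---------------------------------------------------------------------------


def _facet_geometry(mesh: VolumeMesh, mask: np.ndarray):
    """(areas, outward unit normals) of the selected boundary facets."""
    p = mesh.vertices[mesh.boundary_faces[mask]]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    norm = np.linalg.norm(n, axis=1)
    return 0.5 * norm, n / norm[:, None]


def _facet_mean_p1(mesh: VolumeMesh, p: np.ndarray, tag: str) -> float:
    mask = mesh.boundary_tags == tag
    if not mask.any():
        raise SolverError(f"unknown boundary tag {tag!r}")
    areas, _ = _facet_geometry(mesh, mask)
    vals = p[mesh.boundary_faces[mask]].mean(axis=1)
    return float((vals * areas).sum() / areas.sum())


def _inlet_dirichlet(space: _TaylorHood, case: FlowCase):
    """Plug-inflow nodal velocities scaled to the exact discrete flux.

    Returns (nodes, values, shares_per_tag).  Nodes on the patch rim that
    also belong to the wall are excluded later (no-slip wins); the final
    flux scaling happens after that exclusion in :func:`_dirichlet_data`.
    """
    mesh = space.mesh
    tags = [str(t) for t in np.unique(mesh.boundary_tags)
            if str(t).startswith(INLET)]
    if not tags:
        raise SolverError(
            "no inlet boundary group on the mesh (velocity inflow missing)"
        )
    if case.inlet_tags is not None:
        shares = dict(case.inlet_tags)
        unknown = set(shares) - set(tags)
        if unknown:
            raise SolverError(f"unknown inlet tags {sorted(unknown)}")
    else:
        areas = {t: mesh.boundary_area(t) for t in tags}
        total = sum(areas.values())
        shares = {t: a / total for t, a in areas.items()}

    node_dir: dict[int, np.ndarray] = {}
    node_tag: dict[int, str] = {}
    for tag in shares:
        mask = mesh.boundary_tags == tag
        areas_f, normals = _facet_geometry(mesh, mask)
        fnodes = space.facet_nodes[mask]
        for f in range(len(fnodes)):
            for nd in fnodes[f]:
                node_dir.setdefault(nd, np.zeros(3))
                node_dir[nd] -= areas_f[f] * normals[f]  # inward
                node_tag[nd] = tag
    nodes = np.fromiter(node_dir.keys(), dtype=np.int64)
    dirs = np.vstack([node_dir[n] for n in nodes])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    tags_arr = np.array([node_tag[n] for n in nodes])
    return nodes, dirs, tags_arr, shares


def _patch_flux_per_unit_speed(space: _TaylorHood, tag: str,
                               nodes: np.ndarray,
                               values: np.ndarray) -> float:
    """Inward discrete flux of the nodal field through the tagged facets.

    Exact for P2 fields: midpoint (edge-node) rule on each facet.
    """
    mesh = space.mesh
    mask = mesh.boundary_tags == tag
    areas, normals = _facet_geometry(mesh, mask)
    fnodes = space.facet_nodes[mask][:, 3:]  # edge-midpoint nodes
    val = np.zeros((space.n_p2, 3))
    val[nodes] = values
    u_mid = val[fnodes]  # (f, 3, 3)
    flux = np.einsum("fmd,fd->f", u_mid, normals) * areas / 3.0
    return float(-flux.sum())  # inward positive


def _dirichlet_data(space: _TaylorHood, case: FlowCase):
    """Constrained P2 nodes and their velocity vectors (wall + scaled inlets).

    The plug speed on each inlet patch is scaled so that the *discrete*
    inward flux equals the patch's share of Q exactly, after the no-slip
    rim nodes have been zeroed.
    """
    mesh = space.mesh
    wall_tags = [str(t) for t in np.unique(mesh.boundary_tags)
                 if not (str(t).startswith(INLET) or str(t) == case.outlet_tag)]
    wall_nodes = (np.unique(np.concatenate(
        [space.tag_nodes[t] for t in wall_tags]))
        if wall_tags else np.array([], dtype=np.int64))

    in_nodes, in_dirs, in_tags, shares = _inlet_dirichlet(space, case)
    # no-slip wins on the patch rim
    rim = np.isin(in_nodes, wall_nodes)
    in_nodes, in_dirs, in_tags = (in_nodes[~rim], in_dirs[~rim],
                                  in_tags[~rim])

    values = np.zeros((space.n_p2, 3))
    for tag, share in shares.items():
        sel = in_tags == tag
        flux1 = _patch_flux_per_unit_speed(space, tag, in_nodes[sel],
                                           in_dirs[sel])
        if flux1 <= 0:
            raise SolverError(
                f"inlet patch {tag!r} has non-positive unit flux; "
                "check facet orientation"
            )
        values[in_nodes[sel]] = (share * case.flow_rate / flux1) \
            * in_dirs[sel]

    nodes = np.unique(np.concatenate([wall_nodes, in_nodes]))
    return nodes, values[nodes]


# ---------------------------------------------------------------------------
# Point location (pressure/velocity probing)
# ---------------------------------------------------------------------------


def _locate(mesh: VolumeMesh, points: np.ndarray, k: int = 48):
    """Containing cell and barycentric coordinates for each point."""
    points = np.atleast_2d(np.asarray(points, float))
    cent = mesh.vertices[mesh.tets].mean(axis=1)
    k = min(k, len(cent))
    _, cand = cKDTree(cent).query(points, k=k)
    cand = cand.reshape(len(points), -1)
    cells = np.empty(len(points), dtype=np.int64)
    bary = np.empty((len(points), 4))
    v = mesh.vertices
    for p in range(len(points)):
        best, best_b, best_min = -1, None, -np.inf
        for c in cand[p]:
            tet = mesh.tets[c]
            T = np.column_stack([v[tet[1]] - v[tet[0]],
                                 v[tet[2]] - v[tet[0]],
                                 v[tet[3]] - v[tet[0]]])
            try:
                lam123 = np.linalg.solve(T, points[p] - v[tet[0]])
            except np.linalg.LinAlgError:
                continue
            lam = np.concatenate([[1.0 - lam123.sum()], lam123])
            m = lam.min()
            if m > best_min:
                best, best_b, best_min = c, lam, m
            if m >= -1e-10:
                break
        if best_min < -1e-6:
            raise SolverError(
                f"point {points[p].tolist()} lies outside the mesh"
            )
        cells[p] = best
        bary[p] = np.clip(best_b, 0.0, 1.0)
        bary[p] /= bary[p].sum()
    return cells, bary


# ---------------------------------------------------------------------------
# Saddle-point solver
# ---------------------------------------------------------------------------
#
# Unknowns: velocity components on free P2 nodes (the same scalar operator
# acts on all three components) and P1 pressure.  The coupled system
#
#     [ A   0   0  -Bx^T ] [ux]   [bx]
#     [ 0   A   0  -By^T ] [uy] = [by]
#     [ 0   0   A  -Bz^T ] [uz]   [bz]
#     [ Bx  By  Bz   0   ] [ p]   [bp]
#
# is solved by elimination onto the pressure Schur complement
# S = B A^-1 B^T (exact scalar LU for A), with the lumped P1 mass matrix
# over mu as the Schur preconditioner: CG for Stokes (S is SPD), full GMRES
# for the nonsymmetric Picard systems.

_KRYLOV_RTOL = 1e-10
_SCHUR_MAXITER = 20000
_SCHUR_GMRES_RESTART = 400


class _SaddleSystem:
    def __init__(self, space: _TaylorHood, fluid: FluidProperties,
                 case: FlowCase, convection_field: np.ndarray | None = None):
        mesh = space.mesh
        tags = {str(t) for t in np.unique(mesh.boundary_tags)}
        if case.outlet_tag not in tags:
            raise SolverError(
                f"no outlet boundary group {case.outlet_tag!r}: "
                "pressure level undetermined"
            )
        self.space = space
        self.mu = fluid.dynamic_viscosity
        self.symmetric = convection_field is None

        A = self.mu * space.scalar_laplacian()
        if convection_field is not None:
            A = A + space.scalar_convection(fluid.density, convection_field)

        cons_nodes, g = _dirichlet_data(space, case)
        self.cons_nodes = cons_nodes
        self.g = g
        self.free = np.setdiff1d(np.arange(space.n_p2), cons_nodes)
        self.nf = len(self.free)
        self.np_ = space.n_vertices

        Af = A[self.free]
        self.A_red = Af[:, self.free].tocsc()
        A_cons = Af[:, cons_nodes]
        Bd = space.divergence_components()
        self.B_red = [b[:, self.free].tocsr() for b in Bd]
        B_cons = [b[:, cons_nodes] for b in Bd]

        # right-hand side: Dirichlet lift (+ outlet reference pressure term)
        bu = np.zeros((3, self.nf))
        for d in range(3):
            bu[d] = -(A_cons @ g[:, d])
        if case.outlet_pressure != 0.0:
            t = self._outlet_pressure_rhs(case)
            for d in range(3):
                bu[d] += t[self.free, d]
        self.bp = -sum(B_cons[d] @ g[:, d] for d in range(3))
        self.bu = bu
        self.b = np.concatenate([bu.ravel(), self.bp])

        try:
            self.lu = spla.splu(self.A_red)
        except RuntimeError as exc:
            raise SolverError(f"singular velocity block: {exc}") from exc
        self.mp_over_mu = space.pressure_lumped_mass() / self.mu

    def _outlet_pressure_rhs(self, case: FlowCase) -> np.ndarray:
        """-p_out * integral over the outlet of (v . n), as nodal loads."""
        mesh = self.space.mesh
        mask = mesh.boundary_tags == case.outlet_tag
        areas, normals = _facet_geometry(mesh, mask)
        fnodes = self.space.facet_nodes[mask][:, 3:]
        t = np.zeros((self.space.n_p2, 3))
        contrib = -case.outlet_pressure * (areas / 3.0)[:, None] * normals
        for m in range(3):
            np.add.at(t, fnodes[:, m], contrib)
        return t

    # -- linear algebra -----------------------------------------------------
    #
    # Unknown ordering: [u_x(free), u_y(free), u_z(free), p].  The Stokes
    # system is solved in its symmetric indefinite form (pressure sign
    # flipped) by MINRES with a block-diagonal SPD preconditioner — robust
    # even for long narrow throats where the inf-sup constant is small.
    # The nonsymmetric Picard systems use GMRES with a block triangular
    # preconditioner instead.

    def _matvec(self, x: np.ndarray) -> np.ndarray:
        """[[A, -B^T], [B, 0]] (native, nonsymmetric sign convention)."""
        u = x[: 3 * self.nf].reshape(3, self.nf)
        p = x[3 * self.nf:]
        out = np.empty_like(x)
        rp = np.zeros(self.np_)
        for d in range(3):
            out[d * self.nf:(d + 1) * self.nf] = \
                self.A_red @ u[d] - self.B_red[d].T @ p
            rp += self.B_red[d] @ u[d]
        out[3 * self.nf:] = rp
        return out

    def _schur_matvec(self, p: np.ndarray) -> np.ndarray:
        """S p = B A^-1 B^T p (SPD for the Stokes velocity block)."""
        out = np.zeros(self.np_)
        for d in range(3):
            out += self.B_red[d] @ self.lu.solve(self.B_red[d].T @ p)
        return out

    def solve(self, x0: np.ndarray | None = None,
              rtol: float = _KRYLOV_RTOL) -> np.ndarray:
        """Uzawa/Schur-complement solve of the saddle system.

        Eliminating the velocity through the exact scalar LU gives the
        pressure Schur system (B A^-1 B^T) p = b_p - B A^-1 b_u, solved by
        preconditioned CG (Stokes: S is SPD) or full GMRES (Picard
        systems), with the lumped pressure mass matrix over mu as the
        preconditioner.  The momentum equations are then satisfied to
        machine precision by back-substitution; the continuity residual
        equals the Krylov tolerance on the Schur system.
        """
        t = np.stack([self.lu.solve(self.bu[d]) for d in range(3)])
        rhs_s = self.bp - sum(self.B_red[d] @ t[d] for d in range(3))
        S = spla.LinearOperator((self.np_, self.np_),
                                matvec=self._schur_matvec)
        Minv = spla.LinearOperator(
            (self.np_, self.np_), matvec=lambda r: r / self.mp_over_mu)
        p0 = x0[3 * self.nf:] if x0 is not None else None
        if self.symmetric:
            p, info = spla.cg(S, rhs_s, x0=p0, M=Minv, rtol=rtol, atol=0.0,
                              maxiter=_SCHUR_MAXITER)
        else:
            p, info = spla.gmres(S, rhs_s, x0=p0, M=Minv, rtol=rtol,
                                 atol=0.0, restart=_SCHUR_GMRES_RESTART,
                                 maxiter=_SCHUR_MAXITER
                                 // _SCHUR_GMRES_RESTART)
        if info != 0 or not np.all(np.isfinite(p)):
            raise SolverError(
                f"Schur-complement solve failed to reach rtol {rtol:g} "
                f"(info={info})"
            )
        x = np.empty(3 * self.nf + self.np_)
        for d in range(3):
            x[d * self.nf:(d + 1) * self.nf] = \
                self.lu.solve(self.bu[d] + self.B_red[d].T @ p)
        x[3 * self.nf:] = p
        return x

    def residual_linear(self, x: np.ndarray) -> float:
        r = self._matvec(x) - self.b
        return float(np.linalg.norm(r)
                     / max(np.linalg.norm(self.b), 1e-300))

    def residual(self, x: np.ndarray) -> float:
        """Relative residual of this system at state x."""
        r = self._matvec(x) - self.b
        scale = max(float(np.linalg.norm(self.b)), 1e-300)
        return float(np.linalg.norm(r) / scale)

    def expand(self, x: np.ndarray):
        """Reduced state -> full nodal velocity (n_p2, 3) and pressure."""
        u = np.zeros((self.space.n_p2, 3))
        u[self.free] = x[: 3 * self.nf].reshape(3, self.nf).T
        u[self.cons_nodes] = self.g
        return u, x[3 * self.nf:]

    def reduce(self, u: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.concatenate([u[self.free].T.ravel(), p])


def solve_stokes(mesh: VolumeMesh, fluid: FluidProperties,
                 case: FlowCase) -> FlowSolution:
    """Steady Stokes flow: one linear solve (no nonlinear iteration)."""
    if case.model != STOKES:
        raise ValueError("case.model must be 'stokes'")
    space = _TaylorHood(mesh)
    return _stokes_on_space(space, fluid, case)


def _stokes_on_space(space: _TaylorHood, fluid: FluidProperties,
                     case: FlowCase) -> FlowSolution:
    sys = _SaddleSystem(space, fluid, case, None)
    x = sys.solve()
    u, p = sys.expand(x)
    return FlowSolution(space.mesh, u, p, sys.residual(x), 1, STOKES, case,
                        fluid, _space=space)


def solve_navier_stokes(mesh: VolumeMesh, fluid: FluidProperties,
                        case: FlowCase,
                        initial: FlowSolution | None = None) -> FlowSolution:
    """Steady Navier–Stokes by Picard iteration from the Stokes solution.

    ``initial`` optionally seeds the iteration with a previously computed
    solution on the *same mesh* (e.g. the converged field at a neighbouring
    flow rate during a sweep); by default the Stokes solution is used.
    """
    if case.model != NAVIER_STOKES:
        raise ValueError("case.model must be 'navier_stokes'")
    if initial is not None and initial.mesh is not mesh:
        raise SolverError("initial solution was computed on a different mesh")
    space = initial._space if initial is not None else _TaylorHood(mesh)
    if initial is None:
        stokes_case = FlowCase(flow_rate=case.flow_rate,
                               inlet_tags=case.inlet_tags,
                               outlet_tag=case.outlet_tag,
                               outlet_pressure=case.outlet_pressure,
                               model=STOKES)
        initial = _stokes_on_space(space, fluid, stokes_case)
        u0 = initial.velocity
    else:
        # rescale the seed to the new flow rate (exact for Stokes flow)
        u0 = initial.velocity * (case.flow_rate / initial.case.flow_rate)
    return _picard_on_space(space, fluid, case, u0)


def _picard_on_space(space: _TaylorHood, fluid: FluidProperties,
                     case: FlowCase, u0: np.ndarray) -> FlowSolution:
    """Picard iteration with Aitken relaxation and inexact inner solves.

    The inner Krylov tolerance tracks the nonlinear residual so early
    iterations are cheap; convergence is declared on the relative momentum
    residual of the full nonlinear system.
    """
    u = u0
    x = None
    residual = np.inf
    for it in range(1, NS_MAX_ITERATIONS + 1):
        sys = _SaddleSystem(space, fluid, case, convection_field=u)
        if x is not None:
            # residual of the nonlinear system at the current iterate
            residual = sys.residual(x)
            if residual <= NS_TOLERANCE:
                uu, pp = sys.expand(x)
                return FlowSolution(space.mesh, uu, pp, residual, it - 1,
                                    NAVIER_STOKES, case, fluid, _space=space)
        rtol = float(np.clip(0.02 * residual, _KRYLOV_RTOL, 1e-4))
        x = sys.solve(x0=x, rtol=rtol)
        u, _ = sys.expand(x)

    re = reynolds_number(fluid, case.flow_rate,
                         _hydraulic_diameter(space.mesh, case.outlet_tag))
    raise SolverError(
        f"Picard iteration did not reach residual {NS_TOLERANCE:g} in "
        f"{NS_MAX_ITERATIONS} iterations (last residual {residual:.3e}, "
        f"outlet Reynolds number {re:.1f}); the steady laminar assumption "
        "may be violated"
    )


def _hydraulic_diameter(mesh: VolumeMesh, tag: str) -> float:
    area = mesh.boundary_area(tag)
    return 2.0 * np.sqrt(area / np.pi)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def boundary_flux(solution: FlowSolution, tag: str) -> float:
    """Volumetric flux of U through the tagged facets, outward-positive.

    Exact surface integral of the P2 field (edge-midpoint rule per facet).
    """
    mesh = solution.mesh
    mask = mesh.boundary_tags == tag
    if not mask.any():
        raise SolverError(f"unknown boundary tag {tag!r}")
    space = solution._space
    areas, normals = _facet_geometry(mesh, mask)
    fnodes = space.facet_nodes[mask][:, 3:]
    u_mid = solution.velocity[fnodes]
    flux = np.einsum("fmd,fd->f", u_mid, normals) * areas / 3.0
    return float(flux.sum())


def reynolds_number(fluid: FluidProperties, flow_rate: float,
                    diameter: float) -> float:
    """Re = rho * mean_velocity * d / mu for a circular duct of diameter d."""
    if flow_rate <= 0 or diameter <= 0:
        raise ValueError("flow_rate and diameter must be positive")
    mean_v = flow_rate / (np.pi * diameter**2 / 4.0)
    return fluid.density * mean_v * diameter / fluid.dynamic_viscosity
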