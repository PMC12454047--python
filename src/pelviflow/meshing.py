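"""Surface and volume meshing for luminal flow domains.

Turns a tagged, watertight triangulated surface (renal pelvis + ureter lumen,
or any tube-like cavity) into a solver-ready tetrahedral volume mesh whose
boundary facets carry inlet/outlet/wall tags.

Two meshing strategies live here:

* a structured *swept* mesher for axisymmetric lumens described by a radius
  profile r(z) (the synthetic phantoms carry this profile as metadata) —
  layers of a shared disk triangulation are swept along the axis and the
  resulting prisms split into tetrahedra with a globally consistent
  diagonal rule;
* a generic *Delaunay-carve* mesher for arbitrary watertight surfaces
  (e.g. CT-segmentation STL files) — surface vertices, inward offset layers
  and an interior lattice are connected by a Delaunay tetrahedralization,
  then tetrahedra outside the surface are carved away.

All coordinates are SI meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree

# Boundary tag names used throughout the package.
WALL = "wall"
INLET = "inlet"
OUTLET = "outlet"

# Angular tolerance for tag inheritance surface -> volume boundary (degrees).
TAG_ANGLE_TOL_DEG = 30.0


class MeshingError(RuntimeError):
    """Raised when a surface cannot be meshed or violates its contract."""


# ---------------------------------------------------------------------------
# Axisymmetric profile metadata
# ---------------------------------------------------------------------------


@dataclass
class AxisymProfile:
    """Radius profile r(z) of an axisymmetric lumen with flat end caps.

    ``z`` is strictly increasing; ``r`` is strictly positive.  The first
    station is the inflow cap, the last the outflow cap.  Densely sampled so
    linear interpolation reproduces the analytic shape to well below mesh
    resolution.
    """

    z: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.r.shape:
            raise ValueError("profile z and r must be 1-D arrays of equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("profile z must be strictly increasing")
        if np.any(self.r <= 0):
            raise ValueError("profile radii must be strictly positive")

    def radius(self, zq):
        return np.interp(zq, self.z, self.r)

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    @property
    def r_max(self) -> float:
        return float(self.r.max())

    def enclosed_volume(self) -> float:
        """Volume of the solid of revolution (flat caps)."""
        return float(np.pi * np.trapezoid(self.r**2, self.z))

    def to_dict(self) -> dict:
        return {"z": self.z.tolist(), "r": self.r.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AxisymProfile":
        return cls(z=np.asarray(d["z"]), r=np.asarray(d["r"]))


# ---------------------------------------------------------------------------
# Surface mesh
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Watertight triangulated lumen surface with per-facet boundary tags.

    ``face_tags`` partitions the triangles into INLET (one or more groups,
    named ``inlet``, ``inlet_2`` ...), exactly one OUTLET group and WALL.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    face_tags: np.ndarray
    profile: AxisymProfile | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.face_tags = np.asarray(self.face_tags, dtype="U16")
        if len(self.face_tags) != len(self.triangles):
            raise ValueError("face_tags must have one entry per triangle")

    # -- geometry ----------------------------------------------------------

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def enclosed_volume(self) -> float:
        return float(abs(self.as_trimesh().volume))

    def euler_characteristic(self) -> int:
        return int(self.as_trimesh().euler_number)

    def tag_groups(self) -> dict[str, np.ndarray]:
        """Map tag name -> face indices."""
        return {
            t: np.flatnonzero(self.face_tags == t)
            for t in np.unique(self.face_tags)
        }

    def tag_area(self, tag: str) -> float:
        tm = self.as_trimesh()
        return float(tm.area_faces[self.face_tags == tag].sum())

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        return self.as_trimesh().face_normals

    def validate(self) -> None:
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise MeshingError(
                f"surface is not watertight ({len(open_edges(tm))} open edges)"
            )
        if tm.volume <= 0:
            raise MeshingError("surface is not consistently outward-oriented")
        tags = set(np.unique(self.face_tags))
        if OUTLET in tags and (self.face_tags == OUTLET).sum() == 0:
            raise MeshingError("empty outlet tag group")

    # -- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write surface (STL/OFF/PLY by extension) plus a JSON tag sidecar."""
        path = Path(path)
        self.as_trimesh().export(path)
        sidecar = {"face_tags": self.face_tags.tolist()}
        if self.profile is not None:
            sidecar["profile"] = self.profile.to_dict()
        path.with_suffix(path.suffix + ".tags.json").write_text(
            json.dumps(sidecar)
        )


def open_edges(tm: trimesh.Trimesh) -> np.ndarray:
    """Edges referenced by exactly one face (empty for watertight surfaces)."""
    edges = np.sort(tm.edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq[counts == 1]


def read_surface(path: str | Path, unit_scale: float = 1.0) -> SurfaceMesh:
    """Read an STL/OFF/PLY surface, scale vertices into meters, fix orientation.

    A vertex-merge repair is attempted on non-watertight input; if holes
    remain the open edges are reported.  Facet tags are restored from a
    ``<file>.tags.json`` sidecar when present, otherwise all facets are WALL
    (use :func:`tag_boundaries` afterwards).
    """
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    path = Path(path)
    tm = trimesh.load(path, force="mesh", process=False)
    tm = trimesh.Trimesh(vertices=np.asarray(tm.vertices, float) * unit_scale,
                         faces=np.asarray(tm.faces), process=False)
    if not tm.is_watertight:
        # repair: merge duplicate vertices within tolerance, drop degenerates
        tm.merge_vertices(merge_tex=True, merge_norm=True)
        tm.update_faces(tm.nondegenerate_faces())
        tm.remove_unreferenced_vertices()
    if not tm.is_watertight:
        bad = open_edges(tm)
        raise MeshingError(
            f"surface {path.name} is not watertight after repair: "
            f"{len(bad)} open edges, e.g. {bad[:5].tolist()}"
        )
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()

    tags = np.full(len(tm.faces), WALL, dtype="U16")
    profile = None
    sidecar = path.with_suffix(path.suffix + ".tags.json")
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        stored = np.asarray(data["face_tags"], dtype="U16")
        if len(stored) == len(tm.faces):
            tags = stored
        if "profile" in data:
            profile = AxisymProfile.from_dict(data["profile"])
            if unit_scale != 1.0:
                profile = AxisymProfile(profile.z * unit_scale,
                                        profile.r * unit_scale)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), tags,
                       profile=profile)


# ---------------------------------------------------------------------------
# Boundary tagging rules
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def _select(rule, centroids: np.ndarray, normals: np.ndarray,
            vertices: np.ndarray) -> np.ndarray:
    """Evaluate one tagging rule -> boolean face mask."""
    if callable(rule):
        return np.asarray(rule(centroids, normals), dtype=bool)
    kind = rule["kind"]
    if kind == "cap":
        ax = rule["axis"]
        ax = _AXES[ax] if isinstance(ax, str) else int(ax)
        coord = centroids[:, ax]
        lo, hi = vertices[:, ax].min(), vertices[:, ax].max()
        tol = rule.get("tol", 0.02 * (hi - lo))
        target = lo if rule["end"] == "min" else hi
        near = np.abs(coord - target) <= tol
        aligned = np.abs(normals[:, ax]) >= rule.get("min_align", 0.7)
        return near & aligned
    if kind == "plane":
        p = np.asarray(rule["point"], float)
        n = np.asarray(rule["normal"], float)
        n = n / np.linalg.norm(n)
        return np.abs((centroids - p) @ n) <= rule["tol"]
    if kind == "sphere":
        c = np.asarray(rule["center"], float)
        return np.linalg.norm(centroids - c, axis=1) <= rule["radius"]
    raise ValueError(f"unknown tagging rule kind: {kind!r}")


def tag_boundaries(surface: SurfaceMesh, rules: dict) -> SurfaceMesh:
    """Partition facets into INLET(s)/OUTLET/WALL from region rules.

    ``rules`` maps ``"outlet"`` to one selector and ``"inlet"`` to a selector
    or list of selectors (multiple papillary patches).  Selectors are dicts
    (``{"kind": "cap"|"plane"|"sphere", ...}``) or callables
    ``f(centroids, normals) -> mask``.  Untagged facets become WALL.
    """
    if "inlet" not in rules or "outlet" not in rules:
        raise ValueError("rules must define both 'inlet' and 'outlet'")
    centroids = surface.face_centroids()
    normals = surface.face_normals()
    tags = np.full(len(surface.triangles), WALL, dtype="U16")

    out_mask = _select(rules["outlet"], centroids, normals, surface.vertices)
    if not out_mask.any():
        raise MeshingError("outlet rule selects zero facets")
    tags[out_mask] = OUTLET

    inlet_rules = rules["inlet"]
    if not isinstance(inlet_rules, (list, tuple)):
        inlet_rules = [inlet_rules]
    for k, rule in enumerate(inlet_rules):
        mask = _select(rule, centroids, normals, surface.vertices)
        if not mask.any():
            raise MeshingError(f"inlet rule #{k + 1} selects zero facets")
        if (mask & out_mask).any():
            raise MeshingError("inlet and outlet rules select overlapping facets")
        name = INLET if k == 0 else f"{INLET}_{k + 1}"
        tags[mask] = name
    return SurfaceMesh(surface.vertices, surface.triangles, tags,
                       profile=surface.profile)


# ---------------------------------------------------------------------------
# Volume mesh
# ---------------------------------------------------------------------------

# local faces of a positively oriented tet, outward-oriented
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with tagged boundary facets (the solver's domain)."""

    vertices: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_tags: np.ndarray
    cell_size_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.boundary_faces = np.ascontiguousarray(self.boundary_faces,
                                                   dtype=np.int64)
        self.boundary_tags = np.asarray(self.boundary_tags, dtype="U16")

    @property
    def n_cells(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        a, b, c, d = (v[self.tets[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    def tag_groups(self) -> dict[str, np.ndarray]:
        return {
            t: np.flatnonzero(self.boundary_tags == t)
            for t in np.unique(self.boundary_tags)
        }

    def boundary_area(self, tag: str) -> float:
        f = self.boundary_faces[self.boundary_tags == tag]
        p = self.vertices[f]
        return float(
            0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            ).sum()
        )

    def validate(self) -> None:
        vols = self.tet_volumes()
        if len(vols) == 0:
            raise MeshingError("empty volume mesh")
        if vols.min() <= 0:
            raise MeshingError(
                f"{(vols <= 0).sum()} non-positive tetrahedra"
            )
        for f, t in ((self.boundary_faces, "boundary_faces"),):
            if f.min() < 0 or f.max() >= len(self.vertices):
                raise MeshingError(f"{t} index out of range")

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Native .npz exchange format (exact round trip)."""
        np.savez_compressed(
            Path(path),
            vertices=self.vertices,
            tets=self.tets,
            boundary_faces=self.boundary_faces,
            boundary_tags=self.boundary_tags.astype("U16"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "VolumeMesh":
        d = np.load(Path(path), allow_pickle=False)
        return cls(d["vertices"], d["tets"], d["boundary_faces"],
                   d["boundary_tags"])

    def write_vtu(self, path: str | Path, point_data: dict | None = None,
                  cell_data: dict | None = None) -> None:
        write_vtu(path, self.vertices, self.tets,
                  point_data=point_data, cell_data=cell_data)


@dataclass
class MeshQualityReport:
    n_cells: int
    min_dihedral_angle: float  # degrees
    max_radius_ratio: float    # circumradius / (3 * inradius); 1 for regular
    n_boundary_facets_per_tag: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def mesh_quality(mesh: VolumeMesh) -> MeshQualityReport:
    """Dihedral-angle and radius-ratio quality summary of a volume mesh."""
    v = mesh.vertices
    t = mesh.tets
    p = v[t]  # (n, 4, 3)

    # face normals of the four faces (outward)
    normals = np.empty((len(t), 4, 3))
    for i, (a, b, c) in enumerate(_TET_FACES):
        n = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
        normals[:, i] = n / np.linalg.norm(n, axis=1, keepdims=True)
    # dihedral angle along the edge shared by faces i, j:
    # angle = pi - angle between outward normals; the smallest dihedral in a
    # cell corresponds to the largest normal-normal angle (smallest cosine)
    min_cos = np.full(len(t), 1.0)
    for i in range(4):
        for j in range(i + 1, 4):
            c = np.einsum("ij,ij->i", normals[:, i], normals[:, j])
            min_cos = np.minimum(min_cos, c)
    min_dihedral = np.degrees(np.pi - np.arccos(np.clip(min_cos, -1, 1))).min()

    vols = mesh.tet_volumes()
    # inradius r = 3V / (sum of face areas); circumradius via Cayley-Menger-free
    areas = np.zeros(len(t))
    for a, b, c in _TET_FACES:
        areas += 0.5 * np.linalg.norm(
            np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a]), axis=1
        )
    inradius = 3.0 * vols / areas
    # circumradius: |(a-d) x (b-d) . ...| formula
    a, b, c, d = (p[:, i] for i in range(4))
    A, B, C = a - d, b - d, c - d
    num = (np.einsum("ij,ij->i", A, A)[:, None] * np.cross(B, C)
           + np.einsum("ij,ij->i", B, B)[:, None] * np.cross(C, A)
           + np.einsum("ij,ij->i", C, C)[:, None] * np.cross(A, B))
    circum = np.linalg.norm(num, axis=1) / (12.0 * vols)
    ratio = circum / (3.0 * inradius)

    counts = {t_: int(n) for t_, n in
              zip(*np.unique(mesh.boundary_tags, return_counts=True))}
    return MeshQualityReport(
        n_cells=len(t),
        min_dihedral_angle=float(min_dihedral),
        max_radius_ratio=float(ratio.max()),
        n_boundary_facets_per_tag=counts,
    )


# ---------------------------------------------------------------------------
# Shared: disk triangulation and prism splitting (swept mesher)
# ---------------------------------------------------------------------------


def _stitch_rings(inner: np.ndarray, outer: np.ndarray) -> list[tuple]:
    """Triangulate the annulus between two concentric rings of node indices.

    Nodes on each ring are uniformly spaced in angle; the stitch advances the
    ring whose next node comes first in normalized angle (two-pointer merge).
    """
    mi, mo = len(inner), len(outer)
    tris = []
    i = j = 0
    while i < mi or j < mo:
        # normalized parameter of the *next* node on each ring
        ti = (i + 1) / mi if i < mi else np.inf
        tj = (j + 1) / mo if j < mo else np.inf
        a = inner[i % mi]
        b = outer[j % mo]
        if tj <= ti:
            tris.append((a, b, outer[(j + 1) % mo]))
            j += 1
        else:
            tris.append((a, b, inner[(i + 1) % mi]))
            i += 1
    return tris


def _build_disk(n_theta: int, n_rings: int, grading: float = 1.0):
    """Unit-disk triangulation: (points_2d, triangles).

    Ring j sits at normalized radius rho_j with node count proportional to
    rho_j.  ``grading`` > 1 clusters rings toward the rim (near-wall
    refinement); ring spacings follow a geometric progression whose rim
    spacing is ``1/grading`` times the center spacing.
    """
    n_rings = max(2, int(n_rings))
    n_theta = max(9, int(n_theta))
    if grading > 1.0 and n_rings > 1:
        g = grading ** (-1.0 / (n_rings - 1))
        steps = g ** np.arange(n_rings)
        rho = np.cumsum(steps) / steps.sum()
    else:
        rho = np.arange(1, n_rings + 1) / n_rings

    pts = [(0.0, 0.0)]
    rings = []
    for j, rj in enumerate(rho):
        m = max(6, int(round(n_theta * rj)))
        if j == n_rings - 1:
            m = n_theta
        # stagger alternate rings by half a step for better triangles
        off = (np.pi / m) * (j % 2)
        ang = 2 * np.pi * np.arange(m) / m + off
        idx = np.arange(len(pts), len(pts) + m)
        pts.extend(zip(rj * np.cos(ang), rj * np.sin(ang)))
        rings.append(idx)

    tris = [(0, rings[0][k], rings[0][(k + 1) % len(rings[0])])
            for k in range(len(rings[0]))]
    for j in range(1, n_rings):
        tris.extend(_stitch_rings(rings[j - 1], rings[j]))

    pts = np.asarray(pts)
    tris = np.asarray(tris, dtype=np.int64)
    # orient all triangles counter-clockwise in the disk plane
    e1 = pts[tris[:, 1]] - pts[tris[:, 0]]
    e2 = pts[tris[:, 2]] - pts[tris[:, 0]]
    flip = (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return pts, tris


# prism (0,1,2 bottom / 3,4,5 top) -> 3 tets, per diagonal configuration.
# Quad faces (0,1,4,3), (1,2,5,4), (2,0,3,5); choice 0 picks the diagonal
# through the first corner, choice 1 through the second.  The min-vertex rule
# below never produces the two cyclic (unsplittable) configurations.
_PRISM_TEMPLATES = {
    (0, 0, 1): ((0, 1, 2, 5), (0, 1, 4, 5), (0, 3, 4, 5)),
    (0, 1, 0): ((0, 1, 2, 4), (0, 2, 3, 4), (2, 3, 4, 5)),
    (0, 1, 1): ((0, 1, 2, 4), (0, 2, 4, 5), (0, 3, 4, 5)),
    (1, 0, 0): ((0, 1, 2, 3), (1, 2, 3, 5), (1, 3, 4, 5)),
    (1, 0, 1): ((0, 1, 2, 5), (0, 1, 3, 5), (1, 3, 4, 5)),
    (1, 1, 0): ((0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 5)),
}
_PRISM_QUADS = ((0, 1, 4, 3), (1, 2, 5, 4), (2, 0, 3, 5))


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split (n, 6) prisms into (3n, 4) tets with neighbor-consistent diagonals.

    Each quad face takes the diagonal through its smallest global vertex
    index, so adjacent prisms agree on shared faces.
    """
    n = len(prisms)
    choices = np.zeros((n, 3), dtype=np.int64)
    for q, (a, b, c, d) in enumerate(_PRISM_QUADS):
        corners = prisms[:, [a, b, c, d]]
        amin = corners.argmin(axis=1)
        choices[:, q] = amin % 2  # positions 0/2 -> choice 0, 1/3 -> choice 1
    tets = np.empty((n, 3, 4), dtype=np.int64)
    for cfg, template in _PRISM_TEMPLATES.items():
        mask = np.all(choices == cfg, axis=1)
        if not mask.any():
            continue
        tpl = np.asarray(template)  # (3, 4) local indices
        tets[mask] = prisms[mask][:, tpl]
    bad = np.all(choices == (0, 0, 0), axis=1) | np.all(choices == (1, 1, 1),
                                                        axis=1)
    if bad.any():  # cannot happen with min-vertex rule; guard anyway
        raise MeshingError("cyclic prism diagonal configuration encountered")
    return tets.reshape(-1, 4)


def _orient_tets(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (vertices[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    flip = vol6 < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def _boundary_faces_of(tets: np.ndarray) -> np.ndarray:
    """Oriented boundary faces (outward) = tet faces occurring exactly once."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def _sweep_stations(profile: AxisymProfile, edge_target: float,
                    n_rings: int, axial_aspect: float = 3.0) -> np.ndarray:
    """Axial stations with spacing tied to the local in-plane cell size."""
    z0, zL = float(profile.z[0]), float(profile.z[-1])
    stations = [z0]
    z = z0
    while z < zL:
        r = float(profile.radius(z))
        dz = np.clip(axial_aspect * r / n_rings, edge_target / 12.0,
                     edge_target)
        z = z + dz
        stations.append(min(z, zL))
    st = np.asarray(stations)
    if zL - st[-2] < 0.25 * (st[-2] - st[-3]):
        st = np.delete(st, -2)  # avoid a sliver last layer
    return st


def sweep_volume_mesh(profile: AxisymProfile, edge_target: float,
                      near_wall_refine: float = 1.5) -> VolumeMesh:
    """Structured tetrahedral mesh of an axisymmetric lumen (untagged).

    A fixed disk triangulation is scaled to the local radius at each axial
    station; prisms between consecutive layers are split into tetrahedra.
    ``near_wall_refine`` clusters radial rings toward the wall.
    """
    if edge_target <= 0:
        raise ValueError("edge_target must be positive")
    n_rings = max(3, int(np.ceil(profile.r_max / edge_target)))
    n_theta = max(16, int(round(2.5 * np.pi * n_rings)))
    disk_pts, disk_tris = _build_disk(n_theta, n_rings,
                                      grading=max(1.0, near_wall_refine))
    stations = _sweep_stations(profile, edge_target, n_rings)
    radii = profile.radius(stations)

    n_local = len(disk_pts)
    n_layers = len(stations)
    verts = np.empty((n_layers * n_local, 3))
    for k, (zk, rk) in enumerate(zip(stations, radii)):
        sl = slice(k * n_local, (k + 1) * n_local)
        verts[sl, 0] = disk_pts[:, 0] * rk
        verts[sl, 1] = disk_pts[:, 1] * rk
        verts[sl, 2] = zk

    # prisms between consecutive layers for each disk triangle
    tri = disk_tris
    prisms = np.empty(((n_layers - 1) * len(tri), 6), dtype=np.int64)
    for k in range(n_layers - 1):
        lo, hi = k * n_local, (k + 1) * n_local
        sl = slice(k * len(tri), (k + 1) * len(tri))
        prisms[sl, 0:3] = tri + lo
        prisms[sl, 3:6] = tri + hi

    tets = _orient_tets(verts, _split_prisms(prisms))
    bfaces = _boundary_faces_of(tets)
    tags = np.full(len(bfaces), WALL, dtype="U16")
    mesh = VolumeMesh(verts, tets, bfaces, tags)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Native geometric queries (no spatial-index dependency)
# ---------------------------------------------------------------------------


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from points p[i] to triangles tri[i] (paired)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    # barycentric-region closest point (Ericson, Real-Time Collision Detection)
    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3),
                 0.0)
    closest[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6),
                 0.0)
    closest[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    closest[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(p - closest, axis=1)


def nearest_surface_face(surface_vertices: np.ndarray,
                         surface_triangles: np.ndarray,
                         points: np.ndarray, k: int = 12):
    """(face index, distance) of the nearest surface triangle per point.

    Candidate triangles come from a KD-tree over triangle centroids; exact
    point-triangle distances resolve the winner among candidates.
    """
    tri_pts = surface_vertices[surface_triangles]
    centroids = tri_pts.mean(axis=1)
    k = min(k, len(centroids))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    if cand.shape[0] != len(points):
        cand = cand.reshape(len(points), -1)
    n, kk = cand.shape
    prep = np.repeat(points, kk, axis=0)
    tris = tri_pts[cand.ravel()]
    d = _point_triangle_distance(prep, tris).reshape(n, kk)
    best = d.argmin(axis=1)
    rows = np.arange(n)
    return cand[rows, best], d[rows, best]


def winding_number(surface_vertices: np.ndarray,
                   surface_triangles: np.ndarray,
                   points: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Generalized winding number of each point (1 inside, 0 outside).

    Solid-angle sum over triangles (van Oosterom & Strackee), exact for
    watertight oriented surfaces and robust to points near the surface.
    """
    tri = surface_vertices[surface_triangles]  # (F, 3, 3)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        A = tri[None, :, 0] - p[:, None]
        B = tri[None, :, 1] - p[:, None]
        C = tri[None, :, 2] - p[:, None]
        la = np.linalg.norm(A, axis=2)
        lb = np.linalg.norm(B, axis=2)
        lc = np.linalg.norm(C, axis=2)
        det = np.einsum("pfi,pfi->pf", A, np.cross(B, C))
        denom = (la * lb * lc
                 + np.einsum("pfi,pfi->pf", A, B) * lc
                 + np.einsum("pfi,pfi->pf", B, C) * la
                 + np.einsum("pfi,pfi->pf", C, A) * lb)
        omega = 2.0 * np.arctan2(det, denom)
        out[s:s + chunk] = omega.sum(axis=1) / (4.0 * np.pi)
    return out


def points_inside(surface: "SurfaceMesh | trimesh.Trimesh",
                  points: np.ndarray) -> np.ndarray:
    """Boolean mask: which points lie inside the watertight surface."""
    if isinstance(surface, SurfaceMesh):
        v, f = surface.vertices, surface.triangles
    else:
        v, f = np.asarray(surface.vertices), np.asarray(surface.faces)
    return winding_number(v, f, np.asarray(points, float)) > 0.5


def signed_distance_to_surface(surface_vertices: np.ndarray,
                               surface_triangles: np.ndarray,
                               points: np.ndarray) -> np.ndarray:
    """Distance to the surface, positive inside, negative outside."""
    _, d = nearest_surface_face(surface_vertices, surface_triangles, points)
    wn = winding_number(surface_vertices, surface_triangles, points)
    return np.where(wn > 0.5, d, -d)


# ---------------------------------------------------------------------------
# Generic Delaunay-carve mesher
# ---------------------------------------------------------------------------


def _interior_points(tm: trimesh.Trimesh, edge_target: float,
                     near_wall_refine: float) -> np.ndarray:
    """Graded interior point cloud: inward offset layers + coarse lattice."""
    verts = np.asarray(tm.vertices)
    faces = np.asarray(tm.faces)
    vnorm = np.asarray(tm.vertex_normals)

    def signed_distance(_tm, pts):
        return signed_distance_to_surface(verts, faces, pts)

    # local spacing at each surface vertex = mean adjacent edge length
    e = tm.edges_unique
    el = tm.edges_unique_length
    acc = np.zeros(len(verts))
    cnt = np.zeros(len(verts))
    np.add.at(acc, e[:, 0], el)
    np.add.at(acc, e[:, 1], el)
    np.add.at(cnt, e[:, 0], 1)
    np.add.at(cnt, e[:, 1], 1)
    local = np.where(cnt > 0, acc / np.maximum(cnt, 1), edge_target)
    h = np.minimum(local, edge_target)

    points = []
    depth = h / max(near_wall_refine, 1.0)
    step = depth.copy()
    alive = np.ones(len(verts), dtype=bool)
    for _ in range(4):
        cand = verts[alive] - vnorm[alive] * depth[alive, None]
        sd = signed_distance(tm, cand)
        ok = (sd > 0.45 * step[alive]) & (sd > 0.6 * depth[alive])
        keep_idx = np.flatnonzero(alive)[ok]
        points.append(verts[keep_idx]
                      - vnorm[keep_idx] * depth[keep_idx, None])
        dead = np.flatnonzero(alive)[~ok]
        alive[dead] = False
        if not alive.any():
            break
        step[alive] *= 1.5
        depth[alive] += step[alive]
    offset_pts = (np.vstack(points) if points and sum(map(len, points))
                  else np.empty((0, 3)))

    # interior lattice at edge_target spacing
    lo, hi = tm.bounds
    axes = [np.arange(lo[d] + 0.5 * edge_target, hi[d], edge_target)
            for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(grid):
        sd = signed_distance(tm, grid)
        grid = grid[sd > 0.8 * edge_target]
    if len(grid) and len(offset_pts):
        d, _ = cKDTree(offset_pts).query(grid)
        grid = grid[d > 0.55 * edge_target]
    return (np.vstack([offset_pts, grid])
            if len(grid) else offset_pts)


def delaunay_volume_mesh(surface: SurfaceMesh, edge_target: float,
                         near_wall_refine: float = 1.5) -> VolumeMesh:
    """Unstructured mesh of an arbitrary watertight surface (untagged).

    Delaunay tetrahedralization of surface vertices plus graded interior
    points, carved to the inside of the surface, keeping the largest
    face-connected component.
    """
    surface.validate()
    tm = surface.as_trimesh()
    interior = _interior_points(tm, edge_target, near_wall_refine)
    pts = np.vstack([surface.vertices, interior])

    dt = Delaunay(pts)
    tets = _orient_tets(pts, dt.simplices.astype(np.int64))
    cent = pts[tets].mean(axis=1)
    inside = winding_number(surface.vertices, surface.triangles, cent) > 0.5
    vols = np.abs(np.einsum(
        "ij,ij->i",
        np.cross(pts[tets[:, 1]] - pts[tets[:, 0]],
                 pts[tets[:, 2]] - pts[tets[:, 0]]),
        pts[tets[:, 3]] - pts[tets[:, 0]])) / 6.0
    tets = tets[inside & (vols > 1e-9 * np.median(vols[inside]))]
    if len(tets) == 0:
        box = tm.bounds.tolist()
        raise MeshingError(f"carving removed all tetrahedra (region bbox {box})")

    tets = _largest_component(tets)

    # drop unreferenced points
    used = np.unique(tets)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    tets = remap[tets]
    verts = pts[used]

    bfaces = _boundary_faces_of(tets)
    mesh = VolumeMesh(verts, tets, bfaces,
                      np.full(len(bfaces), WALL, dtype="U16"))
    mesh.validate()
    return mesh


def _largest_component(tets: np.ndarray) -> np.ndarray:
    """Keep the largest face-connected set of tets."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    owner = np.repeat(np.arange(len(tets)), 4)
    order = np.lexsort(key.T[::-1])
    key_s = key[order]
    owner_s = owner[order]
    same = np.all(key_s[1:] == key_s[:-1], axis=1)
    a = owner_s[:-1][same]
    b = owner_s[1:][same]
    n = len(tets)
    g = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    ncomp, labels = connected_components(g, directed=False)
    if ncomp == 1:
        return tets
    counts = np.bincount(labels)
    return tets[labels == counts.argmax()]


# ---------------------------------------------------------------------------
# Tag inheritance and the public mesher entry point
# ---------------------------------------------------------------------------


def inherit_tags(mesh: VolumeMesh, surface: SurfaceMesh,
                 angle_tol_deg: float = TAG_ANGLE_TOL_DEG) -> VolumeMesh:
    """Transfer surface facet tags onto mesh boundary facets.

    Nearest-facet matching with an angular tolerance between facet normals;
    ambiguous matches fall back to WALL.
    """
    tm = surface.as_trimesh()
    bf = mesh.boundary_faces
    p = mesh.vertices[bf]
    cent = p.mean(axis=1)
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)

    tri_id, _ = nearest_surface_face(surface.vertices, surface.triangles, cent)
    src_n = tm.face_normals[tri_id]
    cosang = np.einsum("ij,ij->i", n, src_n)
    ok = cosang >= np.cos(np.radians(angle_tol_deg))
    tags = np.where(ok, surface.face_tags[tri_id], WALL).astype("U16")

    out = VolumeMesh(mesh.vertices, mesh.tets, bf, tags,
                     cell_size_field=mesh.cell_size_field)
    missing = ({OUTLET} | {t for t in surface.face_tags if t.startswith(INLET)}) \
        - set(np.unique(tags))
    if missing:
        raise MeshingError(
            f"tag inheritance lost boundary groups: {sorted(missing)}"
        )
    return out


def generate_volume_mesh(surface: SurfaceMesh, edge_target: float,
                         near_wall_refine: float = 1.5) -> VolumeMesh:
    """Tagged tetrahedral volume mesh of a watertight tagged surface.

    Uses the structured swept mesher when the surface carries an
    axisymmetric profile (synthetic phantoms), the Delaunay-carve mesher
    otherwise.  Boundary facets inherit the surface tags.
    """
    if edge_target <= 0:
        raise ValueError("edge_target must be positive")
    surface.validate()
    if surface.profile is not None:
        raw = sweep_volume_mesh(surface.profile, edge_target, near_wall_refine)
    else:
        raw = delaunay_volume_mesh(surface, edge_target, near_wall_refine)
    return inherit_tags(raw, surface)


# ---------------------------------------------------------------------------
# Minimal ASCII VTU writer (no VTK dependency)
# ---------------------------------------------------------------------------


def write_vtu(path: str | Path, vertices: np.ndarray, tets: np.ndarray,
              point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write an unstructured tet mesh with fields as ASCII .vtu XML."""
    vertices = np.asarray(vertices, float)
    tets = np.asarray(tets, np.int64)
    np_, nc = len(vertices), len(tets)

    def arr(a, name, comps):
        a = np.asarray(a)
        flat = " ".join(f"{x:.9g}" for x in a.ravel())
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{comps}" format="ascii">{flat}'
                f"</DataArray>")

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{np_}" NumberOfCells="{nc}">',
             "<Points>", arr(vertices, "Points", 3), "</Points>",
             "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">'
             + " ".join(map(str, tets.ravel())) + "</DataArray>",
             '<DataArray type="Int64" Name="offsets" format="ascii">'
             + " ".join(map(str, np.arange(4, 4 * nc + 1, 4))) + "</DataArray>",
             '<DataArray type="UInt8" Name="types" format="ascii">'
             + " ".join(["10"] * nc) + "</DataArray>",
             "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        for name, a in point_data.items():
            a = np.asarray(a)
            comps = 1 if a.ndim == 1 else a.shape[1]
            parts.append(arr(a, name, comps))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, a in cell_data.items():
            a = np.asarray(a)
            comps = 1 if a.ndim == 1 else a.shape[1]
            parts.append(arr(a, name, comps))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))
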