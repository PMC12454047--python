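"""Synthetic lumen phantoms of the renal pelvis, UPJ and proximal ureter.

Patient CT segmentations of hydronephrotic collecting systems are rarely
shareable, so every downstream stage (meshing, flow solve, pressure sweep,
classification) is exercised on parametric phantoms that emulate the
segmented anatomy: a dilated spheroidal pelvis chamber, a smooth
converging–diverging ureteropelvic-junction throat with a narrow cylindrical
waist, and a short proximal ureter tube.  The papillary urine inflow enters
through a planar patch where the pelvis dome is truncated; the ureter ends
in a flat outlet cap.

All phantoms are axisymmetric about the z axis and carry their radius
profile r(z) as metadata, which the meshing module exploits for structured
swept tetrahedralization.  Units are SI meters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .meshing import (
    INLET,
    OUTLET,
    WALL,
    AxisymProfile,
    MeshingError,
    SurfaceMesh,
    _stitch_rings,
)


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a pelvis–UPJ–ureter lumen.

    Lengths in meters.  Defaults describe a severely obstructed system of a
    pediatric patient: a 30 mm (grade 3–4 hydronephrotic) pelvis, a 1.5 mm
    UPJ waist and a mildly dilated 6 mm proximal ureter segment.

    Parameters
    ----------
    pelvis_ap_diameter : anteroposterior diameter of the pelvis chamber.
    pelvis_length : axial length of the (prolate/oblate) spheroidal pelvis.
    upj_throat_diameter : minimum luminal diameter at the UPJ.
    upj_length : total axial extent of the converging–diverging junction
        (25% convergence, 50% cylindrical waist, 25% divergence).
    ureter_diameter, ureter_length : proximal ureter tube.
    inlet_patch_fraction : fraction of the pelvis dome area carried by the
        papillary inflow patch, in (0, 0.5].
    mesh_edge_target : target surface triangle edge length.
    seed : optional seed for small deterministic wall-surface jitter that
        mimics segmentation roughness (no jitter when None).
    """

    pelvis_ap_diameter: float = 0.030
    pelvis_length: float = 0.030
    upj_throat_diameter: float = 0.0015
    upj_length: float = 0.008
    ureter_diameter: float = 0.006
    ureter_length: float = 0.015
    inlet_patch_fraction: float = 0.15
    mesh_edge_target: float = 0.00375
    seed: int | None = None

    def validate(self) -> None:
        for name in ("pelvis_ap_diameter", "pelvis_length",
                     "upj_throat_diameter", "upj_length",
                     "ureter_diameter", "ureter_length", "mesh_edge_target"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"invariant violated: {name} > 0")
        if self.upj_throat_diameter > self.ureter_diameter:
            raise PhantomSpecError(
                "invariant violated: upj_throat_diameter <= ureter_diameter"
            )
        if self.ureter_diameter > self.pelvis_ap_diameter:
            raise PhantomSpecError(
                "invariant violated: ureter_diameter <= pelvis_ap_diameter"
            )
        if not 0.0 < self.inlet_patch_fraction <= 0.5:
            raise PhantomSpecError(
                "invariant violated: inlet_patch_fraction in (0, 0.5]"
            )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Radius profile
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """C1 monotone ramp 0 -> 1 with zero end slopes."""
    return t * t * (3.0 - 2.0 * t)


def phantom_profile(spec: PhantomSpec) -> AxisymProfile:
    """Axisymmetric radius profile r(z) of the phantom, densely sampled.

    Segments (C1-continuous): truncated spheroidal pelvis; cubic-Hermite
    convergence to the throat; cylindrical throat waist; smoothstep
    divergence to the ureter; cylindrical ureter.
    """
    spec.validate()
    a = spec.pelvis_ap_diameter / 2.0
    c = spec.pelvis_length / 2.0
    r_t = spec.upj_throat_diameter / 2.0
    r_u = spec.ureter_diameter / 2.0

    # dome truncation for the papillary inlet patch: remove the spherical cap
    # whose lateral area is inlet_patch_fraction of the dome (front half)
    zd = np.linspace(0.0, c, 2001)
    rd = a * np.sqrt(np.clip(1.0 - ((zd - c) / c) ** 2, 0.0, None))
    drdz = np.gradient(rd, zd)
    darc = 2.0 * np.pi * rd * np.sqrt(1.0 + drdz**2)
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (darc[1:] + darc[:-1]) * np.diff(zd))])
    z_trunc = float(np.interp(spec.inlet_patch_fraction * cum[-1], cum, zd))
    z_trunc = max(z_trunc, 1e-4 * c)

    # spheroid -> taper junction: keep the junction radius comfortably above
    # the ureter radius so the convergence is monotone
    q_max = 0.8
    if 1.2 * r_u < a:
        q = min(q_max, np.sqrt(1.0 - (1.2 * r_u / a) ** 2))
    else:
        q = 0.0
    z_m = c * (1.0 + q)
    r_m = a * np.sqrt(max(1.0 - q**2, 0.0))
    s_m = -(a / c) * q / max(np.sqrt(1.0 - q**2), 1e-12)  # dr/dz at z_m

    L1 = 0.25 * spec.upj_length          # convergence
    Lt = 0.50 * spec.upj_length          # cylindrical waist
    L2 = 0.25 * spec.upj_length          # divergence
    # clamp the inherited slope for monotone Hermite interpolation
    s_lim = 3.0 * (r_m - r_t) / L1 if r_m > r_t else 0.0
    s_m = -min(abs(s_m), s_lim)
    herm = CubicHermiteSpline([0.0, L1], [r_m, r_t], [s_m, 0.0])

    def seg(z0, z1, fn, n):
        z = np.linspace(z0, z1, n)
        return z, fn(z)

    n_sph = 600
    z1, r1 = seg(z_trunc, z_m, lambda z: a * np.sqrt(
        np.clip(1.0 - ((z - c) / c) ** 2, 1e-12, None)), n_sph)
    z2, r2 = seg(z_m, z_m + L1, lambda z: np.maximum(herm(z - z_m), r_t), 300)
    z3, r3 = seg(z_m + L1, z_m + L1 + Lt, lambda z: np.full_like(z, r_t), 50)
    z4, r4 = seg(z_m + L1 + Lt, z_m + L1 + Lt + L2,
                 lambda z: r_t + (r_u - r_t) * _smoothstep(
                     (z - (z_m + L1 + Lt)) / L2), 300)
    z5, r5 = seg(z_m + spec.upj_length,
                 z_m + spec.upj_length + spec.ureter_length,
                 lambda z: np.full_like(z, r_u), 50)

    z = np.concatenate([z1, z2[1:], z3[1:], z4[1:], z5[1:]]) - z_trunc
    r = np.concatenate([r1, r2[1:], r3[1:], r4[1:], r5[1:]])
    return AxisymProfile(z=z, r=r)


# ---------------------------------------------------------------------------
# Surface triangulation of an axisymmetric profile
# ---------------------------------------------------------------------------


def _cap_disk(center_xy, z, radius, rim_ids, n_theta, edge_target,
              verts: list, flip: bool):
    """Triangulate a flat end cap sharing its rim ring with the wall.

    Appends interior nodes to ``verts``; returns triangles (outward +z when
    ``flip`` is False, outward -z when True).
    """
    tris: list[tuple] = []
    n_rings = max(1, int(np.ceil(radius / edge_target)))
    prev = None
    center_id = len(verts)
    verts.append((center_xy[0], center_xy[1], z))
    for j in range(1, n_rings):
        rho = radius * j / n_rings
        m = max(6, int(round(n_theta * j / n_rings)))
        ang = 2.0 * np.pi * np.arange(m) / m
        ids = np.arange(len(verts), len(verts) + m)
        verts.extend(zip(center_xy[0] + rho * np.cos(ang),
                         center_xy[1] + rho * np.sin(ang),
                         np.full(m, z)))
        if prev is None:
            tris.extend((center_id, ids[k], ids[(k + 1) % m])
                        for k in range(m))
        else:
            tris.extend(_stitch_rings(prev, ids))
        prev = ids
    if prev is None:
        m = len(rim_ids)
        tris.extend((center_id, rim_ids[k], rim_ids[(k + 1) % m])
                    for k in range(m))
    else:
        tris.extend(_stitch_rings(prev, np.asarray(rim_ids)))
    if flip:
        tris = [(t[0], t[2], t[1]) for t in tris]
    return tris


def surface_from_profile(profile: AxisymProfile, edge_target: float,
                         seed: int | None = None,
                         jitter: float = 0.0) -> SurfaceMesh:
    """Closed, tagged triangulated surface of an axisymmetric lumen.

    First cap (low z) is tagged INLET, last cap OUTLET, lateral wall WALL.
    ``jitter`` (fraction of edge_target) adds deterministic radial roughness
    to interior wall rings when a seed is given.
    """
    if edge_target <= 0:
        raise MeshingError("edge_target must be positive")
    from .meshing import _sweep_stations

    n_rings = max(3, int(np.ceil(profile.r_max / edge_target)))
    n_theta = max(16, int(round(2.5 * np.pi * n_rings)))
    stations = _sweep_stations(profile, edge_target, n_rings)
    radii = profile.radius(stations)

    verts: list[tuple] = []
    ring_ids = []
    ang = 2.0 * np.pi * np.arange(n_theta) / n_theta
    cosang, sinang = np.cos(ang), np.sin(ang)
    for zk, rk in zip(stations, radii):
        ids = np.arange(len(verts), len(verts) + n_theta)
        verts.extend(zip(rk * cosang, rk * sinang, np.full(n_theta, zk)))
        ring_ids.append(ids)

    tris: list[tuple] = []
    tags: list[str] = []
    for k in range(len(stations) - 1):
        a, b = ring_ids[k], ring_ids[k + 1]
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            tris.append((a[i], a[i2], b[i2]))
            tris.append((a[i], b[i2], b[i]))
        tags.extend([WALL] * (2 * n_theta))

    inlet_tris = _cap_disk((0.0, 0.0), stations[0], radii[0], ring_ids[0],
                           n_theta, edge_target, verts, flip=True)
    tris.extend(inlet_tris)
    tags.extend([INLET] * len(inlet_tris))
    outlet_tris = _cap_disk((0.0, 0.0), stations[-1], radii[-1], ring_ids[-1],
                            n_theta, edge_target, verts, flip=False)
    tris.extend(outlet_tris)
    tags.extend([OUTLET] * len(outlet_tris))

    v = np.asarray(verts, dtype=float)
    jittered = seed is not None and jitter > 0.0
    if jittered:
        rng = np.random.default_rng(seed)
        # radial roughness on interior wall rings only (caps stay planar),
        # scaled by the local radius so narrow segments stay narrow
        for ids in ring_ids[1:-1]:
            rad = np.linalg.norm(v[ids, :2], axis=1)
            d = rng.normal(0.0, jitter, size=len(ids)) * rad
            d = np.clip(d, -2.5 * jitter * rad, 2.5 * jitter * rad)
            scale = (rad + d) / rad
            v[ids, 0] *= scale
            v[ids, 1] *= scale

    # a jittered wall is no longer axisymmetric: drop the profile metadata
    # so volume meshing honours the rough geometry (Delaunay-carve path)
    sm = SurfaceMesh(v, np.asarray(tris, dtype=np.int64),
                     np.asarray(tags, dtype="U16"),
                     profile=None if jittered else profile)
    if sm.as_trimesh().volume < 0:  # safety: enforce outward orientation
        sm = SurfaceMesh(v, sm.triangles[:, [0, 2, 1]], sm.face_tags,
                         profile=profile)
    sm.validate()
    return sm


# ---------------------------------------------------------------------------
# Public phantom constructors
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec) -> SurfaceMesh:
    """Watertight tagged pelvis–UPJ–ureter lumen surface from a spec.

    The returned surface carries INLET (papillary patch truncating the
    pelvis dome), OUTLET (ureter end cap) and WALL tag groups, plus the
    axisymmetric profile metadata used by the swept volume mesher.
    """
    spec.validate()
    profile = phantom_profile(spec)
    jitter = 0.02 if spec.seed is not None else 0.0
    return surface_from_profile(profile, spec.mesh_edge_target,
                                seed=spec.seed, jitter=jitter)


def make_cylinder(radius: float, length: float,
                  mesh_edge_target: float) -> SurfaceMesh:
    """Closed cylinder with INLET/OUTLET end caps and WALL lateral surface.

    The canonical Hagen–Poiseuille validation geometry.
    """
    if radius <= 0 or length <= 0 or mesh_edge_target <= 0:
        raise PhantomSpecError(
            "invariant violated: radius, length, mesh_edge_target > 0"
        )
    z = np.linspace(0.0, length, 201)
    profile = AxisymProfile(z=z, r=np.full_like(z, float(radius)))
    return surface_from_profile(profile, mesh_edge_target)


def mask_to_surface(mask: np.ndarray, spacing) -> SurfaceMesh:
    """Iso-surface of a binary voxel lumen mask, scaled to physical units.

    The mask must contain a single 6-connected foreground component.  The
    returned surface is watertight and outward-oriented; facet tags are NOT
    assigned (use :func:`pelviflow.meshing.tag_boundaries`).
    """
    from scipy import ndimage
    from skimage import measure
    import trimesh

    mask = np.asarray(mask).astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    if spacing.size == 1:
        spacing = np.full(3, float(spacing))
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    if not mask.any():
        raise ValueError("empty mask: no foreground voxels")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    _, n_comp = ndimage.label(mask, structure=structure)
    if n_comp > 1:
        raise ValueError(
            f"mask has {n_comp} 6-connected components; expected exactly one"
        )

    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(spacing))
    verts = verts - spacing  # undo the one-voxel pad offset

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(tm)
    if not tm.is_watertight:
        tm.fill_holes()
    if not tm.is_watertight:
        raise MeshingError("marching-cubes surface could not be closed")
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       np.full(len(tm.faces), WALL, dtype="U16"))
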