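"""Meshing: surface I/O, tagging rules, volume meshing, quality, VTU."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest
import trimesh

from pelviflow import (
    MeshingError,
    SurfaceMesh,
    VolumeMesh,
    generate_volume_mesh,
    make_cylinder,
    mesh_quality,
    read_surface,
    tag_boundaries,
)
from pelviflow.meshing import points_inside

from conftest import CYL_LENGTH, CYL_RADIUS


# ---------------------------------------------------------------------------
# read_surface
# ---------------------------------------------------------------------------


def test_read_surface_scales_units(tmp_path):
    box = trimesh.creation.box(extents=(10.0, 20.0, 30.0))  # mm-sized
    path = tmp_path / "box.stl"
    box.export(path)
    surf = read_surface(path, unit_scale=1e-3)
    extent = surf.vertices.max(axis=0) - surf.vertices.min(axis=0)
    np.testing.assert_allclose(extent, [0.010, 0.020, 0.030], rtol=1e-6)
    assert surf.euler_characteristic() == 2
    assert len(surf.triangles) == 12


def test_read_surface_reports_open_edges(tmp_path):
    cyl = make_cylinder(CYL_RADIUS, CYL_LENGTH, CYL_RADIUS / 2)
    tm = cyl.as_trimesh()
    holey = trimesh.Trimesh(vertices=tm.vertices, faces=tm.faces[1:],
                            process=False)
    path = tmp_path / "holey.stl"
    holey.export(path)
    with pytest.raises(MeshingError, match="3 open edges"):
        read_surface(path)


def test_read_surface_roundtrip_preserves_tags(tmp_path):
    cyl = make_cylinder(CYL_RADIUS, CYL_LENGTH, CYL_RADIUS / 2)
    path = tmp_path / "cyl.stl"
    cyl.write(path)
    back = read_surface(path)
    assert set(back.tag_groups()) == {"inlet", "outlet", "wall"}
    assert back.profile is not None


# ---------------------------------------------------------------------------
# tag_boundaries
# ---------------------------------------------------------------------------


@pytest.fixture()
def untagged_cylinder():
    cyl = make_cylinder(CYL_RADIUS, CYL_LENGTH, CYL_RADIUS / 2)
    return SurfaceMesh(cyl.vertices, cyl.triangles,
                       np.full(len(cyl.triangles), "wall"))


def test_cap_rules_tag_cylinder(untagged_cylinder):
    tagged = tag_boundaries(untagged_cylinder, {
        "outlet": {"kind": "cap", "axis": "z", "end": "min"},
        "inlet": {"kind": "cap", "axis": "z", "end": "max"},
    })
    groups = tagged.tag_groups()
    assert set(groups) == {"inlet", "outlet", "wall"}
    cents = tagged.face_centroids()
    assert cents[groups["outlet"], 2].max() < 1e-9
    assert cents[groups["inlet"], 2].min() > CYL_LENGTH - 1e-9


def test_tagging_is_idempotent_on_phantom(stenotic_surface):
    z0 = stenotic_surface.vertices[:, 2].min()
    z1 = stenotic_surface.vertices[:, 2].max()
    retagged = tag_boundaries(stenotic_surface, {
        "inlet": {"kind": "plane", "point": [0, 0, z0],
                  "normal": [0, 0, 1], "tol": 1e-9},
        "outlet": {"kind": "plane", "point": [0, 0, z1],
                   "normal": [0, 0, 1], "tol": 1e-9},
    })
    assert np.array_equal(retagged.face_tags, stenotic_surface.face_tags)


def test_overlapping_rules_conflict(untagged_cylinder):
    rule = {"kind": "cap", "axis": "z", "end": "min"}
    with pytest.raises(MeshingError, match="overlap"):
        tag_boundaries(untagged_cylinder, {"outlet": rule, "inlet": rule})


def test_empty_selection_raises(untagged_cylinder):
    with pytest.raises(MeshingError, match="zero facets"):
        tag_boundaries(untagged_cylinder, {
            "outlet": {"kind": "sphere", "center": [1, 1, 1], "radius": 1e-6},
            "inlet": {"kind": "cap", "axis": "z", "end": "max"},
        })


# ---------------------------------------------------------------------------
# generate_volume_mesh (swept and Delaunay-carve paths)
# ---------------------------------------------------------------------------


def test_swept_mesh_volume_and_quality(cylinder_surface, cylinder_mesh):
    q = mesh_quality(cylinder_mesh)
    assert q.n_cells == cylinder_mesh.n_cells > 0
    assert q.min_dihedral_angle > 0
    assert set(q.n_boundary_facets_per_tag) == {"inlet", "outlet", "wall"}
    vol_err = abs(cylinder_mesh.total_volume()
                  - cylinder_surface.enclosed_volume())
    assert vol_err / cylinder_surface.enclosed_volume() <= 0.02


def test_swept_refinement_scaling(cylinder_surface):
    """Halving the edge target multiplies cells by ~8 (within factor 2)."""
    coarse = generate_volume_mesh(cylinder_surface, CYL_RADIUS / 3)
    fine = generate_volume_mesh(cylinder_surface, CYL_RADIUS / 6)
    ratio = fine.n_cells / coarse.n_cells
    assert 4.0 <= ratio <= 16.0
    assert set(np.unique(fine.boundary_tags)) == \
        set(np.unique(coarse.boundary_tags))


def test_refinement_monotonicity(stenotic_surface, stenotic_spec):
    h = stenotic_spec.mesh_edge_target
    cells = [generate_volume_mesh(stenotic_surface, e).n_cells
             for e in (1.5 * h, h)]
    assert cells[1] >= cells[0]


def test_tag_conservation_on_phantom(stenotic_surface, stenotic_mesh):
    assert set(np.unique(stenotic_mesh.boundary_tags)) == \
        set(np.unique(stenotic_surface.face_tags))


def test_delaunay_carve_path_on_generic_surface(cylinder_surface):
    """Without profile metadata the generic carve mesher is used."""
    generic = SurfaceMesh(cylinder_surface.vertices,
                          cylinder_surface.triangles,
                          cylinder_surface.face_tags, profile=None)
    vm = generate_volume_mesh(generic, CYL_RADIUS / 3)
    assert vm.tet_volumes().min() > 0
    vol_err = abs(vm.total_volume() - generic.enclosed_volume())
    assert vol_err / generic.enclosed_volume() <= 0.02
    assert set(np.unique(vm.boundary_tags)) == {"inlet", "outlet", "wall"}


def test_boundary_facets_inherit_exactly_one_tag(stenotic_mesh):
    assert len(stenotic_mesh.boundary_tags) == \
        len(stenotic_mesh.boundary_faces)
    assert all(t in {"inlet", "outlet", "wall"}
               for t in np.unique(stenotic_mesh.boundary_tags))


# ---------------------------------------------------------------------------
# geometric queries, I/O
# ---------------------------------------------------------------------------


def test_winding_number_containment(cylinder_surface, rng):
    pts = np.column_stack([
        rng.uniform(-2 * CYL_RADIUS, 2 * CYL_RADIUS, 300),
        rng.uniform(-2 * CYL_RADIUS, 2 * CYL_RADIUS, 300),
        rng.uniform(-0.2 * CYL_LENGTH, 1.2 * CYL_LENGTH, 300),
    ])
    inside = points_inside(cylinder_surface, pts)
    r = np.linalg.norm(pts[:, :2], axis=1)
    truly = (r < CYL_RADIUS * 0.95) & (pts[:, 2] > 1e-4) \
        & (pts[:, 2] < CYL_LENGTH - 1e-4)
    clearly_out = (r > CYL_RADIUS * 1.02) | (pts[:, 2] < -1e-4) \
        | (pts[:, 2] > CYL_LENGTH + 1e-4)
    assert np.all(inside[truly])
    assert not np.any(inside[clearly_out])


def test_volume_mesh_npz_roundtrip(tmp_path, cylinder_mesh):
    path = tmp_path / "mesh.npz"
    cylinder_mesh.save(path)
    back = VolumeMesh.load(path)
    assert np.array_equal(back.tets, cylinder_mesh.tets)
    assert np.array_equal(back.vertices, cylinder_mesh.vertices)
    assert np.array_equal(back.boundary_tags, cylinder_mesh.boundary_tags)


def test_vtu_output_is_wellformed_xml(tmp_path, cylinder_mesh):
    path = tmp_path / "mesh.vtu"
    cylinder_mesh.write_vtu(path, point_data={
        "pressure": np.zeros(len(cylinder_mesh.vertices))})
    root = ET.parse(path).getroot()
    assert root.tag == "VTKFile"
    piece = root.find(".//Piece")
    assert int(piece.get("NumberOfCells")) == cylinder_mesh.n_cells
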