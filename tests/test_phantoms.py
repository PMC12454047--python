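"""Phantom generation: spec invariants, topology, determinism, volumes."""

import numpy as np
import pytest

from pelviflow import (
    PhantomSpec,
    PhantomSpecError,
    make_cylinder,
    make_phantom,
    mask_to_surface,
    phantom_profile,
)

from conftest import CYL_LENGTH, CYL_RADIUS


@pytest.mark.parametrize(
    ("fields", "fragment"),
    [
        ({"pelvis_ap_diameter": -0.01}, "pelvis_ap_diameter"),
        ({"upj_length": 0.0}, "upj_length"),
        ({"upj_throat_diameter": 0.007, "ureter_diameter": 0.006},
         "upj_throat_diameter <= ureter_diameter"),
        ({"ureter_diameter": 0.05}, "ureter_diameter <= pelvis_ap_diameter"),
        ({"inlet_patch_fraction": 0.0}, "inlet_patch_fraction"),
        ({"inlet_patch_fraction": 0.7}, "inlet_patch_fraction"),
    ],
)
def test_spec_invariants_are_enforced_by_name(fields, fragment):
    """Degenerate specs raise a validation error naming the invariant."""
    with pytest.raises(PhantomSpecError, match=fragment):
        make_phantom(PhantomSpec(**fields))


def test_phantom_is_closed_genus0_with_three_tag_groups():
    spec = PhantomSpec(pelvis_ap_diameter=0.030, upj_throat_diameter=0.001,
                       ureter_diameter=0.003, ureter_length=0.030)
    surf = make_phantom(spec)
    assert surf.is_watertight
    assert surf.euler_characteristic() == 2
    assert set(surf.tag_groups()) == {"inlet", "outlet", "wall"}
    assert surf.enclosed_volume() > 0  # outward orientation


def test_phantom_volume_close_to_analytic_primitives(stenotic_spec,
                                                     stenotic_surface):
    """Enclosed volume within 15% of the profile's solid of revolution."""
    analytic = stenotic_surface.profile.enclosed_volume()
    assert stenotic_surface.enclosed_volume() == pytest.approx(
        analytic, rel=0.15)


def test_phantom_profile_shape(stenotic_spec):
    """The radius profile converges to the waist then re-expands."""
    prof = phantom_profile(stenotic_spec)
    r_t = stenotic_spec.upj_throat_diameter / 2.0
    r_u = stenotic_spec.ureter_diameter / 2.0
    assert prof.r.min() == pytest.approx(r_t, rel=1e-6)
    assert prof.r[-1] == pytest.approx(r_u, rel=1e-6)
    assert prof.r.max() <= stenotic_spec.pelvis_ap_diameter / 2.0 + 1e-12
    # waist located between the pelvis and the ureter
    i_min = prof.r.argmin()
    assert 0 < i_min < len(prof.r) - 1


@pytest.mark.parametrize("seed", [None, 7])
def test_phantom_generation_is_deterministic(seed):
    spec = PhantomSpec(seed=seed)
    a = make_phantom(spec)
    b = make_phantom(spec)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.triangles, b.triangles)
    assert np.array_equal(a.face_tags, b.face_tags)


def test_seeded_jitter_changes_wall_but_keeps_watertightness():
    smooth = make_phantom(PhantomSpec())
    rough = make_phantom(PhantomSpec(seed=3))
    assert not np.array_equal(smooth.vertices, rough.vertices)
    assert rough.is_watertight
    # jitter is small: volumes agree to 1%
    assert rough.enclosed_volume() == pytest.approx(
        smooth.enclosed_volume(), rel=0.01)


class TestCylinder:
    def test_geometry_and_caps(self, cylinder_surface):
        assert cylinder_surface.is_watertight
        assert cylinder_surface.euler_characteristic() == 2
        cap = np.pi * CYL_RADIUS**2
        # flat polygonal caps approximate the disk area from below
        assert cylinder_surface.tag_area("inlet") == pytest.approx(cap,
                                                                   rel=0.03)
        assert cylinder_surface.tag_area("outlet") == pytest.approx(cap,
                                                                    rel=0.03)
        assert cylinder_surface.enclosed_volume() == pytest.approx(
            cap * CYL_LENGTH, rel=0.03)

    def test_refinement_increases_vertex_count_and_keeps_tags(self):
        coarse = make_cylinder(CYL_RADIUS, CYL_LENGTH, CYL_RADIUS / 3)
        fine = make_cylinder(CYL_RADIUS, CYL_LENGTH, CYL_RADIUS / 6)
        assert len(fine.vertices) > len(coarse.vertices)
        assert set(fine.tag_groups()) == set(coarse.tag_groups())

    @pytest.mark.parametrize("bad", [(-1e-3, 1e-2, 1e-3),
                                     (1e-3, 0.0, 1e-3),
                                     (1e-3, 1e-2, -1e-4)])
    def test_rejects_non_positive_dimensions(self, bad):
        with pytest.raises(PhantomSpecError):
            make_cylinder(*bad)


class TestMaskToSurface:
    def _cyl_mask(self, nz=40, nxy=41, r_vox=12):
        z, y, x = np.mgrid[0:nz, 0:nxy, 0:nxy]
        c = (nxy - 1) / 2
        return ((y - c) ** 2 + (x - c) ** 2 <= r_vox**2)

    def test_voxel_cylinder_volume_within_10pct(self):
        spacing = 0.5e-3
        mask = self._cyl_mask()
        surf = mask_to_surface(mask, spacing)
        assert surf.is_watertight
        r = 12 * spacing
        analytic = np.pi * r**2 * (40 * spacing)
        assert surf.enclosed_volume() == pytest.approx(analytic, rel=0.10)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            mask_to_surface(np.zeros((5, 5, 5), dtype=bool), 1e-3)

    def test_two_components_raise(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[6:9, 6:9, 6:9] = True
        with pytest.raises(ValueError, match="2 .*components"):
            mask_to_surface(mask, 1e-3)
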