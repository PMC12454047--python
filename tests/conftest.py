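"""Shared fixtures: geometries, meshes and (expensive) reference solves.

Flow solves are session-scoped so the oracle solutions are computed once
and shared by the unit and acceptance tests.
"""

import numpy as np
import pytest

from pelviflow import (
    FlowCase,
    FluidProperties,
    NAVIER_STOKES,
    PhantomSpec,
    STOKES,
    auto_probe_points,
    generate_volume_mesh,
    make_cylinder,
    make_phantom,
    pressure_sweep,
    solve_navier_stokes,
    solve_stokes,
)

# Hagen-Poiseuille oracle case: R = 1.5 mm, L = 10 mm, Q = 720 mL/day
CYL_RADIUS = 1.5e-3
CYL_LENGTH = 10e-3
Q_720 = 720e-6 / 86400.0


@pytest.fixture(scope="session")
def fluid():
    """Urine: 1050 kg/m^3, 0.001 Pa.s."""
    return FluidProperties()


@pytest.fixture(scope="session")
def cylinder_surface():
    return make_cylinder(CYL_RADIUS, CYL_LENGTH, CYL_RADIUS / 3.0)


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder_surface):
    return generate_volume_mesh(cylinder_surface, CYL_RADIUS / 3.0)


@pytest.fixture(scope="session")
def cylinder_stokes(cylinder_mesh, fluid):
    return solve_stokes(cylinder_mesh, fluid,
                        FlowCase(flow_rate=Q_720, model=STOKES))


@pytest.fixture(scope="session")
def cylinder_ns(cylinder_mesh, fluid):
    return solve_navier_stokes(
        cylinder_mesh, fluid, FlowCase(flow_rate=Q_720, model=NAVIER_STOKES))


@pytest.fixture(scope="session")
def stenotic_spec():
    """Severely obstructed phantom (1.5 mm UPJ waist) at desk-scale mesh."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def stenotic_surface(stenotic_spec):
    return make_phantom(stenotic_spec)


@pytest.fixture(scope="session")
def stenotic_mesh(stenotic_spec, stenotic_surface):
    return generate_volume_mesh(stenotic_surface,
                                stenotic_spec.mesh_edge_target)


@pytest.fixture(scope="session")
def stenotic_probes(stenotic_mesh):
    return auto_probe_points(stenotic_mesh)


@pytest.fixture(scope="session")
def stenotic_ns_sweep(stenotic_mesh, stenotic_probes, fluid):
    """Navier-Stokes ΔP(Q) sweep over 360/720/1440 mL/day."""
    return pressure_sweep(stenotic_mesh, fluid, stenotic_probes,
                          model=NAVIER_STOKES)


@pytest.fixture(scope="session")
def stenotic_stokes_sweep(stenotic_mesh, stenotic_probes, fluid):
    return pressure_sweep(stenotic_mesh, fluid, stenotic_probes,
                          model=STOKES)


@pytest.fixture(scope="session")
def open_upj_spec(stenotic_spec):
    """Non-obstructed phantom: the UPJ is as wide as the ureter."""
    return PhantomSpec(
        upj_throat_diameter=stenotic_spec.ureter_diameter,
        ureter_diameter=stenotic_spec.ureter_diameter,
    )


@pytest.fixture(scope="session")
def open_upj_mesh(open_upj_spec):
    surf = make_phantom(open_upj_spec)
    return generate_volume_mesh(surf, open_upj_spec.mesh_edge_target)


@pytest.fixture(scope="session")
def open_upj_stokes_sweep(open_upj_mesh, fluid):
    probes = auto_probe_points(open_upj_mesh)
    return pressure_sweep(open_upj_mesh, fluid, probes, model=STOKES)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
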