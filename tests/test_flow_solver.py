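"""Flow solver: Poiseuille oracle, conservation, linearity, limits, errors."""

import numpy as np
import pytest

from pelviflow import (
    FlowCase,
    FluidProperties,
    NAVIER_STOKES,
    STOKES,
    SolverError,
    boundary_flux,
    poiseuille_dp,
    reynolds_number,
    solve_navier_stokes,
    solve_stokes,
)
from pelviflow.meshing import VolumeMesh

from conftest import CYL_LENGTH, CYL_RADIUS, Q_720


def _axis_dp(sol, length):
    """ΔP over the central 80% of the pipe, extrapolated to full length."""
    p = sol.pressure_at(np.array([[0, 0, 0.1 * length],
                                  [0, 0, 0.9 * length]]))
    return (p[0] - p[1]) / 0.8


class TestStokesOnCylinder:
    def test_poiseuille_pressure_drop(self, cylinder_stokes, fluid):
        analytic = poiseuille_dp(fluid.dynamic_viscosity, CYL_LENGTH,
                                 Q_720, CYL_RADIUS)
        assert _axis_dp(cylinder_stokes, CYL_LENGTH) == pytest.approx(
            analytic, rel=0.05)

    def test_mass_conservation(self, cylinder_stokes):
        fin = boundary_flux(cylinder_stokes, "inlet")
        fout = boundary_flux(cylinder_stokes, "outlet")
        assert fout == pytest.approx(Q_720, rel=0.005)
        assert fin == pytest.approx(-Q_720, rel=0.005)
        assert abs(fin + fout) <= 0.005 * Q_720
        assert boundary_flux(cylinder_stokes, "wall") == pytest.approx(
            0.0, abs=1e-12 * Q_720 / CYL_RADIUS**2 * CYL_RADIUS**2)

    def test_no_slip_and_outlet_datum(self, cylinder_stokes):
        assert cylinder_stokes.max_wall_speed() == 0.0
        mean_u = Q_720 / (np.pi * CYL_RADIUS**2)
        dp = _axis_dp(cylinder_stokes, CYL_LENGTH)
        assert abs(cylinder_stokes.mean_outlet_pressure()) <= 0.01 * dp
        # plug accelerates to the parabolic profile: centreline ~ 2 * mean
        vc = cylinder_stokes.velocity_at(
            np.array([[0, 0, 0.8 * CYL_LENGTH]]))[0]
        assert vc[2] == pytest.approx(2.0 * mean_u, rel=0.1)

    def test_linearity_in_flow_rate(self, cylinder_mesh, cylinder_stokes,
                                    fluid):
        """The Stokes solution scales exactly with Q."""
        sol2 = solve_stokes(cylinder_mesh, fluid,
                            FlowCase(flow_rate=2 * Q_720, model=STOKES))
        scale = np.abs(sol2.velocity).max()
        dev = np.abs(sol2.velocity - 2.0 * cylinder_stokes.velocity).max()
        assert dev / scale <= 1e-8
        pdev = np.abs(sol2.pressure - 2.0 * cylinder_stokes.pressure).max()
        assert pdev / np.abs(sol2.pressure).max() <= 1e-8

    def test_no_checkerboard_pressure(self, cylinder_stokes):
        """Axial pressure decreases monotonically (inf-sup stability)."""
        z = np.linspace(0.05, 0.95, 19) * CYL_LENGTH
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        p = cylinder_stokes.pressure_at(pts)
        assert np.all(np.diff(p) < 0)


class TestNavierStokes:
    def test_low_re_limit_matches_stokes(self, cylinder_mesh, fluid):
        """Re <= 0.1: the convective term is negligible (gap <= 1%)."""
        q = Q_720 / 40.0  # Re ~ 0.09
        assert reynolds_number(fluid, q, 2 * CYL_RADIUS) <= 0.1
        st = solve_stokes(cylinder_mesh, fluid,
                          FlowCase(flow_rate=q, model=STOKES))
        ns = solve_navier_stokes(cylinder_mesh, fluid,
                                 FlowCase(flow_rate=q, model=NAVIER_STOKES))
        assert _axis_dp(ns, CYL_LENGTH) == pytest.approx(
            _axis_dp(st, CYL_LENGTH), rel=0.01)

    def test_moderate_re_within_10pct_of_stokes(self, cylinder_stokes,
                                                cylinder_ns, fluid):
        """Developed pipe flow at Re~3.7 has no convective axial loss."""
        assert reynolds_number(fluid, Q_720, 2 * CYL_RADIUS) == \
            pytest.approx(3.7, abs=0.2)
        assert _axis_dp(cylinder_ns, CYL_LENGTH) == pytest.approx(
            _axis_dp(cylinder_stokes, CYL_LENGTH), rel=0.10)

    def test_converged_residual_and_conservation(self, cylinder_ns):
        assert cylinder_ns.residual <= 1e-8
        assert 1 <= cylinder_ns.iterations <= 50
        assert boundary_flux(cylinder_ns, "outlet") == pytest.approx(
            Q_720, rel=0.005)


class TestReynolds:
    @pytest.mark.parametrize(("q_ml_day", "expected"),
                             [(1440.0, 7.43), (360.0, 1.86)])
    def test_duct_values(self, fluid, q_ml_day, expected):
        q = q_ml_day * 1e-6 / 86400.0
        assert reynolds_number(fluid, q, 3e-3) == pytest.approx(expected,
                                                                rel=0.01)

    def test_proportionality(self, fluid):
        assert reynolds_number(fluid, 2e-9, 3e-3) == pytest.approx(
            2 * reynolds_number(fluid, 1e-9, 3e-3), rel=1e-12)

    def test_rejects_non_positive(self, fluid):
        with pytest.raises(ValueError):
            reynolds_number(fluid, 0.0, 3e-3)


class TestContracts:
    def test_case_validation(self):
        with pytest.raises(ValueError):
            FlowCase(flow_rate=0.0)
        with pytest.raises(ValueError):
            FlowCase(flow_rate=1e-9, model="potential")
        with pytest.raises(ValueError):
            FlowCase(flow_rate=1e-9, inlet_tags={"inlet": 0.5})

    def test_fluid_validation(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)

    def test_missing_outlet_is_reported(self, cylinder_mesh, fluid):
        tags = np.where(cylinder_mesh.boundary_tags == "outlet", "wall",
                        cylinder_mesh.boundary_tags)
        broken = VolumeMesh(cylinder_mesh.vertices, cylinder_mesh.tets,
                            cylinder_mesh.boundary_faces, tags)
        with pytest.raises(SolverError, match="outlet"):
            solve_stokes(broken, fluid, FlowCase(flow_rate=Q_720))

    def test_missing_inlet_is_reported(self, cylinder_mesh, fluid):
        tags = np.where(cylinder_mesh.boundary_tags == "inlet", "wall",
                        cylinder_mesh.boundary_tags)
        broken = VolumeMesh(cylinder_mesh.vertices, cylinder_mesh.tets,
                            cylinder_mesh.boundary_faces, tags)
        with pytest.raises(SolverError, match="inlet"):
            solve_stokes(broken, fluid, FlowCase(flow_rate=Q_720))

    def test_unknown_flux_tag(self, cylinder_stokes):
        with pytest.raises(SolverError, match="unknown boundary tag"):
            boundary_flux(cylinder_stokes, "nephrostomy")

    def test_probing_outside_mesh_fails(self, cylinder_stokes):
        with pytest.raises(SolverError, match="outside"):
            cylinder_stokes.pressure_at(np.array([[0.0, 0.0, -0.05]]))
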