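"""Closed-form oracles and grid-convergence studies for the flow solver.

The laminar-pipe (Hagen–Poiseuille) limit of the momentum balance gives an
exact pressure drop for a straight circular duct, which anchors the solver
at desk scale; grid-convergence studies justify working far below the
cell counts a commercial solver would use on patient geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshing import SurfaceMesh, generate_volume_mesh
from .phantoms import make_cylinder
from .flow_solver import (
    NAVIER_STOKES,
    STOKES,
    FlowCase,
    FluidProperties,
    _facet_mean_p1,
    solve_navier_stokes,
    solve_stokes,
)


def poiseuille_dp(mu: float, length: float, flow_rate: float,
                  radius: float) -> float:
    """Hagen–Poiseuille pressure drop 8*mu*L*Q/(pi*R^4) for a circular pipe."""
    if min(mu, length, flow_rate, radius) <= 0:
        raise ValueError("all arguments must be positive")
    return 8.0 * mu * length * flow_rate / (np.pi * radius**4)


@dataclass
class OracleResult:
    """Analytic-vs-computed comparison for one oracle case."""

    analytic_value: float    # Pa
    computed_value: float    # Pa
    relative_error: float    # |computed - analytic| / analytic
    mesh_n_cells: int


def verify_poiseuille(radius: float = 1.5e-3, length: float = 10e-3,
                      flow_rate: float = 720e-6 / 86400.0,
                      mesh_edge_target: float | None = None,
                      model: str = STOKES,
                      fluid: FluidProperties | None = None) -> OracleResult:
    """Solve pipe flow and compare the axial ΔP with the closed form.

    The computed pressure gradient is measured over the central 80% of the
    pipe (on the axis), excluding the entrance/exit regions the closed form
    ignores, and extrapolated to the full length.
    """
    if length < 6.0 * radius:
        raise ValueError(
            "length must be at least 6 radii so a fully developed core "
            "dominates the oracle comparison"
        )
    if mesh_edge_target is None:
        mesh_edge_target = radius / 3.0
    fluid = fluid or FluidProperties()

    surface = make_cylinder(radius, length, mesh_edge_target)
    mesh = generate_volume_mesh(surface, mesh_edge_target)
    case = FlowCase(flow_rate=flow_rate, model=model)
    if model == STOKES:
        sol = solve_stokes(mesh, fluid, case)
    elif model == NAVIER_STOKES:
        sol = solve_navier_stokes(mesh, fluid, case)
    else:
        raise ValueError(f"unknown model {model!r}")

    z0, z1 = 0.1 * length, 0.9 * length
    p = sol.pressure_at(np.array([[0.0, 0.0, z0], [0.0, 0.0, z1]]))
    computed = float((p[0] - p[1]) / (z1 - z0) * length)
    analytic = poiseuille_dp(fluid.dynamic_viscosity, length, flow_rate,
                             radius)
    return OracleResult(
        analytic_value=analytic,
        computed_value=computed,
        relative_error=abs(computed - analytic) / analytic,
        mesh_n_cells=mesh.n_cells,
    )


@dataclass
class GridConvergenceResult:
    """ΔP per refinement level and the 2%-gap convergence verdict."""

    table: pd.DataFrame      # columns: edge_target, n_cells, dp_pa
    converged: bool
    final_gap: float         # |dp[-1] - dp[-2]| / dp[-1]


def grid_convergence(surface: SurfaceMesh, edge_targets,
                     flow_rate: float, model: str = STOKES,
                     fluid: FluidProperties | None = None,
                     outlet_pressure: float = 0.0) -> GridConvergenceResult:
    """ΔP(inlet mean − outlet datum) across a refinement ladder.

    ``edge_targets`` must be strictly decreasing with at least 3 levels;
    the study is declared converged when the two finest levels agree
    within 2%.
    """
    edge_targets = np.asarray(edge_targets, dtype=float)
    if len(edge_targets) < 3:
        raise ValueError("at least 3 refinement levels are required")
    if np.any(np.diff(edge_targets) >= 0):
        raise ValueError("edge_targets must be strictly decreasing")
    fluid = fluid or FluidProperties()

    rows = []
    for h in edge_targets:
        mesh = generate_volume_mesh(surface, float(h))
        case = FlowCase(flow_rate=flow_rate, outlet_pressure=outlet_pressure,
                        model=model)
        sol = (solve_stokes(mesh, fluid, case) if model == STOKES
               else solve_navier_stokes(mesh, fluid, case))
        dp = _facet_mean_p1(mesh, sol.pressure, "inlet") - outlet_pressure
        rows.append({"edge_target": float(h), "n_cells": mesh.n_cells,
                     "dp_pa": float(dp)})

    table = pd.DataFrame(rows)
    dp = table["dp_pa"].to_numpy()
    gap = float(abs(dp[-1] - dp[-2]) / abs(dp[-1]))
    return GridConvergenceResult(table=table, converged=bool(gap <= 0.02),
                                 final_gap=gap)
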