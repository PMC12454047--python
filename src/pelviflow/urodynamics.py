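"""Clinical readout: probe pressures, ΔP(Q) sweeps, obstruction severity.

This module turns flow solutions into the quantities a urologist reads off
a pressure-flow study: renal pelvic pressure at probe points (relative to
the ureteral outlet datum), the pressure-difference-versus-flow-rate curve
over the physiological urine output band, a check that the pressure is
uniform throughout the pelvis chamber, and the dichotomous severity call —
does the pelvic pressure rise with urine flow (obstructive pattern) or not.

Flow rates are quoted in mL/day (daily urine output) and mL/min (the rates
imposed during a pressure-flow study); solves use SI m^3/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .meshing import VolumeMesh
from .flow_solver import (
    NAVIER_STOKES,
    STOKES,
    FlowCase,
    FlowSolution,
    FluidProperties,
    SolverError,
    solve_navier_stokes,
    solve_stokes,
)

FLOW_DEPENDENT_OBSTRUCTIVE = "flow_dependent_obstructive"
FLOW_INDEPENDENT = "flow_independent"

#: default physiological urine outputs swept (mL/day): 0.25-1.0 mL/min
DEFAULT_FLOW_RATES_ML_DAY = (360.0, 720.0, 1440.0)

#: default obstruction threshold on ΔP at the top of the physiological band
#: (Pa).  Derived from the lower edge of the reported poor-function band of
#: a single case — configurable, not a validated clinical cutoff.
DEFAULT_THRESHOLD_PA = 0.015


class SweepError(RuntimeError):
    """A solve inside a flow sweep failed; carries the failing flow rate."""


def flow_rate_convert(ml_per_day: float) -> tuple[float, float]:
    """Convert a daily urine output to (mL/min, m^3/s). Exact arithmetic."""
    if ml_per_day <= 0:
        raise ValueError("flow rate must be positive")
    return ml_per_day / 1440.0, ml_per_day * 1e-6 / 86400.0


@dataclass
class ProbeSet:
    """Interior probe points inside the pelvis region (meters)."""

    points: np.ndarray
    labels: list[str] = field(default_factory=lambda: ["1", "2", "3"])
    fallback: bool = False  # True when no enlarged pelvis region was found

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if len(self.labels) != len(self.points):
            self.labels = [str(i + 1) for i in range(len(self.points))]


def auto_probe_points(mesh: VolumeMesh, n_probes: int = 3) -> ProbeSet:
    """Place probe points automatically inside the pelvis chamber.

    The pelvis is identified as the half of the domain (along the principal
    axis) with the larger mean cross-sectional area; probes sit at the
    25/50/75% stations of that region's axial extent, snapped to the
    nearest interior cell centroid.  Degenerate geometries without an
    enlarged region (e.g. a straight tube) fall back to stations over the
    whole domain with ``fallback=True``.
    """
    vols = mesh.tet_volumes()
    cent = mesh.vertices[mesh.tets].mean(axis=1)
    mean = np.average(cent, axis=0, weights=vols)
    cov = np.cov((cent - mean).T, aweights=vols)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]

    t = (cent - mean) @ axis
    t0, t1 = t.min(), t.max()
    nbins = 24
    edges = np.linspace(t0, t1, nbins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, nbins - 1)
    bin_vol = np.bincount(idx, weights=vols, minlength=nbins)
    area = bin_vol / np.diff(edges)  # mean cross-section per axial bin

    lo_half = area[: nbins // 2].mean()
    hi_half = area[nbins // 2:].mean()
    ratio = max(lo_half, hi_half) / max(min(lo_half, hi_half), 1e-300)
    if ratio < 1.5:
        lo, hi, fallback = t0, t1, True
    else:
        fallback = False
        if lo_half > hi_half:
            lo, hi = t0, 0.5 * (t0 + t1)
        else:
            lo, hi = 0.5 * (t0 + t1), t1

    stations = lo + np.linspace(0.25, 0.75, n_probes) * (hi - lo)
    pts = []
    for s in stations:
        window = np.abs(t - s) <= 0.05 * (t1 - t0)
        if not window.any():
            window = np.abs(t - s) <= 0.15 * (t1 - t0)
        target = np.average(cent[window], axis=0, weights=vols[window])
        pts.append(cent[np.linalg.norm(cent - target, axis=1).argmin()])
    return ProbeSet(np.asarray(pts),
                    [str(i + 1) for i in range(n_probes)],
                    fallback=fallback)


def probe_pressure(solution: FlowSolution, probes: ProbeSet) -> np.ndarray:
    """Pressure at each probe point, relative to the outlet datum (Pa)."""
    p = solution.pressure_at(probes.points)
    return p - solution.case.outlet_pressure


@dataclass
class SweepResult:
    """ΔP(Q) table over a flow sweep plus pelvis-uniformity diagnostics."""

    flow_rates_ml_day: np.ndarray
    delta_p: np.ndarray                # Pa, mean probe pressure per Q
    per_probe_pressures: np.ndarray    # (nQ, n_probes) Pa
    uniformity: np.ndarray             # Pa, max pairwise probe spread per Q
    model: str
    probe_labels: list[str] = field(default_factory=list)
    probe_fallback: bool = False
    #: optional per-Q (vertex velocity, vertex pressure) fields for export
    fields: list | None = None
    #: optional per-Q solve diagnostics (residual, iterations, flux balance)
    solve_log: list | None = None

    @property
    def flow_rates_ml_min(self) -> np.ndarray:
        return self.flow_rates_ml_day / 1440.0

    @property
    def flow_rates_m3_s(self) -> np.ndarray:
        return self.flow_rates_ml_day * 1e-6 / 86400.0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "q_ml_day": self.flow_rates_ml_day,
            "q_ml_min": self.flow_rates_ml_min,
            "q_m3_s": self.flow_rates_m3_s,
            "dp_pa": self.delta_p,
        })
        for j, lab in enumerate(self.probe_labels
                                or [str(i + 1) for i in
                                    range(self.per_probe_pressures.shape[1])]):
            df[f"probe{lab}_pa"] = self.per_probe_pressures[:, j]
        df["uniformity_pa"] = self.uniformity
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def pressure_sweep(mesh: VolumeMesh, fluid: FluidProperties,
                   probes: ProbeSet,
                   flow_rates_ml_per_day=DEFAULT_FLOW_RATES_ML_DAY,
                   model: str = NAVIER_STOKES,
                   outlet_pressure: float = 0.0,
                   keep_fields: bool = False) -> SweepResult:
    """Solve the flow at each swept urine output and tabulate ΔP(Q).

    ΔP is the mean of the probe pressures relative to the outlet datum;
    uniformity is the maximum pairwise probe spread.  For the Stokes model
    the solution is computed once and rescaled (the Stokes operator is
    linear in Q, so the rescaling is exact); Navier–Stokes is solved per
    rate, warm-started from the previous rate.
    """
    rates = np.asarray(flow_rates_ml_per_day, dtype=float)
    if len(rates) < 1 or np.any(rates <= 0):
        raise ValueError("flow rates must be positive")
    if np.any(np.diff(rates) <= 0):
        raise ValueError("flow rates must be strictly increasing")

    from .flow_solver import boundary_flux

    def diag(sol, q):
        fout = boundary_flux(sol, sol.case.outlet_tag)
        return {"q_m3_s": q, "residual": sol.residual,
                "iterations": sol.iterations,
                "outlet_flux_error": abs(fout - q) / q}

    per_probe = []
    fields = [] if keep_fields else None
    log = []
    if model == STOKES:
        q_ref = flow_rate_convert(rates[0])[1]
        try:
            sol = solve_stokes(mesh, fluid, FlowCase(
                flow_rate=q_ref, outlet_pressure=outlet_pressure,
                model=STOKES))
        except SolverError as exc:
            raise SweepError(
                f"solve failed at {rates[0]:g} mL/day: {exc}") from exc
        base = probe_pressure(sol, probes)
        for q_ml_day in rates:
            s = q_ml_day / rates[0]  # exact Stokes linearity in Q
            per_probe.append(base * s)
            if keep_fields:
                fields.append((sol.vertex_velocity() * s,
                               sol.pressure * s))
            log.append(diag(sol, q_ref) | {"scaled_from_ml_day": rates[0]})
    elif model == NAVIER_STOKES:
        prev = None
        for q_ml_day in rates:
            q = flow_rate_convert(q_ml_day)[1]
            try:
                sol = solve_navier_stokes(
                    mesh, fluid,
                    FlowCase(flow_rate=q, outlet_pressure=outlet_pressure,
                             model=NAVIER_STOKES),
                    initial=prev)
            except SolverError as exc:
                raise SweepError(
                    f"solve failed at {q_ml_day:g} mL/day: {exc}") from exc
            per_probe.append(probe_pressure(sol, probes))
            if keep_fields:
                fields.append((sol.vertex_velocity(), sol.pressure.copy()))
            log.append(diag(sol, q))
            prev = sol
    else:
        raise ValueError(f"unknown model {model!r}")

    per_probe = np.asarray(per_probe)
    return SweepResult(
        flow_rates_ml_day=rates,
        delta_p=per_probe.mean(axis=1),
        per_probe_pressures=per_probe,
        uniformity=per_probe.max(axis=1) - per_probe.min(axis=1),
        model=model,
        probe_labels=list(probes.labels),
        probe_fallback=probes.fallback,
        fields=fields,
        solve_log=log,
    )


@dataclass
class SeverityReport:
    """Flow-dependence classification of UPJ obstruction severity."""

    pattern: str                     # FLOW_DEPENDENT_OBSTRUCTIVE | FLOW_INDEPENDENT
    delta_p_at_max_q: float          # Pa
    slope: float                     # Pa per (mL/min), least squares
    threshold_used: float            # Pa
    physiological_band: tuple        # (Q_min, Q_max) mL/day

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def classify_obstruction(sweep: SweepResult,
                         threshold_pa: float = DEFAULT_THRESHOLD_PA
                         ) -> SeverityReport:
    """Classify the ΔP(Q) pattern.

    Obstructive (flow-dependent) iff ΔP at the maximum swept urine output
    reaches the threshold AND ΔP is strictly increasing across the sweep;
    otherwise flow-independent.  The slope is a least-squares fit of ΔP
    against the flow rate in mL/min.
    """
    if threshold_pa <= 0:
        raise ValueError("threshold_pa must be positive")
    if len(sweep.flow_rates_ml_day) < 2:
        raise ValueError("sweep must cover at least 2 flow rates")

    dp = np.asarray(sweep.delta_p, dtype=float)
    increasing = bool(np.all(np.diff(dp) > 0))
    dependent = increasing and dp[-1] >= threshold_pa
    slope = float(np.polyfit(sweep.flow_rates_ml_min, dp, 1)[0])
    return SeverityReport(
        pattern=FLOW_DEPENDENT_OBSTRUCTIVE if dependent else FLOW_INDEPENDENT,
        delta_p_at_max_q=float(dp[-1]),
        slope=slope,
        threshold_used=float(threshold_pa),
        physiological_band=(float(sweep.flow_rates_ml_day[0]),
                            float(sweep.flow_rates_ml_day[-1])),
    )
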