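"""Clinical readout: conversions, probes, sweeps, severity classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelviflow import (
    FLOW_DEPENDENT_OBSTRUCTIVE,
    FLOW_INDEPENDENT,
    ProbeSet,
    SweepResult,
    auto_probe_points,
    classify_obstruction,
    flow_rate_convert,
    probe_pressure,
)


class TestFlowRateConvert:
    @pytest.mark.parametrize(("ml_day", "ml_min"),
                             [(360.0, 0.25), (1440.0, 1.0), (720.0, 0.5)])
    def test_daily_to_per_minute(self, ml_day, ml_min):
        assert flow_rate_convert(ml_day)[0] == pytest.approx(ml_min,
                                                             rel=1e-12)

    def test_si_conversion(self):
        assert flow_rate_convert(720.0)[1] == pytest.approx(8.3333e-9,
                                                            rel=1e-4)

    @given(st.floats(min_value=1e-3, max_value=1e5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_conversion_consistency(self, ml_day):
        ml_min, m3_s = flow_rate_convert(ml_day)
        assert ml_min * 1440.0 == pytest.approx(ml_day, rel=1e-12)
        assert m3_s * 86400.0 * 1e6 == pytest.approx(ml_day, rel=1e-12)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            flow_rate_convert(0.0)


class TestAutoProbes:
    def test_phantom_probes_in_pelvis(self, stenotic_mesh, stenotic_spec,
                                      stenotic_probes):
        assert len(stenotic_probes.points) == 3
        assert not stenotic_probes.fallback
        # pairwise distinct
        d = np.linalg.norm(
            stenotic_probes.points[:, None] - stenotic_probes.points[None],
            axis=-1)
        assert d[np.triu_indices(3, 1)].min() > 0
        # inside the pelvis chamber (first half of the axial extent)
        z = stenotic_probes.points[:, 2]
        z_mid = 0.5 * (stenotic_mesh.vertices[:, 2].min()
                       + stenotic_mesh.vertices[:, 2].max())
        assert np.all(z < z_mid)

    def test_cylinder_falls_back_with_warning(self, cylinder_mesh):
        probes = auto_probe_points(cylinder_mesh)
        assert probes.fallback
        assert len(probes.points) == 3

    def test_determinism(self, stenotic_mesh):
        a = auto_probe_points(stenotic_mesh)
        b = auto_probe_points(stenotic_mesh)
        assert np.array_equal(a.points, b.points)


class TestProbePressure:
    def test_outlet_adjacent_point_reads_zero(self, cylinder_stokes):
        from conftest import CYL_LENGTH
        p = probe_pressure(cylinder_stokes, ProbeSet(
            np.array([[0.0, 0.0, 0.999 * CYL_LENGTH]])))
        dp_scale = probe_pressure(cylinder_stokes, ProbeSet(
            np.array([[0.0, 0.0, 0.01 * CYL_LENGTH]])))[0]
        assert abs(p[0]) <= 0.02 * abs(dp_scale)

    def test_interpolation_is_exact_for_uniform_field(self, cylinder_stokes,
                                                      stenotic_probes,
                                                      cylinder_mesh):
        import copy

        sol = copy.copy(cylinder_stokes)
        sol.pressure = np.full(len(cylinder_mesh.vertices), 3.14)
        pts = ProbeSet(np.array([[0, 0, 0.3 * 10e-3],
                                 [0.5e-3, 0.2e-3, 0.7 * 10e-3]]))
        np.testing.assert_allclose(probe_pressure(sol, pts), 3.14,
                                   rtol=1e-12)


def _sweep(rates, dp):
    dp = np.asarray(dp, dtype=float)
    per_probe = np.repeat(dp[:, None], 3, axis=1)
    return SweepResult(flow_rates_ml_day=np.asarray(rates, float),
                       delta_p=dp, per_probe_pressures=per_probe,
                       uniformity=np.zeros(len(dp)), model="navier_stokes")


class TestClassification:
    def test_reported_obstructed_pattern(self):
        """ΔP rising 0.015→0.086 Pa across 360→1440 mL/day: obstructive."""
        rep = classify_obstruction(
            _sweep([360, 720, 1440], [0.015, 0.035, 0.086]))
        assert rep.pattern == FLOW_DEPENDENT_OBSTRUCTIVE
        assert rep.delta_p_at_max_q == pytest.approx(0.086)
        assert rep.slope > 0
        assert rep.physiological_band == (360.0, 1440.0)

    def test_flat_zero_pattern_is_flow_independent(self):
        rep = classify_obstruction(_sweep([360, 720, 1440], [0.0, 0.0, 0.0]))
        assert rep.pattern == FLOW_INDEPENDENT

    def test_boundary_case_below_threshold(self):
        rep = classify_obstruction(
            _sweep([360, 720, 1440], [0.014, 0.014, 0.014]),
            threshold_pa=0.015)
        assert rep.pattern == FLOW_INDEPENDENT

    def test_requires_two_rates(self):
        with pytest.raises(ValueError, match="2 flow rates"):
            classify_obstruction(_sweep([720], [0.05]))

    def test_invariant_to_intermediate_rates(self):
        """Adding intermediate flow rates cannot change the call."""
        coarse = classify_obstruction(_sweep([360, 1440], [0.02, 0.09]))
        fine = classify_obstruction(
            _sweep([360, 540, 720, 1080, 1440],
                   [0.02, 0.032, 0.045, 0.068, 0.09]))
        assert coarse.pattern == fine.pattern == FLOW_DEPENDENT_OBSTRUCTIVE


class TestStokesSweepScaling:
    def test_delta_p_proportional_to_q(self, stenotic_stokes_sweep):
        """One Stokes solve is reused by exact linear rescaling."""
        sw = stenotic_stokes_sweep
        ratio = sw.delta_p / sw.flow_rates_ml_day
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_monotone_and_positive(self, stenotic_stokes_sweep):
        assert np.all(stenotic_stokes_sweep.delta_p > 0)
        assert np.all(np.diff(stenotic_stokes_sweep.delta_p) > 0)

    def test_dataframe_schema(self, stenotic_stokes_sweep):
        df = stenotic_stokes_sweep.to_dataframe()
        assert list(df.columns[:4]) == ["q_ml_day", "q_ml_min", "q_m3_s",
                                        "dp_pa"]
        assert df.shape[0] == 3
        assert "uniformity_pa" in df.columns
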