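"""Validation oracles: closed-form Poiseuille values and ladder contracts."""

import pytest

from pelviflow import grid_convergence, poiseuille_dp, verify_poiseuille


class TestPoiseuilleClosedForm:
    def test_reference_value(self):
        """8 mu L Q / (pi R^4) for the standard oracle case is 0.0419 Pa."""
        dp = poiseuille_dp(mu=0.001, length=0.01, flow_rate=8.333e-9,
                           radius=1.5e-3)
        assert dp == pytest.approx(0.0419, abs=0.0002)

    def test_radius_fourth_power(self):
        base = poiseuille_dp(0.001, 0.01, 8.333e-9, 1.5e-3)
        assert poiseuille_dp(0.001, 0.01, 8.333e-9, 3.0e-3) == \
            pytest.approx(base / 16.0, rel=1e-12)

    def test_linearity_in_q(self):
        base = poiseuille_dp(0.001, 0.01, 8.333e-9, 1.5e-3)
        assert poiseuille_dp(0.001, 0.01, 2 * 8.333e-9, 1.5e-3) == \
            pytest.approx(2 * base, rel=1e-12)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            poiseuille_dp(0.0, 0.01, 1e-9, 1e-3)


class TestVerifyPoiseuilleContract:
    def test_short_pipe_precondition(self):
        with pytest.raises(ValueError, match="6 radii"):
            verify_poiseuille(radius=2e-3, length=5e-3)


class TestGridConvergenceContract:
    def test_requires_three_levels(self, cylinder_surface):
        with pytest.raises(ValueError, match="3 refinement levels"):
            grid_convergence(cylinder_surface, [1e-3, 5e-4],
                             flow_rate=8.33e-9)

    def test_requires_strictly_decreasing(self, cylinder_surface):
        with pytest.raises(ValueError, match="strictly decreasing"):
            grid_convergence(cylinder_surface, [1e-3, 1e-3, 5e-4],
                             flow_rate=8.33e-9)
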