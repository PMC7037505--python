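"""Replicator dynamics: expected payoffs, field, Jacobian, equilibria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evacgame import (
    FieldCoefficients,
    PayoffMatrix,
    StrategyState,
    compute_payoff_matrix,
    expected_payoffs,
    field_coefficients,
    find_equilibria,
    integrate_replicator,
    jacobian,
    replicator_field,
)

from conftest import draw_economics, draw_policy
from test_payoffs import econ_st, policy_st, unit


class TestExpectedPayoffs:
    def test_pure_counterpart_collapses_mixture(self, pm):
        ep = expected_payoffs(pm, StrategyState(0.3, 1.0))
        assert ep.UE1 == pytest.approx(pm.U11)
        assert ep.US1 == pytest.approx(pm.U21)

    def test_midpoint_mixture(self):
        pm = PayoffMatrix(4, 6, 0, 0, 0, 0, 0, 0)
        ep = expected_payoffs(pm, StrategyState(0.5, 0.5))
        assert ep.UE1 == pytest.approx(5.0)

    def test_matches_weighted_sum_oracle(self, pm):
        # independent dot-product evaluation of the six mixtures
        x, y = 0.3, 0.6
        U = np.array([[pm.U11, pm.U12], [pm.U21, pm.U22]])
        V = np.array([[pm.V11, pm.V12], [pm.V21, pm.V22]])
        wy = np.array([y, 1 - y])
        wx = np.array([x, 1 - x])
        ep = expected_payoffs(pm, StrategyState(x, y))
        assert ep.UE1 == pytest.approx(U[0] @ wy)
        assert ep.US1 == pytest.approx(U[1] @ wy)
        assert ep.Ubar1 == pytest.approx(wx @ U @ wy)
        assert ep.UE2 == pytest.approx(wx @ V[:, 0])
        assert ep.US2 == pytest.approx(wx @ V[:, 1])
        assert ep.Ubar2 == pytest.approx(wx @ V @ wy)


class TestFieldCoefficients:
    def test_reference_values(self, coeffs):
        assert coeffs.A1 == pytest.approx(-1.89, abs=1e-12)
        assert coeffs.A2 == pytest.approx(1.36, abs=1e-12)

    def test_symmetric_economics(self, coeffs):
        assert coeffs.A1 == coeffs.B1
        assert coeffs.A2 == coeffs.B2

    def test_slope_vanishes_when_both_terms_cancel(self, econ):
        # beta=0 kills the D term; (1-theta)*epsilon == eta kills the E term
        pol = draw_policy(np.random.default_rng(0)).replace(
            beta=0.0, theta=0.2, epsilon=0.5, eta=0.4
        )
        c = field_coefficients(econ, econ, pol)
        assert c.A1 == pytest.approx(0.0, abs=1e-14)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(e1=econ_st, e2=econ_st, pol=policy_st, x=unit, y=unit)
    def test_affine_advantage_identity(self, e1, e2, pol, x, y):
        # A1*y + A2 must equal UE1 - US1 from the payoff cells (and B for G2):
        # this pins the bracket grouping E*[(1-theta)*eps - eta] in the slope.
        pm = compute_payoff_matrix(e1, e2, pol)
        c = field_coefficients(e1, e2, pol)
        ep = expected_payoffs(pm, StrategyState(x, y))
        assert math.isclose(c.A1 * y + c.A2, ep.UE1 - ep.US1, rel_tol=1e-10, abs_tol=1e-10)
        assert math.isclose(c.B1 * x + c.B2, ep.UE2 - ep.US2, rel_tol=1e-10, abs_tol=1e-10)


class TestReplicatorField:
    @pytest.mark.parametrize("x", [0.0, 1.0])
    def test_boundary_absorbing(self, coeffs, x):
        for y in (0.0, 0.37, 1.0):
            f, _ = replicator_field(coeffs, StrategyState(x, y))
            assert f == 0.0

    def test_reference_value_at_center(self, coeffs):
        f, g = replicator_field(coeffs, StrategyState(0.5, 0.5))
        assert f == pytest.approx(0.25 * 0.415)  # 0.25 * (A1*0.5 + A2)
        assert g == pytest.approx(f)

    def test_payoff_form_equals_coefficient_form(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            e1, e2, pol = draw_economics(rng), draw_economics(rng), draw_policy(rng)
            x, y = rng.uniform(0, 1, size=2)
            pm = compute_payoff_matrix(e1, e2, pol)
            c = field_coefficients(e1, e2, pol)
            ep = expected_payoffs(pm, StrategyState(x, y))
            f, g = replicator_field(c, StrategyState(x, y))
            assert f == pytest.approx(x * (1 - x) * (ep.UE1 - ep.US1), abs=1e-10)
            assert g == pytest.approx(y * (1 - y) * (ep.UE2 - ep.US2), abs=1e-10)


class TestJacobian:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(5)
        h = 1e-6
        for _ in range(100):
            c = field_coefficients(draw_economics(rng), draw_economics(rng), draw_policy(rng))
            x, y = rng.uniform(2 * h, 1 - 2 * h, size=2)
            J = jacobian(c, StrategyState(x, y))

            def f(xx, yy):
                return np.array(replicator_field(c, StrategyState(xx, yy)))

            Jfd = np.column_stack(
                [(f(x + h, y) - f(x - h, y)) / (2 * h), (f(x, y + h) - f(x, y - h)) / (2 * h)]
            )
            assert np.allclose(J, Jfd, atol=1e-5, rtol=0)

    def test_origin_is_diagonal(self, coeffs):
        J = jacobian(coeffs, StrategyState(0.0, 0.0))
        assert J[0, 1] == 0.0 and J[1, 0] == 0.0
        assert J[0, 0] == pytest.approx(coeffs.A2)
        assert J[1, 1] == pytest.approx(coeffs.B2)
        assert np.linalg.det(J) == pytest.approx(coeffs.A2 * coeffs.B2)
        assert np.trace(J) == pytest.approx(coeffs.A2 + coeffs.B2)

    def test_interior_diagonal_vanishes(self, coeffs):
        xs, ys = -coeffs.B2 / coeffs.B1, -coeffs.A2 / coeffs.A1
        J = jacobian(coeffs, StrategyState(xs, ys))
        assert abs(J[0, 0]) < 1e-12 and abs(J[1, 1]) < 1e-12


class TestFindEquilibria:
    def test_reference_profile_has_five_points(self, coeffs):
        rep = find_equilibria(coeffs)
        assert len(rep.points) == 5
        assert rep.interior_exists
        interior = rep.points[-1]
        assert interior.x == pytest.approx(-coeffs.B2 / coeffs.B1)
        assert interior.x == pytest.approx(0.7195767, abs=1e-6)
        assert interior.trJ == pytest.approx(0.0, abs=1e-12)
        # interior diagonal is zero, so Det = -x(1-x)y(1-y)A1B1 < 0: saddle
        assert interior.label == "saddle"

    def test_reference_profile_corner_labels(self, coeffs):
        rep = find_equilibria(coeffs)
        labels = {(p.x, p.y): p.label for p in rep.points}
        assert labels[(0.0, 0.0)] == "unstable_node"
        # miscoordination corners attract: evacuating is worth it exactly
        # when the other group stays (A2 > 0 > A1 + A2 under the defaults)
        assert labels[(0.0, 1.0)] == "stable_node"
        assert labels[(1.0, 0.0)] == "stable_node"
        assert labels[(1.0, 1.0)] == "unstable_node"

    def test_origin_unstable_when_both_intercepts_positive(self):
        rep = find_equilibria(FieldCoefficients(-3.0, 1.0, -4.0, 2.0))
        by_xy = {(p.x, p.y): p for p in rep.points}
        assert by_xy[(0.0, 0.0)].label == "unstable_node"

    def test_full_evacuation_stable_when_advantage_persists(self):
        # A1+A2 > 0 and B1+B2 > 0: evacuating still pays when everyone
        # evacuates, so (1,1) attracts (J = diag(-(A1+A2), -(B1+B2)))
        rep = find_equilibria(FieldCoefficients(-1.0, 2.0, -0.5, 1.0))
        by_xy = {(p.x, p.y): p for p in rep.points}
        assert by_xy[(1.0, 1.0)].label == "stable_node"
        assert by_xy[(1.0, 1.0)].detJ == pytest.approx(0.5)
        assert by_xy[(1.0, 1.0)].trJ == pytest.approx(-1.5)

    def test_zero_slope_reports_absent_interior(self):
        rep = find_equilibria(FieldCoefficients(0.0, 1.0, -2.0, 1.0))
        assert len(rep.points) == 4
        assert not rep.interior_exists
        assert rep.interior_reason == "zero_slope"

    def test_exterior_candidate_reports_absent_interior(self):
        # -A2/A1 = 2 lies outside (0,1)
        rep = find_equilibria(FieldCoefficients(-1.0, 2.0, -1.0, 0.5))
        assert len(rep.points) == 4
        assert rep.interior_reason == "outside_unit_square"

    def test_report_serializes(self, coeffs):
        import json

        d = find_equilibria(coeffs).as_dict()
        assert json.loads(json.dumps(d))["interior_exists"] is True


class TestIntegrate:
    def test_corner_is_constant(self, coeffs):
        traj = integrate_replicator(coeffs, 1.0, 0.0, horizon=1.0, step=0.01)
        assert np.all(traj[:, 1] == 1.0) and np.all(traj[:, 2] == 0.0)

    def test_default_profile_diagonal_attracts_to_interior(self, coeffs):
        # symmetric coefficients keep the flow on the diagonal, where the
        # interior point is the attractor (A1 < 0 < A2)
        traj = integrate_replicator(coeffs, 0.99, 0.99, horizon=200.0, step=0.01)
        xs = -coeffs.B2 / coeffs.B1
        assert traj[-1, 1] == pytest.approx(xs, abs=1e-6)
        assert traj[-1, 2] == pytest.approx(xs, abs=1e-6)

    def test_transverse_perturbation_leaves_interior(self, coeffs):
        # the interior is a saddle: an off-diagonal start escapes it
        xs = -coeffs.B2 / coeffs.B1
        traj = integrate_replicator(coeffs, xs + 0.01, xs - 0.01, horizon=300.0, step=0.01)
        end = traj[-1, 1:]
        assert np.hypot(end[0] - xs, end[1] - xs) > 0.1

    def test_time_reversal_diverges_from_attractor(self, coeffs):
        # forward flow from (0.05, 0.95) approaches the stable corner (0,1);
        # with the field negated the same start moves away from it
        fwd = integrate_replicator(coeffs, 0.05, 0.95, horizon=30.0, step=0.01)
        rev_coeffs = FieldCoefficients(-coeffs.A1, -coeffs.A2, -coeffs.B1, -coeffs.B2)
        rev = integrate_replicator(rev_coeffs, 0.05, 0.95, horizon=30.0, step=0.01)

        def dist(p):
            return np.hypot(p[1] - 0.0, p[2] - 1.0)

        assert dist(fwd[-1]) < dist(fwd[0])
        assert dist(rev[-1]) > dist(rev[0])

    def test_trajectory_stays_in_unit_square(self, coeffs):
        traj = integrate_replicator(coeffs, 0.001, 0.999, horizon=50.0, step=0.05)
        assert np.all(traj[:, 1:] >= 0.0) and np.all(traj[:, 1:] <= 1.0)

    def test_invalid_start_rejected(self, coeffs):
        with pytest.raises(ValueError):
            integrate_replicator(coeffs, 1.2, 0.5)
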