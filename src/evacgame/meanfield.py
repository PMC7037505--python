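"""Mean-field replicator dynamics and equilibrium stability analysis.

Let x be the fraction of Group 1 choosing Evacuate and y the same for
Group 2.  Each group's evacuation advantage is affine in the other
group's evacuation share,

    UE1 - US1 = A1*y + A2,      UE2 - US2 = B1*x + B2,

with coefficients assembled directly from the economics and policy
parameters.  The replicator system is

    dx/dt = f(x, y) = x(1-x)(A1*y + A2)
    dy/dt = g(x, y) = y(1-y)(B1*x + B2)

The four corners of the unit square are always fixed points; an interior
fixed point (x*, y*) = (-B2/B1, -A2/A1) exists when both ratios fall
strictly inside (0, 1).  Stability is read off the Jacobian

    J = [ (1-2x)(A1*y + A2)    x(1-x)*A1          ]
        [ y(1-y)*B1            (1-2y)(B1*x + B2)  ]

whose diagonal vanishes at the interior point, so the interior trace is
exactly zero and the interior point can never be an attractor (it is a
saddle when A1*B1 > 0, a centre candidate when A1*B1 < 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .payoffs import GroupEconomics, PayoffMatrix, PolicyParams

__all__ = [
    "StrategyState",
    "FieldCoefficients",
    "ExpectedPayoffs",
    "Equilibrium",
    "EquilibriumReport",
    "expected_payoffs",
    "field_coefficients",
    "replicator_field",
    "jacobian",
    "find_equilibria",
    "integrate_replicator",
]

# Relative tolerance for the Det/Tr sign classification and for the
# strict-interiority margin of the interior fixed point.
_CLASSIFY_RTOL = 1e-9


@dataclass(frozen=True)
class StrategyState:
    """Population state: evacuating fractions (x, y) of the two groups."""

    x: float
    y: float

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y)):
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a finite real in [0, 1], got {v!r}")


@dataclass(frozen=True)
class FieldCoefficients:
    """Slope/intercept of each group's evacuation advantage.

    ``A1*y + A2`` equals Group 1's advantage UE1 - US1; ``B1*x + B2``
    equals Group 2's UE2 - US2.
    """

    A1: float
    A2: float
    B1: float
    B2: float

    def scale(self) -> float:
        """Magnitude scale used for tolerance-based sign classification."""
        return max(abs(self.A1), abs(self.A2), abs(self.B1), abs(self.B2), 1.0)


class ExpectedPayoffs(NamedTuple):
    UE1: float
    US1: float
    Ubar1: float
    UE2: float
    US2: float
    Ubar2: float


def expected_payoffs(pm: PayoffMatrix, state: StrategyState) -> ExpectedPayoffs:
    """Expected payoffs of each pure strategy and each group's average.

    UE1 = y*U11 + (1-y)*U12 and US1 = y*U21 + (1-y)*U22 mix Group 1's
    row against Group 2's strategy distribution; Ubar1 = x*UE1 +
    (1-x)*US1 averages over Group 1's own mixture.  Symmetrically, an
    evacuating Group 2 member meets an evacuating counterpart with
    probability x (cell V11) and a staying one otherwise (cell V21), so
    UE2 = x*V11 + (1-x)*V21 and US2 = x*V12 + (1-x)*V22 — the pairing
    under which B1*x + B2 reproduces UE2 - US2 exactly.
    """
    x, y = state.x, state.y
    UE1 = y * pm.U11 + (1.0 - y) * pm.U12
    US1 = y * pm.U21 + (1.0 - y) * pm.U22
    Ubar1 = x * UE1 + (1.0 - x) * US1
    UE2 = x * pm.V11 + (1.0 - x) * pm.V21
    US2 = x * pm.V12 + (1.0 - x) * pm.V22
    Ubar2 = y * UE2 + (1.0 - y) * US2
    return ExpectedPayoffs(UE1, US1, Ubar1, UE2, US2, Ubar2)


def field_coefficients(
    econ1: GroupEconomics,
    econ2: GroupEconomics,
    policy: PolicyParams,
) -> FieldCoefficients:
    """Affine coefficients of the evacuation advantage of each group.

    A1 = (delta-1)*beta*D1 + E1*[(1-theta)*epsilon - eta]
    A2 = alpha*P1 - alpha*(C1-C1') - (1-delta)*(1-beta)*D1 + eta*E1

    and B1, B2 analogously with Group 2's economics.  The bracket in A1
    groups the whole stay-cost term ``(1-theta)*epsilon - eta`` under E1:
    that is the unique reading for which ``A1*y + A2`` reproduces
    UE1 - US1 expanded from the payoff cells.
    """
    a, b, th = policy.alpha, policy.beta, policy.theta
    d, eps, eta = policy.delta, policy.epsilon, policy.eta

    def _pair(e: GroupEconomics) -> tuple[float, float]:
        slope = (d - 1.0) * b * e.D + e.E * ((1.0 - th) * eps - eta)
        intercept = (
            a * e.P - a * (e.C - e.Cprime) - (1.0 - d) * (1.0 - b) * e.D + eta * e.E
        )
        return slope, intercept

    A1, A2 = _pair(econ1)
    B1, B2 = _pair(econ2)
    return FieldCoefficients(A1, A2, B1, B2)


def replicator_field(
    coeffs: FieldCoefficients, state: StrategyState
) -> tuple[float, float]:
    """Evaluate (dx/dt, dy/dt) of the replicator system at a state."""
    x, y = state.x, state.y
    f = x * (1.0 - x) * (coeffs.A1 * y + coeffs.A2)
    g = y * (1.0 - y) * (coeffs.B1 * x + coeffs.B2)
    return f, g


def jacobian(coeffs: FieldCoefficients, state: StrategyState) -> np.ndarray:
    """2x2 Jacobian of (f, g) with respect to (x, y).

    The off-diagonal entries are the exact partials x(1-x)*A1 and
    y(1-y)*B1 (verified against central finite differences in the test
    suite).
    """
    x, y = state.x, state.y
    return np.array(
        [
            [(1.0 - 2.0 * x) * (coeffs.A1 * y + coeffs.A2), x * (1.0 - x) * coeffs.A1],
            [y * (1.0 - y) * coeffs.B1, (1.0 - 2.0 * y) * (coeffs.B1 * x + coeffs.B2)],
        ]
    )


@dataclass(frozen=True)
class Equilibrium:
    x: float
    y: float
    detJ: float
    trJ: float
    label: str

    def as_dict(self) -> dict[str, float | str]:
        return {
            "x": self.x,
            "y": self.y,
            "detJ": self.detJ,
            "trJ": self.trJ,
            "label": self.label,
        }


@dataclass(frozen=True)
class EquilibriumReport:
    """Fixed points of the replicator system with stability labels."""

    points: tuple[Equilibrium, ...]
    interior_exists: bool
    interior_reason: str | None = None

    def as_dict(self) -> dict:
        return {
            "points": [p.as_dict() for p in self.points],
            "interior_exists": self.interior_exists,
            "interior_reason": self.interior_reason,
        }


def _classify(detJ: float, trJ: float, scale: float) -> str:
    # scale ~ coefficient magnitude squared, the natural size of Det J.
    tol = _CLASSIFY_RTOL * scale
    if abs(detJ) < tol:
        return "degenerate"
    if detJ < 0.0:
        return "saddle"
    if abs(trJ) < tol:
        return "center"
    return "stable_node" if trJ < 0.0 else "unstable_node"


def find_equilibria(coeffs: FieldCoefficients) -> EquilibriumReport:
    """Enumerate fixed points and classify them by the signs of Det/Tr J.

    The four corners are always returned.  The interior candidate
    (x*, y*) = (-B2/B1, -A2/A1) is included only when both coordinates
    are strictly inside (0, 1) (margin 1e-9); when a slope vanishes the
    interior is reported absent with a reason code rather than raising.
    Labels: saddle (Det<0), stable_node (Det>0, Tr<0), unstable_node
    (Det>0, Tr>0), center (Det>0, Tr~0), degenerate (Det~0).
    """
    scale = coeffs.scale() ** 2
    points: list[Equilibrium] = []
    for cx, cy in ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)):
        J = jacobian(coeffs, StrategyState(cx, cy))
        detJ = float(np.linalg.det(J))
        trJ = float(np.trace(J))
        points.append(Equilibrium(cx, cy, detJ, trJ, _classify(detJ, trJ, scale)))

    interior_exists = False
    reason: str | None = None
    if coeffs.A1 == 0.0 or coeffs.B1 == 0.0:
        reason = "zero_slope"
    else:
        xs = -coeffs.B2 / coeffs.B1
        ys = -coeffs.A2 / coeffs.A1
        margin = _CLASSIFY_RTOL
        if margin < xs < 1.0 - margin and margin < ys < 1.0 - margin:
            J = jacobian(coeffs, StrategyState(xs, ys))
            detJ = float(np.linalg.det(J))
            trJ = float(np.trace(J))
            points.append(Equilibrium(xs, ys, detJ, trJ, _classify(detJ, trJ, scale)))
            interior_exists = True
        else:
            reason = "outside_unit_square"
    return EquilibriumReport(tuple(points), interior_exists, reason)


def integrate_replicator(
    coeffs: FieldCoefficients,
    x0: float,
    y0: float,
    horizon: float = 50.0,
    step: float = 0.01,
) -> np.ndarray:
    """Integrate the replicator system with fixed-step classical RK4.

    Returns an array of shape (n_steps + 1, 3) with columns (t, x, y).
    The flow leaves the unit square invariant, so only accumulated
    round-off is clipped back onto [0, 1]; a state drifting further out
    or turning non-finite aborts with a diagnostic.
    """
    if not (0.0 <= x0 <= 1.0 and 0.0 <= y0 <= 1.0):
        raise ValueError(f"initial state must lie in [0,1]^2, got ({x0!r}, {y0!r})")
    if step <= 0.0 or horizon <= 0.0:
        raise ValueError("horizon and step must be positive")

    def _field(x: float, y: float) -> tuple[float, float]:
        return (
            x * (1.0 - x) * (coeffs.A1 * y + coeffs.A2),
            y * (1.0 - y) * (coeffs.B1 * x + coeffs.B2),
        )

    n = int(round(horizon / step))
    out = np.empty((n + 1, 3))
    x, y = float(x0), float(y0)
    out[0] = (0.0, x, y)
    for i in range(1, n + 1):
        k1 = _field(x, y)
        k2 = _field(x + 0.5 * step * k1[0], y + 0.5 * step * k1[1])
        k3 = _field(x + 0.5 * step * k2[0], y + 0.5 * step * k2[1])
        k4 = _field(x + step * k3[0], y + step * k3[1])
        x += step * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0]) / 6.0
        y += step * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1]) / 6.0
        if not (math.isfinite(x) and math.isfinite(y)):
            raise RuntimeError(
                f"integration aborted: non-finite state at t={i * step:.6g}"
            )
        # invariant square: anything beyond round-off is an integrator bug
        if x < -1e-9 or x > 1.0 + 1e-9 or y < -1e-9 or y > 1.0 + 1e-9:
            raise RuntimeError(
                f"integration aborted: state left [0,1]^2 at t={i * step:.6g}"
            )
        x = min(max(x, 0.0), 1.0)
        y = min(max(y, 0.0), 1.0)
        out[i] = (i * step, x, y)
    return out
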