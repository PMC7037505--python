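"""Two-player payoff matrix for the evacuate-or-stay game.

Two groups of residents under a typhoon warning each choose Evacuate or
Stay.  The government is not a strategic player: it enters only through
policy coefficients that reduce costs or losses.  Each cell of the 2x2
bimatrix is an expected asset balance:

* both evacuate:          ``P - alpha*(C - C') - (1-delta)*D``
* evacuate vs stay:       the evacuator's process cost is further cut by
  the resources the stayer frees up, ``(1-delta)*(1-beta)*D``; the stayer
  keeps ``(1-alpha)*P`` and pays a stay cost ``epsilon*(1-theta)*E``
* both stay:              ``(1-alpha)*P - eta*E``

``P`` is total (material + life) assets, ``C`` the fixed assets abandoned
on evacuation, ``C'`` the part of that loss recovered through government
action, ``D`` the evacuation-process cost and ``E`` the cost of staying.
All quantities live on one abstract value scale; payoffs are single-shot
per game round, with no discounting.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolicyParams",
    "GroupEconomics",
    "PayoffMatrix",
    "compute_payoff_matrix",
]


def _check_unit_interval(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValueError(f"{name} must be a real number, got {value!r}")
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a finite real in [0, 1], got {value!r}")


def _check_nonnegative(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValueError(f"{name} must be a real number, got {value!r}")
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class PolicyParams:
    """Risk estimate and government policy coefficients, all in [0, 1].

    Parameters
    ----------
    alpha
        Residents' estimate of the probability that the typhoon strikes.
    beta
        Evacuation-cost reduction rate when the counterpart stays home and
        frees up road/shelter resources.
    theta
        Stay-cost reduction rate when the counterpart evacuates and frees
        up emergency supplies.
    delta
        Government coefficient cutting the evacuation-process cost
        (transport organisation, traffic channelling).
    epsilon
        Government coefficient multiplying the stay cost when exactly one
        party stays (both groups guaranteed).
    eta
        Government coefficient multiplying the stay cost when both stay
        (maximum-effort supply guarantee).

    Defaults are the documented base profile: the survey-elicited strike
    probability together with the midpoint of each policy grid.
    """

    alpha: float = 0.5
    beta: float = 0.45
    theta: float = 0.45
    delta: float = 0.3
    epsilon: float = 0.7
    eta: float = 0.7

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_unit_interval(f.name, getattr(self, f.name))

    def replace(self, **changes: float) -> "PolicyParams":
        """Return a copy with the named coefficients replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class GroupEconomics:
    """Per-group asset and cost quantities, on a common value scale.

    ``P`` total assets; ``C`` fixed assets abandoned when evacuating;
    ``Cprime`` the abandoned-asset loss recovered by government action
    (cannot exceed ``C``); ``D`` evacuation-process cost; ``E`` stay cost.
    Defaults are the expert-elicited reference values.
    """

    P: float = 10.0
    C: float = 8.0
    Cprime: float = 1.0
    D: float = 4.0
    E: float = 2.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_nonnegative(f.name, getattr(self, f.name))
        if self.Cprime > self.C:
            raise ValueError(
                f"Cprime must not exceed C (recovered loss cannot exceed "
                f"abandoned assets); got Cprime={self.Cprime!r}, C={self.C!r}"
            )

    def replace(self, **changes: float) -> "GroupEconomics":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PayoffMatrix:
    """The eight cell payoffs of the bimatrix game.

    ``U`` entries pay the row player (Group 1), ``V`` entries the column
    player (Group 2).  Strategy index 1 = Evacuate, 2 = Stay; the first
    subscript is Group 1's strategy, the second Group 2's.
    """

    U11: float
    U12: float
    U21: float
    U22: float
    V11: float
    V12: float
    V21: float
    V22: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        """Flat 8-field record (CSV row / JSON object) with keys U11..V22."""
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def row_cells(self, group: int = 1) -> np.ndarray:
        """Row-player cell lookup table for a node of the given group.

        Returns a 2x2 array ``T`` with ``T[s_i, s_j]`` the payoff of a
        group-``group`` node playing strategy code ``s_i`` against a
        neighbour playing ``s_j``, where code 1 = Evacuate, 0 = Stay.
        For group 2 the table is the transposed ``V`` block, so the node
        is always read in its own role of the bimatrix.
        """
        if group == 1:
            return np.array([[self.U22, self.U21], [self.U12, self.U11]], dtype=float)
        if group == 2:
            return np.array([[self.V22, self.V12], [self.V21, self.V11]], dtype=float)
        raise ValueError(f"group must be 1 or 2, got {group!r}")

    def is_symmetric(self, rtol: float = 1e-12, atol: float = 1e-12) -> bool:
        """True when U_ab == V_ba for all cells (identical group economics)."""
        return bool(
            np.allclose(
                [self.U11, self.U12, self.U21, self.U22],
                [self.V11, self.V21, self.V12, self.V22],
                rtol=rtol,
                atol=atol,
            )
        )


def compute_payoff_matrix(
    econ1: GroupEconomics,
    econ2: GroupEconomics,
    policy: PolicyParams,
) -> PayoffMatrix:
    """Build the 2x2 bimatrix from group economics and policy coefficients.

    The mixed cells are where the policy interaction lives: an evacuator
    facing a stayer pays the doubly discounted process cost
    ``(1-delta)*(1-beta)*D``, while a stayer facing an evacuator pays the
    guaranteed-and-discounted stay cost ``epsilon*(1-theta)*E``.  With
    identical economics the game is symmetric (``U_ab == V_ba``).
    """
    a, b, th = policy.alpha, policy.beta, policy.theta
    d, eps, eta = policy.delta, policy.epsilon, policy.eta

    def _cells(e: GroupEconomics) -> tuple[float, float, float, float]:
        evac_loss = a * (e.C - e.Cprime)
        both_evac = e.P - evac_loss - (1.0 - d) * e.D
        evac_vs_stay = e.P - evac_loss - (1.0 - d) * (1.0 - b) * e.D
        stay_vs_evac = (1.0 - a) * e.P - eps * (1.0 - th) * e.E
        both_stay = (1.0 - a) * e.P - eta * e.E
        return both_evac, evac_vs_stay, stay_vs_evac, both_stay

    U11, U12, U21, U22 = _cells(econ1)
    V11, V21, V12, V22 = _cells(econ2)
    return PayoffMatrix(U11, U12, U21, U22, V11, V12, V21, V22)
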