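"""Policy-parameter sweeps and trend statistics.

Each sweep varies one policy coefficient over a grid while holding
everything else at the base configuration, reruns the full Monte-Carlo
ensemble at every grid value with common random numbers (shared
repetition seeds, hence shared graphs, initial strategies and update
draws), and summarises how the final evacuation response rate moves
along the grid: a rank correlation, the endpoint difference, and its
pooled standard error across repetitions.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .abm import EnsembleResult, SimConfig, run_ensemble
from .network import NetworkSpec
from .payoffs import GroupEconomics, PolicyParams, compute_payoff_matrix

__all__ = ["SweepSpec", "SweepResult", "TrendStats", "run_sweep", "trend_statistic"]

PARAMETERS = ("alpha", "beta", "theta", "delta", "epsilon", "eta")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: which policy knob, over which grid, from which base."""

    parameter: str
    grid: tuple[float, ...]
    econ1: GroupEconomics = GroupEconomics()
    econ2: GroupEconomics = GroupEconomics()
    policy: PolicyParams = PolicyParams()
    network: NetworkSpec = NetworkSpec()
    simulation: SimConfig = SimConfig()

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(
                f"parameter must be one of {PARAMETERS}, got {self.parameter!r}"
            )
        object.__setattr__(self, "grid", tuple(float(v) for v in self.grid))
        if len(self.grid) < 2:
            raise ValueError("grid must contain at least 2 values")
        for v in self.grid:
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"grid values must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class TrendStats:
    """How the final rate moves along the grid.

    ``rank_correlation`` is Spearman's rho between grid value and mean
    final rate (nan when either is constant); ``endpoint_delta`` is
    rate(last grid value) - rate(first); ``pooled_se`` is the standard
    error of that difference pooled from the per-repetition finals.
    """

    rank_correlation: float
    endpoint_delta: float
    pooled_se: float


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-value ensemble outcomes plus the trend summary."""

    parameter: str
    values: tuple[float, ...]
    final_means: np.ndarray
    final_sds: np.ndarray
    series_mean: np.ndarray  # (n_grid, rounds+1)
    rep_finals: np.ndarray  # (n_grid, n_reps)
    trend: TrendStats
    metadata: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                self.parameter: self.values,
                "final_mean": self.final_means,
                "final_sd": self.final_sds,
            }
        )

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "values": list(self.values),
            "final_means": self.final_means.tolist(),
            "final_sds": self.final_sds.tolist(),
            "trend": asdict(self.trend),
            "metadata": self.metadata,
        }


def _trend(values: np.ndarray, rep_finals: np.ndarray) -> TrendStats:
    means = rep_finals.mean(axis=1)
    if np.ptp(values) == 0 or np.ptp(means) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(values, means).statistic)
    delta = float(means[-1] - means[0])
    n = rep_finals.shape[1]
    if n > 1:
        v_first = rep_finals[0].var(ddof=1) / n
        v_last = rep_finals[-1].var(ddof=1) / n
        se = float(np.sqrt(v_first + v_last))
    else:
        se = float("nan")
    return TrendStats(rank_correlation=rho, endpoint_delta=delta, pooled_se=se)


def trend_statistic(sweep: SweepResult) -> TrendStats:
    """Recompute the trend summary of a sweep from its stored finals."""
    return _trend(np.asarray(sweep.values, dtype=float), sweep.rep_finals)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the ensemble at every grid value with common random numbers.

    The swept coefficient is overwritten in a copy of the base policy,
    the payoff matrix recomputed, and the ensemble rerun with the same
    master seed, so grid values differ only through the payoffs — the
    variance-reduction device that sharpens endpoint comparisons.
    """
    results: list[EnsembleResult] = []
    for v in spec.grid:
        policy = spec.policy.replace(**{spec.parameter: v})
        pm = compute_payoff_matrix(spec.econ1, spec.econ2, policy)
        results.append(run_ensemble(spec.network, pm, spec.simulation))

    values = np.asarray(spec.grid, dtype=float)
    rep_finals = np.stack([r.rep_finals for r in results])
    final_means = rep_finals.mean(axis=1)
    n = spec.simulation.n_reps
    final_sds = (
        rep_finals.std(axis=1, ddof=1) if n > 1 else np.zeros(len(spec.grid))
    )
    series_mean = np.stack([r.mean_rate for r in results])
    metadata = {
        "parameter": spec.parameter,
        "grid": list(spec.grid),
        "economics": {"group1": asdict(spec.econ1), "group2": asdict(spec.econ2)},
        "base_policy": asdict(spec.policy),
        "network": asdict(spec.network),
        "simulation": asdict(spec.simulation),
    }
    return SweepResult(
        parameter=spec.parameter,
        values=tuple(values),
        final_means=final_means,
        final_sds=final_sds,
        series_mean=series_mean,
        rep_finals=rep_finals,
        trend=_trend(values, rep_finals),
        metadata=metadata,
    )
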