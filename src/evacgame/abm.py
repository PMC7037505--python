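"""Networked evolutionary game: Fermi-rule imitation of evacuation choices.

Each node of the social graph holds a binary strategy (1 = Evacuate,
0 = Stay).  Every round a node accumulates payoff from the bimatrix game
against each neighbour, picks one neighbour at random for comparison,
and — only if that neighbour did strictly better — copies the
neighbour's strategy with the Fermi (pairwise-comparison) probability

    W = 1 / (1 + exp[(pr_i - pr_j) / k])

where k > 0 is the noise intensity of imitation.  The headline output is
the evacuation response rate, the fraction of nodes playing Evacuate,
averaged over a Monte-Carlo ensemble of repetitions.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.special import expit

from .network import NetworkSpec, generate_small_world
from .payoffs import PayoffMatrix

__all__ = [
    "SimConfig",
    "EnsembleResult",
    "init_strategies",
    "node_payoff",
    "fermi_adopt_prob",
    "step",
    "run_ensemble",
]

_UPDATE_SCHEMES = ("synchronous", "asynchronous")
_FERMI_VARIANTS = ("standard", "as_printed")
_AGGREGATIONS = ("sum", "mean")


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol parameters.

    ``rounds`` game rounds T; ``n_reps`` independent Monte-Carlo
    repetitions averaged out; ``noise_k`` Fermi noise intensity;
    ``init_evac_fraction`` probability each node starts as an evacuator;
    ``fixed_graph`` reuses one graph across repetitions instead of
    drawing a fresh network each repetition.
    """

    rounds: int = 20
    n_reps: int = 200
    noise_k: float = 1.0
    init_evac_fraction: float = 0.5
    update_scheme: str = "synchronous"
    fermi_variant: str = "standard"
    payoff_aggregation: str = "sum"
    master_seed: int = 0
    fixed_graph: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.rounds, int) or self.rounds < 1:
            raise ValueError(f"rounds must be an integer >= 1, got {self.rounds!r}")
        if not isinstance(self.n_reps, int) or self.n_reps < 1:
            raise ValueError(f"n_reps must be an integer >= 1, got {self.n_reps!r}")
        if not (math.isfinite(self.noise_k) and self.noise_k > 0):
            raise ValueError(f"noise_k must be > 0, got {self.noise_k!r}")
        if not 0.0 <= self.init_evac_fraction <= 1.0:
            raise ValueError(
                f"init_evac_fraction must be in [0, 1], got {self.init_evac_fraction!r}"
            )
        if self.update_scheme not in _UPDATE_SCHEMES:
            raise ValueError(
                f"update_scheme must be one of {_UPDATE_SCHEMES}, got {self.update_scheme!r}"
            )
        if self.fermi_variant not in _FERMI_VARIANTS:
            raise ValueError(
                f"fermi_variant must be one of {_FERMI_VARIANTS}, got {self.fermi_variant!r}"
            )
        if self.payoff_aggregation not in _AGGREGATIONS:
            raise ValueError(
                f"payoff_aggregation must be one of {_AGGREGATIONS}, "
                f"got {self.payoff_aggregation!r}"
            )

    def replace(self, **changes) -> "SimConfig":
        import dataclasses

        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class EnsembleResult:
    """Per-round ensemble statistics of the evacuation response rate.

    ``mean_rate``/``sd_rate`` have ``rounds + 1`` entries (entry 0 is the
    initial state); ``rep_finals`` keeps each repetition's final rate for
    downstream standard-error computations; ``metadata`` echoes the full
    resolved configuration and seeds.
    """

    mean_rate: np.ndarray
    sd_rate: np.ndarray
    final_rate: float
    rep_finals: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self):
        """Tidy per-round table with columns round, mean_rate, sd_rate."""
        import pandas as pd

        return pd.DataFrame(
            {
                "round": np.arange(len(self.mean_rate)),
                "mean_rate": self.mean_rate,
                "sd_rate": self.sd_rate,
            }
        )


def init_strategies(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Assign Evacuate (1) to each node independently with probability frac."""
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"frac must be in [0, 1], got {frac!r}")
    return (rng.random(n) < frac).astype(np.int8)


def fermi_adopt_prob(pr_i, pr_j, noise_k: float, variant: str = "standard"):
    """Probability that node i adopts neighbour j's strategy.

    The standard pairwise-comparison rule is increasing in the
    neighbour's payoff advantage pr_j - pr_i; the "as_printed" variant
    flips the sign of the exponent.  Computed with the overflow-safe
    logistic, saturating to the 0/1 limits for huge payoff gaps.
    Accepts scalars or arrays.
    """
    if not noise_k > 0:
        raise ValueError(f"noise_k must be > 0, got {noise_k!r}")
    if variant == "standard":
        z = (np.asarray(pr_j, dtype=float) - pr_i) / noise_k
    elif variant == "as_printed":
        z = (np.asarray(pr_i, dtype=float) - pr_j) / noise_k
    else:
        raise ValueError(f"variant must be one of {_FERMI_VARIANTS}, got {variant!r}")
    w = expit(z)
    return float(w) if np.ndim(w) == 0 else w


# -- internal flat-array machinery -------------------------------------------


class _Arrays:
    """CSR neighbour structure plus per-group cell tables for one graph."""

    def __init__(
        self,
        graph: nx.Graph,
        pm: PayoffMatrix,
        groups: Sequence[int] | None,
    ) -> None:
        n = graph.number_of_nodes()
        if sorted(graph.nodes()) != list(range(n)):
            raise ValueError("graph nodes must be labelled 0..n-1")
        A = nx.to_scipy_sparse_array(graph, nodelist=range(n), format="csr")
        self.n = n
        self.indptr = A.indptr
        self.indices = A.indices
        self.deg = np.diff(A.indptr)
        if np.any(self.deg == 0):
            isolated = int(np.flatnonzero(self.deg == 0)[0])
            raise ValueError(f"node {isolated} is isolated: payoff undefined")
        if groups is None:
            g = np.zeros(n, dtype=np.int8)
        else:
            g = np.asarray(groups, dtype=np.int8) - 1
            if g.shape != (n,) or np.any((g < 0) | (g > 1)):
                raise ValueError("groups must be a length-n sequence of 1s and 2s")
        self.g = g
        # cells[g, s_i, s_j]: row payoff of a group-(g+1) node
        self.cells = np.stack([pm.row_cells(1), pm.row_cells(2)])

    def payoffs(self, s: np.ndarray, aggregation: str) -> np.ndarray:
        """Per-node aggregated game payoff against all neighbours."""
        n_evac = np.add.reduceat(s[self.indices].astype(float), self.indptr[:-1])
        vs_evac = self.cells[self.g, s, 1]
        vs_stay = self.cells[self.g, s, 0]
        pay = n_evac * vs_evac + (self.deg - n_evac) * vs_stay
        if aggregation == "mean":
            pay = pay / self.deg
        return pay

    def payoff_one(self, s: np.ndarray, i: int, aggregation: str) -> float:
        nbrs = self.indices[self.indptr[i] : self.indptr[i + 1]]
        n_evac = int(s[nbrs].sum())
        pay = n_evac * self.cells[self.g[i], s[i], 1] + (
            len(nbrs) - n_evac
        ) * self.cells[self.g[i], s[i], 0]
        return pay / len(nbrs) if aggregation == "mean" else float(pay)


def node_payoff(
    graph: nx.Graph,
    strategies: np.ndarray,
    pm: PayoffMatrix,
    i: int,
    aggregation: str = "sum",
    groups: Sequence[int] | None = None,
) -> float:
    """Aggregated payoff of node i against all its neighbours.

    Node i is always read in its own role of the bimatrix (row player for
    group 1, column player for group 2); with symmetric economics the
    roles are interchangeable.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {_AGGREGATIONS}, got {aggregation!r}")
    arrays = _Arrays(graph, pm, groups)
    return arrays.payoff_one(np.asarray(strategies, dtype=np.int8), i, aggregation)


def _step_sync(
    arrays: _Arrays, s: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    pay = arrays.payoffs(s, config.payoff_aggregation)
    pick = rng.integers(0, arrays.deg)
    j = arrays.indices[arrays.indptr[:-1] + pick]
    coins = rng.random(arrays.n)
    w = fermi_adopt_prob(pay, pay[j], config.noise_k, config.fermi_variant)
    flip = (pay < pay[j]) & (coins < w)
    return np.where(flip, s[j], s).astype(np.int8)


def _step_async(
    arrays: _Arrays, s: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    s = s.copy()
    for i in rng.permutation(arrays.n):
        nbrs = arrays.indices[arrays.indptr[i] : arrays.indptr[i + 1]]
        j = int(nbrs[rng.integers(len(nbrs))])
        pr_i = arrays.payoff_one(s, int(i), config.payoff_aggregation)
        pr_j = arrays.payoff_one(s, j, config.payoff_aggregation)
        coin = rng.random()
        if pr_i < pr_j and coin < fermi_adopt_prob(
            pr_i, pr_j, config.noise_k, config.fermi_variant
        ):
            s[i] = s[j]
    return s


def step(
    graph: nx.Graph,
    strategies: np.ndarray,
    pm: PayoffMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    groups: Sequence[int] | None = None,
) -> np.ndarray:
    """Advance the strategy vector by one game round.

    Each node draws one neighbour uniformly; a node whose payoff is
    greater than or equal to that neighbour's keeps its strategy,
    otherwise it adopts the neighbour's strategy with the Fermi
    probability.  Synchronous updates all compare against the
    round-start state and land simultaneously; asynchronous updates
    apply node by node in a random permutation.
    """
    arrays = _Arrays(graph, pm, groups)
    s = np.asarray(strategies, dtype=np.int8)
    if s.shape != (arrays.n,) or np.any((s != 0) & (s != 1)):
        raise ValueError("strategies must be a length-n vector of 0/1")
    if config.update_scheme == "synchronous":
        return _step_sync(arrays, s, config, rng)
    return _step_async(arrays, s, config, rng)


def _rep_seeds(master_seed: int, rep: int) -> tuple[list[int], int]:
    """Child seed material for repetition ``rep``.

    Returns the strategy/update RNG seed sequence and the graph seed.
    Counter-based, so repetitions are independent and individually
    reproducible; the graph seed stays below 2**31.
    """
    return [master_seed, rep], (master_seed + 7919 * rep + 1) % 2**31


def run_ensemble(
    netspec: NetworkSpec,
    pm: PayoffMatrix,
    config: SimConfig,
    groups: Sequence[int] | None = None,
    graph: nx.Graph | None = None,
) -> EnsembleResult:
    """Monte-Carlo ensemble of networked game runs.

    For each repetition: draw the social graph (a fresh one per
    repetition unless ``config.fixed_graph`` or an explicit ``graph`` is
    given), initialise strategies, play ``rounds`` rounds recording the
    evacuation response rate, then average across repetitions.  Fully
    deterministic given ``config.master_seed``.
    """
    T = config.rounds
    rates = np.empty((config.n_reps, T + 1))
    fixed = graph
    if fixed is None and config.fixed_graph:
        fixed = generate_small_world(netspec)
    arrays_fixed = _Arrays(fixed, pm, groups) if fixed is not None else None

    for rep in range(config.n_reps):
        seed_seq, graph_seed = _rep_seeds(config.master_seed, rep)
        rng = np.random.default_rng(seed_seq)
        if arrays_fixed is not None:
            arrays = arrays_fixed
        else:
            G = generate_small_world(netspec.replace(seed=graph_seed))
            arrays = _Arrays(G, pm, groups)
        s = init_strategies(arrays.n, config.init_evac_fraction, rng)
        rates[rep, 0] = s.mean()
        for t in range(1, T + 1):
            if config.update_scheme == "synchronous":
                s = _step_sync(arrays, s, config, rng)
            else:
                s = _step_async(arrays, s, config, rng)
            rates[rep, t] = s.mean()

    mean_rate = rates.mean(axis=0)
    sd_rate = rates.std(axis=0, ddof=1) if config.n_reps > 1 else np.zeros(T + 1)
    metadata = {
        "network": asdict(netspec),
        "payoff_matrix": pm.as_dict(),
        "simulation": asdict(config),
        "groups": None if groups is None else list(map(int, groups)),
        "graph_fixed": fixed is not None,
    }
    return EnsembleResult(
        mean_rate=mean_rate,
        sd_rate=sd_rate,
        final_rate=float(mean_rate[-1]),
        rep_finals=rates[:, -1].copy(),
        metadata=metadata,
    )
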