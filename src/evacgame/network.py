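"""Small-world interaction graph of the evacuee social network.

The kin/friendship network along which evacuation decisions diffuse is
modelled as a Watts-Strogatz small-world graph: a ring lattice where each
node is joined to K/2 neighbours on either side, with every original edge
rewired with probability p to a uniformly chosen non-duplicate, non-self
target.  Rewiring preserves the edge count N*K/2 and the graph is kept
simple (no self-loops or parallel edges).  Because strategy diffusion on
a disconnected graph silently biases the evacuation response rate,
generation retries with an incremented seed until the graph is connected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "NetworkSpec",
    "generate_small_world",
    "neighbor_choice_distribution",
    "graph_statistics",
    "write_edge_list",
    "read_edge_list",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class NetworkSpec:
    """Watts-Strogatz construction parameters.

    ``n_nodes`` evacuees; ``k_ring`` (even) lattice neighbours per node;
    ``p_rewire`` per-edge rewiring probability; ``seed`` for determinism.
    """

    n_nodes: int = 200
    k_ring: int = 4
    p_rewire: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_nodes, int) or self.n_nodes < 3:
            raise ValueError(f"n_nodes must be an integer >= 3, got {self.n_nodes!r}")
        if (
            not isinstance(self.k_ring, int)
            or self.k_ring % 2 != 0
            or not 2 <= self.k_ring < self.n_nodes
        ):
            raise ValueError(
                f"k_ring must be an even integer with 2 <= k_ring < n_nodes, "
                f"got {self.k_ring!r}"
            )
        if not (
            isinstance(self.p_rewire, (int, float))
            and math.isfinite(self.p_rewire)
            and 0.0 <= self.p_rewire <= 1.0
        ):
            raise ValueError(f"p_rewire must be in [0, 1], got {self.p_rewire!r}")
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    def replace(self, **changes) -> "NetworkSpec":
        import dataclasses

        return dataclasses.replace(self, **changes)


def generate_small_world(spec: NetworkSpec, max_attempts: int = 100) -> nx.Graph:
    """Generate a connected Watts-Strogatz graph from the spec.

    If rewiring disconnects the graph, regeneration is retried with the
    seed incremented, up to ``max_attempts`` times (each retry logged).
    The spec and the seed actually used are echoed into ``G.graph`` so
    every downstream result file carries full provenance.
    """
    for attempt in range(max_attempts):
        seed = (spec.seed + attempt) % _SEED_MOD
        G = nx.watts_strogatz_graph(
            spec.n_nodes, spec.k_ring, spec.p_rewire, seed=seed
        )
        if nx.is_connected(G):
            G.graph.update(asdict(spec))
            G.graph["seed_used"] = seed
            return G
        logger.info(
            "rewiring disconnected the graph (seed %d); retrying", seed
        )
    raise RuntimeError(
        f"failed to generate a connected small-world graph in "
        f"{max_attempts} attempts from seed {spec.seed}"
    )


def neighbor_choice_distribution(
    graph: nx.Graph, i: int, weight: str = "weight"
) -> tuple[list[int], np.ndarray]:
    """Probability of node i choosing each neighbour for payoff comparison.

    p_ij = A_ij / sum_k A_ik over the neighbourhood of i.  Edges without
    the given weight attribute count as 1, so an unweighted graph yields
    the uniform distribution 1/|neighbours|.
    """
    if i not in graph:
        raise ValueError(f"node {i!r} not in graph")
    nbrs = sorted(graph.neighbors(i))
    if not nbrs:
        raise ValueError(f"node {i!r} is isolated: no neighbour to choose")
    w = np.array([graph[i][j].get(weight, 1.0) for j in nbrs], dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError(f"edge weights around node {i!r} must be >= 0 with a positive sum")
    return nbrs, w / w.sum()


def graph_statistics(graph: nx.Graph) -> dict:
    """Deterministic summary: degrees, clustering, mean shortest path.

    Path statistics are computed on the largest connected component when
    the graph is disconnected (flagged in the output).
    """
    degrees = np.array([d for _, d in graph.degree()], dtype=int)
    connected = nx.is_connected(graph) if graph.number_of_nodes() else False
    if connected:
        component = graph
    else:
        giant = max(nx.connected_components(graph), key=len, default=set())
        component = graph.subgraph(giant)
    mean_path = (
        float(nx.average_shortest_path_length(component))
        if component.number_of_nodes() > 1
        else 0.0
    )
    hist = np.bincount(degrees) if degrees.size else np.array([], dtype=int)
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "connected": bool(connected),
        "degree_histogram": hist.tolist(),
        "mean_degree": float(degrees.mean()) if degrees.size else 0.0,
        "mean_clustering": float(nx.average_clustering(graph)),
        "mean_shortest_path": mean_path,
        "path_component_size": component.number_of_nodes(),
    }


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Export as a whitespace-delimited edge list (one edge per line)."""
    nx.write_edgelist(graph, str(path), data=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Import a whitespace-delimited edge list with integer node labels."""
    return nx.read_edgelist(str(path), nodetype=int)
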