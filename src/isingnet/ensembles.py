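"""Artificial binary graph ensembles with exactly matched node and edge counts.

Four architectures: ``regular`` (ring lattice), ``small-world`` (Watts–Strogatz
rewiring, default P = 0.25), ``random`` (the P = 1 extreme of the same
algorithm) and ``scale-free`` (Barabási–Albert preferential attachment).
Standard generators cannot hit an arbitrary edge count exactly (e.g. 38 edges at
N = 20), so every graph is post-edited by uniformly random single-edge additions
or deletions — with a connectivity guard — until the target count is met; the
edits are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .connectome import Connectome

_TOPOLOGIES = ("regular", "small-world", "random", "scale-free")
_MAX_RETRIES = 50


class EnsembleError(ValueError):
    pass


@dataclass
class EnsembleSpec:
    """Recipe for an ensemble of binary graphs.

    ``rewire_P`` applies to the small-world family only (regular pins it to 0,
    random to 1).  ``connected`` demands every instance be connected, with
    bounded regeneration retries.
    """

    topology: str
    n: int
    edges: int
    rewire_P: float = 0.25
    instances: int = 1
    seed: int = 0
    connected: bool = True

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise EnsembleError(
                f"unknown topology {self.topology!r}; expected one of {_TOPOLOGIES}"
            )
        max_edges = self.n * (self.n - 1) // 2
        if not 0 <= self.edges <= max_edges:
            raise EnsembleError(
                f"{self.edges} edges infeasible for N={self.n} (max {max_edges})"
            )
        if self.connected and self.edges < self.n - 1:
            raise EnsembleError(
                f"{self.edges} edges cannot connect N={self.n} nodes (need >= {self.n - 1})"
            )
        if not 0.0 <= self.rewire_P <= 1.0:
            raise EnsembleError(f"rewire_P must be in [0, 1], got {self.rewire_P}")

    @property
    def effective_P(self) -> float:
        if self.topology == "regular":
            return 0.0
        if self.topology == "random":
            return 1.0
        return self.rewire_P


def instance_seed(base_seed: int, index: int) -> int:
    """Deterministic per-instance seed derived from (ensemble seed, index)."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def _graph_to_connectome(g: nx.Graph, n: int) -> Connectome:
    w = nx.to_numpy_array(g, nodelist=range(n), dtype=float)
    w = (w > 0).astype(float)
    return Connectome(w)


def _connectome_to_graph(c: Connectome) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(c.n))
    iu, ju = np.nonzero(np.triu(c.weights, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return g


def match_edge_count(c: Connectome, target: int, seed: int,
                     require_connected: bool = True) -> tuple[Connectome, int]:
    """Add/delete uniformly random single edges until exactly ``target`` remain.

    Deletions that would disconnect the graph (when connectivity is required)
    are rejected and resampled, with bounded retries.  Returns the edited graph
    and the number of edits applied.
    """
    n = c.n
    max_edges = n * (n - 1) // 2
    lo = n - 1 if require_connected else 0
    if not lo <= target <= max_edges:
        raise EnsembleError(
            f"target {target} edges infeasible for N={n} "
            f"(feasible range [{lo}, {max_edges}])"
        )
    g = _connectome_to_graph(c)
    rng = np.random.default_rng(seed)
    edits = 0
    stall = 0
    while g.number_of_edges() != target:
        m = g.number_of_edges()
        if m < target:
            non_edges = [e for e in nx.non_edges(g)]
            e = non_edges[rng.integers(len(non_edges))]
            g.add_edge(*e)
            edits += 1
        else:
            edge_list = list(g.edges())
            e = edge_list[rng.integers(len(edge_list))]
            g.remove_edge(*e)
            if require_connected and not nx.is_connected(g):
                g.add_edge(*e)
                stall += 1
                if stall > _MAX_RETRIES * max(1, m):
                    raise EnsembleError(
                        "could not reach the target edge count without disconnecting"
                    )
                continue
            edits += 1
    return _graph_to_connectome(g, n), edits


def generate_network(spec: EnsembleSpec, instance_seed_: int) -> Connectome:
    """One binary graph of the requested topology with exactly ``spec.edges`` edges."""
    n = spec.n
    for attempt in range(_MAX_RETRIES):
        seed = int(np.random.SeedSequence([instance_seed_, attempt]).generate_state(1)[0] % (2**31))
        if spec.topology == "scale-free":
            # preferential attachment yields m*(n-m) edges; pick m closest to target
            disc = n * n - 4 * spec.edges
            m = round((n - disc ** 0.5) / 2) if disc >= 0 else n // 2
            m = max(1, min(n - 1, m))
            g = nx.barabasi_albert_graph(n, m, seed=seed)
        else:
            k = int(round(2 * spec.edges / n / 2) * 2)  # nearest even lattice degree
            k = max(2, min(n - 1 - ((n - 1) % 2), k))
            g = nx.watts_strogatz_graph(n, k, spec.effective_P, seed=seed)
        if spec.connected and not nx.is_connected(g):
            continue
        try:
            c, _ = match_edge_count(_graph_to_connectome(g, n), spec.edges,
                                    seed=seed + 1, require_connected=spec.connected)
        except EnsembleError:
            continue
        if spec.connected and not nx.is_connected(_connectome_to_graph(c)):
            continue
        return c
    raise EnsembleError(
        f"failed to generate a valid {spec.topology} graph after {_MAX_RETRIES} attempts"
    )


def generate_ensemble(spec: EnsembleSpec) -> list[Connectome]:
    """``spec.instances`` graphs, each from a deterministic per-instance seed."""
    return [generate_network(spec, instance_seed(spec.seed, i))
            for i in range(spec.instances)]


def betweenness_centrality(c: Connectome) -> np.ndarray:
    """Normalized shortest-path betweenness on the unweighted support graph.

    Normalization is by (N-1)(N-2)/2; node pairs with no connecting path
    contribute nothing, so disconnected graphs are allowed.
    """
    g = _connectome_to_graph(c)
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(c.n)])
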