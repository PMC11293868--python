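"""Chains-as-nodes droplet graphs and small-worldness against an
Erdos-Renyi null ensemble.

A droplet's chains become nodes; two nodes share an edge when the minimum
approach distance of the corresponding chains is below the contact cutoff.
Small-worldness is S = (C / C_rand) / (L / L_rand) with C the mean local
clustering coefficient, L the mean shortest path length, and the rand terms
ensemble means over connected G(n, m) random graphs of the same size.
S >> 1 marks high clustering with near-random path lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import networkx as nx
import numpy as np

from .aggregates import ClusterAssignment, DENSE_MIN_DEFAULT, min_chain_distance
from .constants import CONTACT_CUTOFF_NM
from .model_io import BeadSystem

CLUSTERING_MODES = ("local-mean", "transitivity")


@dataclass
class SmallWorldness:
    S: float
    C: float
    L: float
    C_rand: float
    L_rand: float
    n_nodes: int
    n_edges: int
    ensemble_size: int
    seed: int | None


def droplet_graph(
    system: BeadSystem,
    frame: int,
    cluster: Sequence[int],
    cutoff: float = CONTACT_CUTOFF_NM,
    use_pbc: bool = True,
) -> nx.Graph:
    """Contact graph of a droplet's chains in one frame.

    The cluster comes from the same cutoff, so the result is connected by
    construction; an inconsistent cutoff raises.
    """
    cluster = sorted(cluster)
    if len(cluster) < 2:
        raise ValueError("cluster must contain at least two chains")
    graph = nx.Graph()
    graph.add_nodes_from(cluster)
    for i, a in enumerate(cluster):
        for b in cluster[i + 1:]:
            if min_chain_distance(system, frame, a, b, use_pbc=use_pbc) < cutoff:
                graph.add_edge(a, b)
    if not nx.is_connected(graph):
        raise ValueError(
            "droplet graph is disconnected; the edge cutoff is inconsistent "
            "with the clustering cutoff that defined this cluster"
        )
    return graph


def clustering_coefficient(graph: nx.Graph, mode: str = "local-mean") -> float:
    """Mean local clustering coefficient (degree < 2 nodes contribute 0),
    or global transitivity when requested."""
    if graph.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    if mode == "local-mean":
        return float(nx.average_clustering(graph))
    if mode == "transitivity":
        return float(nx.transitivity(graph))
    raise ValueError(f"unknown clustering mode {mode!r}")


def avg_shortest_path(graph: nx.Graph) -> float:
    """Mean over unordered node pairs of the shortest path length."""
    if not nx.is_connected(graph):
        raise ValueError("average shortest path length requires a connected graph")
    return float(nx.average_shortest_path_length(graph))


def er_ensemble_stats(
    n_nodes: int,
    n_edges: int,
    ensemble_size: int = 500,
    seed: int | np.random.Generator | None = None,
    clustering: str = "local-mean",
    max_attempts_factor: int = 100,
) -> tuple[float, float]:
    """Mean clustering coefficient and path length over connected G(n, m)
    samples. Disconnected draws are rejected, up to
    ``max_attempts_factor * ensemble_size`` total attempts."""
    if n_edges < n_nodes - 1:
        raise ValueError(
            f"G({n_nodes}, {n_edges}) can never be connected (needs >= {n_nodes - 1} edges)"
        )
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    attempts = 0
    cap = max_attempts_factor * ensemble_size
    while len(cs) < ensemble_size:
        if attempts >= cap:
            raise RuntimeError(
                f"could not draw {ensemble_size} connected G({n_nodes}, {n_edges}) "
                f"samples in {cap} attempts"
            )
        attempts += 1
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        cs.append(clustering_coefficient(g, clustering))
        ls.append(nx.average_shortest_path_length(g))
    return float(np.mean(cs)), float(np.mean(ls))


def small_worldness(C: float, L: float, C_rand: float, L_rand: float) -> float:
    """S = (C / C_rand) / (L / L_rand)."""
    if min(L, C_rand, L_rand) <= 0:
        raise ValueError("C_rand, L and L_rand must be positive")
    return (C / C_rand) / (L / L_rand)


class ERNullCache:
    """Caches G(n, m) null-ensemble statistics keyed by graph size.

    Droplets of identical size share one null ensemble; the cache makes
    per-frame small-worldness over a trajectory affordable.
    """

    def __init__(
        self,
        ensemble_size: int = 500,
        seed: int | None = None,
        clustering: str = "local-mean",
    ) -> None:
        self.ensemble_size = ensemble_size
        self.seed = seed
        self.clustering = clustering
        self._cache: dict[tuple[int, int], tuple[float, float]] = {}

    def stats(self, n_nodes: int, n_edges: int) -> tuple[float, float]:
        key = (n_nodes, n_edges)
        if key not in self._cache:
            # mix sizes into the seed so ensembles differ but stay reproducible
            seed = None if self.seed is None else (self.seed * 1_000_003 + n_nodes * 1009 + n_edges) % (2**31)
            self._cache[key] = er_ensemble_stats(
                n_nodes, n_edges, self.ensemble_size, seed, self.clustering
            )
        return self._cache[key]


def graph_small_worldness(
    graph: nx.Graph,
    null_cache: ERNullCache,
) -> SmallWorldness:
    """Small-worldness of one graph against its size-matched ER ensemble."""
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    C = clustering_coefficient(graph, null_cache.clustering)
    L = avg_shortest_path(graph)
    C_rand, L_rand = null_cache.stats(n, m)
    return SmallWorldness(
        S=small_worldness(C, L, C_rand, L_rand),
        C=C, L=L, C_rand=C_rand, L_rand=L_rand,
        n_nodes=n, n_edges=m,
        ensemble_size=null_cache.ensemble_size,
        seed=null_cache.seed,
    )


def droplet_small_worldness(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    cutoff: float = CONTACT_CUTOFF_NM,
    min_cluster_size: int = DENSE_MIN_DEFAULT,
    ensemble_size: int = 500,
    seed: int | None = None,
    clustering: str = "local-mean",
    use_pbc: bool = True,
) -> list[SmallWorldness]:
    """Per-frame small-worldness of every dense droplet in a trajectory."""
    cache = ERNullCache(ensemble_size=ensemble_size, seed=seed, clustering=clustering)
    out = []
    for assignment in assignments:
        for cluster in assignment.clusters:
            if len(cluster) < max(min_cluster_size, 2):
                continue
            g = droplet_graph(system, assignment.frame_index, cluster, cutoff, use_pbc)
            out.append(graph_small_worldness(g, cache))
    return out
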