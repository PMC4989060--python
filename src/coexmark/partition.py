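"""Graph partitioning of the condition-specific network into gene modules.

The partitioner produces a disjoint cover of the network's nodes using
seeded Louvain modularity optimisation on the binary graph, followed by
the minimum-module-size filter (default: strictly more than 4 genes).
The algorithm is exposed behind a small interface so an alternative
community-detection method can be plugged in; downstream stages depend
only on receiving coherent disjoint modules.
"""

from __future__ import annotations

import logging

import networkx as nx

from .datatypes import FunctionalNetwork, GeneModule, ModuleSet, SpecificNetwork

logger = logging.getLogger(__name__)

__all__ = ["partition_network", "filter_modules"]


def _as_graph(network: SpecificNetwork | FunctionalNetwork | nx.Graph) -> nx.Graph:
    if isinstance(network, SpecificNetwork):
        source = network.graph
        graph = nx.Graph()
        graph.add_nodes_from(sorted(source.nodes))
        graph.add_edges_from(sorted(tuple(sorted(e)) for e in source.edges))
        return graph
    if isinstance(network, FunctionalNetwork):
        graph = nx.Graph()
        graph.add_edges_from(sorted(network.scores))
        return graph
    if isinstance(network, nx.Graph):
        graph = nx.Graph()
        graph.add_nodes_from(sorted(network.nodes))
        graph.add_edges_from(sorted(tuple(sorted(e)) for e in network.edges))
        return graph
    raise TypeError(f"cannot partition object of type {type(network).__name__}")


def partition_network(
    network: SpecificNetwork | FunctionalNetwork | nx.Graph, seed: int = 0
) -> ModuleSet:
    """Partition the network into disjoint gene modules.

    Every node is assigned to exactly one module; the result is
    deterministic for a given (network, seed). Modules are named
    ``M1, M2, ...`` in order of decreasing size, ties broken by the
    smallest gene id.
    """
    graph = _as_graph(network)
    if graph.number_of_nodes() == 0:
        return ModuleSet([], partition_seed=seed, algorithm_tag="louvain")
    communities = nx.community.louvain_communities(graph, seed=int(seed))
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    modules = [
        GeneModule(f"M{i}", frozenset(c)) for i, c in enumerate(ordered, start=1)
    ]
    covered = set().union(*(m.genes for m in modules))
    assert covered == set(graph.nodes), "partition must cover every node"
    logger.info(
        "partitioned %d nodes into %d modules (louvain, seed %d)",
        graph.number_of_nodes(), len(modules), seed,
    )
    return ModuleSet(modules, partition_seed=seed, algorithm_tag="louvain")


def filter_modules(mods: ModuleSet, min_size: int = 5) -> ModuleSet:
    """Retain modules with at least ``min_size`` genes (default > 4)."""
    kept = [m for m in mods.modules if len(m.genes) >= min_size]
    logger.info("size filter (>= %d genes): %d of %d modules kept",
                min_size, len(kept), len(mods.modules))
    return ModuleSet(kept, partition_seed=mods.partition_seed,
                     algorithm_tag=mods.algorithm_tag)
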