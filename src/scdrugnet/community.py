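"""Module detection by iterated walktrap and disease-gene enrichment testing.

Walktrap agglomerates nodes by short-random-walk similarity; the partition is
taken at the maximum-modularity cut.  Oversized modules (> ``max_size`` genes)
are re-modularized on their induced subgraphs, recursively, producing
hierarchical module names (``m_5_7`` = seventh submodule of module five, both
indices ordered by descending size).  Each module is then tested for
over-representation of disease genes with a one-sided Fisher exact test
against the network's own gene universe, BH-corrected per network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import pandas as pd

from scdrugnet.evidence import bh_adjust, fisher_enrichment_p

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """Disjoint cover of a cell network's genes by hierarchically named modules."""

    cell_type: str
    modules: dict[str, set[str]]
    stats: pd.DataFrame | None = field(default=None)

    def gene_to_module(self) -> dict[str, str]:
        return {g: name for name, genes in self.modules.items() for g in genes}

    def ad_modules(self, alpha: float = 0.05) -> list[str]:
        if self.stats is None:
            raise ValueError("module_enrichment has not been run")
        return list(self.stats.loc[self.stats.is_AD_module, "module_id"])


def walktrap_communities(graph: nx.Graph, steps: int = 4) -> list[set[str]]:
    """One walktrap pass at the maximum-modularity cut, as gene sets."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    clustering = g.community_walktrap(steps=steps).as_clustering()
    return [{nodes[i] for i in comm} for comm in clustering if comm]


def iterative_modularize(
    network: nx.Graph, max_size: int = 500, steps: int = 4, prefix: str = "m"
) -> ModulePartition:
    """Walktrap iterated on oversized modules.

    Any module larger than ``max_size`` is re-clustered on its induced
    subgraph; recursion stops when a module fits or walktrap returns a single
    community (indivisible, kept with a warning).  Disconnected networks are
    handled per component by walktrap itself.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot modularize an empty network")

    modules: dict[str, set[str]] = {}

    def recurse(subgraph: nx.Graph, name_parts: tuple[str, ...]) -> None:
        comms = walktrap_communities(subgraph, steps=steps)
        comms.sort(key=lambda c: (-len(c), min(c)))
        if len(comms) == 1 and name_parts:
            # indivisible oversized module: keep as-is
            modules["_".join(name_parts)] = comms[0]
            if len(comms[0]) > max_size:
                logger.warning(
                    "module %s is indivisible with %d genes (> %d)",
                    "_".join(name_parts), len(comms[0]), max_size,
                )
            return
        for i, comm in enumerate(comms, start=1):
            parts = name_parts + (str(i),)
            if len(comm) > max_size:
                recurse(subgraph.subgraph(comm).copy(), parts)
            else:
                modules["_".join(parts)] = comm

    recurse(network, ())
    named = {f"{prefix}_{k}": v for k, v in modules.items()}
    cell = network.graph.get("cell_type", "")
    return ModulePartition(cell_type=cell, modules=named)


def module_enrichment(
    partition: ModulePartition,
    ad_genes: set[str],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> ModulePartition:
    """Per-module one-sided Fisher enrichment in disease genes.

    The universe defaults to the union of the partition's modules (all genes in
    the corresponding network); disease genes are intersected with it.  BH
    correction runs across the modules of this one network; a module is an AD
    module when its adjusted p is below ``alpha``.
    """
    if universe is None:
        universe = set().union(*partition.modules.values())
    ad = ad_genes & universe
    rows = []
    for name in sorted(partition.modules):
        genes = partition.modules[name]
        overlap = len(genes & ad)
        p = fisher_enrichment_p(overlap, len(genes), len(ad), len(universe))
        rows.append(
            {"module_id": name, "n_genes": len(genes), "n_AD": overlap, "p": p}
        )
    stats = pd.DataFrame(rows)
    stats["p_adj"] = bh_adjust(stats["p"].to_numpy())
    stats["is_AD_module"] = stats["p_adj"] < alpha
    partition.stats = stats
    return partition
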