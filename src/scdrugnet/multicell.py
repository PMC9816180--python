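"""Multicellular module graph from ligand-receptor pairs.

Significant ligand-receptor pairs are projected onto the per-cell module
partitions: a pair contributes one edge between the node holding the ligand in
the producing cell and the node holding the receptor in the receiving cell.
Partners outside any significant disease module map to their cell's "other"
node; pairs with neither partner in a disease module are dropped.  Edges are
undirected and weighted by the number of supporting pairs.  Node influence is
measured by classic closeness centrality on hop distances, and the core
disease modules are the highly central, highly enriched ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from scdrugnet.community import ModulePartition

logger = logging.getLogger(__name__)

OTHER = "other"


def node_name(cell: str, module_id: str) -> str:
    return f"{cell}:{module_id}"


@dataclass
class MulticellGraph:
    graph: nx.Graph  # nodes "CELL:module", edges weighted by shared LR pairs
    nodes: pd.DataFrame  # node, cell, module_id, is_other, p_adj, closeness


def map_lr_to_modules(
    lr_pairs: pd.DataFrame,
    partitions: dict[str, ModulePartition],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Project LR pairs onto module-level edges.

    Returns one row per contributing pair: ``node_a, node_b, ligand, receptor``.
    A partner that is not inside any significant disease module of its cell
    (including genes absent from the cell network) maps to the cell's "other"
    node; pairs with neither partner in a disease module are dropped.
    """
    mapped_rows = []
    gene_maps = {}
    ad_sets = {}
    for cell, part in partitions.items():
        gene_maps[cell] = part.gene_to_module()
        ad_sets[cell] = set(part.ad_modules(alpha))

    for row in lr_pairs.itertuples(index=False):
        pc, rc = row.producing_cell, row.receiving_cell
        if pc not in partitions or rc not in partitions:
            raise ValueError(f"LR pair references unknown cell type {pc!r}/{rc!r}")
        lmod = gene_maps[pc].get(row.ligand_gene)
        rmod = gene_maps[rc].get(row.receptor_gene)
        if lmod is None:
            logger.debug("ligand %s absent from %s network", row.ligand_gene, pc)
        if rmod is None:
            logger.debug("receptor %s absent from %s network", row.receptor_gene, rc)
        l_in_ad = lmod in ad_sets[pc]
        r_in_ad = rmod in ad_sets[rc]
        if not l_in_ad and not r_in_ad:
            continue
        node_l = node_name(pc, lmod if l_in_ad else OTHER)
        node_r = node_name(rc, rmod if r_in_ad else OTHER)
        mapped_rows.append(
            {
                "node_a": node_l,
                "node_b": node_r,
                "ligand": row.ligand_gene,
                "receptor": row.receptor_gene,
            }
        )
    return pd.DataFrame(mapped_rows, columns=["node_a", "node_b", "ligand", "receptor"])


def build_multicell_graph(
    mapped_pairs: pd.DataFrame,
    partitions: dict[str, ModulePartition],
    alpha: float = 0.05,
) -> MulticellGraph:
    """Assemble the weighted module graph and compute closeness per node.

    Nodes are every significant disease module plus one "other" node per cell
    type; parallel pairs between the same node pair merge into one edge whose
    weight counts the supporting pairs.  Self-pairs (both partners in the same
    node) are recorded on the node but contribute no edge.
    """
    g = nx.Graph()
    node_meta = []
    for cell, part in partitions.items():
        stats = part.stats.set_index("module_id") if part.stats is not None else None
        for mod in part.ad_modules(alpha):
            name = node_name(cell, mod)
            p_adj = float(stats.loc[mod, "p_adj"]) if stats is not None else np.nan
            g.add_node(name)
            node_meta.append(
                {"node": name, "cell": cell, "module_id": mod, "is_other": False,
                 "p_adj": p_adj}
            )
        oname = node_name(cell, OTHER)
        g.add_node(oname)
        node_meta.append(
            {"node": oname, "cell": cell, "module_id": OTHER, "is_other": True,
             "p_adj": np.nan}
        )

    for row in mapped_pairs.itertuples(index=False):
        if row.node_a == row.node_b:
            continue
        if g.has_edge(row.node_a, row.node_b):
            g[row.node_a][row.node_b]["weight"] += 1
            g[row.node_a][row.node_b]["pairs"].append((row.ligand, row.receptor))
        else:
            g.add_edge(row.node_a, row.node_b, weight=1, pairs=[(row.ligand, row.receptor)])

    nodes = pd.DataFrame(node_meta)
    cc = closeness_scores(g)
    nodes["closeness"] = nodes["node"].map(cc)
    return MulticellGraph(graph=g, nodes=nodes)


def closeness_scores(graph: nx.Graph) -> dict[str, float]:
    """Classic closeness on hop distances, per connected component:
    ``CC(v) = (n_reachable - 1) / sum of distances to reachable nodes``.
    Isolated nodes get 0 by convention."""
    cc = nx.closeness_centrality(graph, wf_improved=False)
    for node, value in cc.items():
        if graph.degree(node) == 0 and value == 0.0:
            logger.debug("isolated node %s: closeness 0 by convention", node)
    return {n: float(v) for n, v in cc.items()}


def select_core_modules(
    nodes: pd.DataFrame,
    cc_threshold_quantile: float = 0.5,
    enrichment_cap: float = 0.05,
) -> pd.DataFrame:
    """Core disease modules: the upper-right quadrant of (enrichment, centrality).

    Among disease-module nodes ("other" nodes are never eligible), core = nodes
    with closeness at or above the given quantile of the disease-module
    closeness distribution AND adjusted enrichment p below ``enrichment_cap``,
    ranked by (-log10 p_adj, closeness) descending.  An empty core set is
    reported with a warning and the caller may fall back to all disease modules.
    """
    mods = nodes.loc[~nodes.is_other].copy()
    if mods.empty:
        logger.warning("no disease-module nodes; core set is empty")
        return mods.assign(is_core=pd.Series(dtype=bool))
    thr = float(np.quantile(mods["closeness"].to_numpy(), cc_threshold_quantile))
    mods["is_core"] = (mods["closeness"] >= thr) & (mods["p_adj"] < enrichment_cap)
    if not mods["is_core"].any():
        logger.warning("core module set is empty at quantile %.2f", cc_threshold_quantile)
    with np.errstate(divide="ignore"):
        mods["neglog_p"] = -np.log10(mods["p_adj"].to_numpy())
    mods = mods.sort_values(
        ["is_core", "neglog_p", "closeness"], ascending=[False, False, False]
    ).reset_index(drop=True)
    return mods


def specificity_matrix(mean_expression: pd.DataFrame) -> pd.DataFrame:
    """Cell-type specificity per gene: mean expression in a cell type divided
    by the gene's summed mean expression across cell types (rows sum to 1).

    ``mean_expression`` is genes x cell types.  All-zero genes are undefined
    and excluded with a note."""
    values = mean_expression.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("mean expression must be non-negative")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d all-zero genes excluded from specificity", int(zero.sum()))
    spec = values[~zero] / totals[~zero, None]
    return pd.DataFrame(
        spec, index=mean_expression.index[~zero], columns=mean_expression.columns
    )
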