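"""Assembly of one merged molecular network per cell type.

Interaction records from several PPI sources are kept only above their
source-specific confidence thresholds (PBA: PBS score strictly < 1, the
IntAct family: MI score strictly > 0.45, HIPPIE: score >= 0.73); the synaptic
IntAct source enters neuron networks only.  The filtered PPI edges are merged
with directed TF->gene regulatory edges and restricted to admissible genes:
genes expressed in the disease condition, or expressed in controls while
differentially expressed and downregulated in disease cells.  The merged graph
is simple and treated as undirected everywhere (GRN direction is kept as edge
metadata only).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from scdrugnet.config import NEURON_CELLS

logger = logging.getLogger(__name__)

PPI_SOURCES = ("PBA", "IntAct", "IntAct_AD", "IntAct_synaptic", "HIPPIE")


def filter_interactions(
    records: pd.DataFrame,
    cell_type: str,
    thresholds: dict[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Apply per-source confidence thresholds and the neuron-only synaptic rule.

    ``thresholds`` maps source -> (op, value) with op in {"lt", "gt", "ge"};
    defaults follow the source conventions (PBA "lt" 1.0, IntAct family "gt"
    0.45, HIPPIE "ge" 0.73).  Records with an unknown source are rejected.
    """
    if thresholds is None:
        thresholds = {
            "PBA": ("lt", 1.0),
            "IntAct": ("gt", 0.45),
            "IntAct_AD": ("gt", 0.45),
            "IntAct_synaptic": ("gt", 0.45),
            "HIPPIE": ("ge", 0.73),
        }
    unknown = set(records["source"]) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown interaction source(s): {sorted(unknown)}")

    keep = pd.Series(False, index=records.index)
    score = records["score"].astype(float)
    for source, (op, value) in thresholds.items():
        mask = records["source"] == source
        if op == "lt":
            keep |= mask & (score < value)
        elif op == "gt":
            keep |= mask & (score > value)
        elif op == "ge":
            keep |= mask & (score >= value)
        else:
            raise ValueError(f"unknown threshold op {op!r}")
    if cell_type not in NEURON_CELLS:
        keep &= records["source"] != "IntAct_synaptic"
    return records[keep].reset_index(drop=True)


def expressed_genes(expression_summary: pd.DataFrame) -> set[str]:
    """Genes expressed in a cell type/condition: at least two cells with more
    than one count (``n_cells_gt1 >= 2``).  Genes without a row are treated as
    not expressed."""
    mask = expression_summary["n_cells_gt1"].astype(int) >= 2
    return set(expression_summary.loc[mask, "gene"])


def admissible_genes(
    expressed_ad: set[str], expressed_control: set[str], deg_table: pd.DataFrame
) -> set[str]:
    """Genes admitted to a cell network: expressed in the disease condition,
    or expressed in controls while a downregulated DEG in disease cells."""
    down = set(deg_table.loc[deg_table["direction"] == "down", "gene"])
    return expressed_ad | (expressed_control & down)


def assemble_cell_network(
    ppi: pd.DataFrame, grn: pd.DataFrame, admissible: set[str], cell_type: str = ""
) -> nx.Graph:
    """Merge filtered PPI edges and GRN edges into one simple undirected graph
    over admissible genes.

    Self-loops are removed; parallel edges from different sources collapse into
    one edge whose ``sources`` attribute accumulates the source labels; GRN
    direction survives as a ``tf`` edge attribute.  Isolated admissible genes
    do not appear (they can contribute neither to modules nor to distances).
    """
    g = nx.Graph(cell_type=cell_type)
    for row in ppi.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if a == b or a not in admissible or b not in admissible:
            continue
        if g.has_edge(a, b):
            g[a][b]["sources"].add(row.source)
        else:
            g.add_edge(a, b, sources={row.source})
    for row in grn.itertuples(index=False):
        a, b = row.tf, row.target
        if a == b or a not in admissible or b not in admissible:
            continue
        if g.has_edge(a, b):
            g[a][b]["sources"].add("GRN")
            g[a][b]["tf"] = a
        else:
            g.add_edge(a, b, sources={"GRN"}, tf=a)
    if g.number_of_nodes() == 0:
        raise ValueError(f"cell network {cell_type or '?'} is empty after filtering")
    return g


def network_to_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "gene_a": min(a, b),
            "gene_b": max(a, b),
            "sources": ",".join(sorted(data["sources"])),
        }
        for a, b, data in g.edges(data=True)
    ]
    return (
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "sources"])
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
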