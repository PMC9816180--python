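"""Drug module construction on a cell network.

A drug module contains the drug target, the drug-modulated genes (top-ranked
up- and down-regulated signature genes mapped into the network) and the
connecting genes: the interior nodes of one deterministic shortest path from
each mapped signature gene to the target (breadth-first, ties broken by the
lexicographically smallest path).  Modules with fewer than ten genes are not
screened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DrugRecord:
    drug_id: str
    target_genes: list[str]
    signature_up: list[str]  # rank order, most regulated first
    signature_down: list[str]


@dataclass
class DrugModule:
    drug_id: str
    target_gene: str
    cell_type: str
    genes: set[str]
    roles: dict[str, str] = field(default_factory=dict)  # gene -> target|signature|connector
    n_unreachable: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def parse_drug_table(drugs: pd.DataFrame) -> list[DrugRecord]:
    """Parse a long drug table (drug, target, rank, gene, direction) into
    records; a drug with several targets yields one record per target."""
    records = []
    for (drug, target), grp in drugs.groupby(["drug", "target"], sort=True):
        up = grp[grp.direction == "up"].sort_values("rank")["gene"].tolist()
        down = grp[grp.direction == "down"].sort_values("rank")["gene"].tolist()
        records.append(DrugRecord(str(drug), [str(target)], up, down))
    return records


def select_signature(
    signature_up: list[str], signature_down: list[str], k: int = 100
) -> set[str]:
    """Top-``k`` most up- plus top-``k`` most down-regulated genes,
    deduplicated; shorter lists are taken whole."""
    return set(signature_up[:k]) | set(signature_down[:k])


def _lexicographic_shortest_path(
    graph: nx.Graph, target: str, gene: str, dist_from_gene: dict[str, int]
) -> list[str] | None:
    """Lexicographically smallest shortest path target -> gene, walking greedily
    toward the gene along nodes on some shortest path."""
    if target not in dist_from_gene:
        return None
    path = [target]
    current = target
    remaining = dist_from_gene[target]
    while remaining > 0:
        nxt = min(
            n for n in graph.neighbors(current) if dist_from_gene.get(n, -1) == remaining - 1
        )
        path.append(nxt)
        current = nxt
        remaining -= 1
    return path


def build_drug_module(
    target: str,
    signature: set[str],
    network: nx.Graph,
    drug_id: str = "",
    min_size: int = 10,
) -> DrugModule | None:
    """Build the drug module for one (drug, target, cell network) triple.

    Signature genes absent from the network are dropped; each remaining gene is
    connected to the target by one deterministic shortest path whose interior
    nodes become connector genes; unreachable signature genes are dropped with
    a logged count.  Returns ``None`` when the module has fewer than
    ``min_size`` genes (or the target is not in the network)."""
    if target not in network:
        logger.debug("drug %s: target %s absent from %s network",
                     drug_id, target, network.graph.get("cell_type", "?"))
        return None
    mapped = sorted(g for g in signature if g in network)
    genes: set[str] = {target}
    roles: dict[str, str] = {target: "target"}
    unreachable = 0
    for gene in mapped:
        if gene == target:
            continue
        dist_from_gene = nx.single_source_shortest_path_length(network, gene)
        path = _lexicographic_shortest_path(network, target, gene, dist_from_gene)
        if path is None:
            unreachable += 1
            continue
        roles[gene] = "signature"
        genes.add(gene)
        for interior in path[1:-1]:
            genes.add(interior)
            roles.setdefault(interior, "connector")
    if unreachable:
        logger.debug("drug %s target %s: %d signature genes unreachable",
                     drug_id, target, unreachable)
    module = DrugModule(
        drug_id=drug_id,
        target_gene=target,
        cell_type=network.graph.get("cell_type", ""),
        genes=genes,
        roles=roles,
        n_unreachable=unreachable,
    )
    if module.n_genes < min_size:
        logger.debug("drug %s target %s: module of %d genes rejected (< %d)",
                     drug_id, target, module.n_genes, min_size)
        return None
    return module


def module_table(modules: list[DrugModule]) -> pd.DataFrame:
    rows = [
        {"drug": m.drug_id, "target": m.target_gene, "cell": m.cell_type,
         "gene": g, "role": m.roles.get(g, "connector")}
        for m in modules
        for g in sorted(m.genes)
    ]
    return pd.DataFrame(rows, columns=["drug", "target", "cell", "gene", "role"])
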