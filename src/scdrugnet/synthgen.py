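"""Synthetic input bundle with planted ground truth.

The generator emulates the tabular outputs that the real pipeline consumes from
upstream tools and databases: per-cell-type interaction edge lists with
per-source confidence scores, directed TF->gene regulatory edges, evidence gene
sets (genetics / expression / literature), DEG tables, significant
ligand-receptor pairs, a drug library with ranked signatures, GO biological
process annotations, an HPA-style tissue-specificity table, and per-condition
expression summaries.

Ground truth is planted so that recovery is checkable:

* each cell-type graph follows a stochastic block model (planted partition);
* a configurable subset of blocks is disease-enriched — the *same* member genes
  in every cell type, so that cross-cell evidence sources and ligand-receptor
  wiring are coherent (the remaining blocks are shuffled independently per
  cell type);
* evidence sub-sources hit disease-block genes at ``evidence_hit_rate`` and
  the rest at ``background_rate``;
* ligand-receptor pairs connect disease blocks across cell types;
* positive drugs target disease-block genes with signatures drawn from within
  or one hop around the block, decoys target and modulate uniform random genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scdrugnet.config import NEURON_CELLS, SyntheticConfig, block_sizes
from scdrugnet.io import write_gmt, write_tsv

#: undirected interaction sources and the score ranges that pass / fail their
#: confidence filters (PBA passes strictly below 1, IntAct strictly above 0.45,
#: HIPPIE at or above 0.73)
_PASS_RANGES = {
    "PBA": (0.0, 0.999),
    "IntAct": (0.46, 1.0),
    "IntAct_AD": (0.46, 1.0),
    "IntAct_synaptic": (0.46, 1.0),
    "HIPPIE": (0.73, 1.0),
}
_FAIL_RANGES = {
    "PBA": (1.0, 2.0),
    "IntAct": (0.0, 0.45),
    "IntAct_AD": (0.0, 0.45),
    "IntAct_synaptic": (0.0, 0.45),
    "HIPPIE": (0.30, 0.7299),
}

_FUNCGEN_CELLS = ("EX", "IN", "MIC", "OLI")  # cells with functional-genomics evidence
_LIT_SOURCES = ("lit_harmonizome", "lit_kegg", "lit_agora", "lit_aruk")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    cell_types: tuple[str, ...]
    blocks: dict[str, dict[str, int]]  # cell -> gene -> block id
    disease_block_ids: tuple[int, ...]
    disease_genes: list[str]  # shared across cell types
    positive_drugs: list[str] = field(default_factory=list)
    decoy_drugs: list[str] = field(default_factory=list)
    drug_targets: dict[str, str] = field(default_factory=dict)
    lr_pairs: list[dict] = field(default_factory=list)
    control_only: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def block_genes(self, cell: str, block: int) -> set[str]:
        return {g for g, b in self.blocks[cell].items() if b == block}

    def to_json(self, path: str | Path) -> None:
        data = {
            "cell_types": list(self.cell_types),
            "blocks": self.blocks,
            "disease_block_ids": list(self.disease_block_ids),
            "disease_genes": self.disease_genes,
            "positive_drugs": self.positive_drugs,
            "decoy_drugs": self.decoy_drugs,
            "drug_targets": self.drug_targets,
            "lr_pairs": self.lr_pairs,
            "control_only": self.control_only,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            cell_types=tuple(data["cell_types"]),
            blocks={c: {g: int(b) for g, b in m.items()} for c, m in data["blocks"].items()},
            disease_block_ids=tuple(data["disease_block_ids"]),
            disease_genes=list(data["disease_genes"]),
            positive_drugs=list(data["positive_drugs"]),
            decoy_drugs=list(data["decoy_drugs"]),
            drug_targets=dict(data["drug_targets"]),
            lr_pairs=list(data["lr_pairs"]),
            control_only=data.get("control_only", {}),
        )


def gene_universe(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _draw_scores(rng: np.random.Generator, sources: np.ndarray, passing: bool) -> np.ndarray:
    ranges = _PASS_RANGES if passing else _FAIL_RANGES
    lo = np.array([ranges[s][0] for s in sources])
    hi = np.array([ranges[s][1] for s in sources])
    return np.round(lo + rng.random(len(sources)) * (hi - lo), 4)


def generate_cell_graphs(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], PlantedTruth]:
    """Generate per-cell-type PPI edge tables and GRN tables with planted blocks.

    Returns ``{cell: (ppi_df, grn_df)}`` and the :class:`PlantedTruth`.  The
    PPI table carries columns ``gene_a, gene_b, source, score``; edges realized
    by the planted-partition model receive scores that pass their source's
    confidence filter, and an extra ``junk_edge_fraction`` of edges is emitted
    with sub-threshold scores (plus synaptic-source edges for non-neuron cells)
    so that the filters are exercised.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    genes = np.array(gene_universe(config.genes_per_cell))
    sizes = block_sizes(config.genes_per_cell, config.n_blocks)
    disease_ids = tuple(config.disease_block_ids)
    n_disease = sum(sizes[b] for b in disease_ids)

    # disease-block membership is shared across cell types
    disease_genes = sorted(rng.choice(genes, size=n_disease, replace=False))
    disease_assign: dict[str, int] = {}
    pos = 0
    for b in disease_ids:
        for g in disease_genes[pos : pos + sizes[b]]:
            disease_assign[g] = b
        pos += sizes[b]
    other_genes = np.array(sorted(set(genes) - set(disease_genes)))
    other_block_ids = [b for b in range(config.n_blocks) if b not in disease_ids]

    blocks: dict[str, dict[str, int]] = {}
    graphs: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}

    # TFs are a global list, as a curated TF catalogue would be
    n_tf = max(1, round(config.tf_fraction * config.genes_per_cell))
    tf_list = sorted(rng.choice(genes, size=n_tf, replace=False))

    iu, ju = np.triu_indices(config.genes_per_cell, k=1)
    gene_index = {g: i for i, g in enumerate(genes)}

    for cell in config.cell_types:
        assign = dict(disease_assign)
        shuffled = rng.permutation(other_genes)
        pos = 0
        for b in other_block_ids:
            for g in shuffled[pos : pos + sizes[b]]:
                assign[g] = b
            pos += sizes[b]
        blocks[cell] = {g: int(assign[g]) for g in genes}

        labels = np.array([assign[g] for g in genes])
        same = labels[iu] == labels[ju]
        p_edge = np.where(same, config.p_in, config.p_out)
        keep = rng.random(len(iu)) < p_edge
        a_idx, b_idx = iu[keep], ju[keep]

        allowed = list(_PASS_RANGES) if cell in NEURON_CELLS else [
            s for s in _PASS_RANGES if s != "IntAct_synaptic"
        ]
        src = rng.choice(allowed, size=len(a_idx))
        ppi = pd.DataFrame(
            {
                "gene_a": genes[a_idx],
                "gene_b": genes[b_idx],
                "source": src,
                "score": _draw_scores(rng, src, passing=True),
            }
        )

        # deliberately sub-threshold edges, plus synaptic edges for non-neuron
        # cells (dropped by the cell rule regardless of score)
        n_junk = round(config.junk_edge_fraction * len(ppi))
        if n_junk:
            ja = rng.integers(0, config.genes_per_cell, size=n_junk)
            jb = rng.integers(0, config.genes_per_cell, size=n_junk)
            ok = ja != jb
            ja, jb = ja[ok], jb[ok]
            jsrc = rng.choice(list(_FAIL_RANGES), size=len(ja))
            junk = pd.DataFrame(
                {
                    "gene_a": genes[np.minimum(ja, jb)],
                    "gene_b": genes[np.maximum(ja, jb)],
                    "source": jsrc,
                    "score": _draw_scores(rng, jsrc, passing=False),
                }
            )
            if cell not in NEURON_CELLS:
                n_syn = max(1, n_junk // 5)
                sa = rng.integers(0, config.genes_per_cell, size=n_syn)
                sb = rng.integers(0, config.genes_per_cell, size=n_syn)
                ok = sa != sb
                syn_src = np.array(["IntAct_synaptic"] * int(ok.sum()))
                syn = pd.DataFrame(
                    {
                        "gene_a": genes[np.minimum(sa[ok], sb[ok])],
                        "gene_b": genes[np.maximum(sa[ok], sb[ok])],
                        "source": syn_src,
                        "score": _draw_scores(rng, syn_src, passing=True),
                    }
                )
                junk = pd.concat([junk, syn], ignore_index=True)
            ppi = pd.concat([ppi, junk], ignore_index=True)

        # GRN: each TF regulates a handful of genes of its own block plus an
        # occasional cross-block target
        grn_rows = []
        block_members = {
            b: [g for g in genes if assign[g] == b] for b in range(config.n_blocks)
        }
        for tf in tf_list:
            own = [g for g in block_members[assign[tf]] if g != tf]
            n_own = min(6, len(own))
            targets = list(rng.choice(own, size=n_own, replace=False)) if n_own else []
            extra = genes[rng.integers(0, config.genes_per_cell)]
            if extra != tf:
                targets.append(extra)
            for t in targets:
                grn_rows.append((tf, t))
        grn = pd.DataFrame(grn_rows, columns=["tf", "target"]).drop_duplicates()
        graphs[cell] = (ppi, grn)

    truth = PlantedTruth(
        cell_types=config.cell_types,
        blocks=blocks,
        disease_block_ids=disease_ids,
        disease_genes=list(disease_genes),
    )
    return graphs, truth


def generate_evidence_tables(
    truth: PlantedTruth, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, set[str]], pd.DataFrame, dict[str, pd.DataFrame]]:
    """Sample evidence sub-source gene sets around the planted disease blocks.

    Returns ``(evidence_sets, source_map, deg_tables)``.  ``source_map`` is a
    table with columns ``source, category, cell, proximity_only, functional``
    (``cell`` empty for sub-sources that apply to every cell type).  Disease
    genes enter each sub-source with probability ``evidence_hit_rate``, the
    rest with ``background_rate``.  A genomic-proximity-only genetics source is
    always present so the downstream exclusion rule is exercised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = np.array(gene_universe(config.genes_per_cell))
    is_disease = np.isin(genes, truth.disease_genes)
    p = np.where(is_disease, config.evidence_hit_rate, config.background_rate)

    def sample() -> set[str]:
        return set(genes[rng.random(len(genes)) < p])

    sources: list[tuple[str, str, str, bool, bool]] = [
        ("magma_proximity", "genetics", "", True, False),
        ("emagma_eqtl", "genetics", "", False, True),
    ]
    for cell in truth.cell_types:
        if cell in _FUNCGEN_CELLS:
            sources.append((f"funcgen_{cell}", "genetics", cell, False, True))
    for cell in truth.cell_types:
        sources.append((f"deg_{cell}", "expression", cell, False, False))
    for name in _LIT_SOURCES:
        sources.append((name, "literature", "", False, False))

    evidence_sets = {name: sample() for name, *_ in sources}
    source_map = pd.DataFrame(
        sources, columns=["source", "category", "cell", "proximity_only", "functional"]
    )

    deg_tables: dict[str, pd.DataFrame] = {}
    for cell in truth.cell_types:
        deg_genes = sorted(evidence_sets[f"deg_{cell}"])
        direction = rng.choice(["up", "down"], size=len(deg_genes))
        deg_tables[cell] = pd.DataFrame({"gene": deg_genes, "direction": direction})
    return evidence_sets, source_map, deg_tables


def generate_lr_and_drugs(
    truth: PlantedTruth,
    config: SyntheticConfig,
    graphs: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    rng: np.random.Generator | None = None,
) -> dict[str, object]:
    """Generate LR pairs, the drug library, GO annotations, the tissue table,
    and per-condition expression summaries.

    LR pairs wire the planted disease blocks across cell types (a minority has
    its receptor outside any disease block, to exercise the "other" nodes).
    Positive drugs target disease-block genes and draw their signatures from
    the block and its one-hop neighborhood; decoys are uniform.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genes = np.array(gene_universe(config.genes_per_cell))
    cells = truth.cell_types
    disease = set(truth.disease_genes)
    non_disease = np.array(sorted(set(genes) - disease))

    # ---- ligand-receptor pairs -------------------------------------------
    combos = []
    for i, ci in enumerate(cells):
        for cj in cells[i + 1 :]:
            for ba in truth.disease_block_ids:
                for bb in truth.disease_block_ids:
                    combos.append((ci, cj, ba, bb))
    n_other = max(0, config.n_lr_pairs // 6)
    n_module = config.n_lr_pairs - n_other
    lr_rows = []
    for k in range(n_module):
        ci, cj, ba, bb = combos[k % len(combos)]
        lig = rng.choice(sorted(truth.block_genes(ci, ba)))
        rec = rng.choice(sorted(truth.block_genes(cj, bb)))
        lr_rows.append((lig, rec, ci, cj, "module", ba, bb))
    for k in range(n_other):
        ci, cj, ba, _ = combos[k % len(combos)]
        lig = rng.choice(sorted(truth.block_genes(ci, ba)))
        rec = rng.choice(non_disease)
        lr_rows.append((lig, rec, ci, cj, "other", ba, -1))
    lr_df = pd.DataFrame(
        [r[:4] for r in lr_rows],
        columns=["ligand_gene", "receptor_gene", "producing_cell", "receiving_cell"],
    )
    lr_df["specificity_ligand"] = np.round(rng.uniform(0.5, 1.0, len(lr_df)), 3)
    lr_df["specificity_receptor"] = np.round(rng.uniform(0.5, 1.0, len(lr_df)), 3)
    truth.lr_pairs = [
        {
            "ligand": r[0],
            "receptor": r[1],
            "producing_cell": r[2],
            "receiving_cell": r[3],
            "kind": r[4],
            "ligand_block": int(r[5]),
            "receptor_block": int(r[6]),
        }
        for r in lr_rows
    ]

    # ---- drugs ------------------------------------------------------------
    # one-hop neighborhood of the disease blocks in the reference cell graph,
    # restricted to confidently scored edges
    ref_ppi, _ = graphs[cells[0]]
    adj: dict[str, set[str]] = {}
    passing = _passing_mask(ref_ppi)
    for a, b in zip(ref_ppi.gene_a[passing], ref_ppi.gene_b[passing]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    halo = sorted(
        {n for g in disease for n in adj.get(g, ())} - disease
    )  # distance exactly 1 from a disease block

    drug_rows = []
    positives, decoys = [], []
    for d in range(config.n_positive_drugs):
        drug = f"DRUGP{d + 1:03d}"
        positives.append(drug)
        target = rng.choice(sorted(disease))
        block = truth.blocks[cells[0]][target]
        pool_block = sorted(truth.block_genes(cells[0], block) - {target})
        for direction in ("up", "down"):
            n_in = int(round(0.75 * config.signature_size))
            n_out = config.signature_size - n_in
            sig = list(rng.choice(pool_block, size=min(n_in, len(pool_block)), replace=False))
            if halo and n_out:
                sig += list(rng.choice(halo, size=min(n_out, len(halo)), replace=False))
            for rank, g in enumerate(dict.fromkeys(sig), start=1):
                drug_rows.append((drug, target, rank, g, direction))
        truth.drug_targets[drug] = str(target)
    for d in range(config.n_decoy_drugs):
        drug = f"DRUGD{d + 1:03d}"
        decoys.append(drug)
        target = rng.choice(genes)
        for direction in ("up", "down"):
            sig = rng.choice(genes, size=config.signature_size, replace=False)
            for rank, g in enumerate(dict.fromkeys(sig), start=1):
                drug_rows.append((drug, target, rank, g, direction))
        truth.drug_targets[drug] = str(target)
    truth.positive_drugs = positives
    truth.decoy_drugs = decoys
    drugs_df = pd.DataFrame(
        drug_rows, columns=["drug", "target", "rank", "gene", "direction"]
    )

    # ---- GO annotations ---------------------------------------------------
    vocab = np.array([f"GOBP{i:04d}" for i in range(1, config.n_go_terms + 1)])
    go_rows: list[tuple[str, str]] = []
    for cell in cells:
        pools = {
            b: rng.choice(vocab, size=4, replace=False) for b in range(config.n_blocks)
        }
        for g in genes:
            pool = pools[truth.blocks[cell][g]]
            for t in rng.choice(pool, size=2, replace=False):
                go_rows.append((g, t))
    for g in genes:  # one noise term per gene
        go_rows.append((g, rng.choice(vocab)))
    go_df = pd.DataFrame(go_rows, columns=["gene", "term"]).drop_duplicates()
    go_df = go_df.sort_values(["gene", "term"]).reset_index(drop=True)

    # ---- tissue-specificity table ----------------------------------------
    categories = [
        ("Low specificity", ""),
        ("Not detected", ""),
        ("Tissue enhanced", "brain"),
        ("Tissue enriched", "liver"),
        ("Group enriched", "blood"),
        ("Tissue enriched", "lymphoid tissue"),
    ]
    probs = [0.60, 0.10, 0.10, 0.10, 0.05, 0.05]
    picks = rng.choice(len(categories), size=len(genes), p=probs)
    tissue_df = pd.DataFrame(
        {
            "gene": genes,
            "category": [categories[i][0] for i in picks],
            "tissue": [categories[i][1] for i in picks],
        }
    )
    # planted positives have brain-compatible targets by construction
    pos_targets = {truth.drug_targets[d] for d in positives}
    mask = tissue_df.gene.isin(pos_targets)
    tissue_df.loc[mask, "category"] = "Low specificity"
    tissue_df.loc[mask, "tissue"] = ""

    # ---- expression summaries --------------------------------------------
    expr: dict[tuple[str, str], pd.DataFrame] = {}
    control_only: dict[str, dict[str, list[str]]] = {}
    for cell in cells:
        co = rng.choice(non_disease, size=6, replace=False)
        co_down, co_silent = sorted(co[:3]), sorted(co[3:])
        control_only[cell] = {"deg_down": list(co_down), "not_deg": list(co_silent)}
        co_set = set(co)
        n_ad = rng.integers(2, 80, size=len(genes))
        n_ad[np.isin(genes, list(co_set))] = rng.integers(0, 2, size=len(co_set))
        expr[("AD", cell)] = pd.DataFrame(
            {
                "gene": genes,
                "n_cells_gt1": n_ad,
                "mean_expr": np.round(rng.lognormal(0.0, 1.0, len(genes)), 4),
            }
        )
        expr[("control", cell)] = pd.DataFrame(
            {
                "gene": genes,
                "n_cells_gt1": rng.integers(2, 80, size=len(genes)),
                "mean_expr": np.round(rng.lognormal(0.0, 1.0, len(genes)), 4),
            }
        )
    truth.control_only = control_only

    return {
        "lr_pairs": lr_df,
        "drugs": drugs_df,
        "go_annotations": go_df,
        "tissue": tissue_df,
        "expression": expr,
        "control_only": control_only,
    }


def _passing_mask(ppi: pd.DataFrame) -> np.ndarray:
    src = ppi["source"].to_numpy()
    score = ppi["score"].to_numpy(dtype=float)
    mask = np.zeros(len(ppi), dtype=bool)
    mask |= (src == "PBA") & (score < 1)
    mask |= np.isin(src, ["IntAct", "IntAct_AD", "IntAct_synaptic"]) & (score > 0.45)
    mask |= (src == "HIPPIE") & (score >= 0.73)
    return mask


def generate_bundle(config: SyntheticConfig, out_dir: str | Path) -> PlantedTruth:
    """Generate and write the complete synthetic input bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    graphs, truth = generate_cell_graphs(config, rng)
    evidence_sets, source_map, deg_tables = generate_evidence_tables(truth, config, rng)
    extras = generate_lr_and_drugs(truth, config, graphs, rng)

    # force the control-only admissible genes into the DEG tables (down in AD)
    for cell in truth.cell_types:
        forced = truth.control_only[cell]["deg_down"]
        deg = deg_tables[cell]
        deg = deg[~deg.gene.isin(forced)]
        deg = pd.concat(
            [deg, pd.DataFrame({"gene": forced, "direction": "down"})], ignore_index=True
        ).sort_values("gene").reset_index(drop=True)
        deg_tables[cell] = deg
        # a downregulated DEG must not be flagged as expressed in AD, and is an
        # expression-evidence hit by definition
        evidence_sets[f"deg_{cell}"] |= set(forced)

    for cell, (ppi, grn) in graphs.items():
        write_tsv(ppi, out / f"edges.{cell}.tsv")
        write_tsv(grn, out / f"grn.{cell}.tsv")
    for name, gene_set in evidence_sets.items():
        write_gmt({name: gene_set}, out / "evidence" / f"{name}.gmt")
    write_tsv(source_map, out / "evidence" / "sources.tsv")
    for cell, deg in deg_tables.items():
        write_tsv(deg, out / f"deg.{cell}.tsv")
    write_tsv(extras["lr_pairs"], out / "lr_pairs.tsv")
    write_tsv(extras["drugs"], out / "drugs.tsv")
    write_tsv(extras["go_annotations"], out / "go_annotations.tsv")
    write_tsv(extras["tissue"], out / "tissue.tsv")
    for (cond, cell), df in extras["expression"].items():
        write_tsv(df, out / f"expression_summary.{cond}.{cell}.tsv")
    truth.to_json(out / "truth.json")
    return truth
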