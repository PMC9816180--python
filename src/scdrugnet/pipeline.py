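"""End-to-end orchestration of the repurposing pipeline.

Stages communicate through plain TSV tables in the output directory so that
every stage can also be run on its own from the command line:

    simulate -> score-genes -> build -> modules -> multicell -> screen -> report

A JSON manifest with the configuration and SHA-256 checksums of every written
table makes runs byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from scdrugnet import __version__, community, drugnet, evidence, multicell, netbuild, proximity, report, synthgen
from scdrugnet.config import PipelineConfig
from scdrugnet.io import read_tsv, write_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.inputs = Path(config.input_dir) if config.input_dir else self.out / "inputs"

    # ---- helpers ----------------------------------------------------------

    @property
    def cells(self) -> tuple[str, ...]:
        return self.config.synthetic.cell_types

    def _require(self, path: Path, stage: str) -> Path:
        if not path.exists():
            raise PipelineError(stage, f"missing input file {path}")
        return path

    def _load_network(self, cell: str, stage: str) -> nx.Graph:
        table = read_tsv(self._require(self.out / f"network.{cell}.tsv", stage))
        g = nx.Graph(cell_type=cell)
        for row in table.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, sources=set(row.sources.split(",")))
        return g

    def _load_partition(self, cell: str, stage: str) -> community.ModulePartition:
        mods = read_tsv(self._require(self.out / f"modules.{cell}.tsv", stage))
        stats = read_tsv(self._require(self.out / f"module_stats.{cell}.tsv", stage))
        modules = {
            str(mid): set(grp["gene"]) for mid, grp in mods.groupby("module_id")
        }
        part = community.ModulePartition(cell_type=cell, modules=modules)
        stats["is_AD_module"] = stats["is_AD_module"].astype(bool)
        part.stats = stats
        return part

    def _admissible(self, cell: str, stage: str) -> set[str]:
        expr_ad = read_tsv(self._require(self.inputs / f"expression_summary.AD.{cell}.tsv", stage))
        expr_ct = read_tsv(self._require(self.inputs / f"expression_summary.control.{cell}.tsv", stage))
        deg = read_tsv(self._require(self.inputs / f"deg.{cell}.tsv", stage))
        return netbuild.admissible_genes(
            netbuild.expressed_genes(expr_ad), netbuild.expressed_genes(expr_ct), deg
        )

    # ---- stages -----------------------------------------------------------

    def simulate(self) -> None:
        synthgen.generate_bundle(self.config.synthetic, self.inputs)

    def score_genes(self) -> None:
        stage = "score-genes"
        source_map = read_tsv(self._require(self.inputs / "evidence" / "sources.tsv", stage))
        paths = {
            row.source: str(self.inputs / "evidence" / f"{row.source}.gmt")
            for row in source_map.itertuples(index=False)
        }
        matrix = evidence.load_evidence(paths, source_map)
        admissible = {cell: self._admissible(cell, stage) for cell in self.cells}
        scores = evidence.score_disease_genes(matrix, self.cells, admissible)
        for cell in self.cells:
            write_tsv(scores[scores.cell_type == cell], self.out / f"ad_genes.{cell}.tsv")

    def build(self) -> None:
        stage = "build"
        for cell in self.cells:
            ppi = read_tsv(self._require(self.inputs / f"edges.{cell}.tsv", stage))
            grn = read_tsv(self._require(self.inputs / f"grn.{cell}.tsv", stage))
            filtered = netbuild.filter_interactions(ppi, cell)
            admissible = self._admissible(cell, stage)
            g = netbuild.assemble_cell_network(filtered, grn, admissible, cell)
            write_tsv(netbuild.network_to_table(g), self.out / f"network.{cell}.tsv")

    def modules(self) -> None:
        stage = "modules"
        for cell in self.cells:
            g = self._load_network(cell, stage)
            part = community.iterative_modularize(
                g, max_size=self.config.max_module_size, steps=self.config.walk_steps
            )
            ad_table = read_tsv(self._require(self.out / f"ad_genes.{cell}.tsv", stage))
            ad = set(ad_table.loc[ad_table.is_AD_gene.astype(bool), "gene"])
            community.module_enrichment(part, ad, alpha=self.config.alpha)
            rows = [
                {"module_id": mid, "gene": gene}
                for mid in sorted(part.modules)
                for gene in sorted(part.modules[mid])
            ]
            write_tsv(pd.DataFrame(rows), self.out / f"modules.{cell}.tsv")
            write_tsv(part.stats, self.out / f"module_stats.{cell}.tsv")

    def multicell_stage(self) -> None:
        stage = "multicell"
        lr = read_tsv(self._require(self.inputs / "lr_pairs.tsv", stage))
        partitions = {cell: self._load_partition(cell, stage) for cell in self.cells}
        mapped = multicell.map_lr_to_modules(lr, partitions, alpha=self.config.alpha)
        mc = multicell.build_multicell_graph(mapped, partitions, alpha=self.config.alpha)
        edges = pd.DataFrame(
            [
                {
                    "node_a": a,
                    "node_b": b,
                    "weight": data["weight"],
                    "supporting_pairs": ";".join(f"{l}-{r}" for l, r in data["pairs"]),
                }
                for a, b, data in sorted(mc.graph.edges(data=True))
            ],
            columns=["node_a", "node_b", "weight", "supporting_pairs"],
        )
        write_tsv(edges, self.out / "multicell_edges.tsv")
        core = multicell.select_core_modules(
            mc.nodes, self.config.cc_quantile, self.config.enrichment_cap
        )
        nodes = mc.nodes.merge(core[["node", "is_core"]], on="node", how="left")
        nodes["is_core"] = nodes["is_core"].astype("boolean").fillna(False).astype(bool)
        write_tsv(nodes, self.out / "multicell_nodes.tsv")

        means = {}
        for cell in self.cells:
            expr = read_tsv(self.inputs / f"expression_summary.AD.{cell}.tsv")
            means[cell] = expr.set_index("gene")["mean_expr"]
        mat = pd.DataFrame(means).fillna(0.0)
        spec = multicell.specificity_matrix(mat)
        spec.insert(0, "gene", spec.index)
        write_tsv(spec.reset_index(drop=True), self.out / "specificity.tsv")

    def screen(self) -> None:
        stage = "screen"
        drugs = read_tsv(self._require(self.inputs / "drugs.tsv", stage))
        go_table = read_tsv(self._require(self.inputs / "go_annotations.tsv", stage))
        annotations: dict[str, set[str]] = {}
        for row in go_table.itertuples(index=False):
            annotations.setdefault(row.gene, set()).add(row.term)
        nodes = read_tsv(self._require(self.out / "multicell_nodes.tsv", stage))
        core = nodes[nodes["is_core"].astype(bool)]
        records = drugnet.parse_drug_table(drugs)

        results: list[proximity.ProximityResult] = []
        all_modules: list[drugnet.DrugModule] = []
        pair_counter = 0
        for cell in self.cells:
            core_here = core[core["cell"] == cell]
            if core_here.empty:
                continue
            g = self._load_network(cell, stage)
            nd = proximity.NetworkDistances(g)
            go = proximity.GOIndex(nd, annotations)
            part = self._load_partition(cell, stage)
            for rec in records:
                signature = drugnet.select_signature(
                    rec.signature_up, rec.signature_down, self.config.signature_top_k
                )
                if not signature:
                    logger.info("drug %s has an empty signature; skipped", rec.drug_id)
                    continue
                for target in rec.target_genes:
                    module = drugnet.build_drug_module(
                        target, signature, g, rec.drug_id, self.config.min_drug_module_size
                    )
                    if module is None:
                        continue
                    all_modules.append(module)
                    for mrow in core_here.itertuples(index=False):
                        disease_genes = part.modules[str(mrow.module_id)]
                        seed = (self.config.seed * 100003 + pair_counter) % (2**31)
                        pair_counter += 1
                        res = proximity.score_drug(
                            module, disease_genes, nd, go,
                            n_perm=self.config.n_perm, seed=seed,
                            alpha=self.config.alpha,
                            disease_module_id=str(mrow.module_id),
                        )
                        if res is not None:
                            results.append(res)
        mod_table = drugnet.module_table(all_modules)
        for cell in self.cells:
            write_tsv(
                mod_table[mod_table["cell"] == cell].drop(columns="cell"),
                self.out / f"drug_modules.{cell}.tsv",
            )
        write_tsv(proximity.results_table(results), self.out / "screen_results.tsv")

    def report_stage(self) -> None:
        stage = "report"
        screen = read_tsv(self._require(self.out / "screen_results.tsv", stage))
        screen["significant"] = screen["significant"].astype(bool)
        tissue = read_tsv(self._require(self.inputs / "tissue.tsv", stage))
        candidates = report.build_candidate_table(screen)
        filtered = report.tissue_filter(
            candidates, tissue, self.config.brain_tissues, self.config.immune_tissues
        )
        write_tsv(filtered, self.out / "candidates.tsv")
        self._write_manifest()

    def _write_manifest(self) -> None:
        checksums = {}
        for path in sorted(self.out.rglob("*.tsv")) + sorted(self.out.rglob("*.gmt")) + sorted(
            self.out.rglob("*.json")
        ):
            if path.name == "manifest.json":
                continue
            checksums[str(path.relative_to(self.out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
        manifest = {
            "version": __version__,
            "seed": self.config.seed,
            "parameters": asdict(self.config),
            "checksums": checksums,
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    # ---- orchestration ----------------------------------------------------

    STAGES = (
        "simulate", "score-genes", "build", "modules", "multicell", "screen", "report",
    )

    def run(self, stage: str) -> None:
        fn = {
            "simulate": self.simulate,
            "score-genes": self.score_genes,
            "build": self.build,
            "modules": self.modules,
            "multicell": self.multicell_stage,
            "screen": self.screen,
            "report": self.report_stage,
        }[stage]
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:  # halt with stage name and cause
            raise PipelineError(stage, str(exc)) from exc

    def run_all(self) -> None:
        stages = list(self.STAGES) if self.config.simulate else list(self.STAGES[1:])
        for stage in stages:
            logger.info("running stage %s", stage)
            self.run(stage)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    pipe = Pipeline(config)
    pipe.run_all()
    return pipe.out
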