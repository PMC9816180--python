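"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

#: Cell types of the prefrontal-cortex analysis: excitatory neurons, inhibitory
#: neurons, microglia, astrocytes, oligodendrocytes, oligodendrocyte precursors.
CELL_TYPES: tuple[str, ...] = ("EX", "IN", "MIC", "AST", "OLI", "OPC")

#: Cell types that receive the synaptic interaction source.
NEURON_CELLS: frozenset[str] = frozenset({"EX", "IN"})


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic input bundle with planted ground truth.

    The generator plants a stochastic-block-model community structure in each
    cell-type graph (within-block edge probability ``p_in``, between-block
    ``p_out``), marks ``disease_block_ids`` as disease-enriched, samples
    evidence tables at ``evidence_hit_rate`` inside those blocks versus
    ``background_rate`` outside, wires the disease blocks across cell types
    with ligand-receptor pairs, and plants drugs whose targets and signatures
    sit inside/near the disease blocks (positives) or anywhere (decoys).
    """

    n_cell_types: int = 6
    genes_per_cell: int = 300
    n_blocks: int = 5
    p_in: float = 0.25
    p_out: float = 0.01
    tf_fraction: float = 0.05
    disease_block_ids: tuple[int, ...] = (0, 1)
    evidence_hit_rate: float = 0.6
    background_rate: float = 0.05
    n_lr_pairs: int = 60
    n_positive_drugs: int = 10
    n_decoy_drugs: int = 90
    signature_size: int = 40  # genes per direction (up / down)
    n_go_terms: int = 150
    junk_edge_fraction: float = 0.1  # extra edges emitted below threshold on purpose
    seed: int = 7

    @property
    def cell_types(self) -> tuple[str, ...]:
        return CELL_TYPES[: self.n_cell_types]

    def validate(self) -> None:
        probs = {
            "p_in": self.p_in,
            "p_out": self.p_out,
            "evidence_hit_rate": self.evidence_hit_rate,
            "background_rate": self.background_rate,
            "tf_fraction": self.tf_fraction,
            "junk_edge_fraction": self.junk_edge_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability in [0, 1]")
        if self.p_in <= self.p_out:
            raise ValueError("p_in must exceed p_out for a planted partition")
        if self.evidence_hit_rate <= self.background_rate:
            raise ValueError("evidence_hit_rate must exceed background_rate")
        if self.n_blocks > self.genes_per_cell:
            raise ValueError(
                f"n_blocks={self.n_blocks} exceeds genes_per_cell={self.genes_per_cell}"
            )
        if not 1 <= self.n_cell_types <= len(CELL_TYPES):
            raise ValueError(f"n_cell_types must be in [1, {len(CELL_TYPES)}]")
        if any(b < 0 or b >= self.n_blocks for b in self.disease_block_ids):
            raise ValueError("disease_block_ids out of range")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serializable)."""

    out_dir: str = "out"
    input_dir: str | None = None  # defaults to out_dir when simulate is true
    simulate: bool = True
    seed: int = 7
    n_perm: int = 1000
    alpha: float = 0.05
    max_module_size: int = 500
    walk_steps: int = 4
    cc_quantile: float = 0.5
    enrichment_cap: float = 0.05
    min_drug_module_size: int = 10
    signature_top_k: int = 100
    brain_tissues: tuple[str, ...] = ("brain", "cerebral cortex", "cerebellum")
    immune_tissues: tuple[str, ...] = (
        "lymphoid tissue",
        "blood",
        "bone marrow",
        "gallbladder",
    )
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        # one seed drives everything, including the synthetic bundle
        self.synthetic.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def block_sizes(n_genes: int, n_blocks: int) -> list[int]:
    """Split ``n_genes`` into ``n_blocks`` nearly equal block sizes."""
    base = n_genes // n_blocks
    sizes = [base] * n_blocks
    for i in range(n_genes - base * n_blocks):
        sizes[i] += 1
    return sizes
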