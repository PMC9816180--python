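"""Generator tests: planted structure, determinism, rate calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from scdrugnet.config import SyntheticConfig
from scdrugnet.synthgen import (
    PlantedTruth,
    _passing_mask,
    generate_bundle,
    generate_cell_graphs,
    generate_evidence_tables,
    generate_lr_and_drugs,
    gene_universe,
)


def make_config(**kw):
    base = dict(
        n_cell_types=2, genes_per_cell=60, n_blocks=3, disease_block_ids=(0,),
        n_positive_drugs=2, n_decoy_drugs=2, signature_size=10, n_lr_pairs=6,
        seed=5,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.mark.parametrize(
    "kw",
    [
        dict(n_blocks=999),
        dict(p_in=0.1, p_out=0.2),
        dict(evidence_hit_rate=0.05, background_rate=0.5),
        dict(p_in=1.5),
    ],
)
def test_degenerate_configs_rejected(kw):
    with pytest.raises(ValueError):
        make_config(**kw).validate()


def test_complete_and_empty_blocks():
    """p_in=1, p_out=0 with two blocks of three genes yields two 3-cliques."""
    cfg = make_config(
        n_cell_types=1, genes_per_cell=6, n_blocks=2, p_in=1.0, p_out=0.0,
        disease_block_ids=(0,), junk_edge_fraction=0.0, tf_fraction=0.0,
    )
    graphs, truth = generate_cell_graphs(cfg)
    ppi, _ = graphs[cfg.cell_types[0]]
    assert len(ppi) == 6  # two 3-cliques
    blocks = truth.blocks[cfg.cell_types[0]]
    for row in ppi.itertuples(index=False):
        assert blocks[row.gene_a] == blocks[row.gene_b]


def test_fixed_seed_is_byte_identical(tmp_path):
    cfg = make_config()
    generate_bundle(cfg, tmp_path / "a")
    generate_bundle(cfg, tmp_path / "b")
    for f in sorted((tmp_path / "a").rglob("*")):
        if f.is_file():
            twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert twin.read_bytes() == f.read_bytes(), f.name


def test_planted_partition_edge_counts_within_3_sigma():
    cfg = make_config(genes_per_cell=300, n_blocks=5, junk_edge_fraction=0.0)
    graphs, truth = generate_cell_graphs(cfg)
    cell = cfg.cell_types[0]
    ppi, _ = graphs[cell]
    blocks = truth.blocks[cell]
    within = sum(blocks[a] == blocks[b] for a, b in zip(ppi.gene_a, ppi.gene_b))
    between = len(ppi) - within
    n_within_pairs = sum(
        s * (s - 1) // 2
        for s in pd.Series(blocks).value_counts()
    )
    n_between_pairs = 300 * 299 // 2 - n_within_pairs
    for count, n, p in [(within, n_within_pairs, cfg.p_in), (between, n_between_pairs, cfg.p_out)]:
        mu, sd = n * p, np.sqrt(n * p * (1 - p))
        assert abs(count - mu) <= 3 * sd


def test_evidence_extremes_recover_planted_genes_exactly():
    cfg = make_config(evidence_hit_rate=1.0, background_rate=0.0)
    graphs, truth = generate_cell_graphs(cfg)
    sets, source_map, _ = generate_evidence_tables(truth, cfg)
    for name, genes in sets.items():
        assert genes == set(truth.disease_genes), name


def test_evidence_rates_within_binomial_ci():
    """Observed hit fractions sit inside the exact binomial 99% interval."""
    cfg = make_config(genes_per_cell=1000, evidence_hit_rate=0.6, background_rate=0.05)
    graphs, truth = generate_cell_graphs(cfg)
    sets, _, _ = generate_evidence_tables(truth, cfg)
    disease = set(truth.disease_genes)
    background = set(gene_universe(cfg.genes_per_cell)) - disease
    for name, genes in sets.items():
        n_hit = len(genes & disease)
        lo, hi = binom.ppf([0.005, 0.995], len(disease), cfg.evidence_hit_rate)
        assert lo <= n_hit <= hi, name
        n_bg = len(genes & background)
        lo, hi = binom.ppf([0.005, 0.995], len(background), cfg.background_rate)
        assert lo <= n_bg <= hi, name


def test_drug_labels_balanced_and_decoy_only_config():
    cfg = make_config(n_positive_drugs=0, n_decoy_drugs=4)
    graphs, truth = generate_cell_graphs(cfg)
    extras = generate_lr_and_drugs(truth, cfg, graphs)
    assert truth.positive_drugs == []
    assert len(truth.decoy_drugs) == 4
    assert set(extras["drugs"].drug) == set(truth.decoy_drugs)


def test_positive_targets_in_disease_blocks_and_signatures_local():
    cfg = make_config(n_positive_drugs=3)
    graphs, truth = generate_cell_graphs(cfg)
    extras = generate_lr_and_drugs(truth, cfg, graphs)
    disease = set(truth.disease_genes)
    # one-hop halo in the reference cell graph, confident edges only
    ppi, _ = graphs[cfg.cell_types[0]]
    conf = ppi[_passing_mask(ppi)]
    halo = set()
    for a, b in zip(conf.gene_a, conf.gene_b):
        if a in disease:
            halo.add(b)
        if b in disease:
            halo.add(a)
    drugs = extras["drugs"]
    for drug in truth.positive_drugs:
        target = truth.drug_targets[drug]
        assert target in disease  # inside a planted block
        sig = set(drugs.loc[drugs.drug == drug, "gene"])
        assert sig <= disease | halo  # within one hop of the blocks


def test_lr_pairs_wire_disease_blocks_across_cells():
    cfg = make_config(n_lr_pairs=12)
    graphs, truth = generate_cell_graphs(cfg)
    extras = generate_lr_and_drugs(truth, cfg, graphs)
    lr = extras["lr_pairs"]
    disease = set(truth.disease_genes)
    assert (lr.producing_cell != lr.receiving_cell).all()
    assert lr.ligand_gene.isin(disease).all()  # ligands always from planted blocks


def test_co_block_go_jaccard_exceeds_cross_block():
    cfg = make_config(genes_per_cell=120, seed=3)
    graphs, truth = generate_cell_graphs(cfg)
    extras = generate_lr_and_drugs(truth, cfg, graphs)
    go = extras["go_annotations"]
    ann = go.groupby("gene")["term"].agg(set).to_dict()
    cell = cfg.cell_types[0]
    blocks = truth.blocks[cell]
    rng = np.random.default_rng(0)
    genes = sorted(ann)
    co, cross = [], []
    for _ in range(3000):
        a, b = rng.choice(genes, 2, replace=False)
        j = len(ann[a] & ann[b]) / len(ann[a] | ann[b])
        (co if blocks[a] == blocks[b] else cross).append(j)
    assert np.mean(co) > np.mean(cross)


def test_truth_roundtrip(tmp_path, small_bundle):
    out, truth, cfg = small_bundle
    loaded = PlantedTruth.from_json(out / "truth.json")
    assert loaded.disease_genes == truth.disease_genes
    assert loaded.blocks == truth.blocks
    assert loaded.drug_targets == truth.drug_targets
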