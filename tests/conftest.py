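import json
import time
from pathlib import Path

import networkx as nx
import pandas as pd
import pytest

from scdrugnet.config import PipelineConfig, SyntheticConfig
from scdrugnet.pipeline import Pipeline
from scdrugnet.synthgen import PlantedTruth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic configuration.

    Returns (output directory, planted truth, config, wall time in seconds).
    Shared by the module-recovery, drug-recovery and end-to-end tests.
    """
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(out_dir=str(out), seed=7)
    t0 = time.time()
    Pipeline(cfg).run_all()
    elapsed = time.time() - t0
    truth = PlantedTruth.from_json(out / "inputs" / "truth.json")
    return out, truth, cfg, elapsed


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced synthetic bundle for cheap unit-level checks."""
    from scdrugnet.synthgen import generate_bundle

    out = tmp_path_factory.mktemp("bundle")
    cfg = SyntheticConfig(
        genes_per_cell=150, n_blocks=3, disease_block_ids=(0,),
        n_positive_drugs=2, n_decoy_drugs=3, signature_size=15,
        n_lr_pairs=20, seed=11,
    )
    truth = generate_bundle(cfg, out)
    return out, truth, cfg


@pytest.fixture
def path_graph():
    g = nx.Graph(cell_type="TOY")
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


def read_out(out: Path, name: str) -> pd.DataFrame:
    return pd.read_csv(out / name, sep="\t")


def load_manifest(out: Path) -> dict:
    with open(out / "manifest.json") as fh:
        return json.load(fh)
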