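"""Evidence scoring: Gini oracle, category scoring, ORA statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from scdrugnet.evidence import (
    EvidenceMatrix,
    SubSource,
    bh_adjust,
    gini,
    load_evidence,
    overrepresentation_test,
    score_disease_genes,
)
from scdrugnet.io import write_gmt


def gini_bruteforce(x):
    """Independent oracle: explicit double loop over pairwise differences with
    the n/(n-1) small-sample correction."""
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += abs(x[i] - x[j])
    g = total / (2.0 * n * n * (sum(x) / n))
    return g * n / (n - 1)


@pytest.mark.parametrize(
    "vec,expected",
    [((1, 1, 1), 0.0), ((1, 0, 0), 1.0), ((1, 1, 0), 0.5)],
)
def test_gini_binary_vectors(vec, expected):
    assert gini(vec) == pytest.approx(expected, abs=1e-12)


def test_gini_matches_bruteforce_on_all_binary_3_vectors_and_random():
    for vec in itertools.product([0, 1], repeat=3):
        if not any(vec):
            continue
        assert gini(vec) == pytest.approx(gini_bruteforce(vec), abs=1e-12)
    rng = np.random.default_rng(42)
    for _ in range(200):
        x = rng.uniform(0, 10, size=rng.integers(2, 12))
        if not x.sum():
            continue
        assert gini(x) == pytest.approx(gini_bruteforce(list(x)), rel=1e-10)


def test_gini_rejects_degenerate_input():
    with pytest.raises(ValueError):
        gini([0, 0, 0])
    with pytest.raises(ValueError):
        gini([])
    with pytest.raises(ValueError):
        gini([1, -1, 2])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0.001, max_value=1e3), min_size=2, max_size=20))
def test_gini_bounded_and_scale_invariant(x):
    g = gini(x)
    assert -1e-9 <= g <= 1.0 + 1e-9
    assert gini([v * 7.5 for v in x]) == pytest.approx(g, rel=1e-9, abs=1e-9)


def make_matrix(hits: dict[str, set[str]]) -> EvidenceMatrix:
    meta = {
        "magma_proximity": ("genetics", True, False),
        "emagma_eqtl": ("genetics", False, True),
        "deg_EX": ("expression", False, False),
        "lit_kegg": ("literature", False, False),
    }
    sources = {
        name: SubSource(
            name=name, category=cat, cell="EX" if name.startswith("deg") else None,
            proximity_only=prox, functional=func, genes=hits.get(name, set()),
        )
        for name, (cat, prox, func) in meta.items()
    }
    return EvidenceMatrix(sources)


def test_three_categories_score_four():
    m = make_matrix({"emagma_eqtl": {"g1"}, "deg_EX": {"g1"}, "lit_kegg": {"g1"}})
    row = score_disease_genes(m, ["EX"]).iloc[0]
    assert row.category_sum == 3
    assert row.diversification == pytest.approx(1.0)
    assert row.final_score == pytest.approx(4.0)
    assert row.is_AD_gene


def test_two_categories_score_two_point_five():
    m = make_matrix({"emagma_eqtl": {"g1"}, "lit_kegg": {"g1"}})
    row = score_disease_genes(m, ["EX"]).iloc[0]
    assert row.final_score == pytest.approx(2.5)


def test_proximity_only_gene_is_not_a_disease_gene():
    m = make_matrix({"magma_proximity": {"g1", "g2"}, "lit_kegg": {"g2"}})
    scores = score_disease_genes(m, ["EX"]).set_index("gene")
    assert not scores.loc["g1", "is_AD_gene"]  # locus membership alone
    assert scores.loc["g2", "is_AD_gene"]  # rescued by literature support


def test_single_category_diversification_is_zero_and_score_monotone():
    sources = ["emagma_eqtl", "deg_EX", "lit_kegg"]
    prev = 0.0
    for k in range(1, 4):
        m = make_matrix({s: {"g"} for s in sources[:k]})
        row = score_disease_genes(m, ["EX"]).iloc[0]
        assert row.category_sum <= row.final_score <= row.category_sum + 1
        assert row.final_score > prev
        prev = row.final_score
    m1 = make_matrix({"emagma_eqtl": {"g"}})
    assert score_disease_genes(m1, ["EX"]).iloc[0].diversification == pytest.approx(0.0)


def test_ranking_sorted_with_lexicographic_ties():
    m = make_matrix({"emagma_eqtl": {"zz", "aa"}, "lit_kegg": {"mm", "aa"}})
    df = score_disease_genes(m, ["EX"])
    # aa scores 2.5; zz and mm tie at 1.0 and order lexicographically
    assert list(df.gene) == ["aa", "mm", "zz"]


def test_load_evidence_roundtrip_and_errors(tmp_path):
    write_gmt({"emagma_eqtl": ["g1", "g2", "g2"]}, tmp_path / "eqtl.gmt")
    write_gmt({"lit_kegg": ["g3"]}, tmp_path / "kegg.gmt")
    source_map = pd.DataFrame(
        {
            "source": ["emagma_eqtl", "lit_kegg"],
            "category": ["genetics", "literature"],
            "cell": ["", ""],
            "proximity_only": [False, False],
            "functional": [True, False],
        }
    )
    paths = {"emagma_eqtl": str(tmp_path / "eqtl.gmt"), "lit_kegg": str(tmp_path / "kegg.gmt")}
    matrix = load_evidence(paths, source_map)
    assert matrix.sources["emagma_eqtl"].genes == {"g1", "g2"}  # duplicates collapse
    assert matrix.genes == {"g1", "g2", "g3"}
    with pytest.raises(ValueError, match="unknown sub-source"):
        load_evidence({**paths, "mystery": "x.gmt"}, source_map)
    with pytest.raises(ValueError, match="missing evidence file"):
        load_evidence({"lit_kegg": paths["lit_kegg"]}, source_map)


def bh_stepup_oracle(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def test_bh_matches_stepup_oracle():
    assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
    rng = np.random.default_rng(1)
    for _ in range(50):
        p = rng.uniform(0, 1, size=rng.integers(1, 30))
        assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(list(p)), abs=1e-12)


def test_ora_hypergeometric_tail_and_trivial_case():
    universe = {f"g{i}" for i in range(100)}
    term = {f"g{i}" for i in range(10)}
    query = {f"g{i}" for i in range(5, 15)}
    df = overrepresentation_test(query, {"t": term}, universe)
    # tail sum oracle: P(X >= 5) for overlap 5, term 10, query 10, universe 100
    expected = sum(hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11))
    assert df.iloc[0].p == pytest.approx(expected, abs=1e-12)
    trivial = overrepresentation_test(term, {"t": term}, term)
    assert trivial.iloc[0].p == pytest.approx(1.0)


def test_ora_rejects_bad_inputs():
    with pytest.raises(ValueError):
        overrepresentation_test(set(), {"t": {"a"}}, {"a"})
    with pytest.raises(ValueError):
        overrepresentation_test({"b"}, {"t": {"a"}}, {"a"})
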