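"""Disease-gene evidence aggregation and scoring.

Evidence sub-sources (GMT gene sets) are grouped into three categories —
genetics, expression, literature.  Each gene gets a 0/1 indicator per category
(logical OR over the category's sub-sources applicable to the cell type), a
diversification score ``1 - Gini`` of the category indicator vector that
rewards evidence spread across categories, and a final score = category sum +
diversification.  Genes whose only evidence is the genomic-proximity-only
genetics sub-source (GWAS locus membership without any functional support) are
not considered disease genes: linkage disequilibrium places many bystander
genes inside risk loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from scdrugnet.io import read_gmt

logger = logging.getLogger(__name__)

CATEGORIES = ("genetics", "expression", "literature")


@dataclass
class SubSource:
    name: str
    category: str
    cell: str | None = None  # None: applies to every cell type
    proximity_only: bool = False
    functional: bool = False
    genes: set[str] = field(default_factory=set)


@dataclass
class EvidenceMatrix:
    """Binary gene x sub-source evidence membership with category metadata."""

    sources: dict[str, SubSource]

    def __post_init__(self) -> None:
        for s in self.sources.values():
            if s.category not in CATEGORIES:
                raise ValueError(f"sub-source {s.name}: unknown category {s.category!r}")

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sources.values():
            out |= s.genes
        return out

    def sources_for_cell(self, cell: str) -> list[SubSource]:
        return [s for s in self.sources.values() if s.cell is None or s.cell == cell]


def load_evidence(paths: dict[str, str], source_map: pd.DataFrame) -> EvidenceMatrix:
    """Load GMT evidence files into an :class:`EvidenceMatrix`.

    ``paths`` maps sub-source name to GMT file; ``source_map`` must carry one
    row per sub-source with columns ``source, category, cell, proximity_only,
    functional``.  Every file named in ``source_map`` must be present in
    ``paths``; unknown sub-source names are rejected.
    """
    known = set(source_map["source"])
    unknown = set(paths) - known
    if unknown:
        raise ValueError(f"unknown sub-source name(s): {sorted(unknown)}")
    missing = known - set(paths)
    if missing:
        raise ValueError(f"missing evidence file(s) for: {sorted(missing)}")

    sources: dict[str, SubSource] = {}
    for row in source_map.itertuples(index=False):
        sets = read_gmt(paths[row.source])
        genes: set[str] = set()
        for gs in sets.values():
            genes |= gs
        if not genes:
            logger.warning("evidence sub-source %s is empty; kept", row.source)
        cell = row.cell if isinstance(row.cell, str) and row.cell else None
        sources[row.source] = SubSource(
            name=row.source,
            category=row.category,
            cell=cell,
            proximity_only=bool(row.proximity_only),
            functional=bool(row.functional),
            genes=genes,
        )
    return EvidenceMatrix(sources)


def gini(x) -> float:
    """Unbiased Gini index of a non-negative vector.

    ``G = [sum_ij |x_i - x_j| / (2 n^2 mean)] * n / (n - 1)`` — the
    sample-bias-corrected estimator.  Undefined (raises) for an all-zero or
    empty vector.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("gini of an empty vector is undefined")
    if np.any(x < 0):
        raise ValueError("gini requires non-negative values")
    if not np.any(x > 0):
        raise ValueError("gini of an all-zero vector is undefined")
    n = x.size
    if n == 1:
        return 0.0
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    g = diff_sum / (2.0 * n * n * x.mean())
    return float(g * n / (n - 1))


def score_disease_genes(
    matrix: EvidenceMatrix,
    cell_types,
    admissible: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Score genes per cell type from the evidence matrix.

    Returns one row per (cell_type, gene with any applicable evidence):
    category indicators, ``category_sum``, ``diversification`` (= 1 - Gini of
    the indicator 3-vector; 0 when only one category is hit), ``final_score``
    and ``is_AD_gene``.  Genes whose only evidence is a proximity-only
    genetics sub-source are flagged ``is_AD_gene = False``.  When
    ``admissible`` is given, each cell's rows are restricted to its admissible
    gene set.  Rows are sorted by descending final score, ties broken
    lexicographically by gene symbol.
    """
    frames = []
    for cell in cell_types:
        srcs = matrix.sources_for_cell(cell)
        genes: set[str] = set()
        for s in srcs:
            genes |= s.genes
        if admissible is not None:
            genes &= admissible.get(cell, set())
        rows = []
        for gene in sorted(genes):
            hits = [s for s in srcs if gene in s.genes]
            cats = {s.category for s in hits}
            indicator = np.array([int(c in cats) for c in CATEGORIES])
            csum = int(indicator.sum())
            diversification = 1.0 - gini(indicator) if csum else 0.0
            proximity_only = all(s.proximity_only for s in hits)
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell,
                    "genetics": int(indicator[0]),
                    "expression": int(indicator[1]),
                    "literature": int(indicator[2]),
                    "category_sum": csum,
                    "diversification": diversification,
                    "final_score": csum + diversification,
                    "is_AD_gene": bool(csum) and not proximity_only,
                }
            )
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(
                ["final_score", "gene"], ascending=[False, True]
            ).reset_index(drop=True)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ad_gene_sets(scores: pd.DataFrame) -> dict[str, set[str]]:
    """Per-cell-type disease gene sets (rows with ``is_AD_gene``)."""
    out: dict[str, set[str]] = {}
    for cell, grp in scores.groupby("cell_type"):
        out[str(cell)] = set(grp.loc[grp.is_AD_gene, "gene"])
    return out


def fisher_enrichment_p(overlap: int, query_size: int, term_size: int, universe_size: int) -> float:
    """One-sided Fisher exact p-value, P(X >= overlap) for the hypergeometric
    overlap of a query and a term set drawn from a finite universe."""
    return float(hypergeom.sf(overlap - 1, universe_size, term_size, query_size))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    query: set[str], term_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each term set,
    BH-adjusted across terms.  ``query`` must be a subset of ``universe``;
    term sets are intersected with the universe."""
    if not query:
        raise ValueError("empty query gene set")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    rows = []
    n_u = len(universe)
    n_q = len(query)
    for term, genes in term_sets.items():
        tset = genes & universe
        overlap = len(query & tset)
        p = fisher_enrichment_p(overlap, n_q, len(tset), n_u)
        rows.append({"term": term, "overlap": overlap, "term_size": len(tset), "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "term"]).reset_index(drop=True)
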