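"""Network proximity screening of drug modules against disease modules.

The proximity of a drug module S to a disease module T combines physical and
functional closeness on the cell network:

* ``d_closest(S, T)`` — the average over genes of S of the hop distance to the
  nearest gene of T (the "closest" distance measure);
* ``go_sim(S, T)`` — best-match-average GO biological-process similarity:
  per-gene Jaccard similarity of annotation term sets, averaged over the best
  match of each gene of S in T and vice versa.

Both components are standardized against a null of random gene sets matched to
the drug module's degree sequence (log2 degree bins, small bins merged), with
similarity converted to dissimilarity so that a *lower* combined z means more
proximal and more functionally similar.  Significance is the add-one empirical
p-value of the combined z under the same null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)


class NetworkDistances:
    """All-pairs hop distances for one cell network (cached, index-addressed)."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.nodes: list[str] = sorted(graph.nodes)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols = [], []
        for a, b in graph.edges:
            ia, ib = self.index[a], self.index[b]
            rows += [ia, ib]
            cols += [ib, ia]
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        self.dist = shortest_path(adj, method="D", unweighted=True)
        self.degrees = np.array([graph.degree(node) for node in self.nodes])

    def to_indices(self, genes) -> np.ndarray:
        return np.array(sorted(self.index[g] for g in genes if g in self.index), dtype=int)


def _as_distances(network) -> NetworkDistances:
    return network if isinstance(network, NetworkDistances) else NetworkDistances(network)


def closest_distance(S, T, network) -> float | None:
    """Average closest hop distance from S to T.

    ``d_c(S, T) = mean over s in S' of min_t d(s, t)``, where S' are the
    members of S with at least one reachable member of T; unreachable members
    are excluded with a logged count.  Returns None when S' is empty (the pair
    is skipped)."""
    nd = _as_distances(network)
    s_idx = nd.to_indices(S)
    t_idx = nd.to_indices(T)
    if len(s_idx) == 0 or len(t_idx) == 0:
        return None
    mins = nd.dist[np.ix_(s_idx, t_idx)].min(axis=1)
    finite = np.isfinite(mins)
    if not finite.any():
        logger.debug("closest_distance: no member of S reaches T; pair skipped")
        return None
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.debug("closest_distance: %d unreachable members of S excluded", n_dropped)
    return float(mins[finite].mean())


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def go_bp_similarity(S, T, annotations: dict[str, set[str]]) -> float:
    """Best-match-average Jaccard similarity of GO-BP annotation sets.

    Unannotated genes are excluded; if either side has no annotated gene the
    similarity is 0 (with a warning)."""
    s_ann = [g for g in sorted(set(S)) if annotations.get(g)]
    t_ann = [g for g in sorted(set(T)) if annotations.get(g)]
    if not s_ann or not t_ann:
        logger.warning("go_bp_similarity: no annotated genes on one side; similarity 0")
        return 0.0
    total = 0.0
    best_t = {t: 0.0 for t in t_ann}
    for s in s_ann:
        best = 0.0
        a_s = annotations[s]
        for t in t_ann:
            j = jaccard(a_s, annotations[t])
            if j > best:
                best = j
            if j > best_t[t]:
                best_t[t] = j
        total += best
    total += sum(best_t.values())
    return total / (len(s_ann) + len(t_ann))


class GOIndex:
    """Gene x GO-term binary index aligned to a network's node order, with a
    precomputed pairwise Jaccard matrix for fast best-match averaging."""

    def __init__(self, nd: NetworkDistances, annotations: dict[str, set[str]]):
        self.nd = nd
        n = len(nd.nodes)
        terms = sorted({t for g in nd.nodes for t in annotations.get(g, ())})
        t_index = {t: i for i, t in enumerate(terms)}
        mat = np.zeros((n, len(terms)), dtype=np.float64)
        for i, g in enumerate(nd.nodes):
            for t in annotations.get(g, ()):
                mat[i, t_index[t]] = 1.0
        sizes = mat.sum(axis=1)
        self.annotated = sizes > 0
        inter = mat @ mat.T
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            self.jaccard = np.where(union > 0, inter / union, 0.0)

    def bma_similarity(self, s_idx: np.ndarray, t_idx: np.ndarray) -> float:
        s = s_idx[self.annotated[s_idx]]
        t = t_idx[self.annotated[t_idx]]
        if len(s) == 0 or len(t) == 0:
            return 0.0
        block = self.jaccard[np.ix_(s, t)]
        return float((block.max(axis=1).sum() + block.max(axis=0).sum()) / (len(s) + len(t)))


def degree_bins(nd: NetworkDistances, min_bin_size: int = 10) -> np.ndarray:
    """Assign every network node a log2-degree bin label; bins with fewer than
    ``min_bin_size`` candidate genes merge with the next lower bin (the lowest
    merges upward)."""
    deg = np.maximum(nd.degrees, 1)
    labels = np.floor(np.log2(deg)).astype(int)
    uniq = sorted(set(labels))
    # merge small bins downward, lowest upward, until all are big enough
    merged = {b: b for b in uniq}
    counts = {b: int((labels == b).sum()) for b in uniq}
    order = sorted(counts)
    for b in order[::-1]:
        if counts[b] < min_bin_size:
            lower = [x for x in counts if x < b and counts[x] > 0]
            tgt = max(lower) if lower else min(x for x in counts if x != b and counts[x] > 0)
            counts[tgt] += counts[b]
            counts[b] = 0
            for k, v in merged.items():
                if v == b:
                    merged[k] = tgt
            logger.debug("degree bin %d merged into %d", b, tgt)
    return np.array([merged[l] for l in labels])


def sample_degree_matched(
    nd: NetworkDistances,
    module_idx: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    min_bin_size: int = 10,
) -> np.ndarray:
    """``n_perm`` random gene sets matched to the module's degree-bin profile.

    Sampling is without replacement within each draw.  Returns an integer
    array (n_perm, module size) of node indices."""
    bins = degree_bins(nd, min_bin_size)
    samples = np.empty((n_perm, len(module_idx)), dtype=int)
    col = 0
    for b in sorted(set(bins[module_idx])):
        need = int((bins[module_idx] == b).sum())
        candidates = np.flatnonzero(bins == b)
        if need > len(candidates):  # cannot happen after merging, kept defensive
            raise RuntimeError(f"degree bin {b} exhausted")
        keys = rng.random((n_perm, len(candidates)))
        chosen = np.argpartition(keys, need - 1, axis=1)[:, :need]
        samples[:, col : col + need] = candidates[chosen]
        col += need
    return samples


def null_distribution(
    network,
    module_genes,
    disease_genes,
    annotations: dict[str, set[str]] | GOIndex,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    min_bin_size: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Null samples of (closest distance, GO dissimilarity) for degree-matched
    random gene sets of the drug module's size/degree profile, scored against
    the fixed disease module.  Reproducible under a fixed seed."""
    nd = _as_distances(network)
    go = annotations if isinstance(annotations, GOIndex) else GOIndex(nd, annotations)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s_idx = nd.to_indices(module_genes)
    t_idx = nd.to_indices(disease_genes)
    samples = sample_degree_matched(nd, s_idx, n_perm, rng, min_bin_size)

    dmin_t = nd.dist[:, t_idx].min(axis=1)  # per-node distance to nearest disease gene
    vals = dmin_t[samples]
    finite = np.isfinite(vals)
    with np.errstate(invalid="ignore"):
        d_null = np.where(
            finite.any(axis=1),
            np.nansum(np.where(finite, vals, 0.0), axis=1) / finite.sum(axis=1),
            np.nan,
        )
    dissim_null = np.array([1.0 - go.bma_similarity(row, t_idx) for row in samples])
    bad = ~np.isfinite(d_null)
    if bad.any():
        logger.debug("null_distribution: dropping %d unreachable null draws", int(bad.sum()))
        d_null, dissim_null = d_null[~bad], dissim_null[~bad]
    return d_null, dissim_null


@dataclass
class ProximityResult:
    drug_id: str
    target: str
    cell_type: str
    disease_module_id: str
    d_closest: float
    go_sim: float
    z_distance: float
    z_dissimilarity: float
    combined_z: float
    empirical_p: float
    n_permutations: int
    significant: bool


def _zscore(obs: float, null: np.ndarray, label: str) -> tuple[float, np.ndarray]:
    mu = float(null.mean())
    sigma = float(null.std(ddof=0))
    if sigma == 0.0:
        logger.warning("null %s has zero variance; z set to 0", label)
        return 0.0, np.zeros_like(null)
    return (obs - mu) / sigma, (null - mu) / sigma


def score_drug(
    drug_module,
    disease_module,
    network,
    annotations: dict[str, set[str]] | GOIndex,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    drug_id: str = "",
    target: str = "",
    disease_module_id: str = "",
    min_bin_size: int = 10,
) -> ProximityResult | None:
    """Score one drug module against one disease module.

    Combined z = z(distance) + z(dissimilarity), both standardized against the
    degree-matched null; empirical p uses the add-one rule
    ``(1 + #{null combined <= observed}) / (n_perm + 1)``.  Returns None when
    the drug module cannot reach the disease module at all."""
    nd = _as_distances(network)
    go = annotations if isinstance(annotations, GOIndex) else GOIndex(nd, annotations)
    genes = drug_module.genes if hasattr(drug_module, "genes") else set(drug_module)
    d_obs = closest_distance(genes, disease_module, nd)
    if d_obs is None:
        return None
    sim_obs = go.bma_similarity(nd.to_indices(genes), nd.to_indices(disease_module))
    d_null, dissim_null = null_distribution(
        nd, genes, disease_module, go, n_perm=n_perm, seed=seed, min_bin_size=min_bin_size
    )
    z_d, zn_d = _zscore(d_obs, d_null, "distance")
    z_s, zn_s = _zscore(1.0 - sim_obs, dissim_null, "dissimilarity")
    combined = z_d + z_s
    null_combined = zn_d + zn_s
    n_eff = len(null_combined)
    p = (1 + int((null_combined <= combined).sum())) / (n_eff + 1)
    return ProximityResult(
        drug_id=drug_id or getattr(drug_module, "drug_id", ""),
        target=target or getattr(drug_module, "target_gene", ""),
        cell_type=getattr(drug_module, "cell_type", "") or network_cell(nd),
        disease_module_id=disease_module_id,
        d_closest=d_obs,
        go_sim=sim_obs,
        z_distance=z_d,
        z_dissimilarity=z_s,
        combined_z=combined,
        empirical_p=p,
        n_permutations=n_eff,
        significant=p < alpha,
    )


def network_cell(nd: NetworkDistances) -> str:
    return nd.graph.graph.get("cell_type", "")


def results_table(results: list[ProximityResult]) -> pd.DataFrame:
    rows = [
        {
            "drug": r.drug_id, "target": r.target, "cell": r.cell_type,
            "module": r.disease_module_id, "d_closest": r.d_closest,
            "go_sim": r.go_sim, "z_d": r.z_distance, "z_s": r.z_dissimilarity,
            "combined_z": r.combined_z, "p": r.empirical_p,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["drug", "target", "cell", "module", "d_closest", "go_sim",
                 "z_d", "z_s", "combined_z", "p", "significant"],
    )
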