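"""Score standardization and rank-aggregation strategies.

The model emits a |D|×n score matrix over |D| diseases and n drugs.
Every strategy first standardizes scores per disease (z-scores across
drugs) so that "mild" diseases with globally inflated scores do not
dominate, then reduces the matrix to a single top-r drug ranking:

* global mean / global max over diseases,
* mean with the worst ℓ per-drug entries dropped as outliers,
* union of per-disease (or per-cluster) top-x lists with minimal x,
* k-means or Louvain disease clusters with mean reduction inside and
  max reduction across clusters,
* k-means drug clusters ranked by mean cluster score,
* weighted-biclique strategies built on a prefix heuristic: drugs are
  sorted by their summed weight into a disease subset S and the prefix
  length i maximizing i·sum(d_i, S) defines a biclique of value
  i·sum(d_i, S)·|S|.

Tie-breaks are deterministic everywhere: descending score, then
ascending drug index; for the biclique prefix, the smallest maximizing i.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import networkx as nx
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .linkpred import ScoreMatrix

__all__ = [
    "StandardizedScores",
    "Ranking",
    "DiseaseClustering",
    "BicliqueResult",
    "standardize",
    "top_r",
    "agg_global_mean",
    "agg_global_max",
    "agg_mean_outliers",
    "agg_union_diseases",
    "cluster_diseases_kmeans",
    "cluster_diseases_louvain",
    "reduce_clusters",
    "agg_cluster_max",
    "agg_union_clusters",
    "agg_drug_clusters_mean",
    "biclique_core",
    "agg_biclique",
    "agg_cumulative_max",
    "pca_diagnostic",
]

#: Enumeration guard for the per-cluster disease-subset sweep.
MAX_BICLIQUE_CLUSTER_SIZE = 20


@dataclass
class StandardizedScores:
    """Per-disease z-scores ŝ_dc with the row statistics that produced them."""

    Shat: np.ndarray
    row_means: np.ndarray
    row_stds: np.ndarray
    disease_indices: list[int] = field(default_factory=list)
    drug_indices: list[int] = field(default_factory=list)

    @property
    def n_diseases(self) -> int:
        return self.Shat.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.Shat.shape[1]


@dataclass
class Ranking:
    """An ordered, de-duplicated top-r drug list with its scores."""

    drug_order: np.ndarray  # column indices into Shat, length <= r
    scores: np.ndarray
    strategy: str
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.drug_order.size


@dataclass
class DiseaseClustering:
    labels: np.ndarray  # contiguous from 0, one per disease
    method: str
    k: int
    seed: int | None = None


@dataclass
class BicliqueResult:
    disease_subset: np.ndarray
    drug_order: np.ndarray  # all drugs, sorted by decreasing sum(d, S)
    drug_sums: np.ndarray  # aligned to drug_order
    split_index: int  # 1-based prefix length i
    value: float  # i * sum(d_i, S) * |S|


def _as_matrix(scores: ScoreMatrix | StandardizedScores | np.ndarray) -> np.ndarray:
    if isinstance(scores, ScoreMatrix):
        return scores.S
    if isinstance(scores, StandardizedScores):
        return scores.Shat
    return np.asarray(scores, dtype=np.float64)


def standardize(scores: ScoreMatrix | np.ndarray) -> StandardizedScores:
    """Per-disease z-scores: ŝ_dc = (s_dc − μ(s_d·)) / σ(s_d·).

    σ is the population standard deviation (ddof 0).  Rows with zero
    spread become all-zero with a warning instead of NaN.
    """
    S = np.atleast_2d(_as_matrix(scores))
    mu = S.mean(axis=1)
    sigma = S.std(axis=1, ddof=0)
    flat = sigma == 0.0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} disease row(s) have zero score spread; z-scores set to 0",
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, sigma)
    Shat = (S - mu[:, None]) / safe[:, None]
    Shat[flat] = 0.0
    meta = scores if isinstance(scores, ScoreMatrix) else None
    return StandardizedScores(
        Shat=Shat,
        row_means=mu,
        row_stds=sigma,
        disease_indices=list(meta.disease_indices) if meta else [],
        drug_indices=list(meta.drug_indices) if meta else [],
    )


def _descending_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score, ties by ascending index."""
    return np.lexsort((np.arange(scores.size), -scores))


def top_r(scores_per_drug: np.ndarray, r: int, strategy: str = "", params: dict | None = None) -> Ranking:
    """Deterministic top-r selection shared by all strategies."""
    if r < 1:
        raise ValueError("r must be >= 1")
    scores_per_drug = np.asarray(scores_per_drug, dtype=np.float64)
    n = scores_per_drug.size
    if r > n:
        warnings.warn(f"r={r} exceeds n={n}; returning all drugs", stacklevel=2)
        r = n
    order = _descending_order(scores_per_drug)[:r]
    return Ranking(
        drug_order=order,
        scores=scores_per_drug[order],
        strategy=strategy,
        params=dict(params or {}),
    )


# ---------------------------------------------------------------------------
# Flat strategies


def agg_global_mean(scores, r: int) -> Ranking:
    """Mean standardized score over all diseases per drug."""
    Shat = _as_matrix(scores)
    return top_r(Shat.mean(axis=0), r, "global_mean", {"r": r})


def agg_global_max(scores, r: int) -> Ranking:
    """Best single-disease standardized score per drug."""
    Shat = _as_matrix(scores)
    return top_r(Shat.max(axis=0), r, "global_max", {"r": r})


def agg_mean_outliers(scores, l: int, r: int) -> Ranking:
    """Mean over each drug's best |D| − ℓ scores (ℓ worst treated as outliers)."""
    Shat = _as_matrix(scores)
    n_dis = Shat.shape[0]
    if not (0 <= l < n_dis):
        raise ValueError(f"l must satisfy 0 <= l < |D| (got l={l}, |D|={n_dis})")
    kept = np.sort(Shat, axis=0)[l:, :]
    return top_r(kept.mean(axis=0), r, "mean_outliers", {"l": l, "r": r})


def _union_over_rows(rows: np.ndarray, r: int) -> tuple[np.ndarray, int]:
    """Minimal-x union of per-row top-x lists, round-robin merged.

    Rows are ranked independently (descending, index tie-break).  x grows
    from 1 until the union of per-row top-x sets reaches r unique drugs
    (or everything is included).  The merge walks rank positions 1..x,
    rows in order, keeping first occurrences, and truncates to r.
    """
    n_rows, n = rows.shape
    orders = np.stack([_descending_order(rows[i]) for i in range(n_rows)])
    x = 0
    for x in range(1, n + 1):
        if len(set(orders[:, :x].ravel().tolist())) >= min(r, n):
            break
    merged: list[int] = []
    seen: set[int] = set()
    for pos in range(x):
        for row in range(n_rows):
            d = int(orders[row, pos])
            if d not in seen:
                seen.add(d)
                merged.append(d)
            if len(merged) == r:
                return np.asarray(merged), x
    return np.asarray(merged), x


def agg_union_diseases(scores, r: int) -> Ranking:
    """Union of per-disease top-x lists with x minimal to reach r drugs."""
    Shat = _as_matrix(scores)
    if r > Shat.shape[1]:
        warnings.warn(f"r={r} exceeds n={Shat.shape[1]}; returning all drugs", stacklevel=2)
        r = Shat.shape[1]
    order, x = _union_over_rows(Shat, r)
    # score attached = the drug's best rank-producing row score
    scores_out = Shat[:, order].max(axis=0)
    return Ranking(order, scores_out, "union_diseases", {"r": r, "x": x})


# ---------------------------------------------------------------------------
# Disease clustering


def cluster_diseases_kmeans(scores, k: int, seed: int = 0) -> DiseaseClustering:
    """k-means over disease rows (drug scores as features), 10 restarts."""
    Shat = _as_matrix(scores)
    n_dis = Shat.shape[0]
    if not (1 <= k <= n_dis):
        raise ValueError(f"k must satisfy 1 <= k <= |D| (got k={k}, |D|={n_dis})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Shat)
    return DiseaseClustering(labels=_contiguous(labels), method="kmeans", k=k, seed=seed)


def cluster_diseases_louvain(scores, seed: int = 0, resolution: float = 1.0) -> DiseaseClustering:
    """Louvain communities on the thresholded bipartite score graph.

    Negative standardized scores are clipped to zero weight (Louvain
    needs positive weights) and zero-weight edges are omitted, which
    sparsifies the network.  The cluster count is inferred by modularity;
    disease labels are community memberships restricted to disease nodes.
    """
    Shat = _as_matrix(scores)
    n_dis, n_drugs = Shat.shape
    G = nx.Graph()
    G.add_nodes_from(f"dis{i}" for i in range(n_dis))
    rows, cols = np.nonzero(Shat > 0)
    G.add_weighted_edges_from(
        (f"dis{i}", f"drug{j}", float(Shat[i, j])) for i, j in zip(rows, cols)
    )
    if rows.size == 0:
        warnings.warn("no positive scores; all diseases placed in one cluster", stacklevel=2)
        return DiseaseClustering(np.zeros(n_dis, dtype=np.int64), "louvain", 1, seed)
    comms = nx.community.louvain_communities(G, weight="weight", seed=seed, resolution=resolution)
    labels = np.full(n_dis, -1, dtype=np.int64)
    cluster = 0
    for comm in comms:
        members = [int(node[3:]) for node in comm if isinstance(node, str) and node.startswith("dis")]
        if not members:
            continue  # drug-only communities carry no disease label
        for m in members:
            labels[m] = cluster
        cluster += 1
    assert np.all(labels >= 0)
    return DiseaseClustering(_contiguous(labels), "louvain", int(labels.max()) + 1, seed)


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k−1 in order of first appearance."""
    labels = np.asarray(labels, dtype=np.int64)
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if int(lab) not in remap:
            remap[int(lab)] = len(remap)
        out[i] = remap[int(lab)]
    return out


def reduce_clusters(scores, clustering: DiseaseClustering) -> np.ndarray:
    """cluster×drug matrix: each row is the mean of its member disease rows."""
    Shat = _as_matrix(scores)
    k = int(clustering.labels.max()) + 1
    return np.stack([Shat[clustering.labels == g].mean(axis=0) for g in range(k)])


def agg_cluster_max(scores, clustering: DiseaseClustering, r: int) -> Ranking:
    """Mean within disease clusters, max across clusters."""
    reduced = reduce_clusters(scores, clustering)
    return top_r(
        reduced.max(axis=0), r, f"{clustering.method}_cluster_max",
        {"k": clustering.k, "r": r},
    )


def agg_union_clusters(scores, clustering: DiseaseClustering, r: int) -> Ranking:
    """Union-of-top-x applied to cluster-reduced rows instead of diseases."""
    reduced = reduce_clusters(scores, clustering)
    if r > reduced.shape[1]:
        warnings.warn(f"r={r} exceeds n={reduced.shape[1]}; returning all drugs", stacklevel=2)
        r = reduced.shape[1]
    order, x = _union_over_rows(reduced, r)
    return Ranking(
        order, reduced[:, order].max(axis=0), f"union_{clustering.method}_clusters",
        {"k": clustering.k, "r": r, "x": x},
    )


def agg_drug_clusters_mean(scores, k: int, r: int, seed: int = 0) -> Ranking:
    """k-means over drug columns; clusters ranked by mean member score.

    Whole clusters are appended in decreasing mean-score order until r
    drugs are reached; the last cluster is cut by the per-drug mean score
    (ties by drug index).
    """
    Shat = _as_matrix(scores)
    n = Shat.shape[1]
    k = min(k, n)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Shat.T)
    drug_means = Shat.mean(axis=0)
    cluster_means = np.asarray([drug_means[labels == g].mean() for g in range(k)])
    cluster_order = np.lexsort((np.arange(k), -cluster_means))
    picked: list[int] = []
    for g in cluster_order:
        members = np.flatnonzero(labels == g)
        members = members[_descending_order(drug_means[members])]
        remaining = min(r, Shat.shape[1]) - len(picked)
        if remaining <= 0:
            break
        picked.extend(members[:remaining].tolist())
        if len(picked) >= r:
            break
    order = np.asarray(picked[:r])
    return Ranking(order, drug_means[order], "drug_clusters_mean", {"k": k, "r": r})


# ---------------------------------------------------------------------------
# Biclique strategies


def biclique_core(scores, disease_subset: Sequence[int]) -> BicliqueResult:
    """Prefix-maximal weighted biclique induced by a disease subset S.

    Drugs are sorted by decreasing sum(d, S) of (signed) standardized
    scores into S; the prefix length i maximizing i·sum(d_i, S) (smallest
    i on ties) defines the biclique ({d_1..d_i}, S) of value
    i·sum(d_i, S)·|S|.
    """
    Shat = _as_matrix(scores)
    S_idx = np.asarray(sorted(disease_subset), dtype=np.int64)
    if S_idx.size == 0:
        raise ValueError("disease subset must be non-empty")
    sums = Shat[S_idx].sum(axis=0)
    order = _descending_order(sums)
    sorted_sums = sums[order]
    i_range = np.arange(1, order.size + 1, dtype=np.float64)
    objective = i_range * sorted_sums
    i = int(np.argmax(objective)) + 1  # argmax returns the first (smallest) maximizer
    return BicliqueResult(
        disease_subset=S_idx,
        drug_order=order,
        drug_sums=sorted_sums,
        split_index=i,
        value=float(i * sorted_sums[i - 1] * S_idx.size),
    )


def _best_subset(Shat: np.ndarray, diseases: np.ndarray) -> BicliqueResult:
    """Exhaustive sweep over non-empty disease subsets of one cluster."""
    if diseases.size > MAX_BICLIQUE_CLUSTER_SIZE:
        raise ValueError(
            f"cluster of {diseases.size} diseases exceeds the enumeration bound "
            f"({MAX_BICLIQUE_CLUSTER_SIZE}); use more clusters"
        )
    best: BicliqueResult | None = None
    for size in range(1, diseases.size + 1):
        for combo in itertools.combinations(diseases.tolist(), size):
            res = biclique_core(Shat, combo)
            if best is None or res.value > best.value:
                best = res
    assert best is not None
    return best


def agg_biclique(scores, r: int, mode: str = "max", n_clusters: int = 3, seed: int = 0) -> Ranking:
    """Best-biclique ranking within k-means disease clusters.

    Within each cluster the disease subset S* with the largest biclique
    value is found by enumeration; drugs are scored by sum(d, S*).  The
    per-cluster score vectors combine by elementwise max (mode="max") or
    by the union-of-top-x rule (mode="union").
    """
    if mode not in ("max", "union"):
        raise ValueError("mode must be 'max' or 'union'")
    Shat = _as_matrix(scores)
    n_dis = Shat.shape[0]
    k = min(n_clusters, n_dis)
    if k == 1:
        clustering = DiseaseClustering(np.zeros(n_dis, dtype=np.int64), "kmeans", 1, seed)
    else:
        clustering = cluster_diseases_kmeans(Shat, k, seed=seed)
    score_rows = []
    subsets = []
    for g in range(int(clustering.labels.max()) + 1):
        members = np.flatnonzero(clustering.labels == g)
        best = _best_subset(Shat, members)
        score_rows.append(Shat[best.disease_subset].sum(axis=0))
        subsets.append(best.disease_subset.tolist())
    rows = np.stack(score_rows)
    params = {"r": r, "mode": mode, "k": k, "subsets": subsets}
    if mode == "max":
        return top_r(rows.max(axis=0), r, "biclique_max", params)
    if r > rows.shape[1]:
        warnings.warn(f"r={r} exceeds n={rows.shape[1]}; returning all drugs", stacklevel=2)
        r = rows.shape[1]
    order, x = _union_over_rows(rows, r)
    params["x"] = x
    return Ranking(order, rows[:, order].max(axis=0), "union_biclique", params)


def agg_cumulative_max(scores, r: int) -> Ranking:
    """Biclique of the full disease set (no enumeration): rank by sum(d, D)."""
    Shat = _as_matrix(scores)
    res = biclique_core(Shat, np.arange(Shat.shape[0]))
    sums = Shat.sum(axis=0)
    return top_r(sums, r, "cumulative_max", {"r": r, "split_index": res.split_index,
                                             "value": res.value})


# ---------------------------------------------------------------------------
# Diagnostics


def pca_diagnostic(scores, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of disease rows for the cluster-count pair plot.

    Returns (coordinates |D|×n_components, explained-variance shares).
    The cluster count k stays a user decision informed by the plot; no
    automatic choice is made.
    """
    Shat = _as_matrix(scores)
    n_components = min(n_components, *Shat.shape)
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(Shat - Shat.mean(axis=0, keepdims=True))
    return coords, pca.explained_variance_ratio_
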