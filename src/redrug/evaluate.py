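"""Evaluation against a truth list of drug names.

Rankings of drug entity columns are compared to an external list of
drugs in clinical trials.  A ranked drug is a hit iff its mapped,
normalized (trimmed + case-folded) name appears in the truth set; drugs
without a name-map entry are counted as unmatched and can never be hits.
Besides hits@top-r per strategy, the module provides a per-disease
median baseline, the hit-position profile, and the collaborative-
filtering experiment (randomly pre-selected truth drugs, hits among the
remainder).
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import aggregate as agg
from .aggregate import Ranking, StandardizedScores, _as_matrix, top_r
from .collab import SimilarityQuery, rank_similar
from .kg_io import NameMap, normalize_name

__all__ = [
    "HitResult",
    "EvaluationReport",
    "hits_at_r",
    "single_disease_median",
    "default_strategy_registry",
    "evaluate_all",
    "cf_experiment",
    "random_baseline",
]


@dataclass
class HitResult:
    hits: int
    positions: list[int]  # 1-based ranks of hits
    hit_names: list[str]
    unmatched: int  # ranked drugs without a name-map entry


@dataclass
class EvaluationReport:
    rows: pd.DataFrame  # strategy, params, hits, positions
    truth_size: int
    r: int

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _drug_name(local_ids: Sequence[str], names: NameMap, col: int) -> str:
    return names.get(local_ids[col])


def hits_at_r(
    ranking: Ranking,
    truth: set[str],
    names: NameMap,
    drug_local_ids: Sequence[str],
) -> HitResult:
    """Count ranked drugs whose mapped name is in the truth set.

    ``drug_local_ids[c]`` is the local (DrugBank) ID of score column c.
    Hit positions are recorded 1-based for the rank-distribution profile.
    """
    truth_norm = {normalize_name(t) for t in truth}
    hits, positions, hit_names, unmatched = 0, [], [], 0
    for pos, col in enumerate(ranking.drug_order, start=1):
        name = _drug_name(drug_local_ids, names, int(col))
        if name == NameMap.UNKNOWN:
            unmatched += 1
            continue
        if normalize_name(name) in truth_norm:
            hits += 1
            positions.append(pos)
            hit_names.append(name)
    return HitResult(hits=hits, positions=positions, hit_names=hit_names, unmatched=unmatched)


def single_disease_median(
    scores,
    truth: set[str],
    names: NameMap,
    drug_local_ids: Sequence[str],
    r: int = 100,
) -> tuple[float, list[int]]:
    """Median over diseases of each single disease's own top-r hits.

    This is the baseline of ranking drugs for each disease alone; the
    median of the per-disease hit counts summarizes it (even count: mean
    of the middle two).  It cannot emit a single drug list, so it lives
    here rather than among the ranking strategies.
    """
    Shat = _as_matrix(scores)
    per_disease: list[int] = []
    for row in Shat:
        ranking = top_r(row, r, "single_disease")
        per_disease.append(hits_at_r(ranking, truth, names, drug_local_ids).hits)
    return float(statistics.median(per_disease)), per_disease


def default_strategy_registry(seed: int = 0) -> list[tuple[str, dict, Callable]]:
    """The sixteen reported strategy configurations.

    Each entry is (display name, params, callable(Shat, r) -> Ranking or
    the median baseline).  Cluster counts follow the reported defaults
    (disease k ∈ {3, 8}, drug k ∈ {250, 500}); the biclique strategies
    use 3-means disease clusters.
    """
    def kmeans_max(k):
        return lambda Shat, r: agg.agg_cluster_max(Shat, agg.cluster_diseases_kmeans(Shat, min(k, Shat.shape[0]), seed), r)

    def kmeans_union(k):
        return lambda Shat, r: agg.agg_union_clusters(Shat, agg.cluster_diseases_kmeans(Shat, min(k, Shat.shape[0]), seed), r)

    def louvain_max(Shat, r):
        return agg.agg_cluster_max(Shat, agg.cluster_diseases_louvain(Shat, seed), r)

    def louvain_union(Shat, r):
        return agg.agg_union_clusters(Shat, agg.cluster_diseases_louvain(Shat, seed), r)

    return [
        ("single_disease_median", {}, None),  # handled specially
        ("global_max", {}, lambda Shat, r: agg.agg_global_max(Shat, r)),
        ("global_mean", {}, lambda Shat, r: agg.agg_global_mean(Shat, r)),
        ("mean_outliers", {"l": 2}, lambda Shat, r: agg.agg_mean_outliers(Shat, 2, r)),
        ("union_diseases", {}, lambda Shat, r: agg.agg_union_diseases(Shat, r)),
        ("kmeans_cluster_max", {"k": 8}, kmeans_max(8)),
        ("kmeans_cluster_max", {"k": 3}, kmeans_max(3)),
        ("union_kmeans_clusters", {"k": 8}, kmeans_union(8)),
        ("union_kmeans_clusters", {"k": 3}, kmeans_union(3)),
        ("union_louvain_clusters", {}, louvain_union),
        ("louvain_cluster_max", {}, louvain_max),
        ("drug_clusters_mean", {"k": 250}, lambda Shat, r: agg.agg_drug_clusters_mean(Shat, 250, r, seed)),
        ("drug_clusters_mean", {"k": 500}, lambda Shat, r: agg.agg_drug_clusters_mean(Shat, 500, r, seed)),
        ("biclique_max", {}, lambda Shat, r: agg.agg_biclique(Shat, r, "max", seed=seed)),
        ("union_biclique", {}, lambda Shat, r: agg.agg_biclique(Shat, r, "union", seed=seed)),
        ("cumulative_max", {}, lambda Shat, r: agg.agg_cumulative_max(Shat, r)),
    ]


def evaluate_all(
    scores,
    truth: set[str],
    names: NameMap,
    drug_local_ids: Sequence[str],
    r: int = 100,
    seed: int = 0,
    strategies: list[tuple[str, dict, Callable]] | None = None,
) -> EvaluationReport:
    """Run every registered strategy and tabulate hits@top-r.

    A strategy that raises is recorded as an error row; the others
    continue.  With fixed seeds the report is reproducible.
    """
    Shat = _as_matrix(scores)
    registry = strategies if strategies is not None else default_strategy_registry(seed)
    records = []
    for name, params, fn in registry:
        try:
            if fn is None:  # the median baseline
                med, per = single_disease_median(Shat, truth, names, drug_local_ids, r)
                records.append({"strategy": name, "params": params, "hits": med,
                                "positions": [], "error": ""})
                continue
            ranking = fn(Shat, r)
            res = hits_at_r(ranking, truth, names, drug_local_ids)
            records.append({"strategy": name, "params": params, "hits": res.hits,
                            "positions": res.positions, "error": ""})
        except Exception as exc:  # keep the rest of the table usable
            records.append({"strategy": name, "params": params, "hits": np.nan,
                            "positions": [], "error": str(exc)})
    return EvaluationReport(rows=pd.DataFrame.from_records(records), truth_size=len(truth), r=r)


def _resolve_truth_columns(
    truth: set[str],
    names: NameMap,
    drug_local_ids: Sequence[str],
) -> np.ndarray:
    truth_norm = {normalize_name(t) for t in truth}
    cols = [
        c for c, lid in enumerate(drug_local_ids)
        if normalize_name(names.get(lid)) in truth_norm
    ]
    return np.asarray(cols, dtype=np.int64)


def cf_experiment(
    scores,
    truth: set[str],
    names: NameMap,
    drug_local_ids: Sequence[str],
    n_preselected: int = 15,
    n_trials: int = 50,
    r: int = 100,
    seed: int = 0,
    pooling: str = "global-pairs",
) -> dict[str, float]:
    """Collaborative-filtering hit statistics over random pre-selections.

    Each trial samples ``n_preselected`` truth drugs without replacement,
    ranks the remaining drugs by score-profile similarity, and counts
    hits among the *other* truth drugs.  Returns mean/min/max hits.
    """
    Shat = _as_matrix(scores)
    truth_cols = _resolve_truth_columns(truth, names, drug_local_ids)
    if truth_cols.size < n_preselected:
        raise ValueError(
            f"only {truth_cols.size} truth drugs resolve to score columns; "
            f"need at least n_preselected={n_preselected}"
        )
    rng = np.random.default_rng(seed)
    hit_counts = []
    truth_set = set(truth_cols.tolist())
    for _ in range(n_trials):
        pre = rng.choice(truth_cols, size=n_preselected, replace=False)
        query = SimilarityQuery(preselected=pre.tolist(), r=r, pooling=pooling)
        ranking = rank_similar(Shat, query)
        remaining_truth = truth_set - set(pre.tolist())
        hit_counts.append(sum(1 for c in ranking.drug_order if int(c) in remaining_truth))
    return {
        "mean": float(np.mean(hit_counts)),
        "min": float(np.min(hit_counts)),
        "max": float(np.max(hit_counts)),
        "n_trials": n_trials,
        "n_preselected": n_preselected,
    }


def random_baseline(
    n_drugs: int,
    truth_cols: set[int] | np.ndarray,
    r: int = 100,
    n_rankings: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Hit counts of uniformly random top-r rankings (null reference)."""
    rng = np.random.default_rng(seed)
    truth_set = set(int(c) for c in np.asarray(list(truth_cols)).ravel())
    out = np.empty(n_rankings, dtype=np.int64)
    for i in range(n_rankings):
        picks = rng.choice(n_drugs, size=min(r, n_drugs), replace=False)
        out[i] = sum(1 for c in picks if int(c) in truth_set)
    return out
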