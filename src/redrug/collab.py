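"""Collaborative filtering over disease-score profiles.

Given drugs already pre-selected as candidates, the remaining drugs are
ranked by cosine similarity of their standardized per-disease score
columns — drugs predicted to help the same diseases are deemed similar.
Two poolings are provided for multi-drug pre-selections: the per-drug
maximum similarity, and a global sweep over all (pre-selected, remaining)
pairs in decreasing similarity emitting each remaining drug at its first
appearance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .aggregate import Ranking, StandardizedScores, _as_matrix

__all__ = ["SimilarityQuery", "drug_similarity", "similarity_matrix", "rank_similar"]


@dataclass
class SimilarityQuery:
    preselected: list[int]
    r: int = 100
    pooling: str = "global-pairs"  # or "max"
    normalize: bool = True  # True = cosine; False = raw dot product

    def __post_init__(self):
        if not self.preselected:
            raise ValueError("preselected set must be non-empty")
        if self.pooling not in ("global-pairs", "max"):
            raise ValueError("pooling must be 'global-pairs' or 'max'")


def _columns(scores, idx: Iterable[int] | None = None) -> np.ndarray:
    Shat = _as_matrix(scores)
    return Shat if idx is None else Shat[:, np.asarray(list(idx), dtype=np.int64)]


def drug_similarity(scores, i: int, j: int, normalize: bool = True) -> float:
    """Cosine similarity of two drugs' disease-score columns.

    Zero-norm columns yield similarity 0 with a warning.  With
    ``normalize=False`` the plain dot product is returned instead (kept
    for sensitivity checks).
    """
    Shat = _as_matrix(scores)
    a, b = Shat[:, i], Shat[:, j]
    if not normalize:
        return float(a @ b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn(f"zero-norm score column in pair ({i}, {j}); similarity set to 0", stacklevel=2)
        return 0.0
    return float((a @ b) / (na * nb))


def similarity_matrix(scores, preselected: list[int], remaining: np.ndarray,
                      normalize: bool = True) -> np.ndarray:
    """(n_preselected × n_remaining) similarity block."""
    Shat = _as_matrix(scores)
    P = Shat[:, preselected].T  # (p, |D|)
    Q = Shat[:, remaining].T  # (m, |D|)
    if normalize:
        def unit(M):
            norms = np.linalg.norm(M, axis=1, keepdims=True)
            zero = norms.ravel() == 0.0
            if np.any(zero):
                warnings.warn(f"{int(zero.sum())} zero-norm score column(s); similarity 0", stacklevel=3)
            norms[norms == 0.0] = 1.0
            return M / norms
        P, Q = unit(P), unit(Q)
    return P @ Q.T


def rank_similar(scores, query: SimilarityQuery) -> Ranking:
    """Rank non-preselected drugs by similarity to the pre-selection.

    pooling="max": each remaining drug is scored by its best similarity
    to any pre-selected drug.  pooling="global-pairs": all pairs are
    pooled and swept in decreasing similarity; a remaining drug enters
    the ranking the first time any of its pairs is reached.  With a
    single pre-selected drug the two poolings coincide.
    """
    Shat = _as_matrix(scores)
    n = Shat.shape[1]
    pre = np.asarray(sorted(set(query.preselected)), dtype=np.int64)
    remaining = np.setdiff1d(np.arange(n), pre)
    r = query.r
    if r > remaining.size:
        warnings.warn(f"r={r} exceeds {remaining.size} remaining drugs; returning all", stacklevel=2)
        r = remaining.size
    sims = similarity_matrix(Shat, pre.tolist(), remaining, normalize=query.normalize)
    if query.pooling == "max":
        best = sims.max(axis=0)
        order_local = np.lexsort((remaining, -best))[:r]
        return Ranking(remaining[order_local], best[order_local], "cofilter_max",
                       {"r": r, "n_preselected": pre.size})
    # global-pairs: sweep (similarity desc, remaining-drug index asc, pre index asc)
    p_idx, m_idx = np.meshgrid(np.arange(pre.size), np.arange(remaining.size), indexing="ij")
    flat_sim = sims.ravel()
    flat_m = m_idx.ravel()
    order = np.lexsort((p_idx.ravel(), remaining[flat_m], -flat_sim))
    chosen: list[int] = []
    chosen_sim: list[float] = []
    seen: set[int] = set()
    for pos in order:
        drug = int(remaining[flat_m[pos]])
        if drug in seen:
            continue
        seen.add(drug)
        chosen.append(drug)
        chosen_sim.append(float(flat_sim[pos]))
        if len(chosen) == r:
            break
    return Ranking(np.asarray(chosen), np.asarray(chosen_sim), "cofilter_global_pairs",
                   {"r": r, "n_preselected": pre.size})
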