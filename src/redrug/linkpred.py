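"""Link-prediction model over precomputed neighborhood features.

Training data is the set of compound-treats-disease pairs (positives)
plus uniformly sampled non-edge (drug, disease) pairs — 30 per positive
by default.  Positives carry a higher loss weight because the knowledge
graph is incomplete: absent edges are not certainly negative.  A weighted
random batch sampler over-samples positives so each minibatch holds an
expected 1 : 1.5 positive-to-negative ratio regardless of the global
30 : 1 imbalance.

The scoring model is an encoder-decoder: for each adjacency power k a
linear map embeds Ã^k X, the concatenation is combined linearly into a
250-dimensional node embedding y passed through tanh, and a pair (u, v)
with u the drug and v the disease is scored σ(y_v·ℓ1(y_u) + y_u·ℓ2(y_v))
with ℓ1, ℓ2 linear.  The loss is weighted binary cross-entropy on the
logits, minimized with Adam.  Forward and backward passes are explicit
numpy; the gradients are exercised against finite differences in the
test suite.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .graph_features import NeighborhoodFeatures
from .kg_io import KnowledgeGraph, is_treats_relation

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "SamplerConfig",
    "ModelParams",
    "TrainConfig",
    "ScoreMatrix",
    "extract_treats_pairs",
    "build_training_set",
    "split_train_val",
    "sample_batches",
    "init_params",
    "encode",
    "decode",
    "weighted_bce_loss",
    "train",
    "predict_matrix",
]


@dataclass
class TrainingSet:
    """Labeled (compound, disease) pairs with per-pair loss weights."""

    compound_index: np.ndarray  # int, shape (m,)
    disease_index: np.ndarray  # int, shape (m,)
    label: np.ndarray  # {0, 1}, shape (m,)
    loss_weight: np.ndarray  # positive float, shape (m,)
    neg_per_pos: int
    split: np.ndarray | None = None  # 0 = train, 1 = validation

    def __len__(self) -> int:
        return self.label.size

    @property
    def n_pos(self) -> int:
        return int(self.label.sum())

    @property
    def n_neg(self) -> int:
        return int((self.label == 0).sum())

    def subset(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            compound_index=self.compound_index[mask],
            disease_index=self.disease_index[mask],
            label=self.label[mask],
            loss_weight=self.loss_weight[mask],
            neg_per_pos=self.neg_per_pos,
        )

    @property
    def train(self) -> "TrainingSet":
        if self.split is None:
            raise ValueError("training set has not been split")
        return self.subset(self.split == 0)

    @property
    def validation(self) -> "TrainingSet":
        if self.split is None:
            raise ValueError("training set has not been split")
        return self.subset(self.split == 1)


@dataclass
class SamplerConfig:
    """Weighted batch sampler targeting pos:neg = 1 : target_ratio."""

    target_ratio: float = 1.5
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


@dataclass
class TrainConfig:
    epochs: int = 25
    learning_rate: float = 1e-5
    weight_decay: float = 1e-2
    batch_size: int = 512
    target_ratio: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "learning_rate", "weight_decay", "batch_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ModelParams:
    """Encoder (per-power maps + combiner) and decoder (ℓ1, ℓ2) weights."""

    power_weights: list[np.ndarray]  # each (in_dim, hidden)
    power_biases: list[np.ndarray]  # each (hidden,)
    comb_weight: np.ndarray  # ((K+1)*hidden, out_dim)
    comb_bias: np.ndarray  # (out_dim,)
    l1_weight: np.ndarray  # (out_dim, out_dim)
    l1_bias: np.ndarray  # (out_dim,)
    l2_weight: np.ndarray  # (out_dim, out_dim)
    l2_bias: np.ndarray  # (out_dim,)

    @property
    def K(self) -> int:
        return len(self.power_weights) - 1

    @property
    def out_dim(self) -> int:
        return self.comb_weight.shape[1]

    def named(self) -> dict[str, np.ndarray]:
        out = {
            "comb_weight": self.comb_weight,
            "comb_bias": self.comb_bias,
            "l1_weight": self.l1_weight,
            "l1_bias": self.l1_bias,
            "l2_weight": self.l2_weight,
            "l2_bias": self.l2_bias,
        }
        for k, (w, b) in enumerate(zip(self.power_weights, self.power_biases)):
            out[f"power_weight_{k}"] = w
            out[f"power_bias_{k}"] = b
        return out

    def save(self, path: str | Path) -> None:
        np.savez(Path(path), K=np.asarray(self.K), **self.named())

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(Path(path), allow_pickle=False) as a:
            K = int(a["K"])
            return cls(
                power_weights=[np.asarray(a[f"power_weight_{k}"]) for k in range(K + 1)],
                power_biases=[np.asarray(a[f"power_bias_{k}"]) for k in range(K + 1)],
                comb_weight=np.asarray(a["comb_weight"]),
                comb_bias=np.asarray(a["comb_bias"]),
                l1_weight=np.asarray(a["l1_weight"]),
                l1_bias=np.asarray(a["l1_bias"]),
                l2_weight=np.asarray(a["l2_weight"]),
                l2_bias=np.asarray(a["l2_bias"]),
            )


@dataclass
class ScoreMatrix:
    """|D|×n matrix of edge probabilities, rows diseases, columns drugs."""

    S: np.ndarray
    disease_indices: list[int]
    drug_indices: list[int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape


# ---------------------------------------------------------------------------
# Training data


def extract_treats_pairs(
    graph: KnowledgeGraph,
    drugs: Sequence[int],
    diseases: Sequence[int],
) -> list[tuple[int, int]]:
    """All (drug, disease) entity-index pairs joined by a treats triple.

    Direction-agnostic (compound→disease and disease→compound both
    count); duplicates collapse.
    """
    drug_set, disease_set = set(drugs), set(diseases)
    pairs: set[tuple[int, int]] = set()
    for t in graph.triples:
        if not is_treats_relation(t.relation):
            continue
        u = graph.index[t.head.raw_id]
        v = graph.index[t.tail.raw_id]
        if u in drug_set and v in disease_set:
            pairs.add((u, v))
        elif v in drug_set and u in disease_set:
            pairs.add((v, u))
    return sorted(pairs)


def build_training_set(
    graph: KnowledgeGraph,
    drugs: Sequence[int],
    diseases: Sequence[int],
    neg_per_pos: int = 30,
    positive_weight: float | None = None,
    negative_weight: float = 1.0,
    seed: int = 0,
) -> TrainingSet:
    """Positives = treats pairs; negatives = uniform non-edge pairs.

    Exactly ``neg_per_pos`` negatives are drawn per positive, uniformly
    over drug×disease pairs outside the positive set, with replacement
    across draws.  The default positive loss weight equals ``neg_per_pos``
    so the aggregate class contributions balance.
    """
    positives = extract_treats_pairs(graph, drugs, diseases)
    if not positives:
        raise ValueError("no compound-treats-disease pairs between the given drugs and diseases")
    if positive_weight is None:
        positive_weight = float(neg_per_pos)

    rng = np.random.default_rng(seed)
    drugs_arr = np.asarray(drugs)
    dis_arr = np.asarray(diseases)
    pos_set = set(positives)
    n_universe = drugs_arr.size * dis_arr.size
    if n_universe - len(pos_set) <= 0:
        raise ValueError("no non-edges available to sample negatives from")
    n_needed = neg_per_pos * len(positives)
    if n_needed > n_universe - len(pos_set):
        warnings.warn(
            "negative demand exceeds the non-edge universe; sampled negatives will repeat",
            stacklevel=2,
        )
    neg_c: list[int] = []
    neg_d: list[int] = []
    while len(neg_c) < n_needed:
        chunk = max(1024, n_needed - len(neg_c))
        cs = drugs_arr[rng.integers(0, drugs_arr.size, size=chunk)]
        ds = dis_arr[rng.integers(0, dis_arr.size, size=chunk)]
        for c, d in zip(cs, ds):
            if (int(c), int(d)) in pos_set:
                continue
            neg_c.append(int(c))
            neg_d.append(int(d))
            if len(neg_c) == n_needed:
                break

    comp = np.asarray([p[0] for p in positives] + neg_c, dtype=np.int64)
    dis = np.asarray([p[1] for p in positives] + neg_d, dtype=np.int64)
    label = np.concatenate(
        [np.ones(len(positives), dtype=np.int8), np.zeros(n_needed, dtype=np.int8)]
    )
    weight = np.where(label == 1, positive_weight, negative_weight).astype(np.float64)
    return TrainingSet(
        compound_index=comp,
        disease_index=dis,
        label=label,
        loss_weight=weight,
        neg_per_pos=neg_per_pos,
    )


def split_train_val(ts: TrainingSet, train_frac: float = 0.9, seed: int = 0) -> TrainingSet:
    """Random 90/10 split, stratified by label so both sides see positives."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = np.zeros(len(ts), dtype=np.int8)
    for lab in (0, 1):
        idx = np.flatnonzero(ts.label == lab)
        if idx.size < 2:
            warnings.warn(
                f"too few label-{lab} pairs to stratify; all assigned to train",
                stacklevel=2,
            )
            continue
        perm = rng.permutation(idx)
        n_val = max(1, int(round(idx.size * (1.0 - train_frac))))
        split[perm[:n_val]] = 1
    ts.split = split
    return ts


def sample_batches(
    ts: TrainingSet,
    cfg: SamplerConfig,
    n_batches: int | None = None,
) -> Iterator[np.ndarray]:
    """Weighted sampling with replacement targeting 1 : target_ratio.

    Each pair's sampling probability is set so the expected per-batch
    positive fraction is 1/(1 + target_ratio): positives share mass
    1/(1+R), negatives share R/(1+R), independent of neg_per_pos.
    """
    labels = ts.label
    n_pos, n_neg = ts.n_pos, ts.n_neg
    if n_pos == 0 or n_neg == 0:
        warnings.warn("training set is single-class; batches will be too", stacklevel=2)
        probs = np.full(len(ts), 1.0 / len(ts))
    else:
        p_pos = 1.0 / (1.0 + cfg.target_ratio)
        probs = np.where(labels == 1, p_pos / n_pos, (1.0 - p_pos) / n_neg)
    rng = np.random.default_rng(cfg.seed)
    produced = 0
    while n_batches is None or produced < n_batches:
        yield rng.choice(len(ts), size=cfg.batch_size, replace=True, p=probs)
        produced += 1


# ---------------------------------------------------------------------------
# Model


def init_params(
    K: int = 2,
    in_dim: int = 400,
    hidden_dim: int = 128,
    out_dim: int = 250,
    seed: int = 0,
) -> ModelParams:
    """Glorot-uniform encoder, down-scaled decoder, zero biases, seeded.

    The decoder weights start at 1/10 Glorot scale so initial pair
    logits sit near zero (score ≈ 0.5) instead of at saturated random
    values; the bilinear form y_v·W·y_u otherwise produces logits with a
    standard deviation of several units at Glorot scale.
    """
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out, scale=1.0):
        limit = scale * math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return ModelParams(
        power_weights=[glorot(in_dim, hidden_dim) for _ in range(K + 1)],
        power_biases=[np.zeros(hidden_dim) for _ in range(K + 1)],
        comb_weight=glorot((K + 1) * hidden_dim, out_dim),
        comb_bias=np.zeros(out_dim),
        l1_weight=glorot(out_dim, out_dim, scale=0.1),
        l1_bias=np.zeros(out_dim),
        l2_weight=glorot(out_dim, out_dim, scale=0.1),
        l2_bias=np.zeros(out_dim),
    )


def encode(
    features: NeighborhoodFeatures,
    params: ModelParams,
    nodes: np.ndarray | Sequence[int],
) -> np.ndarray:
    """Node embeddings y = tanh(combiner(concat_k map_k(Ã^k X)[node]))."""
    if features.K != params.K:
        raise ValueError(f"feature stack has K={features.K} but params expect K={params.K}")
    nodes = np.asarray(nodes, dtype=np.int64)
    parts = [
        features.stack[k][nodes] @ params.power_weights[k] + params.power_biases[k]
        for k in range(params.K + 1)
    ]
    h = np.concatenate(parts, axis=1)
    return np.tanh(h @ params.comb_weight + params.comb_bias)


def decode(
    y_u: np.ndarray,
    y_v: np.ndarray,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair scores σ(y_v·ℓ1(y_u) + y_u·ℓ2(y_v)); returns (score, logit).

    The roles are asymmetric: u is the drug, v the disease.  Accepts
    single vectors or aligned batches (rows).
    """
    y_u = np.atleast_2d(np.asarray(y_u, dtype=np.float64))
    y_v = np.atleast_2d(np.asarray(y_v, dtype=np.float64))
    l1u = y_u @ params.l1_weight.T + params.l1_bias
    l2v = y_v @ params.l2_weight.T + params.l2_bias
    logit = np.sum(y_v * l1u, axis=1) + np.sum(y_u * l2v, axis=1)
    score = _sigmoid(logit)
    if score.size == 1:
        return float(score[0]), float(logit[0])
    return score, logit


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def weighted_bce_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Weighted mean of per-pair BCE on logits, stable for large |logit|."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    # log(1 + e^l) - t*l written stably
    per = np.maximum(logits, 0.0) - logits * labels + np.log1p(np.exp(-np.abs(logits)))
    return float(np.sum(weights * per) / np.sum(weights))


def _loss_and_grads(
    features: NeighborhoodFeatures,
    params: ModelParams,
    comp: np.ndarray,
    dis: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Forward + explicit backward for one batch of pairs."""
    nodes, inverse = np.unique(np.concatenate([comp, dis]), return_inverse=True)
    u_pos = inverse[: comp.size]
    v_pos = inverse[comp.size :]

    # forward over unique nodes
    X_parts = [features.stack[k][nodes] for k in range(params.K + 1)]
    parts = [X_parts[k] @ params.power_weights[k] + params.power_biases[k] for k in range(params.K + 1)]
    h = np.concatenate(parts, axis=1)
    z = h @ params.comb_weight + params.comb_bias
    y = np.tanh(z)

    y_u = y[u_pos]
    y_v = y[v_pos]
    l1u = y_u @ params.l1_weight.T + params.l1_bias
    l2v = y_v @ params.l2_weight.T + params.l2_bias
    logit = np.sum(y_v * l1u, axis=1) + np.sum(y_u * l2v, axis=1)

    labels = labels.astype(np.float64)
    weights = weights.astype(np.float64)
    w_sum = np.sum(weights)
    per = np.maximum(logit, 0.0) - logit * labels + np.log1p(np.exp(-np.abs(logit)))
    loss = float(np.sum(weights * per) / w_sum)

    # backward
    g = weights * (_sigmoid(logit) - labels) / w_sum  # dL/dlogit
    gy_u = g[:, None] * (y_v @ params.l1_weight + l2v)
    gy_v = g[:, None] * (l1u + y_u @ params.l2_weight)
    gv = y_v * g[:, None]
    gu = y_u * g[:, None]
    grads: dict[str, np.ndarray] = {
        "l1_weight": gv.T @ y_u,
        "l1_bias": gv.sum(axis=0),
        "l2_weight": gu.T @ y_v,
        "l2_bias": gu.sum(axis=0),
    }

    gy = np.zeros_like(y)
    np.add.at(gy, u_pos, gy_u)
    np.add.at(gy, v_pos, gy_v)
    gz = gy * (1.0 - y * y)
    grads["comb_weight"] = h.T @ gz
    grads["comb_bias"] = gz.sum(axis=0)
    gh = gz @ params.comb_weight.T
    hid = params.power_weights[0].shape[1]
    for k in range(params.K + 1):
        gh_k = gh[:, k * hid : (k + 1) * hid]
        grads[f"power_weight_{k}"] = X_parts[k].T @ gh_k
        grads[f"power_bias_{k}"] = gh_k.sum(axis=0)
    return loss, grads


class _Adam:
    """Adam with coupled weight decay (decay added to the gradient)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _evaluate_loss(features, params, ts: TrainingSet) -> float:
    if len(ts) == 0:
        return float("nan")
    y_u = encode(features, params, ts.compound_index)
    y_v = encode(features, params, ts.disease_index)
    _, logit = decode(y_u, y_v, params)
    return weighted_bce_loss(np.atleast_1d(logit), ts.label, ts.loss_weight)


def train(
    features: NeighborhoodFeatures,
    ts: TrainingSet,
    cfg: TrainConfig,
    params: ModelParams | None = None,
) -> tuple[ModelParams, dict[str, list[float]]]:
    """Minibatch Adam training; returns final params and the loss trace.

    One epoch is ceil(|train| / batch_size) batches from the weighted
    sampler.  The trace records the full-split train and validation loss
    after every epoch (and at epoch 0, i.e. at initialization).
    """
    if ts.split is None:
        raise ValueError("split the training set before training (split_train_val)")
    train_ts = ts.train
    val_ts = ts.validation
    if params is None:
        params = init_params(K=features.K, in_dim=features.dim, seed=cfg.seed)
    named = params.named()
    opt = _Adam(named, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    sampler = sample_batches(
        train_ts,
        SamplerConfig(target_ratio=cfg.target_ratio, batch_size=cfg.batch_size, seed=cfg.seed),
    )
    batches_per_epoch = max(1, math.ceil(len(train_ts) / cfg.batch_size))
    trace: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    trace["train_loss"].append(_evaluate_loss(features, params, train_ts))
    trace["val_loss"].append(_evaluate_loss(features, params, val_ts))
    for epoch in range(1, cfg.epochs + 1):
        for _ in range(batches_per_epoch):
            idx = next(sampler)
            loss, grads = _loss_and_grads(
                features,
                params,
                train_ts.compound_index[idx],
                train_ts.disease_index[idx],
                train_ts.label[idx],
                train_ts.loss_weight[idx],
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.step(named, grads)
        trace["train_loss"].append(_evaluate_loss(features, params, train_ts))
        trace["val_loss"].append(_evaluate_loss(features, params, val_ts))
        logger.info(
            "epoch %d/%d train_loss=%.5f val_loss=%.5f",
            epoch, cfg.epochs, trace["train_loss"][-1], trace["val_loss"][-1],
        )
    return params, trace


def predict_matrix(
    features: NeighborhoodFeatures,
    params: ModelParams,
    drugs: Sequence[int],
    diseases: Sequence[int],
) -> ScoreMatrix:
    """Score every disease×drug combination in one vectorized pass."""
    y_c = encode(features, params, drugs)  # (n, out)
    y_d = encode(features, params, diseases)  # (|D|, out)
    # logit[d, c] = y_d·ℓ1(y_c) + y_c·ℓ2(y_d)
    term1 = y_d @ (y_c @ params.l1_weight.T).T + (y_d @ params.l1_bias)[:, None]
    term2 = (y_c @ (y_d @ params.l2_weight.T).T).T + (y_c @ params.l2_bias)[None, :]
    S = _sigmoid(term1 + term2)
    return ScoreMatrix(S=S, disease_indices=list(diseases), drug_indices=list(drugs))
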