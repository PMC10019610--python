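"""End-to-end orchestration: simulate → prepare → train → predict →
aggregate → evaluate / cofilter.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected)
drives every stage.  Each stage writes its artifacts plus a manifest
entry (input checksums, parameters, seed, wall time); re-running with
unchanged inputs skips the stage, so a pipeline run is idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from .collab import SimilarityQuery, rank_similar
from .evaluate import evaluate_all
from .graph_features import (
    build_adjacency,
    load_features,
    neighborhood_features,
    normalize_adjacency,
    save_features,
)
from .kg_io import (
    EntityType,
    filter_graph,
    read_candidate_list,
    read_embeddings,
    read_name_map,
    read_triples,
    select_covid_diseases,
    select_drugs,
    write_embeddings,
)
from .linkpred import (
    ModelParams,
    ScoreMatrix,
    TrainConfig,
    build_training_set,
    predict_matrix,
    split_train_val,
    train,
)
from .synth import SyntheticKGSpec, gen_kg

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "train", "predict", "aggregate", "evaluate", "cofilter")


@dataclass
class RunConfig:
    """Paths, hyperparameters and seeds for a pipeline run."""

    out_dir: str = "run"
    triples: str | None = None
    embeddings: str | None = None
    truth: str | None = None
    name_map: str | None = None
    strict: bool = True
    # graph features
    K: int = 2
    # model
    hidden_dim: int = 128
    out_dim: int = 250
    epochs: int = 25
    learning_rate: float = 1e-5
    weight_decay: float = 1e-2
    neg_per_pos: int = 30
    batch_size: int = 512
    target_ratio: float = 1.5
    # aggregation / evaluation
    r: int = 100
    strategy: str = "union_kmeans_clusters"
    l_outliers: int = 2
    k_clusters: int = 3
    drug_k: int = 250
    biclique_mode: str = "max"
    # collaborative filtering
    preselected: str | None = None  # file of drug local IDs
    pooling: str = "global-pairs"
    # synthetic stage
    synth_kg: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fingerprint(self, inputs: list[Path], params: dict) -> str:
        parts = [f"{p.name}:{_checksum(p)}" for p in inputs if p.exists()]
        parts.append(json.dumps(params, sort_keys=True, default=str))
        return hashlib.sha256("|".join(parts).encode()).hexdigest()

    def is_cached(self, stage: str, fp: str, outputs: list[Path]) -> bool:
        entry = self.data.get(stage)
        return bool(entry and entry.get("fingerprint") == fp and all(p.exists() for p in outputs))

    def record(self, stage: str, fp: str, seconds: float, seed: int) -> None:
        self.data[stage] = {
            "fingerprint": fp,
            "seconds": round(seconds, 3),
            "seed": seed,
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def _load_graph(cfg: RunConfig):
    triples = read_triples(cfg.triples, strict=cfg.strict)
    return filter_graph(triples)


def _drug_disease_sets(graph):
    drugs = select_drugs(graph)
    diseases = select_covid_diseases(graph)
    if not diseases:  # fall back to every disease entity
        from .kg_io import select_entities

        diseases = select_entities(graph, EntityType.DISEASE)
    return drugs, diseases


def run(cfg: RunConfig, stages: list[str] | None = None) -> dict[str, Path]:
    """Execute the requested stages in pipeline order.

    Raises if a stage's upstream artifact is missing.  Returns the map
    of produced artifact paths.
    """
    stages = list(stages or STAGES[1:])  # simulate only on request
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage '{s}'; choose from {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    artifacts: dict[str, Path] = {}

    paths = {
        "features": out / "features.npz",
        "params": out / "model_params.npz",
        "trace": out / "loss_trace.csv",
        "scores": out / "score_matrix.csv",
        "ranking": out / "ranking.tsv",
        "report": out / "evaluation.tsv",
        "cofilter": out / "cofilter.tsv",
    }

    if "simulate" in stages:
        _stage_simulate(cfg, out, manifest)
        cfg.triples = str(out / "synthetic_triples.tsv")
        cfg.embeddings = str(out / "synthetic_embeddings.npz")
        cfg.truth = str(out / "synthetic_truth.txt")
        cfg.name_map = str(out / "synthetic_name_map.tsv")

    if "prepare" in stages:
        _require(cfg.triples, "prepare", "triples")
        _require(cfg.embeddings, "prepare", "embeddings")
        fp = manifest.fingerprint([Path(cfg.triples), Path(cfg.embeddings)],
                                  {"K": cfg.K, "strict": cfg.strict})
        if manifest.is_cached("prepare", fp, [paths["features"]]):
            logger.info("prepare: cached")
        else:
            t0 = time.time()
            graph = _load_graph(cfg)
            X = read_embeddings(cfg.embeddings, graph, strict=cfg.strict)
            feats = neighborhood_features(normalize_adjacency(build_adjacency(graph)), X, cfg.K)
            save_features(paths["features"], graph, feats)
            manifest.record("prepare", fp, time.time() - t0, cfg.seed)
        artifacts["features"] = paths["features"]

    if "train" in stages:
        _require_file(paths["features"], "train", "prepare")
        fp = manifest.fingerprint(
            [paths["features"]],
            {k: getattr(cfg, k) for k in
             ("epochs", "learning_rate", "weight_decay", "neg_per_pos",
              "batch_size", "target_ratio", "seed", "hidden_dim", "out_dim")},
        )
        if manifest.is_cached("train", fp, [paths["params"], paths["trace"]]):
            logger.info("train: cached")
        else:
            t0 = time.time()
            graph = _load_graph(cfg)
            _, feats = load_features(paths["features"])
            drugs, diseases = _drug_disease_sets(graph)
            ts = build_training_set(graph, drugs, diseases, cfg.neg_per_pos, seed=cfg.seed)
            ts = split_train_val(ts, seed=cfg.seed)
            tc = TrainConfig(
                epochs=cfg.epochs, learning_rate=cfg.learning_rate,
                weight_decay=cfg.weight_decay, batch_size=cfg.batch_size,
                target_ratio=cfg.target_ratio, seed=cfg.seed,
            )
            from .linkpred import init_params

            params = init_params(K=feats.K, in_dim=feats.dim, hidden_dim=cfg.hidden_dim,
                                 out_dim=cfg.out_dim, seed=cfg.seed)
            params, trace = train(feats, ts, tc, params=params)
            params.save(paths["params"])
            pd.DataFrame(trace).to_csv(paths["trace"], index_label="epoch")
            manifest.record("train", fp, time.time() - t0, cfg.seed)
        artifacts["params"] = paths["params"]
        artifacts["trace"] = paths["trace"]

    if "predict" in stages:
        _require_file(paths["params"], "predict", "train")
        fp = manifest.fingerprint([paths["features"], paths["params"]], {})
        if manifest.is_cached("predict", fp, [paths["scores"]]):
            logger.info("predict: cached")
        else:
            t0 = time.time()
            graph = _load_graph(cfg)
            _, feats = load_features(paths["features"])
            params = ModelParams.load(paths["params"])
            drugs, diseases = _drug_disease_sets(graph)
            sm = predict_matrix(feats, params, drugs, diseases)
            _write_scores(paths["scores"], graph, sm)
            manifest.record("predict", fp, time.time() - t0, cfg.seed)
        artifacts["scores"] = paths["scores"]

    if "aggregate" in stages:
        _require_file(paths["scores"], "aggregate", "predict")
        t0 = time.time()
        shat, drug_ids, _ = _read_scores_standardized(paths["scores"])
        ranking = _run_strategy(cfg, shat)
        _write_ranking(paths["ranking"], ranking, drug_ids, cfg)
        manifest.record("aggregate", manifest.fingerprint([paths["scores"]], {"strategy": cfg.strategy}),
                        time.time() - t0, cfg.seed)
        artifacts["ranking"] = paths["ranking"]

    if "evaluate" in stages:
        _require_file(paths["scores"], "evaluate", "predict")
        _require(cfg.truth, "evaluate", "truth")
        _require(cfg.name_map, "evaluate", "name_map")
        t0 = time.time()
        shat, drug_ids, _ = _read_scores_standardized(paths["scores"])
        truth = read_candidate_list(cfg.truth)
        names = read_name_map(cfg.name_map)
        local_ids = [d.split("::", 1)[-1] for d in drug_ids]
        report = evaluate_all(shat, truth, names, local_ids, r=cfg.r, seed=cfg.seed)
        report.to_tsv(paths["report"])
        manifest.record("evaluate", manifest.fingerprint([paths["scores"]], {"r": cfg.r}),
                        time.time() - t0, cfg.seed)
        artifacts["report"] = paths["report"]

    if "cofilter" in stages:
        _require_file(paths["scores"], "cofilter", "predict")
        _require(cfg.preselected, "cofilter", "preselected")
        t0 = time.time()
        shat, drug_ids, _ = _read_scores_standardized(paths["scores"])
        wanted = {line.strip() for line in Path(cfg.preselected).read_text().splitlines() if line.strip()}
        local_ids = [d.split("::", 1)[-1] for d in drug_ids]
        pre = [i for i, lid in enumerate(local_ids) if lid in wanted or drug_ids[i] in wanted]
        if not pre:
            raise ValueError("none of the preselected drug IDs match score columns")
        ranking = rank_similar(shat, SimilarityQuery(preselected=pre, r=cfg.r, pooling=cfg.pooling))
        _write_ranking(paths["cofilter"], ranking, drug_ids, cfg)
        manifest.record("cofilter", manifest.fingerprint([paths["scores"]], {"r": cfg.r}),
                        time.time() - t0, cfg.seed)
        artifacts["cofilter"] = paths["cofilter"]

    return artifacts


def _stage_simulate(cfg: RunConfig, out: Path, manifest: _Manifest) -> None:
    t0 = time.time()
    spec = SyntheticKGSpec(**{**cfg.synth_kg, "seed": cfg.seed})
    synth = gen_kg(spec)
    with (out / "synthetic_triples.tsv").open("w") as fh:
        for t in synth.graph.triples:
            fh.write(f"{t.head.raw_id}\t{t.relation}\t{t.tail.raw_id}\n")
    write_embeddings(out / "synthetic_embeddings.npz", synth.graph, synth.embeddings)
    # synthetic truth: compounds most likely to treat, by planted probability
    mean_prob = synth.treats_prob.mean(axis=1)
    top = np.argsort(-mean_prob)[: max(10, spec.n_compounds // 5)]
    with (out / "synthetic_name_map.tsv").open("w") as fh:
        for cid in synth.compound_ids:
            local = cid.split("::", 1)[1]
            fh.write(f"{local}\tsynthetic drug {local}\n")
    with (out / "synthetic_truth.txt").open("w") as fh:
        for ci in top:
            local = synth.compound_ids[int(ci)].split("::", 1)[1]
            fh.write(f"synthetic drug {local}\n")
    manifest.record("simulate", "synthetic", time.time() - t0, cfg.seed)


def _run_strategy(cfg: RunConfig, shat: np.ndarray):
    s = cfg.strategy
    if s == "global_mean":
        return agg.agg_global_mean(shat, cfg.r)
    if s == "global_max":
        return agg.agg_global_max(shat, cfg.r)
    if s == "mean_outliers":
        return agg.agg_mean_outliers(shat, cfg.l_outliers, cfg.r)
    if s == "union_diseases":
        return agg.agg_union_diseases(shat, cfg.r)
    if s == "kmeans_cluster_max":
        cl = agg.cluster_diseases_kmeans(shat, min(cfg.k_clusters, shat.shape[0]), cfg.seed)
        return agg.agg_cluster_max(shat, cl, cfg.r)
    if s == "union_kmeans_clusters":
        cl = agg.cluster_diseases_kmeans(shat, min(cfg.k_clusters, shat.shape[0]), cfg.seed)
        return agg.agg_union_clusters(shat, cl, cfg.r)
    if s == "louvain_cluster_max":
        return agg.agg_cluster_max(shat, agg.cluster_diseases_louvain(shat, cfg.seed), cfg.r)
    if s == "union_louvain_clusters":
        return agg.agg_union_clusters(shat, agg.cluster_diseases_louvain(shat, cfg.seed), cfg.r)
    if s == "drug_clusters_mean":
        return agg.agg_drug_clusters_mean(shat, cfg.drug_k, cfg.r, cfg.seed)
    if s == "biclique":
        return agg.agg_biclique(shat, cfg.r, cfg.biclique_mode, seed=cfg.seed)
    if s == "cumulative_max":
        return agg.agg_cumulative_max(shat, cfg.r)
    raise ValueError(f"unknown strategy '{s}'")


def _write_scores(path: Path, graph, sm: ScoreMatrix) -> None:
    drug_ids = [graph.entities[i].raw_id for i in sm.drug_indices]
    dis_ids = [graph.entities[i].raw_id for i in sm.disease_indices]
    pd.DataFrame(sm.S, index=dis_ids, columns=drug_ids).to_csv(path)


def _read_scores_standardized(path: Path):
    df = pd.read_csv(path, index_col=0)
    std = agg.standardize(df.to_numpy(dtype=np.float64))
    return std.Shat, list(df.columns), list(df.index)


def _write_ranking(path: Path, ranking, drug_ids, cfg: RunConfig) -> None:
    rows = [
        {
            "rank": pos,
            "drug_id": drug_ids[int(c)],
            "aggregate_score": float(s),
            "strategy": ranking.strategy,
            "params": json.dumps(ranking.params, default=str),
        }
        for pos, (c, s) in enumerate(zip(ranking.drug_order, ranking.scores), start=1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _require(value, stage: str, what: str) -> None:
    if not value:
        raise FileNotFoundError(f"stage '{stage}' needs '{what}' (missing config or upstream stage)")


def _require_file(path: Path, stage: str, upstream: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run the '{upstream}' stage first"
        )
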