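"""Run-directory management: the three-stage pipeline behind the CLI.

Executes graph construction -> feature extraction -> agent training ->
evaluation -> explanation in order from a single YAML configuration,
fanning one global seed out to per-stage generators by fixed offsets so
each stage is independently reproducible, and records every artifact in a
digest-checked run manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import agent
from .errors import ConfigError, KrdqnError
from .evaluate import (
    compute_metrics,
    cross_validate,
    score_pairs,
    split_by_drug,
    stratified_confusion,
    write_confusion_tsv,
)
from .features import compute_all_features
from .graph import (
    EntityType,
    KnowledgeGraph,
    extract_demonstration_paths,
    load_graph,
    prune_graph,
)
from .interpret import top_k_paths
from .network import QNetwork
from .synth import SyntheticSpec, generate_eval_pairs, generate_kg, write_dataset

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"synth": 1, "features": 2, "train": 3, "evaluate": 4}

REQUIRED_KEYS = ("seed", "synth", "training", "evaluate")


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)
    episode_log: str | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, verify: bool = True) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        manifest = cls(**data)
        if verify:
            for name, digest in manifest.input_digests.items():
                actual = _sha256(Path(name))
                if actual != digest:
                    raise KrdqnError(f"digest mismatch for {name}: {actual} != {digest}")
        return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    try:
        config = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    validate_config(config)
    return config


def validate_config(config: Any) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ConfigError(f"missing config key: {key!r}")


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + SEED_OFFSETS[stage]) % (2 ** 31)


def write_feature_tsvs(g: KnowledgeGraph, features: dict, out_dir: Path) -> dict[str, Path]:
    out: dict[str, Path] = {}
    for etype in EntityType:
        nids = g.nodes_of_type(etype)
        if not nids:
            continue
        path = out_dir / f"features_{etype.value}.tsv"
        with open(path, "w") as fh:
            for nid in nids:
                vals = "\t".join(f"{v:.6g}" for v in features[nid])
                fh.write(f"{nid}\t{vals}\n")
        out[etype.value] = path
    return out


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline described by ``config`` into ``out_dir``."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config.get("stages", {})
    manifest = RunManifest(seed=seed, config=config)
    stage = "synth"
    try:
        # -- data ------------------------------------------------------------
        synth_cfg = dict(config["synth"])
        synth_cfg.setdefault("seed", _stage_seed(seed, "synth"))
        spec = SyntheticSpec(**synth_cfg)
        g_raw, ground_truth = generate_kg(spec)
        data_dir = out / "data"
        eval_rng = np.random.default_rng(_stage_seed(seed, "evaluate"))
        pair_table = generate_eval_pairs(
            ground_truth, g_raw.nodes_of_type(EntityType.ADR), eval_rng
        )
        files = write_dataset(g_raw, data_dir, pairs=pair_table)
        for name, path in files.items():
            manifest.input_digests[str(path)] = _sha256(path)

        stage = "build-kg"
        g = prune_graph(
            load_graph(
                {r: files[r] for r in ("drug_target", "target_pathway",
                                       "pathway_gene", "gene_adr")},
                {
                    EntityType.DRUG: files["drug_smiles"],
                    EntityType.TARGET: files["target_fasta"],
                    EntityType.GENE: files["gene_fasta"],
                    EntityType.PATHWAY: files["pathway_members"],
                },
            ),
            float(config.get("min_confidence", 0.0)),
        )
        demo_paths = extract_demonstration_paths(g)
        logger.info("pruned graph: %d nodes, %d edges, %d demonstration paths",
                    g.n_nodes, g.n_edges, len(demo_paths))

        stage = "features"
        features = None
        if stages.get("features", True):
            features = compute_all_features(g, seed=_stage_seed(seed, "features"))
            for name, path in write_feature_tsvs(g, features, out).items():
                manifest.artifacts[f"features_{name}"] = str(path)

        # -- split -----------------------------------------------------------
        stage = "evaluate"
        eval_cfg = dict(config["evaluate"])
        drugs_with_pos = sorted({p.drug for p in ground_truth})
        plan = split_by_drug(
            drugs_with_pos, float(eval_cfg.get("ratio", 0.8)),
            np.random.default_rng(_stage_seed(seed, "evaluate")),
        )
        train_pairs = [
            (p.drug, p.adr) for p in ground_truth
            if p.drug in plan.train_drugs and p.drug in g.nodes and p.adr in g.nodes
        ]

        stage = "train"
        net = None
        if stages.get("train", True):
            train_cfg = dict(config["training"])
            train_cfg.setdefault("seed", _stage_seed(seed, "train"))
            tconfig = agent.TrainingConfig(**train_cfg)
            ckpt = out / "checkpoint"
            net, log = agent.train(
                g, demo_paths, train_pairs, tconfig, features=features,
                checkpoint_path=ckpt,
            )
            manifest.artifacts["checkpoint"] = str(ckpt.with_suffix(".npz"))
            log_path = out / "episodes.tsv"
            with open(log_path, "w") as fh:
                fh.write("episode\ttotal_reward\tepsilon\tloss\tlr\treached\n")
                for rec in log:
                    loss = "" if rec.loss is None else f"{rec.loss:.6g}"
                    fh.write(
                        f"{rec.episode}\t{rec.total_reward}\t{rec.epsilon:.6g}\t"
                        f"{loss}\t{rec.lr:.6g}\t{int(rec.reached)}\n"
                    )
            manifest.episode_log = str(log_path)

        stage = "evaluate"
        if stages.get("evaluate", True) and net is not None:
            beam = int(eval_cfg.get("beam_width", 10))
            threshold = float(eval_cfg.get("threshold", 0.5))
            test_pairs = [(d, a, l) for d, a, l in pair_table if d in plan.test_drugs]
            test_pairs = [
                (d, a, l) for d, a, l in test_pairs if d in g.nodes and a in g.nodes
            ]
            records = score_pairs(net, g, test_pairs, beam)
            metrics = compute_metrics(records, threshold)
            metrics["n_test_pairs"] = len(records)
            metrics_path = out / "metrics.json"
            metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
            manifest.artifacts["metrics"] = str(metrics_path)

            freq: dict[str, float] = {a: 0.0 for a in g.nodes_of_type(EntityType.ADR)}
            for p in ground_truth:
                if p.adr in freq:
                    freq[p.adr] += 1
            strat = stratified_confusion(records, freq, threshold=threshold)
            confusion_path = out / "confusion_strata.tsv"
            write_confusion_tsv(strat, confusion_path)
            manifest.artifacts["confusion_strata"] = str(confusion_path)

        stage = "explain"
        if stages.get("explain", True) and net is not None:
            k = int(config.get("explain", {}).get("k", 10))
            n_queries = int(config.get("explain", {}).get("n_pairs", 5))
            queries = [(p.drug, p.adr) for p in ground_truth
                       if p.drug in plan.test_drugs][:n_queries]
            lines = ["drug\tadr\trank\tq_value\tpath"]
            for d, a in queries:
                for ep in top_k_paths(net, g, d, a, k):
                    lines.append(
                        f"{d}\t{a}\t{ep.rank}\t{ep.q_value:.4f}\t"
                        + "->".join(ep.node_ids)
                    )
            paths_path = out / "explanations.tsv"
            paths_path.write_text("\n".join(lines) + "\n")
            manifest.artifacts["explanations"] = str(paths_path)
    except KrdqnError as exc:
        raise KrdqnError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest.save(manifest_path)
    logger.info("manifest written to %s", manifest_path)
    return manifest
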