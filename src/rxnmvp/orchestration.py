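"""Configuration, seeding, and the staged pipeline runner.

A run directory accumulates one artifact set per stage (dataset, vocabulary,
checkpoints, metrics) plus a manifest recording the configuration hash and
input-artifact hashes. Re-running a stage with identical configuration and
inputs is a no-op unless forced. A single global seed fans out to per-stage
seeds by stable hashing, so the whole pipeline is reproducible from one
integer and stages stay decoupled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import chem_data, synthetic_data
from .checkpoint import (checkpoint_hash, load_stage1, save_stage1,
                         load_yield_model, save_yield_model)
from .eval_diagnostics import regression_metrics
from .pretrain_align import Stage1Config, train_stage1
from .tokenizer import Vocabulary, build_vocabulary, tokenize_smiles
from .yield_model import TrainConfig, train_yield_model, _predictions_raw

__all__ = ["RunConfig", "OrchestrationError", "stage_seed", "run_pipeline", "STAGES"]

STAGES = ("make-synthetic", "prep", "pretrain-align", "pretrain-yield", "evaluate")


class OrchestrationError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)       # SyntheticSpec overrides
    curation: dict = field(default_factory=dict)        # low_cut/low_fraction/ratio/bins
    vocab_min_frequency: int = 1
    stage1: dict = field(default_factory=dict)          # Stage1Config overrides
    stage2: dict = field(default_factory=dict)          # TrainConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.manifest.json"


def _stage_current(out: Path, stage: str, cfg_hash: str, inputs: dict[str, str]) -> bool:
    mpath = _manifest_path(out, stage)
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    if manifest.get("config_hash") != cfg_hash or manifest.get("inputs") != inputs:
        return False
    return all(Path(p).exists() for p in manifest.get("artifacts", {}).values())


def _write_manifest(out: Path, stage: str, cfg_hash: str, inputs: dict[str, str],
                    artifacts: dict[str, Path], metrics: Optional[dict] = None) -> None:
    payload = {
        "stage": stage,
        "config_hash": cfg_hash,
        "inputs": inputs,
        "artifacts": {k: str(p) for k, p in artifacts.items()},
        "artifact_hashes": {k: _file_hash(p) for k, p in artifacts.items()},
    }
    if metrics is not None:
        payload["metrics"] = metrics
    _manifest_path(out, stage).write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig, stages: Optional[list[str]] = None,
                 force: bool = False) -> dict:
    """Run the requested stages in order; returns a summary manifest.

    Stage dependencies are checked up front: a stage whose input artifact is
    missing raises an OrchestrationError naming the stage.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise OrchestrationError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    summary: dict = {"config_hash": cfg_hash, "stages": {}}

    dataset_path = out / "dataset.csv"
    curated_path = out / "curated.csv"
    vocab_path = out / "vocab.txt"
    stage1_path = out / "stage1.npz"
    yield_path = out / "yield.npz"
    metrics_path = out / "metrics.json"

    def require(path: Path, stage: str, what: str) -> None:
        if not path.exists():
            raise OrchestrationError(f"stage {stage!r} requires missing {what}: {path}")

    for stage in stages:
        if stage == "make-synthetic":
            inputs: dict[str, str] = {}
            if not force and _stage_current(out, stage, cfg_hash, inputs):
                summary["stages"][stage] = "skipped"
                continue
            spec = synthetic_data.SyntheticSpec(
                seed=stage_seed(cfg.seed, stage), **cfg.synthetic
            )
            dataset = synthetic_data.make_synthetic_dataset(spec)
            chem_data.write_dataset(dataset, dataset_path, format="csv")
            _write_manifest(out, stage, cfg_hash, inputs, {"dataset": dataset_path})
            summary["stages"][stage] = "done"

        elif stage == "prep":
            require(dataset_path, stage, "dataset")
            inputs = {"dataset": _file_hash(dataset_path)}
            if not force and _stage_current(out, stage, cfg_hash, inputs):
                summary["stages"][stage] = "skipped"
                continue
            dataset = chem_data.load_dataset(dataset_path, format="csv")
            seed = stage_seed(cfg.seed, stage)
            cur = cfg.curation
            dataset, rep1 = chem_data.deduplicate_dataset(dataset)
            dataset, rep2 = chem_data.filter_by_yield(
                dataset, cur.get("low_cut", 50.0), cur.get("low_fraction", 1.0), seed
            )
            dataset = chem_data.stratified_split(
                dataset, tuple(cur.get("ratio", (18, 1, 1))), cur.get("bins", 10), seed
            )
            chem_data.write_dataset(dataset, curated_path, format="csv")
            report = rep1.merged_with(rep2)
            report.to_json(out / "curation_report.json")
            _write_manifest(out, stage, cfg_hash, inputs,
                            {"dataset": curated_path,
                             "report": out / "curation_report.json"})
            summary["stages"][stage] = "done"

        elif stage == "pretrain-align":
            src_path = curated_path if curated_path.exists() else dataset_path
            require(src_path, stage, "dataset")
            inputs = {"dataset": _file_hash(src_path)}
            if not force and _stage_current(out, stage, cfg_hash, inputs):
                summary["stages"][stage] = "skipped"
                continue
            dataset = chem_data.load_dataset(src_path, format="csv")
            vocab = build_vocabulary(
                (tokenize_smiles(m.smiles) for r in dataset.records for m in r.molecules()),
                min_frequency=cfg.vocab_min_frequency,
            )
            vocab.save(vocab_path)
            s1cfg = Stage1Config(seed=stage_seed(cfg.seed, stage), **cfg.stage1)
            model, history = train_stage1(dataset, vocab, s1cfg,
                                          log_path=out / "stage1_history.jsonl")
            save_stage1(model, vocab, stage1_path)
            _write_manifest(out, stage, cfg_hash, inputs,
                            {"vocab": vocab_path, "checkpoint": stage1_path},
                            metrics={"final_train_l_total": history[-1]["train_l_total"]})
            summary["stages"][stage] = "done"

        elif stage == "pretrain-yield":
            src_path = curated_path if curated_path.exists() else dataset_path
            for p, what in ((src_path, "dataset"), (vocab_path, "vocabulary"),
                            (stage1_path, "stage-1 checkpoint")):
                require(p, stage, what)
            inputs = {"dataset": _file_hash(src_path),
                      "stage1": checkpoint_hash(stage1_path)}
            if not force and _stage_current(out, stage, cfg_hash, inputs):
                summary["stages"][stage] = "skipped"
                continue
            dataset = chem_data.load_dataset(src_path, format="csv")
            vocab = Vocabulary.load(vocab_path)
            stage1 = load_stage1(stage1_path, vocab)
            cfg2 = TrainConfig(seed=stage_seed(cfg.seed, stage), **cfg.stage2)
            model, history = train_yield_model(
                dataset, vocab, cfg2,
                seq_encoder=stage1.seq_encoder, conf_encoder=stage1.conf_encoder,
            )
            save_yield_model(model, vocab, yield_path)
            _write_manifest(out, stage, cfg_hash, inputs, {"checkpoint": yield_path},
                            metrics={"best_valid_rmse": min(h["valid_rmse"] for h in history)})
            summary["stages"][stage] = "done"

        elif stage == "evaluate":
            src_path = curated_path if curated_path.exists() else dataset_path
            for p, what in ((src_path, "dataset"), (vocab_path, "vocabulary"),
                            (yield_path, "yield checkpoint")):
                require(p, stage, what)
            inputs = {"dataset": _file_hash(src_path),
                      "model": checkpoint_hash(yield_path)}
            if not force and _stage_current(out, stage, cfg_hash, inputs):
                summary["stages"][stage] = "skipped"
                continue
            dataset = chem_data.load_dataset(src_path, format="csv")
            vocab = Vocabulary.load(vocab_path)
            model = load_yield_model(yield_path, vocab)
            test = dataset.subset("test")
            preds = _predictions_raw(model, test.records, vocab, max_len=128)
            truth = np.array([r.yield_pct for r in test.records])
            metrics = regression_metrics(truth, np.clip(preds, 0, 100)).as_dict()
            metrics["n_test"] = len(test.records)
            metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
            _write_manifest(out, stage, cfg_hash, inputs, {"metrics": metrics_path},
                            metrics=metrics)
            summary["stages"][stage] = "done"

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
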