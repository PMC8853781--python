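"""End-to-end orchestration: build -> train -> predict -> evaluate.

A run directory is self-describing: it holds the exported graph, the
embedding checkpoint, per-record recommendations, the metrics report, and
a log of the effective configuration, seeds, and an input content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .corpus import DEFAULT_PUNCTUATION, read_corpus
from .embedding import TrainConfig, save_checkpoint, train_model
from .kg import build_kg, export_triples
from .metrics import evaluate_split
from .recommender import RecordNotDiagnosableError, recommend

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    corpus_path: str
    out_dir: str
    dialect: str | None = None
    punctuation: str = DEFAULT_PUNCTUATION
    train: TrainConfig = field(default_factory=TrainConfig)
    shortlist_k: int = 10
    top_n_list: tuple[int, ...] = (1, 3, 5)
    train_fraction: float = 0.8
    seed: int = 0
    include_nursing: bool = True

    def validate(self) -> None:
        if not Path(self.corpus_path).exists():
            raise FileNotFoundError(f"corpus file not found: {self.corpus_path}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    train_raw = raw.pop("train", {}) or {}
    cfg = PipelineConfig(train=TrainConfig(**train_raw), **raw)
    if isinstance(cfg.top_n_list, list):
        cfg.top_n_list = tuple(cfg.top_n_list)
    return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing all artifacts under the run directory.

    A failing stage aborts with the stage name; artifacts written before the
    failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    current = {"stage": "init", "t0": time.perf_counter()}
    run_log: dict = {
        "config": _config_dict(config),
        "corpus_sha256": _sha256(Path(config.corpus_path)),
    }

    def _stage(name: str) -> None:
        logger.info("stage %s starting", name)
        current["stage"] = name
        current["t0"] = time.perf_counter()

    def _done(name: str) -> None:
        stage_times[name] = time.perf_counter() - current["t0"]
        logger.info("stage %s done in %.2fs", name, stage_times[name])

    try:
        _stage("build")
        records = read_corpus(config.corpus_path, config.dialect, require_labels=True)
        config.train.seed = config.seed
        kg = build_kg(
            records,
            include_nursing=config.include_nursing,
            punctuation=config.punctuation,
        )
        export_triples(kg, out / "kg")
        _done("build")

        _stage("train")
        emb = train_model(kg, config.train)
        save_checkpoint(emb, out / "embeddings.npz", vocab_hash=run_log["corpus_sha256"])
        _done("train")

        _stage("predict")
        with (out / "recommendations.tsv").open("w", encoding="utf-8") as fh:
            fh.write("record_id\trank\tsyndrome\tvotes\tsummed_score\n")
            for rec in records:
                try:
                    result = recommend(
                        rec, kg, emb,
                        k=config.shortlist_k,
                        top_n=max(config.top_n_list),
                        punctuation=config.punctuation,
                    )
                except RecordNotDiagnosableError:
                    continue
                for rank, item in enumerate(result.items, start=1):
                    name = kg.entities[item.syndrome_id].name
                    fh.write(
                        f"{rec.record_id}\t{rank}\t{name}\t{item.votes}"
                        f"\t{item.summed_score:.6f}\n"
                    )
        _done("predict")

        _stage("evaluate")
        report = evaluate_split(
            records,
            train_fraction=config.train_fraction,
            seed=config.seed,
            train_config=config.train,
            k=config.shortlist_k,
            top_n_list=config.top_n_list,
        )
        (out / "metrics.json").write_text(
            json.dumps(report.as_dict(), indent=2), encoding="utf-8"
        )
        _done("evaluate")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {exc}") from exc

    run_log["stage_seconds"] = stage_times
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2), encoding="utf-8")
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["top_n_list"] = list(config.top_n_list)
    return d
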