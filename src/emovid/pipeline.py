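"""End-to-end experiment orchestration.

``run_experiment`` executes the whole chain — synthesize corpus, gap-fill,
segment to the emotional phase, score subject difficulty, assign splits,
train every model in the task x head x feature grid, and evaluate on the
validation and test splits — writing all artifacts (summary tables, per-model
reports, split file, config copy with seeds) into one output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .datamodel import VideoRecord, fill_face_gaps
from .evaluation import evaluate_predictions
from .models import (
    BINARY_CLASSES,
    MULTICLASS_CLASSES,
    LeakageError,
    ModelConfig,
    predict_records,
    train_model,
)
from .partitioning import assign_splits, loso_difficulty_scores, split_records
from .segmentation import segment_record
from .synthetic import SyntheticConfig, attach_deep_features, generate_corpus

__all__ = ["ExperimentConfig", "run_experiment", "ExperimentError"]

logger = logging.getLogger("emovid")


class ExperimentError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    tasks: tuple = ("binary", "multiclass")
    heads: tuple = ("average", "attention", "convolution")
    feature_kinds: tuple = ("appearance",)
    pad_after_s: float = 1.0
    threshold_frac: float = 0.1
    min_gap_s: float = 0.3
    split_pattern: tuple = (3, 1, 1)
    split_tail: str = "strict"
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0
    bootstrap_B: int = 1000

    def __post_init__(self) -> None:
        if not self.tasks or not self.heads or not self.feature_kinds:
            raise ValueError("the task x head x feature grid must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        for key in ("tasks", "heads", "feature_kinds", "split_pattern"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        syn = dict(self.synthetic.__dict__)
        syn["per_emotion_counts"] = {k.value: v for k, v in syn["per_emotion_counts"].items()}
        d["synthetic"] = syn
        for key in ("tasks", "heads", "feature_kinds", "split_pattern", "phase_durations"):
            if key in d and isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d


def _prepare_corpus(cfg: ExperimentConfig) -> list[VideoRecord]:
    syn = SyntheticConfig(**{**cfg.synthetic.__dict__, "seed": cfg.synthetic.seed + cfg.seed})
    t0 = time.time()
    corpus = generate_corpus(syn)
    logger.info("simulate: %d videos, %d subjects (%.1fs)",
                len(corpus), len({r.subject_id for r in corpus}), time.time() - t0)
    needs_deep = any(k in ("deep", "concatenated") for k in cfg.feature_kinds)
    if needs_deep:
        attach_deep_features(corpus, seed=cfg.seed)
    segmented = []
    for rec in corpus:
        try:
            rec = VideoRecord(
                subject_id=rec.subject_id, label=rec.label,
                features=fill_face_gaps(rec.features),
                audio_envelope=rec.audio_envelope, envelope_fps=rec.envelope_fps,
                phase=rec.phase, video_id=rec.video_id, deep_features=rec.deep_features,
            )
            segmented.append(
                segment_record(rec, cfg.pad_after_s, cfg.threshold_frac, cfg.min_gap_s)
            )
        except Exception as e:
            raise ExperimentError(f"segment: failed on record {rec.video_id!r}: {e}") from e
    logger.info("segment: done")
    return segmented


def _verify_no_leakage(splits: dict) -> None:
    seen: dict[str, str] = {}
    for split, records in splits.items():
        for rec in records:
            if rec.subject_id in seen and seen[rec.subject_id] != split:
                raise LeakageError(
                    f"subject {rec.subject_id!r} in both {seen[rec.subject_id]} and {split}"
                )
            seen[rec.subject_id] = split


def run_experiment(cfg: ExperimentConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns a dict of summary tables and reports.

    Writes to ``outdir``: config.yaml (immutable run copy), splits.csv,
    summary_<task>.csv (rows = feature kinds, columns = heads, values =
    test UAR %), and report.json with the full metric battery per model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({"emovid_version": __version__, **cfg.to_dict()}, fh, sort_keys=False)

    corpus = _prepare_corpus(cfg)

    try:
        scores = loso_difficulty_scores(corpus)
    except Exception as e:
        raise ExperimentError(f"split: difficulty scoring failed: {e}") from e
    assignment = assign_splits(scores, cfg.split_pattern, cfg.split_tail)
    assignment.to_csv(outdir / "splits.csv")
    splits = split_records(corpus, assignment)
    _verify_no_leakage(splits)
    logger.info("split: sizes %s", assignment.sizes())

    reports: dict = {}
    summaries: dict = {}
    for task in cfg.tasks:
        class_names = BINARY_CLASSES if task == "binary" else MULTICLASS_CLASSES
        chance = 1.0 / len(class_names)
        table = pd.DataFrame(index=list(cfg.feature_kinds), columns=list(cfg.heads), dtype=float)
        for kind in cfg.feature_kinds:
            for head in cfg.heads:
                mc = ModelConfig(
                    task=task, head=head, feature_kind=kind,
                    max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed,
                )
                t0 = time.time()
                try:
                    model = train_model(splits["train"], splits["validation"], mc)
                except Exception as e:
                    raise ExperimentError(f"train: {task}/{head}/{kind} failed: {e}") from e
                entry = {}
                for split in ("validation", "test"):
                    pred = predict_records(model, splits[split])
                    truth = [
                        r.label.valence if task == "binary" else r.label.value
                        for r in splits[split]
                    ]
                    rep = evaluate_predictions(
                        truth, pred, class_names, chance_p0=chance,
                        bootstrap_B=cfg.bootstrap_B, seed=cfg.seed,
                    )
                    entry[split] = rep.to_dict()
                entry["best_epoch"] = model.best_epoch
                entry["epochs_run"] = len(model.history)
                reports[f"{task}/{head}/{kind}"] = entry
                table.loc[kind, head] = round(100 * entry["test"]["uar"], 1)
                logger.info(
                    "train: %s/%s/%s test UAR %.1f%% (%.1fs)",
                    task, head, kind, 100 * entry["test"]["uar"], time.time() - t0,
                )
        table.to_csv(outdir / f"summary_{task}.csv")
        summaries[task] = table

    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "split_sizes": assignment.sizes(),
                "difficulty_scores": {k: float(v) for k, v in scores.items()},
                "models": reports,
            },
            fh, indent=2,
        )
    return {"summaries": summaries, "reports": reports, "assignment": assignment}
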