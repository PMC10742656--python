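"""End-to-end orchestration: train on one cohort, screen across cohorts.

The pipeline mirrors the screening protocol: normalize the training
cohort, annotate/partition its features, hold out a random 70% of its
healthy controls to fit the regression models, then — for the training
cohort's remaining samples and for every independent evaluation cohort —
gate targets by predicted-vs-observed PCC, compute mqTrans residuals,
run the two-level differential screen, and classify dark biomarkers
across all screened datasets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mqio
from .containers import AnnotatedExpression
from .preprocess import annotate_and_partition, minmax_normalize, split_controls
from .regression import RegulationResults, TranscriptionRegulationModel
from .screen import DatasetScreenResult, ScreenPolicy, classify_dark_biomarkers, screen_dataset, write_report

logger = logging.getLogger(__name__)


@dataclass
class DatasetPaths:
    """File locations of one cohort (expression + labels)."""

    dataset_id: str
    expression: str
    labels: str


@dataclass
class RunConfig:
    """Configuration of a full train-and-screen run."""

    training: DatasetPaths
    evaluation: list[DatasetPaths]
    annotation: str
    tf_list: str
    output_dir: str = "mqtrans_run"
    train_fraction: float = 0.7
    seed: int = 0
    include_tf_targets: bool = False
    ridge: float = 0.0
    screen_training_remainder: bool = True
    policy: ScreenPolicy = field(default_factory=ScreenPolicy)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.evaluation and not self.screen_training_remainder:
            raise ValueError("need at least one evaluation dataset")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["training"] = DatasetPaths(**d["training"])
        d["evaluation"] = [DatasetPaths(**e) for e in d.get("evaluation", [])]
        if "policy" in d:
            d["policy"] = ScreenPolicy(**d["policy"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_annotated(paths: DatasetPaths, config: RunConfig) -> AnnotatedExpression:
    matrix = mqio.read_expression_matrix(paths.expression, labels=paths.labels)
    annotation = mqio.read_annotation(config.annotation, config.tf_list)
    annotated = annotate_and_partition(matrix, annotation, config.include_tf_targets)
    return minmax_normalize(annotated)


def run_train(config: RunConfig):
    """Fit the regression models; returns (results, held-out evaluation cohort).

    Writes the serialized model set and a training log under the run
    directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _load_annotated(config.training, config)
    train, holdout = split_controls(data, config.train_fraction, config.seed)
    model = TranscriptionRegulationModel(
        train, include_tf_targets=config.include_tf_targets, ridge=config.ridge
    )
    results = model.fit()
    results.save(outdir / "model_set.tsv")
    log = {
        "training_dataset": config.training.dataset_id,
        "n_features_in": int(data.matrix.n_features),
        "n_tf": int(len(train.tf_features)),
        "n_targets_modeled": int(len(results.target_ids)),
        "n_degenerate": int(results.training_pcc.isna().sum()),
        "n_train_controls": int(train.matrix.n_samples),
        "n_holdout_samples": int(holdout.matrix.n_samples),
    }
    (outdir / "train_log.json").write_text(json.dumps(log, indent=2))
    _write_manifest(config, outdir)
    return results, holdout


def screen_one(
    dataset_id: str,
    data: AnnotatedExpression,
    results: RegulationResults,
    policy: ScreenPolicy,
) -> DatasetScreenResult:
    """PCC-gate, mqTrans and two-level screen for one evaluation cohort."""
    present = results.target_ids[results.target_ids.isin(data.matrix.feature_ids)]
    missing = len(results.target_ids) - len(present)
    if missing:
        logger.warning("dataset %s: %d modeled targets absent; screened on the rest", dataset_id, missing)
    sub = RegulationResults(
        tf_order=results.tf_order,
        weights=results.weights.loc[present],
        intercepts=results.intercepts.loc[present],
        training_pcc=results.training_pcc.loc[present],
        training_rmse=results.training_rmse.loc[present],
        n_train=results.n_train,
        annotation=results.annotation,
    ) if missing else results
    pcc = sub.pcc(data)
    pcc[sub.training_pcc.isna()] = float("nan")  # degenerate in training: never screened
    mq = sub.mqtrans(data)
    return screen_dataset(dataset_id, data, mq, pcc, policy)


def run_screen(config: RunConfig, results: RegulationResults, holdout: AnnotatedExpression | None = None):
    """Screen every evaluation cohort and classify dark biomarkers.

    Returns (per-dataset results, cross-dataset call table).  Writes the
    summary and full-statistics reports plus a screen log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    screened: list[DatasetScreenResult] = []
    if config.screen_training_remainder and holdout is not None:
        screened.append(screen_one(config.training.dataset_id, holdout, results, config.policy))
    for paths in config.evaluation:
        data = _load_annotated(paths, config)
        screened.append(screen_one(paths.dataset_id, data, results, config.policy))
    if not screened:
        raise ValueError("nothing to screen: no evaluation datasets and no training remainder")
    calls = classify_dark_biomarkers(screened, config.policy)
    write_report(calls, screened, outdir / "dark_biomarkers.tsv", outdir / "screen_statistics.tsv")
    log = {
        r.dataset_id: {
            "n_targets": int(len(r.feature_ids)),
            "n_eligible": int(r.table["evaluable"].sum()),
            "n_detour": int(r.table["is_detour"].sum()),
            "n_dark": int(r.table["is_dark"].sum()),
        }
        for r in screened
    }
    log["calls"] = {
        "strong": int((calls["call"] == "strong").sum()),
        "weak": int((calls["call"] == "weak").sum()),
    }
    (outdir / "screen_log.json").write_text(json.dumps(log, indent=2))
    _write_manifest(config, outdir)
    return screened, calls


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    cfg = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "seed": config.seed,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def write_config_yaml(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
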