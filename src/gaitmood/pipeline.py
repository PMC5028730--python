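"""End-to-end orchestration: skeleton CSVs -> features -> CV reports.

``run_pipeline`` is fail-soft: a record that cannot be preprocessed or
featurized (parse error, too short, one walking orientation missing) is
dropped with its reason itemized in the manifest, and the remaining
records continue through the pipeline.  Re-running with identical
inputs, configuration and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import features as feat
from .classify import CLASSIFIER_NAMES, evaluate_all, make_binary_task
from .errors import EmptyInputError, GaitError
from .preprocess import PipelineConfig, preprocess_record
from .skeleton_io import (
    FeatureTable,
    read_skeleton_csv,
    write_feature_table,
)

logger = logging.getLogger("gaitmood")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (YAML-serializable)."""

    preprocess: PipelineConfig = field(default_factory=PipelineConfig)
    variance_threshold: float = 0.95
    fft_window: str | None = None
    phase_mean: str = "arithmetic"
    tasks: list[tuple[str, str]] = field(default_factory=list)
    classifiers: list[str] = field(default_factory=lambda: list(CLASSIFIER_NAMES))
    folds: int = 10
    seed: int = 0
    merge_cameras: bool = False
    global_fit: bool = False
    stratified: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"]["kernel"] = [float(w) for w in self.preprocess.kernel]
        d["tasks"] = [list(t) for t in self.tasks]
        return d

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(os.fspath(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        pre = PipelineConfig(**raw.pop("preprocess", {}))
        tasks = [tuple(t) for t in raw.pop("tasks", [])]
        return cls(preprocess=pre, tasks=tasks, **raw)


@dataclass
class RunManifest:
    """Bookkeeping of one run: counts reconcile exactly across stages."""

    config: dict
    inputs: list[str]
    seed: int
    n_records_in: int
    n_records_featurized: int
    drops: list[dict]  # [{"input": ..., "reason": ...}]
    n_segments: int
    feature_table_shape: tuple[int, int]
    outputs: list[str]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "inputs": self.inputs,
            "seed": self.seed,
            "n_records_in": self.n_records_in,
            "n_records_featurized": self.n_records_featurized,
            "drops": self.drops,
            "n_segments": self.n_segments,
            "feature_table_shape": list(self.feature_table_shape),
            "outputs": self.outputs,
        }


def extract_features_from_files(
    paths: list[str], config: RunConfig
) -> tuple[FeatureTable, list[dict], int]:
    """Featurize skeleton CSVs; returns (table, drops, total segment count)."""
    vectors, ids, labels, drops = [], [], [], []
    n_segments = 0
    for path in paths:
        try:
            record = read_skeleton_csv(path)
            segments = preprocess_record(record, config.preprocess)
            n_segments += len(segments)
            seg_feats = [
                feat.segment_features(
                    s, record.frame_rate, window=config.fft_window
                )
                for s in segments
            ]
            vector = feat.aggregate_record(
                seg_feats,
                provenance=os.path.basename(path),
                phase_mean=config.phase_mean,
            )
        except GaitError as err:
            logger.warning("dropping %s: %s", path, err)
            drops.append({"input": path, "reason": str(err)})
            continue
        vectors.append(vector)
        ids.append((record.subject_id, record.condition, record.camera_id))
        labels.append(record.condition)
        logger.info(
            "%s: %d segments (%d front, %d back)",
            os.path.basename(path),
            len(seg_feats),
            vector.n_front,
            vector.n_back,
        )
    return feat.records_to_table(vectors, ids, labels), drops, n_segments


def run_pipeline(
    input_dir: str | os.PathLike,
    config: RunConfig,
    out_dir: str | os.PathLike,
) -> RunManifest:
    """Process every skeleton CSV in ``input_dir`` and write all outputs.

    Writes ``features.csv``, ``reports.json`` (one entry per task x
    classifier) and ``manifest.json`` into ``out_dir``.
    """
    input_dir = os.fspath(input_dir)
    out_dir = os.fspath(out_dir)
    paths = sorted(
        os.path.join(input_dir, f)
        for f in os.listdir(input_dir)
        if f.endswith(".csv")
    )
    if not paths:
        raise EmptyInputError(f"no skeleton CSVs found in {input_dir}")
    os.makedirs(out_dir, exist_ok=True)

    table, drops, n_segments = extract_features_from_files(paths, config)

    features_path = os.path.join(out_dir, "features.csv")
    write_feature_table(table, features_path)
    outputs = [features_path]

    reports = []
    cameras = table.cameras if not config.merge_cameras else [None]
    for label_a, label_b in config.tasks:
        for camera in cameras:
            try:
                task = make_binary_task(
                    table,
                    label_a,
                    label_b,
                    camera=camera,
                    merge_cameras=config.merge_cameras,
                )
                results = evaluate_all(
                    task,
                    classifiers=tuple(config.classifiers),
                    k=config.folds,
                    seed=config.seed,
                    variance_threshold=config.variance_threshold,
                    global_fit=config.global_fit,
                    stratified=config.stratified,
                )
            except GaitError as err:
                logger.warning(
                    "skipping task %s vs %s (camera %s): %s",
                    label_a,
                    label_b,
                    camera,
                    err,
                )
                continue
            for name, report in results.items():
                entry = report.to_dict()
                entry["camera"] = camera
                reports.append(entry)

    reports_path = os.path.join(out_dir, "reports.json")
    with open(reports_path, "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append(reports_path)

    manifest = RunManifest(
        config=config.to_dict(),
        inputs=[os.path.basename(p) for p in paths],
        seed=config.seed,
        n_records_in=len(paths),
        n_records_featurized=table.n_instances,
        drops=[
            {"input": os.path.basename(d["input"]), "reason": d["reason"]}
            for d in drops
        ],
        n_segments=n_segments,
        feature_table_shape=table.values.shape,
        outputs=[os.path.basename(p) for p in outputs],
    )
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
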