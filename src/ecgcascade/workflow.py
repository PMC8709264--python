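"""High-level pipeline stages tying preprocessing, datasets, models, and metrics together.

These are the library entry points the CLI (and any batch script) wraps:
prepare annotated records into interpatient train/test beat datasets, train
the baseline or two-phase models, and evaluate them with the full metric
suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import classifiers, dataset_builder, evaluation, preprocess
from .types import (
    FIVE_CLASS,
    WORKING_RATE_HZ,
    BeatAnnotation,
    BeatDataset,
    ECGRecord,
    Heartbeat,
)
from .synthetic_ecg import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


def preprocess_record(
    record: ECGRecord, annotations: Sequence[BeatAnnotation]
) -> list[Heartbeat]:
    """Run one record through the full conditioning chain and segment it.

    Order is fixed: resample to 360 Hz (annotations rescaled alongside),
    two-median-filter baseline removal, [0,1] normalization, 600 ms
    windowing with AAMI label mapping.
    """
    source_rate = record.sampling_rate_hz
    if not np.isclose(source_rate, WORKING_RATE_HZ):
        record = preprocess.resample_signal(record, WORKING_RATE_HZ)
        annotations = preprocess.rescale_annotations(
            list(annotations), source_rate, WORKING_RATE_HZ
        )
    record = preprocess.remove_baseline(record)
    record = preprocess.normalize_amplitude(record)
    return preprocess.segment_heartbeats(record, list(annotations), dataset_builder.LABEL_MAP)


def prepare_datasets(
    records: Iterable[tuple[ECGRecord, Sequence[BeatAnnotation]]],
    assignment: Mapping[str, str],
) -> tuple[BeatDataset, BeatDataset, dict]:
    """Preprocess a cohort and split it into interpatient train/test datasets.

    ``assignment`` maps record id to ``train``/``test``; records too short
    for the baseline filter are skipped with a log message. Returns the two
    datasets plus a manifest of per-class counts.
    """
    train_beats: list[Heartbeat] = []
    test_beats: list[Heartbeat] = []
    skipped: list[str] = []
    for record, annotations in records:
        split = assignment.get(record.record_id)
        if split is None:
            raise ValueError(f"record {record.record_id!r} has no split assignment")
        try:
            beats = preprocess_record(record, annotations)
        except ValueError as exc:
            logger.warning("skipping record %s: %s", record.record_id, exc)
            skipped.append(record.record_id)
            continue
        (train_beats if split == "train" else test_beats).extend(beats)

    train = dataset_builder.assemble_dataset(train_beats, split="train")
    test = dataset_builder.assemble_dataset(test_beats, split="test")
    dataset_builder.check_interpatient(train, test)
    manifest = {
        "working_rate_hz": WORKING_RATE_HZ,
        "skipped_records": skipped,
        "train": {"n_beats": len(train), "records": sorted(train.record_ids),
                  "class_counts": train.class_counts()},
        "test": {"n_beats": len(test), "records": sorted(test.record_ids),
                 "class_counts": test.class_counts()},
    }
    return train, test, manifest


def _require_train_split(dataset: BeatDataset) -> None:
    if dataset.split != "train":
        raise ValueError(
            f"training requested on the {dataset.split!r} split; "
            "models may only be fitted on the training dataset"
        )


def train_baseline(
    train: BeatDataset,
    n_trees: int = classifiers.DEFAULT_N_TREES,
    candidate_count: int = classifiers.DEFAULT_CANDIDATE_COUNT,
    seed: int = 0,
) -> classifiers.ForestModel:
    """Fit the single 5-class forest."""
    _require_train_split(train)
    return classifiers.train_forest(train, n_trees, candidate_count, seed)


def train_two_phase(
    train: BeatDataset,
    n_trees: int = classifiers.DEFAULT_N_TREES,
    candidate_count: int = classifiers.DEFAULT_CANDIDATE_COUNT,
    seed: int = 0,
) -> classifiers.CompositeModel:
    """Fit the binary stage and the abnormal-subtype stage, then bundle them."""
    _require_train_split(train)
    train_a, train_b = dataset_builder.build_two_phase_datasets(train)
    model_a = classifiers.train_forest(train_a, n_trees, candidate_count, seed)
    model_b = classifiers.train_forest(train_b, n_trees, candidate_count, seed + 1)
    return classifiers.CompositeModel(model_a=model_a, model_b=model_b)


@dataclass
class EvaluationResult:
    matrix: evaluation.ConfusionMatrix
    normalized: np.ndarray
    report: evaluation.MetricsReport
    predictions: np.ndarray


def evaluate_model(
    model: classifiers.ForestModel | classifiers.CompositeModel,
    test: BeatDataset,
) -> EvaluationResult:
    """Predict on the test split and compute the full metric suite."""
    if isinstance(model, classifiers.CompositeModel):
        predicted = classifiers.predict_composite(model, test)
        label_order = list(FIVE_CLASS)
    else:
        predicted = classifiers.predict(model, test)
        label_order = list(model.label_space)
        if set(test.label_space) != set(label_order):
            raise ValueError(
                f"model labels {label_order} do not match dataset labels {test.label_space}"
            )
    matrix, report = evaluation.evaluate(test.labels, predicted, label_order)
    return EvaluationResult(
        matrix=matrix,
        normalized=evaluation.normalize_confusion(matrix),
        report=report,
        predictions=predicted,
    )


def run_experiment(
    config: SyntheticConfig,
    n_trees: int = classifiers.DEFAULT_N_TREES,
    candidate_count: int = classifiers.DEFAULT_CANDIDATE_COUNT,
    model_seed: int = 0,
) -> dict:
    """The full baseline-vs-two-phase comparison on a synthetic cohort.

    Generates an annotated cohort, splits records alternately (interpatient),
    prepares datasets, trains the 5-class baseline and the composite model on
    the training split only, and evaluates everything on the shared test
    split. Model A / Model B are additionally evaluated on their own views of
    the test set.
    """
    cohort = generate_cohort(config)
    ids = sorted(rec.record_id for rec, _, _ in cohort)
    assignment = dataset_builder.alternate_assign(ids)
    train, test, manifest = prepare_datasets(
        ((rec, anns) for rec, anns, _ in cohort), assignment
    )

    baseline = train_baseline(train, n_trees, candidate_count, seed=model_seed)
    composite = train_two_phase(train, n_trees, candidate_count, seed=model_seed)

    test_a, test_b = dataset_builder.build_two_phase_datasets(test)
    results = {
        "manifest": manifest,
        "baseline": evaluate_model(baseline, test),
        "composite": evaluate_model(composite, test),
        "model_a": evaluate_model(composite.model_a, test_a),
        "model_b": evaluate_model(composite.model_b, test_b),
        "models": {"baseline": baseline, "composite": composite},
    }
    return results
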