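"""AAMI-style dataset assembly: label mapping, interpatient splits, cascade relabeling.

The 15 MIT-BIH beat annotation symbols collapse onto the five AAMI EC57
super-classes (N normal, S supraventricular ectopic, V ventricular ectopic,
F fusion, Q unclassifiable/paced). Records are partitioned so no patient
contributes beats to both the training and the test set; the four
pacemaker-dominated records are excluded entirely.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import FIVE_CLASS, FOUR_CLASS, TWO_CLASS, BeatDataset, Heartbeat

logger = logging.getLogger(__name__)

#: The 15-symbol annotation alphabet -> AAMI five-class label.
LABEL_MAP: dict[str, str] = {
    "N": "N",  # normal beat
    "L": "N",  # left bundle branch block beat
    "R": "N",  # right bundle branch block beat
    "A": "S",  # atrial premature beat
    "a": "S",  # aberrated atrial premature beat
    "J": "S",  # nodal (junctional) premature beat
    "S": "S",  # supraventricular premature or ectopic beat
    "e": "S",  # atrial escape beat
    "j": "S",  # nodal (junctional) escape beat
    "V": "V",  # premature ventricular contraction
    "E": "V",  # ventricular escape beat
    "F": "F",  # fusion of ventricular and normal beat
    "/": "Q",  # paced beat
    "f": "Q",  # fusion of paced and normal beat
    "Q": "Q",  # unclassifiable beat
}

#: MIT-BIH records dominated by paced beats, excluded per AAMI practice.
PACED_RECORDS = ("102", "104", "107", "217")

#: Interpatient split: 22 training records ...
MITBIH_TRAIN_RECORDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119", "122",
    "124", "201", "203", "205", "207", "208", "209", "215", "220", "223", "230",
)
#: ... and 22 disjoint test records.
MITBIH_TEST_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202", "210",
    "212", "213", "214", "219", "221", "222", "228", "231", "232", "233", "234",
)


def map_annotation_label(symbol: str) -> str:
    """Map an original annotation symbol to its AAMI five-class label."""
    try:
        return LABEL_MAP[symbol]
    except KeyError:
        raise KeyError(f"annotation symbol {symbol!r} has no five-class mapping") from None


def split_mitbih_records(
    available_ids: Iterable[str],
) -> tuple[list[str], list[str], list[str]]:
    """Partition MIT-BIH record ids into (train, test, excluded) per the fixed lists."""
    train, test, excluded = [], [], []
    for rid in available_ids:
        if rid in PACED_RECORDS:
            excluded.append(rid)
        elif rid in MITBIH_TRAIN_RECORDS:
            train.append(rid)
        elif rid in MITBIH_TEST_RECORDS:
            test.append(rid)
        else:
            raise ValueError(f"record id {rid!r} is not an MIT-BIH arrhythmia record")
    return train, test, excluded


def alternate_assign(sorted_record_ids: Sequence[str]) -> dict[str, str]:
    """Assign ids alternately to train/test, the first id going to train.

    Callers pass ids already sorted ascending (the fixed-width identifier
    string is the sort key), matching the convention used for the
    supplementary noisy-record pool.
    """
    return {
        rid: ("train" if i % 2 == 0 else "test")
        for i, rid in enumerate(sorted_record_ids)
    }


def assemble_dataset(
    beats: Iterable[Heartbeat], split: str, label_space: Sequence[str] = FIVE_CLASS
) -> BeatDataset:
    """Bundle segmented heartbeats into a split-tagged dataset."""
    return BeatDataset.from_heartbeats(list(beats), split=split, label_space=label_space)


def build_two_phase_datasets(dataset: BeatDataset) -> tuple[BeatDataset, BeatDataset]:
    """Derive the cascade's two training/evaluation views from a five-class dataset.

    The binary view keeps every beat, relabeling the four non-normal classes
    to ``A`` (abnormal); the subtype view keeps only the non-normal beats
    with their original S/V/F/Q labels.
    """
    if set(dataset.label_space) != set(FIVE_CLASS):
        raise ValueError(f"expected a five-class dataset, got label space {dataset.label_space}")
    binary_labels = np.where(dataset.labels == "N", "N", "A").astype(object)
    model_a = BeatDataset(
        windows=dataset.windows,
        labels=binary_labels,
        record_ids_per_beat=dataset.record_ids_per_beat,
        r_peak_indices=dataset.r_peak_indices,
        original_symbols=dataset.original_symbols,
        split=dataset.split,
        label_space=TWO_CLASS,
    )
    abnormal = dataset.subset(dataset.labels != "N")
    model_b = BeatDataset(
        windows=abnormal.windows,
        labels=abnormal.labels,
        record_ids_per_beat=abnormal.record_ids_per_beat,
        r_peak_indices=abnormal.r_peak_indices,
        original_symbols=abnormal.original_symbols,
        split=dataset.split,
        label_space=FOUR_CLASS,
    )
    return model_a, model_b


def check_interpatient(train: BeatDataset, test: BeatDataset) -> None:
    """Raise if any record contributes beats to both splits."""
    shared = train.record_ids & test.record_ids
    if shared:
        raise ValueError(f"records {sorted(shared)} appear in both train and test splits")
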