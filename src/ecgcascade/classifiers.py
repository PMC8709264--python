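"""Random-forest heartbeat classifiers: the 5-class baseline and the two-phase cascade.

The feature vector is the raw 216-sample normalized window; no engineered
features. Training draws ``candidate_count`` independently seeded bagged-tree
ensembles of ``n_trees`` trees each and keeps the candidate with the best
out-of-bag accuracy, so a run is fully reproducible from (data, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .types import LABEL_ORDER, WINDOW_SAMPLES, BeatDataset

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 220
DEFAULT_CANDIDATE_COUNT = 10

_MODEL_SCHEMA_VERSION = 1


def _canonical(labels) -> tuple[str, ...]:
    return tuple(sorted(labels, key=LABEL_ORDER.index))


@dataclass
class ForestModel:
    """A fitted bagged-tree ensemble over a fixed label space."""

    n_trees: int
    label_space: tuple[str, ...]
    seed: int
    candidate_count: int
    forest: RandomForestClassifier | None = None
    oob_score: float | None = None

    @property
    def fitted(self) -> bool:
        return self.forest is not None

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Majority-vote labels; ties break by the fixed order N<S<V<F<Q<A."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        windows = np.asarray(windows, dtype=float).reshape(-1, WINDOW_SAMPLES)
        if windows.shape[0] == 0:
            return np.array([], dtype=object)
        proba = self.forest.predict_proba(windows)
        order = _canonical(self.forest.classes_)
        cols = [list(self.forest.classes_).index(lab) for lab in order]
        # argmax returns the first maximum, i.e. the earliest label in
        # canonical order on a vote tie
        picks = np.argmax(proba[:, cols], axis=1)
        return np.array([order[i] for i in picks], dtype=object)


@dataclass
class CompositeModel:
    """Two-phase cascade: binary normal/abnormal stage, then abnormal subtype."""

    model_a: ForestModel
    model_b: ForestModel

    def __post_init__(self) -> None:
        if set(self.model_a.label_space) != {"N", "A"}:
            raise ValueError(f"model A label space must be {{N,A}}, got {self.model_a.label_space}")
        if set(self.model_b.label_space) != {"S", "V", "F", "Q"}:
            raise ValueError(
                f"model B label space must be {{S,V,F,Q}}, got {self.model_b.label_space}"
            )


def train_forest(
    dataset: BeatDataset,
    n_trees: int = DEFAULT_N_TREES,
    candidate_count: int = DEFAULT_CANDIDATE_COUNT,
    seed: int = 0,
) -> ForestModel:
    """Fit the best of ``candidate_count`` independently seeded forests.

    Each candidate is a bagged ensemble of ``n_trees`` fully grown trees with
    sqrt(216) features considered per split; selection is by out-of-bag
    accuracy (ties keep the earliest candidate). Only the provided dataset is
    touched — callers are responsible for passing the training split.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    if dataset.windows.shape[1] != WINDOW_SAMPLES:
        raise ValueError(f"windows must have {WINDOW_SAMPLES} samples")
    present = set(dataset.labels)
    if len(present) < 2:
        raise ValueError(f"training requires >= 2 classes, found {sorted(present)}")
    if candidate_count < 1:
        raise ValueError("candidate_count must be >= 1")

    rng = np.random.default_rng(seed)
    candidate_seeds = rng.integers(0, 2**31 - 1, size=candidate_count)
    best: RandomForestClassifier | None = None
    best_score = -np.inf
    for i, cand_seed in enumerate(candidate_seeds):
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=True,
            bootstrap=True,
            random_state=int(cand_seed),
            n_jobs=1,
        )
        forest.fit(dataset.windows, dataset.labels.astype(str))
        logger.debug("candidate %d/%d: OOB accuracy %.4f", i + 1, candidate_count,
                     forest.oob_score_)
        if forest.oob_score_ > best_score:
            best, best_score = forest, forest.oob_score_
    assert best is not None
    return ForestModel(
        n_trees=n_trees,
        label_space=_canonical(dataset.label_space),
        seed=seed,
        candidate_count=candidate_count,
        forest=best,
        oob_score=float(best_score),
    )


def predict(model: ForestModel, beats: BeatDataset | np.ndarray) -> np.ndarray:
    """One label per beat from the model's label space."""
    windows = beats.windows if isinstance(beats, BeatDataset) else beats
    return model.predict(windows)


def predict_composite(composite: CompositeModel, beats: BeatDataset | np.ndarray) -> np.ndarray:
    """Cascade prediction: N where the binary stage says normal, else the subtype.

    The subtype model is only invoked on the beats the binary stage flags
    abnormal.
    """
    windows = beats.windows if isinstance(beats, BeatDataset) else np.asarray(beats, dtype=float)
    windows = windows.reshape(-1, WINDOW_SAMPLES)
    stage_a = predict(composite.model_a, windows)
    out = np.array(["N"] * len(stage_a), dtype=object)
    abnormal = stage_a != "N"
    if abnormal.any():
        out[abnormal] = predict(composite.model_b, windows[abnormal])
    return out


def save_model(model: ForestModel | CompositeModel, path: str | Path) -> None:
    """Serialize a model plus its training config to a single artifact file."""
    if isinstance(model, CompositeModel):
        payload = {"kind": "composite", "model_a": model.model_a, "model_b": model.model_b}
    else:
        payload = {"kind": "forest", "model": model}
    payload["schema_version"] = _MODEL_SCHEMA_VERSION
    joblib.dump(payload, path)


def load_model(path: str | Path) -> ForestModel | CompositeModel:
    payload = joblib.load(path)
    if payload.get("schema_version") != _MODEL_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported model schema version")
    if payload["kind"] == "composite":
        return CompositeModel(model_a=payload["model_a"], model_b=payload["model_b"])
    return payload["model"]
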