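"""Difficulty-homogenized subject-level train/validation/test splits.

Speaker-independent evaluation requires that no subject's videos appear in
more than one split.  To keep the three splits comparable in recognition
difficulty, each subject first receives a difficulty score: the 16-class UAR
of an SVM trained on all other subjects' time-averaged appearance features
and evaluated on that subject (leave-one-subject-out).  Subjects are then
sorted by score (descending) and dealt out round-robin in a
3-train / 1-validation / 1-test pattern.

Two tail rules are provided for subject counts not divisible by 5: ``strict``
continues the pattern from its start (63 subjects -> 39/12/12), ``balanced``
assigns leftover subjects to whichever split is furthest below the ideal
3:1:1 ratio (63 subjects -> 37/13/13).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import FeatureSequence, VideoRecord
from .evaluation import contingency, uar
from .models import MULTICLASS_CLASSES, fit_svm_baseline

__all__ = [
    "SplitAssignment",
    "video_level_features",
    "loso_difficulty_scores",
    "assign_splits",
    "split_records",
]

SPLITS = ("train", "validation", "test")
DEFAULT_PATTERN = (3, 1, 1)


@dataclass
class SplitAssignment:
    """Mapping subject_id -> split name ('train', 'validation' or 'test')."""

    mapping: dict

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")

    def subjects(self, split: str) -> list:
        return sorted(s for s, v in self.mapping.items() if v == split)

    def sizes(self) -> dict:
        return {s: len(self.subjects(s)) for s in SPLITS}

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"subject_id": list(self.mapping), "split": list(self.mapping.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SplitAssignment":
        df = pd.read_csv(path)
        return cls(dict(zip(df["subject_id"].astype(str), df["split"])))


def video_level_features(seq: FeatureSequence) -> np.ndarray:
    """Time-averaged appearance features: the per-column mean over frames."""
    if seq.feature_kind != "appearance":
        raise ValueError("video-level features are defined on appearance sequences")
    if seq.n_frames < 1:
        raise ValueError("empty sequence")
    return seq.values.mean(axis=0)


def loso_difficulty_scores(corpus: Sequence[VideoRecord]) -> dict:
    """Leave-one-subject-out recognition difficulty per subject.

    For each subject, an SVM baseline is trained on every other subject's
    video-level features (16-class task) and evaluated on the held-out
    subject; the subject's score is the resulting UAR, averaged only over the
    emotion classes that subject actually has.
    """
    subjects = sorted({r.subject_id for r in corpus})
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for leave-one-subject-out")
    labels = [r.label.value for r in corpus]
    if len(set(labels)) < 2:
        raise ValueError("need at least two emotion classes")
    X = np.array([video_level_features(r.features) for r in corpus])
    y = np.array(labels)
    groups = np.array([r.subject_id for r in corpus])
    scores = {}
    for subj in subjects:
        held = groups == subj
        model = fit_svm_baseline(X[~held], y[~held])
        pred = model.predict(X[held])
        scores[subj] = uar(contingency(list(y[held]), list(pred), MULTICLASS_CLASSES))
    return scores


def assign_splits(
    scores: dict,
    pattern: tuple[int, int, int] = DEFAULT_PATTERN,
    tail: str = "strict",
) -> SplitAssignment:
    """Deal subjects into splits by difficulty-sorted round-robin.

    Subjects are sorted by score descending (ties by subject_id) and the
    (train, validation, test) ``pattern`` is applied cyclically.  With
    ``tail='strict'`` the final partial round simply continues the pattern;
    with ``tail='balanced'`` the subjects of the final partial round go to
    whichever split is currently furthest below the ideal pattern ratio
    (ties resolved train, validation, test).
    """
    if not scores:
        raise ValueError("scores must be nonempty")
    if tail not in ("strict", "balanced"):
        raise ValueError(f"unknown tail rule {tail!r}")
    if len(pattern) != 3 or any(p < 0 for p in pattern) or sum(pattern) == 0:
        raise ValueError("pattern must be three nonnegative counts, not all zero")
    order = sorted(scores, key=lambda s: (-scores[s], str(s)))
    round_len = sum(pattern)
    seq_splits = [s for s, p in zip(SPLITS, pattern) for _ in range(p)]

    mapping: dict = {}
    n_full = (len(order) // round_len) * round_len
    for i, subj in enumerate(order[:n_full]):
        mapping[subj] = seq_splits[i % round_len]
    remainder = order[n_full:]
    if tail == "strict":
        for i, subj in enumerate(remainder):
            mapping[subj] = seq_splits[i % round_len]
    else:
        counts = {s: sum(1 for v in mapping.values() if v == s) for s in SPLITS}
        weight = dict(zip(SPLITS, pattern))
        for subj in remainder:
            # fill the split with the smallest count per unit of ideal share
            target = min(
                (s for s in SPLITS if weight[s] > 0),
                key=lambda s: (counts[s] / weight[s], SPLITS.index(s)),
            )
            mapping[subj] = target
            counts[target] += 1
    return SplitAssignment(mapping)


def split_records(
    corpus: Sequence[VideoRecord], assignment: SplitAssignment
) -> dict:
    """Group records by their subject's split; errors on unassigned subjects."""
    out = {s: [] for s in SPLITS}
    for rec in corpus:
        if rec.subject_id not in assignment.mapping:
            raise ValueError(f"subject {rec.subject_id!r} has no split assignment")
        out[assignment.mapping[rec.subject_id]].append(rec)
    return out
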