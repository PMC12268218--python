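"""Domain types and file I/O for per-frame facial-feature sequences.

The appearance representation is the OpenFace action-unit (AU) output: 17 AU
intensities on a 0-5 scale plus 18 AU presences (the intensity set plus AU28,
lip suck, for which only presence is available), giving a 35-dimensional
vector per video frame.  Deep features are 2048-dimensional per-frame vectors
from an external CNN extractor; this package only consumes them from files or
from the synthetic generator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmotionLabel",
    "NEGATIVE_EMOTIONS",
    "FeatureSequence",
    "VideoRecord",
    "FormatError",
    "EmptyInputError",
    "NoFaceError",
    "AlignmentError",
    "AU_INTENSITY_COLUMNS",
    "AU_PRESENCE_COLUMNS",
    "APPEARANCE_DIM",
    "DEEP_DIM",
    "read_openface_features",
    "write_openface_features",
    "fill_face_gaps",
    "concat_features",
    "read_manifest",
    "write_manifest",
    "read_envelope",
    "write_envelope",
]


class FormatError(ValueError):
    """A required column or structural element is missing from an input file."""


class EmptyInputError(ValueError):
    """An input file or sequence contains no usable rows."""


class NoFaceError(ValueError):
    """No frame in the sequence has a detected face."""


class AlignmentError(ValueError):
    """Two sequences that must be frame-aligned are not."""


# AU numbers for which OpenFace reports an intensity (17) and a presence (18;
# AU28 has presence only).
_AU_INTENSITY_NUMBERS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)
_AU_PRESENCE_NUMBERS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 28, 45)

AU_INTENSITY_COLUMNS = tuple(f"AU{n:02d}_r" for n in _AU_INTENSITY_NUMBERS)
AU_PRESENCE_COLUMNS = tuple(f"AU{n:02d}_c" for n in _AU_PRESENCE_NUMBERS)

APPEARANCE_DIM = len(AU_INTENSITY_COLUMNS) + len(AU_PRESENCE_COLUMNS)  # 35
DEEP_DIM = 2048
CONCAT_DIM = APPEARANCE_DIM + DEEP_DIM  # 2083

#: Column order of the 35-dim appearance vector: intensities ascending AU
#: number, then presences ascending AU number.  Fixed so trained models are
#: reproducible across feature files.
APPEARANCE_COLUMNS = AU_INTENSITY_COLUMNS + AU_PRESENCE_COLUMNS

_SUCCESS_COLUMN = "success"
_DETECTION_THRESHOLD = 0.5


class EmotionLabel(enum.Enum):
    """The 16 emotion categories, each with a fixed valence.

    Four are negative (anger, anxiety, disgust, sadness); the remaining
    twelve are positive.
    """

    ANGER = "anger"
    ANXIETY = "anxiety"
    DISGUST = "disgust"
    SADNESS = "sadness"
    CONFIDENCE = "confidence"
    CONTENTMENT = "contentment"
    COURAGE = "courage"
    EXCITEMENT = "excitement"
    GRATITUDE = "gratitude"
    HAPPINESS = "happiness"
    JOY = "joy"
    LOVE = "love"
    PRIDE = "pride"
    RELAXATION = "relaxation"
    RESOLVE = "resolve"
    TRANQUILITY = "tranquility"

    @property
    def valence(self) -> str:
        """'negative' or 'positive'; a pure function of the label."""
        return "negative" if self in NEGATIVE_EMOTIONS else "positive"

    @classmethod
    def from_name(cls, name: str) -> "EmotionLabel":
        try:
            return cls(name.strip().lower())
        except ValueError:
            raise ValueError(f"unknown emotion label: {name!r}") from None


NEGATIVE_EMOTIONS = frozenset(
    {EmotionLabel.ANGER, EmotionLabel.ANXIETY, EmotionLabel.DISGUST, EmotionLabel.SADNESS}
)


@dataclass
class FeatureSequence:
    """A T x D per-frame feature matrix at a fixed frame rate.

    Parameters
    ----------
    values
        Feature matrix, one row per frame.
    feature_kind
        'appearance' (D=35), 'deep' (D=2048) or 'concatenated' (D=2083).
    fps
        Frame rate in frames per second (default 30).
    detection_flags
        Per-frame booleans: whether a face was detected in that frame.
    """

    values: np.ndarray
    feature_kind: str = "appearance"
    fps: float = 30.0
    detection_flags: Optional[np.ndarray] = None

    _KIND_DIMS = {"appearance": APPEARANCE_DIM, "deep": DEEP_DIM, "concatenated": CONCAT_DIM}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (frames x features) array")
        if self.feature_kind not in self._KIND_DIMS:
            raise ValueError(f"unknown feature_kind: {self.feature_kind!r}")
        expected = self._KIND_DIMS[self.feature_kind]
        if self.values.shape[1] != expected:
            raise ValueError(
                f"{self.feature_kind} features must have {expected} columns, "
                f"got {self.values.shape[1]}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.detection_flags is None:
            self.detection_flags = np.ones(len(self.values), dtype=bool)
        else:
            self.detection_flags = np.asarray(self.detection_flags, dtype=bool)
            if self.detection_flags.shape != (len(self.values),):
                raise ValueError("detection_flags must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def slice_frames(self, start: int, end: int) -> "FeatureSequence":
        """Restrict to the half-open frame window [start, end)."""
        return FeatureSequence(
            self.values[start:end],
            feature_kind=self.feature_kind,
            fps=self.fps,
            detection_flags=self.detection_flags[start:end],
        )


@dataclass
class VideoRecord:
    """One recording: subject, label, features, and optional audio envelope.

    ``phase``, when set, is a half-open (start_frame, end_frame) interval in
    feature-frame units marking the emotional phase of the recording.
    """

    subject_id: str
    label: EmotionLabel
    features: FeatureSequence
    audio_envelope: Optional[np.ndarray] = None
    envelope_fps: float = 30.0
    phase: Optional[tuple[int, int]] = None
    video_id: str = ""
    deep_features: Optional[FeatureSequence] = None

    def __post_init__(self) -> None:
        if self.audio_envelope is not None:
            self.audio_envelope = np.asarray(self.audio_envelope, dtype=float)
            if self.audio_envelope.ndim != 1:
                raise ValueError("audio_envelope must be 1-D")
            if np.any(self.audio_envelope < 0):
                raise ValueError("audio_envelope values must be nonnegative")
        if self.phase is not None:
            s, e = self.phase
            if not (0 <= s < e <= self.features.n_frames):
                raise ValueError(f"phase {self.phase} outside [0, {self.features.n_frames}]")


# ---------------------------------------------------------------------------
# OpenFace-dialect CSV
# ---------------------------------------------------------------------------

def read_openface_features(path: str | Path) -> FeatureSequence:
    """Read an OpenFace-style per-frame CSV into an appearance FeatureSequence.

    The file must contain the 17 AU intensity columns (``AU01_r`` ...
    ``AU45_r``), the 18 AU presence columns (including ``AU28_c``) and a
    ``success`` column.  Header names may carry leading spaces (OpenFace
    convention); whitespace is stripped before matching.  Presences are read
    as floats and binarized at 0.5; a frame counts as detected when its
    success value is >= 0.5.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    df.columns = [str(c).strip() for c in df.columns]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no frame rows")

    for col in APPEARANCE_COLUMNS + (_SUCCESS_COLUMN,):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    intens = df[list(AU_INTENSITY_COLUMNS)].to_numpy(dtype=float)
    pres = (df[list(AU_PRESENCE_COLUMNS)].to_numpy(dtype=float) >= 0.5).astype(float)
    flags = df[_SUCCESS_COLUMN].to_numpy(dtype=float) >= _DETECTION_THRESHOLD
    values = np.hstack([intens, pres])
    return FeatureSequence(values, feature_kind="appearance", detection_flags=flags)


def write_openface_features(seq: FeatureSequence, path: str | Path) -> None:
    """Write an appearance sequence in the CSV dialect read_openface_features reads."""
    if seq.feature_kind != "appearance":
        raise ValueError("only appearance sequences use the OpenFace dialect")
    df = pd.DataFrame(seq.values, columns=list(APPEARANCE_COLUMNS))
    df.insert(0, _SUCCESS_COLUMN, seq.detection_flags.astype(int))
    df.to_csv(path, index=False)


def fill_face_gaps(seq: FeatureSequence) -> FeatureSequence:
    """Fill frames where face detection failed.

    Internal undetected frames are replaced with the most recent detected
    frame's features (the last extracted face is carried forward until a new
    face appears); undetected frames at the beginning or end of the sequence
    are dropped.  The result has all detection flags true.  Idempotent.
    """
    flags = seq.detection_flags
    if not flags.any():
        raise NoFaceError("no frame with a detected face")
    idx = np.flatnonzero(flags)
    start, end = idx[0], idx[-1] + 1
    values = seq.values[start:end].copy()
    inner = flags[start:end]
    # indices of the most recent detected frame at or before each position
    last_good = np.maximum.accumulate(np.where(inner, np.arange(len(inner)), -1))
    values = values[last_good]
    return FeatureSequence(values, feature_kind=seq.feature_kind, fps=seq.fps)


def concat_features(app: FeatureSequence, deep: FeatureSequence) -> FeatureSequence:
    """Concatenate appearance and deep features frame-by-frame (appearance first)."""
    if app.feature_kind != "appearance" or deep.feature_kind != "deep":
        raise ValueError("inputs must be (appearance, deep) in that order")
    if app.n_frames != deep.n_frames:
        raise AlignmentError(
            f"frame count mismatch: appearance T={app.n_frames}, deep T={deep.n_frames}"
        )
    if app.fps != deep.fps:
        raise AlignmentError(f"fps mismatch: {app.fps} vs {deep.fps}")
    values = np.hstack([app.values, deep.values])
    flags = app.detection_flags & deep.detection_flags
    return FeatureSequence(values, feature_kind="concatenated", fps=app.fps, detection_flags=flags)


# ---------------------------------------------------------------------------
# Manifest and envelope files
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a video manifest: columns subject_id, emotion, feature_path
    and optionally video_id, envelope_path, deep_path."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("subject_id", "emotion", "feature_path"):
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    return df


def write_manifest(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_envelope(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a one-column envelope CSV whose header states the frame rate
    (``energy@<rate>``). Returns (values, frame_rate)."""
    df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise FormatError(f"{path}: envelope file must have exactly one column")
    header = str(df.columns[0]).strip()
    if "@" not in header:
        raise FormatError(f"{path}: envelope header must be 'energy@<rate>'")
    rate = float(header.split("@", 1)[1])
    values = df.iloc[:, 0].to_numpy(dtype=float)
    if len(values) == 0:
        raise EmptyInputError(f"{path}: empty envelope")
    return values, rate


def write_envelope(values: np.ndarray, rate: float, path: str | Path) -> None:
    pd.DataFrame({f"energy@{rate:g}": np.asarray(values, dtype=float)}).to_csv(path, index=False)
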