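"""Emotional-phase detection from audio energy envelopes.

A recording has three phases (preparation, emotional, disengagement); only
the emotional phase — where the subject speaks while displaying the target
emotion — is used for modelling.  The detector is a relative-threshold energy
gate: frames at or above ``threshold_frac`` of the envelope maximum are
active, active runs separated by short silences are merged, and the longest
merged run (ties broken by earliest start) is taken as the voiced emotional
segment, extended by one second to capture expressions that outlast speech.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import VideoRecord

__all__ = [
    "Segment",
    "SegmentationError",
    "detect_nonsilent_segments",
    "extract_emotional_phase",
    "trim_to_phase",
    "segment_record",
]

DEFAULT_THRESHOLD_FRAC = 0.1
DEFAULT_MIN_GAP_S = 0.3
DEFAULT_PAD_AFTER_S = 1.0


class SegmentationError(ValueError):
    """No usable emotional phase could be determined."""


@dataclass(frozen=True)
class Segment:
    """Half-open frame interval [start_frame, end_frame) at a frame rate."""

    start_frame: int
    end_frame: int
    frame_rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(f"invalid segment [{self.start_frame}, {self.end_frame})")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


def detect_nonsilent_segments(
    envelope: np.ndarray,
    frame_rate: float,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
) -> list[Segment]:
    """Maximal nonsilent runs of an energy envelope, in temporal order.

    A frame is active when its value is >= ``threshold_frac * max(envelope)``;
    active runs separated by silences shorter than ``min_gap_s`` are merged.
    An all-zero envelope yields no segments.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.ndim != 1 or len(envelope) == 0:
        raise ValueError("envelope must be a nonempty 1-D array")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    peak = envelope.max()
    if peak <= 0:
        return []
    active = envelope >= threshold_frac * peak
    if not active.any():
        return []
    # raw runs
    padded = np.diff(np.concatenate([[0], active.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    # merge runs separated by < min_gap_s of silence
    max_gap = min_gap_s * frame_rate
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [Segment(s, e, frame_rate) for s, e in merged]


def extract_emotional_phase(
    envelope: np.ndarray,
    frame_rate: float,
    pad_after_s: float = DEFAULT_PAD_AFTER_S,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
) -> Segment:
    """The longest nonsilent segment, extended by ``pad_after_s`` seconds.

    Ties on length go to the earliest segment; the extension is clipped to
    the end of the recording.
    """
    segments = detect_nonsilent_segments(envelope, frame_rate, threshold_frac, min_gap_s)
    if not segments:
        raise SegmentationError("no nonsilent segment found")
    longest = max(segments, key=lambda s: s.n_frames)  # max() keeps the earliest tie
    end = min(longest.end_frame + int(round(pad_after_s * frame_rate)), len(envelope))
    return Segment(longest.start_frame, end, frame_rate)


def trim_to_phase(rec: VideoRecord, seg: Segment) -> VideoRecord:
    """Restrict a record's feature streams to the emotional phase.

    The segment may be expressed at the envelope's frame rate; its bounds are
    mapped to feature frames with floor for the start and ceil for the end.
    """
    fps = rec.features.fps
    start = math.floor(seg.start_frame * fps / seg.frame_rate)
    end = math.ceil(seg.end_frame * fps / seg.frame_rate)
    end = min(end, rec.features.n_frames)
    if end - start < 1:
        raise SegmentationError(
            f"segment maps to an empty feature window for video {rec.video_id!r}"
        )
    deep = rec.deep_features.slice_frames(start, end) if rec.deep_features is not None else None
    return VideoRecord(
        subject_id=rec.subject_id,
        label=rec.label,
        features=rec.features.slice_frames(start, end),
        audio_envelope=rec.audio_envelope,
        envelope_fps=rec.envelope_fps,
        phase=(0, end - start),
        video_id=rec.video_id,
        deep_features=deep,
    )


def segment_record(
    rec: VideoRecord,
    pad_after_s: float = DEFAULT_PAD_AFTER_S,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_gap_s: float = DEFAULT_MIN_GAP_S,
) -> VideoRecord:
    """Detect the emotional phase from the record's envelope and trim to it."""
    if rec.audio_envelope is None:
        raise SegmentationError(f"video {rec.video_id!r} has no audio envelope")
    seg = extract_emotional_phase(
        rec.audio_envelope, rec.envelope_fps, pad_after_s, threshold_frac, min_gap_s
    )
    return trim_to_phase(rec, seg)
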