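"""Seeded synthetic corpora with the structure of a Wizard-of-Oz emotion study.

Each generated recording mimics a smartphone selfie video reduced to its
per-frame action-unit features: a preparation phase (camera being moved into
place), an emotional phase in which the subject utters a sentence while
displaying one of 16 target emotions, and a disengagement phase.  Facial
activity follows a rise-sustain-decay envelope over the emotional phase and
persists about one second after the voiced utterance ends, reflecting that an
expression outlasts speech; the stored ground-truth phase covers that full
expressive window.  The audio energy envelope is high only while the subject
speaks.

Class structure is controlled by per-emotion archetype directions in
action-unit space; the ``separability`` parameter scales the pairwise
distance between emotion archetypes linearly, so ``separability=0`` produces
class-uninformative features.  Subject identity enters as an additive
per-subject offset, which is what makes speaker-independent evaluation
meaningfully harder than a random split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .datamodel import (
    APPEARANCE_DIM,
    AU_INTENSITY_COLUMNS,
    AU_PRESENCE_COLUMNS,
    DEEP_DIM,
    EmotionLabel,
    FeatureSequence,
    VideoRecord,
    write_envelope,
    write_manifest,
    write_openface_features,
)

__all__ = [
    "SyntheticConfig",
    "emotion_archetype",
    "generate_corpus",
    "attach_deep_features",
    "generate_human_predictions",
    "write_corpus",
    "DEFAULT_PER_EMOTION_COUNTS",
]

_N_INTENSITY = len(AU_INTENSITY_COLUMNS)  # 17
_N_PRESENCE = len(AU_PRESENCE_COLUMNS)  # 18

# Baseline (neutral-face) appearance vector: low intensities, low presence
# propensity.  Presence columns are propensities here; frames binarize them.
_BASELINE_INTENSITY = 0.3
_BASELINE_PRESENCE = 0.1

# Canonical AU-emotion associations (FACS-style) for the emotions with a
# conventional coding; weights are relative intensity pushes.  Emotions not
# listed get a deterministic pseudo-random sparse direction.
_AU_TABLE: dict[EmotionLabel, dict[int, float]] = {
    EmotionLabel.ANGER: {4: 1.0, 5: 0.6, 7: 0.8, 23: 1.0},
    EmotionLabel.ANXIETY: {1: 0.8, 2: 0.6, 4: 0.7, 5: 0.8, 20: 1.0, 26: 0.6},
    EmotionLabel.DISGUST: {9: 1.0, 10: 0.8, 15: 0.6, 17: 0.5},
    EmotionLabel.SADNESS: {1: 1.0, 4: 0.6, 15: 1.0, 17: 0.4},
    EmotionLabel.HAPPINESS: {6: 1.1, 12: 1.2},
    EmotionLabel.JOY: {6: 0.9, 12: 0.8, 25: 0.8, 26: 0.5},
}

_AU_NUMBER_TO_INTENSITY_IDX = {
    int(c[2:4]): i for i, c in enumerate(AU_INTENSITY_COLUMNS)
}
_AU_NUMBER_TO_PRESENCE_IDX = {
    int(c[2:4]): i for i, c in enumerate(AU_PRESENCE_COLUMNS)
}

#: Default per-emotion video counts at reduced scale, preserving the source
#: study's imbalance: each negative emotion is recorded ~2.5x as often as
#: each positive one.
DEFAULT_PER_EMOTION_COUNTS: dict[EmotionLabel, int] = {
    lab: (15 if lab.valence == "negative" else 6) for lab in EmotionLabel
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic corpus.

    Defaults describe the study conditions the generator emulates: 15
    subjects, 30 fps video, a ~1 s preparation phase, ~2 s voiced emotional
    phase and ~1 s disengagement phase (each jittered per video), and a
    negative:positive per-emotion count ratio of 2.5.
    """

    n_subjects: int = 15
    per_emotion_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_PER_EMOTION_COUNTS)
    )
    separability: float = 1.5
    subject_sd: float = 0.12
    noise_sd: float = 0.12
    phase_durations: tuple = (1.0, 2.0, 1.0)
    phase_jitter: float = 0.25
    expression_tail_s: float = 1.0
    fps: float = 30.0
    envelope_fps: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or any(v < 0 for v in self.per_emotion_counts.values()):
            raise ValueError("counts must be nonnegative")
        if self.separability < 0 or self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("scales must be nonnegative")
        if self.fps <= 0 or self.envelope_fps <= 0:
            raise ValueError("frame rates must be positive")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        self.per_emotion_counts = {
            (EmotionLabel.from_name(k) if isinstance(k, str) else k): int(v)
            for k, v in self.per_emotion_counts.items()
        }


class EmptyConfigError(ValueError):
    """The configuration produces an empty corpus."""


def _direction(label: EmotionLabel) -> np.ndarray:
    """Unit-free 35-dim direction for one emotion, deterministic per label."""
    intens = np.zeros(_N_INTENSITY)
    pres = np.zeros(_N_PRESENCE)
    if label in _AU_TABLE:
        table = _AU_TABLE[label]
    else:
        # deterministic sparse pseudo-random association for unlisted emotions
        rng = np.random.default_rng(abs(hash_label(label)) % (2**31))
        aus = rng.choice(list(_AU_NUMBER_TO_INTENSITY_IDX), size=4, replace=False)
        weights = rng.uniform(0.5, 1.0, size=4)
        table = {int(a): float(w) for a, w in zip(aus, weights)}
    for au, w in table.items():
        if au in _AU_NUMBER_TO_INTENSITY_IDX:
            intens[_AU_NUMBER_TO_INTENSITY_IDX[au]] = w
        pres[_AU_NUMBER_TO_PRESENCE_IDX[au]] = 0.6 * w
    return np.concatenate([intens, pres])


def hash_label(label: EmotionLabel) -> int:
    """Stable per-label integer (independent of PYTHONHASHSEED)."""
    h = 0
    for ch in label.value:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def emotion_archetype(label: EmotionLabel, separability: float) -> np.ndarray:
    """Mean appearance vector for an emotion at full expressive intensity.

    Returns ``baseline + separability * direction(label)``; pairwise L2
    distances between distinct labels therefore scale linearly with
    ``separability`` and vanish at 0.  The first 17 entries are AU
    intensities, the remaining 18 are presence propensities (binarized only
    when frames are sampled).
    """
    if separability < 0:
        raise ValueError("separability must be nonnegative")
    base = np.concatenate(
        [np.full(_N_INTENSITY, _BASELINE_INTENSITY), np.full(_N_PRESENCE, _BASELINE_PRESENCE)]
    )
    return base + separability * _direction(label)


def _expression_envelope(
    n_frames: int, fps: float, voiced: tuple[int, int], tail_s: float, ramp_s: float = 0.3
) -> np.ndarray:
    """Rise-sustain-decay saliency in [0, 1] over feature frames.

    Rises over ``ramp_s`` from the voiced onset, sustains through the voiced
    interval plus ``tail_s - ramp_s`` seconds, then decays over ``ramp_s``.
    """
    ramp = max(int(round(ramp_s * fps)), 1)
    tail = int(round(tail_s * fps))
    start, v_end = voiced
    end = min(v_end + tail, n_frames)  # expressive window end
    i = np.arange(n_frames)
    rise = (i - start + 1) / ramp
    fall = (end - i) / ramp
    g = np.minimum(np.minimum(rise, fall), 1.0)
    g[(i < start) | (i >= end)] = 0.0
    return np.clip(g, 0.0, 1.0)


def generate_corpus(cfg: SyntheticConfig) -> list[VideoRecord]:
    """Generate a seeded corpus of VideoRecord with exact per-emotion counts.

    Each record carries appearance features (three concatenated phases), an
    audio energy envelope that is high only while the subject 'speaks', and
    the true emotional-phase boundaries in feature frames.  Bitwise
    reproducible from ``cfg.seed``.
    """
    if cfg.n_subjects == 0 or sum(cfg.per_emotion_counts.values()) == 0:
        raise EmptyConfigError("no subjects or no videos configured")
    rng = np.random.default_rng(cfg.seed)
    subjects = [f"S{i:03d}" for i in range(cfg.n_subjects)]
    subject_offset = {
        s: rng.normal(0.0, cfg.subject_sd, size=APPEARANCE_DIM) for s in subjects
    }

    records: list[VideoRecord] = []
    vid = 0
    for k, label in enumerate(sorted(cfg.per_emotion_counts, key=lambda l: l.value)):
        count = cfg.per_emotion_counts[label]
        arch = emotion_archetype(label, cfg.separability)
        base = emotion_archetype(label, 0.0)
        lift = arch - base
        for j in range(count):
            subj = subjects[(k + j) % cfg.n_subjects]  # offset start mixes emotions
            prep, emo, dis = (
                d * rng.uniform(1 - cfg.phase_jitter, 1 + cfg.phase_jitter)
                for d in cfg.phase_durations
            )
            n_prep = int(round(prep * cfg.fps))
            n_emo = max(int(round(emo * cfg.fps)), 1)
            n_dis = int(round(dis * cfg.fps))
            n_frames = n_prep + n_emo + n_dis
            voiced = (n_prep, n_prep + n_emo)

            g = _expression_envelope(n_frames, cfg.fps, voiced, cfg.expression_tail_s)
            frames = (
                base[None, :]
                + g[:, None] * lift[None, :]
                + subject_offset[subj][None, :]
                + rng.normal(0.0, cfg.noise_sd, size=(n_frames, APPEARANCE_DIM))
            )
            frames[:, :_N_INTENSITY] = np.clip(frames[:, :_N_INTENSITY], 0.0, 5.0)
            frames[:, _N_INTENSITY:] = (frames[:, _N_INTENSITY:] >= 0.5).astype(float)

            # audio: energetic during the voiced interval only, short ramps
            n_env = int(round(n_frames / cfg.fps * cfg.envelope_fps))
            env = np.abs(rng.normal(0.0, 0.01, size=n_env))
            e0 = int(round(voiced[0] / cfg.fps * cfg.envelope_fps))
            e1 = int(round(voiced[1] / cfg.fps * cfg.envelope_fps))
            env[e0:e1] = 1.0 + 0.2 * np.abs(rng.normal(0.0, 1.0, size=max(e1 - e0, 0)))
            eramp = max(int(round(0.1 * cfg.envelope_fps)), 1)
            env[e0: min(e0 + eramp, n_env)] *= np.linspace(0.3, 1.0, min(eramp, n_env - e0))
            phase_end = min(voiced[1] + int(round(cfg.expression_tail_s * cfg.fps)), n_frames)

            records.append(
                VideoRecord(
                    subject_id=subj,
                    label=label,
                    features=FeatureSequence(frames, feature_kind="appearance", fps=cfg.fps),
                    audio_envelope=env,
                    envelope_fps=cfg.envelope_fps,
                    phase=(voiced[0], phase_end),
                    video_id=f"V{vid:05d}",
                )
            )
            vid += 1
    return records


_DEEP_MAP_SEED = 1_234_567  # fixed: the deep extractor is the same for every corpus


def attach_deep_features(
    records: list[VideoRecord], noise_sd: float = 0.05, seed: int = 0
) -> list[VideoRecord]:
    """Synthesize 2048-dim 'deep' features as a fixed random linear map of the
    appearance features plus frame noise, attached in place.

    The linear map is shared across corpora (a stand-in for a fixed external
    CNN extractor); only the additive noise depends on ``seed``.
    """
    map_rng = np.random.default_rng(_DEEP_MAP_SEED)
    M = map_rng.normal(0.0, 1.0 / np.sqrt(APPEARANCE_DIM), size=(APPEARANCE_DIM, DEEP_DIM))
    rng = np.random.default_rng(seed)
    for rec in records:
        deep = rec.features.values @ M
        if noise_sd > 0:
            deep = deep + rng.normal(0.0, noise_sd, size=deep.shape)
        rec.deep_features = FeatureSequence(deep, feature_kind="deep", fps=rec.features.fps)
    return records


def generate_human_predictions(
    corpus: list[VideoRecord],
    accuracy_target: float,
    seed: int = 0,
    n_raters: int = 3,
) -> np.ndarray:
    """Simulated rater labels: each rater is independently correct with
    probability ``accuracy_target``, otherwise uniform over the wrong labels.

    Returns an (n_videos, n_raters) array of EmotionLabel objects.
    """
    if not 0.0 <= accuracy_target <= 1.0:
        raise ValueError("accuracy_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(EmotionLabel)
    out = np.empty((len(corpus), n_raters), dtype=object)
    for i, rec in enumerate(corpus):
        wrong = [l for l in labels if l is not rec.label]
        for r in range(n_raters):
            if rng.random() < accuracy_target:
                out[i, r] = rec.label
            else:
                out[i, r] = wrong[rng.integers(len(wrong))]
    return out


def write_corpus(records: list[VideoRecord], outdir: str | Path) -> Path:
    """Write a corpus as manifest + OpenFace-dialect CSVs + envelope CSVs.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fpath = outdir / f"{rec.video_id}_features.csv"
        write_openface_features(rec.features, fpath)
        row = {
            "video_id": rec.video_id,
            "subject_id": rec.subject_id,
            "emotion": rec.label.value,
            "feature_path": fpath.name,
        }
        if rec.audio_envelope is not None:
            epath = outdir / f"{rec.video_id}_envelope.csv"
            write_envelope(rec.audio_envelope, rec.envelope_fps, epath)
            row["envelope_path"] = epath.name
        rows.append(row)
    manifest = outdir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
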