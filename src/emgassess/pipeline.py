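"""End-to-end orchestration: recordings -> segments -> features -> reports."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .emg_io import ClinicalScores, GestureLabel, Recording, read_recording, read_scores
from .features import FeatureConfig, compute_feature_table
from .preprocess import GestureSegment, PreprocessConfig, segment_recording
from .synthetic import SyntheticCohort


def segment_cohort(
    recordings: dict[str, dict[GestureLabel, Recording]],
    config: PreprocessConfig = PreprocessConfig(),
) -> list[GestureSegment]:
    """Condition and segment every recording of a cohort.

    ``recordings`` maps subject id -> gesture label -> Recording.
    """
    segments: list[GestureSegment] = []
    for sid in sorted(recordings):
        for label in sorted(recordings[sid], key=lambda g: g.value):
            segments.extend(segment_recording(recordings[sid][label], label, config))
    return segments


def cohort_recordings(cohort: SyntheticCohort) -> dict[str, dict[GestureLabel, Recording]]:
    return {sub.subject_id: dict(sub.recordings) for sub in cohort.subjects}


def cohort_feature_table(
    cohort: SyntheticCohort,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Synthetic cohort -> per-attempt feature table (the assessment input)."""
    segments = segment_cohort(cohort_recordings(cohort), preprocess_config)
    return compute_feature_table(segments, feature_config)


def load_cohort_from_files(
    directory: str | Path,
    fs: float = 1000.0,
    n_channels: int = 4,
) -> tuple[dict[str, dict[GestureLabel, Recording]], dict[str, ClinicalScores]]:
    """Read a directory written by :meth:`SyntheticCohort.write` (or laid out
    the same way: ``<subject>_<gesture>.csv`` recordings plus ``scores.csv``)."""
    directory = Path(directory)
    scores = read_scores(directory / "scores.csv")
    recordings: dict[str, dict[GestureLabel, Recording]] = {}
    for path in sorted(directory.glob("*_*.csv")):
        stem = path.stem
        sid, _, gesture = stem.rpartition("_")
        if sid not in scores:
            continue
        try:
            label = GestureLabel(gesture)
        except ValueError:
            continue
        rec = read_recording(path, fs=fs, n_channels=n_channels, subject_id=sid)
        recordings.setdefault(sid, {})[label] = rec
    return recordings, scores
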