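"""Reading and writing raw EMG recordings and clinical score tables.

Recordings are delimited text (comma or tab, auto-detected), one column per
channel, one row per sample.  Values are either raw 16-bit ADC counts or
microvolts; :func:`adc_to_microvolts` applies the device transfer function
for a wireless surface-EMG amplifier with a 16-bit converter and a +/-1.5 mV
input range sampled at 1 kHz.

Clinical scores are one CSV row per subject with the three hand/upper-limb
scales used for ground truth: Fugl-Meyer upper-extremity total (0-66),
Brunnstrom recovery stage of the hand (1-6) and Modified Ashworth grade of
the hand (0, 1, 1+, 2, 3, 4; "1+" is stored as 1.5).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, ValidationError

ADC_FULL_SCALE = 65535          # 16-bit converter
ADC_RANGE_UV = 3000.0           # +/-1.5 mV input range, in microvolts
DEFAULT_FS = 1000.0
DEFAULT_CHANNEL_NAMES = (
    "flexor_digitorum",
    "extensor_digitorum",
    "extensor_carpi",
    "thenar",
)

#: Valid Modified Ashworth grades ("1+" maps to 1.5).
MAS_GRADES = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0)


class GestureLabel(str, enum.Enum):
    """The seven recorded gesture classes; ``R`` is the unique passive class."""

    R = "R"    # rest
    F = "F"    # hand fist
    P = "P"    # index pinch
    FL = "FL"  # wrist flexion
    E = "E"    # wrist extension
    O = "O"    # hand opening
    T = "T"    # thumbs-up

    @property
    def is_rest(self) -> bool:
        return self is GestureLabel.R


MOVEMENT_LABELS = tuple(g for g in GestureLabel if not g.is_rest)


class UnitState(str, enum.Enum):
    ADC_COUNTS = "adc_counts"
    MICROVOLTS = "microvolts"


@dataclass
class Recording:
    """One subject's multi-channel EMG session.

    ``data`` is an array of shape (T, C) with channels in column order.
    """

    subject_id: str
    data: np.ndarray
    fs: float = DEFAULT_FS
    unit_state: UnitState = UnitState.MICROVOLTS
    channel_names: Sequence[str] = field(default_factory=lambda: list(DEFAULT_CHANNEL_NAMES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("recording data must be a 2-D (samples x channels) array")
        if self.n_channels < 2:
            raise ValidationError("a recording needs at least 2 channels")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_names) != self.n_channels:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def to_microvolts(self) -> "Recording":
        """Return a copy in microvolts, applying the ADC map if needed."""
        if self.unit_state is UnitState.MICROVOLTS:
            return self
        return Recording(
            subject_id=self.subject_id,
            data=adc_to_microvolts(self.data),
            fs=self.fs,
            unit_state=UnitState.MICROVOLTS,
            channel_names=list(self.channel_names),
        )


@dataclass(frozen=True)
class ClinicalScores:
    """Per-subject ground-truth clinical assessment."""

    subject_id: str
    fma_ue: int
    brs_hand: int
    mas_hand: float

    def __post_init__(self) -> None:
        if not 0 <= self.fma_ue <= 66:
            raise ValidationError(
                f"subject {self.subject_id}: fma_ue={self.fma_ue} outside 0-66"
            )
        if not 1 <= self.brs_hand <= 6:
            raise ValidationError(
                f"subject {self.subject_id}: brs_hand={self.brs_hand} outside 1-6"
            )
        if float(self.mas_hand) not in MAS_GRADES:
            raise ValidationError(
                f"subject {self.subject_id}: mas_hand={self.mas_hand} not a valid grade"
            )


def adc_to_microvolts(counts: np.ndarray | float) -> np.ndarray | float:
    """Map 16-bit ADC counts to microvolts.

    The symmetric linear transfer function ``v = (c / 65535 - 1/2) * 3000``
    places mid-scale at 0 V and the code endpoints at -1500 and +1500 uV.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or np.any(c > ADC_FULL_SCALE):
        raise ValidationError("ADC counts must lie in [0, 65535]")
    v = (c / ADC_FULL_SCALE - 0.5) * ADC_RANGE_UV
    return v if np.ndim(counts) else float(v)


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    return ","


def _has_header(first_line: str, delimiter: str) -> bool:
    for tok in first_line.strip().split(delimiter):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_recording(
    path: str | Path,
    fs: float = DEFAULT_FS,
    unit_state: UnitState | str = UnitState.MICROVOLTS,
    n_channels: int = 4,
    subject_id: str | None = None,
) -> Recording:
    """Read a delimited-text recording (one column per channel)."""
    path = Path(path)
    unit_state = UnitState(unit_state)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(first)
    header = _has_header(first, delim)
    try:
        df = pd.read_csv(
            path, sep=delim, header=0 if header else None,
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != n_channels:
        raise FormatError(
            f"{path}: expected {n_channels} channels, found {df.shape[1]} columns"
        )
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric cell in column {col!r}, row {row}")
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
        raise ParseError(f"{path}: missing cell at row {row}")
    names = [str(c) for c in df.columns] if header else [f"ch{i+1}" for i in range(n_channels)]
    return Recording(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        fs=fs,
        unit_state=unit_state,
        channel_names=names,
    )


def write_recording(recording: Recording, path: str | Path, delimiter: str = ",") -> None:
    """Write a recording as delimited text with a one-line channel header.

    Floats are written with :func:`repr` precision so a read/write round trip
    is bit-exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(recording.channel_names) + "\n")
        for row in recording.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def _parse_mas(value) -> float:
    if isinstance(value, str):
        value = value.strip()
        if value == "1+":
            return 1.5
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"unparseable MAS grade {value!r}") from exc


def read_scores(path: str | Path) -> dict[str, ClinicalScores]:
    """Read the clinical-score table, keyed by subject id."""
    df = pd.read_csv(path)
    required = {"subject_id", "fma_ue", "brs_hand", "mas_hand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    scores: dict[str, ClinicalScores] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in scores:
            raise ValidationError(f"duplicate subject_id {sid!r}")
        scores[sid] = ClinicalScores(
            subject_id=sid,
            fma_ue=int(row["fma_ue"]),
            brs_hand=int(row["brs_hand"]),
            mas_hand=_parse_mas(row["mas_hand"]),
        )
    return scores


def write_scores(scores: dict[str, ClinicalScores] | Sequence[ClinicalScores], path: str | Path) -> None:
    if isinstance(scores, dict):
        scores = list(scores.values())
    rows = []
    for s in scores:
        mas = "1+" if s.mas_hand == 1.5 else (int(s.mas_hand) if float(s.mas_hand).is_integer() else s.mas_hand)
        rows.append({"subject_id": s.subject_id, "fma_ue": s.fma_ue, "brs_hand": s.brs_hand, "mas_hand": mas})
    pd.DataFrame(rows).to_csv(path, index=False)
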