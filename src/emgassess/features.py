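"""The 16-feature EMG catalogue and per-task feature-vector assembly.

Each clinical threshold task uses exactly two features for the passive
(rest-state) evaluation and two for the active (volitional movement)
evaluation.  Single-channel features are computed per channel and
concatenated in channel order; the cross-channel correlation feature (CCS)
is computed once per segment over all unordered channel pairs.

Feature definitions (x is one channel of a segment, length N, non-negative
normalized envelope units unless the band-passed domain is selected):

========  =====================================================================
MAV/AAV   mean absolute value, (1/N) sum |x_i|
MMAV      weighted MAV emphasizing the middle half (w=1 on 0.25N<=i<=0.75N,
          0.5 elsewhere, 1-based inclusive)
MMAV3     weighted MAV emphasizing the initial quarter (w=1 for i<=0.25N,
          0.5 after)
SMAV      MAV scaled by segment duration: MAV / (N/fs), per second
MAVS      slopes of MAV over K=3 consecutive equal sub-windows (K-1 values)
LSSI      ln(sum x_i^2 + 1e-12)
RMSV2     v-order statistic with v=2 (classic RMS)
EWL       sum over i=2..N of |x_i - x_{i-1}|^p, p=0.75 on 0.2N<=i<=0.8N,
          p=0.5 outside
PERC2     median of |x_i|
LPC3      order-3 linear-prediction coefficients (Levinson-Durbin on the
          biased autocorrelation; prediction-error convention
          A(z)=1+a1 z^-1+a2 z^-2+a3 z^-3)
FTHT4     periodogram power in the four equal bands of the 20-300 Hz
          passband, normalized to sum 1
PSR       periodogram power within +/-10 Hz of the in-band spectral peak,
          divided by total in-band power
EWP       total terminal-node energy of a level-3 Daubechies-4 wavelet-packet
          decomposition (periodic extension)
MEWP      median terminal-node energy
WENT      Shannon entropy (natural log) of the normalized node energies
CCS       Pearson correlations of sqrt-transformed channels, all unordered
          pairs in lexicographic order
========  =====================================================================
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sps

from .emg_io import GestureLabel
from .exceptions import (
    ConfigurationError,
    DegenerateSignalError,
    LengthError,
)
from .preprocess import GestureSegment

LSSI_FLOOR = 1e-12


class FeatureId(str, enum.Enum):
    MAVS = "MAVS"
    LSSI = "LSSI"
    LPC3 = "LPC3"
    EWP = "EWP"
    AAV = "AAV"
    FTHT4 = "FTHT4"
    MMAV3 = "MMAV3"
    RMSV2 = "RMSV2"
    EWL = "EWL"
    PERC2 = "PERC2"
    PSR = "PSR"
    MEWP = "MEWP"
    MMAV = "MMAV"
    SMAV = "SMAV"
    WENT = "WENT"
    CCS = "CCS"


#: Per-channel output dimension (CCS is cross-channel: C(channels, 2) total).
FEATURE_DIMS = {
    FeatureId.MAVS: 2,
    FeatureId.LPC3: 3,
    FeatureId.FTHT4: 4,
    **{f: 1 for f in FeatureId if f not in (FeatureId.MAVS, FeatureId.LPC3, FeatureId.FTHT4, FeatureId.CCS)},
}


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet-packet basis for EWP / MEWP / WENT."""

    wavelet: str = "db4"
    level: int = 3

    @property
    def n_nodes(self) -> int:
        return 2**self.level


@dataclass(frozen=True)
class ThresholdTask:
    """A clinical cutoff with its active and passive feature pairs.

    ``label = 1`` iff the scale value is strictly greater than ``cutoff``.
    """

    name: str
    scale: str                     # "fma_ue" | "brs_hand" | "mas_hand"
    cutoff: float
    active_pair: tuple[FeatureId, FeatureId]
    passive_pair: tuple[FeatureId, FeatureId]


BUILTIN_TASKS: tuple[ThresholdTask, ...] = (
    ThresholdTask("FMA_UE>29", "fma_ue", 29,
                  (FeatureId.MAVS, FeatureId.LSSI), (FeatureId.LPC3, FeatureId.EWP)),
    ThresholdTask("FMA_UE>44", "fma_ue", 44,
                  (FeatureId.MAVS, FeatureId.LSSI), (FeatureId.LPC3, FeatureId.EWP)),
    ThresholdTask("BRS>3", "brs_hand", 3,
                  (FeatureId.AAV, FeatureId.FTHT4), (FeatureId.MMAV3, FeatureId.RMSV2)),
    ThresholdTask("BRS>4", "brs_hand", 4,
                  (FeatureId.EWL, FeatureId.PERC2), (FeatureId.PSR, FeatureId.MEWP)),
    ThresholdTask("MAS>0", "mas_hand", 0,
                  (FeatureId.MMAV, FeatureId.SMAV), (FeatureId.WENT, FeatureId.CCS)),
)


# ---------------------------------------------------------------------------
# single-channel features


def _check_len(x: np.ndarray, n_min: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < n_min:
        raise LengthError(f"{name}: needs at least {n_min} samples, got {x.size}")
    return x


def mav_family(x: np.ndarray, variant: str = "AAV", fs: float = 1000.0) -> float:
    """MAV and its weighted/scaled variants (AAV, MMAV, MMAV3, SMAV)."""
    x = _check_len(x, 4, variant)
    n = x.size
    a = np.abs(x)
    i = np.arange(1, n + 1)  # 1-based sample index
    if variant in ("MAV", "AAV", "MAV_plain"):
        return float(a.mean())
    if variant == "MMAV":
        w = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
        return float((w * a).sum() / n)
    if variant == "MMAV3":
        w = np.where(i <= 0.25 * n, 1.0, 0.5)
        return float((w * a).sum() / n)
    if variant == "SMAV":
        return float(a.mean() / (n / fs))
    raise ConfigurationError(f"unknown MAV variant {variant!r}")


def mavs(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Mean-absolute-value slope: K-1 differences of sub-window MAVs."""
    if k < 2:
        raise ConfigurationError("mavs needs at least 2 sub-windows")
    x = _check_len(x, k, "MAVS")
    m = x.size // k
    sub = np.abs(x[: m * k]).reshape(k, m).mean(axis=1)
    return np.diff(sub)


def lssi(x: np.ndarray) -> float:
    """Log of the simple square integral, floored against all-zero input."""
    x = _check_len(x, 1, "LSSI")
    return float(np.log(np.sum(x**2) + LSSI_FLOOR))


def rmsv2(x: np.ndarray) -> float:
    """v-order statistic with v = 2 (root mean square)."""
    x = _check_len(x, 1, "RMSV2")
    return float(np.sqrt(np.mean(x**2)))


def ewl(x: np.ndarray) -> float:
    """Enhanced wavelength: fractionally powered first differences, with the
    exponent raised to 0.75 over the central 60% of the segment."""
    x = _check_len(x, 3, "EWL")
    n = x.size
    d = np.abs(np.diff(x))
    i = np.arange(2, n + 1)  # 1-based index of the leading sample
    p = np.where((i >= 0.2 * n) & (i <= 0.8 * n), 0.75, 0.5)
    return float(np.sum(d**p))


def perc2(x: np.ndarray) -> float:
    """50th-percentile amplitude (median of |x|, midpoint interpolation)."""
    x = _check_len(x, 1, "PERC2")
    return float(np.median(np.abs(x)))


def lpc3(x: np.ndarray, order: int = 3) -> np.ndarray:
    """Linear-prediction coefficients via Levinson-Durbin.

    Uses the biased autocorrelation r_k = (1/N) sum x_i x_{i+k} and returns
    (a1, .., a_order) of the prediction-error filter
    A(z) = 1 + a1 z^-1 + ... .
    """
    x = _check_len(x, 16, "LPC3")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("LPC3: constant signal has no spectral shape")
    n = x.size
    r = np.array([np.dot(x[: n - k], x[k:]) for k in range(order + 1)]) / n
    if r[0] <= 0:
        raise DegenerateSignalError("LPC3: zero autocorrelation at lag 0")
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for m in range(1, order + 1):
        acc = r[m] + np.dot(a[1:m], r[m - 1 : 0 : -1])
        k = -acc / err
        new = a[: m + 1].copy()
        new[m] = k
        new[1:m] = a[1:m] + k * a[1:m][::-1]
        a[: m + 1] = new
        err *= 1 - k * k
        if err <= 0:
            raise DegenerateSignalError("LPC3: perfectly predictable signal")
    return a[1:]


def spectral_features(
    x: np.ndarray,
    fs: float = 1000.0,
    variant: str = "FTHT4",
    band: tuple[float, float] = (20.0, 300.0),
    peak_halfwidth: float = 10.0,
):
    """Periodogram-based features.

    FTHT4: total power in the four equal sub-bands of ``band`` (default
    [20,90), [90,160), [160,230), [230,300) Hz), normalized to sum 1.
    PSR: power within ``peak_halfwidth`` Hz of the in-band spectral peak
    over the total in-band power.
    """
    x = _check_len(x, 64, variant)
    if not np.any(x):
        raise DegenerateSignalError(f"{variant}: all-zero signal has no spectrum")
    f, p = sps.periodogram(x, fs=fs, detrend=False)
    low, high = band
    if variant == "FTHT4":
        edges = np.linspace(low, high, 5)
        powers = np.array(
            [p[(f >= edges[j]) & (f < edges[j + 1])].sum() for j in range(4)]
        )
        total = powers.sum()
        if total <= 0:
            raise DegenerateSignalError("FTHT4: no in-band power")
        return powers / total
    if variant == "PSR":
        in_band = (f >= low) & (f < high)
        if not np.any(in_band) or p[in_band].sum() <= 0:
            raise DegenerateSignalError("PSR: no in-band power")
        fb, pb = f[in_band], p[in_band]
        f0 = fb[np.argmax(pb)]
        window = np.abs(fb - f0) <= peak_halfwidth
        return float(pb[window].sum() / pb.sum())
    raise ConfigurationError(f"unknown spectral variant {variant!r}")


def wavelet_packet_energies(x: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Terminal-node energies of the full wavelet-packet decomposition.

    The signal is periodically extended (wrapped) to the next multiple of
    ``2**level`` so every decomposition stage sees an even length and the
    periodized basis stays orthogonal (energy-preserving).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < spec.n_nodes:
        raise LengthError(
            f"wavelet packet level {spec.level} needs >= {spec.n_nodes} samples"
        )
    pad = (-x.size) % spec.n_nodes
    if pad:
        x = np.concatenate([x, x[:pad]])
    wp = pywt.WaveletPacket(data=x, wavelet=spec.wavelet, mode="periodization",
                            maxlevel=spec.level)
    nodes = wp.get_level(spec.level, order="natural")
    return np.array([float(np.sum(node.data**2)) for node in nodes])


def wavelet_packet_features(
    x: np.ndarray, spec: WaveletSpec = WaveletSpec(), variant: str = "EWP"
) -> float:
    """EWP (total node energy), MEWP (median node energy) or WENT (node-energy
    Shannon entropy, natural log; defined as 0 for a zero signal)."""
    energies = wavelet_packet_energies(x, spec)
    if variant == "EWP":
        return float(energies.sum())
    if variant == "MEWP":
        return float(np.median(energies))
    if variant == "WENT":
        total = energies.sum()
        if total <= 0:
            return 0.0
        p = energies / total
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))
    raise ConfigurationError(f"unknown wavelet variant {variant!r}")


def ccs(samples: np.ndarray) -> np.ndarray:
    """Cross-channel correlations of square-root-normalized envelopes.

    ``samples`` is (channels x N) with non-negative entries.  Returns the
    Pearson correlation of sqrt(x) for every unordered channel pair in
    lexicographic order (C(channels, 2) values).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    c = samples.shape[0]
    if c < 2:
        raise ConfigurationError("CCS needs at least 2 channels")
    if np.any(samples < 0):
        raise DegenerateSignalError("CCS expects non-negative envelope samples")
    y = np.sqrt(samples)
    stds = y.std(axis=1)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        raise DegenerateSignalError(
            f"CCS: constant transformed channel(s) {bad.tolist()}: correlation undefined"
        )
    r = np.corrcoef(y)
    return np.array([r[i, j] for i, j in itertools.combinations(range(c), 2)])


# ---------------------------------------------------------------------------
# assembly


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs shared by all feature computations."""

    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    mavs_windows: int = 3
    spectral_band: tuple[float, float] = (20.0, 300.0)
    psr_halfwidth: float = 10.0


def _single_channel_features(
    x: np.ndarray, fs: float, cfg: FeatureConfig
) -> dict[FeatureId, np.ndarray]:
    """All per-channel features for one channel of a segment."""
    out: dict[FeatureId, np.ndarray] = {}
    out[FeatureId.AAV] = np.array([mav_family(x, "AAV", fs)])
    out[FeatureId.MMAV] = np.array([mav_family(x, "MMAV", fs)])
    out[FeatureId.MMAV3] = np.array([mav_family(x, "MMAV3", fs)])
    out[FeatureId.SMAV] = np.array([mav_family(x, "SMAV", fs)])
    out[FeatureId.MAVS] = mavs(x, cfg.mavs_windows)
    out[FeatureId.LSSI] = np.array([lssi(x)])
    out[FeatureId.RMSV2] = np.array([rmsv2(x)])
    out[FeatureId.EWL] = np.array([ewl(x)])
    out[FeatureId.PERC2] = np.array([perc2(x)])
    out[FeatureId.LPC3] = lpc3(x)
    out[FeatureId.FTHT4] = np.asarray(
        spectral_features(x, fs, "FTHT4", cfg.spectral_band)
    )
    out[FeatureId.PSR] = np.array(
        [spectral_features(x, fs, "PSR", cfg.spectral_band, cfg.psr_halfwidth)]
    )
    energies = wavelet_packet_energies(x, cfg.wavelet)
    total = energies.sum()
    out[FeatureId.EWP] = np.array([total])
    out[FeatureId.MEWP] = np.array([float(np.median(energies))])
    if total <= 0:
        went = 0.0
    else:
        p = energies / total
        p = p[p > 0]
        went = float(-np.sum(p * np.log(p)))
    out[FeatureId.WENT] = np.array([went])
    return out


def segment_features(
    segment: GestureSegment, cfg: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """All 16 features of one segment as a flat named mapping.

    Column naming: ``<FID>_ch<c>`` for scalar per-channel features,
    ``<FID><k>_ch<c>`` for multi-component ones, ``CCS_ch<i>ch<j>`` for the
    cross-channel pairs.
    """
    values: dict[str, float] = {}
    for c in range(segment.n_channels):
        per = _single_channel_features(segment.samples[c], segment.fs, cfg)
        for fid, vec in per.items():
            if vec.size == 1:
                values[f"{fid.value}_ch{c + 1}"] = float(vec[0])
            else:
                for k, v in enumerate(vec, start=1):
                    values[f"{fid.value}{k}_ch{c + 1}"] = float(v)
    for (i, j), v in zip(
        itertools.combinations(range(segment.n_channels), 2), ccs(segment.samples)
    ):
        values[f"CCS_ch{i + 1}ch{j + 1}"] = float(v)
    return values


def feature_columns(fid: FeatureId, n_channels: int) -> list[str]:
    """Ordered column names contributed by one feature id."""
    if fid is FeatureId.CCS:
        return [
            f"CCS_ch{i + 1}ch{j + 1}"
            for i, j in itertools.combinations(range(n_channels), 2)
        ]
    dim = FEATURE_DIMS[fid]
    cols = []
    for k in range(1, dim + 1):
        for c in range(1, n_channels + 1):
            cols.append(f"{fid.value}{k}_ch{c}" if dim > 1 else f"{fid.value}_ch{c}")
    return cols


def pair_columns(pair: Sequence[FeatureId], n_channels: int) -> list[str]:
    """Columns of a feature pair: feature 1 over channels, then feature 2."""
    return feature_columns(pair[0], n_channels) + feature_columns(pair[1], n_channels)


def task_pair_for(label: GestureLabel, task: ThresholdTask) -> tuple[FeatureId, FeatureId]:
    """Rest segments use the passive pair, movement segments the active pair."""
    return task.passive_pair if label.is_rest else task.active_pair


def task_vector_dim(
    task: ThresholdTask, gesture_set: Sequence[GestureLabel], n_channels: int = 4
) -> int:
    """Dimension of the assembled vector for a task and gesture set."""
    dim = 0
    for g in gesture_set:
        for fid in task_pair_for(g, task):
            if fid is FeatureId.CCS:
                dim += n_channels * (n_channels - 1) // 2
            else:
                dim += FEATURE_DIMS[fid] * n_channels
    return dim


@dataclass
class FeatureVector:
    """Assembled per-attempt vector for one task and gesture set."""

    subject_id: str
    task: ThresholdTask
    gesture_labels: tuple[GestureLabel, ...]
    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.size


def extract_task_vector(
    segments: Sequence[GestureSegment],
    task: ThresholdTask,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the paired-feature vector for 1 or 2 segments of one subject.

    Per segment, both features of the applicable pair are computed on each
    channel (CCS once across channels) and concatenated feature-major; for a
    two-gesture model the two segments' vectors are concatenated in the
    given order.
    """
    if not 1 <= len(segments) <= 2:
        raise ConfigurationError("extract_task_vector takes 1 or 2 segments")
    sid = segments[0].subject_id
    if any(s.subject_id != sid for s in segments):
        raise ConfigurationError("segments must belong to the same subject")
    parts = []
    for seg in segments:
        named = segment_features(seg, cfg)
        cols = pair_columns(task_pair_for(seg.label, task), seg.n_channels)
        parts.append(np.array([named[c] for c in cols]))
    values = np.concatenate(parts)
    if not np.all(np.isfinite(values)):
        raise DegenerateSignalError(f"non-finite feature values for subject {sid}")
    return FeatureVector(sid, task, tuple(s.label for s in segments), values)


def compute_feature_table(
    segments: Sequence[GestureSegment], cfg: FeatureConfig = FeatureConfig()
):
    """Full per-attempt feature table for a cohort of segments.

    Returns a pandas DataFrame with identifying columns (subject_id, label,
    attempt_index) followed by every named feature column; task vectors are
    then column selections of this table.
    """
    import pandas as pd

    rows = []
    for seg in segments:
        row = {
            "subject_id": seg.subject_id,
            "label": seg.label.value,
            "attempt_index": seg.attempt_index,
        }
        row.update(segment_features(seg, cfg))
        rows.append(row)
    return pd.DataFrame(rows)
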