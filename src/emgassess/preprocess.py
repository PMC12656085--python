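"""Signal conditioning and gesture-attempt segmentation.

The conditioning chain for each channel is:

1. band-pass filter (4th-order Butterworth, 20-300 Hz, zero-phase),
2. demean and full-wave rectify,
3. centered moving-RMS envelope,
4. amplitude normalization per channel by a recording-level reference
   statistic (95th percentile by default) to remove inter-patient scale.

Gesture attempts are then located as peaks of the channel-summed,
moving-averaged envelope and cut into fixed windows of 750 samples at
1 kHz (``segment_length = round(0.75 * fs)`` in general), centered on the
peak.  Rest recordings bypass peak detection: they are tiled into
non-overlapping quiet windows below the detection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .emg_io import GestureLabel, Recording
from .exceptions import (
    ConfigurationError,
    DegenerateReferenceError,
    LengthError,
)

SEGMENT_SECONDS = 0.75


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    order: int = 4
    band: tuple[float, float] = (20.0, 300.0)
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high < fs / 2:
            raise ConfigurationError(
                f"band {self.band} must satisfy 0 < low < high < fs/2 (fs={fs})"
            )


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the moving-average burst detector."""

    ma_window: int = 150          # samples; made odd internally for centering
    threshold_factor: float = 3.0  # multiple of the baseline (median) level
    min_separation: int = 1000     # samples between accepted peaks
    segment_length: int = 750      # samples per attempt window

    def __post_init__(self) -> None:
        if self.ma_window < 1:
            raise ConfigurationError("ma_window must be >= 1")
        if self.threshold_factor <= 0:
            raise ConfigurationError("threshold_factor must be positive")
        if self.min_separation < self.segment_length:
            raise ConfigurationError("min_separation must be >= segment_length")


@dataclass
class GestureSegment:
    """One fixed-length gesture attempt: (channels x segment_length) samples."""

    subject_id: str
    label: GestureLabel
    attempt_index: int
    samples: np.ndarray           # shape (C, segment_length), non-negative
    fs: float = 1000.0
    start: int = -1               # window start in the source recording

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise LengthError("segment samples must be (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _odd(w: int) -> int:
    return w if w % 2 else w + 1


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the band-pass filter along the first axis.

    Zero-phase mode applies the filter forward and backward (doubling the
    effective attenuation and cancelling the phase response).
    """
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.shape[0] <= 3 * (2 * spec.order):
        raise LengthError(
            f"signal of length {x.shape[0]} too short for order-{spec.order} band-pass"
        )
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def demean_rectify(x: np.ndarray) -> np.ndarray:
    """Remove the per-channel mean, then full-wave rectify."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 1:
        raise LengthError("empty signal")
    return np.abs(x - x.mean(axis=0, keepdims=True))


def rms_envelope(x: np.ndarray, window: int = 151) -> np.ndarray:
    """Centered moving-RMS envelope with edge truncation.

    ``e_i = sqrt(mean(x_j^2))`` over the window centered at ``i``; near the
    edges the window is truncated to the available samples.  Even windows are
    widened by one sample so the window is symmetric about ``i``.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if window > n:
        raise ConfigurationError(f"window {window} exceeds signal length {n}")
    w = _odd(window)
    kernel = np.ones(w)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    if x.ndim == 1:
        num = np.convolve(x**2, kernel, mode="same")
        return np.sqrt(num / counts)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = np.sqrt(np.convolve(x[:, c] ** 2, kernel, mode="same") / counts)
    return out


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (odd-adjusted window)."""
    w = _odd(max(int(window), 1))
    n = x.shape[0]
    kernel = np.ones(w)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return np.convolve(x, kernel, mode="same") / counts


_REFERENCES = ("p95", "max", "rms")


def _reference_statistic(col: np.ndarray, reference: str) -> float:
    if reference == "p95":
        return float(np.percentile(col, 95))
    if reference == "max":
        return float(col.max())
    return float(np.sqrt(np.mean(col**2)))


def normalize_amplitude(envelope: np.ndarray, reference: str = "p95") -> np.ndarray:
    """Divide each channel by its recording-level reference statistic."""
    if reference not in _REFERENCES:
        raise ConfigurationError(f"reference must be one of {_REFERENCES}")
    env = np.asarray(envelope, dtype=float)
    if env.ndim == 1:
        ref = _reference_statistic(env, reference)
        if ref <= 0:
            raise DegenerateReferenceError("zero reference statistic")
        return env / ref
    out = np.empty_like(env)
    for c in range(env.shape[1]):
        ref = _reference_statistic(env[:, c], reference)
        if ref <= 0:
            raise DegenerateReferenceError(f"channel {c}: zero reference statistic")
        out[:, c] = env[:, c] / ref
    return out


def preprocess_recording(
    recording: Recording,
    filter_spec: FilterSpec = FilterSpec(),
    rms_window: int = 151,
    reference: str = "p95",
) -> np.ndarray:
    """Full conditioning chain; returns the normalized envelope (T x C).

    ADC-count recordings are converted to microvolts first.
    """
    rec = recording.to_microvolts()
    x = bandpass_filter(rec.data, rec.fs, filter_spec)
    x = demean_rectify(x)
    env = rms_envelope(x, rms_window)
    return normalize_amplitude(env, reference)


def bandpassed_recording(
    recording: Recording, filter_spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Band-passed (pre-envelope) signals, for the raw-domain feature switch."""
    rec = recording.to_microvolts()
    return bandpass_filter(rec.data, rec.fs, filter_spec)


def _window_start(n: int, center: int, length: int) -> int:
    """Start of the window of ``length`` samples centered on ``center``,
    shifted inward at the recording edges."""
    return int(np.clip(center - length // 2, 0, n - length))


def detect_gesture_segments(
    envelope: np.ndarray,
    params: SegmentationParams,
    expected_label: GestureLabel,
    subject_id: str = "",
    fs: float = 1000.0,
) -> list[GestureSegment]:
    """Detect gesture-attempt windows in a normalized multi-channel envelope.

    Movement labels: local maxima of the channel-summed, moving-averaged
    envelope above ``threshold_factor`` times the baseline (median) level,
    at least ``min_separation`` samples apart, each yielding one centered
    ``segment_length`` window.  The rest label instead tiles the recording
    into non-overlapping quiet windows (below the same threshold).
    """
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    if env.shape[0] < env.shape[1]:  # accept (C, T) too
        env = env.T
    n = env.shape[0]
    L = params.segment_length
    if n <= L:
        raise LengthError(f"recording of {n} samples shorter than segment_length {L}")
    summed = env.sum(axis=1)
    smooth = moving_average(summed, params.ma_window)
    baseline = float(np.median(smooth))
    threshold = params.threshold_factor * baseline

    if expected_label is GestureLabel.R:
        segments = []
        idx = 1
        for k in range(n // L):
            window = smooth[k * L : (k + 1) * L]
            if window.max() < threshold:
                segments.append(
                    GestureSegment(subject_id, expected_label, idx,
                                   env[k * L : (k + 1) * L].T, fs, start=k * L)
                )
                idx += 1
        if not segments:
            warnings.warn(f"{subject_id}: no quiet rest windows found", stacklevel=2)
        return segments

    peaks, _ = sps.find_peaks(smooth, height=threshold, distance=params.min_separation)
    if peaks.size == 0:
        warnings.warn(
            f"{subject_id}: no bursts above threshold for label {expected_label.value}",
            stacklevel=2,
        )
        return []
    out = []
    for i, p in enumerate(peaks):
        start = _window_start(n, int(p), L)
        out.append(
            GestureSegment(subject_id, expected_label, i + 1,
                           env[start : start + L].T, fs, start=start)
        )
    return out


@dataclass
class PreprocessConfig:
    """Bundle of the conditioning and segmentation settings.

    ``domain`` selects what the emitted segments contain: the normalized
    RMS envelope (default, the conditioning-chain output) or the rectified
    band-passed signal normalized by the same per-channel reference
    (preserving the raw interference spectrum for the spectral features).
    Detection always runs on the envelope.
    """

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    rms_window: int = 151
    reference: str = "p95"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    max_rest_attempts: int = 15
    domain: str = "envelope"

    def __post_init__(self) -> None:
        if self.domain not in ("envelope", "bandpassed"):
            raise ConfigurationError("domain must be 'envelope' or 'bandpassed'")


def segment_recording(
    recording: Recording,
    label: GestureLabel,
    config: PreprocessConfig = PreprocessConfig(),
) -> list[GestureSegment]:
    """Condition a recording and extract its labeled attempt windows."""
    rec = recording.to_microvolts()
    rectified = demean_rectify(bandpass_filter(rec.data, rec.fs, config.filter_spec))
    env = normalize_amplitude(rms_envelope(rectified, config.rms_window), config.reference)
    segments = detect_gesture_segments(
        env, config.segmentation, label, subject_id=recording.subject_id, fs=recording.fs
    )
    if label is GestureLabel.R:
        segments = segments[: config.max_rest_attempts]
    if config.domain == "bandpassed":
        source = normalize_amplitude(rectified, config.reference)
        L = config.segmentation.segment_length
        for seg in segments:
            seg.samples = source[seg.start : seg.start + L].T
    return segments
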