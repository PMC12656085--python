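"""Synthetic paretic-EMG cohort generator with known ground truth.

A single latent severity ``s`` in [0, 1] per subject drives everything:

* clinical scores — Fugl-Meyer decreases linearly in ``s`` (with a small
  clinical-noise term), the Brunnstrom hand stage falls in steps, and the
  Ashworth grade becomes positive once ``s`` crosses the spasticity onset;
* volitional movement bursts — peak amplitude decreases in ``s`` while
  attempt-to-attempt variability grows (degrading burst "quality");
* resting activity — tonic amplitude and its slow modulation depth grow in
  ``s``, involuntary spasticity bursts appear above the onset, and the
  cross-channel coupling of the tonic drive rises with ``s`` (abnormal
  synergies).

Carriers are exactly band-limited Gaussian noise (frequency-domain
synthesis on [20, 300] Hz at 1 kHz); volitional bursts are 400 ms
raised-cosine envelopes placed at known positions, which are retained so
that segmentation can be scored against ground truth.

The effect-size multiplier ``kappa`` interpolates between the fully linked
cohort (``kappa = 1``, signals driven by the same severity as the scores)
and a null cohort (``kappa = 0``, signals driven by an independent latent,
so EMG carries no information about the clinical labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .emg_io import (
    ClinicalScores,
    GestureLabel,
    MOVEMENT_LABELS,
    Recording,
    UnitState,
    write_recording,
    write_scores,
)
from .exceptions import ConfigurationError, ProtocolError
from .preprocess import GestureSegment, PreprocessConfig, preprocess_recording

_GESTURE_WEIGHTS = {
    # per-gesture channel activation pattern over
    # (flexor_digitorum, extensor_digitorum, extensor_carpi, thenar)
    GestureLabel.F: (1.0, 0.5, 0.4, 0.7),
    GestureLabel.P: (0.6, 0.4, 0.4, 1.0),
    GestureLabel.FL: (1.0, 0.45, 0.4, 0.4),
    GestureLabel.E: (0.4, 1.0, 0.9, 0.4),
    GestureLabel.O: (0.4, 1.0, 0.8, 0.5),
    GestureLabel.T: (0.5, 0.5, 0.4, 1.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the simulated cohort.

    Amplitudes are microvolt RMS of the underlying carriers; durations in
    seconds.  Defaults emulate a 4-channel 1 kHz forearm montage with about
    15 attempts per gesture over 7 classes and 25 subjects.
    """

    n_subjects: int = 25
    fs: float = 1000.0
    channels: int = 4
    gestures: tuple[GestureLabel, ...] = tuple(GestureLabel)
    attempts_per_gesture: int = 15
    # volitional bursts: peak carrier RMS = burst_base + burst_span * (1 - s)
    burst_base_uv: float = 120.0
    burst_span_uv: float = 400.0
    burst_duration_s: float = 0.4
    attempt_period_s: float = 2.0
    lead_in_s: float = 1.0
    # attempt-to-attempt lognormal amplitude jitter: SD = base + slope * s
    quality_jitter_base: float = 0.1
    quality_jitter_slope: float = 0.25
    # resting activity
    rest_duration_s: float = 31.0
    noise_floor_uv: float = 3.0
    tonic_max_uv: float = 12.0
    modulation_band_hz: tuple[float, float] = (0.5, 3.0)
    modulation_depth_max: float = 0.6
    # spasticity
    spasticity_onset: float = 0.4
    spasticity_rate_max_hz: float = 0.25
    spasticity_duration_s: float = 0.3
    spasticity_gain: float = 2.5
    # cross-channel coupling of the tonic drive: rho(s) = rho0 + rho_slope * s
    coupling_base: float = 0.2
    coupling_slope: float = 0.6
    # clinical-score noise
    fma_noise_sd: float = 2.0
    brs_noise_sd: float = 0.2
    # severity -> signal linkage (0 = null cohort)
    kappa: float = 1.0
    carrier_band_hz: tuple[float, float] = (20.0, 300.0)
    unit_state: UnitState = UnitState.MICROVOLTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.n_subjects < 4:
            raise ConfigurationError("cohorts need at least 4 subjects")
        for name in ("burst_base_uv", "burst_span_uv", "noise_floor_uv",
                     "tonic_max_uv", "spasticity_rate_max_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class SyntheticSubject:
    """One simulated subject with ground truth retained."""

    subject_id: str
    severity: float                 # drives the clinical scores
    signal_severity: float          # drives the EMG (equals severity at kappa=1)
    scores: ClinicalScores
    recordings: dict[GestureLabel, Recording]
    burst_positions: dict[GestureLabel, np.ndarray]  # sample index of burst centers


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    subjects: list[SyntheticSubject]

    @property
    def scores(self) -> dict[str, ClinicalScores]:
        return {s.subject_id: s.scores for s in self.subjects}

    def write(self, directory: str | Path) -> None:
        """Emit the recording/score files consumed by :mod:`emgassess.emg_io`
        plus a manifest of severities and ground-truth burst positions."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = ["subject_id,gesture,severity,burst_centers"]
        for sub in self.subjects:
            for label, rec in sub.recordings.items():
                write_recording(rec, directory / f"{sub.subject_id}_{label.value}.csv")
                centers = ";".join(str(int(c)) for c in sub.burst_positions.get(label, []))
                lines.append(
                    f"{sub.subject_id},{label.value},{sub.severity!r},{centers}"
                )
        write_scores(self.scores, directory / "scores.csv")
        (directory / "manifest.csv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# signal primitives


def bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise with spectrum confined exactly to ``band``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = np.zeros(freqs.size, dtype=complex)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spectrum[mask] = rng.normal(size=mask.sum()) + 1j * rng.normal(size=mask.sum())
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def raised_cosine(n: int, center: int, duration: int) -> np.ndarray:
    """A raised-cosine (Hann) bump of ``duration`` samples centered at
    ``center``, zero elsewhere, peak 1."""
    env = np.zeros(n)
    half = duration // 2
    start, stop = max(0, center - half), min(n, center + half)
    t = np.arange(start, stop) - center
    env[start:stop] = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / duration))
    return env


def _slow_modulation(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD slow amplitude-modulation trace."""
    m = bandlimited_noise(n, fs, band, rng)
    sd = m.std()
    return m / sd if sd > 0 else m


def _tonic_activity(
    n: int, cfg: SyntheticConfig, s_sig: float, g_rest: float, rng: np.random.Generator
) -> np.ndarray:
    """(n x C) resting tonic EMG: coupled slow-modulated band-limited noise."""
    rho = float(np.clip(cfg.coupling_base + cfg.coupling_slope * s_sig, 0.0, 1.0))
    depth = cfg.modulation_depth_max * s_sig
    common = _slow_modulation(n, cfg.fs, cfg.modulation_band_hz, rng)
    out = np.empty((n, cfg.channels))
    for c in range(cfg.channels):
        own = _slow_modulation(n, cfg.fs, cfg.modulation_band_hz, rng)
        mod = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
        amp = g_rest * np.clip(1.0 + depth * mod, 0.0, None)
        out[:, c] = amp * bandlimited_noise(n, cfg.fs, cfg.carrier_band_hz, rng)
    return out


def _noise_floor(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    return np.column_stack(
        [
            cfg.noise_floor_uv * bandlimited_noise(n, cfg.fs, cfg.carrier_band_hz, rng)
            for _ in range(cfg.channels)
        ]
    )


# ---------------------------------------------------------------------------
# scores


def scores_from_severity(
    subject_id: str, s: float, cfg: SyntheticConfig, rng: np.random.Generator
) -> ClinicalScores:
    """Clinical scores consistent with the latent severity."""
    fma = int(np.clip(round(66.0 * (1.0 - s) + rng.normal(0.0, cfg.fma_noise_sd)), 0, 66))
    brs = int(np.clip(1 + np.floor(5.0 * (1.0 - s) + rng.normal(0.0, cfg.brs_noise_sd)), 1, 6))
    if s <= cfg.spasticity_onset:
        mas = 0.0
    else:
        u = (s - cfg.spasticity_onset) / (1.0 - cfg.spasticity_onset)
        mas = (1.0, 1.5, 2.0, 3.0, 4.0)[min(int(u * 5), 4)]
    return ClinicalScores(subject_id, fma, brs, mas)


# ---------------------------------------------------------------------------
# subjects and cohorts


def simulate_subject(
    subject_id: str,
    s: float,
    config: SyntheticConfig = SyntheticConfig(),
    seed: int | np.random.Generator = 0,
    scores: ClinicalScores | None = None,
) -> SyntheticSubject:
    """Simulate one subject's full session (rest plus movement gestures)."""
    if not 0.0 <= s <= 1.0:
        raise ConfigurationError("severity must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config
    fs = cfg.fs
    # signal-driving severity: interpolate toward an independent latent
    s_indep = rng.uniform()
    s_sig = float(np.clip(cfg.kappa * s + (1.0 - cfg.kappa) * s_indep, 0.0, 1.0))
    if scores is None:
        scores = scores_from_severity(subject_id, s, cfg, rng)
    gain_jitter = float(np.exp(rng.normal(0.0, 0.15)))
    g_rest = cfg.tonic_max_uv * s_sig * gain_jitter
    burst_peak = (cfg.burst_base_uv + cfg.burst_span_uv * (1.0 - s_sig)) * gain_jitter
    quality_sd = cfg.quality_jitter_base + cfg.quality_jitter_slope * s_sig

    recordings: dict[GestureLabel, Recording] = {}
    positions: dict[GestureLabel, np.ndarray] = {}
    burst_len = int(round(cfg.burst_duration_s * fs))
    period = int(round(cfg.attempt_period_s * fs))
    lead = int(round(cfg.lead_in_s * fs))

    for label in cfg.gestures:
        if label is GestureLabel.R:
            n = int(round(cfg.rest_duration_s * fs))
            x = _noise_floor(n, cfg, rng) + _tonic_activity(n, cfg, s_sig, g_rest, rng)
            # involuntary spasticity bursts above the onset severity
            rate = cfg.spasticity_rate_max_hz * max(
                0.0, (s_sig - cfg.spasticity_onset) / (1.0 - cfg.spasticity_onset)
            )
            n_bursts = rng.poisson(rate * cfg.rest_duration_s)
            sp_len = int(round(cfg.spasticity_duration_s * fs))
            centers = np.sort(rng.integers(sp_len, n - sp_len, size=n_bursts)) if n_bursts else np.array([], dtype=int)
            for c0 in centers:
                env = raised_cosine(n, int(c0), sp_len)
                amp = cfg.spasticity_gain * max(g_rest, cfg.noise_floor_uv)
                for c in range(cfg.channels):
                    w = rng.uniform(0.4, 1.0)
                    x[:, c] += amp * w * env * bandlimited_noise(n, fs, cfg.carrier_band_hz, rng)
            positions[label] = centers
        else:
            n = lead + period * cfg.attempts_per_gesture + int(0.5 * fs)
            x = _noise_floor(n, cfg, rng) + _tonic_activity(n, cfg, s_sig, g_rest, rng)
            weights = np.asarray(_GESTURE_WEIGHTS[label])[: cfg.channels]
            centers = []
            for k in range(cfg.attempts_per_gesture):
                c0 = lead + k * period + int(rng.integers(-int(0.1 * fs), int(0.1 * fs) + 1))
                centers.append(c0)
                env = raised_cosine(n, c0, burst_len)
                amp = burst_peak * float(np.exp(rng.normal(0.0, quality_sd)))
                for c in range(cfg.channels):
                    x[:, c] += amp * weights[c] * env * bandlimited_noise(n, fs, cfg.carrier_band_hz, rng)
            positions[label] = np.asarray(centers, dtype=int)
        x = np.clip(x, -1500.0, 1500.0)
        if cfg.unit_state is UnitState.ADC_COUNTS:
            x = np.round((x / 3000.0 + 0.5) * 65535.0)
        recordings[label] = Recording(
            subject_id=subject_id,
            data=x,
            fs=fs,
            unit_state=cfg.unit_state,
            channel_names=[f"ch{i+1}" for i in range(cfg.channels)],
        )
    return SyntheticSubject(subject_id, float(s), s_sig, scores, recordings, positions)


def _coverage_ok(score_list: list[ClinicalScores], min_per_class: int = 2) -> bool:
    from .assessment import binarize_label
    from .features import BUILTIN_TASKS

    for task in BUILTIN_TASKS:
        labels = [binarize_label(s, task) for s in score_list]
        if sum(labels) < min_per_class or len(labels) - sum(labels) < min_per_class:
            return False
    return True


def simulate_cohort(config: SyntheticConfig = SyntheticConfig(), max_retries: int = 200) -> SyntheticCohort:
    """Simulate an independent cohort with both classes present for every
    built-in task (severities are redrawn if a task would be single-class)."""
    root = np.random.default_rng(config.seed)
    for _ in range(max_retries):
        draw_rng = np.random.default_rng(root.integers(2**31))
        severities = draw_rng.uniform(0.0, 1.0, size=config.n_subjects)
        score_rng = np.random.default_rng(draw_rng.integers(2**31))
        ids = [f"S{i+1:02d}" for i in range(config.n_subjects)]
        score_list = [
            scores_from_severity(sid, s, config, score_rng)
            for sid, s in zip(ids, severities)
        ]
        if _coverage_ok(score_list):
            break
    else:
        raise ProtocolError(
            f"could not draw a cohort with two-class coverage in {max_retries} tries"
        )
    subjects = []
    for sid, s, sc in zip(ids, severities, score_list):
        sub_rng = np.random.default_rng(draw_rng.integers(2**31))
        subjects.append(simulate_subject(sid, s, config, sub_rng, scores=sc))
    return SyntheticCohort(config, subjects)


def null_cohort(config: SyntheticConfig = SyntheticConfig(), **kwargs) -> SyntheticCohort:
    """Convenience: the same generator with the severity-signal link severed."""
    return simulate_cohort(replace(config, kappa=0.0), **kwargs)


# ---------------------------------------------------------------------------
# ground truth access


def ground_truth_segments(
    subject: SyntheticSubject,
    label: GestureLabel | None = None,
    config: PreprocessConfig = PreprocessConfig(),
) -> list[GestureSegment]:
    """Segments cut at the true burst positions, bypassing detection.

    The recording is conditioned with the same chain as the detector and
    windows of ``segment_length`` samples are centered on each known burst
    (shifted inward at edges).  This is the oracle segmentation against
    which the automatic detector is scored.
    """
    labels = [label] if label is not None else [
        g for g in subject.recordings if g is not GestureLabel.R
    ]
    out = []
    L = config.segmentation.segment_length
    for g in labels:
        env = preprocess_recording(
            subject.recordings[g], config.filter_spec, config.rms_window, config.reference
        )
        n = env.shape[0]
        for i, center in enumerate(subject.burst_positions.get(g, []), start=1):
            start = int(np.clip(int(center) - L // 2, 0, n - L))
            out.append(
                GestureSegment(subject.subject_id, g, i, env[start : start + L].T, subject.recordings[g].fs)
            )
    return out


def burst_energy(subject: SyntheticSubject, label: GestureLabel) -> float:
    """Mean raw-signal energy over the true burst windows (ground truth
    diagnostic used by the monotonicity checks)."""
    rec = subject.recordings[label].to_microvolts()
    L = int(round(0.4 * rec.fs))
    energies = []
    for center in subject.burst_positions.get(label, []):
        start = int(np.clip(int(center) - L // 2, 0, rec.n_samples - L))
        energies.append(float(np.sum(rec.data[start : start + L] ** 2)))
    return float(np.mean(energies)) if energies else 0.0


def resting_tonic_energy(subject: SyntheticSubject) -> float:
    """Mean per-sample raw energy of the rest recording."""
    rec = subject.recordings[GestureLabel.R].to_microvolts()
    return float(np.mean(rec.data**2))
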