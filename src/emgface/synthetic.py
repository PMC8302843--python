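"""Synthetic facial-sEMG generator.

Emulates the statistical structure the recognition pipeline relies on:

* each expression activates a distinct subset of the ten AU channels
  (happiness is maximal on the mouth-corner channels CH6/CH8/CH10);
* signal amplitude grows monotonically but nonlinearly with the posed
  intensity level 1-5 (default amplitude ∝ level^1.5);
* the carrier is band-limited (20-450 Hz) zero-mean Gaussian noise, the
  standard surrogate for surface EMG interference patterns;
* acquisition batches differ by per-channel multiplicative gains (electrode
  placement / skin condition), the nuisance the robust scaler removes;
* additive baseline instrumentation noise.

Everything is a pure function of (config, profile, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .signal_io import (
    EXPRESSIONS,
    N_CHANNELS,
    MOUTH_CORNER_CHANNELS,
    ExpressionLabel,
    Recording,
)

__all__ = [
    "ActivationProfile",
    "GeneratorConfig",
    "default_activation_matrix",
    "default_intensity_curve",
    "simulate_emg_channel",
    "generate_recording",
    "generate_dataset",
]


@dataclass(frozen=True)
class ActivationProfile:
    """Per-expression, per-channel activation weights in [0, 1].

    Row order follows :data:`~emgface.signal_io.EXPRESSIONS`; column order is
    CH1..CH10.  Every expression activates at least one channel above 0.5,
    rows are pairwise distinct, and the happiness row peaks strictly on the
    three mouth-corner channels.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(EXPRESSIONS), N_CHANNELS):
            raise ValueError(f"activation matrix must be 7x10, got {m.shape}")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("activation weights must lie in [0, 1]")
        if not (m.max(axis=1) > 0.5).all():
            raise ValueError("every expression needs at least one weight > 0.5")
        for i in range(len(EXPRESSIONS)):
            for j in range(i + 1, len(EXPRESSIONS)):
                if np.array_equal(m[i], m[j]):
                    raise ValueError(
                        f"rows {EXPRESSIONS[i]} and {EXPRESSIONS[j]} are identical"
                    )
        happy = m[EXPRESSIONS.index("happiness")]
        corner_idx = [c - 1 for c in MOUTH_CORNER_CHANNELS]
        others = np.delete(happy, corner_idx)
        if not happy[corner_idx].min() > others.max():
            raise ValueError(
                "happiness must peak strictly on the mouth-corner channels CH6/CH8/CH10"
            )

    def row(self, expression: str) -> np.ndarray:
        return self.matrix[EXPRESSIONS.index(expression)]


def default_activation_matrix() -> ActivationProfile:
    """The documented default 7x10 activation profile.

    Weights follow the FACS reading of each expression on the recorded AUs
    (CH1..CH10 = AU1, AU2, AU4, AU9, AU10, AU26, AU12, AU23, AU17, AU15):
    surprise raises the brows and drops the jaw, sadness lowers the brows and
    lip corners, anger lowers the brows and tightens the lips, disgust
    wrinkles the nose, fear mixes raised brows with a dropped jaw, contempt
    pulls one lip corner, and happiness drives the mouth-corner channels.
    """
    matrix = np.array(
        [
            # CH:  1     2     3     4     5     6     7     8     9    10
            [0.05, 0.05, 0.15, 0.10, 0.35, 0.10, 0.70, 0.30, 0.40, 0.15],  # contempt
            [0.85, 0.80, 0.05, 0.05, 0.10, 0.75, 0.05, 0.05, 0.05, 0.05],  # surprise
            [0.60, 0.10, 0.65, 0.05, 0.05, 0.05, 0.05, 0.10, 0.55, 0.75],  # sadness
            [0.15, 0.10, 0.05, 0.10, 0.45, 0.90, 0.55, 0.85, 0.30, 0.80],  # happiness
            [0.10, 0.05, 0.85, 0.40, 0.25, 0.15, 0.05, 0.70, 0.50, 0.20],  # anger
            [0.05, 0.05, 0.30, 0.85, 0.75, 0.05, 0.10, 0.15, 0.60, 0.35],  # disgust
            [0.70, 0.65, 0.60, 0.10, 0.15, 0.55, 0.05, 0.30, 0.10, 0.25],  # fear
        ]
    )
    return ActivationProfile(matrix)


#: Microvolt RMS of a fully activated channel (weight 1.0) at level 1.
DEFAULT_UNIT_AMPLITUDE_UV: float = 8.0


def default_intensity_curve(unit_uv: float = DEFAULT_UNIT_AMPLITUDE_UV) -> dict[int, float]:
    """Monotone but nonlinear level -> amplitude map: ``unit_uv * level**1.5``."""
    return {level: unit_uv * level**1.5 for level in range(1, 6)}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults: 1 s recordings at 1000 Hz, 20-450 Hz EMG passband, 2 uV
    baseline instrumentation noise, amplitude ∝ level^1.5 with 8 uV per unit
    weight at level 1, and two acquisition batches whose gains differ by 2x.
    """

    duration_s: float = 1.0
    fs: float = 1000.0
    baseline_noise_sd: float = 2.0
    burst_band: tuple[float, float] = (20.0, 450.0)
    intensity_curve: Mapping[int, float] = field(default_factory=default_intensity_curve)
    batch_gains: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"B1": 1.0, "B2": 2.0}
    )
    recordings_per_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.burst_band
        if not 0 < low < high < self.fs / 2:
            raise ValueError(
                f"burst_band must satisfy 0 < low < high < fs/2, got {self.burst_band}"
            )
        levels = sorted(self.intensity_curve)
        if levels != [1, 2, 3, 4, 5]:
            raise ValueError("intensity_curve must map levels 1..5")
        values = [self.intensity_curve[l] for l in levels]
        if not all(b > a for a, b in zip(values, values[1:])):
            raise ValueError("intensity_curve must be strictly increasing")
        for bid, gain in self.batch_gains.items():
            g = np.atleast_1d(np.asarray(gain, dtype=float))
            if (g <= 0).any():
                raise ValueError(f"batch gains must be positive (batch {bid!r})")

    def channel_gains(self, batch_id: str) -> np.ndarray:
        if batch_id not in self.batch_gains:
            raise KeyError(f"unknown batch_id {batch_id!r}; configured: {list(self.batch_gains)}")
        g = np.asarray(self.batch_gains[batch_id], dtype=float)
        if g.ndim == 0:
            g = np.full(N_CHANNELS, float(g))
        if g.shape != (N_CHANNELS,):
            raise ValueError(f"per-channel gain for {batch_id!r} must have length {N_CHANNELS}")
        return g


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Zero-phase band-pass filtered white noise, edge transients trimmed."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band {band} for fs={fs}")
    pad = max(int(0.25 * fs), 64)
    white = rng.standard_normal(n + 2 * pad)
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, white)
    return filtered[pad : pad + n]


def simulate_emg_channel(
    duration_s: float,
    fs: float = 1000.0,
    amplitude: float = 1.0,
    band: tuple[float, float] = (20.0, 450.0),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One channel of surrogate sEMG: band-limited Gaussian noise at a set RMS.

    The output is zero-mean noise in the EMG passband, rescaled so its sample
    RMS equals ``amplitude`` (exactly, up to floating point).  Deterministic
    given the seed.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration too short for one sample")
    x = _bandlimited_noise(n, fs, band, rng)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x * (amplitude / rms)
    return x


def generate_recording(
    expression: str,
    intensity: int,
    batch_id: str,
    profile: ActivationProfile | None = None,
    cfg: GeneratorConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S1",
) -> Recording:
    """Generate one labelled 10-channel recording.

    Channel c carries ``gain_c * (burst(A[expr, c] * curve[intensity]) +
    baseline noise)``: the batch gain multiplies every sample, so batches
    differ by an exact per-channel factor.
    """
    profile = profile if profile is not None else default_activation_matrix()
    cfg = cfg if cfg is not None else GeneratorConfig()
    label = ExpressionLabel(expression, intensity)
    gains = cfg.channel_gains(batch_id)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # One child stream per channel for burst and baseline: the burst stream
    # depends only on (seed, channel), so two intensities at the same seed
    # share the same carrier and differ purely in amplitude.
    children = ss.spawn(2 * N_CHANNELS)
    weights = profile.row(expression)
    level_amp = cfg.intensity_curve[int(intensity)]
    n = int(round(cfg.duration_s * cfg.fs))
    signals = np.empty((N_CHANNELS, n))
    for c in range(N_CHANNELS):
        burst_rng = np.random.default_rng(children[c])
        burst = simulate_emg_channel(
            cfg.duration_s, cfg.fs, weights[c] * level_amp, cfg.burst_band, burst_rng
        )
        noise_rng = np.random.default_rng(children[N_CHANNELS + c])
        baseline = cfg.baseline_noise_sd * noise_rng.standard_normal(n)
        signals[c] = gains[c] * (burst + baseline)
    return Recording(
        signals=signals,
        fs=cfg.fs,
        label=label,
        subject_id=subject_id,
        batch_id=batch_id,
    )


def generate_dataset(
    cfg: GeneratorConfig | None = None,
    profile: ActivationProfile | None = None,
    batches: Sequence[str] | None = None,
    seed: int | None = None,
) -> list[Recording]:
    """A balanced dataset: ``recordings_per_class`` recordings for every
    (expression x intensity x batch) cell, reproducible from the seed.
    """
    cfg = cfg if cfg is not None else GeneratorConfig()
    profile = profile if profile is not None else default_activation_matrix()
    batches = list(batches) if batches is not None else list(cfg.batch_gains)
    if cfg.recordings_per_class < 1:
        raise ValueError("recordings_per_class must be >= 1")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    n_cells = len(batches) * len(EXPRESSIONS) * 5 * cfg.recordings_per_class
    children = root.spawn(n_cells)
    recordings = []
    i = 0
    for batch_id in batches:
        for expression in EXPRESSIONS:
            for intensity in range(1, 6):
                for _rep in range(cfg.recordings_per_class):
                    recordings.append(
                        generate_recording(
                            expression, intensity, batch_id, profile, cfg,
                            seed=children[i],
                        )
                    )
                    i += 1
    return recordings
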