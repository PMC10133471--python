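"""Synthetic SSVEP trial generation.

Emulates the 40-target visual speller paradigm: stimulation frequencies
8–15 Hz in 0.2 Hz strides with a 0.5π phase increment between adjacent
frequencies, sampled at 250 Hz.  A trial for class ``k`` (frequency
``f``, phase ``φ``) on channel ``c`` with gain ``g_c`` is

    s_c(t) = g_c * Σ_{h=1..H} a^{h-1} sin(2π h f t + h φ) + n_c(t)

where ``a`` is the per-harmonic amplitude decay and the noise ``n_c`` is
scaled so that the ratio of clean power to noise power (averaged over
channels with non-zero gain) matches a target SNR in dB.  Noise is white
Gaussian by default with an optional 1/f ("pink") mode.  The channel
gain profile defaults to an occipital-peaked shape, reflecting where
SSVEP responses are strongest on the scalp.

Nothing here attempts biophysical realism: there is no cortical forward
model and no eye-blink/EMG artifact simulation.  The generator exists so
that the network, preprocessing and evaluation code can be exercised
end-to-end with a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# stimulus table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEntry:
    class_index: int
    frequency: float      # Hz
    phase: float          # radians, in [0, 2*pi)


@dataclass(frozen=True)
class StimulusTable:
    """Ordered stimulation-frequency/phase table for the speller paradigm."""

    entries: tuple[StimulusEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, class_index: int) -> StimulusEntry:
        return self.entries[class_index]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([e.frequency for e in self.entries])

    @property
    def phases(self) -> np.ndarray:
        return np.array([e.phase for e in self.entries])

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class_index", "frequency_hz", "phase_rad"])
            for e in self.entries:
                writer.writerow([e.class_index, f"{e.frequency:.6g}", f"{e.phase:.10g}"])


def build_stimulus_table(n_classes: int = 40, base_frequency: float = 8.0,
                         stride: float = 0.2, phase_step: float = 0.5 * math.pi,
                         base_phase: float = 0.0) -> StimulusTable:
    """Frequencies ``base + k*stride`` and phases ``base_phase + k*phase_step``
    (reduced modulo 2π) for classes ``k = 0..n_classes-1``.

    Defaults give the 40-target layout: 8–15.8 Hz in 0.2 Hz strides with a
    0.5π phase difference between adjacent frequencies.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 stimulation classes, got {n_classes}")
    if stride <= 0:
        raise ValueError(f"frequency stride must be positive, got {stride}")
    entries = tuple(
        StimulusEntry(
            class_index=k,
            frequency=base_frequency + k * stride,
            phase=(base_phase + k * phase_step) % TWO_PI,
        )
        for k in range(n_classes)
    )
    return StimulusTable(entries)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def occipital_gain_profile(n_channels: int) -> np.ndarray:
    """Smooth gain profile peaking at the occipital end of the montage.

    Channels are assumed ordered front to back (the canonical ordering in
    :mod:`gdnet.io` ends with the occipital electrodes), so the gain rises
    towards the last channels: ``0.3 + 0.7 * exp(-(distance from back)/(C/4))``.
    """
    idx = np.arange(n_channels)
    scale = max(n_channels / 4.0, 1.0)
    return 0.3 + 0.7 * np.exp(-(n_channels - 1 - idx) / scale)


@dataclass(frozen=True)
class SyntheticConfig:
    """Acquisition and signal-model constants for the synthetic paradigm.

    Defaults mirror the emulated recordings: 64 channels at 250 Hz, 5 s of
    stimulation per trial, 6 trials per class (one per block), 3 harmonics
    decaying by 0.5, and a 0 dB trial SNR.
    """

    n_channels: int = 64
    sampling_rate: float = 250.0
    trial_duration: float = 5.0
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    snr_db: float = 0.0
    channel_gains: tuple[float, ...] | None = None   # None -> occipital profile
    noise_model: str = "white"                        # "white" or "pink"
    n_trials_per_class: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.noise_model not in ("white", "pink"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        gains = self.resolved_gains()
        if np.any(gains < 0) or not np.any(gains > 0):
            raise ValueError("channel gains must be >= 0 with at least one > 0")

    def resolved_gains(self) -> np.ndarray:
        if self.channel_gains is None:
            return occipital_gain_profile(self.n_channels)
        gains = np.asarray(self.channel_gains, dtype=float)
        if gains.shape != (self.n_channels,):
            raise ValueError(
                f"gain profile has {gains.size} entries for {self.n_channels} channels")
        return gains

    @property
    def n_samples(self) -> int:
        n = self.trial_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration * sampling_rate must be an integer")
        return int(round(n))

    def validate_aliasing(self, max_frequency: float) -> None:
        if self.sampling_rate <= 2.0 * max_frequency * self.n_harmonics:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz aliases harmonic "
                f"{self.n_harmonics} of {max_frequency} Hz")


@dataclass(frozen=True)
class TrialRecord:
    """One EEG trial: a channels x samples matrix plus stimulus metadata."""

    data: np.ndarray          # (n_channels, n_samples)
    class_index: int
    frequency: float          # Hz
    phase: float              # radians
    sampling_rate: float      # Hz
    subject_id: str = "synthetic"
    session_id: str = "s01"
    dataset_tag: str = "synthetic"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _clean_signal(cfg: SyntheticConfig, frequency: float, phase: float) -> np.ndarray:
    gains = cfg.resolved_gains()
    t = np.arange(cfg.n_samples) / cfg.sampling_rate
    wave = np.zeros_like(t)
    for h in range(1, cfg.n_harmonics + 1):
        amp = cfg.harmonic_decay ** (h - 1)
        wave += amp * np.sin(TWO_PI * h * frequency * t + h * phase)
    return gains[:, None] * wave[None, :]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Gaussian noise shaped to a 1/f amplitude spectrum, unit variance."""
    n_ch, n = shape
    spec = np.fft.rfft(rng.standard_normal(shape), axis=1)
    freqs = np.fft.rfftfreq(n)
    weight = np.ones_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])
    weight[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spec * weight[None, :], n=n, axis=1)
    noise /= noise.std(axis=1, keepdims=True) + 1e-30
    return noise


def generate_trial(cfg: SyntheticConfig, table: StimulusTable, class_index: int,
                   rng: np.random.Generator) -> TrialRecord:
    """One labelled trial.  Identical ``(cfg, class_index, rng state)`` give
    bitwise-identical data; the realized clean/noise power ratio matches
    ``cfg.snr_db`` by construction (exactly, up to float rounding)."""
    if not (0 <= class_index < len(table)):
        raise IndexError(f"class index {class_index} outside stimulus table "
                         f"of {len(table)} entries")
    entry = table[class_index]
    cfg.validate_aliasing(max(e.frequency for e in table.entries))
    clean = _clean_signal(cfg, entry.frequency, entry.phase)
    data = clean
    if np.isfinite(cfg.snr_db):
        gains = cfg.resolved_gains()
        active = gains > 0
        p_clean = float(np.mean(clean[active] ** 2))
        if cfg.noise_model == "pink":
            noise = _pink_noise(rng, clean.shape)
        else:
            noise = rng.standard_normal(clean.shape)
        p_noise = float(np.mean(noise[active] ** 2))
        target = p_clean / (10.0 ** (cfg.snr_db / 10.0))
        noise *= math.sqrt(target / p_noise)
        data = clean + noise
    return TrialRecord(
        data=data,
        class_index=class_index,
        frequency=entry.frequency,
        phase=entry.phase,
        sampling_rate=cfg.sampling_rate,
    )


def generate_dataset(cfg: SyntheticConfig, table: StimulusTable,
                     class_indices: Sequence[int] | None = None) -> list[TrialRecord]:
    """Class-balanced dataset: ``n_trials_per_class`` trials for every class
    (or for ``class_indices`` if given), reproducible from ``cfg.seed``."""
    if cfg.n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    classes = list(range(len(table))) if class_indices is None else list(class_indices)
    rng = np.random.default_rng(cfg.seed)
    trials: list[TrialRecord] = []
    for k in classes:
        for b in range(cfg.n_trials_per_class):
            rec = generate_trial(cfg, table, k, rng)
            trials.append(replace(rec, session_id=f"block{b:02d}"))
    return trials
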