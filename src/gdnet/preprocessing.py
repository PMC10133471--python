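"""Band-pass filtering, stimulation-interval cropping and segmentation.

Raw trials are filtered with a Chebyshev Type I band-pass (6–90 Hz
passband, 4–100 Hz stopband corners), the cue/offset intervals around the
stimulation window are cropped, and each trial is cut into fixed-length
non-overlapping segments that inherit the trial's class label.  The
filter order is the minimal Chebyshev Type I order meeting 1 dB passband
ripple and 40 dB stopband attenuation at the stated corners, and the
filter is applied forward–backward (zero phase) by default so segment
boundaries carry no group delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .synthetic import TrialRecord

logger = logging.getLogger("gdnet")


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev Type I band-pass specification."""

    passband: tuple[float, float] = (6.0, 90.0)          # Hz
    stopband: tuple[float, float] = (4.0, 100.0)         # Hz
    passband_ripple_db: float = 1.0
    stopband_attenuation_db: float = 40.0
    zero_phase: bool = True

    def __post_init__(self):
        lo_s, hi_s = self.stopband
        lo_p, hi_p = self.passband
        if not (lo_s < lo_p < hi_p < hi_s):
            raise ValueError(
                f"corners must satisfy stop_lo < pass_lo < pass_hi < stop_hi, "
                f"got {self.stopband} / {self.passband}")


def design_bandpass(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Second-order sections of the minimal-order Chebyshev Type I filter
    meeting ``spec`` at ``sampling_rate``.

    Raises a ``ValueError`` when the upper stopband corner is at or above
    the Nyquist frequency.
    """
    nyq = sampling_rate / 2.0
    if spec.stopband[1] >= nyq:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz too low: stopband corner "
            f"{spec.stopband[1]} Hz is not below Nyquist ({nyq} Hz)")
    order, wn = signal.cheb1ord(
        wp=list(spec.passband), ws=list(spec.stopband),
        gpass=spec.passband_ripple_db, gstop=spec.stopband_attenuation_db,
        fs=sampling_rate)
    sos = signal.cheby1(order, spec.passband_ripple_db, wn,
                        btype="bandpass", output="sos", fs=sampling_rate)
    if not np.all(np.isfinite(sos)):
        raise ValueError("filter design produced non-finite coefficients")
    return sos


def filter_trial(trial: TrialRecord, spec: FilterSpec) -> TrialRecord:
    """Filter every channel independently; zero-phase when ``spec.zero_phase``."""
    if not np.all(np.isfinite(trial.data)):
        raise ValueError("trial contains NaN or infinite samples")
    sos = design_bandpass(spec, trial.sampling_rate)
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, trial.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, trial.data, axis=1)
    return replace(trial, data=np.ascontiguousarray(filtered))


def crop_stimulation(trial: TrialRecord, cue_s: float = 0.5,
                     offset_s: float = 0.5) -> TrialRecord:
    """Drop the leading gaze-shift cue and trailing offset around the
    stimulation window."""
    if cue_s < 0 or offset_s < 0:
        raise ValueError("cue and offset durations must be non-negative")
    fs = trial.sampling_rate
    lead = int(round(cue_s * fs))
    trail = int(round(offset_s * fs))
    remaining = trial.n_samples - lead - trail
    if remaining <= 0:
        raise ValueError(
            f"cropping {cue_s}+{offset_s} s leaves no samples from a "
            f"{trial.duration:.3g} s trial")
    stop = trial.n_samples - trail
    return replace(trial, data=trial.data[:, lead:stop].copy())


@dataclass
class SegmentBatch:
    """Fixed-length labelled segments ready for the model.

    ``X`` is ``(batch, n_channels, n_samples)``; ``y`` holds class indices;
    ``source_trial_ids`` maps each segment back to the trial it came from
    (used to keep segments of one trial on the same side of a CV split).
    """

    X: np.ndarray
    y: np.ndarray
    ratio: float                       # window length in seconds
    sampling_rate: float
    source_trial_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.source_trial_ids = np.asarray(self.source_trial_ids, dtype=np.int64)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]

    def subset(self, idx) -> "SegmentBatch":
        return SegmentBatch(self.X[idx], self.y[idx], self.ratio,
                            self.sampling_rate, self.source_trial_ids[idx])

    @staticmethod
    def concatenate(batches: Sequence["SegmentBatch"]) -> "SegmentBatch":
        first = batches[0]
        return SegmentBatch(
            np.concatenate([b.X for b in batches]),
            np.concatenate([b.y for b in batches]),
            first.ratio, first.sampling_rate,
            np.concatenate([b.source_trial_ids for b in batches]))

    # -- HDF5 round trip ----------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("X", data=self.X)
            fh.create_dataset("y", data=self.y)
            fh.create_dataset("source_trial_ids", data=self.source_trial_ids)
            fh.attrs["ratio"] = self.ratio
            fh.attrs["sampling_rate"] = self.sampling_rate

    @staticmethod
    def from_hdf5(path) -> "SegmentBatch":
        import h5py
        with h5py.File(path, "r") as fh:
            return SegmentBatch(fh["X"][...], fh["y"][...],
                                float(fh.attrs["ratio"]),
                                float(fh.attrs["sampling_rate"]),
                                fh["source_trial_ids"][...])


def segment_trial(trial: TrialRecord, ratio: float,
                  trial_id: int = 0) -> SegmentBatch:
    """Cut a trial into ``floor(Len / (ratio*fs))`` non-overlapping windows
    of ``ratio`` seconds; the trailing remainder is discarded.  A window
    longer than the trial yields an empty batch (logged), not an error."""
    fs = trial.sampling_rate
    window = int(round(ratio * fs))
    if window < 1:
        raise ValueError(f"window of {ratio} s is shorter than one sample at {fs} Hz")
    t = trial.n_samples // window
    if t == 0:
        logger.warning("window of %d samples longer than trial of %d samples; "
                       "returning empty batch", window, trial.n_samples)
        return SegmentBatch(
            np.empty((0, trial.n_channels, window), dtype=np.float32),
            np.empty(0, dtype=np.int64), ratio, fs, np.empty(0, dtype=np.int64))
    usable = trial.data[:, :t * window]
    X = usable.reshape(trial.n_channels, t, window).transpose(1, 0, 2)
    y = np.full(t, trial.class_index, dtype=np.int64)
    ids = np.full(t, trial_id, dtype=np.int64)
    return SegmentBatch(X, y, ratio, fs, ids)


def segment_trials(trials: Sequence[TrialRecord], ratio: float) -> SegmentBatch:
    """Segment a collection of trials, numbering source trials 0..n-1."""
    batches = [segment_trial(tr, ratio, trial_id=i) for i, tr in enumerate(trials)]
    batches = [b for b in batches if len(b) > 0]
    if not batches:
        window = int(round(ratio * trials[0].sampling_rate)) if trials else 0
        n_ch = trials[0].n_channels if trials else 0
        return SegmentBatch(np.empty((0, n_ch, window), dtype=np.float32),
                            np.empty(0, dtype=np.int64), ratio,
                            trials[0].sampling_rate if trials else 0.0,
                            np.empty(0, dtype=np.int64))
    return SegmentBatch.concatenate(batches)


def preprocess_trials(trials: Sequence[TrialRecord], spec: FilterSpec | None,
                      ratio: float, cue_s: float = 0.0,
                      offset_s: float = 0.0) -> SegmentBatch:
    """Filter → crop → segment convenience pipeline.

    Cropping defaults to zero on both sides because synthetic trials are
    generated stimulation-only; pass ``cue_s=offset_s=0.5`` for real-dataset
    trial layouts that include the cue and offset intervals.
    """
    out: list[TrialRecord] = []
    for tr in trials:
        if spec is not None:
            tr = filter_trial(tr, spec)
        if cue_s > 0 or offset_s > 0:
            tr = crop_stimulation(tr, cue_s, offset_s)
        out.append(tr)
    return segment_trials(out, ratio)
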