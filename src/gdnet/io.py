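"""Dataset IO: channel montages, the MAT trial reader, HDF5 serialisation
and the YAML run configuration.

The canonical 64-channel ordering follows the channel file published with
the public 40-target speller benchmark recordings (international 10-10
labels, front to back, ending at the occipital electrodes).  Synthetic
data uses the same ordering so the occipital-peaked gain profile and the
named channel subsets line up.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .model import GDNetConfig
from .preprocessing import FilterSpec
from .synthetic import StimulusTable, SyntheticConfig, TrialRecord, build_stimulus_table
from .training import TrainConfig

logger = logging.getLogger("gdnet")

# Canonical 64-channel 10-10 ordering (benchmark montage).
CHANNELS_64 = (
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ",
    "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2",
    "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4",
    "C6", "T8", "M1", "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4",
    "CP6", "TP8", "M2", "P7", "P5", "P3", "P1", "PZ", "P2", "P4",
    "P6", "P8", "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", "CB1",
    "O1", "OZ", "O2", "CB2",
)

# Named subsets.  cp32 is our documented reading of "occipital, parietal,
# central and centro-parietal regions": the C/CP/P/PO/O rows of the 10-10
# grid minus the vertex Cz, which brings the count to exactly 32.
SUBSETS: dict[str, tuple[str, ...]] = {
    "occ3": ("O1", "OZ", "O2"),
    "occ6": ("O1", "OZ", "O2", "POZ", "PO3", "PO4"),
    "po9": ("O1", "OZ", "O2", "PZ", "PO3", "PO5", "PO4", "PO6", "POZ"),
    "cp32": (
        "C5", "C3", "C1", "C2", "C4", "C6",
        "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
        "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
        "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
        "O1", "OZ", "O2",
    ),
    "all64": CHANNELS_64,
}


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered channel subset with indices into the 64-channel ordering."""

    subset_name: str
    labels: tuple[str, ...]
    indices: tuple[int, ...]

    @classmethod
    def named(cls, subset_name: str) -> "ChannelMontage":
        if subset_name not in SUBSETS:
            raise KeyError(f"unknown montage {subset_name!r}; "
                           f"choose from {sorted(SUBSETS)}")
        labels = SUBSETS[subset_name]
        return cls.from_labels(labels, subset_name=subset_name)

    @classmethod
    def from_labels(cls, labels: Sequence[str],
                    subset_name: str = "custom") -> "ChannelMontage":
        idx = []
        for lab in labels:
            lab_u = lab.upper()
            if lab_u not in CHANNELS_64:
                raise KeyError(f"unknown channel label {lab!r}")
            idx.append(CHANNELS_64.index(lab_u))
        return cls(subset_name, tuple(l.upper() for l in labels), tuple(idx))

    def __len__(self) -> int:
        return len(self.labels)

    def subselect(self, labels: Sequence[str]) -> "ChannelMontage":
        """A montage whose indices are positions *within this montage*, so
        selections compose: ``select(select(t, m), m.subselect(ls))`` equals
        ``select(t, from_labels(ls))``."""
        idx = []
        for lab in labels:
            lab_u = lab.upper()
            if lab_u not in self.labels:
                raise KeyError(f"channel {lab!r} not in montage {self.subset_name!r}")
            idx.append(self.labels.index(lab_u))
        return ChannelMontage("custom", tuple(l.upper() for l in labels), tuple(idx))


def select_channels(trials: Sequence[TrialRecord],
                    montage: ChannelMontage) -> list[TrialRecord]:
    """Subset/re-order trial rows per the montage.

    Trials must carry at least ``max(montage.indices)+1`` channels in the
    canonical ordering.
    """
    needed = max(montage.indices) + 1
    out = []
    for tr in trials:
        if tr.n_channels < needed:
            raise ValueError(
                f"montage {montage.subset_name!r} needs {needed} channels, "
                f"trial has {tr.n_channels}")
        out.append(dataclasses.replace(tr, data=tr.data[list(montage.indices)].copy()))
    return out


# ---------------------------------------------------------------------------
# MAT reader (optional real-data path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatLayout:
    """Describes the trial array inside a MAT file.

    ``axes`` names the order of the array's dimensions using the letters
    c (channels), s (samples), k (conditions) and b (blocks); the public
    benchmark layout is ``key='data'``, ``axes='cskb'``.
    """

    key: str = "data"
    axes: str = "cskb"
    sampling_rate: float = 250.0

    def __post_init__(self):
        if sorted(self.axes) != ["b", "c", "k", "s"]:
            raise ValueError(f"axes must be a permutation of 'cskb', got {self.axes!r}")


def read_mat_trials(path, layout: MatLayout = MatLayout(),
                    table: StimulusTable | None = None,
                    subject_id: str = "unknown") -> list[TrialRecord]:
    """Read one TrialRecord per (condition, block) from a MAT file.

    Class indices map through the stimulus table ordering (condition k is
    class k); the sampling rate comes from the layout descriptor.
    """
    from scipy.io import loadmat
    mat = loadmat(path)
    if layout.key not in mat:
        raise ValueError(f"MAT file {path} has no array {layout.key!r}; "
                         f"keys: {[k for k in mat if not k.startswith('__')]}")
    arr = np.asarray(mat[layout.key])
    if arr.ndim != 4:
        raise ValueError(f"array {layout.key!r} has {arr.ndim} axes, expected 4 "
                         f"(channels, samples, conditions, blocks)")
    order = [layout.axes.index(a) for a in "cskb"]
    arr = arr.transpose(order)          # -> (C, S, K, B)
    n_ch, n_s, n_cond, n_blocks = arr.shape
    if table is None:
        table = build_stimulus_table(max(n_cond, 2))
    trials = []
    for k in range(n_cond):
        entry = table[k]
        for b in range(n_blocks):
            trials.append(TrialRecord(
                data=np.ascontiguousarray(arr[:, :, k, b], dtype=np.float64),
                class_index=k, frequency=entry.frequency, phase=entry.phase,
                sampling_rate=layout.sampling_rate,
                subject_id=subject_id, session_id=f"block{b:02d}",
                dataset_tag="mat"))
    return trials


# ---------------------------------------------------------------------------
# HDF5 trial serialisation
# ---------------------------------------------------------------------------

def save_trials_hdf5(path, trials: Sequence[TrialRecord], seed: int | None = None) -> None:
    """One array per trial group, stimulus metadata as attributes."""
    import h5py
    with h5py.File(path, "w") as fh:
        if seed is not None:
            fh.attrs["seed"] = seed
        for i, tr in enumerate(trials):
            g = fh.create_group(f"trial{i:05d}")
            g.create_dataset("data", data=tr.data)
            g.attrs.update({
                "class_index": tr.class_index, "frequency": tr.frequency,
                "phase": tr.phase, "sampling_rate": tr.sampling_rate,
                "subject_id": tr.subject_id, "session_id": tr.session_id,
                "dataset_tag": tr.dataset_tag,
            })


def load_trials_hdf5(path) -> list[TrialRecord]:
    import h5py
    trials = []
    with h5py.File(path, "r") as fh:
        for name in sorted(k for k in fh if k.startswith("trial")):
            g = fh[name]
            trials.append(TrialRecord(
                data=g["data"][...],
                class_index=int(g.attrs["class_index"]),
                frequency=float(g.attrs["frequency"]),
                phase=float(g.attrs["phase"]),
                sampling_rate=float(g.attrs["sampling_rate"]),
                subject_id=str(g.attrs["subject_id"]),
                session_id=str(g.attrs["session_id"]),
                dataset_tag=str(g.attrs["dataset_tag"])))
    return trials


def save_attention_maps(path, maps: Sequence[tuple[int, np.ndarray, np.ndarray | None]]) -> None:
    """Dump per-block attention maps: (block index, C x M gate, M gate)."""
    import h5py
    with h5py.File(path, "w") as fh:
        for block, m_ec, m_sn in maps:
            g = fh.create_group(f"block{block}")
            if m_ec is not None:
                g.create_dataset("channel_gate", data=m_ec)
            if m_sn is not None:
                g.create_dataset("network_gate", data=m_sn)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_RATIOS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RunConfig:
    """Everything one run needs, YAML round-trippable."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: GDNetConfig | None = None
    montage: str = "all64"
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "synthetic": dataclasses.asdict(self.synthetic),
            "filter": dataclasses.asdict(self.filter),
            "train": dataclasses.asdict(self.train),
            "model": dataclasses.asdict(self.model) if self.model else None,
            "montage": self.montage,
            "ratios": list(self.ratios),
            "seed": self.seed,
        }
        return d

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        syn = dict(d.get("synthetic", {}))
        if syn.get("channel_gains") is not None:
            syn["channel_gains"] = tuple(syn["channel_gains"])
        filt = dict(d.get("filter", {}))
        for key in ("passband", "stopband"):
            if key in filt:
                filt[key] = tuple(filt[key])
        return cls(
            synthetic=SyntheticConfig(**syn),
            filter=FilterSpec(**filt),
            train=TrainConfig(**d.get("train", {})),
            model=GDNetConfig(**d["model"]) if d.get("model") else None,
            montage=d.get("montage", "all64"),
            ratios=tuple(d.get("ratios", DEFAULT_RATIOS)),
            seed=int(d.get("seed", 0)))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
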