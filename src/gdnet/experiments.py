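"""Scaled-down end-to-end experiments on synthetic SSVEP data.

These harnesses exercise the whole pipeline (simulate → filter → segment
→ train → evaluate) at sizes a single CPU handles in minutes:

* :func:`run_frequency_recovery` — an 8-class recognition problem
  (frequencies spread over the 8–15 Hz band at 1 Hz spacing), 8 channels,
  1 s segments at 250 Hz, 0 dB SNR, 800 training / 200 test segments
  split by trial, classified by a reduced network (16 maps, 2 group
  blocks, attention on).  With ``shuffle_labels=True`` the same harness
  trains on permuted labels, which must stay at chance — together the two
  runs certify that learning is signal-driven.

* :func:`run_ablation` — trains the full model and selected ablation
  variants on a small low-SNR set over several seeds and reports mean
  test accuracy per variant.
"""

from __future__ import annotations

import numpy as np

from .model import GDNetConfig, build_model, build_variant
from .preprocessing import FilterSpec, SegmentBatch, preprocess_trials
from .synthetic import SyntheticConfig, build_stimulus_table, generate_dataset
from .training import TrainConfig, init_weights, macro_metrics, train


def make_scaled_dataset(n_classes: int = 8, n_channels: int = 8,
                        trials_per_class: int = 25, trial_duration: float = 5.0,
                        snr_db: float = 0.0, ratio: float = 1.0,
                        seed: int = 0, bandpass: bool = True) -> SegmentBatch:
    """Synthetic segments for the scaled experiments.

    Classes are spread evenly across the 40-entry stimulus table so the
    frequencies span the full 8–15 Hz band (1 Hz apart for 8 classes) and
    labels are remapped to 0..n_classes-1.
    """
    table = build_stimulus_table(40)
    step = len(table) // n_classes
    class_indices = [k * step for k in range(n_classes)]
    cfg = SyntheticConfig(
        n_channels=n_channels, trial_duration=trial_duration, snr_db=snr_db,
        n_trials_per_class=trials_per_class, seed=seed)
    trials = generate_dataset(cfg, table, class_indices=class_indices)
    spec = FilterSpec() if bandpass else None
    segments = preprocess_trials(trials, spec, ratio=ratio)
    remap = {orig: new for new, orig in enumerate(class_indices)}
    segments.y = np.array([remap[int(v)] for v in segments.y], dtype=np.int64)
    return segments


def split_by_trial(segments: SegmentBatch, test_fraction: float,
                   seed: int) -> tuple[SegmentBatch, SegmentBatch]:
    """Class-stratified train/test split on whole trials."""
    rng = np.random.default_rng(seed)
    test_trials = []
    for cls in np.unique(segments.y):
        trials = np.unique(segments.source_trial_ids[segments.y == cls])
        n_test = max(1, int(round(test_fraction * len(trials))))
        test_trials.extend(rng.choice(trials, size=n_test, replace=False))
    mask = np.isin(segments.source_trial_ids, test_trials)
    return segments.subset(~mask), segments.subset(mask)


def run_frequency_recovery(seed: int = 0, shuffle_labels: bool = False,
                           max_epochs: int = 40, patience: int = 5) -> dict:
    """Train the reduced network on the 8-class problem and return test
    accuracy (fraction), chance level and the training history."""
    segments = make_scaled_dataset(seed=seed)
    train_all, test_b = split_by_trial(segments, test_fraction=0.2, seed=seed)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        # permute labels at the trial level so segments stay self-consistent
        trials = np.unique(train_all.source_trial_ids)
        trial_labels = np.array([train_all.y[train_all.source_trial_ids == t][0]
                                 for t in trials])
        shuffled = rng.permutation(trial_labels)
        lut = dict(zip(trials.tolist(), shuffled.tolist()))
        train_all.y = np.array([lut[int(t)] for t in train_all.source_trial_ids])
    train_b, val_b = split_by_trial(train_all, test_fraction=0.15, seed=seed + 2)

    n_classes = len(np.unique(segments.y))
    model_cfg = GDNetConfig(
        n_channels=train_b.n_channels, n_samples=train_b.n_samples,
        n_classes=n_classes, n_feature_maps=16, n_group_blocks=2)
    train_cfg = TrainConfig(seed=seed, max_epochs=max_epochs,
                            early_stop_patience=patience)
    model = init_weights(build_model(model_cfg), seed)
    history = train(model, train_b, val_b, train_cfg)
    preds = []
    for start in range(0, len(test_b), 256):
        preds.append(model.predict(test_b.X[start:start + 256]))
    y_pred = np.concatenate(preds)
    accuracy = float((y_pred == test_b.y).mean())
    acc, sen, spe = macro_metrics(test_b.y, y_pred, n_classes)
    return {
        "accuracy": accuracy,
        "macro_acc": acc, "macro_sen": sen, "macro_spe": spe,
        "chance": 1.0 / n_classes,
        "n_train": len(train_b) + len(val_b), "n_test": len(test_b),
        "epochs_run": len(history["train_loss"]),
        "history": history,
    }


def run_ablation(seeds=(0, 1, 2, 3, 4), variants=("full", "model2", "model3"),
                 snr_db: float = -8.0, max_epochs: int = 15) -> dict:
    """Mean test accuracy per variant over several seeds on a small
    low-SNR 4-class set (4 blocks for the full model so the shallow
    variant is a genuine depth ablation)."""
    results: dict[str, list[float]] = {v: [] for v in variants}
    for seed in seeds:
        segments = make_scaled_dataset(
            n_classes=4, n_channels=6, trials_per_class=15,
            trial_duration=2.0, snr_db=snr_db, ratio=0.5, seed=seed)
        train_all, test_b = split_by_trial(segments, test_fraction=0.25, seed=seed)
        train_b, val_b = split_by_trial(train_all, test_fraction=0.2, seed=seed + 2)
        base_cfg = GDNetConfig(
            n_channels=segments.n_channels, n_samples=segments.n_samples,
            n_classes=4, n_feature_maps=8, n_group_blocks=4)
        for variant in variants:
            model = build_variant(variant, base_cfg)
            init_weights(model, seed)
            cfg = TrainConfig(seed=seed, max_epochs=max_epochs, early_stop_patience=4)
            train(model, train_b, val_b, cfg)
            acc = float((model.predict(test_b.X) == test_b.y).mean())
            results[variant].append(acc)
    return {
        "seeds": list(seeds),
        "per_seed_accuracy": results,
        "mean_accuracy": {v: float(np.mean(a)) for v, a in results.items()},
    }
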