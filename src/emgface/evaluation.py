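"""Evaluation procedures for the sEMG expression-recognition pipeline.

Covers: confusion matrices; exact and fuzzy intensity accuracy (a
prediction one level off the true intensity counts as correct — intensity
is a continuum and adjacent confusions are benign); channel-ablation
experiments; cross-batch robustness with and without the robust scaler;
classical baseline classifiers; and majority-vote smoothing of continuous
frame-label streams with short-run (outlier) suppression.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .classifier import NetworkConfig, build_network, predict, train
from .features import (
    FeatureMatrix,
    apply_robust_scaler,
    extract_features_from_recordings,
    fit_robust_scaler,
)
from .signal_io import EXPRESSIONS, N_CHANNELS, Recording

__all__ = [
    "ConfusionMatrix",
    "ExperimentResult",
    "confusion_matrix",
    "accuracy",
    "fuzzy_intensity_accuracy",
    "classify_heldout",
    "channel_ablation",
    "batch_robustness_experiment",
    "compare_baselines",
    "smooth_stream",
]


@dataclass
class ConfusionMatrix:
    """k x k count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k class names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


def confusion_matrix(true_labels, predicted_labels, class_names: Sequence) -> ConfusionMatrix:
    """counts[i, j] = number of frames with true class i predicted as j."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    known = set(class_names)
    for l in true_labels + predicted_labels:
        if l not in known:
            raise ValueError(f"label {l!r} not among class names {list(class_names)}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_names))
    return ConfusionMatrix(counts, list(class_names))


def accuracy(true_labels, predicted_labels) -> float:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(t == p))


def fuzzy_intensity_accuracy(true_levels, predicted_levels) -> float:
    """Fraction of predictions within one level of the true intensity.

    Equivalent to counting the diagonal of the 5x5 intensity confusion
    matrix together with the cells immediately left and right of it.
    """
    t = np.asarray(true_levels, dtype=int)
    p = np.asarray(predicted_levels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for arr in (t, p):
        if ((arr < 1) | (arr > 5)).any():
            raise ValueError("intensity levels must lie in [1, 5]")
    return float(np.mean(np.abs(t - p) <= 1))


@dataclass
class ExperimentResult:
    """Accuracies per experimental condition, with full reproducibility
    bookkeeping (seeds, splits, confusion matrices)."""

    name: str
    conditions: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.conditions.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {k: v for k, v in c.items() if not isinstance(v, ConfusionMatrix)}
            for c in self.conditions
        ]
        return pd.DataFrame(rows)

    def mean_accuracy(self, **filters) -> float:
        vals = [
            c["accuracy"]
            for c in self.conditions
            if all(c.get(k) == v for k, v in filters.items())
        ]
        if not vals:
            raise KeyError(f"no conditions match {filters}")
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Shared pipeline runner


def _subset_columns(channels: Sequence[int]) -> list[str]:
    return [f"RMS_CH{c}" for c in channels] + [f"IEMG_CH{c}" for c in channels]


def _target_labels(fm: FeatureMatrix, target: str):
    if target == "expression":
        return fm.expressions(), list(EXPRESSIONS)
    if target == "intensity":
        return fm.intensities(), [1, 2, 3, 4, 5]
    raise ValueError(f"unknown target {target!r}")


def classify_heldout(
    features: FeatureMatrix,
    target: Literal["expression", "intensity"] = "expression",
    channels: Sequence[int] | None = None,
    scaler_scope: str | None = "per_batch",
    seed: int = 0,
    network: NetworkConfig | None = None,
) -> tuple[float, ConfusionMatrix]:
    """Scale, train and score the network on its held-out validation split.

    ``channels`` restricts the pipeline to a subset of 1-based channel
    indices (the per-channel features of a subset are exactly the features
    an acquisition restricted to those channels would produce).
    ``scaler_scope=None`` skips scaling entirely.
    """
    channels = list(channels) if channels is not None else list(range(1, N_CHANNELS + 1))
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channels in subset")
    if not channels or any(not 1 <= c <= N_CHANNELS for c in channels):
        raise ValueError("channel subset must be nonempty with indices in 1..10")

    if scaler_scope is not None:
        scaled = apply_robust_scaler(features, fit_robust_scaler(features, scaler_scope))
    else:
        scaled = features
    X = scaled.data[_subset_columns(channels)].to_numpy(dtype=float)
    y, class_names = _target_labels(features, target)

    k = 7 if target == "expression" else 5
    if network is None:
        cfg = NetworkConfig(k=k, n_features=2 * len(channels), seed=seed)
    else:
        kwargs = {**network.__dict__, "k": k, "n_features": 2 * len(channels), "seed": seed}
        cfg = NetworkConfig(**kwargs)
    model, report = train(
        build_network(cfg), X, y, cfg, class_names=class_names,
        scaler_scope=scaler_scope or "none",
    )
    # Re-derive the identical validation split for the confusion matrix.
    idx = np.arange(len(y))
    _, val_idx = train_test_split(
        idx, test_size=cfg.val_fraction, random_state=cfg.seed,
        stratify=np.array([class_names.index(l) for l in y]),
    )
    pred = predict(model, X[val_idx])
    cm = confusion_matrix(list(np.asarray(y)[val_idx]), list(pred), class_names)
    return report.final_val_accuracy, cm


# ---------------------------------------------------------------------------
# Experiments


def channel_ablation(
    recordings: Sequence[Recording],
    channel_subsets: Sequence[Sequence[int]],
    target: Literal["expression", "intensity"] = "expression",
    seeds: Sequence[int] = (0, 1, 2),
    scaler_scope: str = "per_batch",
    network: NetworkConfig | None = None,
) -> ExperimentResult:
    """Held-out accuracy per channel subset, the network retrained (input
    layer resized to 2*|subset| features) and averaged over seeds."""
    for subset in channel_subsets:
        if not subset:
            raise ValueError("channel subsets must be nonempty")
        if len(set(subset)) != len(subset):
            raise ValueError(f"duplicate entries in subset {list(subset)}")
    features = extract_features_from_recordings(recordings)
    result = ExperimentResult("channel_ablation")
    for subset in channel_subsets:
        for seed in seeds:
            acc, cm = classify_heldout(
                features, target=target, channels=subset,
                scaler_scope=scaler_scope, seed=seed, network=network,
            )
            result.add(
                n_channels=len(subset), channels=tuple(subset), seed=seed,
                accuracy=acc, confusion=cm,
            )
    return result


def batch_robustness_experiment(
    recordings: Sequence[Recording],
    train_batch: str,
    test_batch: str,
    target: Literal["expression", "intensity"] = "expression",
    seeds: Sequence[int] = (0, 1, 2),
    network: NetworkConfig | None = None,
) -> ExperimentResult:
    """Cross-batch accuracy with and without robust scaling.

    The model trains on one acquisition batch and is tested on another; with
    scaling on, each batch is scaled with parameters fitted on its own
    (unlabeled) frames.  Identical splits and seeds in both conditions.
    """
    batches = {r.batch_id for r in recordings}
    if train_batch == test_batch or not {train_batch, test_batch} <= batches:
        raise ValueError(
            f"need two distinct batches among {sorted(batches)}; "
            f"got train={train_batch!r}, test={test_batch!r}"
        )
    features = extract_features_from_recordings(recordings)
    train_mask = features.batches() == train_batch
    test_mask = features.batches() == test_batch
    result = ExperimentResult("batch_robustness")
    for use_scaler in (True, False):
        if use_scaler:
            scaled = apply_robust_scaler(features, fit_robust_scaler(features, "per_batch"))
        else:
            scaled = features
        X = scaled.values
        y, class_names = _target_labels(features, target)
        for seed in seeds:
            k = 7 if target == "expression" else 5
            if network is None:
                cfg = NetworkConfig(k=k, seed=seed)
            else:
                cfg = NetworkConfig(**{**network.__dict__, "k": k, "n_features": 20, "seed": seed})
            model, _ = train(
                build_network(cfg), X[train_mask], np.asarray(y)[train_mask], cfg,
                class_names=class_names,
                scaler_scope="per_batch" if use_scaler else "none",
            )
            pred = predict(model, X[test_mask])
            true = list(np.asarray(y)[test_mask])
            acc = accuracy(true, pred)
            result.add(
                scaler=use_scaler, seed=seed, train_batch=train_batch,
                test_batch=test_batch, accuracy=acc,
                confusion=confusion_matrix(true, list(pred), class_names),
            )
    return result


BASELINE_CLASSIFIERS = ("svm", "random_forest", "knn", "lda")


def _make_baseline(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {name!r}; choose from {BASELINE_CLASSIFIERS}")


def compare_baselines(
    features: np.ndarray,
    labels: Sequence,
    classifiers: Sequence[str] = BASELINE_CLASSIFIERS,
    seeds: Sequence[int] = (0,),
    include_network: bool = True,
    network: NetworkConfig | None = None,
) -> ExperimentResult:
    """Paired comparison: every classifier scored on the identical stratified
    2/3 / 1/3 split of the same scaled features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    class_names = sorted(set(y.tolist()))
    result = ExperimentResult("baseline_comparison")
    for seed in seeds:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=1.0 / 3.0, random_state=seed, stratify=y
        )
        for name in classifiers:
            clf = _make_baseline(name, seed)
            clf.fit(X_tr, y_tr)
            acc = accuracy(y_val, clf.predict(X_val))
            result.add(classifier=name, seed=seed, accuracy=acc)
        if include_network:
            k = len(class_names)
            if k not in (5, 7):
                raise ValueError("network comparison needs 5 or 7 classes")
            cfg = (
                NetworkConfig(k=k, n_features=X.shape[1], seed=seed)
                if network is None
                else NetworkConfig(**{**network.__dict__, "k": k,
                                      "n_features": X.shape[1], "seed": seed})
            )
            # train() re-derives the same seeded split internally.
            model, report = train(build_network(cfg), X, y, cfg, class_names=class_names)
            result.add(classifier="cnn", seed=seed, accuracy=report.final_val_accuracy)
    return result


# ---------------------------------------------------------------------------
# Continuous-stream smoothing


def _majority_vote(labels: list, window: int) -> list:
    half = window // 2
    n = len(labels)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        votes = Counter(labels[lo:hi])
        top = votes.most_common()
        best = top[0][1]
        # Deterministic tie-break: keep the current label if tied, else the
        # earliest-appearing tied label.
        tied = [l for l, c in top if c == best]
        if labels[i] in tied:
            out.append(labels[i])
        else:
            out.append(tied[0])
    return out


def _runs(labels: list) -> list[tuple[int, int, object]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def smooth_stream(
    frame_labels: Sequence,
    window_frames: int = 5,
    min_run: int = 3,
) -> tuple[list, list[int]]:
    """Stabilise a continuous frame-label stream.

    Sliding-window majority vote (window must be odd) followed by merging of
    runs shorter than ``min_run`` into their longer neighbour — isolated
    outlier frames around expression changes are suppressed while stable
    stretches pass through unchanged.  Returns the smoothed sequence (same
    length as the input) and the indices where the stabilised label changes.
    """
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 1")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    labels = list(frame_labels)
    if not labels:
        return [], []
    smoothed = _majority_vote(labels, window_frames)
    # Merge short runs until every run reaches min_run (or one run remains).
    changed = True
    while changed:
        changed = False
        runs = _runs(smoothed)
        if len(runs) == 1:
            break
        for idx, (start, end, lab) in enumerate(runs):
            if end - start < min_run:
                left = runs[idx - 1] if idx > 0 else None
                right = runs[idx + 1] if idx + 1 < len(runs) else None
                if left is None:
                    target = right
                elif right is None:
                    target = left
                else:
                    # Merge into the longer neighbour; ties go to the left
                    # (earlier) run so causality is preserved.
                    target = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
                smoothed[start:end] = [target[2]] * (end - start)
                changed = True
                break
    transitions = [start for start, _end, _lab in _runs(smoothed)[1:]]
    return smoothed, transitions
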