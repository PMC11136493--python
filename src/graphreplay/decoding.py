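"""One-vs-all L1-penalized logistic stimulus decoders.

Ten binary decoders (one per stimulus) are trained on sensor vectors at a
single time point of the localizer epochs.  Probabilities are read out
per-decoder and never normalized across states, so all states can be
simultaneously improbable — essential when the decoders are later applied to
retrieval epochs to detect off-screen reactivation.  The final decoders add a
null class sampled from pre-stimulus data, which suppresses the baseline
probability of every state in the absence of a matching pattern.

The regularization is expressed as scikit-learn's ``C`` (inverse penalty
weight; larger C = weaker penalty, default C = 6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .synthetic_data import TrialArray

__all__ = [
    "DecoderSet",
    "StateProbabilities",
    "ConvergenceError",
    "stratify_trials",
    "normalize_and_clip",
    "sample_null_examples",
    "crossval_accuracy_timecourse",
    "temporal_generalization_matrix",
    "train_final_decoders",
    "apply_decoders",
    "apply_exclusion_criteria",
]

DEFAULT_C = 6.0
PEAK_ACCURACY_CUTOFF = 0.30
RETRIEVAL_ACCURACY_CUTOFF = 0.50


class ConvergenceError(RuntimeError):
    def __init__(self, n_iter: int, state: int):
        super().__init__(f"decoder for state {state} did not converge "
                         f"({n_iter} iterations)")
        self.n_iter = n_iter


@dataclass
class DecoderSet:
    """Per-state linear decoders trained at one time point."""

    weights: np.ndarray      # (n_states, n_sensors)
    intercepts: np.ndarray   # (n_states,)
    t_train: float
    C: float
    null_ratio: float

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-state logistic probabilities for sensor vectors X (..., n_sensors)."""
        if X.shape[-1] != self.weights.shape[1]:
            raise ValueError("sensor dimension mismatch")
        logits = X @ self.weights.T + self.intercepts
        return 1.0 / (1.0 + np.exp(-logits))

    def to_hdf5(self, h5group) -> None:
        h5group.create_dataset("weights", data=self.weights)
        h5group.create_dataset("intercepts", data=self.intercepts)
        h5group.attrs.update(t_train=self.t_train, C=self.C,
                             null_ratio=self.null_ratio)

    @classmethod
    def from_hdf5(cls, h5group) -> "DecoderSet":
        return cls(h5group["weights"][()], h5group["intercepts"][()],
                   float(h5group.attrs["t_train"]), float(h5group.attrs["C"]),
                   float(h5group.attrs["null_ratio"]))


@dataclass
class StateProbabilities:
    """Decoded one-vs-all probability time courses (trial x time x state)."""

    probs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 3 or self.probs.shape[1] != len(self.times):
            raise ValueError("probs must be trial x time x state")


def _fit_binary(X: np.ndarray, y: np.ndarray, C: float, seed: int,
                state: int, check_convergence: bool = True,
                tol: float = 1e-6):
    clf = LogisticRegression(l1_ratio=1, C=C, solver="liblinear",
                             max_iter=1000, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    n_iter = int(np.max(clf.n_iter_))
    if check_convergence and n_iter >= 1000:
        raise ConvergenceError(n_iter, state)
    return clf.coef_[0], float(clf.intercept_[0])


def stratify_trials(trials: TrialArray, rng: np.random.Generator) -> TrialArray:
    """Equalize class counts by randomly dropping trials of over-represented
    stimuli down to the minimum class count."""
    labels = trials.meta["stimulus"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() == 0:
        empty = classes[counts == 0]
        raise ValueError(f"empty stimulus class: {empty}")
    n_keep = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        keep.append(rng.choice(idx, size=n_keep, replace=False))
    keep = np.sort(np.concatenate(keep))
    return trials.select(keep)


def normalize_and_clip(trials: TrialArray, scale_factors=None,
                       clip_bound: float = 1.0,
                       clip_scale: float = 0.01) -> TrialArray:
    """Scale channels, then shrink outliers: values with \\|v\\| > clip_bound are
    replaced by v * clip_scale (sign-preserving)."""
    data = trials.data.copy()
    if scale_factors is not None:
        data *= np.asarray(scale_factors).reshape(1, -1, 1)
    mask = np.abs(data) > clip_bound
    data[mask] *= clip_scale
    return TrialArray(data, trials.times, trials.meta.copy())


def sample_null_examples(localizer: TrialArray, ratio: float = 2.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Sensor vectors from the pre-stimulus (-0.1..0 s) segment.

    Returns ``round(ratio * n_trials)`` vectors, each taken from one randomly
    selected trial at one random pre-onset sample.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    pre_idx = np.flatnonzero(localizer.times < 0)
    if len(pre_idx) == 0:
        raise ValueError("epochs contain no pre-onset samples")
    n_null = int(round(ratio * localizer.n_trials))
    if n_null == 0:
        return np.empty((0, localizer.n_sensors))
    tr = rng.integers(localizer.n_trials, size=n_null)
    tp = rng.choice(pre_idx, size=n_null)
    return localizer.data[tr, :, tp]


def _class_folds(labels: np.ndarray, n_folds: int | None,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Cross-validation folds leaving an equal number of trials per class out.

    With ``n_folds=None``, each fold leaves exactly one trial per class out
    (the number of folds equals the per-class trial count).
    """
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per class for cross-validation")
    if len(set(counts)) != 1:
        raise ValueError("stratify trials before cross-validation")
    k = counts.min() if n_folds is None else n_folds
    per_class = [rng.permutation(np.flatnonzero(labels == c)) for c in classes]
    folds = []
    for f in range(k):
        fold = np.concatenate([np.array_split(idx, k)[f] for idx in per_class])
        folds.append(np.sort(fold))
    return folds


# cross-validation fits use a looser optimizer tolerance than the final
# decoders; accuracy estimates are insensitive to it and it halves the cost
CV_TOL = 1e-4


def _ovr_fit_predict(Xtr, ytr, Xte, classes, C, seed):
    """Train one binary decoder per class; return (n_test, n_classes) probs."""
    logits = np.empty((Xte.shape[0], len(classes)))
    for ci, c in enumerate(classes):
        w, b = _fit_binary(Xtr, (ytr == c).astype(int), C, seed,
                           state=int(c), check_convergence=False, tol=CV_TOL)
        logits[:, ci] = Xte @ w + b
    return 1.0 / (1.0 + np.exp(-logits))


def crossval_accuracy_timecourse(localizer: TrialArray, C: float = DEFAULT_C,
                                 n_folds: int | None = None,
                                 rng: np.random.Generator | None = None):
    """Cross-validated decoding accuracy at each 10 ms time step.

    Decoders are trained and tested at the same step, so the accuracy curve
    reflects the separability of the stimulus classes at each latency
    independently.  Predicted class = argmax of the one-vs-all probabilities
    (ties resolved toward the lowest state index).

    Returns ``(accuracy, peak_time, peak_accuracy)``; accuracy has one entry
    per time sample.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = localizer.meta["stimulus"].to_numpy()
    classes = np.unique(labels)
    folds = _class_folds(labels, n_folds, rng)
    seed = int(rng.integers(2 ** 31))
    n_t = len(localizer.times)
    correct = np.zeros(n_t)
    total = 0
    for fold in folds:
        test_mask = np.zeros(len(labels), bool)
        test_mask[fold] = True
        ytr, yte = labels[~test_mask], labels[test_mask]
        total += len(yte)
        for ti in range(n_t):
            Xtr = localizer.data[~test_mask, :, ti]
            Xte = localizer.data[test_mask, :, ti]
            proba = _ovr_fit_predict(Xtr, ytr, Xte, classes, C, seed)
            pred = classes[np.argmax(proba, axis=1)]
            correct[ti] += (pred == yte).sum()
    accuracy = correct / total
    peak = int(np.argmax(accuracy))
    return accuracy, float(localizer.times[peak]), float(accuracy[peak])


def temporal_generalization_matrix(train_trials: TrialArray,
                                   test_trials: TrialArray | None = None,
                                   C: float = DEFAULT_C,
                                   n_folds: int | None = None,
                                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Train-time x test-time accuracy matrix.

    Within-session (``test_trials=None``): cross-validated; the diagonal then
    equals the cross-validated accuracy time course.  Cross-session: decoders
    are trained on all ``train_trials`` at each step and tested on the labeled
    ``test_trials`` epochs at each step.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = train_trials.meta["stimulus"].to_numpy()
    classes = np.unique(labels)
    n_train_t = len(train_trials.times)
    seed = int(rng.integers(2 ** 31))

    if test_trials is None:
        folds = _class_folds(labels, n_folds, rng)
        n_test_t = n_train_t
        correct = np.zeros((n_train_t, n_test_t))
        total = 0
        for fold in folds:
            test_mask = np.zeros(len(labels), bool)
            test_mask[fold] = True
            ytr, yte = labels[~test_mask], labels[test_mask]
            total += len(yte)
            for ti in range(n_train_t):
                Xtr = train_trials.data[~test_mask, :, ti]
                ws, bs = [], []
                for c in classes:
                    w, b = _fit_binary(Xtr, (ytr == c).astype(int), C, seed,
                                       int(c), check_convergence=False,
                                       tol=CV_TOL)
                    ws.append(w)
                    bs.append(b)
                W, B = np.array(ws), np.array(bs)
                for tj in range(n_test_t):
                    logits = train_trials.data[test_mask, :, tj] @ W.T + B
                    pred = classes[np.argmax(logits, axis=1)]
                    correct[ti, tj] += (pred == yte).sum()
        return correct / total

    yte = test_trials.meta["stimulus"].to_numpy()
    n_test_t = len(test_trials.times)
    acc = np.zeros((n_train_t, n_test_t))
    for ti in range(n_train_t):
        Xtr = train_trials.data[:, :, ti]
        ws, bs = [], []
        for c in classes:
            w, b = _fit_binary(Xtr, (labels == c).astype(int), C, seed,
                               int(c), check_convergence=False, tol=CV_TOL)
            ws.append(w)
            bs.append(b)
        W, B = np.array(ws), np.array(bs)
        for tj in range(n_test_t):
            logits = test_trials.data[:, :, tj] @ W.T + B
            pred = classes[np.argmax(logits, axis=1)]
            acc[ti, tj] = (pred == yte).mean()
    return acc


def train_final_decoders(localizer: TrialArray, t_train: float = 0.21,
                         C: float = DEFAULT_C, null_ratio: float = 2.0,
                         rng: np.random.Generator | None = None) -> DecoderSet:
    """Train the final per-state decoders at one latency.

    Positives for state s are s's trials at ``t_train``; negatives are every
    other state's trials at ``t_train`` plus the shared null examples sampled
    from pre-onset data (``null_ratio`` x total trial count of them).
    """
    rng = np.random.default_rng() if rng is None else rng
    idx = localizer.time_index(t_train)
    labels = localizer.meta["stimulus"].to_numpy()
    classes = np.unique(labels)
    X = localizer.data[:, :, idx]
    nulls = sample_null_examples(localizer, null_ratio, rng)
    X_all = np.vstack([X, nulls])
    seed = int(rng.integers(2 ** 31))
    ws, bs = [], []
    for c in classes:
        y = np.concatenate([(labels == c).astype(int),
                            np.zeros(len(nulls), dtype=int)])
        w, b = _fit_binary(X_all, y, C, seed, int(c))
        ws.append(w)
        bs.append(b)
    return DecoderSet(np.array(ws), np.array(bs), float(t_train), C,
                      float(null_ratio))


def apply_decoders(dec: DecoderSet, trials: TrialArray) -> StateProbabilities:
    """Per-state logistic probability at every trial/time point (no
    normalization across states)."""
    if trials.n_sensors != dec.weights.shape[1]:
        raise ValueError("sensor dimension mismatch between decoders and trials")
    X = np.moveaxis(trials.data, 1, 2)  # trial x time x sensor
    return StateProbabilities(dec.predict_proba(X), trials.times)


def apply_exclusion_criteria(peak_accuracy, retrieval_accuracy,
                             min_peak: float = PEAK_ACCURACY_CUTOFF,
                             min_retrieval: float = RETRIEVAL_ACCURACY_CUTOFF) -> np.ndarray:
    """Boolean inclusion mask: peak cross-validated localizer accuracy >= 30%
    and retrieval performance >= 50%."""
    peak_accuracy = np.asarray(peak_accuracy, float)
    retrieval_accuracy = np.asarray(retrieval_accuracy, float)
    return (peak_accuracy >= min_peak) & (retrieval_accuracy >= min_retrieval)
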