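"""Temporally delayed linear modeling (TDLM) of sequential replay.

First level: for each time lag, each state's decoded probability time course
is regressed on all states' time courses lagged by that amount, giving an
empirical transition matrix Te(lag) per trial.  Second level: Te(lag) is
compared with ground-truth transition matrices (forward Tf from the task
edges; backward Tb = Tf') via the Frobenius inner product, yielding a single
"sequenceness" value Z(lag).  Statistical inference uses identity-based
permutations of the transition matrix: row reorderings preserve the matrix
structure while destroying the assignment of states to transitions.  The null
distribution of the lag-resolved curve is summarized by the maximum (and its
95th percentile) across lags per permutation; a lag-unspecific mean-across-
lags statistic gets a two-sided permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import StateProbabilities
from .task_graph import GraphTask
from . import stats as _stats

__all__ = [
    "TransitionMatrices",
    "SequencenessResult",
    "build_transition_matrices",
    "first_level_glm",
    "second_level_sequenceness",
    "sequenceness_for_trials",
    "empirical_transitions",
    "draw_row_permutations",
    "identity_permutations",
    "null_sequenceness",
    "permutation_thresholds",
    "mean_lag_test",
    "correlate_with_performance",
    "sequenceness_analysis",
]

DT_MS = 10.0


@dataclass
class TransitionMatrices:
    forward: np.ndarray   # Tf[j, i] = 1 iff j -> i is a task edge
    backward: np.ndarray  # Tb = Tf.T


def build_transition_matrices(g: GraphTask) -> TransitionMatrices:
    n = len(g.node_ids)
    tf = np.zeros((n, n))
    for a, b in g.edges:
        tf[a, b] = 1.0
    return TransitionMatrices(tf, tf.T.copy())


def _lags_ms(max_lag_ms: float) -> np.ndarray:
    return np.arange(DT_MS, max_lag_ms + DT_MS / 2, DT_MS)


def first_level_glm(probs: np.ndarray, max_lag_ms: float = 250.0):
    """Lagged multiple regression for one trial.

    ``probs`` is a (n_times, n_states) array.  For each lag, each target
    state's series Y_i(t) is regressed on all states' lagged series
    Y_j(t - lag) plus an intercept, over valid samples only (the first
    ``lag`` samples are dropped; no padding).  Returns ``(te, lags_ms)``
    where ``te[k][j, i]`` is the coefficient of lagged predictor j for
    target i at the k-th lag.
    """
    probs = np.asarray(probs, float)
    n_t, n_states = probs.shape
    lags = _lags_ms(max_lag_ms)
    n_lags = len(lags)
    if n_t < n_lags + 10:
        raise ValueError("trial too short for the requested maximum lag")
    te = np.zeros((n_lags, n_states, n_states))
    for k in range(1, n_lags + 1):
        X = np.column_stack([probs[:-k], np.ones(n_t - k)])
        Y = probs[k:]
        if np.allclose(X[:, :-1].std(axis=0), 0):
            warnings.warn(f"constant predictors at lag {k * DT_MS:.0f} ms; "
                          "coefficients set to zero")
            continue
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(f"rank-deficient design at lag {k * DT_MS:.0f} ms; "
                          "using least-norm solution")
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        te[k - 1] = beta[:-1]
    return te, lags


def second_level_sequenceness(te: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Frobenius inner product <Te(lag), T> per lag.

    ``te`` may be a single (n, n) matrix or a stack (..., n, n); T has a zero
    diagonal so self-transitions never contribute.
    """
    te = np.asarray(te, float)
    return np.tensordot(te, T, axes=([-2, -1], [0, 1]))


def empirical_transitions(probs: StateProbabilities,
                          max_lag_ms: float = 250.0):
    """Trial-averaged empirical transition matrices (n_lags, n, n)."""
    tes = []
    for tr in range(probs.probs.shape[0]):
        te, lags = first_level_glm(probs.probs[tr], max_lag_ms)
        tes.append(te)
    return np.mean(tes, axis=0), lags


def sequenceness_for_trials(probs: StateProbabilities, tf: np.ndarray,
                            tb: np.ndarray, max_lag_ms: float = 250.0):
    """Per-participant forward/backward sequenceness per lag.

    The first-level GLM and Frobenius projection are applied per trial and
    the resulting Z values averaged across trials (linearity makes this equal
    to projecting the trial-averaged Te).  Returns ``(zf, zb, lags_ms)``.
    """
    te_mean, lags = empirical_transitions(probs, max_lag_ms)
    return (second_level_sequenceness(te_mean, tf),
            second_level_sequenceness(te_mean, tb), lags)


def draw_row_permutations(n_states: int, n_perm: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform state-identity permutations, identity excluded (n_perm, n_states)."""
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    ident = np.arange(n_states)
    perms = np.empty((n_perm, n_states), dtype=int)
    for i in range(n_perm):
        while True:
            p = rng.permutation(n_states)
            if not np.array_equal(p, ident):
                perms[i] = p
                break
    return perms


def identity_permutations(T: np.ndarray, n: int = 1000,
                          rng: np.random.Generator | None = None,
                          mode: str = "rows",
                          perms: np.ndarray | None = None) -> list[np.ndarray]:
    """Null transition matrices from state-identity permutations.

    ``mode='rows'`` reorders the rows of T; ``mode='relabel'`` permutes rows
    and columns jointly.  Pass a shared ``perms`` array to reuse the same
    permutation list across participants and for Tf/Tb consistently.
    """
    if perms is None:
        rng = np.random.default_rng() if rng is None else rng
        perms = draw_row_permutations(T.shape[0], n, rng)
    if mode == "rows":
        return [T[p, :] for p in perms]
    if mode == "relabel":
        return [T[np.ix_(p, p)] for p in perms]
    raise ValueError(f"unknown permutation mode: {mode!r}")


def null_sequenceness(te_group: np.ndarray, T: np.ndarray,
                      perms: np.ndarray, mode: str = "rows") -> np.ndarray:
    """Group-mean null sequenceness (n_perm, n_lags).

    ``te_group`` is (n_participants, n_lags, n, n); each permuted matrix is
    projected against the group-mean empirical transitions.
    """
    te_mean = te_group.mean(axis=0)  # (n_lags, n, n)
    mats = identity_permutations(T, perms=perms, mode=mode)
    return np.stack([second_level_sequenceness(te_mean, m) for m in mats])


def permutation_thresholds(null: np.ndarray):
    """(max_threshold, pct95_threshold) from per-permutation maxima over lags."""
    null = np.asarray(null, float)
    if null.shape[0] < 2:
        raise ValueError("need at least 2 permutations")
    peaks = null.max(axis=1)
    if null.shape[0] < 20:
        warnings.warn("fewer than 20 permutations: 95th percentile unstable")
    return float(peaks.max()), float(np.percentile(peaks, 95))


def mean_lag_test(z_obs: np.ndarray, null: np.ndarray):
    """Lag-unspecific sequenceness test.

    statistic = group mean over participants of the per-participant mean over
    lags; the null statistic per permutation is the mean over lags of the
    group-mean null curve.  Two-sided permutation p with the add-one rule.
    """
    z_obs = np.atleast_2d(z_obs)
    stat = float(z_obs.mean())
    null_stats = np.asarray(null).mean(axis=1)
    p = _stats.permutation_pvalue(stat, null_stats, sided="two-sided")
    return stat, p


def correlate_with_performance(mean_sequenceness, retrieval_accuracy):
    """Pearson correlation (r, two-sided p) between per-participant mean
    sequenceness and retrieval accuracy."""
    return _stats.pearson(mean_sequenceness, retrieval_accuracy)


@dataclass
class SequencenessResult:
    """Cohort-level sequenceness with permutation inference."""

    lags_ms: np.ndarray
    zf: np.ndarray                # (n_participants, n_lags)
    zb: np.ndarray
    null_f: np.ndarray            # (n_perm, n_lags) group-mean null
    null_b: np.ndarray
    max_threshold_f: float
    pct95_threshold_f: float
    max_threshold_b: float
    pct95_threshold_b: float
    mean_lag_stat_f: float
    mean_lag_p_f: float
    mean_lag_stat_b: float
    mean_lag_p_b: float

    @property
    def group_zf(self) -> np.ndarray:
        return self.zf.mean(axis=0)

    @property
    def group_zb(self) -> np.ndarray:
        return self.zb.mean(axis=0)

    def summary_tsv(self) -> str:
        lines = ["lag_ms\tzf\tzb\tpct95_f\tmax_f\tpct95_b\tmax_b"]
        for i, lag in enumerate(self.lags_ms):
            lines.append("\t".join([
                f"{lag:.0f}", f"{self.group_zf[i]:.6g}", f"{self.group_zb[i]:.6g}",
                f"{self.pct95_threshold_f:.6g}", f"{self.max_threshold_f:.6g}",
                f"{self.pct95_threshold_b:.6g}", f"{self.max_threshold_b:.6g}"]))
        return "\n".join(lines) + "\n"


def sequenceness_analysis(prob_list, tmats: TransitionMatrices,
                          max_lag_ms: float = 250.0, n_perm: int = 1000,
                          rng: np.random.Generator | None = None,
                          mode: str = "rows") -> SequencenessResult:
    """Full cohort analysis: per-participant Zf/Zb, shared-permutation null,
    lag-wise thresholds and the mean-lag permutation test."""
    rng = np.random.default_rng() if rng is None else rng
    te_group, zf, zb = [], [], []
    lags = None
    for probs in prob_list:
        te, lags = empirical_transitions(probs, max_lag_ms)
        te_group.append(te)
        zf.append(second_level_sequenceness(te, tmats.forward))
        zb.append(second_level_sequenceness(te, tmats.backward))
    te_group = np.stack(te_group)
    zf, zb = np.stack(zf), np.stack(zb)
    perms = draw_row_permutations(tmats.forward.shape[0], n_perm, rng)
    null_f = null_sequenceness(te_group, tmats.forward, perms, mode)
    null_b = null_sequenceness(te_group, tmats.backward, perms, mode)
    max_f, p95_f = permutation_thresholds(null_f)
    max_b, p95_b = permutation_thresholds(null_b)
    stat_f, p_f = mean_lag_test(zf, null_f)
    stat_b, p_b = mean_lag_test(zb, null_b)
    return SequencenessResult(lags, zf, zb, null_f, null_b, max_f, p95_f,
                              max_b, p95_b, stat_f, p_f, stat_b, p_b)
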