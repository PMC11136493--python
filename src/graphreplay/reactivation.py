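"""Clustered (non-sequential) reactivation analyses.

During cued recall the two items that follow the on-screen cue on the graph
("near": the triplet-valid successor and its follower) tend to be reactivated
together.  The differential reactivation statistic contrasts the mean decoded
probability of those near items with the mean over all remaining off-screen
items ("distant"); a label-shuffle permutation test localizes when this
difference exceeds chance.  A complementary distance-resolved profile sorts
every off-screen item by its directed graph distance to the cue and tests,
with a repeated-measures ANOVA, whether reactivation strength at the peak
latency declines with distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .decoding import StateProbabilities
from .task_graph import GraphTask
from . import stats as _stats

__all__ = [
    "ReactivationProfile",
    "smooth_probabilities",
    "near_distant_sets",
    "differential_timecourse",
    "reactivation_permutation_test",
    "global_peak_time",
    "distance_profile",
    "pre_post_comparison",
]

N_DISTANCE_LEVELS = 5  # distances 1..4 plus a pooled >=5 level


def smooth_probabilities(probs: StateProbabilities,
                         sigma: float = 1.0) -> StateProbabilities:
    """Gaussian smoothing along time (truncation radius 4*sigma, kernel
    normalized to sum 1, edges renormalized over the valid support)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return StateProbabilities(probs.probs.copy(), probs.times)
    radius = int(np.ceil(4 * sigma))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    num = convolve1d(probs.probs, kernel, axis=1, mode="constant")
    den = convolve1d(np.ones(probs.probs.shape[1]), kernel, mode="constant")
    return StateProbabilities(num / den[None, :, None], probs.times)


def near_distant_sets(g: GraphTask, predecessor: int, current: int):
    """Partition off-screen items for one cue.

    near = the context-valid successor of the cued edge and that successor's
    own triplet follower (the two items "ahead" of the cue); distant = every
    other item except the two on-screen (predecessor, current).  At a hub cue
    the context-invalid successor therefore falls into the distant set.
    """
    s1 = g.triplet_successor[(predecessor, current)]
    s2 = g.triplet_successor[(current, s1)]
    near = frozenset({s1, s2})
    distant = frozenset(g.node_ids) - near - {predecessor, current}
    return near, distant


def _trial_differential(probs: np.ndarray, g: GraphTask,
                        meta: pd.DataFrame) -> np.ndarray:
    """Per-trial near-minus-distant time course (n_trials, n_times)."""
    out = np.empty(probs.shape[:2])
    for tr in range(probs.shape[0]):
        pred = int(meta["predecessor"].iloc[tr])
        cur = int(meta["current"].iloc[tr])
        near, distant = near_distant_sets(g, pred, cur)
        out[tr] = (probs[tr][:, sorted(near)].mean(axis=1)
                   - probs[tr][:, sorted(distant)].mean(axis=1))
    return out


def _qualify(meta: pd.DataFrame, correct_only: bool) -> np.ndarray:
    if correct_only:
        return meta["correct"].to_numpy().astype(bool)
    return np.ones(len(meta), dtype=bool)


def differential_timecourse(prob_list, g: GraphTask, meta_list,
                            correct_only: bool = True):
    """Per-participant and group-mean near-minus-distant time course.

    Expects smoothed probabilities.  Participants without a single qualifying
    trial are excluded with a warning.  Returns ``(per_participant, group)``
    where per_participant is (n_participants, n_times).
    """
    per = []
    for p, (probs, meta) in enumerate(zip(prob_list, meta_list)):
        keep = _qualify(meta, correct_only)
        if not keep.any():
            warnings.warn(f"participant {p} has no qualifying trials; excluded")
            continue
        diffs = _trial_differential(probs.probs[keep], g, meta[keep])
        per.append(diffs.mean(axis=0))
    if not per:
        raise ValueError("no participants with qualifying trials")
    per = np.stack(per)
    return per, per.mean(axis=0)


def reactivation_permutation_test(prob_list, g: GraphTask, meta_list,
                                  n_shuffles: int = 10000, alpha: float = 0.05,
                                  rng: np.random.Generator | None = None,
                                  correct_only: bool = True,
                                  chunk: int = 500):
    """Label-shuffle permutation test of the differential time course.

    The null reassigns the state identities of the decoded probability
    columns within each trial before the near/distant averaging, destroying
    the mapping between decoders and graph positions while keeping the
    temporal structure.  Per-time-point p = fraction of shuffles whose group
    differential is >= the observed one (add-one rule).

    Returns ``(observed_group_curve, pvalues, significant_mask)``.
    """
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles: p-values unstable")
    rng = np.random.default_rng() if rng is None else rng
    n_states = prob_list[0].probs.shape[2]
    n_times = prob_list[0].probs.shape[1]

    per_obs = []
    trials_per_participant = []
    for probs, meta in zip(prob_list, meta_list):
        keep = _qualify(meta, correct_only)
        if not keep.any():
            continue
        diffs = _trial_differential(probs.probs[keep], g, meta[keep])
        per_obs.append(diffs.mean(axis=0))
        trials_per_participant.append((probs.probs[keep], meta[keep]))
    observed = np.stack(per_obs).mean(axis=0)

    # Under the shuffle the role of each column is random, so the null
    # differential is: mean over |near| random columns minus mean over the
    # remaining off-screen columns, with 2 random columns cast as on-screen.
    null = np.zeros((n_shuffles, n_times))
    for probs, meta in trials_per_participant:
        n_trials = probs.shape[0]
        sizes = []
        for tr in range(n_trials):
            near, distant = near_distant_sets(
                g, int(meta["predecessor"].iloc[tr]), int(meta["current"].iloc[tr]))
            sizes.append((len(near), len(distant)))
        part_null = np.zeros((n_shuffles, n_times))
        for s0 in range(0, n_shuffles, chunk):
            s1 = min(s0 + chunk, n_shuffles)
            w = np.zeros((s1 - s0, n_trials, n_states))
            order = np.argsort(rng.random((s1 - s0, n_trials, n_states)), axis=2)
            for tr in range(n_trials):
                n_near, n_dist = sizes[tr]
                near_cols = order[:, tr, 2:2 + n_near]
                dist_cols = order[:, tr, 2 + n_near:2 + n_near + n_dist]
                rows = np.arange(s1 - s0)[:, None]
                w[rows, tr, near_cols] = 1.0 / n_near
                w[rows, tr, dist_cols] = -1.0 / n_dist
            part_null[s0:s1] = np.einsum("cts,tys->cy", w, probs) / n_trials
        null += part_null
    null /= len(trials_per_participant)

    pvals = (1 + (null >= observed[None, :]).sum(axis=0)) / (n_shuffles + 1)
    return observed, pvals, pvals < alpha


def global_peak_time(prob_list, meta_list) -> float:
    """Latency of the peak mean decoded probability across all trials and all
    states except each trial's predecessor item (ties -> earliest time).

    Expects smoothed probabilities.
    """
    total = None
    count = 0
    times = prob_list[0].times
    for probs, meta in zip(prob_list, meta_list):
        n_states = probs.probs.shape[2]
        for tr in range(probs.probs.shape[0]):
            pred = int(meta["predecessor"].iloc[tr])
            cols = [s for s in range(n_states) if s != pred]
            curve = probs.probs[tr][:, cols].mean(axis=1)
            total = curve if total is None else total + curve
            count += 1
    return float(times[int(np.argmax(total / count))])


@dataclass
class ReactivationProfile:
    """Distance-resolved reactivation at the peak latency."""

    peak_time: float
    levels: np.ndarray            # distance levels 1..5 (5 pools >=5)
    table: np.ndarray             # (n_participants, n_levels) mean probability
    anova: _stats.AnovaTable
    included: list[int]           # participant indices entering the ANOVA


def distance_profile(prob_list, g: GraphTask, meta_list, peak_time: float,
                     correct_only: bool | None = None) -> ReactivationProfile:
    """Mean decoded probability per graph-distance level at the peak latency.

    For every trial each off-screen, non-predecessor item is assigned to a
    distance level (1, 2, 3, 4, >=5 pooled) by its directed distance from the
    current on-screen item; probabilities at ``peak_time`` are averaged per
    level per participant and tested with a one-way repeated-measures ANOVA.
    ``correct_only``: None = all trials, True/False = that response type only.
    """
    levels = np.arange(1, N_DISTANCE_LEVELS + 1)
    rows, included = [], []
    for p, (probs, meta) in enumerate(zip(prob_list, meta_list)):
        ti = probs.time_index(peak_time) if hasattr(probs, "time_index") else \
            int(np.argmin(np.abs(probs.times - peak_time)))
        if abs(probs.times[ti] - peak_time) > 1e-6:
            raise ValueError("peak_time not on the sample grid")
        if correct_only is None:
            keep = np.ones(len(meta), bool)
        else:
            keep = meta["correct"].to_numpy().astype(bool) == bool(correct_only)
        sums = np.zeros(N_DISTANCE_LEVELS)
        counts = np.zeros(N_DISTANCE_LEVELS)
        for tr in np.flatnonzero(keep):
            pred = int(meta["predecessor"].iloc[tr])
            cur = int(meta["current"].iloc[tr])
            for s in g.node_ids:
                if s in (pred, cur):
                    continue
                lev = min(int(g.distance[cur, s]), N_DISTANCE_LEVELS)
                sums[lev - 1] += probs.probs[tr, ti, s]
                counts[lev - 1] += 1
        if (counts == 0).any():
            warnings.warn(f"participant {p} missing a distance level; "
                          "excluded from ANOVA")
            continue
        rows.append(sums / counts)
        included.append(p)
    table = np.stack(rows)
    anova = _stats.rm_anova_oneway(table)
    return ReactivationProfile(float(peak_time), levels, table, anova, included)


def pre_post_comparison(learning_probs, retrieval_probs, g: GraphTask,
                        learning_meta, retrieval_meta,
                        window: tuple = (0.22, 0.26)):
    """Paired comparison of mean differential reactivation (learning vs
    retrieval) over a time window.  Returns ``(t, p)``; t < 0 means the
    post-consolidation (retrieval) phase shows the larger differential."""
    if len(learning_probs) < 3:
        raise ValueError("need at least 3 participants")
    times = learning_probs[0].times
    win = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    pre, post = [], []
    for lp, lm, rp, rm in zip(learning_probs, learning_meta,
                              retrieval_probs, retrieval_meta):
        d_pre = _trial_differential(lp.probs, g, lm).mean(axis=0)
        d_post = _trial_differential(rp.probs, g, rm).mean(axis=0)
        pre.append(d_pre[win].mean())
        post.append(d_post[win].mean())
    return _stats.paired_t(np.array(pre), np.array(post))
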