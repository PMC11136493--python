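"""Smoothing, near/distant contrast, peak time, distance profile, pre/post."""

import numpy as np
import pandas as pd
import pytest

from graphreplay import reactivation as ra, stats as st
from graphreplay.decoding import StateProbabilities
from graphreplay.task_graph import enumerate_triplets


def _probs(arr):
    arr = np.asarray(arr, float)
    return StateProbabilities(arr, np.arange(arr.shape[1]) * 0.01)


class TestSmoothing:
    def test_sigma_zero_is_identity(self, rng):
        p = _probs(rng.random((2, 30, 10)))
        out = ra.smooth_probabilities(p, 0.0)
        np.testing.assert_array_equal(out.probs, p.probs)

    def test_kernel_weights_match_discrete_gaussian(self):
        # sigma=1 discrete kernel: ~40% center, ~25% at +-1, ~5% at +-2
        x = np.zeros((1, 21, 1))
        x[0, 10, 0] = 1.0
        out = ra.smooth_probabilities(_probs(x), 1.0).probs[0, :, 0]
        assert out[10] == pytest.approx(0.40, abs=0.01)
        assert out[9] == pytest.approx(0.25, abs=0.01)
        assert out[8] == pytest.approx(0.05, abs=0.01)
        assert out[7] == pytest.approx(0.005, abs=0.003)

    def test_constant_series_unchanged_and_mean_preserved(self, rng):
        p = _probs(np.full((1, 40, 3), 0.3))
        out = ra.smooth_probabilities(p, 1.0)
        np.testing.assert_allclose(out.probs, 0.3, atol=1e-12)
        q = _probs(rng.random((1, 60, 2)))
        sm = ra.smooth_probabilities(q, 1.0)
        interior = slice(5, -5)
        assert sm.probs[0, interior, 0].mean() == pytest.approx(
            np.convolve(q.probs[0, :, 0], np.ones(1)).mean(), abs=0.02)


class TestNearDistantSets:
    def test_partition_over_all_triplets(self, graph):
        for pred, cur, suc in enumerate_triplets(graph):
            near, distant = ra.near_distant_sets(graph, pred, cur)
            assert len(near) == 2
            assert suc in near
            assert not near & {pred, cur}
            assert near | distant | {pred, cur} == set(graph.node_ids)
            assert not near & distant

    def test_near_items_are_one_and_two_steps_ahead(self, graph):
        for pred, cur, _ in enumerate_triplets(graph):
            near, _ = ra.near_distant_sets(graph, pred, cur)
            dists = sorted(graph.distance[cur, n] for n in near)
            assert dists == [1, 2]


class TestDifferential:
    def test_antisymmetry_under_set_swap(self, graph, rng):
        probs = rng.random((1, 20, 10))
        meta = pd.DataFrame({"predecessor": [0], "current": [3],
                             "correct": [True]})
        d = ra._trial_differential(probs, graph, meta)[0]
        near, distant = ra.near_distant_sets(graph, 0, 3)
        swapped = (probs[0][:, sorted(distant)].mean(axis=1)
                   - probs[0][:, sorted(near)].mean(axis=1))
        np.testing.assert_allclose(d, -swapped * len(near) / len(near))

    def test_symmetric_probabilities_give_zero(self, graph):
        probs = np.full((3, 20, 10), 0.2)
        meta = pd.DataFrame({"predecessor": [0, 3, 4],
                             "current": [3, 4, 5],
                             "correct": [True] * 3})
        per, group = ra.differential_timecourse(
            [_probs(probs)], graph, [meta])
        np.testing.assert_allclose(group, 0.0, atol=1e-12)

    def test_participant_without_qualifying_trials_excluded(self, graph, rng):
        probs = rng.random((2, 20, 10))
        meta_ok = pd.DataFrame({"predecessor": [0, 3], "current": [3, 4],
                                "correct": [True, True]})
        meta_bad = meta_ok.assign(correct=[False, False])
        with pytest.warns(UserWarning, match="no qualifying"):
            per, _ = ra.differential_timecourse(
                [_probs(probs), _probs(probs)], graph, [meta_ok, meta_bad])
        assert per.shape[0] == 1


class TestPermutationTest:
    def test_null_probabilities_rarely_significant(self, graph):
        rng = np.random.default_rng(0)
        probs = [_probs(rng.uniform(0.1, 0.3, size=(6, 30, 10)))
                 for _ in range(3)]
        metas = []
        triplets = enumerate_triplets(graph)
        for _ in range(3):
            rows = [triplets[i][:2] for i in rng.choice(12, 6, replace=False)]
            metas.append(pd.DataFrame(rows, columns=["predecessor", "current"])
                         .assign(correct=True))
        obs, pvals, sig = ra.reactivation_permutation_test(
            probs, graph, metas, n_shuffles=500, rng=rng)
        assert sig.mean() < 0.2  # pointwise alpha=0.05, no real effect

    def test_injected_near_excess_detected(self, graph):
        rng = np.random.default_rng(1)
        triplets = enumerate_triplets(graph)
        probs, metas = [], []
        for _ in range(3):
            arr = rng.uniform(0.1, 0.2, size=(12, 30, 10))
            meta = pd.DataFrame([t[:2] for t in triplets],
                                columns=["predecessor", "current"]).assign(correct=True)
            for tr, (pred, cur, suc) in enumerate(triplets):
                near, _ = ra.near_distant_sets(graph, pred, cur)
                for s in near:
                    arr[tr, 14:18, s] += 0.5
            probs.append(_probs(arr))
            metas.append(meta)
        obs, pvals, sig = ra.reactivation_permutation_test(
            probs, graph, metas, n_shuffles=500, rng=rng)
        assert sig[14:18].all()


class TestPeakTime:
    def test_noiseless_argmax_and_tiebreak(self, graph):
        arr = np.full((1, 50, 10), 0.1)
        arr[0, 24, :] = 0.6  # single event at 240 ms
        meta = pd.DataFrame({"predecessor": [0], "current": [3]})
        assert ra.global_peak_time([_probs(arr)], [meta]) == pytest.approx(0.24)
        arr2 = np.full((1, 50, 10), 0.1)
        arr2[0, 10, :] = arr2[0, 30, :] = 0.6
        assert ra.global_peak_time([_probs(arr2)], [meta]) == pytest.approx(0.10)

    def test_predecessor_excluded_from_peak(self, graph):
        arr = np.full((1, 50, 10), 0.1)
        arr[0, 40, 0] = 0.9   # predecessor-only burst must not set the peak
        arr[0, 20, 5] = 0.5
        meta = pd.DataFrame({"predecessor": [0], "current": [3]})
        assert ra.global_peak_time([_probs(arr)], [meta]) == pytest.approx(0.20)


class TestDistanceProfile:
    def test_level_counts_partition_offscreen_items(self, graph):
        for pred, cur, _ in enumerate_triplets(graph):
            counts = np.zeros(5)
            for s in graph.node_ids:
                if s in (pred, cur):
                    continue
                counts[min(graph.distance[cur, s], 5) - 1] += 1
            assert counts.sum() == 8

    def test_graded_injection_recovers_ordering_and_df(self, graph):
        rng = np.random.default_rng(2)
        triplets = enumerate_triplets(graph)
        probs, metas = [], []
        grad = {1: 0.5, 2: 0.4, 3: 0.3, 4: 0.2, 5: 0.1}
        for _ in range(6):
            arr = rng.uniform(0.05, 0.15, size=(12, 30, 10))
            for tr, (pred, cur, suc) in enumerate(triplets):
                for s in graph.node_ids:
                    if s in (pred, cur):
                        continue
                    arr[tr, 20, s] += grad[min(int(graph.distance[cur, s]), 5)]
            probs.append(_probs(arr))
            metas.append(pd.DataFrame([t[:2] for t in triplets],
                                      columns=["predecessor", "current"])
                         .assign(correct=True))
        prof = ra.distance_profile(probs, graph, metas, peak_time=0.20)
        assert prof.anova.df_effect == 4
        assert prof.anova.df_error == 4 * (6 - 1)
        assert np.all(np.diff(prof.anova.level_means) < 0)
        assert prof.anova.p < 0.05


class TestPrePost:
    def test_identical_phases_give_zero_t(self, graph):
        rng = np.random.default_rng(3)
        arr = rng.random((4, 40, 10))
        meta = pd.DataFrame({"predecessor": [0, 3, 4, 5],
                             "current": [3, 4, 5, 6],
                             "correct": [True] * 4})
        probs = [_probs(arr)] * 3
        metas = [meta] * 3
        t, p = ra.pre_post_comparison(probs, probs, graph, metas, metas)
        assert t == 0.0 and p == 1.0

    def test_matches_paired_t_oracle(self, graph):
        rng = np.random.default_rng(4)
        meta = pd.DataFrame({"predecessor": [0], "current": [3],
                             "correct": [True]})
        pre_list = [_probs(rng.random((1, 40, 10))) for _ in range(5)]
        post_list = [_probs(rng.random((1, 40, 10))) for _ in range(5)]
        t, p = ra.pre_post_comparison(pre_list, post_list, graph,
                                      [meta] * 5, [meta] * 5)
        win = (pre_list[0].times >= 0.22 - 1e-9) & (pre_list[0].times <= 0.26 + 1e-9)
        pre_vals, post_vals = [], []
        for lp, rp in zip(pre_list, post_list):
            pre_vals.append(ra._trial_differential(lp.probs, graph, meta)[0][win].mean())
            post_vals.append(ra._trial_differential(rp.probs, graph, meta)[0][win].mean())
        t2, p2 = st.paired_t(np.array(pre_vals), np.array(post_vals))
        assert t == pytest.approx(t2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)
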