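"""Decoder training, calibration and exclusion rules."""

import numpy as np
import pytest

from graphreplay import decoding as dec, synthetic_data as sd


def _noiseless_localizer(n_sensors=24, reps=4, amplitude=3.0):
    rng = np.random.default_rng(1)
    cfg = sd.SimulationConfig(n_sensors=n_sensors, noise_sd=0.0,
                              pattern_amplitude=amplitude)
    pats = sd.make_stimulus_patterns(n_sensors, 10, rng)
    order = sd.generate_localizer_sequence(10, reps, rng)
    return sd.generate_localizer_trials(pats, order, cfg, rng), pats


class TestStratify:
    def test_balanced_input_unchanged_counts(self, small_localizer, rng):
        loc, _ = small_localizer
        out = dec.stratify_trials(loc, rng)
        counts = out.meta["stimulus"].value_counts()
        assert counts.nunique() == 1
        assert out.n_trials == loc.n_trials  # already balanced

    def test_min_rule(self, small_localizer, rng):
        loc, _ = small_localizer
        drop = loc.meta.index[loc.meta["stimulus"] == 0][:2]
        unbalanced = loc.select(np.setdiff1d(np.arange(loc.n_trials), drop))
        out = dec.stratify_trials(unbalanced, rng)
        counts = out.meta["stimulus"].value_counts()
        assert set(counts) == {counts.min()}
        assert counts.min() == (loc.meta["stimulus"] == 0).sum() - 2


class TestNormalizeAndClip:
    def test_values(self, rng):
        trials = sd.TrialArray(
            np.array([0.5, 3.0, -1.5, 1.0]).reshape(1, 1, 4),
            np.arange(4) * 0.01, __import__("pandas").DataFrame({"stimulus": [0]}))
        out = dec.normalize_and_clip(trials)
        np.testing.assert_allclose(out.data.ravel(), [0.5, 0.03, -0.015, 1.0])

    def test_channel_scaling_applied_before_clip(self):
        import pandas as pd

        trials = sd.TrialArray(np.full((1, 2, 2), 0.6),
                               np.arange(2) * 0.01,
                               pd.DataFrame({"stimulus": [0]}))
        out = dec.normalize_and_clip(trials, scale_factors=[1.0, 2.0])
        np.testing.assert_allclose(out.data[0, 0], 0.6)
        np.testing.assert_allclose(out.data[0, 1], 0.012)  # 1.2 clipped


class TestNullExamples:
    def test_count_and_provenance(self, small_localizer, rng):
        loc, _ = small_localizer
        nulls = dec.sample_null_examples(loc, ratio=2, rng=rng)
        assert nulls.shape == (2 * loc.n_trials, loc.n_sensors)
        assert dec.sample_null_examples(loc, ratio=0, rng=rng).shape[0] == 0
        with pytest.raises(ValueError):
            dec.sample_null_examples(loc, ratio=-1, rng=rng)

    def test_null_vectors_come_from_pre_onset(self, rng):
        loc, _ = _noiseless_localizer()
        # pre-onset samples are exactly zero in a noiseless localizer
        nulls = dec.sample_null_examples(loc, ratio=1, rng=rng)
        np.testing.assert_array_equal(nulls, 0.0)


class TestFinalDecoders:
    def test_noiseless_training_accuracy_is_one(self, rng):
        loc, pats = _noiseless_localizer()
        d = dec.train_final_decoders(loc, rng=rng)
        probs = dec.apply_decoders(d, loc)
        ti = loc.time_index(0.21)
        pred = np.argmax(probs.probs[:, ti, :], axis=1)
        assert (pred == loc.meta["stimulus"].to_numpy()).all()

    def test_strong_penalty_shrinks_all_weights(self, rng):
        loc, _ = _noiseless_localizer()
        d = dec.train_final_decoders(loc, C=1e-3, rng=rng)
        assert np.all(d.weights == 0)

    def test_l1_produces_sparse_weights(self, small_localizer, rng):
        loc, _ = small_localizer
        d = dec.train_final_decoders(loc, rng=rng)
        assert np.mean(d.weights == 0) > 0.05
        assert np.isfinite(d.weights).all()

    def test_null_class_suppresses_baseline(self, rng):
        loc, _ = _noiseless_localizer()
        d = dec.train_final_decoders(loc, null_ratio=2.0, rng=rng)
        # on pure pre-onset (null) input every state is simultaneously improbable
        probs = d.predict_proba(np.zeros((1, loc.n_sensors)))
        assert np.all(probs < 0.5)

    def test_probabilities_at_zero_input_equal_intercept_logistic(self, rng):
        loc, _ = _noiseless_localizer()
        d = dec.train_final_decoders(loc, rng=rng)
        expected = 1 / (1 + np.exp(-d.intercepts))
        np.testing.assert_allclose(
            d.predict_proba(np.zeros(loc.n_sensors)), expected)

    def test_dimension_mismatch_raises(self, rng):
        import pandas as pd

        loc, _ = _noiseless_localizer()
        d = dec.train_final_decoders(loc, rng=rng)
        bad = sd.TrialArray(np.zeros((1, 5, 3)), np.arange(3) * 0.01,
                            pd.DataFrame({"stimulus": [0]}))
        with pytest.raises(ValueError):
            dec.apply_decoders(d, bad)


class TestCrossValidation:
    def test_noiseless_data_perfectly_separable_at_latency(self, rng):
        loc, _ = _noiseless_localizer(reps=3)
        acc, peak_t, peak_a = dec.crossval_accuracy_timecourse(loc, rng=rng)
        assert peak_a == 1.0
        assert acc[loc.time_index(0.21)] == 1.0
        # pre-onset samples carry no signal at all
        assert acc[loc.time_index(-0.05)] <= 0.3

    def test_noisy_peak_latency_matches_generator_ground_truth(self):
        rng = np.random.default_rng(6)
        cfg = sd.SimulationConfig(n_sensors=48, noise_sd=1.0,
                                  pattern_amplitude=3.0)
        pats = sd.make_stimulus_patterns(48, 10, rng)
        order = sd.generate_localizer_sequence(10, 8, rng)
        loc = sd.generate_localizer_trials(pats, order, cfg, rng)
        _, peak_t, peak_a = dec.crossval_accuracy_timecourse(loc, n_folds=4,
                                                             rng=rng)
        assert abs(peak_t - cfg.evoked_latency) <= 0.02
        assert peak_a > 0.3

    def test_accuracy_monotone_in_amplitude(self):
        accs = []
        for amp in (0.5, 1.5, 4.0):
            vals = []
            for seed in range(3):
                rng = np.random.default_rng(seed)
                cfg = sd.SimulationConfig(n_sensors=32, noise_sd=1.0,
                                          pattern_amplitude=amp)
                pats = sd.make_stimulus_patterns(32, 10, rng)
                order = sd.generate_localizer_sequence(10, 6, rng)
                loc = sd.generate_localizer_trials(pats, order, cfg, rng)
                _, _, pa = dec.crossval_accuracy_timecourse(loc, n_folds=3,
                                                            rng=rng)
                vals.append(pa)
            accs.append(np.mean(vals))
        assert accs[0] < accs[1] < accs[2]

    def test_temporal_generalization_diagonal_and_decay(self, rng):
        loc, _ = _noiseless_localizer(reps=3)
        mat = dec.temporal_generalization_matrix(loc, rng=rng)
        ti = loc.time_index(0.21)
        assert mat[ti, ti] == 1.0
        far = loc.time_index(-0.1)
        assert mat[ti, far] < mat[ti, ti]

    def test_temporal_generalization_cross_session(self, rng):
        # decoders trained on one session transfer to labeled epochs of
        # another session generated from the same spatial patterns
        rng1 = np.random.default_rng(11)
        cfg = sd.SimulationConfig(n_sensors=24, noise_sd=0.0)
        pats = sd.make_stimulus_patterns(24, 10, rng1)
        train = sd.generate_localizer_trials(
            pats, sd.generate_localizer_sequence(10, 3, rng1), cfg, rng1)
        test = sd.generate_localizer_trials(
            pats, sd.generate_localizer_sequence(10, 2, rng1), cfg, rng1)
        mat = dec.temporal_generalization_matrix(train, test, rng=rng)
        ti = train.time_index(0.21)
        assert mat[ti, test.time_index(0.21)] == 1.0

    def test_too_few_trials_raises(self, rng):
        loc, _ = _noiseless_localizer(reps=4)
        one_per_class = loc.select(
            [np.flatnonzero(loc.meta["stimulus"] == c)[0] for c in range(10)])
        with pytest.raises(ValueError):
            dec.crossval_accuracy_timecourse(one_per_class, rng=rng)


def test_exclusion_criteria():
    peak = [0.29, 0.42, 0.35, 0.31]
    ret = [0.9, 0.82, 0.40, 0.50]
    mask = dec.apply_exclusion_criteria(peak, ret)
    np.testing.assert_array_equal(mask, [False, True, False, True])


def test_decoderset_hdf5_roundtrip(tmp_path, rng):
    import h5py

    loc, _ = _noiseless_localizer()
    d = dec.train_final_decoders(loc, rng=rng)
    with h5py.File(tmp_path / "d.h5", "w") as f:
        d.to_hdf5(f.create_group("dec"))
    with h5py.File(tmp_path / "d.h5", "r") as f:
        back = dec.DecoderSet.from_hdf5(f["dec"])
    np.testing.assert_array_equal(back.weights, d.weights)
    assert back.t_train == d.t_train
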