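import numpy as np
import pytest

import stimdecode as sd
from stimdecode.decoding import ConvolvedResponse, PCABasis, _group_by_pattern


def make_responses(rng, n_per_pattern=6, n_samples=30, patterns=("a", "b", "c")):
    return [
        ConvolvedResponse(rng.random(n_samples), name, i)
        for name in patterns
        for i in range(1, n_per_pattern + 1)
    ]


class TestConvolveResponse:
    def test_empty_train_gives_zero_vector(self):
        cfg = sd.DecodingConfig()
        r = sd.convolve_response(np.empty(0), cfg)
        assert np.all(r.values == 0) and r.values.size == cfg.n_samples

    def test_single_spike_exponential_decay(self):
        cfg = sd.DecodingConfig()
        r = sd.convolve_response(np.array([0.0]), cfg)
        expected = np.exp(-cfg.grid_ms / cfg.kernel_tau_ms) / cfg.kernel_tau_ms
        assert np.allclose(r.values, expected)
        assert r.values.argmax() == 0

    def test_unit_area_kernel_integrates_to_spike_count(self):
        # Quadrature of the sampled response ~ number of in-window spikes.
        cfg = sd.DecodingConfig(sample_step_ms=0.05)
        spikes = np.array([100.0, 300.0, 301.0, 702.5])
        r = sd.convolve_response(spikes, cfg)
        assert r.values.sum() * cfg.sample_step_ms == pytest.approx(len(spikes), rel=0.02)

    def test_out_of_window_spikes_dropped_with_warning(self, caplog):
        cfg = sd.DecodingConfig(sample_step_ms=0.05)
        with caplog.at_level("WARNING", logger="stimdecode.decoding"):
            r = sd.convolve_response(np.array([-5.0, 10.0, 1500.0]), cfg)
        assert "dropping 2" in caplog.text
        assert r.values.sum() * cfg.sample_step_ms == pytest.approx(1.0, rel=0.05)


class TestSplitTrainTest:
    def test_half_half_stratified(self):
        rng = np.random.default_rng(0)
        responses = make_responses(rng, n_per_pattern=10)
        train, test = sd.split_train_test(responses, rng)
        for name in ("a", "b", "c"):
            assert len(_group_by_pattern(train)[name]) == 5
            assert len(_group_by_pattern(test)[name]) == 5

    def test_partition_preserves_all_responses(self):
        rng = np.random.default_rng(1)
        responses = make_responses(rng, n_per_pattern=7)  # odd: extra goes to train
        train, test = sd.split_train_test(responses, rng)
        assert len(train) == 12 and len(test) == 9
        ids = lambda rs: sorted((r.pattern_name, r.trial_index) for r in rs)
        assert ids(train + test) == ids(responses)

    def test_different_rngs_differ(self):
        base = np.random.default_rng(2)
        responses = make_responses(base, n_per_pattern=20)
        t1, _ = sd.split_train_test(responses, np.random.default_rng(3))
        t2, _ = sd.split_train_test(responses, np.random.default_rng(4))
        ids = lambda rs: sorted((r.pattern_name, r.trial_index) for r in rs)
        assert ids(t1) != ids(t2)

    def test_undersized_pattern_rejected(self):
        rng = np.random.default_rng(5)
        responses = make_responses(rng, n_per_pattern=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            sd.split_train_test(responses, rng)


class TestBootstrap:
    def test_single_response_group_degenerate(self):
        cfg = sd.DecodingConfig(n_bootstrap_per_pattern=5)
        rng = np.random.default_rng(0)
        r = ConvolvedResponse(np.arange(4.0), "a", 1)
        boot, labels, names = sd.bootstrap_responses([r], cfg, rng)
        # N = 1: every bootstrapped response is the single response itself.
        assert np.array_equal(boot, np.tile(r.values, (5, 1)))
        assert names == ("a",)

    def test_output_count(self):
        cfg = sd.DecodingConfig(n_bootstrap_per_pattern=11)
        rng = np.random.default_rng(1)
        responses = make_responses(rng, n_per_pattern=4, patterns=tuple("abcdefgh"))
        boot, labels, names = sd.bootstrap_responses(responses, cfg, rng)
        assert boot.shape[0] == 8 * 11
        assert len(names) == 8

    def test_expected_value_is_n_times_group_mean(self):
        # Monte-Carlo over >= 1000 resamples.
        cfg = sd.DecodingConfig(n_bootstrap_per_pattern=3000)
        rng = np.random.default_rng(2)
        responses = make_responses(rng, n_per_pattern=5, patterns=("a",), n_samples=8)
        group_mean = np.mean([r.values for r in responses], axis=0)
        boot, _, _ = sd.bootstrap_responses(responses, cfg, rng)
        sem = boot.std(axis=0, ddof=1) / np.sqrt(boot.shape[0])
        assert np.all(np.abs(boot.mean(axis=0) - 5 * group_mean) < 4 * sem + 1e-12)

    def test_matches_index_resampling_moments(self):
        # Independent oracle: explicit index draws summed, same distribution.
        cfg = sd.DecodingConfig(n_bootstrap_per_pattern=4000)
        rng = np.random.default_rng(3)
        vals = np.random.default_rng(4).random((6, 5))
        responses = [ConvolvedResponse(v, "a", i) for i, v in enumerate(vals)]
        boot, _, _ = sd.bootstrap_responses(responses, cfg, rng)
        oracle_rng = np.random.default_rng(5)
        idx = oracle_rng.integers(0, 6, size=(4000, 6))
        oracle = vals[idx].sum(axis=1)
        for moment in (np.mean, np.std):
            assert np.allclose(moment(boot, axis=0), moment(oracle, axis=0), rtol=0.08)


class TestPCA:
    def test_one_dimensional_data_needs_one_component(self):
        rng = np.random.default_rng(0)
        direction = rng.random(20)
        data = np.outer(rng.normal(size=200), direction)
        data += rng.normal(scale=1e-6, size=data.shape)
        basis = sd.fit_pca(data, 0.95)
        assert basis.n_components == 1

    def test_isotropic_gaussian_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(1)
        d = 40
        data = rng.normal(size=(3000, d))
        basis = sd.fit_pca(data, 0.95)
        # Oracle: eigenvalues of the sample covariance, cumulative 95 %.
        evals = np.sort(np.linalg.eigvalsh(np.cov(data.T)))[::-1]
        n_oracle = int(np.searchsorted(np.cumsum(evals) / evals.sum(), 0.95) + 1)
        assert basis.n_components == n_oracle
        assert abs(basis.n_components - 0.95 * d) <= 3

    def test_retained_variance_at_least_threshold(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(100, 12)) * np.arange(1, 13)
        basis = sd.fit_pca(data, 0.95)
        assert basis.explained_variance_ratio.sum() >= 0.95

    def test_zero_variance_flagged_degenerate(self):
        basis = sd.fit_pca(np.ones((10, 4)), 0.95)
        assert basis.degenerate and basis.n_components == 1


class TestProjection:
    def test_basis_vector_projects_to_unit_coordinate(self):
        basis = PCABasis(
            components=np.eye(3)[:2], mean=np.zeros(3),
            explained_variance_ratio=np.array([0.6, 0.4]),
        )
        coords = sd.project(np.array([[0.0, 1.0, 0.0]]), basis)
        assert np.allclose(coords, [[0.0, 1.0]])

    def test_stored_mean_projects_to_origin(self):
        rng = np.random.default_rng(0)
        basis = sd.fit_pca(rng.normal(size=(50, 6)), 0.95)
        assert np.allclose(sd.project(basis.mean, basis), 0.0)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(60, 10)) * np.arange(1, 11)
        basis = sd.fit_pca(data, 0.99)
        x = rng.normal(size=10)
        coords = sd.project(x, basis)[0]
        oracle, *_ = np.linalg.lstsq(basis.components.T, x - basis.mean, rcond=None)
        assert np.allclose(coords, oracle, atol=1e-8)

    def test_length_mismatch_rejected(self):
        basis = PCABasis(np.eye(3), np.zeros(3), np.ones(3) / 3)
        with pytest.raises(ValueError, match="length"):
            sd.project(np.zeros((2, 5)), basis)


class TestKNN:
    def test_unanimous_neighbourhood(self):
        train = np.vstack([np.zeros((9, 2)), np.ones((9, 2)) * 10])
        labels = np.array([0] * 9 + [1] * 9)
        pred = sd.knn_classify(np.zeros((1, 2)), train, labels, k=9)
        assert pred[0] == 0

    def test_tie_broken_by_summed_distance(self):
        # k = 9: 4 of class 0, 4 of class 1, 1 of class 2; class 0 nearer.
        train = np.array(
            [[1.0], [1.1], [1.2], [1.3],      # class 0, summed 4.6
             [2.0], [2.1], [2.2], [2.3],      # class 1, summed 8.6
             [3.0],                            # class 2
             [50.0]]                           # far away, excluded from k=9
        )
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 1])
        pred = sd.knn_classify(np.array([[0.0]]), train, labels, k=9)
        assert pred[0] == 0

    def test_training_order_invariance(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        test = rng.normal(size=(10, 3))
        pred = sd.knn_classify(test, train, labels, k=9)
        perm = rng.permutation(30)
        pred_perm = sd.knn_classify(test, train[perm], labels[perm], k=9)
        assert np.array_equal(pred, pred_perm)

    def test_small_training_set_rejected(self):
        with pytest.raises(ValueError, match="smaller than k"):
            sd.knn_classify(np.zeros((1, 2)), np.zeros((5, 2)), np.zeros(5), k=9)


class TestF1FromConfusion:
    def test_identity_matrix_perfect_score(self):
        _, _, f1 = sd.f1_from_confusion(np.eye(8) * 50)
        assert f1 == 1.0

    def test_uniform_matrix_chance_level(self):
        precision, recall, f1 = sd.f1_from_confusion(np.full((8, 8), 25.0))
        assert np.allclose(precision, 1 / 8)
        assert np.allclose(recall, 1 / 8)
        assert f1 == pytest.approx(0.125)

    def test_hand_computed_matrix(self):
        # diag 6, off-diag 2 (row sum 20): precision = recall = F1 = 0.3.
        cm = np.full((8, 8), 2.0)
        np.fill_diagonal(cm, 6.0)
        precision, recall, f1 = sd.f1_from_confusion(cm)
        assert np.allclose(precision, 0.3) and np.allclose(recall, 0.3)
        assert f1 == pytest.approx(0.3)

    def test_empty_class_zero_by_convention(self):
        cm = np.array([[5.0, 0.0], [3.0, 0.0]])
        precision, recall, f1 = sd.f1_from_confusion(cm)
        assert precision[1] == 0.0 and recall[1] == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            sd.f1_from_confusion(np.zeros((8, 8)))


class TestRunDecoding:
    def test_deterministic_given_seed(self, small_noise_neuron, small_config):
        a = sd.run_decoding(small_noise_neuron, small_config)
        b = sd.run_decoding(small_noise_neuron, small_config)
        assert a.f1_score == b.f1_score
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_rows_sum_to_test_set_size(self, small_noise_neuron, small_config):
        result = sd.run_decoding(small_noise_neuron, small_config)
        assert np.allclose(
            result.confusion.sum(axis=1), small_config.n_bootstrap_per_pattern
        )

    def test_separable_neuron_beats_noise_neuron(
        self, small_separable_neuron, small_noise_neuron, small_config
    ):
        high = sd.run_decoding(small_separable_neuron, small_config)
        low = sd.run_decoding(small_noise_neuron, small_config)
        assert high.f1_score > 0.9 > 0.4 > low.f1_score

    def test_missing_pattern_rejected(self, small_noise_neuron, small_config):
        partial = sd.TrialResponseSet(
            neuron_id="x",
            trials={
                k: v
                for k, v in small_noise_neuron.trials.items()
                if k[0] != "0.5 fa"
            },
        )
        with pytest.raises(ValueError, match="expected 8 patterns"):
            sd.run_decoding(partial, small_config)

    def test_label_permutation_symmetry(self, small_separable_neuron, small_config):
        # Renaming patterns permutes confusion rows/cols, macro F1 unchanged.
        names = small_separable_neuron.pattern_names
        mapping = dict(zip(names, names[1:] + names[:1]))
        renamed = sd.TrialResponseSet(
            neuron_id="renamed",
            trials={
                (mapping[name], idx): s
                for (name, idx), s in small_separable_neuron.trials.items()
            },
            spontaneous_segments=small_separable_neuron.spontaneous_segments,
        )
        a = sd.run_decoding(small_separable_neuron, small_config)
        b = sd.run_decoding(renamed, small_config)
        assert b.f1_score == pytest.approx(a.f1_score, abs=0.05)
        perm = [b.pattern_names.index(mapping[n]) for n in a.pattern_names]
        assert np.allclose(
            b.confusion[np.ix_(perm, perm)], a.confusion, atol=a.confusion.max() * 0.3
        )


class TestShuffledNull:
    def test_identity_permutation_reproduces_run(self, small_noise_neuron, small_config):
        n = len(small_noise_neuron.trials)
        plain = sd.run_decoding(small_noise_neuron, small_config)
        ident = sd.shuffled_null(
            small_noise_neuron, small_config,
            permutation=np.arange(n), reshuffle_each_iteration=False,
        )
        assert ident.f1_score == plain.f1_score

    def test_shuffle_nullifies_separable_neuron(self, small_separable_neuron, small_config):
        cfg = sd.DecodingConfig(
            n_bootstrap_per_pattern=20, n_iterations=10, seed=9
        )
        shuffled = sd.shuffled_null(small_separable_neuron, cfg)
        assert shuffled.f1_score < 0.25


class TestDecoderThreshold:
    def test_mean_plus_two_sd(self):
        # Population with mean 12.42 % and SD 0.85 % -> threshold 14.12 %.
        pop = np.array([0.1242 - 0.0085 / np.sqrt(2), 0.1242 + 0.0085 / np.sqrt(2)])
        assert sd.decoder_threshold(pop) == pytest.approx(0.1412, abs=1e-4)

    def test_constant_population(self):
        assert sd.decoder_threshold(np.full(5, 0.2)) == pytest.approx(0.2)

    def test_outlier_raises_threshold(self):
        base = np.array([0.12, 0.125, 0.13])
        assert sd.decoder_threshold(np.append(base, 0.4)) > sd.decoder_threshold(base)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            sd.decoder_threshold(np.array([0.125]))

    def test_flag_decoder(self):
        r = sd.DecodingResult(
            pattern_names=("a",), confusion=np.ones((1, 1)),
            precision_per_class=np.ones(1), recall_per_class=np.ones(1),
            f1_score=0.30,
        )
        r.flag_decoder(0.1412)
        assert r.is_decoder and r.threshold_used == pytest.approx(0.1412)
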