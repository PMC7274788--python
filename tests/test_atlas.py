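"""Atlas regression: curation rules, channel and count regressors."""

import numpy as np
import pytest

from cloudmorph.atlas import (filter_samples_by_mean_count, predict_channel,
                              select_training_cells, train_channel_regressor,
                              train_count_regressor)
from cloudmorph.core import FeatureMatrix
from cloudmorph.synthgen import generate_paired_channels

# span decades like the full protocol, but sparsely, to keep tests quick
SMALL_GRID = {"est__estimator__C": [0.01, 1.0, 100.0],
              "est__estimator__epsilon": [0.01, 0.1],
              "est__estimator__gamma": ["scale"]}


def feature_matrix(n, p, seed=0, scale=1.0):
    x = np.random.default_rng(seed).normal(size=(n, p)) * scale
    return FeatureMatrix(x, feature_names=[f"f{i}" for i in range(p)])


class TestTrainingCuration:
    def test_counts_follow_percentile_plus_contamination_arithmetic(self):
        rng = np.random.default_rng(0)
        n = 300
        joint = rng.normal(size=(n, 6))
        intensity = rng.permutation(n).astype(float)  # tie-free
        idx = select_training_cells(joint, intensity, contamination=0.05)
        n_pass = int(np.sum(intensity > np.percentile(intensity, 33)))
        expected = n_pass - int(np.floor(0.05 * n_pass))
        assert idx.size == expected

    def test_equal_intensities_keep_everyone(self):
        rng = np.random.default_rng(1)
        joint = rng.normal(size=(60, 4))
        idx = select_training_cells(joint, np.full(60, 7.0),
                                    contamination=0.0)
        assert idx.size == 60

    def test_planted_extreme_outlier_removed(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            joint = rng.normal(size=(200, 5))
            joint[17] *= 100.0  # extreme outlier
            intensity = rng.permutation(200).astype(float)
            intensity[17] = 1000.0  # passes the percentile filter
            idx = select_training_cells(joint, intensity, rng=seed)
            hits += 17 not in idx
        assert hits >= 19

    def test_too_few_survivors_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="survive"):
            select_training_cells(rng.normal(size=(20, 3)),
                                  rng.permutation(20).astype(float),
                                  min_survivors=30)


class TestChannelRegression:
    def test_noiseless_linear_link_is_recovered(self):
        ref = feature_matrix(400, 5, seed=0)
        link_mat = np.random.default_rng(1).normal(size=(5, 4))
        _, target = generate_paired_channels(ref, lambda x: x @ link_mat,
                                             noise_sd=0.0)
        model, report = train_channel_regressor(ref, target, rng=0,
                                               param_grid=SMALL_GRID)
        assert report.test_mean > 0.95

    def test_pure_noise_target_has_no_skill(self):
        ref = feature_matrix(150, 5, seed=2)
        target = feature_matrix(150, 4, seed=3)
        _, report = train_channel_regressor(ref, target, rng=1,
                                            param_grid=SMALL_GRID)
        assert abs(report.test_mean) < 0.1

    def test_folds_have_disjoint_test_indices(self):
        ref = feature_matrix(80, 4, seed=4)
        _, target = generate_paired_channels(ref, lambda x: x, noise_sd=0.1,
                                             rng=0)
        _, report = train_channel_regressor(ref, target, rng=2,
                                            param_grid=SMALL_GRID)
        for train_idx, test_idx in report.fold_indices:
            assert np.intersect1d(train_idx, test_idx).size == 0

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_channel_regressor(feature_matrix(30, 3),
                                    feature_matrix(40, 3))

    def test_noise_skill_centered_at_zero_across_seeds(self):
        # pure-noise targets: mean test explained variance near 0 over seeds
        grid = {"est__estimator__C": [0.01, 1.0],
                "est__estimator__epsilon": [0.1],
                "est__estimator__gamma": ["scale"]}
        means = []
        for seed in range(20):
            ref = feature_matrix(120, 4, seed=seed)
            target = feature_matrix(120, 3, seed=1000 + seed)
            _, report = train_channel_regressor(ref, target, rng=seed,
                                                param_grid=grid, cv_folds=2)
            means.append(report.test_mean)
        assert abs(np.mean(means)) < 0.05

    def test_rbf_svr_beats_linear_models_on_nonlinear_link(self):
        ref = feature_matrix(300, 4, seed=9)
        link = np.random.default_rng(10).normal(size=(4, 3))
        _, target = generate_paired_channels(
            ref, lambda x: np.tanh(x @ link) ** 2, noise_sd=0.05, rng=0)
        _, rep_svr = train_channel_regressor(ref, target, rng=1,
                                             param_grid=SMALL_GRID)
        _, rep_lasso = train_channel_regressor(
            ref, target, rng=1, algorithm="lasso",
            param_grid={"est__estimator__alpha": [0.001, 0.01, 0.1]})
        assert rep_svr.test_mean >= rep_lasso.test_mean


class TestPrediction:
    def _fitted(self):
        ref = feature_matrix(100, 4, seed=5)
        link = np.random.default_rng(6).normal(size=(4, 3))
        _, target = generate_paired_channels(ref, lambda x: x @ link,
                                             noise_sd=0.0)
        model, _ = train_channel_regressor(ref, target, rng=3,
                                           param_grid=SMALL_GRID)
        return model, ref, target

    def test_training_rows_reproduced(self):
        model, ref, target = self._fitted()
        pred = predict_channel(model, ref.values)
        ev = 1 - np.var(target.values - pred) / np.var(target.values)
        assert ev > 0.9

    def test_duplicate_rows_get_identical_predictions(self):
        model, ref, _ = self._fitted()
        row = ref.values[[0]]
        pred = predict_channel(model, np.vstack([row, row]))
        np.testing.assert_array_equal(pred[0], pred[1])

    def test_standardization_applied_before_kernel(self):
        # scaled inputs must yield different predictions than the originals
        model, ref, _ = self._fitted()
        a = predict_channel(model, ref.values[:5])
        b = predict_channel(model, ref.values[:5] * 2.0)
        assert not np.allclose(a, b)

    def test_dimension_mismatch_rejected(self):
        model, _, _ = self._fitted()
        with pytest.raises(ValueError):
            predict_channel(model, np.zeros((3, 2)))


class TestCountRegression:
    def _inputs(self, n=150, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        tfor = rng.normal(size=(n, 12))
        cfor = rng.normal(size=(n, 12))
        cent = rng.normal(size=(n, 3)) * np.array([10, 20, 40])
        counts = 10 + 5 * np.sin(cent[:, 2] / 20.0) + rng.normal(0, noise_sd, n)
        return tfor, cfor, cent, np.clip(counts, 0, None)

    def test_input_width_is_23_features(self):
        tfor, cfor, cent, counts = self._inputs()
        model, _ = train_count_regressor(tfor, cfor, cent, counts, rng=0,
                                         param_grid=SMALL_GRID)
        assert model.n_inputs == 23

    def test_skill_increases_as_noise_vanishes(self):
        scores = []
        for noise in [4.0, 0.0]:
            tfor, cfor, cent, counts = self._inputs(noise_sd=noise, seed=1)
            _, report = train_count_regressor(tfor, cfor, cent, counts, rng=1,
                                              param_grid=SMALL_GRID)
            scores.append(report.test_mean)
        assert scores[1] > scores[0]

    def test_counts_independent_of_features_give_no_skill(self):
        rng = np.random.default_rng(2)
        tfor, cfor, cent, _ = self._inputs(seed=2)
        counts = rng.poisson(5, 150).astype(float)
        _, report = train_count_regressor(tfor, cfor, cent, counts, rng=2,
                                          param_grid=SMALL_GRID)
        assert abs(report.test_mean) < 0.25

    def test_negative_counts_rejected(self):
        tfor, cfor, cent, counts = self._inputs()
        counts[0] = -1
        with pytest.raises(ValueError):
            train_count_regressor(tfor, cfor, cent, counts)


class TestSampleFilter:
    def test_boundary_and_exclusion_rules(self):
        counts = {"a": [1, 1, 1], "b": [0, 4], "c": [5, 5]}
        kept = filter_samples_by_mean_count(counts)
        assert "a" not in kept and "b" in kept and "c" in kept

    def test_arithmetic_on_known_means(self):
        rng = np.random.default_rng(0)
        counts = {f"s{i}": rng.poisson(mu, 20)
                  for i, mu in enumerate([0.5, 1.5, 2.5, 4.0, 8.0])}
        kept = filter_samples_by_mean_count(counts, min_mean=2.0)
        expected = [s for s, v in counts.items() if np.mean(v) >= 2.0]
        assert kept == expected

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            kept = filter_samples_by_mean_count({"a": [0, 0]})
        assert kept == []
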