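import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from tasksal import (
    GazePoint,
    LinearGazeSaliency,
    assemble_training_set,
    cross_validate,
    fixation_map,
    sample_training_pixels,
    standardize,
    train_linear_svm,
    weight_report,
)
from tasksal.datatypes import FEATURE_NAMES, ContractError
from tasksal.learning import TrainingSet, load_model, save_model
from tasksal.synthetic import SyntheticConfig, generate_dataset
from tasksal.learning import compute_stacks, _per_image_truth_samples


def _truth_map(rng):
    pts = [GazePoint("s", "im", rng.integers(0, 200), rng.integers(0, 200))
           for _ in range(10)]
    return fixation_map(pts, sigma=10)


class TestSampleTrainingPixels:
    def test_counts_and_distinctness(self, rng):
        samples = sample_training_pixels(_truth_map(rng), rng=rng)
        labels = [lab for _, _, lab in samples]
        assert labels.count(+1) == 20 and labels.count(-1) == 20
        assert len({(x, y) for x, y, _ in samples}) == 40

    def test_positives_at_or_above_80th_percentile(self, rng):
        truth = _truth_map(rng)
        thr = np.quantile(truth.ravel(), 0.80)
        for x, y, lab in sample_training_pixels(truth, rng=rng):
            if lab == +1:
                assert truth[y, x] >= thr
            else:
                assert truth[y, x] <= np.quantile(truth.ravel(), 0.70)

    def test_seed_determinism(self, rng):
        truth = _truth_map(rng)
        a = sample_training_pixels(truth, rng=np.random.default_rng(5))
        b = sample_training_pixels(truth, rng=np.random.default_rng(5))
        c = sample_training_pixels(truth, rng=np.random.default_rng(6))
        assert a == b
        assert a != c

    def test_two_level_map_positives_all_from_top_stratum(self):
        # exactly the top 20% of pixels are 1, the rest 0
        flat = np.zeros(40000)
        flat[:8000] = 1.0
        truth = flat.reshape(200, 200)
        samples = sample_training_pixels(truth, rng=np.random.default_rng(0))
        for x, y, lab in samples:
            if lab == +1:
                assert truth[y, x] == 1.0
            else:
                assert truth[y, x] == 0.0

    def test_zero_map_rejected(self):
        with pytest.raises(ContractError):
            sample_training_pixels(np.zeros((200, 200)))


class TestAssembleTrainingSet:
    def test_row_values_equal_direct_map_lookup(self, toy_dataset, toy_stacks, rng):
        image_id = toy_dataset.images[0].id
        truth = fixation_map(toy_dataset.gaze_for(image_id), sigma=10)
        samples = {image_id: sample_training_pixels(truth, rng=rng)}
        ts = assemble_training_set(toy_stacks, samples)
        assert ts.X.shape == (40, 5)
        for row, (img, x, y) in zip(ts.X, ts.provenance):
            for j, name in enumerate(FEATURE_NAMES):
                assert row[j] == toy_stacks[img][name].values[y, x]

    def test_balanced_counts_across_images(self, toy_dataset, toy_stacks, rng):
        samples = {
            im.id: sample_training_pixels(
                fixation_map(toy_dataset.gaze_for(im.id), sigma=10), rng=rng)
            for im in toy_dataset.images
        }
        ts = assemble_training_set(toy_stacks, samples)
        assert (ts.y == 1).sum() == (ts.y == -1).sum() == 20 * len(toy_dataset.images)

    def test_dangling_image_id_rejected(self, toy_stacks):
        with pytest.raises(ContractError):
            assemble_training_set(toy_stacks, {"ghost": [(0, 0, 1)]})

    def test_feature_subset_for_ablation(self, toy_dataset, toy_stacks, rng):
        image_id = toy_dataset.images[0].id
        truth = fixation_map(toy_dataset.gaze_for(image_id), sigma=10)
        samples = {image_id: sample_training_pixels(truth, rng=rng)}
        subset = ("color", "intensity", "orientation", "center")
        ts = assemble_training_set(toy_stacks, samples, feature_subset=subset)
        assert ts.X.shape[1] == 4 and ts.feature_names == subset


class TestStandardize:
    def test_train_columns_zero_mean_unit_sd(self, rng):
        ts = TrainingSet(X=rng.normal(3, 5, (100, 5)),
                         y=np.where(rng.random(100) > 0.5, 1, -1))
        std, _, means, sds = standardize(ts)
        assert np.all(np.abs(std.X.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(std.X.std(axis=0) - 1) < 1e-9)

    def test_other_transformed_with_train_statistics(self, rng):
        ts = TrainingSet(X=rng.normal(3, 5, (100, 5)),
                         y=np.where(rng.random(100) > 0.5, 1, -1))
        std, other, _, _ = standardize(ts, ts)
        assert np.array_equal(std.X, other.X)

    def test_constant_feature_rejected_by_name(self, rng):
        X = rng.normal(size=(50, 5))
        X[:, 3] = 2.0
        ts = TrainingSet(X=X, y=np.where(rng.random(50) > 0.5, 1, -1))
        with pytest.raises(ContractError, match="target"):
            standardize(ts)


class TestLinearGazeSaliency:
    def _separable(self, rng, n=200):
        X = rng.normal(size=(n, 2)) * [0.1, 1.0]
        y = np.where(rng.random(n) > 0.5, 1, -1)
        X[:, 0] = y * 1.0  # feature 0 alone separates the classes
        return X, y

    def test_separable_toy_weights(self, rng):
        X, y = self._separable(rng)
        model = LinearGazeSaliency(feature_names=("f1", "f2")).fit(X, y)
        assert model.weights_[0] > 0
        assert abs(model.weights_[1]) < 1e-3 * abs(model.weights_[0]) + 1e-3

    def test_label_flip_negates_weights(self, rng):
        X, y = self._separable(rng)
        a = LinearGazeSaliency(feature_names=("f1", "f2")).fit(X, y)
        b = LinearGazeSaliency(feature_names=("f1", "f2")).fit(X, -y)
        assert np.allclose(a.weights_, -b.weights_, atol=1e-4)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ContractError):
            LinearGazeSaliency().fit(X, np.ones(20, dtype=int))

    def test_sklearn_get_set_params_round_trip(self):
        model = LinearGazeSaliency(C=2.5, category="dog")
        params = model.get_params()
        clone = LinearGazeSaliency().set_params(**params)
        assert clone.C == 2.5 and clone.category == "dog"

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = self._separable(rng)
        model = LinearGazeSaliency(feature_names=("f1", "f2"),
                                   category="car").fit(X, y)
        path = tmp_path / "m.txt"
        save_model(model, str(path))
        back = load_model(str(path))
        assert np.array_equal(back.weights_, model.weights_)
        assert back.bias_ == model.bias_
        assert back.category == "car"
        assert np.array_equal(back.decision_function(X), model.decision_function(X))


class TestPredictSaliency:
    def test_negative_center_weight_peaks_at_frame_center(self, toy_stacks):
        stack = next(iter(toy_stacks.values()))
        model = LinearGazeSaliency()
        model.weights_ = np.array([0.0, 0, 0, 0, -1.0])
        model.bias_ = 0.0
        model.feature_means_ = np.zeros(5)
        model.feature_sds_ = np.ones(5)
        model.n_features_in_ = 5
        pred = model.predict_map(stack)
        # prediction is the min-max normalized negated center-distance map
        center = stack["center"].values
        expected = (center.max() - center) / (center.max() - center.min())
        assert np.allclose(pred, expected, atol=1e-12)
        assert pred[100, 100] > pred[0, 0]

    def test_all_zero_weights_give_flat_zero_map(self, toy_stacks):
        stack = next(iter(toy_stacks.values()))
        model = LinearGazeSaliency()
        model.weights_ = np.zeros(5)
        model.bias_ = 1.0
        model.feature_means_ = np.zeros(5)
        model.feature_sds_ = np.ones(5)
        assert np.all(model.predict_map(stack) == 0)

    def test_scaling_weights_and_bias_leaves_map_unchanged(self, toy_stacks):
        stack = next(iter(toy_stacks.values()))
        model = LinearGazeSaliency()
        model.weights_ = np.array([0.3, -0.2, 0.1, 1.5, -0.9])
        model.bias_ = 0.4
        model.feature_means_ = np.zeros(5)
        model.feature_sds_ = np.ones(5)
        a = model.predict_map(stack)
        model.weights_ = model.weights_ * 2
        model.bias_ = model.bias_ * 2
        assert np.allclose(a, model.predict_map(stack), atol=1e-12)


class TestCrossValidate:
    def test_folds_partition_all_images(self, toy_dataset, toy_stacks):
        res = cross_validate(toy_dataset, k=2, rng=np.random.default_rng(1),
                             stacks=toy_stacks)
        all_ids = sorted(im.id for im in toy_dataset.images)
        seen = sorted(i for fold in res.folds for i in fold)
        assert seen == all_ids
        assert not (set(res.folds[0]) & set(res.folds[1]))

    def test_leave_one_image_out_when_k_equals_n(self, toy_dataset, toy_stacks):
        res = cross_validate(toy_dataset, k=4, rng=np.random.default_rng(1),
                             stacks=toy_stacks)
        assert len(res.folds) == 4
        assert all(len(f) == 2 for f in res.folds)  # one image per category

    def test_fixed_rng_reproduces_result(self, toy_dataset, toy_stacks):
        a = cross_validate(toy_dataset, k=2, rng=np.random.default_rng(9),
                           stacks=toy_stacks)
        b = cross_validate(toy_dataset, k=2, rng=np.random.default_rng(9),
                           stacks=toy_stacks)
        assert a.folds == b.folds
        assert a.fold_aucs == b.fold_aucs
        assert a.weights.equals(b.weights)

    def test_too_few_images_rejected(self, toy_dataset, toy_stacks):
        with pytest.raises(ContractError):
            cross_validate(toy_dataset, k=5, stacks=toy_stacks)


class TestWeightReport:
    def _model(self, weights, category="car"):
        m = LinearGazeSaliency(category=category)
        m.weights_ = np.asarray(weights, dtype=float)
        m.bias_ = 0.0
        m.feature_means_ = np.zeros(len(weights))
        m.feature_sds_ = np.ones(len(weights))
        return m

    def test_identical_runs_have_zero_std(self):
        runs = [{"car": self._model([1, 2, 3, 4, 5])}] * 3
        out = weight_report(runs)
        assert all(out.loc[0, f"{n}_std"] == 0 for n in FEATURE_NAMES)

    def test_opposite_runs_average_to_zero(self):
        runs = [{"car": self._model([1, -2, 3, -4, 5])},
                {"car": self._model([-1, 2, -3, 4, -5])}]
        out = weight_report(runs)
        assert all(out.loc[0, f"{n}_avg"] == 0 for n in FEATURE_NAMES)

    def test_one_row_per_category_and_rank_order(self):
        runs = [
            {"car": self._model([0.1, 0.2, 0.3, 2.0, -1.0]),
             "dog": self._model([0.1, 0.2, 0.3, 0.4, -3.0])}
        ] * 2
        out = weight_report(runs)
        assert len(out) == 2
        car = out[out.category == "car"].iloc[0]
        dog = out[out.category == "dog"].iloc[0]
        assert car["target_rank"] == 1
        assert dog["center_rank"] == 1

    def test_single_run_rejected(self):
        with pytest.raises(ContractError):
            weight_report([{"car": self._model([1, 1, 1, 1, 1])}])


class TestTargetWeightRecovery:
    def test_target_dominated_gaze_yields_dominant_target_weight(self):
        """Gaze generated almost entirely from the target location must
        hand the target feature the largest weight; a logistic-regression
        fit on the same samples serves as an independent cross-check."""
        wins = svm_agree = 0
        for seed in range(4):
            cfg = SyntheticConfig(
                n_images_per_category=5, categories=("car", "dog"),
                target_present_fraction=1.0, n_subjects=3,
                n_gaze_per_subject_per_image=30,
                mix=(0.9, 0.05, 0.05), seed=seed)
            ds = generate_dataset(cfg)
            stacks = compute_stacks(ds)
            rng = np.random.default_rng(seed)
            samples = _per_image_truth_samples(
                ds, [im.id for im in ds.images], 10.0, 20, 20, 0.2, 0.7, rng)
            ts = assemble_training_set(stacks, samples)
            model = train_linear_svm(ts, rng=seed)
            target_idx = FEATURE_NAMES.index("target")
            if np.argmax(np.abs(model.weights_)) == target_idx:
                wins += 1
            lr = LogisticRegression(max_iter=5000).fit(
                (ts.X - ts.X.mean(0)) / ts.X.std(0), ts.y)
            if np.argmax(np.abs(lr.coef_.ravel())) == target_idx:
                svm_agree += 1
        assert wins >= 3
        assert svm_agree >= 3  # the independent fit agrees
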