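import math

import numpy as np
import pytest

from irpnn import (
    FeatureVector,
    TissueClass,
    loo_error_rate,
    model_from_json,
    model_to_json,
    pattern_layer,
    pnn_output,
    pnn_predict,
    pnn_train,
    select_sigma,
)

NORMAL, EARLY, ADVANCED = TissueClass.NORMAL, TissueClass.EARLY, TissueClass.ADVANCED


def make_features(X, y):
    dim = X.shape[1]
    index = [(3, i + 1) for i in range(dim)]
    return [
        FeatureVector(x, index, label=TissueClass(lab), sample_id=f"s{i}")
        for i, (x, lab) in enumerate(zip(X, y))
    ]


def random_problem(rng, n_per_class=10, dim=2, spread=1.0):
    X, y = [], []
    for tc in TissueClass:
        center = rng.normal(0, 2, dim)
        X.append(center + spread * rng.normal(size=(n_per_class, dim)))
        y += [int(tc)] * n_per_class
    return np.vstack(X), np.array(y)


def kde_bayes_predict(Xtrain, ytrain, x, sigma):
    """Independently coded Gaussian kernel-density Bayes rule, equal priors."""
    best_label, best_density = None, -1.0
    for lab in sorted(set(ytrain)):
        pts = Xtrain[ytrain == lab]
        dens = 0.0
        for p in pts:
            d2 = float(np.sum((x - p) ** 2))
            dens += math.exp(-d2 / (2.0 * sigma**2))
        dens /= len(pts)
        if dens > best_density:  # ties keep the earlier (lower) label
            best_label, best_density = lab, dens
    return best_label


class TestTraining:
    def test_one_sample_per_class(self):
        features = make_features(np.eye(3), [1, 2, 3])
        model = pnn_train(features, sigma=1.0)
        assert model.n_centers() == {NORMAL: 1, EARLY: 1, ADVANCED: 1}

    def test_default_weights_are_inverse_class_counts(self, rng):
        X = rng.normal(size=(10, 2))
        y = [1] * 2 + [2] * 5 + [3] * 3
        model = pnn_train(make_features(X, y), sigma=1.0)
        assert np.allclose(np.diag(model.weights), [1 / 2, 1 / 5, 1 / 3])
        assert np.allclose(model.weights - np.diag(np.diag(model.weights)), 0.0)

    def test_unlabeled_sample_rejected(self):
        fv = FeatureVector(np.zeros(2), [(3, 1), (3, 2)])
        with pytest.raises(ValueError, match="label"):
            pnn_train([fv], sigma=1.0)

    def test_missing_required_class_rejected(self):
        features = make_features(np.eye(2), [1, 2])
        with pytest.raises(ValueError, match="advanced"):
            pnn_train(features, sigma=1.0, classes=list(TissueClass))

    def test_kmeans_center_reduction(self, rng):
        X, y = random_problem(rng, n_per_class=20)
        model = pnn_train(make_features(X, y), sigma=0.5, n_centers=4, seed=0)
        assert all(n == 4 for n in model.n_centers().values())


class TestPatternLayer:
    def test_kernel_is_one_at_its_center(self):
        model = pnn_train(make_features(np.eye(3), [1, 2, 3]), sigma=0.7)
        H = pattern_layer(model, np.array([0.0, 1.0, 0.0]))
        assert H[1] == pytest.approx(1.0)

    def test_closed_form_at_unit_distance(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 9.0]])
        model = pnn_train(make_features(X, [1, 2, 3]), sigma=1.0)
        H = pattern_layer(model, np.array([1.0, 0.0]))
        assert H[0] == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        X, y = random_problem(rng)
        model = pnn_train(make_features(X, y), sigma=0.8)
        x = rng.normal(size=2)
        H = pattern_layer(model, x)
        for k, tc in enumerate(model.classes):
            expected = sum(
                math.exp(-float(np.sum((x - c) ** 2)) / (2 * 0.8**2))
                for c in model.centers[tc]
            )
            assert H[k] == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = random_problem(rng)
        model = pnn_train(make_features(X, y), sigma=1.0)
        with pytest.raises(ValueError, match="dimension"):
            pattern_layer(model, np.zeros(5))


class TestOutputLayer:
    def test_unit_counts_make_output_equal_pattern_response(self):
        model = pnn_train(make_features(np.eye(3), [1, 2, 3]), sigma=1.0)
        x = np.array([0.3, 0.3, 0.4])
        assert np.allclose(pnn_output(model, x), pattern_layer(model, x))

    def test_zero_weights_zero_output(self, rng):
        X, y = random_problem(rng)
        model = pnn_train(make_features(X, y), sigma=1.0)
        model.weights = np.zeros_like(model.weights)
        assert np.allclose(pnn_output(model, rng.normal(size=2)), 0.0)

    def test_general_weights_match_matrix_product(self, rng):
        X, y = random_problem(rng)
        model = pnn_train(make_features(X, y), sigma=1.0)
        model.weights = rng.uniform(0, 1, (3, 3))
        x = rng.normal(size=2)
        H = pattern_layer(model, x)
        expected = [sum(model.weights[j, k] * H[k] for k in range(3)) for j in range(3)]
        assert np.allclose(pnn_output(model, x), expected)


class TestPrediction:
    def test_coincident_center_wins_at_small_sigma(self):
        X = np.array([[0.0, 0.0], [3.0, 3.0], [6.0, 6.0]])
        model = pnn_train(make_features(X, [1, 2, 3]), sigma=0.05)
        assert pnn_predict(model, np.array([3.0, 3.0])) == EARLY

    def test_exact_tie_goes_to_lower_ordinal(self):
        # centers of classes 1 and 2 symmetric about the query point
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        model = pnn_train(make_features(X, [1, 2]), sigma=1.0)
        assert pnn_predict(model, np.array([0.0, 0.0])) == NORMAL

    def test_equivalence_with_kernel_density_bayes(self, rng):
        agreements = 0
        X, y = random_problem(rng, n_per_class=8, spread=1.5)
        model = pnn_train(make_features(X, y), sigma=0.6)
        for _ in range(50):
            x = rng.normal(0, 2.5, 2)
            mine = int(pnn_predict(model, x))
            oracle = kde_bayes_predict(X, y, x, 0.6)
            agreements += mine == oracle
        assert agreements == 50

    def test_duplicating_training_set_leaves_predictions_unchanged(self, rng):
        X, y = random_problem(rng)
        features = make_features(X, y)
        single = pnn_train(features, sigma=0.5)
        doubled = pnn_train(features + features, sigma=0.5)
        queries = rng.normal(0, 2, (20, 2))
        assert pnn_predict(single, queries) == pnn_predict(doubled, queries)

    def test_sigma_to_zero_classifies_training_points_as_themselves(self, rng):
        X, y = random_problem(rng, spread=2.0)
        dists = [
            np.linalg.norm(X[i] - X[j]) for i in range(len(X)) for j in range(i + 1, len(X))
        ]
        sigma = 1e-3 * min(d for d in dists if d > 0)
        model = pnn_train(make_features(X, y), sigma=sigma)
        preds = pnn_predict(model, X)
        assert [int(p) for p in preds] == list(y)


class TestSigmaSelection:
    def test_separable_clusters_take_first_passing_width(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(10, 0.05, (10, 2)),
                       rng.normal(20, 0.05, (10, 2))])
        y = [1] * 10 + [2] * 10 + [3] * 10
        assert select_sigma(make_features(X, y), np.array([0.1, 1.0])) == 0.1

    def test_vacuous_goal_returns_first_grid_value(self, rng):
        X, y = random_problem(rng)
        features = make_features(X, y)
        grid = np.array([0.3, 0.7, 2.0])
        assert select_sigma(features, grid, error_goal=1.0) == 0.3

    def test_matches_brute_force_grid_scan(self, rng):
        X, y = random_problem(rng, n_per_class=6, spread=2.5)
        features = make_features(X, y)
        grid = np.geomspace(0.01, 3.0, 12)
        chosen = select_sigma(features, grid, error_goal=0.01)
        # independent scan: recompute every LOO rate and apply the rule
        rates = [loo_error_rate(features, float(s)) for s in np.sort(grid)]
        passing = [s for s, r in zip(np.sort(grid), rates) if r <= 0.01]
        expected = passing[0] if passing else np.sort(grid)[int(np.argmin(rates))]
        assert chosen == pytest.approx(float(expected))

    def test_nonpositive_grid_rejected(self, rng):
        X, y = random_problem(rng)
        with pytest.raises(ValueError, match="positive"):
            select_sigma(make_features(X, y), np.array([0.0, 1.0]))

    def test_loo_rate_matches_per_sample_retraining(self, rng):
        X, y = random_problem(rng, n_per_class=5, spread=2.0)
        features = make_features(X, y)
        sigma = 0.7
        errors = 0
        for i in range(len(features)):  # brute-force leave-one-out
            rest = features[:i] + features[i + 1 :]
            model = pnn_train(rest, sigma=sigma)
            errors += pnn_predict(model, X[i]) != TissueClass(y[i])
        assert loo_error_rate(features, sigma) == pytest.approx(errors / len(features))


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        X, y = random_problem(rng)
        model = pnn_train(make_features(X, y), sigma=0.4)
        path = tmp_path / "model.json"
        model_to_json(model, path)
        back = model_from_json(path)
        assert back.sigma == model.sigma
        assert back.classes == model.classes
        assert np.array_equal(back.weights, model.weights)
        for tc in model.classes:
            assert np.array_equal(back.centers[tc], model.centers[tc])
        queries = rng.normal(0, 2, (10, 2))
        assert pnn_predict(back, queries) == pnn_predict(model, queries)
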