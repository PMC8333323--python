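"""GMDH polynomial network: neuron fits, layer growth, prediction, wiring."""

import numpy as np
import pandas as pd
import pytest

from gmdhscreen import synthetic as syn
from gmdhscreen.experiments import codes_frame
from gmdhscreen.gmdh import (
    GMDHConfig,
    GMDHNetwork,
    GMDHTrainingError,
    Neuron,
    best_mcc_threshold,
    build_layer,
    classify,
    design_matrix,
    feature_importance,
    fit_neuron_rls,
    mcc_at_threshold,
    neuron_predict,
    train_multiclass,
    train_network,
    tune_lambda,
)


class TestNeuronFit:
    def test_zero_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(0)
        u, v = rng.normal(size=20), rng.normal(size=20)
        A = fit_neuron_rls(u, v, np.zeros(20), lam=1.0)
        np.testing.assert_allclose(A, 0.0, atol=1e-12)

    def test_exact_recovery_of_planted_polynomial(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=8), rng.normal(size=8)
        y = 1.0 + 2.0 * u * v
        A = fit_neuron_rls(u, v, y, lam=0.0)
        np.testing.assert_allclose(A, [1, 0, 0, 0, 0, 2], atol=1e-8)

    def test_huge_ridge_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        u, v = rng.uniform(-1, 1, 30), rng.uniform(-1, 1, 30)
        y = rng.uniform(-1, 1, 30)
        A = fit_neuron_rls(u, v, y, lam=1e12)
        assert np.max(np.abs(A)) < 1e-6

    def test_singular_unregularized_fit_raises_with_guidance(self):
        u = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        with pytest.raises(np.linalg.LinAlgError, match="lam > 0"):
            fit_neuron_rls(u, u, np.arange(8.0), lam=0.0)

    def test_matches_least_squares_oracle(self):
        """Unregularized fit equals an independent lstsq solve to 1e-8."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            u, v = rng.normal(size=40), rng.normal(size=40)
            y = rng.normal(size=40)
            A = fit_neuron_rls(u, v, y, lam=0.0)
            oracle, *_ = np.linalg.lstsq(design_matrix(u, v), y, rcond=None)
            assert np.max(np.abs(A - oracle)) < 1e-8

    def test_ridge_matches_augmented_lstsq_oracle(self):
        """Ridge solution equals lstsq on the sqrt(lam)-augmented system."""
        rng = np.random.default_rng(4)
        u, v, y = rng.normal(size=30), rng.normal(size=30), rng.normal(size=30)
        lam = 0.37
        X = design_matrix(u, v)
        Xa = np.vstack([X, np.sqrt(lam) * np.eye(6)])
        ya = np.concatenate([y, np.zeros(6)])
        oracle, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
        np.testing.assert_allclose(fit_neuron_rls(u, v, y, lam), oracle,
                                   atol=1e-8)


class TestNeuronPredict:
    def test_hand_evaluated_example(self):
        n = Neuron(parents=(("x", 0), ("x", 1)),
                   coef=np.array([1, 0, 0, 0, 0, 2.0]), lam=0.0,
                   fitness=0.0, threshold=None, layer=0)
        assert neuron_predict(n, [3.0], [4.0])[0] == 25.0

    def test_zero_coefficients_give_zero(self):
        n = Neuron(parents=(("x", 0), ("x", 1)), coef=np.zeros(6), lam=0.0,
                   fitness=0.0, threshold=None, layer=0)
        assert (neuron_predict(n, np.linspace(-5, 5, 7),
                               np.linspace(2, 3, 7)) == 0).all()

    def test_matches_independent_polynomial_evaluation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            coef = rng.normal(size=6)
            u, v = rng.normal(size=15), rng.normal(size=15)
            n = Neuron(parents=(("x", 0), ("x", 1)), coef=coef, lam=0.0,
                       fitness=0.0, threshold=None, layer=0)
            oracle = coef @ np.stack(
                [np.ones(15), u, v, u**2, v**2, u * v])
            np.testing.assert_allclose(neuron_predict(n, u, v), oracle,
                                       atol=1e-12)


def _brute_force_best_mcc(scores, y):
    """Exhaustive threshold sweep over midpoints of sorted unique scores."""
    uniq = np.sort(np.unique(scores))
    cand = [uniq[0], uniq[-1] + 1.0]
    cand += [0.5 * (a + b) for a, b in zip(uniq[:-1], uniq[1:])]
    best = max(cand, key=lambda t: (mcc_at_threshold(scores, y, t), t))
    return best, mcc_at_threshold(scores, y, best)


class TestThresholdSearch:
    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = rng.integers(5, 40)
            scores = np.round(rng.normal(size=n), 1)  # force ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            thr, fit = best_mcc_threshold(scores, y)
            _, fit_oracle = _brute_force_best_mcc(scores, y)
            assert fit == pytest.approx(fit_oracle, abs=1e-12)
            assert mcc_at_threshold(scores, y, thr) == pytest.approx(fit,
                                                                     abs=1e-12)


class TestTuneLambda:
    def _xy(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=n)
        v = u + 0.01 * rng.normal(size=n)  # nearly collinear
        y = (u * v + 0.5 * rng.normal(size=n) > 0.3).astype(int)
        half = n // 2
        return (u[:half], v[:half], y[:half]), (u[half:], v[half:], y[half:])

    def test_single_value_grid_returned(self):
        (ue, ve, ye), (uv, vv, yv) = self._xy()
        lam, *_ = tune_lambda(ue, ve, ye, uv, vv, yv, grid=[0.5])
        assert lam == 0.5

    def test_collinear_inputs_prefer_regularization(self):
        (ue, ve, ye), (uv, vv, yv) = self._xy(seed=1)
        grid = (0.0, *np.logspace(-4, 2, 10))
        lam, _, fit, _ = tune_lambda(ue, ve, ye, uv, vv, yv, grid=grid)
        assert lam > 0

    def test_ties_break_toward_smaller_lambda(self):
        # a grid of two equal-fitness points: huge values shrink both fits
        # to the all-negative rule, so fitness ties and the smaller wins
        (ue, ve, ye), (uv, vv, yv) = self._xy(seed=2)
        lam, *_ = tune_lambda(ue, ve, ye, uv, vv, yv, grid=[1e11, 1e12])
        assert lam == 1e11

    def test_single_class_validation_rejected(self):
        (ue, ve, ye), (uv, vv, _) = self._xy(seed=3)
        with pytest.raises(GMDHTrainingError):
            tune_lambda(ue, ve, ye, uv, vv, np.zeros_like(uv), grid=[1.0])


class TestBuildLayer:
    def _data(self, p, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, (n, p)).astype(float)
        y = ((X[:, 0] != X[:, 1]) ^ (rng.random(n) < 0.1)).astype(int)
        half = n // 2
        return X[:half], X[half:], y[:half], y[half:]

    def test_two_inputs_one_candidate(self):
        Xe, Xv, ye, yv = self._data(2)
        neurons, est, val = build_layer(Xe, Xv, ye, yv, GMDHConfig())
        assert len(neurons) == 1 and est.shape[1] == 1

    def test_retention_cap_at_ten(self):
        Xe, Xv, ye, yv = self._data(6)
        neurons, *_ = build_layer(Xe, Xv, ye, yv, GMDHConfig())
        assert 1 <= len(neurons) <= 10  # 15 candidates, at most 10 kept

    def test_enumeration_order_invariance(self):
        """The winning pair is the same pair of columns under permutation."""
        Xe, Xv, ye, yv = self._data(5, seed=4)
        neurons, *_ = build_layer(Xe, Xv, ye, yv, GMDHConfig())
        perm = [4, 2, 0, 3, 1]
        neurons_p, *_ = build_layer(Xe[:, perm], Xv[:, perm], ye, yv,
                                    GMDHConfig())
        top = {perm[r[1]] for r in [n.parents for n in neurons_p[:1]][0]}
        orig = {r[1] for r in neurons[0].parents}
        assert top == orig


class TestTrainNetwork:
    def test_noisy_xor_recovered_with_high_mcc(self):
        cfg = syn.xor_config(400, n_noise=2, weight=8.0, prevalence=0.5,
                             seed=3)
        ds = syn.generate_dataset(cfg)
        X = codes_frame(ds.features)
        net = train_network(X, ds.outcomes["y"], GMDHConfig(seed=3))
        assert net.fitness_trajectory[-1] >= 0.9
        imp = feature_importance(net)
        assert set(list(imp)[:2]) == {"a", "b"}

    def test_perfect_layer_one_forces_single_layer(self):
        """A first-layer neuron with MCC 1.0 cannot be strictly beaten."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.integers(0, 2, 200),
                          "b": rng.integers(0, 2, 200),
                          "c": rng.integers(0, 2, 200)}).astype(float)
        y = (X["a"] != X["b"]).astype(int)
        net = train_network(X, y, GMDHConfig(seed=0))
        assert net.n_layers == 1
        assert net.fitness_trajectory == [1.0]

    def test_fitness_trajectory_strictly_increasing(self):
        ds = syn.generate_dataset(syn.xor_config(2_000, weight=2.0, seed=9))
        X = codes_frame(ds.features)
        net = train_network(X, ds.outcomes["y"], GMDHConfig(seed=9))
        traj = net.fitness_trajectory
        assert all(b > a for a, b in zip(traj, traj[1:]))
        # retained neurons all beat the previous layer's best
        for li in range(1, net.n_layers):
            prev_best = net.layers[li - 1][0].fitness
            assert all(n.fitness > prev_best for n in net.layers[li])

    def test_single_feature_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0] * 10})
        with pytest.raises(GMDHTrainingError):
            train_network(X, [0, 1] * 10, GMDHConfig())

    def test_degenerate_constant_features_rejected(self):
        X = pd.DataFrame({"a": np.ones(40), "b": np.ones(40)})
        y = np.array([0, 1] * 20)
        with pytest.raises(GMDHTrainingError):
            train_network(X, y, GMDHConfig())


class TestClassify:
    def _trained(self, seed=3):
        cfg = syn.xor_config(600, n_noise=2, weight=6.0, prevalence=0.3,
                             seed=seed)
        ds = syn.generate_dataset(cfg)
        X = codes_frame(ds.features)
        net = train_network(X, ds.outcomes["y"], GMDHConfig(seed=seed))
        return net, X, ds.outcomes["y"].to_numpy()

    def test_threshold_is_validation_mcc_maximizer(self):
        net, X, y = self._trained()
        val_mask = np.ones(len(X), dtype=bool)
        val_mask[net.est_indices] = False
        _, scores = classify(net, X)
        thr_oracle, _ = _brute_force_best_mcc(scores[val_mask], y[val_mask])
        assert net.threshold == pytest.approx(thr_oracle, abs=1e-12)

    def test_estimation_scores_reproduced_bitwise(self):
        net, X, _ = self._trained(seed=4)
        _, scores = classify(net, X)
        assert np.array_equal(scores[net.est_indices], net.est_scores)

    def test_simple_thresholding(self):
        net, X, _ = self._trained(seed=5)
        labels, scores = classify(net, X)
        assert np.array_equal(labels, (scores >= net.threshold).astype(int))

    def test_missing_feature_rejected(self):
        net, X, _ = self._trained(seed=6)
        with pytest.raises(KeyError):
            classify(net, X.drop(columns=["a"]))

    def test_serialization_round_trip_is_bit_exact(self):
        net, X, _ = self._trained(seed=7)
        clone = GMDHNetwork.from_json(net.to_json())
        l1, s1 = classify(net, X)
        l2, s2 = classify(clone, X)
        assert np.array_equal(s1, s2) and np.array_equal(l1, l2)

    def test_wiring_export_names_features(self):
        net, X, _ = self._trained(seed=8)
        edges = net.to_graph()
        parents = {p for p, _ in edges}
        assert parents & set(X.columns)


class TestFeatureImportance:
    def test_depth_one_network(self):
        net, X, _ = TestClassify()._trained(seed=3)
        if net.n_layers == 1:
            assert set(feature_importance(net).values()) == {1}

    def test_manual_two_layer_wiring(self):
        """Counts match a hand-walked traversal of a constructed graph."""
        coef = np.array([0, 1, 1, 0, 0, 0.0])
        mk = lambda parents, layer: Neuron(parents=parents, coef=coef,
                                           lam=0.0, fitness=0.5,
                                           threshold=0.5, layer=layer)
        layers = [
            [mk((("x", 0), ("x", 1)), 0), mk((("x", 0), ("x", 2)), 0),
             mk((("x", 3), ("x", 4)), 0)],
            [mk((("n", 0, 0), ("n", 0, 1)), 1)],
        ]
        net = GMDHNetwork(layers=layers, output_ref=("n", 1, 0),
                          threshold=0.5, fitness_trajectory=[0.4, 0.5],
                          config=GMDHConfig(),
                          feature_names=list("abcde"))
        # reachable: N1.1 (a,b), N1.2 (a,c); N1.3 unreachable
        assert feature_importance(net) == {"a": 2, "b": 1, "c": 1}

    def test_empty_network_rejected(self):
        net = GMDHNetwork(layers=[], output_ref=("n", 0, 0), threshold=None,
                          fitness_trajectory=[], config=GMDHConfig(),
                          feature_names=[])
        with pytest.raises(GMDHTrainingError):
            feature_importance(net)


class TestMulticlass:
    def test_perfectly_separable_macro_f1_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"u": rng.integers(0, 3, 600),
                          "v": rng.integers(0, 3, 600)}).astype(float)
        y = X["u"].astype(int).to_numpy()
        net = train_multiclass(X, y, GMDHConfig(seed=1))
        assert net.fitness_trajectory[-1] == 1.0
        labels, _ = classify(net, X)
        assert (labels == y).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permuted_labels_stay_at_chance(self, seed):
        """Label-permuted outcome: macro-F1 no better than chance level.

        Regressing the class index collapses null predictions toward the
        middle class, so the macro-F1 sits at or below the 1/3 of uniform
        guessing."""
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"u": rng.integers(0, 3, 600),
                          "v": rng.integers(0, 3, 600)}).astype(float)
        y = np.random.default_rng(seed).permutation(
            X["u"].astype(int).to_numpy())
        net = train_multiclass(X, y, GMDHConfig(seed=seed))
        assert net.fitness_trajectory[-1] <= 1 / 3 + 0.05

    def test_binary_labels_delegate_to_mcc_path(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"u": rng.integers(0, 3, 600),
                          "v": rng.integers(0, 3, 600)}).astype(float)
        y = (X["u"] > 1).astype(int).to_numpy()
        l1, _ = classify(train_multiclass(X, y, GMDHConfig(seed=2)), X)
        l2, _ = classify(train_network(X, y, GMDHConfig(seed=2)), X)
        assert np.array_equal(l1, l2)

    def test_class_absent_from_split_rejected(self):
        X = pd.DataFrame({"u": [0.0, 1.0] * 10, "v": [1.0, 0.0] * 10})
        y = np.array([0] * 19 + [2])  # class 2 has a single member
        with pytest.raises(GMDHTrainingError):
            train_multiclass(X, y, GMDHConfig(seed=0))
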