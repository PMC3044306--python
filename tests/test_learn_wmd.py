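import numpy as np
import pytest

from actsite.geometry import ImportanceWeights, RigidTransform, superpose, umd
from actsite.learn_wmd import (TrainingSetError, WMDModel, WMDTrainingSet,
                               hinge_objective, lp_stage,
                               site_distance_features, train_wmd,
                               transform_stage)
from actsite.synthetic import NoiseProfile, make_sites, make_template
from oracles import lp_vertex_enum_objective


class TestSiteDistanceFeatures:
    def test_identity_transform_on_identical_site_is_zero(self):
        T = np.random.default_rng(0).uniform(0, 8, (4, 3))
        f = site_distance_features(T, T, RigidTransform.identity())
        np.testing.assert_allclose(f, 0.0, atol=1e-15)

    def test_uniform_beta_under_optimal_transform_recovers_umd(self):
        rng = np.random.default_rng(1)
        T = rng.uniform(0, 8, (5, 3))
        S = T + 0.5 * rng.standard_normal((5, 3))
        f = site_distance_features(S, T, superpose(S, T))
        assert np.full(5, 1 / 5) @ f == pytest.approx(umd(S, T), abs=1e-10)

    def test_two_atom_hand_computation(self):
        T = np.array([[0., 0, 0], [1, 0, 0]])
        S = np.array([[0., 0, 1], [1, 0, 0]])
        f = site_distance_features(S, T, RigidTransform.identity())
        np.testing.assert_allclose(f, [1.0, 0.0], atol=1e-15)


class TestLpStage:
    def test_single_atom_is_fully_constrained(self):
        F = np.array([[0.2], [0.8], [1.5]])
        y = np.array([1, -1, -1])
        w, theta, obj = lp_stage(F, y, np.ones(3), epsilon=0.1)
        np.testing.assert_allclose(w.beta, [1.0])
        assert obj == pytest.approx(0.0, abs=1e-9)
        assert 0.3 <= theta <= 0.7

    def test_worked_two_feature_example(self):
        F = np.array([[0.1, 0.9], [0.5, 0.5]])
        y = np.array([1, -1])
        w, theta, obj = lp_stage(F, y, np.ones(2), epsilon=0.1)
        assert obj == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(w.beta, [1.0, 0.0], atol=1e-8)
        assert 0.2 - 1e-8 <= theta <= 0.4 + 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_vertex_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 5)), int(rng.integers(2, 4))
        F = rng.uniform(0, 3, (n, m))
        y = np.array([1] * (n // 2 + 1) + [-1] * (n - n // 2 - 1))
        costs = rng.uniform(0.5, 2.0, n)
        eps = 0.05
        _, _, obj = lp_stage(F, y, costs, epsilon=eps)
        oracle = lp_vertex_enum_objective(F, y, costs, eps)
        assert obj == pytest.approx(oracle, abs=1e-7)

    def test_duplicating_sites_with_renormalized_costs_is_invariant(self):
        rng = np.random.default_rng(3)
        F = rng.uniform(0, 2, (4, 3))
        y = np.array([1, 1, -1, -1])
        costs = np.where(y == 1, 1 / 2, 1 / 2)
        _, theta1, obj1 = lp_stage(F, y, costs, epsilon=0.05)
        F2 = np.vstack([F, F])
        y2 = np.concatenate([y, y])
        costs2 = np.where(y2 == 1, 1 / 4, 1 / 4)
        _, theta2, obj2 = lp_stage(F2, y2, costs2, epsilon=0.05)
        assert obj1 == pytest.approx(obj2, abs=1e-8)

    def test_constraints_satisfied_at_the_solution(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(0, 3, (6, 3))
        y = np.array([1, 1, 1, -1, -1, -1])
        w, theta, obj = lp_stage(F, y, np.ones(6), epsilon=0.02)
        beta = w.beta
        assert np.all(beta >= -1e-9)
        assert np.all(beta <= 2 / 3 + 1e-9)
        assert beta.sum() == pytest.approx(1.0, abs=1e-9)
        # objective equals the hinge loss at (beta, theta)
        assert hinge_objective(F, y, np.ones(6), beta, theta, 0.02) == \
            pytest.approx(obj, abs=1e-7)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingSetError):
            lp_stage(np.ones((2, 2)), np.array([1, 1]), np.ones(2), 0.1)


class TestTransformStage:
    def test_uniform_weights_reduce_to_unweighted_kabsch(self):
        template = make_template(4, seed=5)
        sites = make_sites(template, 3, 3, seed=6)
        uniform = ImportanceWeights.uniform(4)
        for site, tr in zip(sites, transform_stage(sites, template, uniform)):
            expected = superpose(site.coords, template.coords)
            np.testing.assert_allclose(tr.rotation, expected.rotation,
                                       atol=1e-10)

    def test_stage_never_increases_per_site_deviation(self):
        template = make_template(5, seed=7)
        sites = make_sites(template, 4, 4, seed=8)
        w = ImportanceWeights(np.array([0.4, 0.3, 0.1, 0.1, 0.1]))
        old = transform_stage(sites, template, ImportanceWeights.uniform(5))
        new = transform_stage(sites, template, w)
        for site, tr_old, tr_new in zip(sites, old, new):
            f_old = site_distance_features(site.coords, template.coords,
                                           tr_old)
            f_new = site_distance_features(site.coords, template.coords,
                                           tr_new)
            assert w.beta @ f_new <= w.beta @ f_old + 1e-10


class TestTrainWmd:
    def test_recovers_informative_atom(self):
        # atom 0 noiseless in positives, all atoms equally noisy in decoys
        gains = []
        for seed in range(10):
            template = make_template(3, seed=100 + seed)
            profile = NoiseProfile(per_atom_sigma=np.array([0.0, 1.0, 1.0]),
                                   decoy_sigma=1.0, n_conserved=1)
            sites = make_sites(template, 20, 60, profile=profile,
                               seed=200 + seed)
            model = train_wmd(WMDTrainingSet(sites=sites), template)
            gains.append(model.weights.beta[0])
        assert np.mean(gains) > 1 / 3

    def test_no_signal_data_gives_chance_roc(self):
        from actsite.evaluation import roc_score
        from actsite.geometry import wmd
        rocs = []
        for seed in range(5):
            template = make_template(4, seed=300 + seed)
            profile = NoiseProfile(per_atom_sigma=np.full(4, 1.0),
                                   decoy_sigma=1.0, n_conserved=0)
            train = make_sites(template, 25, 25, profile=profile,
                               seed=400 + seed)
            test = make_sites(template, 25, 25, profile=profile,
                              seed=500 + seed)
            model = train_wmd(WMDTrainingSet(sites=train), template)
            scores = [-wmd(s.coords, template.coords, model.weights)
                      for s in test]
            rocs.append(roc_score(scores, [s.label for s in test]))
        assert abs(np.mean(rocs) - 0.5) < 0.1

    def test_lp_objective_non_increasing_across_iterations(self):
        template = make_template(4, seed=9)
        sites = make_sites(template, 15, 40, seed=10)
        model = train_wmd(WMDTrainingSet(sites=sites), template, iterations=3)
        history = model.objective_history
        assert len(history) == 3
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_learned_weights_respect_upper_bound(self):
        template = make_template(5, seed=11)
        sites = make_sites(template, 10, 30, seed=12)
        model = train_wmd(WMDTrainingSet(sites=sites), template)
        assert np.all(model.weights.beta <= 2 / 5 + 1e-9)

    def test_single_class_training_set_rejected(self):
        template = make_template(3, seed=13)
        sites = make_sites(template, 2, 2, seed=14)
        with pytest.raises(TrainingSetError):
            WMDTrainingSet(sites=[s for s in sites if s.label == 1])

    def test_model_json_round_trip(self, tmp_path):
        template = make_template(4, seed=15)
        sites = make_sites(template, 8, 20, seed=16)
        model = train_wmd(WMDTrainingSet(sites=sites), template)
        model.to_json(tmp_path / "m.json")
        back = WMDModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.weights.beta, model.weights.beta)
        assert back.threshold == pytest.approx(model.threshold)
        assert back.iterations_used == model.iterations_used
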