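import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orco_vscreen.bayes import (
    BayesModel,
    feature_weight,
    loo_scores,
    loo_scores_from_features,
    score_features,
    train,
    train_from_features,
)
from orco_vscreen.chem_io import ACTIVE


# ---------------------------------------------------------------------------
# independent brute-force oracle: recompute every count from scratch


def _brute_p_good(n_active, n_total):
    eps = 0.5 / max(1, n_total)
    return min(max(n_active / max(1, n_total), eps), 1.0 - eps)


def brute_train(features, y):
    n_total = len(y)
    p = _brute_p_good(sum(y), n_total)
    all_feats = set().union(*features) if features else set()
    weights = {}
    for f in sorted(all_feats):
        t = sum(f in fs for fs in features)
        a = sum(f in fs for fs, label in zip(features, y) if label)
        weights[f] = math.log((a + p * (1 / p)) / (t + 1 / p) / p)
    return weights, p


def brute_score(weights, feats):
    raw = sum(weights.get(f, 0.0) for f in feats)
    return raw, raw / max(1, len(feats))


def brute_loo(features, y):
    out = []
    for i in range(len(y)):
        rest_f = features[:i] + features[i + 1 :]
        rest_y = y[:i] + y[i + 1 :]
        weights, _ = brute_train(rest_f, rest_y)
        out.append(brute_score(weights, features[i])[1])
    return out


def _random_dataset(rng, max_mols=12, max_feats=8):
    n = int(rng.integers(3, max_mols + 1))
    while True:
        y = rng.integers(0, 2, size=n).tolist()
        if 0 < sum(y) < n:
            break
    features = [
        frozenset(int(f) for f in rng.choice(max_feats, size=rng.integers(1, max_feats + 1), replace=False))
        for _ in range(n)
    ]
    return features, y


class TestFeatureWeight:
    def test_hand_computed_values(self):
        assert feature_weight(2, 2, 0.5) == pytest.approx(math.log(1.5))
        assert feature_weight(0, 2, 0.5) == pytest.approx(math.log(0.5))

    def test_weight_zero_at_base_rate(self):
        # a feature sampled exactly at the base rate carries no information
        checked = 0
        for t in range(1, 41):
            for p_num, p_den in [(1, 2), (1, 4), (3, 4), (2, 5), (5, 8)]:
                p = p_num / p_den
                a = t * p
                if a != int(a):
                    continue
                assert feature_weight(int(a), t, p) == pytest.approx(0.0, abs=1e-12)
                checked += 1
        assert checked > 30

    @given(
        t=st.integers(min_value=2, max_value=50),
        p=st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_counts(self, t, p):
        a = t // 2
        assert feature_weight(a + 1, t + 1, p) > feature_weight(a, t + 1, p)
        assert feature_weight(a, t + 1, p) < feature_weight(a, t, p)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            feature_weight(1, 0, 0.5)
        with pytest.raises(ValueError):
            feature_weight(3, 2, 0.5)
        with pytest.raises(ValueError):
            feature_weight(1, 2, 0.0)


class TestTrainAndScore:
    def test_toy_signs(self):
        # 2 actives share f1, 2 inactives share f2
        features = [frozenset({1}), frozenset({1}), frozenset({2}), frozenset({2})]
        y = [1, 1, 0, 0]
        weights, p = train_from_features(features, y)
        assert p == pytest.approx(0.5)
        assert weights[1] > 0 > weights[2]

    def test_empty_feature_set_scores_zero(self):
        weights, _ = train_from_features([frozenset({1}), frozenset({2})], [1, 0])
        assert score_features(weights, frozenset()) == (0.0, 0.0)

    def test_raw_score_additive_over_disjoint_subsets(self):
        weights = {1: 0.5, 2: -0.3, 3: 1.1}
        raw_fg = score_features(weights, frozenset({1, 2, 3}))[0]
        raw_f = score_features(weights, frozenset({1}))[0]
        raw_g = score_features(weights, frozenset({2, 3}))[0]
        assert raw_fg == pytest.approx(raw_f + raw_g)

    def test_unseen_features_contribute_zero(self):
        weights = {1: 0.5}
        raw, _ = score_features(weights, frozenset({1, 99}))
        assert raw == pytest.approx(0.5)

    def test_active_own_features_score_positive(self):
        features = [frozenset({1, 3}), frozenset({1}), frozenset({2}), frozenset({2, 4})]
        y = [1, 1, 0, 0]
        weights, _ = train_from_features(features, y)
        assert score_features(weights, frozenset({1, 3}))[0] > 0

    def test_single_class_dataset_fatal(self, toy_set):
        from dataclasses import replace

        from orco_vscreen.chem_io import MoleculeSet

        all_active = MoleculeSet([replace(r, label=ACTIVE, ic50_um=None) for r in toy_set.records])
        with pytest.raises(ValueError, match="2 actives and 2 inactives"):
            train(all_active)

    def test_oracle_equivalence_randomized(self):
        # brute-force oracle recomputes every count from scratch; the
        # implementation must agree exactly on weights, scores and LOO
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            features, y = _random_dataset(rng)
            w_fast, p_fast = train_from_features(features, y)
            w_brute, p_brute = brute_train(features, y)
            assert p_fast == pytest.approx(p_brute, abs=1e-14)
            assert set(w_fast) == set(w_brute)
            for f in w_fast:
                assert w_fast[f] == pytest.approx(w_brute[f], abs=1e-12)
            loo_fast = loo_scores_from_features(features, y)
            loo_brute = brute_loo(features, y)
            assert loo_fast == pytest.approx(loo_brute, abs=1e-12)


class TestLooScores:
    def test_identical_duplicated_molecules_keep_sign(self):
        # n identical actives + n identical inactives: each active's LOO
        # score stays positive for n >= 3
        for n in (3, 5):
            features = [frozenset({1})] * n + [frozenset({2})] * n
            y = [1] * n + [0] * n
            loo = loo_scores_from_features(features, y)
            assert all(s > 0 for s in loo[:n])
            assert all(s < 0 for s in loo[n:])

    def test_toy_set_ordering(self, toy_set):
        scores = loo_scores(toy_set)
        assert len(scores) == 4
        assert np.mean(scores[:2]) > np.mean(scores[2:])

    def test_degenerate_fold_single_class_still_scored(self):
        # removing the only active leaves a single-class fold; the record is
        # still scored (clipped base rate), never an exception
        features = [frozenset({1}), frozenset({2}), frozenset({2, 3})]
        y = [1, 0, 0]
        scores = loo_scores_from_features(features, y)
        assert all(np.isfinite(scores))


class TestEstPGood:
    def _model(self, mu_a=2.0, sigma_a=1.0, mu_i=-2.0, sigma_i=1.0):
        from orco_vscreen.chem_io import Featurizer

        return BayesModel(
            p_good=0.5, weights={}, mu_active=mu_a, sigma_active=sigma_a,
            mu_inactive=mu_i, sigma_inactive=sigma_i, threshold=0.0,
            featurizer=Featurizer(use_descriptors=False),
        )

    def test_symmetry_midpoint(self):
        assert self._model().est_p_good(0.0) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # equal sigmas: EstPGood(1) = 1 / (1 + exp(-4))
        assert self._model().est_p_good(1.0) == pytest.approx(1.0 / (1.0 + math.exp(-4.0)))

    def test_limits_saturate_without_nan(self):
        m = self._model()
        assert m.est_p_good(1e6) == pytest.approx(1.0)
        assert m.est_p_good(-1e6) == pytest.approx(0.0)

    @given(st.floats(min_value=-50, max_value=50), st.floats(min_value=-50, max_value=50))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_when_equal_sigmas(self, s1, s2):
        m = self._model()
        lo, hi = sorted((s1, s2))
        assert m.est_p_good(lo) <= m.est_p_good(hi) + 1e-12


class TestModelTraining:
    def test_model_a_vs_model_b_base_rates(self, model_a, model_b):
        assert model_a.p_good == pytest.approx(58 / 83)
        assert model_b.p_good == pytest.approx(
            len(model_b.training_ids) and
            sum(1 for l in model_b.training_labels if l == ACTIVE) / len(model_b.training_ids)
        )
        assert model_a.p_good != model_b.p_good
        assert model_a.weights != model_b.weights

    def test_training_active_repredicted_confidently(self, toy_set):
        model = train(toy_set)
        pred = model.predict(toy_set.records[0])
        assert pred.est_p_good > 0.5
        assert pred.binary_call == ACTIVE

    def test_zero_trained_features_maps_through_est_p_good(self, toy_set):
        from orco_vscreen.chem_io import Featurizer, standardize, MoleculeRecord

        model = train(toy_set, Featurizer(use_descriptors=False))
        exotic = standardize(MoleculeRecord("x", "FC(F)(F)S(=O)(=O)N"))
        pred = model.predict(exotic)
        assert pred.raw_score == 0.0
        assert pred.est_p_good == pytest.approx(model.est_p_good(0.0))

    def test_predictions_independent_across_models(self, model_a, model_b, training_set):
        rec = training_set.records[0]
        pa, pb = model_a.predict(rec), model_b.predict(rec)
        assert pa != pb

    def test_sigma_floor_on_degenerate_training(self):
        features = [frozenset({1})] * 3 + [frozenset({2})] * 3
        y = [1, 1, 1, 0, 0, 0]
        from orco_vscreen.bayes import SIGMA_FLOOR, _choose_threshold

        # identical molecules per class give zero LOO variance; downstream
        # Gaussian machinery must still be defined
        loo = loo_scores_from_features(features, y)
        assert max(np.std(loo[:3]), np.std(loo[3:])) == pytest.approx(0.0)
        assert SIGMA_FLOOR > 0
        cut = _choose_threshold(loo, y)
        assert min(loo[3:]) < cut < max(loo[:3]) or cut < min(loo)

    def test_serialization_roundtrip(self, model_a, training_set, tmp_path):
        path = tmp_path / "model.json"
        model_a.save(path)
        loaded = BayesModel.load(path)
        assert loaded.p_good == model_a.p_good
        assert loaded.weights == model_a.weights
        assert loaded.threshold == model_a.threshold
        rec = training_set.records[0]
        assert loaded.predict(rec) == model_a.predict(rec)
        # JSON really is on disk and self-contained
        payload = json.loads(path.read_text())
        assert "featurizer" in payload
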