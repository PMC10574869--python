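"""Patch features, classifier training, and candidate selection rules."""

import numpy as np
import pytest

from flatfoot.features import FEATURE_LENGTH, FeatureError, extract_features
from flatfoot.poi_selection import (
    MissingLandmarkError,
    PoIPatchClassifier,
    build_training_set,
    score_candidates,
    select_best,
    train_poi_classifier,
)
from flatfoot.template_matching import CandidatePatch


class TestExtractFeatures:
    def test_constant_patch_has_zero_gradient_block(self):
        v = extract_features(np.full((100, 100), 120.0))
        assert v.shape == (FEATURE_LENGTH,)
        assert np.all(v[256:] == 0.0)  # gradient histogram block

    def test_deterministic_for_identical_patches(self, rng):
        p = rng.uniform(0, 255, (100, 100))
        np.testing.assert_array_equal(extract_features(p), extract_features(p.copy()))

    def test_rotated_patch_differs_in_general(self, rng):
        p = rng.uniform(0, 255, (100, 100))
        assert not np.allclose(extract_features(p), extract_features(np.rot90(p)))

    def test_wrong_patch_size_rejected(self):
        with pytest.raises(FeatureError):
            extract_features(np.zeros((50, 50)))

    def test_length_independent_of_content(self, rng):
        for _ in range(3):
            assert extract_features(rng.uniform(0, 255, (100, 100))).size == FEATURE_LENGTH


def _toy_patches(rng, n_per_class=3):
    """Nine visually distinct synthetic patch classes."""
    patches, labels = [], []
    for poi in range(1, 10):
        for i in range(n_per_class):
            p = np.zeros((100, 100))
            # distinct geometry per class: a band whose position encodes the class
            p[poi * 10 : poi * 10 + 8, :] = 200.0
            p += rng.normal(0, 2.0, p.shape)
            patches.append(p)
            labels.append(poi)
    return np.asarray(patches), np.asarray(labels)


class TestPoIPatchClassifier:
    def test_distinct_classes_reach_perfect_training_accuracy(self, rng):
        X, y = _toy_patches(rng)
        clf = PoIPatchClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_same_seed_gives_identical_predictions(self, rng):
        X, y = _toy_patches(rng)
        p1 = PoIPatchClassifier(random_state=42).fit(X, y).predict_proba(X)
        p2 = PoIPatchClassifier(random_state=42).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_probabilities_sum_to_one(self, rng):
        X, y = _toy_patches(rng)
        proba = PoIPatchClassifier().fit(X, y).predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all()

    def test_missing_class_error_names_it(self, rng):
        X, y = _toy_patches(rng)
        keep = y != 7
        with pytest.raises(ValueError, match="7"):
            PoIPatchClassifier().fit(X[keep], y[keep])

    def test_mlp_backend_behind_same_interface(self, rng):
        X, y = _toy_patches(rng, n_per_class=2)
        clf = PoIPatchClassifier(backend="mlp_small", random_state=0).fit(X, y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_backend_rejected(self, rng):
        X, y = _toy_patches(rng, n_per_class=2)
        with pytest.raises(ValueError, match="backend"):
            PoIPatchClassifier(backend="svm").fit(X, y)

    def test_train_poi_classifier_wrapper(self, rng):
        X, y = _toy_patches(rng, n_per_class=2)
        clf = train_poi_classifier(list(zip(X, y)), {"n_trees": 20})
        assert clf.n_trees == 20
        assert set(clf.classes_) == set(range(1, 10))


class TestScoreAndSelect:
    def _cands(self, likelihoods, poi_id=3):
        return [
            CandidatePatch(poi_id=poi_id, start=(10 * i, 5), similarity=0.95, likelihood=l, scan_index=i)
            for i, l in enumerate(likelihoods)
        ]

    def test_argmax_selection(self):
        lm = select_best(self._cands([0.2, 0.9, 0.4]), 3)
        assert lm.point == (60.0, 55.0)  # second candidate start (10,5) + 50
        assert lm.likelihood == 0.9

    def test_exact_tie_selects_first_in_scan_order(self):
        lm = select_best(self._cands([0.7, 0.7]), 3)
        assert lm.point == (50.0, 55.0)

    def test_single_candidate_wins_regardless_of_likelihood(self):
        lm = select_best(self._cands([0.01]), 3)
        assert lm.likelihood == 0.01

    def test_no_candidates_raises_typed_error_with_poi(self):
        with pytest.raises(MissingLandmarkError) as exc:
            select_best([], 6, image_id="img-1")
        assert exc.value.poi_id == 6
        assert "PoI6" in str(exc.value)

    def test_score_candidates_fills_own_class_probability(self, rng):
        X, y = _toy_patches(rng)
        clf = PoIPatchClassifier(n_trees=30).fit(X, y)
        cands = [
            CandidatePatch(poi_id=int(y[k]), start=(0, 0), similarity=0.95, patch=X[k])
            for k in (0, 10, 20)
        ]
        out = score_candidates(clf, cands)
        proba = clf.predict_proba(np.asarray([c.patch for c in cands]))
        for c, row in zip(out, proba):
            assert c.likelihood == pytest.approx(row[clf.class_index(c.poi_id)])
        # training patches of distinct classes: own-class probability is high
        assert all(c.likelihood > 0.5 for c in out)

    def test_empty_candidate_list_passes_through(self, rng):
        X, y = _toy_patches(rng, n_per_class=2)
        clf = PoIPatchClassifier(n_trees=10).fit(X, y)
        assert score_candidates(clf, []) == []


class TestBuildTrainingSet:
    def test_centered_and_jittered_crops_labeled_with_own_poi(self, phantom_normal):
        img, gt = phantom_normal
        patches, labels = build_training_set([(img, gt)], n_jitter=4, seed=0)
        assert patches.shape[1:] == (100, 100)
        assert len(patches) == 9 * 5  # 1 centered + 4 jittered per PoI
        assert sorted(set(labels.tolist())) == list(range(1, 10))

    def test_background_class_sampled_away_from_landmarks(self, phantom_normal):
        img, gt = phantom_normal
        patches, labels = build_training_set(
            [(img, gt)], n_jitter=1, include_background=True, n_background=5, seed=0
        )
        assert (labels == 0).sum() == 5


class TestEndToEndSelection:
    def test_selected_landmarks_beat_random_qualifying_candidates(self):
        """Classifier re-ranking must localize better than chance.

        Over 50 phantoms, the mean localization score of the selected
        landmark must exceed the mean over uniformly random qualifying
        candidates for the same PoI.
        """
        from flatfoot.phantom import sample_dataset, build_templates
        from flatfoot.template_matching import ImageMatcher, find_candidates, localization_score
        from flatfoot.poi_selection import build_training_set
        from flatfoot.angle_geometry import poi_center

        train, _ = sample_dataset({"normal": 2, "mild": 2, "moderate": 2}, seed=51)
        library = build_templates(train)
        patches, labels = build_training_set(train, seed=42)
        clf = PoIPatchClassifier(n_trees=50).fit(patches, labels)

        test, _ = sample_dataset({"normal": 17, "mild": 17, "moderate": 16}, seed=52)
        rng = np.random.default_rng(0)
        sel_scores, rand_scores = [], []
        for img, gt in test:
            pixels = np.asarray(img.pixels, float)
            matcher = ImageMatcher(pixels, dtype=np.float32)
            for poi_id in range(1, 10):
                cands = []
                for smap in matcher.score_many(library.templates_for(poi_id, limit=2)):
                    cands.extend(find_candidates(smap, poi_id=poi_id, top_k=25))
                if not cands:
                    continue
                for c in cands:
                    sx, sy = c.start
                    c.patch = pixels[sy : sy + 100, sx : sx + 100]
                score_candidates(clf, cands)
                chosen = select_best(cands, poi_id)
                gt_pt = gt.landmark_points[poi_id]
                sel_scores.append(localization_score(gt_pt, chosen.point))
                random_c = cands[rng.integers(len(cands))]
                rand_scores.append(localization_score(gt_pt, poi_center(random_c.start)))
        assert len(sel_scores) >= 100
        assert np.mean(sel_scores) > np.mean(rand_scores)
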