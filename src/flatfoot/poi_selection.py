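"""Candidate re-ranking: one landmark per PoI by classifier likelihood.

Template matching returns many near-threshold patches per PoI; a
patch classifier trained on landmark-centered crops assigns each
candidate a probability of belonging to its own PoI class, and the
candidate with the highest likelihood wins (exact ties go to the first
candidate in row-major scan order). The winning patch's center —
start + 50 px on each axis — is the landmark.

The classifier is a scikit-learn style estimator over deterministic patch
features (see :mod:`flatfoot.features`); the default backend is a random
forest with 100 trees and random state 42, matching the configuration that
graded best. Training patches are ground-truth-centered crops plus
jittered copies (default +-8 px) so the forest tolerates the few-pixel
slack of thresholded matches. An optional background class (random
non-landmark crops) can be enabled for rejection-style training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .features import extract_features_batch
from .template_matching import POI_IDS, TEMPLATE_SIZE, CandidatePatch

__all__ = [
    "PoIPatchClassifier",
    "PoILandmark",
    "MissingLandmarkError",
    "train_poi_classifier",
    "score_candidates",
    "select_best",
    "build_training_set",
    "BACKGROUND_CLASS",
]

#: Label used for optional non-landmark training patches.
BACKGROUND_CLASS = 0


class MissingLandmarkError(RuntimeError):
    """A PoI ended up with no candidates; diagnosis cannot proceed."""

    def __init__(self, poi_id: int, image_id: str = ""):
        self.poi_id = poi_id
        self.image_id = image_id
        where = f" on image {image_id!r}" if image_id else ""
        super().__init__(f"no qualifying candidate for PoI{poi_id}{where}")


@dataclass(frozen=True)
class PoILandmark:
    """A resolved landmark: PoI identity, pixel point, winning likelihood."""

    poi_id: int
    point: tuple[float, float]
    likelihood: float = float("nan")


class PoIPatchClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass patch classifier over the nine PoI identities.

    Parameters
    ----------
    backend : {"random_forest", "mlp_small"}
        Classifier family. The random forest is the default and the
        reference configuration; ``mlp_small`` is a compact neural
        alternative for comparisons.
    n_trees : int
        Forest size (random forest backend only).
    random_state : int
        Seed; identical data and seed give identical predictions.
    feature_backend : str
        Patch feature extractor registered in :mod:`flatfoot.features`.

    ``fit`` accepts either raw patches with shape (n, 100, 100) or
    precomputed feature matrices with shape (n, n_features).
    """

    def __init__(
        self,
        backend: str = "random_forest",
        n_trees: int = 100,
        random_state: int = 42,
        feature_backend: str = "grid_hog",
    ):
        self.backend = backend
        self.n_trees = n_trees
        self.random_state = random_state
        self.feature_backend = feature_backend

    def _make_model(self):
        if self.backend == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.random_state
            )
        if self.backend == "mlp_small":
            return MLPClassifier(
                hidden_layer_sizes=(128, 128),
                max_iter=400,
                random_state=self.random_state,
            )
        raise ValueError(f"unknown classifier backend {self.backend!r}")

    def _featurize(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            if X.shape[1:] != (TEMPLATE_SIZE, TEMPLATE_SIZE):
                raise ValueError(
                    f"patches must be (n, {TEMPLATE_SIZE}, {TEMPLATE_SIZE}), got {X.shape}"
                )
            return extract_features_batch(X, backend=self.feature_backend)
        if X.ndim == 2:
            return X
        raise ValueError(f"X must be 2-D features or 3-D patches, got ndim={X.ndim}")

    def fit(self, X, y):
        F = self._featurize(X)
        y = np.asarray(y)
        present = set(int(c) for c in np.unique(y))
        missing = [p for p in POI_IDS if p not in present]
        if missing:
            raise ValueError(
                f"training set lacks examples for poi_ids {missing}; every PoI "
                "class needs at least one (ideally >= 2) labeled patch"
            )
        self.model_ = self._make_model().fit(F, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = F.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._featurize(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(self._featurize(X))

    def class_index(self, poi_id: int) -> int:
        check_is_fitted(self, "model_")
        idx = np.nonzero(self.classes_ == poi_id)[0]
        if idx.size == 0:
            raise ValueError(f"classifier was not trained with class {poi_id}")
        return int(idx[0])


def build_training_set(
    dataset,
    jitter_radius: int = 8,
    n_jitter: int = 8,
    include_background: bool = False,
    n_background: int = 9,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Landmark-centered crops plus jittered copies from annotated images.

    ``dataset`` is an iterable of ``(Radiograph, landmarks)`` where
    landmarks maps poi_id -> (x, y) (a GroundTruth object with a
    ``.landmarks`` attribute also works). Each landmark yields one
    centered crop and ``n_jitter`` crops offset uniformly within
    ``+-jitter_radius`` px, labeled with the landmark's own PoI; optional
    background crops are sampled away from every landmark and labeled
    :data:`BACKGROUND_CLASS`. Returns ``(patches, labels)``.
    """
    rng = np.random.default_rng(seed)
    half = TEMPLATE_SIZE // 2
    patches: list[np.ndarray] = []
    labels: list[int] = []
    for img, landmarks in dataset:
        pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
        lm = getattr(landmarks, "landmark_points", None)
        if lm is None:
            lm = {int(l.poi_id): tuple(l.point) for l in landmarks} if not isinstance(
                landmarks, dict
            ) else landmarks
        H, W = pixels.shape
        pts = []
        for poi_id, (x, y) in lm.items():
            offsets = [(0, 0)] + [
                tuple(rng.integers(-jitter_radius, jitter_radius + 1, size=2))
                for _ in range(n_jitter)
            ]
            for dx, dy in offsets:
                sx = int(round(x)) + int(dx) - half
                sy = int(round(y)) + int(dy) - half
                if sx < 0 or sy < 0 or sx + TEMPLATE_SIZE > W or sy + TEMPLATE_SIZE > H:
                    continue
                patches.append(pixels[sy : sy + TEMPLATE_SIZE, sx : sx + TEMPLATE_SIZE].copy())
                labels.append(int(poi_id))
            pts.append((x, y))
        if include_background:
            made = 0
            for _ in range(50 * n_background):
                if made >= n_background:
                    break
                sx = int(rng.integers(0, W - TEMPLATE_SIZE + 1))
                sy = int(rng.integers(0, H - TEMPLATE_SIZE + 1))
                cx, cy = sx + half, sy + half
                if all(np.hypot(cx - x, cy - y) > 2 * jitter_radius for x, y in pts):
                    patches.append(
                        pixels[sy : sy + TEMPLATE_SIZE, sx : sx + TEMPLATE_SIZE].copy()
                    )
                    labels.append(BACKGROUND_CLASS)
                    made += 1
    return np.asarray(patches), np.asarray(labels)


def train_poi_classifier(training_set, config: dict | None = None) -> PoIPatchClassifier:
    """Fit a :class:`PoIPatchClassifier` on ``(patch, poi_id)`` pairs."""
    config = config or {}
    patches = np.asarray([p for p, _ in training_set], dtype=np.float64)
    labels = np.asarray([int(c) for _, c in training_set])
    return PoIPatchClassifier(**config).fit(patches, labels)


def score_candidates(
    clf: PoIPatchClassifier, cands: list[CandidatePatch]
) -> list[CandidatePatch]:
    """Fill each candidate's likelihood with P(own PoI class | patch)."""
    check_is_fitted(clf, "model_")
    if not cands:
        return cands
    for c in cands:
        if c.patch is None:
            raise ValueError(
                f"candidate at {c.start} carries no pixel patch; rerun "
                "find_candidates with the source image"
            )
    proba = clf.predict_proba(np.asarray([c.patch for c in cands]))
    for c, row in zip(cands, proba):
        c.likelihood = float(row[clf.class_index(c.poi_id)])
    return cands


def select_best(cands: list[CandidatePatch], poi_id: int, image_id: str = "") -> PoILandmark:
    """Pick the candidate with the highest likelihood for one PoI.

    Exact likelihood ties are broken by the original row-major scan order
    (the first candidate wins); the landmark is the patch center,
    start + (50, 50). No candidates -> :class:`MissingLandmarkError`.
    """
    mine = [c for c in cands if c.poi_id == poi_id]
    if not mine:
        raise MissingLandmarkError(poi_id, image_id)
    best = mine[0]
    for c in mine[1:]:
        lik_c = c.likelihood if c.likelihood is not None else float("-inf")
        lik_b = best.likelihood if best.likelihood is not None else float("-inf")
        if lik_c > lik_b:  # strict: equal keeps the earlier candidate
            best = c
    from .angle_geometry import poi_center

    return PoILandmark(
        poi_id=poi_id,
        point=poi_center((float(best.start[0]), float(best.start[1]))),
        likelihood=best.likelihood if best.likelihood is not None else float("nan"),
    )
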