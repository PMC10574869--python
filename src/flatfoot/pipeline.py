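"""End-to-end diagnosis: standardize -> match -> select -> measure -> vote.

:class:`FlatFootDiagnoser` is a scikit-learn style estimator wrapping the
whole method. ``fit`` takes annotated radiographs (image + nine landmark
coordinates): it crops the per-PoI template library and trains the patch
classifier on jittered landmark crops. ``predict`` runs the two-stage
method on new radiographs — template matching proposes candidate patches
per PoI, the classifier picks one, the patch centers become landmarks,
the three clinical angles are measured and graded, and the majority vote
yields the final class. ``diagnose`` returns the full audit bundle
(landmarks, angles, votes, flags) for one image.

Module-level functions (:func:`run_diagnosis`, :func:`evaluate_dataset`)
are thin wrappers over the estimator for script use.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, asdict


import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import diagnosis as dx
from .angle_geometry import DegenerateGeometryError, measure_all
from .diagnosis import DEFAULT_INTERVALS, AngleIntervalTable
from .evaluation import (
    confusion,
    class_metrics,
    macro_average,
    overall_accuracy,
    per_angle_error_rates,
)
from .imaging import CANONICAL_SIZE, Radiograph, orient, standardize
from .poi_selection import (
    MissingLandmarkError,
    PoILandmark,
    PoIPatchClassifier,
    build_training_set,
    score_candidates,
    select_best,
)
from .template_matching import (
    POI_IDS,
    ImageMatcher,
    TemplateLibrary,
    find_candidates,
)
from .phantom import build_templates

__all__ = ["PipelineConfig", "FlatFootDiagnoser", "run_diagnosis", "evaluate_dataset"]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable knobs of a pipeline run; embedded verbatim in outputs."""

    canonical_size: int = CANONICAL_SIZE
    matching_threshold: float = 0.90
    top_k: int | None = 50
    max_templates_per_poi: int | None = None
    min_separation: int = 0
    classifier_backend: str = "random_forest"
    n_trees: int = 100
    random_state: int = 42
    feature_backend: str = "grid_hog"
    jitter_radius: int = 8
    n_jitter: int = 8
    include_background: bool = False
    assume_left: bool = False
    intensity_method: str = "none"
    tie_break_priority: tuple[str, ...] = dx.TIE_BREAK_PRIORITY

    def to_json(self) -> str:
        d = asdict(self)
        d["tie_break_priority"] = list(d["tie_break_priority"])
        return json.dumps(d, indent=2, sort_keys=True)


class FlatFootDiagnoser(BaseEstimator):
    """Template-matching + classifier flat-foot severity grader.

    Parameters mirror :class:`PipelineConfig` (use ``get_params`` /
    ``set_params`` for sklearn-style configuration). Fitted attributes:

    ``templates_``
        Per-PoI template library cropped from the training images.
    ``classifier_``
        Fitted :class:`~flatfoot.poi_selection.PoIPatchClassifier`.
    """

    def __init__(
        self,
        canonical_size: int = CANONICAL_SIZE,
        matching_threshold: float = 0.90,
        top_k: int | None = 50,
        max_templates_per_poi: int | None = None,
        min_separation: int = 0,
        classifier_backend: str = "random_forest",
        n_trees: int = 100,
        random_state: int = 42,
        feature_backend: str = "grid_hog",
        jitter_radius: int = 8,
        n_jitter: int = 8,
        include_background: bool = False,
        assume_left: bool = False,
        intensity_method: str = "none",
        interval_table: AngleIntervalTable = DEFAULT_INTERVALS,
    ):
        self.canonical_size = canonical_size
        self.matching_threshold = matching_threshold
        self.top_k = top_k
        self.max_templates_per_poi = max_templates_per_poi
        self.min_separation = min_separation
        self.classifier_backend = classifier_backend
        self.n_trees = n_trees
        self.random_state = random_state
        self.feature_backend = feature_backend
        self.jitter_radius = jitter_radius
        self.n_jitter = n_jitter
        self.include_background = include_background
        self.assume_left = assume_left
        self.intensity_method = intensity_method
        self.interval_table = interval_table

    # -- training ---------------------------------------------------------

    def fit(self, X, y=None):
        """Build templates and train the patch classifier.

        ``X`` is a sequence of ``(Radiograph, ground_truth)`` pairs where
        the ground truth exposes ``landmark_points`` (poi_id -> (x, y));
        ``y`` is unused (landmark supervision lives in ``X``).
        """
        data = list(X)
        if not data:
            raise ValueError("cannot fit on an empty training set")
        self.templates_ = build_templates(data)
        patches, labels = build_training_set(
            ((img, gt) for img, gt in data),
            jitter_radius=self.jitter_radius,
            n_jitter=self.n_jitter,
            include_background=self.include_background,
            seed=self.random_state,
        )
        self.classifier_ = PoIPatchClassifier(
            backend=self.classifier_backend,
            n_trees=self.n_trees,
            random_state=self.random_state,
            feature_backend=self.feature_backend,
        ).fit(patches, labels)
        return self

    def set_pretrained(self, templates: TemplateLibrary, classifier: PoIPatchClassifier):
        """Adopt an existing template library and fitted classifier."""
        self.templates_ = templates
        self.classifier_ = classifier
        return self

    # -- inference --------------------------------------------------------

    def _standardized(self, img: Radiograph) -> Radiograph:
        from .imaging import adjust_intensity

        img = standardize(img, self.canonical_size)
        img = orient(img, assume_left=self.assume_left)
        return adjust_intensity(img, method=self.intensity_method)

    def locate_landmarks(self, img: Radiograph) -> list[PoILandmark]:
        """Run matching + classifier selection; returns nine landmarks.

        Raises :class:`MissingLandmarkError` naming the PoI if no
        candidate clears the matching threshold for it.
        """
        check_is_fitted(self, "classifier_")
        img = self._standardized(img)
        pixels = np.asarray(img.pixels, dtype=np.float64)
        # single-precision matching: ample for 8-bit data at a 0.90 gate
        matcher = ImageMatcher(pixels, dtype=np.float32)
        landmarks = []
        for poi_id in POI_IDS:
            cands = []
            tmpls = self.templates_.templates_for(poi_id, self.max_templates_per_poi)
            for smap in matcher.score_many(tmpls):
                cands.extend(
                    find_candidates(
                        smap,
                        poi_id=poi_id,
                        threshold=self.matching_threshold,
                        top_k=self.top_k,
                        min_separation=self.min_separation,
                    )
                )
            if self.top_k is not None and len(cands) > self.top_k:
                # merged across templates: keep the overall best, stable order
                order = sorted(
                    range(len(cands)),
                    key=lambda i: (-cands[i].similarity, i),
                )[: self.top_k]
                cands = [cands[i] for i in sorted(order)]
            if not cands:
                raise MissingLandmarkError(poi_id, img.image_id)
            for c in cands:  # cut pixels only for the capped survivors
                sx, sy = c.start
                c.patch = pixels[sy : sy + 100, sx : sx + 100].copy()
            score_candidates(self.classifier_, cands)
            landmarks.append(select_best(cands, poi_id, image_id=img.image_id))
        return landmarks

    def diagnose(self, img: Radiograph, oracle_landmarks=None) -> dict:
        """Full audit bundle for one image.

        ``oracle_landmarks`` (poi_id -> (x, y)) substitutes perfect
        landmarks for the matching + classifier stage — the upper-bound
        control used in evaluation.
        """
        if oracle_landmarks is not None:
            landmarks = [
                PoILandmark(poi_id=k, point=tuple(map(float, oracle_landmarks[k])), likelihood=1.0)
                for k in POI_IDS
            ]
        else:
            landmarks = self.locate_landmarks(img)
        angles = measure_all(landmarks)
        votes: dict[str, str] = {}
        flags: list[str] = []
        for name, value in angles.as_dict().items():
            cls, flag = dx.classify_angle(name, value, self.interval_table)
            votes[name] = cls
            if flag:
                flags.append(flag)
        result = dx.majority_vote(votes, flags=tuple(flags))
        return {
            "image_id": img.image_id,
            "landmarks": landmarks,
            "angles": angles,
            "diagnosis": result,
        }

    def predict(self, X) -> np.ndarray:
        """Final foot class per radiograph in ``X``."""
        return np.asarray([self.diagnose(img)["diagnosis"].final for img in X])


def run_diagnosis(
    img: Radiograph,
    templates: TemplateLibrary,
    clf: PoIPatchClassifier,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict:
    """One-shot functional entry point over a pre-built model."""
    est = FlatFootDiagnoser(
        **{
            f.name: getattr(cfg, f.name)
            for f in dataclasses.fields(cfg)
            if f.name not in ("tie_break_priority",)
        }
    ).set_pretrained(templates, clf)
    return est.diagnose(img)


def evaluate_dataset(
    dataset,
    estimator: FlatFootDiagnoser,
    use_oracle_landmarks: bool = False,
) -> dict:
    """Run the pipeline over an annotated dataset and build a metrics report.

    ``dataset`` is an iterable of ``(Radiograph, GroundTruth)``. Per-image
    failures (missing landmark, degenerate geometry) are recorded and
    excluded; one bad image never aborts the run. The report contains
    per-class one-vs-rest metrics, per-angle one-vs-rest error rates, the
    overall (mean per-angle) accuracy, the final-diagnosis accuracy, and
    the mean localization score of the selected landmarks.
    """
    from .template_matching import localization_score

    records = []
    failures = []
    for img, gt in dataset:
        try:
            bundle = estimator.diagnose(
                img, oracle_landmarks=gt.landmark_points if use_oracle_landmarks else None
            )
        except (MissingLandmarkError, DegenerateGeometryError) as exc:
            failures.append({"image_id": img.image_id, "error": str(exc)})
            continue
        loc_scores = [
            localization_score(gt.landmark_points[lm.poi_id], lm.point)
            for lm in bundle["landmarks"]
        ]
        records.append(
            {
                "image_id": img.image_id,
                "truth": gt.class_label,
                "final": bundle["diagnosis"].final,
                "votes": bundle["diagnosis"].votes,
                "angles": bundle["angles"],
                "gt_angles": gt.angles,
                "mean_localization": float(np.mean(loc_scores)),
            }
        )
    if not records:
        raise ValueError("no image in the dataset was successfully diagnosed")
    truth = [r["truth"] for r in records]
    final = [r["final"] for r in records]
    per_angle = {a: [r["votes"][a] for r in records] for a in ("CIA", "AA", "MA")}
    classes = tuple(c for c in (dx.NORMAL, dx.MILD, dx.MODERATE) if c in set(truth) | set(final))
    cs = confusion(final, truth, classes=classes)
    per_class = {c: class_metrics(cs, c) for c in classes}
    angle_errors = {c: per_angle_error_rates(per_angle, truth, c) for c in classes}
    final_acc = 100.0 * sum(p == t for p, t in zip(final, truth)) / len(truth)
    mean_acc, _ = macro_average([per_class[c]["accuracy"] for c in classes])
    return {
        "n_images": len(records),
        "n_failures": len(failures),
        "failures": failures,
        "per_class_metrics": per_class,
        "per_angle_error_rates": angle_errors,
        "overall_accuracy_pct": overall_accuracy(per_angle, truth),
        "final_diagnosis_accuracy_pct": final_acc,
        "mean_one_vs_rest_accuracy_pct": mean_acc,
        "mean_localization_score": float(np.mean([r["mean_localization"] for r in records])),
        "records": records,
    }
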