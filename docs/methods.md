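# Methods

`flatfoot` grades the severity of pes planus (flat foot) from a lateral
weight-bearing foot radiograph. This note describes the model the package
implements, the choices that were genuinely open, the synthetic phantoms
used to validate it, and what the validation does and does not show.

## The measurement model

Severity grading rests on three clinical angles drawn between nine
anatomical points of interest (PoIs) on the lateral view:

| # | PoI | Bone |
|---|-----|------|
| 1, 2 | posterior / anterior axis points | first metatarsal |
| 3, 4 | posterior / anterior inferior points | fifth metatarsal |
| 5, 6 | posterior / anterior inferior points | calcaneus |
| 7, 8 | posterior / anterior axis points | talus |
| 9 | center | sesamoid |

All coordinates are 0-based raster coordinates: `x` = column (rightward),
`y` = row (downward), origin top-left. The canonical orientation is a
left foot; right-foot images are mirrored on input.

**Calcaneal Inclination Angle (CIA)** — acute angle between the calcaneal
inferior line (PoI5→PoI6) and the base line from the posterior calcaneus
to the sesamoid (PoI5→PoI9). A healthy heel is pitched 20–30° above its
base; flattening lowers it.

**Meary's Angle (MA)** — acute angle between the talar axis (PoI7→PoI8)
and the first-metatarsal axis (PoI1→PoI2). In a healthy foot the two are
nearly collinear (MA < 4°); the midfoot break of a flat foot opens it.

Both are computed from line slopes `m = (y2−y1)/(x2−x1)` via
`θ = arctan(|m2−m1| / |1+m1·m2|)`, with vertical lines handled through
the perpendicular complement and `1+m1·m2 = 0` mapping to exactly 90°.

**Arch Angle (AA)** — the angle between the calcaneal inferior line and
the fifth-metatarsal inferior line (PoI3→PoI4). Its grading intervals
extend to 180° and beyond (a collapsed, reflex arch), which no acute-angle
formula can express, so AA is computed as a signed directed angle:

    AA = 180° − atan2(u×v, u·v),   u = PoI5→PoI6,  v = PoI3→PoI4

The sign convention is frozen in one constant (`angle_geometry.AA_SIGN`):
a raised arch — apex above the heel–toe chord, i.e. smaller raster `y` —
gives AA < 180°, a collapsed arch AA ≥ 180°. The phantom generator uses
the same constant, so generated and measured arch angles agree by
construction rather than by coincidence.

### Grading intervals

| angle | normal | mild | moderate |
|-------|--------|------|----------|
| CIA | 20 ≤ a ≤ 30 | 10 ≤ a < 20 | a < 10 |
| AA | 150 ≤ a ≤ 165 | 165 < a < 180 | a ≥ 180 |
| MA | 0 ≤ a < 4 | 4 ≤ a < 15 | a ≥ 15 |

Two published gaps are closed deliberately: AA's mild interval is the full
open interval (165, 180), and MA's mild interval runs up to (not
including) the moderate bound at 15. Values on the healthy side of every
interval (cavus-direction CIA > 30, AA < 150, MA < 0) are outside the
method's scope; they are mapped to the nearest interval's class and
*flagged*, never silently graded. Severe/rigid flat foot is not a class.

### Majority vote

Each angle casts one vote; the class with the most votes wins. A 1-1-1
split is broken by per-angle reliability, CIA > MA > AA — CIA grades most
reliably and AA least (AA is also the angle whose published interval
needed gap resolution) — so the CIA's vote wins a three-way tie. Tallies
are literal vote counts.

## Landmark localization

**Template matching.** Each PoI owns a library of 100×100-px templates
cropped so the PoI sits at the exact patch center. A template slides over
the radiograph; each start position `(Sx, Sy)` is scored with the
normalized squared difference

    R = Σ(T − I)² / sqrt(ΣT² · ΣI²)

(0 = perfect). Similarity is `1 − R`, so the default acceptance threshold
0.90 reads as "≥ 90% match". Implementation: FFT cross-correlation plus
cumulative-sum window energies — algebraically identical to the sliding
window, checked against a brute-force double loop at 1e−9 in the tests.
Zero-energy windows (blank background under the template) score R = 1
with a warning; ratios above 1 (possible for energy-mismatched windows)
saturate at 1, which is irrelevant to thresholding at R ≤ 0.1. The
full-resolution pipeline matches in single precision (differences from
float64 are ~1e−6, three orders below anything the 0.90 gate can see);
the public `score_map` stays float64.

**Candidate selection.** All starts above threshold become candidates,
kept in row-major scan order, capped at `top_k` (default 50) by
similarity. A patch classifier then assigns each candidate the
probability of belonging to its own PoI class; the highest-probability
candidate wins, with exact ties going to the first candidate in scan
order (ties compare exactly — the rule is positional, not numeric). The
winning patch center, start + (50, 50), is the landmark. A PoI with no
qualifying candidate raises a typed missing-landmark error naming the
PoI; the pipeline never emits a diagnosis from fewer than nine landmarks.

**Features and classifier.** The default feature vector is deterministic
and self-contained: a 16×16 block-mean intensity grid over the central
96×96 px (256 values) concatenated with an 8-bin unsigned
gradient-orientation histogram per cell of a 4×4 grid (128 values), each
block L2-normalized. The classifier is a 9-class random forest, 100
trees, random state 42 — the reference configuration — trained on
landmark-centered crops plus 8 copies jittered within ±8 px, so the
forest tolerates the few-pixel slack of thresholded matches. The ±8-px
jitter radius matches the localization slack the templates themselves
admit; it is the label-noise scale, not a tuning knob. Alternative
backends exist behind the same interface: a small MLP, an optional
background class for rejection training (off by default — how negatives
were mined for the reference model is not documented anywhere, so neither
behaviour is baked in), and a hook for external CNN features
(off by default; the default path needs no downloaded weights).

When a template library holds many near-duplicate templates per PoI, the
pipeline can cap how many it matches (`max_templates_per_poi`, evenly
spaced over the library to preserve class diversity). The default is no
cap: matching every template costs ~9 s per 1024² image on one CPU and is
the most robust setting; the cap exists for interactive use.

## The phantom generator

Real weight-bearing radiographs with expert landmark annotations are not
publicly shareable, so validation runs on synthetic phantoms: 1024×1024
8-bit images with five stylized bright "bones" (calcaneus wedge, talus /
first-metatarsal / fifth-metatarsal capsules with bulbous metatarsal
heads, sesamoid blob) on black background. The construction starts from
requested angles: the base line gets a small sampled tilt (±2.5°), the
calcaneal line rises at CIA above it, the fifth-metatarsal line is the
calcaneal direction turned by 180 − AA (same `AA_SIGN` convention), and
the first-metatarsal axis is the talar axis (declination sampled 17–23°)
turned by MA. The nine landmarks are the construction's endpoints, so
ground truth is exact; lengths and positions carry small uniform jitter
so no two phantoms are congruent.

Rendering choices that matter:

* each bone has a distinct intensity band, an along-axis intensity ramp
  and a long-wavelength (40–62 px) sinusoidal striation, so patches
  around different PoIs are discriminable by the classifier. The
  striation wavelengths are deliberately long: real trabecular texture is
  smooth at the 100-px patch scale, and short wavelengths would make the
  squared-difference score collapse under the few-degree orientation
  differences that exist between any two feet;
* the sesamoid sits on the base ray from PoI5 at an offset that keeps it
  clear of the fifth-metatarsal head's patch, mirroring its anatomical
  position under the metatarsal heads;
* degradation: Gaussian blur (sd 2.5 px — focal-spot/detector blur plus
  soft-tissue scatter) and additive Gaussian noise (sd 4 intensity
  units — quantum mottle), both configurable and zero-able for exact
  tests.

Class-targeted phantoms sample all three angles inside the target class's
grading interval, with a margin of roughly 15% of the interval width
(open-ended moderate tails capped at geometrically sensible values:
CIA ≥ 3°, AA ≤ 192°, MA ≤ 24°). A phantom is therefore an unambiguous
exemplar of its class — the role a curated, expert-annotated teaching set
plays for real data — and all three ground-truth angles classify to the
class label, so majority voting on perfect landmarks is unanimous by
construction (this invariant is tested, and makes the oracle-landmark
control's 100% accuracy a theorem rather than an observation).

**Augmentation** draws a rotation in ±15° and a scale in [1, 1.5] about
the image center, maps landmarks with the same similarity transform
(which preserves every angle between lines — ground-truth angles carry
over unchanged), and re-renders with bilinear interpolation on black.
Draws that push a landmark out of the template-safe frame are rejected
and redrawn (bounded retries), so the effective scale distribution thins
near ×1.5 for far-from-center landmarks.

### What the phantoms do not show

Phantoms are geometric, not radiological: no soft tissue, no bone
superposition beyond simple overlap, no exposure variation, no
inter-annotator disagreement, and bone shapes far simpler than real
anatomy. Passing on phantoms validates the *machinery* — matcher
exactness, angle algebra, interval logic, vote fusion, the end-to-end
data path — and shows the method recovers known geometry under noise,
blur and appearance variation of the kind it creates. It does not
estimate clinical accuracy on hospital data, which depends on template
curation and patient variability the phantoms cannot represent.

## Evaluation machinery

Metrics are one-vs-rest per class from TP/FP/FN/TN tallies, on the
percent scale (F-score also 0–100): precision, recall, specificity,
accuracy, F-score, error rate. Zero-denominator metrics return an
explicit undefined marker (`None`), and averages skip and count them —
silently coercing to 0 would bias small-sample reports. (One deliberate
exception: when precision and recall are both defined and both zero, the
F-score is 0 — the harmonic-mean limit — rather than undefined.) The overall
accuracy of a three-angle run is the mean of the three per-angle accuracy
percentages (per-angle accuracy first, then the mean — pooling before
averaging would weight angles unevenly when lists differ). Ten-fold
cross-validation uses a seeded shuffled split with fold sizes differing
by at most one. The threshold sweep re-runs matching over thresholds
0.50–0.95 and reports the mean localization score `1/(1+d)` (d =
Euclidean distance to ground truth) of the rank-1 match per PoI; since
score maps do not depend on the threshold, the sweep matches once and
filters per level, asserting on the way that candidate counts never
increase with a stricter threshold.

## Problem sizes

The shipped validation runs at desk scale, chosen so the whole suite and
the acceptance script each complete comfortably on one CPU: the
end-to-end experiment uses 20 training phantoms (templates + classifier)
and 60 disjoint evaluation phantoms; angle recovery uses 100 phantoms;
the sweep uses a 3-phantom template source and 10 evaluation phantoms.
At this scale the end-to-end run achieves 100% final-diagnosis accuracy
with zero missing-landmark failures at the suite's fixed seeds, and the
mid-90s across other seeds (an occasional image loses one PoI to the
0.90 matching gate and is counted as wrong); the acceptance gate is
≥ 90%. Larger phantom populations change runtime, not the machinery
being validated.

## Numerical and degenerate-input policy

* Slopes of vertical lines are `inf`, handled via the perpendicular
  complement; coincident landmarks raise a degenerate-geometry error
  naming the PoIs rather than producing NaN angles.
* Angles are floats end to end; rounding (2 dp) happens only in reports.
* Landmark coordinates stay real-valued in memory; only template crops
  and integer-pixel manifests round.
* Standardization pads with intensity 0 (black background) and uses
  floor-division center offsets; it never resamples, so pixel geometry —
  and therefore every angle — is exactly preserved.
* Per-phantom seeds are spawned from one master seed; every random draw
  in the package flows through a seeded generator, and identical seeds
  reproduce bit-identical images, manifests and predictions.

## Known limitations

* Laterality must be supplied (flag or manifest); it is never inferred
  from pixels.
* The matcher is single-scale and rotation-sensitive by design; the
  template library carries the appearance diversity. Feet imaged at
  strongly non-standard magnification or rotation would need the
  augmentation path or a rescaled library.
* DICOM ingestion, severe/rigid flat foot, and pediatric feet are out of
  scope.
* AA's directed-angle extension is this package's documented resolution
  of intervals that reach beyond 90°; other software may report the
  unsigned supplement instead.
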