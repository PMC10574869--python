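"""Synthetic lateral-foot radiograph phantoms with exact ground truth.

Real weight-bearing foot radiographs (and their expert annotations) are
not publicly shareable, so the package ships a phantom generator: it
renders five stylized bright "bones" — calcaneus, talus, first
metatarsal, fifth metatarsal, sesamoid — on a black 1024x1024 background
at orientations constructed directly from requested clinical angles.
Because the nine landmark points ARE the construction's endpoints, the
ground-truth Calcaneal Inclination Angle, Arch Angle and Meary's Angle
are known exactly, and every stage of the pipeline (matching, selection,
measurement, grading) can be tested end to end without patient data.

Geometry (raster coordinates, toes pointing right; the canonical
orientation the rest of the pipeline assumes):

* the sesamoid base line runs from the posterior-inferior calcaneus
  point (PoI5) to the sesamoid (PoI9) at a small sampled tilt;
* the calcaneal inferior line PoI5->PoI6 rises anteriorly at CIA above
  that base line;
* the fifth-metatarsal inferior line PoI3->PoI4 is the calcaneal
  direction turned by 180 - AA (the same frozen sign convention as
  :func:`flatfoot.angle_geometry.measure_aa`, so a raised arch has
  AA < 180 and a collapsed one AA >= 180);
* the talar axis PoI7->PoI8 points anterior-inferior and the
  first-metatarsal axis PoI1->PoI2 is that axis turned by MA.

Each bone gets a distinct intensity band, an along-axis intensity ramp
and a sinusoidal striation so that 100x100 patches around different PoIs
are discriminable by the patch classifier. Gaussian blur (default
sd 2.5 px, mimicking focal-spot/detector and soft-tissue blur) and additive Gaussian
noise (default sd 4 intensity units, mimicking quantum mottle) complete
the render; both are configurable and may be zeroed for exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.transform import SimilarityTransform, warp

from . import diagnosis
from .angle_geometry import AA_SIGN, FootAngleSet, measure_all
from .imaging import CANONICAL_SIZE, Laterality, Radiograph
from .poi_selection import PoILandmark
from .template_matching import TEMPLATE_SIZE, POI_IDS, Template, TemplateLibrary

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "GenerationError",
    "CLASS_ANGLE_RANGES",
    "generate_phantom",
    "build_templates",
    "augment",
    "sample_dataset",
]

#: Margin (px) every landmark must keep from the frame border so a full
#: 100x100 template can be cropped around it.
SAFE_MARGIN = TEMPLATE_SIZE // 2 + 1

#: Per-class sampling ranges (degrees) for each angle. Each range sits in
#: the interior of its published grading interval with a margin of roughly
#: 15% of the interval width (open-ended moderate intervals are capped at
#: geometrically sensible values), so a phantom is an unambiguous exemplar
#: of its class the way a curated teaching set would be.
CLASS_ANGLE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    diagnosis.NORMAL: {"cia": (21.5, 28.5), "aa": (152.0, 163.0), "ma": (0.6, 3.4)},
    diagnosis.MILD: {"cia": (11.5, 18.5), "aa": (167.0, 178.0), "ma": (5.6, 13.4)},
    diagnosis.MODERATE: {"cia": (3.0, 8.5), "aa": (181.5, 192.0), "ma": (16.5, 24.0)},
}


class GenerationError(ValueError):
    """Requested geometry does not fit the frame."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom.

    Exactly one of ``target_class`` / ``angles`` drives the geometry:
    either the three angles are sampled inside the target class's grading
    intervals (so all three angles agree with the class label), or an
    explicit ``(cia_deg, aa_deg, ma_deg)`` triple is realized verbatim.
    """

    target_class: str | None = diagnosis.NORMAL
    angles: tuple[float, float, float] | None = None
    noise_sd: float = 4.0
    blur_sd: float = 2.5
    size: int = CANONICAL_SIZE
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Exact landmarks, angles and class label of one phantom."""

    landmarks: tuple[PoILandmark, ...]
    angles: FootAngleSet
    class_label: str
    image_id: str = ""

    @property
    def landmark_points(self) -> dict[int, tuple[float, float]]:
        return {lm.poi_id: lm.point for lm in self.landmarks}


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


def _sample_angles(spec: PhantomSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    if spec.angles is not None:
        return tuple(float(a) for a in spec.angles)  # type: ignore[return-value]
    if spec.target_class not in CLASS_ANGLE_RANGES:
        raise GenerationError(f"unknown target class {spec.target_class!r}")
    r = CLASS_ANGLE_RANGES[spec.target_class]
    return (
        float(rng.uniform(*r["cia"])),
        float(rng.uniform(*r["aa"])),
        float(rng.uniform(*r["ma"])),
    )


def _layout(
    cia: float, aa: float, ma: float, size: int, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Place the nine landmarks realizing (CIA, AA, MA) exactly.

    Polar angles are raster polar angles (positive = downward turn on
    screen). The base line is nearly horizontal; all other directions are
    derived from it and the requested angles.
    """
    scale = size / CANONICAL_SIZE
    j = lambda lo, hi: float(rng.uniform(lo, hi)) * scale  # noqa: E731
    beta = float(rng.uniform(-2.5, 2.5))  # base-line tilt, degrees

    p5 = np.array([j(200, 235), j(720, 750)])
    b_hat = _unit(beta)  # posterior -> anterior base direction
    u_hat = _unit(beta - cia)  # calcaneal inferior line, rising anteriorly
    # Arch Angle: AA = 180 - AA_SIGN * directed(u, v)  =>  turn by the residual
    v_hat = _unit((beta - cia) + AA_SIGN * (180.0 - aa))  # fifth metatarsal
    tau = float(rng.uniform(17.0, 23.0))  # talar axis declination
    t_hat = _unit(tau)
    m_hat = _unit(tau - ma)  # first metatarsal axis

    p6 = p5 + j(215, 235) * u_hat
    p3 = p6 + j(48, 62) * v_hat
    p4 = p3 + j(245, 265) * v_hat
    # Sesamoid on the base ray from PoI5, anterior to the fifth-metatarsal
    # head (it sits under the metatarsal heads). The offset keeps the blob
    # outside the 100-px patches of PoI4 so each patch sees one bone only,
    # and being on the base ray it never perturbs the CIA base direction.
    p9 = p5 + (float((p4 - p5) @ b_hat) + j(115, 130)) * b_hat
    p7 = p5 + np.array([j(160, 180), -j(185, 205)])
    p8 = p7 + j(138, 152) * t_hat
    p1 = p8 + j(48, 62) * m_hat
    p2 = p1 + j(225, 245) * m_hat

    pts = {1: p1, 2: p2, 3: p3, 4: p4, 5: p5, 6: p6, 7: p7, 8: p8, 9: p9}
    margin = SAFE_MARGIN * scale if scale < 1 else SAFE_MARGIN
    for poi_id, p in pts.items():
        if not (margin <= p[0] <= size - 1 - margin and margin <= p[1] <= size - 1 - margin):
            raise GenerationError(
                f"PoI{poi_id} at ({p[0]:.0f}, {p[1]:.0f}) leaves the usable frame "
                f"for angles (CIA={cia:.1f}, AA={aa:.1f}, MA={ma:.1f}); "
                "use a smaller scale or milder angles"
            )
    return pts


def _capsule_mask(
    shape: tuple[int, int], a: np.ndarray, b: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixels within ``radius`` of segment ab; returns (ys, xs, axial fraction)."""
    x0 = max(int(min(a[0], b[0]) - radius) - 1, 0)
    x1 = min(int(max(a[0], b[0]) + radius) + 2, shape[1])
    y0 = max(int(min(a[1], b[1]) - radius) - 1, 0)
    y1 = min(int(max(a[1], b[1]) + radius) + 2, shape[0])
    if x0 >= x1 or y0 >= y1:
        return np.array([], int), np.array([], int), np.array([])
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    ab = b - a
    denom = float(ab @ ab) or 1.0
    t = ((xs - a[0]) * ab[0] + (ys - a[1]) * ab[1]) / denom
    tc = np.clip(t, 0.0, 1.0)
    dx = xs - (a[0] + tc * ab[0])
    dy = ys - (a[1] + tc * ab[1])
    inside = dx * dx + dy * dy <= radius * radius
    return ys[inside], xs[inside], tc[inside]


def _paint_capsule(canvas, a, b, radius, base, ramp, stripe_period, stripe_amp):
    ys, xs, t = _capsule_mask(canvas.shape, np.asarray(a, float), np.asarray(b, float), radius)
    if ys.size == 0:
        return
    length = float(np.hypot(*(np.asarray(b, float) - np.asarray(a, float))))
    axial = t * length
    val = base + ramp * t + stripe_amp * np.sin(2 * np.pi * axial / stripe_period)
    np.maximum.at(canvas, (ys, xs), val)


def _render(pts: dict[int, np.ndarray], spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.size
    canvas = np.zeros((size, size), dtype=np.float64)
    scale = size / CANONICAL_SIZE

    # Calcaneus: rounded wedge whose inferior edge is exactly PoI5->PoI6.
    p5, p6 = pts[5], pts[6]
    u = p6 - p5
    u_hat = u / np.linalg.norm(u)
    n_hat = np.array([u_hat[1], -u_hat[0]])  # upward normal (smaller y)
    mid = (p5 + p6) / 2
    poly = np.array(
        [
            p5,
            p6,
            p6 + 45 * scale * n_hat,
            mid + 85 * scale * n_hat + 10 * scale * u_hat,
            p5 + 90 * scale * n_hat - 15 * scale * u_hat,
            p5 - 18 * scale * u_hat + 25 * scale * n_hat,
        ]
    )
    ry, rx = draw_polygon(poly[:, 1], poly[:, 0], shape=canvas.shape)
    axial = (rx - p5[0]) * u_hat[0] + (ry - p5[1]) * u_hat[1]
    span = float(np.linalg.norm(u)) or 1.0
    val = 188.0 + 26.0 * np.clip(axial / span, 0, 1) + 5.0 * np.sin(2 * np.pi * axial / (62 * scale))
    np.maximum.at(canvas, (ry, rx), val)

    # Shaft bones: capsules slightly longer than their landmark segments.
    # Striation wavelengths are long relative to the few-pixel misalignment
    # between phantoms, as the smooth trabecular texture of a real
    # radiograph would be — short wavelengths would make the squared
    # difference collapse under tiny rotations no real matcher sees.
    def ext(a, b, e):
        d = (b - a) / np.linalg.norm(b - a)
        return a - e * scale * d, b + e * scale * d

    a, b = ext(pts[7], pts[8], 24)
    _paint_capsule(canvas, a, b, 36 * scale, 158.0, -18.0, 45 * scale, 6.0)
    def head_bulb(center, radius, peak):
        # metatarsal heads are bulbous; the bulb anchors the distal PoI patch
        ry, rx = draw_disk((center[1], center[0]), radius * scale, shape=canvas.shape)
        r = np.hypot(rx - center[0], ry - center[1]) / (radius * scale)
        np.maximum.at(canvas, (ry, rx), peak - 22.0 * r * r)

    a, b = ext(pts[1], pts[2], 20)
    _paint_capsule(canvas, a, b, 27 * scale, 132.0, 22.0, 40 * scale, 5.0)
    head_bulb(b, 36, 156.0)
    a, b = ext(pts[3], pts[4], 20)
    _paint_capsule(canvas, a, b, 24 * scale, 104.0, 20.0, 55 * scale, 5.0)
    head_bulb(b, 36, 128.0)

    # Sesamoid: bright blob with a radial falloff.
    p9 = pts[9]
    ry, rx = draw_disk((p9[1], p9[0]), 30 * scale, shape=canvas.shape)
    r = np.hypot(rx - p9[0], ry - p9[1]) / (30 * scale)
    np.maximum.at(canvas, (ry, rx), 235.0 - 45.0 * r * r)

    if spec.blur_sd > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma=spec.blur_sd)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec) -> tuple[Radiograph, GroundTruth]:
    """Render one phantom radiograph with exact ground truth.

    Deterministic in ``spec.seed``: the same spec twice gives bit-identical
    pixels and landmarks. The ground-truth angles are re-measured from the
    constructed landmarks (not merely echoed), so the recorded values and
    the geometry cannot drift apart.
    """
    rng = np.random.default_rng(spec.seed)
    cia, aa, ma = _sample_angles(spec, rng)
    pts = _layout(cia, aa, ma, spec.size, rng)
    pixels = _render(pts, spec, rng)
    landmarks = tuple(
        PoILandmark(poi_id=k, point=(float(pts[k][0]), float(pts[k][1])), likelihood=1.0)
        for k in POI_IDS
    )
    angles = measure_all({k: pts[k] for k in POI_IDS})
    if spec.target_class is not None and spec.angles is None:
        label = spec.target_class
    else:
        label = diagnosis.diagnose_angles(angles).final
    image_id = f"phantom-{label}-{spec.seed}"
    img = Radiograph(pixels=pixels, laterality=Laterality.LEFT, image_id=image_id)
    return img, GroundTruth(landmarks=landmarks, angles=angles, class_label=label, image_id=image_id)


def build_templates(dataset, warn=None) -> TemplateLibrary:
    """Crop one 100x100 landmark-centered template per PoI per image.

    Crop start = landmark - (50, 50), so
    :func:`~flatfoot.angle_geometry.poi_center` of the start recovers the
    landmark. Landmarks too close to the border are skipped with a
    warning; a PoI left with zero templates is an error.
    """
    import warnings as _warnings

    lib = TemplateLibrary()
    half = TEMPLATE_SIZE // 2
    for img, gt in dataset:
        pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
        H, W = pixels.shape
        source = getattr(gt, "image_id", "") or getattr(img, "image_id", "")
        for poi_id, (x, y) in gt.landmark_points.items():
            sx, sy = int(round(x)) - half, int(round(y)) - half
            if sx < 0 or sy < 0 or sx + TEMPLATE_SIZE > W or sy + TEMPLATE_SIZE > H:
                (warn or _warnings.warn)(
                    f"PoI{poi_id} of {source!r} too close to the border; template skipped"
                )
                continue
            lib.add(
                Template(
                    poi_id=poi_id,
                    patch=pixels[sy : sy + TEMPLATE_SIZE, sx : sx + TEMPLATE_SIZE].copy(),
                    source_id=str(source),
                )
            )
    missing = [k for k in POI_IDS if k not in lib.poi_ids_covered()]
    if missing:
        raise GenerationError(f"template library has no patches for PoIs {missing}")
    return lib


def augment(
    img: Radiograph,
    gt: GroundTruth,
    rotation_range: tuple[float, float] = (-15.0, 15.0),
    max_scale: float = 1.5,
    seed: int = 0,
    max_retries: int = 25,
) -> tuple[Radiograph, GroundTruth]:
    """Random rotation and up-scaling about the image center.

    The rotation angle is drawn uniformly from ``rotation_range`` and the
    scale factor uniformly from [1, max_scale]; landmarks are mapped by the
    same similarity transform, which preserves every angle between lines,
    so the ground-truth angles carry over unchanged. Draws that push any
    landmark outside the template-safe frame are rejected and redrawn; a
    run of ``max_retries`` rejections is an error.
    """
    if not (-15.0 <= rotation_range[0] <= rotation_range[1] <= 15.0):
        raise GenerationError(f"rotation range {rotation_range} outside +-15 degrees")
    if not 1.0 <= max_scale <= 1.5:
        raise GenerationError(f"max_scale {max_scale} outside [1, 1.5]")
    rng = np.random.default_rng(seed)
    size = img.height
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    pts = gt.landmark_points
    for _ in range(max_retries):
        theta = float(rng.uniform(*rotation_range))
        s = float(rng.uniform(1.0, max_scale))
        rad = math.radians(theta)
        rot = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]])
        new_pts = {
            k: tuple(center + s * rot @ (np.asarray(p) - center)) for k, p in pts.items()
        }
        if all(
            SAFE_MARGIN <= p[0] <= size - 1 - SAFE_MARGIN
            and SAFE_MARGIN <= p[1] <= size - 1 - SAFE_MARGIN
            for p in new_pts.values()
        ):
            break
    else:
        raise GenerationError(
            f"augmentation rejected {max_retries} draws; geometry too close to the frame"
        )
    # Inverse map for warp: output pixel -> input pixel.
    tf = (
        SimilarityTransform(translation=-center)
        + SimilarityTransform(scale=s, rotation=rad)
        + SimilarityTransform(translation=center)
    )
    warped = warp(
        img.pixels.astype(np.float64),
        inverse_map=tf.inverse,
        output_shape=img.pixels.shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    new_img = replace(img, pixels=np.clip(np.rint(warped), 0, 255).astype(np.uint8))
    new_landmarks = tuple(
        PoILandmark(poi_id=k, point=new_pts[k], likelihood=1.0) for k in POI_IDS
    )
    return new_img, GroundTruth(
        landmarks=new_landmarks,
        angles=gt.angles,  # similarity transforms preserve angles
        class_label=gt.class_label,
        image_id=gt.image_id + f"-aug{seed}",
    )


def sample_dataset(
    n_per_class: dict[str, int],
    seed: int = 0,
    noise_sd: float = 4.0,
    blur_sd: float = 2.5,
    size: int = CANONICAL_SIZE,
) -> tuple[list[tuple[Radiograph, GroundTruth]], pd.DataFrame]:
    """Seeded phantom dataset plus its manifest.

    Per-phantom seeds are spawned deterministically from ``seed``, so the
    manifest (image_id, class, exact angles, seed) fully reproduces the
    dataset. Returns ``(list of (Radiograph, GroundTruth), manifest)``.
    """
    ss = np.random.SeedSequence(seed)
    dataset: list[tuple[Radiograph, GroundTruth]] = []
    rows = []
    child_seeds = iter(ss.generate_state(sum(max(n, 0) for n in n_per_class.values())))
    for cls in FOOT_CLASS_ORDER:
        for _ in range(int(n_per_class.get(cls, 0))):
            child = int(next(child_seeds)) % (2**31)
            spec = PhantomSpec(
                target_class=cls, noise_sd=noise_sd, blur_sd=blur_sd, size=size, seed=child
            )
            img, gt = generate_phantom(spec)
            img = replace(img, image_id=f"{gt.image_id}-{len(dataset):03d}")
            gt = GroundTruth(
                landmarks=gt.landmarks,
                angles=gt.angles,
                class_label=gt.class_label,
                image_id=img.image_id,
            )
            dataset.append((img, gt))
            rows.append(
                {
                    "image_id": img.image_id,
                    "class": cls,
                    "cia_deg": gt.angles.cia_deg,
                    "aa_deg": gt.angles.aa_deg,
                    "ma_deg": gt.angles.ma_deg,
                    "seed": child,
                }
            )
    return dataset, pd.DataFrame(rows)


FOOT_CLASS_ORDER = (diagnosis.NORMAL, diagnosis.MILD, diagnosis.MODERATE)
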