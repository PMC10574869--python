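"""Normalized squared-difference template matching for landmark candidates.

Each of the nine anatomical points of interest (PoIs) owns a set of
100x100-pixel templates, each cropped so its PoI sits at the exact patch
center. A template is slid over the radiograph and scored at every start
position ``(Sx, Sy)`` with the normalized squared difference

    R(Sx, Sy) = sum((T - I)^2) / sqrt(sum(T^2) * sum(I^2))

over the window ``I`` under the template ``T``; R = 0 is a perfect match
and similarity is reported as ``1 - R`` so the acceptance threshold (default
0.90) reads directly as "at least 90% match". Positions whose similarity
clears the threshold become candidate patches, later re-ranked by the
patch classifier.

The score map is computed with FFT cross-correlation plus cumulative-sum
window energies, which is algebraically identical to the sliding-window
definition (the test suite checks this against a brute-force double loop).
Windows or templates with zero energy get the worst score (R = 1) instead
of dividing by zero; energy-mismatched windows can push the raw ratio
above 1, and such scores are saturated at 1 since anything with R > 0.1
is discarded anyway.

PoI numbering (fixed across the package):
1-2 first metatarsal (posterior, anterior), 3-4 fifth metatarsal
(posterior, anterior), 5-6 calcaneus (posterior-inferior,
anterior-inferior), 7-8 talus (posterior, anterior), 9 sesamoid.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "TEMPLATE_SIZE",
    "POI_IDS",
    "Template",
    "ScoreMap",
    "CandidatePatch",
    "TemplateLibrary",
    "ImageMatcher",
    "score_map",
    "find_candidates",
    "localization_score",
]

#: Template edge length in pixels; the PoI sits at (start + 50, start + 50).
TEMPLATE_SIZE = 100

#: Half of the template edge: offset from a patch start to its center PoI.
POI_CENTER_OFFSET = TEMPLATE_SIZE // 2

#: The nine landmark identities.
POI_IDS: tuple[int, ...] = tuple(range(1, 10))


class MatchingError(ValueError):
    """Raised for dimension errors and invalid thresholds."""


@dataclass(frozen=True)
class Template:
    """One 100x100 patch whose PoI lies at its exact center."""

    poi_id: int
    patch: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.poi_id not in POI_IDS:
            raise MatchingError(f"poi_id must be 1..9, got {self.poi_id}")
        patch = np.asarray(self.patch, dtype=np.float64)
        if patch.shape != (TEMPLATE_SIZE, TEMPLATE_SIZE):
            raise MatchingError(
                f"template patch must be {TEMPLATE_SIZE}x{TEMPLATE_SIZE}, got {patch.shape}"
            )
        object.__setattr__(self, "patch", patch)


@dataclass(frozen=True)
class ScoreMap:
    """Normalized squared-difference scores, one per valid start position.

    ``values[sy, sx]`` is R for template start ``(Sx=sx, Sy=sy)``; shape is
    ``(H - th + 1, W - tw + 1)``. Lower is better.
    """

    values: np.ndarray
    poi_id: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CandidatePatch:
    """A thresholded match: a patch start plus its similarity (= 1 - R).

    ``likelihood`` stays None until the patch classifier fills it in.
    """

    poi_id: int
    start: tuple[int, int]  # (Sx, Sy)
    similarity: float
    patch: np.ndarray | None = None
    likelihood: float | None = None
    scan_index: int = 0  # row-major position; the tie-break order


def _window_sums(sq: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Sliding-window sums of ``sq`` over every th x tw window (integral image)."""
    ii = np.zeros((sq.shape[0] + 1, sq.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = sq.cumsum(axis=0).cumsum(axis=1)
    return (
        ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw]
    )


class ImageMatcher:
    """Scores many templates against one image, reusing per-image FFT work.

    The image FFT and window energies are computed once; each template then
    costs one forward and one inverse FFT. Used by the pipeline where nine
    PoIs times several templates hit the same radiograph.
    """

    def __init__(
        self,
        pixels: np.ndarray,
        template_shape: tuple[int, int] = (TEMPLATE_SIZE, TEMPLATE_SIZE),
        dtype=np.float64,
    ):
        img = np.asarray(pixels, dtype=dtype)
        if img.ndim != 2:
            raise MatchingError("image must be 2-D")
        th, tw = template_shape
        if img.shape[0] < th or img.shape[1] < tw:
            raise MatchingError(
                f"image {img.shape} smaller than template {template_shape}"
            )
        # float32 halves FFT cost and is ample for 8-bit images scored
        # against a 0.90 threshold; float64 is the default for exactness.
        self.dtype = np.dtype(dtype)
        self.img = img
        self.template_shape = (th, tw)
        self._fshape = (
            sp_fft.next_fast_len(img.shape[0] + th - 1, real=True),
            sp_fft.next_fast_len(img.shape[1] + tw - 1, real=True),
        )
        self._img_fft = sp_fft.rfft2(img, self._fshape)
        # window energies in float64: cumulative sums lose precision fast
        self._win_energy = _window_sums(
            img.astype(np.float64) ** 2, th, tw
        ).astype(self.dtype)

    def score(self, tmpl: Template | np.ndarray) -> ScoreMap:
        """Score map of one template over the image (lower = better)."""
        if isinstance(tmpl, Template):
            patch, poi_id = tmpl.patch, tmpl.poi_id
        else:
            patch, poi_id = np.asarray(tmpl, dtype=np.float64), 0
        th, tw = self.template_shape
        if patch.shape != (th, tw):
            raise MatchingError(
                f"template shape {patch.shape} does not match matcher shape {(th, tw)}"
            )
        patch = patch.astype(self.dtype, copy=False)
        t_energy = float((patch.astype(np.float64) ** 2).sum())
        # cross-correlation via convolution with the flipped template
        tf = sp_fft.rfft2(patch[::-1, ::-1], self._fshape)
        full = sp_fft.irfft2(self._img_fft * tf, self._fshape)
        H, W = self.img.shape
        cross = full[th - 1 : H, tw - 1 : W]
        num = t_energy - 2.0 * cross + self._win_energy
        den = np.sqrt(np.maximum(t_energy * self._win_energy, 0.0))
        bad = den <= 0.0
        if bad.any() or t_energy == 0.0:
            warnings.warn(
                "zero-energy template or window encountered; scoring as worst match",
                RuntimeWarning,
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(bad, 1.0, num / np.where(bad, 1.0, den))
        r = np.clip(r, 0.0, 1.0)
        return ScoreMap(values=r, poi_id=poi_id)

    def score_many(self, templates: list[Template]) -> list[ScoreMap]:
        """Score a batch of templates in one vectorized FFT pass."""
        if not templates:
            return []
        th, tw = self.template_shape
        stack = np.stack([t.patch[::-1, ::-1] for t in templates]).astype(self.dtype)
        if stack.shape[1:] != (th, tw):
            raise MatchingError("batched templates must all match the matcher shape")
        tf = sp_fft.rfft2(stack, self._fshape, axes=(-2, -1))
        full = sp_fft.irfft2(self._img_fft[None] * tf, self._fshape, axes=(-2, -1))
        H, W = self.img.shape
        cross = full[:, th - 1 : H, tw - 1 : W]
        out = []
        warned = False
        for t, c in zip(templates, cross):
            t_energy = float((t.patch * t.patch).sum())
            num = t_energy - 2.0 * c + self._win_energy
            den = np.sqrt(np.maximum(t_energy * self._win_energy, 0.0))
            bad = (den <= 0.0) | (t_energy == 0.0)
            if bad.any() and not warned:
                warned = True
                warnings.warn(
                    "zero-energy template or window encountered; scoring as worst match",
                    RuntimeWarning,
                    stacklevel=2,
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(bad, 1.0, num / np.where(bad, 1.0, den))
            out.append(ScoreMap(values=np.clip(r, 0.0, 1.0), poi_id=t.poi_id))
        return out


def score_map(img, tmpl: Template | np.ndarray) -> ScoreMap:
    """Normalized squared-difference score map of one template over one image.

    ``img`` may be a :class:`~flatfoot.imaging.Radiograph` or a bare 2-D
    array. For repeated matching against the same image prefer
    :class:`ImageMatcher`, which caches the image-side FFT.
    """
    pixels = getattr(img, "pixels", img)
    patch = tmpl.patch if isinstance(tmpl, Template) else np.asarray(tmpl, dtype=np.float64)
    return ImageMatcher(pixels, template_shape=patch.shape).score(tmpl)


def find_candidates(
    smap: ScoreMap,
    poi_id: int | None = None,
    threshold: float = 0.90,
    top_k: int | None = 50,
    image: np.ndarray | None = None,
    min_separation: int = 0,
) -> list[CandidatePatch]:
    """Threshold a score map into candidate patches.

    Returns every start with similarity ``1 - R >= threshold`` in row-major
    scan order; if more than ``top_k`` qualify, the ``top_k`` best by
    similarity are kept (ties resolved by scan order). ``min_separation``
    optionally suppresses candidates within that Chebyshev distance of an
    already-kept better one (off by default — score plateaus otherwise
    produce stacks of adjacent duplicates). An empty result is not an
    error: the caller decides how to react.
    """
    if not 0.0 < threshold < 1.0:
        raise MatchingError(f"threshold must lie in (0, 1), got {threshold}")
    if poi_id is None:
        poi_id = smap.poi_id
    sim = 1.0 - smap.values
    ys, xs = np.nonzero(sim >= threshold)
    if ys.size == 0:
        return []
    order = np.arange(ys.size)  # nonzero is already row-major
    if min_separation > 0:
        keep: list[int] = []
        by_sim = np.lexsort((order, -sim[ys, xs]))
        taken_x: list[int] = []
        taken_y: list[int] = []
        for i in by_sim:
            if any(
                max(abs(xs[i] - tx), abs(ys[i] - ty)) < min_separation
                for tx, ty in zip(taken_x, taken_y)
            ):
                continue
            keep.append(i)
            taken_x.append(int(xs[i]))
            taken_y.append(int(ys[i]))
        keep_idx = np.sort(np.array(keep, dtype=int))
        ys, xs, order = ys[keep_idx], xs[keep_idx], order[keep_idx]
    if top_k is not None and ys.size > top_k:
        by_sim = np.lexsort((order, -sim[ys, xs]))[:top_k]
        by_sim.sort()  # restore scan order among the keepers
        ys, xs = ys[by_sim], xs[by_sim]
    cands = []
    for rank, (sy, sx) in enumerate(zip(ys.tolist(), xs.tolist())):
        patch = None
        if image is not None:
            patch = np.asarray(image, dtype=np.float64)[
                sy : sy + TEMPLATE_SIZE, sx : sx + TEMPLATE_SIZE
            ].copy()
        cands.append(
            CandidatePatch(
                poi_id=poi_id,
                start=(int(sx), int(sy)),
                similarity=float(sim[sy, sx]),
                patch=patch,
                scan_index=rank,
            )
        )
    return cands


def localization_score(gt: tuple[float, float], pred: tuple[float, float]) -> float:
    """Localization similarity 1 / (1 + d) with d the Euclidean distance.

    1.0 for an exact hit, decaying toward 0 with distance; means over
    landmark sets are taken of these per-point scores.
    """
    d = float(np.hypot(gt[0] - pred[0], gt[1] - pred[1]))
    return 1.0 / (1.0 + d)


class TemplateLibrary:
    """Per-PoI collections of templates, with a simple on-disk layout.

    On disk: a directory of PNG patches named ``poi<k>_<source_id>.png``
    plus an ``index.csv`` (``poi_id,filename``).
    """

    def __init__(self, templates: list[Template] | None = None):
        self._by_poi: dict[int, list[Template]] = {k: [] for k in POI_IDS}
        for t in templates or []:
            self._by_poi[t.poi_id].append(t)

    def add(self, tmpl: Template) -> None:
        self._by_poi[tmpl.poi_id].append(tmpl)

    def templates_for(self, poi_id: int, limit: int | None = None) -> list[Template]:
        """Templates of one PoI; ``limit`` keeps an evenly spaced subset.

        Even spacing (rather than the first ``limit``) preserves the
        diversity of a library built from a class-ordered dataset.
        """
        ts = self._by_poi[poi_id]
        if limit is None or len(ts) <= limit:
            return ts
        idx = np.unique(np.linspace(0, len(ts) - 1, limit).round().astype(int))
        return [ts[i] for i in idx]

    def poi_ids_covered(self) -> list[int]:
        return [k for k in POI_IDS if self._by_poi[k]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_poi.values())

    def save(self, directory: str | Path) -> None:
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for poi_id in POI_IDS:
            for i, t in enumerate(self._by_poi[poi_id]):
                name = f"poi{poi_id}_{t.source_id or i}.png"
                arr = np.clip(np.rint(t.patch), 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(directory / name)
                rows.append((poi_id, name))
        with open(directory / "index.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["poi_id", "filename"])
            w.writerows(rows)

    @classmethod
    def load(cls, directory: str | Path) -> "TemplateLibrary":
        from PIL import Image

        directory = Path(directory)
        lib = cls()
        with open(directory / "index.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                arr = np.asarray(Image.open(directory / row["filename"]))
                source = Path(row["filename"]).stem.split("_", 1)[-1]
                lib.add(Template(int(row["poi_id"]), arr, source_id=source))
        return lib
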