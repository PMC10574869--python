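"""Radiograph I/O and geometric standardization.

Coordinate convention used throughout the package: 0-based raster
coordinates with ``x`` = column (increasing rightward) and ``y`` = row
(increasing downward), origin at the top-left pixel. Points are ``(x, y)``
pairs; arrays are indexed ``pixels[y, x]``.

Every radiograph entering the measurement pipeline is standardized to a
square canonical frame (default 1024x1024) by center padding or center
cropping — never by resampling, so pixel geometry (and therefore every
measured angle) is preserved. Right-foot images are mirrored to the
left-foot orientation so a single template library serves both sides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Laterality",
    "Radiograph",
    "read_image",
    "write_image",
    "standardize",
    "orient",
    "adjust_intensity",
    "CANONICAL_SIZE",
]

#: Default canonical frame edge length in pixels.
CANONICAL_SIZE = 1024

#: Intensity used when padding to the canonical frame (black background).
PAD_INTENSITY = 0


class Laterality(str, enum.Enum):
    """Which foot the image depicts."""

    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class ImagingError(ValueError):
    """Raised for unreadable files, bad configuration, or unknown laterality."""


@dataclass(frozen=True)
class Radiograph:
    """A single-channel 8-bit radiograph with laterality metadata.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (height, width)
        Grayscale intensities in [0, 255].
    laterality : Laterality
        Side of the body the foot belongs to.
    image_id : str
        Opaque identifier carried through reports.
    """

    pixels: np.ndarray
    laterality: Laterality = Laterality.UNKNOWN
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ImagingError("radiograph pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ImagingError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def read_image(
    path: str | Path,
    laterality: Laterality | str = Laterality.UNKNOWN,
    image_id: str | None = None,
) -> Radiograph:
    """Read a PNG/TIFF radiograph as 8-bit grayscale.

    RGB inputs of grayscale scans are collapsed by channel averaging.
    Multi-frame images are rejected. ``laterality`` comes from the caller
    (CLI flag or manifest); it is never inferred from pixel content.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise ImagingError(f"multi-frame image not supported: {path}")
            arr = np.asarray(im)
    except ImagingError:
        raise
    except Exception as exc:  # truncated / undecodable file
        raise ImagingError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.max() > 255:  # 16-bit TIFF: rescale to the 8-bit range
        arr = arr * (255.0 / arr.max())
    arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return Radiograph(
        pixels=arr,
        laterality=Laterality(laterality),
        image_id=image_id if image_id is not None else path.stem,
    )


def write_image(img: Radiograph, path: str | Path) -> None:
    """Write a radiograph as an 8-bit grayscale PNG/TIFF."""
    Image.fromarray(img.pixels, mode="L").save(Path(path))


def _center_offsets(src: int, dst: int) -> tuple[int, int]:
    """(source start, destination start) for centering src inside dst.

    Floor division on both sides; deterministic for odd differences.
    """
    if src >= dst:
        return (src - dst) // 2, 0
    return 0, (dst - src) // 2


def standardize(img: Radiograph, size: int = CANONICAL_SIZE) -> Radiograph:
    """Pad or center-crop to a ``size``x``size`` frame (no resampling).

    Smaller axes are centered on a black (intensity 0) background; larger
    axes are center-cropped. Idempotent, and a no-op on already-canonical
    input.
    """
    if size <= 100:
        raise ImagingError(f"canonical size must exceed the 100-px template, got {size}")
    if img.height == size and img.width == size:
        return img
    out = np.full((size, size), PAD_INTENSITY, dtype=np.uint8)
    sy, dy = _center_offsets(img.height, size)
    sx, dx = _center_offsets(img.width, size)
    h = min(img.height, size)
    w = min(img.width, size)
    out[dy : dy + h, dx : dx + w] = img.pixels[sy : sy + h, sx : sx + w]
    return replace(img, pixels=out)


def orient(img: Radiograph, assume_left: bool = False) -> Radiograph:
    """Mirror right-foot images to the canonical left-foot orientation.

    A pixel at ``(x, y)`` moves to ``(width - 1 - x, y)``; the laterality
    label flips accordingly, so the operation is an involution. Unknown
    laterality is an error unless ``assume_left`` is set.
    """
    if img.laterality is Laterality.UNKNOWN:
        if assume_left:
            return replace(img, laterality=Laterality.LEFT)
        raise ImagingError(
            "laterality unknown; pass laterality metadata or set assume_left"
        )
    if img.laterality is Laterality.LEFT:
        return img
    return replace(img, pixels=img.pixels[:, ::-1].copy(), laterality=Laterality.LEFT)


def adjust_intensity(
    img: Radiograph,
    method: str = "none",
    clip_limit: float = 0.01,
) -> Radiograph:
    """Optional brightness/contrast adjustment.

    Real scans occasionally need contrast help before the bones are clearly
    visible; this is an explicit, default-off step, not an automatic one.
    ``linear_stretch`` maps the observed [min, max] to [0, 255] (constant
    images pass through unchanged); ``clahe`` applies contrast-limited
    adaptive histogram equalization.
    """
    if method == "none":
        return img
    if method == "linear_stretch":
        px = img.pixels.astype(np.float64)
        lo, hi = px.min(), px.max()
        if hi == lo:
            return img
        out = np.rint((px - lo) * (255.0 / (hi - lo))).astype(np.uint8)
        return replace(img, pixels=out)
    if method == "clahe":
        from skimage import exposure

        eq = exposure.equalize_adapthist(img.pixels, clip_limit=clip_limit)
        return replace(img, pixels=np.rint(eq * 255).astype(np.uint8))
    raise ImagingError(f"unknown intensity adjustment method: {method!r}")
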