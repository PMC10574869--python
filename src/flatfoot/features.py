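"""Deterministic feature vectors for 100x100 candidate patches.

The default ``grid_hog`` backend concatenates two L2-normalized blocks:

* a 16x16 downsampled intensity grid (block means over the central
  96x96 pixels, 256 values), capturing coarse appearance, and
* an 8-bin gradient-orientation histogram per cell of a 4x4 spatial grid
  (25x25-pixel cells, 128 values), capturing local edge structure.

Both blocks are pure array arithmetic: the vector depends only on the
patch, never on external weights, so training and inference are exactly
reproducible. A constant patch has an all-zero gradient block. An
``external_cnn`` backend hook accepts any callable patch->vector (e.g. a
pre-trained convolutional feature extractor); it is opt-in and unused by
the default pipeline and tests.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["FEATURE_LENGTH", "extract_features", "extract_features_batch"]

PATCH_SIZE = 100
_GRID = 16  # intensity grid edge
_CROP = 96  # central crop divisible by the grid
_CELLS = 4  # gradient cells per axis
_BINS = 8  # unsigned orientation bins over [0, 180)

#: Length of the default feature vector: 16*16 intensities + 4*4*8 gradients.
FEATURE_LENGTH = _GRID * _GRID + _CELLS * _CELLS * _BINS


class FeatureError(ValueError):
    pass


def _l2(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _grid_hog(patch: np.ndarray) -> np.ndarray:
    p = np.asarray(patch, dtype=np.float64)
    if p.shape != (PATCH_SIZE, PATCH_SIZE):
        raise FeatureError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {p.shape}")
    off = (PATCH_SIZE - _CROP) // 2
    core = p[off : off + _CROP, off : off + _CROP]
    step = _CROP // _GRID
    grid = core.reshape(_GRID, step, _GRID, step).mean(axis=(1, 3)) / 255.0

    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    # unsigned orientation in [0, 180)
    ori = np.degrees(np.arctan2(gy, gx)) % 180.0
    b = np.minimum((ori / (180.0 / _BINS)).astype(np.intp), _BINS - 1)
    cell = PATCH_SIZE // _CELLS
    cy = (np.arange(PATCH_SIZE) // cell)[:, None]
    cx = (np.arange(PATCH_SIZE) // cell)[None, :]
    flat_idx = ((cy * _CELLS + cx) * _BINS + b).ravel()
    hist = np.bincount(flat_idx, weights=mag.ravel(), minlength=_CELLS * _CELLS * _BINS)
    return np.concatenate([_l2(grid.ravel()), _l2(hist)])


_BACKENDS: dict[str, Callable[[np.ndarray], np.ndarray]] = {"grid_hog": _grid_hog}


def register_backend(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an alternative patch->vector extractor (e.g. CNN features)."""
    _BACKENDS[name] = fn


def extract_features(patch: np.ndarray, backend: str = "grid_hog") -> np.ndarray:
    """Feature vector of one patch under the named backend."""
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise FeatureError(
            f"unknown feature backend {backend!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    return fn(patch)


def extract_features_batch(patches, backend: str = "grid_hog") -> np.ndarray:
    """Stack of feature vectors, shape (n_patches, n_features)."""
    return np.asarray([extract_features(p, backend) for p in patches], dtype=np.float64)
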