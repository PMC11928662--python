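"""Descriptor invariance benchmarks on generated texture slices.

Repeatability is the fraction of keypoints detected on a reference slice
that reappear (within a pixel tolerance, after mapping through the known
geometric transform) on a transformed copy; matched pairs also report the
cosine similarity of their descriptors.  The harness exercises the scale
and rotation invariance the descriptors are chosen for.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from scipy.spatial import cKDTree

from .descriptors import LocalFeature, descriptor_matrix, detect_features
from .dti_maps import RoiSlice, rescale_to_8bit


def texture_slice(size: int = 128, granularity: float = 2.0, seed: int = 0) -> RoiSlice:
    """A full-frame 8-bit band-limited random texture slice."""
    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.normal(size=(size, size)), granularity)
    return RoiSlice(
        pixels=rescale_to_8bit(field),
        slice_index=0,
        bbox=(0, 0, size, size),
        mask=np.ones((size, size), dtype=bool),
    )


def match_statistics(
    ref: list[LocalFeature],
    moved: list[LocalFeature],
    map_back,
    tol: float = 2.0,
) -> dict:
    """Repeatability and matched-descriptor cosine similarity.

    ``map_back(positions)`` maps (row, col) keypoint positions of the moved
    slice back into the reference frame; a reference keypoint is repeated if
    a mapped keypoint lies within ``tol`` pixels.
    """
    if not ref or not moved:
        return {"repeatability": 0.0, "mean_cosine": 0.0, "n_ref": len(ref)}
    p_ref = np.array([[f.y, f.x] for f in ref])
    p_mov = map_back(np.array([[f.y, f.x] for f in moved]))
    dist, idx = cKDTree(p_mov).query(p_ref)
    matched = dist <= tol
    v_ref = descriptor_matrix(ref)
    v_mov = descriptor_matrix(moved)
    cos = np.sum(v_ref[matched] * v_mov[idx[matched]], axis=1)
    return {
        "repeatability": float(matched.mean()),
        "mean_cosine": float(cos.mean()) if matched.any() else 0.0,
        "n_ref": len(ref),
    }


def rotation_benchmark(
    detector: str, size: int = 128, granularity: float = 2.0, seed: int = 0,
    tol: float = 2.0,
) -> dict:
    """Keypoint repeatability under a 90° in-plane rotation."""
    sl = texture_slice(size, granularity, seed)
    rot = RoiSlice(
        pixels=np.rot90(sl.pixels).copy(),
        slice_index=0,
        bbox=(0, 0, size, size),
        mask=np.ones((size, size), dtype=bool),
    )
    f0 = detect_features(sl, detector)
    f90 = detect_features(rot, detector)

    def map_back(p):  # inverse of np.rot90: (r', c') -> (c', size-1-r')
        return np.column_stack([p[:, 1], size - 1 - p[:, 0]])

    return match_statistics(f0, f90, map_back, tol)


def scale_benchmark(
    detector: str, factor: float = 2.0, size: int = 128, granularity: float = 2.0,
    seed: int = 0, tol: float = 2.0,
) -> dict:
    """Keypoint repeatability under isotropic rescaling by ``factor``.

    Positions on the rescaled slice are mapped back by 1/factor and matched
    with the tolerance expressed in reference-frame pixels.
    """
    sl = texture_slice(size, granularity, seed)
    big = np.clip(zoom(sl.pixels.astype(np.float64), factor, order=3), 0, 255)
    big_slice = RoiSlice(
        pixels=big.astype(np.uint8),
        slice_index=0,
        bbox=(0, 0, *big.shape),
        mask=np.ones(big.shape, dtype=bool),
    )
    f0 = detect_features(sl, detector)
    f2 = detect_features(big_slice, detector)
    return match_statistics(f0, f2, lambda p: p / factor, tol)
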