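"""Keypoint detection and local descriptors on ROI slices.

Two detector/descriptor families are supported: SIFT (128-d,
difference-of-Gaussians scale-space extrema, subpixel localization with
low-contrast and edge rejection, 36-bin dominant-orientation assignment, and
the 4×4×8 gradient descriptor with normalize–clip(0.2)–renormalize) and SURF
(64-d, integral-image box-filter Hessian; see :mod:`dtibow.surf`).

SIFT is computed with scikit-image's implementation of the standard
algorithm; descriptors are re-normalized to unit Euclidean length.  Keypoints
whose (rounded) center falls outside the ROI mask are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import SIFT as _SkimageSIFT

from .dti_maps import MAP_KINDS, RoiMask, RoiSlice, ScalarMapVolume, extract_roi_slices

DETECTORS = ("SIFT", "SURF")
DESCRIPTOR_DIM = {"SIFT": 128, "SURF": 64}

#: Minimum in-plane slice extent for keypoint detection.
MIN_SLICE_SIZE = 16


@dataclass
class LocalFeature:
    """One keypoint with its descriptor vector.

    ``x``/``y`` are in-plane column/row positions in pixels of the (cropped)
    ROI slice, subpixel where the detector provides it; ``orientation`` is in
    [0, 2π); ``vector`` has unit Euclidean norm and length 128 (SIFT) or
    64 (SURF).
    """

    slice_index: int
    x: float
    y: float
    scale: float
    orientation: float
    detector: str
    vector: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}")
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.shape != (DESCRIPTOR_DIM[self.detector],):
            raise ValueError(
                f"{self.detector} descriptor must have length "
                f"{DESCRIPTOR_DIM[self.detector]}, got {self.vector.shape}"
            )


@dataclass
class SiftParams:
    """SIFT detector parameters (literature-standard defaults)."""

    n_octaves: int = 8  # capped by image size inside the detector
    n_scales: int = 3
    sigma_min: float = 1.6
    c_dog: float = 0.04 / 3  # Lowe's 0.04 contrast threshold per scale triplet
    c_edge: float = 10.0
    upsampling: int = 2


@dataclass
class SurfParams:
    """SURF detector parameters."""

    hessian_threshold: float = 100.0  # on 8-bit images, area-normalized responses
    n_octaves: int = 4
    init_step: int = 1


def descriptor_matrix(features: list[LocalFeature]) -> np.ndarray:
    """Stack descriptor vectors into an (n, d) array (0×0 when empty)."""
    if not features:
        return np.empty((0, 0))
    return np.stack([f.vector for f in features])


def features_to_frame(features: list[LocalFeature]) -> pd.DataFrame:
    """Tabulate features with columns slice_index,x,y,scale,orientation,detector,v0..v{d-1}."""
    if not features:
        return pd.DataFrame(
            columns=["slice_index", "x", "y", "scale", "orientation", "detector"]
        )
    meta = pd.DataFrame(
        {
            "slice_index": [f.slice_index for f in features],
            "x": [f.x for f in features],
            "y": [f.y for f in features],
            "scale": [f.scale for f in features],
            "orientation": [f.orientation for f in features],
            "detector": [f.detector for f in features],
        }
    )
    vecs = descriptor_matrix(features)
    vcols = pd.DataFrame(vecs, columns=[f"v{i}" for i in range(vecs.shape[1])])
    return pd.concat([meta, vcols], axis=1)


def features_from_frame(frame: pd.DataFrame) -> list[LocalFeature]:
    """Inverse of :func:`features_to_frame`."""
    vcols = [c for c in frame.columns if c.startswith("v") and c[1:].isdigit()]
    vcols.sort(key=lambda c: int(c[1:]))
    out = []
    for _, row in frame.iterrows():
        out.append(
            LocalFeature(
                slice_index=int(row["slice_index"]),
                x=float(row["x"]),
                y=float(row["y"]),
                scale=float(row["scale"]),
                orientation=float(row["orientation"]),
                detector=str(row["detector"]),
                vector=row[vcols].to_numpy(dtype=np.float64),
            )
        )
    return out


def _slice_too_small(roi_slice: RoiSlice) -> bool:
    h, w = roi_slice.pixels.shape
    if min(h, w) < MIN_SLICE_SIZE:
        warnings.warn(
            f"slice {roi_slice.slice_index} smaller than {MIN_SLICE_SIZE}px; skipped",
            stacklevel=3,
        )
        return True
    return False


def _in_roi(roi_slice: RoiSlice, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    h, w = roi_slice.mask.shape
    r = np.clip(np.rint(rows).astype(int), 0, h - 1)
    c = np.clip(np.rint(cols).astype(int), 0, w - 1)
    return roi_slice.mask[r, c]


def sift_features(
    roi_slice: RoiSlice, params: SiftParams | None = None
) -> list[LocalFeature]:
    """Detect SIFT keypoints on one ROI slice and compute 128-d descriptors.

    Returns an empty list (with a warning) for slices below the minimum size
    and for slices without detectable extrema (e.g. constant intensity).
    """
    params = params or SiftParams()
    if _slice_too_small(roi_slice):
        return []
    det = _SkimageSIFT(
        upsampling=params.upsampling,
        n_octaves=params.n_octaves,
        n_scales=params.n_scales,
        sigma_min=params.sigma_min,
        c_dog=params.c_dog,
        c_edge=params.c_edge,
    )
    img = roi_slice.pixels.astype(np.float32) / 255.0
    try:
        det.detect_and_extract(img)
    except (RuntimeError, ValueError):
        # no extrema survived (constant or near-constant slice)
        return []
    if det.positions.shape[0] == 0:
        return []
    rows, cols = det.positions[:, 0], det.positions[:, 1]
    keep = _in_roi(roi_slice, rows, cols)
    feats: list[LocalFeature] = []
    for i in np.flatnonzero(keep):
        vec = det.descriptors[i].astype(np.float64)
        norm = np.linalg.norm(vec)
        if norm == 0:
            continue
        feats.append(
            LocalFeature(
                slice_index=roi_slice.slice_index,
                x=float(cols[i]),
                y=float(rows[i]),
                scale=float(det.sigmas[i]),
                orientation=float(np.mod(det.orientations[i], 2 * np.pi)),
                detector="SIFT",
                vector=vec / norm,
            )
        )
    return feats


def detect_features(
    roi_slice: RoiSlice,
    detector: str,
    sift_params: SiftParams | None = None,
    surf_params: SurfParams | None = None,
) -> list[LocalFeature]:
    """Dispatch to the requested detector on one ROI slice."""
    if detector == "SIFT":
        return sift_features(roi_slice, sift_params)
    if detector == "SURF":
        from .surf import surf_features

        return surf_features(roi_slice, surf_params)
    raise ValueError(f"unknown detector {detector!r}")


def extract_subject_features(
    maps: dict[str, ScalarMapVolume],
    mask: RoiMask,
    detector: str = "SIFT",
    axis: int = 2,
    min_roi_pixels: int = 16,
    percentiles: tuple[float, float] = (1.0, 99.0),
    sift_params: SiftParams | None = None,
    surf_params: SurfParams | None = None,
) -> dict[str, list[LocalFeature]]:
    """Extract per-slice features for each scalar map of one subject.

    Returns ``{map_kind: [LocalFeature, ...]}`` with features concatenated
    over all ROI slices.  Subjects may legitimately yield different feature
    counts per map (the motivation for the bag-of-words signature); a map
    yielding zero features is flagged with a warning.
    """
    out: dict[str, list[LocalFeature]] = {}
    for kind, vol in maps.items():
        if kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {kind!r}")
        feats: list[LocalFeature] = []
        for sl in extract_roi_slices(
            vol, mask, axis=axis, min_roi_pixels=min_roi_pixels, percentiles=percentiles
        ):
            feats.extend(
                detect_features(sl, detector, sift_params=sift_params, surf_params=surf_params)
            )
        if not feats:
            warnings.warn(f"subject yielded zero {detector} features on {kind}", stacklevel=2)
        out[kind] = feats
    return out
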