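"""Volumetric DTI scalar maps, ROI masks, and 2-D slice extraction.

The pipeline consumes already-registered per-subject scalar maps — mean
diffusivity (MD), fractional anisotropy (FA) and radial diffusivity (RD) —
together with a binary region-of-interest mask on the same voxel grid
(typically a segmented hippocampus).  Upstream tensor fitting from raw
diffusion-weighted images is out of scope; when tensor eigenvalues are
available the three maps can be computed here from their standard
definitions:

    MD = (λ1 + λ2 + λ3) / 3
    RD = (λ2 + λ3) / 2
    FA = sqrt(3/2) · sqrt(Σ(λi − MD)²) / sqrt(Σ λi²)

Slices of the masked ROI are cropped to the in-plane mask bounding box and
rescaled to 8-bit so that gradient-based keypoint descriptors can operate on
them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

MAP_KINDS = ("MD", "FA", "RD")

#: FA values may exceed [0, 1] by at most this much before read_volume warns.
FA_TOL = 1e-6


@dataclass
class ScalarMapVolume:
    """One 3-D scalar map (MD, FA or RD) of a single subject.

    Units are mm²/s for MD/RD and dimensionless for FA.
    """

    data: np.ndarray
    kind: str | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"scalar map must be 3-D, got {self.data.ndim}-D")
        if self.kind is not None and self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class RoiMask:
    """Binary 3-D mask delimiting the analysed region (e.g. hippocampus)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = "roi"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be binary (0/1)")
        self.data = arr.astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class EigenvalueVolume:
    """Voxelwise diffusion-tensor eigenvalues, sorted so λ1 ≥ λ2 ≥ λ3.

    The constructor sorts the three arrays voxelwise; callers may pass the
    eigenvalues in any order.
    """

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        lams = np.stack(
            [np.asarray(l, dtype=np.float64) for l in (self.lam1, self.lam2, self.lam3)]
        )
        if lams.shape[1:] == ():
            raise ValueError("eigenvalue arrays must be 3-D")
        if not (lams.shape[1:] == np.asarray(self.lam1).shape):
            raise ValueError("eigenvalue arrays must share one shape")
        lams = np.sort(lams, axis=0)[::-1]  # descending voxelwise
        self.lam1, self.lam2, self.lam3 = lams[0], lams[1], lams[2]
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class RoiSlice:
    """A 2-D, 8-bit, mask-cropped slice of the ROI.

    ``bbox`` is the half-open in-plane bounding box (row0, col0, row1, col1)
    of the mask on this slice; ``pixels`` has shape (row1-row0, col1-col0)
    with out-of-mask pixels set to 0.  ``mask`` is the matching boolean crop.
    """

    pixels: np.ndarray
    slice_index: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if r1 <= r0 or c1 <= c0:
            raise ValueError("bbox must be nonempty")
        if self.mask is None:
            self.mask = self.pixels > 0


# ---------------------------------------------------------------------------
# I/O


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(vol: ScalarMapVolume, path: str | Path) -> Path:
    """Write a scalar map as a NIfTI file (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine_from_spacing(vol.spacing))
    if vol.kind:
        img.header["descrip"] = vol.kind.encode()
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, expected_kind: str | None = None) -> ScalarMapVolume:
    """Read a 3-D scalar map from a NIfTI file.

    ``expected_kind`` (MD/FA/RD) sets the map kind and, for FA, triggers a
    range check: finite values outside [-1e-6, 1+1e-6] are clipped to [0, 1]
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D image, got {data.ndim}-D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    kind = expected_kind
    if kind is None:
        descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        if descrip in MAP_KINDS:
            kind = descrip
    if kind == "FA":
        finite = np.isfinite(data)
        out = finite & ((data < -FA_TOL) | (data > 1 + FA_TOL))
        if out.any():
            warnings.warn(
                f"{int(out.sum())} FA values outside [0, 1] in {path.name}; clipping",
                stacklevel=2,
            )
        data = np.where(finite, np.clip(data, 0.0, 1.0), data)
    return ScalarMapVolume(data=data, kind=kind, spacing=spacing)


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine_from_spacing(mask.spacing))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, label: str = "roi") -> RoiMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D mask, got {data.ndim}-D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RoiMask(data=data > 0, spacing=spacing, label=label)


# ---------------------------------------------------------------------------
# Scalar maps from eigenvalues


def scalar_maps_from_eigenvalues(
    ev: EigenvalueVolume,
) -> tuple[ScalarMapVolume, ScalarMapVolume, ScalarMapVolume]:
    """Compute (MD, FA, RD) maps from sorted tensor eigenvalues.

    Negative eigenvalues below -1e-9 are clamped to 0 with a warning (noise
    floor).  Voxels where all three eigenvalues are 0 get FA = 0.
    """
    lams = np.stack([ev.lam1, ev.lam2, ev.lam3])
    if not np.isfinite(lams).all():
        raise ValueError("eigenvalues must be finite")
    if (lams < -1e-9).any():
        warnings.warn(
            f"{int((lams < -1e-9).sum())} negative eigenvalues clamped to 0",
            stacklevel=2,
        )
    lams = np.clip(lams, 0.0, None)
    l1, l2, l3 = lams

    md = (l1 + l2 + l3) / 3.0
    rd = (l2 + l3) / 2.0
    num = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    den = np.sqrt(l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    return (
        ScalarMapVolume(md, "MD", ev.spacing),
        ScalarMapVolume(fa, "FA", ev.spacing),
        ScalarMapVolume(rd, "RD", ev.spacing),
    )


# ---------------------------------------------------------------------------
# Slice extraction


def rescale_to_8bit(
    values: np.ndarray,
    roi: np.ndarray | None = None,
    lo: float = 1.0,
    hi: float = 99.0,
) -> np.ndarray:
    """Linearly map the in-ROI [p_lo, p_hi] intensity range to [0, 255].

    Values outside the percentile window are clipped.  A constant-valued ROI
    maps to 128 everywhere inside; pixels outside ``roi`` are 0.
    """
    values = np.asarray(values, dtype=np.float64)
    if roi is None:
        roi = np.ones(values.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    inside = values[roi]
    if inside.size == 0:
        raise ValueError("ROI is empty")
    vlo, vhi = np.percentile(inside, [lo, hi])
    out = np.zeros(values.shape, dtype=np.uint8)
    if vhi <= vlo:
        out[roi] = 128
        return out
    scaled = np.clip((values - vlo) / (vhi - vlo), 0.0, 1.0) * 255.0
    out[roi] = np.rint(scaled[roi]).astype(np.uint8)
    return out


def extract_roi_slices(
    volume: ScalarMapVolume,
    mask: RoiMask,
    axis: int = 2,
    min_roi_pixels: int = 16,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> list[RoiSlice]:
    """Extract masked, cropped, 8-bit 2-D slices of the ROI.

    One :class:`RoiSlice` is produced per index along ``axis`` where the mask
    has at least ``min_roi_pixels`` in-plane voxels; each is cropped to the
    in-plane mask bounding box and intensity-rescaled per slice.
    """
    if volume.data.shape != mask.data.shape:
        raise ValueError("map and mask must share a grid")
    if mask.n_voxels == 0:
        raise ValueError("ROI mask is empty")
    n = volume.data.shape[axis]
    slices: list[RoiSlice] = []
    for idx in range(n):
        m2d = np.take(mask.data, idx, axis=axis)
        if int(m2d.sum()) < min_roi_pixels:
            continue
        v2d = np.take(volume.data, idx, axis=axis)
        rows = np.flatnonzero(m2d.any(axis=1))
        cols = np.flatnonzero(m2d.any(axis=0))
        r0, r1 = int(rows[0]), int(rows[-1]) + 1
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        crop_mask = m2d[r0:r1, c0:c1]
        crop_vals = v2d[r0:r1, c0:c1]
        pixels = rescale_to_8bit(crop_vals, crop_mask, *percentiles)
        slices.append(
            RoiSlice(pixels=pixels, slice_index=idx, bbox=(r0, c0, r1, c1), mask=crop_mask)
        )
    if not slices:
        warnings.warn(
            f"no slice reaches min_roi_pixels={min_roi_pixels}; returning empty list",
            stacklevel=2,
        )
    return slices
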