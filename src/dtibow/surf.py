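"""SURF keypoints and 64-d descriptors (speeded-up robust features).

Interest points are located as local maxima of the determinant of an
approximated Hessian, computed with box filters on an integral image; the
approximation error of the box-filter mixed derivative is compensated by the
standard 0.9 relative weight:

    det(H_approx) = Dxx · Dyy − (0.9 · Dxy)²

Box responses are normalized by filter area, so the detection threshold is
expressed on 8-bit intensity scale.  The filter-size pyramid uses four
octaves (9-15-21-27, 15-27-39-51, 27-51-75-99, 51-99-147-195) and the
standard scale mapping s = 1.2·L/9.  Keypoints are localized on the pixel
grid (no subpixel interpolation).

Orientation is the dominant direction of Gaussian-weighted Haar-wavelet
responses inside a radius-6s circle, found with a sliding 60° window; the
descriptor splits an oriented 20s square into 4×4 subregions of 5×5 samples
and accumulates (Σdx, Σ|dx|, Σdy, Σ|dy|) of rotated Haar responses, then
normalizes to unit length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter

from .descriptors import LocalFeature, SurfParams, _slice_too_small
from .dti_maps import RoiSlice

#: filter sizes per octave; s = 1.2 L / 9
OCTAVE_FILTER_SIZES = (
    (9, 15, 21, 27),
    (15, 27, 39, 51),
    (27, 51, 75, 99),
    (51, 99, 147, 195),
)

_ORI_WINDOW = np.pi / 3
_ORI_STEPS = 64


@dataclass
class IntegralImage:
    """Summed-area table: ``table[r, c]`` = Σ pixels in rows < r, cols < c."""

    table: np.ndarray

    @classmethod
    def from_image(cls, img: np.ndarray) -> "IntegralImage":
        img = np.asarray(img, dtype=np.float64)
        h, w = img.shape
        table = np.zeros((h + 1, w + 1))
        table[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
        return cls(table)

    @property
    def shape(self) -> tuple[int, int]:
        return self.table.shape[0] - 1, self.table.shape[1] - 1

    def rect_sum(self, r0, c0, r1, c1):
        """Sum of pixels in the half-open rectangle [r0, r1) × [c0, c1).

        Accepts scalars or broadcastable index arrays; indices are clipped to
        the image bounds.
        """
        h, w = self.shape
        r0 = np.clip(r0, 0, h)
        r1 = np.clip(r1, 0, h)
        c0 = np.clip(c0, 0, w)
        c1 = np.clip(c1, 0, w)
        t = self.table
        return t[r1, c1] - t[r0, c1] - t[r1, c0] + t[r0, c0]


def _hessian_det(ii: IntegralImage, L: int) -> np.ndarray:
    """Area-normalized box-filter Hessian determinant at every pixel.

    Pixels whose L×L support leaves the image are set to -inf.
    """
    h, w = ii.shape
    l = L // 3
    hr = (L - 1) // 2
    hm = (l - 1) // 2
    R = np.arange(h)[:, None]
    C = np.arange(w)[None, :]

    def box(dr0, dc0, dr1, dc1):
        return ii.rect_sum(R + dr0, C + dc0, R + dr1, C + dc1)

    dyy = box(-hr, -(l - 1), hr + 1, l) - 3.0 * box(-hm, -(l - 1), hm + 1, l)
    dxx = box(-(l - 1), -hr, l, hr + 1) - 3.0 * box(-(l - 1), -hm, l, hm + 1)
    dxy = (
        box(-l, -l, 0, 0)
        + box(1, 1, l + 1, l + 1)
        - box(-l, 1, 0, l + 1)
        - box(1, -l, l + 1, 0)
    )
    inv_area = 1.0 / (L * L)
    dxx *= inv_area
    dyy *= inv_area
    dxy *= inv_area
    det = dxx * dyy - (0.9 * dxy) ** 2
    valid = (R >= hr) & (R < h - hr) & (C >= hr) & (C < w - hr)
    det[~valid] = -np.inf
    return det


def detect_keypoints(
    ii: IntegralImage, threshold: float = 100.0, n_octaves: int = 4
) -> list[tuple[int, int, float]]:
    """Detect (row, col, scale) interest points by 3×3×3 non-max suppression
    of the Hessian-determinant pyramid."""
    h, w = ii.shape
    found: dict[tuple[int, int, int], float] = {}
    for octave in OCTAVE_FILTER_SIZES[:n_octaves]:
        sizes = [L for L in octave if L <= min(h, w)]
        if len(sizes) < 3:
            continue
        stack = np.stack([_hessian_det(ii, L) for L in sizes])
        mf = maximum_filter(stack, size=3, mode="constant", cval=-np.inf)
        for i in range(1, len(sizes) - 1):
            peaks = (stack[i] >= mf[i]) & (stack[i] > threshold)
            for r, c in zip(*np.nonzero(peaks)):
                key = (int(r), int(c), sizes[i])
                if key not in found:
                    found[key] = float(stack[i, r, c])
    return [(r, c, 1.2 * L / 9.0) for (r, c, L) in found]


def _haar(ii: IntegralImage, pr: np.ndarray, pc: np.ndarray, half: int):
    """Haar-wavelet responses dx, dy of box side 2·half centered at (pr, pc).

    Returns (dx, dy, valid); responses are zero where the wavelet support
    leaves the image.
    """
    h, w = ii.shape
    valid = (pr - half >= 0) & (pr + half <= h) & (pc - half >= 0) & (pc + half <= w)
    dx = ii.rect_sum(pr - half, pc, pr + half, pc + half) - ii.rect_sum(
        pr - half, pc - half, pr + half, pc
    )
    dy = ii.rect_sum(pr, pc - half, pr + half, pc + half) - ii.rect_sum(
        pr - half, pc - half, pr, pc + half
    )
    dx = np.where(valid, dx, 0.0)
    dy = np.where(valid, dy, 0.0)
    return dx, dy, valid


_ori_grid = np.arange(-6, 7)
_ORI_J, _ORI_I = np.meshgrid(_ori_grid, _ori_grid, indexing="ij")
_ORI_SEL = (_ORI_I**2 + _ORI_J**2) <= 36
_ORI_DI = _ORI_I[_ORI_SEL]
_ORI_DJ = _ORI_J[_ORI_SEL]
_ORI_WEIGHT = np.exp(-(_ORI_DI**2 + _ORI_DJ**2) / (2 * 2.5**2))


def assign_orientation(ii: IntegralImage, r: int, c: int, s: float) -> float:
    """Dominant orientation in [0, 2π) from Haar responses in a radius-6s
    circle, maximized over a sliding 60° window."""
    pr = np.rint(r + _ORI_DJ * s).astype(int)
    pc = np.rint(c + _ORI_DI * s).astype(int)
    half = max(1, int(round(2 * s)))
    dx, dy, valid = _haar(ii, pr, pc, half)
    dx = dx * _ORI_WEIGHT
    dy = dy * _ORI_WEIGHT
    phi = np.arctan2(dy, dx)
    best_norm = -1.0
    best = 0.0
    for theta in np.linspace(0.0, 2 * np.pi, _ORI_STEPS, endpoint=False):
        m = (np.mod(phi - theta, 2 * np.pi) < _ORI_WINDOW) & valid
        sx = dx[m].sum()
        sy = dy[m].sum()
        n = sx * sx + sy * sy
        if n > best_norm:
            best_norm = n
            best = float(np.arctan2(sy, sx))
    return float(np.mod(best, 2 * np.pi))


_desc_idx = np.arange(20) - 9.5
_DESC_V, _DESC_U = np.meshgrid(_desc_idx, _desc_idx, indexing="ij")
_DESC_WEIGHT = np.exp(-(_DESC_U**2 + _DESC_V**2) / (2 * 3.3**2))


def compute_descriptor(
    ii: IntegralImage, r: int, c: int, s: float, theta: float
) -> np.ndarray | None:
    """64-d SURF descriptor: 4×4 subregions × (Σdx, Σ|dx|, Σdy, Σ|dy|) of
    rotated, Gaussian-weighted Haar responses in an oriented 20s window."""
    co, si = np.cos(theta), np.sin(theta)
    X = (_DESC_U * co - _DESC_V * si) * s
    Y = (_DESC_U * si + _DESC_V * co) * s
    pr = np.rint(r + Y).astype(int)
    pc = np.rint(c + X).astype(int)
    half = max(1, int(round(s)))
    dx, dy, valid = _haar(ii, pr.ravel(), pc.ravel(), half)
    dx = dx.reshape(20, 20)
    dy = dy.reshape(20, 20)
    du = (dx * co + dy * si) * _DESC_WEIGHT
    dv = (-dx * si + dy * co) * _DESC_WEIGHT
    blocks = np.stack(
        [
            du.reshape(4, 5, 4, 5).sum(axis=(1, 3)),
            np.abs(du).reshape(4, 5, 4, 5).sum(axis=(1, 3)),
            dv.reshape(4, 5, 4, 5).sum(axis=(1, 3)),
            np.abs(dv).reshape(4, 5, 4, 5).sum(axis=(1, 3)),
        ],
        axis=-1,
    )
    vec = blocks.ravel()
    norm = np.linalg.norm(vec)
    if norm == 0:
        return None
    return vec / norm


def surf_features(
    roi_slice: RoiSlice, params: SurfParams | None = None
) -> list[LocalFeature]:
    """Detect SURF keypoints on one ROI slice and compute 64-d descriptors.

    Constant slices yield no keypoints (the Hessian determinant is
    identically zero).  Keypoints outside the ROI mask are discarded.
    """
    params = params or SurfParams()
    if _slice_too_small(roi_slice):
        return []
    img = roi_slice.pixels.astype(np.float64)
    ii = IntegralImage.from_image(img)
    feats: list[LocalFeature] = []
    h, w = roi_slice.mask.shape
    for r, c, s in detect_keypoints(ii, params.hessian_threshold, params.n_octaves):
        if not roi_slice.mask[min(r, h - 1), min(c, w - 1)]:
            continue
        theta = assign_orientation(ii, r, c, s)
        vec = compute_descriptor(ii, r, c, s, theta)
        if vec is None:
            continue
        feats.append(
            LocalFeature(
                slice_index=roi_slice.slice_index,
                x=float(c),
                y=float(r),
                scale=float(s),
                orientation=theta,
                detector="SURF",
                vector=vec,
            )
        )
    return feats
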