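"""Bag-of-visual-words vocabularies and volume-signature histograms.

Descriptors pooled from the training subjects are clustered into K "visual
words" (k-means); each subject's descriptors are then assigned to their
nearest word and the occurrence counts, L1-normalized, form the subject's
volume-signature histogram — a fixed-length fingerprint of the ROI that is
comparable across subjects despite varying keypoint counts.

Feature-level fusion pools the descriptor sets of the MD, FA and RD maps
into one clustering problem before the vocabulary is built
(``fuse_features``); the alternative reading — concatenating three per-map
K-bin histograms into a 3K vector — is available as the
``histogram_concat`` fusion mode in :mod:`dtibow.pipeline`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .descriptors import LocalFeature, descriptor_matrix

logger = logging.getLogger(__name__)


@dataclass
class Codebook:
    """K visual-word centroids in descriptor space."""

    centroids: np.ndarray  # (K, d)
    detector: str
    source_maps: tuple[str, ...]
    rng_seed: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 2:
            raise ValueError("codebook needs K >= 2 centroid rows")
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            centroids=self.centroids,
            detector=self.detector,
            source_maps=np.array(self.source_maps),
            rng_seed=self.rng_seed,
        )

    @classmethod
    def load(cls, path) -> "Codebook":
        z = np.load(path, allow_pickle=False)
        return cls(
            centroids=z["centroids"],
            detector=str(z["detector"]),
            source_maps=tuple(z["source_maps"]),
            rng_seed=int(z["rng_seed"]),
        )


@dataclass
class VolumeSignature:
    """Per-subject L1-normalized histogram of visual-word occurrences.

    A subject with zero features gets an all-zero histogram and is flagged
    (``n_features == 0``) rather than excluded.
    """

    counts: np.ndarray
    histogram: np.ndarray
    subject_id: str = ""
    source_maps: tuple[str, ...] = ()

    @property
    def n_features(self) -> int:
        return int(self.counts.sum())


def build_codebook(
    features: list[LocalFeature] | np.ndarray,
    K: int,
    seed: int,
    source_maps: tuple[str, ...] = (),
    detector: str | None = None,
) -> Codebook:
    """Cluster pooled training descriptors into K visual words.

    k-means with k-means++ initialization, a fixed seed, at most 300
    iterations and relative-inertia tolerance 1e-4; empty clusters are
    reseeded to the farthest points.
    """
    if isinstance(features, np.ndarray):
        X = features
        if detector is None:
            raise ValueError("detector must be given with a raw descriptor matrix")
    else:
        dets = {f.detector for f in features}
        if len(dets) > 1:
            raise ValueError(f"mixed detectors in descriptor pool: {sorted(dets)}")
        X = descriptor_matrix(features)
        detector = detector or (dets.pop() if dets else "SIFT")
    if X.shape[0] < K:
        raise ValueError(
            f"{X.shape[0]} descriptors < K={K}; reduce the vocabulary size"
        )
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    ).fit(X)
    return Codebook(
        centroids=km.cluster_centers_,
        detector=detector,
        source_maps=tuple(source_maps),
        rng_seed=seed,
    )


def assign_words(descriptors: np.ndarray, book: Codebook) -> np.ndarray:
    """Index of the Euclidean-nearest centroid per descriptor (ties → lowest
    index, the argmin convention)."""
    if descriptors.shape[0] == 0:
        return np.empty(0, dtype=int)
    if descriptors.shape[1] != book.dim:
        raise ValueError(
            f"descriptor dim {descriptors.shape[1]} != codebook dim {book.dim}"
        )
    return cdist(descriptors, book.centroids).argmin(axis=1)


def quantize(
    features: list[LocalFeature] | np.ndarray,
    book: Codebook,
    subject_id: str = "",
) -> VolumeSignature:
    """Quantize one subject's descriptors into a volume-signature histogram."""
    X = features if isinstance(features, np.ndarray) else descriptor_matrix(features)
    if X.shape[0] == 0:
        logger.warning("subject %r has zero features; all-zero signature", subject_id)
        z = np.zeros(book.K)
        return VolumeSignature(
            counts=z.astype(int), histogram=z, subject_id=subject_id,
            source_maps=book.source_maps,
        )
    words = assign_words(X, book)
    counts = np.bincount(words, minlength=book.K)
    return VolumeSignature(
        counts=counts,
        histogram=counts / counts.sum(),
        subject_id=subject_id,
        source_maps=book.source_maps,
    )


def fuse_features(
    per_map_features: dict[str, list[LocalFeature]],
) -> list[LocalFeature]:
    """Pool the MD/FA/RD descriptor sets into one list (feature-level fusion).

    All lists must come from the same detector; descriptor vectors are kept
    bit-exactly.
    """
    detectors = {f.detector for feats in per_map_features.values() for f in feats}
    if len(detectors) > 1:
        raise ValueError(f"cannot fuse features from mixed detectors: {sorted(detectors)}")
    pooled: list[LocalFeature] = []
    for kind in sorted(per_map_features):
        pooled.extend(per_map_features[kind])
    return pooled


def signature_matrix(signatures: list[VolumeSignature]) -> pd.DataFrame:
    """Subjects × K histogram matrix, indexed by subject id."""
    return pd.DataFrame(
        np.stack([s.histogram for s in signatures]),
        index=[s.subject_id for s in signatures],
        columns=[f"w{k}" for k in range(signatures[0].histogram.size)],
    )
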