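"""Shared fixtures: generated texture slices and small phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from dtibow.benchmark import texture_slice
from dtibow.descriptors import extract_subject_features
from dtibow.synthetic import CLASSES, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def texture128():
    """A 128×128 band-limited texture slice (full-frame mask)."""
    return texture_slice(size=128, granularity=2.0, seed=0)


def small_spec(n_per_class: int = 6, seed: int = 0, **overrides) -> CohortSpec:
    """A fast cohort spec for unit tests.

    The 48×48×16 grid keeps the central ROI crops ~25 px across — the
    smallest extent on which both detectors' scale pyramids still operate.
    """
    if not isinstance(n_per_class, dict):
        n_per_class = {c: n_per_class for c in CLASSES}
    kw = dict(grid=(48, 48, 16), n_per_class=n_per_class, seed=seed)
    kw.update(overrides)
    return CohortSpec.test_scale(**kw)


def cohort_features(spec: CohortSpec, detector: str = "SIFT", kinds=("MD",)):
    """Generate a cohort and extract per-map features in memory."""
    feats, labels = {}, {}
    for sid, cls, maps, mask in generate_cohort(spec):
        feats[sid] = extract_subject_features(
            {k: maps[k] for k in kinds}, mask, detector=detector
        )
        labels[sid] = cls
    return feats, labels


@pytest.fixture()
def rng():
    # fresh, per-test stream so results are order-independent
    return np.random.default_rng(12345)
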