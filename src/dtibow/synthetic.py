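"""Synthetic phantom cohorts: MD/FA/RD volumes with class-dependent ROI texture.

Real cohorts of registered DTI scalar maps come from access-controlled
archives, so every pipeline stage is exercised on phantoms instead.  A
phantom subject consists of three scalar-map volumes around plausible
baselines (MD 0.7e-3 mm²/s, FA 0.35, RD 0.5e-3 mm²/s) plus an ellipsoidal
ROI mask.  Inside the ROI each map receives a band-limited random texture —
Gaussian-smoothed white noise at a class-specific granularity length-scale,
scaled to a class-specific contrast amplitude — plus a class-specific mean
shift (diffusivity up and anisotropy down with increasing impairment).
Outside the ROI only baseline plus acquisition-like Gaussian noise remains.

What the generator emulates is the abstraction "within-ROI texture
statistics differ by class", which is the property the keypoint-descriptor
pipeline is sensitive to; it makes no attempt at biophysical realism.  The
``map_split`` weights apportion each class's signal across the three maps,
so experiments with the signal confined to one map, or split across maps
(the fusion setting), can be generated on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dti_maps import MAP_KINDS, RoiMask, ScalarMapVolume, write_mask, write_volume

CLASSES = ("NC", "MCI", "AD")

#: plausible hippocampal baselines per map kind
BASELINES = {"MD": 0.7e-3, "FA": 0.35, "RD": 0.5e-3}

#: direction of the disease-related mean shift (diffusivity ↑, anisotropy ↓)
SHIFT_SIGN = {"MD": +1.0, "FA": -1.0, "RD": +1.0}


@dataclass(frozen=True)
class ClassEffect:
    """Texture parameters of one class.

    mean_shift: fractional shift of the in-ROI mean relative to baseline
    (applied with :data:`SHIFT_SIGN` per map); contrast: texture amplitude as
    a fraction of baseline; granularity: Gaussian smoothing length-scale of
    the texture field, in voxels (smaller = finer-grained texture).
    """

    mean_shift: float
    contrast: float
    granularity: float


#: Default class effects (full effect = effect_scale 1): progressive
#: impairment shifts the in-ROI mean by 0–10 %, raises texture contrast
#: 10→20 % and refines the granularity 4.0→1.4 voxels.  Because every slice
#: is percentile-rescaled to 8-bit before descriptor extraction, the class
#: signal the descriptors actually see is carried by the granularity
#: length-scale and the texture-to-noise ratio, not the absolute levels.
DEFAULT_EFFECTS: dict[str, ClassEffect] = {
    "NC": ClassEffect(0.00, 0.10, 4.0),
    "MCI": ClassEffect(0.05, 0.15, 2.4),
    "AD": ClassEffect(0.10, 0.20, 1.4),
}

#: Cohort sizes of the emulated study population.
DEFAULT_N_PER_CLASS = {"NC": 31, "MCI": 30, "AD": 35}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``map_split`` gives, per class (or one triple for all classes), the
    fraction of that class's signal carried by each of (MD, FA, RD); the
    per-map effect interpolates between the class-neutral parameters and the
    class's own parameters with weight ``split / max(split)``, so a split of
    (1, 0, 0) confines the class signal entirely to MD while the other two
    maps keep class-independent texture.  ``effect_scale`` globally
    interpolates every class's parameters toward their across-class mean:
    0 makes the classes statistically identical (a null cohort).
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    grid: tuple[int, int, int] = (256, 256, 59)
    spacing: tuple[float, float, float] = (1.3, 1.3, 2.7)
    roi_center: tuple[float, float, float] | None = None
    roi_radii: tuple[float, float, float] | None = None
    effects: dict[str, ClassEffect] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    effect_scale: float = 1.0
    map_split: dict[str, tuple[float, float, float]] | tuple[float, float, float] = (
        1 / 3,
        1 / 3,
        1 / 3,
    )
    noise_sd: float = 0.02  # fraction of baseline, everywhere
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry ---------------------------------------------------

    @property
    def center(self) -> tuple[float, float, float]:
        if self.roi_center is not None:
            return self.roi_center
        return tuple((g - 1) / 2.0 for g in self.grid)

    @property
    def radii(self) -> tuple[float, float, float]:
        if self.roi_radii is not None:
            return self.roi_radii
        nx, ny, nz = self.grid
        return (nx / 4.0, ny / 4.0, nz / 3.0)

    def split_for(self, class_label: str) -> tuple[float, float, float]:
        if isinstance(self.map_split, dict):
            return tuple(self.map_split[class_label])
        return tuple(self.map_split)

    def validate(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 1:
                raise ValueError("n_per_class entries must be >= 1")
        for cls in self.n_per_class:
            if cls not in self.effects:
                raise ValueError(f"no effect parameters for class {cls!r}")
            s = self.split_for(cls)
            if len(s) != 3 or min(s) < 0 or abs(sum(s) - 1.0) > 1e-9:
                raise ValueError("map_split must be 3 nonnegative fractions summing to 1")
        for c, r, g in zip(self.center, self.radii, self.grid):
            if c - r < 0 or c + r > g - 1:
                raise ValueError("ROI ellipsoid must fit inside the grid")
        # FA must stay representable: baseline·(1 + shift + ~4·contrast) in [0, 1]
        for cls, eff in self.effects.items():
            hi = BASELINES["FA"] * (1 + abs(eff.mean_shift) + 4 * eff.contrast)
            if hi > 1.0 or hi < 0.0:
                raise ValueError(f"class {cls!r} effect pushes FA outside [0, 1]")

    @classmethod
    def test_scale(cls, **overrides) -> "CohortSpec":
        """A scaled-down geometry (64×64×24) for desk-scale experiments."""
        kw = dict(grid=(64, 64, 24), n_per_class={c: 10 for c in CLASSES})
        kw.update(overrides)
        return cls(**kw)


def ellipsoid_mask(
    grid: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    label: str = "synthetic-hippocampus",
) -> RoiMask:
    """Binary ellipsoidal ROI mask (radii in voxels)."""
    ax = [np.arange(n) for n in grid]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    d = (
        ((X - center[0]) / radii[0]) ** 2
        + ((Y - center[1]) / radii[1]) ** 2
        + ((Z - center[2]) / radii[2]) ** 2
    )
    return RoiMask(data=(d <= 1.0).astype(np.uint8), spacing=spacing, label=label)


def _neutral_effect(effects: dict[str, ClassEffect]) -> ClassEffect:
    vals = np.array([(e.mean_shift, e.contrast, e.granularity) for e in effects.values()])
    m = vals.mean(axis=0)
    return ClassEffect(*m)


def _blend(a: ClassEffect, b: ClassEffect, w: float) -> ClassEffect:
    """a + w·(b − a), componentwise."""
    return ClassEffect(
        a.mean_shift + w * (b.mean_shift - a.mean_shift),
        a.contrast + w * (b.contrast - a.contrast),
        a.granularity + w * (b.granularity - a.granularity),
    )


def make_subject(
    spec: CohortSpec, class_label: str, subject_seed: int
) -> tuple[dict[str, ScalarMapVolume], RoiMask]:
    """Generate one subject's (MD, FA, RD) volumes and ROI mask.

    Deterministic in (spec.seed, subject_seed).
    """
    if class_label not in spec.n_per_class and class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng([spec.seed, int(subject_seed)])
    mask = ellipsoid_mask(spec.grid, spec.center, spec.radii, spec.spacing)
    inside = mask.data

    neutral = _neutral_effect(spec.effects)
    class_eff = _blend(neutral, spec.effects[class_label], spec.effect_scale)
    split = spec.split_for(class_label)
    wmax = max(max(split), 1e-12)

    maps: dict[str, ScalarMapVolume] = {}
    for kind, s in zip(("MD", "FA", "RD"), split):
        base = BASELINES[kind]
        eff = _blend(neutral, class_eff, s / wmax)
        white = rng.normal(size=spec.grid)
        texture = gaussian_filter(white, sigma=eff.granularity)
        t_in = texture[inside]
        sd = t_in.std()
        texture = (texture - t_in.mean()) / (sd if sd > 0 else 1.0)
        data = base * (1.0 + spec.noise_sd * rng.normal(size=spec.grid))
        data = data + inside * base * (
            SHIFT_SIGN[kind] * eff.mean_shift + eff.contrast * texture
        )
        if kind == "FA":
            data = np.clip(data, 0.0, 1.0)
        else:
            data = np.clip(data, base * 1e-3, None)
        maps[kind] = ScalarMapVolume(data=data, kind=kind, spacing=spec.spacing)
    return maps, mask


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[str, str, dict[str, ScalarMapVolume], RoiMask]]:
    """Generate all subjects in memory.

    Returns [(subject_id, class_label, maps, mask), ...] in a deterministic
    order; subject seeds are derived from the enumeration order.
    """
    out = []
    idx = 0
    for cls in CLASSES:
        for _ in range(spec.n_per_class.get(cls, 0)):
            sid = f"{cls}_{idx:03d}"
            maps, mask = make_subject(spec, cls, idx)
            out.append((sid, cls, maps, mask))
            idx += 1
    return out


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full cohort to disk in the pipeline's input formats.

    Produces one NIfTI volume per map plus the mask per subject, and a
    ``manifest.csv`` with columns subject_id, class_label, md_path, fa_path,
    rd_path, mask_path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, cls, maps, mask in generate_cohort(spec):
        paths = {}
        for kind in MAP_KINDS:
            p = out_dir / f"{sid}_{kind.lower()}.nii.gz"
            write_volume(maps[kind], p)
            paths[f"{kind.lower()}_path"] = str(p)
        mp = out_dir / f"{sid}_mask.nii.gz"
        write_mask(mask, mp)
        rows.append({"subject_id": sid, "class_label": cls, **paths, "mask_path": str(mp)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same cohort with effect_scale = 0 (labels independent of data)."""
    return replace(spec, effect_scale=0.0)
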