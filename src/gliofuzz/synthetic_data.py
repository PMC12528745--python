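"""Synthetic 4-channel pseudo-MRI cohorts with ground-truth lesions.

Every other module is exercised on volumes from this generator, so it
encodes the class structure the classifier is supposed to detect: an
ellipsoidal "brain" with smooth tissue texture carries an ellipsoidal
lesion whose size, core heterogeneity and rim enhancement differ between
the two grades.  High-grade (HGG-like) cases get a larger lesion
(radius 0.18-0.28 of the brain's short semi-axis), multiplicative core
speckle, a bright contrast rim in the T1ce-like channel and stronger
FLAIR-like hyperintensity; low-grade (LGG-like) cases are smaller
(0.08-0.14) and homogeneous.  All channels receive Rician-like noise
(magnitude of a complex Gaussian), matching MRI magnitude statistics.

Cohort composition mirrors the study cohort: 230 HGG + 70 LGG with
train/val/test splits of (172, 32, 26) and (48, 8, 14) per class.  The
desk-scale preset (:meth:`CohortSpec.desk`) keeps the ~3:1 imbalance at
100 cases (80 train / 20 test) on 32x32x16 volumes so a full two-stage
training run finishes in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["CohortSpec", "VolumeSample", "Cohort", "generate_case", "generate_cohort"]

LABELS = ("HGG", "LGG")
SPLITS = ("train", "val", "test")
CHANNELS = ("t1", "t1ce", "t2", "flair")

_T1, _T1CE, _T2, _FLAIR = range(4)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and lesion/noise model parameters."""

    n_hgg: int = 230
    n_lgg: int = 70
    #: per-class (train, val, test) counts
    split_counts: Dict[str, Tuple[int, int, int]] = field(
        default_factory=lambda: {"HGG": (172, 32, 26), "LGG": (48, 8, 14)}
    )
    shape: Tuple[int, int, int] = (32, 32, 16)
    #: lesion radius as a fraction of the brain's short semi-axis
    lesion_radius_frac: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"HGG": (0.18, 0.28), "LGG": (0.08, 0.14)}
    )
    contrast_effect: float = 0.5  # T1ce rim boost, HGG only (post-normalization scale)
    heterogeneity: float = 0.3  # multiplicative speckle sigma, HGG core
    noise_sigma: float = 0.05  # Rician-like noise scale
    seed: int = 0

    def __post_init__(self) -> None:
        for label, total in (("HGG", self.n_hgg), ("LGG", self.n_lgg)):
            counts = self.split_counts[label]
            if sum(counts) != total:
                raise ValueError(
                    f"{label} split counts {counts} sum to {sum(counts)}, "
                    f"expected {total}"
                )
        for lo, hi in self.lesion_radius_frac.values():
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("lesion radius fractions must lie in (0, 1)")
        if min(self.shape) < 16:
            raise ValueError("spatial dims must be >= 16")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """100-case desk-scale cohort: 80 train / 20 test, ~3:1 imbalance."""
        return cls(
            n_hgg=70,
            n_lgg=30,
            split_counts={"HGG": (56, 0, 14), "LGG": (24, 0, 6)},
            seed=seed,
            **overrides,
        )


@dataclass
class VolumeSample:
    """One labeled 4-channel volume with its ground-truth lesion mask."""

    volume: np.ndarray  # (4, X, Y, Z)
    label: str  # "HGG" | "LGG"
    mask: np.ndarray  # bool (X, Y, Z), lesion voxels
    split: str  # "train" | "val" | "test"
    case_id: str

    @property
    def y(self) -> int:
        """Binary label with HGG as the positive class."""
        return 1 if self.label == "HGG" else 0


@dataclass
class Cohort:
    samples: List[VolumeSample]
    spec: CohortSpec

    def __iter__(self) -> Iterator[VolumeSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, split: str) -> List[VolumeSample]:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return [s for s in self.samples if s.split == split]

    def volumes(self, split: Optional[str] = None) -> List[np.ndarray]:
        samples = self.samples if split is None else self.subset(split)
        return [s.volume for s in samples]

    def labels(self, split: Optional[str] = None) -> np.ndarray:
        samples = self.samples if split is None else self.subset(split)
        return np.array([s.y for s in samples])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"case_id": s.case_id, "label": s.label, "split": s.split}
                for s in self.samples
            ]
        )


def _ellipsoid_mask(
    shape: Sequence[int], center: np.ndarray, semi_axes: np.ndarray
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes)
    )
    return dist2 <= 1.0


def _rician(volume: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    # magnitude of (signal + complex Gaussian noise)
    real = volume + sigma * rng.standard_normal(volume.shape)
    imag = sigma * rng.standard_normal(volume.shape)
    return np.sqrt(real**2 + imag**2)


def generate_case(
    class_label: str, spec: CohortSpec, rng: np.random.Generator
) -> VolumeSample:
    """Generate one labeled case; deterministic for a given generator state."""
    if class_label not in LABELS:
        raise ValueError(f"class_label must be one of {LABELS}")
    shape = np.array(spec.shape)

    # brain: centered ellipsoid with +-5% jittered semi-axes
    brain_center = shape / 2.0 + rng.uniform(-0.5, 0.5, size=3)
    brain_axes = shape * np.array([0.42, 0.42, 0.40]) * rng.uniform(0.95, 1.05, size=3)
    brain = _ellipsoid_mask(spec.shape, brain_center, brain_axes)

    # lesion: random-centered ellipsoid guaranteed inside the brain;
    # radius is a fraction of the volume's short axis
    lo, hi = spec.lesion_radius_frac[class_label]
    radius = rng.uniform(lo, hi) * min(spec.shape)
    lesion_axes = radius * rng.uniform(0.85, 1.15, size=3)
    if np.any(lesion_axes >= brain_axes):
        raise ValueError("lesion does not fit inside the brain; check radius fractions")
    margin = brain_axes - lesion_axes
    while True:
        offset = rng.uniform(-1.0, 1.0, size=3) * margin * 0.8
        if np.sum((offset / margin) ** 2) <= 1.0:
            break
    lesion_center = brain_center + offset
    lesion = _ellipsoid_mask(spec.shape, lesion_center, lesion_axes) & brain
    core = ndimage.binary_erosion(lesion, iterations=1)
    rim = lesion & ~core

    # smooth tissue texture shared across channels
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=2.0)
    tissue = 0.5 + 0.08 * texture

    channels = np.zeros((4, *spec.shape))
    channels[_T1] = np.where(lesion, tissue - 0.12, tissue)
    channels[_T1CE] = tissue.copy()
    channels[_T2] = np.where(lesion, tissue + 0.25, tissue)
    flair_boost = 0.35 if class_label == "HGG" else 0.25
    channels[_FLAIR] = np.where(lesion, tissue + flair_boost, tissue)

    if class_label == "HGG":
        channels[_T1CE][rim] += spec.contrast_effect
        speckle = 1.0 + spec.heterogeneity * rng.standard_normal(spec.shape)
        speckle = np.clip(speckle, 0.0, None)
        for ch in range(4):
            channels[ch][core] *= speckle[core]
    else:
        channels[_T1CE][lesion] += 0.05  # faint, non-enhancing

    channels *= brain  # background is air
    channels = _rician(channels, spec.noise_sigma, rng)
    channels = np.clip(channels, 0.0, None)

    return VolumeSample(
        volume=channels,
        label=class_label,
        mask=lesion,
        split="train",  # assigned by generate_cohort
        case_id="",
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort with stratified, seeded split assignment."""
    rng = np.random.default_rng(spec.seed)
    samples: List[VolumeSample] = []
    for label, total in (("HGG", spec.n_hgg), ("LGG", spec.n_lgg)):
        n_train, n_val, n_test = spec.split_counts[label]
        split_tags = (
            ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        )
        order = rng.permutation(total)
        for idx in range(total):
            sample = generate_case(label, spec, rng)
            sample.split = split_tags[order[idx]]
            sample.case_id = f"{label.lower()}_{idx:04d}"
            samples.append(sample)
    return Cohort(samples=samples, spec=spec)
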