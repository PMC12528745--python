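"""Readers/writers and run configuration.

Native fixture format is a compressed NumPy bundle (one ``.npz`` per case
plus a CSV manifest), which keeps synthetic cohorts fast and dependency
free.  NIfTI (.nii/.nii.gz) is supported for interoperability with
BraTS-style directories: one file per modality with suffixes _t1, _t1ce,
_t2, _flair, channels stacked in that fixed order, affine preserved so
masks can be written back aligned.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .evaluation import SCHEMA_VERSION, MetricsReport
from .synthetic_data import CHANNELS, Cohort, CohortSpec, VolumeSample

__all__ = [
    "save_cohort",
    "load_cohort",
    "read_case",
    "write_nifti_case",
    "write_mask",
    "write_report",
    "read_report",
    "RunConfig",
]

logger = logging.getLogger(__name__)

MODALITY_SUFFIXES = tuple(f"_{c}" for c in CHANNELS)  # _t1, _t1ce, _t2, _flair


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as per-case .npz bundles plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in cohort:
        np.savez_compressed(
            out_dir / f"{sample.case_id}.npz",
            volume=sample.volume,
            mask=sample.mask,
        )
    manifest = cohort.manifest()
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    spec_dict = dataclasses.asdict(cohort.spec)
    (out_dir / "cohort_spec.json").write_text(json.dumps(spec_dict, default=list, indent=2))
    logger.info("wrote %d cases to %s", len(cohort), out_dir)
    return out_dir


def load_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    spec_raw = json.loads((in_dir / "cohort_spec.json").read_text())
    spec_raw["shape"] = tuple(spec_raw["shape"])
    spec_raw["split_counts"] = {k: tuple(v) for k, v in spec_raw["split_counts"].items()}
    spec_raw["lesion_radius_frac"] = {
        k: tuple(v) for k, v in spec_raw["lesion_radius_frac"].items()
    }
    spec = CohortSpec(**spec_raw)
    samples: List[VolumeSample] = []
    for row in manifest.itertuples():
        with np.load(in_dir / f"{row.case_id}.npz") as data:
            samples.append(
                VolumeSample(
                    volume=data["volume"],
                    mask=data["mask"],
                    label=row.label,
                    split=row.split,
                    case_id=row.case_id,
                )
            )
    return Cohort(samples=samples, spec=spec)


def _find_modality(case_dir: Path, suffix: str) -> Path:
    for ext in (".nii.gz", ".nii"):
        matches = sorted(case_dir.glob(f"*{suffix}{ext}"))
        if matches:
            return matches[0]
    raise FileNotFoundError(
        f"missing modality file with suffix '{suffix}' in {case_dir}"
    )


def read_case(case_dir: str | Path):
    """Read a BraTS-style subject directory into (volume, affine).

    Channels are stacked in the fixed order (T1, T1ce, T2, FLAIR).
    """
    case_dir = Path(case_dir)
    arrays = []
    affine = None
    for suffix in MODALITY_SUFFIXES:
        img = nib.load(str(_find_modality(case_dir, suffix)))
        arrays.append(np.asarray(img.dataobj, dtype=float))
        if affine is None:
            affine = img.affine
    return np.stack(arrays), affine


def write_nifti_case(
    sample: VolumeSample, out_dir: str | Path, affine: Optional[np.ndarray] = None
) -> Path:
    """Export one sample as four NIfTI modality files (+ mask)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    for ch, suffix in enumerate(MODALITY_SUFFIXES):
        img = nib.Nifti1Image(sample.volume[ch].astype(np.float32), affine)
        nib.save(img, str(out_dir / f"{sample.case_id}{suffix}.nii.gz"))
    nib.save(
        nib.Nifti1Image(sample.mask.astype(np.uint8), affine),
        str(out_dir / f"{sample.case_id}_mask.nii.gz"),
    )
    return out_dir


def write_mask(mask: np.ndarray, path: str | Path, affine: Optional[np.ndarray] = None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_report(report: MetricsReport, path: str | Path) -> Path:
    """Serialize a metrics report as JSON with a CSV twin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    path.write_text(json.dumps(payload, indent=2))
    pd.DataFrame([payload]).to_csv(path.with_suffix(".csv"), index=False)
    logger.info("report written to %s (schema v%d)", path, SCHEMA_VERSION)
    return path


def read_report(path: str | Path) -> Dict[str, object]:
    return json.loads(Path(path).read_text())


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration; unknown keys are rejected fail-fast."""

    seed: int = 0
    out_dir: str = "runs"
    verbosity: int = 1
    cohort: Dict[str, object] = dataclasses.field(default_factory=dict)
    preprocess: Dict[str, object] = dataclasses.field(default_factory=dict)
    train: Dict[str, object] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; expected a subset of "
                f"{sorted(known)}"
            )
        return cls(**raw)

    def write_resolved(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path
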