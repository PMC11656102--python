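"""File I/O: NIfTI images, cohort/weights CSVs, configs and result records.

Conventions: volumes are stored in mm^3 throughout; CSVs are UTF-8 with a
header row; every result record echoes the seed and a hash of the
configuration that produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import VolumeSamples, BootstrapConfig, WeightRecord
from .images import IntensityImage, LabelImage

__all__ = [
    "read_image",
    "write_image",
    "read_cohort",
    "read_replicate_volumes",
    "write_weights",
    "write_results",
    "load_config",
    "provenance_record",
]

COHORT_REQUIRED = ("subject_id", "volume_mm3")


def read_image(path: str | Path, kind: str = "intensity") -> IntensityImage | LabelImage:
    """Read a NIfTI-1 image; ``kind`` selects intensity or label semantics.

    Voxel sizes come from the header zooms.  A file declared as labels must
    hold integer values.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if kind == "intensity":
        return IntensityImage(data.astype(float), voxel_size)
    if kind == "label":
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.array_equal(rounded, data):
                raise ValueError(f"{path}: declared as labels but holds non-integer values")
            data = rounded
        return LabelImage(data.astype(np.int32), voxel_size)
    raise ValueError(f"unknown image kind {kind!r}")


def write_image(image: IntensityImage | LabelImage, path: str | Path) -> None:
    """Write an image as NIfTI-1 (labels as integer datatype)."""
    if isinstance(image, LabelImage):
        data = image.labels.astype(np.int32)
    else:
        data = image.values.astype(np.float32)
    affine = np.diag(list(image.voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(image.voxel_size)
    nib.save(img, str(path))


def read_cohort(
    path: str | Path, required_columns: tuple[str, ...] = COHORT_REQUIRED
) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Checks the required columns, positive volumes, positive weights in any
    weight column present, and unique subject ids.
    """
    table = pd.read_csv(path)
    missing = set(required_columns) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_id values: {dupes[:5]}")
    if "volume_mm3" in table.columns and (table["volume_mm3"] <= 0).any():
        raise ValueError(f"{path}: volumes must be positive")
    for col in ("precision_weight", "cv_weight"):
        if col in table.columns and (table[col] <= 0).any():
            raise ValueError(f"{path}: column {col} must be strictly positive")
    return table


def read_replicate_volumes(path: str | Path) -> dict[str, VolumeSamples]:
    """Read precomputed bootstrap replicate volumes (the statistical route).

    Expects columns subject_id, replicate_index, volume_mm3; replicate
    order within a subject follows replicate_index.
    """
    table = pd.read_csv(path)
    missing = {"subject_id", "replicate_index", "volume_mm3"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    out: dict[str, VolumeSamples] = {}
    for sid, grp in table.groupby("subject_id", sort=True):
        grp = grp.sort_values("replicate_index")
        vols = grp["volume_mm3"].to_numpy(dtype=float)
        cfg = BootstrapConfig(n_replicates=len(vols))
        out[str(sid)] = VolumeSamples(subject_id=str(sid), volumes=vols, config=cfg)
    return out


def write_weights(records: list[WeightRecord], path: str | Path) -> None:
    """Write per-subject weight records as CSV."""
    rows = [
        {
            "subject_id": r.subject_id,
            "boot_variance_mm6": r.boot_variance,
            "precision_weight": r.precision_weight,
            "cv": r.cv,
            "cv_weight": r.cv_weight,
            "n_replicates": r.n_replicates,
            "flags": ";".join(r.flags),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def provenance_record(config, seed: int | None) -> dict:
    """Machine-readable provenance: config hash, seed, package version."""
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "seed": seed,
        "package_version": __version__,
    }


def write_results(result: dict, path: str | Path, config=None, seed: int | None = None) -> None:
    """Write a JSON result record with provenance attached."""
    record = dict(_jsonable(result))
    record["provenance"] = provenance_record(config, seed)
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
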