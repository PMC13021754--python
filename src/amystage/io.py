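"""CSV / NIfTI / JSON plumbing with provenance headers.

Every table written by the pipeline carries a provenance block (comment
lines: config hash, seed, stage name) so that two runs with equal config
hashes can be compared file-by-file.  Volumes and masks use NIfTI with an
identity affine scaled to 2 mm isotropic voxels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_volume",
    "read_volume",
    "write_json",
    "read_json",
    "config_hash",
]

VOXEL_MM = 2.0


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a provenance-headed CSV; malformed rows raise with the
    offending line number."""
    try:
        return pd.read_csv(path, comment="#", on_bad_lines="error")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err


def write_volume(data: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_json(obj, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": provenance or {}, "data": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def read_json(path):
    with open(path) as fh:
        payload = json.load(fh)
    return payload["data"]


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
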