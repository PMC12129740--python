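"""NIfTI-1 / TSV / JSON serialisation with grid bookkeeping."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import VolumeGrid

__all__ = ["save_volume", "load_volume", "save_table", "load_table",
           "save_json", "load_json", "grid_from_img"]


def grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size_mm=tuple(float(v) for v in np.diag(aff[:3, :3])),
        origin=tuple(float(v) for v in aff[:3, 3]),
    )


def save_volume(data: np.ndarray, grid: VolumeGrid, path,
                sidecar: Optional[dict] = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_size_mm + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path).replace(".nii.gz", "").replace(".nii", "")) \
            .with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), grid_from_img(img)


def save_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
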