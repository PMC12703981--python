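"""NIfTI and table I/O.

Volumes are carried as NIfTI-1 with the affine preserved; voxel sizes are
taken from the header zooms.  Phase volumes stored as scaled integers are
rescaled (nibabel applies the scl slope/intercept) and validated to lie in
(-pi, pi] within a small quantization tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import Mask, PhaseVolume, Volume

__all__ = ["read_volume", "write_volume", "read_phase", "read_mask", "write_table", "read_table", "write_json"]


def read_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])  # header stores float32
    return Volume(data=data, voxel_mm=zooms, affine=np.asarray(img.affine))


def write_volume(vol: Volume, path: str | Path) -> None:
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.voxel_mm) + [1.0])
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.iscomplexobj(data):
        raise ValueError("complex volumes must be written as separate magnitude/phase (or real/imag) files")
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    img.header.set_zooms(vol.voxel_mm)
    nib.save(img, str(path))


def read_phase(path: str | Path, tol: float = 1e-3) -> PhaseVolume:
    """Read a phase volume, validating the (-pi, pi] convention.

    Integer-stored phase rescaled by the NIfTI slope may land marginally
    outside the interval; values within ``tol`` are wrapped back, anything
    further out is an error.
    """
    vol = read_volume(path)
    d = vol.data
    if d.max() > np.pi + tol or d.min() < -np.pi - tol:
        raise ValueError(f"{path}: phase outside (-pi, pi] beyond tolerance ({d.min():.4f}..{d.max():.4f})")
    d = np.angle(np.exp(1j * d))
    d = np.where(d == -np.pi, np.pi, d)
    return PhaseVolume(data=d, voxel_mm=vol.voxel_mm, affine=vol.affine)


def read_mask(path: str | Path) -> Mask:
    vol = read_volume(path)
    return Mask(data=vol.data > 0.5, voxel_mm=vol.voxel_mm, affine=vol.affine)


def check_same_grid(*vols: Volume, names: list[str] | None = None) -> None:
    names = names or [f"input{i}" for i in range(len(vols))]
    ref = vols[0]
    for v, nm in zip(vols[1:], names[1:]):
        if v.data.shape != ref.data.shape:
            raise ValueError(f"shape mismatch between {names[0]} {ref.data.shape} and {nm} {v.data.shape}")
        if v.affine is not None and ref.affine is not None and not np.allclose(v.affine, ref.affine, atol=1e-4):
            raise ValueError(f"affine mismatch between {names[0]} and {nm}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
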