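"""Core grid containers and acquisition metadata.

Volumes are thin wrappers around 3-D numpy arrays carrying voxel geometry
(edge lengths in mm) and, optionally, a world affine.  All processing is done
in voxel space; the affine is only carried through for serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionParams",
    "Volume",
    "ComplexVolume",
    "PhaseVolume",
    "FieldMap",
    "Mask",
    "LabelVolume",
    "SusceptibilityMap",
    "WeightMap",
    "rad_per_ppm",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition constants for phase <-> field conversion.

    Parameters
    ----------
    te_s : echo time in seconds.
    tr_s : repetition time in seconds (carried for provenance only).
    b0_T : main field strength in tesla.
    gamma_bar_MHz_per_T : gyromagnetic ratio over 2*pi, in MHz/T.
    voxel_mm : voxel edge lengths in mm.
    b0_axis : grid axis parallel to B0 (0, 1 or 2).
    """

    te_s: float = 0.019
    tr_s: float = 0.040
    b0_T: float = 7.0
    gamma_bar_MHz_per_T: float = 42.577
    voxel_mm: tuple[float, float, float] = (0.4, 0.4, 0.4)
    b0_axis: int = 2

    def __post_init__(self) -> None:
        if self.te_s <= 0:
            raise ValueError(f"te_s must be > 0, got {self.te_s}")
        if self.b0_T <= 0:
            raise ValueError(f"b0_T must be > 0, got {self.b0_T}")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be positive, got {self.voxel_mm}")
        if self.b0_axis not in (0, 1, 2):
            raise ValueError(f"b0_axis must be 0, 1 or 2, got {self.b0_axis}")


def rad_per_ppm(acq: AcquisitionParams) -> float:
    """Phase accrued (rad) at TE per ppm of field offset.

    phi = 2*pi * gamma_bar * B0 * TE * delta(ppm) * 1e-6, with gamma_bar in
    Hz/T; the 1e6 (MHz) and 1e-6 (ppm) factors cancel.
    """
    return 2.0 * np.pi * acq.gamma_bar_MHz_per_T * acq.b0_T * acq.te_s


@dataclass
class Volume:
    """A 3-D scalar grid with voxel geometry."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class ComplexVolume(Volume):
    """Complex-valued gradient-echo volume (one average)."""

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


class PhaseVolume(Volume):
    """Phase in radians; wrapped phase lives in (-pi, pi]."""


@dataclass
class FieldMap(Volume):
    """Field perturbation in ppm; zero outside its validity mask."""

    mask: Optional[np.ndarray] = None


@dataclass
class Mask(Volume):
    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelVolume(Volume):
    """Integer parcellation labels with a lookup table.

    ``lookup`` maps label id -> (name, hemisphere, lobe); hemisphere is one of
    ``"L"``, ``"R"``, ``"midline"``.
    """

    lookup: dict[int, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.int32)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"labels without lookup entries: {sorted(missing)}")

    def homologue(self, label: int) -> Optional[int]:
        """Label id of the opposite-hemisphere parcel, or None for midline."""
        name, hemi, lobe = self.lookup[label]
        if hemi == "midline":
            return None
        other_hemi = "R" if hemi == "L" else "L"
        base = name[2:] if name[:2] in ("L_", "R_") else name
        for lid, (n, h, lo) in self.lookup.items():
            nbase = n[2:] if n[:2] in ("L_", "R_") else n
            if h == other_hemi and nbase == base:
                return lid
        return None


@dataclass
class SusceptibilityMap(Volume):
    """Susceptibility chi in ppm, zero outside ``mask``."""

    mask: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)


@dataclass
class WeightMap(Volume):
    """Per-voxel inverse-noise weights W in [0, 1] for dipole inversion."""

    flags: Optional[np.ndarray] = None  # voxels whose raw weight was replaced
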