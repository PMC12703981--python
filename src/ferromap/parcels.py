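"""Zero-referencing, parcel aggregation, left-right flipping and z-maps.

Susceptibility from single-orientation QSM is defined up to an additive
constant, so maps are referenced to the mean over a CSF region (the left
lateral ventricle in the standard segmentation; the designated "ventricle"
label on the phantom) before any between-subject comparison.  Parcel values
are means over the intersection of the parcel label, the brain mask and the
background-removal eroded mask.  Subjects with a right-hemispheric seizure
onset are flipped in label space (homologue swap, no image interpolation)
for group analyses, but not for lateralized memory analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import LabelVolume, Mask, SusceptibilityMap

__all__ = ["zero_reference", "parcel_means", "flip_lr", "zscore_vs_controls"]


def zero_reference(chi: SusceptibilityMap, ref_mask: Mask) -> SusceptibilityMap:
    """Subtract the mean susceptibility over the reference region."""
    rm = ref_mask.data.astype(bool)
    if not rm.any():
        raise ValueError("empty reference region")
    m = np.asarray(chi.mask).astype(bool) if chi.mask is not None else np.ones(chi.data.shape, bool)
    if (rm & ~m).any():
        raise ValueError("reference region extends outside the susceptibility mask")
    offset = float(np.asarray(chi.data)[rm].mean())
    out = np.where(m, chi.data - offset, 0.0)
    prov = dict(chi.provenance)
    prov["zero_reference_offset_ppm"] = offset
    return SusceptibilityMap(data=out, voxel_mm=chi.voxel_mm, affine=chi.affine, mask=chi.mask, provenance=prov)


def parcel_means(chi_ref: SusceptibilityMap, labels: LabelVolume, valid_mask: Mask | None = None) -> pd.DataFrame:
    """Mean susceptibility per nonzero label over label ∧ validity mask.

    Labels with no surviving voxels are reported with NaN mean and zero
    voxel count (missing, not zero).
    """
    if chi_ref.data.shape != labels.data.shape:
        raise ValueError("chi and labels must share a grid")
    valid = valid_mask.data.astype(bool) if valid_mask is not None else None
    if valid is None:
        valid = chi_ref.mask.astype(bool) if chi_ref.mask is not None else np.ones(chi_ref.data.shape, bool)
    rows = []
    for lid, (name, hemi, lobe) in sorted(labels.lookup.items()):
        sel = (labels.data == lid) & valid
        n = int(sel.sum())
        mean = float(np.asarray(chi_ref.data)[sel].mean()) if n else float("nan")
        rows.append({"parcel": name, "label": lid, "hemisphere": hemi, "lobe": lobe, "mean_ppm": mean, "n_voxels": n})
    return pd.DataFrame(rows)


def _homologue_map(columns, parcel_lookup=None) -> dict[str, str]:
    """Map each parcel name to its opposite-hemisphere homologue.

    Uses the ``L_``/``R_`` naming convention unless an explicit lookup
    (parcel -> (hemisphere, homologue)) is given; midline parcels map to
    themselves.
    """
    out = {}
    cols = set(columns)
    for p in columns:
        if parcel_lookup and p in parcel_lookup:
            hemi, hom = parcel_lookup[p]
            if hemi == "midline":
                out[p] = p
                continue
            if not hom:
                raise ValueError(f"parcel {p!r} has no {'R' if hemi == 'L' else 'L'} homologue")
            out[p] = hom
            continue
        if p.startswith(("L_", "R_")):
            hom = ("R_" if p[0] == "L" else "L_") + p[2:]
            if hom not in cols:
                raise ValueError(f"parcel {p!r} has no homologue {hom!r}")
            out[p] = hom
        else:
            out[p] = p  # midline
    return out


def flip_lr(
    values: pd.DataFrame,
    onset_side: pd.Series,
    parcel_lookup: dict[str, tuple[str, str]] | None = None,
    enabled: bool = True,
) -> pd.DataFrame:
    """Swap L/R homologue parcel values for subjects with right-sided onset.

    ``values`` is wide (subjects x parcels).  With ``enabled=False`` (the
    lateralized verbal/figural memory analyses) the table is returned
    unchanged.  Flipping twice is the identity.
    """
    if not enabled:
        return values.copy()
    hom = _homologue_map(values.columns, parcel_lookup)
    out = values.copy()
    to_flip = onset_side.reindex(values.index).fillna("none") == "R"
    if to_flip.any():
        flipped = values.loc[to_flip, [hom[c] for c in values.columns]]
        flipped.columns = values.columns
        out.loc[to_flip] = flipped
    return out


def zscore_vs_controls(subject_values: pd.Series, control_values: pd.DataFrame) -> pd.Series:
    """Per-parcel z-score of one subject against the control distribution
    (sample SD, ddof=1).  Parcels with zero control SD are returned NaN."""
    if len(control_values) < 2:
        raise ValueError("need at least 2 controls")
    mu = control_values.mean(axis=0)
    sd = control_values.std(axis=0, ddof=1)
    z = (subject_values - mu) / sd.replace(0.0, np.nan)
    return z
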