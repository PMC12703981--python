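"""From raw complex averages to a total field map in ppm with noise weights.

The chain is: remove the global phase offset between the two averages and
take the complex mean; extract a brain mask from the magnitude; unwrap the
phase with quality-guided region growing (a path-based scheme robust in
highly wrapped regions); convert radians to ppm at the acquisition TE/B0;
and estimate a per-voxel inverse-noise weight map from the disagreement of
the two averages.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy import ndimage

from .grids import AcquisitionParams, ComplexVolume, FieldMap, Mask, PhaseVolume, Volume, WeightMap, rad_per_ppm

__all__ = [
    "phase_match_average",
    "brain_mask",
    "unwrap_phase",
    "phase_to_field",
    "estimate_weight_map",
]

TWO_PI = 2.0 * np.pi


def phase_match_average(avg1: ComplexVolume, avg2: ComplexVolume, mask: Mask) -> ComplexVolume:
    """Remove the global phase offset of avg2 relative to avg1, then average.

    The offset is phi0 = angle(sum over the mask of avg2 * conj(avg1)) — the
    maximum-likelihood single-offset estimate — so a pure instrumental phase
    shift between averages does not cause destructive interference.
    """
    if avg1.data.shape != avg2.data.shape:
        raise ValueError("averages must share a grid")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    phi0 = np.angle(np.sum(avg2.data[m] * np.conj(avg1.data[m])))
    out = 0.5 * (avg1.data + avg2.data * np.exp(-1j * phi0))
    return ComplexVolume(data=out, voxel_mm=avg1.voxel_mm, affine=avg1.affine)


def brain_mask(magnitude: Volume, frac: float = 0.4) -> Mask:
    """Threshold-and-largest-component brain extraction.

    Voxels above ``frac`` times the robust maximum (99th percentile) of the
    magnitude are kept; the largest 26-connected component is returned with
    interior holes filled.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    mag = np.asarray(magnitude.data, dtype=float)
    if not np.any(mag > 0):
        raise ValueError("magnitude is identically zero")
    robust_max = np.percentile(mag[mag > 0], 99)
    fg = mag > frac * robust_max
    structure = np.ones((3, 3, 3), dtype=bool)
    lab, n = ndimage.label(fg, structure=structure)
    if n == 0:
        raise ValueError("no voxels above threshold")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    keep = lab == np.argmax(counts)
    keep = ndimage.binary_fill_holes(keep)
    return Mask(data=keep, voxel_mm=magnitude.voxel_mm, affine=magnitude.affine)


def _neighbor_offsets(shape) -> np.ndarray:
    """Flat-index offsets of the 26-neighborhood."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs)


def unwrap_phase(wrapped: PhaseVolume, quality: Volume, mask: Mask) -> PhaseVolume:
    """Quality-guided path-based 3-D phase unwrapping.

    Best-first region growing over the 26-connected in-mask graph.  Edges are
    prioritized by reliability min(q_a, q_b) / (|wrapped difference| + eps):
    the unwrapping path prefers high-quality voxels connected by small phase
    steps, crossing steep or noisy regions only where no safer route exists
    (at which point both sides are usually already unwrapped).  Each voxel is
    unwrapped against the endpoint of the edge that reached it, adding the
    2*pi multiple that minimizes the jump; ties in the heap break by linear
    voxel index.  Afterwards the global 2*pi ambiguity is fixed by
    subtracting 2*pi * round(median(phi) / 2*pi).
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("mask has no voxels")
    shape = m.shape
    w = np.asarray(wrapped.data, dtype=float).ravel()
    q = np.asarray(quality.data, dtype=float).ravel()
    mflat = m.ravel()
    out = w.copy()

    strides = np.array([shape[1] * shape[2], shape[2], 1])
    noffs = _neighbor_offsets(shape)
    flat_offs = noffs @ strides

    visited = np.zeros(w.size, dtype=bool)
    n12 = shape[1] * shape[2]
    eps_phase = 1e-3

    def neighbors(idx):
        x, rem = divmod(idx, n12)
        y, z = divmod(rem, shape[2])
        for off_flat, (dx, dy, dz) in zip(flat_offs, noffs):
            if 0 <= x + dx < shape[0] and 0 <= y + dy < shape[1] and 0 <= z + dz < shape[2]:
                nb = idx + off_flat
                if mflat[nb] and not visited[nb]:
                    yield int(nb)

    def push_edges(heap, cur):
        qc = q[cur]
        for nb in neighbors(cur):
            dphi = abs(wrap_to_pi(w[nb] - out[cur]))
            rel = min(qc, q[nb]) / (dphi + eps_phase)
            heapq.heappush(heap, (-rel, nb, int(cur)))

    inmask_idx = np.flatnonzero(mflat)
    order = inmask_idx[np.argsort(-q[inmask_idx], kind="stable")]
    for seed in order:
        if visited[seed]:
            continue
        visited[seed] = True
        heap: list = []
        push_edges(heap, int(seed))
        while heap:
            _, nb, cur = heapq.heappop(heap)
            if visited[nb]:
                continue
            visited[nb] = True
            out[nb] = w[nb] - TWO_PI * np.round((w[nb] - out[cur]) / TWO_PI)
            push_edges(heap, nb)

    out3 = out.reshape(shape)
    med = np.median(out3[m])
    out3 = out3 - TWO_PI * np.round(med / TWO_PI)
    out3 = np.where(m, out3, 0.0)
    return PhaseVolume(data=out3, voxel_mm=wrapped.voxel_mm, affine=wrapped.affine)


def wrap_to_pi(x: float) -> float:
    return (x + np.pi) % TWO_PI - np.pi


def phase_to_field(unwrapped: PhaseVolume, acq: AcquisitionParams) -> FieldMap:
    """Convert unwrapped phase (rad) to field perturbation in ppm:
    f_ppm = phi / (2*pi * gamma_bar * B0 * TE).  Exactly linear."""
    c = rad_per_ppm(acq)
    return FieldMap(data=np.asarray(unwrapped.data, dtype=float) / c, voxel_mm=unwrapped.voxel_mm, affine=unwrapped.affine)


def estimate_weight_map(
    avg1_field: FieldMap,
    avg2_field: FieldMap,
    mask: Mask,
    pool_radius: int = 0,
) -> WeightMap:
    """Inverse-noise weighting map for dipole inversion.

    The field-map SD is estimated from the two independent averages as
    s = |f1 - f2| / sqrt(2), floored at its in-mask 1st percentile.  Raw
    weights w = 1/s are thresholded at T = median(w) + 3*IQR(w) over the
    mask; voxels with w strictly above T are flagged and replaced by the
    3x3x3 boxcar mean of unflagged neighborhood weights; finally W is
    normalized so the in-mask maximum is exactly 1.

    With ``pool_radius`` > 0 the variance estimate s^2 is first averaged
    over a (2r+1)^3 in-mask neighborhood.  The pointwise |f1 - f2| estimate
    has a single degree of freedom and its reciprocal is so heavy-tailed
    that the weights are dominated by estimation noise; pooling trades a
    little spatial resolution of the noise map for a usable variance
    estimate (27 df at r = 1).
    """
    m = mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    s = np.abs(np.asarray(avg1_field.data) - np.asarray(avg2_field.data)) / np.sqrt(2.0)
    s_in = s[m]
    if np.all(s_in == 0):
        raise ValueError("identical averages: field-map SD is zero everywhere, cannot estimate noise")
    if pool_radius > 0:
        size = 2 * pool_radius + 1
        num = ndimage.uniform_filter(np.where(m, s**2, 0.0), size=size, mode="constant")
        den = ndimage.uniform_filter(m.astype(float), size=size, mode="constant")
        s = np.where(m & (den > 0), np.sqrt(num / np.maximum(den, 1e-30)), s)
        s_in = s[m]
    # the floor exists to keep 1/s finite; a floor at the raw 1st percentile
    # would also clip genuinely low-noise voxels and hide them from the
    # threshold-and-replace step, so it sits two decades below it
    floor = np.percentile(s_in[s_in > 0], 1) / 100.0 if np.any(s_in > 0) else 0.0
    s = np.maximum(s, floor)

    with np.errstate(divide="ignore"):
        w = np.where(m, 1.0 / s, 0.0)
    w_in = w[m]
    q1, med, q3 = np.percentile(w_in, [25, 50, 75])
    thr = med + 3.0 * (q3 - q1)
    flags = m & (w > thr)

    if flags.any():
        ok = (m & ~flags).astype(float)
        num = ndimage.uniform_filter(np.where(m & ~flags, w, 0.0), size=3, mode="constant")
        den = ndimage.uniform_filter(ok, size=3, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(den > 0, num / den, med)
        w = np.where(flags, smoothed, w)

    wmax = w[m].max()
    w = np.where(m, w / wmax, 0.0)
    return WeightMap(data=w, voxel_mm=avg1_field.voxel_mm, flags=flags)
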