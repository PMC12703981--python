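"""Background-field removal: variable-kernel SHARP and polynomial detrending.

Fields generated by susceptibility sources outside the brain are harmonic
inside it, so they are annihilated by (delta - S_r), the difference between
the identity and the spherical-mean-value filter of radius r.  V-SHARP
applies this with a schedule of decreasing radii — large kernels deep in the
brain for maximal suppression, small kernels near the boundary to limit
erosion — then deconvolves the (delta - S_rmax) footprint by truncated
division in the frequency domain.  Residual smooth instrumental fields
(e.g. transmit-field effects) are removed by a least-squares polynomial fit
over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import FieldMap, Mask

__all__ = ["BackgroundConfig", "vsharp", "polyfit_remove"]


@dataclass
class BackgroundConfig:
    """smv_radii_mm must be strictly decreasing; when None, a schedule of
    6, 5, 4, 3, 2, 1 voxels scaled by the voxel size is used.
    tsvd_threshold is the truncated-deconvolution cutoff; poly_order the
    residual-fit degree."""

    smv_radii_mm: tuple[float, ...] | None = None
    tsvd_threshold: float = 0.05
    poly_order: int = 4

    def __post_init__(self) -> None:
        r = self.smv_radii_mm
        if r is not None and (not r or any(a <= b for a, b in zip(r, r[1:])) or any(x <= 0 for x in r)):
            raise ValueError("smv_radii_mm must be strictly decreasing and positive")
        if not 0 < self.tsvd_threshold < 1:
            raise ValueError("tsvd_threshold must be in (0, 1)")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")

    def radii_mm(self, voxel_mm) -> tuple[float, ...]:
        if self.smv_radii_mm is not None:
            return self.smv_radii_mm
        v = float(min(voxel_mm))
        return tuple(k * v for k in (6.0, 5.0, 4.0, 3.0, 2.0, 1.0))


def _smv_kernels_fft(shape, radius_vox) -> tuple[np.ndarray, np.ndarray]:
    """rfft of the spherical-mean kernel and of its (unnormalized) support
    indicator, both centered at the origin with wrap-around placement.

    The mean kernel uses anti-aliased (clipped-linear) boundary weights so
    the discrete mean-value property of harmonic fields holds to high order;
    the support indicator is used for FFT-based mask erosion.  Anisotropic
    voxels are handled by measuring distance in mm.
    """
    rv = np.asarray(radius_vox, dtype=float)
    ri = np.maximum(np.ceil(rv).astype(int) + 1, 1)
    grids = np.meshgrid(*(np.arange(-r, r + 1) for r in ri), indexing="ij", sparse=True)
    # distance in units of the per-axis radius; w falls linearly over the
    # last voxel shell
    d = np.sqrt(sum((g / rvi) ** 2 for g, rvi in zip(grids, rv))) * rv.min()
    w = np.clip(rv.min() + 0.5 - d, 0.0, 1.0)
    idx = np.argwhere(w > 0) - ri
    vals = w[w > 0]
    k = np.zeros(shape)
    k[tuple((idx % np.array(shape)).T)] = vals
    k_ind = np.zeros(shape)
    k_ind[tuple((idx % np.array(shape)).T)] = 1.0
    k /= k.sum()
    return np.fft.rfftn(k), np.fft.rfftn(k_ind)


def _fft_erode(mask: np.ndarray, support_hat: np.ndarray) -> np.ndarray:
    """Erode a binary mask by the kernel support via FFT convolution: a voxel
    survives iff no out-of-mask voxel falls under the support."""
    outside = (~mask).astype(float)
    occ = np.fft.irfftn(support_hat * np.fft.rfftn(outside), s=mask.shape, axes=(0, 1, 2))
    return mask & (occ < 0.5)


def vsharp(total_field: FieldMap, mask: Mask, cfg: BackgroundConfig) -> tuple[FieldMap, Mask]:
    """Variable-kernel SHARP background removal.

    For each radius (largest to smallest) the high-pass (delta - S_r) field
    is computed and kept on the mask eroded by r, each voxel taking the
    largest kernel still valid there; the (delta - S_rmax) footprint is then
    deconvolved by truncated frequency-domain division.  Returns the local
    field supported on the final eroded mask (erosion by the smallest
    radius) together with that mask.
    """
    m = mask.data.astype(bool)
    f = np.where(m, np.asarray(total_field.data, dtype=float), 0.0)
    voxel_mm = np.asarray(total_field.voxel_mm, dtype=float)
    radii = cfg.radii_mm(voxel_mm)
    if 2 * max(radii) / min(voxel_mm) >= min(m.shape):
        raise ValueError(f"largest radius {max(radii)} mm too big for grid {m.shape}")

    pad = int(np.ceil(max(radii) / min(voxel_mm))) + 2
    shape_p = tuple(s + 2 * pad for s in m.shape)
    sl = tuple(slice(pad, pad + s) for s in m.shape)
    fp = np.zeros(shape_p)
    fp[sl] = f
    mp = np.zeros(shape_p, dtype=bool)
    mp[sl] = m
    f_hat = np.fft.rfftn(fp)

    composite = np.zeros(shape_p)
    assigned = np.zeros(shape_p, dtype=bool)
    eroded_final = None
    k_max_hat = None
    for i, r_mm in enumerate(radii):
        r_vox = r_mm / voxel_mm
        k_hat, ind_hat = _smv_kernels_fft(shape_p, r_vox)
        if i == 0:
            k_max_hat = k_hat
        hp = fp - np.fft.irfftn(k_hat * f_hat, s=shape_p, axes=(0, 1, 2))
        eroded = _fft_erode(mp, ind_hat)
        take = eroded & ~assigned
        composite[take] = hp[take]
        assigned |= eroded
        eroded_final = eroded  # radii decrease, so the last is the largest region
    if eroded_final is None or not eroded_final.any():
        raise ValueError(f"eroded mask empty for radii {radii} mm")

    # deconvolve (delta - S_rmax) with truncated division
    c = 1.0 - k_max_hat
    h_hat = np.fft.rfftn(np.where(assigned, composite, 0.0))
    inv = np.where(np.abs(c) >= cfg.tsvd_threshold, 1.0 / np.where(c == 0, 1.0, c), 0.0)
    local = np.fft.irfftn(h_hat * inv, s=shape_p, axes=(0, 1, 2))
    local = np.where(eroded_final, local, 0.0)

    out_mask = eroded_final[sl]
    out = local[sl]
    return (
        FieldMap(data=out, voxel_mm=total_field.voxel_mm, affine=total_field.affine, mask=out_mask),
        Mask(data=out_mask, voxel_mm=total_field.voxel_mm, affine=total_field.affine),
    )


def _monomial_basis(shape, mask, order):
    """Design matrix of 3-D monomials of total degree <= order over in-mask
    voxels, with coordinates centered at the mask centroid and scaled to
    roughly [-1, 1] for conditioning."""
    idx = np.argwhere(mask)
    ctr = idx.mean(axis=0)
    scale = np.maximum(np.abs(idx - ctr).max(axis=0), 1.0)
    u = (idx - ctr) / scale
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(u[:, 0] ** i * u[:, 1] ** j * u[:, 2] ** k)
    return np.stack(cols, axis=1)


def polyfit_remove(
    local_field: FieldMap,
    mask: Mask,
    order: int = 4,
    kernel=None,
    tkd_threshold: float = 0.1,
) -> FieldMap:
    """Subtract a least-squares polynomial of total degree <= order fitted
    over in-mask voxels.

    In the default form the polynomial is fitted to the field itself: the
    residual is orthogonal to the monomial basis over the mask, a pure
    polynomial input is annihilated to numerical precision, and applying the
    operation twice equals applying it once.

    When a frequency-domain dipole ``kernel`` is supplied the fit becomes
    dipole-aware: the polynomial is fitted to the dipole-inconsistent part of
    the field, f - d * chi_TKD, where chi_TKD is a quick truncated-kernel
    inversion (cutoff ``tkd_threshold``).  Tissue dipole fields project
    substantially onto low-order polynomials over a convex mask, so the plain
    fit removes real signal along with the instrumental trend; fitting the
    model residual instead keeps the dipole-consistent tissue contribution
    while still capturing smooth non-dipole (e.g. transmit-field) effects.
    """
    m = mask.data.astype(bool)
    f = np.asarray(local_field.data, dtype=float)
    n_basis = (order + 1) * (order + 2) * (order + 3) // 6
    n_vox = int(m.sum())
    if n_vox < 2 * n_basis:
        raise ValueError(f"under-determined polynomial fit: {n_vox} voxels for {n_basis} monomials")
    A = _monomial_basis(m.shape, m, order)
    if kernel is None:
        target = f[m]
    else:
        d = kernel.rfft_values
        with np.errstate(divide="ignore"):
            d_inv = np.where(np.abs(d) > tkd_threshold, 1.0 / np.where(d == 0, 1.0, d), 0.0)
        fm = np.where(m, f, 0.0)
        chi_tkd = np.fft.irfftn(d_inv * np.fft.rfftn(fm), s=f.shape, axes=(0, 1, 2))
        f_model = np.fft.irfftn(d * np.fft.rfftn(np.where(m, chi_tkd, 0.0)), s=f.shape, axes=(0, 1, 2))
        target = (f - f_model)[m]
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    out = np.where(m, f, 0.0)
    out[m] = f[m] - A @ coef
    return FieldMap(data=out, voxel_mm=local_field.voxel_mm, affine=local_field.affine, mask=m)
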