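"""Synthetic ground truth for the reconstruction and statistics chain.

Three generators live here:

* a geometric susceptibility phantom (labeled primitives inside a brain-like
  mask) together with the dipole-physics forward simulation of wrapped
  gradient-echo phase at 7 T, including two independently noisy "averages"
  and a harmonic background field from sources placed outside the mask;
* a parcel-wise cohort simulator with known group effects, age/sex covariate
  structure and score models, emulating a case-control susceptibility study
  (80 patients + 50 controls by default);
* a multi-rater hemisphere-by-lobe label simulator for inter-rater
  agreement statistics.

All randomness is seeded explicitly; the package-wide default seed is
``DEFAULT_SEED = 20240601``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import AcquisitionParams, ComplexVolume, LabelVolume, Mask, PhaseVolume, SusceptibilityMap, rad_per_ppm
from .inversion import dipole_kernel, forward_field

__all__ = [
    "DEFAULT_SEED",
    "Sphere",
    "Box",
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "AcquisitionSim",
    "CohortSpec",
    "ScoreModel",
    "RaterTable",
    "build_phantom",
    "simulate_acquisition",
    "simulate_cohort",
    "simulate_raters",
    "default_phantom_spec",
    "default_cohort_spec",
    "wrap_phase",
    "HEMISPHERES",
    "LOBES",
]

DEFAULT_SEED = 20240601

HEMISPHERES = ("L", "R")
LOBES = ("frontal", "temporal", "parietal", "occipital")


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Box:
    center: tuple[float, float, float]
    half_size: tuple[float, float, float]

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        hx, hy, hz = self.half_size
        return (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)


@dataclass(frozen=True)
class Region:
    label: int
    primitive: Sphere | Box
    chi_ppm: float
    name: str = ""
    hemisphere: str = "midline"
    lobe: str = "none"
    magnitude: float = 1.0  # piecewise-constant magnitude level of the region


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    regions: list[Region]
    ventricle_label: int
    mask_primitive: Sphere | Box | None = None
    background_dipoles: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    background_poly_ppm: float = 0.0  # amplitude of a smooth harmonic polynomial background
    b1_poly_ppm: float = 0.0  # amplitude of a non-harmonic instrumental (B1-like) polynomial
    snr: float = 100.0
    seed: int = DEFAULT_SEED
    inter_average_phase_offset_rad: float = 0.5
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if self.ventricle_label not in labels:
            raise ValueError(f"ventricle_label {self.ventricle_label} not among region labels")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


@dataclass
class GroundTruth:
    chi_true: SusceptibilityMap
    labels: LabelVolume
    mask: Mask
    magnitude: np.ndarray  # noise-free piecewise-constant magnitude


@dataclass
class AcquisitionSim:
    """Forward-simulated acquisition: two noisy complex averages plus the
    noise-free wrapped phase and the underlying total field (ppm).

    ``field_background_ppm`` holds the harmonic (outside-source) background;
    ``field_b1_ppm`` the non-harmonic instrumental trend that V-SHARP cannot
    remove and the polynomial detrend targets."""

    avg1: ComplexVolume
    avg2: ComplexVolume
    phase_true: PhaseVolume  # wrapped, noise-free
    field_total_ppm: np.ndarray  # tissue + background + instrumental, unwrapped truth
    field_background_ppm: np.ndarray
    field_b1_ppm: np.ndarray


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(phi)))
    # np.angle returns [-pi, pi]; move -pi to +pi for the half-open convention
    return np.where(out == -np.pi, np.pi, out)


def _voxel_grids(shape):
    return np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij", sparse=True)


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize the phantom: voxels belong to a region if their center lies
    inside its primitive.  Overlapping regions with different labels are an
    error."""
    shape = tuple(spec.grid_shape)
    x, y, z = _voxel_grids(shape)
    if spec.mask_primitive is not None:
        mask = spec.mask_primitive.contains(x, y, z)
    else:
        # default head: centered sphere filling ~84% of the smallest extent
        r = 0.42 * min(shape)
        c = tuple((n - 1) / 2.0 for n in shape)
        mask = Sphere(c, r).contains(x, y, z)

    labels = np.zeros(shape, dtype=np.int32)
    chi = np.zeros(shape, dtype=float)
    magnitude = np.where(mask, 1.0, 0.0)
    lookup: dict[int, tuple[str, str, str]] = {}
    for reg in spec.regions:
        inside = reg.primitive.contains(x, y, z)
        clash = inside & (labels != 0) & (labels != reg.label)
        if clash.any():
            other = int(labels[clash][0])
            raise ValueError(f"regions with labels {other} and {reg.label} overlap")
        labels[inside] = reg.label
        chi[inside] = reg.chi_ppm
        magnitude[inside & mask] = reg.magnitude
        lookup[reg.label] = (reg.name or f"region_{reg.label}", reg.hemisphere, reg.lobe)

    labels[~mask] = 0
    chi[~mask] = 0.0
    return GroundTruth(
        chi_true=SusceptibilityMap(data=chi, voxel_mm=spec.voxel_mm, mask=mask),
        labels=LabelVolume(data=labels, voxel_mm=spec.voxel_mm, lookup=lookup),
        mask=Mask(data=mask, voxel_mm=spec.voxel_mm),
        magnitude=magnitude,
    )


def _background_field(spec: PhantomSpec, mask: np.ndarray, b0_axis: int = 2) -> np.ndarray:
    """Harmonic-inside-the-mask background field.

    Point dipole sources strictly outside the mask are evaluated with the
    closed-form dipole response amp * (3 cos^2 theta - 1) / (4 pi d^3) (theta
    measured from the B0 axis), plus an optional smooth *harmonic* polynomial
    so the whole background satisfies the mean-value property inside the
    brain — the assumption V-SHARP rests on.
    """
    shape = mask.shape
    bg = np.zeros(shape)
    if spec.background_dipoles:
        x, y, z = _voxel_grids(shape)
        for pos, amp in spec.background_dipoles:
            idx = tuple(int(round(p)) for p in pos)
            if any(i < 0 or i >= n for i, n in zip(idx, shape)):
                raise ValueError(f"background source {pos} outside the grid")
            if mask[idx]:
                raise ValueError(f"background source {pos} lies inside the mask")
            d_ax = (x - pos[0], y - pos[1], z - pos[2])
            d2 = d_ax[0] ** 2 + d_ax[1] ** 2 + d_ax[2] ** 2
            d2 = np.maximum(d2, 0.25)  # guard the source voxel itself
            cos2 = d_ax[b0_axis] ** 2 / d2
            bg = bg + amp * (3.0 * cos2 - 1.0) / (4.0 * np.pi * d2**1.5)
    if spec.background_poly_ppm != 0.0:
        x, y, z = _voxel_grids(shape)
        u, v, w = [(g - (n - 1) / 2.0) / max((n - 1) / 2.0, 1) for g, n in zip((x, y, z), shape)]
        # harmonic polynomial: Laplacian of each term vanishes
        poly = 0.6 * u + 0.3 * (u * u - v * v) - 0.4 * w + 0.2 * u * w
        bg = bg + spec.background_poly_ppm * poly
    return bg


def _b1_field(spec: PhantomSpec, shape) -> np.ndarray:
    """Smooth non-harmonic instrumental trend emulating residual
    transmit-field effects on the measured phase."""
    if spec.b1_poly_ppm == 0.0:
        return np.zeros(shape)
    x, y, z = _voxel_grids(shape)
    u, v, w = [(g - (n - 1) / 2.0) / max((n - 1) / 2.0, 1) for g, n in zip((x, y, z), shape)]
    return spec.b1_poly_ppm * (u * u + 0.5 * v * v * w - 0.3 * w * w * u * u)


def simulate_acquisition(gt: GroundTruth, acq: AcquisitionParams, spec: PhantomSpec) -> AcquisitionSim:
    """Forward-simulate the single-echo acquisition.

    Noise-free phase = wrap(c * (dipole field of chi_true + background)), with
    c the rad/ppm conversion at TE and B0.  Each average is
    magnitude * exp(i phase) plus independent complex Gaussian noise of SD
    (reference magnitude 1.0) / snr per real/imaginary channel; the second
    average additionally carries a global phase offset which the
    reconstruction must remove.
    """
    if spec.snr <= 0:
        raise ValueError("snr must be > 0")
    shape = gt.mask.data.shape
    kernel = dipole_kernel(shape, acq.voxel_mm, acq.b0_axis)
    field_tissue = forward_field(gt.chi_true, kernel).data
    field_bg = _background_field(spec, gt.mask.data, acq.b0_axis)
    field_b1 = _b1_field(spec, shape)
    field_total = field_tissue + field_bg + field_b1

    c = rad_per_ppm(acq)
    phase_nf = wrap_phase(c * field_total)
    signal = gt.magnitude * np.exp(1j * c * field_total)

    rng = np.random.default_rng(spec.seed)
    sd = 1.0 / spec.snr  # reference magnitude is 1.0 inside the mask
    noise1 = sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    noise2 = sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    avg1 = signal + noise1
    avg2 = (signal + noise2) * np.exp(1j * spec.inter_average_phase_offset_rad)

    return AcquisitionSim(
        avg1=ComplexVolume(data=avg1, voxel_mm=acq.voxel_mm),
        avg2=ComplexVolume(data=avg2, voxel_mm=acq.voxel_mm),
        phase_true=PhaseVolume(data=phase_nf, voxel_mm=acq.voxel_mm),
        field_total_ppm=field_total,
        field_background_ppm=field_bg,
        field_b1_ppm=field_b1,
    )


def default_phantom_spec(
    n: int = 64,
    snr: float = 100.0,
    seed: int = DEFAULT_SEED,
    with_background: bool = True,
) -> PhantomSpec:
    """A three-compartment phantom: a paramagnetic "deep gray" sphere
    (+0.10 ppm), a diamagnetic "lesion" sphere (-0.05 ppm), a mildly
    paramagnetic "cortex" sphere (+0.05 ppm), and a central zero-susceptibility
    ventricle used for referencing."""
    c = (n - 1) / 2.0
    s = n / 64.0  # scale primitives with the grid
    regions = [
        Region(1, Sphere((c, c, c), 4 * s), 0.0, "ventricle", "midline", "none", magnitude=1.15),
        Region(2, Sphere((c - 10 * s, c + 6 * s, c), 6 * s), 0.10, "L_deep_gray", "L", "temporal", magnitude=0.85),
        Region(3, Sphere((c + 10 * s, c - 6 * s, c + 4 * s), 5 * s), -0.05, "R_lesion", "R", "frontal", magnitude=1.10),
        Region(4, Sphere((c, c + 2 * s, c - 10 * s), 5 * s), 0.05, "L_cortex", "L", "parietal", magnitude=0.92),
    ]
    dipoles = []
    if with_background:
        # sources >= 10 voxels outside the default mask sphere (radius 0.42 n)
        far = 0.42 * n + 10 * s
        dipoles = [
            ((min(c + far, n - 1), c, c), 500.0 * s**3),
            ((c, max(c - far, 0), c), -400.0 * s**3),
        ]
    return PhantomSpec(
        grid_shape=(n, n, n),
        regions=regions,
        ventricle_label=1,
        background_dipoles=dipoles,
        background_poly_ppm=0.02 if with_background else 0.0,
        b1_poly_ppm=0.01 if with_background else 0.0,
        snr=snr,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class ScoreModel:
    """Linear score model: score = mean + slope * sum_p (chi_p - baseline_p)
    + N(0, noise_sd), over the designated parcels."""

    name: str
    parcels: tuple[str, ...]
    slope: float
    noise_sd: float
    mean: float = 100.0


@dataclass
class CohortSpec:
    n_group_a: int = 80  # patients
    n_group_b: int = 50  # controls
    parcels: tuple[str, ...] = ()
    baseline_ppm: dict[str, float] = field(default_factory=dict)
    effect_ppm: dict[str, float] = field(default_factory=dict)
    beta_age: dict[str, float] = field(default_factory=dict)
    beta_sex: dict[str, float] = field(default_factory=dict)
    score_models: tuple[ScoreModel, ...] = ()
    noise_sd_ppm: float = 0.01
    age_range: tuple[float, float] = (18.0, 72.0)
    p_right_onset: float = 29.0 / 80.0
    effect_ipsilateral: bool = True
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("cohort sizes must be >= 2")
        if self.noise_sd_ppm < 0:
            raise ValueError("noise_sd_ppm must be >= 0")


def default_cohort_spec(
    n_parcels: int = 100,
    n_affected: int = 10,
    effect_ppm: float = 0.02,
    noise_sd_ppm: float = 0.01,
    seed: int = DEFAULT_SEED,
) -> CohortSpec:
    """Homologous L/R parcel pairs with a group effect injected into the
    first ``n_affected`` left-hemisphere parcels."""
    n_pairs = n_parcels // 2
    parcels = tuple(f"{h}_parcel{i:02d}" for i in range(n_pairs) for h in ("L", "R"))
    affected = [f"L_parcel{i:02d}" for i in range(n_affected)]
    return CohortSpec(
        parcels=parcels,
        baseline_ppm={p: 0.02 for p in parcels},
        effect_ppm={p: effect_ppm for p in affected},
        beta_age={p: 2e-4 for p in parcels},  # ppm per year, iron accrual with age
        beta_sex={p: 2e-3 for p in parcels},
        score_models=(
            ScoreModel("episodic_memory", tuple(affected[:3]) or parcels[:1], -300.0, 8.0),
            ScoreModel("bdi", tuple(affected[3:6]) or parcels[:1], 150.0, 6.0),
        ),
        noise_sd_ppm=noise_sd_ppm,
        seed=seed,
    )


@dataclass
class CohortTable:
    """Wide per-subject parcel values plus covariates.

    ``values``: DataFrame indexed by subject id, one column per parcel (ppm).
    ``covariates``: DataFrame with group, age, sex, onset_side and scores.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    parcel_lookup: dict[str, tuple[str, str]] = field(default_factory=dict)  # parcel -> (hemisphere, homologue)


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a case-control cohort with injected parcel-wise group effects.

    Per subject i in group g:
        chi_ip = baseline_p + effect_p * 1[g = a] + beta_age_p * age_i
                 + beta_sex_p * sex_i + N(0, noise_sd).
    Ages are Uniform(18, 72); sex is Bernoulli(0.5) coded 0/1.  Patients get
    an onset side (R with probability 29/80); controls have none.

    With ``effect_ipsilateral`` (default), effects named on a left-hemisphere
    parcel land on its right homologue for right-onset patients — the
    disease effect sits ipsilateral to the seizure onset, which is what the
    downstream left-right flip assumes and undoes.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_group_a + spec.n_group_b
    group = np.array(["a"] * spec.n_group_a + ["b"] * spec.n_group_b)
    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    onset = np.where(
        group == "a",
        np.where(rng.random(n) < spec.p_right_onset, "R", "L"),
        "none",
    )
    subjects = [f"sub{i:03d}" for i in range(n)]

    def homologue(p: str) -> str:
        if p.startswith(("L_", "R_")):
            other = ("R_" if p[0] == "L" else "L_") + p[2:]
            return other if other in spec.parcels else p
        return p

    # per-subject effect per parcel, honoring laterality
    eff_mat = {p: np.zeros(n) for p in spec.parcels}
    for p, eff in spec.effect_ppm.items():
        if spec.effect_ipsilateral and p.startswith(("L_", "R_")):
            target = np.where(onset == "R", homologue(p), p)
            for pp in np.unique(target):
                eff_mat[pp] += eff * (group == "a") * (target == pp)
        else:
            eff_mat[p] += eff * (group == "a")

    vals = {}
    for p in spec.parcels:
        base = spec.baseline_ppm.get(p, 0.0)
        ba = spec.beta_age.get(p, 0.0)
        bs = spec.beta_sex.get(p, 0.0)
        vals[p] = (
            base
            + eff_mat[p]
            + ba * age
            + bs * sex
            + rng.normal(0.0, spec.noise_sd_ppm, size=n)
        )
    values = pd.DataFrame(vals, index=pd.Index(subjects, name="subject"))

    cov = pd.DataFrame(
        {"group": group, "age": age, "sex": sex, "onset_side": onset},
        index=values.index,
    )
    for sm in spec.score_models:
        centered = sum(values[p] - spec.baseline_ppm.get(p, 0.0) for p in sm.parcels)
        cov[sm.name] = sm.mean + sm.slope * centered + rng.normal(0.0, sm.noise_sd, size=n)

    lookup = {}
    for p in spec.parcels:
        if p.startswith("L_") or p.startswith("R_"):
            hemi = p[0]
            other = ("R_" if hemi == "L" else "L_") + p[2:]
            lookup[p] = (hemi, other if other in spec.parcels else "")
        else:
            lookup[p] = ("midline", "")
    return CohortTable(values=values, covariates=cov, parcel_lookup=lookup)


# ---------------------------------------------------------------------------
# Rater simulation


@dataclass
class RaterTable:
    """Long table of (participant, rater, labels) where labels is a frozenset
    of "hemisphere-lobe" strings; empty cells are recorded as missing."""

    data: pd.DataFrame  # columns: participant, rater, labels (frozenset or None)

    def __post_init__(self) -> None:
        if self.data["rater"].nunique() < 2:
            raise ValueError("need at least 2 raters")


ALL_LABELS = tuple(f"{h}-{lo}" for h in HEMISPHERES for lo in LOBES)


def simulate_raters(n_participants: int, n_raters: int = 5, fidelity: float = 0.8, seed: int = DEFAULT_SEED) -> RaterTable:
    """Each participant has a latent true label set (one hemisphere-lobe
    combination, or two with probability 0.2, multiple choices being
    permitted); each rater reproduces it with probability ``fidelity`` and
    otherwise draws a single random label uniformly."""
    if not 0 <= fidelity <= 1:
        raise ValueError("fidelity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        k = 2 if rng.random() < 0.2 else 1
        truth = frozenset(rng.choice(len(ALL_LABELS), size=k, replace=False))
        truth = frozenset(ALL_LABELS[j] for j in truth)
        for r in range(n_raters):
            if rng.random() < fidelity:
                labels = truth
            else:
                labels = frozenset({ALL_LABELS[rng.integers(len(ALL_LABELS))]})
            rows.append({"participant": f"p{i:03d}", "rater": f"rater{r}", "labels": labels})
    return RaterTable(data=pd.DataFrame(rows))
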