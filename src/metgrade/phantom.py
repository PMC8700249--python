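"""Synthetic PET phantom cohorts.

The patient scans behind this workflow are not public, so this module
generates cohorts of hot-lesion phantoms whose statistical structure
matches what the analysis assumes: an ellipsoidal lesion ramping to a peak
SUV well above a ~1 SUV background, grade-dependent intra-lesion
heterogeneity (a multiplicative Gaussian random field, plus an optional
low-uptake necrotic core for high-grade lesions), scanner-dependent voxel
geometry and point-spread blur, and the clinical ~70/30 high/low-grade
imbalance across two scanner subgroups.

Everything is a pure function of (spec, seed): the same cohort spec always
reproduces bit-identical volumes and manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import SuvVolume, ValidationError, write_volume

__all__ = [
    "ScannerProfile",
    "LesionSpec",
    "CohortSpec",
    "make_default_profiles",
    "synthesize_volume",
    "generate_cohort",
    "reference_histology",
    "who_grade_is_high",
    "cohort_composition",
]

BACKGROUND_SUV = 1.0  # low uniform background; lesion peaks sit in [4, 15]
_NECROTIC_UPTAKE = 0.35  # multiplicative uptake drop inside a necrotic core


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition geometry and noise model of one scanner."""

    name: str
    voxel_spacing: tuple[float, float, float]  # mm
    psf_fwhm: float = 4.0  # mm, isotropic Gaussian point-spread blur
    noise_sd: float = 0.08  # additive SUV noise

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel spacings must be positive")
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ValidationError("psf_fwhm and noise_sd must be non-negative")


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth description of one synthetic lesion."""

    centre: tuple[int, int, int]  # voxel index
    semi_axes: tuple[float, float, float]  # mm
    peak_suv: float
    grade: int  # 0 low, 1 high
    heterogeneity_amp: float = 0.0  # in [0, 1]
    heterogeneity_scale: float = 3.0  # mm correlation length
    necrotic_core_fraction: float = 0.0  # in [0, 1): volume fraction
    edge_power: int = 4  # radial profile exponent: 1 = paraboloid, >1 = plateau

    def __post_init__(self) -> None:
        if self.peak_suv <= BACKGROUND_SUV:
            raise ValidationError("peak_suv must exceed the background mean")
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi_axes must be positive")
        if self.grade not in (0, 1):
            raise ValidationError("grade must be 0 (low) or 1 (high)")
        if not 0.0 <= self.heterogeneity_amp <= 1.0:
            raise ValidationError("heterogeneity_amp must lie in [0, 1]")
        if not 0.0 <= self.necrotic_core_fraction < 1.0:
            raise ValidationError("necrotic_core_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a whole synthetic cohort.

    Defaults mirror the study conditions: 56 patients, ~70% high grade,
    ~24/32 split between the two scanner geometries. Per-grade texture and
    peak-SUV settings are the separability dial: with the defaults the two
    grades differ strongly in intra-lesion heterogeneity; setting the
    ``*_low`` values equal to the ``*_high`` ones yields a null cohort whose
    labels carry no image information.
    """

    n_patients: int = 56
    high_grade_fraction: float = 0.70
    scanner_a_fraction: float = 24 / 56
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 20)
    amp_high: float = 0.60
    amp_low: float = 0.05
    heterogeneity_scale: float = 3.0
    peak_range_high: tuple[float, float] = (6.0, 12.0)
    peak_range_low: tuple[float, float] = (4.0, 9.0)
    necrotic_fraction_high: float = 0.35  # volume fraction of every high-grade lesion
    base_semi_axes: tuple[float, float, float] = (9.0, 9.0, 9.0)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be at least 2")
        if not 0.0 < self.high_grade_fraction < 1.0:
            raise ValidationError("high_grade_fraction must lie in (0, 1)")


def make_default_profiles() -> tuple[ScannerProfile, ScannerProfile]:
    """The two default scanner geometries.

    Profile A is the high-resolution TOF/PSF geometry (0.4821 mm in-plane,
    3 mm slices); profile B the coarser one (1.17 mm in-plane, 3.27 mm
    slices, wider effective point spread).
    """
    a = ScannerProfile(
        name="scanner_a", voxel_spacing=(0.4821, 0.4821, 3.0), psf_fwhm=4.0, noise_sd=0.08
    )
    b = ScannerProfile(
        name="scanner_b", voxel_spacing=(1.17, 1.17, 3.27), psf_fwhm=5.0, noise_sd=0.08
    )
    return a, b


def _radial_field(
    shape: tuple[int, int, int],
    centre: tuple[int, int, int],
    semi_axes: tuple[float, float, float],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Normalized squared ellipsoidal radius (<= 1 inside the lesion)."""
    axes = [
        ((np.arange(n) - c) * s / a) ** 2
        for n, c, s, a in zip(shape, centre, spacing, semi_axes)
    ]
    return axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]


def synthesize_volume(
    lesion: LesionSpec,
    profile: ScannerProfile,
    seed: int,
    grid_shape: tuple[int, int, int] = (64, 64, 20),
) -> SuvVolume:
    """Render one lesion phantom.

    The noise-free, blur-free, homogeneous case is a deterministic radial
    ramp ``bg + (peak - bg) * (1 - r^(2 * edge_power))`` inside the ellipsoid
    (``r`` the normalized ellipsoidal radius): a paraboloid for
    ``edge_power=1`` and, at the default ``edge_power=4``, a plateau near
    ``peak_suv`` that falls to background over the outer rim — so that a
    homogeneous (low-grade) lesion really is near-uniform inside its
    segmented volume rather than dominated by its own radial gradient.
    Heterogeneity multiplies the lesion by
    ``1 + amp * G`` with ``G`` a unit-variance Gaussian random field of the
    requested correlation length; a necrotic core scales the central
    ``necrotic_core_fraction`` of the lesion volume down to 35% uptake.
    PSF blur and additive Gaussian noise are applied last.
    """
    spacing = profile.voxel_spacing
    half_extent = [a / s for a, s in zip(lesion.semi_axes, spacing)]
    for c, h, n in zip(lesion.centre, half_extent, grid_shape):
        if c - h < 2 or c + h > n - 3:
            raise ValidationError(
                f"lesion (centre {lesion.centre}, semi-axes {lesion.semi_axes} mm) "
                f"does not fit grid {grid_shape} with a 2-voxel margin"
            )
    rng = np.random.default_rng(seed)
    r2 = _radial_field(grid_shape, lesion.centre, lesion.semi_axes, spacing)
    inside = r2 <= 1.0
    vol = np.full(grid_shape, BACKGROUND_SUV, dtype=np.float64)
    vol[inside] += (lesion.peak_suv - BACKGROUND_SUV) * (
        1.0 - r2[inside] ** lesion.edge_power
    )
    if lesion.heterogeneity_amp > 0:
        sigma = [lesion.heterogeneity_scale / s for s in spacing]
        g = gaussian_filter(rng.standard_normal(grid_shape), sigma=sigma)
        sd = g[inside].std()
        if sd > 0:
            g = g / sd
        vol[inside] *= np.clip(1.0 + lesion.heterogeneity_amp * g[inside], 0.05, None)
    if lesion.necrotic_core_fraction > 0:
        core = r2 <= lesion.necrotic_core_fraction ** (2.0 / 3.0)
        vol[core] *= _NECROTIC_UPTAKE
    if profile.psf_fwhm > 0:
        sigma = [profile.psf_fwhm / 2.3548 / s for s in spacing]
        vol = gaussian_filter(vol, sigma=sigma)
    if profile.noise_sd > 0:
        vol += rng.normal(0.0, profile.noise_sd, grid_shape)
    return SuvVolume(values=np.clip(vol, 0.0, None), spacing=spacing)


def lesion_bounding_box(
    lesion: LesionSpec,
    spacing: tuple[float, float, float],
    grid_shape: tuple[int, int, int],
    margin: int = 2,
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Operator-box surrogate: the lesion extent plus a margin, clipped."""
    lo, hi = [], []
    for c, a, s, n in zip(lesion.centre, lesion.semi_axes, spacing, grid_shape):
        h = int(math.ceil(a / s)) + margin
        lo.append(max(0, c - h))
        hi.append(min(n - 1, c + h))
    return tuple(lo), tuple(hi)


def _class_counts(n: int, fraction: float) -> tuple[int, int]:
    """(high, low) counts: high = round(n * fraction), remainder low."""
    n_high = int(round(n * fraction))
    n_high = min(max(n_high, 1), n - 1)  # both classes always represented
    return n_high, n - n_high


def _plan_patients(spec: CohortSpec, profiles: tuple[ScannerProfile, ScannerProfile]):
    """Deterministic (scanner, grade) plan for every patient."""
    n_high, _ = _class_counts(spec.n_patients, spec.high_grade_fraction)
    n_a = int(round(spec.n_patients * spec.scanner_a_fraction))
    n_a = min(max(n_a, 2), spec.n_patients - 2)
    high_a = min(int(round(n_a * spec.high_grade_fraction)), n_a - 1, n_high)
    high_b = n_high - high_a
    plan = []
    for scanner, n_grp, h_grp in ((profiles[0], n_a, high_a), (profiles[1], spec.n_patients - n_a, high_b)):
        plan.extend((scanner, 1) for _ in range(h_grp))
        plan.extend((scanner, 0) for _ in range(n_grp - h_grp))
    return plan


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    profiles: tuple[ScannerProfile, ScannerProfile] | None = None,
) -> pd.DataFrame:
    """Write one phantom volume per patient plus a cohort manifest.

    The manifest (``manifest.csv``) holds one row per patient: id, scanner,
    grade, lesion ground truth, the operator bounding box and the volume
    path. Returns the manifest as a DataFrame.
    """
    profiles = profiles or make_default_profiles()
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    plan = _plan_patients(spec, profiles)
    master = np.random.default_rng(spec.seed)
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(len(plan))
    rows = []
    for i, (scanner, grade) in enumerate(plan):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(master.integers(0, 2**31))
        scale = rng.uniform(0.8, 1.3)
        semi = tuple(a * scale for a in spec.base_semi_axes)
        centre = tuple(
            int(n // 2 + rng.integers(-2, 3)) for n in spec.grid_shape
        )
        if grade == 1:
            peak = rng.uniform(*spec.peak_range_high)
            amp = spec.amp_high
            core = spec.necrotic_fraction_high
        else:
            peak = rng.uniform(*spec.peak_range_low)
            amp = spec.amp_low
            core = 0.0
        lesion = LesionSpec(
            centre=centre,
            semi_axes=semi,
            peak_suv=float(peak),
            grade=grade,
            heterogeneity_amp=amp,
            heterogeneity_scale=spec.heterogeneity_scale,
            necrotic_core_fraction=core,
        )
        vol = synthesize_volume(lesion, scanner, int(child_seeds[i]), spec.grid_shape)
        vpath = out_dir / "volumes" / f"{pid}.nii.gz"
        write_volume(vol, vpath)
        lo, hi = lesion_bounding_box(lesion, scanner.voxel_spacing, spec.grid_shape)
        rows.append(
            {
                "patient_id": pid,
                "scanner": scanner.name,
                "grade": grade,
                "centre_x": centre[0],
                "centre_y": centre[1],
                "centre_z": centre[2],
                "semi_x_mm": semi[0],
                "semi_y_mm": semi[1],
                "semi_z_mm": semi[2],
                "peak_suv": float(peak),
                "heterogeneity_amp": amp,
                "heterogeneity_scale_mm": spec.heterogeneity_scale,
                "necrotic_core_fraction": core,
                "box_x0": lo[0],
                "box_y0": lo[1],
                "box_z0": lo[2],
                "box_x1": hi[0],
                "box_y1": hi[1],
                "box_z1": hi[2],
                "volume_path": str(Path("volumes") / f"{pid}.nii.gz"),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def null_cohort_spec(spec: CohortSpec) -> CohortSpec:
    """A grade-independent variant of ``spec`` (labels carry no signal)."""
    return replace(
        spec,
        amp_low=spec.amp_high,
        peak_range_low=spec.peak_range_high,
        necrotic_fraction_high=0.0,
    )


# --- reference cohort bookkeeping -----------------------------------------
#
# Histological composition of the study cohort (56 patients over two
# scanner subgroups), with WHO grades I-II mapped to low grade (0) and
# III-IV to high grade (1).

_ReferenceRow = tuple[str, str, int, int]  # diagnosis, WHO grade, scanner A (Siemens), scanner B (GE)

_REFERENCE_HISTOLOGY: tuple[_ReferenceRow, ...] = (
    ("glioblastoma", "IV", 13, 20),
    ("anaplastic_astrocytoma", "III", 3, 3),
    ("diffuse_astrocytoma", "II", 0, 5),
    ("oligodendroglioma", "II", 4, 2),
    ("pilocytic_astrocytoma", "I", 3, 0),
    ("ganglioglioma", "I", 1, 0),
    ("meningioma", "I", 0, 2),
)


def reference_histology() -> pd.DataFrame:
    """The study cohort's histology table (counts per scanner subgroup)."""
    return pd.DataFrame(
        _REFERENCE_HISTOLOGY, columns=["diagnosis", "who_grade", "siemens", "ge"]
    )


def who_grade_is_high(who_grade: str) -> bool:
    """WHO grade to binary label: I-II low (False), III-IV high (True)."""
    grade = who_grade.strip().upper()
    if grade not in ("I", "II", "III", "IV"):
        raise ValidationError(f"unknown WHO grade {who_grade!r}")
    return grade in ("III", "IV")


def cohort_composition() -> dict[str, tuple[int, int]]:
    """(high, low) counts for the whole cohort and both scanner subgroups."""
    table = reference_histology()
    is_high = table["who_grade"].map(who_grade_is_high)
    out = {}
    for group, col in (("siemens", "siemens"), ("ge", "ge")):
        out[group] = (
            int(table.loc[is_high, col].sum()),
            int(table.loc[~is_high, col].sum()),
        )
    out["all"] = (
        out["siemens"][0] + out["ge"][0],
        out["siemens"][1] + out["ge"][1],
    )
    return out
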