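"""Synthetic vertebra phantoms and cohort tables with analytic ground truth.

The imaging phantom is an elliptic cylinder: a dense cortical shell of
controllable thickness around a lower-density trabecular core, embedded in
soft-tissue background, optionally degraded by Gaussian partial-volume blur
and additive Gaussian noise.  Ground truth (masks, per-slice thickness and
annulus area, shell volume) is derived from the continuous geometry before
any degradation, so downstream segmentation/morphometry can be validated
against exact values.

The cohort generator draws per-subject parameter vectors from per-group
Gaussians (a Gaussian copula supplies within-subject rank correlation) and
reproduces the reference study's group sizes and age/sex strata by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference_tables as ref

__all__ = [
    "PhantomSpec",
    "VoxelVolume",
    "GroundTruth",
    "GroupDefinition",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "generate_screening_registry",
]

#: default in-plane spacing: 512-voxel matrix over a nominal ~360 mm FOV
DEFAULT_SPACING = (1.25, 0.70, 0.70)  # (slice, row, col) mm


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one synthetic vertebra."""

    outer_semi_axes: tuple[float, float] = (20.0, 15.0)  # (a, b) mm in-plane
    body_height: float = 30.0                            # mm cranio-caudal
    cortical_thickness: float = 2.0                      # mm, uniform shell
    cortical_hu: float = 1200.0
    trabecular_hu: float = 100.0
    background_hu: float = 40.0
    noise_sd: float = 0.0                                # HU
    psf_fwhm: float = 0.0                                # mm
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    taper: float = 0.0        # fractional thickness reduction at endplates
    margin: float = 5.0       # mm of background around the body in-plane
    pad_slices: int = 2       # background slices above/below the body
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.outer_semi_axes
        if not (0 < self.cortical_thickness < min(a, b)):
            raise ValueError("cortical_thickness must be positive and smaller "
                             "than the smallest outer semi-axis")
        if not (self.cortical_hu > self.trabecular_hu > self.background_hu):
            raise ValueError("HU ordering must be cortical > trabecular > background")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if self.body_height <= 0 or a <= 0 or b <= 0:
            raise ValueError("dimensions must be strictly positive")
        if not 0.0 <= self.taper < 1.0:
            raise ValueError("taper must be in [0, 1)")


@dataclass
class VoxelVolume:
    """A 3-D HU grid with physical spacing; axis order is (slice, row, col)."""

    hu_grid: np.ndarray
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu_grid = np.asarray(self.hu_grid, dtype=float)
        if self.hu_grid.ndim != 3 or self.hu_grid.size == 0:
            raise ValueError("hu_grid must be a non-empty 3-D array")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.hu_grid)):
            raise ValueError("HU values must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_spacing
        return dz * dy * dx


@dataclass
class GroundTruth:
    """Analytic truth for one phantom, from the un-degraded geometry."""

    cortical_mask: np.ndarray
    trabecular_mask: np.ndarray
    true_thickness_by_slice: np.ndarray  # mm, NaN outside the body
    true_area_by_slice: np.ndarray       # mm^2, NaN outside the body
    true_volume: float                   # mm^3, analytic shell volume

    def __post_init__(self) -> None:
        if np.logical_and(self.cortical_mask, self.trabecular_mask).any():
            raise ValueError("cortical and trabecular masks must be disjoint")


def _slice_thickness_profile(spec: PhantomSpec, z_centers: np.ndarray,
                             z_mid: float, half_height: float) -> np.ndarray:
    """Per-slice shell thickness; linear taper toward the endplates."""
    t = np.full(z_centers.shape, spec.cortical_thickness)
    if spec.taper > 0:
        frac = np.abs(z_centers - z_mid) / half_height
        t = spec.cortical_thickness * (1.0 - spec.taper * np.clip(frac, 0, 1))
    return t


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Voxelize the phantom and return the degraded volume plus ground truth.

    Voxels belong to a region when their center lies inside the continuous
    boundary.  Blur (Gaussian PSF of the stated FWHM) and then noise are
    applied to the HU grid only; truth masks always reflect the clean
    geometry.  Bit-identical output for equal specs (seed included).
    """
    a, b = spec.outer_semi_axes
    dz, dy, dx = spec.voxel_spacing

    n_body = max(1, round(spec.body_height / dz))
    nz = n_body + 2 * spec.pad_slices
    ny = int(math.ceil(2 * (b + spec.margin) / dy))
    nx = int(math.ceil(2 * (a + spec.margin) / dx))

    z = np.arange(nz) * dz
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    z_lo = spec.pad_slices * dz - dz / 2.0
    z_hi = z_lo + n_body * dz
    body_slices = (z > z_lo) & (z < z_hi)
    z_mid = (z_lo + z_hi) / 2.0

    thickness = np.full(nz, np.nan)
    thickness[body_slices] = _slice_thickness_profile(
        spec, z[body_slices], z_mid, (z_hi - z_lo) / 2.0)

    cortical = np.zeros((nz, ny, nx), dtype=bool)
    trabecular = np.zeros((nz, ny, nx), dtype=bool)
    area = np.full(nz, np.nan)
    for k in np.flatnonzero(body_slices):
        t = thickness[k]
        ai, bi = a - t, b - t
        outer = (x[None, :] / a) ** 2 + (y[:, None] / b) ** 2 <= 1.0
        inner = (x[None, :] / ai) ** 2 + (y[:, None] / bi) ** 2 <= 1.0
        cortical[k] = outer & ~inner
        trabecular[k] = inner
        area[k] = math.pi * (a * b - ai * bi)

    hu = np.full((nz, ny, nx), spec.background_hu, dtype=float)
    hu[trabecular] = spec.trabecular_hu
    hu[cortical] = spec.cortical_hu

    if spec.psf_fwhm > 0:
        sigma_mm = spec.psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        hu = ndimage.gaussian_filter(hu, sigma=[sigma_mm / s for s in (dz, dy, dx)])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)

    meta: dict = {"spec": spec, "warnings": []}
    if spec.cortical_thickness < min(dy, dx):
        meta["warnings"].append(
            "shell_below_resolution: cortical thickness "
            f"{spec.cortical_thickness:g} mm < in-plane voxel {min(dy, dx):g} mm")

    true_volume = float(np.nansum(area) * dz)
    volume = VoxelVolume(hu, spec.voxel_spacing, meta=meta)
    truth = GroundTruth(cortical, trabecular, thickness, area, true_volume)
    return volume, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDefinition:
    """One cohort stratum: label, size, per-parameter Gaussians, covariates."""

    label: str
    n: int
    means: dict
    sds: dict
    sex: str | None = None            # "male" / "female" / None
    vbmd_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    rank_correlation: float = 0.7  # equicorrelation of the Gaussian copula
    floor: float = 0.01            # truncation floor for positive quantities
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("group list must be non-empty")
        if not -1.0 / 3.0 < self.rank_correlation < 1.0:
            raise ValueError("equicorrelation must be in (-1/3, 1) for 4 parameters")

    @classmethod
    def default(cls, seed: int = 0) -> "CohortSpec":
        """Reference-cohort layout: vBMD-class Gaussians per parameter, group
        sizes split by sex so that the per-sex osteoporosis counts match the
        reference (female 32/41, male 20/76)."""
        per_sex_n = {  # (female, male) per class; sums give 59/58/52
            "normal": (21, 38),
            "osteopenia": (20, 38),
            "osteoporosis": (32, 20),
        }
        vbmd_ranges = {
            "normal": (121.0, 200.0),
            "osteopenia": (80.0, 120.0),
            "osteoporosis": (25.0, 79.5),
        }
        groups = []
        table = ref.BMD_GROUPS_ALL
        for ci, label in enumerate(table["labels"]):
            means = {p: table["mean_sd"][p][ci][0] for p in ref.PARAMETERS}
            sds = {p: table["mean_sd"][p][ci][1] for p in ref.PARAMETERS}
            for sex, n in zip(("female", "male"), per_sex_n[label]):
                groups.append(GroupDefinition(
                    label=label, n=n, means=means, sds=sds, sex=sex,
                    vbmd_range=vbmd_ranges[label]))
        return cls(groups=tuple(groups), seed=seed)


def _copula_draws(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """n x k standard normals with equicorrelation rho (Cholesky of the
    compound-symmetric matrix)."""
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((n, k)) @ chol.T


def _assign_age_strata(rng: np.random.Generator, sexes: pd.Series) -> pd.DataFrame:
    """Assign age strata per sex with the reference per-sex stratum counts,
    scaled proportionally when the cohort size differs; ages drawn uniformly
    within stratum (70+ capped at the reference maximum age)."""
    bounds = {"50-59": (50, 59), "60-69": (60, 69),
              "70+": (70, ref.DEMOGRAPHICS["age_max"])}
    strata = pd.Series(index=sexes.index, dtype=object)
    ages = pd.Series(index=sexes.index, dtype=int)
    for sex in ("female", "male"):
        idx = sexes.index[sexes == sex]
        counts = np.array(ref.AGE_STRATUM_COUNTS[sex], dtype=float)
        total = len(idx)
        if total == 0:
            continue
        scaled = np.floor(counts / counts.sum() * total).astype(int)
        while scaled.sum() < total:  # largest-remainder top-up
            frac = counts / counts.sum() * total - scaled
            scaled[int(np.argmax(frac))] += 1
        labels = np.repeat(ref.AGE_STRATA, scaled)
        perm = rng.permutation(total)
        for pos, i in enumerate(idx):
            s = labels[perm[pos]]
            lo, hi = bounds[s]
            strata[i] = s
            ages[i] = int(rng.integers(lo, hi + 1))
    return pd.DataFrame({"age": ages, "age_stratum": strata})


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic subject table from per-group Gaussians.

    Negative draws of physically positive quantities are truncated at
    ``spec.floor`` and flagged in ``truncated_parameters``.  Deterministic
    for a fixed spec/seed.
    """
    if spec is None:
        spec = CohortSpec.default(seed=0 if seed is None else seed)
    elif seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    params = ref.PARAMETERS
    rows = []
    sid = 0
    for g in spec.groups:
        z = _copula_draws(rng, g.n, len(params), spec.rank_correlation)
        for i in range(g.n):
            sid += 1
            rec = {"subject_id": f"S{sid:04d}", "bmd_class": g.label,
                   "sex": g.sex or "female"}
            truncated = []
            for j, p in enumerate(params):
                val = g.means[p] + g.sds[p] * z[i, j]
                if val < spec.floor:
                    val = spec.floor
                    truncated.append(p)
                rec[p] = val
            rec["truncated_parameters"] = ";".join(truncated)
            if g.vbmd_range is not None:
                lo, hi = g.vbmd_range
                rec["vbmd"] = float(rng.uniform(lo, hi))
            else:
                rec["vbmd"] = float("nan")
            rows.append(rec)
    df = pd.DataFrame(rows)
    cov = _assign_age_strata(rng, df["sex"])
    df["age"] = cov["age"]
    df["age_stratum"] = cov["age_stratum"]
    # tabulated volume unit is 10^3 mm^3; expose raw mm^3 alongside
    df["total_volume_mm3"] = df["total_volume"] * 1000.0
    order = ["subject_id", "sex", "age", "age_stratum", "bmd_class", "vbmd",
             *params, "total_volume_mm3", "truncated_parameters"]
    return df[order]


# ---------------------------------------------------------------------------
# Screening registry
# ---------------------------------------------------------------------------

def generate_screening_registry(seed: int = 0) -> pd.DataFrame:
    """Synthetic screening registry reproducing the reference STROBE flow.

    326 records; 157 carry exactly one of five mutually exclusive exclusion
    categories (category counts fixed); the remaining 169 are eligible.
    Row order is a seeded permutation, so the flow counts are deterministic
    but the registry is not sorted by category.
    """
    rng = np.random.default_rng(seed)
    flow = ref.SCREENING_FLOW
    categories: list[str | None] = []
    for cat, n in flow["excluded"].items():
        categories.extend([cat] * n)
    categories.extend([None] * flow["included"])
    assert len(categories) == flow["screened"]
    perm = rng.permutation(len(categories))
    ages = rng.integers(ref.DEMOGRAPHICS["age_min"],
                        ref.DEMOGRAPHICS["age_max"] + 1, size=len(categories))
    sexes = rng.choice(["male", "female"], size=len(categories))
    rows = [{
        "subject_id": f"R{i + 1:04d}",
        "age": int(ages[i]),
        "sex": sexes[i],
        "exclusion_category": categories[perm[i]] or "",
    } for i in range(len(categories))]
    return pd.DataFrame(rows)
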