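"""Synthetic longitudinal grey-matter cohort with planted ground truth.

Emulates the study design every downstream stage assumes: healthy controls
(HC) scanned once and patients (AD) scanned twice one year apart, with

* planted atrophy in named spherical regions (fractional GMV loss per
  group/timepoint),
* a planted across-subject covariance difference between groups on one
  region pair (a latent-factor loading present in HC only),
* a planted cross-lagged effect of baseline "source" regions on follow-up
  "target" regions (a stable subject trait expressed in sources at both
  timepoints and in targets at follow-up only),
* a planted correlation between regional GMV change and MoCA change.

Each scan is a smooth "cortical slab" — a thick sheet with a parabolic
through-thickness profile peaking at its medial plane, so the true skeleton
is known analytically — plus region spheres whose column intensities are
scaled per subject. At a medial-plane voxel inside region R of a scan of
subject s the value is

    v = mu_R * (1 - delta[group, timepoint, R])
        + loading[group, R] * f_s            (shared covariance factor)
        + kappa * g_s        if R is a causal source
        + gamma * g_s        if R is a causal target, at T2 only
        + b[s, R]            (stable subject-region effect, sd subject_sd)
        + eta[s, R, t]       (per-scan region scatter, sd noise_sd)
        + eps                (per-voxel noise, sd voxel_noise_sd)

with f_s, g_s standard-normal per subject, shared across the subject's two
scans. Off the medial plane the deterministic and scalar terms are scaled
by the through-thickness profile so each region modulates a whole column of
the slab. Values are clipped at zero (modulated GM maps are non-negative).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecValidationError
from .volume_io import (
    PHENOTYPE_COLUMNS,
    ScanVolume,
    VolumeImage,
    volume_filename,
    write_phenotypes,
    write_volume,
)

GROUPS = ("HC", "AD")
TIMEPOINTS = ("T1", "T2")

# Region categories the planted effect sizes are designed to produce:
# "overlapped"  — deficit vs HC at both timepoints, no appreciable worsening;
# "continuing"  — deficit vs HC at follow-up that also worsens T1 -> T2;
# "progressive" — within-patient T1 -> T2 decline too small to separate the
#                 patient group from HC cross-sectionally.
DEFAULT_REGION_CATEGORIES = {
    "frontal": "overlapped",
    "hippocampus": "overlapped",
    "cingulate": "continuing",
    "STG_left": "progressive",
    "STG_right": "progressive",
    "caudate_left": "progressive",
}

# Group-specific score distributions: (mean, sd, low, high). CDR is fixed 0
# for HC. Ages at follow-up are the baseline age plus the scan interval.
SCORE_DISTRIBUTIONS = {
    ("HC", "age"): (74.78, 4.95, 66.6, 84.8),
    ("HC", "MMSE"): (29.13, 1.25, 24, 30),
    ("HC", "MoCA"): (24.35, 2.46, 18, 29),
    ("AD_T1", "age"): (74.66, 7.23, 56, 88),
    ("AD_T1", "CDR"): (0.76, 0.32, 0.5, 2.0),
    ("AD_T1", "MMSE"): (23.1, 2.06, 19, 26),
    ("AD_T1", "MoCA"): (18.65, 4.62, 11, 27),
    ("AD_T2", "CDR"): (0.94, 0.47, 0.5, 2.0),
    ("AD_T2", "MMSE"): (21.0, 4.5, 9, 29),
}
SCAN_INTERVAL_YEARS = 1.07  # difference between the baseline and follow-up age means
MOCA_CHANGE_MEAN = -2.07  # follow-up minus baseline MoCA group means
MOCA_CHANGE_SD = 3.0
SEX_COUNTS = {"AD": (22, 18), "HC": (27, 18)}  # (male, female)


@dataclass(frozen=True)
class RegionDef:
    """A named sphere: center (voxel indices) and radius (voxels)."""

    name: str
    center: tuple[int, int, int]
    radius: float


def _default_regions() -> tuple[RegionDef, ...]:
    # Centers on the medial plane (z = 12) of the default 48x48x24 grid,
    # pairwise >= 14 voxels apart so spheres of radius 4 never touch.
    z = 12
    return (
        RegionDef("frontal", (10, 12, z), 4.0),
        RegionDef("hippocampus", (10, 34, z), 4.0),
        RegionDef("cingulate", (24, 16, z), 4.0),
        RegionDef("STG_left", (38, 10, z), 4.0),
        RegionDef("STG_right", (38, 38, z), 4.0),
        RegionDef("caudate_left", (24, 38, z), 4.0),
    )


def _default_atrophy() -> dict[str, tuple[float, float]]:
    # (fractional loss at T1, fractional loss at T2) relative to baseline GMV.
    # Overlapped regions carry a large stable deficit; the continuing region
    # is intact at baseline and strongly atrophic at follow-up; progressive
    # regions decline by an amount detectable within subjects (low
    # within-subject noise) but not across groups (high between-subject
    # noise).
    return {
        "frontal": (0.45, 0.48),
        "hippocampus": (0.45, 0.48),
        "cingulate": (0.0, 0.28),
        "STG_left": (0.0, 0.10),
        "STG_right": (0.0, 0.10),
        "caudate_left": (0.0, 0.10),
    }


def default_edge_loading(target_r: float = 0.7, subject_sd: float = 0.14, noise_sd: float = 0.02) -> float:
    """Loading that yields an across-subject edge correlation ``target_r``.

    Two regions loading l on one standard-normal factor, each with residual
    region-level variance subject_sd^2 + noise_sd^2, correlate at
    r = l^2 / (l^2 + residual); invert for l.
    """
    resid = subject_sd**2 + noise_sd**2
    return math.sqrt(target_r / (1.0 - target_r) * resid)


def _default_loadings() -> dict[tuple[str, str], float]:
    l = default_edge_loading()
    return {("HC", "STG_right"): l, ("HC", "caudate_left"): l}


@dataclass
class CohortSpec:
    """Design of the synthetic cohort; defaults are the study conditions."""

    n_hc: int = 45
    n_ad: int = 40
    n_ad_with_moca_both: int = 38
    n_hc_with_moca: int = 43
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size_mm: float = 2.0
    region_definitions: tuple[RegionDef, ...] = field(default_factory=_default_regions)
    atrophy_effects: dict[str, tuple[float, float]] = field(default_factory=_default_atrophy)
    covariance_loadings: dict[tuple[str, str], float] = field(default_factory=_default_loadings)
    behavior_coupling: float = 0.44
    behavior_regions: tuple[str, ...] = ("STG_right",)
    noise_sd: float = 0.02  # per-scan region scatter (eta)
    voxel_noise_sd: float = 0.04  # iid per-voxel noise (eps)
    subject_sd: float = 0.14  # stable subject-region effect (b)
    causal_source_regions: tuple[str, ...] = ("frontal", "hippocampus")
    causal_target_regions: tuple[str, ...] = ("cingulate", "STG_left", "STG_right", "caudate_left")
    causal_kappa: float = 0.07  # trait expression in source regions (both timepoints)
    causal_gamma: float = 0.05  # trait expression in target regions (T2 only)
    slab_peak: float = 0.7  # GM value at the medial plane
    slab_half_thickness: float = 3.0  # voxels; parabola reaches zero here
    slab_plane_z: int | None = None  # default: grid_shape[2] // 2
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_hc < 1:
            raise SpecValidationError("n_hc", "must be >= 1")
        if self.n_ad < 1:
            raise SpecValidationError("n_ad", "must be >= 1")
        if not 0 <= self.n_ad_with_moca_both <= self.n_ad:
            raise SpecValidationError("n_ad_with_moca_both", "must be in [0, n_ad]")
        if not 0 <= self.n_hc_with_moca <= self.n_hc:
            raise SpecValidationError("n_hc_with_moca", "must be in [0, n_hc]")
        if len(self.grid_shape) != 3 or any(int(s) < 4 for s in self.grid_shape):
            raise SpecValidationError("grid_shape", "needs 3 dimensions of >= 4 voxels")
        if self.voxel_size_mm <= 0:
            raise SpecValidationError("voxel_size_mm", "must be positive")
        if self.noise_sd <= 0:
            raise SpecValidationError("noise_sd", "must be positive")
        if self.voxel_noise_sd <= 0:
            raise SpecValidationError("voxel_noise_sd", "must be positive")
        if self.subject_sd < 0:
            raise SpecValidationError("subject_sd", "must be non-negative")
        if not -1 < self.behavior_coupling < 1:
            raise SpecValidationError("behavior_coupling", "must lie in (-1, 1)")
        names = [r.name for r in self.region_definitions]
        if len(set(names)) != len(names):
            raise SpecValidationError("region_definitions", "region names must be unique")
        for r in self.region_definitions:
            if r.radius <= 0:
                raise SpecValidationError("region_definitions", f"{r.name}: radius must be > 0")
            for c, n in zip(r.center, self.grid_shape):
                if c - r.radius < 0 or c + r.radius > n - 1:
                    raise SpecValidationError(
                        "region_definitions", f"{r.name}: sphere extends outside the grid"
                    )
        for name, deltas in self.atrophy_effects.items():
            if name not in names:
                raise SpecValidationError("atrophy_effects", f"unknown region {name!r}")
            for d in deltas:
                if not 0 <= d < 1:
                    raise SpecValidationError("atrophy_effects", f"{name}: deltas must be in [0, 1)")
        for (group, name) in self.covariance_loadings:
            if group not in GROUPS:
                raise SpecValidationError("covariance_loadings", f"unknown group {group!r}")
            if name not in names:
                raise SpecValidationError("covariance_loadings", f"unknown region {name!r}")
        for fieldname in ("behavior_regions", "causal_source_regions", "causal_target_regions"):
            for name in getattr(self, fieldname):
                if name not in names:
                    raise SpecValidationError(fieldname, f"unknown region {name!r}")
        if self.slab_plane_z is not None and not 0 <= self.slab_plane_z < self.grid_shape[2]:
            raise SpecValidationError("slab_plane_z", "outside grid")

    # -- derived geometry --------------------------------------------------
    @property
    def medial_plane_z(self) -> int:
        return self.grid_shape[2] // 2 if self.slab_plane_z is None else self.slab_plane_z

    def region_names(self) -> list[str]:
        return [r.name for r in self.region_definitions]

    def delta(self, group: str, timepoint: str, region: str) -> float:
        if group == "HC":
            return 0.0
        d1, d2 = self.atrophy_effects.get(region, (0.0, 0.0))
        return d1 if timepoint == "T1" else d2

    def loading(self, group: str, region: str) -> float:
        return float(self.covariance_loadings.get((group, region), 0.0))

    def scaled_down(self, factor: float = 0.5) -> "CohortSpec":
        """A geometrically reduced copy (grid, centers, radii scaled)."""
        grid = tuple(max(4, int(round(s * factor))) for s in self.grid_shape)
        plane = grid[2] // 2
        regions = tuple(
            RegionDef(
                r.name,
                (
                    int(round(r.center[0] * factor)),
                    int(round(r.center[1] * factor)),
                    plane,
                ),
                max(1.5, r.radius * factor),
            )
            for r in self.region_definitions
        )
        return replace(
            self,
            grid_shape=grid,
            region_definitions=regions,
            slab_plane_z=plane,
            slab_half_thickness=max(1.5, self.slab_half_thickness * factor),
        )


def null_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A spec with no planted effects of any kind (calibration runs)."""
    base = CohortSpec(seed=seed, **overrides)
    zero_atrophy = {name: (0.0, 0.0) for name in base.region_names()}
    equal_loadings = {}
    for (_, name), l in base.covariance_loadings.items():
        equal_loadings[("HC", name)] = l
        equal_loadings[("AD", name)] = l
    return replace(
        base,
        atrophy_effects=zero_atrophy,
        covariance_loadings=equal_loadings,
        behavior_coupling=0.0,
        causal_kappa=0.0,
        causal_gamma=0.0,
    )


@dataclass
class PlantedTruth:
    """Ground-truth manifest for parameter-recovery tests."""

    true_region_masks: dict[str, np.ndarray]
    label_image: np.ndarray
    region_labels: dict[str, int]
    true_group_means: dict[tuple[str, str, str], float]  # (group, timepoint, region)
    true_cov_difference_edges: list[tuple[str, str]]
    true_behavior_r: float
    true_causal_coefficient: float
    expected_categories: dict[str, str]
    medial_plane_z: int

    def to_manifest(self) -> dict:
        return {
            "region_labels": self.region_labels,
            "true_group_means": {
                f"{g}|{t}|{r}": v for (g, t, r), v in self.true_group_means.items()
            },
            "true_cov_difference_edges": [list(e) for e in self.true_cov_difference_edges],
            "true_behavior_r": self.true_behavior_r,
            "true_causal_coefficient": self.true_causal_coefficient,
            "expected_categories": self.expected_categories,
            "medial_plane_z": self.medial_plane_z,
        }


# ---------------------------------------------------------------------------
# Latent draws shared by phenotype and volume synthesis
# ---------------------------------------------------------------------------


def _subject_ids(spec: CohortSpec) -> tuple[list[str], list[str]]:
    ad = [f"AD{i + 1:03d}" for i in range(spec.n_ad)]
    hc = [f"HC{i + 1:03d}" for i in range(spec.n_hc)]
    return ad, hc


@dataclass
class _Latents:
    """Per-subject/scan random effects, drawn once per (spec, seed)."""

    f: dict[str, float]  # covariance factor
    g: dict[str, float]  # causal trait
    b: dict[tuple[str, str], float]  # (subject, region) stable effect
    eta: dict[tuple[str, str, str], float]  # (subject, region, timepoint)


def _draw_latents(spec: CohortSpec) -> _Latents:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    ad, hc = _subject_ids(spec)
    subjects = ad + hc
    names = spec.region_names()
    f = dict(zip(subjects, rng.standard_normal(len(subjects))))
    g = dict(zip(subjects, rng.standard_normal(len(subjects))))
    b_draw = rng.normal(0.0, spec.subject_sd, size=(len(subjects), len(names)))
    eta_draw = rng.normal(0.0, spec.noise_sd, size=(len(subjects), len(names), 2))
    b = {}
    eta = {}
    for i, s in enumerate(subjects):
        for j, r in enumerate(names):
            b[(s, r)] = float(b_draw[i, j])
            eta[(s, r, "T1")] = float(eta_draw[i, j, 0])
            eta[(s, r, "T2")] = float(eta_draw[i, j, 1])
    return _Latents(f=f, g=g, b=b, eta=eta)


def _region_deviation(spec: CohortSpec, lat: _Latents, subject: str, group: str, region: str, timepoint: str) -> float:
    """Scalar deviation added to mu_R(1-delta) at medial-plane voxels."""
    dev = (
        spec.loading(group, region) * lat.f[subject]
        + lat.b[(subject, region)]
        + lat.eta[(subject, region, timepoint)]
    )
    if region in spec.causal_source_regions:
        dev += spec.causal_kappa * lat.g[subject]
    if region in spec.causal_target_regions and timepoint == "T2":
        dev += spec.causal_gamma * lat.g[subject]
    return dev


def _planted_change(spec: CohortSpec, lat: _Latents, subject: str, region: str) -> float:
    """Planted T2 - T1 region signal for an AD subject (without voxel noise)."""
    d1 = spec.delta("AD", "T1", region)
    d2 = spec.delta("AD", "T2", region)
    change = -spec.slab_peak * (d2 - d1)
    change += lat.eta[(subject, region, "T2")] - lat.eta[(subject, region, "T1")]
    if region in spec.causal_target_regions:
        change += spec.causal_gamma * lat.g[subject]
    return change


def _planted_change_sd(spec: CohortSpec, region: str) -> float:
    var = 2.0 * spec.noise_sd**2
    if region in spec.causal_target_regions:
        var += spec.causal_gamma**2
    return math.sqrt(var)


def _truncnorm(rng: np.random.Generator, mean, sd, low, high, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """Demographics and cognitive scores for the synthetic cohort.

    Scores are truncated normals parameterized by group-level means/SDs and
    ranges; sex counts are fixed (22/18 patients, 27/18 controls); CDR is
    exactly 0 for every control. The patient MoCA change score is coupled to
    the planted GMV change in the designated behavior regions with
    correlation ``behavior_coupling``; subjects without MoCA (at both
    timepoints) are chosen at random to match the completion counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    lat = _draw_latents(spec)
    ad, hc = _subject_ids(spec)

    rows: list[dict] = []

    def sexes(group, n):
        m, f = SEX_COUNTS.get(group, (n // 2, n - n // 2))
        # Fixed counts; scale down proportionally for non-default sizes.
        if m + f != n:
            m = int(round(n * m / (m + f)))
            f = n - m
        arr = np.array(["M"] * m + ["F"] * f)
        return rng.permutation(arr)

    ad_sex = sexes("AD", spec.n_ad)
    hc_sex = sexes("HC", spec.n_hc)

    # -- AD subjects: paired T1/T2 rows ---------------------------------
    age1 = _truncnorm(rng, *SCORE_DISTRIBUTIONS[("AD_T1", "age")], size=spec.n_ad)
    cdr1 = _truncnorm(rng, *SCORE_DISTRIBUTIONS[("AD_T1", "CDR")], size=spec.n_ad)
    cdr2 = _truncnorm(rng, *SCORE_DISTRIBUTIONS[("AD_T2", "CDR")], size=spec.n_ad)
    mmse1 = np.round(_truncnorm(rng, *SCORE_DISTRIBUTIONS[("AD_T1", "MMSE")], size=spec.n_ad))
    mmse2 = np.round(_truncnorm(rng, *SCORE_DISTRIBUTIONS[("AD_T2", "MMSE")], size=spec.n_ad))
    moca1 = np.round(_truncnorm(rng, *SCORE_DISTRIBUTIONS[("AD_T1", "MoCA")], size=spec.n_ad))

    # MoCA change coupled to the planted change signal of the behavior regions
    rho = spec.behavior_coupling
    z = np.zeros(spec.n_ad)
    if spec.behavior_regions:
        sig = np.zeros(spec.n_ad)
        for i, s in enumerate(ad):
            vals = []
            for r in spec.behavior_regions:
                mu = -spec.slab_peak * (spec.delta("AD", "T2", r) - spec.delta("AD", "T1", r))
                sd = _planted_change_sd(spec, r)
                vals.append((_planted_change(spec, lat, s, r) - mu) / sd)
            sig[i] = np.mean(vals)
        denom = np.std(sig) if len(spec.behavior_regions) > 1 else 1.0
        z = sig / (denom if denom > 0 else 1.0)
    noise = rng.standard_normal(spec.n_ad)
    delta_moca = np.round(MOCA_CHANGE_MEAN + MOCA_CHANGE_SD * (rho * z + math.sqrt(1 - rho**2) * noise))
    moca2 = np.clip(moca1 + delta_moca, 0, 30)

    n_missing_ad = spec.n_ad - spec.n_ad_with_moca_both
    ad_missing = set(rng.choice(spec.n_ad, size=n_missing_ad, replace=False)) if n_missing_ad else set()
    n_missing_hc = spec.n_hc - spec.n_hc_with_moca
    hc_missing = set(rng.choice(spec.n_hc, size=n_missing_hc, replace=False)) if n_missing_hc else set()

    for i, s in enumerate(ad):
        moca_t1 = np.nan if i in ad_missing else float(moca1[i])
        moca_t2 = np.nan if i in ad_missing else float(moca2[i])
        rows.append(
            dict(subject_id=s, group="AD", timepoint="T1", sex=ad_sex[i], age=round(float(age1[i]), 1),
                 CDR=round(float(cdr1[i]), 2), MMSE=int(mmse1[i]), MoCA=moca_t1)
        )
        rows.append(
            dict(subject_id=s, group="AD", timepoint="T2", sex=ad_sex[i],
                 age=round(float(age1[i]) + SCAN_INTERVAL_YEARS, 1),
                 CDR=round(float(cdr2[i]), 2), MMSE=int(mmse2[i]), MoCA=moca_t2)
        )

    # -- HC subjects: single T1 row --------------------------------------
    age_hc = _truncnorm(rng, *SCORE_DISTRIBUTIONS[("HC", "age")], size=spec.n_hc)
    mmse_hc = np.round(_truncnorm(rng, *SCORE_DISTRIBUTIONS[("HC", "MMSE")], size=spec.n_hc))
    moca_hc = np.round(_truncnorm(rng, *SCORE_DISTRIBUTIONS[("HC", "MoCA")], size=spec.n_hc))
    for i, s in enumerate(hc):
        rows.append(
            dict(subject_id=s, group="HC", timepoint="T1", sex=hc_sex[i], age=round(float(age_hc[i]), 1),
                 CDR=0.0, MMSE=int(mmse_hc[i]),
                 MoCA=np.nan if i in hc_missing else float(moca_hc[i]))
        )

    df = pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))
    return df.sort_values(["subject_id", "timepoint"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------


def slab_profile(spec: CohortSpec) -> np.ndarray:
    """Through-thickness profile: peak at the medial plane, parabolic falloff."""
    z = np.arange(spec.grid_shape[2], dtype=float)
    u = (z - spec.medial_plane_z) / spec.slab_half_thickness
    return spec.slab_peak * np.clip(1.0 - u**2, 0.0, None)


def region_masks(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Boolean sphere masks, one per region definition."""
    nx, ny, nz = spec.grid_shape
    ii, jj, kk = np.ogrid[:nx, :ny, :nz]
    masks = {}
    for r in spec.region_definitions:
        cx, cy, cz = r.center
        d2 = (ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2
        masks[r.name] = d2 <= r.radius**2
    return masks


def _build_truth(spec: CohortSpec, masks: dict[str, np.ndarray]) -> PlantedTruth:
    label_image = np.zeros(spec.grid_shape, dtype=np.int16)
    labels = {}
    for i, name in enumerate(spec.region_names(), start=1):
        label_image[masks[name]] = i
        labels[name] = i
    means = {}
    for g in GROUPS:
        for t in TIMEPOINTS:
            if g == "HC" and t == "T2":
                continue
            for r in spec.region_names():
                means[(g, t, r)] = spec.slab_peak * (1.0 - spec.delta(g, t, r))
    edges = []
    names = spec.region_names()
    for i, a in enumerate(names):
        for b_name in names[i + 1:]:
            la_hc, lb_hc = spec.loading("HC", a), spec.loading("HC", b_name)
            la_ad, lb_ad = spec.loading("AD", a), spec.loading("AD", b_name)
            if not math.isclose(la_hc * lb_hc, la_ad * lb_ad, abs_tol=1e-12):
                edges.append((a, b_name))
    resid = spec.subject_sd**2 + spec.noise_sd**2
    k = max(1, len(spec.causal_source_regions))
    var_x = spec.causal_kappa**2 + resid / k
    var_y = spec.causal_gamma**2 + resid
    causal = 0.0
    if spec.causal_kappa and spec.causal_gamma and var_x > 0 and var_y > 0:
        causal = spec.causal_kappa * spec.causal_gamma / math.sqrt(var_x * var_y)
    categories = {
        name: DEFAULT_REGION_CATEGORIES.get(name, "unknown") for name in names
    }
    return PlantedTruth(
        true_region_masks=masks,
        label_image=label_image,
        region_labels=labels,
        true_group_means=means,
        true_cov_difference_edges=edges,
        true_behavior_r=spec.behavior_coupling,
        true_causal_coefficient=causal,
        expected_categories=categories,
        medial_plane_z=spec.medial_plane_z,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[ScanVolume], pd.DataFrame, PlantedTruth]:
    """Generate volumes, phenotypes, and the ground-truth manifest.

    Deterministic for a fixed (spec, seed); emits ``n_hc + 2 * n_ad``
    volumes in sorted (subject_id, timepoint) order.
    """
    spec.validate()
    phen = generate_phenotypes(spec)
    lat = _draw_latents(spec)
    masks = region_masks(spec)
    truth = _build_truth(spec, masks)

    profile = slab_profile(spec)  # (nz,)
    background = np.broadcast_to(profile, spec.grid_shape).copy()
    p0 = spec.slab_peak
    vs = (spec.voxel_size_mm,) * 3

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 3]))
    scans: list[ScanVolume] = []
    for row in phen.drop_duplicates(["subject_id", "timepoint"]).itertuples(index=False):
        s, g, t = str(row.subject_id), str(row.group), str(row.timepoint)
        colscale = np.ones(spec.grid_shape)
        for name in spec.region_names():
            dev = _region_deviation(spec, lat, s, g, name, t)
            colscale[masks[name]] = (1.0 - spec.delta(g, t, name)) + dev / p0
        data = background * colscale + rng.normal(0.0, spec.voxel_noise_sd, spec.grid_shape)
        np.clip(data, 0.0, None, out=data)
        scans.append(ScanVolume(s, t, g, VolumeImage(data, voxel_size_mm=vs)))
    return scans, phen, truth


def planted_change_table(spec: CohortSpec) -> pd.DataFrame:
    """Per-patient planted GMV change signals (no voxel noise), per region.

    The noise-free substrate of the brain-behavior coupling; used to verify
    the coupling without running the imaging stages.
    """
    lat = _draw_latents(spec)
    ad, _ = _subject_ids(spec)
    rows = []
    for s in ad:
        rec = {"subject_id": s}
        for r in spec.region_names():
            rec[f"delta_{r}"] = _planted_change(spec, lat, s, r)
        rows.append(rec)
    return pd.DataFrame(rows)


def write_cohort(
    scans: Sequence[ScanVolume],
    phenotypes: pd.DataFrame,
    truth: PlantedTruth,
    out_dir: str | Path,
) -> Path:
    """Write volumes (.nii.gz), phenotypes (CSV), and the truth manifest."""
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    for scan in scans:
        write_volume(scan.image, vol_dir / volume_filename(scan.subject_id, scan.timepoint))
    write_phenotypes(phenotypes, out_dir / "phenotypes.csv")
    ref = scans[0].image
    write_volume(
        VolumeImage(truth.label_image.astype(float), voxel_size_mm=ref.voxel_size_mm),
        out_dir / "truth_labels.nii.gz",
    )
    (out_dir / "truth_manifest.json").write_text(json.dumps(truth.to_manifest(), indent=2))
    return out_dir
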