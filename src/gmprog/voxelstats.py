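"""Voxelwise group statistics on the skeleton, FDR correction, cluster
filtering, and derivation of the overlapped / continuing / progressive
region groups.

Conventions
-----------
* Voxelwise maps use the pooled-variance Student t (the usual voxel-based
  morphometry convention); demographic comparisons use Welch's t, which is
  the right model for summary-statistic group tables.
* Multiple comparisons are handled with the Benjamini-Hochberg FDR step-up
  at alpha = 0.05, followed by a cluster-extent filter that keeps clusters
  strictly larger than ``min_cluster_voxels`` (default 30, i.e. surviving
  size >= 31) under 26-connectivity.
* Zero-variance voxels get t = 0, p = 1, and are counted in
  ``StatMap.n_zero_variance`` rather than producing NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientDataError,
    PairingError,
    ShapeError,
    SpecValidationError,
)
from .skeleton import SkeletonModel
from .volume_io import VolumeImage

logger = logging.getLogger(__name__)

CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


# ---------------------------------------------------------------------------
# Stat maps
# ---------------------------------------------------------------------------


@dataclass
class StatMap:
    """Per-skeleton-voxel statistic, p, and FDR-adjusted q values."""

    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    df: float
    contrast: str
    model: SkeletonModel
    n_zero_variance: int = 0

    def __post_init__(self):
        n = self.model.n_voxels
        for name in ("statistic", "p", "q"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ShapeError(f"{name} has shape {arr.shape}, expected ({n},)")

    def significant_mask(self, alpha: float, sign: int = 0) -> np.ndarray:
        """3D boolean grid of voxels with q < alpha (and the given t sign)."""
        keep = self.q < alpha
        if sign > 0:
            keep &= self.statistic > 0
        elif sign < 0:
            keep &= self.statistic < 0
        return self.model.embed(keep.astype(float)) > 0.5


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (monotone; rejection via q <= alpha
    reproduces the classic step-up rule's rejection set)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise SpecValidationError("p", "p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize_map(t, p, df, contrast, model, n_zero) -> StatMap:
    if n_zero:
        logger.warning("%s: %d zero-variance voxels set to p = 1", contrast, n_zero)
    return StatMap(
        statistic=t, p=p, q=fdr_bh(p), df=float(df), contrast=contrast,
        model=model, n_zero_variance=int(n_zero),
    )


def two_sample_t_map(
    group_a: np.ndarray,
    group_b: np.ndarray,
    model: SkeletonModel,
    contrast: str = "A_vs_B",
) -> StatMap:
    """Voxelwise pooled-variance Student t of group A minus group B.

    ``group_a``/``group_b`` are (n_subjects, n_voxels) matrices of skeleton
    samples. Two-tailed p values.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise InsufficientDataError("each group needs >= 3 subjects")
    if a.shape[1] != b.shape[1]:
        raise ShapeError(f"vector lengths differ: {a.shape[1]} vs {b.shape[1]}")
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ssa = a.var(axis=0, ddof=1) * (na - 1)
    ssb = b.var(axis=0, ddof=1) * (nb - 1)
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    zero = se <= 0
    t = np.zeros_like(mean_diff)
    np.divide(mean_diff, se, out=t, where=~zero)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero] = 1.0
    return _finalize_map(t, p, df, contrast, model, zero.sum())


def paired_t_map(
    vectors_t1: np.ndarray,
    vectors_t2: np.ndarray,
    subjects_t1: Sequence[str],
    subjects_t2: Sequence[str],
    model: SkeletonModel,
    contrast: str = "T2_vs_T1_paired",
) -> StatMap:
    """Voxelwise paired t on T2 - T1 differences of the same subjects."""
    s1, s2 = list(subjects_t1), list(subjects_t2)
    if s1 != s2:
        broken = sorted(set(s1).symmetric_difference(s2)) or [
            a for a, b in zip(s1, s2) if a != b
        ]
        raise PairingError(f"timepoints are not paired for subjects: {broken}", broken)
    x1 = np.atleast_2d(np.asarray(vectors_t1, dtype=float))
    x2 = np.atleast_2d(np.asarray(vectors_t2, dtype=float))
    if x1.shape != x2.shape:
        raise ShapeError(f"paired matrices differ in shape: {x1.shape} vs {x2.shape}")
    n = x1.shape[0]
    if n < 3:
        raise InsufficientDataError("paired test needs >= 3 pairs")
    d = x2 - x1
    df = n - 1
    sd = d.std(axis=0, ddof=1)
    zero = sd <= 0
    t = np.zeros(d.shape[1])
    np.divide(d.mean(axis=0), sd / np.sqrt(n), out=t, where=~zero)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero] = 1.0
    return _finalize_map(t, p, df, contrast, model, zero.sum())


# ---------------------------------------------------------------------------
# Total GMV
# ---------------------------------------------------------------------------


def total_gmv(volume: VolumeImage, model: SkeletonModel) -> float:
    """Total GMV (mm^3) over the skeleton: sum of values times voxel volume."""
    if volume.shape != model.skeleton_mask.shape:
        raise ShapeError("volume grid does not match the skeleton grid")
    return float(volume.data[model.skeleton_mask].sum() * volume.voxel_volume_mm3)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    name: str
    label: int
    size: int
    peak_voxel: tuple[int, int, int]
    category: str


@dataclass
class RegionSet:
    """Labeled voxel clusters on the skeleton grid, one category per set."""

    label_image: np.ndarray  # 3D int, 0 = background
    clusters: list[Cluster] = field(default_factory=list)
    category: str = ""

    @property
    def is_empty(self) -> bool:
        return len(self.clusters) == 0

    def mask(self) -> np.ndarray:
        return self.label_image > 0

    def cluster_mask(self, name: str) -> np.ndarray:
        for c in self.clusters:
            if c.name == name:
                return self.label_image == c.label
        raise KeyError(f"no cluster named {name!r} in {self.category} regions")

    def rename(self, mapping: dict[str, str]) -> None:
        for c in self.clusters:
            c.name = mapping.get(c.name, c.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(name=c.name, label=c.label, size=c.size,
                     peak_voxel="|".join(map(str, c.peak_voxel)), category=c.category)
                for c in self.clusters
            ],
            columns=["name", "label", "size", "peak_voxel", "category"],
        )


def _cluster_mask(
    sig_grid: np.ndarray,
    stat_grid: np.ndarray,
    min_cluster_voxels: int,
    category: str,
) -> RegionSet:
    """Label 26-connected components of ``sig_grid``; keep strictly larger
    than ``min_cluster_voxels``; order clusters by size descending."""
    labels, n = ndimage.label(sig_grid, structure=CONNECTIVITY_STRUCTURE)
    out = np.zeros_like(labels)
    clusters: list[Cluster] = []
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        order = np.argsort(-sizes, kind="stable")
        new_label = 0
        for k in order:
            size = int(sizes[k])
            if size <= min_cluster_voxels:
                continue
            new_label += 1
            comp = labels == (k + 1)
            out[comp] = new_label
            peak_flat = np.flatnonzero(comp.ravel())[np.argmax(np.abs(stat_grid.ravel()[comp.ravel()]))]
            peak = tuple(int(v) for v in np.unravel_index(peak_flat, comp.shape))
            clusters.append(
                Cluster(name=f"{category}_{new_label}", label=new_label, size=size,
                        peak_voxel=peak, category=category)
            )
    return RegionSet(label_image=out, clusters=clusters, category=category)


def threshold_and_cluster(
    statmap: StatMap,
    alpha: float = 0.05,
    min_cluster_voxels: int = 30,
    sign: int = -1,
) -> RegionSet:
    """Threshold a stat map at q < alpha with the requested t sign, then
    label 26-connected clusters and drop those of size <= min_cluster_voxels."""
    sig = statmap.significant_mask(alpha, sign)
    stat_grid = statmap.model.embed(statmap.statistic)
    return _cluster_mask(sig, stat_grid, min_cluster_voxels, category="cluster")


def overlapped_regions(
    map_t1_vs_hc: StatMap,
    map_t2_vs_hc: StatMap,
    alpha: float = 0.05,
    min_cluster_voxels: int = 30,
) -> RegionSet:
    """Areas atrophic in both patient-vs-control comparisons.

    Voxelwise intersection of the two thresholded decrease maps
    (t < 0, q < alpha in both), then cluster-filtered.
    """
    if map_t1_vs_hc.model is not map_t2_vs_hc.model and not np.array_equal(
        map_t1_vs_hc.model.skeleton_mask, map_t2_vs_hc.model.skeleton_mask
    ):
        raise ShapeError("stat maps live on different skeletons")
    sig = map_t1_vs_hc.significant_mask(alpha, -1) & map_t2_vs_hc.significant_mask(alpha, -1)
    stat_grid = map_t2_vs_hc.model.embed(map_t2_vs_hc.statistic)
    rs = _cluster_mask(sig, stat_grid, min_cluster_voxels, category="overlapped")
    return rs


def continuing_regions(
    map_t1_vs_hc: StatMap,
    map_t2_vs_hc: StatMap,
    paired_map: StatMap,
    alpha: float = 0.05,
    min_cluster_voxels: int = 30,
    rule: str = "t2_and_paired",
) -> RegionSet:
    """Areas whose deficit relative to controls continues to worsen.

    Default rule ("t2_and_paired"): significant decrease at follow-up vs
    controls AND significant within-patient decline (paired map), minus
    voxels already labeled overlapped. Alternative rule ("t2_not_t1"):
    significant at follow-up but not at baseline, minus overlapped voxels.
    The result is disjoint from the overlapped set by construction.
    """
    if rule not in ("t2_and_paired", "t2_not_t1"):
        raise SpecValidationError("rule", f"unknown continuing-regions rule {rule!r}")
    ov = overlapped_regions(map_t1_vs_hc, map_t2_vs_hc, alpha, min_cluster_voxels)
    sig_t2 = map_t2_vs_hc.significant_mask(alpha, -1)
    if rule == "t2_and_paired":
        sig = sig_t2 & paired_map.significant_mask(alpha, -1)
    else:
        sig = sig_t2 & ~map_t1_vs_hc.significant_mask(alpha, -1)
    sig &= ~ov.mask()
    stat_grid = map_t2_vs_hc.model.embed(map_t2_vs_hc.statistic)
    return _cluster_mask(sig, stat_grid, min_cluster_voxels, category="continuing")


def progressive_regions(
    paired_map: StatMap,
    overlapped: RegionSet,
    continuing: RegionSet,
    alpha: float = 0.05,
    min_cluster_voxels: int = 30,
) -> RegionSet:
    """Within-patient decline areas not already labeled overlapped or
    continuing; keeps the three categories mutually disjoint."""
    sig = paired_map.significant_mask(alpha, -1)
    sig &= ~overlapped.mask()
    sig &= ~continuing.mask()
    stat_grid = paired_map.model.embed(paired_map.statistic)
    return _cluster_mask(sig, stat_grid, min_cluster_voxels, category="progressive")


# ---------------------------------------------------------------------------
# Demographic tests
# ---------------------------------------------------------------------------


def sex_chi2_test(table: np.ndarray) -> tuple[float, float]:
    """Yates-continuity-corrected chi-squared on a 2x2 sex-count table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=True)
    return float(chi2), float(p)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-tailed Welch t computed from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("Welch test needs n >= 2 per group")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def cohort_demographic_tests(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison table: sex by Yates chi-squared, continuous scores
    by two-tailed Welch t, for HC vs each patient timepoint."""
    hc = phenotypes[(phenotypes["group"] == "HC")]
    if hc.empty:
        raise InsufficientDataError("no HC rows")
    rows = []
    for tp in ("T1", "T2"):
        ad = phenotypes[(phenotypes["group"] == "AD") & (phenotypes["timepoint"] == tp)]
        if ad.empty:
            continue
        comparison = f"HC_vs_AD-{tp}"
        tab = [
            [int((ad["sex"] == "M").sum()), int((ad["sex"] == "F").sum())],
            [int((hc["sex"] == "M").sum()), int((hc["sex"] == "F").sum())],
        ]
        chi2, p = sex_chi2_test(np.array(tab))
        rows.append(dict(measure="sex", comparison=comparison, statistic=chi2, p=p, test="chi2_yates"))
        for col in ("age", "CDR", "MMSE", "MoCA"):
            a = ad[col].dropna().to_numpy(dtype=float)
            h = hc[col].dropna().to_numpy(dtype=float)
            if len(a) < 2 or len(h) < 2:
                raise InsufficientDataError(f"{col}: fewer than 2 observations per group")
            if np.allclose(a, a[0]) and np.allclose(h, h[0]) and np.isclose(a[0], h[0]):
                t, p = 0.0, 1.0
            else:
                res = stats.ttest_ind(h, a, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(dict(measure=col, comparison=comparison, statistic=t, p=p, test="welch_t"))
    return pd.DataFrame(rows, columns=["measure", "comparison", "statistic", "p", "test"])
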