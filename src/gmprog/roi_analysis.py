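"""Region-level GMV extraction, longitudinal change scores, and
brain-behavior correlation.

Regions enter as named boolean masks on the skeleton grid (derived region
sets, pooled categories, or ground-truth lookups); the ROI table holds one
mean-GMV value per scan and region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstructionError,
    InsufficientDataError,
    PairingError,
    ShapeError,
)
from .skeleton import SkeletonModel, sample_on_skeleton
from .volume_io import ScanVolume
from .voxelstats import RegionSet


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ShapeError("masks have different shapes")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def region_columns(
    model: SkeletonModel,
    overlapped: RegionSet | None = None,
    continuing: RegionSet | None = None,
    progressive: RegionSet | None = None,
) -> dict[str, np.ndarray]:
    """Build the named region masks that become ROI-table columns.

    The overlapped and continuing categories are pooled into one column
    each; progressive clusters keep their individual (possibly renamed)
    cluster names, since each is a distinct correlation/feature substrate.
    """
    columns: dict[str, np.ndarray] = {}
    if overlapped is not None and not overlapped.is_empty:
        columns["overlapped"] = overlapped.mask()
    if continuing is not None and not continuing.is_empty:
        columns["continuing"] = continuing.mask()
    if progressive is not None:
        for c in progressive.clusters:
            columns[c.name] = progressive.cluster_mask(c.name)
    for name, mask in columns.items():
        if not (mask & model.skeleton_mask).any():
            raise ConstructionError(f"region {name!r} has no skeleton voxels")
    return columns


def match_clusters_to_truth(
    regions: RegionSet,
    truth_masks: Mapping[str, np.ndarray],
    model: SkeletonModel,
    min_dice: float = 0.1,
) -> dict[str, str]:
    """Map discovered cluster names to planted region names by best Dice.

    Overlap is scored on the skeleton (detected clusters live there). A
    manifest lookup, not an anatomical atlas query. Returns a renaming
    mapping for clusters whose best Dice reaches ``min_dice``.
    """
    skel = model.skeleton_mask
    mapping: dict[str, str] = {}
    used: set[str] = set()
    scored = []
    for c in regions.clusters:
        cmask = regions.cluster_mask(c.name)
        for name, tmask in truth_masks.items():
            scored.append((dice(cmask, np.asarray(tmask, bool) & skel), c.name, name))
    for score, cname, tname in sorted(scored, reverse=True):
        if score < min_dice or cname in mapping or tname in used:
            continue
        mapping[cname] = tname
        used.add(tname)
    return mapping


def roi_mean_gmv(
    scans: Sequence[ScanVolume],
    columns: Mapping[str, np.ndarray],
    model: SkeletonModel,
) -> pd.DataFrame:
    """Mean GMV over each region's skeleton voxels, per scan.

    Returns a DataFrame indexed by (subject_id, timepoint) with one column
    per region, no missing cells.
    """
    if not columns:
        raise ConstructionError("no regions given")
    on_skel = {}
    for name, mask in columns.items():
        sel = np.asarray(mask, bool)[model.skeleton_mask]
        if not sel.any():
            raise ConstructionError(f"region {name!r} has no skeleton voxels")
        on_skel[name] = sel
    index = pd.MultiIndex.from_tuples(
        [(s.subject_id, s.timepoint) for s in scans], names=["subject_id", "timepoint"]
    )
    data = {}
    vectors = [sample_on_skeleton(s.image, model) for s in scans]
    for name, sel in on_skel.items():
        data[name] = [float(v[sel].mean()) for v in vectors]
    return pd.DataFrame(data, index=index)


def change_scores(roitable: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-patient T2 - T1 change in each region's mean GMV and in MoCA.

    One row per patient; ``delta_moca`` is missing where MoCA is missing at
    either timepoint (complete-case downstream).
    """
    ad = phenotypes[phenotypes["group"] == "AD"]
    subjects = sorted(ad["subject_id"].unique())
    moca = ad.set_index(["subject_id", "timepoint"])["MoCA"]
    broken = []
    rows = []
    for s in subjects:
        has_t1 = (s, "T1") in roitable.index
        has_t2 = (s, "T2") in roitable.index
        if not (has_t1 and has_t2):
            broken.append(s)
            continue
        rec: dict = {"subject_id": s}
        for col in roitable.columns:
            rec[f"delta_{col}"] = float(roitable.loc[(s, "T2"), col] - roitable.loc[(s, "T1"), col])
        m1 = moca.get((s, "T1"), np.nan)
        m2 = moca.get((s, "T2"), np.nan)
        rec["delta_moca"] = float(m2 - m1) if pd.notna(m1) and pd.notna(m2) else np.nan
        rows.append(rec)
    if broken:
        raise PairingError(f"patients missing a timepoint in the ROI table: {broken}", broken)
    return pd.DataFrame(rows)


def brain_behavior_correlation(
    changes: pd.DataFrame, region: str
) -> tuple[float, float, int]:
    """Pearson correlation between a region's GMV change and MoCA change.

    Complete-case; two-tailed p from the t transform with df = n - 2.
    Returns (r, p, n).
    """
    col = f"delta_{region}" if f"delta_{region}" in changes.columns else region
    if col not in changes.columns:
        raise ConstructionError(f"no change column for region {region!r}")
    sub = changes[[col, "delta_moca"]].dropna()
    n = len(sub)
    if n < 4:
        raise InsufficientDataError(f"brain-behavior correlation needs >= 4 complete pairs, got {n}")
    r, p = stats.pearsonr(sub[col], sub["delta_moca"])
    return float(r), float(p), n
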