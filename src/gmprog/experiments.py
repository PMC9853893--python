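"""Calibration, power, and parameter-recovery studies.

Each function re-runs a pipeline component over many simulated cohorts (or
direct Monte-Carlo draws of the generator's statistical model) and returns
the operating characteristic a user would quote: type-I error of the edge
permutation test, its power under the planted covariance difference,
recovery of the planted brain-behavior coupling and of a known cross-lagged
coefficient, and exact agreement of the FDR step with the textbook step-up
rule. These are the package's own validation experiments; cohort studies
use a geometrically reduced grid (24 x 24 x 12) so each runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covnet import causal_coefficient, causal_effect_resampled, edge_group_difference

from .synthetic_cohort import CohortSpec, PlantedTruth, generate_cohort, null_spec
from .volume_io import ScanVolume
from .voxelstats import fdr_bh

_MOD = 2**31 - 1


def _seed_stream(seed: int, stream: int) -> int:
    """Derive a per-replicate seed below 2^31."""
    return (int(seed) * 1_000_003 + stream * 7_919 + 17) % _MOD


def reduced_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default cohort design on the reduced 24 x 24 x 12 grid."""
    return replace(CohortSpec(seed=seed).scaled_down(0.5), **overrides)


def reduced_null_spec(seed: int = 0) -> CohortSpec:
    return null_spec(seed=seed).scaled_down(0.5)


def truth_region_means(
    scans: Sequence[ScanVolume], truth: PlantedTruth, regions: Sequence[str]
) -> pd.DataFrame:
    """Per-scan mean GMV over the planted (full-sphere) region masks."""
    masks = {r: np.asarray(truth.true_region_masks[r], bool) for r in regions}
    index = pd.MultiIndex.from_tuples(
        [(s.subject_id, s.timepoint) for s in scans], names=["subject_id", "timepoint"]
    )
    data = {r: [float(s.image.data[m].mean()) for s in scans] for r, m in masks.items()}
    return pd.DataFrame(data, index=index)


def _edge_rejections(
    spec_factory, n_cohorts: int, n_perm: int, seed: int,
    edge: tuple[str, str] = ("STG_right", "caudate_left"),
) -> float:
    hits = 0
    for k in range(n_cohorts):
        sk = _seed_stream(seed, k)
        spec = spec_factory(sk)
        scans, _, truth = generate_cohort(spec)
        means = truth_region_means(scans, truth, edge)
        hc = means.loc[[(s.subject_id, s.timepoint) for s in scans if s.group == "HC"]]
        ad = means.loc[[
            (s.subject_id, s.timepoint)
            for s in scans
            if s.group == "AD" and s.timepoint == "T1"
        ]]
        res = edge_group_difference(
            hc.to_numpy(), ad.to_numpy(), n_perm=n_perm, seed=sk, region_pair=edge
        )
        hits += int(res.significant)
    return hits / n_cohorts


def edge_test_calibration(n_cohorts: int = 800, n_perm: int = 1000, seed: int = 0) -> float:
    """Type-I error of the edge permutation test under null cohorts
    (no atrophy, equal covariance loadings in both groups)."""
    return _edge_rejections(lambda s: reduced_null_spec(seed=s), n_cohorts, n_perm, seed)


def edge_test_power(n_cohorts: int = 100, n_perm: int = 1000, seed: int = 0) -> float:
    """Power of the edge permutation test for the planted covariance
    difference (r = 0.7 in controls vs 0 in patients, n = 45/40)."""
    return _edge_rejections(lambda s: reduced_spec(seed=s), n_cohorts, n_perm, seed)


def behavior_coupling_recovery(
    n_cohorts: int = 500, seed: int = 0, region: str = "STG_right"
) -> tuple[float, float]:
    """Mean (over cohorts) sample correlation between the measured regional
    GMV change and the MoCA change, for the planted coupling region.

    Region means are taken over the planted masks, isolating the coupling
    model from the detection stages. Returns (mean r, SE of the mean).
    """
    rs = []
    for k in range(n_cohorts):
        spec = reduced_spec(seed=_seed_stream(seed, k))
        scans, phen, truth = generate_cohort(spec)
        means = truth_region_means(
            scans, truth, [region]
        )[region]
        ad = phen[phen["group"] == "AD"]
        moca = ad.pivot(index="subject_id", columns="timepoint", values="MoCA")
        dmoca = (moca["T2"] - moca["T1"]).dropna()
        dgmv = pd.Series(
            {
                s: means[(s, "T2")] - means[(s, "T1")]
                for s in dmoca.index
            }
        )
        rs.append(stats.pearsonr(dgmv[dmoca.index], dmoca)[0])
    rs = np.asarray(rs)
    return float(rs.mean()), float(rs.std(ddof=1) / np.sqrt(len(rs)))


@dataclass
class CrossLaggedRecovery:
    mean_coefficient: float
    se_mean: float
    theoretical: float
    n_sims: int


def crosslagged_recovery(
    n_sims: int = 500, n_subjects: int = 40, beta: float = 0.5, seed: int = 0
) -> CrossLaggedRecovery:
    """Recovery of a known cross-lagged coefficient by direct simulation.

    y_T2 = beta * x_T1 + noise with x_T1 independent of y_T1; the
    standardized coefficient is beta * sd(x) / sd(y_T2) in closed form.
    """
    rng = np.random.default_rng(seed)
    coefs = np.empty(n_sims)
    for i in range(n_sims):
        x = rng.standard_normal(n_subjects)
        y1 = rng.standard_normal(n_subjects)
        y2 = beta * x + rng.standard_normal(n_subjects)
        coefs[i] = causal_coefficient(x, y1, y2)
    theo = beta / np.sqrt(beta**2 + 1.0)
    return CrossLaggedRecovery(
        mean_coefficient=float(coefs.mean()),
        se_mean=float(coefs.std(ddof=1) / np.sqrt(n_sims)),
        theoretical=float(theo),
        n_sims=n_sims,
    )


def causal_bootstrap_rates(
    n_sims: int = 200,
    n_subjects: int = 40,
    std_effect: float = 0.5,
    n_resamples: int = 500,
    seed: int = 0,
) -> float:
    """Fraction of simulations where the bootstrap flags the cross-lagged
    effect (p < 0.05). ``std_effect`` is the true standardized coefficient
    (0 gives the null calibration rate)."""
    rng = np.random.default_rng(seed)
    hits = 0
    resid = np.sqrt(max(1.0 - std_effect**2, 1e-9))
    for i in range(n_sims):
        x = rng.standard_normal(n_subjects)
        y1 = rng.standard_normal(n_subjects)
        y2 = std_effect * x + resid * rng.standard_normal(n_subjects)
        res = causal_effect_resampled(
            x, y1, y2, n_resamples=n_resamples, seed=_seed_stream(seed, i)
        )
        hits += int(res.p_value < 0.05)
    return hits / n_sims


def step_up_rejections(p: np.ndarray, alpha: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up rule, by exhaustive scan: find
    the largest k with p_(k) <= k/m * alpha and reject all p <= p_(k)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if order[k - 1] <= k / m * alpha:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool)
    return p <= order[k_star - 1]


def adjusted_values_bruteforce(p: np.ndarray) -> np.ndarray:
    """Independent computation of BH adjusted values:
    q_i = min_{j : p_j >= p_i} (m / rank_j) * p_(rank_j), with monotonicity."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def fdr_agreement(
    n_draws: int = 1000,
    max_len: int = 12,
    alphas: Sequence[float] = (0.01, 0.05, 0.10, 0.25),
    seed: int = 0,
) -> float:
    """Fraction of random p-vectors (length <= max_len) on which the FDR
    implementation matches the exhaustive step-up rule exactly: identical
    rejection sets at every alpha and adjusted values to 1e-12."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_draws):
        n = int(rng.integers(1, max_len + 1))
        p = rng.random(n)
        q = fdr_bh(p)
        ok = np.allclose(q, adjusted_values_bruteforce(p), atol=1e-12)
        for alpha in alphas:
            ok &= np.array_equal(q <= alpha, step_up_rejections(p, alpha))
        agree += int(ok)
    return agree / n_draws


def null_voxel_false_positive_rate(
    n_cohorts: int = 120, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of null cohorts in which the voxelwise paired test rejects
    any skeleton voxel after FDR (reduced grid; full skeleton pipeline)."""
    from .skeleton import mean_image, sample_matrix, skeletonize
    from .voxelstats import paired_t_map

    hits = 0
    for k in range(n_cohorts):
        spec = reduced_null_spec(seed=_seed_stream(seed, k))
        scans, _, _ = generate_cohort(spec)
        model = skeletonize(mean_image([s.image for s in scans]))
        t1 = [s for s in scans if s.group == "AD" and s.timepoint == "T1"]
        t2 = [s for s in scans if s.group == "AD" and s.timepoint == "T2"]
        pm = paired_t_map(
            sample_matrix([s.image for s in t1], model),
            sample_matrix([s.image for s in t2], model),
            [s.subject_id for s in t1],
            [s.subject_id for s in t2],
            model,
        )
        hits += int(np.any(pm.q < alpha))
    return hits / n_cohorts
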