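"""Structural covariance network (SCN) edges with permutation group tests,
and cross-lagged ("causal SCN") effects with subject-level bootstrap.

An SCN edge is the across-subject Pearson correlation between two regions'
mean GMVs within one group. Group differences in an edge are tested by
permuting group labels (sizes preserved) and asking whether the observed
r_A - r_B falls outside the central 95% of the permutation null; the
reported p uses the add-one estimator and can never be zero.

With only two timepoints, the "causal" effect of a source region on a
target is the standardized coefficient of the source's baseline value in
the regression of the target's follow-up value on the target's own
baseline value — the two-wave cross-lagged analogue of Granger causality.
Its stability is assessed by bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CollinearityError, DegenerateInputError, InsufficientDataError

_EPS = 1e-12


@dataclass
class CovEdgeResult:
    region_pair: tuple[str, str]
    r_group_a: float
    r_group_b: float
    observed_diff: float
    null_q025: float
    null_q975: float
    p_value: float
    significant: bool
    n_permutations: int
    seed: int


@dataclass
class CausalEffectResult:
    source: str
    target: str
    coefficient: float
    boot_mean: float
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    seed: int


def covariance_edge(values_region1: np.ndarray, values_region2: np.ndarray) -> float:
    """Pearson r between two regions' mean GMVs across one group's subjects."""
    x = np.asarray(values_region1, dtype=float)
    y = np.asarray(values_region2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("edge values must be two equal-length 1D vectors")
    if x.size < 4:
        raise InsufficientDataError("covariance edge needs >= 4 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateInputError("edge values must be finite")
    if x.std() <= _EPS or y.std() <= _EPS:
        raise DegenerateInputError("zero variance in a region's values")
    return float(np.corrcoef(x, y)[0, 1])


def _pearson_rows(block: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of a (m, k, 2) stack of paired columns."""
    x = block[..., 0]
    y = block[..., 1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def edge_group_difference(
    group_a_pairs: np.ndarray,
    group_b_pairs: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    region_pair: tuple[str, str] = ("region1", "region2"),
) -> CovEdgeResult:
    """Permutation test of the between-group difference in one SCN edge.

    Subjects are pooled and group labels randomly reassigned preserving
    group sizes; r_A - r_B is recomputed per permutation. Significance is
    the observed difference lying outside the null's central 95%
    (two-tailed); p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    a = np.asarray(group_a_pairs, dtype=float)
    b = np.asarray(group_b_pairs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise DegenerateInputError("group pairs must be (n, 2) arrays")
    r_a = covariance_edge(a[:, 0], a[:, 1])
    r_b = covariance_edge(b[:, 0], b[:, 1])
    observed = r_a - r_b

    pooled = np.vstack([a, b])
    n, na = pooled.shape[0], a.shape[0]
    if np.any(pooled.std(axis=0) <= _EPS):
        raise DegenerateInputError("zero variance after pooling groups")

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    ra = _pearson_rows(pooled[perms[:, :na]])
    rb = _pearson_rows(pooled[perms[:, na:]])
    null = ra - rb
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise DegenerateInputError("all permutations degenerate")
    q025, q975 = np.quantile(null, [0.025, 0.975])
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (null.size + 1.0)
    return CovEdgeResult(
        region_pair=tuple(region_pair),
        r_group_a=r_a,
        r_group_b=r_b,
        observed_diff=observed,
        null_q025=float(q025),
        null_q975=float(q975),
        p_value=float(p),
        significant=bool(observed < q025 or observed > q975),
        n_permutations=int(n_perm),
        seed=int(seed),
    )


def _validate_causal_inputs(x_t1, y_t1, y_t2):
    x1 = np.asarray(x_t1, dtype=float)
    y1 = np.asarray(y_t1, dtype=float)
    y2 = np.asarray(y_t2, dtype=float)
    if not (x1.shape == y1.shape == y2.shape) or x1.ndim != 1:
        raise DegenerateInputError("causal inputs must be three equal-length 1D vectors")
    if x1.size < 5:
        raise InsufficientDataError("cross-lagged effect needs >= 5 paired subjects")
    for name, v in (("x_t1", x1), ("y_t1", y1), ("y_t2", y2)):
        if v.std() <= _EPS:
            raise DegenerateInputError(f"zero variance in {name}")
    r_xy1 = np.corrcoef(x1, y1)[0, 1]
    if abs(r_xy1) > 0.999:
        raise CollinearityError(f"x_t1 and y_t1 are collinear (|r| = {abs(r_xy1):.4f})")
    return x1, y1, y2


def _crosslagged_from_corr(r_xy2, r_xy1, r_y1y2):
    return (r_xy2 - r_xy1 * r_y1y2) / (1.0 - r_xy1**2)


def causal_coefficient(x_t1: np.ndarray, y_t1: np.ndarray, y_t2: np.ndarray) -> float:
    """Standardized cross-lagged coefficient of x(T1) on y(T2) given y(T1).

    The coefficient of standardized x_t1 in OLS of standardized y_t2 on
    {y_t1, x_t1}: does the source at baseline explain the target at
    follow-up beyond the target's own baseline value?
    """
    x1, y1, y2 = _validate_causal_inputs(x_t1, y_t1, y_t2)
    c = np.corrcoef(np.vstack([x1, y1, y2]))
    return float(_crosslagged_from_corr(c[0, 2], c[0, 1], c[1, 2]))


def causal_effect_resampled(
    x_t1: np.ndarray,
    y_t1: np.ndarray,
    y_t2: np.ndarray,
    n_resamples: int = 10000,
    seed: int = 0,
    source: str = "source",
    target: str = "target",
) -> CausalEffectResult:
    """Bootstrap (over subjects, with replacement) of the cross-lagged
    coefficient: distribution mean, central 95% interval, and a two-sided
    p for the distribution lying off zero (add-one, never exactly 0)."""
    x1, y1, y2 = _validate_causal_inputs(x_t1, y_t1, y_t2)
    point = causal_coefficient(x1, y1, y2)
    n = x1.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    bx, by1, by2 = x1[idx], y1[idx], y2[idx]

    def _corr_rows(u, v):
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        den = np.sqrt((uc**2).sum(axis=1) * (vc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return (uc * vc).sum(axis=1) / den

    r_xy1 = _corr_rows(bx, by1)
    r_xy2 = _corr_rows(bx, by2)
    r_y1y2 = _corr_rows(by1, by2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coefs = _crosslagged_from_corr(r_xy2, r_xy1, r_y1y2)
    coefs = coefs[np.isfinite(coefs)]
    if coefs.size == 0:
        raise DegenerateInputError("all bootstrap resamples degenerate")
    b = coefs.size
    lo, hi = np.quantile(coefs, [0.025, 0.975])
    frac_le = (1.0 + np.sum(coefs <= 0)) / (b + 1.0)
    frac_ge = (1.0 + np.sum(coefs >= 0)) / (b + 1.0)
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return CausalEffectResult(
        source=source,
        target=target,
        coefficient=point,
        boot_mean=float(coefs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        n_resamples=int(n_resamples),
        seed=int(seed),
    )
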