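"""Comparison statistics for cross-platform normalization.

Differential expression is scored gene-wise by a two-sided Welch t-test,
p-values are converted to q-values with the Storey–Tibshirani null-proportion
estimator, and the empirical cdf of the q-values on a 0.001-step FDR grid is
the "ROC-like" curve: the fraction of genes called differentially expressed
as a function of the FDR threshold.  Gene-wise minima/maxima of two q-value
lists give union/intersection curves, and trapezoid areas between suitable
curve pairs define the over-detection (o) and under-detection (u)
statistics.  Inter-platform concordance is the squared Pearson correlation
of a mean–mean plot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .core import CombinedDataset, ExpressionMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PValueList",
    "QValueList",
    "RocCurve",
    "DetectionAreas",
    "ConcordanceStats",
    "mean_mean_r2",
    "welch_pvalues",
    "qvalues",
    "roc_like_curve",
    "combine_qlists",
    "detection_areas",
    "brown_forsythe",
    "rank_methods",
    "RankingResult",
]

GRID_STEP = 0.001


@dataclass
class PValueList:
    gene_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.gene_ids),):
            raise ValidationError("p-value vector length must match gene list")
        if np.any((self.p < 0) | (self.p > 1) | ~np.isfinite(self.p)):
            raise ValidationError("p-values must lie in [0, 1]")


@dataclass
class QValueList:
    gene_ids: list[str]
    q: np.ndarray
    pi0: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.gene_ids),):
            raise ValidationError("q-value vector length must match gene list")
        if np.any((self.q < 0) | (self.q > 1) | ~np.isfinite(self.q)):
            raise ValidationError("q-values must lie in [0, 1]")


@dataclass
class RocCurve:
    grid: np.ndarray    # FDR thresholds, 0..1
    height: np.ndarray  # fraction of genes with q <= threshold


@dataclass
class DetectionAreas:
    o: float  # over-detection
    u: float  # under-detection


@dataclass
class ConcordanceStats:
    r2: float
    points: pd.DataFrame  # columns: gene_id, mean_platform1, mean_platform2
    ccc: float | None = None


def _concordance_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (agreement with y = x)."""
    sxy = np.cov(x, y, ddof=1)
    return float(2.0 * sxy[0, 1] / (sxy[0, 0] + sxy[1, 1] + (x.mean() - y.mean()) ** 2))


def mean_mean_r2(
    d: CombinedDataset, group: str, with_ccc: bool = False
) -> ConcordanceStats:
    """Squared Pearson correlation of per-gene group means across platforms."""
    lab1, lab2 = d.platform_labels
    s1 = [s for s in d.platform1.sample_ids if d.annotation.treatment_of(s) == group]
    s2 = [s for s in d.platform2.sample_ids if d.annotation.treatment_of(s) == group]
    if not s1 or not s2:
        raise ValidationError(
            f"concordance undefined: treatment {group!r} absent from "
            f"{'both platforms' if not (s1 or s2) else (lab2 if s1 else lab1)!r}"
        )
    idx1 = [d.platform1.sample_ids.index(s) for s in s1]
    idx2 = [d.platform2.sample_ids.index(s) for s in s2]
    m1 = d.platform1.values[:, idx1].mean(axis=1)
    m2 = d.platform2.values[:, idx2].mean(axis=1)
    r = stats.pearsonr(m1, m2)[0]
    points = pd.DataFrame(
        {"gene_id": d.gene_ids, f"mean_{lab1}": m1, f"mean_{lab2}": m2}
    )
    ccc = _concordance_ccc(m1, m2) if with_ccc else None
    return ConcordanceStats(r2=float(r**2), points=points, ccc=ccc)


def welch_pvalues(
    m: ExpressionMatrix, group_a_ids: list[str], group_b_ids: list[str]
) -> PValueList:
    """Gene-wise two-sided Welch t-test (unequal variances) p-values.

    Genes with zero variance in both groups get p = 1 when the group means
    are equal and p = 0 otherwise.
    """
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise ValidationError("each group needs at least 2 samples")
    idx = pd.Index(m.sample_ids)
    ia = idx.get_indexer(group_a_ids)
    ib = idx.get_indexer(group_b_ids)
    if np.any(ia < 0) or np.any(ib < 0):
        raise ValidationError("group sample ids absent from matrix")
    a = m.values[:, ia]
    b = m.values[:, ib]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes are handled by the conventions below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        logger.warning("%d gene(s) with zero variance in both groups", degenerate.sum())
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    return PValueList(list(m.gene_ids), np.clip(p, 0.0, 1.0))


_SPLINE_DF = 3.0
_df3_penalty_cache: dict[tuple[float, ...], float] = {}


def _df3_penalty(x: np.ndarray) -> float:
    """Smoothing-spline penalty giving ~3 effective degrees of freedom.

    The effective df is the trace of the linear smoother's hat matrix, found
    by bisection; it depends only on the abscissae, so the result is cached.
    """
    key = tuple(np.round(x, 12))
    if key in _df3_penalty_cache:
        return _df3_penalty_cache[key]

    def trace(lam: float) -> float:
        tr = 0.0
        for i in range(x.size):
            e = np.zeros(x.size)
            e[i] = 1.0
            tr += make_smoothing_spline(x, e, lam=lam)(x[i])
        return tr

    lo, hi = 1e-8, 1e3
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if trace(mid) > _SPLINE_DF:
            lo = mid
        else:
            hi = mid
    lam = float(np.sqrt(lo * hi))
    _df3_penalty_cache[key] = lam
    return lam


def estimate_pi0(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Storey–Tibshirani null-proportion estimate via a smoothing spline.

    ``pi0(lambda) = #{p > lambda} / (G (1 - lambda))`` is computed on the
    lambda grid (default 0, 0.05, ..., 0.95), smoothed by a cubic smoothing
    spline with 3 effective degrees of freedom, and evaluated at the largest
    lambda; the result is clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    G = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.951, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if G < 20:
        logger.warning("fewer than 20 p-values; forcing pi0 = 1 (spline unstable)")
        return 1.0
    pi0_lam = np.array(
        [(p > lam).sum() / (G * (1.0 - lam)) for lam in lambda_grid]
    )
    spline = make_smoothing_spline(lambda_grid, pi0_lam,
                                   lam=_df3_penalty(lambda_grid))
    pi0 = float(spline(lambda_grid.max()))
    return float(min(max(pi0, 1e-8), 1.0))


def qvalues(p: PValueList, lambda_grid: np.ndarray | None = None,
            pi0: float | None = None) -> QValueList:
    """Storey–Tibshirani q-values from a p-value list.

    The step-down rule sets ``q(p_(G)) = pi0 * p_(G)`` and
    ``q(p_(i)) = min(pi0 * G * p_(i) / i, q(p_(i+1)))`` on the ascending
    order statistics.  ``pi0`` may be supplied to bypass estimation.
    """
    if pi0 is None:
        pi0 = estimate_pi0(p.p, lambda_grid)
    G = p.p.size
    order = np.argsort(p.p, kind="stable")
    ps = p.p[order]
    q_sorted = np.empty(G)
    q_sorted[-1] = pi0 * ps[-1]
    for i in range(G - 2, -1, -1):
        q_sorted[i] = min(pi0 * G * ps[i] / (i + 1), q_sorted[i + 1])
    q = np.empty(G)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueList(list(p.gene_ids), q, pi0=float(pi0))


def _grid(step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def _ecdf_on_grid(q: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(q), grid, side="right") / q.size


def roc_like_curve(q: QValueList, step: float = GRID_STEP) -> RocCurve:
    """Empirical cdf of the q-values on the fixed FDR grid."""
    grid = _grid(step)
    return RocCurve(grid=grid, height=_ecdf_on_grid(q.q, grid))


def combine_qlists(q1: QValueList, q2: QValueList, mode: str) -> QValueList:
    """Union (gene-wise min) or intersection (gene-wise max) of two q-lists."""
    if q1.gene_ids != q2.gene_ids:
        raise ValidationError("q-value lists must share an identical gene list")
    if mode == "union":
        q = np.minimum(q1.q, q2.q)
    elif mode == "intersection":
        q = np.maximum(q1.q, q2.q)
    else:
        raise ValidationError("mode must be 'union' or 'intersection'")
    return QValueList(list(q1.gene_ids), q, pi0=float(min(q1.pi0, q2.pi0)))


def detection_areas(
    q_cross: QValueList,
    q_native1: QValueList,
    q_native2: QValueList,
    step: float = GRID_STEP,
) -> DetectionAreas:
    """Over- and under-detection areas between ROC-like curves.

    ``o`` is the area between the cross-platform curve and its intersection
    with the union of the native curves; ``u`` is the area between the
    native-intersection curve and its intersection with the cross-platform
    curve.  Curves are sampled on the FDR grid and integrated by the
    trapezoid rule.
    """
    if not (q_cross.gene_ids == q_native1.gene_ids == q_native2.gene_ids):
        raise ValidationError("all q-value lists must share one gene list")
    grid = _grid(step)
    q_u = np.minimum(q_native1.q, q_native2.q)   # union of native sets
    q_i = np.maximum(q_native1.q, q_native2.q)   # intersection of native sets
    h_cross = _ecdf_on_grid(q_cross.q, grid)
    h_cross_and_union = _ecdf_on_grid(np.maximum(q_cross.q, q_u), grid)
    h_i = _ecdf_on_grid(q_i, grid)
    h_i_and_cross = _ecdf_on_grid(np.maximum(q_i, q_cross.q), grid)
    o = float(np.trapezoid(h_cross - h_cross_and_union, grid))
    u = float(np.trapezoid(h_i - h_i_and_cross, grid))
    return DetectionAreas(o=o, u=u)


def brown_forsythe(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene-type variance-homogeneity test on absolute deviations
    from group medians (one-way ANOVA on |x - median|)."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    stat, p = stats.levene(*arrays, center="median")
    return float(stat), float(p)


@dataclass
class RankingResult:
    ordered: list[str]   # method names, ascending by median
    medians: list[float]
    marks: list[str]     # "<" (significant) or "," between adjacent methods
    alpha: float         # per-comparison level actually used

    def render(self) -> str:
        parts = [self.ordered[0]]
        for mark, name in zip(self.marks, self.ordered[1:]):
            parts.append(f" {mark} {name}")
        return "".join(parts)


def rank_methods(
    distributions: dict[str, np.ndarray], alpha_base: float = 0.05
) -> RankingResult:
    """Order methods by median; mark adjacent pairs by Mann–Whitney U.

    Adjacent pairs whose two-sided Mann–Whitney p-value falls below
    ``alpha_base / n**2`` (n = number of methods, controls included) are
    marked "<", otherwise ",".
    """
    if len(distributions) < 2:
        raise ValidationError("need at least 2 methods to rank")
    clean: dict[str, np.ndarray] = {}
    for name, vals in distributions.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            raise ValidationError(f"method {name!r} has fewer than 2 values")
        clean[name] = v
    n = len(clean)
    alpha = alpha_base / n**2
    ordered = sorted(clean, key=lambda k: np.median(clean[k]))
    marks = []
    for a, b in zip(ordered, ordered[1:]):
        if np.array_equal(clean[a], clean[b]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(clean[a], clean[b],
                                         alternative="two-sided").pvalue)
        marks.append("<" if p < alpha else ",")
    return RankingResult(
        ordered=ordered,
        medians=[float(np.median(clean[k])) for k in ordered],
        marks=marks,
        alpha=alpha,
    )
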