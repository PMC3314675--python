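"""Distribution- and rank-based cross-platform normalization methods.

Six methods operate purely on value distributions or ranks: quantile
normalization (QN), median rank scores (MRS), gene quantiles (GQ), quantile
discretization (QD), normalized discretization (NorDi), and the distribution
transformation (DisTran).  None of them model gene-wise location shifts;
their common primitive is mapping a sample's rank-k value to the k-th entry
of a reference distribution, with ties receiving the mean of their tied
reference values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import CombinedDataset
from .errors import ValidationError

__all__ = [
    "quantile_normalize",
    "mrs",
    "gq",
    "qd",
    "nordi",
    "distran",
    "map_to_reference",
]


def _require_continuous(d: CombinedDataset) -> None:
    if d.discrete_flag:
        raise ValidationError("operation requires continuous (non-discretized) data")


def map_to_reference(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace the rank-k value of ``x`` with ``reference[k]``.

    ``reference`` must be sorted and of the same length as ``x``.  Tied
    values in ``x`` receive the mean of their tied reference values.
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    y = np.empty_like(x)
    y[order] = reference
    if len(np.unique(x)) != len(x):  # average over tie groups
        y = pd.Series(y).groupby(pd.Series(x)).transform("mean").to_numpy()
    return y


def _rank_mean_reference(values: np.ndarray) -> np.ndarray:
    """Per-rank mean across the columns of ``values`` (each sorted)."""
    return np.sort(values, axis=0).mean(axis=1)


def _check_nonconstant(values: np.ndarray, sample_ids: list[str]) -> None:
    const = values.max(axis=0) == values.min(axis=0)
    if const.any():
        bad = [sample_ids[i] for i in np.flatnonzero(const)[:5]]
        raise ValidationError(f"constant-valued sample(s), ranks undefined: {bad}")


def quantile_normalize(d: CombinedDataset) -> CombinedDataset:
    """Quantile normalization over the pooled samples of both platforms.

    The reference is the per-rank mean across all pooled samples; every
    sample's rank-k value is replaced by the reference value of rank k.
    After the transform all samples share one sorted value vector.
    """
    _require_continuous(d)
    merged = d.merged()
    _check_nonconstant(merged.values, merged.sample_ids)
    ref = _rank_mean_reference(merged.values)
    out = np.column_stack(
        [map_to_reference(merged.values[:, j], ref) for j in range(merged.n_samples)]
    )
    n1 = d.platform1.n_samples
    return d.with_values(out[:, :n1], out[:, n1:])


def _reference_platform_split(
    d: CombinedDataset, reference_platform: str | None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Return (reference values, query values, reference_is_platform1)."""
    lab1, lab2 = d.platform_labels
    if reference_platform is None:
        reference_platform = lab1
    if reference_platform == lab1:
        return d.platform1.values, d.platform2.values, True
    if reference_platform == lab2:
        return d.platform2.values, d.platform1.values, False
    raise ValidationError(
        f"unknown platform label {reference_platform!r}; dataset has {lab1!r}, {lab2!r}"
    )


def mrs(d: CombinedDataset, reference_platform: str | None = None) -> CombinedDataset:
    """Median rank scores: map query samples onto the reference platform.

    The reference distribution is the per-rank median across the reference
    platform's samples (each sorted); every query sample's rank-k value
    becomes that reference value.  The reference platform is unchanged.
    """
    _require_continuous(d)
    ref_vals, qry_vals, ref_is_1 = _reference_platform_split(d, reference_platform)
    ref = np.median(np.sort(ref_vals, axis=0), axis=1)
    out_q = np.column_stack(
        [map_to_reference(qry_vals[:, j], ref) for j in range(qry_vals.shape[1])]
    )
    if ref_is_1:
        return d.with_values(ref_vals, out_q)
    return d.with_values(out_q, ref_vals)


def gq(d: CombinedDataset, reference_platform: str | None = None) -> CombinedDataset:
    """Gene quantiles: MRS followed by a per-gene median alignment.

    After the MRS step, each gene's per-platform medians are computed and the
    query platform is shifted gene-wise so both platforms share the reference
    platform's median for every gene.
    """
    step1 = mrs(d, reference_platform)
    lab1, _ = step1.platform_labels
    if reference_platform is None:
        reference_platform = lab1
    ref_is_1 = reference_platform == lab1
    ref_m = step1.platform1 if ref_is_1 else step1.platform2
    qry_m = step1.platform2 if ref_is_1 else step1.platform1
    med_ref = np.median(ref_m.values, axis=1)
    med_qry = np.median(qry_m.values, axis=1)
    adj = qry_m.values + (med_ref - med_qry)[:, None]
    if ref_is_1:
        return step1.with_values(ref_m.values, adj)
    return step1.with_values(adj, qry_m.values)


def qd(d: CombinedDataset, bins: int = 8) -> CombinedDataset:
    """Quantile discretization into equiprobable, zero-centered codes.

    Each sample's values are partitioned by rank into ``bins`` equally sized
    groups; the code of bin ``i`` is ``i - (bins - 1) / 2`` so codes sum to
    roughly zero per sample.
    """
    _require_continuous(d)
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    if bins > d.n_genes:
        raise ValidationError("bins cannot exceed the number of genes")
    code_set = tuple(i - (bins - 1) / 2.0 for i in range(bins))

    def discretize(values: np.ndarray) -> np.ndarray:
        n = values.shape[0]
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            r = stats.rankdata(values[:, j], method="average")
            idx = np.ceil(r * bins / n).astype(int) - 1
            np.clip(idx, 0, bins - 1, out=idx)
            out[:, j] = idx - (bins - 1) / 2.0
        return out

    return d.with_values(
        discretize(d.platform1.values),
        discretize(d.platform2.values),
        discrete=True,
        code_set=code_set,
    )


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def _nordi_column(x: np.ndarray, p: float, alpha: float) -> np.ndarray:
    if x.size < 3:
        raise ValidationError("NorDi needs at least 3 values per sample for the Grubbs test")
    retained = x.copy()
    # strip outliers until the two-sided Grubbs test stops rejecting
    while retained.size > 3:
        mu = retained.mean()
        sd = retained.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(retained - mu)
        i = int(np.argmax(dev))
        g_stat = dev[i] / sd
        if g_stat > _grubbs_critical(retained.size, alpha):
            retained = np.delete(retained, i)
        else:
            break
    mu = retained.mean()
    sd = retained.std(ddof=1)
    z = stats.norm.ppf(1.0 - p)
    codes = np.zeros_like(x)
    codes[x > mu + z * sd] = 1.0
    codes[x < mu - z * sd] = -1.0
    return codes


def nordi(d: CombinedDataset, p: float = 0.01, alpha: float = 0.05) -> CombinedDataset:
    """Normalized discretization into {-1, 0, +1} codes.

    Per sample, outliers are stripped by an iterated two-sided Grubbs test at
    level ``alpha``; a normal is fitted to the retained values, and values
    beyond the two-sided ``p`` tail of that normal are coded +1 / -1.
    """
    _require_continuous(d)
    if not (0 < p < 1 and 0 < alpha < 1):
        raise ValidationError("p and alpha must lie in (0, 1)")

    def discretize(values: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [_nordi_column(values[:, j], p, alpha) for j in range(values.shape[1])]
        )

    return d.with_values(
        discretize(d.platform1.values),
        discretize(d.platform2.values),
        discrete=True,
        code_set=(-1.0, 0.0, 1.0),
    )


def _cluster_samples_jointly(
    merged_values: np.ndarray,
    platform_of_col: np.ndarray,
    k: int,
    max_retries: int,
    seed: int,
    standardize: bool = True,
) -> np.ndarray:
    """K-means over all samples; every cluster must span both platforms.

    Gene values are standardized within each platform first so the platform
    signature does not dominate the clustering, then each sample is z-scored
    (unless ``standardize`` is off).
    """
    X = merged_values.copy()
    for p in (0, 1):
        cols = platform_of_col == p
        mu = X[:, cols].mean(axis=1, keepdims=True)
        sd = X[:, cols].std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X[:, cols] = (X[:, cols] - mu) / sd
    pts = X.T
    if standardize:
        mu = pts.mean(axis=1, keepdims=True)
        sd = pts.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        pts = (pts - mu) / sd
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(pts)
        ok = all(
            len(set(platform_of_col[labels == c])) == 2 for c in range(k)
        )
        if ok:
            return labels
    raise ValidationError(
        f"no clustering with both platforms in every cluster found in {max_retries} "
        f"attempts; consider a smaller k"
    )


def distran(
    d: CombinedDataset,
    k: int | None = None,
    max_retries: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> CombinedDataset:
    """Distribution transformation with a k-means surrogate for group labels.

    Samples of both platforms are clustered jointly into ``k`` groups (the
    intended number of treatment groups).  Within each cluster the per-rank
    mean vector is computed for each platform; the target distribution is the
    unweighted mean of the two platform vectors, and every sample in the
    cluster is rank-mapped onto it.
    """
    _require_continuous(d)
    if k is None:
        k = len(d.annotation.treatments)
    if k < 1:
        raise ValidationError("k must be >= 1")
    n1, n2 = d.platform1.n_samples, d.platform2.n_samples
    if min(n1, n2) < k:
        raise ValidationError("each platform needs at least k samples")
    merged = d.merged()
    platform_of_col = np.array([0] * n1 + [1] * n2)
    labels = _cluster_samples_jointly(
        merged.values, platform_of_col, k, max_retries, seed, standardize
    )
    out = merged.values.copy()
    for c in range(k):
        in_c = labels == c
        cols1 = np.flatnonzero(in_c & (platform_of_col == 0))
        cols2 = np.flatnonzero(in_c & (platform_of_col == 1))
        ref1 = _rank_mean_reference(merged.values[:, cols1])
        ref2 = _rank_mean_reference(merged.values[:, cols2])
        target = 0.5 * (ref1 + ref2)
        for j in np.flatnonzero(in_c):
            out[:, j] = map_to_reference(merged.values[:, j], target)
    return d.with_values(out[:, :n1], out[:, n1:])
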