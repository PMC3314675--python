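"""Model-based cross-platform normalization: empirical Bayes and XPN.

The empirical Bayes (EB) adjustment fits gene-wise platform means and scales
on standardized data, shrinks them toward parametric priors (normal for the
means, inverse-gamma for the scales) whose hyperparameters come from the
method of moments, and removes the shrunken effects.

XPN fits a block model ``x_gj = A[alpha(g), beta(j)] * b_gp + c_gp +
sigma_gp * eps`` with gene clusters ``alpha`` and assay clusters ``beta``
shared across platforms, replaces the platform-specific sensitivities,
offsets, and noise scales by cross-platform averages, and reconstructs every
value from its standardized residual.  The whole procedure is repeated with
fresh random clusterings and the results averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import CombinedDataset
from .errors import ConvergenceError, ValidationError

__all__ = ["EBParams", "XPNModel", "eb_adjust", "eb_posteriors", "xpn_normalize", "match_clusters"]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Empirical Bayes (ComBat-style, parametric prior, no covariates)
# ---------------------------------------------------------------------------


@dataclass
class EBParams:
    """Fitted EB quantities, exposed for inspection and testing."""

    alpha: np.ndarray          # grand mean per gene
    sigma: np.ndarray          # pooled scale per gene
    gamma_hat: list[np.ndarray]    # per platform: batch mean per gene
    delta2_hat: list[np.ndarray]   # per platform: batch variance per gene
    gamma_bar: list[float]         # normal prior mean
    tau2_bar: list[float]          # normal prior variance
    lam: list[float]               # inverse-gamma shape
    theta: list[float]             # inverse-gamma scale
    gamma_star: list[np.ndarray]   # posterior batch means
    delta2_star: list[np.ndarray]  # posterior batch variances


def _invgamma_moments(d2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma (shape, scale) for the batch variances."""
    m = float(np.mean(d2))
    s2 = float(np.var(d2, ddof=1))
    if s2 <= 0:
        return np.inf, np.inf
    lam = 2.0 + m * m / s2
    theta = m * (lam - 1.0)
    return lam, theta


def eb_posteriors(
    z: np.ndarray,
    gamma_bar: float,
    tau2_bar: float,
    lam: float,
    theta: float,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled posterior updates for one platform's standardized data.

    ``z`` is genes x samples.  Iterates the conditional posterior means of
    the batch effect and batch variance until the largest parameter change
    falls below ``tol``.
    """
    n = z.shape[1]
    gamma_hat = z.mean(axis=1)
    delta2 = z.var(axis=1, ddof=1)
    gamma = gamma_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau2_bar * gamma_hat + delta2 * gamma_bar) / (
            n * tau2_bar + delta2
        )
        ss = ((z - gamma_new[:, None]) ** 2).sum(axis=1)
        delta2_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        change = max(
            np.abs(gamma_new - gamma).max(), np.abs(delta2_new - delta2).max()
        )
        gamma, delta2 = gamma_new, delta2_new
        if change < tol:
            return gamma, delta2
    raise ConvergenceError(
        f"EB posterior updates did not converge in {max_iter} iterations "
        f"(last max change {change:.3g})"
    )


def eb_adjust(d: CombinedDataset, return_params: bool = False):
    """Empirical Bayes platform adjustment with a parametric prior.

    Values are standardized gene-wise using all samples with equal weight,
    per-platform means and variances are shrunk toward their moment-matched
    priors, and the shrunken effects are removed.
    """
    if d.discrete_flag:
        raise ValidationError("EB requires continuous data")
    if d.platform1.n_samples < 2 or d.platform2.n_samples < 2:
        raise ValidationError("EB needs at least 2 samples per platform")
    X = d.merged().values
    alpha = X.mean(axis=1)
    sigma2 = ((X - alpha[:, None]) ** 2).mean(axis=1)
    if np.any(sigma2 <= 0):
        raise ValidationError("gene(s) with zero pooled variance; EB scale undefined")
    sigma = np.sqrt(sigma2)
    Z = (X - alpha[:, None]) / sigma[:, None]
    n1 = d.platform1.n_samples
    blocks = [Z[:, :n1], Z[:, n1:]]

    gamma_hat, delta2_hat, gbar, t2bar, lams, thetas = [], [], [], [], [], []
    gamma_star, delta2_star, adjusted = [], [], []
    for zb in blocks:
        gh = zb.mean(axis=1)
        dh = zb.var(axis=1, ddof=1)
        gb = float(np.mean(gh))
        t2 = float(np.var(gh, ddof=1))
        lam, theta = _invgamma_moments(dh)
        gs, ds = eb_posteriors(zb, gb, t2, lam, theta)
        adjusted.append((zb - gs[:, None]) / np.sqrt(ds)[:, None])
        gamma_hat.append(gh)
        delta2_hat.append(dh)
        gbar.append(gb)
        t2bar.append(t2)
        lams.append(lam)
        thetas.append(theta)
        gamma_star.append(gs)
        delta2_star.append(ds)

    out = [a * sigma[:, None] + alpha[:, None] for a in adjusted]
    result = d.with_values(out[0], out[1])
    if return_params:
        params = EBParams(
            alpha, sigma, gamma_hat, delta2_hat, gbar, t2bar, lams, thetas,
            gamma_star, delta2_star,
        )
        return result, params
    return result


# ---------------------------------------------------------------------------
# XPN
# ---------------------------------------------------------------------------


@dataclass
class XPNModel:
    """One fitted XPN block model (single clustering draw)."""

    gene_clusters: np.ndarray   # alpha: gene -> cluster in 0..K-1
    assay_clusters: np.ndarray  # beta: merged sample -> cluster in 0..L-1
    A: np.ndarray               # K x L block means (shared across platforms)
    b: list[np.ndarray]         # per platform: gene sensitivities
    c: list[np.ndarray]         # per platform: gene offsets
    sigma2: list[np.ndarray]    # per platform: gene noise variances
    iterations: int = 1


def match_clusters(centroids1: np.ndarray, centroids2: np.ndarray) -> np.ndarray:
    """Greedy maximum-correlation pairing of two equal-sized centroid sets.

    Returns ``pairing`` such that cluster ``i`` of the first set is paired
    with cluster ``pairing[i]`` of the second.
    """
    c1 = np.atleast_2d(np.asarray(centroids1, float))
    c2 = np.atleast_2d(np.asarray(centroids2, float))
    if c1.shape[0] != c2.shape[0]:
        raise ValidationError("cluster counts differ between the two sides")
    k = c1.shape[0]
    corr = np.full((k, k), -np.inf)
    s1 = c1.std(axis=1)
    s2 = c2.std(axis=1)
    for i in range(k):
        if s1[i] == 0:
            continue
        for j in range(k):
            if s2[j] == 0:
                continue
            corr[i, j] = np.corrcoef(c1[i], c2[j])[0, 1]
    if not np.isfinite(corr).any():
        raise ValidationError("all centroids degenerate; no correlations defined")
    pairing = np.full(k, -1, dtype=int)
    used_i: set[int] = set()
    used_j: set[int] = set()
    flat = corr.copy()
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        if not np.isfinite(flat[i, j]):
            # pair remaining degenerate clusters arbitrarily but deterministically
            rem_i = sorted(set(range(k)) - used_i)
            rem_j = sorted(set(range(k)) - used_j)
            for a, bj in zip(rem_i, rem_j):
                pairing[a] = bj
            break
        pairing[i] = j
        used_i.add(i)
        used_j.add(j)
        flat[i, :] = -np.inf
        flat[:, j] = -np.inf
    return pairing


def _row_standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _platform_standardized(X: np.ndarray, platform_of_col: np.ndarray) -> np.ndarray:
    """Row-standardize within each platform so the platform signature does
    not dominate the clustering features."""
    Z = np.empty_like(X)
    for p in (0, 1):
        cols = platform_of_col == p
        Z[:, cols] = _row_standardize(X[:, cols])
    return Z


def _cluster_assays(
    X: np.ndarray,
    platform_of_col: np.ndarray,
    L: int,
    modified: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assay clusters spanning both platforms.

    Joint mode redraws a joint k-means until every cluster contains samples
    from both platforms; modified mode clusters each platform separately and
    matches clusters by centroid correlation.
    """
    Z = _platform_standardized(X, platform_of_col)
    if L == 1:
        return np.zeros(X.shape[1], dtype=int)
    if modified:
        beta = np.empty(X.shape[1], dtype=int)
        cents = []
        for p in (0, 1):
            cols = np.flatnonzero(platform_of_col == p)
            km = KMeans(n_clusters=L, n_init=10,
                        random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(Z[:, cols].T)
            beta[cols] = lab
            cents.append(km.cluster_centers_)
        pairing = match_clusters(cents[0], cents[1])
        # relabel platform 2's clusters into platform 1's indexing
        inverse = np.empty(L, dtype=int)
        inverse[pairing] = np.arange(L)
        cols2 = platform_of_col == 1
        beta[cols2] = inverse[beta[cols2]]
        return beta
    for _ in range(100):
        km = KMeans(n_clusters=L, n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        beta = km.fit_predict(Z.T)
        if all(len(set(platform_of_col[beta == c])) == 2 for c in range(L)):
            return beta
    raise ValidationError(
        "no joint assay clustering spanning both platforms found in 100 redraws; "
        "consider modified=True"
    )


def _fit_block_model(
    X: np.ndarray,
    platform_of_col: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    K: int,
    L: int,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> XPNModel:
    """Alternating ML fit of the XPN block model with shared block means."""
    G, N = X.shape
    Mg = np.zeros((K, G))
    Mg[alpha, np.arange(G)] = 1.0
    b = [np.ones(G), np.ones(G)]
    c = [np.zeros(G), np.zeros(G)]
    s2 = [np.ones(G), np.ones(G)]
    cols = [np.flatnonzero(platform_of_col == p) for p in (0, 1)]
    # per platform: column sums of X per assay cluster, and cluster sizes
    Ml = [np.zeros((len(cols[p]), L)) for p in (0, 1)]
    for p in (0, 1):
        Ml[p][np.arange(len(cols[p])), beta[cols[p]]] = 1.0
    Xp = [X[:, cols[p]] for p in (0, 1)]
    n_l = [Ml[p].sum(axis=0) for p in (0, 1)]  # samples per assay cluster

    A = np.zeros((K, L))
    ll_old = -np.inf
    for _ in range(max_iter):
        # update A given (b, c, s2)
        num = np.zeros((K, L))
        den = np.zeros((K, L))
        for p in (0, 1):
            w = b[p] / s2[p]
            S = Xp[p] @ Ml[p] - np.outer(c[p], n_l[p])  # G x L
            num += Mg @ (w[:, None] * S)
            den += np.outer(Mg @ (b[p] ** 2 / s2[p]), n_l[p])
        A = num / np.maximum(den, _EPS)
        # update (b, c, s2) given A
        for p in (0, 1):
            a = A[alpha][:, beta[cols[p]]]  # G x n_p predictor
            am = a.mean(axis=1)
            xm = Xp[p].mean(axis=1)
            av = ((a - am[:, None]) ** 2).mean(axis=1)
            cov = ((a - am[:, None]) * (Xp[p] - xm[:, None])).mean(axis=1)
            bp = np.where(av > _EPS, cov / np.maximum(av, _EPS), 1.0)
            cp = xm - bp * am
            resid = Xp[p] - a * bp[:, None] - cp[:, None]
            b[p], c[p] = bp, cp
            s2[p] = np.maximum((resid**2).mean(axis=1), 1e-8)
        ll = -0.5 * sum(len(cols[p]) * np.log(s2[p]).sum() for p in (0, 1))
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    return XPNModel(alpha, beta, A, b, c, s2)


def _xpn_single(
    X: np.ndarray,
    platform_of_col: np.ndarray,
    K: int,
    L: int,
    modified: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """One clustering draw + fit + reconstruction; returns the transformed matrix."""
    Z = _platform_standardized(X, platform_of_col)
    if K == 1:
        alpha = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=10,
                    random_state=int(rng.integers(2**31 - 1)))
        alpha = km.fit_predict(Z)
    beta = _cluster_assays(X, platform_of_col, L, modified, rng)
    model = _fit_block_model(X, platform_of_col, alpha, beta, K, L)
    b_bar = 0.5 * (model.b[0] + model.b[1])
    c_bar = 0.5 * (model.c[0] + model.c[1])
    s_bar = np.sqrt(0.5 * (model.sigma2[0] + model.sigma2[1]))
    out = np.empty_like(X)
    for p in (0, 1):
        cols = np.flatnonzero(platform_of_col == p)
        a = model.A[alpha][:, beta[cols]]
        resid = (X[:, cols] - a * model.b[p][:, None] - model.c[p][:, None]) / np.sqrt(
            model.sigma2[p]
        )[:, None]
        out[:, cols] = a * b_bar[:, None] + c_bar[:, None] + s_bar[:, None] * resid
    return out


def xpn_normalize(
    d: CombinedDataset,
    gene_clusters: int = 3,
    assay_clusters: int | None = None,
    iterations: int = 30,
    modified: bool = False,
    seed: int = 0,
) -> CombinedDataset:
    """Cross-platform normalization by the XPN block model.

    ``gene_clusters`` (K, default 3) and ``iterations`` (default 30) follow
    the customary defaults; ``assay_clusters`` (L) defaults to the number of
    treatment labels in the annotation.  Each iteration redraws the random
    clusterings; the output is the mean of the transformed matrices.
    """
    if d.discrete_flag:
        raise ValidationError("XPN requires continuous data")
    K = int(gene_clusters)
    L = int(assay_clusters) if assay_clusters is not None else max(
        len(d.annotation.treatments), 1
    )
    if K < 1 or L < 1:
        raise ValidationError("cluster counts must be >= 1")
    n1, n2 = d.platform1.n_samples, d.platform2.n_samples
    if L > min(n1, n2):
        raise ValidationError("assay_clusters exceeds a platform's sample count")
    X = d.merged().values
    platform_of_col = np.array([0] * n1 + [1] * n2)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(X)
    for _ in range(int(iterations)):
        acc += _xpn_single(X, platform_of_col, K, L, modified, rng)
    acc /= iterations
    return d.with_values(acc[:, :n1], acc[:, n1:])
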