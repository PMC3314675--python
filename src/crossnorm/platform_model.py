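"""Theoretical platform-effect machinery.

A coarse physical model of hybridization gives the equilibrium probe signal
``S = I * g0 * p0 * k / (1 + k * g0)`` (``k`` the association/dissociation
rate ratio), whose logarithm is linear in ``log(g0)`` at low target
concentration and saturates at high concentration.  On the log scale this
motivates the gene-wise linear model

    y_ijk = T_i + P_j + C_ij + eps_ijk

with treatment effects ``T_i``, platform effects ``P_j``,
treatment-platform interactions ``C_ij`` and replicate noise.  This module
tests the interaction term gene-wise by ANOVA, estimates the fraction of
genes with real interactions, and provides the least-squares optimal
location shift and the residual bias left when a shift trained on one
dataset is applied to another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CombinedDataset
from .errors import ValidationError
from .evaluation import PValueList, estimate_pi0

__all__ = [
    "HybridizationParams",
    "PlatformEffectTruth",
    "hybridization_signal",
    "anova_interaction",
    "estimate_pi1",
    "optimal_location_shift",
    "residual_difference",
]


@dataclass
class HybridizationParams:
    """Parameters of the equilibrium hybridization signal (all positive).

    ``I``: label intensity per target molecule; ``p0``: available probe-site
    quantity; ``k_ratio``: association/dissociation rate ratio k+/k-;
    ``g0``: initial target concentration.
    """

    I: float
    p0: float
    k_ratio: float
    g0: float

    def __post_init__(self) -> None:
        for name in ("I", "p0", "k_ratio", "g0"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be strictly positive")


def hybridization_signal(hp: HybridizationParams) -> tuple[float, float]:
    """Equilibrium signal and its log for a hybridized probe.

    ``S = I * g0 * p0 * k / (1 + k * g0)``;
    ``log S = log(g0) + log(I * p0 * k) - log(1 + g0 * k)``.
    """
    k = hp.k_ratio
    S = hp.I * hp.g0 * hp.p0 * k / (1.0 + k * hp.g0)
    logS = np.log(hp.g0) + np.log(hp.I * hp.p0 * k) - np.log1p(hp.g0 * k)
    return float(S), float(logS)


@dataclass
class PlatformEffectTruth:
    """Ground-truth effects of the linear model for one gene.

    ``T``: treatment effects (m,); ``P``: platform effects (2,);
    ``C``: interaction matrix (m, 2); ``sigma``: replicate noise sd;
    ``n``: replication counts (m, 2).
    """

    T: np.ndarray
    P: np.ndarray
    C: np.ndarray
    sigma: float
    n: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.atleast_1d(np.asarray(self.T, dtype=float))
        self.P = np.asarray(self.P, dtype=float)
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.n = np.atleast_2d(np.asarray(self.n))
        m = self.T.size
        if self.P.shape != (2,):
            raise ValidationError("P must have one entry per platform (2)")
        if self.C.shape != (m, 2):
            raise ValidationError(f"C must be (m, 2) = ({m}, 2)")
        if self.n.shape != (m, 2):
            raise ValidationError(f"n must be (m, 2) = ({m}, 2)")
        if not np.issubdtype(self.n.dtype, np.integer) or np.any(self.n < 0):
            raise ValidationError("replication counts must be non-negative integers")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")

    @property
    def m(self) -> int:
        return self.T.size

    def cell_means(self) -> np.ndarray:
        """Noise-free cell means T_i + P_j + C_ij, shape (m, 2)."""
        return self.T[:, None] + self.P[None, :] + self.C


def optimal_location_shift(
    truth: PlatformEffectTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares optimal per-platform location shift and corrected means.

    ``eta_j = P_j + sum_i n_ij C_ij / sum_i n_ij`` minimizes
    ``sum_ij n_ij (P_j + C_ij - eta_j)^2``; the corrected (noise-free) cell
    means are ``T_i + P_j + C_ij - eta_j``.
    """
    n = truth.n.astype(float)
    tot = n.sum(axis=0)
    if np.any(tot == 0):
        raise ValidationError("a platform has zero total replication; eta undefined")
    eta = truth.P + (n * truth.C).sum(axis=0) / tot
    corrected = truth.cell_means() - eta[None, :]
    return eta, corrected


def residual_difference(
    truth: PlatformEffectTruth, truth_train: PlatformEffectTruth
) -> float:
    """Residual treatment-difference bias after a transferred location shift.

    For two treatments measured in a missing-group layout (treatment 1 on
    platform 1, treatment 2 on platform 2, equally sized groups) with the
    shift estimated on a training dataset sharing the platform effects, the
    difference of the treatment averages is

        T1 - T2 + (1/2) sum_i sum_j (-1)^(j-1) (C_ij - C'_ij)

    where ``C'`` are the training interactions.  Interactions are assumed
    row-centered (sum over platforms zero per treatment), the convention
    under which the interaction is identified separately from the treatment
    effects.
    """
    if truth.m != 2 or truth_train.m != 2:
        raise ValidationError("residual_difference requires exactly 2 treatments")
    for t in (truth, truth_train):
        if len(set(t.n.ravel()[t.n.ravel() > 0])) > 1:
            raise ValidationError("treatment groups must be equally sized")
    signs = np.array([1.0, -1.0])  # (-1)^(j-1) over platforms
    interaction_term = 0.5 * ((truth.C - truth_train.C) * signs[None, :]).sum()
    return float(truth.T[0] - truth.T[1] + interaction_term)


def _design_from_dataset(d: CombinedDataset):
    """Per-column treatment/platform codes for the merged matrix."""
    merged = d.merged()
    treatments = d.annotation.treatments
    t_of = np.array(
        [treatments.index(d.annotation.treatment_of(s)) for s in merged.sample_ids]
    )
    p_of = np.array(
        [0] * d.platform1.n_samples + [1] * d.platform2.n_samples
    )
    return merged, treatments, t_of, p_of


def anova_interaction(d: CombinedDataset) -> PValueList:
    """Gene-wise F-test of the treatment-platform interaction.

    Fits, per gene, the two-way fixed-effects model with interaction and the
    additive sub-model, and compares them by the standard extra-sum-of-
    squares F-test (identical to the type-II/III interaction test, since the
    interaction enters last).  Vectorized across genes: both models share
    one design, so one hat matrix serves all genes.
    """
    merged, treatments, t_of, p_of = _design_from_dataset(d)
    m = len(treatments)
    if m < 2:
        raise ValidationError(
            "interaction unidentifiable with a single treatment group"
        )
    # every (treatment, platform) cell must have >= 2 replicates
    for ti, t in enumerate(treatments):
        for pj in (0, 1):
            count = int(((t_of == ti) & (p_of == pj)).sum())
            if count < 2:
                raise ValidationError(
                    f"design cell (treatment {t!r}, platform {pj + 1}) has "
                    f"{count} replicate(s); need >= 2"
                )
    X = merged.values  # G x N
    N = X.shape[1]
    cell = t_of * 2 + p_of
    n_cells = 2 * m
    # full model: cell means
    counts = np.bincount(cell, minlength=n_cells).astype(float)
    sums = np.stack([np.bincount(cell, weights=X[g], minlength=n_cells)
                     for g in range(X.shape[0])])
    cell_means = sums / counts[None, :]
    rss_full = ((X - cell_means[:, cell]) ** 2).sum(axis=1)
    df_full = N - n_cells
    # additive model: shared projection
    D = np.zeros((N, 1 + (m - 1) + 1))
    D[:, 0] = 1.0
    for ti in range(1, m):
        D[:, ti] = (t_of == ti).astype(float)
    D[:, m] = (p_of == 1).astype(float)
    Q, _ = np.linalg.qr(D)
    resid_add = X - (X @ Q) @ Q.T
    rss_add = (resid_add**2).sum(axis=1)
    df_add = N - D.shape[1]
    df_int = df_add - df_full  # (m - 1) * 1
    from scipy.stats import f as f_dist

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_add - rss_full) / df_int) / (rss_full / df_full)
    p = f_dist.sf(F, df_int, df_full)
    p = np.nan_to_num(p, nan=1.0)
    return PValueList(list(merged.gene_ids), np.clip(p, 0.0, 1.0))


def estimate_pi1(p: PValueList) -> tuple[float, float]:
    """Fraction of genes with (pi0) and without (pi1) a true null."""
    if p.p.size == 0:
        raise ValidationError("empty p-value list")
    pi0 = estimate_pi0(p.p)
    return pi0, 1.0 - pi0
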