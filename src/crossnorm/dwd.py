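"""Distance weighted discrimination (DWD) and location-shift normalization.

DWD finds the direction ``w`` (||w|| <= 1) and intercept ``beta`` minimizing
``sum_i 1/r_i + C * sum_i xi_i`` with ``r_i = y_i (w . x_i + beta) + xi_i``,
``r_i > 0``, ``xi_i >= 0`` — a second-order cone program.  The slack
variables can be eliminated in closed form, leaving the convex loss
``V(m) = 1/m`` for ``m >= 1/sqrt(C)`` and its tangent line below, which this
module minimizes over the unit ball after reducing to the span of the data.

For platform adjustment the class labels are platform membership; each
platform's samples are shifted by the per-platform mean projection onto the
DWD direction, yielding one location vector per platform that can be stored,
transferred to another dataset, or scrambled as a negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import NonlinearConstraint, minimize
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .core import CombinedDataset
from .errors import ConvergenceError, ValidationError

__all__ = [
    "DWDModel",
    "DWDShift",
    "solve_dwd",
    "dwd_objective",
    "dwd_normalize",
    "transfer_shift",
    "scramble_shift",
    "shift_correlation",
    "auto_penalty",
]


@dataclass
class DWDModel:
    """A fitted DWD separating direction."""

    w: np.ndarray      # direction over features, ||w|| <= 1
    beta: float        # intercept
    C: float           # penalty actually used
    objective: float   # optimal objective value
    kkt_residual: float

    def margins(self, points: np.ndarray, labels: np.ndarray) -> np.ndarray:
        return labels * (points @ self.w + self.beta)


@dataclass
class DWDShift:
    """Per-platform, per-gene location vectors ("the location parameters")."""

    gene_ids: list[str]
    eta: dict[str, np.ndarray]  # platform label -> shift vector over genes
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab, v in self.eta.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(self.gene_ids),):
                raise ValidationError(
                    f"shift vector for platform {lab!r} has wrong length"
                )
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"non-finite shift entries for platform {lab!r}")
            self.eta[lab] = v

    def to_tsv(self, path: str | Path) -> None:
        labels = sorted(self.eta)
        df = pd.DataFrame(
            {f"eta_{lab}": self.eta[lab] for lab in labels},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )
        with open(path, "w") as fh:
            for k, v in self.provenance.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DWDShift":
        provenance = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                provenance[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        eta = {
            col[len("eta_"):]: df[col].to_numpy(dtype=float)
            for col in df.columns
            if col.startswith("eta_")
        }
        return cls(list(df.index.astype(str)), eta, provenance)


def auto_penalty(points: np.ndarray, labels: np.ndarray) -> float:
    """Customary DWD default: 100 / (median between-class distance)^2."""
    pos = points[labels > 0]
    neg = points[labels < 0]
    dists = cdist(pos, neg)
    med = float(np.median(dists))
    if med <= 0:
        raise ValidationError("between-class distances are all zero")
    return 100.0 / med**2


def dwd_objective(
    points: np.ndarray, labels: np.ndarray, C: float, w: np.ndarray, beta: float
) -> float:
    """Objective ``sum 1/r + C sum xi`` at the optimal slack for (w, beta)."""
    m = labels * (points @ w + beta)
    thresh = 1.0 / np.sqrt(C)
    r = np.maximum(m, thresh)
    xi = r - m
    return float(np.sum(1.0 / r) + C * np.sum(xi))


def _loss_and_grad(u: np.ndarray, P: np.ndarray, y: np.ndarray, C: float):
    """Smooth reduced DWD loss over (v, beta); returns (f, grad)."""
    v, beta = u[:-1], u[-1]
    m = y * (P @ v + beta)
    thresh = 1.0 / np.sqrt(C)
    hi = m >= thresh
    f = np.sum(1.0 / m[hi]) + np.sum(2.0 * np.sqrt(C) - C * m[~hi])
    dV = np.where(hi, -1.0 / np.maximum(m, thresh) ** 2, -C)
    coeff = dV * y
    grad = np.empty_like(u)
    grad[:-1] = P.T @ coeff
    grad[-1] = coeff.sum()
    return f, grad


def solve_dwd(
    points: np.ndarray,
    labels: np.ndarray,
    C: float | str = "auto",
    tol: float = 1e-9,
) -> DWDModel:
    """Solve the DWD program for a samples x features matrix and +/-1 labels.

    The problem is solved in the span of the (feature-centered) data, which
    contains the optimum, so the optimization dimension is at most the
    number of samples.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if points.ndim != 2 or points.shape[0] != labels.shape[0]:
        raise ValidationError("points must be samples x features matching labels")
    if points.shape[0] < 2:
        raise ValidationError("DWD needs at least 2 samples")
    if not (np.any(labels > 0) and np.any(labels < 0)):
        raise ValidationError("both classes must be present")
    if C == "auto":
        C = auto_penalty(points, labels)
    C = float(C)

    center = points.mean(axis=0)
    Xc = points - center
    # orthonormal basis of the data span
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > max(s.max(), 1.0) * 1e-12 if s.size else np.array([], bool)
    B = Vt[keep]                      # r x features
    P = Xc @ B.T                      # samples x r
    r_dim = P.shape[1]
    if r_dim == 0:
        raise ValidationError("all samples identical; DWD direction undefined")

    mdiff = P[labels > 0].mean(axis=0) - P[labels < 0].mean(axis=0)
    nrm = np.linalg.norm(mdiff)
    v0 = mdiff / nrm * 0.9 if nrm > 0 else np.zeros(r_dim)
    mid = 0.5 * (P[labels > 0].mean(axis=0) + P[labels < 0].mean(axis=0))
    u0 = np.concatenate([v0, [-v0 @ mid]])

    ball = NonlinearConstraint(
        lambda u: u[:-1] @ u[:-1],
        -np.inf,
        1.0,
        jac=lambda u: np.concatenate([2.0 * u[:-1], [0.0]]),
    )
    with warnings.catch_warnings():
        # quasi-Newton curvature updates warn on the loss's flat linear branch
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        res = minimize(
            _loss_and_grad,
            u0,
            args=(P, labels, C),
            jac=True,
            method="trust-constr",
            constraints=[ball],
            options={"gtol": tol, "xtol": 1e-14, "maxiter": 3000},
        )
    kkt = float(res.optimality)
    if kkt > 1e-6:
        raise ConvergenceError(
            f"DWD solver did not reach KKT tolerance (residual {kkt:.3g})"
        )
    v, beta_c = res.x[:-1], res.x[-1]
    w = B.T @ v
    beta = float(beta_c - w @ center)
    obj = dwd_objective(points, labels, C, w, beta)
    return DWDModel(w=w, beta=beta, C=C, objective=obj, kkt_residual=kkt)


def dwd_normalize(
    d: CombinedDataset, C: float | str = "auto"
) -> tuple[CombinedDataset, DWDShift]:
    """Remove the platform effect along the DWD direction.

    Platform membership is the class label.  With the unit DWD direction
    ``w``, each platform's samples are shifted by ``eta_j = mu_j * w`` where
    ``mu_j`` is the platform's mean projection, so both projected platform
    means become zero.
    """
    if d.discrete_flag:
        raise ValidationError("DWD requires continuous data")
    if d.platform1.n_samples < 2 or d.platform2.n_samples < 2:
        raise ValidationError("DWD needs at least 2 samples per platform")
    X = d.merged().values  # genes x samples
    n1 = d.platform1.n_samples
    labels = np.array([1.0] * n1 + [-1.0] * d.platform2.n_samples)
    model = solve_dwd(X.T, labels, C=C)
    nrm = np.linalg.norm(model.w)
    if nrm <= 0:
        raise ConvergenceError("degenerate zero DWD direction")
    w = model.w / nrm
    lab1, lab2 = d.platform_labels
    # project deviations from the pooled gene means, so the shift carries the
    # platform separation only, not the common expression level
    proj = (X - X.mean(axis=1, keepdims=True)).T @ w
    mu1 = proj[:n1].mean()
    mu2 = proj[n1:].mean()
    eta = {lab1: mu1 * w, lab2: mu2 * w}
    v1 = d.platform1.values - eta[lab1][:, None]
    v2 = d.platform2.values - eta[lab2][:, None]
    shift = DWDShift(
        list(d.gene_ids),
        eta,
        provenance={"platform_pair": f"{lab1}|{lab2}", "trained_on": "self"},
    )
    return d.with_values(v1, v2), shift


def transfer_shift(shift: DWDShift, d: CombinedDataset) -> CombinedDataset:
    """Apply a previously estimated location shift to a dataset, no refit.

    Genes are matched by id; the shift's gene set must cover the dataset's
    (application is restricted to the intersection).
    """
    lab1, lab2 = d.platform_labels
    for lab in (lab1, lab2):
        if lab not in shift.eta:
            raise ValidationError(f"platform {lab!r} absent from the shift")
    shift_idx = pd.Index(shift.gene_ids)
    pos = shift_idx.get_indexer(d.gene_ids)
    have = pos >= 0
    if not have.any():
        raise ValidationError("no overlapping genes between shift and dataset")
    v1 = d.platform1.values.copy()
    v2 = d.platform2.values.copy()
    v1[have] -= shift.eta[lab1][pos[have]][:, None]
    v2[have] -= shift.eta[lab2][pos[have]][:, None]
    return d.with_values(v1, v2)


def scramble_shift(shift: DWDShift, seed: int) -> DWDShift:
    """Negative control: permute the entries of every platform's vector.

    One shared random permutation over genes is used for all platforms, so
    gene correspondence is destroyed while each vector's norm and the
    inter-platform difference structure are preserved.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(shift.gene_ids))
    eta = {lab: v[perm] for lab, v in shift.eta.items()}
    prov = dict(shift.provenance)
    prov["scrambled"] = "true"
    return DWDShift(list(shift.gene_ids), eta, prov)


def shift_correlation(a: DWDShift, b: DWDShift) -> float:
    """Pearson correlation of two shifts' inter-platform difference vectors.

    Each shift is summarized by ``eta_2 - eta_1`` (platform labels sorted);
    the correlation is computed on the common gene subset.
    """
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValidationError("no common genes between the two shifts")

    def diff_vector(s: DWDShift) -> np.ndarray:
        labs = sorted(s.eta)
        if len(labs) != 2:
            raise ValidationError("shift must cover exactly two platforms")
        idx = pd.Index(s.gene_ids).get_indexer(common)
        return (s.eta[labs[1]] - s.eta[labs[0]])[idx]

    da, db = diff_vector(a), diff_vector(b)
    if np.std(da) == 0 or np.std(db) == 0:
        raise ValidationError("zero-variance shift difference; correlation undefined")
    return float(pearsonr(da, db)[0])
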