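"""Smoothed-bootstrap benchmark harness.

Each replicate resamples both platforms with replacement within treatment
groups, perturbs every value with zero-centered Gaussian noise (sd 0.1 by
default), applies each normalization method, and records the concordance
(r^2), over-detection (o) and under-detection (u) statistics.  Native
single-platform curves are built from same-platform resamples with the
relevant treatment-group sizes doubled, keeping the total sample size equal
to the cross-platform analysis.  Two kinds of controls accompany the
methods: ``resample.1`` / ``resample.2`` (two independent same-platform
resamples treated as a platform pair; positive control) and ``no.norm``
(the merged data unadjusted; negative control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import CombinedDataset, ExpressionMatrix, SampleAnnotation
from .dwd import dwd_normalize, scramble_shift, transfer_shift
from .errors import ValidationError
from .evaluation import detection_areas, mean_mean_r2, qvalues, welch_pvalues
from .marginal import distran, gq, mrs, quantile_normalize
from .modelbased import eb_adjust, xpn_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapDesign",
    "BootstrapDistributions",
    "smoothed_resample",
    "run_benchmark",
    "unequal_design",
    "transfer_experiment",
]

DEFAULT_METHODS = ("dwd", "eb", "gq", "xpn", "qn", "mrs", "distran")


@dataclass
class BootstrapDesign:
    """Replicate layout of one bootstrap run.

    ``sizes`` holds one treatment->count mapping per platform, aligned with
    (platform1, platform2) of the dataset.  ``B`` defaults to 100, the one
    replicate count conventionally reported for such benchmarks.
    """

    sizes: tuple[dict[str, int], dict[str, int]]
    noise_sd: float = 0.1
    B: int = 100
    seed: int = 0
    methods: tuple[str, ...] = DEFAULT_METHODS
    include_controls: bool = True
    de_groups: tuple[str, str] | None = None
    xpn_iterations: int = 30
    xpn_gene_clusters: int = 3
    max_failure_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        for s in self.sizes:
            for t, n in s.items():
                if n < 0:
                    raise ValidationError(f"negative group size for treatment {t!r}")


@dataclass
class BootstrapDistributions:
    """method -> statistic name (r2, o, u) -> B values (NaN = failed)."""

    values: dict[str, dict[str, np.ndarray]]
    aborted: set[str] = field(default_factory=set)
    metadata: dict[str, str] = field(default_factory=dict)

    def stat(self, method: str, name: str) -> np.ndarray:
        return self.values[method][name]


def smoothed_resample(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    sizes: dict[str, int],
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
    tag: str = "bs",
) -> ExpressionMatrix:
    """Treatment-restricted resampling with replacement plus Gaussian noise.

    New sample ids have the form ``{platform}@{treatment}@{tag}{i}`` so the
    treatment and platform labels travel with the resampled columns.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols, ids = [], []
    platform = ann.platform_of(m.sample_ids[0])
    for treatment, n in sorted(sizes.items()):
        if n == 0:
            continue
        pool = [
            i for i, s in enumerate(m.sample_ids)
            if ann.treatment_of(s) == treatment
        ]
        if not pool:
            raise ValidationError(
                f"treatment {treatment!r} absent from platform {platform!r}"
            )
        draws = rng.integers(0, len(pool), size=n)
        for i, di in enumerate(draws):
            cols.append(m.values[:, pool[di]])
            ids.append(f"{platform}@{treatment}@{tag}{i}")
    vals = np.column_stack(cols)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return ExpressionMatrix(list(m.gene_ids), ids, vals)


def _annotation_from_ids(sample_ids: list[str]) -> SampleAnnotation:
    records = []
    for sid in sample_ids:
        platform, treatment, _ = sid.split("@")
        records.append((sid, platform, treatment, "bootstrap"))
    return SampleAnnotation.from_records(records)


def _make_pair(m1: ExpressionMatrix, m2: ExpressionMatrix) -> CombinedDataset:
    ann = _annotation_from_ids(m1.sample_ids + m2.sample_ids)
    return CombinedDataset(m1, m2, ann)


def _method_registry(design: BootstrapDesign) -> dict[str, Callable]:
    def xpn(d: CombinedDataset, seed: int) -> CombinedDataset:
        return xpn_normalize(
            d,
            gene_clusters=design.xpn_gene_clusters,
            iterations=design.xpn_iterations,
            seed=seed,
        )

    return {
        "qn": lambda d, seed: quantile_normalize(d),
        "mrs": lambda d, seed: mrs(d),
        "gq": lambda d, seed: gq(d),
        "distran": lambda d, seed: distran(d, seed=seed),
        "eb": lambda d, seed: eb_adjust(d),
        "xpn": xpn,
        "dwd": lambda d, seed: dwd_normalize(d)[0],
        "no.norm": lambda d, seed: d,
    }


def _de_statistics(
    d: CombinedDataset,
    de_groups: tuple[str, str],
    q_native1,
    q_native2,
) -> tuple[float, float, float]:
    """Mean r^2 over the DE groups, plus (o, u) against the native curves."""
    r2s = []
    for g in de_groups:
        r2s.append(mean_mean_r2(d, g).r2)
    merged = d.merged()
    ga = [s for s in merged.sample_ids if d.annotation.treatment_of(s) == de_groups[0]]
    gb = [s for s in merged.sample_ids if d.annotation.treatment_of(s) == de_groups[1]]
    q_cross = qvalues(welch_pvalues(merged, ga, gb))
    areas = detection_areas(q_cross, q_native1, q_native2)
    return float(np.mean(r2s)), areas.o, areas.u


def _native_sizes(design: BootstrapDesign, de_groups: tuple[str, str]) -> dict[str, int]:
    """Per-group sizes of a native single-platform curve: the summed (for
    equal designs, doubled) sizes of the relevant treatment groups."""
    return {
        g: design.sizes[0].get(g, 0) + design.sizes[1].get(g, 0) for g in de_groups
    }


def run_benchmark(d: CombinedDataset, design: BootstrapDesign) -> BootstrapDistributions:
    """Bootstrap distributions of r^2, o, u for every method and control."""
    de_groups = design.de_groups
    if de_groups is None:
        shared = [
            t
            for t in d.annotation.treatments
            if design.sizes[0].get(t, 0) > 0 and design.sizes[1].get(t, 0) > 0
        ]
        if len(shared) < 2:
            raise ValidationError("need two treatment groups present on both platforms")
        de_groups = (shared[0], shared[1])
    registry = _method_registry(design)
    methods = list(design.methods)
    if design.include_controls:
        methods += ["resample.1", "resample.2", "no.norm"]
    stats_names = ("r2", "o", "u")
    out = {m: {s: np.full(design.B, np.nan) for s in stats_names} for m in methods}
    failures = {m: 0 for m in methods}
    aborted: set[str] = set()
    native_sizes = _native_sizes(design, de_groups)
    mats = (d.platform1, d.platform2)

    for b in range(design.B):
        rng = np.random.default_rng([design.seed, b])
        m1b = smoothed_resample(mats[0], d.annotation, design.sizes[0],
                                design.noise_sd, rng, tag=f"b{b}x")
        m2b = smoothed_resample(mats[1], d.annotation, design.sizes[1],
                                design.noise_sd, rng, tag=f"b{b}x")
        db = _make_pair(m1b, m2b)
        natives = []
        for m in mats:
            nat = smoothed_resample(m, d.annotation, native_sizes,
                                    design.noise_sd, rng, tag=f"b{b}n")
            ga = [s for s in nat.sample_ids if s.split("@")[1] == de_groups[0]]
            gb = [s for s in nat.sample_ids if s.split("@")[1] == de_groups[1]]
            natives.append(qvalues(welch_pvalues(nat, ga, gb)))
        q_n1, q_n2 = natives

        for name in methods:
            if name in aborted:
                continue
            try:
                if name.startswith("resample."):
                    p = int(name.split(".")[1]) - 1
                    ra = smoothed_resample(mats[p], d.annotation, design.sizes[p],
                                           design.noise_sd, rng, tag=f"b{b}ra")
                    rb = smoothed_resample(mats[p], d.annotation, design.sizes[p],
                                           design.noise_sd, rng, tag=f"b{b}rb")
                    # two independent same-platform resamples as a platform pair
                    rb = ExpressionMatrix(
                        list(rb.gene_ids),
                        [s.replace("@", "+rep@", 1) for s in rb.sample_ids],
                        rb.values,
                    )
                    dn = _make_pair(ra, rb)
                else:
                    seed_m = int(rng.integers(2**31 - 1))
                    dn = registry[name](db, seed_m)
                r2, o, u = _de_statistics(dn, de_groups, q_n1, q_n2)
                out[name]["r2"][b] = r2
                out[name]["o"][b] = o
                out[name]["u"][b] = u
            except Exception as exc:  # noqa: BLE001 - failures are data, not fatal
                failures[name] += 1
                logger.warning("replicate %d: method %s failed: %s", b, name, exc)
                if failures[name] > design.max_failure_fraction * design.B:
                    logger.error("method %s exceeded the failure budget; aborted", name)
                    aborted.add(name)
    return BootstrapDistributions(
        values=out,
        aborted=aborted,
        metadata={
            "B": str(design.B),
            "noise_sd": str(design.noise_sd),
            "de_groups": ",".join(de_groups),
        },
    )


def unequal_design(
    mA: int,
    nA: int,
    mB: int | None = None,
    nB: int | None = None,
    treatments: tuple[str, str] = ("A", "B"),
    **kwargs,
) -> BootstrapDesign:
    """Crossed unequal-group design: platform 1 gets (mA, nA) of the two
    treatments and platform 2 the mirrored counts (nA, mA) unless given."""
    if mB is None or nB is None:
        mB, nB = nA, mA
    if min(mA, nA, mB, nB) == 0:
        raise ValidationError(
            "a zero-sized treatment group makes this a missing-group problem; "
            "use transfer_experiment instead"
        )
    a, b = treatments
    return BootstrapDesign(sizes=({a: mA, b: nA}, {a: mB, b: nB}), **kwargs)


TRANSFER_MODES = ("self.transfer", "transfer", "no.transfer", "scrambled")


def transfer_experiment(
    train: CombinedDataset,
    test: CombinedDataset,
    drop: dict[str, str],
    design: BootstrapDesign,
    modes: tuple[str, ...] = TRANSFER_MODES,
) -> BootstrapDistributions:
    """Missing-treatment-group DWD transfer experiment.

    ``drop`` removes one treatment per platform label from the test data
    before adjustment.  Per replicate, each mode derives the location shift
    differently: ``self.transfer`` trains on the full test resample,
    ``transfer`` on a resample of ``train``, ``no.transfer`` on the reduced
    set itself (which removes the treatment differences), and ``scrambled``
    permutes the transfer shift.  Only o and u are recorded (concordance is
    undefined when each treatment lives on one platform).
    """
    if sorted(train.gene_ids) != sorted(test.gene_ids):
        common = sorted(set(train.gene_ids) & set(test.gene_ids))
        if not common:
            raise ValidationError("train and test share no genes")
        train = CombinedDataset(
            train.platform1.reorder_genes(common),
            train.platform2.reorder_genes(common),
            train.annotation,
        )
        test = CombinedDataset(
            test.platform1.reorder_genes(common),
            test.platform2.reorder_genes(common),
            test.annotation,
        )
    lab1, lab2 = test.platform_labels
    if set(drop) != {lab1, lab2}:
        raise ValidationError("drop must name one treatment per platform label")
    de_groups = design.de_groups
    if de_groups is None:
        raise ValidationError("transfer_experiment needs explicit de_groups")
    retained = {
        lab1: [t for t in de_groups if t != drop[lab1]],
        lab2: [t for t in de_groups if t != drop[lab2]],
    }
    kept_union = set(retained[lab1]) | set(retained[lab2])
    if kept_union != set(de_groups):
        raise ValidationError(
            "dropping the same treatment from both platforms leaves a platform "
            "pair with one treatment; treatment effects would be unidentifiable"
        )

    stats_names = ("o", "u")
    out = {m: {s: np.full(design.B, np.nan) for s in stats_names} for m in modes}
    failures = {m: 0 for m in modes}
    aborted: set[str] = set()
    native_sizes = _native_sizes(design, de_groups)
    test_mats = (test.platform1, test.platform2)
    train_mats = (train.platform1, train.platform2)

    for b in range(design.B):
        rng = np.random.default_rng([design.seed, b])
        # full-test resample: training set for self.transfer
        f1 = smoothed_resample(test_mats[0], test.annotation, design.sizes[0],
                               design.noise_sd, rng, tag=f"t{b}f")
        f2 = smoothed_resample(test_mats[1], test.annotation, design.sizes[1],
                               design.noise_sd, rng, tag=f"t{b}f")
        full_b = _make_pair(f1, f2)
        # reduced set: the dataset actually being adjusted
        red_sizes = (
            {t: design.sizes[0].get(t, 0) for t in retained[lab1]},
            {t: design.sizes[1].get(t, 0) for t in retained[lab2]},
        )
        r1 = smoothed_resample(test_mats[0], test.annotation, red_sizes[0],
                               design.noise_sd, rng, tag=f"t{b}r")
        r2m = smoothed_resample(test_mats[1], test.annotation, red_sizes[1],
                                design.noise_sd, rng, tag=f"t{b}r")
        reduced_b = _make_pair(r1, r2m)
        # native curves from the full test data, per platform
        natives = []
        for m in test_mats:
            nat = smoothed_resample(m, test.annotation, native_sizes,
                                    design.noise_sd, rng, tag=f"t{b}n")
            ga = [s for s in nat.sample_ids if s.split("@")[1] == de_groups[0]]
            gb = [s for s in nat.sample_ids if s.split("@")[1] == de_groups[1]]
            natives.append(qvalues(welch_pvalues(nat, ga, gb)))
        q_n1, q_n2 = natives

        shift_transfer = None
        for mode in modes:
            if mode in aborted:
                continue
            try:
                if mode == "self.transfer":
                    _, shift = dwd_normalize(full_b)
                    adjusted = transfer_shift(shift, reduced_b)
                elif mode in ("transfer", "scrambled"):
                    if shift_transfer is None:
                        t1 = smoothed_resample(
                            train_mats[0], train.annotation, design.sizes[0],
                            design.noise_sd, rng, tag=f"t{b}tr")
                        t2 = smoothed_resample(
                            train_mats[1], train.annotation, design.sizes[1],
                            design.noise_sd, rng, tag=f"t{b}tr")
                        _, shift_transfer = dwd_normalize(_make_pair(t1, t2))
                    shift = shift_transfer
                    if mode == "scrambled":
                        shift = scramble_shift(shift, int(rng.integers(2**31 - 1)))
                    # transfer shifts are keyed by the training platform labels;
                    # rekey positionally onto the test pair
                    shift = _rekey_shift(shift, reduced_b)
                    adjusted = transfer_shift(shift, reduced_b)
                elif mode == "no.transfer":
                    adjusted, _ = dwd_normalize(reduced_b)
                else:
                    raise ValidationError(f"unknown transfer mode {mode!r}")
                merged = adjusted.merged()
                ga = [s for s in merged.sample_ids
                      if adjusted.annotation.treatment_of(s) == de_groups[0]]
                gb = [s for s in merged.sample_ids
                      if adjusted.annotation.treatment_of(s) == de_groups[1]]
                q_cross = qvalues(welch_pvalues(merged, ga, gb))
                areas = detection_areas(q_cross, q_n1, q_n2)
                out[mode]["o"][b] = areas.o
                out[mode]["u"][b] = areas.u
            except Exception as exc:  # noqa: BLE001
                failures[mode] += 1
                logger.warning("replicate %d: mode %s failed: %s", b, mode, exc)
                if failures[mode] > design.max_failure_fraction * design.B:
                    aborted.add(mode)
    return BootstrapDistributions(
        values=out,
        aborted=aborted,
        metadata={
            "B": str(design.B),
            "native_curves": "full test data, per platform",
            "de_groups": ",".join(de_groups),
        },
    )


def _rekey_shift(shift, d: CombinedDataset):
    """Map a shift's platform keys onto a dataset's labels positionally."""
    from .dwd import DWDShift

    labs_shift = sorted(shift.eta)
    lab1, lab2 = d.platform_labels
    if {lab1, lab2} == set(labs_shift):
        return shift
    eta = {lab1: shift.eta[labs_shift[0]], lab2: shift.eta[labs_shift[1]]}
    return DWDShift(list(shift.gene_ids), eta, dict(shift.provenance))
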