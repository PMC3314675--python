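"""Data model and I/O for two-platform expression datasets.

Expression values are natural-log scale throughout.  The on-disk formats are
plain delimited text: an expression matrix has sample ids in the header row
and gene ids in the first column; a sample annotation table has columns
``sample_id``, ``platform``, ``treatment`` and optionally ``study``; a probe
mapping table has columns ``platform``, ``probe_id``, ``gene_id``.  Tab is
the default delimiter and comma is auto-detected from the header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "ProbeMapping",
    "CombinedDataset",
    "read_expression_matrix",
    "read_sample_annotation",
    "read_probe_mapping",
    "build_combined_dataset",
    "write_dataset",
    "read_dataset",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what} id(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of natural-log expression for one platform."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def reorder_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(list(genes))
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids), values)


@dataclass
class SampleAnnotation:
    """Sample -> (platform, treatment, study) lookup."""

    table: pd.DataFrame  # index: sample_id; columns: platform, treatment, study

    REQUIRED = ("platform", "treatment")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = sorted(set(self.table.index[self.table.index.duplicated()]))
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        if len(self.table) == 0:
            raise ValidationError("no samples in annotation")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ParseError(f"annotation is missing required column {col!r}")
        if "study" not in self.table.columns:
            self.table = self.table.assign(study="default")
        self.table = self.table.astype(str)
        self.table.index = self.table.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def platforms(self) -> list[str]:
        return sorted(self.table["platform"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.table["treatment"].unique())

    def platform_of(self, sample_id: str) -> str:
        return self.table.at[str(sample_id), "platform"]

    def treatment_of(self, sample_id: str) -> str:
        return self.table.at[str(sample_id), "treatment"]

    def samples(self, platform: str | None = None, treatment: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if platform is not None:
            mask &= self.table["platform"] == platform
        if treatment is not None:
            mask &= self.table["treatment"] == treatment
        return list(self.table.index[mask])

    def subset(self, sample_ids: Iterable[str]) -> "SampleAnnotation":
        ids = [str(s) for s in sample_ids]
        missing = [s for s in ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples absent from annotation: {missing[:5]}")
        return SampleAnnotation(self.table.loc[ids].copy())

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str] | tuple[str, str, str, str]]
    ) -> "SampleAnnotation":
        rows = []
        for rec in records:
            if len(rec) == 3:
                rows.append((rec[0], rec[1], rec[2], "default"))
            else:
                rows.append(tuple(rec))
        df = pd.DataFrame(rows, columns=["sample_id", "platform", "treatment", "study"])
        return cls(df.set_index("sample_id"))


@dataclass
class ProbeMapping:
    """Rows of (platform, probe_id, gene_id); (platform, probe_id) unique."""

    table: pd.DataFrame  # columns: platform, probe_id, gene_id

    def __post_init__(self) -> None:
        for col in ("platform", "probe_id", "gene_id"):
            if col not in self.table.columns:
                raise ParseError(f"probe mapping is missing column {col!r}")
        self.table = self.table.astype(str)
        key = self.table[["platform", "probe_id"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].head().to_records(index=False).tolist()
            raise ValidationError(f"duplicate (platform, probe_id) pairs: {dups}")

    def gene_for(self, platform: str, probe_ids: Sequence[str]) -> pd.Series:
        sub = self.table[self.table["platform"] == platform].set_index("probe_id")
        return sub["gene_id"].reindex([str(p) for p in probe_ids])


@dataclass
class CombinedDataset:
    """Two gene-aligned expression matrices plus sample annotations.

    The universal input/output of every normalization method.  The two
    matrices carry an identical, identically ordered gene list, and every
    sample appears on exactly one platform.
    """

    platform1: ExpressionMatrix
    platform2: ExpressionMatrix
    annotation: SampleAnnotation
    discrete_flag: bool = False
    code_set: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.platform1.gene_ids != self.platform2.gene_ids:
            raise ValidationError("gene lists of the two platforms differ")
        if self.platform1.n_samples < 1 or self.platform2.n_samples < 1:
            raise ValidationError("each platform needs at least one sample")
        overlap = set(self.platform1.sample_ids) & set(self.platform2.sample_ids)
        if overlap:
            raise ValidationError(f"samples on both platforms: {sorted(overlap)[:5]}")
        for sid in self.platform1.sample_ids + self.platform2.sample_ids:
            if sid not in self.annotation.table.index:
                raise ValidationError(f"sample {sid!r} missing from annotation")

    @property
    def gene_ids(self) -> list[str]:
        return self.platform1.gene_ids

    @property
    def n_genes(self) -> int:
        return self.platform1.n_genes

    @property
    def platform_labels(self) -> tuple[str, str]:
        lab1 = {self.annotation.platform_of(s) for s in self.platform1.sample_ids}
        lab2 = {self.annotation.platform_of(s) for s in self.platform2.sample_ids}
        if len(lab1) != 1 or len(lab2) != 1:
            raise ValidationError("each matrix must hold samples of exactly one platform")
        return lab1.pop(), lab2.pop()

    def matrix_for(self, platform_label: str) -> ExpressionMatrix:
        lab1, lab2 = self.platform_labels
        if platform_label == lab1:
            return self.platform1
        if platform_label == lab2:
            return self.platform2
        raise ValidationError(f"unknown platform label {platform_label!r}")

    def merged(self) -> ExpressionMatrix:
        """Both platforms side by side (platform1 columns first)."""
        return ExpressionMatrix(
            list(self.gene_ids),
            self.platform1.sample_ids + self.platform2.sample_ids,
            np.hstack([self.platform1.values, self.platform2.values]),
        )

    def with_values(
        self, v1: np.ndarray, v2: np.ndarray, discrete: bool = False,
        code_set: tuple[float, ...] | None = None,
    ) -> "CombinedDataset":
        return CombinedDataset(
            self.platform1.with_values(v1),
            self.platform2.with_values(v2),
            self.annotation,
            discrete_flag=discrete,
            code_set=code_set,
        )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a delimited genes x samples table (header = sample ids)."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.columns.has_duplicates or df.index.has_duplicates:
        dup = sorted(
            set(df.columns[df.columns.duplicated()]) | set(df.index[df.index.duplicated()])
        )
        raise ValidationError(f"duplicate id(s) in {path.name}: {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, sample {sample!r} "
                        f"in {path.name}"
                    ) from None
        raise  # pragma: no cover - unreachable
    if np.any(pd.isna(values)):
        bad = np.argwhere(pd.isna(values))[0]
        raise ParseError(
            f"missing value at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r} "
            f"in {path.name}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Read the sample_id/platform/treatment[/study] table."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"annotation {path.name} is missing required column 'sample_id'")
    known = {"sample_id", "platform", "treatment", "study"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown annotation column(s): %s", extra)
        df = df.drop(columns=extra)
    return SampleAnnotation(df.set_index("sample_id"))


def read_probe_mapping(path: str | Path) -> ProbeMapping:
    path = Path(path)
    sep = _detect_sep(path)
    return ProbeMapping(pd.read_csv(path, sep=sep, dtype=str))


def _collapse_probes(m: ExpressionMatrix, mapping: ProbeMapping, platform: str) -> ExpressionMatrix:
    """Map probe rows to genes, averaging duplicate probes (log-scale mean)."""
    genes = mapping.gene_for(platform, m.gene_ids)
    keep = genes.notna().to_numpy()
    if not keep.any():
        raise ValidationError(f"no probes of platform {platform!r} resolve through the mapping")
    df = pd.DataFrame(m.values[keep], index=genes.to_numpy()[keep], columns=m.sample_ids)
    collapsed = df.groupby(level=0, sort=True).mean()
    return ExpressionMatrix.from_frame(collapsed)


def build_combined_dataset(
    m1: ExpressionMatrix,
    m2: ExpressionMatrix,
    ann: SampleAnnotation,
    mapping: ProbeMapping | None = None,
) -> CombinedDataset:
    """Merge two platforms onto their common gene list.

    Probes mapping to one gene are averaged (arithmetic mean of log values)
    within each platform; the merged gene list is the lexicographically
    sorted intersection.
    """
    if mapping is not None:
        labels = [ann.platform_of(s) for s in m1.sample_ids]
        lab1 = labels[0] if labels else None
        lab2 = ann.platform_of(m2.sample_ids[0]) if m2.sample_ids else None
        m1 = _collapse_probes(m1, mapping, lab1)
        m2 = _collapse_probes(m2, mapping, lab2)
    common = sorted(set(m1.gene_ids) & set(m2.gene_ids))
    if not common:
        raise ValidationError("empty intersection of gene lists")
    d = CombinedDataset(m1.reorder_genes(common), m2.reorder_genes(common), ann)
    return d


def _format_frame(df: pd.DataFrame, discrete: bool) -> pd.DataFrame:
    if discrete:
        vals = df.to_numpy()
        if np.allclose(vals, np.round(vals)):
            return df.astype(int)
    return df


def write_dataset(d: CombinedDataset, path_prefix: str | Path) -> list[Path]:
    """Write one matrix per platform plus the annotation table (TSV)."""
    if d.n_genes == 0:
        raise ValidationError("refusing to write a dataset with 0 genes")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix, m in (("platform1", d.platform1), ("platform2", d.platform2)):
        p = prefix.with_name(prefix.name + f".{suffix}.tsv")
        df = _format_frame(m.to_frame(), d.discrete_flag)
        df.to_csv(p, sep="\t", index_label="gene_id")
        paths.append(p)
    p = prefix.with_name(prefix.name + ".annotation.tsv")
    d.annotation.table.to_csv(p, sep="\t", index_label="sample_id")
    paths.append(p)
    return paths


def read_dataset(path_prefix: str | Path, discrete: bool = False) -> CombinedDataset:
    """Read back the files written by :func:`write_dataset`."""
    prefix = Path(path_prefix)
    m1 = read_expression_matrix(prefix.with_name(prefix.name + ".platform1.tsv"))
    m2 = read_expression_matrix(prefix.with_name(prefix.name + ".platform2.tsv"))
    ann = read_sample_annotation(prefix.with_name(prefix.name + ".annotation.tsv"))
    return CombinedDataset(m1, m2, ann, discrete_flag=discrete)
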