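"""Reading and integrating expression matrices and GMT gene-set collections.

Expression tables are plain text (TSV or CSV): first column gene
identifiers, header row sample identifiers, one row per gene.  Multiple
cohorts are merged into a single matrix by intersecting genes, dropping any
gene with a missing value, and concatenating samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "integrate_datasets",
    "read_gmt",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples real-valued matrix with identifier bookkeeping.

    ``values[i, j]`` is the expression abundance of gene ``gene_ids[i]`` in
    sample ``sample_ids[j]``.  Missing entries are NaN; an integrated matrix
    (output of :func:`integrate_datasets`) contains none.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError(f"expression values must be 2-D, got {values.ndim}-D")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({g for g in ids if list(ids).count(g) > 1})
                raise ValidationError(f"duplicate {kind} ids: {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT contents): set name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


def _infer_delimiter(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(
    path: str | os.PathLike,
    delimiter: str | None = None,
    orientation: str = "genes",
) -> ExpressionMatrix:
    """Read a delimited expression table.

    Parameters
    ----------
    path
        Text file; first column gene ids, header row sample ids.
    delimiter
        Field separator. Default: ``,`` for ``.csv`` files, tab otherwise.
    orientation
        ``"genes"`` (rows are genes, the default) or ``"samples"`` (rows are
        samples; the table is transposed after reading).
    """
    if orientation not in ("genes", "samples"):
        raise ValidationError(f"orientation must be 'genes' or 'samples', got {orientation!r}")
    delimiter = delimiter or _infer_delimiter(path)
    try:
        frame = pd.read_csv(
            path, sep=delimiter, index_col=0, header=0, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    non_numeric = [
        c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])
    ]
    if non_numeric:
        frame[non_numeric] = frame[non_numeric].apply(pd.to_numeric, errors="raise")
    if orientation == "samples":
        frame = frame.T
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene ids: {dupes[:5]}")
    return ExpressionMatrix.from_frame(frame)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    delimiter: str | None = None,
    float_format: str = "%.17g",
) -> None:
    """Write a matrix as delimited text; %.17g round-trips doubles exactly."""
    delimiter = delimiter or _infer_delimiter(path)
    matrix.to_frame().to_csv(path, sep=delimiter, float_format=float_format)


def integrate_datasets(
    matrices: list[ExpressionMatrix],
    labels: list[str] | None = None,
    sort_genes: bool = False,
) -> ExpressionMatrix:
    """Merge cohorts into one complete matrix.

    Genes are intersected across inputs (order of the first input, or sorted
    if ``sort_genes``), samples concatenated in input order, and every gene
    carrying a missing value in any retained sample is dropped so the result
    is complete.  Sample-id collisions across cohorts are resolved by
    prefixing the dataset label (``"PAAD:TCGA-..."``).
    """
    if not matrices:
        raise ValidationError("need at least one matrix to integrate")
    if labels is not None and len(labels) != len(matrices):
        raise ValidationError("labels must match the number of matrices")

    shared = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        shared &= set(m.gene_ids)
    if not shared:
        raise ValidationError("zero shared genes across input matrices")
    if sort_genes:
        genes = sorted(shared)
    else:
        genes = [g for g in matrices[0].gene_ids if g in shared]

    all_samples = [s for m in matrices for s in m.sample_ids]
    collide = len(set(all_samples)) != len(all_samples)
    blocks, sample_ids = [], []
    for i, m in enumerate(matrices):
        frame = m.to_frame().loc[genes]
        if labels is not None:
            prefix = labels[i]
        elif collide:
            prefix = f"d{i + 1}"
        else:
            prefix = None
        sample_ids.extend(
            s if prefix is None else f"{prefix}:{s}" for s in m.sample_ids
        )
        blocks.append(frame.to_numpy(dtype=float))
    values = np.hstack(blocks)

    keep = ~np.isnan(values).any(axis=1)
    values = values[keep]
    genes = [g for g, k in zip(genes, keep) if k]
    if not genes:
        raise ValidationError("all shared genes were dropped for missing values")
    return ExpressionMatrix(tuple(genes), tuple(sample_ids), values)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member [TAB member ...]``.

    Members are deduplicated preserving first occurrence.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one member, got {len(fields)} field(s)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(f for f in fields[2:] if f))
            if not members:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = (description, members)
    return GeneSetCollection(sets)
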