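"""Containers, I/O and preprocessing for grouped expression matrices.

The central object is :class:`ExpressionMatrix`, a genes x samples grid of
normalized, non-negative expression values (typically log2 of RPKM / FPKM /
TMM / RLE / size-factor-normalized counts).  The matrix is assumed to be
normalized so that values are comparable *between* samples; no normalization
is performed here.  :class:`SampleAnnotation` groups the samples into sample
types (cell types, tissues, ...) with their replicate counts, which is what
the marker detectors operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ExpressionMatrixError(ValueError):
    """Raised when a matrix, annotation or mapping violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ExpressionMatrixError(f"duplicated {what} {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Normalized expression values for ``n`` genes across ``s`` samples.

    Parameters
    ----------
    values
        ``(n, s)`` array of finite, non-negative reals. Columns follow
        ``sample_ids`` order, rows follow ``gene_ids`` order.
    gene_ids, sample_ids
        Unique row / column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionMatrixError("values must be a 2-D genes x samples grid")
        n, s = self.values.shape
        if s < 2:
            raise ExpressionMatrixError("at least two samples are required")
        if len(self.gene_ids) != n or len(self.sample_ids) != s:
            raise ExpressionMatrixError(
                f"shape {self.values.shape} does not match {len(self.gene_ids)} "
                f"gene ids and {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionMatrixError("expression values must be finite")
        if np.any(self.values < 0):
            raise ExpressionMatrixError(
                "negative expression values are not allowed; the matrix must be "
                "normalized to a non-negative scale"
            )

    @property
    def n(self) -> int:
        """Number of genes."""
        return self.values.shape[0]

    @property
    def s(self) -> int:
        """Number of samples."""
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset preserving the requested gene order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        genes = list(genes)
        missing = [g for g in genes if g not in index]
        if missing:
            raise ExpressionMatrixError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], genes, list(self.sample_ids))


@dataclass
class SampleAnnotation:
    """Sample -> sample-type labels with derived replicate counts.

    ``types`` preserves first-appearance order of the labels;
    ``replicate_counts`` maps each type to its number of replicate samples.
    Types with a single replicate trigger a warning (a single sample cannot
    corroborate itself); ``strict=True`` turns the warning into an error.
    """

    mapping: dict[str, str]
    strict: bool = False
    types: list[str] = field(init=False)
    replicate_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if len(self.mapping) < 2:
            raise ExpressionMatrixError("annotation must cover at least two samples")
        self.types = list(dict.fromkeys(self.mapping.values()))
        self.replicate_counts = {t: 0 for t in self.types}
        for t in self.mapping.values():
            self.replicate_counts[t] += 1
        if len(self.types) >= len(self.mapping):
            raise ExpressionMatrixError(
                "number of sample types must be smaller than the number of samples"
            )
        singletons = [t for t, c in self.replicate_counts.items() if c < 2]
        if singletons:
            msg = f"sample types with a single replicate: {singletons}"
            if self.strict:
                raise ExpressionMatrixError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)

    @property
    def t(self) -> int:
        return len(self.types)

    @classmethod
    def from_labels(
        cls, sample_ids: Sequence[str], labels: Sequence[str], strict: bool = False
    ) -> "SampleAnnotation":
        if len(sample_ids) != len(labels):
            raise ExpressionMatrixError("sample_ids and labels differ in length")
        return cls(dict(zip(sample_ids, labels)), strict=strict)

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        """Type labels in the order of ``sample_ids``; errors on missing samples."""
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ExpressionMatrixError(
                f"samples without a type annotation: {missing[:10]}"
            )
        return [self.mapping[s] for s in sample_ids]


@dataclass
class GeneIdMapping:
    """Offline gene-identifier lookup: (source_id, gene_symbol, entrez_id) rows."""

    table: pd.DataFrame  # columns: source_id, gene_symbol, entrez_id
    namespace: str = "Ensembl"  # Ensembl | RefSeq | UCSC

    def __post_init__(self) -> None:
        required = ["source_id", "gene_symbol", "entrez_id"]
        if list(self.table.columns[:3]) != required:
            raise ExpressionMatrixError(f"mapping table must have columns {required}")
        if len(self.table) == 0:
            raise ExpressionMatrixError("empty gene-id mapping table")
        if self.table["source_id"].duplicated().any():
            dup = self.table.loc[self.table["source_id"].duplicated(), "source_id"]
            raise ExpressionMatrixError(f"duplicated source_id {dup.iloc[0]!r}")

    def lookup(self, target: str) -> dict[str, str]:
        if target not in ("symbol", "entrez"):
            raise ExpressionMatrixError("target must be 'symbol' or 'entrez'")
        col = "gene_symbol" if target == "symbol" else "entrez_id"
        return dict(zip(self.table["source_id"].astype(str), self.table[col].astype(str)))


@dataclass
class MappingReport:
    """Outcome of a gene-id mapping pass."""

    n_mapped: int
    unmapped: list[str]
    collisions: dict[str, list[str]]  # target id -> source ids that shared it


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression table (header = sample ids, first column = gene ids).

    Errors name the offending duplicate id, or give row/column coordinates for
    non-numeric cells, or report negative values.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionMatrixError(f"empty expression table: {path}")
    _check_unique(list(df.index), "gene id")
    _check_unique(list(df.columns), "sample id")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ExpressionMatrixError(
                f"non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        numeric[col] = converted
    if numeric.isna().any().any():
        raise ExpressionMatrixError("missing values in expression table")
    if (numeric.to_numpy() < 0).any():
        rows, cols = np.nonzero(numeric.to_numpy() < 0)
        raise ExpressionMatrixError(
            f"negative value at row {numeric.index[rows[0]]!r}, "
            f"column {numeric.columns[cols[0]]!r}"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_expression_table(
    m: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    m.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Read a Matrix Market coordinate file with one-per-line gene/sample side files.

    Orientation is genes x samples, matching the dense table format.
    """
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = _read_id_list(genes_path)
    samples = _read_id_list(samples_path)
    return ExpressionMatrix(np.asarray(mat, dtype=float), genes, samples)


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_annotation(path: str | Path, strict: bool = False) -> SampleAnnotation:
    """Read a two-column TSV ``sample_id<TAB>sample_type`` annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "sample_type"]:
        raise ExpressionMatrixError(
            "annotation table must have columns 'sample_id' and 'sample_type'"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ExpressionMatrixError(f"duplicated sample id {dup!r} in annotation")
    return SampleAnnotation(
        dict(zip(df["sample_id"], df["sample_type"])), strict=strict
    )


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(ann.mapping), "sample_type": list(ann.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_id_mapping(path: str | Path, namespace: str = "Ensembl") -> GeneIdMapping:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GeneIdMapping(df, namespace=namespace)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def log2_pseudocount(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1); shape and identifiers unchanged."""
    return ExpressionMatrix(np.log2(m.values + 1.0), list(m.gene_ids), list(m.sample_ids))


def filter_expressed(m: ExpressionMatrix, min_samples: int = 2) -> ExpressionMatrix:
    """Keep genes with strictly positive values in at least ``min_samples`` samples.

    "Expressed" is interpreted as a strictly positive value, matching the
    zero-inflation of count-derived data.  May return a matrix with zero genes.
    """
    if min_samples < 1:
        raise ExpressionMatrixError("min_samples must be >= 1")
    keep = (m.values > 0).sum(axis=1) >= min_samples
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(m.values[keep], genes, list(m.sample_ids))


def map_gene_ids(
    m: ExpressionMatrix, mapping: GeneIdMapping, target: str = "symbol"
) -> tuple[ExpressionMatrix, MappingReport]:
    """Rename gene ids through an offline lookup table.

    Unmapped genes keep their source ids and are listed in the report.  When
    several source ids map to the same target, every colliding row is kept and
    disambiguated with ``.1``, ``.2``, ... suffixes in row order.
    """
    lut = mapping.lookup(target)
    new_ids: list[str] = []
    unmapped: list[str] = []
    for g in m.gene_ids:
        if g in lut and lut[g] and lut[g].lower() != "nan":
            new_ids.append(lut[g])
        else:
            new_ids.append(g)
            unmapped.append(g)
    counts: dict[str, int] = {}
    for g in new_ids:
        counts[g] = counts.get(g, 0) + 1
    collisions: dict[str, list[str]] = {}
    seen: dict[str, int] = {}
    final: list[str] = []
    for src, g in zip(m.gene_ids, new_ids):
        if counts[g] > 1:
            seen[g] = seen.get(g, 0) + 1
            collisions.setdefault(g, []).append(src)
            final.append(f"{g}.{seen[g]}")
        else:
            final.append(g)
    out = ExpressionMatrix(m.values.copy(), final, list(m.sample_ids))
    return out, MappingReport(
        n_mapped=m.n - len(unmapped), unmapped=unmapped, collisions=collisions
    )
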