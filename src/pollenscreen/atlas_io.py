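"""Reading, validating and writing gene x tissue FPKM expression matrices.

An expression atlas is a non-negative matrix of FPKM values (fragments per
kilobase of exon model per million mapped fragments) with genes as rows and
tissues as columns.  Gene identifiers are opaque strings: both GRMZM... (B73
RefGen_v3) and Zm00001d... (v4) style ids pass through untranslated, and the
mapping between gene-model versions is deliberately left to the user.

Input files are delimited text with a mandatory header row; the first column
(configurable) holds gene ids and the remaining columns one tissue each.
Values may be written in plain or scientific notation.  An empty cell is a
missing value and a hard error -- silently zero-filling would corrupt the
downstream ratio screens.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionAtlas",
    "read_atlas",
    "select_tissues",
    "write_atlas",
    "write_gene_table",
]


@dataclass
class ExpressionAtlas:
    """A validated gene x tissue FPKM matrix.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene ids and
    whose columns hold unique tissue labels.  Every cell is finite and
    non-negative; row and column order are meaningful and preserved.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1:
            raise ValueError("atlas must contain at least 1 gene")
        if df.shape[1] < 2:
            raise ValueError("atlas must contain at least 2 tissues")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate tissue name {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("atlas values must be numeric")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid FPKM value {values[i, j]!r} for gene "
                f"{df.index[i]!r} in tissue {df.columns[j]!r} "
                "(values must be finite and >= 0)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]

    def tissue(self, name: str) -> pd.Series:
        """FPKM values of one tissue, indexed by gene id."""
        if name not in self.data.columns:
            raise KeyError(f"unknown tissue {name!r}")
        return self.data[name]


def _parse_cell(raw: str, gene: str, tissue: str) -> float:
    raw = raw.strip()
    if raw == "":
        raise ValueError(f"missing value for gene {gene!r} in tissue {tissue!r}")
    try:
        value = float(raw)
    except ValueError:
        raise ValueError(
            f"non-numeric value {raw!r} for gene {gene!r} in tissue {tissue!r}"
        ) from None
    if math.isnan(value) or math.isinf(value):
        raise ValueError(
            f"non-finite value {raw!r} for gene {gene!r} in tissue {tissue!r}"
        )
    if value < 0:
        raise ValueError(
            f"negative FPKM {raw!r} for gene {gene!r} in tissue {tissue!r}"
        )
    return value


def read_atlas(
    path: str | Path,
    delimiter: str = "\t",
    gene_id_column: str | None = None,
) -> ExpressionAtlas:
    """Read a delimited gene x tissue FPKM matrix.

    Parameters
    ----------
    path:
        Delimited text file with a header row; one row per gene.
    delimiter:
        Field separator (tab by default; pass ``","`` for CSV).
    gene_id_column:
        Header name of the gene-id column.  Defaults to the first column.

    Raises
    ------
    ValueError
        On duplicate gene ids or tissue names, and on any missing,
        non-numeric, non-finite or negative cell (the offending gene and
        tissue are named).
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, header row required") from None
        rows = list(reader)

    header = [h.strip() for h in header]
    if gene_id_column is None:
        gene_col = 0
    else:
        if gene_id_column not in header:
            raise ValueError(
                f"{path}: gene id column {gene_id_column!r} not in header"
            )
        gene_col = header.index(gene_id_column)
    tissues = [h for i, h in enumerate(header) if i != gene_col]
    seen_tissues: set[str] = set()
    for t in tissues:
        if t in seen_tissues:
            raise ValueError(f"{path}: duplicate tissue name {t!r}")
        seen_tissues.add(t)

    genes: list[str] = []
    seen_genes: set[str] = set()
    matrix = np.empty((len(rows), len(tissues)), dtype=float)
    for r, row in enumerate(rows):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {r + 2} has {len(row)} fields, expected {len(header)}"
            )
        gene = row[gene_col].strip()
        if gene == "":
            raise ValueError(f"{path}: empty gene id on row {r + 2}")
        if gene in seen_genes:
            raise ValueError(f"duplicate gene id {gene}")
        seen_genes.add(gene)
        genes.append(gene)
        j = 0
        for i, raw in enumerate(row):
            if i == gene_col:
                continue
            matrix[r, j] = _parse_cell(raw, gene, tissues[j])
            j += 1

    frame = pd.DataFrame(matrix, index=pd.Index(genes, name=header[gene_col]),
                         columns=tissues)
    return ExpressionAtlas(frame)


def select_tissues(atlas: ExpressionAtlas, names: Sequence[str]) -> ExpressionAtlas:
    """Restrict an atlas to the named tissues, in the given order.

    Genes are unchanged.  The operation is order-defining and idempotent:
    selecting ``[B, A]`` then ``[A]`` equals selecting ``[A]`` directly.
    """
    unknown = [n for n in names if n not in atlas.data.columns]
    if unknown:
        raise ValueError(f"unknown tissue name(s): {', '.join(map(repr, unknown))}")
    if len(set(names)) != len(names):
        raise ValueError("tissue selection contains duplicates")
    return ExpressionAtlas(atlas.data[list(names)].copy())


def write_atlas(atlas: ExpressionAtlas, path: str | Path, delimiter: str = "\t") -> None:
    """Write an atlas as delimited text (full float precision, LF endings).

    ``read_atlas(write_atlas(a))`` reproduces ``a`` cell-for-cell: floats are
    rendered with :func:`repr` precision, which round-trips exactly.
    """
    df = atlas.data.copy()
    index_name = df.index.name or "gene_id"
    df.index.name = index_name
    df.to_csv(path, sep=delimiter, lineterminator="\n")


def write_gene_table(
    records,
    path: str | Path,
    delimiter: str = "\t",
    columns: Iterable[str] | None = None,
) -> None:
    """Write a tabular result (DataFrame, or iterable of mappings/dataclasses)
    as delimited UTF-8 text with a header row and stable row order.

    An empty record list with a known schema (an empty DataFrame with columns,
    or ``columns=...`` given explicitly) yields a header-only file; a record
    list with no schema at all is an error.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = list(records)
        dicts = []
        for row in rows:
            if hasattr(row, "__dataclass_fields__"):
                dicts.append({k: getattr(row, k) for k in row.__dataclass_fields__})
            else:
                dicts.append(dict(row))
        frame = pd.DataFrame(dicts, columns=list(columns) if columns else None)
    if frame.shape[1] == 0:
        raise ValueError("records have no columns; nothing to write")
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory {path.parent} does not exist")
    frame.to_csv(path, sep=delimiter, index=False, lineterminator="\n",
                 encoding="utf-8")
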