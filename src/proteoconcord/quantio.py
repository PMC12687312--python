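"""Reading and writing protein-quantification matrices and sample metadata.

The central container is :class:`QuantMatrix`: a proteins x samples intensity
matrix with an explicit observation mask and a scale flag (``raw`` or
``log2``).  Supported on-disk dialects are the DIA-NN protein-group matrix
(``pg_matrix`` style: a ``Protein.Group`` column plus one column per run,
zeros meaning *not quantified*) and generic wide TSV/CSV where only empty
cells and missing tokens are treated as absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuantMatrix",
    "SampleMetadata",
    "read_quant_table",
    "write_quant_table",
    "read_metadata",
    "write_metadata",
]

RAW = "raw"
LOG2 = "log2"

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "N/A", "null", "None"})

#: column DIA-NN uses for the protein-group key
DIANN_PG_COLUMN = "Protein.Group"
#: non-quantitative annotation columns DIA-NN may emit alongside runs
DIANN_ANNOTATION_COLUMNS = frozenset(
    {"Protein.Ids", "Protein.Names", "Genes", "First.Protein.Description"}
)


@dataclass
class QuantMatrix:
    """Proteins x samples abundance matrix with an explicit missingness mask.

    Parameters
    ----------
    protein_ids : sequence of str
        Unique accession keys, one per row.
    sample_ids : sequence of str
        Unique sample names, one per column.
    values : ndarray of float, shape (n_proteins, n_samples)
        Intensities; cells where ``mask`` is False hold NaN and carry no
        numeric meaning.
    mask : ndarray of bool
        True where a value was observed.
    scale : {"raw", "log2"}
        Raw-scale observed values must be strictly positive; the log2
        transform is recorded exactly once.
    imputed : ndarray of bool, optional
        Record of cells filled in by imputation (all observed afterwards).
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    scale: str = RAW
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, m = self.values.shape
        if len(self.protein_ids) != n or len(self.sample_ids) != m:
            raise ValueError(
                f"id lengths ({len(self.protein_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for name, ids in (("protein", self.protein_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        observed = self.values[self.mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("observed cells must be finite")
        if self.scale == RAW and observed.size and np.any(observed <= 0):
            raise ValueError("raw-scale observed values must be strictly positive")
        # missing cells carry no numeric meaning
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame view, NaN at missing cells."""
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )

    def copy(self) -> "QuantMatrix":
        return replace(
            self,
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            mask=self.mask.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    def select_rows(self, row_index: np.ndarray) -> "QuantMatrix":
        row_index = np.asarray(row_index)
        return replace(
            self,
            protein_ids=[self.protein_ids[i] for i in row_index],
            sample_ids=list(self.sample_ids),
            values=self.values[row_index],
            mask=self.mask[row_index],
            imputed=None if self.imputed is None else self.imputed[row_index],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "QuantMatrix":
        col = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([col[s] for s in sample_ids], dtype=int)
        return replace(
            self,
            protein_ids=list(self.protein_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            mask=self.mask[:, idx],
            imputed=None if self.imputed is None else self.imputed[:, idx],
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: study center (cohort), biological group, fold."""

    sample_id: str
    cohort: str
    group: str
    fold: int | None = None


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes


def leader_accession(protein_group: str) -> str:
    """Collapse a semicolon-separated protein group to its leader accession."""
    return protein_group.split(";")[0].strip()


def read_quant_table(
    path,
    dialect: str = "generic_tsv",
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
) -> QuantMatrix:
    """Read a wide protein-quantification table into a :class:`QuantMatrix`.

    Dialects:

    ``diann_pg``
        DIA-NN protein-group matrix: the ``Protein.Group`` column keys rows
        (collapsed to the leader accession), known annotation columns are
        skipped, and **zero intensities are treated as missing** — DIA-NN
        writes zeros for quantities absent from a run.
    ``generic_tsv`` / ``generic_csv``
        First column holds accessions; only empty cells and
        ``missing_tokens`` are treated as missing.
    """
    if dialect not in ("diann_pg", "generic_tsv", "generic_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "generic_csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect == "diann_pg":
        if DIANN_PG_COLUMN not in df.columns:
            raise ValueError(f"diann_pg table lacks a {DIANN_PG_COLUMN!r} column")
        ids = [leader_accession(g) for g in df[DIANN_PG_COLUMN]]
        sample_cols = [
            c
            for c in df.columns
            if c != DIANN_PG_COLUMN and c not in DIANN_ANNOTATION_COLUMNS
        ]
    else:
        ids = [str(v).strip() for v in df.iloc[:, 0]]
        sample_cols = list(df.columns[1:])
    if not sample_cols:
        raise ValueError("table contains zero sample columns")
    dupes = _duplicates(ids)
    if dupes:
        raise ValueError(f"duplicate protein ids: {sorted(dupes)}")

    tokens = set(missing_tokens)
    n, m = len(ids), len(sample_cols)
    values = np.full((n, m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in tokens:
                continue
            try:
                x = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at protein {ids[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if dialect == "diann_pg" and x == 0.0:
                continue  # DIA-NN writes 0 for not-quantified
            values[i, j] = x
            mask[i, j] = True
    return QuantMatrix(ids, [str(c) for c in sample_cols], values, mask, scale=RAW)


def write_quant_table(matrix: QuantMatrix, path) -> None:
    """Write a canonical TSV: protein ids first, empty string at missing cells.

    Output is UTF-8, tab-separated, decimal point, byte-stable for a fixed
    input; round-trips losslessly through :func:`read_quant_table` with the
    matching generic dialect.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, pid in enumerate(matrix.protein_ids):
            cells = [
                repr(float(matrix.values[i, j])) if matrix.mask[i, j] else ""
                for j in range(matrix.n_samples)
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def read_metadata(path) -> list[SampleMetadata]:
    """Read a sample-metadata TSV with columns sample_id, cohort, group[, fold]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "cohort", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    dupes = _duplicates(df["sample_id"])
    if dupes:
        raise ValueError(f"duplicate sample_id values: {sorted(dupes)}")
    out = []
    for _, row in df.iterrows():
        fold: int | None = None
        if "fold" in df.columns and row["fold"].strip() != "":
            fold = int(row["fold"])
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                cohort=row["cohort"],
                group=row["group"],
                fold=fold,
            )
        )
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tcohort\tgroup\tfold\n")
        for m in metadata:
            fold = "" if m.fold is None else str(m.fold)
            fh.write(f"{m.sample_id}\t{m.cohort}\t{m.group}\t{fold}\n")


def join_metadata(
    matrix: QuantMatrix, metadata: Sequence[SampleMetadata]
) -> dict[str, SampleMetadata]:
    """Map the matrix's sample ids onto metadata rows.

    Samples without a metadata row are reported with a warning; every matched
    sample maps to exactly one row (uniqueness enforced at read time).
    """
    by_id = {m.sample_id: m for m in metadata}
    dupes = _duplicates([m.sample_id for m in metadata])
    if dupes:
        raise ValueError(f"duplicate sample_id values: {sorted(dupes)}")
    unmatched = [s for s in matrix.sample_ids if s not in by_id]
    if unmatched:
        warnings.warn(
            f"samples absent from metadata: {unmatched}", UserWarning, stacklevel=2
        )
    return {s: by_id[s] for s in matrix.sample_ids if s in by_id}
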