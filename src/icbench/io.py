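"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices are genes x samples TSV/CSV with HGNC symbols in the
first column; gene sets are GMT; clinical tables are TSV/CSV with a fixed
column vocabulary (``sample_id``, ``response_category``, ``pfs_months``,
``pfs_event``, ``os_months``, ``os_event``, ``biopsy_time``, ``patient_id``,
``arm``). All identifiers are case-normalized (genes upper-cased, response
categories upper-cased); no gene alias mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

RESPONSE_CATEGORIES = frozenset({"CR", "PR", "SD", "PD", "NA"})
BIOPSY_TIMES = frozenset({"pre", "on", "NA"})

CLINICAL_COLUMNS = (
    "sample_id",
    "patient_id",
    "response_category",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "biopsy_time",
    "arm",
)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression in TPM-like units.

    ``values`` is a DataFrame indexed by unique upper-case gene symbols with
    unique sample-id columns. ``log_transformed`` records whether
    ``log2(x + 1)`` has already been applied; raw matrices must be
    non-negative.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dups)[:5]}")
        if not self.log_transformed and (self.values.to_numpy() < 0).any():
            raise FormatError("negative expression values in a raw (non-log) matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2p1(self) -> "ExpressionMatrix":
        """Return the matrix on the log2(x+1) scale (idempotent)."""
        if self.log_transformed:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), log_transformed=True)


@dataclass
class GeneSetCollection:
    """Ordered GMT-style container: (name, description, genes) triples."""

    entries: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.entries]
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate gene-set names: {dups}")
        for name, _, genes in self.entries:
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def __getitem__(self, name: str) -> list[str]:
        for set_name, _, genes in self.entries:
            if set_name == name:
                return list(genes)
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations keyed by unique ``sample_id``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" not in df.columns:
            raise FormatError("clinical table lacks a sample_id column")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in clinical table")
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df["response_category"] = (
            df["response_category"].astype("string").str.strip().str.upper().fillna("NA")
        )
        bad = set(df["response_category"]) - RESPONSE_CATEGORIES
        if bad:
            raise FormatError(f"unknown response categories: {sorted(bad)}")
        bt = df["biopsy_time"].astype("string").str.strip().str.lower().fillna("na")
        bt = bt.replace({"na": "NA"})
        bad = set(bt) - BIOPSY_TIMES
        if bad:
            raise FormatError(f"unknown biopsy_time values: {sorted(bad)}")
        df["biopsy_time"] = bt
        for stem in ("pfs", "os"):
            months = pd.to_numeric(df[f"{stem}_months"], errors="coerce")
            events = pd.to_numeric(df[f"{stem}_event"], errors="coerce")
            if ((months < 0).fillna(False)).any():
                raise FormatError(f"negative {stem}_months")
            orphan = events.notna() & months.isna()
            if orphan.any():
                sid = df.loc[orphan, "sample_id"].iloc[0]
                raise FormatError(
                    f"{stem}_event present without {stem}_months (sample {sid})"
                )
            bad_event = events.notna() & ~events.isin([0, 1])
            if bad_event.any():
                raise FormatError(f"{stem}_event must be 0/1")
            df[f"{stem}_months"] = months
            df[f"{stem}_event"] = events
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path) as handle:
        header = handle.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    has_tab, has_comma = "\t" in header, "," in header
    if has_tab and not has_comma:
        return "\t"
    if has_comma and not has_tab:
        return ","
    if has_tab and has_comma:
        raise FormatError(f"{path}: ambiguous delimiter (both tab and comma in header)")
    raise FormatError(f"{path}: could not detect a tab or comma delimiter")


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    log_transformed: bool = False,
    keep_genes: set[str] | None = None,
) -> ExpressionMatrix:
    """Read a genes-x-samples expression table.

    Gene symbols are upper-cased; duplicate gene rows are collapsed by the
    per-sample maximum (logged). ``keep_genes`` optionally restricts the
    matrix to a gene universe (e.g. protein-coding symbols).
    """
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: no data rows/columns")
    try:
        values = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at gene {row!r}, sample {col!r}"
                ) from None
        values = df.apply(pd.to_numeric, errors="coerce")
    values.index = values.index.astype(str).str.strip().str.upper()
    values.columns = values.columns.astype(str)
    if keep_genes is not None:
        keep = {g.upper() for g in keep_genes}
        values = values.loc[values.index.isin(keep)]
        if values.empty:
            raise FormatError(f"{path}: no genes left after gene-universe filtering")
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by per-sample max", n_dup)
        values = values.groupby(level=0, sort=False).max()
    return ExpressionMatrix(values, log_transformed=log_transformed)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Genes are upper-cased and deduplicated within each set, preserving first
    occurrence order.
    """
    entries: list[tuple[str, str, list[str]]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for raw in fields[2:]:
                gene = raw.strip().upper()
                if gene and gene not in seen:
                    seen.add(gene)
                    genes.append(gene)
            entries.append((name, description, genes))
    return GeneSetCollection(entries)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, description, genes in collection.entries:
            handle.write("\t".join([name, description, *genes]) + "\n")


def read_clinical_table(path: str | Path, delimiter: str | None = None) -> ClinicalTable:
    """Read a clinical annotation table (NA-tolerant)."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column sample_id")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_score_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a samples-in-rows score table (adapter scores, benchmark output)."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in score table")
    return df
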