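"""Reading quantification data and writing ranked candidate tables.

Two input routes:

* a pre-averaged table (CSV/TSV/XLSX) — gene identifiers in the first
  column, one mean-TPM column per condition, no replicate columns;
* a set of Salmon ``quant.sf`` files plus a replicate→condition design,
  from which condition means are computed here (unweighted arithmetic mean
  of the TPM column over each condition's replicates).

Output candidate tables carry the columns Rank, ID, SD, TPM_Avrg, CV and
are written as TSV or XLSX.  On the validation path the CV column holds the
literal text "Not calculated".  Numeric formatting defaults to 7 decimal
places for SD/CV and 4 for TPM_Avrg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .selection import CandidateTable, build_candidate_table

__all__ = [
    "ReplicateDesign",
    "read_expression_table",
    "read_salmon_quants",
    "read_design_file",
    "write_candidates",
    "read_candidates",
    "write_expression_table",
]

TABLE_DIALECTS = ("csv", "tsv", "xlsx")
OUTPUT_DIALECTS = ("tsv", "xlsx")
NOT_CALCULATED = "Not calculated"

_SUFFIX_DIALECT = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}
_SALMON_REQUIRED = ("Name", "TPM")


@dataclass
class ReplicateDesign:
    """Assignment of replicate inputs (file paths or column names) to
    condition labels; every condition must receive at least one replicate."""

    condition_labels: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise ValueError("duplicate condition labels in design")
        known = set(self.condition_labels)
        for key, cond in self.assignment.items():
            if cond not in known:
                raise ValueError(f"input {key!r} assigned to unknown condition {cond!r}")
        empty = [c for c in self.condition_labels if c not in set(self.assignment.values())]
        if empty:
            raise ValueError(f"condition(s) with no assigned replicate: {empty}")

    def replicates_of(self, condition: str) -> list[str]:
        return [k for k, c in self.assignment.items() if c == condition]


def _infer_dialect(path: Path, dialect: str | None, allowed: Sequence[str]) -> str:
    if dialect is None:
        dialect = _SUFFIX_DIALECT.get(path.suffix.lower())
        if dialect is None:
            raise ValueError(
                f"cannot infer dialect from suffix {path.suffix!r}; pass dialect="
            )
    if dialect not in allowed:
        raise ValueError(f"unrecognized dialect {dialect!r}; expected one of {list(allowed)}")
    return dialect


def read_expression_table(
    path: str | Path,
    dialect: str | None = None,
    sheet: int | str = 0,
) -> ExpressionMatrix:
    """Load a pre-averaged quantification table.

    The first row is a header, the first column holds gene identifiers and
    every following column is one condition's mean TPM.  Values must be
    plain decimals ('.' separator); duplicate identifiers, blank
    identifiers, non-numeric cells and tables with fewer than two condition
    columns are rejected.

    Parameters
    ----------
    path : str or Path
    dialect : {"csv", "tsv", "xlsx"}, optional
        Inferred from the file suffix when omitted (.txt reads as TSV).
    sheet : int or str
        Worksheet to read from an XLSX workbook (first sheet by default).
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect, TABLE_DIALECTS)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet, header=0, index_col=0, dtype=object)
    else:
        sep = "," if dialect == "csv" else "\t"
        raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str,
                          skipinitialspace=True)
    numeric = {}
    for col in raw.columns:
        conv = pd.to_numeric(raw[col], errors="coerce")
        bad = conv.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric TPM value {raw[col][bad].iloc[0]!r} for gene "
                f"{gene!r} in column {col!r}"
            )
        numeric[col] = conv
    frame = pd.DataFrame(numeric, index=raw.index)
    return ExpressionMatrix(frame)


def _read_one_salmon(path: Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in _SALMON_REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: not a Salmon quant.sf file (missing column(s) {missing})")
    names = table["Name"].astype(str)
    if names.duplicated().any():
        dup = sorted(set(names[names.duplicated()]))
        raise ValueError(f"{path}: duplicate identifiers {dup}")
    tpm = pd.to_numeric(table["TPM"], errors="raise")
    return pd.Series(tpm.to_numpy(dtype=float), index=pd.Index(names), name=str(path))


def read_salmon_quants(
    paths: Sequence[str | Path],
    design: ReplicateDesign,
) -> ExpressionMatrix:
    """Average Salmon per-replicate TPMs into per-condition means.

    Every file must contain the same gene set; the per-condition value is
    the unweighted arithmetic mean of the TPM column over the condition's
    replicate files (full precision, no rounding).  Gene order follows the
    first file; condition order follows the design.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no quant.sf files given")
    unassigned = [str(p) for p in paths if str(p) not in design.assignment]
    if unassigned:
        raise ValueError(f"file(s) assigned to no condition in the design: {unassigned}")

    series = [_read_one_salmon(p) for p in paths]
    ref_genes = series[0].index
    for s in series[1:]:
        if not s.index.equals(ref_genes):
            only_ref = sorted(set(ref_genes) - set(s.index))
            only_this = sorted(set(s.index) - set(ref_genes))
            if only_ref or only_this:
                raise ValueError(
                    f"gene sets differ between quant files: missing from {s.name}: "
                    f"{only_ref[:10]}; extra in {s.name}: {only_this[:10]}"
                )
            # same set in a different order: realigned below

    by_path = {s.name: s.reindex(ref_genes) for s in series}
    columns = {}
    for cond in design.condition_labels:
        reps = [by_path[str(p)] for p in paths if design.assignment[str(p)] == cond]
        if not reps:
            raise ValueError(f"no replicate file for condition {cond!r}")
        columns[cond] = np.mean(np.column_stack([r.to_numpy() for r in reps]), axis=1)
    frame = pd.DataFrame(columns, index=ref_genes)
    return ExpressionMatrix(frame)


def read_design_file(path: str | Path) -> ReplicateDesign:
    """Parse a two-column TSV design: replicate key (file path or column
    name), condition label.  No header; condition order is first-appearance
    order."""
    assignment: dict[str, str] = {}
    conditions: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        key, cond = parts[0].strip(), parts[1].strip()
        if not key or not cond:
            raise ValueError(f"{path}:{lineno}: empty replicate key or condition label")
        if key in assignment:
            raise ValueError(f"{path}:{lineno}: replicate {key!r} assigned twice")
        assignment[key] = cond
        if cond not in conditions:
            conditions.append(cond)
    return ReplicateDesign(conditions, assignment)


def _format_table(
    table: CandidateTable, sd_cv_decimals: int, mean_decimals: int
) -> pd.DataFrame:
    rows = []
    for rec in table.records:
        cv = (
            NOT_CALCULATED
            if rec.cv is None
            else f"{rec.cv:.{sd_cv_decimals}f}"
        )
        rows.append(
            {
                "Rank": rec.rank,
                "ID": rec.gene_id,
                "SD": f"{rec.sd:.{sd_cv_decimals}f}",
                "TPM_Avrg": f"{rec.log2_mean:.{mean_decimals}f}",
                "CV": cv,
            }
        )
    return pd.DataFrame(rows, columns=["Rank", "ID", "SD", "TPM_Avrg", "CV"])


def write_candidates(
    table: CandidateTable,
    path: str | Path,
    dialect: str | None = None,
    sd_cv_decimals: int = 7,
    mean_decimals: int = 4,
) -> Path:
    """Write a ranked candidate table as TSV or XLSX.

    One row per record in rank order; validation-path CV cells read
    "Not calculated".  Returns the path written.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect, OUTPUT_DIALECTS)
    frame = _format_table(table, sd_cv_decimals, mean_decimals)
    if dialect == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, sep="\t", index=False)
    return path


def read_candidates(path: str | Path, path_kind: str, dialect: str | None = None) -> CandidateTable:
    """Read back a candidate table written by :func:`write_candidates`."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect, OUTPUT_DIALECTS)
    if dialect == "xlsx":
        frame = pd.read_excel(path, dtype={"ID": str})
    else:
        frame = pd.read_csv(path, sep="\t", dtype={"ID": str})
    entries = []
    for _, row in frame.iterrows():
        cv = row["CV"]
        cv = None if (isinstance(cv, str) and cv == NOT_CALCULATED) else float(cv)
        entries.append((str(row["ID"]), float(row["SD"]), float(row["TPM_Avrg"]), cv))
    return build_candidate_table(path_kind, entries)


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    dialect: str | None = None,
    gene_column: str = "gene",
) -> Path:
    """Write an expression matrix in the table-input layout (gene ids in the
    first column), so it can be re-read with :func:`read_expression_table`."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect, TABLE_DIALECTS)
    frame = matrix.data.rename_axis(gene_column)
    if dialect == "xlsx":
        frame.to_excel(path)
    else:
        frame.to_csv(path, sep="," if dialect == "csv" else "\t")
    return path
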