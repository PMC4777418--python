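"""Readers and writers for the tabular formats used throughout the pipeline.

All files are plain CSV (comma separated, UTF-8, header required, "."
decimal).  Percentages are stored on the 0-100 scale everywhere.  Every
reader validates its input and reports offending rows by line number;
every writer/reader pair round-trips losslessly at six decimals.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

#: 384-well geometry: rows A-P, columns 1-24, 1-based.
PLATE_ROWS = [chr(ord("A") + i) for i in range(16)]
PLATE_COLS = list(range(1, 25))

#: Control classes spotted in the first four columns under the standard
#: screen layout: transfection-reagent wells (rnaimax), a transfection
#: efficiency control whose silencing is lethal (plk1), non-targeting
#: siRNA (scramble), and the sensitization positive control (brca2).
CONTROL_ROLES = ("rnaimax", "plk1", "scramble", "brca2")

#: Wells per plate for each control class under layout="paper".
CONTROL_LAYOUT_COUNTS = {"rnaimax": 24, "plk1": 16, "scramble": 8, "brca2": 16}

ARMS = ("untreated", "cisplatin")

GENE_TABLE_COLUMNS = [
    "gene",
    "survival_index",
    "pct_survival_cddp",
    "difference",
    "potentiation",
    "gene_score",
    "rank",
]

_GENE_ROLE_RE = re.compile(r"^gene:(\S+)$")


class PlateTableError(ValueError):
    """Raised when a plate table violates the well-record schema."""


def is_gene_role(role: str) -> bool:
    return role.startswith("gene:")


def gene_symbol(role: str) -> str:
    """Extract the gene symbol from a ``gene:<symbol>`` role string."""
    m = _GENE_ROLE_RE.match(role)
    if m is None:
        raise ValueError(f"not a gene role: {role!r}")
    return m.group(1)


def validate_plate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a well-record table in place and return it.

    Checks the column schema, well coordinates, role vocabulary, treatment
    arms, count non-negativity, and (plate, row, col) uniqueness.
    """
    required = ["plate_id", "row", "col", "role", "arm", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateTableError(f"plate table missing columns: {missing}")

    problems = []
    for idx, rec in enumerate(df.itertuples(index=False), start=2):
        where = f"line {idx} ({rec.plate_id},{rec.row},{rec.col})"
        if rec.row not in PLATE_ROWS:
            problems.append(f"{where}: row {rec.row!r} outside A-P")
        if rec.col not in PLATE_COLS:
            problems.append(f"{where}: col {rec.col!r} outside 1-24")
        if rec.arm not in ARMS:
            problems.append(f"{where}: unknown arm {rec.arm!r}")
        role = str(rec.role)
        if not (role in CONTROL_ROLES or _GENE_ROLE_RE.match(role)):
            problems.append(f"{where}: unknown role {role!r}")
        if rec.count < 0:
            problems.append(f"{where}: negative count {rec.count}")
    if problems:
        raise PlateTableError("invalid plate table:\n" + "\n".join(problems))

    dup = df.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        wells = df.loc[dup, ["plate_id", "row", "col"]].drop_duplicates()
        names = "; ".join(f"({w.plate_id},{w.row},{w.col})" for w in wells.itertuples())
        raise PlateTableError(f"duplicate wells: {names}")
    return df


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-well count CSV.

    The file must have the header ``plate_id,row,col,role,arm,count``.
    Counts are non-negative integers (nuclei counts); malformed rows are
    reported with their line numbers.
    """
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "row": str, "role": str, "arm": str},
    )
    if "count" in df.columns and not pd.api.types.is_integer_dtype(df["count"]):
        bad = df[pd.to_numeric(df["count"], errors="coerce").isna()]
        if len(bad):
            raise PlateTableError(
                f"non-numeric counts at lines {[i + 2 for i in bad.index[:5]]}"
            )
        df["count"] = df["count"].astype(float)
        if not (df["count"] == df["count"].round()).all():
            raise PlateTableError("counts must be integers")
        df["count"] = df["count"].astype(int)
    return validate_plate_table(df)


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_plate_table(df)
    df.to_csv(path, index=False)


def write_gene_table(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write per-gene screen summaries (Survival Index, Potentiation, ...).

    Numeric columns are written at six decimals so that a write/read cycle
    is lossless at that precision.  Rank ties are written as computed.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries to write")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    summaries[GENE_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    return df


def read_expression(matrix_path: str | Path, meta_path: str | Path):
    """Read a genes x samples log2 matrix plus its sample metadata.

    The matrix CSV has gene ids in the first column; the metadata CSV has
    columns ``sample,arm,timepoint,replicate`` with samples matching the
    matrix columns.
    """
    matrix = pd.read_csv(matrix_path, index_col=0)
    meta = pd.read_csv(meta_path, dtype={"sample": str, "arm": str, "timepoint": str})
    if matrix.index.hasnans or matrix.index.duplicated().any():
        raise ValueError("expression matrix gene ids must be unique and non-missing")
    extra = set(meta["sample"]) ^ set(matrix.columns)
    if extra:
        raise ValueError(f"matrix columns and metadata samples disagree: {sorted(extra)}")
    meta = meta.set_index("sample").loc[list(matrix.columns)].reset_index()
    return matrix, meta


def write_expression(matrix: pd.DataFrame, meta: pd.DataFrame,
                     matrix_path: str | Path, meta_path: str | Path) -> None:
    matrix.to_csv(matrix_path, float_format="%.6f")
    meta.to_csv(meta_path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table with columns ``sample,gene,ct``."""
    df = pd.read_csv(path, dtype={"sample": str, "gene": str})
    for col in ("sample", "gene", "ct"):
        if col not in df.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def read_growth_curves(path: str | Path) -> pd.DataFrame:
    """Read OD600 growth curves in long form.

    Columns: ``strain,condition,replicate,time_h,od600``.  The time grid
    must be uniform within each (strain, condition, replicate) curve.
    """
    df = pd.read_csv(path, dtype={"strain": str, "condition": str})
    for col in ("strain", "condition", "replicate", "time_h", "od600"):
        if col not in df.columns:
            raise ValueError(f"growth table missing column {col!r}")
    if (df["od600"] < 0).any():
        raise ValueError("OD600 readings must be non-negative")
    return df


def write_growth_curves(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
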