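"""Reading and writing per-cell quantification tables and dataset manifests.

The per-cell table dialect mirrors the deposited lineage-analysis format:
delimited text in which, by default (1-based), column 1 holds the Sulston
cell name, column 3 the birth time in minutes post first cleavage, and
column 7 the "blot" — mean background-subtracted nuclear intensity over the
cell's lifetime.  Remaining columns are undocumented in the deposit, so
every index is configurable and extra columns are tolerated.  Negative blot
values are legal (nuclear intensity minus local background) and preserved.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from wntlineage.lineage_model import (
    CellRecord,
    LineageTree,
    NameError_,
    build_tree,
    parse_name,
)

__all__ = [
    "TableDialect",
    "EmbryoManifest",
    "FormatError",
    "read_cell_table",
    "write_cell_table",
    "read_manifest",
    "write_manifest",
    "load_dataset",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed table or manifest."""


@dataclass(frozen=True)
class TableDialect:
    """Column layout of a per-cell table.  Indices are 1-based to match the
    deposit's description ('birth time is in column 3 ... blot in column 7')."""

    delimiter: str = ","
    name_col: int = 1
    birth_col: int = 3
    end_col: int = 4
    blot_col: int = 7
    total_col: Optional[int] = None
    has_header: bool = False
    n_columns: int = 7
    on_bad_name: str = "skip"  # or "raise"


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class EmbryoManifest:
    """One embryo's metadata row: id, data file, strain, reporter, condition."""

    embryo_id: str
    path: str
    strain: str = ""
    reporter: str = ""
    condition: str = "wild type"
    replicate_group: str = ""


def _get(row: list[str], col: Optional[int]) -> Optional[str]:
    if col is None or col > len(row):
        return None
    v = row[col - 1].strip()
    return v or None


def read_cell_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[CellRecord]:
    """Read one embryo's per-cell table.

    Rows whose cell name fails validation are skipped with a log entry (or
    raise, per ``dialect.on_bad_name``).  A missing mandatory column raises
    :class:`FormatError` with the row number.  An empty file yields an empty
    list with a warning.
    """
    records: list[CellRecord] = []
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for i, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if i == 1 and dialect.has_header:
                continue
            name_txt = _get(row, dialect.name_col)
            if name_txt is None:
                raise FormatError(f"{path}: row {i}: missing cell-name column")
            try:
                cell = parse_name(name_txt)
            except NameError_ as exc:
                if dialect.on_bad_name == "raise":
                    raise FormatError(f"{path}: row {i}: {exc}") from exc
                logger.warning("%s: row %d skipped: %s", path, i, exc)
                continue
            birth = _get(row, dialect.birth_col)
            blot = _get(row, dialect.blot_col)
            if birth is None or blot is None:
                raise FormatError(
                    f"{path}: row {i}: missing birth-time or blot column"
                )
            end = _get(row, dialect.end_col)
            total = _get(row, dialect.total_col)
            records.append(
                CellRecord(
                    cell=cell,
                    birth_time=float(birth),
                    end_time=float(end) if end is not None else float("nan"),
                    blot=float(blot),
                    total=float(total) if total is not None else None,
                )
            )
    if not records:
        logger.warning("%s: no records read", path)
    return records


def write_cell_table(
    records: Iterable[CellRecord],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write records in the dialect's column layout, sorted by cell name.

    Output is bit-stable for a fixed dialect.  Optional fields that are
    absent are written as empty cells, never as zeros.
    """
    ncol = max(
        dialect.n_columns,
        dialect.name_col,
        dialect.birth_col,
        dialect.end_col,
        dialect.blot_col,
        dialect.total_col or 0,
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        for rec in sorted(records, key=lambda r: r.cell):
            row = [""] * ncol
            row[dialect.name_col - 1] = str(rec.cell)
            row[dialect.birth_col - 1] = repr(rec.birth_time)
            if rec.end_time == rec.end_time:  # not NaN
                row[dialect.end_col - 1] = repr(rec.end_time)
            row[dialect.blot_col - 1] = repr(rec.blot)
            if dialect.total_col is not None and rec.total is not None:
                row[dialect.total_col - 1] = repr(rec.total)
            writer.writerow(row)


_MANIFEST_COLS = ["id", "path", "strain", "reporter", "condition", "replicate_group"]


def read_manifest(path: str | Path) -> list[EmbryoManifest]:
    """Read a dataset manifest (delimited text with header)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in ("id", "path") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest lacks column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            EmbryoManifest(
                embryo_id=row["id"],
                path=row["path"],
                strain=row.get("strain", ""),
                reporter=row.get("reporter", ""),
                condition=row.get("condition", "") or "wild type",
                replicate_group=row.get("replicate_group", ""),
            )
        )
    ids = [m.embryo_id for m in out]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate embryo ids in manifest")
    return out


def write_manifest(manifests: Iterable[EmbryoManifest], path: str | Path) -> None:
    rows = [
        [m.embryo_id, m.path, m.strain, m.reporter, m.condition, m.replicate_group]
        for m in manifests
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, index=False)


def load_dataset(
    manifest_path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> dict[tuple[str, str], list[LineageTree]]:
    """Load every embryo in a manifest, grouped by (reporter, condition).

    Relative data paths resolve against the manifest's directory.  Dangling
    file references raise with the full list of missing files.
    """
    manifest_path = Path(manifest_path)
    manifests = read_manifest(manifest_path)
    missing = []
    for m in manifests:
        p = Path(m.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            missing.append(str(p))
    if missing:
        raise FormatError(f"manifest references missing files: {missing}")

    groups: dict[tuple[str, str], list[LineageTree]] = {}
    for m in manifests:
        p = Path(m.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        tree = build_tree(
            read_cell_table(p, dialect),
            embryo_id=m.embryo_id,
            reporter=m.reporter,
            condition=m.condition,
        )
        groups.setdefault((m.reporter, m.condition), []).append(tree)
    for key, trees in groups.items():
        logger.info("group %s: %d embryos", key, len(trees))
    return groups
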