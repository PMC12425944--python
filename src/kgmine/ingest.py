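"""Read heterogeneous supplementary tables into a uniform typed frame.

Supplementary tables arrive as CSV, TSV, or XLSX with wildly inconsistent
conventions (log-transformed p-values, taxon labels embedded in composite
strings, assorted null tokens). This module only solves the *reading*
problem: everything becomes a :class:`SupplementaryTable` whose cells are
text, float, bool, or ``None``, with explicit provenance. Interpretation of
the contents is the transform engine's job.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NA_TOKENS = frozenset({"", "NA", "NaN", "null"})

#: fraction of parseable non-null cells required to coerce a column to number
NUMERIC_COERCION_THRESHOLD = 0.95

Cell = Optional[object]  # str | float | bool | None


class IngestConfigError(ValueError):
    """Configuration problem: bad sheet name, header row out of range, ..."""


@dataclass
class SupplementaryTable:
    """A typed tabular frame with caption and provenance.

    ``frame`` holds object-dtype cells restricted to str, float, bool, or
    ``None``. Column names are unique (duplicates deduplicated with ``.1``,
    ``.2``, ... suffixes).
    """

    table_id: str
    publication_id: str
    caption: str
    frame: pd.DataFrame = field(repr=False)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_rows(self) -> int:
        return int(self.frame.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.frame.shape[1])

    def validate(self) -> None:
        if self.n_cols < 1:
            raise ValueError("table must have at least one column")
        if len(set(self.columns)) != self.n_cols:
            raise ValueError("column names must be unique")

    def copy_with(self, frame: pd.DataFrame) -> "SupplementaryTable":
        return SupplementaryTable(
            table_id=self.table_id,
            publication_id=self.publication_id,
            caption=self.caption,
            frame=frame,
        )

    def to_csv(self, path: str | Path) -> None:
        """Write cells back to RFC-4180 CSV; None becomes the empty field."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(self.columns)
            for _, row in self.frame.iterrows():
                writer.writerow(["" if v is None else _cell_str(v) for v in row])


def _cell_str(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _dedupe_columns(names: Sequence[str]) -> list[str]:
    seen: dict[str, int] = {}
    out: list[str] = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def _parse_cell(raw: Any, na_tokens: frozenset[str]) -> Cell:
    """Type a single cell: boolean > number > text, NA tokens to None."""
    if raw is None:
        return None
    if isinstance(raw, bool):
        return raw
    if isinstance(raw, (int, float)):
        if isinstance(raw, float) and math.isnan(raw):
            return None
        return float(raw)
    text = str(raw).strip()
    if text in na_tokens:
        return None
    low = text.lower()
    if low == "true":
        return True
    if low == "false":
        return False
    return text


def _try_float(v: Cell) -> Optional[float]:
    if isinstance(v, bool):
        return None
    if isinstance(v, float):
        return v
    if isinstance(v, str):
        try:
            return float(v)
        except ValueError:
            return None
    return None


def _coerce_numeric_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Coerce columns where >=95% of non-null cells parse as numbers."""
    for col in frame.columns:
        cells = [v for v in frame[col] if v is not None]
        if not cells:
            continue
        parsed = [_try_float(v) for v in cells]
        ok = sum(1 for p in parsed if p is not None)
        if ok / len(cells) >= NUMERIC_COERCION_THRESHOLD:
            # object dtype keeps None as None (float64 would coerce to NaN)
            frame[col] = pd.Series(
                [_try_float(v) if v is not None else None for v in frame[col]],
                index=frame.index, dtype=object,
            )
    return frame


def _rows_to_table(
    raw_rows: list[list[Any]],
    header_row: int,
    na_tokens: frozenset[str],
    table_id: str,
    publication_id: str,
    caption: str,
) -> SupplementaryTable:
    if header_row >= len(raw_rows):
        raise IngestConfigError(
            f"header_row {header_row} out of range for file with "
            f"{len(raw_rows)} rows"
        )
    header = [str(h) if h is not None else "" for h in raw_rows[header_row]]
    columns = _dedupe_columns(header)
    n_cols = len(columns)
    if n_cols < 1:
        raise IngestConfigError("no columns found in header row")

    body: list[list[Cell]] = []
    ragged = 0
    for raw in raw_rows[header_row + 1 :]:
        cells = [_parse_cell(v, na_tokens) for v in raw]
        if len(cells) != n_cols:
            ragged += 1
            cells = (cells + [None] * n_cols)[:n_cols]
        body.append(cells)
    if ragged:
        logger.warning(
            "%s: %d ragged row(s) padded/truncated to %d columns",
            table_id, ragged, n_cols,
        )

    frame = pd.DataFrame(body, columns=columns, dtype=object)
    frame = _coerce_numeric_columns(frame)
    table = SupplementaryTable(
        table_id=table_id,
        publication_id=publication_id,
        caption=caption,
        frame=frame,
    )
    table.validate()
    return table


def read_table(
    path: str | Path,
    format: str | None = None,
    sheet: str | int | None = None,
    header_row: int = 0,
    na_tokens: Sequence[str] | frozenset[str] = DEFAULT_NA_TOKENS,
    table_id: str | None = None,
    publication_id: str = "",
    caption: str = "",
) -> SupplementaryTable:
    """Read a CSV/TSV/XLSX file into a :class:`SupplementaryTable`.

    Parameters
    ----------
    path
        Input file. Must exist and parse in the declared format.
    format
        One of ``csv``, ``tsv``, ``xlsx``; inferred from the suffix when
        omitted. Header detection is never sniffed — ``header_row`` is
        explicit (default 0), because supplementary tables are too
        heterogeneous for reliable inference.
    sheet
        XLSX sheet name or index (default: first sheet). Absent sheet is a
        configuration failure.
    na_tokens
        Cell strings treated as null (default ``{"", "NA", "NaN", "null"}``).

    Encoding is UTF-8 with BOM tolerance. Ragged rows are padded with nulls
    (with a logged warning), never an error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    tokens = frozenset(na_tokens)
    tid = table_id or path.stem

    if fmt in ("csv", "tsv"):
        delim = "," if fmt == "csv" else "\t"
        with open(path, "r", encoding="utf-8-sig", newline="") as fh:
            reader = csv.reader(fh, delimiter=delim)
            raw_rows = [row for row in reader]
    elif fmt == "xlsx":
        try:
            df = pd.read_excel(
                path, sheet_name=0 if sheet is None else sheet, header=None,
                dtype=object, engine="openpyxl",
            )
        except ValueError as exc:  # openpyxl signals missing sheet this way
            raise IngestConfigError(f"sheet {sheet!r} not found in {path}") from exc
        raw_rows = [
            [None if (isinstance(v, float) and math.isnan(v)) else v for v in row]
            for row in df.itertuples(index=False, name=None)
        ]
        raw_rows = [list(r) for r in raw_rows]
    else:
        raise IngestConfigError(f"unknown table format: {fmt!r}")

    return _rows_to_table(raw_rows, header_row, tokens, tid, publication_id, caption)


def read_table_string(
    text: str,
    format: str = "csv",
    header_row: int = 0,
    na_tokens: Sequence[str] | frozenset[str] = DEFAULT_NA_TOKENS,
    table_id: str = "inline",
    publication_id: str = "",
    caption: str = "",
) -> SupplementaryTable:
    """Parse CSV/TSV content from a string (fixtures, tests)."""
    delim = "," if format == "csv" else "\t"
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    raw_rows = [row for row in reader]
    return _rows_to_table(
        raw_rows, header_row, frozenset(na_tokens), table_id, publication_id, caption
    )
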