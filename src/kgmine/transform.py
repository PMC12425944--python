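"""Declarative table-to-assertion transformation engine.

Each supplementary table is paired with one human-curated configuration
(serialized as YAML) that specifies, in order, the value transformations
(exponentiating log p-values, regex extraction, text cleaning, unary
arithmetic) and row operations (filters, duplicate/null drops, cutoffs)
needed to turn its rows into subject–predicate–object knowledge assertions.
Running a config is entirely automated and deterministic: the only human
judgement lives in the config itself.

Ops execute in exactly the declared order — value ops and row ops share one
ordered list; the partition in a YAML file is purely for readability. The
final step is always the p-value cutoff (default 0.1, keeping significant
and merely suggestive assertions alike), applied to the adjusted p-value
when one is mapped, else to the raw p-value.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .ingest import SupplementaryTable

logger = logging.getLogger(__name__)

ATTRIBUTE_KEYS = (
    "p_value",
    "adjusted_p",
    "correction_method",
    "effect_size",
    "effect_metric",
    "sample_size",
    "statistical_test",
    "nlp_type",
    "notes",
)


class ConfigError(ValueError):
    """The config references missing columns, bad predicates, etc."""


# ---------------------------------------------------------------------------
# Config model


class ValueOp(BaseModel):
    """One transformation of a single column's cells into an output column."""

    kind: Literal["exponentiate", "negate", "regex_extract", "text_clean", "arithmetic"]
    input_column: str
    output_column: str
    base: Union[float, Literal["e"]] = 10  # exponentiate
    pattern: str = ""  # regex_extract
    group: int = 1
    rules: list[str] = Field(  # text_clean
        default_factory=lambda: ["underscore_to_space", "collapse_whitespace", "lowercase"]
    )
    expr: str = ""  # arithmetic, unary in x

    @field_validator("pattern")
    @classmethod
    def _pattern_compiles(cls, v: str) -> str:
        if v:
            re.compile(v)
        return v

    @field_validator("base")
    @classmethod
    def _base_positive(cls, v):
        if v != "e" and float(v) <= 0:
            raise ValueError("exponentiate base must be > 0")
        return v


class RowOp(BaseModel):
    """One row-removing operation; survivors keep their order."""

    kind: Literal["filter", "drop_duplicates", "drop_nulls", "cutoff"]
    column: str = ""
    comparator: Literal["<", "<=", ">", ">=", "=", "!=", "is_true", "is_false"] = "<"
    threshold: Optional[Union[float, str, bool]] = None
    subset: list[str] = Field(default_factory=list)
    max: Optional[float] = None  # cutoff


AnyOp = Union[ValueOp, RowOp]


class RoleMap(BaseModel):
    subject: str  # column name, or "const:<label>"
    object: str
    predicate: str
    subject_category: str
    object_category: str


class TableLocator(BaseModel):
    path: str = ""
    format: Literal["csv", "tsv", "xlsx"] = "tsv"
    sheet: Optional[Union[str, int]] = None
    header_row: int = 0


class TransformConfig(BaseModel):
    """The declarative recipe pairing one supplementary table to assertions."""

    table_locator: TableLocator = Field(default_factory=TableLocator)
    ops: list[AnyOp] = Field(default_factory=list)
    role_map: RoleMap
    attribute_map: dict[str, str] = Field(default_factory=dict)
    constants: dict[str, Any] = Field(default_factory=dict)
    p_cutoff: float = 0.1

    @field_validator("p_cutoff")
    @classmethod
    def _cutoff_in_range(cls, v: float) -> float:
        if not (0 < v <= 1):
            raise ValueError("p_cutoff must be in (0, 1]")
        return v

    @field_validator("attribute_map")
    @classmethod
    def _known_attributes(cls, v: dict[str, str]) -> dict[str, str]:
        unknown = set(v) - set(ATTRIBUTE_KEYS)
        if unknown:
            raise ValueError(f"unknown attribute_map keys: {sorted(unknown)}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TransformConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Assertions


@dataclass
class Assertion:
    """A subject–predicate–object statement with statistical attributes."""

    subject_label: str
    object_label: str
    predicate: str
    subject_category: str
    object_category: str
    attributes: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.subject_label or not self.object_label:
            raise ValueError("subject and object labels must be non-empty")
        for key in ("p_value", "adjusted_p"):
            v = self.attributes.get(key)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{key}={v} outside (0, 1]")


@dataclass
class DropLedger:
    """Per-op audit of how many rows each operation removed, and why."""

    entries: list[dict[str, Any]] = field(default_factory=list)

    def record(self, op: str, rows_in: int, rows_out: int, reason: str) -> None:
        self.entries.append(
            {"op": op, "rows_in": rows_in, "rows_out": rows_out, "reason": reason}
        )

    def total_dropped(self) -> int:
        return sum(e["rows_in"] - e["rows_out"] for e in self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("op\trows_in\trows_out\treason\n")
            for e in self.entries:
                fh.write(f"{e['op']}\t{e['rows_in']}\t{e['rows_out']}\t{e['reason']}\n")


# ---------------------------------------------------------------------------
# Value ops

_CLEAN_RULES = {
    "underscore_to_space": lambda s: s.replace("_", " "),
    "collapse_whitespace": lambda s: re.sub(r"\s+", " ", s).strip(),
    "lowercase": lambda s: s.lower(),
    "strip_rank_prefix": lambda s: re.sub(r"^[a-z]__", "", s),
}

_ARITH_NAMES = {
    "abs": abs, "log": math.log, "log10": math.log10, "log2": math.log2,
    "exp": math.exp, "sqrt": math.sqrt, "min": min, "max": max,
}


def _apply_value_cell(op: ValueOp, cell: Any, warn_count: list[int]) -> Any:
    if cell is None:
        return None
    if op.kind == "exponentiate":
        if not isinstance(cell, (int, float)) or isinstance(cell, bool):
            warn_count[0] += 1
            return None
        base = math.e if op.base == "e" else float(op.base)
        return base ** float(cell)
    if op.kind == "negate":
        if not isinstance(cell, (int, float)) or isinstance(cell, bool):
            warn_count[0] += 1
            return None
        return -float(cell)
    if op.kind == "regex_extract":
        m = re.search(op.pattern, str(cell))
        if m is None:
            return None
        return m.group(op.group)
    if op.kind == "text_clean":
        s = str(cell)
        for rule in op.rules:
            try:
                s = _CLEAN_RULES[rule](s)
            except KeyError:
                raise ConfigError(f"unknown text_clean rule: {rule!r}") from None
        return s
    if op.kind == "arithmetic":
        if not isinstance(cell, (int, float)) or isinstance(cell, bool):
            warn_count[0] += 1
            return None
        env = dict(_ARITH_NAMES)
        env["x"] = float(cell)
        return float(eval(op.expr, {"__builtins__": {}}, env))  # restricted DSL
    raise ConfigError(f"unknown value op kind: {op.kind!r}")


def apply_value_op(table: SupplementaryTable, op: ValueOp) -> SupplementaryTable:
    """Add (or overwrite) ``op.output_column`` with transformed cells.

    Nulls propagate to nulls; a regex that does not match yields null; a
    numeric op applied to a text cell yields null and counts a warning.
    """
    if op.input_column not in table.columns:
        raise ConfigError(f"value op input column {op.input_column!r} not in table")
    warn_count = [0]
    frame = table.frame.copy()
    frame[op.output_column] = pd.Series(
        [_apply_value_cell(op, v, warn_count) for v in frame[op.input_column]],
        index=frame.index, dtype=object,
    )
    if warn_count[0]:
        logger.warning(
            "%s on %r: %d non-numeric cell(s) became null",
            op.kind, op.input_column, warn_count[0],
        )
    return table.copy_with(frame)


# ---------------------------------------------------------------------------
# Row ops

_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}


def apply_row_op(
    table: SupplementaryTable, op: RowOp, ledger: DropLedger | None = None
) -> SupplementaryTable:
    """Remove rows per the op; survivor order is preserved."""
    frame = table.frame
    n_in = len(frame)

    if op.kind == "filter":
        if op.column not in table.columns:
            raise ConfigError(f"filter column {op.column!r} not in table")
        col = frame[op.column]
        if op.comparator in ("is_true", "is_false"):
            want = op.comparator == "is_true"
            mask = [isinstance(v, bool) and v is want for v in col]
        else:
            cmp = _COMPARATORS[op.comparator]
            mask = []
            for v in col:
                if v is None:
                    mask.append(False)
                    continue
                try:
                    mask.append(bool(cmp(v, op.threshold)))
                except TypeError as exc:
                    raise ConfigError(
                        f"filter {op.comparator} on {op.column!r}: incompatible "
                        f"types {type(v).__name__} vs {type(op.threshold).__name__}"
                    ) from exc
        out = frame[mask]
        reason = f"filter {op.column} {op.comparator} {op.threshold}"
    elif op.kind == "cutoff":
        if op.column not in table.columns:
            raise ConfigError(f"cutoff column {op.column!r} not in table")
        mask = []
        for v in frame[op.column]:
            if v is None or isinstance(v, bool) or not isinstance(v, (int, float)):
                mask.append(False)
            else:
                mask.append(v <= op.max)
        out = frame[mask]
        reason = f"cutoff {op.column} <= {op.max}"
    elif op.kind == "drop_duplicates":
        subset = op.subset or list(table.columns)
        missing = [c for c in subset if c not in table.columns]
        if missing:
            raise ConfigError(f"drop_duplicates subset not in table: {missing}")
        seen: set[tuple] = set()
        mask = []
        for _, row in frame.iterrows():
            key = tuple(row[c] for c in subset)
            if key in seen:
                mask.append(False)
            else:
                seen.add(key)
                mask.append(True)
        out = frame[mask]
        reason = f"drop_duplicates {subset}"
    elif op.kind == "drop_nulls":
        subset = op.subset or list(table.columns)
        missing = [c for c in subset if c not in table.columns]
        if missing:
            raise ConfigError(f"drop_nulls subset not in table: {missing}")
        mask = [
            all(row[c] is not None for c in subset) for _, row in frame.iterrows()
        ]
        out = frame[mask]
        reason = f"drop_nulls {subset}"
    else:
        raise ConfigError(f"unknown row op kind: {op.kind!r}")

    out = out.reset_index(drop=True)
    if ledger is not None:
        ledger.record(op.kind, n_in, len(out), reason)
    return table.copy_with(out)


# ---------------------------------------------------------------------------
# Config runner


def _resolve_role(row, spec: str) -> str:
    if spec.startswith("const:"):
        return spec[len("const:"):]
    v = row[spec]
    return "" if v is None else str(v)


def run_config(
    table: SupplementaryTable,
    config: TransformConfig,
    registry=None,
    ledger: DropLedger | None = None,
) -> list[Assertion]:
    """Run a full config over a table and return one assertion per survivor.

    The registry (a :class:`kgmine.graph.PredicateRegistry`) is consulted, when
    given, to reject configs whose predicate is unknown. The governing-p
    cutoff is always the final operation; rows whose governing p-value is
    null survive it (tables with no mapped p column are legitimate).
    """
    if registry is not None and config.role_map.predicate not in registry:
        raise ConfigError(
            f"predicate {config.role_map.predicate!r} not in registry"
        )
    ledger = ledger if ledger is not None else DropLedger()

    for op in config.ops:
        if isinstance(op, ValueOp):
            table = apply_value_op(table, op)
        else:
            table = apply_row_op(table, op, ledger)

    # Governing p-value filter, strict <, applied last.
    p_col = config.attribute_map.get("adjusted_p") or config.attribute_map.get("p_value")
    if p_col is not None:
        if p_col not in table.columns:
            raise ConfigError(f"attribute_map p column {p_col!r} not in table")
        n_in = table.n_rows
        mask = [
            v is not None and isinstance(v, (int, float)) and v < config.p_cutoff
            for v in table.frame[p_col]
        ]
        table = table.copy_with(table.frame[mask].reset_index(drop=True))
        ledger.record("p_cutoff", n_in, table.n_rows, f"{p_col} < {config.p_cutoff}")

    role = config.role_map
    assertions: list[Assertion] = []
    for _, row in table.frame.iterrows():
        attrs: dict[str, Any] = {}
        for attr, col in config.attribute_map.items():
            if col not in table.columns:
                raise ConfigError(f"attribute_map column {col!r} not in table")
            v = row[col]
            if v is not None:
                if attr == "sample_size":
                    v = int(v)
                attrs[attr] = v
        for key, v in config.constants.items():
            if key in ("publication_id", "table_id"):
                continue
            attrs.setdefault(key, v)
        if table.caption:
            attrs.setdefault("caption", table.caption)
        a = Assertion(
            subject_label=_resolve_role(row, role.subject),
            object_label=_resolve_role(row, role.object),
            predicate=role.predicate,
            subject_category=role.subject_category,
            object_category=role.object_category,
            attributes=attrs,
            provenance={
                "publication_id": config.constants.get(
                    "publication_id", table.publication_id
                ),
                "table_id": table.table_id,
            },
        )
        a.validate()
        assertions.append(a)

    if not assertions:
        logger.warning("%s: config produced zero assertions", table.table_id)
    return assertions


def flag_significance(attributes: dict[str, Any], alpha: float = 0.05) -> Optional[bool]:
    """True iff the governing p-value (adjusted when present) is < alpha.

    The strict inequality separates significant from merely suggestive
    assertions (an adjusted p of exactly 0.05 is not significant). Returns
    None when neither p field is present — unknown, never a crash.
    """
    p = attributes.get("adjusted_p")
    if p is None:
        p = attributes.get("p_value")
    if p is None:
        return None
    return bool(p < alpha)
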