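"""End-to-end orchestration: configs + tables + resolver -> scored KGX graph."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Iterable, Sequence

from .graph import KnowledgeGraph, PredicateRegistry, Resolver, normalize_assertions
from .ingest import read_table
from .transform import Assertion, DropLedger, TransformConfig, run_config


def build_assertions(
    config_paths: Sequence[str | Path],
    registry: PredicateRegistry | None = None,
    ledger: DropLedger | None = None,
) -> list[Assertion]:
    """Run every config over its table (per its locator) and pool assertions."""
    registry = registry or PredicateRegistry()
    assertions: list[Assertion] = []
    for cpath in sorted(str(p) for p in config_paths):
        config = TransformConfig.from_yaml(cpath)
        loc = config.table_locator
        table = read_table(
            loc.path,
            format=loc.format,
            sheet=loc.sheet,
            header_row=loc.header_row,
            table_id=Path(loc.path).stem,
            publication_id=config.constants.get("publication_id", ""),
            caption=str(config.constants.get("caption", "")),
        )
        assertions.extend(run_config(table, config, registry=registry, ledger=ledger))
    return assertions


def build_graph(
    config_paths: Sequence[str | Path],
    resolver_path: str | Path,
    registry: PredicateRegistry | None = None,
    ledger: DropLedger | None = None,
) -> tuple[KnowledgeGraph, list[dict[str, str]]]:
    """Full build: mine assertions, normalize to CURIEs, drop-on-failure."""
    registry = registry or PredicateRegistry()
    assertions = build_assertions(config_paths, registry, ledger)
    resolver = Resolver.from_tsv(resolver_path)
    return normalize_assertions(assertions, resolver)
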