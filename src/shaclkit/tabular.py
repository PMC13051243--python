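"""Tabularization of violating focus nodes.

The instance data is filtered to violating focus nodes and joined with the
report: rows are focus-node subjects, columns are predicates, cells hold the
(possibly multiple) object values, and one boolean indicator column per
violated property shape is appended.  Grouping rows by their indicator
pattern recovers the same partition as the violation-pattern analysis, which
is the cross-view consistency the whole workflow relies on.

Graph data tabularizes raggedly — many predicates do not apply to many
subjects — so blank cells and wide tables are accepted as-is, and columns
can be projected away instead.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from rdflib.namespace import RDF, XSD

from .kg_io import KGBundle, NamespaceTable, Term, term_text
from .report_model import ViolationRecord

log = logging.getLogger(__name__)

_RDF_TYPE = str(RDF.type)
_TYPE_COLUMN = "rdf:type"

_NUMERIC_DATATYPES = {
    str(XSD.integer), str(XSD.decimal), str(XSD.double), str(XSD.float),
    str(XSD.int), str(XSD.long), str(XSD.short), str(XSD.byte),
    str(XSD.nonNegativeInteger), str(XSD.positiveInteger),
}

#: Histograms keep at most this many distinct values; the rest go to "other".
HISTOGRAM_CAP = 50


@dataclass
class FocusTable:
    rows: list[str]
    data_columns: list[str]
    indicator_columns: list[str]
    cells: dict[tuple[str, str], frozenset[Term]]
    indicators: dict[tuple[str, str], bool]
    column_kinds: dict[str, str] = field(default_factory=dict)
    namespaces: NamespaceTable = field(default_factory=NamespaceTable)

    def cell(self, row: str, column: str) -> frozenset[Term]:
        return self.cells.get((row, column), frozenset())

    def cell_texts(self, row: str, column: str) -> tuple[str, ...]:
        return tuple(sorted(term_text(t, self.namespaces) for t in self.cell(row, column)))

    def indicator(self, row: str, column: str) -> bool:
        return self.indicators.get((row, column), False)

    def row_pattern(self, row: str) -> frozenset[str]:
        return frozenset(c for c in self.indicator_columns if self.indicator(row, c))


@dataclass(frozen=True)
class RowGroup:
    pattern: frozenset[str]
    rows: tuple[str, ...]
    summaries: Mapping[str, Mapping[str, int]]

    @property
    def size(self) -> int:
        return len(self.rows)


def build_focus_table(bundle: KGBundle, records: Sequence[ViolationRecord]) -> FocusTable:
    """Join instance data of violating focus nodes with their violations.

    Data columns are the predicates that have at least one violating focus
    node as subject (``rdf:type`` always included — it drives class-level
    diagnosis); indicator columns are the distinct violated source shapes.
    """
    ns = bundle.namespaces
    focus_ids = sorted({term_text(r.focus_node, ns) for r in records})
    focus_set = set(focus_ids)

    cells: dict[tuple[str, str], set[Term]] = {}
    predicates: set[str] = set()
    for t in bundle.instances:
        subject_id = term_text(t.subject, ns)
        if subject_id not in focus_set:
            continue
        column = ns.compact(t.predicate.value)
        predicates.add(column)
        cells.setdefault((subject_id, column), set()).add(t.object)
    predicates.add(_TYPE_COLUMN)

    indicator_columns = sorted({term_text(r.source_shape, ns) for r in records})
    indicators: dict[tuple[str, str], bool] = {}
    for r in records:
        indicators[(term_text(r.focus_node, ns), term_text(r.source_shape, ns))] = True

    table = FocusTable(
        rows=focus_ids,
        data_columns=sorted(predicates),
        indicator_columns=indicator_columns,
        cells={k: frozenset(v) for k, v in cells.items()},
        indicators=indicators,
        namespaces=ns,
    )
    return infer_column_kinds(table)


def _is_numeric_literal(term: Term) -> bool:
    if not term.is_literal:
        return False
    if term.datatype in _NUMERIC_DATATYPES:
        return True
    if term.datatype is None and term.language is None:
        try:
            float(term.value)
            return True
        except ValueError:
            return False
    return False


def infer_column_kinds(table: FocusTable) -> FocusTable:
    """Classify columns: boolean (indicators), set (any multi-valued cell),
    numeric (every non-empty cell a single numeric literal), else categorical."""
    kinds: dict[str, str] = {c: "boolean" for c in table.indicator_columns}
    for column in table.data_columns:
        non_empty = [table.cell(row, column) for row in table.rows if table.cell(row, column)]
        if any(len(values) >= 2 for values in non_empty):
            kinds[column] = "set"
        elif non_empty and all(
            _is_numeric_literal(next(iter(values))) for values in non_empty
        ):
            kinds[column] = "numeric"
        else:
            kinds[column] = "categorical"
    table.column_kinds = kinds
    return table


def _histogram(values: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    if len(counts) <= HISTOGRAM_CAP:
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = dict(ranked[:HISTOGRAM_CAP])
    kept["other"] = sum(c for _, c in ranked[HISTOGRAM_CAP:])
    return kept


def group_rows_by_violations(table: FocusTable) -> list[RowGroup]:
    """Partition rows by their violated-constraint indicator pattern, largest
    group first, with per-column value histograms for each group."""
    buckets: dict[frozenset[str], list[str]] = {}
    for row in table.rows:
        buckets.setdefault(table.row_pattern(row), []).append(row)

    groups = []
    for pattern, rows in buckets.items():
        summaries = {}
        for column in table.data_columns:
            values = [v for row in rows for v in table.cell_texts(row, column)]
            summaries[column] = _histogram(values)
        groups.append(RowGroup(pattern=pattern, rows=tuple(sorted(rows)), summaries=summaries))
    groups.sort(key=lambda g: (-g.size, tuple(sorted(g.pattern))))
    return groups


def project_columns(table: FocusTable, hidden: Iterable[str]) -> FocusTable:
    """Drop the given columns; rows are unchanged.  Hiding an indicator
    column is allowed (patterns are then over the remaining indicators) but
    warned about, since it changes the row-group partition."""
    hidden = set(hidden)
    unknown = hidden - set(table.data_columns) - set(table.indicator_columns)
    if unknown:
        raise KeyError(f"unknown columns: {sorted(unknown)}")
    hidden_indicators = hidden & set(table.indicator_columns)
    for column in sorted(hidden_indicators):
        log.warning("hiding indicator column %r; violation patterns will be "
                    "recomputed over the remaining indicators", column)
    data_columns = [c for c in table.data_columns if c not in hidden]
    indicator_columns = [c for c in table.indicator_columns if c not in hidden]
    projected = FocusTable(
        rows=list(table.rows),
        data_columns=data_columns,
        indicator_columns=indicator_columns,
        cells={k: v for k, v in table.cells.items() if k[1] not in hidden},
        indicators={k: v for k, v in table.indicators.items() if k[1] not in hidden},
        namespaces=table.namespaces,
    )
    return infer_column_kinds(projected)


# --- CSV / JSON export ----------------------------------------------------

def to_dataframe(table: FocusTable) -> pd.DataFrame:
    """One row per focus node; multi-valued cells as sorted |-joined text."""
    data = {"focus_node": table.rows}
    for column in table.data_columns:
        data[column] = ["|".join(table.cell_texts(row, column)) for row in table.rows]
    for column in table.indicator_columns:
        data[column] = [table.indicator(row, column) for row in table.rows]
    return pd.DataFrame(data)


def to_csv(table: FocusTable, path: str | Path) -> None:
    to_dataframe(table).to_csv(path, index=False, encoding="utf-8")


def _parse_cell_token(token: str, ns: NamespaceTable) -> Term:
    if token.startswith("_:"):
        return Term("blank", token[2:])
    if token.startswith('"'):
        body, _, suffix = token[1:].rpartition('"')
        if suffix.startswith("@"):
            return Term("literal", body, language=suffix[1:])
        if suffix.startswith("^^"):
            dt = suffix[2:]
            if ":" in dt and "://" not in dt:
                prefix, local = dt.split(":", 1)
                dt = ns.get(prefix, prefix + ":") + local
            return Term("literal", body, datatype=dt)
        return Term("literal", body)
    if "://" in token:
        return Term("iri", token)
    if ":" in token:
        prefix, local = token.split(":", 1)
        if prefix in ns:
            return Term("iri", ns[prefix] + local)
    return Term("literal", token)


def from_csv(
    path: str | Path,
    indicator_columns: Sequence[str],
    ns: Optional[NamespaceTable] = None,
) -> FocusTable:
    """Re-import a CSV export.  The caller names the indicator columns (CSV
    carries no kind metadata); cell texts round-trip exactly."""
    ns = ns or NamespaceTable()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = list(frame["focus_node"])
    indicator_columns = list(indicator_columns)
    data_columns = [c for c in frame.columns if c != "focus_node" and c not in indicator_columns]

    cells: dict[tuple[str, str], frozenset[Term]] = {}
    indicators: dict[tuple[str, str], bool] = {}
    for _, record in frame.iterrows():
        row = record["focus_node"]
        for column in data_columns:
            text = record[column]
            if text:
                cells[(row, column)] = frozenset(
                    _parse_cell_token(tok, ns) for tok in text.split("|")
                )
        for column in indicator_columns:
            if record[column] == "True":
                indicators[(row, column)] = True
    table = FocusTable(
        rows=rows,
        data_columns=data_columns,
        indicator_columns=indicator_columns,
        cells=cells,
        indicators=indicators,
        namespaces=ns,
    )
    return infer_column_kinds(table)


def table_to_json(table: FocusTable, groups: Optional[Sequence[RowGroup]] = None) -> str:
    payload: dict = {
        "rows": table.rows,
        "data_columns": table.data_columns,
        "indicator_columns": table.indicator_columns,
        "column_kinds": table.column_kinds,
        "cells": {
            row: {
                column: list(table.cell_texts(row, column))
                for column in table.data_columns
                if table.cell(row, column)
            }
            for row in table.rows
        },
        "indicators": {
            row: [c for c in table.indicator_columns if table.indicator(row, c)]
            for row in table.rows
        },
    }
    if groups is not None:
        payload["row_groups"] = [
            {
                "pattern": sorted(g.pattern),
                "size": g.size,
                "rows": list(g.rows),
                "summaries": {c: dict(h) for c, h in g.summaries.items()},
            }
            for g in groups
        ]
    return json.dumps(payload, indent=2, ensure_ascii=False)
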