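"""Flatten a SHACL validation-report graph into violation records.

The W3C report vocabulary (``sh:ValidationReport`` / ``sh:result``) is read
into one :class:`ViolationRecord` per top-level result.  Records are the unit
every downstream structure (groups, counts, tables, feature vectors) is built
from, so their ordering is made deterministic here once and for all.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdflib.namespace import RDF, SH

from .kg_io import KGBundle, NamespaceTable, Term, Triple, term_text

log = logging.getLogger(__name__)

SH_VIOLATION = str(SH.Violation)

_P_CONFORMS = str(SH.conforms)
_P_RESULT = str(SH.result)
_P_FOCUS = str(SH.focusNode)
_P_PATH = str(SH.resultPath)
_P_VALUE = str(SH.value)
_P_SOURCE_SHAPE = str(SH.sourceShape)
_P_COMPONENT = str(SH.sourceConstraintComponent)
_P_MESSAGE = str(SH.resultMessage)
_P_SEVERITY = str(SH.resultSeverity)
_P_DETAIL = str(SH.detail)
_T_REPORT = str(SH.ValidationReport)


@dataclass(frozen=True)
class ViolationRecord:
    """One parsed ``sh:result``: who violated what, where, and with what value."""

    focus_node: Term
    source_shape: Term
    result_path: Optional[Term] = None
    value: Optional[Term] = None
    message: str = ""
    severity: str = SH_VIOLATION
    constraint_component: Optional[str] = None


@dataclass(frozen=True)
class ReportSummary:
    n_records: int
    n_focus_nodes: int
    n_constraints: int
    conforms: bool


def _index(triples: Iterable[Triple]) -> dict[Term, dict[str, list[Term]]]:
    """subject → predicate-IRI → objects."""
    idx: dict[Term, dict[str, list[Term]]] = {}
    for t in triples:
        idx.setdefault(t.subject, {}).setdefault(t.predicate.value, []).append(t.object)
    return idx


def _pick_message(objects: Sequence[Term]) -> str:
    """Choose one message deterministically from possibly multilingual values:
    the lexicographically first (language-tag, text) pair."""
    if not objects:
        return ""
    ranked = sorted((o.language or "", o.value) for o in objects)
    return ranked[0][1]


def parse_report(report: Iterable[Triple], namespaces: NamespaceTable) -> list[ViolationRecord]:
    """Parse report triples into a deterministically ordered record list.

    Only top-level results become records; nested ``sh:detail`` messages are
    appended to the owning record's message as opaque text.  A result node
    without ``sh:focusNode`` is skipped with a warning.  A graph holding
    result nodes but no ``sh:ValidationReport`` subject is still parsed, with
    a warning about the malformed envelope.
    """
    triples = list(report)
    idx = _index(triples)

    report_nodes = [s for s, po in idx.items() if any(
        o.value == _T_REPORT for o in po.get(str(RDF.type), [])
    )]
    if len(report_nodes) > 1:
        raise ValueError("report graph contains more than one sh:ValidationReport node")

    if report_nodes:
        result_nodes = list(idx.get(report_nodes[0], {}).get(_P_RESULT, []))
    else:
        result_nodes = [s for s, po in idx.items() if _P_FOCUS in po]
        if result_nodes:
            log.warning(
                "report graph has result nodes but no sh:ValidationReport envelope; parsing anyway"
            )

    records: list[ViolationRecord] = []
    for node in result_nodes:
        po = idx.get(node, {})
        focus = po.get(_P_FOCUS)
        if not focus:
            log.warning("skipping sh:result node %s with no sh:focusNode", node)
            continue
        source_shapes = po.get(_P_SOURCE_SHAPE) or [Term("blank", "unknown-shape")]
        message = _pick_message(po.get(_P_MESSAGE, []))
        for detail_node in po.get(_P_DETAIL, []):
            detail_msg = _pick_message(idx.get(detail_node, {}).get(_P_MESSAGE, []))
            if detail_msg:
                message = f"{message} [detail: {detail_msg}]" if message else f"[detail: {detail_msg}]"
        severities = po.get(_P_SEVERITY, [])
        paths = po.get(_P_PATH, [])
        values = po.get(_P_VALUE, [])
        components = po.get(_P_COMPONENT, [])
        records.append(
            ViolationRecord(
                focus_node=focus[0],
                source_shape=source_shapes[0],
                result_path=paths[0] if paths else None,
                value=values[0] if values else None,
                message=message,
                severity=severities[0].value if severities else SH_VIOLATION,
                constraint_component=components[0].value if components else None,
            )
        )

    records.sort(key=lambda r: record_sort_key(r, namespaces))
    return records


def record_sort_key(record: ViolationRecord, ns: NamespaceTable) -> tuple[str, str, str]:
    return (
        term_text(record.focus_node, ns),
        term_text(record.source_shape, ns),
        term_text(record.value, ns) if record.value is not None else "",
    )


def records_from_bundle(bundle: KGBundle) -> list[ViolationRecord]:
    """Convenience: parse the bundle's report component."""
    return parse_report(bundle.report, bundle.namespaces)


def summarize(records: Sequence[ViolationRecord]) -> ReportSummary:
    return ReportSummary(
        n_records=len(records),
        n_focus_nodes=len({r.focus_node for r in records}),
        n_constraints=len({r.source_shape for r in records}),
        conforms=not records,
    )


def records_to_jsonl(records: Sequence[ViolationRecord], ns: NamespaceTable) -> str:
    """One compact JSON object per line, IRIs compacted."""
    lines = []
    for r in records:
        lines.append(json.dumps({
            "focus_node": term_text(r.focus_node, ns),
            "source_shape": term_text(r.source_shape, ns),
            "result_path": term_text(r.result_path, ns) if r.result_path else None,
            "value": term_text(r.value, ns) if r.value else None,
            "message": r.message,
            "severity": ns.compact(r.severity),
            "constraint_component": ns.compact(r.constraint_component) if r.constraint_component else None,
        }, ensure_ascii=False))
    return "\n".join(lines)
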