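"""Equivalence grouping of violations and per-focus-node lookup tables.

Two violations are equivalent when they share the violated (property) shape,
the message, and the reported value; each equivalence class is summarized by
a single exemplar plus a size, which is what makes reports with thousands of
repeated results digestible.  Violations with no reported value (typical for
minimum-count constraints) share a reserved no-value marker so that, e.g.,
every character missing the same required property lands in one group.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .kg_io import KGBundle, NamespaceTable, Term, Triple, term_text
from .report_model import ViolationRecord

#: Reserved grouping token for records that carry no sh:value.
NO_VALUE = "∅"

_RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"

_WS = re.compile(r"\s+")


def normalize_message(message: str) -> str:
    """Collapse whitespace runs and trim, so incidental validator spacing
    never splits a group."""
    return _WS.sub(" ", message).strip()


@dataclass(frozen=True, order=True)
class GroupKey:
    """The equivalence key: (shape, message, value), all as compacted text."""

    source_shape: str
    message: str
    value: str  # compacted term text, or NO_VALUE

    def as_dict(self) -> dict[str, str]:
        return {"shape": self.source_shape, "message": self.message, "value": self.value}


@dataclass(frozen=True)
class ViolationGroup:
    key: GroupKey
    members: tuple[ViolationRecord, ...]
    exemplar: ViolationRecord

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FocusEntry:
    classes: frozenset[str]
    constraints: frozenset[str]
    groups: frozenset[GroupKey]


#: focus-node id (compacted text) → its classes, violated constraints, groups.
FocusIndex = dict[str, FocusEntry]


def record_key(record: ViolationRecord, ns: NamespaceTable) -> GroupKey:
    return GroupKey(
        source_shape=term_text(record.source_shape, ns),
        message=normalize_message(record.message),
        value=term_text(record.value, ns) if record.value is not None else NO_VALUE,
    )


def group_violations(records: Iterable[ViolationRecord], ns: NamespaceTable) -> list[ViolationGroup]:
    """Partition records into equivalence groups.

    Groups are ordered by descending size, ties broken by key; members are
    ordered by focus node; the exemplar is the member with the
    lexicographically smallest compacted focus node.  The result is invariant
    under permutation of the input.
    """
    buckets: dict[GroupKey, list[ViolationRecord]] = {}
    for record in records:
        buckets.setdefault(record_key(record, ns), []).append(record)

    groups = []
    for key, members in buckets.items():
        members.sort(key=lambda r: (term_text(r.focus_node, ns), term_text(r.source_shape, ns)))
        groups.append(ViolationGroup(key=key, members=tuple(members), exemplar=members[0]))
    groups.sort(key=lambda g: (-g.size, g.key))
    return groups


def violation_pattern(
    records: Iterable[ViolationRecord], focus_node: Term | str, ns: NamespaceTable
) -> frozenset[str]:
    """The set of distinct violated source shapes of one focus node."""
    focus_id = focus_node if isinstance(focus_node, str) else term_text(focus_node, ns)
    shapes = {
        term_text(r.source_shape, ns)
        for r in records
        if term_text(r.focus_node, ns) == focus_id
    }
    if not shapes:
        raise KeyError(f"focus node {focus_id!r} has no violation records")
    return frozenset(shapes)


def patterns_by_focus(
    records: Sequence[ViolationRecord], ns: NamespaceTable
) -> dict[str, frozenset[str]]:
    """focus-node id → violated-shape set, for all focus nodes at once."""
    acc: dict[str, set[str]] = {}
    for r in records:
        acc.setdefault(term_text(r.focus_node, ns), set()).add(term_text(r.source_shape, ns))
    return {focus: frozenset(shapes) for focus, shapes in acc.items()}


def distinct_patterns(
    records: Sequence[ViolationRecord], ns: NamespaceTable
) -> frozenset[frozenset[str]]:
    """The distinct violation patterns over all focus nodes; these are the
    cluster identities the 2-D projection is expected to separate."""
    return frozenset(patterns_by_focus(records, ns).values())


def build_focus_index(
    records: Sequence[ViolationRecord],
    groups: Sequence[ViolationGroup],
    instance_triples: Iterable[Triple],
    ns: NamespaceTable,
) -> FocusIndex:
    """Lookup table mapping each violating focus node to its asserted classes
    (direct ``rdf:type`` in the instance data), violated constraints, and
    violation groups."""
    types: dict[str, set[str]] = {}
    for t in instance_triples:
        if t.predicate.value == _RDF_TYPE:
            types.setdefault(term_text(t.subject, ns), set()).add(term_text(t.object, ns))

    constraints: dict[str, set[str]] = {}
    for r in records:
        constraints.setdefault(term_text(r.focus_node, ns), set()).add(
            term_text(r.source_shape, ns)
        )

    group_keys: dict[str, set[GroupKey]] = {}
    for g in groups:
        for member in g.members:
            group_keys.setdefault(term_text(member.focus_node, ns), set()).add(g.key)

    return {
        focus: FocusEntry(
            classes=frozenset(types.get(focus, ())),
            constraints=frozenset(shapes),
            groups=frozenset(group_keys.get(focus, ())),
        )
        for focus, shapes in constraints.items()
    }


def focus_index_for_bundle(bundle: KGBundle, records: Sequence[ViolationRecord]) -> FocusIndex:
    groups = group_violations(records, bundle.namespaces)
    return build_focus_index(records, groups, bundle.instances, bundle.namespaces)


def groups_to_json(
    groups: Sequence[ViolationGroup],
    ns: NamespaceTable,
    selection: Optional[Iterable[str]] = None,
) -> str:
    """JSON export of groups; with a selection of focus-node ids the export
    carries the ``n/m`` annotation (n = selected members, m = group size)."""
    selected = set(selection) if selection is not None else None
    out = []
    for g in groups:
        member_ids = [term_text(m.focus_node, ns) for m in g.members]
        entry: dict = {
            "key": g.key.as_dict(),
            "size": g.size,
            "exemplar_focus_node": term_text(g.exemplar.focus_node, ns),
            "member_focus_nodes": member_ids,
        }
        if selected is not None:
            entry["n_selected"] = sum(1 for m in member_ids if m in selected)
            entry["label"] = f"{entry['n_selected']}/{g.size}"
        out.append(entry)
    return json.dumps(out, indent=2, ensure_ascii=False)
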