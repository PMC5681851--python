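"""Concept taxonomy: a polyhierarchical controlled vocabulary of concepts.

The taxonomy plays the role of MeSH: every concept carries a preferred label,
zero or more synonyms ("entry terms") and zero or more parents.  Because a
concept may sit under several parents, the hierarchy is a DAG, not a tree.
A designated set of *method roots* (the Investigative Techniques analogue)
marks the subtree that defines the space of laboratory methods.

The on-disk format is a UTF-8 CSV with columns
``concept_id,preferred_label,synonyms,parent_ids`` and an optional
``is_method_root`` flag column; multi-valued fields are pipe-separated.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "Concept",
    "Taxonomy",
    "TaxonomyError",
    "Violation",
    "load_taxonomy",
    "write_taxonomy",
    "descendants",
    "validate_taxonomy",
]

CSV_COLUMNS = ("concept_id", "preferred_label", "synonyms", "parent_ids")
_ROOT_COLUMN = "is_method_root"
_SEP = "|"


class TaxonomyError(ValueError):
    """Raised when a taxonomy file or structure is invalid."""


@dataclass(frozen=True)
class Concept:
    """One vocabulary concept: an identifier, a label, synonyms and parents."""

    concept_id: str
    preferred_label: str
    synonyms: frozenset[str] = frozenset()
    parent_ids: frozenset[str] = frozenset()


@dataclass
class Taxonomy:
    """A validated set of concepts plus the roots of the method subtree."""

    concepts: dict[str, Concept] = field(default_factory=dict)
    method_root_ids: frozenset[str] = frozenset()

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def children_map(self) -> dict[str, set[str]]:
        """Map each concept id to the ids of its direct children."""
        children: dict[str, set[str]] = {cid: set() for cid in self.concepts}
        for concept in self.concepts.values():
            for pid in concept.parent_ids:
                if pid in children:
                    children[pid].add(concept.concept_id)
        return children

    def to_digraph(self) -> "nx.DiGraph":
        """Parent-to-child directed graph over known concepts only."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for concept in self.concepts.values():
            for pid in concept.parent_ids:
                if pid in self.concepts:
                    g.add_edge(pid, concept.concept_id)
        return g

    def method_subtree(self) -> frozenset[str]:
        """Self-inclusive descendant closure of the method roots."""
        out: set[str] = set()
        for root in self.method_root_ids:
            if root in self.concepts:
                out.add(root)
                out |= descendants(self, root)
        return frozenset(out)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_taxonomy`."""

    kind: str  # duplicate_id | dangling_parent | cycle | empty_label | empty_synonym | unknown_method_root
    concept_ids: tuple[str, ...]
    message: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "concept_ids": list(self.concept_ids),
            "message": self.message,
        }


def _split_multi(value: str) -> frozenset[str]:
    if not value:
        return frozenset()
    return frozenset(part for part in value.split(_SEP) if part != "")


def load_taxonomy(
    path: str | Path,
    method_root_ids: Iterable[str] | None = None,
) -> Taxonomy:
    """Load and validate a taxonomy from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Synonym strings are preserved verbatim;
        no normalization happens at load time.
    method_root_ids
        Explicit method roots; merged with any ``is_method_root`` column.

    Raises
    ------
    TaxonomyError
        Missing file, malformed row, duplicate concept id, parent reference
        to an unknown id, or a cycle in the parent relation.
    """
    path = Path(path)
    if not path.exists():
        raise TaxonomyError(f"taxonomy file not found: {path}")

    concepts: dict[str, Concept] = {}
    roots: set[str] = set(method_root_ids or ())
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            # empty file: no header at all
            raise TaxonomyError(f"taxonomy file has no header row: {path}")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TaxonomyError(f"taxonomy CSV missing columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in CSV_COLUMNS):
                raise TaxonomyError(f"malformed row at line {lineno}: {row}")
            cid = row["concept_id"]
            if cid == "":
                raise TaxonomyError(f"empty concept_id at line {lineno}")
            if cid in concepts:
                raise TaxonomyError(f"duplicate concept_id {cid!r} at line {lineno}")
            concepts[cid] = Concept(
                concept_id=cid,
                preferred_label=row["preferred_label"],
                synonyms=_split_multi(row["synonyms"]),
                parent_ids=_split_multi(row["parent_ids"]),
            )
            if row.get(_ROOT_COLUMN, "").strip() in {"1", "true", "True"}:
                roots.add(cid)

    tax = Taxonomy(concepts=concepts, method_root_ids=frozenset(roots))
    violations = validate_taxonomy(tax)
    if violations:
        raise TaxonomyError(
            "invalid taxonomy: " + "; ".join(v.message for v in violations)
        )
    return tax


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    """Write a taxonomy to CSV in the dialect :func:`load_taxonomy` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS + (_ROOT_COLUMN,))
        for cid in sorted(tax.concepts):
            c = tax.concepts[cid]
            writer.writerow(
                [
                    c.concept_id,
                    c.preferred_label,
                    _SEP.join(sorted(c.synonyms)),
                    _SEP.join(sorted(c.parent_ids)),
                    "1" if cid in tax.method_root_ids else "0",
                ]
            )


def descendants(tax: Taxonomy, concept_id: str) -> set[str]:
    """All concepts reachable from ``concept_id`` via one or more child steps.

    Excludes ``concept_id`` itself.  Traversal uses a visited set, so each
    id appears once even over a polyhierarchy (diamond-shaped ancestry).
    """
    if concept_id not in tax.concepts:
        raise TaxonomyError(f"unknown concept_id: {concept_id!r}")
    return set(nx.descendants(tax.to_digraph(), concept_id))


def validate_taxonomy(tax: Taxonomy) -> list[Violation]:
    """Check every structural invariant; an empty report means valid.

    Violations are data, not exceptions: each names the offending ids.
    """
    report: list[Violation] = []
    for cid, concept in tax.concepts.items():
        if concept.preferred_label == "":
            report.append(
                Violation("empty_label", (cid,), f"concept {cid!r} has an empty preferred_label")
            )
        if "" in concept.synonyms:
            report.append(
                Violation("empty_synonym", (cid,), f"concept {cid!r} has an empty synonym")
            )
        for pid in sorted(concept.parent_ids):
            if pid not in tax.concepts:
                report.append(
                    Violation(
                        "dangling_parent",
                        (cid, pid),
                        f"concept {cid!r} references unknown parent {pid!r}",
                    )
                )
    g = tax.to_digraph()
    if not nx.is_directed_acyclic_graph(g):
        for cycle in nx.simple_cycles(g):
            report.append(
                Violation(
                    "cycle",
                    tuple(sorted(cycle)),
                    f"cycle in parent relation: {sorted(cycle)}",
                )
            )
    for rid in sorted(tax.method_root_ids):
        if rid not in tax.concepts:
            report.append(
                Violation(
                    "unknown_method_root",
                    (rid,),
                    f"method root {rid!r} is not a known concept",
                )
            )
    return report


def validation_report_json(violations: list[Violation]) -> str:
    """Serialize a validation report as JSON (empty list = valid)."""
    return json.dumps([v.to_dict() for v in violations], indent=2, sort_keys=True)
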