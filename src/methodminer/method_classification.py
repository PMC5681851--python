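"""Robotic-method classification by descendant closure.

A small manually curated seed list names the concepts that a commercial
robotic ("cloud") lab can execute.  The robotic set is the self-inclusive
descendant closure of those seeds: a seed together with everything below it
in the hierarchy, on the assumption that children of a mapped concept are
finer-grained variants of the same method.  The closure never ascends — a
parent of a seed is *not* robotic.

Every concept then falls into exactly one of three classes:

* ``ROBOTIC`` — in the robotic closure;
* ``NON_ROBOTIC`` — in the method subtree but not robotic;
* ``NON_METHOD`` — outside the method subtree (or unknown entirely).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from .taxonomy import Taxonomy, TaxonomyError, descendants

__all__ = [
    "MethodClass",
    "MethodMapping",
    "UnknownSeedError",
    "expand_robotic_set",
    "classify_concept",
    "load_seed_ids",
    "write_mapping_csv",
]


class MethodClass(Enum):
    ROBOTIC = "ROBOTIC"
    NON_ROBOTIC = "NON_ROBOTIC"
    NON_METHOD = "NON_METHOD"


class UnknownSeedError(TaxonomyError):
    """One or more seed ids do not exist in the taxonomy."""

    def __init__(self, unknown: Iterable[str]):
        self.unknown = sorted(unknown)
        super().__init__(f"unknown seed ids: {self.unknown}")


@dataclass
class MethodMapping:
    """The robotic seed set, its closure, and the whole method subtree.

    ``via_seed`` records, for audit, one seed through which each robotic
    concept entered the closure (the lexicographically smallest such seed).
    ``warnings`` lists seeds that fall outside the method subtree; they are
    retained rather than dropped, since the seed list is curated externally.
    """

    seed_ids: frozenset[str]
    robotic_ids: frozenset[str]
    method_ids: frozenset[str]
    via_seed: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def expand_robotic_set(tax: Taxonomy, seed_ids: Iterable[str]) -> MethodMapping:
    """Expand seeds to the robotic set by self-inclusive descendant closure.

    Idempotent: expanding the resulting ``robotic_ids`` again yields the
    same set, because closure of a closed set is itself.

    Raises
    ------
    UnknownSeedError
        Listing *all* seeds absent from the taxonomy.
    """
    seeds = frozenset(seed_ids)
    unknown = {s for s in seeds if s not in tax.concepts}
    if unknown:
        raise UnknownSeedError(unknown)

    via: dict[str, str] = {}
    robotic: set[str] = set()
    for seed in sorted(seeds):
        closure = {seed} | descendants(tax, seed)
        robotic |= closure
        for cid in closure:
            if cid not in via or seed < via[cid]:
                via[cid] = seed

    method_ids = tax.method_subtree()
    warnings = [
        f"seed {s!r} lies outside the method subtree"
        for s in sorted(seeds - method_ids)
    ]
    return MethodMapping(
        seed_ids=seeds,
        robotic_ids=frozenset(robotic),
        method_ids=method_ids,
        via_seed=via,
        warnings=warnings,
    )


def classify_concept(mapping: MethodMapping, concept_id: str) -> MethodClass:
    """Assign the unique class of a concept id (unknown ids are legal)."""
    if concept_id in mapping.robotic_ids:
        return MethodClass.ROBOTIC
    if concept_id in mapping.method_ids:
        return MethodClass.NON_ROBOTIC
    return MethodClass.NON_METHOD


def load_seed_ids(path: str | Path) -> frozenset[str]:
    """Read a seed list CSV: column ``concept_id``, optional ``label``."""
    path = Path(path)
    if not path.exists():
        raise TaxonomyError(f"seed file not found: {path}")
    seeds: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "concept_id" not in reader.fieldnames:
            raise TaxonomyError(f"seed CSV must have a concept_id column: {path}")
        for row in reader:
            cid = (row.get("concept_id") or "").strip()
            if cid:
                seeds.add(cid)
    return frozenset(seeds)


def write_seed_ids(seed_ids: Iterable[str], path: str | Path, tax: Taxonomy | None = None) -> None:
    """Write a seed list CSV, with labels when a taxonomy is supplied."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept_id", "label"])
        for cid in sorted(set(seed_ids)):
            label = ""
            if tax is not None and cid in tax.concepts:
                label = tax.concepts[cid].preferred_label
            writer.writerow([cid, label])


def write_mapping_csv(mapping: MethodMapping, tax: Taxonomy, path: str | Path) -> None:
    """Audit export: every taxonomy concept with its class and entry seed."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept_id", "class", "via_seed_id"])
        for cid in sorted(tax.concepts):
            cls = classify_concept(mapping, cid)
            writer.writerow([cid, cls.value, mapping.via_seed.get(cid, "")])
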