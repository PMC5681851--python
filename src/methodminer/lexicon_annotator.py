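"""Exact, case-insensitive, longest-match dictionary annotation.

This is the concept-recognition step: every preferred label and synonym in
the taxonomy becomes a lexicon entry, and text is scanned for greedy
leftmost-longest, non-overlapping occurrences of entries at token
boundaries.  Matching is otherwise exact — no stemming, no inflection, no
label inversion ("Blotting, Western" matches only literally).  A term owned
by several concepts (an ambiguous entry) yields one mention per concept at
the same span, since no disambiguation model is applied.

Token boundaries are transitions between alphanumeric and non-alphanumeric
characters: an entry may not start or end in the middle of an alphanumeric
run, so "PCR" does not match inside "ePCR2".

The matcher indexes entries by folded string and probes candidate spans by
entry length, longest first, at each boundary position.  An adapter ingests
externally produced annotations (e.g., a MetaMap export) from TSV so that
both annotation routes share one downstream analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from .corpus import Document, content_paragraphs_indexed
from .taxonomy import Taxonomy

__all__ = [
    "Lexicon",
    "Mention",
    "AnnotationError",
    "ExternalAnnotations",
    "build_lexicon",
    "annotate_text",
    "annotate_document",
    "annotate_corpus",
    "write_annotations_tsv",
    "ingest_external_annotations",
]

TSV_COLUMNS = ("doc_id", "concept_id", "start", "end", "matched_text", "paragraph_index")


class AnnotationError(ValueError):
    """Raised for malformed external annotation files."""


def fold(s: str) -> str:
    """Case-fold a string without changing its length.

    Offsets must survive folding, so characters whose lowercase form has a
    different length (rare outside Latin-1) are kept as-is.
    """
    lowered = s.lower()
    if len(lowered) == len(s):
        return lowered
    return "".join(c if len(c.lower()) != 1 else c.lower() for c in s)


@dataclass(frozen=True)
class Mention:
    """One recognized concept occurrence.

    ``start``/``end`` are character offsets into the *paragraph* text
    (0-based, end-exclusive); ``matched_text`` is the verbatim slice.
    ``doc_id`` and ``paragraph_index`` are unset (None) for bare-text
    annotation and filled by :func:`annotate_document`.
    """

    concept_id: str
    start: int
    end: int
    matched_text: str
    doc_id: str | None = None
    paragraph_index: int | None = None


@dataclass(frozen=True)
class Lexicon:
    """Folded term string -> set of owning concept ids, plus a length index."""

    entries: Mapping[str, frozenset[str]]
    lengths_desc: tuple[int, ...]  # distinct entry lengths, longest first

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(tax: Taxonomy, restrict_to_method_subtree: bool = False) -> Lexicon:
    """Compile a taxonomy into a matching lexicon.

    One entry per distinct case-folded string over all preferred labels and
    synonyms; a string shared by k concepts maps to all k.  By default the
    whole taxonomy is indexed (annotation is not restricted to the method
    subtree); set ``restrict_to_method_subtree`` to index only the method
    space.
    """
    allowed = tax.method_subtree() if restrict_to_method_subtree else None
    entries: dict[str, set[str]] = {}
    for cid, concept in tax.concepts.items():
        if allowed is not None and cid not in allowed:
            continue
        for term in {concept.preferred_label, *concept.synonyms}:
            key = fold(term)
            if key:
                entries.setdefault(key, set()).add(cid)
    frozen = {k: frozenset(v) for k, v in entries.items()}
    lengths = tuple(sorted({len(k) for k in frozen}, reverse=True))
    return Lexicon(entries=frozen, lengths_desc=lengths)


def _boundary_ok(folded: str, start: int, end: int) -> bool:
    """True when [start, end) starts and ends at token boundaries."""
    if start > 0 and folded[start - 1].isalnum() and folded[start].isalnum():
        return False
    if end < len(folded) and folded[end - 1].isalnum() and folded[end].isalnum():
        return False
    return True


def annotate_text(lex: Lexicon, text: str) -> list[Mention]:
    """Greedy leftmost-longest non-overlapping matching over one text.

    Deterministic: mentions are ordered by span, and co-located mentions of
    an ambiguous entry by concept id.
    """
    folded = fold(text)
    n = len(folded)
    mentions: list[Mention] = []
    i = 0
    while i < n:
        hit_len = 0
        hit_ids: frozenset[str] | None = None
        for length in lex.lengths_desc:
            end = i + length
            if end > n:
                continue
            if not _boundary_ok(folded, i, end):
                continue
            ids = lex.entries.get(folded[i:end])
            if ids:
                hit_len, hit_ids = length, ids
                break  # lengths are probed longest-first
        if hit_ids is not None:
            span_text = text[i : i + hit_len]
            for cid in sorted(hit_ids):
                mentions.append(Mention(concept_id=cid, start=i, end=i + hit_len, matched_text=span_text))
            i += hit_len
        else:
            i += 1
    return mentions


def annotate_document(lex: Lexicon, doc: Document) -> list[Mention]:
    """Annotate the content paragraphs of a document.

    Equivalent to annotating each content paragraph on its own: no mention
    may span a paragraph boundary.  Offsets remain paragraph-local.
    """
    out: list[Mention] = []
    for idx, para in content_paragraphs_indexed(doc):
        for m in annotate_text(lex, para.text):
            out.append(replace(m, doc_id=doc.doc_id, paragraph_index=idx))
    return out


def annotate_corpus(lex: Lexicon, documents: Iterable[Document]) -> list[Mention]:
    """Concatenated :func:`annotate_document` over a corpus, in given order."""
    out: list[Mention] = []
    for doc in documents:
        out.extend(annotate_document(lex, doc))
    return out


def write_annotations_tsv(mentions: Iterable[Mention], path: str | Path) -> None:
    """Export mentions as TSV with the interoperability column set."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for m in mentions:
            writer.writerow(
                [
                    m.doc_id if m.doc_id is not None else "",
                    m.concept_id,
                    m.start,
                    m.end,
                    m.matched_text,
                    m.paragraph_index if m.paragraph_index is not None else "",
                ]
            )


@dataclass
class ExternalAnnotations:
    """Mentions ingested from an external annotator, plus unknown-id audit."""

    mentions: list[Mention]
    unknown_concept_ids: frozenset[str]

    @property
    def n_warnings(self) -> int:
        return len(self.unknown_concept_ids)


def ingest_external_annotations(path: str | Path, tax: Taxonomy) -> ExternalAnnotations:
    """Read externally produced annotations (the MetaMap-style route).

    Concept ids unknown to the taxonomy are retained — they will classify
    as NON_METHOD downstream — but counted as warnings so the run report
    can surface them.  Downstream analysis is identical for internal and
    external mentions.

    Raises
    ------
    AnnotationError
        Malformed rows, non-integer offsets, or negative/inverted spans.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotations file not found: {path}")
    mentions: list[Mention] = []
    unknown: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return ExternalAnnotations(mentions=[], unknown_concept_ids=frozenset())
        missing = [c for c in TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise AnnotationError(f"annotation TSV missing columns: {missing}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in TSV_COLUMNS):
                raise AnnotationError(f"malformed row at line {lineno}")
            try:
                start = int(row["start"])
                end = int(row["end"])
                pidx = int(row["paragraph_index"]) if row["paragraph_index"] != "" else None
            except ValueError as exc:
                raise AnnotationError(f"non-integer span at line {lineno}") from exc
            if start < 0 or end <= start:
                raise AnnotationError(
                    f"negative or inverted span [{start}, {end}) at line {lineno}"
                )
            cid = row["concept_id"]
            if cid not in tax.concepts:
                unknown.add(cid)
            mentions.append(
                Mention(
                    concept_id=cid,
                    start=start,
                    end=end,
                    matched_text=row["matched_text"],
                    doc_id=row["doc_id"] or None,
                    paragraph_index=pidx,
                )
            )
    return ExternalAnnotations(mentions=mentions, unknown_concept_ids=frozenset(unknown))
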