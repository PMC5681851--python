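"""Document corpora and content-paragraph selection.

A corpus is a JSON-Lines file (or a directory of them), one document per
line: ``{"doc_id": ..., "paragraphs": [{"text": ..., "role": ...}],
"keywords": [...]}``.  Paragraph roles come from a closed set; only *content*
paragraphs — roles ``body`` and ``other`` — are annotated, mirroring the
practice of excluding titles, abstracts, section headings, figure captions
and reference lists from method detection.  Optional per-document keywords
(indexed-term concept ids) feed the keyword-overlap analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ROLES",
    "CONTENT_ROLES",
    "Paragraph",
    "Document",
    "CorpusError",
    "load_corpus",
    "write_corpus",
    "content_paragraphs",
    "content_paragraphs_indexed",
]

ROLES = frozenset({"title", "abstract", "heading", "body", "figure", "references", "other"})
CONTENT_ROLES = frozenset({"body", "other"})


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus files."""


@dataclass(frozen=True)
class Paragraph:
    text: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CorpusError(f"unknown paragraph role: {self.role!r}")


@dataclass
class Document:
    doc_id: str
    paragraphs: list[Paragraph] = field(default_factory=list)
    keywords: frozenset[str] | None = None

    def to_record(self) -> dict:
        rec: dict = {
            "doc_id": self.doc_id,
            "paragraphs": [{"text": p.text, "role": p.role} for p in self.paragraphs],
        }
        if self.keywords is not None:
            rec["keywords"] = sorted(self.keywords)
        return rec


def _parse_record(rec: dict, source: str) -> Document:
    if not isinstance(rec, dict) or "doc_id" not in rec or "paragraphs" not in rec:
        raise CorpusError(f"record missing doc_id/paragraphs in {source}")
    paragraphs = []
    for p in rec["paragraphs"]:
        if not isinstance(p, dict) or "text" not in p or "role" not in p:
            raise CorpusError(f"paragraph missing text/role in {source} doc {rec['doc_id']!r}")
        paragraphs.append(Paragraph(text=p["text"], role=p["role"]))
    keywords = rec.get("keywords")
    return Document(
        doc_id=str(rec["doc_id"]),
        paragraphs=paragraphs,
        keywords=None if keywords is None else frozenset(str(k) for k in keywords),
    )


def load_corpus(path: str | Path) -> list[Document]:
    """Load a corpus from a JSON-Lines file or a directory of ``*.jsonl``.

    Documents are returned in deterministic order (lexicographic by doc_id).

    Raises
    ------
    CorpusError
        Missing path, undecodable line, record missing required fields, or
        a doc_id appearing more than once across the corpus.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus path not found: {path}")
    files = sorted(path.glob("*.jsonl")) if path.is_dir() else [path]

    docs: dict[str, Document] = {}
    for fp in files:
        with fp.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"undecodable JSON at {fp}:{lineno}: {exc}") from exc
                doc = _parse_record(rec, f"{fp}:{lineno}")
                if doc.doc_id in docs:
                    raise CorpusError(f"duplicate doc_id {doc.doc_id!r} at {fp}:{lineno}")
                docs[doc.doc_id] = doc
    return [docs[did] for did in sorted(docs)]


def write_corpus(documents: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSON-Lines, one record per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps(doc.to_record(), sort_keys=True) + "\n")


def content_paragraphs(doc: Document) -> list[Paragraph]:
    """Exactly the paragraphs with role ``body`` or ``other``, in order."""
    return [p for p in doc.paragraphs if p.role in CONTENT_ROLES]


def content_paragraphs_indexed(doc: Document) -> list[tuple[int, Paragraph]]:
    """Like :func:`content_paragraphs` but paired with the position of each
    paragraph in ``doc.paragraphs``, so mentions can point back into the
    full document."""
    return [(i, p) for i, p in enumerate(doc.paragraphs) if p.role in CONTENT_ROLES]
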