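"""Per-document method profiles and corpus-level coverage statistics.

All statistics are *distinct-concept* based: a method counts once per
document however many times it is mentioned, and frequency tables report
document frequency (the number of articles containing the concept at least
once), not raw mention counts.  Percentages are reported both unrounded and
rounded half-away-from-zero to integers for display.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Document
from .lexicon_annotator import Mention
from .method_classification import MethodClass, MethodMapping, classify_concept

__all__ = [
    "DocumentMethodProfile",
    "CorpusStats",
    "KeywordOverlap",
    "profile_document",
    "profile_corpus",
    "summarize_corpus",
    "method_frequency_table",
    "coverage_threshold_table",
    "unique_method_distribution",
    "keyword_overlap",
    "round_half_away",
]

COVERAGE_THRESHOLDS = (1.0, 0.75, 0.50)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DocumentMethodProfile:
    """Distinct recognized methods of one document, split by class.

    ``robotic_fraction`` is the share of distinct detected methods that are
    robotic; it is None (undefined) when no method was detected.
    """

    doc_id: str
    method_ids: frozenset[str]
    robotic_ids: frozenset[str]
    nonrobotic_ids: frozenset[str]

    @property
    def robotic_fraction(self) -> float | None:
        if not self.method_ids:
            return None
        return len(self.robotic_ids) / len(self.method_ids)


def profile_document(
    mentions: Iterable[Mention],
    mapping: MethodMapping,
    doc_id: str | None = None,
) -> DocumentMethodProfile:
    """Collapse one document's mentions into its distinct-method profile.

    NON_METHOD mentions (concepts outside the method subtree, including
    unknown external ids) are dropped.  All mentions must carry the same
    doc_id; pass ``doc_id`` explicitly for an empty mention list.
    """
    mentions = list(mentions)
    ids = {m.doc_id for m in mentions}
    if len(ids) > 1:
        raise ValueError(f"mentions from multiple documents: {sorted(map(str, ids))}")
    if ids:
        (seen_id,) = ids
        if doc_id is not None and seen_id is not None and seen_id != doc_id:
            raise ValueError(f"doc_id {doc_id!r} does not match mentions ({seen_id!r})")
        doc_id = seen_id if seen_id is not None else doc_id
    if doc_id is None:
        doc_id = ""

    robotic: set[str] = set()
    nonrobotic: set[str] = set()
    for m in mentions:
        cls = classify_concept(mapping, m.concept_id)
        if cls is MethodClass.ROBOTIC:
            robotic.add(m.concept_id)
        elif cls is MethodClass.NON_ROBOTIC:
            nonrobotic.add(m.concept_id)
    return DocumentMethodProfile(
        doc_id=doc_id,
        method_ids=frozenset(robotic | nonrobotic),
        robotic_ids=frozenset(robotic),
        nonrobotic_ids=frozenset(nonrobotic),
    )


def profile_corpus(
    documents: Sequence[Document],
    mentions: Iterable[Mention],
    mapping: MethodMapping,
) -> list[DocumentMethodProfile]:
    """One profile per document, in document order.

    Documents without any mention get an empty profile, so the corpus
    denominator is preserved.
    """
    by_doc: dict[str, list[Mention]] = {doc.doc_id: [] for doc in documents}
    for m in mentions:
        if m.doc_id in by_doc:
            by_doc[m.doc_id].append(m)
    return [profile_document(by_doc[doc.doc_id], mapping, doc_id=doc.doc_id) for doc in documents]


@dataclass
class CorpusStats:
    """Corpus-level coverage counts and percentages.

    ``mean_robotic_per_method_paper`` averages the number of distinct
    robotic methods over documents with at least one detected method;
    undefined (None) on an empty or method-free corpus.
    """

    n_docs: int
    n_docs_with_method: int
    n_docs_without_method: int
    n_distinct_methods: int
    n_docs_with_robotic: int
    mean_robotic_per_method_paper: float | None
    pct_docs_with_robotic: float | None

    def to_dict(self) -> dict:
        pct = self.pct_docs_with_robotic
        return {
            "n_docs": self.n_docs,
            "n_docs_with_method": self.n_docs_with_method,
            "n_docs_without_method": self.n_docs_without_method,
            "n_distinct_methods": self.n_distinct_methods,
            "n_docs_with_robotic": self.n_docs_with_robotic,
            "mean_robotic_per_method_paper": self.mean_robotic_per_method_paper,
            "pct_docs_with_robotic": pct,
            "pct_docs_with_robotic_rounded": None if pct is None else round_half_away(pct),
        }


def summarize_corpus(
    profiles: Sequence[DocumentMethodProfile],
    n_docs_total: int | None = None,
) -> CorpusStats:
    """Aggregate per-document profiles into corpus statistics."""
    if n_docs_total is None:
        n_docs_total = len(profiles)
    if n_docs_total < len(profiles):
        raise ValueError(
            f"n_docs_total={n_docs_total} < number of profiles ({len(profiles)})"
        )
    with_method = [p for p in profiles if p.method_ids]
    n_with = len(with_method)
    n_robotic_docs = sum(1 for p in profiles if p.robotic_ids)
    distinct: set[str] = set()
    for p in profiles:
        distinct |= p.method_ids
    mean_robotic = (
        sum(len(p.robotic_ids) for p in with_method) / n_with if n_with else None
    )
    pct_robotic = 100.0 * n_robotic_docs / n_docs_total if n_docs_total else None
    return CorpusStats(
        n_docs=n_docs_total,
        n_docs_with_method=n_with,
        n_docs_without_method=n_docs_total - n_with,
        n_distinct_methods=len(distinct),
        n_docs_with_robotic=n_robotic_docs,
        mean_robotic_per_method_paper=mean_robotic,
        pct_docs_with_robotic=pct_robotic,
    )


def _class_ids(profile: DocumentMethodProfile, class_filter: MethodClass) -> frozenset[str]:
    if class_filter is MethodClass.ROBOTIC:
        return profile.robotic_ids
    if class_filter is MethodClass.NON_ROBOTIC:
        return profile.nonrobotic_ids
    raise ValueError("class_filter must be ROBOTIC or NON_ROBOTIC")


def method_frequency_table(
    profiles: Sequence[DocumentMethodProfile],
    mapping: MethodMapping,
    labels: Mapping[str, str],
    class_filter: MethodClass,
    top_k: int,
) -> pd.DataFrame:
    """Top-k concepts of a class by document frequency.

    Document frequency counts documents whose profile contains the concept,
    regardless of mention multiplicity.  Sorted by frequency descending,
    ties broken by label ascending; truncated to ``top_k`` rows.
    ``labels`` maps concept ids to display labels (missing ids fall back to
    the id itself).
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    freq: Counter[str] = Counter()
    for p in profiles:
        freq.update(_class_ids(p, class_filter))
    rows = [
        {"concept_id": cid, "label": labels.get(cid, cid), "document_frequency": n}
        for cid, n in freq.items()
    ]
    df = pd.DataFrame(rows, columns=["concept_id", "label", "document_frequency"])
    if not df.empty:
        df = df.sort_values(
            ["document_frequency", "label"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df.head(top_k)


def coverage_threshold_table(
    profiles: Sequence[DocumentMethodProfile],
) -> pd.DataFrame:
    """Share of method-bearing documents whose robotic fraction reaches
    each threshold (100%, >=75%, >=50% of detected methods robotic).

    Documents without a detected method (fraction undefined) are excluded
    from the denominator.  The thresholds are nested, so the reported
    percentages are non-decreasing from 1.0 down to 0.5.
    """
    fractions = [p.robotic_fraction for p in profiles if p.robotic_fraction is not None]
    n = len(fractions)
    rows = []
    for thr in COVERAGE_THRESHOLDS:
        pct = 100.0 * sum(1 for f in fractions if f >= thr) / n if n else None
        rows.append(
            {
                "threshold": thr,
                "pct_documents": pct,
                "pct_documents_rounded": None if pct is None else round_half_away(pct),
            }
        )
    return pd.DataFrame(rows, columns=["threshold", "pct_documents", "pct_documents_rounded"])


def unique_method_distribution(
    profiles: Sequence[DocumentMethodProfile],
    class_filter: MethodClass,
) -> dict[int, int]:
    """Histogram of documents by count of distinct methods of one class.

    Documents with zero methods of the class land in bin 0, so histogram
    values always sum to the number of profiles.
    """
    hist: Counter[int] = Counter(len(_class_ids(p, class_filter)) for p in profiles)
    return dict(sorted(hist.items()))


@dataclass
class KeywordOverlap:
    """Per-document overlap between detected methods and indexed keywords.

    Overlap for one document is |methods ∩ keywords| / |methods|.  Documents
    without keywords, or without detected methods, cannot be scored and are
    excluded from the summary fractions but counted separately.
    """

    per_doc: dict[str, float] = field(default_factory=dict)
    n_excluded_no_keywords: int = 0
    n_excluded_no_methods: int = 0

    @property
    def n_scored(self) -> int:
        return len(self.per_doc)

    @property
    def frac_any_overlap(self) -> float | None:
        if not self.per_doc:
            return None
        return sum(1 for v in self.per_doc.values() if v > 0) / len(self.per_doc)

    @property
    def frac_over_half(self) -> float | None:
        if not self.per_doc:
            return None
        return sum(1 for v in self.per_doc.values() if v > 0.5) / len(self.per_doc)

    def to_dict(self) -> dict:
        return {
            "per_doc": dict(sorted(self.per_doc.items())),
            "n_scored": self.n_scored,
            "n_excluded_no_keywords": self.n_excluded_no_keywords,
            "n_excluded_no_methods": self.n_excluded_no_methods,
            "frac_any_overlap": self.frac_any_overlap,
            "frac_over_half": self.frac_over_half,
        }


def keyword_overlap(
    profiles: Sequence[DocumentMethodProfile],
    documents: Sequence[Document],
) -> KeywordOverlap:
    """Compare detected method sets against per-document keyword sets."""
    keywords_by_doc = {d.doc_id: d.keywords for d in documents}
    result = KeywordOverlap()
    for p in profiles:
        kw = keywords_by_doc.get(p.doc_id)
        if kw is None:
            result.n_excluded_no_keywords += 1
            continue
        if not p.method_ids:
            result.n_excluded_no_methods += 1
            continue
        result.per_doc[p.doc_id] = len(p.method_ids & kw) / len(p.method_ids)
    return result
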