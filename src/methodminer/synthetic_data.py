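"""Synthetic taxonomies and corpora with planted, known ground truth.

The generator emulates the statistical shape of a real method-mining run —
a polyhierarchical method vocabulary with synonyms, a curated robotic seed
subset, and articles whose content paragraphs mention a handful of methods
(a right-skewed count per paper) — while staying fully synthetic: labels
are pronounceable nonsense built from one character alphabet, and filler
text is built from a *disjoint* alphabet, so no filler token can ever match
a lexicon entry.  That disjointness makes perfect recovery unconditional:
annotating a generated document must reproduce the planted mentions
exactly.

Decoy method terms may be planted in abstracts; they are excluded from the
ground truth because abstracts are not content paragraphs, which exercises
the content-paragraph rule end to end.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Document, Paragraph, write_corpus
from .method_classification import MethodMapping, write_seed_ids
from .coverage_analysis import DocumentMethodProfile
from .taxonomy import Concept, Taxonomy, write_taxonomy

__all__ = [
    "SyntheticSpec",
    "SyntheticSpecError",
    "GroundTruth",
    "generate_taxonomy",
    "generate_corpus",
    "generate_dataset",
    "write_synthetic_dataset",
    "ground_truth_profiles",
]

# Disjoint character pools: terms never share a letter with filler, so the
# lexicon and the filler vocabulary are disjoint by construction.
_TERM_CONSONANTS = "bcdfghklmn"
_TERM_VOWELS = "aeiou"
_FILLER_ALPHABET = "pqrstvwxyz"


class SyntheticSpecError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a mid-sized corpus: a couple hundred concepts, a few
    hundred articles, and a right-skewed distinct-method count per article
    (negative binomial, mean ~7) of which roughly half are robotic once the
    seed fraction is expanded by closure — most articles then carry a few
    robotic methods, echoing what method-coverage studies observe.
    """

    seed: int = 0
    n_concepts: int = 200
    max_children: int = 4
    extra_parent_prob: float = 0.15  # polyhierarchy: chance of a second parent
    synonyms_mean: float = 2.0
    max_synonyms: int = 5
    n_docs: int = 500
    methods_per_doc_mean: float = 7.0
    methods_per_doc_dispersion: float = 4.0
    robotic_seed_fraction: float = 0.12
    filler_vocab_size: int = 200
    n_body_paragraphs: int = 2
    duplicate_mention_prob: float = 0.3
    decoy_abstract_prob: float = 0.5
    keyword_doc_prob: float = 0.8
    keyword_pick_prob: float = 0.4

    def validate(self) -> None:
        if self.n_concepts < 1:
            raise SyntheticSpecError("n_concepts must be >= 1")
        if self.n_concepts > 1 and self.max_children < 1:
            raise SyntheticSpecError("max_children must be >= 1 when n_concepts > 1")
        if not (0.0 <= self.robotic_seed_fraction <= 1.0):
            raise SyntheticSpecError("robotic_seed_fraction must be in [0, 1]")
        if self.n_docs < 0 or self.filler_vocab_size < 1 or self.n_body_paragraphs < 1:
            raise SyntheticSpecError("counts must be non-negative (filler/body >= 1)")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by document.

    ``mentions_by_doc`` records each planted occurrence as
    (concept_id, paragraph_index, start, end, surface) with paragraph-local
    character offsets; ``method_ids_by_doc`` the distinct planted concepts;
    ``document_frequency`` the corpus-level per-concept document counts.
    Abstract decoys are kept separately — they are not content and must not
    be recovered.
    """

    mentions_by_doc: dict[str, list[tuple[str, int, int, int, str]]] = field(default_factory=dict)
    method_ids_by_doc: dict[str, frozenset[str]] = field(default_factory=dict)
    document_frequency: Counter = field(default_factory=Counter)
    decoys_by_doc: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "mentions_by_doc": {
                d: [list(m) for m in ms] for d, ms in sorted(self.mentions_by_doc.items())
            },
            "method_ids_by_doc": {
                d: sorted(s) for d, s in sorted(self.method_ids_by_doc.items())
            },
            "document_frequency": dict(sorted(self.document_frequency.items())),
            "decoys_by_doc": {d: v for d, v in sorted(self.decoys_by_doc.items())},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _syllable(rng: np.random.Generator) -> str:
    return rng.choice(list(_TERM_CONSONANTS)) + rng.choice(list(_TERM_VOWELS))


def _term_word(rng: np.random.Generator) -> str:
    return "".join(_syllable(rng) for _ in range(rng.integers(2, 5)))


def _unique_term(rng: np.random.Generator, used: set[str], two_word_prob: float = 0.3) -> str:
    # rejection loop: term space is vast relative to taxonomy size
    while True:
        term = _term_word(rng)
        if rng.random() < two_word_prob:
            term = term + " " + _term_word(rng)
        if term.lower() not in used:
            used.add(term.lower())
            return term


def generate_taxonomy(spec: SyntheticSpec) -> tuple[Taxonomy, frozenset[str]]:
    """Generate a rooted DAG taxonomy and its robotic seed set.

    The first concept is the single method root; every later concept gets
    one parent among earlier concepts (respecting ``max_children``) and,
    with probability ``extra_parent_prob``, a second parent — parents always
    precede children, so the result is acyclic by construction.  Labels and
    synonyms are unique pronounceable nonsense strings.  Deterministic for
    a given seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = [f"C{i:04d}" for i in range(spec.n_concepts)]
    used_terms: set[str] = set()
    child_count = [0] * spec.n_concepts
    concepts: dict[str, Concept] = {}

    for i, cid in enumerate(ids):
        parents: set[str] = set()
        if i > 0:
            capacity = [j for j in range(i) if child_count[j] < spec.max_children]
            if not capacity:
                raise SyntheticSpecError(
                    f"max_children={spec.max_children} leaves no parent for concept {i}"
                )
            first = int(rng.choice(capacity))
            parents.add(ids[first])
            child_count[first] += 1
            if rng.random() < spec.extra_parent_prob:
                extra = [j for j in range(i) if child_count[j] < spec.max_children and j != first]
                if extra:
                    second = int(rng.choice(extra))
                    parents.add(ids[second])
                    child_count[second] += 1
        n_syn = int(min(rng.poisson(spec.synonyms_mean), spec.max_synonyms))
        concepts[cid] = Concept(
            concept_id=cid,
            preferred_label=_unique_term(rng, used_terms),
            synonyms=frozenset(_unique_term(rng, used_terms) for _ in range(n_syn)),
            parent_ids=frozenset(parents),
        )

    tax = Taxonomy(concepts=concepts, method_root_ids=frozenset({ids[0]}))

    n_seeds = int(round(spec.robotic_seed_fraction * max(spec.n_concepts - 1, 0)))
    if spec.robotic_seed_fraction > 0 and spec.n_concepts > 1:
        n_seeds = max(n_seeds, 1)
    # Seed lists in practice attach at leaf level (an exact-match leaf and its
    # children), occasionally at a more general internal concept; drawing
    # mostly leaves keeps the robotic closure a moderate share of the space.
    children = tax.children_map()
    leaves = [cid for cid in ids[1:] if not children[cid]]
    internal = [cid for cid in ids[1:] if children[cid]]
    n_leaf = min(int(round(0.75 * n_seeds)), len(leaves))
    n_int = min(n_seeds - n_leaf, len(internal))
    seeds: set[str] = set()
    if n_leaf:
        seeds |= {str(s) for s in rng.choice(leaves, size=n_leaf, replace=False)}
    if n_int:
        seeds |= {str(s) for s in rng.choice(internal, size=n_int, replace=False)}
    return tax, frozenset(seeds)


def _filler_vocab(rng: np.random.Generator, size: int) -> list[str]:
    vocab: set[str] = set()
    while len(vocab) < size:
        length = int(rng.integers(3, 9))
        vocab.add("".join(rng.choice(list(_FILLER_ALPHABET)) for _ in range(length)))
    return sorted(vocab)


def _filler_tokens(rng: np.random.Generator, vocab: list[str], n: int) -> list[str]:
    return [vocab[int(i)] for i in rng.integers(0, len(vocab), size=n)]


_CASE_TRANSFORMS = (str, str.lower, str.upper, str.title)


def _random_case(rng: np.random.Generator, term: str) -> str:
    return _CASE_TRANSFORMS[int(rng.integers(0, len(_CASE_TRANSFORMS)))](term)


def generate_corpus(
    spec: SyntheticSpec,
    tax: Taxonomy,
) -> tuple[list[Document], GroundTruth]:
    """Generate documents with planted method mentions and their ground truth.

    Each document has a filler-only title and abstract plus
    ``n_body_paragraphs`` body paragraphs.  The number of distinct planted
    methods per document is negative-binomial (right-skewed); each planted
    concept appears once, sometimes twice (to exercise mention-multiplicity
    invariance), under a uniformly chosen surface form (label or synonym)
    in a random letter case, separated from its neighbours by filler
    tokens.  Keyword sets mix planted and unrelated concept ids.
    """
    spec.validate()
    rng = np.random.default_rng((spec.seed + 0x5EED) % 2**31)
    vocab = _filler_vocab(rng, spec.filler_vocab_size)
    ids = sorted(tax.concepts)
    surfaces = {cid: [tax.concepts[cid].preferred_label, *sorted(tax.concepts[cid].synonyms)] for cid in ids}
    p_nb = spec.methods_per_doc_dispersion / (spec.methods_per_doc_dispersion + spec.methods_per_doc_mean)

    documents: list[Document] = []
    gt = GroundTruth()
    for d in range(spec.n_docs):
        doc_id = f"doc{d:05d}"
        k = int(min(rng.negative_binomial(spec.methods_per_doc_dispersion, p_nb), len(ids)))
        planted = [str(c) for c in rng.choice(ids, size=k, replace=False)] if k else []

        instances = list(planted)
        for cid in planted:
            if rng.random() < spec.duplicate_mention_prob:
                instances.append(cid)
        order = rng.permutation(len(instances))
        instances = [instances[int(i)] for i in order]

        # deal mention instances round-robin onto body paragraphs
        per_para: list[list[str]] = [[] for _ in range(spec.n_body_paragraphs)]
        for j, cid in enumerate(instances):
            per_para[j % spec.n_body_paragraphs].append(cid)

        paragraphs = [
            Paragraph(" ".join(_filler_tokens(rng, vocab, int(rng.integers(3, 8)))), "title"),
        ]
        abstract_tokens = _filler_tokens(rng, vocab, int(rng.integers(10, 25)))
        if ids and rng.random() < spec.decoy_abstract_prob:
            decoy = str(rng.choice(ids))
            pos = int(rng.integers(0, len(abstract_tokens) + 1))
            abstract_tokens.insert(pos, _random_case(rng, surfaces[decoy][int(rng.integers(0, len(surfaces[decoy])))]))
            gt.decoys_by_doc[doc_id] = [decoy]
        paragraphs.append(Paragraph(" ".join(abstract_tokens), "abstract"))

        mention_records: list[tuple[str, int, int, int, str]] = []
        for p_local, cids in enumerate(per_para):
            para_index = len(paragraphs)  # title + abstract precede bodies
            tokens = _filler_tokens(rng, vocab, int(rng.integers(2, 6)))
            text = " ".join(tokens)
            for cid in cids:
                forms = surfaces[cid]
                surface = _random_case(rng, forms[int(rng.integers(0, len(forms)))])
                start = len(text) + 1 if text else 0
                text = (text + " " + surface) if text else surface
                mention_records.append((cid, para_index, start, start + len(surface), surface))
                gap = " ".join(_filler_tokens(rng, vocab, int(rng.integers(1, 4))))
                text = text + " " + gap
            paragraphs.append(Paragraph(text, "body"))

        keywords: frozenset[str] | None = None
        if rng.random() < spec.keyword_doc_prob:
            kws = {cid for cid in planted if rng.random() < spec.keyword_pick_prob}
            others = set(ids) - set(planted)
            for _ in range(int(rng.integers(0, 3))):
                if others:
                    kws.add(str(rng.choice(sorted(others))))
            keywords = frozenset(kws)

        documents.append(Document(doc_id=doc_id, paragraphs=paragraphs, keywords=keywords))
        gt.mentions_by_doc[doc_id] = mention_records
        gt.method_ids_by_doc[doc_id] = frozenset(planted)
        gt.document_frequency.update(set(planted))
    return documents, gt


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[Taxonomy, frozenset[str], list[Document], GroundTruth]:
    """Taxonomy, robotic seeds, corpus and ground truth from one spec."""
    tax, seeds = generate_taxonomy(spec)
    documents, gt = generate_corpus(spec, tax)
    return tax, seeds, documents, gt


def write_synthetic_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit the files the pipeline consumes, plus the ground truth JSON.

    Returns the paths of ``taxonomy.csv``, ``seeds.csv``, ``corpus.jsonl``
    and ``ground_truth.json`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tax, seeds, documents, gt = generate_dataset(spec)
    paths = {
        "taxonomy": out_dir / "taxonomy.csv",
        "seeds": out_dir / "seeds.csv",
        "corpus": out_dir / "corpus.jsonl",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_taxonomy(tax, paths["taxonomy"])
    write_seed_ids(seeds, paths["seeds"], tax)
    write_corpus(documents, paths["corpus"])
    paths["ground_truth"].write_text(gt.to_json(), encoding="utf-8")
    return paths


def ground_truth_profiles(gt: GroundTruth, mapping: MethodMapping) -> list[DocumentMethodProfile]:
    """Profiles computed directly from planted sets — the end-to-end oracle."""
    profiles = []
    for doc_id in sorted(gt.method_ids_by_doc):
        planted = gt.method_ids_by_doc[doc_id]
        robotic = frozenset(c for c in planted if c in mapping.robotic_ids)
        profiles.append(
            DocumentMethodProfile(
                doc_id=doc_id,
                method_ids=planted,
                robotic_ids=robotic,
                nonrobotic_ids=planted - robotic,
            )
        )
    return profiles
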