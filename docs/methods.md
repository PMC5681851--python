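# Methods

## Model and procedure

The pipeline treats method detection as dictionary-based concept
recognition (entity linking against a controlled vocabulary) followed by
set-level coverage statistics.

**Method space.** The vocabulary is a polyhierarchical DAG of concepts,
each with a preferred label, optional synonyms ("entry terms") and any
number of parents.  A designated set of method roots defines the method
subtree: the union of `{root} ∪ descendants(root)` over all roots.
Descendant traversal uses a visited set, so a concept reachable along
several paths (a diamond) counts once.

**Robotic classification.** A curated seed list names concepts a
commercial robotic lab can execute.  The robotic set is the self-inclusive
descendant closure of the seeds — children of a mapped concept are taken
to be finer-grained variants of the same method — and is idempotent under
re-expansion.  The closure deliberately never ascends: a general concept
whose child is a seed remains non-robotic.  Every concept id is then
exactly one of ROBOTIC, NON_ROBOTIC (method subtree minus the closure) or
NON_METHOD (everything else, including ids unknown to the taxonomy).
Seeds lying outside the method subtree are retained in the robotic set but
reported as warnings: the seed list is an external curation the pipeline
should surface, not silently repair.

**Annotation.** Every preferred label and synonym becomes a lexicon entry
keyed by its case-folded string; a string owned by k concepts maps to all
k, and each match of it yields k co-located mentions (no disambiguation
model).  Matching is exact (no stemming, no inflection, no inversion of
"Blotting, Western"-style labels — inverted forms must be supplied as
synonyms) and case-insensitive, with greedy leftmost-longest,
non-overlapping selection.  Token boundaries are transitions between
alphanumeric and non-alphanumeric characters; a match must start and end
at boundaries, so "PCR" never fires inside "ePCR2".  Only content
paragraphs (roles `body` and `other`) are annotated; titles, abstracts,
headings, figure text and references are skipped.  Because paragraphs are
annotated independently, no mention spans a paragraph boundary, and
offsets are paragraph-local.  By default the lexicon indexes the whole
taxonomy, not just the method subtree, mirroring the practice of
annotating against the full vocabulary and classifying afterwards.

The matcher itself is a length-indexed hash lookup: at each candidate
position the distinct entry lengths are probed longest-first.  With a few
hundred to a few thousand entries this is linear in text length times the
number of distinct entry lengths, which is ample for corpus-scale runs;
its behaviour is pinned by equivalence tests against a brute-force
find-all-then-select oracle on adversarial small-alphabet lexicons.

**Statistics.** All downstream quantities are distinct-concept based: a
method counts once per document regardless of mention multiplicity, and
frequency tables report document frequency.  The per-document robotic
fraction |robotic|/|detected methods| is undefined (not zero) for
method-free documents, which are excluded from threshold tables and from
the mean-robotic denominator but retained in corpus totals.  The
coverage-threshold table reports the share of method-bearing documents
with fraction = 1.0, ≥ 0.75 and ≥ 0.50; these are nested by construction.
Keyword overlap compares a document's detected method set against its
indexed-keyword set as |methods ∩ keywords| / |methods|, scoring only
documents that have both keywords and at least one detected method and
counting the excluded ones separately.  Percentages are kept unrounded in
machine output and rounded half-away-from-zero for display.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `restrict_to_method_subtree` | off | index only the method subtree instead of the whole vocabulary |
| `top_k` | 10 | rows in the document-frequency tables |
| `SyntheticSpec.n_concepts` | 200 | taxonomy size |
| `SyntheticSpec.max_children` | 4 | out-degree cap of the concept DAG |
| `SyntheticSpec.extra_parent_prob` | 0.15 | chance of a second parent (polyhierarchy) |
| `SyntheticSpec.synonyms_mean` | 2.0 | Poisson mean synonyms per concept (capped at 5) |
| `SyntheticSpec.n_docs` | 500 | corpus size |
| `SyntheticSpec.methods_per_doc_mean` | 7.0 | mean distinct planted methods per article |
| `SyntheticSpec.methods_per_doc_dispersion` | 4.0 | negative-binomial dispersion (right skew) |
| `SyntheticSpec.robotic_seed_fraction` | 0.12 | share of non-root concepts drawn as robotic seeds |

The per-document distinct-method count is negative binomial with the
given mean and dispersion, truncated at the taxonomy size: method-usage
counts in real articles are right-skewed, with most articles using a
handful of methods and a tail using many.  Robotic seeds are drawn 75%
from leaves and 25% from internal nodes, echoing how such seed lists are
curated in practice (an exact-match leaf concept plus its children,
occasionally a more general concept); under the defaults the expanded
closure covers roughly a quarter to a half of the vocabulary, so a
typical article carries a few robotic methods and roughly three quarters
to nine tenths of articles carry at least one.

## What the generator emulates — and what it does not

The generator reproduces the *structural* conditions of a method-coverage
study: a DAG-shaped vocabulary with synonyms, a seed subset expanded by
closure, articles whose content paragraphs embed method terms (label or a
synonym, in random letter case) amid filler, decoy method terms placed in
abstracts to exercise the content-paragraph rule, duplicate mentions to
exercise distinct-concept semantics, and keyword sets mixing planted and
unrelated concepts.  Term strings are pronounceable nonsense built from
one character alphabet; filler tokens use a disjoint alphabet, so no
filler can match a lexicon entry, and because planted surfaces are whole
terms separated by filler, greedy leftmost-longest matching recovers
exactly the planted mentions.  Recovery being perfect is therefore a
*design property*, and the end-to-end tests assert identity, not
approximation.

That is also the limitation: real text has inflected and abbreviated
method names, ambiguous strings shared with non-method senses, hyphenation
and line-break artifacts, and vocabulary gaps.  Passing the synthetic
suite shows the bookkeeping — closure, matching policy, paragraph
selection, distinct-concept statistics — is correct; it says nothing about
the recall of exact matching on real prose, which published comparisons
of dictionary annotators place far below 1.

## Numerical and design choices

- **Offsets.** Case folding is per-character and length-preserving (the
  rare characters whose lowercase expands are left unfolded), so mention
  offsets always index the original paragraph string.
- **Ties and determinism.** Frequency tables sort by frequency descending
  then label ascending (stable sort); co-located ambiguous mentions sort
  by concept id; corpus loading sorts by document id; all JSON is emitted
  with sorted keys and no timestamps, making rerun outputs byte-identical.
- **Degenerate inputs.** Empty corpora yield zero counts with undefined
  (null) means and percentages rather than NaNs; header-only CSV/TSV files
  yield empty collections; a document whose only method term sits in the
  abstract yields an empty profile.
- **Taxonomy CSV.** Multi-valued fields are pipe-separated, which reserves
  `|` inside synonym strings; an optional `is_method_root` column persists
  the method roots so one file round-trips the whole structure.
- **Validation reporting.** Structural violations (cycles, dangling
  parents, empty labels) are returned as data from `validate_taxonomy`;
  `load_taxonomy` turns any violation into an error so later stages can
  assume a valid DAG.
- **External annotations.** Unknown concept ids in an ingested TSV are
  retained (they classify as NON_METHOD) and surfaced as a warning count,
  so an external annotator's broader vocabulary does not crash the run but
  is visible in the report.
- **Problem sizes.** The test suite and the acceptance script run the full
  pipeline at 500 documents × 200 concepts, which exercises every code
  path at comfortably interactive speed; the matcher and closure
  operations scale linearly well beyond that.

## Known limitations

- Exact matching cannot see morphological variants or abbreviations that
  are not explicit synonyms; recall on real corpora depends entirely on
  vocabulary coverage.
- No disambiguation: an ambiguous term contributes one mention per owning
  concept, which can inflate distinct-method counts where vocabularies
  share strings.
- The mention-level overlap policy (leftmost-longest) discards shorter
  nested matches; statistics that needed *all* candidate interpretations
  would require a different matcher mode.
- Synonyms containing the `|` character cannot be represented in the CSV
  dialect.
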