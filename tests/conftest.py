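from __future__ import annotations

import pytest

from methodminer.taxonomy import Concept, Taxonomy


def make_taxonomy(
    edges: dict[str, set[str]],
    labels: dict[str, str] | None = None,
    synonyms: dict[str, set[str]] | None = None,
    method_roots: set[str] | None = None,
) -> Taxonomy:
    """Build a Taxonomy from a child -> parents edge mapping."""
    labels = labels or {}
    synonyms = synonyms or {}
    concepts = {
        cid: Concept(
            concept_id=cid,
            preferred_label=labels.get(cid, f"label {cid}"),
            synonyms=frozenset(synonyms.get(cid, set())),
            parent_ids=frozenset(parents),
        )
        for cid, parents in edges.items()
    }
    return Taxonomy(concepts=concepts, method_root_ids=frozenset(method_roots or set()))


@pytest.fixture
def chain_taxonomy() -> Taxonomy:
    """a -> b -> c, method root a."""
    return make_taxonomy({"a": set(), "b": {"a"}, "c": {"b"}}, method_roots={"a"})


@pytest.fixture
def diamond_taxonomy() -> Taxonomy:
    """a -> {b, c} -> d (polyhierarchy: d has two parents)."""
    return make_taxonomy(
        {"a": set(), "b": {"a"}, "c": {"a"}, "d": {"b", "c"}}, method_roots={"a"}
    )


def random_dag_edges(rng, n_nodes: int, edge_prob: float = 0.25) -> dict[str, set[str]]:
    """Random DAG as child -> parents; node i may only have parents j < i."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges: dict[str, set[str]] = {name: set() for name in names}
    for i in range(1, n_nodes):
        for j in range(i):
            if rng.random() < edge_prob:
                edges[names[i]].add(names[j])
    return edges
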