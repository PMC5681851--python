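"""Independent brute-force oracles used by property and acceptance tests.

Everything here is deliberately naive — repeated-join reachability and a
find-all-then-select matcher — and shares no code with the implementation
it checks.
"""

from __future__ import annotations


def brute_force_descendants(parent_ids_by_node: dict[str, set[str]], node: str) -> set[str]:
    """Transitive children of ``node`` by fixed-point over the edge list.

    ``parent_ids_by_node`` maps each node to its parents (the raw CSV
    relation).  Repeatedly joins the child relation until nothing new is
    reachable.
    """
    edges = {
        (parent, child)
        for child, parents in parent_ids_by_node.items()
        for parent in parents
    }
    reached: set[str] = set()
    frontier = {child for parent, child in edges if parent == node}
    while frontier - reached:
        reached |= frontier
        frontier = {child for parent, child in edges if parent in reached}
    return reached


def brute_force_closure(parent_ids_by_node: dict[str, set[str]], seeds: set[str]) -> set[str]:
    """Self-inclusive descendant closure of a seed set."""
    out = set(seeds)
    for s in seeds:
        out |= brute_force_descendants(parent_ids_by_node, s)
    return out


def _fold(s: str) -> str:
    return s.lower()


def _boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and text[start - 1].isalnum() and text[start].isalnum():
        return False
    if end < len(text) and text[end - 1].isalnum() and text[end].isalnum():
        return False
    return True


def brute_force_annotate(entries: dict[str, set[str]], text: str) -> list[tuple[str, int, int]]:
    """All-candidates matcher: find every case-insensitive occurrence of
    every entry, keep those at token boundaries, then select greedy
    leftmost-longest non-overlapping spans.

    Returns (concept_id, start, end) triples sorted by (start, concept_id).
    """
    folded = _fold(text)
    candidates: list[tuple[int, int, frozenset[str]]] = []
    for term, cids in entries.items():
        needle = _fold(term)
        if not needle:
            continue
        pos = folded.find(needle)
        while pos != -1:
            end = pos + len(needle)
            if _boundary_ok(folded, pos, end):
                candidates.append((pos, end, frozenset(cids)))
            pos = folded.find(needle, pos + 1)

    # leftmost-longest sweep: scan positions left to right, at each free
    # position take the longest candidate starting there
    by_start: dict[int, list[tuple[int, int, frozenset[str]]]] = {}
    for c in candidates:
        by_start.setdefault(c[0], []).append(c)
    out: list[tuple[str, int, int]] = []
    cursor = 0
    for start in sorted(by_start):
        if start < cursor:
            continue
        best = max(by_start[start], key=lambda c: c[1])
        for cid in sorted(best[2]):
            out.append((cid, best[0], best[1]))
        cursor = best[1]
    return sorted(out, key=lambda t: (t[1], t[0]))
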