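"""Shared fixtures and independent brute-force oracles.

The oracle functions work on a plain ``{child: set(parents)}`` adjacency
dict with hand-rolled breadth-first search, deliberately independent of the
package's graph machinery, so hierarchy distances can be cross-checked.
"""

from __future__ import annotations

from collections import deque

import pytest

from heleval.ontology import Entity, HierVocabulary
from heleval.synthetic import fruit_fixture


@pytest.fixture(scope="session")
def fruit():
    return fruit_fixture()


@pytest.fixture()
def diamond():
    """A -> (B, C) -> D: the smallest multi-parent DAG."""
    ents = {i: Entity(i) for i in "ABCD"}
    return HierVocabulary(ents, [("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


def parent_map(vocab: HierVocabulary) -> dict[str, set[str]]:
    """Extract the raw child -> parents adjacency for the oracles."""
    out: dict[str, set[str]] = {e: set() for e in vocab}
    for child, parent in vocab.parent_edges:
        out[child].add(parent)
    return out


def bfs_up(parents: dict[str, set[str]], start: str) -> dict[str, int]:
    """Upward BFS distances from ``start`` to every inclusive ancestor."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for p in parents[node]:
            if p not in dist:
                dist[p] = dist[node] + 1
                queue.append(p)
    return dist


def brute_depth(parents: dict[str, set[str]], node: str) -> int:
    dist = bfs_up(parents, node)
    return min(d for n, d in dist.items() if not parents[n])


def brute_lca(parents: dict[str, set[str]], a: str, b: str):
    """(minimising common-ancestor set, minimal summed distance) or (set(), None)."""
    da, db = bfs_up(parents, a), bfs_up(parents, b)
    common = da.keys() & db.keys()
    if not common:
        return set(), None
    best = min(da[c] + db[c] for c in common)
    return {c for c in common if da[c] + db[c] == best}, best


def brute_match_distance(parents: dict[str, set[str]], target: str, predicted: str):
    """0 / one-directional ancestor distance / up-up sum through a common ancestor."""
    if target == predicted:
        return 0
    up_from_pred = bfs_up(parents, predicted)
    if target in up_from_pred:
        return up_from_pred[target]
    up_from_target = bfs_up(parents, target)
    if predicted in up_from_target:
        return up_from_target[predicted]
    return brute_lca(parents, target, predicted)[1]
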