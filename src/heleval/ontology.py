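"""Hierarchical vocabularies as rooted, multi-parent directed acyclic graphs.

An entity-linking vocabulary (MeSH, an OBO ontology, SNOMED CT, ...) orders
its entities by the ``subClassOf`` (``is_a``) relation.  This module loads
such a vocabulary from an OBO file or a plain child/parent edge list and
answers the structural queries every hierarchy-aware metric needs:

* ``depth`` — shortest upward distance from an entity to a root, a proxy for
  granularity;
* ``ancestor_distance`` — shortest strictly-upward path between an entity
  and one of its ancestors;
* ``lowest_common_ancestors`` — the common ancestors minimising the summed
  upward distance from both query entities.

Edges are stored child → parent, so "upward" always follows edge direction.
Because real vocabularies are poly-hierarchies (a MeSH descriptor can sit
under several parents), every quantity is a minimum over parent paths, never
a tree traversal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Identifier of the synthetic super-root optionally inserted above all roots
#: so that entities in disconnected components still share an ancestor.
VIRTUAL_ROOT = "__VIRTUAL_ROOT__"


class VocabularyError(ValueError):
    """The vocabulary violates a structural invariant (cycle, missing id, ...)."""


class CycleError(VocabularyError):
    """The subClassOf graph contains a cycle."""


class UnknownEntityError(KeyError):
    """An entity id was queried that is not part of the vocabulary."""


class NoCommonAncestorError(VocabularyError):
    """Two entities share no ancestor (disconnected components, no virtual root)."""


@dataclass(frozen=True)
class Entity:
    """One vocabulary concept.

    ``synonyms`` are carried through from the source file for reporting; no
    metric in this package reads them.
    """

    id: str
    label: str = ""
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise VocabularyError("entity id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)


class HierVocabulary:
    """A rooted multi-parent DAG of entities linked by subClassOf edges.

    Parameters
    ----------
    entities
        Mapping from entity id to :class:`Entity`.  Every edge endpoint must
        appear here.
    parent_edges
        Iterable of ``(child_id, parent_id)`` pairs.

    Raises
    ------
    VocabularyError
        If an edge endpoint is missing, the graph is cyclic, or there is no
        root.
    """

    def __init__(
        self,
        entities: Mapping[str, Entity],
        parent_edges: Iterable[tuple[str, str]],
    ) -> None:
        self._entities: dict[str, Entity] = dict(entities)
        graph = nx.DiGraph()
        graph.add_nodes_from(self._entities)
        for child, parent in parent_edges:
            missing = [e for e in (child, parent) if e not in self._entities]
            if missing:
                raise VocabularyError(
                    f"edge ({child!r}, {parent!r}) references unknown ids: {missing}"
                )
            if child == parent:
                raise CycleError(f"self-loop on {child!r}")
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise CycleError(f"subClassOf graph is cyclic, e.g. {cycle}")
        self._graph = graph
        roots = frozenset(n for n in graph.nodes if graph.out_degree(n) == 0)
        if not roots:
            raise VocabularyError("vocabulary has no root entity")
        self._roots = roots
        self._leaves = frozenset(n for n in graph.nodes if graph.in_degree(n) == 0)
        self._depths: dict[str, int] | None = None
        self._leaf_dist: dict[str, int] | None = None
        self._up_cache: dict[str, dict[str, int]] = {}

    # -- basic container protocol -------------------------------------------------

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._entities

    def __len__(self) -> int:
        return len(self._entities)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entities)

    @property
    def entities(self) -> Mapping[str, Entity]:
        return self._entities

    @property
    def roots(self) -> frozenset[str]:
        return self._roots

    @property
    def leaves(self) -> frozenset[str]:
        """Entities with no children."""
        return self._leaves

    @property
    def parent_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._graph.edges)

    def entity(self, entity_id: str) -> Entity:
        self._check(entity_id)
        return self._entities[entity_id]

    def parents(self, entity_id: str) -> frozenset[str]:
        self._check(entity_id)
        return frozenset(self._graph.successors(entity_id))

    def children(self, entity_id: str) -> frozenset[str]:
        self._check(entity_id)
        return frozenset(self._graph.predecessors(entity_id))

    # -- structural queries -------------------------------------------------------

    def depth(self, entity_id: str) -> int:
        """Shortest upward distance to any root; 0 iff the entity is a root."""
        self._check(entity_id)
        if self._depths is None:
            reverse = self._graph.reverse(copy=False)
            self._depths = dict(
                nx.multi_source_dijkstra_path_length(reverse, set(self._roots))
            )
        return self._depths[entity_id]

    def leaf_distance(self, entity_id: str) -> int:
        """Shortest downward distance to a leaf descendant; 0 iff a leaf."""
        self._check(entity_id)
        if self._leaf_dist is None:
            # BFS upward from all leaves: the distance at which a node is first
            # reached equals its shortest downward distance to any leaf.
            self._leaf_dist = dict(
                nx.multi_source_dijkstra_path_length(self._graph, set(self._leaves))
            )
        return self._leaf_dist[entity_id]

    def ancestor_distances(self, entity_id: str) -> Mapping[str, int]:
        """Distances from ``entity_id`` to every inclusive ancestor (self at 0)."""
        self._check(entity_id)
        cached = self._up_cache.get(entity_id)
        if cached is None:
            cached = dict(nx.single_source_shortest_path_length(self._graph, entity_id))
            self._up_cache[entity_id] = cached
        return cached

    def ancestor_distance(self, descendant: str, ancestor: str) -> int | None:
        """Shortest strictly-upward path length, or None if not an ancestor.

        ``ancestor_distance(e, e)`` is 0: for subset semantics an entity is
        its own (improper) ancestor.
        """
        self._check(ancestor)
        return self.ancestor_distances(descendant).get(ancestor)

    def ancestors(self, entity_id: str) -> frozenset[str]:
        """Strict ancestors (excludes the entity itself)."""
        dists = self.ancestor_distances(entity_id)
        return frozenset(k for k in dists if k != entity_id)

    def descendants(self, entity_id: str) -> frozenset[str]:
        self._check(entity_id)
        return frozenset(nx.ancestors(self._graph, entity_id))

    def lowest_common_ancestors(self, a: str, b: str) -> frozenset[str]:
        """All common ancestors minimising summed upward distance from a and b.

        Both entities are compared inclusively, so the LCA of an
        ancestor/descendant pair is the ancestor itself and the LCA of
        ``(e, e)`` is ``e``.
        """
        return self.lca_with_distance(a, b)[0]

    def lca_with_distance(self, a: str, b: str) -> tuple[frozenset[str], int]:
        """Minimising common-ancestor set together with the minimal summed distance."""
        da = self.ancestor_distances(a)
        db = self.ancestor_distances(b)
        common = da.keys() & db.keys()
        if not common:
            raise NoCommonAncestorError(
                f"{a!r} and {b!r} share no ancestor; enable the virtual root to bridge components"
            )
        best = min(da[c] + db[c] for c in common)
        return frozenset(c for c in common if da[c] + db[c] == best), best

    def with_virtual_root(self) -> "HierVocabulary":
        """Copy of the vocabulary with a synthetic super-root above all roots.

        Guarantees every pair of entities has a common ancestor; distances
        across formerly disconnected components pass through the new root.
        """
        if VIRTUAL_ROOT in self._entities:
            return self
        entities = dict(self._entities)
        entities[VIRTUAL_ROOT] = Entity(VIRTUAL_ROOT, "virtual root")
        edges = list(self._graph.edges)
        edges.extend((r, VIRTUAL_ROOT) for r in self._roots)
        return HierVocabulary(entities, edges)

    # -- helpers ------------------------------------------------------------------

    def _check(self, entity_id: str) -> None:
        if entity_id not in self._entities:
            raise UnknownEntityError(f"unknown entity id {entity_id!r}")


# -- file formats -----------------------------------------------------------------

_SYNONYM_RE = re.compile(r'"([^"]*)"')


def _obo_synonyms(data: Mapping) -> tuple[str, ...]:
    out = []
    for raw in data.get("synonym", ()):
        m = _SYNONYM_RE.search(raw)
        out.append(m.group(1) if m else raw)
    return tuple(out)


def load_obo(path: str | Path) -> HierVocabulary:
    """Load a vocabulary from an OBO 1.2/1.4 flat file.

    Only ``is_a`` edges define the hierarchy.  Obsolete terms are dropped,
    together with any edge touching them (logged).  An ``is_a`` target that
    has no stanza of its own is a validation error.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    obsolete = {
        n
        for n, d in graph.nodes(data=True)
        if str(d.get("is_obsolete", "false")).lower() == "true"
    }
    # obonet materialises is_a targets without stanzas as data-less nodes
    missing = sorted(n for n, d in graph.nodes(data=True) if not d)
    if missing:
        raise VocabularyError(f"is_a targets with no term stanza: {missing}")
    entities = {
        n: Entity(n, d.get("name", n), _obo_synonyms(d))
        for n, d in graph.nodes(data=True)
        if n not in obsolete
    }
    edges = []
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        if child in obsolete or parent in obsolete:
            logger.warning("dropping is_a edge %r -> %r touching an obsolete term", child, parent)
            continue
        edges.append((child, parent))
    return HierVocabulary(entities, edges)


def load_edge_list(path: str | Path) -> HierVocabulary:
    """Load a vocabulary from a two-column TSV ``child<TAB>parent`` with header.

    Entities are the union of both columns; labels default to the ids.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise VocabularyError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip().lower() for h in header] != ["child", "parent"]:
        raise VocabularyError(f"{path}: expected header 'child<TAB>parent', got {lines[0]!r}")
    edges: list[tuple[str, str]] = []
    ids: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise VocabularyError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        child, parent = (f.strip() for f in fields)
        ids.update((child, parent))
        edges.append((child, parent))
    if not ids:
        raise VocabularyError(f"{path}: no edges after header (roots would be empty)")
    return HierVocabulary({i: Entity(i) for i in sorted(ids)}, edges)


def write_obo(vocab: HierVocabulary, path: str | Path) -> None:
    """Serialise a vocabulary as a minimal OBO flat file (``is_a`` only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: heleval-vocabulary\n")
        for eid in sorted(vocab):
            ent = vocab.entity(eid)
            fh.write(f"\n[Term]\nid: {eid}\nname: {ent.label}\n")
            for syn in ent.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(vocab.parents(eid)):
                fh.write(f"is_a: {parent} ! {vocab.entity(parent).label}\n")


def write_edge_list(vocab: HierVocabulary, path: str | Path) -> None:
    """Serialise the parent edges as a ``child<TAB>parent`` TSV with header."""
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(vocab.parent_edges):
            fh.write(f"{child}\t{parent}\n")
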