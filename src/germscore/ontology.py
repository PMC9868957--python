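"""Phenotype ontology handling: parsing, annotation propagation, term mapping.

A phenotype ontology is modelled as a rooted directed acyclic graph of terms
linked by is-a edges (child -> parent).  Gene-phenotype annotations obey the
true-path rule: a gene annotated to a term is implicitly annotated to every
ancestor of that term.  Annotation expansion applies that rule *after*
removing an excluded subtree (typically the neoplasm branch), so a gene
annotated only inside the excluded subtree contributes nothing to any
ancestor, while a gene that also reaches an ancestor through a non-excluded
descendant keeps that ancestor.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class Ontology:
    """Rooted DAG of phenotype terms with is-a (child -> parent) edges."""

    terms: frozenset[str]
    parents: dict[str, tuple[str, ...]]
    children: dict[str, tuple[str, ...]]
    root: str
    names: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise OntologyError(f"unknown term: {term!r}")

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Child -> parent pairs."""
        return {(c, p) for c, ps in self.parents.items() for p in ps}


@dataclass(frozen=True)
class AnnotationSet:
    """Gene <-> term association pairs, either as deposited or propagated."""

    pairs: frozenset[tuple[str, str]]
    state: str  # "direct" | "expanded"

    def __post_init__(self) -> None:
        if self.state not in ("direct", "expanded"):
            raise ValueError(f"invalid state: {self.state!r}")

    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def genes_for(self, term: str) -> set[str]:
        return {g for g, t in self.pairs if t == term}


def _build(terms: Iterable[str], edges: Iterable[tuple[str, str]],
           names: Mapping[str, str] | None = None,
           alt_ids: Mapping[str, str] | None = None) -> Ontology:
    """Assemble and validate an Ontology from terms and child->parent edges."""
    terms = frozenset(terms)
    parents: dict[str, list[str]] = {t: [] for t in terms}
    children: dict[str, list[str]] = {t: [] for t in terms}
    for child, parent in edges:
        for t in (child, parent):
            if t not in terms:
                raise OntologyError(f"is_a reference to undeclared term: {t!r}")
        parents[child].append(parent)
        children[parent].append(child)

    g = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    try:
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology graph contains a cycle through edge "
                            f"{cycle[0][0]!r} -> {cycle[0][1]!r}")
    except nx.NetworkXNoCycle:
        pass

    roots = sorted(t for t in terms if not parents[t])
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one root term, found {len(roots)}: {roots[:5]}")

    return Ontology(
        terms=terms,
        parents={t: tuple(sorted(ps)) for t, ps in parents.items()},
        children={t: tuple(sorted(cs)) for t, cs in children.items()},
        root=roots[0],
        names=dict(names or {}),
        alt_ids=dict(alt_ids or {}),
    )


def load_obo(path) -> Ontology:
    """Parse an OBO 1.2 file (id / name / is_a / alt_id / is_obsolete subset).

    Obsolete terms are dropped (obonet skips them; a count is logged when the
    file declares any).  alt_ids are recorded and resolved to primary ids on
    lookup.  A term whose ``is_a`` target is never declared, a cyclic graph,
    or a graph without a unique root is a hard error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)

    undeclared = [n for n, d in graph.nodes(data=True) if "name" not in d]
    if undeclared:
        raise OntologyError(
            f"is_a reference to undeclared term: {sorted(undeclared)[0]!r}")

    terms = set(graph.nodes)
    edges = [(c, p) for c, p, k in graph.edges(keys=True) if k == "is_a"]
    names = {n: d.get("name", n) for n, d in graph.nodes(data=True)}
    alt_ids: dict[str, str] = {}
    for n, d in graph.nodes(data=True):
        for alt in d.get("alt_id", []):
            alt_ids[alt] = n

    return _build(terms, edges, names, alt_ids)


def write_obo(ontology: Ontology, path) -> None:
    """Serialize an Ontology back to the OBO subset ``load_obo`` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: germscore-synthetic\n")
        for term in sorted(ontology.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {ontology.names.get(term, term)}\n")
            for parent in ontology.parents[term]:
                fh.write(f"is_a: {parent}\n")


def _check_term(ontology: Ontology, term: str) -> str:
    if term not in ontology.terms:
        return ontology.resolve(term)  # raises OntologyError when unknown
    return term


def descendants(ontology: Ontology, term: str) -> set[str]:
    """All terms below ``term`` (transitive closure of the child relation)."""
    term = _check_term(ontology, term)
    seen: set[str] = set()
    queue = deque(ontology.children[term])
    while queue:
        t = queue.popleft()
        if t not in seen:
            seen.add(t)
            queue.extend(ontology.children[t])
    return seen


def ancestors(ontology: Ontology, term: str) -> set[str]:
    """All terms above ``term`` (transitive closure of the parent relation)."""
    term = _check_term(ontology, term)
    seen: set[str] = set()
    queue = deque(ontology.parents[term])
    while queue:
        t = queue.popleft()
        if t not in seen:
            seen.add(t)
            queue.extend(ontology.parents[t])
    return seen


def expand_annotations(direct: AnnotationSet, ontology: Ontology,
                       exclude_root: str) -> AnnotationSet:
    """Propagate annotations to ancestors after deleting an excluded subtree.

    Every pair whose term is ``exclude_root`` or one of its descendants is
    deleted first; each surviving pair is then propagated to all ancestors of
    its term.  A gene annotated only inside the excluded subtree therefore
    loses all its annotations, while a second, non-excluded annotation still
    carries the gene to shared ancestors.

    Accepts an already-expanded set as input, in which case the operation is
    idempotent.
    """
    exclude_root = _check_term(ontology, exclude_root)
    excluded = descendants(ontology, exclude_root) | {exclude_root}

    out: set[tuple[str, str]] = set()
    anc_cache: dict[str, set[str]] = {}
    for gene, term in direct.pairs:
        term = _check_term(ontology, term)
        if term in excluded:
            continue
        if term not in anc_cache:
            anc_cache[term] = ancestors(ontology, term)
        out.add((gene, term))
        out.update((gene, a) for a in anc_cache[term])
    return AnnotationSet(pairs=frozenset(out), state="expanded")


def closest_scored_ancestor(term: str, scored: set[str], ontology: Ontology,
                            gene_counts: Mapping[str, int] | None = None,
                            ) -> str | None:
    """Map a term to itself or the nearest scored ancestor.

    Distance is the minimal number of upward is-a edges (breadth-first search
    over parent edges).  Ties at equal distance are broken by higher
    annotated-gene count (when ``gene_counts`` is given), then by term id.
    Returns None when no ancestor is scored.
    """
    term = _check_term(ontology, term)
    if term in scored:
        return term
    frontier = [term]
    seen = {term}
    while frontier:
        nxt: set[str] = set()
        for t in frontier:
            nxt.update(p for p in ontology.parents[t] if p not in seen)
        if not nxt:
            return None
        hits = nxt & scored
        if hits:
            if gene_counts is not None:
                return min(hits, key=lambda t: (-gene_counts.get(t, 0), t))
            return min(hits)
        seen.update(nxt)
        frontier = sorted(nxt)
    return None
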