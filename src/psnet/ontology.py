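"""Rooted ontology DAGs, Resnik information content and shared-ancestor queries.

The similarity machinery rests on three primitives over an ``is_a`` hierarchy:

* :func:`ancestors` — the reflexive transitive closure of a term's parents,
  which always contains the ontology root;
* :func:`compute_ic` — annotation-frequency information content,
  ``IC(t) = -ln p(t)`` with ``p(t)`` the fraction of annotated entities whose
  annotations fall on ``t`` or any of its descendants (Resnik);
* :func:`mica` / :func:`closest_common_ancestor` — the most informative,
  respectively the hop-nearest, common ancestor of two terms.

Ontologies are loaded from OBO 1.2/1.4 flat files (``hp.obo``, ``go.obo``,
``doid.obo`` dialects). Only ``is_a`` edges are used; ``part_of`` and other
relationship types are ignored. Obsolete terms are kept (flagged) so that
stale annotations can be remapped or reported, but they never take part in
ancestor queries.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO

logger = logging.getLogger(__name__)

#: Recognised namespace tags. GO is split into its three sub-ontologies.
NAMESPACES = ("HPO", "GO-BP", "GO-CC", "GO-MF", "DO")

_GO_NAMESPACE_TAGS = {
    "biological_process": "GO-BP",
    "cellular_component": "GO-CC",
    "molecular_function": "GO-MF",
}


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, missing root, ...)."""


@dataclass
class OntologyTerm:
    """A single ontology term with its ``is_a`` parents."""

    id: str
    name: str = ""
    parent_ids: set[str] = field(default_factory=set)
    namespace: str = ""
    obsolete: bool = False
    alt_ids: set[str] = field(default_factory=set)
    replaced_by: str | None = None


@dataclass
class OntologyDAG:
    """A rooted, acyclic ``is_a`` hierarchy for one namespace.

    ``terms`` maps primary accession to :class:`OntologyTerm`. Exactly one
    non-obsolete term has no parents: the root. Alternate accessions are
    resolved to primary ids through :meth:`resolve`.
    """

    terms: dict[str, OntologyTerm]
    namespace: str
    root_id: str
    _alt: dict[str, str] = field(default_factory=dict, repr=False)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _hops_cache: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str | None:
        """Map an accession (primary or alternate) to its primary id."""
        if term_id in self.terms:
            return term_id
        return self._alt.get(term_id)

    @property
    def active_ids(self) -> list[str]:
        """Sorted ids of non-obsolete terms."""
        return sorted(t for t, term in self.terms.items() if not term.obsolete)

    def children(self, term_id: str) -> set[str]:
        return {
            t.id
            for t in self.terms.values()
            if not t.obsolete and term_id in t.parent_ids
        }

    def depth(self, term_id: str) -> int:
        """Minimum number of is_a hops from ``term_id`` up to the root."""
        return _min_hops(self, term_id)[self.root_id]


def _iter_stanzas(stream: TextIO) -> Iterator[tuple[str, list[tuple[str, str]]]]:
    kind = None
    tags: list[tuple[str, str]] = []
    for raw in stream:
        line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            if kind is not None:
                yield kind, tags
            kind, tags = line.strip("[]"), []
        elif kind is not None and ":" in line:
            tag, value = line.split(":", 1)
            tags.append((tag.strip(), value.strip()))
    if kind is not None:
        yield kind, tags


def parse_obo(stream: TextIO | str, namespace: str) -> OntologyDAG:
    """Load an OBO 1.2/1.4 file as a rooted DAG for one namespace.

    For ``GO-BP``/``GO-CC``/``GO-MF`` only terms of the matching GO
    sub-ontology are kept; for ``HPO`` and ``DO`` every term is kept. Only
    ``is_a`` edges are retained. Raises :class:`OntologyError` on a cycle or
    when the namespace does not have exactly one root.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace tag {namespace!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    terms: dict[str, OntologyTerm] = {}
    for kind, tags in _iter_stanzas(stream):
        if kind != "Term":
            continue
        term = OntologyTerm(id="")
        ns_tag = None
        for tag, value in tags:
            if tag == "id":
                term.id = value
            elif tag == "name":
                term.name = value
            elif tag == "is_a":
                term.parent_ids.add(value.split()[0])
            elif tag == "alt_id":
                term.alt_ids.add(value)
            elif tag == "namespace":
                ns_tag = value
            elif tag == "is_obsolete" and value.lower() == "true":
                term.obsolete = True
            elif tag == "replaced_by" and term.replaced_by is None:
                term.replaced_by = value.split()[0]
        if not term.id:
            continue
        if namespace.startswith("GO-"):
            if ns_tag is not None and _GO_NAMESPACE_TAGS.get(ns_tag) != namespace:
                continue
        term.namespace = namespace
        if term.obsolete:
            term.parent_ids.clear()
        terms[term.id] = term

    # parents outside the kept term set (e.g. pruned by namespace filtering)
    # cannot appear in a valid DAG; drop them with a count.
    dangling = 0
    for term in terms.values():
        missing = {p for p in term.parent_ids if p not in terms}
        if missing:
            dangling += len(missing)
            term.parent_ids -= missing
    if dangling:
        logger.warning("%s: dropped %d unresolvable is_a parents", namespace, dangling)

    active = {t: term for t, term in terms.items() if not term.obsolete}
    if not active:
        raise OntologyError(f"{namespace}: no non-obsolete terms found")
    _check_acyclic(active)

    roots = sorted(t for t, term in active.items() if not term.parent_ids)
    if len(roots) != 1:
        raise OntologyError(
            f"{namespace}: expected exactly one root, found {len(roots)}: {roots[:5]}"
        )

    alt: dict[str, str] = {}
    for term in terms.values():
        for a in term.alt_ids:
            alt.setdefault(a, term.id)
    return OntologyDAG(terms=terms, namespace=namespace, root_id=roots[0], _alt=alt)


def _check_acyclic(active: Mapping[str, OntologyTerm]) -> None:
    # Kahn's algorithm; whatever survives sits on a cycle.
    n_children: dict[str, int] = {t: 0 for t in active}
    for term in active.values():
        for p in term.parent_ids:
            n_children[p] += 1
    queue = [t for t, n in n_children.items() if n == 0]
    seen = 0
    while queue:
        t = queue.pop()
        seen += 1
        for p in active[t].parent_ids:
            n_children[p] -= 1
            if n_children[p] == 0:
                queue.append(p)
    if seen != len(active):
        cyclic = sorted(t for t, n in n_children.items() if n > 0)
        raise OntologyError(f"cycle detected among terms: {cyclic[:10]}")


def write_obo(dag: OntologyDAG, stream: TextIO) -> None:
    """Emit the DAG as a minimal, valid OBO 1.2 document (sorted stanzas)."""
    stream.write("format-version: 1.2\n")
    go_ns = {v: k for k, v in _GO_NAMESPACE_TAGS.items()}
    for term_id in sorted(dag.terms):
        term = dag.terms[term_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        if term.name:
            stream.write(f"name: {term.name}\n")
        if dag.namespace in go_ns:
            stream.write(f"namespace: {go_ns[dag.namespace]}\n")
        for a in sorted(term.alt_ids):
            stream.write(f"alt_id: {a}\n")
        for p in sorted(term.parent_ids):
            stream.write(f"is_a: {p}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
            if term.replaced_by:
                stream.write(f"replaced_by: {term.replaced_by}\n")


def _require_active(dag: OntologyDAG, term_id: str) -> str:
    primary = dag.resolve(term_id)
    if primary is None:
        raise KeyError(f"unknown term {term_id!r} in {dag.namespace}")
    if dag.terms[primary].obsolete:
        raise KeyError(f"term {term_id!r} is obsolete in {dag.namespace}")
    return primary


def ancestors(dag: OntologyDAG, term_id: str) -> frozenset[str]:
    """Reflexive transitive is_a closure of ``term_id`` (always contains root)."""
    primary = _require_active(dag, term_id)
    cached = dag._anc_cache.get(primary)
    if cached is not None:
        return cached
    out: set[str] = {primary}
    stack = list(dag.terms[primary].parent_ids)
    while stack:
        p = stack.pop()
        if p not in out:
            out.add(p)
            stack.extend(dag.terms[p].parent_ids)
    result = frozenset(out)
    dag._anc_cache[primary] = result
    return result


def descendants(dag: OntologyDAG, term_id: str) -> frozenset[str]:
    """Reflexive transitive closure downward: all terms having ``term_id``
    as an ancestor (non-obsolete terms only)."""
    primary = _require_active(dag, term_id)
    return frozenset(t for t in dag.active_ids if primary in ancestors(dag, t))


@dataclass
class ICTable:
    """Resnik information content per term, in nats.

    ``ic[root] == 0`` and IC never decreases from parent to child. Terms with
    no annotated descendants receive the maximum IC observed in the corpus so
    similarity coefficients stay finite.
    """

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    @property
    def max_ic(self) -> float:
        return max(self.ic.values(), default=0.0)


def compute_ic(
    dag: OntologyDAG, annotations: Mapping[str, Iterable[str]]
) -> ICTable:
    """Annotation-frequency IC over a corpus of entity -> term-set annotations.

    An entity annotated to ``t`` counts for ``t`` and all its ancestors, so
    ``count(t)`` is the number of entities annotated to ``t`` or any
    descendant. Annotations to alternate ids are remapped; annotations to
    obsolete terms are remapped via ``replaced_by`` when possible, otherwise
    dropped with a warning. Raises ``ValueError`` on an empty corpus.
    """
    counts: dict[str, int] = {}
    n_entities = 0
    n_dropped = 0
    for entity, term_ids in annotations.items():
        closure: set[str] = set()
        for t in term_ids:
            primary = _remap_annotation(dag, t)
            if primary is None:
                n_dropped += 1
                continue
            closure |= ancestors(dag, primary)
        if not closure:
            continue
        n_entities += 1
        for a in closure:
            counts[a] = counts.get(a, 0) + 1
    if n_dropped:
        logger.warning(
            "%s: dropped %d annotations to unknown/obsolete terms",
            dag.namespace,
            n_dropped,
        )
    if n_entities == 0:
        raise ValueError("empty annotation corpus: no entity has a usable term")

    root_count = counts[dag.root_id]
    ic: dict[str, float] = {}
    for t in dag.active_ids:
        c = counts.get(t, 0)
        if c > 0:
            ic[t] = -math.log(c / root_count)
    fallback = max(ic.values(), default=0.0)
    for t in dag.active_ids:
        ic.setdefault(t, fallback)
    ic[dag.root_id] = 0.0
    return ICTable(ic=ic, corpus_size=n_entities)


def _remap_annotation(dag: OntologyDAG, term_id: str) -> str | None:
    primary = dag.resolve(term_id)
    if primary is None:
        return None
    term = dag.terms[primary]
    if term.obsolete:
        if term.replaced_by is not None:
            repl = dag.resolve(term.replaced_by)
            if repl is not None and not dag.terms[repl].obsolete:
                return repl
        return None
    return primary


def mica(dag: OntologyDAG, ic: ICTable, t1: str, t2: str) -> str:
    """Most informative common ancestor; IC ties break to the smallest id."""
    common = ancestors(dag, t1) & ancestors(dag, t2)
    return min(common, key=lambda a: (-ic.ic.get(a, 0.0), a))


def _min_hops(dag: OntologyDAG, term_id: str) -> dict[str, int]:
    """BFS hop distance from a term to each of its ancestors (upward only)."""
    primary = _require_active(dag, term_id)
    cached = dag._hops_cache.get(primary)
    if cached is not None:
        return cached
    dist = {primary: 0}
    frontier = [primary]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for p in dag.terms[t].parent_ids:
                if p not in dist:
                    dist[p] = dist[t] + 1
                    nxt.append(p)
        frontier = nxt
    dag._hops_cache[primary] = dist
    return dist


def closest_common_ancestor(
    dag: OntologyDAG, t1: str, t2: str, ic: ICTable | None = None
) -> str:
    """Common ancestor minimising the summed hop distance to both terms.

    Ties break to the higher-IC ancestor (when an IC table is supplied), then
    to the lexicographically smallest id.
    """
    d1 = _min_hops(dag, t1)
    d2 = _min_hops(dag, t2)
    common = set(d1) & set(d2)
    icmap = ic.ic if ic is not None else {}
    return min(common, key=lambda a: (d1[a] + d2[a], -icmap.get(a, 0.0), a))
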