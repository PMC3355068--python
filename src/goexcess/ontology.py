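"""Ontology DAG: parsing, ancestor closures, common-ancestor queries.

The ontology is a rooted DAG of terms in up to three namespaces
(``molecular_function``, ``biological_process``, ``cellular_component``).
Annotation propagation and all similarity measures traverse the two
GO-standard relations ``is_a`` and ``part_of``; other relations
(``regulates`` etc.) are ignored.  The ancestor closure is reflexive: a
term counts among its own ancestors, so identical annotations have
themselves as most-informative common ancestor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import OboParseError, OntologyValidationError, UnknownTermError

#: relations traversed for propagation and ancestor queries
TRAVERSED_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass
class Ontology:
    """A validated ontology DAG restricted to traversed relations.

    Parameters
    ----------
    graph
        Directed multigraph with edges pointing child -> parent and the
        relation name as edge key; only ``is_a``/``part_of`` edges.
    namespace_of
        Term -> namespace mapping for every non-obsolete term.
    roots
        Namespace -> root-term mapping (the terms with no parents).
    obsolete
        Identifiers excluded from the analysis at parse time.
    alt_ids
        Alias identifier -> canonical term mapping.
    """

    graph: nx.MultiDiGraph
    namespace_of: dict[str, str]
    roots: dict[str, str]
    obsolete: frozenset[str] = frozenset()
    alt_ids: dict[str, str] = field(default_factory=dict)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _depth_cache: dict[str, int] = field(default_factory=dict, repr=False)

    # -- lookups ---------------------------------------------------------
    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.namespace_of)

    def resolve(self, term: str) -> str:
        """Map an identifier (possibly an alt_id) to its canonical term."""
        if term in self.namespace_of:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(term)

    def parents_of(self, term: str) -> set[tuple[str, str]]:
        """Return ``{(parent, relation), ...}`` for a term."""
        term = self.resolve(term)
        return {(p, k) for _, p, k in self.graph.out_edges(term, keys=True)}

    def is_root(self, term: str) -> bool:
        return self.resolve(term) in set(self.roots.values())

    # -- closures --------------------------------------------------------
    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure over traversed relations."""
        term = self.resolve(term)
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._anc_cache[term] = cached
        return cached

    def common_ancestors(self, c_i: str, c_j: str) -> frozenset[str]:
        """Shared ancestors of two terms; empty for cross-namespace queries."""
        c_i, c_j = self.resolve(c_i), self.resolve(c_j)
        if self.namespace_of[c_i] != self.namespace_of[c_j]:
            return frozenset()
        return self.ancestors(c_i) & self.ancestors(c_j)

    def depth(self, term: str) -> int:
        """Longest path length from the term up to its namespace root."""
        term = self.resolve(term)
        cached = self._depth_cache.get(term)
        if cached is not None:
            return cached
        # iterative longest-path on the DAG, memoised
        stack = [term]
        while stack:
            t = stack[-1]
            if t in self._depth_cache:
                stack.pop()
                continue
            parents = [p for _, p, k in self.graph.out_edges(t, keys=True)]
            pending = [p for p in parents if p not in self._depth_cache]
            if pending:
                stack.extend(pending)
                continue
            self._depth_cache[t] = (
                1 + max(self._depth_cache[p] for p in parents) if parents else 0
            )
            stack.pop()
        return self._depth_cache[term]

    def terms_at_depth(self, namespace: str, depth: int, tolerance: int = 1) -> list[str]:
        """All terms of a namespace whose depth is within ``tolerance`` of ``depth``."""
        return sorted(
            t
            for t, ns in self.namespace_of.items()
            if ns == namespace and abs(self.depth(t) - depth) <= tolerance
        )


# -- module-level operations (thin wrappers kept for a functional API) ----

def ancestors(o: Ontology, term: str) -> frozenset[str]:
    return o.ancestors(term)


def common_ancestors(o: Ontology, c_i: str, c_j: str) -> frozenset[str]:
    return o.common_ancestors(c_i, c_j)


def _prescan(text: str) -> None:
    """Reject structurally malformed stanza lines before handing to obonet."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("[") :
            if not stripped.endswith("]"):
                raise OboParseError(f"line {lineno}: unterminated stanza header: {stripped!r}")
            continue
        if ":" not in stripped:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {stripped!r}")


def parse_obo(path) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into a validated :class:`Ontology`.

    Obsolete terms are excluded, their identifiers recorded, and ``alt_id``
    aliases mapped to their canonical term so downstream modules never see
    an alias.

    Raises
    ------
    OboParseError
        On malformed stanza lines (the message names the line).
    OntologyValidationError
        If the traversed graph is cyclic, a term cannot reach a namespace
        root, or a term reaches roots of more than one namespace.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    _prescan(text)
    try:
        raw = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet rarely raises after prescan
        raise OboParseError(str(exc)) from exc

    obsolete = {
        n for n, d in raw.nodes(data=True) if str(d.get("is_obsolete", "")).lower() == "true"
    }
    namespace_of: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for n, d in raw.nodes(data=True):
        if n in obsolete:
            continue
        ns = d.get("namespace")
        if ns is None:
            raise OntologyValidationError(f"term {n} has no namespace")
        namespace_of[n] = ns
        for alias in d.get("alt_id", []):
            alt_ids[alias] = n

    g = nx.MultiDiGraph()
    g.add_nodes_from(namespace_of)
    for child, parent, rel in raw.edges(keys=True):
        if rel not in TRAVERSED_RELATIONS:
            continue
        if child in namespace_of and parent in namespace_of:
            if namespace_of[child] != namespace_of[parent]:
                raise OntologyValidationError(
                    f"edge {child} -> {parent} crosses namespaces"
                )
            g.add_edge(child, parent, key=rel)

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyValidationError(f"traversed relations contain a cycle: {cycle}")

    roots: dict[str, str] = {}
    for n in g.nodes:
        if g.out_degree(n) == 0:
            ns = namespace_of[n]
            if ns in roots:
                raise OntologyValidationError(
                    f"namespace {ns} has multiple roots: {roots[ns]}, {n}"
                )
            roots[ns] = n

    o = Ontology(
        graph=g, namespace_of=namespace_of, roots=roots,
        obsolete=frozenset(obsolete), alt_ids=alt_ids,
    )
    root_set = set(roots.values())
    for n in g.nodes:
        hit = o.ancestors(n) & root_set
        if len(hit) != 1:
            raise OntologyValidationError(
                f"term {n} reaches {len(hit)} namespace roots (expected exactly 1)"
            )
    return o


def build_ontology(
    namespace_of: Mapping[str, str],
    edges: Iterable[tuple[str, str, str]],
) -> Ontology:
    """Construct an :class:`Ontology` directly from term/edge listings.

    Used by the synthetic generator and by tests; applies the same
    validation as :func:`parse_obo`.  ``edges`` are ``(child, parent,
    relation)`` triples.
    """
    lines = ["format-version: 1.2", "ontology: constructed", ""]
    by_term: dict[str, list[str]] = {t: [] for t in namespace_of}
    for child, parent, rel in edges:
        if rel == "is_a":
            by_term[child].append(f"is_a: {parent}")
        else:
            by_term[child].append(f"relationship: {rel} {parent}")
    for t in sorted(namespace_of):
        lines += [
            "[Term]", f"id: {t}", f"name: {t}", f"namespace: {namespace_of[t]}",
            *sorted(by_term[t]), "",
        ]
    return parse_obo(io.StringIO("\n".join(lines)))
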