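"""Controlled-vocabulary graphs: OBO parsing, ancestor closure and
annotation propagation.

A feature annotated to a term is *directly* annotated there and
*inheritedly* (indirectly) annotated to every ancestor of that term
reachable over the closure predicates (``is_a`` and ``part_of`` by
default, the standard GO propagation rules). Term-count summaries use
distinct-feature semantics: because a feature may be annotated under
several children of a focus term, per-child counts may legitimately sum
to more than the distinct total.

Ancestor sets are memoized on demand rather than materialized as a full
closure table, so only the visited fraction of the DAG is ever held.
"""

from __future__ import annotations

import io
import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

DEFAULT_CLOSURE_PREDICATES = frozenset({"is_a", "part_of"})

_CURIE_RE = re.compile(r"^[A-Za-z_][\w.\-]*:\S+$")
_SYNONYM_RE = re.compile(r'"([^"]*)"')


class OntologyError(ValueError):
    """Malformed or inconsistent ontology input."""


class OntologyCycleError(OntologyError):
    def __init__(self, nodes: Iterable[str]):
        self.nodes = sorted(set(nodes))
        super().__init__(
            "cycle among closure predicates involving: " + ", ".join(self.nodes)
        )


class UnknownTermError(KeyError):
    pass


@dataclass
class Term:
    term_id: str
    name: str = ""
    namespace: Optional[str] = None
    definition: Optional[str] = None
    is_obsolete: bool = False
    synonyms: list[str] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TermRelation:
    subject_id: str
    predicate: str
    object_id: str


@dataclass
class TermCountSummary:
    focus: str
    child_counts: dict[str, int]
    total: int


class OntologyGraph:
    """A DAG of terms and typed relations with ancestor closure."""

    def __init__(
        self,
        ontology_name: str = "ontology",
        closure_predicates: Iterable[str] = DEFAULT_CLOSURE_PREDICATES,
    ):
        self.ontology_name = ontology_name
        self.closure_predicates = frozenset(closure_predicates)
        self.terms: dict[str, Term] = {}
        self.relations: list[TermRelation] = []
        self._parents: dict[str, set[str]] = defaultdict(set)
        self._children: dict[str, set[str]] = defaultdict(set)
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- construction -------------------------------------------------

    def add_term(self, term: Term) -> None:
        if term.term_id in self.terms:
            raise OntologyError(f"duplicate term id {term.term_id!r}")
        if not _CURIE_RE.match(term.term_id):
            raise OntologyError(f"term id {term.term_id!r} is not CURIE-shaped")
        self.terms[term.term_id] = term

    def add_relation(self, subject_id: str, predicate: str, object_id: str) -> None:
        for endpoint in (subject_id, object_id):
            if endpoint not in self.terms:
                raise OntologyError(f"relation endpoint {endpoint!r} not declared")
        if subject_id == object_id:
            raise OntologyError(f"self-loop on {subject_id!r}")
        rel = TermRelation(subject_id, predicate, object_id)
        self.relations.append(rel)
        if predicate in self.closure_predicates:
            # obsolete terms carry no outgoing closure edges
            if not self.terms[subject_id].is_obsolete:
                self._parents[subject_id].add(object_id)
                self._children[object_id].add(subject_id)
        self._anc_cache.clear()

    def validate_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t, ps in self._parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyCycleError({u for u, _ in cyc} | {v for _, v in cyc})

    # -- traversal ----------------------------------------------------

    def _require(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` over closure predicates,
        excluding ``term_id`` itself. Memoized; iterative (no recursion)."""
        self._require(term_id)
        cache = self._anc_cache
        stack = [term_id]
        while stack:
            t = stack[-1]
            if t in cache:
                stack.pop()
                continue
            pending = [p for p in self._parents.get(t, ()) if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            stack.pop()
            acc: set[str] = set()
            for p in self._parents.get(t, ()):
                acc.add(p)
                acc |= cache[p]
            cache[t] = frozenset(acc)
        return set(cache[term_id])

    def children(self, term_id: str) -> set[str]:
        self._require(term_id)
        return set(self._children.get(term_id, ()))

    # -- annotation semantics -----------------------------------------

    def propagate_annotations(
        self, direct: Mapping[str, Iterable[str]]
    ) -> dict[str, dict[str, set[str]]]:
        """Per feature: the asserted (direct) terms and the inherited
        closure (ancestors of direct terms minus the direct set).

        Annotations to obsolete terms are dropped with a warning and do
        not propagate.
        """
        out: dict[str, dict[str, set[str]]] = {}
        for feature, term_ids in direct.items():
            keep: set[str] = set()
            for t in term_ids:
                term = self._require(t)
                if term.is_obsolete:
                    warnings.warn(
                        f"annotation of {feature!r} to obsolete term {t}; excluded",
                        stacklevel=2,
                    )
                    continue
                keep.add(t)
            inherited: set[str] = set()
            for t in keep:
                inherited |= self.ancestors(t)
            inherited -= keep
            out[feature] = {"direct": keep, "inherited": inherited}
        return out

    def term_count_summary(
        self,
        annotations: Mapping[str, Mapping[str, set[str]]],
        focus: str,
    ) -> TermCountSummary:
        """Distinct-feature counts at or below each direct child of
        ``focus``, plus the distinct total at or below ``focus``.

        ``annotations`` is the output of :meth:`propagate_annotations`.
        A feature sits at or below a term exactly when the term appears
        in its direct or inherited set, so multiply-annotated features
        are counted once per child slice and once in the total.
        """
        self._require(focus)
        membership = {
            f: ann["direct"] | ann["inherited"] for f, ann in annotations.items()
        }
        child_counts = {
            c: sum(1 for terms in membership.values() if c in terms)
            for c in sorted(self.children(focus))
        }
        total = sum(1 for terms in membership.values() if focus in terms)
        return TermCountSummary(focus=focus, child_counts=child_counts, total=total)

    def annotation_subgraph(self, term_ids: Iterable[str]) -> "OntologyGraph":
        """The reduced ontology view for one feature's annotation: the
        given terms, all their ancestors, and every closure edge among
        the retained terms. Retained nodes are flagged on the returned
        graph as ``direct_terms`` vs ``inherited_terms``."""
        direct = set(term_ids)
        for t in direct:
            self._require(t)
        inherited: set[str] = set()
        for t in direct:
            inherited |= self.ancestors(t)
        inherited -= direct
        retained = direct | inherited
        sub = OntologyGraph(
            ontology_name=f"{self.ontology_name}|subgraph",
            closure_predicates=self.closure_predicates,
        )
        for t in sorted(retained):
            sub.add_term(Term(**vars(self.terms[t])))
        for rel in self.relations:
            if (
                rel.predicate in self.closure_predicates
                and rel.subject_id in retained
                and rel.object_id in retained
            ):
                sub.add_relation(rel.subject_id, rel.predicate, rel.object_id)
        sub.direct_terms = direct                   # type: ignore[attr-defined]
        sub.inherited_terms = inherited             # type: ignore[attr-defined]
        return sub

    # -- comparison helper (used by tests and backup checks) ----------

    def same_structure(self, other: "OntologyGraph") -> bool:
        return (
            set(self.terms) == set(other.terms)
            and set(self.relations) == set(other.relations)
        )


# ---------------------------------------------------------------------
# OBO parsing


def _scan_declared_ids(text: str) -> list[str]:
    """Stanza ids in order of declaration (for duplicate detection;
    obonet silently merges duplicate stanzas)."""
    ids: list[str] = []
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term and line.startswith("id:"):
            ids.append(line[3:].strip())
            in_term = False  # only the first id line of the stanza
    return ids


def parse_obo(stream, ontology_name: Optional[str] = None,
              closure_predicates: Iterable[str] = DEFAULT_CLOSURE_PREDICATES,
              ) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    ``stream`` may be a file-like object, a path, or the OBO text
    itself. Unknown relationship labels are kept verbatim as typed
    relations but only the closure predicates propagate. Duplicate term
    ids, relations to undeclared terms, and cycles over the closure
    predicates are load errors.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        s = str(stream)
        text = s if "[Term]" in s or "\n" in s else open(s).read()

    declared = _scan_declared_ids(text)
    seen: set[str] = set()
    for tid in declared:
        if tid in seen:
            raise OntologyError(f"duplicate term id {tid!r}")
        seen.add(tid)

    g = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    name = ontology_name or g.graph.get("ontology") or g.graph.get("name") or "ontology"
    graph = OntologyGraph(ontology_name=name, closure_predicates=closure_predicates)

    for node in declared:
        data = g.nodes[node] if node in g.nodes else {}
        syns = [
            m.group(1)
            for raw in data.get("synonym", [])
            if (m := _SYNONYM_RE.search(raw))
        ]
        graph.add_term(
            Term(
                term_id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace"),
                definition=data.get("def"),
                is_obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                synonyms=syns,
                xrefs=list(data.get("xref", [])),
            )
        )
    for subject, obj, predicate in g.edges(keys=True):
        if obj not in graph.terms:
            raise OntologyError(
                f"relation {subject} -[{predicate}]-> {obj}: {obj!r} not declared"
            )
        if graph.terms[subject].is_obsolete and predicate in graph.closure_predicates:
            continue  # obsolete stanzas keep no closure edges
        graph.add_relation(subject, predicate, obj)
    graph.validate_acyclic()
    return graph


# ---------------------------------------------------------------------
# dbxref -> ontology mapping (interpro2go style)


@dataclass
class DbxrefMapResult:
    terms: set[str]
    unmapped: list[str]


class DbxrefMapping:
    """External-id -> ontology-term table (e.g. InterPro -> GO)."""

    def __init__(self) -> None:
        self._map: dict[str, set[str]] = defaultdict(set)

    @classmethod
    def from_stream(cls, stream) -> "DbxrefMapping":
        """Two-column TAB/CSV (external id, term id); lines starting
        with ``!`` or ``#`` are comments. Malformed rows raise with
        their line number."""
        text = stream.read() if hasattr(stream, "read") else open(stream).read()
        mapping = cls()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2 or not _CURIE_RE.match(parts[1]):
                raise OntologyError(f"line {lineno}: malformed dbxref row {line!r}")
            mapping._map[parts[0]].add(parts[1])
        return mapping

    def add(self, external_id: str, term_id: str) -> None:
        self._map[external_id].add(term_id)

    def map(self, external_ids: Iterable[str]) -> DbxrefMapResult:
        terms: set[str] = set()
        unmapped: list[str] = []
        for xid in external_ids:
            hit = self._map.get(xid)
            if hit:
                terms |= hit
            else:
                unmapped.append(xid)
        return DbxrefMapResult(terms=terms, unmapped=unmapped)

    def __contains__(self, external_id: str) -> bool:
        return external_id in self._map

    def items(self):
        return ((k, sorted(v)) for k, v in sorted(self._map.items()))


# -- module-level operation aliases (the functional surface) ----------


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    return graph.ancestors(term_id)


def propagate_annotations(graph: OntologyGraph, direct: Mapping[str, Iterable[str]]):
    return graph.propagate_annotations(direct)


def term_count_summary(graph: OntologyGraph, annotations, focus: str) -> TermCountSummary:
    return graph.term_count_summary(annotations, focus)


def annotation_subgraph(graph: OntologyGraph, terms: Iterable[str]) -> OntologyGraph:
    return graph.annotation_subgraph(terms)


def map_dbxref(mapping: DbxrefMapping, external_ids: Iterable[str]) -> DbxrefMapResult:
    return mapping.map(external_ids)
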