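"""Search surface and integrated reports.

Searches return deterministic, unique_name-sorted
:class:`~txstore.model.QueryResult` tables; `like` mode uses SQL-style
wildcards (``%`` multi-character, ``_`` single-character,
case-insensitive by default), translated internally to the regex
engine. Term searches flag each row ``direct`` or ``indirect``, with
direct taking precedence when both apply.

Reports render store content for one entity; every field of a report is
re-derivable from store queries, and display coordinates are 1-based
inclusive while storage stays interbase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .expression import expression_profile
from .model import ExpressionSummary, QueryResult, QueryRow
from .ontology import OntologyGraph
from .store import FeatureStore, NotFoundError

SECTION_NAMES = ("residues", "relationships", "structural_annotation",
                 "functional_annotation", "blast_results",
                 "expression_results")


class InvalidPatternError(ValueError):
    def __init__(self, message: str, position: Optional[int] = None):
        self.position = position
        super().__init__(message)


def _like_to_regex(pattern: str) -> str:
    out = []
    for ch in pattern:
        if ch == "%":
            out.append(".*")
        elif ch == "_":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return "^" + "".join(out) + "$"


def _matcher(pattern: str, mode: str, case_sensitive: bool = False):
    if not pattern:
        raise InvalidPatternError("empty pattern")
    flags = 0 if case_sensitive else re.IGNORECASE
    if mode == "exact":
        return lambda s: s is not None and (
            s == pattern if case_sensitive else s.lower() == pattern.lower())
    if mode == "like":
        rx = re.compile(_like_to_regex(pattern), flags)
        return lambda s: s is not None and rx.match(s) is not None
    if mode == "regex":
        try:
            rx = re.compile(pattern, flags)
        except re.error as exc:
            raise InvalidPatternError(
                f"invalid regex at position {exc.pos}: {exc.msg}",
                position=exc.pos) from None
        return lambda s: s is not None and rx.search(s) is not None
    raise ValueError(f"unknown mode {mode!r}")


def _feature_rows(store: FeatureStore, so_type: Optional[str] = None):
    sql = "SELECT unique_name, so_type, display_name FROM feature"
    params: tuple = ()
    if so_type is not None:
        sql += " WHERE so_type=?"
        params = (so_type,)
    return store.conn.execute(sql + " ORDER BY unique_name", params).fetchall()


def search_by_name(store: FeatureStore, pattern: str, mode: str = "like",
                   so_type: Optional[str] = None,
                   case_sensitive: bool = False) -> QueryResult:
    """Text search over unique_name and display_name."""
    match = _matcher(pattern, mode, case_sensitive)
    rows = [
        QueryRow(unique_name=name, so_type=sot, display_name=disp)
        for name, sot, disp in _feature_rows(store, so_type)
        if match(name) or match(disp)
    ]
    return QueryResult(rows=rows,
                       provenance=f"name {mode} {pattern!r}"
                                  + (f" type={so_type}" if so_type else ""))


def search_by_term(store: FeatureStore, graph: OntologyGraph, term_id: str,
                   include_inherited: bool = True,
                   so_type: Optional[str] = None) -> QueryResult:
    """Features annotated at a term: directly, plus (optionally) those
    whose direct annotations descend from it. Rows carry a
    direct/indirect flag; direct wins when both apply."""
    graph._require(term_id)  # not-found on unknown terms
    direct_map = store.direct_annotations()
    # only terms the graph knows can propagate (EC numbers etc. are
    # annotations too, but carry no DAG structure here)
    filtered = {f: {t for t in ts if t in graph.terms}
                for f, ts in direct_map.items()}
    propagated = graph.propagate_annotations(filtered)
    info = {name: (sot, disp) for name, sot, disp in _feature_rows(store, so_type)}
    rows = []
    for fname in sorted(propagated):
        if fname not in info:
            continue
        ann = propagated[fname]
        if term_id in ann["direct"]:
            flag = "direct"
        elif include_inherited and term_id in ann["inherited"]:
            flag = "indirect"
        else:
            continue
        sot, disp = info[fname]
        rows.append(QueryRow(unique_name=fname, so_type=sot,
                             display_name=disp, flag=flag))
    return QueryResult(rows=rows,
                       provenance=f"term {term_id} "
                                  f"inherited={include_inherited}")


def search_by_blast_description(store: FeatureStore, pattern: str,
                                mode: str = "like",
                                case_sensitive: bool = False) -> QueryResult:
    """Features whose BLAST hit descriptions match; one row per query
    feature no matter how many hits matched."""
    match = _matcher(pattern, mode, case_sensitive)
    rows = store.conn.execute(
        "SELECT DISTINCT f.unique_name, f.so_type, f.display_name, "
        "h.description FROM blast_hit h JOIN feature f ON f.id = h.query_id "
        "ORDER BY f.unique_name").fetchall()
    seen: dict[str, QueryRow] = {}
    for name, sot, disp, desc in rows:
        if name not in seen and match(desc):
            seen[name] = QueryRow(unique_name=name, so_type=sot,
                                  display_name=disp)
    return QueryResult(rows=[seen[k] for k in sorted(seen)],
                       provenance=f"blast description {mode} {pattern!r}")


def filter_by_marker(result: QueryResult, store: FeatureStore,
                     marker_type: str, min_count: int = 1) -> QueryResult:
    """Keep rows whose feature carries >= min_count markers of the given
    type; observed marker counts are attached to the surviving rows."""
    counts = store.marker_counts_for(result.feature_names())
    rows = []
    for row in result.rows:
        n = counts.get(row.unique_name, {}).get(marker_type, 0)
        if n >= min_count:
            kept = QueryRow(unique_name=row.unique_name, so_type=row.so_type,
                            display_name=row.display_name, flag=row.flag,
                            marker_counts={**row.marker_counts,
                                           marker_type: n},
                            attributes=dict(row.attributes))
            rows.append(kept)
    return QueryResult(
        rows=rows,
        provenance=f"{result.provenance} & >={min_count} {marker_type}")


def term_summary_for_result(store: FeatureStore, graph: OntologyGraph,
                            result: QueryResult, focus: str):
    """Term-count summary (distinct features per direct child of the
    focus) restricted to the features in a result table."""
    direct_map = store.direct_annotations(features=result.feature_names())
    filtered = {f: {t for t in ts if t in graph.terms}
                for f, ts in direct_map.items()}
    propagated = graph.propagate_annotations(filtered)
    return graph.term_count_summary(propagated, focus)


# ---------------------------------------------------------------------
# reports


@dataclass
class SequenceReport:
    feature: str
    is_general: bool                      # residue-less: relationships only
    sections: dict[str, object] = field(default_factory=dict)


@dataclass
class MarkerReport:
    marker: str
    marker_type: str
    location: Optional[dict] = None       # 1-based display coordinates
    motif: Optional[str] = None
    ref_allele: Optional[str] = None
    alt_alleles: Optional[str] = None
    alleles: list[dict] = field(default_factory=list)


@dataclass
class ExperimentReport:
    experiment: str
    condition_terms: list[dict] = field(default_factory=list)
    genotype: Optional[str] = None
    libraries: list[dict] = field(default_factory=list)


@dataclass
class GenotypeReport:
    genotype: str
    attributes: list[dict] = field(default_factory=list)
    alleles: list[dict] = field(default_factory=list)


def _display_loc(start: int, end: int) -> dict:
    """Interbase to 1-based inclusive for human-facing tables."""
    return {"start": start + 1, "end": end}


def sequence_report(store: FeatureStore, graph: Optional[OntologyGraph],
                    feature: str) -> SequenceReport:
    """The six-section integrated view of one transcript: residues,
    non-positional relationships, structural annotation, functional
    annotation (with the reduced ontology subgraph), BLAST results and
    the expression profile. A residue-less feature (e.g. an isogroup)
    gets the general report: the relationships section only."""
    feat = store.get_feature(feature)
    fid = store.require_feature_id(feature)

    rel_rows = store.conn.execute(
        "SELECT s.unique_name, r.predicate, o.unique_name "
        "FROM feature_relationship r "
        "JOIN feature s ON s.id = r.subject_id "
        "JOIN feature o ON o.id = r.object_id "
        "WHERE r.subject_id=? OR r.object_id=? "
        "ORDER BY r.predicate, s.unique_name, o.unique_name",
        (fid, fid)).fetchall()
    relationships = [
        {"subject": s, "predicate": p, "object": o} for s, p, o in rel_rows]

    if feat.residues is None:
        return SequenceReport(feature=feature, is_general=True,
                              sections={"relationships": relationships})

    struct_rows = store.conn.execute(
        "SELECT c.unique_name, c.so_type, l.start, l.end, l.strand, l.phase "
        "FROM featureloc l JOIN feature c ON c.id = l.feature_id "
        "WHERE l.source_feature_id=? "
        "ORDER BY l.start, l.end, c.unique_name", (fid,)).fetchall()
    structural = [
        {"feature": n, "so_type": t, **_display_loc(s, e),
         "strand": strand, "phase": phase}
        for n, t, s, e, strand, phase in struct_rows]

    direct_terms = sorted(store.direct_annotations([feature]).get(feature, ()))
    functional: dict[str, object] = {"direct": direct_terms, "inherited": [],
                                     "subgraph": None}
    if graph is not None:
        in_graph = [t for t in direct_terms if t in graph.terms]
        sub = graph.annotation_subgraph(in_graph)
        functional["inherited"] = sorted(sub.inherited_terms)
        functional["subgraph"] = sub

    blast_rows = store.conn.execute(
        "SELECT hit_accession, description, e_value, bit_score, identity_pct, "
        "query_start, query_end, db_name FROM blast_hit WHERE query_id=? "
        "ORDER BY e_value, hit_accession", (fid,)).fetchall()
    blast = [
        {"accession": a, "description": d, "e_value": e, "bit_score": b,
         "identity_pct": i, **_display_loc(qs, qe), "db": db}
        for a, d, e, b, i, qs, qe, db in blast_rows]

    profiles: list[ExpressionSummary] = []
    for measure in ("RPKM", "raw_count"):
        profiles.extend(expression_profile(store, feature, measure=measure))

    sections = {
        "residues": {"residues": feat.residues, "seqlen": feat.seqlen},
        "relationships": relationships,
        "structural_annotation": structural,
        "functional_annotation": functional,
        "blast_results": blast,
        "expression_results": profiles,
    }
    return SequenceReport(feature=feature, is_general=False, sections=sections)


def marker_report(store: FeatureStore, marker: str) -> MarkerReport:
    fid = store.require_feature_id(marker)
    row = store.conn.execute(
        "SELECT id, marker_type, motif, ref_allele, alt_alleles "
        "FROM marker WHERE feature_id=?", (fid,)).fetchone()
    if row is None:
        raise NotFoundError(f"{marker!r} is not a marker")
    mid, mtype, motif, ref, alts = row
    loc = store.conn.execute(
        "SELECT src.unique_name, l.start, l.end FROM featureloc l "
        "JOIN feature src ON src.id = l.source_feature_id "
        "WHERE l.feature_id=? ORDER BY l.id LIMIT 1", (fid,)).fetchone()
    location = None
    if loc:
        location = {"on": loc[0], **_display_loc(loc[1], loc[2])}
    alleles = [
        {"genotype": g, "value": v}
        for g, v in store.conn.execute(
            "SELECT g.name, a.value FROM allele a "
            "JOIN genotype g ON g.id = a.genotype_id "
            "WHERE a.marker_id=? ORDER BY g.name", (mid,))]
    return MarkerReport(marker=marker, marker_type=mtype, location=location,
                        motif=motif, ref_allele=ref, alt_alleles=alts,
                        alleles=alleles)


def experiment_report(store: FeatureStore, experiment: str) -> ExperimentReport:
    row = store.conn.execute(
        "SELECT e.id, g.name FROM experiment e "
        "LEFT JOIN genotype g ON g.id = e.genotype_id WHERE e.name=?",
        (experiment,)).fetchone()
    if row is None:
        raise NotFoundError(f"unknown experiment {experiment!r}")
    eid, genotype = row
    conditions = [
        {"term_id": t, "value": v}
        for t, v in store.conn.execute(
            "SELECT term_id, value FROM experiment_condition "
            "WHERE experiment_id=? ORDER BY term_id", (eid,))]
    libraries = [
        {"library": n, "replicate_index": r, "total_reads": tot}
        for n, r, tot in store.conn.execute(
            "SELECT name, replicate_index, total_reads FROM seq_library "
            "WHERE experiment_id=? ORDER BY replicate_index", (eid,))]
    return ExperimentReport(experiment=experiment, condition_terms=conditions,
                            genotype=genotype, libraries=libraries)


def genotype_report(store: FeatureStore, genotype: str) -> GenotypeReport:
    gid = store.genotype_id(genotype)
    if gid is None:
        raise NotFoundError(f"unknown genotype {genotype!r}")
    attributes = [
        {"term_id": t, "value": v}
        for t, v in store.conn.execute(
            "SELECT term_id, value FROM genotype_attribute "
            "WHERE genotype_id=? ORDER BY term_id", (gid,))]
    alleles = [
        {"marker": m, "marker_type": mt, "value": v}
        for m, mt, v in store.conn.execute(
            "SELECT f.unique_name, m.marker_type, a.value FROM allele a "
            "JOIN marker m ON m.id = a.marker_id "
            "JOIN feature f ON f.id = m.feature_id "
            "WHERE a.genotype_id=? ORDER BY f.unique_name", (gid,))]
    return GenotypeReport(genotype=genotype, attributes=attributes,
                          alleles=alleles)
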