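"""Search surface, combined filters and reports."""

import io
import warnings

import pytest

from txstore import BlastHit, Feature, NotFoundError, init_store
from txstore.fixtures import FixtureSpec, load_bundle, make_toy_project, replay_case_study
from txstore.formats import SO_TRANSCRIPT
from txstore.queries import (
    InvalidPatternError,
    experiment_report,
    filter_by_marker,
    genotype_report,
    marker_report,
    search_by_blast_description,
    search_by_name,
    search_by_term,
    sequence_report,
    term_summary_for_result,
)


@pytest.fixture
def named_store(store):
    for i in range(1, 6):
        store.upsert_feature(Feature(unique_name=f"isotig00{i}",
                                     so_type=SO_TRANSCRIPT, residues="ACGT"))
    store.conn.commit()
    return store


class TestSearchByName:
    def test_percent_matches_all(self, named_store):
        assert len(search_by_name(named_store, "%")) == 5

    def test_exact(self, named_store):
        res = search_by_name(named_store, "isotig001", mode="exact")
        assert res.feature_names() == ["isotig001"]

    def test_regex(self, named_store):
        res = search_by_name(named_store, "^isotig00[12]$", mode="regex")
        assert res.feature_names() == ["isotig001", "isotig002"]

    def test_like_underscore_single_char(self, named_store):
        res = search_by_name(named_store, "isotig00_")
        assert len(res) == 5

    def test_invalid_regex_reports_position(self, named_store):
        with pytest.raises(InvalidPatternError) as exc:
            search_by_name(named_store, "[unclosed", mode="regex")
        assert exc.value.position is not None

    def test_rows_sorted_and_unique(self, named_store):
        names = search_by_name(named_store, "%").feature_names()
        assert names == sorted(names) and len(names) == len(set(names))


class TestSearchByTerm:
    @pytest.fixture
    def annotated(self, named_store, chain_graph):
        from txstore.model import TermAnnotation
        named_store.add_term_annotation(
            TermAnnotation(feature="isotig001", term_id="T:2"))
        named_store.conn.commit()
        return named_store, chain_graph

    def test_inherited_flagged_indirect(self, annotated):
        store, graph = annotated
        res = search_by_term(store, graph, "T:1", include_inherited=True)
        assert [(r.unique_name, r.flag) for r in res.rows] == [
            ("isotig001", "indirect")]

    def test_without_inheritance_empty(self, annotated):
        store, graph = annotated
        assert len(search_by_term(store, graph, "T:1",
                                  include_inherited=False)) == 0

    def test_direct_flag(self, annotated):
        store, graph = annotated
        res = search_by_term(store, graph, "T:2")
        assert res.rows[0].flag == "direct"

    def test_direct_wins_over_indirect(self, annotated):
        store, graph = annotated
        from txstore.model import TermAnnotation
        store.add_term_annotation(
            TermAnnotation(feature="isotig001", term_id="T:1"))
        store.conn.commit()
        res = search_by_term(store, graph, "T:1")
        assert res.rows[0].flag == "direct"

    def test_unknown_term(self, annotated):
        store, graph = annotated
        from txstore.ontology import UnknownTermError
        with pytest.raises(UnknownTermError):
            search_by_term(store, graph, "T:404")

    def test_matches_brute_force_on_bundle(self, bundle):
        """Inheritance search equals scanning 'focus in direct or
        inherited' per feature (the manifest's ground truth)."""
        store, graph = bundle["store"], bundle["graph"]
        focus = bundle["manifest"]["focus_term"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = search_by_term(store, graph, focus,
                                 so_type=SO_TRANSCRIPT)
        assert res.feature_names() == bundle["manifest"]["under_focus"]


class TestSearchByBlastDescription:
    @pytest.fixture
    def with_hits(self, named_store):
        for feat, desc in [("isotig001", "alpha kinase"),
                           ("isotig001", "alpha kinase isoform"),
                           ("isotig002", "MAP kinase"),
                           ("isotig003", "structural protein")]:
            named_store.add_blast_hit(BlastHit(
                query=feat, hit_accession="X", description=desc,
                e_value=1e-5, bit_score=50, identity_pct=90,
                query_start=0, query_end=4))
        named_store.conn.commit()
        return named_store

    def test_deduplicated_rows(self, with_hits):
        res = search_by_blast_description(with_hits, "alpha kinase%")
        assert res.feature_names() == ["isotig001"]

    def test_no_match(self, with_hits):
        assert len(search_by_blast_description(with_hits, "%zinc%")) == 0

    def test_substring_like(self, with_hits):
        res = search_by_blast_description(with_hits, "%kinase%")
        assert res.feature_names() == ["isotig001", "isotig002"]


class TestFilterByMarker:
    def test_counts_against_manifest(self, bundle):
        store = bundle["store"]
        res = search_by_name(store, "%", so_type=SO_TRANSCRIPT)
        ssr = filter_by_marker(res, store, "SSR", min_count=1)
        assert ssr.feature_names() == bundle["manifest"]["ssr_features"]
        assert all(r.marker_counts["SSR"] >= 1 for r in ssr.rows)

    def test_min_count_excludes(self, bundle):
        store = bundle["store"]
        res = search_by_name(store, "%", so_type=SO_TRANSCRIPT)
        one = {r.unique_name for r in
               filter_by_marker(res, store, "SSR", 1).rows
               if r.marker_counts["SSR"] == 1}
        two = set(filter_by_marker(res, store, "SSR", 2).feature_names())
        assert one and not (one & two)

    def test_empty_input(self, bundle):
        from txstore.model import QueryResult
        out = filter_by_marker(QueryResult(rows=[]), bundle["store"], "SSR")
        assert len(out) == 0

    def test_idempotent(self, bundle):
        store = bundle["store"]
        res = search_by_name(store, "%", so_type=SO_TRANSCRIPT)
        once = filter_by_marker(res, store, "SSR", 1)
        twice = filter_by_marker(once, store, "SSR", 1)
        assert once.feature_names() == twice.feature_names()


class TestTermSummaryForResult:
    def test_full_restriction_equals_unrestricted(self, bundle):
        store, graph = bundle["store"], bundle["graph"]
        root = bundle["manifest"]["root_term"]
        everything = search_by_name(store, "%", so_type=SO_TRANSCRIPT)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            restricted = term_summary_for_result(store, graph, everything, root)
            ann = graph.propagate_annotations(
                {f: {t for t in ts if t in graph.terms}
                 for f, ts in store.direct_annotations().items()})
        unrestricted = graph.term_count_summary(ann, root)
        # transcripts carry all annotations in the fixture
        assert restricted.child_counts == unrestricted.child_counts
        assert restricted.total == unrestricted.total

    def test_disjoint_result_all_zero(self, bundle):
        store, graph = bundle["store"], bundle["graph"]
        root = bundle["manifest"]["root_term"]
        res = search_by_name(store, "isogroup%")
        summary = term_summary_for_result(store, graph, res, root)
        assert summary.total == 0
        assert all(v == 0 for v in summary.child_counts.values())


class TestSequenceReport:
    def test_fully_loaded_transcript_has_six_sections(self, bundle):
        store, graph = bundle["store"], bundle["graph"]
        # a transcript with hits, markers, annotation and expression
        name = bundle["manifest"]["ssr_features"][0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = sequence_report(store, graph, name)
        assert not rep.is_general
        assert list(rep.sections) == [
            "residues", "relationships", "structural_annotation",
            "functional_annotation", "blast_results", "expression_results"]
        assert rep.sections["residues"]["seqlen"] == \
            bundle["manifest"]["transcripts"][name]["length"]
        assert rep.sections["relationships"]
        assert rep.sections["structural_annotation"]
        assert rep.sections["functional_annotation"]["direct"]
        assert rep.sections["expression_results"]

    def test_residueless_feature_gets_relationships_only(self, bundle):
        store = bundle["store"]
        group = bundle["manifest"]["isogroups"][0]
        rep = sequence_report(store, None, group)
        assert rep.is_general
        assert list(rep.sections) == ["relationships"]
        assert rep.sections["relationships"]  # its isotigs point at it

    def test_empty_blast_section_present(self, named_store):
        rep = sequence_report(named_store, None, "isotig001")
        assert rep.sections["blast_results"] == []
        assert "blast_results" in rep.sections

    def test_unknown_feature(self, named_store):
        with pytest.raises(NotFoundError):
            sequence_report(named_store, None, "ghost")

    def test_report_fields_rederivable_from_store(self, bundle):
        """The functional section's terms equal a fresh store query
        plus graph closure (reports hold no extra state)."""
        store, graph = bundle["store"], bundle["graph"]
        name = bundle["manifest"]["ssr_features"][0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = sequence_report(store, graph, name)
        direct = sorted(store.direct_annotations([name])[name])
        assert rep.sections["functional_annotation"]["direct"] == direct


class TestEntityReports:
    def test_marker_report_alleles_across_genotypes(self, bundle):
        store = bundle["store"]
        row = store.conn.execute(
            "SELECT f.unique_name FROM marker m JOIN feature f "
            "ON f.id=m.feature_id JOIN allele a ON a.marker_id=m.id "
            "GROUP BY m.id HAVING COUNT(*)=2 LIMIT 1").fetchone()
        if row is None:
            pytest.skip("no marker with alleles in both genotypes this seed")
        rep = marker_report(store, row[0])
        assert len(rep.alleles) == 2
        assert rep.location is not None and rep.location["start"] >= 1

    def test_experiment_report_one_library(self, bundle):
        rep = experiment_report(bundle["store"], "male_larvae")
        assert len(rep.libraries) == 1
        assert rep.libraries[0]["replicate_index"] == 1
        assert rep.condition_terms

    def test_genotype_report(self, bundle):
        rep = genotype_report(bundle["store"], "g1")
        assert rep.attributes
        assert all(set(a) == {"marker", "marker_type", "value"}
                   for a in rep.alleles)

    def test_genotype_without_alleles(self, store):
        store.add_genotype("lonely", [("T:1", None)])
        rep = genotype_report(store, "lonely")
        assert rep.alleles == [] and rep.attributes


def test_case_study_replay_matches_ground_truth(bundle):
    """'>=1 SSR and annotated under the focus term' via the query
    layer equals the generator's brute-force set intersection."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        replay = replay_case_study(bundle["store"], bundle["graph"],
                                   bundle["manifest"]["focus_term"])
    assert replay == bundle["manifest"]["replay_answer"]


def test_case_study_replay_on_fresh_random_spec(tmp_path):
    spec = FixtureSpec(seed=321, n_isogroups=6, n_ssr=5, n_snp=5,
                       n_ontology_terms=18)
    manifest = make_toy_project(spec, tmp_path / "b")
    store = init_store(tmp_path / "p.db")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = load_bundle(store, tmp_path / "b")
        replay = replay_case_study(store, out["graph"],
                                   manifest["focus_term"])
    assert replay == manifest["replay_answer"]
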