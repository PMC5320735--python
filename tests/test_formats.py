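"""Loaders and exporters: coordinate conventions, warnings, round trips."""

import io

import pytest

from txstore import Feature, QueryResult, QueryRow
from txstore.formats import (
    export_annot,
    export_fasta,
    export_table,
    load_annot,
    load_association_table,
    load_blast_xml,
    load_fasta,
    load_feature_list,
    load_gff3,
    load_interproscan,
    load_vcf_markers,
)
from txstore.ontology import DbxrefMapping

FASTA = """>isotig001 len=500
ACGTACGTAC
>isotig002
GGGGCCCC
>isotig003
TTTT
"""

BLAST_XML = """<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "NCBI_BlastOutput.dtd">
<BlastOutput>
 <BlastOutput_program>blastn</BlastOutput_program>
 <BlastOutput_version>BLASTN 2.2.31+</BlastOutput_version>
 <BlastOutput_db>nt</BlastOutput_db>
 <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
 <BlastOutput_query-def>{query} extra tokens</BlastOutput_query-def>
 <BlastOutput_query-len>10</BlastOutput_query-len>
 <BlastOutput_param><Parameters><Parameters_expect>10</Parameters_expect></Parameters></BlastOutput_param>
 <BlastOutput_iterations>
  <Iteration>
   <Iteration_iter-num>1</Iteration_iter-num>
   <Iteration_query-ID>Query_1</Iteration_query-ID>
   <Iteration_query-def>{query} extra tokens</Iteration_query-def>
   <Iteration_query-len>10</Iteration_query-len>
   <Iteration_hits>
    <Hit>
     <Hit_num>1</Hit_num><Hit_id>gnl|x|H1</Hit_id>
     <Hit_def>alpha kinase</Hit_def>
     <Hit_accession>H1</Hit_accession><Hit_len>100</Hit_len>
     <Hit_hsps>
      <Hsp><Hsp_num>1</Hsp_num><Hsp_bit-score>50</Hsp_bit-score>
       <Hsp_score>100</Hsp_score><Hsp_evalue>1e-10</Hsp_evalue>
       <Hsp_query-from>1</Hsp_query-from><Hsp_query-to>10</Hsp_query-to>
       <Hsp_hit-from>1</Hsp_hit-from><Hsp_hit-to>10</Hsp_hit-to>
       <Hsp_query-frame>1</Hsp_query-frame><Hsp_hit-frame>0</Hsp_hit-frame>
       <Hsp_identity>90</Hsp_identity><Hsp_positive>95</Hsp_positive>
       <Hsp_gaps>0</Hsp_gaps><Hsp_align-len>100</Hsp_align-len>
       <Hsp_qseq>A</Hsp_qseq><Hsp_hseq>A</Hsp_hseq><Hsp_midline>|</Hsp_midline>
      </Hsp>
      <Hsp><Hsp_num>2</Hsp_num><Hsp_bit-score>40</Hsp_bit-score>
       <Hsp_score>80</Hsp_score><Hsp_evalue>1e-5</Hsp_evalue>
       <Hsp_query-from>2</Hsp_query-from><Hsp_query-to>9</Hsp_query-to>
       <Hsp_hit-from>2</Hsp_hit-from><Hsp_hit-to>9</Hsp_hit-to>
       <Hsp_query-frame>1</Hsp_query-frame><Hsp_hit-frame>0</Hsp_hit-frame>
       <Hsp_identity>40</Hsp_identity><Hsp_positive>45</Hsp_positive>
       <Hsp_gaps>0</Hsp_gaps><Hsp_align-len>50</Hsp_align-len>
       <Hsp_qseq>A</Hsp_qseq><Hsp_hseq>A</Hsp_hseq><Hsp_midline>|</Hsp_midline>
      </Hsp>
     </Hit_hsps>
    </Hit>
    <Hit>
     <Hit_num>2</Hit_num><Hit_id>gnl|x|H2</Hit_id>
     <Hit_def>beta protein</Hit_def>
     <Hit_accession>H2</Hit_accession><Hit_len>90</Hit_len>
     <Hit_hsps>
      <Hsp><Hsp_num>1</Hsp_num><Hsp_bit-score>30</Hsp_bit-score>
       <Hsp_score>60</Hsp_score><Hsp_evalue>1e-3</Hsp_evalue>
       <Hsp_query-from>3</Hsp_query-from><Hsp_query-to>8</Hsp_query-to>
       <Hsp_hit-from>1</Hsp_hit-from><Hsp_hit-to>6</Hsp_hit-to>
       <Hsp_query-frame>1</Hsp_query-frame><Hsp_hit-frame>0</Hsp_hit-frame>
       <Hsp_identity>30</Hsp_identity><Hsp_positive>32</Hsp_positive>
       <Hsp_gaps>0</Hsp_gaps><Hsp_align-len>60</Hsp_align-len>
       <Hsp_qseq>A</Hsp_qseq><Hsp_hseq>A</Hsp_hseq><Hsp_midline>|</Hsp_midline>
      </Hsp>
     </Hit_hsps>
    </Hit>
   </Iteration_hits>
  </Iteration>
 </BlastOutput_iterations>
</BlastOutput>
"""

VCF = """##fileformat=VCFv4.2
##INFO=<ID=MOTIF,Number=1,Type=String,Description="SSR motif">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=isotig001,length=200>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tg1\tg2
isotig001\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t1/1\t./.
"""


@pytest.fixture
def seq_store(store):
    """Store with one 200 bp transcript and genotypes g1/g2."""
    store.upsert_feature(Feature(unique_name="isotig001",
                                 so_type="SO:0000673", residues="A" * 200))
    store.add_genotype("g1")
    store.add_genotype("g2")
    store.conn.commit()
    return store


class TestFasta:
    def test_three_records(self, store):
        rep = load_fasta(store, io.StringIO(FASTA))
        assert (rep.records_read, rep.records_loaded) == (3, 3)
        assert store.get_feature("isotig002").seqlen == 8

    def test_header_tokenization(self, store):
        load_fasta(store, io.StringIO(FASTA))
        assert store.feature_id("isotig001") is not None
        assert store.feature_id("isotig001 len=500") is None

    def test_duplicate_header_skipped_with_warning(self, store):
        dup = FASTA + ">isotig001\nAAAA\n"
        rep = load_fasta(store, io.StringIO(dup))
        assert (rep.records_loaded, rep.records_skipped) == (3, 1)
        assert any("duplicate" in msg for _, msg in rep.warnings)

    def test_empty_sequence_skipped(self, store):
        rep = load_fasta(store, io.StringIO(">a\nACGT\n>empty\n>b\nGG\n"))
        assert rep.records_skipped == 1

    def test_export_round_trip(self, store):
        load_fasta(store, io.StringIO(FASTA))
        out = export_fasta(store)
        store2_seqs = {}
        name = None
        for line in out.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                store2_seqs[name] = ""
            else:
                store2_seqs[name] += line
        assert store2_seqs == {"isotig001": "ACGTACGTAC",
                               "isotig002": "GGGGCCCC", "isotig003": "TTTT"}


class TestFeatureList:
    def test_list_load(self, store):
        rep = load_feature_list(store, io.StringIO("g1\ng2\ng3\ng4\ng5\n"))
        assert rep.records_loaded == 5
        assert store.get_feature("g3").residues is None

    def test_duplicate_skipped(self, store):
        rep = load_feature_list(store, io.StringIO("a\nb\na\nc\nd\n"))
        assert rep.records_loaded == 4

    def test_empty_file(self, store):
        rep = load_feature_list(store, io.StringIO(""))
        assert (rep.records_read, len(rep.warnings)) == (0, 0)


class TestGff3:
    GFF = ("##gff-version 3\n"
           "isotig001\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=m1\n"
           "isotig001\t.\tCDS\t10\t90\t.\t-\t2\tID=c1;Parent=m1\n"
           "isotig001\t.\tmRNA\t1\t200\t.\t+\t.\tID=m1\n")

    def test_coordinates_strand_and_relationship(self, seq_store):
        rep = load_gff3(seq_store, io.StringIO(self.GFF))
        assert rep.records_loaded == 3
        row = seq_store.conn.execute(
            "SELECT l.start, l.end, l.strand FROM featureloc l "
            "JOIN feature f ON f.id=l.feature_id WHERE f.unique_name='e1'"
        ).fetchone()
        assert row == (0, 100, 1)
        # Parent defined later in the file still resolves (two-pass)
        rel = seq_store.conn.execute(
            "SELECT COUNT(*) FROM feature_relationship").fetchone()[0]
        assert rel == 2

    def test_phase_and_minus_strand(self, seq_store):
        load_gff3(seq_store, io.StringIO(self.GFF))
        row = seq_store.conn.execute(
            "SELECT l.strand, l.phase FROM featureloc l "
            "JOIN feature f ON f.id=l.feature_id WHERE f.unique_name='c1'"
        ).fetchone()
        assert row == (-1, 2)

    def test_unresolvable_seqid_skipped(self, seq_store):
        gff = "##gff-version 3\nnosuchtig\t.\texon\t1\t10\t.\t+\t.\tID=x\n"
        rep = load_gff3(seq_store, io.StringIO(gff))
        assert rep.records_skipped == 1 and rep.warnings

    def test_end_before_start_rejected(self, seq_store):
        gff = "##gff-version 3\nisotig001\t.\texon\t50\t10\t.\t+\t.\tID=x\n"
        rep = load_gff3(seq_store, io.StringIO(gff))
        assert rep.records_skipped == 1

    def test_unknown_type_falls_back_to_region(self, seq_store):
        gff = "##gff-version 3\nisotig001\t.\tweird_thing\t1\t10\t.\t+\t.\tID=w\n"
        rep = load_gff3(seq_store, io.StringIO(gff))
        assert rep.records_loaded == 1
        assert seq_store.get_feature("w").so_type == "SO:0000001"

    def test_coordinate_round_trip(self, seq_store):
        """1-based inclusive in, interbase stored, 1-based back out."""
        from txstore.queries import sequence_report
        load_gff3(seq_store, io.StringIO(self.GFF))
        rep = sequence_report(seq_store, None, "isotig001")
        rows = {r["feature"]: (r["start"], r["end"])
                for r in rep.sections["structural_annotation"]}
        assert rows["e1"] == (1, 100)
        assert rows["c1"] == (10, 90)
        assert rows["m1"] == (1, 200)


class TestBlastXml:
    def test_one_hit_per_hsp(self, seq_store):
        xml = BLAST_XML.format(query="isotig001")
        rep = load_blast_xml(seq_store, io.StringIO(xml))
        assert (rep.records_read, rep.records_loaded) == (3, 3)

    def test_identity_percent(self, seq_store):
        load_blast_xml(seq_store, io.StringIO(BLAST_XML.format(query="isotig001")))
        pcts = sorted(r[0] for r in seq_store.conn.execute(
            "SELECT identity_pct FROM blast_hit"))
        assert pcts == [50.0, 80.0, 90.0]  # 30/60, 40/50, 90/100

    def test_unknown_query_skipped_with_warning(self, seq_store):
        rep = load_blast_xml(seq_store,
                             io.StringIO(BLAST_XML.format(query="unknownseq")))
        assert rep.records_loaded == 0 and rep.records_skipped == 3
        assert rep.warnings


class TestAnnot:
    def test_row_stored(self, seq_store):
        rep = load_annot(seq_store, io.StringIO("isotig001\tT:2\n"))
        assert rep.records_loaded == 1
        assert seq_store.direct_annotations()["isotig001"] == {"T:2"}

    def test_unknown_term_skipped_with_line(self, seq_store):
        rep = load_annot(seq_store, io.StringIO("isotig001\tT:404\n"))
        assert rep.records_skipped == 1
        assert rep.warnings[0][0] == 1

    def test_duplicate_row_idempotent(self, seq_store):
        load_annot(seq_store, io.StringIO("isotig001\tT:2\nisotig001\tT:2\n"))
        assert seq_store.table_counts()["term_annotation"] == 1

    def test_ec_number_accepted(self, seq_store):
        rep = load_annot(seq_store, io.StringIO("isotig001\tEC:2.7.11.1\n"))
        assert rep.records_loaded == 1

    def test_export_round_trip(self, seq_store, store):
        load_annot(seq_store, io.StringIO("isotig001\tT:2\nisotig001\tT:1\n"))
        text = export_annot(seq_store)
        rep = load_annot(seq_store, io.StringIO(text))
        assert rep.records_skipped == 0
        assert seq_store.table_counts()["term_annotation"] == 2


class TestInterproscan:
    ROW = ("isotig001\tmd5\t200\tPfam\tPF00069\tkinase domain\t10\t50\t"
           "1e-20\tT\t2017-01-01\tIPR000001\tkinase entry\t-\n")

    def test_domain_and_mapped_annotation(self, seq_store):
        mapping = DbxrefMapping()
        mapping.add("IPR000001", "T:2")
        rep = load_interproscan(seq_store, io.StringIO(self.ROW), mapping)
        assert rep.records_loaded == 1
        assert "T:2" in seq_store.direct_annotations()["isotig001"]
        # 1-based 10..50 -> interbase 9..50
        loc = seq_store.conn.execute(
            "SELECT start, end FROM featureloc").fetchone()
        assert loc == (9, 50)

    def test_unmapped_reported(self, seq_store):
        mapping = DbxrefMapping()
        row = self.ROW.replace("IPR000001", "IPR999999")
        rep = load_interproscan(seq_store, io.StringIO(row), mapping)
        assert rep.records_loaded == 1
        assert any("unmapped" in m for _, m in rep.warnings)
        assert "isotig001" not in seq_store.direct_annotations()


class TestVcfMarkers:
    def test_snp_location_and_gt_translation(self, seq_store, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(VCF)
        rep = load_vcf_markers(seq_store, vcf, "SNP")
        assert rep.records_loaded == 1
        loc = seq_store.conn.execute(
            "SELECT start, end FROM featureloc l JOIN feature f "
            "ON f.id=l.feature_id WHERE f.unique_name='snp1'").fetchone()
        assert loc == (99, 100)
        alleles = seq_store.conn.execute(
            "SELECT g.name, a.value FROM allele a "
            "JOIN genotype g ON g.id=a.genotype_id").fetchall()
        # g2 has a missing call './.' -> no allele row
        assert alleles == [("g1", "G/G")]

    def test_ssr_motif_from_info(self, seq_store, tmp_path):
        vcf = tmp_path / "s.vcf"
        text = VCF.replace(
            "100\tsnp1\tA\tG\t.\t.\t.", "50\tssr1\tAGAGAG\tAGAGAGAG\t.\t.\tMOTIF=AG")
        vcf.write_text(text)
        load_vcf_markers(seq_store, vcf, "SSR")
        motif = seq_store.conn.execute("SELECT motif FROM marker").fetchone()[0]
        assert motif == "AG"

    def test_unresolvable_chrom_skipped(self, seq_store, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(VCF.replace("isotig001", "ghosttig"))
        rep = load_vcf_markers(seq_store, vcf, "SNP")
        assert rep.records_skipped == 1


class TestAssociationTables:
    def test_feature_library_value(self, seq_store):
        from txstore.expression import add_library, create_experiment
        create_experiment(seq_store, "exp1", [])
        add_library(seq_store, "exp1", "lib_male_larvae_1", 1, 1_000_000)
        rep = load_association_table(
            seq_store, io.StringIO("isotig001\tlib_male_larvae_1\t154\n"),
            kind="feature_library")
        assert rep.records_loaded == 1
        val = seq_store.conn.execute(
            "SELECT value FROM expression_value WHERE measure='raw_count'"
        ).fetchone()[0]
        assert val == 154.0

    def test_feature_feature_relationship(self, seq_store):
        load_feature_list(seq_store, io.StringIO("isogroup01\n"))
        rep = load_association_table(
            seq_store, io.StringIO("isotig001\tpart_of\tisogroup01\n"),
            kind="feature_feature")
        assert rep.records_loaded == 1
        assert seq_store.table_counts()["feature_relationship"] == 1

    def test_header_row_auto_skipped(self, seq_store):
        rep = load_association_table(
            seq_store, io.StringIO("feature\tterm\nisotig001\tT:2\n"),
            kind="feature_cv")
        assert (rep.records_read, rep.records_loaded) == (1, 1)

    def test_unresolvable_row_skipped(self, seq_store):
        rep = load_association_table(
            seq_store, io.StringIO("ghost\tT:2\n"), kind="feature_cv")
        assert rep.records_skipped == 1 and rep.warnings


def test_export_table_quotes_delimiters():
    result = QueryResult(rows=[QueryRow(
        unique_name="t1", so_type="SO:0000673",
        display_name="protein, partial")])
    text = export_table(result)
    assert '"protein, partial"' in text


def test_every_loader_report_is_balanced(bundle):
    for rep in bundle["reports"].values():
        assert rep.records_read == rep.records_loaded + rep.records_skipped


def test_loader_idempotence_on_bundle(bundle, tmp_path):
    """Loading the same bundle twice leaves the store in the same state
    as loading it once."""
    import warnings as w

    from txstore import init_store
    from txstore.fixtures import load_bundle
    s = init_store(tmp_path / "twice.db")
    with w.catch_warnings():
        w.simplefilter("ignore")
        load_bundle(s, bundle["dir"])
        counts_once = {t: c for t, c in s.table_counts().items()
                       if t != "audit_log"}
        load_bundle(s, bundle["dir"])
        counts_twice = {t: c for t, c in s.table_counts().items()
                        if t != "audit_log"}
    assert counts_once == counts_twice
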