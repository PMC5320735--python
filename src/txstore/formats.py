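"""Bulk loaders and exporters for the standard de novo transcriptome
result formats: FASTA, plain feature lists, GFF3, NCBI BLAST XML,
Blast2GO ANNOT, InterProScan TSV, VCF markers and generic association
tables.

Every loader writes through the typed operations of
:class:`~txstore.store.FeatureStore` (the single write path) and
returns a :class:`~txstore.model.LoadReport` whose counts always
satisfy ``read = loaded + skipped``. File coordinates (GFF3, VCF,
InterProScan: 1-based inclusive) are converted to interbase at this
boundary and nowhere else.
"""

from __future__ import annotations

import csv
import io
import os
import tempfile
from typing import Optional

from Bio import SeqIO
from Bio.Blast import NCBIXML
from gffutils.iterators import DataIterator

from .model import (
    Analysis,
    BlastHit,
    Feature,
    FeatureLocation,
    FeatureRelationship,
    LoadReport,
    TermAnnotation,
)
from .ontology import DbxrefMapping
from .store import FeatureStore, StoreError

# SO CURIEs for the feature types the loaders create.
SO_TRANSCRIPT = "SO:0000673"
SO_GENE = "SO:0000704"
SO_REGION = "SO:0000001"
SO_SNP = "SO:0000694"
SO_SSR = "SO:0000289"       # microsatellite
SO_DOMAIN = "SO:0000417"    # polypeptide domain match

#: GFF3 column-3 type -> SO term; unknown types fall back to region.
GFF3_TYPE_MAP = {
    "gene": SO_GENE,
    "mRNA": "SO:0000234",
    "transcript": SO_TRANSCRIPT,
    "exon": "SO:0000147",
    "CDS": "SO:0000316",
    "five_prime_UTR": "SO:0000204",
    "three_prime_UTR": "SO:0000205",
    "region": SO_REGION,
}

_STRAND = {"+": 1, "-": -1}


def _text(stream) -> str:
    if hasattr(stream, "read"):
        return stream.read()
    return open(stream).read()


# ---------------------------------------------------------------------
# sequences


def load_fasta(store: FeatureStore, stream, so_type: str = SO_TRANSCRIPT,
               organism_id: Optional[int] = None) -> LoadReport:
    """One feature per FASTA record; unique_name is the first
    whitespace-delimited header token, residues stored verbatim."""
    report = LoadReport()
    seen: set[str] = set()
    handle = io.StringIO(_text(stream))
    for rec in SeqIO.parse(handle, "fasta"):
        report.records_read += 1
        name = rec.id
        if name in seen:
            report.records_skipped += 1
            report.warn(report.records_read, f"duplicate header {name!r}; skipped")
            continue
        seq = str(rec.seq)
        if not seq:
            report.records_skipped += 1
            report.warn(report.records_read, f"empty sequence for {name!r}; skipped")
            continue
        seen.add(name)
        store.upsert_feature(
            Feature(unique_name=name, so_type=so_type, residues=seq,
                    display_name=rec.description if rec.description != name else None),
            organism_id=organism_id)
        report.records_loaded += 1
    store._audit("load_fasta", f"{report.records_loaded} features")
    store.conn.commit()
    report.check()
    return report


def load_feature_list(store: FeatureStore, stream, so_type: str = SO_GENE,
                      organism_id: Optional[int] = None) -> LoadReport:
    """Residue-less features (e.g. Newbler isogroups) from a one-name-
    per-line file; blank lines ignored, duplicates skipped."""
    report = LoadReport()
    seen: set[str] = set()
    for lineno, line in enumerate(_text(stream).splitlines(), start=1):
        name = line.strip()
        if not name:
            continue
        report.records_read += 1
        if name in seen:
            report.records_skipped += 1
            report.warn(lineno, f"duplicate name {name!r}; skipped")
            continue
        seen.add(name)
        store.upsert_feature(Feature(unique_name=name, so_type=so_type),
                             organism_id=organism_id)
        report.records_loaded += 1
    store._audit("load_feature_list", f"{report.records_loaded} features")
    store.conn.commit()
    report.check()
    return report


# ---------------------------------------------------------------------
# GFF3 structural annotation


def load_gff3(store: FeatureStore, stream,
              organism_id: Optional[int] = None) -> LoadReport:
    """Structural annotation: one feature + one location per GFF3
    record, ``Parent=`` attributes becoming part_of relationships.

    Two passes, so a Parent may name an ID defined later in the file.
    Column-1 seqids must already be stored (they are the transcripts);
    1-based inclusive coordinates become interbase.
    """
    report = LoadReport()
    records = list(DataIterator(_text(stream), from_string=True))
    loaded: list[tuple[str, Optional[str]]] = []  # (unique_name, parent id)
    ids_in_file: set[str] = set()
    for rec in records:
        ids_in_file.update(rec.attributes.get("ID", []))
    autogen = 0
    for lineno, rec in enumerate(records, start=1):
        report.records_read += 1
        if store.feature_id(rec.seqid) is None:
            report.records_skipped += 1
            report.warn(lineno, f"seqid {rec.seqid!r} not in store; record skipped")
            continue
        if rec.end < rec.start:
            report.records_skipped += 1
            report.warn(lineno, f"end {rec.end} < start {rec.start}; record rejected")
            continue
        ids = rec.attributes.get("ID", [])
        if ids:
            name = ids[0]
        else:
            autogen += 1
            name = f"{rec.seqid}:{rec.featuretype}:{rec.start}-{rec.end}.{autogen}"
        so_type = GFF3_TYPE_MAP.get(rec.featuretype)
        if so_type is None:
            so_type = SO_REGION
            report.warn(lineno,
                        f"unknown type {rec.featuretype!r}; stored as region")
        store.upsert_feature(Feature(unique_name=name, so_type=so_type),
                             organism_id=organism_id)
        phase = int(rec.frame) if rec.frame in ("0", "1", "2") else None
        store.add_location(FeatureLocation(
            feature=name, source_feature=rec.seqid,
            start=rec.start - 1, end=rec.end,
            strand=_STRAND.get(rec.strand, 0), phase=phase))
        parents = rec.attributes.get("Parent", [])
        loaded.append((name, parents[0] if parents else None))
        report.records_loaded += 1
    # second pass: relationships, now that every ID exists
    for lineno, (name, parent) in enumerate(loaded, start=1):
        if parent is None:
            continue
        if parent not in ids_in_file and store.feature_id(parent) is None:
            report.warn(lineno, f"Parent {parent!r} unresolved; relationship dropped")
            continue
        store.add_relationship(FeatureRelationship(
            subject=name, predicate="part_of", object=parent))
    store._audit("load_gff3", f"{report.records_loaded} records")
    store.conn.commit()
    report.check()
    return report


# ---------------------------------------------------------------------
# BLAST XML


def load_blast_xml(store: FeatureStore, stream,
                   analysis: Optional[Analysis] = None) -> LoadReport:
    """One BlastHit per HSP from NCBI BlastOutput XML. Query
    definitions resolve to stored features by their first token;
    malformed XML aborts the load."""
    report = LoadReport()
    analysis_id = store.add_analysis(analysis) if analysis else None
    handle = io.StringIO(_text(stream))
    for record in NCBIXML.parse(handle):
        qname = (record.query or "").split()[0] if record.query else ""
        known = qname and store.feature_id(qname) is not None
        for alignment in record.alignments:
            for hsp in alignment.hsps:
                report.records_read += 1
                if not known:
                    report.records_skipped += 1
                    report.warn(report.records_read,
                                f"query {qname!r} not in store; HSP skipped")
                    continue
                identity_pct = 100.0 * hsp.identities / hsp.align_length
                store.add_blast_hit(BlastHit(
                    query=qname,
                    hit_accession=alignment.accession or alignment.hit_id,
                    description=alignment.hit_def,
                    e_value=hsp.expect,
                    bit_score=hsp.bits,
                    identity_pct=identity_pct,
                    query_start=hsp.query_start - 1,
                    query_end=hsp.query_end,
                    db_name=record.database or "",
                    analysis_id=analysis_id))
                report.records_loaded += 1
    store._audit("load_blast_xml", f"{report.records_loaded} HSPs")
    store.conn.commit()
    report.check()
    return report


# ---------------------------------------------------------------------
# functional annotation


def load_annot(store: FeatureStore, stream,
               source: str = "blast2go") -> LoadReport:
    """Blast2GO ANNOT dialect: TAB-separated, feature name then a term
    CURIE (GO:... or EC:...), optional description. Unknown features or
    unresolvable terms skip the row with a line-numbered warning."""
    report = LoadReport()
    for lineno, line in enumerate(_text(stream).splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        report.records_read += 1
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            report.records_skipped += 1
            report.warn(lineno, f"malformed row: {line!r}")
            continue
        fname, term = parts[0].strip(), parts[1].strip()
        if store.feature_id(fname) is None:
            report.records_skipped += 1
            report.warn(lineno, f"unknown feature {fname!r}; row skipped")
            continue
        if not store.term_known(term):
            report.records_skipped += 1
            report.warn(lineno, f"unknown term {term!r}; row skipped")
            continue
        store.add_term_annotation(TermAnnotation(
            feature=fname, term_id=term, source=source))
        report.records_loaded += 1
    store._audit("load_annot", f"{report.records_loaded} annotations")
    store.conn.commit()
    report.check()
    return report


def load_interproscan(store: FeatureStore, stream,
                      dbxref_mapping: Optional[DbxrefMapping] = None,
                      columns: Optional[dict[str, int]] = None) -> LoadReport:
    """InterProScan 5 style TSV: a protein-domain feature located on the
    transcript per row; InterPro accessions are mapped through the
    dbxref table to ontology annotations; a GO column, when present, is
    loaded directly.

    ``columns`` overrides the default column layout
    (feature 0, signature 4, start 6, end 7, interpro 11, go 13).
    """
    cols = {"feature": 0, "signature": 4, "start": 6, "end": 7,
            "interpro": 11, "go": 13}
    if columns:
        cols.update(columns)
    report = LoadReport()
    unmapped: list[str] = []
    for lineno, line in enumerate(_text(stream).splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        report.records_read += 1
        parts = line.rstrip("\n").split("\t")
        try:
            fname = parts[cols["feature"]].strip()
            sig = parts[cols["signature"]].strip()
            start = int(parts[cols["start"]])
            end = int(parts[cols["end"]])
        except (IndexError, ValueError):
            report.records_skipped += 1
            report.warn(lineno, f"malformed row: {line!r}")
            continue
        if store.feature_id(fname) is None:
            report.records_skipped += 1
            report.warn(lineno, f"unknown feature {fname!r}; row skipped")
            continue
        domain_name = f"{fname}:{sig}:{start}-{end}"
        store.upsert_feature(Feature(unique_name=domain_name, so_type=SO_DOMAIN,
                                     display_name=sig))
        store.add_location(FeatureLocation(
            feature=domain_name, source_feature=fname,
            start=start - 1, end=end))
        ipr = parts[cols["interpro"]].strip() if len(parts) > cols["interpro"] else ""
        if ipr and ipr != "-" and dbxref_mapping is not None:
            res = dbxref_mapping.map([ipr])
            for term in sorted(res.terms):
                store.add_term_annotation(TermAnnotation(
                    feature=fname, term_id=term, source="dbxref-mapped"))
            for xid in res.unmapped:
                unmapped.append(xid)
                report.warn(lineno, f"unmapped dbxref {xid!r}")
        go_col = parts[cols["go"]].strip() if len(parts) > cols["go"] else ""
        if go_col and go_col != "-":
            for term in go_col.replace(",", "|").split("|"):
                term = term.strip()
                if term and store.term_known(term):
                    store.add_term_annotation(TermAnnotation(
                        feature=fname, term_id=term, source="interproscan"))
        report.records_loaded += 1
    store._audit("load_interproscan", f"{report.records_loaded} domain rows")
    store.conn.commit()
    report.check()
    return report


# ---------------------------------------------------------------------
# VCF markers


def _gt_string(genotype_row, ref: str, alts: list[str]) -> Optional[str]:
    """cyvcf2 genotype row -> 'A/G' style allele string; None when any
    call is missing ('./.')."""
    allele_idx = genotype_row[:-1]  # last element is the phased flag
    if any(i < 0 for i in allele_idx):
        return None
    alleles = [ref] + list(alts)
    return "/".join(alleles[i] for i in allele_idx)


def load_vcf_markers(store: FeatureStore, source, marker_type: str,
                     genotype_column_map: Optional[dict[str, str]] = None
                     ) -> LoadReport:
    """SSR/SNP markers from VCF 4.x. CHROM values must resolve to
    stored transcripts; each record becomes a marker feature located at
    (POS-1, POS-1+len(REF)) interbase, with per-sample GT fields stored
    as alleles of mapped genotypes. SSR motifs are taken from the INFO
    key ``MOTIF`` when present.
    """
    from cyvcf2 import VCF

    if marker_type not in ("SSR", "SNP"):
        raise ValueError(f"marker_type must be SSR or SNP, got {marker_type!r}")
    report = LoadReport()
    tmp = None
    if hasattr(source, "read"):
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False)
        tmp.write(source.read())
        tmp.close()
        path = tmp.name
    else:
        path = str(source)
    try:
        vcf = VCF(path)
        samples = list(vcf.samples)
        gmap = genotype_column_map or {s: s for s in samples}
        warned_samples: set[str] = set()
        for rec in vcf:
            report.records_read += 1
            if store.feature_id(rec.CHROM) is None:
                report.records_skipped += 1
                report.warn(report.records_read,
                            f"CHROM {rec.CHROM!r} not in store; record skipped")
                continue
            name = rec.ID or f"{rec.CHROM}_{rec.POS}_{marker_type}"
            so_type = SO_SSR if marker_type == "SSR" else SO_SNP
            store.upsert_feature(Feature(unique_name=name, so_type=so_type))
            start = rec.POS - 1
            store.add_location(FeatureLocation(
                feature=name, source_feature=rec.CHROM,
                start=start, end=start + len(rec.REF)))
            motif = rec.INFO.get("MOTIF") if marker_type == "SSR" else None
            marker_id = store.add_marker(
                name, marker_type, motif=motif,
                ref_allele=rec.REF if marker_type == "SNP" else None,
                alt_alleles=",".join(rec.ALT) if marker_type == "SNP" else None)
            for i, sample in enumerate(samples):
                gname = gmap.get(sample)
                if gname is None or store.genotype_id(gname) is None:
                    if sample not in warned_samples:
                        warned_samples.add(sample)
                        report.warn(report.records_read,
                                    f"sample {sample!r} has no stored genotype; "
                                    "alleles skipped")
                    continue
                value = _gt_string(rec.genotypes[i], rec.REF, rec.ALT)
                if value is None:
                    continue  # missing call: no allele stored
                store.add_allele(marker_id, gname, value)
            report.records_loaded += 1
    finally:
        if tmp is not None:
            os.unlink(tmp.name)
    store._audit("load_vcf_markers", f"{report.records_loaded} {marker_type}s")
    store.conn.commit()
    report.check()
    return report


# ---------------------------------------------------------------------
# generic association tables

_HEADER_WORDS = {"feature", "name", "term", "library", "value", "predicate",
                 "target", "genotype", "count"}


def _rows(text: str):
    """(lineno, cells) pairs from a TAB or comma table, comments and the
    auto-detected header row removed."""
    delim = "\t" if "\t" in text.splitlines()[0] else "," if text else "\t"
    first_data = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split(delim)]
        if first_data:
            first_data = False
            if any(c.lower() in _HEADER_WORDS for c in cells):
                continue  # header row
        yield lineno, cells


def load_association_table(store: FeatureStore, stream, kind: str) -> LoadReport:
    """Simple 2-3 column TAB/CSV loaders:

    - ``feature_cv``: feature, term -> manual term annotation
    - ``feature_library``: feature, library, value -> raw_count
      expression value
    - ``feature_feature``: feature, predicate, feature -> relationship
    - ``genotype``: name, optional term, optional value -> genotype with
      ontology-described attributes
    """
    kinds = {"feature_cv", "feature_library", "feature_feature", "genotype"}
    if kind not in kinds:
        raise ValueError(f"kind must be one of {sorted(kinds)}, got {kind!r}")
    report = LoadReport()
    for lineno, cells in _rows(_text(stream)):
        report.records_read += 1
        try:
            if kind == "genotype":
                name = cells[0]
                attrs = []
                if len(cells) >= 2 and cells[1]:
                    attrs = [(cells[1], cells[2] if len(cells) > 2 else None)]
                store.add_genotype(name, attrs)
            elif kind == "feature_cv":
                fname, term = cells[0], cells[1]
                if store.feature_id(fname) is None:
                    raise LookupError(f"unknown feature {fname!r}")
                if not store.term_known(term):
                    raise LookupError(f"unknown term {term!r}")
                store.add_term_annotation(TermAnnotation(
                    feature=fname, term_id=term, source="manual"))
            elif kind == "feature_library":
                fname, lib, value = cells[0], cells[1], float(cells[2])
                fid = store.feature_id(fname)
                row = store.conn.execute(
                    "SELECT id FROM seq_library WHERE name=?", (lib,)).fetchone()
                if fid is None or row is None:
                    raise LookupError(
                        f"unknown {'feature' if fid is None else 'library'}")
                if value < 0:
                    raise ValueError("negative expression value")
                store.conn.execute(
                    "INSERT OR REPLACE INTO expression_value "
                    "(feature_id, library_id, measure, value) "
                    "VALUES (?,?,?,?)", (fid, row[0], "raw_count", value))
            else:  # feature_feature
                subj, pred, obj = cells[0], cells[1], cells[2]
                store.add_relationship(FeatureRelationship(
                    subject=subj, predicate=pred, object=obj))
        except (LookupError, ValueError, IndexError, StoreError) as exc:
            report.records_skipped += 1
            report.warn(lineno, f"row skipped: {exc}")
            continue
        report.records_loaded += 1
    store._audit(f"load_association_table[{kind}]",
                 f"{report.records_loaded} rows")
    store.conn.commit()
    report.check()
    return report


# ---------------------------------------------------------------------
# exports


def export_fasta(store: FeatureStore, feature_names=None, width: int = 60) -> str:
    """FASTA text for the selection (default: every feature with
    residues); residue-less features in an explicit selection are
    skipped."""
    if feature_names is None:
        rows = store.conn.execute(
            "SELECT unique_name, residues FROM feature "
            "WHERE residues IS NOT NULL ORDER BY unique_name").fetchall()
    else:
        rows = []
        for name in feature_names:
            feat = store.get_feature(name)
            if feat.residues is None:
                continue
            rows.append((name, feat.residues))
    out = []
    for name, seq in rows:
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + ("\n" if out else "")


def export_annot(store: FeatureStore) -> str:
    """Complete functional annotation in the ANNOT dialect, re-loadable
    by :func:`load_annot` to give back the identical annotation set."""
    rows = store.conn.execute(
        "SELECT f.unique_name, a.term_id FROM term_annotation a "
        "JOIN feature f ON f.id = a.feature_id "
        "ORDER BY f.unique_name, a.term_id").fetchall()
    seen = set()
    lines = []
    for name, term in rows:
        if (name, term) in seen:
            continue
        seen.add((name, term))
        lines.append(f"{name}\t{term}")
    return "\n".join(lines) + ("\n" if lines else "")


def export_table(result, stream=None) -> str:
    """A QueryResult as CSV (delimiter-containing fields quoted)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["unique_name", "so_type", "display_name", "flag",
                     "marker_counts", "attributes"])
    for row in result.rows:
        writer.writerow([
            row.unique_name, row.so_type, row.display_name or "",
            row.flag or "",
            ";".join(f"{k}={v}" for k, v in sorted(row.marker_counts.items())),
            ";".join(f"{k}={v}" for k, v in sorted(row.attributes.items())),
        ])
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text
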