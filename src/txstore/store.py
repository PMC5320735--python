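"""Embedded relational store with a Chado-style modular schema.

Tables are grouped into the five core module groups (Sequence, General,
Publication, Audit, Controlled vocabularies) plus seven additional
groups (Organism, Companalysis, Phenotype, Strain, Genetics, Stock,
Expression); group membership is queryable metadata. The backend is a
single-file SQLite database, and the backup format is a deterministic
plain-text dump (stable row order, version header) so that dumps are
diffable and restore is all-or-nothing.

All loaders write exclusively through the typed operations here; no
other module touches SQL directly except through a StoreHandle.
"""

from __future__ import annotations

import datetime
import json
import os
import re
import sqlite3
from pathlib import Path
from typing import Iterable, Optional

from .model import (
    Analysis,
    BlastHit,
    Feature,
    FeatureLocation,
    FeatureRelationship,
    Organism,
    TermAnnotation,
)
from .ontology import OntologyGraph

DUMP_HEADER = "#txstore-dump v1"
DUMP_FOOTER = "#end"

#: table -> module group; the first five groups are the Chado core.
CORE_MODULE_GROUPS = {
    "Sequence": ["feature", "feature_relationship", "featureloc",
                 "term_annotation", "blast_hit"],
    "General": ["dbxref"],
    "Publication": ["pub"],
    "Audit": ["audit_log"],
    "Controlled vocabularies": ["cv", "cvterm", "ontology_source"],
}
ADDITIONAL_MODULE_GROUPS = {
    "Organism": ["organism"],
    "Companalysis": ["analysis"],
    "Phenotype": ["phenotype"],
    "Strain": ["strain"],
    "Genetics": ["genotype", "genotype_attribute", "marker", "allele"],
    "Stock": ["stock"],
    "Expression": ["experiment", "experiment_condition", "seq_library",
                   "expression_value"],
}
MODULE_GROUPS = {**CORE_MODULE_GROUPS, **ADDITIONAL_MODULE_GROUPS}

_SCHEMA = """
CREATE TABLE organism (
    id INTEGER PRIMARY KEY,
    genus TEXT NOT NULL, species TEXT NOT NULL,
    common_name TEXT, abbreviation TEXT,
    UNIQUE (genus, species));
CREATE TABLE feature (
    id INTEGER PRIMARY KEY,
    organism_id INTEGER NOT NULL REFERENCES organism(id),
    unique_name TEXT NOT NULL, display_name TEXT,
    so_type TEXT NOT NULL, residues TEXT, seqlen INTEGER,
    analysis_id INTEGER REFERENCES analysis(id),
    UNIQUE (organism_id, unique_name));
CREATE TABLE feature_relationship (
    id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES feature(id),
    predicate TEXT NOT NULL,
    object_id INTEGER NOT NULL REFERENCES feature(id),
    rank INTEGER NOT NULL DEFAULT 0,
    UNIQUE (subject_id, predicate, object_id));
CREATE TABLE featureloc (
    id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL REFERENCES feature(id),
    source_feature_id INTEGER NOT NULL REFERENCES feature(id),
    start INTEGER NOT NULL, end INTEGER NOT NULL,
    strand INTEGER NOT NULL DEFAULT 0, phase INTEGER,
    CHECK (start >= 0 AND start <= end),
    UNIQUE (feature_id, source_feature_id, start, end, strand));
CREATE TABLE analysis (
    id INTEGER PRIMARY KEY,
    program TEXT NOT NULL, version TEXT NOT NULL DEFAULT '',
    parameters TEXT NOT NULL DEFAULT '', timestamp TEXT NOT NULL DEFAULT '',
    UNIQUE (program, version, parameters, timestamp));
CREATE TABLE blast_hit (
    id INTEGER PRIMARY KEY,
    query_id INTEGER NOT NULL REFERENCES feature(id),
    hit_accession TEXT NOT NULL, description TEXT NOT NULL DEFAULT '',
    e_value REAL NOT NULL CHECK (e_value >= 0),
    bit_score REAL NOT NULL,
    identity_pct REAL NOT NULL CHECK (identity_pct BETWEEN 0 AND 100),
    query_start INTEGER NOT NULL, query_end INTEGER NOT NULL,
    db_name TEXT NOT NULL DEFAULT '',
    analysis_id INTEGER REFERENCES analysis(id),
    CHECK (query_start <= query_end),
    UNIQUE (query_id, hit_accession, query_start, query_end, e_value,
            bit_score));
CREATE TABLE term_annotation (
    id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL REFERENCES feature(id),
    term_id TEXT NOT NULL, source TEXT NOT NULL DEFAULT 'manual',
    analysis_id INTEGER REFERENCES analysis(id),
    UNIQUE (feature_id, term_id, source));
CREATE TABLE dbxref (
    id INTEGER PRIMARY KEY,
    external_id TEXT NOT NULL, term_id TEXT NOT NULL,
    UNIQUE (external_id, term_id));
CREATE TABLE pub (id INTEGER PRIMARY KEY, uniquename TEXT UNIQUE, title TEXT);
CREATE TABLE phenotype (id INTEGER PRIMARY KEY, uniquename TEXT UNIQUE,
    observable_term TEXT, value TEXT);
CREATE TABLE strain (id INTEGER PRIMARY KEY, name TEXT UNIQUE,
    organism_id INTEGER REFERENCES organism(id));
CREATE TABLE stock (id INTEGER PRIMARY KEY, name TEXT UNIQUE,
    stock_type TEXT);
CREATE TABLE audit_log (
    id INTEGER PRIMARY KEY,
    ts TEXT NOT NULL, action TEXT NOT NULL, detail TEXT NOT NULL DEFAULT '');
CREATE TABLE cv (id INTEGER PRIMARY KEY, name TEXT NOT NULL UNIQUE);
CREATE TABLE cvterm (
    id INTEGER PRIMARY KEY,
    cv_id INTEGER NOT NULL REFERENCES cv(id),
    term_id TEXT NOT NULL UNIQUE, name TEXT NOT NULL DEFAULT '',
    is_obsolete INTEGER NOT NULL DEFAULT 0);
CREATE TABLE ontology_source (
    id INTEGER PRIMARY KEY,
    cv_id INTEGER NOT NULL REFERENCES cv(id) UNIQUE,
    obo_text TEXT NOT NULL);
CREATE TABLE genotype (id INTEGER PRIMARY KEY, name TEXT NOT NULL UNIQUE);
CREATE TABLE genotype_attribute (
    id INTEGER PRIMARY KEY,
    genotype_id INTEGER NOT NULL REFERENCES genotype(id),
    term_id TEXT NOT NULL, value TEXT,
    UNIQUE (genotype_id, term_id));
CREATE TABLE marker (
    id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL UNIQUE REFERENCES feature(id),
    marker_type TEXT NOT NULL CHECK (marker_type IN ('SSR', 'SNP')),
    motif TEXT, ref_allele TEXT, alt_alleles TEXT);
CREATE TABLE allele (
    id INTEGER PRIMARY KEY,
    marker_id INTEGER NOT NULL REFERENCES marker(id),
    genotype_id INTEGER NOT NULL REFERENCES genotype(id),
    value TEXT NOT NULL,
    UNIQUE (marker_id, genotype_id));
CREATE TABLE experiment (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    genotype_id INTEGER REFERENCES genotype(id));
CREATE TABLE experiment_condition (
    id INTEGER PRIMARY KEY,
    experiment_id INTEGER NOT NULL REFERENCES experiment(id),
    term_id TEXT NOT NULL, value TEXT,
    UNIQUE (experiment_id, term_id));
CREATE TABLE seq_library (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    experiment_id INTEGER NOT NULL REFERENCES experiment(id),
    replicate_index INTEGER NOT NULL CHECK (replicate_index >= 1),
    total_reads INTEGER CHECK (total_reads IS NULL OR total_reads > 0),
    UNIQUE (experiment_id, replicate_index));
CREATE TABLE expression_value (
    id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL REFERENCES feature(id),
    library_id INTEGER NOT NULL REFERENCES seq_library(id),
    measure TEXT NOT NULL, value REAL NOT NULL CHECK (value >= 0),
    UNIQUE (feature_id, library_id, measure));
"""

_TABLES = [m.group(1) for m in re.finditer(r"CREATE TABLE (\w+)", _SCHEMA)]


class StoreError(Exception):
    pass


class NotFoundError(StoreError, KeyError):
    pass


class DanglingReferenceError(StoreError):
    pass


class FeatureStore:
    """Handle to one project store. Use :meth:`create` / :meth:`open`."""

    def __init__(self, path, conn: sqlite3.Connection):
        self.path = Path(path)
        self.conn = conn
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle ----------------------------------------------------

    @classmethod
    def create(cls, path, overwrite: bool = False) -> "FeatureStore":
        path = Path(path)
        if path.exists():
            if not overwrite:
                raise StoreError(f"store already exists at {path}")
            path.unlink()
        path.parent.mkdir(parents=True, exist_ok=True)
        conn = sqlite3.connect(path)
        conn.executescript(_SCHEMA)
        store = cls(path, conn)
        store._audit("init_store", str(path))
        store.conn.commit()
        return store

    @classmethod
    def open(cls, path) -> "FeatureStore":
        path = Path(path)
        if not path.exists():
            raise NotFoundError(f"no store at {path}")
        return cls(path, sqlite3.connect(path))

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.conn.commit()
        self.close()

    # -- schema metadata ----------------------------------------------

    def module_groups(self) -> dict[str, list[str]]:
        present = {
            r[0] for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table'")
        }
        return {g: [t for t in ts if t in present]
                for g, ts in MODULE_GROUPS.items()}

    def core_module_groups(self) -> list[str]:
        return list(CORE_MODULE_GROUPS)

    def additional_module_groups(self) -> list[str]:
        return list(ADDITIONAL_MODULE_GROUPS)

    def table_counts(self) -> dict[str, int]:
        return {
            t: self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in _TABLES
        }

    # -- audit --------------------------------------------------------

    def _audit(self, action: str, detail: str = "") -> None:
        ts = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
        self.conn.execute(
            "INSERT INTO audit_log (ts, action, detail) VALUES (?, ?, ?)",
            (ts, action, detail),
        )

    # -- organisms ----------------------------------------------------

    def add_organism(self, organism: Organism) -> int:
        cur = self.conn.execute(
            "SELECT id FROM organism WHERE genus=? AND species=?",
            (organism.genus, organism.species),
        ).fetchone()
        if cur:
            return cur[0]
        c = self.conn.execute(
            "INSERT INTO organism (genus, species, common_name, abbreviation) "
            "VALUES (?, ?, ?, ?)",
            (organism.genus, organism.species, organism.common_name,
             organism.abbreviation),
        )
        self._audit("add_organism", f"{organism.genus} {organism.species}")
        return c.lastrowid

    def default_organism_id(self) -> int:
        row = self.conn.execute("SELECT id FROM organism ORDER BY id LIMIT 1"
                                ).fetchone()
        if row is None:
            raise NotFoundError("no organism in store; add one first")
        return row[0]

    # -- ontologies registered with the store -------------------------

    def register_ontology(self, graph: OntologyGraph,
                          obo_text: Optional[str] = None) -> int:
        """Record a parsed ontology's terms in the Controlled
        vocabularies tables (and optionally its OBO source text so CLI
        sessions can rebuild the graph later)."""
        row = self.conn.execute("SELECT id FROM cv WHERE name=?",
                                (graph.ontology_name,)).fetchone()
        if row:
            cv_id = row[0]
        else:
            cv_id = self.conn.execute("INSERT INTO cv (name) VALUES (?)",
                                      (graph.ontology_name,)).lastrowid
        self.conn.executemany(
            "INSERT OR REPLACE INTO cvterm (cv_id, term_id, name, is_obsolete) "
            "VALUES (?, ?, ?, ?)",
            [(cv_id, t.term_id, t.name, int(t.is_obsolete))
             for t in graph.terms.values()],
        )
        if obo_text is not None:
            self.conn.execute(
                "INSERT OR REPLACE INTO ontology_source (cv_id, obo_text) "
                "VALUES (?, ?)", (cv_id, obo_text))
        self._audit("register_ontology", graph.ontology_name)
        self.conn.commit()
        return cv_id

    def ontology_sources(self) -> dict[str, str]:
        return dict(self.conn.execute(
            "SELECT cv.name, s.obo_text FROM ontology_source s "
            "JOIN cv ON cv.id = s.cv_id ORDER BY cv.name"))

    def term_known(self, term_id: str) -> bool:
        """A term resolves when it is registered, or when no vocabulary
        with its CURIE prefix has been loaded at all (so e.g. EC numbers
        pass through untouched while a bad GO id is rejected once GO is
        registered)."""
        if self.conn.execute("SELECT 1 FROM cvterm WHERE term_id=?",
                             (term_id,)).fetchone():
            return True
        prefix = term_id.split(":", 1)[0] + ":"
        row = self.conn.execute(
            "SELECT 1 FROM cvterm WHERE term_id LIKE ? LIMIT 1",
            (prefix + "%",)).fetchone()
        return row is None

    # -- features -----------------------------------------------------

    def feature_id(self, unique_name: str,
                   organism_id: Optional[int] = None) -> Optional[int]:
        if organism_id is None:
            row = self.conn.execute(
                "SELECT id FROM feature WHERE unique_name=?", (unique_name,)
            ).fetchone()
        else:
            row = self.conn.execute(
                "SELECT id FROM feature WHERE unique_name=? AND organism_id=?",
                (unique_name, organism_id)).fetchone()
        return row[0] if row else None

    def require_feature_id(self, unique_name: str) -> int:
        fid = self.feature_id(unique_name)
        if fid is None:
            raise NotFoundError(f"unknown feature {unique_name!r}")
        return fid

    def upsert_feature(self, feature: Feature,
                       organism_id: Optional[int] = None) -> int:
        org = organism_id if organism_id is not None else self.default_organism_id()
        fid = self.feature_id(feature.unique_name, org)
        if fid is None:
            c = self.conn.execute(
                "INSERT INTO feature (organism_id, unique_name, display_name, "
                "so_type, residues, seqlen, analysis_id) VALUES (?,?,?,?,?,?,?)",
                (org, feature.unique_name, feature.display_name,
                 feature.so_type, feature.residues, feature.seqlen,
                 feature.analysis_id),
            )
            fid = c.lastrowid
        else:
            self.conn.execute(
                "UPDATE feature SET display_name=?, so_type=?, residues=?, "
                "seqlen=?, analysis_id=? WHERE id=?",
                (feature.display_name, feature.so_type, feature.residues,
                 feature.seqlen, feature.analysis_id, fid),
            )
        return fid

    def get_feature(self, unique_name: str) -> Feature:
        row = self.conn.execute(
            "SELECT unique_name, display_name, so_type, residues, seqlen, "
            "analysis_id FROM feature WHERE unique_name=?",
            (unique_name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown feature {unique_name!r}")
        return Feature(unique_name=row[0], display_name=row[1], so_type=row[2],
                       residues=row[3], seqlen=row[4], analysis_id=row[5])

    def add_relationship(self, rel: FeatureRelationship) -> int:
        sid = self.feature_id(rel.subject)
        oid = self.feature_id(rel.object)
        if sid is None or oid is None:
            missing = rel.subject if sid is None else rel.object
            raise DanglingReferenceError(f"unknown feature {missing!r}")
        if sid == oid:
            raise StoreError(f"self-relationship on {rel.subject!r}")
        c = self.conn.execute(
            "INSERT OR IGNORE INTO feature_relationship "
            "(subject_id, predicate, object_id, rank) VALUES (?,?,?,?)",
            (sid, rel.predicate, oid, rel.rank),
        )
        if c.rowcount == 0:
            return self.conn.execute(
                "SELECT id FROM feature_relationship WHERE subject_id=? AND "
                "predicate=? AND object_id=?", (sid, rel.predicate, oid)
            ).fetchone()[0]
        return c.lastrowid

    def add_location(self, loc: FeatureLocation) -> int:
        fid = self.feature_id(loc.feature)
        srcid = self.feature_id(loc.source_feature)
        if fid is None or srcid is None:
            missing = loc.feature if fid is None else loc.source_feature
            raise DanglingReferenceError(f"unknown feature {missing!r}")
        if not (0 <= loc.start <= loc.end):
            raise StoreError(f"bad interbase range {loc.start}..{loc.end}")
        seqlen = self.conn.execute(
            "SELECT seqlen FROM feature WHERE id=?", (srcid,)).fetchone()[0]
        if seqlen is not None and loc.end > seqlen:
            raise StoreError(
                f"location end {loc.end} exceeds {loc.source_feature!r} "
                f"seqlen {seqlen}")
        c = self.conn.execute(
            "INSERT OR IGNORE INTO featureloc (feature_id, "
            "source_feature_id, start, end, strand, phase) "
            "VALUES (?,?,?,?,?,?)",
            (fid, srcid, loc.start, loc.end, loc.strand, loc.phase),
        )
        if c.rowcount == 0:  # identical location already stored
            return self.conn.execute(
                "SELECT id FROM featureloc WHERE feature_id=? AND "
                "source_feature_id=? AND start=? AND end=? AND strand=?",
                (fid, srcid, loc.start, loc.end, loc.strand)).fetchone()[0]
        return c.lastrowid

    # -- analyses, hits, annotations ----------------------------------

    def add_analysis(self, analysis: Analysis) -> int:
        row = self.conn.execute(
            "SELECT id FROM analysis WHERE program=? AND version=? AND "
            "parameters=? AND timestamp=?",
            (analysis.program, analysis.version, analysis.parameters,
             analysis.timestamp)).fetchone()
        if row:
            return row[0]
        return self.conn.execute(
            "INSERT INTO analysis (program, version, parameters, timestamp) "
            "VALUES (?,?,?,?)",
            (analysis.program, analysis.version, analysis.parameters,
             analysis.timestamp)).lastrowid

    def add_blast_hit(self, hit: BlastHit) -> int:
        qid = self.require_feature_id(hit.query)
        return self.conn.execute(
            "INSERT OR IGNORE INTO blast_hit (query_id, hit_accession, "
            "description, "
            "e_value, bit_score, identity_pct, query_start, query_end, "
            "db_name, analysis_id) VALUES (?,?,?,?,?,?,?,?,?,?)",
            (qid, hit.hit_accession, hit.description, hit.e_value,
             hit.bit_score, hit.identity_pct, hit.query_start, hit.query_end,
             hit.db_name, hit.analysis_id)).lastrowid

    def add_term_annotation(self, ann: TermAnnotation) -> int:
        fid = self.require_feature_id(ann.feature)
        c = self.conn.execute(
            "INSERT OR IGNORE INTO term_annotation (feature_id, term_id, "
            "source, analysis_id) VALUES (?,?,?,?)",
            (fid, ann.term_id, ann.source, ann.analysis_id))
        if c.rowcount == 0:
            return self.conn.execute(
                "SELECT id FROM term_annotation WHERE feature_id=? AND "
                "term_id=? AND source=?",
                (fid, ann.term_id, ann.source)).fetchone()[0]
        return c.lastrowid

    def direct_annotations(self, features: Optional[Iterable[str]] = None
                           ) -> dict[str, set[str]]:
        """unique_name -> set of directly annotated term CURIEs."""
        sql = ("SELECT f.unique_name, a.term_id FROM term_annotation a "
               "JOIN feature f ON f.id = a.feature_id")
        rows = self.conn.execute(sql).fetchall()
        wanted = set(features) if features is not None else None
        out: dict[str, set[str]] = {}
        for name, term in rows:
            if wanted is not None and name not in wanted:
                continue
            out.setdefault(name, set()).add(term)
        return out

    # -- genotypes, markers, alleles ----------------------------------

    def add_genotype(self, name: str,
                     attributes: Iterable[tuple[str, Optional[str]]] = ()
                     ) -> int:
        row = self.conn.execute("SELECT id FROM genotype WHERE name=?",
                                (name,)).fetchone()
        gid = row[0] if row else self.conn.execute(
            "INSERT INTO genotype (name) VALUES (?)", (name,)).lastrowid
        for term_id, value in attributes:
            self.conn.execute(
                "INSERT OR REPLACE INTO genotype_attribute "
                "(genotype_id, term_id, value) VALUES (?,?,?)",
                (gid, term_id, value))
        return gid

    def genotype_id(self, name: str) -> Optional[int]:
        row = self.conn.execute("SELECT id FROM genotype WHERE name=?",
                                (name,)).fetchone()
        return row[0] if row else None

    def add_marker(self, feature_name: str, marker_type: str,
                   motif: Optional[str] = None,
                   ref_allele: Optional[str] = None,
                   alt_alleles: Optional[str] = None) -> int:
        fid = self.require_feature_id(feature_name)
        row = self.conn.execute("SELECT id FROM marker WHERE feature_id=?",
                                (fid,)).fetchone()
        if row:
            self.conn.execute(
                "UPDATE marker SET marker_type=?, motif=?, ref_allele=?, "
                "alt_alleles=? WHERE id=?",
                (marker_type, motif, ref_allele, alt_alleles, row[0]))
            return row[0]
        return self.conn.execute(
            "INSERT INTO marker (feature_id, marker_type, motif, ref_allele, "
            "alt_alleles) VALUES (?,?,?,?,?)",
            (fid, marker_type, motif, ref_allele, alt_alleles)).lastrowid

    def add_allele(self, marker_id: int, genotype_name: str, value: str) -> int:
        gid = self.genotype_id(genotype_name)
        if gid is None:
            raise DanglingReferenceError(f"unknown genotype {genotype_name!r}")
        self.conn.execute(
            "INSERT OR REPLACE INTO allele (marker_id, genotype_id, value) "
            "VALUES (?,?,?)", (marker_id, gid, value))
        return self.conn.execute(
            "SELECT id FROM allele WHERE marker_id=? AND genotype_id=?",
            (marker_id, gid)).fetchone()[0]

    def marker_counts_for(self, feature_names: Iterable[str]
                          ) -> dict[str, dict[str, int]]:
        """unique_name -> {marker_type: count of markers located on it}."""
        out = {n: {} for n in feature_names}
        rows = self.conn.execute(
            "SELECT src.unique_name, m.marker_type, COUNT(*) "
            "FROM marker m "
            "JOIN featureloc l ON l.feature_id = m.feature_id "
            "JOIN feature src ON src.id = l.source_feature_id "
            "GROUP BY src.unique_name, m.marker_type").fetchall()
        for name, mtype, n in rows:
            if name in out:
                out[name][mtype] = n
        return out

    # -- deletion with cascade ----------------------------------------

    def delete_entity(self, kind: str, identifier: str) -> int:
        """Remove one entity and every dependent record; returns the
        total number of rows removed (entity included)."""
        handlers = {
            "feature": self._delete_feature,
            "genotype": self._delete_genotype,
            "experiment": self._delete_experiment,
            "marker": self._delete_marker,
        }
        if kind not in handlers:
            raise StoreError(f"unknown entity kind {kind!r}")
        n = handlers[kind](identifier)
        self._audit("delete_entity", f"{kind}:{identifier} ({n} rows)")
        self.conn.commit()
        return n

    def _exec_count(self, sql: str, params) -> int:
        return self.conn.execute(sql, params).rowcount

    def _delete_marker_rows(self, marker_ids: list[int]) -> int:
        n = 0
        for mid in marker_ids:
            n += self._exec_count("DELETE FROM allele WHERE marker_id=?", (mid,))
            n += self._exec_count("DELETE FROM marker WHERE id=?", (mid,))
        return n

    def _delete_feature(self, unique_name: str) -> int:
        fid = self.require_feature_id(unique_name)
        n = 0
        marker_ids = [r[0] for r in self.conn.execute(
            "SELECT id FROM marker WHERE feature_id=?", (fid,))]
        n += self._delete_marker_rows(marker_ids)
        n += self._exec_count(
            "DELETE FROM featureloc WHERE feature_id=? OR source_feature_id=?",
            (fid, fid))
        n += self._exec_count(
            "DELETE FROM feature_relationship WHERE subject_id=? OR object_id=?",
            (fid, fid))
        n += self._exec_count("DELETE FROM term_annotation WHERE feature_id=?",
                              (fid,))
        n += self._exec_count("DELETE FROM blast_hit WHERE query_id=?", (fid,))
        n += self._exec_count("DELETE FROM expression_value WHERE feature_id=?",
                              (fid,))
        n += self._exec_count("DELETE FROM feature WHERE id=?", (fid,))
        return n

    def _delete_genotype(self, name: str) -> int:
        gid = self.genotype_id(name)
        if gid is None:
            raise NotFoundError(f"unknown genotype {name!r}")
        n = self._exec_count("DELETE FROM allele WHERE genotype_id=?", (gid,))
        n += self._exec_count(
            "DELETE FROM genotype_attribute WHERE genotype_id=?", (gid,))
        self.conn.execute("UPDATE experiment SET genotype_id=NULL "
                          "WHERE genotype_id=?", (gid,))
        n += self._exec_count("DELETE FROM genotype WHERE id=?", (gid,))
        return n

    def _delete_experiment(self, name: str) -> int:
        row = self.conn.execute("SELECT id FROM experiment WHERE name=?",
                                (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown experiment {name!r}")
        eid = row[0]
        n = 0
        lib_ids = [r[0] for r in self.conn.execute(
            "SELECT id FROM seq_library WHERE experiment_id=?", (eid,))]
        for lid in lib_ids:
            n += self._exec_count(
                "DELETE FROM expression_value WHERE library_id=?", (lid,))
        n += self._exec_count("DELETE FROM seq_library WHERE experiment_id=?",
                              (eid,))
        n += self._exec_count(
            "DELETE FROM experiment_condition WHERE experiment_id=?", (eid,))
        n += self._exec_count("DELETE FROM experiment WHERE id=?", (eid,))
        return n

    def _delete_marker(self, feature_name: str) -> int:
        fid = self.require_feature_id(feature_name)
        marker_ids = [r[0] for r in self.conn.execute(
            "SELECT id FROM marker WHERE feature_id=?", (fid,))]
        if not marker_ids:
            raise NotFoundError(f"no marker on feature {feature_name!r}")
        return self._delete_marker_rows(marker_ids)

    # -- backup / restore ---------------------------------------------

    def backup(self) -> str:
        """Deterministic plain-text dump: one JSON array per row,
        tables in schema order, rows in primary-key order."""
        lines = [DUMP_HEADER]
        for table in _TABLES:
            cols = [r[1] for r in self.conn.execute(f"PRAGMA table_info({table})")]
            rows = self.conn.execute(
                f"SELECT {', '.join(cols)} FROM {table} ORDER BY id").fetchall()
            lines.append(f"#table {table} {len(rows)}")
            for row in rows:
                lines.append(json.dumps(list(row), separators=(",", ":")))
        lines.append(DUMP_FOOTER)
        return "\n".join(lines) + "\n"

    @classmethod
    def restore(cls, dump: str, path, overwrite: bool = False) -> "FeatureStore":
        """Rebuild a store from a :meth:`backup` dump. The dump is fully
        validated before anything is written, so a truncated or
        version-mismatched dump leaves the target path untouched."""
        lines = dump.splitlines()
        if not lines or lines[0] != DUMP_HEADER:
            raise StoreError("not a txstore dump (bad or missing header)")
        if lines[-1] != DUMP_FOOTER:
            raise StoreError("truncated dump (missing end marker)")
        tables: list[tuple[str, list[list]]] = []
        i = 1
        while i < len(lines) - 1:
            m = re.match(r"#table (\w+) (\d+)$", lines[i])
            if not m:
                raise StoreError(f"malformed dump at line {i + 1}")
            name, nrows = m.group(1), int(m.group(2))
            if name not in _TABLES:
                raise StoreError(f"unknown table {name!r} in dump")
            rows = []
            for j in range(nrows):
                try:
                    rows.append(json.loads(lines[i + 1 + j]))
                except (IndexError, json.JSONDecodeError) as exc:
                    raise StoreError("truncated dump") from exc
            tables.append((name, rows))
            i += 1 + nrows
        store = cls.create(path, overwrite=overwrite)
        store.conn.execute("PRAGMA foreign_keys = OFF")
        store.conn.execute("DELETE FROM audit_log")  # dump carries its own
        for name, rows in tables:
            cols = [r[1] for r in store.conn.execute(f"PRAGMA table_info({name})")]
            ph = ", ".join("?" for _ in cols)
            store.conn.executemany(
                f"INSERT INTO {name} ({', '.join(cols)}) VALUES ({ph})", rows)
        store.conn.execute("PRAGMA foreign_keys = ON")
        store.conn.commit()
        return store


def init_store(path, overwrite: bool = False) -> FeatureStore:
    """Create an empty project store at ``path``."""
    return FeatureStore.create(path, overwrite=overwrite)
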