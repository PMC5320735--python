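"""Replicate-structured RNA-seq experiments and RPKM summaries.

An experiment is a biological condition described by ontology terms
(e.g. anatomy-ontology terms for phenological state and sex) and
optionally tied to a genotype; it owns one sequencing library per
replicate. Per-library measured values are stored per feature, and
profiles report the arithmetic mean and sample standard deviation
(n-1 denominator, 0 when n = 1) across the replicates of each
condition.

RPKM (reads per kilobase of transcript per million mapped reads)
normalizes a raw count by transcript length and library depth:

    RPKM = count * 1e9 / (length_bp * total_reads)

When every mapped read of a library is assigned to exactly one
transcript, sum(RPKM * length) = 1e9 over the library — a useful
conservation check. Raw counts need not be integers (pseudo-aligned or
otherwise fractional counts are accepted).
"""

from __future__ import annotations

import statistics
import warnings
from typing import Iterable, Optional, Sequence

from .model import ExpressionSummary
from .store import FeatureStore, NotFoundError, StoreError

RPKM_SCALE = 1e9  # per-kilobase (1e3) times per-million (1e6)


def create_experiment(store: FeatureStore, name: str,
                      condition_terms: Sequence[tuple[str, Optional[str]]] = (),
                      genotype: Optional[str] = None) -> int:
    """Persist an experiment with its ontology-term condition
    descriptors; the name must be unused and every term must resolve."""
    if store.conn.execute("SELECT 1 FROM experiment WHERE name=?",
                          (name,)).fetchone():
        raise StoreError(f"experiment {name!r} already exists")
    genotype_id = None
    if genotype is not None:
        genotype_id = store.genotype_id(genotype)
        if genotype_id is None:
            raise NotFoundError(f"unknown genotype {genotype!r}")
    for term_id, _ in condition_terms:
        if not store.term_known(term_id):
            raise NotFoundError(f"unknown condition term {term_id!r}")
    eid = store.conn.execute(
        "INSERT INTO experiment (name, genotype_id) VALUES (?, ?)",
        (name, genotype_id)).lastrowid
    for term_id, value in condition_terms:
        store.conn.execute(
            "INSERT INTO experiment_condition (experiment_id, term_id, value) "
            "VALUES (?,?,?)", (eid, term_id, value))
    store._audit("create_experiment", name)
    store.conn.commit()
    return eid


def add_library(store: FeatureStore, experiment: str, name: str,
                replicate_index: int, total_reads: Optional[int] = None) -> int:
    """One sequencing library = one replicate of an experiment."""
    row = store.conn.execute("SELECT id FROM experiment WHERE name=?",
                             (experiment,)).fetchone()
    if row is None:
        raise NotFoundError(f"unknown experiment {experiment!r}")
    eid = row[0]
    if store.conn.execute(
            "SELECT 1 FROM seq_library WHERE experiment_id=? AND "
            "replicate_index=?", (eid, replicate_index)).fetchone():
        raise StoreError(
            f"replicate {replicate_index} already exists in {experiment!r}")
    lid = store.conn.execute(
        "INSERT INTO seq_library (name, experiment_id, replicate_index, "
        "total_reads) VALUES (?,?,?,?)",
        (name, eid, replicate_index, total_reads)).lastrowid
    store._audit("add_library", f"{experiment}/{name}")
    store.conn.commit()
    return lid


def compute_rpkm(raw_count: float, transcript_length_bp: int,
                 library_total_reads: int) -> float:
    """raw_count * 1e9 / (length * total_reads)."""
    if transcript_length_bp <= 0:
        raise ValueError(f"non-positive transcript length {transcript_length_bp}")
    if library_total_reads <= 0:
        raise ValueError(f"non-positive library total {library_total_reads}")
    if raw_count < 0:
        raise ValueError(f"negative raw count {raw_count}")
    return raw_count * RPKM_SCALE / (transcript_length_bp * library_total_reads)


def rpkm_for_library(store: FeatureStore, library: str) -> int:
    """Derive one RPKM value per stored raw_count in the library, using
    each feature's seqlen; features without a sequence length are
    skipped with a warning. Idempotent (re-running overwrites)."""
    row = store.conn.execute(
        "SELECT id, total_reads FROM seq_library WHERE name=?",
        (library,)).fetchone()
    if row is None:
        raise NotFoundError(f"unknown library {library!r}")
    lid, total_reads = row
    if not total_reads:
        raise StoreError(f"library {library!r} has no total_reads")
    rows = store.conn.execute(
        "SELECT v.feature_id, v.value, f.seqlen, f.unique_name "
        "FROM expression_value v JOIN feature f ON f.id = v.feature_id "
        "WHERE v.library_id=? AND v.measure='raw_count' ORDER BY f.unique_name",
        (lid,)).fetchall()
    written = 0
    for fid, count, seqlen, name in rows:
        if not seqlen:
            warnings.warn(f"{name!r} has no sequence length; RPKM skipped",
                          stacklevel=2)
            continue
        store.conn.execute(
            "INSERT OR REPLACE INTO expression_value "
            "(feature_id, library_id, measure, value) VALUES (?,?,?,?)",
            (fid, lid, "RPKM", compute_rpkm(count, seqlen, total_reads)))
        written += 1
    store._audit("rpkm_for_library", f"{library}: {written} values")
    store.conn.commit()
    return written


def expression_profile(store: FeatureStore, feature: str,
                       experiments: Optional[Iterable[str]] = None,
                       measure: str = "RPKM") -> list[ExpressionSummary]:
    """Mean and standard deviation of the stored replicate values of one
    feature, per experiment. Experiments with no stored value for the
    feature are absent from the output."""
    fid = store.require_feature_id(feature)
    sql = (
        "SELECT e.name, g.name, v.value "
        "FROM expression_value v "
        "JOIN seq_library l ON l.id = v.library_id "
        "JOIN experiment e ON e.id = l.experiment_id "
        "LEFT JOIN genotype g ON g.id = e.genotype_id "
        "WHERE v.feature_id=? AND v.measure=? "
        "ORDER BY e.name, l.replicate_index")
    rows = store.conn.execute(sql, (fid, measure)).fetchall()
    wanted = set(experiments) if experiments is not None else None
    grouped: dict[str, tuple[Optional[str], list[float]]] = {}
    for exp, geno, value in rows:
        if wanted is not None and exp not in wanted:
            continue
        grouped.setdefault(exp, (geno, []))[1].append(value)
    out = []
    for exp in sorted(grouped):
        geno, values = grouped[exp]
        mean = statistics.fmean(values)
        sd = statistics.stdev(values) if len(values) > 1 else 0.0
        out.append(ExpressionSummary(
            feature=feature, experiment=exp, measure=measure,
            mean=mean, sd=sd, n=len(values), genotype=geno))
    return out
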