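# txstore

An ontology-driven relational store, bulk loaders and query layer for
**de novo transcriptome projects** — the downstream half of an RNA-seq
study of a species without a reference genome, where the data arrive as
a pile of third-party results: an assembly FASTA of *isotigs*
(transcript contigs), the *isogroup* (gene locus) list, GFF3 structural
annotation, BLAST XML, Blast2GO/InterProScan functional annotation, SSR
and SNP marker VCFs, genotypes, and per-library expression counts from
a replicate-structured experimental design.

`txstore` loads all of it into a single-file relational store organized
after the Chado modular schema, propagates functional annotations
through ontology DAGs, and answers the integrated questions such
projects ask — e.g. *"which transcripts are annotated under
`developmental process involved in reproduction` (directly or by
inheritance) **and** carry at least one microsatellite marker, and how
are they expressed across conditions?"* — without a database server or
web stack. It is aimed at small research groups and at pipelines that
need a scriptable, reproducible project store.

## The model in brief

**Annotation propagation.** For an ontology DAG with closure predicates
`{is_a, part_of}` (the standard GO propagation rules), a feature
annotated to term *t* is *directly* annotated at *t* and *inheritedly*
annotated at every ancestor of *t*:

    inherited(f) = ( ⋃_{t ∈ direct(f)} ancestors(t) ) \ direct(f)

Term-count summaries use **distinct-feature** semantics: the count at a
term is the number of distinct features annotated at or below it, so
per-child counts of a focus term may legitimately sum to more than the
distinct total when features are multiply annotated.

**Expression.** Raw counts per (feature, library) are normalized as
RPKM (reads per kilobase of transcript per million mapped reads):

    RPKM = count × 10⁹ / (length_bp × library_total_reads)

Profiles report the arithmetic mean and sample standard deviation
(n − 1 denominator; 0 when n = 1) over the replicate libraries of each
experiment.

**Coordinates.** Storage is interbase (0-based half-open, the Chado
convention); GFF3/VCF/InterProScan coordinates are converted at the I/O
boundary and reports display 1-based inclusive positions.

## Worked example

```python
import tempfile, pathlib
from txstore import init_store
from txstore.fixtures import FixtureSpec, make_toy_project, load_bundle, replay_case_study

tmp = pathlib.Path(tempfile.mkdtemp())
manifest = make_toy_project(FixtureSpec(seed=1), tmp / "bundle")
store = init_store(tmp / "project.db")
out = load_bundle(store, tmp / "bundle")      # every loader, tutorial order

hits = replay_case_study(store, out["graph"], manifest["focus_term"])
print(len(manifest["ssr_features"]), "SSR-bearing transcripts")
print(len(hits), "of them annotated under", manifest["focus_term"])
print(hits[:3])
```

prints (seed 1):

```
8 SSR-bearing transcripts
8 of them annotated under TGO:0000006
['isotig00001', 'isotig00002', 'isotig00003']
```

i.e. of the 16 toy transcripts, 8 carry a planted microsatellite, and
all 8 of those are annotated — directly or through the ontology DAG —
under the toy reproduction-process term; the set is byte-identical to
the generator's brute-force ground truth (`manifest["replay_answer"]`).

The same workflow is available from the shell:

```bash
txstore fixture /tmp/bundle --seed 1
txstore --store /tmp/p.db init --organism "Synthetica exemplaris"
txstore --store /tmp/p.db load-ontology /tmp/bundle/toy_go.obo
txstore --store /tmp/p.db load-fasta /tmp/bundle/transcripts.fasta
# ... load-gff, load-annot, load-markers, create-experiment, ...
txstore --store /tmp/p.db search --term TGO:0000006 --with-marker SSR
```

## File formats

FASTA (Biopython), plain feature-name lists, GFF3 (gffutils), NCBI
BLAST XML (Biopython), Blast2GO ANNOT (TAB: feature, term CURIE,
optional description), InterProScan 5 TSV, VCF 4.x markers (cyvcf2;
SSR motifs from the INFO key `MOTIF`), interpro2go-style dbxref tables,
OBO 1.2/1.4 ontologies (obonet), and generic TAB/CSV association
tables. Exports: FASTA, ANNOT (both exact inverses of their loaders)
and CSV result tables. Backups are deterministic plain-text dumps;
restore is all-or-nothing.

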