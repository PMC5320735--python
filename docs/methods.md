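# Methods

## Scope and data model

`txstore` is a headless re-implementation of the computational core of
an ontology-driven transcriptome data-integration application: a
modular relational store, bulk loaders for the standard result formats
of a de novo RNA-seq project, ontology-aware queries, and integrated
per-entity reports. There is deliberately no web layer; the library
functions and the `txstore` CLI are the interface.

The store follows the Chado convention of grouping tables into modules.
Five core groups — *Sequence*, *General*, *Publication*, *Audit*,
*Controlled vocabularies* — hold features, relationships, locations,
annotations, BLAST hits, cross-references, the operation log and
registered vocabularies; seven additional groups — *Organism*,
*Companalysis*, *Phenotype*, *Strain*, *Genetics*, *Stock*,
*Expression* — hold organisms, analysis provenance, genotypes, markers,
alleles and the replicate-structured expression design. Group
membership is queryable metadata (`FeatureStore.module_groups()`).
Chado proper has no ready-made home for replicate-structured RNA-seq
values; the `experiment` / `experiment_condition` / `seq_library` /
`expression_value` tables are this package's concrete rendering of that
extension. The *Publication*, *Phenotype*, *Strain* and *Stock* groups
are instantiated as tables but carry no loaders or queries — they mark
the schema surface without inventing behaviour no loader exercises.

The backend is a single-file SQLite database (stdlib `sqlite3`): a
project of this scale fits comfortably in an embedded engine on a
desktop machine, needs no server, and makes backup a pure function of
the file. The audit module is an append-only log of mutating
operations, written by the store methods themselves.

## Ontology handling

OBO 1.2/1.4 files are parsed with `obonet`; a pre-scan of stanza `id:`
lines adds duplicate-term detection (obonet silently merges duplicate
stanzas), and relation endpoints that never appear as `[Term]` stanzas
are rejected as dangling. Closure predicates default to
`{is_a, part_of}` — the standard GO propagation set — and are
configurable per graph. Cycles over the closure predicates are a hard
load error (the offending terms are listed): annotation inheritance is
only well-defined on a DAG. Obsolete terms load, but carry no outgoing
closure edges and are excluded from propagation and counting, with a
warning when an annotation points at one; this is ordinary OBO
practice.

Ancestor sets are computed by iterative depth-first traversal with
per-term memoization, filled on demand rather than materialized as a
full closure table — only the visited fraction of the DAG is ever held
in memory, and repeated queries are O(answer size). Correctness is
checked in the tests against an independent boolean-matrix transitive
closure (`closure = Σ Aᵏ` over the parent adjacency matrix), never
against the traversal itself.

Counting semantics: the count at a term is the number of **distinct**
features annotated at or below it (`term ∈ direct ∪ inherited`).
Because one feature may sit below several children of a focus term,
child counts may sum to more than the focus total; that is a property
of multiple annotation, not double counting, and is asserted explicitly
in the acceptance tests.

## Coordinates

All stored coordinates are interbase (0-based, half-open) — the Chado
convention, under which length is simply `end − start`. GFF3,
InterProScan and VCF positions (1-based inclusive) are converted at the
I/O boundary: `(start−1, end)` for ranges, `(POS−1, POS−1+len(REF))`
for VCF records. Reports convert back to 1-based inclusive for display
in one central helper, so round trips are exact by construction and are
tested end to end (GFF3 in → store → report out).

## Loaders

Every loader writes through the typed store operations (single write
path) and returns a `LoadReport` with the invariant
`read = loaded + skipped`; warnings carry line numbers and are never
fatal to the rest of the file, except malformed XML, which aborts the
BLAST load. Loading the same file twice leaves the store in the same
state as loading it once: features upsert by unique name, and
locations, hits, annotations and alleles deduplicate on their natural
keys.

Choices worth stating:

- **ANNOT dialect**: 2–3 column TAB (feature, term CURIE, optional
  description). EC numbers are accepted as annotations with a non-GO
  CURIE.
- **Term validation**: a term resolves if it is registered in the
  store's vocabulary tables, or if no vocabulary with its CURIE prefix
  has been registered at all — so a bad GO id is rejected once GO is
  loaded, while EC numbers pass through untouched.
- **GFF3** is parsed in two passes so `Parent=` may name an ID defined
  later in the file; unknown column-3 types fall back to the generic
  region type with a warning rather than failing the file.
- **BLAST XML**: one stored hit per HSP (unambiguous and testable);
  identity% = identities / alignment length × 100.
- **SSR markers in VCF**: the SSR motif is read from the INFO key
  `MOTIF`. VCF is the marker path; native outputs of SSR/SNP discovery
  tools are expected to be converted to VCF upstream.
- **Genotypes**: loaded via a fourth association-table kind
  (`genotype`: name, optional ontology term, optional value), since no
  standard file format exists for them.
- **Missing VCF calls** (`./.`) store no allele.

## Expression

`RPKM = count × 10⁹ / (length_bp × total_reads)`, with the standard
scaling constant (per kilobase × per million). Raw counts may be
non-integral (pseudo-aligned or otherwise fractional counts are legal
inputs). When every read of a library is assigned to exactly one
transcript, `Σ_f RPKM(f) × len(f) = 10⁹` exactly; the tests assert this
to 1e-6 relative on random count vectors. Replicate summaries use the
arithmetic mean and the sample (n − 1) standard deviation, reported as
0 when n = 1 with `n` exposed so callers can tell the two apart.

## Queries and reports

`like` search translates SQL-style wildcards to the regex engine
(`%` → `.*`, `_` → `.`), case-insensitive by default; `regex` mode
reports the error position on a bad pattern. Term search flags rows
`direct` or `indirect`, with direct taking precedence when both apply.
Results are deterministic (unique_name ascending). The sequence report
has six sections (residues, relationships, structural annotation,
functional annotation with the reduced ontology subgraph, BLAST
results, expression profile); a residue-less feature (a gene locus in a
de novo assembly) gets the general report: relationships only. Reports
hold nothing that is not re-derivable from store queries.

## Synthetic data

The fixture generator emulates the *structure* of a real project — a
Newbler-style isotig/isogroup assembly, planted SSR tracts, SNPs,
GFF3/BLAST/ANNOT/InterProScan/VCF/expression files that are mutually
consistent by construction, and a three-condition design (male larvae,
male adults, female adults) with one library per condition and one
larval-biased gene locus. Defaults: 10 isogroups of 1–3 isoforms,
300–1200 bp transcripts, 8 SSRs, 10 SNPs, a 30-term random rooted
ontology DAG with ~30% diamond terms and a designated
reproduction-process term, 2 genotypes, 10⁶ reads per library — sizes
at which every code path is exercised and the whole suite runs in
seconds. Sequence content is uniform-random nucleotide: the generator
makes no attempt at codon structure, homology or realistic expression
distributions, so passing tests demonstrate correctness of storage,
propagation, arithmetic and query logic — not biological plausibility,
and not performance at the scale of a real 454/Illumina project.

Ground truth in the bundle manifest is computed inside the generator by
independent brute force (boolean-matrix closure, direct set scans),
never by calling the modules under test; test and acceptance
comparisons are therefore dual-route.

## Numerical and degenerate-input choices

- Empty ontology (header-only OBO) and empty files load to empty
  structures without error; empty search results are valid.
- `Feature.seqlen` is derived from residues and an inconsistent
  explicit value is rejected at construction.
- Locations past the end of a reference with known length are rejected;
  `start ≤ end` is a schema-level constraint.
- Backup dumps are deterministic (schema-ordered tables, primary-key
  ordered rows, version header, end marker); restore validates the
  whole dump before touching the target path.
- Deletes cascade to dependent rows (locations, relationships,
  annotations, hits, expression values, markers and their alleles) and
  report the total rows removed.

## Limitations

- One writer at a time (SQLite); no user accounts or multi-database
  switching.
- OBO only; OWL/XML ontologies are out of scope.
- No differential-expression statistics: the store keeps and summarizes
  expression values, it does not test them.
- BLAST execution against stored sequences is not built in; export the
  FASTA and run an external BLAST if needed.
- The genotype/phenotype side is minimal: genotypes, ontology-described
  attributes and marker alleles, nothing more.
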