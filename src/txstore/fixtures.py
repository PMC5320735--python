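"""Deterministic synthetic project generation.

Real de novo transcriptome projects arrive as a bundle of third-party
results: an assembly FASTA of isotigs (transcript contigs), the isogroup
(gene locus) list, GFF3 structural annotation, BLAST XML, functional
annotation tables, marker VCFs and expression counts. This module
fabricates a structurally faithful toy bundle — Newbler-style
isotig/isogroup relationships, planted SSR motifs, replicate-structured
experiments mirroring a three-condition (male larvae / male adults /
female adults) insect study — so that every loader and query can be
exercised with no external data.

Sequence content is uniform-random nucleotide; biological realism is a
non-goal, structural realism is. Alongside the files, a ground-truth
manifest records the exact expected answer to the queries the tests
replay. The manifest is computed here by independent brute force (set
scans and a boolean-matrix transitive closure), never by calling the
modules under test.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

TOY_PREFIX = "TGO"
FOCUS_NAME = "developmental process involved in reproduction"

#: tiny anatomy/attribute vocabulary for experiment condition terms
CONDITION_OBO = """format-version: 1.2
ontology: toy_anatomy

[Term]
id: TAN:0000001
name: organism attribute

[Term]
id: TAN:0000002
name: larva
is_a: TAN:0000001

[Term]
id: TAN:0000003
name: adult
is_a: TAN:0000001

[Term]
id: TAN:0000004
name: male
is_a: TAN:0000001

[Term]
id: TAN:0000005
name: female
is_a: TAN:0000001
"""

CONDITION_TERMS = {
    "larva": "TAN:0000002",
    "adult": "TAN:0000003",
    "male": "TAN:0000004",
    "female": "TAN:0000005",
}

_MOTIFS = ["AG", "AC", "AT", "AAG", "ATC"]
_DESCRIPTIONS = [
    "serine/threonine protein kinase",
    "receptor tyrosine kinase",
    "hypothetical protein",
    "doublesex-related transcription factor",
    "vitellogenin precursor",
    "heat shock protein 70",
]

BUNDLE_FILES = {
    "ontology": "toy_go.obo",
    "conditions": "conditions.obo",
    "fasta": "transcripts.fasta",
    "isogroups": "isogroups.txt",
    "gff3": "structure.gff3",
    "relationships": "relationships.tsv",
    "blast": "blast.xml",
    "annot": "annotations.annot",
    "interpro": "interpro.tsv",
    "dbxref": "dbxref2go.tsv",
    "ssr_vcf": "ssrs.vcf",
    "snp_vcf": "snps.vcf",
    "expression": "expression.tsv",
    "genotypes": "genotypes.tsv",
    "manifest": "manifest.json",
}


@dataclass
class FixtureSpec:
    """Knobs of the synthetic project. Defaults mirror the toy-scale
    three-condition study the tutorial replays: one RNA-seq library per
    condition, Newbler-style isotig/isogroup structure, a handful of
    SSR and SNP markers."""

    seed: int = 1
    n_isogroups: int = 10
    isoforms_per_group: tuple[int, int] = (1, 3)
    transcript_length_bp: tuple[int, int] = (300, 1200)
    n_ssr: int = 8
    n_snp: int = 10
    n_ontology_terms: int = 30
    n_genotypes: int = 2
    experiments: tuple = (
        ("male_larvae", ("larva", "male"), 1, 1_000_000),
        ("male_adult", ("adult", "male"), 1, 1_000_000),
        ("female_adult", ("adult", "female"), 1, 1_000_000),
    )


def _term_id(i: int) -> str:
    return f"{TOY_PREFIX}:{i:07d}"


def _ontology_structure(spec: FixtureSpec):
    """Draw the random DAG skeleton: (parents, focus index, obsolete
    index). Single root; ~30% of eligible terms get two parents
    (diamonds); the focus term is guaranteed a descendant; one term is
    obsolete when room allows."""
    n = spec.n_ontology_terms
    if n < 1:
        raise ValueError("n_ontology_terms must be >= 1")
    rng = random.Random(spec.seed)
    parents: dict[int, list[int]] = {0: []}
    focus = min(max(1, n // 5), n - 1) if n > 1 else 0
    obsolete_idx = n - 2 if n >= 8 else None
    for i in range(1, n):
        if i == obsolete_idx:
            parents[i] = []
            continue
        k = 2 if (i >= 3 and rng.random() < 0.3) else 1
        ps = rng.sample(range(i), min(k, i))
        if i == focus + 1 and focus not in ps and focus < i:
            ps[0] = focus
        parents[i] = sorted(set(ps))
    return parents, focus, obsolete_idx


def make_toy_ontology(spec: FixtureSpec) -> str:
    """A rooted random DAG in OBO text with a designated term playing
    the reproduction-process role for tutorial replays. Same spec +
    seed => identical bytes."""
    n = spec.n_ontology_terms
    parents, focus, obsolete_idx = _ontology_structure(spec)
    lines = ["format-version: 1.2", "ontology: toy_go", ""]
    for i in range(n):
        lines.append("[Term]")
        lines.append(f"id: {_term_id(i)}")
        if i == 0:
            lines.append("name: toy biological process")
        elif i == focus:
            lines.append(f"name: {FOCUS_NAME}")
        else:
            lines.append(f"name: toy process {i:03d}")
        lines.append("namespace: biological_process")
        if i == obsolete_idx:
            lines.append("is_obsolete: true")
        for p in parents[i]:
            lines.append(f"is_a: {_term_id(p)}")
        lines.append("")
    return "\n".join(lines)


def brute_force_closure(parents: dict[int, list[int]]) -> np.ndarray:
    """Boolean-matrix transitive closure: C[i, j] iff j is an ancestor
    of i. Independent oracle for the graph traversal code."""
    n = len(parents)
    adj = np.zeros((n, n), dtype=bool)
    for child, ps in parents.items():
        for p in ps:
            adj[child, p] = True
    closure = adj.copy()
    while True:
        nxt = closure | (closure @ adj)
        if (nxt == closure).all():
            return closure
        closure = nxt


def make_toy_project(spec: FixtureSpec, outdir) -> dict:
    """Write the full mutually consistent file bundle plus the
    ground-truth manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed + 10_007)

    parents, focus_idx, obsolete_idx = _ontology_structure(spec)
    n_terms = spec.n_ontology_terms
    focus_term = _term_id(focus_idx)
    closure = brute_force_closure(parents)
    usable_terms = [
        i for i in range(1, n_terms) if i != obsolete_idx
    ] or [0]

    # -- transcripts and gene loci ------------------------------------
    lo, hi = spec.isoforms_per_group
    transcripts: dict[str, dict] = {}
    isogroups: list[str] = []
    idx = 0
    for g in range(1, spec.n_isogroups + 1):
        group = f"isogroup{g:03d}"
        isogroups.append(group)
        for _ in range(rng.randint(lo, hi)):
            idx += 1
            name = f"isotig{idx:05d}"
            length = rng.randint(*spec.transcript_length_bp)
            seq = "".join(rng.choice("ACGT") for _ in range(length))
            transcripts[name] = {"isogroup": group, "length": length,
                                 "seq": seq}
    names = list(transcripts)

    # -- planted SSRs --------------------------------------------------
    if spec.n_ssr > len(names):
        raise ValueError(
            f"infeasible spec: {spec.n_ssr} SSRs for {len(names)} transcripts")
    ssr_features = sorted(rng.sample(names, spec.n_ssr))
    ssr_records = []
    for i, name in enumerate(ssr_features, start=1):
        t = transcripts[name]
        motif = rng.choice(_MOTIFS)
        reps = rng.randint(6, 10)
        tract = motif * reps
        if t["length"] < len(tract) + len(motif) + 40:
            raise ValueError("infeasible spec: transcript too short for SSR")
        pos = rng.randrange(10, t["length"] - len(tract) - len(motif) - 10)
        t["seq"] = t["seq"][:pos] + tract + t["seq"][pos + len(tract):]
        ssr_records.append({
            "id": f"ssr{i:03d}", "chrom": name, "pos": pos + 1,
            "ref": tract, "alt": motif * (reps + 1), "motif": motif})

    # -- SNPs ----------------------------------------------------------
    snp_records = []
    snp_features = set()
    for i in range(1, spec.n_snp + 1):
        name = rng.choice(names)
        t = transcripts[name]
        pos0 = rng.randrange(0, t["length"])
        ref = t["seq"][pos0]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snp_records.append({
            "id": f"snp{i:03d}", "chrom": name, "pos": pos0 + 1,
            "ref": ref, "alt": alt})
        snp_features.add(name)

    genotypes = [f"g{i}" for i in range(1, spec.n_genotypes + 1)]
    gt_choices = ["0/0", "0/1", "1/1", "./."]
    for rec in ssr_records + snp_records:
        rec["gts"] = [rng.choice(gt_choices) for _ in genotypes]

    # -- functional annotation ----------------------------------------
    annot_pairs: dict[str, set[int]] = {n: set() for n in names}
    for name in names:
        for t in rng.sample(usable_terms, rng.randint(1, 3)):
            annot_pairs[name].add(t)
    # plant: an SSR transcript annotated under the focus term, and one
    # transcript on a multi-parent term so slice sums can exceed totals
    if ssr_features:
        annot_pairs[ssr_features[0]].add(focus_idx)
    multi_parent = [i for i in usable_terms if len(parents[i]) > 1]
    if multi_parent:
        annot_pairs[names[0]].add(multi_parent[0])
    if obsolete_idx is not None:
        annot_pairs[names[-1]].add(obsolete_idx)  # exercised warning path

    # -- InterProScan + dbxref map ------------------------------------
    dbxref_rows = [("IPR000001", _term_id(usable_terms[0])),
                   ("IPR000002", _term_id(usable_terms[-1]))]
    ipr_targets = names[: min(3, len(names))]
    ipr_rows = []
    for j, name in enumerate(ipr_targets):
        ipr = ["IPR000001", "IPR000002", "IPR999999"][j % 3]
        length = transcripts[name]["length"]
        start = 10
        end = min(90, length)
        ipr_rows.append((name, f"PF{j + 1:05d}", start, end, ipr))
    mapped = {x: t for x, t in dbxref_rows}
    interpro_pairs: dict[str, set[int]] = {}
    for name, _sig, _s, _e, ipr in ipr_rows:
        if ipr in mapped:
            tid = int(mapped[ipr].split(":")[1])
            interpro_pairs.setdefault(name, set()).add(tid)

    # -- expression counts --------------------------------------------
    libraries = []
    for exp_name, labels, n_rep, total_reads in spec.experiments:
        for r in range(1, n_rep + 1):
            libraries.append({"experiment": exp_name, "labels": list(labels),
                              "name": f"lib_{exp_name}_{r}",
                              "replicate_index": r,
                              "total_reads": total_reads})
    biased_group = isogroups[0]
    counts: dict[str, dict[str, float]] = {}
    for name in names:
        counts[name] = {}
        for lib in libraries:
            c = float(rng.randint(0, 500))
            if (transcripts[name]["isogroup"] == biased_group
                    and "larva" in lib["labels"]):
                c = c * 10 + 2000  # larval-biased locus
            counts[name][lib["name"]] = c

    # -- ground truth by brute force ----------------------------------
    def membership_terms(direct: set[int]) -> set[int]:
        out: set[int] = set()
        for t in direct:
            if t == obsolete_idx:
                continue
            out.add(t)
            out |= {j for j in range(n_terms) if closure[t, j]}
        return out

    all_pairs = {
        n: set(annot_pairs[n]) | interpro_pairs.get(n, set()) for n in names}
    under_focus = sorted(
        n for n in names if focus_idx in membership_terms(all_pairs[n]))
    replay_answer = sorted(set(ssr_features) & set(under_focus))
    root_children = sorted(i for i in range(n_terms) if 0 in parents[i])
    root_child_counts = {
        _term_id(c): sum(
            1 for n in names if c in membership_terms(all_pairs[n]))
        for c in root_children}
    root_total = sum(1 for n in names if 0 in membership_terms(all_pairs[n]))

    manifest = {
        "spec": asdict(spec),
        "files": dict(BUNDLE_FILES),
        "focus_term": focus_term,
        "focus_name": FOCUS_NAME,
        "root_term": _term_id(0),
        "obsolete_term": _term_id(obsolete_idx) if obsolete_idx is not None else None,
        "transcripts": {n: {"isogroup": transcripts[n]["isogroup"],
                            "length": transcripts[n]["length"]}
                        for n in names},
        "isogroups": isogroups,
        "genotypes": genotypes,
        "ssr_features": ssr_features,
        "snp_features": sorted(snp_features),
        "annotation_pairs": {
            n: sorted(_term_id(t) for t in all_pairs[n]) for n in names},
        "under_focus": under_focus,
        "replay_answer": replay_answer,
        "root_child_counts": root_child_counts,
        "root_total": root_total,
        "libraries": [{k: v for k, v in lib.items()} for lib in libraries],
        "counts": counts,
        "biased_isogroup": biased_group,
    }

    _write_bundle(spec, outdir, transcripts, isogroups, ssr_records,
                  snp_records, genotypes, annot_pairs, ipr_rows, dbxref_rows,
                  libraries, counts, manifest)
    return manifest


# ---------------------------------------------------------------------
# file emission


def _write_bundle(spec, outdir, transcripts, isogroups, ssr_records,
                  snp_records, genotypes, annot_pairs, ipr_rows, dbxref_rows,
                  libraries, counts, manifest) -> None:
    f = {k: outdir / v for k, v in BUNDLE_FILES.items()}

    f["ontology"].write_text(make_toy_ontology(spec))
    f["conditions"].write_text(CONDITION_OBO)

    with f["fasta"].open("w") as out:
        for name, t in transcripts.items():
            out.write(f">{name} len={t['length']} group={t['isogroup']}\n")
            for i in range(0, t["length"], 60):
                out.write(t["seq"][i:i + 60] + "\n")

    f["isogroups"].write_text("".join(g + "\n" for g in isogroups))

    with f["gff3"].open("w") as out:
        out.write("##gff-version 3\n")
        rng = random.Random(spec.seed + 77)
        for name, t in transcripts.items():
            L = t["length"]
            mrna = f"{name}.m"
            out.write(f"{name}\ttoy\tmRNA\t1\t{L}\t.\t+\t.\tID={mrna}\n")
            n_exons = rng.choice([1, 2])
            if n_exons == 1:
                exons = [(1, L)]
            else:
                cut = rng.randint(L // 3, 2 * L // 3)
                exons = [(1, cut), (cut + 1, L)]
            for k, (s, e) in enumerate(exons, start=1):
                out.write(f"{name}\ttoy\texon\t{s}\t{e}\t.\t+\t.\t"
                          f"ID={name}.e{k};Parent={mrna}\n")
            cs, ce = max(1, L // 10), max(2, (9 * L) // 10)
            out.write(f"{name}\ttoy\tCDS\t{cs}\t{ce}\t.\t+\t0\t"
                      f"ID={name}.c;Parent={mrna}\n")

    with f["relationships"].open("w") as out:
        out.write("feature\tpredicate\ttarget\n")
        for name, t in transcripts.items():
            out.write(f"{name}\tpart_of\t{t['isogroup']}\n")

    f["blast"].write_text(_blast_xml(spec, transcripts))

    with f["annot"].open("w") as out:
        for name in annot_pairs:
            for t in sorted(annot_pairs[name]):
                out.write(f"{name}\t{_term_id(t)}\n")
        # one enzyme-code row: annotations need not be GO-shaped
        first = next(iter(annot_pairs))
        out.write(f"{first}\tEC:2.7.11.1\n")

    with f["interpro"].open("w") as out:
        for name, sig, start, end, ipr in ipr_rows:
            cols = [name, "md5", str(transcripts[name]["length"]), "Pfam",
                    sig, f"{sig} domain", str(start), str(end), "1e-10", "T",
                    "2017-01-01", ipr, f"{ipr} entry", "-"]
            out.write("\t".join(cols) + "\n")

    with f["dbxref"].open("w") as out:
        out.write("! external id -> ontology term\n")
        for xid, term in dbxref_rows:
            out.write(f"{xid}\t{term}\n")

    for key, records in (("ssr_vcf", ssr_records), ("snp_vcf", snp_records)):
        with f[key].open("w") as out:
            out.write("##fileformat=VCFv4.2\n")
            if key == "ssr_vcf":
                out.write('##INFO=<ID=MOTIF,Number=1,Type=String,'
                          'Description="SSR motif">\n')
            out.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                      'Description="Genotype">\n')
            chroms = sorted({r["chrom"] for r in records})
            for c in chroms:
                out.write(f"##contig=<ID={c},length={transcripts[c]['length']}>\n")
            out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                      + "\t".join(genotypes) + "\n")
            for r in sorted(records, key=lambda r: (r["chrom"], r["pos"])):
                info = f"MOTIF={r['motif']}" if "motif" in r else "."
                row = [r["chrom"], str(r["pos"]), r["id"], r["ref"], r["alt"],
                       ".", ".", info, "GT"] + r["gts"]
                out.write("\t".join(row) + "\n")

    with f["expression"].open("w") as out:
        out.write("feature\tlibrary\tvalue\n")
        for name in counts:
            for lib_name, c in counts[name].items():
                out.write(f"{name}\t{lib_name}\t{c:g}\n")

    with f["genotypes"].open("w") as out:
        out.write("name\tterm\tvalue\n")
        sexes = [CONDITION_TERMS["male"], CONDITION_TERMS["female"]]
        for i, g in enumerate(genotypes):
            out.write(f"{g}\t{sexes[i % 2]}\t\n")

    f["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _blast_xml(spec: FixtureSpec, transcripts: dict) -> str:
    rng = random.Random(spec.seed + 31)
    names = list(transcripts)
    chosen = sorted(rng.sample(names, max(2, len(names) // 2)))
    iterations = []
    for qnum, name in enumerate(chosen, start=1):
        if qnum <= 2:
            desc = _DESCRIPTIONS[qnum - 1]  # two kinase-described queries
        else:
            desc = rng.choice(_DESCRIPTIONS)
        L = transcripts[name]["length"]
        qfrom, qto = 10, max(11, min(L, 10 + rng.randint(60, 300)))
        align_len = qto - qfrom + 1
        ident = int(align_len * rng.uniform(0.5, 0.99))
        acc = f"ACC{qnum:05d}"
        iterations.append(f"""  <Iteration>
   <Iteration_iter-num>{qnum}</Iteration_iter-num>
   <Iteration_query-ID>Query_{qnum}</Iteration_query-ID>
   <Iteration_query-def>{name} len={L}</Iteration_query-def>
   <Iteration_query-len>{L}</Iteration_query-len>
   <Iteration_hits>
    <Hit>
     <Hit_num>1</Hit_num>
     <Hit_id>gnl|toy|{acc}</Hit_id>
     <Hit_def>{desc}</Hit_def>
     <Hit_accession>{acc}</Hit_accession>
     <Hit_len>{align_len}</Hit_len>
     <Hit_hsps>
      <Hsp>
       <Hsp_num>1</Hsp_num>
       <Hsp_bit-score>{50 + qnum}</Hsp_bit-score>
       <Hsp_score>{120 + qnum}</Hsp_score>
       <Hsp_evalue>1e-{10 + qnum}</Hsp_evalue>
       <Hsp_query-from>{qfrom}</Hsp_query-from>
       <Hsp_query-to>{qto}</Hsp_query-to>
       <Hsp_hit-from>1</Hsp_hit-from>
       <Hsp_hit-to>{align_len}</Hsp_hit-to>
       <Hsp_query-frame>1</Hsp_query-frame>
       <Hsp_hit-frame>0</Hsp_hit-frame>
       <Hsp_identity>{ident}</Hsp_identity>
       <Hsp_positive>{ident}</Hsp_positive>
       <Hsp_gaps>0</Hsp_gaps>
       <Hsp_align-len>{align_len}</Hsp_align-len>
       <Hsp_qseq>{'A' * 10}</Hsp_qseq>
       <Hsp_hseq>{'A' * 10}</Hsp_hseq>
       <Hsp_midline>{'|' * 10}</Hsp_midline>
      </Hsp>
     </Hit_hsps>
    </Hit>
   </Iteration_hits>
  </Iteration>""")
    body = "\n".join(iterations)
    return f"""<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "NCBI_BlastOutput.dtd">
<BlastOutput>
 <BlastOutput_program>blastx</BlastOutput_program>
 <BlastOutput_version>BLASTX 2.2.31+</BlastOutput_version>
 <BlastOutput_reference>toy</BlastOutput_reference>
 <BlastOutput_db>toy_proteins</BlastOutput_db>
 <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
 <BlastOutput_query-def>{chosen[0]}</BlastOutput_query-def>
 <BlastOutput_query-len>100</BlastOutput_query-len>
 <BlastOutput_param>
  <Parameters>
   <Parameters_expect>10</Parameters_expect>
   <Parameters_gap-open>11</Parameters_gap-open>
   <Parameters_gap-extend>1</Parameters_gap-extend>
   <Parameters_filter>F</Parameters_filter>
  </Parameters>
 </BlastOutput_param>
 <BlastOutput_iterations>
{body}
 </BlastOutput_iterations>
</BlastOutput>
"""


# ---------------------------------------------------------------------
# tutorial replay: load the bundle through the public loaders


def load_bundle(store, bundle_dir, compute_rpkm: bool = True) -> dict:
    """Replay the full loading tutorial on a generated bundle, in the
    same order a user would: ontologies, organism, transcripts, gene
    loci, structure, relationships, functional annotation, BLAST,
    genotypes, markers, experiment design, expression. Returns the
    parsed ontology graphs and every loader's report."""
    from . import expression as expr
    from . import formats
    from .model import Analysis, Organism
    from .ontology import DbxrefMapping, parse_obo

    bundle_dir = Path(bundle_dir)
    f = {k: bundle_dir / v for k, v in BUNDLE_FILES.items()}
    manifest = json.loads(f["manifest"].read_text())

    obo_text = f["ontology"].read_text()
    graph = parse_obo(obo_text)
    store.register_ontology(graph, obo_text=obo_text)
    cond_graph = parse_obo(CONDITION_OBO)
    store.register_ontology(cond_graph, obo_text=CONDITION_OBO)

    store.add_organism(Organism(genus="Synthetica", species="exemplaris",
                                common_name="toy wasp"))

    reports = {}
    reports["fasta"] = formats.load_fasta(store, f["fasta"])
    reports["isogroups"] = formats.load_feature_list(store, f["isogroups"])
    reports["gff3"] = formats.load_gff3(store, f["gff3"])
    reports["relationships"] = formats.load_association_table(
        store, f["relationships"], kind="feature_feature")
    reports["annot"] = formats.load_annot(store, f["annot"])
    mapping = DbxrefMapping.from_stream(f["dbxref"])
    reports["interpro"] = formats.load_interproscan(store, f["interpro"],
                                                    dbxref_mapping=mapping)
    reports["blast"] = formats.load_blast_xml(
        store, f["blast"], analysis=Analysis(program="blastx",
                                             version="2.2.31+"))
    reports["genotypes"] = formats.load_association_table(
        store, f["genotypes"], kind="genotype")
    reports["ssr"] = formats.load_vcf_markers(store, f["ssr_vcf"], "SSR")
    reports["snp"] = formats.load_vcf_markers(store, f["snp_vcf"], "SNP")

    made = set()
    for lib in manifest["libraries"]:
        if lib["experiment"] not in made:
            made.add(lib["experiment"])
            exists = store.conn.execute(
                "SELECT 1 FROM experiment WHERE name=?",
                (lib["experiment"],)).fetchone()
            if not exists:
                terms = [(CONDITION_TERMS[lab], None) for lab in lib["labels"]]
                expr.create_experiment(store, lib["experiment"], terms)
        if not store.conn.execute("SELECT 1 FROM seq_library WHERE name=?",
                                  (lib["name"],)).fetchone():
            expr.add_library(store, lib["experiment"], lib["name"],
                             lib["replicate_index"], lib["total_reads"])
    reports["expression"] = formats.load_association_table(
        store, f["expression"], kind="feature_library")
    if compute_rpkm:
        for lib in manifest["libraries"]:
            expr.rpkm_for_library(store, lib["name"])

    return {"graph": graph, "condition_graph": cond_graph,
            "manifest": manifest, "reports": reports}


def replay_case_study(store, graph, focus_term: str) -> list[str]:
    """The tutorial's combined query, through the query layer: all
    transcripts, filtered to those carrying at least one SSR, filtered
    to those annotated (directly or by inheritance) under the focus
    term. Returns the sorted transcript names."""
    from . import formats, queries

    everything = queries.search_by_name(store, "%", mode="like",
                                        so_type=formats.SO_TRANSCRIPT)
    with_ssr = queries.filter_by_marker(everything, store, "SSR", min_count=1)
    under = set(queries.search_by_term(
        store, graph, focus_term, include_inherited=True,
        so_type=formats.SO_TRANSCRIPT).feature_names())
    return sorted(set(with_ssr.feature_names()) & under)
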