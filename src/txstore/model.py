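"""Shared domain records.

Plain dataclasses passed between the store, the loaders and the query
layer. Coordinates on these records are interbase (0-based, half-open),
the Chado convention; 1-based inclusive coordinates exist only at the
I/O and report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class Organism:
    genus: str
    species: str
    common_name: Optional[str] = None
    abbreviation: Optional[str] = None


@dataclass
class Feature:
    """Any sequence-associated record: transcript (isotig), gene locus
    (isogroup), exon, CDS, marker, protein-domain match.

    ``so_type`` is a Sequence Ontology CURIE. ``residues`` may be absent
    (gene loci from a de novo assembly have no sequence of their own);
    when present, ``seqlen`` is derived from it.
    """

    unique_name: str
    so_type: str
    display_name: Optional[str] = None
    residues: Optional[str] = None
    seqlen: Optional[int] = None
    analysis_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.residues is not None:
            n = len(self.residues)
            if self.seqlen is not None and self.seqlen != n:
                raise ValueError(
                    f"seqlen {self.seqlen} != len(residues) {n} for "
                    f"{self.unique_name!r}"
                )
            self.seqlen = n


@dataclass
class FeatureRelationship:
    subject: str            # unique_name of the subject feature
    predicate: str          # e.g. part_of, derives_from
    object: str             # unique_name of the object feature
    rank: int = 0


@dataclass
class FeatureLocation:
    feature: str            # located feature unique_name
    source_feature: str     # reference feature unique_name
    start: int              # interbase
    end: int
    strand: int = 0         # +1 / -1 / 0
    phase: Optional[int] = None


@dataclass
class Analysis:
    program: str
    version: str = ""
    parameters: str = ""
    timestamp: str = ""


@dataclass
class BlastHit:
    query: str
    hit_accession: str
    description: str
    e_value: float
    bit_score: float
    identity_pct: float
    query_start: int        # interbase
    query_end: int
    db_name: str = ""
    analysis_id: Optional[int] = None


@dataclass
class TermAnnotation:
    feature: str
    term_id: str
    source: str = "manual"  # blast2go | interproscan | manual | dbxref-mapped
    analysis_id: Optional[int] = None


@dataclass
class LoadReport:
    """Outcome of one bulk load: read = loaded + skipped always holds."""

    records_read: int = 0
    records_loaded: int = 0
    records_skipped: int = 0
    warnings: list[tuple[int, str]] = field(default_factory=list)

    def warn(self, line: int, message: str) -> None:
        self.warnings.append((line, message))

    def check(self) -> None:
        if self.records_read != self.records_loaded + self.records_skipped:
            raise AssertionError("LoadReport invariant violated")


@dataclass
class ExpressionSummary:
    feature: str
    experiment: str
    measure: str
    mean: float
    sd: float
    n: int
    genotype: Optional[str] = None


@dataclass
class QueryRow:
    unique_name: str
    so_type: str
    display_name: Optional[str] = None
    flag: Optional[str] = None          # direct | indirect
    marker_counts: dict[str, int] = field(default_factory=dict)
    attributes: dict[str, object] = field(default_factory=dict)


@dataclass
class QueryResult:
    rows: list[QueryRow]
    provenance: str = ""

    def feature_names(self) -> list[str]:
        return [r.unique_name for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)
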