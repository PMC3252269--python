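"""Shared domain records used across the sieve.

These are the three datatypes that flow between pipeline stages: a protein
sequence tagged with its taxonomic group, a pairwise homology hit, and the
per-gene annotation bundle (GC, introns, ESTs, placement) consumed by the
contamination triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

#: Closed set of taxonomic group labels.  ``recipient_insect`` marks the
#: lineage being screened for foreign genes (the focal insect clade); the
#: remaining eukaryote labels map onto the six-set distribution spectrum;
#: the two prokaryote labels mark potential donors.
GROUPS = frozenset(
    {
        "recipient_insect",
        "other_insect",
        "non_insect_arthropod",
        "non_arthropod_metazoan",
        "plant",
        "fungus",
        "protist",
        "eubacterium",
        "archaebacterium",
    }
)

PROKARYOTE_GROUPS = frozenset({"eubacterium", "archaebacterium"})

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein with species and taxonomic-group labels."""

    id: str
    species: str
    group: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.group not in GROUPS:
            raise ValueError(f"unknown taxonomic group {self.group!r} for {self.id}")
        if len(self.residues) < 1:
            raise ValueError(f"empty residues for {self.id}")

    @property
    def is_prokaryote(self) -> bool:
        return self.group in PROKARYOTE_GROUPS

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HomologyHit:
    """One query-vs-subject similarity result (the sieve's currency).

    ``identity_pct`` and ``overlap_pct`` are percentages in [0, 100];
    ``evalue`` is the expected number of chance hits at this score.
    """

    query_id: str
    subject_id: str
    raw_score: float = 0.0
    bit_score: float = 0.0
    evalue: float = 0.0
    identity_pct: float = 0.0
    overlap_pct: float = 0.0
    aligned_length: int = 1
    query_cov_span: Tuple[int, int] = (0, 0)
    subject_cov_span: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if not (0.0 <= self.overlap_pct <= 100.0):
            raise ValueError(f"overlap_pct out of range: {self.overlap_pct}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")


@dataclass
class AnnotationRecord:
    """Per-gene annotation: composition, evidence and genomic placement.

    Coordinates are 1-based inclusive.  ``gc`` is a fraction in [0, 1].
    """

    gene_id: str
    gc: float
    intron_count: int = 0
    est_count: int = 0
    cloned: bool = False
    probe_id: Optional[str] = None
    chromosome: Optional[str] = None
    scaffold: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    protein_length: int = 1
    # extra columns carried by the packaged candidate table
    type_group: Optional[str] = None
    annotation: Optional[str] = None
    microarray: bool = False
    top_hit_species: Optional[str] = None
    top_hit_score: Optional[float] = None
    top_hit_evalue: Optional[float] = None
    top_hit_identity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc out of [0,1] for {self.gene_id}: {self.gc}")
        if self.intron_count < 0 or self.est_count < 0:
            raise ValueError(f"negative count for {self.gene_id}")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise ValueError(f"end < start for {self.gene_id}")
        if self.protein_length < 1:
            raise ValueError(f"protein_length must be positive for {self.gene_id}")
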