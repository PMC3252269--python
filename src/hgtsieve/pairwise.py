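"""Local protein alignment and the first/third-tier similarity filters.

The screen needs three quantities per query/subject pair: an E-value, an
overlap value (aligned span as a percentage of the query length, optionally
subject-anchored) and an identity value (identical pairs over alignment
columns, gap columns included — the BLAST convention).  Alignments are exact
Smith–Waterman with affine gaps (no heuristic seeding), scored with a
substitution matrix (default BLOSUM62); E-values follow the ungapped
Karlin–Altschul form ``E = K m n exp(-lambda S)`` with published BLOSUM62
parameters.  At desk scale the filters depend only on the thresholds, not on
absolute E-value calibration, and hit tables produced by external BLAST runs
are accepted interchangeably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .records import HomologyHit, SequenceRecord

#: Ungapped Karlin-Altschul parameters for common scoring systems.
KARLIN_ALTSCHUL = {
    "BLOSUM62": (0.3176, 0.134),
    "BLOSUM50": (0.2318, 0.112),
}


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap penalties (as positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def aligner(self) -> Align.PairwiseAligner:
        aln = Align.PairwiseAligner()
        aln.mode = "local"
        aln.substitution_matrix = substitution_matrices.load(self.matrix)
        aln.open_gap_score = -(self.gap_open)
        aln.extend_gap_score = -(self.gap_extend)
        return aln

    def karlin_altschul(self) -> Tuple[float, float]:
        try:
            return KARLIN_ALTSCHUL[self.matrix]
        except KeyError:
            raise ValueError(f"no Karlin-Altschul parameters for {self.matrix!r}")


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class ThresholdConfig:
    """One tier of the similarity sieve.

    The first tier (``blast1``) is the insect-vs-prokaryote screen
    (E <= 1e-40, overlap >= 25%, identity >= 25%); the third tier
    (``blast3``) is the broad confirmation screen (E <= 1e-3, same
    overlap/identity floors) where a sub-threshold identity is rescued when
    query and subject share an annotated protein domain.
    """

    stage: str
    max_evalue: float
    min_overlap_pct: float = 25.0
    min_identity_pct: float = 25.0
    domain_rescue: bool = False

    def __post_init__(self) -> None:
        if self.stage not in ("blast1", "blast3"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        for pct in (self.min_overlap_pct, self.min_identity_pct):
            if not (0.0 <= pct <= 100.0):
                raise ValueError("percent thresholds must lie in [0, 100]")

    @classmethod
    def blast1(cls) -> "ThresholdConfig":
        return cls(stage="blast1", max_evalue=1e-40)

    @classmethod
    def blast3(cls) -> "ThresholdConfig":
        return cls(stage="blast3", max_evalue=1e-3, domain_rescue=True)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    overlap_anchor: str = "query",
    gap_columns_in_identity: bool = True,
) -> Optional[HomologyHit]:
    """Best local alignment of two proteins, or None when no positive score.

    Identity counts identical residue pairs over alignment columns; gap
    columns are included in the denominator by default (the BLAST
    convention) and excluded with ``gap_columns_in_identity=False``.
    Overlap is the aligned span divided by the query (or subject) length,
    as a percentage.  E-value/bit-score fields are left at zero; use
    :func:`estimate_evalue` or :func:`search` to fill them against a
    database size.
    """
    if len(query.residues) == 0 or len(subject.residues) == 0:
        raise ValueError("zero-length sequence")
    if overlap_anchor not in ("query", "subject"):
        raise ValueError("overlap_anchor must be 'query' or 'subject'")
    aligner = scoring.aligner()
    score = aligner.score(query.residues, subject.residues)
    if score <= 0:
        return None
    best = aligner.align(query.residues, subject.residues)[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches
    if gap_columns_in_identity:
        columns += counts.gaps
    qspan = (int(best.aligned[0][0][0]) + 1, int(best.aligned[0][-1][1]))
    sspan = (int(best.aligned[1][0][0]) + 1, int(best.aligned[1][-1][1]))
    anchor_len = len(query.residues) if overlap_anchor == "query" else len(subject.residues)
    span = (qspan[1] - qspan[0] + 1) if overlap_anchor == "query" else (sspan[1] - sspan[0] + 1)
    return HomologyHit(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=float(score),
        identity_pct=100.0 * counts.identities / columns,
        overlap_pct=min(100.0, 100.0 * span / anchor_len),
        aligned_length=int(columns),
        query_cov_span=qspan,
        subject_cov_span=sspan,
    )


def estimate_evalue(
    raw_score: float,
    query_len: int,
    db_residues: int,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> Tuple[float, float]:
    """Karlin-Altschul E-value and bit score for a raw alignment score.

    ``E = K m n exp(-lambda S)``; ``bit = (lambda S - ln K) / ln 2``.  The
    E-value is strictly decreasing in the score and linear in the database
    size.
    """
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("lengths must be positive")
    lam, k = scoring.karlin_altschul()
    bit = (lam * raw_score - math.log(k)) / math.log(2.0)
    evalue = float(query_len) * float(db_residues) * math.pow(2.0, -bit)
    return evalue, bit


def search(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    overlap_anchor: str = "query",
    db_residues: Optional[int] = None,
) -> List[HomologyHit]:
    """All-vs-all local alignment of queries against a subject set.

    E-values are calibrated against ``db_residues`` (default: total residues
    in ``subjects``).  Hits with non-positive score are omitted.
    """
    n = db_residues if db_residues is not None else sum(len(s) for s in subjects)
    hits: List[HomologyHit] = []
    for q in queries:
        for s in subjects:
            if q.id == s.id:
                continue
            hit = local_align(q, s, scoring, overlap_anchor)
            if hit is None:
                continue
            hit.evalue, hit.bit_score = estimate_evalue(hit.raw_score, len(q), n, scoring)
            hits.append(hit)
    return hits


def apply_hit_filter(
    hits: Iterable[HomologyHit],
    thresholds: ThresholdConfig,
    domain_annotations: Optional[Mapping[str, Set[str]]] = None,
) -> List[HomologyHit]:
    """Keep hits passing the tier's E-value/overlap/identity thresholds.

    A hit survives iff its E-value and overlap pass, and its identity passes
    or (third tier only, with rescue enabled) query and subject share at
    least one annotated domain.  Order is preserved; the result is a subset
    of the input, so the filter is idempotent.
    """
    domains = domain_annotations or {}
    out: List[HomologyHit] = []
    for h in hits:
        if h.evalue > thresholds.max_evalue:
            continue
        if h.overlap_pct < thresholds.min_overlap_pct:
            continue
        if h.identity_pct < thresholds.min_identity_pct:
            shared = domains.get(h.query_id, set()) & domains.get(h.subject_id, set())
            if not (thresholds.stage == "blast3" and thresholds.domain_rescue and shared):
                continue
        out.append(h)
    return out
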