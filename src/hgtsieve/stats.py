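"""Contamination triage, transfer-event typing, and resampling statistics.

This module carries the study's quantitative backbone: the evidence-based
rule separating genuine host genes from assembly contaminants; the grouping
of candidate genes into transfer-event types (tandem copies on one scaffold,
or reciprocal-best high-identity pairs, closed transitively); a Monte-Carlo
test for whether transferred genes are more similar to their bacterial
homologs than the genome-wide background; an exact + simulated test for the
candidates being uniformly intron-free; a GC amelioration summary; and
composition fractions of the prokaryote genome panel.

Summary statistics use the population form of the standard deviation
(divisor N), and per-type aggregation skips missing values — both choices
are validated against the published per-type summaries in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .records import AnnotationRecord
from .core_io import PanelComposition


# ---------------------------------------------------------------------------
# Contamination triage

@dataclass
class CandidateEvidence:
    """Per-gene evidence bundle for the contaminant-vs-genuine decision."""

    gene_id: str
    est_count: int = 0
    cloned: bool = False
    probe_present: bool = False
    anchored: bool = False
    relative_genome_homolog: bool = False
    top_hit_identity_pct: Optional[float] = None
    gc: Optional[float] = None
    intron_count: int = 0


@dataclass(frozen=True)
class TriageRule:
    """High identity alone never condemns a candidate; it is a flag only."""

    identity_alert_pct: float = 60.0


@dataclass
class TriageResult:
    gene_id: str
    status: str  # genuine | suspected_contaminant
    flags: List[str] = field(default_factory=list)


def triage_contamination(ev: CandidateEvidence, rule: TriageRule = TriageRule()) -> TriageResult:
    """Suspect contamination only when every line of evidence is absent.

    A candidate is a suspected contaminant iff it has no EST, was never
    cloned, is not anchored in the assembly (chromosome/scaffold placement
    with neighbours), and has no homolog in a relative's genome.  A top-hit
    identity above the alert level is reported as a supporting flag but is
    never decisive on its own.
    """
    flags: List[str] = []
    if ev.top_hit_identity_pct is not None and ev.top_hit_identity_pct >= rule.identity_alert_pct:
        flags.append(f"high_identity:{ev.top_hit_identity_pct:.1f}")
    no_evidence = (
        ev.est_count == 0
        and not ev.cloned
        and not ev.anchored
        and not ev.relative_genome_homolog
    )
    if no_evidence:
        flags.insert(0, "no_supporting_evidence")
        return TriageResult(ev.gene_id, "suspected_contaminant", flags)
    return TriageResult(ev.gene_id, "genuine", flags)


def evidence_from_annotation(
    rec: AnnotationRecord,
    relative_genome_homolog: bool = False,
) -> CandidateEvidence:
    """Build a triage evidence bundle from an annotation record.

    Anchoring means a chromosome or scaffold placement with coordinates.
    """
    anchored = rec.chromosome is not None or (rec.scaffold is not None and rec.start is not None)
    return CandidateEvidence(
        gene_id=rec.gene_id,
        est_count=rec.est_count,
        cloned=rec.cloned,
        probe_present=rec.probe_id is not None,
        anchored=anchored,
        relative_genome_homolog=relative_genome_homolog,
        top_hit_identity_pct=rec.top_hit_identity_pct,
        gc=rec.gc,
        intron_count=rec.intron_count,
    )


# ---------------------------------------------------------------------------
# Transfer-event type grouping

def group_transfer_types(
    candidates: Sequence[AnnotationRecord],
    similarity_fn: Optional[Callable[[AnnotationRecord, AnnotationRecord], float]] = None,
    max_gap_bp: int = 50_000,
    min_identity: float = 40.0,
) -> List[List[str]]:
    """Partition candidates into transfer-event types (one type = one event).

    Two candidates share a type iff they are tandem copies — same scaffold
    with an interval gap of at most ``max_gap_bp`` — or they are each
    other's reciprocal best match within the candidate set at pairwise
    identity >= ``min_identity`` (per ``similarity_fn``).  Types are the
    transitive closure; output groups are sorted for determinism.
    """
    ids = [c.gene_id for c in candidates]
    index = {gid: i for i, gid in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, a in enumerate(candidates):
        for j in range(i + 1, len(candidates)):
            b = candidates[j]
            if (
                a.scaffold is not None
                and a.scaffold == b.scaffold
                and a.start is not None
                and b.start is not None
            ):
                gap = max(a.start, b.start) - min(a.end or a.start, b.end or b.start) - 1
                if gap <= max_gap_bp:
                    union(i, j)

    if similarity_fn is not None and len(candidates) > 1:
        sim = np.zeros((len(candidates), len(candidates)))
        for i, a in enumerate(candidates):
            for j in range(i + 1, len(candidates)):
                sim[i, j] = sim[j, i] = similarity_fn(a, candidates[j])
        best = sim.max(axis=1)
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if (
                    sim[i, j] >= min_identity
                    and sim[i, j] >= best[i] - 1e-9
                    and sim[i, j] >= best[j] - 1e-9
                ):
                    union(i, j)

    groups: Dict[int, List[str]] = {}
    for i, gid in enumerate(ids):
        groups.setdefault(find(i), []).append(gid)
    return sorted(sorted(g) for g in groups.values())


def annotation_similarity(a: AnnotationRecord, b: AnnotationRecord) -> float:
    """Similarity stand-in when sequences are unavailable: identical
    functional annotation counts as a perfect match, otherwise zero."""
    if a.annotation is None or b.annotation is None:
        return 0.0
    base_a = a.annotation.split("(")[0].strip()
    base_b = b.annotation.split("(")[0].strip()
    return 100.0 if base_a == base_b and base_a not in ("unknown", "") else 0.0


# ---------------------------------------------------------------------------
# Per-type aggregation helpers

def per_type_values(
    candidates: Sequence[AnnotationRecord],
    attr: str,
    scale: float = 1.0,
) -> Dict[str, float]:
    """Mean of ``attr`` per type group, skipping missing values."""
    by_type: Dict[str, List[float]] = {}
    for c in candidates:
        val = getattr(c, attr)
        if val is None:
            continue
        by_type.setdefault(c.type_group or c.gene_id, []).append(float(val) * scale)
    return {t: float(np.mean(v)) for t, v in sorted(by_type.items())}


def population_sd(values: Sequence[float]) -> float:
    return float(np.std(np.asarray(values, dtype=float)))  # divisor N


# ---------------------------------------------------------------------------
# Resampling statistics

@dataclass
class ResamplingResult:
    observed_statistic: float
    null_mean: float
    null_sd: float
    n_replicates: int
    n_extreme: int
    empirical_p: float
    seed: int
    exact_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.empirical_p <= 1.0):
            raise ValueError("empirical_p out of [0,1]")
        if self.n_extreme > self.n_replicates:
            raise ValueError("n_extreme > n_replicates")


def similarity_enrichment_test(
    per_type_identities: Sequence[float],
    background_values: Sequence[float],
    k: Optional[int] = None,
    n_reps: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Are candidates more similar to bacteria than the screened background?

    The observed statistic is the mean of the per-type identities.  Each
    replicate draws ``k`` background values without replacement and records
    their mean; the one-sided empirical p is the fraction of replicate
    means at or above the observed mean.
    """
    observed = float(np.mean(per_type_identities))
    bg = np.asarray(background_values, dtype=float)
    k = k if k is not None else len(per_type_identities)
    if k > bg.size:
        raise ValueError(f"k={k} exceeds background size {bg.size}")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_reps, bg.size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    means = bg[idx].mean(axis=1)
    n_extreme = int(np.count_nonzero(means >= observed))
    return ResamplingResult(
        observed_statistic=observed,
        null_mean=float(means.mean()),
        null_sd=float(means.std()),
        n_replicates=n_reps,
        n_extreme=n_extreme,
        empirical_p=n_extreme / n_reps,
        seed=seed,
    )


def intron_free_test(
    n_background: int,
    n_intron_free: int,
    k: int,
    n_reps: int = 10_000,
    seed: int = 0,
) -> ResamplingResult:
    """Probability that k genes drawn without replacement are all intron-free.

    The empirical estimate simulates the draws; the exact value is the
    hypergeometric product ``prod_i (n_intron_free - i) / (n_background - i)``
    evaluated in log space.
    """
    if not (0 <= n_intron_free <= n_background) or not (0 <= k <= n_background):
        raise ValueError("invalid counts")
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n_intron_free, n_background - n_intron_free, k, size=n_reps)
    successes = int(np.count_nonzero(draws == k))
    if k > n_intron_free:
        exact = 0.0
    else:
        log_p = sum(
            math.log(n_intron_free - i) - math.log(n_background - i) for i in range(k)
        )
        exact = math.exp(log_p)
    return ResamplingResult(
        observed_statistic=float(k),
        null_mean=float(draws.mean()),
        null_sd=float(draws.std()),
        n_replicates=n_reps,
        n_extreme=successes,
        empirical_p=successes / n_reps,
        seed=seed,
        exact_p=exact,
    )


# ---------------------------------------------------------------------------
# GC amelioration & panel composition

@dataclass
class GcSummary:
    recipient_mean: float
    recipient_sd: float
    donor_mean: Optional[float]
    donor_sd: Optional[float]
    centralized: Optional[bool]


def gc_amelioration_summary(
    recipient_gc_by_type: Sequence[float],
    donor_gc: Sequence[float] = (),
) -> GcSummary:
    """Compare GC dispersion of transferred genes vs their donors.

    Anciently transferred genes drift toward the recipient's base
    composition (amelioration), so their GC spread should be narrower than
    that of the donor sequences.  SDs use divisor N.
    """
    r_mean = float(np.mean(recipient_gc_by_type))
    r_sd = population_sd(recipient_gc_by_type)
    if len(donor_gc) == 0:
        return GcSummary(r_mean, r_sd, None, None, None)
    d_mean = float(np.mean(donor_gc))
    d_sd = population_sd(donor_gc)
    return GcSummary(r_mean, r_sd, d_mean, d_sd, r_sd < d_sd)


def composition_fractions(
    panel: PanelComposition,
    taxon_query: str,
    basis: str = "species",
) -> float:
    """Percentage of the panel belonging to a taxon, one decimal place."""
    if basis not in ("species", "organisms"):
        raise ValueError("basis must be 'species' or 'organisms'")
    if basis == "species":
        count, total = panel.species(taxon_query), panel.total_species
    else:
        count, total = panel.organisms(taxon_query), panel.total_organisms
    return round(100.0 * count / total, 1)
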