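"""End-to-end orchestration of the detection funnel.

Stages, in order: first-tier similarity screen of each recipient protein
against the prokaryote panel; the eukaryote distribution-spectrum filter;
the broad third-tier confirmation filter; distance-tree construction and
topology classification; bootstrap refinement of unresolved candidates;
evidence-based contamination triage; donor and transfer-depth inference;
and the summary statistics (similarity enrichment, intron-freeness, GC
amelioration) computed on the survivors against the first-tier background.
Every input gene leaves the funnel exactly once — either as a survivor or
with a stage and reason in the audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .records import PROKARYOTE_GROUPS, AnnotationRecord, HomologyHit, SequenceRecord
from . import pairwise, spectrum, stats
from .caller import (
    DEFAULT_MIN_SUPPORT,
    Donor,
    HgtCall,
    SUPERFAMILY_LEVEL,
    TopologyCall,
    classify_topology,
    infer_donor,
    infer_transfer_depth,
    refine_and_recall,
)
from .phylo import GeneTree, bionj, midpoint_root, protein_distance_matrix


@dataclass
class PipelineConfig:
    """All tunables of the funnel; every stochastic step is seeded."""

    seed: int = 0
    blast1: pairwise.ThresholdConfig = field(default_factory=pairwise.ThresholdConfig.blast1)
    blast3: pairwise.ThresholdConfig = field(default_factory=pairwise.ThresholdConfig.blast3)
    max_better_species: int = 2
    min_support: float = DEFAULT_MIN_SUPPORT
    k_per_group: int = 3
    n_bootstrap: int = 200
    distance_model: str = "kimura"
    triage: stats.TriageRule = field(default_factory=stats.TriageRule)
    type_max_gap_bp: int = 50_000
    type_min_identity: float = 40.0
    n_resampling_reps: int = 10_000

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "blast1" in d:
            d["blast1"] = pairwise.ThresholdConfig(**d["blast1"])
        if "blast3" in d:
            d["blast3"] = pairwise.ThresholdConfig(**d["blast3"])
        if "triage" in d:
            d["triage"] = stats.TriageRule(**d["triage"])
        return cls(**d)


@dataclass
class PipelineInputs:
    """Sequences, taxonomy, annotations and family structure for one run.

    ``families`` maps a family id to the sequence ids considered homologous
    (the candidate search space); precomputed hit tables may substitute the
    built-in aligner for the similarity tiers.
    """

    sequences: Sequence[SequenceRecord]
    species_info: Mapping[str, Tuple[str, str]]
    annotations: Mapping[str, AnnotationRecord]
    families: Mapping[str, Sequence[str]]
    recipient_species: str = "Bombyx_mori"
    species_superfamily: Mapping[str, str] = field(default_factory=dict)
    prokaryote_hits: Optional[Sequence[HomologyHit]] = None
    eukaryote_hits: Optional[Sequence[HomologyHit]] = None

    def validate(self) -> None:
        ids = {r.id for r in self.sequences}
        for gid in self.annotations:
            if gid not in ids:
                raise ValueError(f"annotated gene {gid!r} has no sequence")
        for fid, members in self.families.items():
            missing = set(members) - ids
            if missing:
                raise ValueError(f"family {fid} references unknown ids {sorted(missing)[:3]}")


@dataclass
class AuditEntry:
    gene_id: str
    stage: str
    decision: str  # survived | removed
    reason: str = ""


@dataclass
class FunnelReport:
    """Per-stage surviving counts plus a per-candidate audit trail."""

    stage_counts: List[Tuple[str, int]] = field(default_factory=list)
    audit: List[AuditEntry] = field(default_factory=list)

    def removed(self, gene_id: str, stage: str, reason: str) -> None:
        self.audit.append(AuditEntry(gene_id, stage, "removed", reason))

    def survived(self, gene_id: str, stage: str) -> None:
        self.audit.append(AuditEntry(gene_id, stage, "survived"))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstage\tdecision\treason\n")
            for e in self.audit:
                fh.write(f"{e.gene_id}\t{e.stage}\t{e.decision}\t{e.reason}\n")


@dataclass
class PipelineResult:
    calls: List[HgtCall]
    contaminants: List[str]
    funnel: FunnelReport
    background_identities: List[float]
    enrichment: Optional[stats.ResamplingResult]
    intron_test: Optional[stats.ResamplingResult]
    gc_summary: Optional[stats.GcSummary]
    type_groups: List[List[str]]

    def family_calls(self, family_of: Mapping[str, str]) -> Dict[str, str]:
        """Collapse per-gene outcomes to per-family calls for evaluation."""
        out: Dict[str, str] = {}
        for call in self.calls:
            out[family_of[call.candidate_id]] = "hgt"
        for gid in self.contaminants:
            out.setdefault(family_of[gid], "contaminant")
        return out


def funnel_check(report: FunnelReport) -> None:
    """Assert monotone stage counts and reason-coded removals."""
    previous = None
    for stage, count in report.stage_counts:
        if previous is not None and count > previous:
            raise ValueError(f"stage {stage!r} count {count} exceeds previous {previous}")
        previous = count
    offenders = [e.gene_id for e in report.audit if e.decision == "removed" and not e.reason]
    if offenders:
        raise ValueError(f"removed without reason: {offenders[:5]}")


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    inputs.validate()
    by_id = {r.id: r for r in inputs.sequences}
    family_of = {sid: fid for fid, members in inputs.families.items() for sid in members}
    superfamily = dict(inputs.species_superfamily)

    queries = sorted(inputs.annotations)
    funnel = FunnelReport()
    funnel.stage_counts.append(("input", len(queries)))

    # ---- tier 1: recipient vs prokaryote panel --------------------------
    prok_hits: Dict[str, List[HomologyHit]] = {q: [] for q in queries}
    if inputs.prokaryote_hits is not None:
        for h in inputs.prokaryote_hits:
            if h.query_id in prok_hits:
                prok_hits[h.query_id].append(h)
    else:
        for q in queries:
            fam = inputs.families[family_of[q]]
            subjects = [by_id[s] for s in fam if by_id[s].is_prokaryote]
            prok_hits[q] = pairwise.search([by_id[q]], subjects)
    top_hit: Dict[str, HomologyHit] = {}
    survivors: List[str] = []
    for q in queries:
        kept = pairwise.apply_hit_filter(prok_hits[q], config.blast1)
        if not kept:
            funnel.removed(q, "blast1", "no prokaryote hit above thresholds")
            continue
        top_hit[q] = max(kept, key=lambda h: (h.bit_score, h.identity_pct))
        prok_hits[q] = kept
        survivors.append(q)
    funnel.stage_counts.append(("blast1", len(survivors)))
    background = [top_hit[q].identity_pct for q in survivors]

    # ---- tier 2: eukaryote distribution spectrum ------------------------
    euk_hits: Dict[str, List[HomologyHit]] = {q: [] for q in survivors}
    if inputs.eukaryote_hits is not None:
        for h in inputs.eukaryote_hits:
            if h.query_id in euk_hits:
                euk_hits[h.query_id].append(h)
    else:
        for q in survivors:
            fam = inputs.families[family_of[q]]
            subjects = [
                by_id[s]
                for s in fam
                if not by_id[s].is_prokaryote
                and inputs.species_info[s][0] != inputs.recipient_species
            ]
            euk_hits[q] = pairwise.search([by_id[q]], subjects)
    stage2: List[str] = []
    for q in survivors:
        profile = spectrum.SpectrumProfile(q, top_hit[q])
        for h in pairwise.apply_hit_filter(euk_hits[q], config.blast1):
            sp, grp = inputs.species_info[h.subject_id]
            profile.add_hit(spectrum._GROUP_TO_SET[grp], sp, h.bit_score, h.identity_pct)
        decision = spectrum.spectrum_decision(profile, config.max_better_species)
        if decision.decision == "drop":
            funnel.removed(
                q, "blast2",
                f"{decision.species_count} {decision.triggering_set} species beat top bacterial hit",
            )
        else:
            stage2.append(q)
    funnel.stage_counts.append(("blast2", len(stage2)))

    # ---- tier 3: broad confirmation filter ------------------------------
    stage3: List[str] = []
    for q in stage2:
        kept = pairwise.apply_hit_filter(prok_hits[q], config.blast3)
        if not kept:
            funnel.removed(q, "blast3", "top hits fail broad-search thresholds")
        else:
            stage3.append(q)
    funnel.stage_counts.append(("blast3", len(stage3)))

    # ---- trees: classification and refinement ---------------------------
    calls_by_gene: Dict[str, TopologyCall] = {}
    stage_tree: List[str] = []
    rng = np.random.default_rng(config.seed)
    for q in stage3:
        fam_ids = list(inputs.families[family_of[q]])
        rows = [(sid, by_id[sid].residues) for sid in fam_ids]
        groups = {sid: inputs.species_info[sid][1] for sid in fam_ids}
        species = {sid: inputs.species_info[sid][0] for sid in fam_ids}
        if len(rows) < 4:
            funnel.removed(q, "tree1", "fewer than 4 taxa in family")
            continue
        tree = bionj(protein_distance_matrix(rows, model=config.distance_model))
        tree.groups, tree.species = groups, species
        tree = midpoint_root(tree)
        call = classify_topology(tree, [q], min_support=config.min_support)
        if call.call == "unresolved":
            call = refine_and_recall(
                q, rows, groups, species,
                k_per_group=config.k_per_group,
                n_bootstrap=config.n_bootstrap,
                seed=int(rng.integers(0, 2**31 - 1)),
                min_support=config.min_support,
            )
        if call.call == "vertical":
            funnel.removed(q, "tree", "vertical topology")
        elif call.call == "unresolved":
            funnel.removed(q, "tree", call.reason or "unresolved after refinement")
        else:
            calls_by_gene[q] = call
            stage_tree.append(q)
    funnel.stage_counts.append(("tree", len(stage_tree)))

    # ---- determination: contamination triage ----------------------------
    genuine: List[str] = []
    contaminants: List[str] = []
    for q in stage_tree:
        fam_ids = inputs.families[family_of[q]]
        relative = any(
            inputs.species_info[s][1] == "recipient_insect"
            and inputs.species_info[s][0] != inputs.recipient_species
            for s in fam_ids
        )
        ev = stats.evidence_from_annotation(inputs.annotations[q], relative)
        ev.top_hit_identity_pct = top_hit[q].identity_pct
        verdict = stats.triage_contamination(ev, config.triage)
        if verdict.status == "suspected_contaminant":
            contaminants.append(q)
            funnel.removed(q, "determination", "no supporting evidence: suspected contaminant")
        else:
            genuine.append(q)
            funnel.survived(q, "determination")
    funnel.stage_counts.append(("determination", len(genuine)))

    # ---- donors, depth, type groups -------------------------------------
    final_calls: List[HgtCall] = []
    final_anns = [inputs.annotations[q] for q in genuine]
    type_groups = stats.group_transfer_types(
        final_anns,
        similarity_fn=None,
        max_gap_bp=config.type_max_gap_bp,
        min_identity=config.type_min_identity,
    )
    type_of = {gid: f"T{gi:03d}" for gi, grp in enumerate(type_groups) for gid in grp}
    for q in genuine:
        topo = calls_by_gene[q]
        ranking = [
            inputs.species_info[h.subject_id][0]
            for h in sorted(prok_hits[q], key=lambda h: -h.bit_score)
        ]
        donor = infer_donor(topo, ranking) if topo.call == "hgt" else None
        fam_ids = inputs.families[family_of[q]]
        presence = {
            superfamily.get(inputs.species_info[s][0])
            for s in fam_ids
            if inputs.species_info[s][1] == "recipient_insect"
        } & set(SUPERFAMILY_LEVEL)
        depth = infer_transfer_depth(presence) if presence else None
        final_calls.append(
            HgtCall(q, topo, donor=donor, transfer_depth=depth, type_group=type_of[q])
        )

    # ---- statistics on survivors vs tier-1 background -------------------
    enrichment = intron = gc_sum = None
    if final_calls and len(background) > len(type_groups):
        per_type_ident = {}
        per_type_gc = {}
        for call in final_calls:
            t = call.type_group
            per_type_ident.setdefault(t, []).append(top_hit[call.candidate_id].identity_pct)
            per_type_gc.setdefault(t, []).append(inputs.annotations[call.candidate_id].gc * 100)
        type_idents = [float(np.mean(v)) for _, v in sorted(per_type_ident.items())]
        type_gc = [float(np.mean(v)) for _, v in sorted(per_type_gc.items())]
        enrichment = stats.similarity_enrichment_test(
            type_idents, background, n_reps=config.n_resampling_reps, seed=config.seed,
        )
        n_intron_free_bg = sum(
            1 for q in survivors if inputs.annotations[q].intron_count == 0
        )
        intron = stats.intron_free_test(
            len(survivors), n_intron_free_bg, len(type_groups),
            n_reps=config.n_resampling_reps, seed=config.seed,
        )
        gc_sum = stats.gc_amelioration_summary(type_gc)

    return PipelineResult(
        calls=final_calls,
        contaminants=contaminants,
        funnel=funnel,
        background_identities=background,
        enrichment=enrichment,
        intron_test=intron,
        gc_summary=gc_sum,
        type_groups=type_groups,
    )
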