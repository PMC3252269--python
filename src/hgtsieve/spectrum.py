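"""Second-tier sieve: the eukaryote taxonomic distribution-spectrum filter.

A candidate that looks bacterial in the first screen may simply be a
conserved eukaryotic gene.  This tier compares, per eukaryote species set,
how many distinct species carry a homolog that beats the candidate's top
bacterial hit on BOTH bit score and identity.  More than two such species in
any of the five non-insect sets marks the candidate as vertically inherited
and drops it; a candidate that would drop but has no insect homolog at all
is recovered (a lineage-restricted gene cannot be explained vertically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .records import HomologyHit, SequenceRecord

#: The six eukaryote species sets of the distribution spectrum.
SPECTRUM_SETS = (
    "protist",
    "fungus",
    "plant",
    "insect",
    "non_insect_arthropod",
    "non_arthropod_metazoan",
)

#: Non-insect sets whose species counts can veto a candidate.
VETO_SETS = tuple(s for s in SPECTRUM_SETS if s != "insect")

_GROUP_TO_SET = {
    "protist": "protist",
    "fungus": "fungus",
    "plant": "plant",
    "recipient_insect": "insect",
    "other_insect": "insect",
    "non_insect_arthropod": "non_insect_arthropod",
    "non_arthropod_metazoan": "non_arthropod_metazoan",
}


def assign_species_set(record: SequenceRecord) -> str:
    """Map a sequence's taxonomic group to one of the six eukaryote sets."""
    try:
        return _GROUP_TO_SET[record.group]
    except KeyError:
        raise ValueError(
            f"{record.id}: group {record.group!r} is not part of the eukaryote spectrum"
        )


@dataclass
class SpectrumProfile:
    """Distribution spectrum of one candidate across the six eukaryote sets.

    Each eukaryote hit is recorded as (species, bit_score, identity_pct);
    the reference is the candidate's top bacterial hit from the first tier.
    """

    candidate_id: str
    top_bacterial_hit: HomologyHit
    eukaryote_hits: Dict[str, List[Tuple[str, float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.eukaryote_hits:
            if label not in SPECTRUM_SETS:
                raise ValueError(f"unknown spectrum set {label!r}")

    def add_hit(self, set_label: str, species: str, bit_score: float, identity_pct: float) -> None:
        if set_label not in SPECTRUM_SETS:
            raise ValueError(f"unknown spectrum set {set_label!r}")
        self.eukaryote_hits.setdefault(set_label, []).append((species, bit_score, identity_pct))


@dataclass(frozen=True)
class SpectrumDecision:
    candidate_id: str
    decision: str  # retain | drop | recover
    triggering_set: Optional[str] = None
    species_count: int = 0


def spectrum_decision(
    profile: SpectrumProfile,
    max_better_species: int = 2,
    score_field: str = "bit_score",
) -> SpectrumDecision:
    """Retain/drop/recover a candidate from its distribution spectrum.

    Drop iff some non-insect set holds strictly more than
    ``max_better_species`` distinct species, each with a homolog strictly
    beating the top bacterial hit on both score and identity (ties never
    count against the candidate).  Distinct species are counted once no
    matter how many hits they contribute.  A droppable candidate with zero
    insect-set hits is recovered instead.
    """
    if score_field not in ("bit_score", "raw_score"):
        raise ValueError("score_field must be 'bit_score' or 'raw_score'")
    ref = profile.top_bacterial_hit
    ref_score = getattr(ref, score_field)
    ref_ident = ref.identity_pct
    worst: Optional[Tuple[str, int]] = None
    for set_label in VETO_SETS:
        species = {
            sp
            for (sp, score, ident) in profile.eukaryote_hits.get(set_label, [])
            if score > ref_score and ident > ref_ident
        }
        if len(species) > max_better_species:
            if worst is None or len(species) > worst[1]:
                worst = (set_label, len(species))
    if worst is None:
        return SpectrumDecision(profile.candidate_id, "retain")
    if not profile.eukaryote_hits.get("insect"):
        return SpectrumDecision(profile.candidate_id, "recover", worst[0], worst[1])
    return SpectrumDecision(profile.candidate_id, "drop", worst[0], worst[1])


def build_profiles(
    candidate_top_hits: Mapping[str, HomologyHit],
    eukaryote_hits: Iterable[HomologyHit],
    subject_info: Mapping[str, Tuple[str, str]],
) -> List[SpectrumProfile]:
    """Assemble spectrum profiles from hit lists and a subject species map.

    ``candidate_top_hits`` maps candidate id -> its top bacterial hit;
    ``eukaryote_hits`` are candidate-vs-eukaryote hits whose subjects
    resolve through ``subject_info`` (id -> (species, group)).
    """
    profiles = {
        cid: SpectrumProfile(cid, top) for cid, top in candidate_top_hits.items()
    }
    for hit in eukaryote_hits:
        if hit.query_id not in profiles:
            continue
        species, group = subject_info[hit.subject_id]
        set_label = _GROUP_TO_SET.get(group)
        if set_label is None:
            raise ValueError(f"subject {hit.subject_id!r} is not a eukaryote spectrum member")
        profiles[hit.query_id].add_hit(set_label, species, hit.bit_score, hit.identity_pct)
    return list(profiles.values())


def write_decision_log(decisions: Iterable[SpectrumDecision], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tdecision\ttriggering_set\tspecies_count\n")
        for d in decisions:
            fh.write(f"{d.candidate_id}\t{d.decision}\t{d.triggering_set or ''}\t{d.species_count}\n")
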