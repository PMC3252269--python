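"""Gene-tree topology classification, donor inference and transfer depth.

A candidate is called horizontally transferred when, on a rooted gene tree,
the walk from the focal (recipient-lineage) clade toward the root meets only
prokaryote sister subtrees until the clade separating the focal set from all
other eukaryotes — i.e. the recipient sequences nest inside the prokaryote
part of the tree.  Meeting a purely eukaryotic sister first is the vertical
signal; a mixed sister leaves the candidate unresolved for refinement.  The
optional A-F sub-labels summarise the sister-composition pattern (single
prokaryote leaf, prokaryote clade, deep nesting / insect, metazoan, other
eukaryote sister) and are heuristic; the binary call is normative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .records import PROKARYOTE_GROUPS
from .phylo import GeneTree, bootstrap_support, midpoint_root, protein_distance_matrix

#: Nested recipient-lineage hierarchy used for transfer-depth labels:
#: each entry maps a superfamily to the shallowest hierarchy level at which
#: it joins the recipient's clade.
SUPERFAMILY_LEVEL = {
    "Bombycoidea": 0,
    "Papilionoidea": 1,
    "Noctuoidea": 1,
    "Pyraloidea": 2,
    "Tortricoidea": 3,
}

HIERARCHY_LABELS = ("Bombycoidea", "Macrolepidoptera", "Obtectmera", "Apoditrysia")

DEFAULT_MIN_SUPPORT = 50.0


@dataclass
class TopologyCall:
    candidate_id: str
    call: str  # hgt | vertical | unresolved
    six_type: Optional[str] = None
    nesting_support: Optional[float] = None
    sister_taxa: List[Tuple[str, str]] = field(default_factory=list)
    reason: Optional[str] = None


@dataclass(frozen=True)
class Donor:
    genus: str
    species: Optional[str]
    rank: str  # species | genus


@dataclass
class HgtCall:
    candidate_id: str
    topology: TopologyCall
    donor: Optional[Donor] = None
    transfer_depth: Optional[str] = None
    type_group: Optional[str] = None


def _leaf_info(gtree: GeneTree, leaf_id: str) -> Tuple[str, str]:
    return (gtree.species.get(leaf_id, leaf_id), gtree.groups.get(leaf_id, ""))


def classify_topology(
    gtree: GeneTree,
    focal_ids: Sequence[str],
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> TopologyCall:
    """Classify one candidate's gene tree as hgt / vertical / unresolved.

    ``focal_ids`` is the candidate plus its recipient-lineage homologs;
    any other leaf labelled ``recipient_insect`` is merged into the focal
    set so lineage-wide transfers are not mistaken for singletons.  The
    tree is midpoint-rooted if unrooted.  The hgt call additionally
    requires the decisive nesting clade's bootstrap support to reach
    ``min_support`` when supports are present.
    """
    candidate_id = focal_ids[0]
    leaf_ids = set(gtree.leaf_ids())
    for fid in focal_ids:
        if fid not in leaf_ids:
            raise KeyError(f"focal id {fid!r} absent from tree")
    if not gtree.tree.is_rooted:
        gtree = midpoint_root(gtree)
    focal = set(focal_ids) | {
        lid for lid in leaf_ids if gtree.groups.get(lid) == "recipient_insect"
    }

    leaf_nodes = {lf.taxon.label: lf for lf in gtree.tree.leaf_node_iter()}
    mrca = gtree.tree.mrca(taxa=[leaf_nodes[i].taxon for i in focal]) if len(focal) > 1 else leaf_nodes[next(iter(focal))]

    def composition(leaves: Iterable[str]) -> Tuple[bool, bool]:
        has_prok = has_euk = False
        for lid in leaves:
            grp = gtree.groups.get(lid, "")
            if grp in PROKARYOTE_GROUPS:
                has_prok = True
            else:
                has_euk = True
        return has_prok, has_euk

    # sister levels from the focal MRCA toward the root
    levels: List[List[str]] = []
    below = set(lf.taxon.label for lf in mrca.leaf_iter())
    interlopers = below - focal
    if interlopers:
        levels.append(sorted(interlopers))
    node = mrca
    level_nodes: List[object] = [mrca] * len(levels)
    while node.parent_node is not None:
        parent = node.parent_node
        sister = [
            lf.taxon.label
            for sib in parent.child_nodes()
            if sib is not node
            for lf in sib.leaf_iter()
        ]
        if sister:
            levels.append(sorted(sister))
            level_nodes.append(parent)
        node = parent

    if not levels:
        return TopologyCall(candidate_id, "unresolved", reason="focal set spans the whole tree")

    prok_levels: List[List[str]] = []
    decisive_node = mrca
    outcome: Optional[str] = None
    for lvl, lvl_node in zip(levels, level_nodes):
        has_prok, has_euk = composition(lvl)
        if has_prok and has_euk:
            outcome = "unresolved" if not prok_levels else "mixed_stop"
            break
        if has_euk:
            outcome = "vertical" if not prok_levels else "euk_stop"
            break
        prok_levels.append(lvl)
        decisive_node = lvl_node

    if outcome == "unresolved":
        return TopologyCall(candidate_id, "unresolved", reason="mixed prokaryote/eukaryote sister")
    if outcome == "vertical":
        first = levels[0]
        _, groups = zip(*(_leaf_info(gtree, lid) for lid in first))
        if any(g.endswith("insect") for g in groups):
            six = "C"
        elif any(g in ("non_insect_arthropod", "non_arthropod_metazoan") for g in groups):
            six = "D"
        else:
            six = "E"
        return TopologyCall(candidate_id, "vertical", six_type=six)

    # nested among prokaryotes up to the separating clade (or the root)
    support = gtree.support_of(decisive_node) if decisive_node is not mrca else None
    if support is not None and support < min_support:
        return TopologyCall(
            candidate_id,
            "unresolved",
            nesting_support=support,
            reason=f"nesting support {support:.0f} below {min_support:.0f}",
        )
    sisters = [_leaf_info(gtree, lid) for lid in prok_levels[0]]
    if len(prok_levels) > 1:
        six = "F"
    elif len(prok_levels[0]) == 1:
        six = "A"
    else:
        six = "B"
    return TopologyCall(
        candidate_id,
        "hgt",
        six_type=six,
        nesting_support=support,
        sister_taxa=sisters,
    )


def refine_and_recall(
    candidate_id: str,
    alignment,
    groups: Mapping[str, str],
    species: Optional[Mapping[str, str]] = None,
    k_per_group: int = 3,
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> TopologyCall:
    """Second-pass refinement: prune clutter homologs, rebuild, re-classify.

    ``alignment`` holds aligned (id, residues) rows including the candidate.
    The candidate and all recipient-lineage rows are retained; every other
    taxonomic group keeps its ``k_per_group`` rows most similar to the
    candidate (by p-distance).  The reduced alignment is rebuilt with a
    bootstrap tree and re-classified.  Fewer than 4 retained taxa returns
    an unresolved call with a reason code.
    """
    rows = {rid: seq for rid, seq in (r if isinstance(r, tuple) else (r.id, r.residues) for r in alignment)}
    if candidate_id not in rows:
        raise KeyError(f"candidate {candidate_id!r} absent from alignment")
    dm = protein_distance_matrix(list(rows.items()), model="p")
    dist_to_cand = {rid: dm[candidate_id, rid] for rid in rows if rid != candidate_id}

    keep = {candidate_id}
    keep |= {rid for rid in rows if groups.get(rid) == "recipient_insect"}
    by_group: Dict[str, List[str]] = {}
    for rid in rows:
        if rid in keep:
            continue
        by_group.setdefault(groups.get(rid, ""), []).append(rid)
    for grp, members in by_group.items():
        members.sort(key=lambda rid: (dist_to_cand[rid], rid))
        keep |= set(members[:k_per_group])

    if len(keep) < 4:
        return TopologyCall(candidate_id, "unresolved", reason="fewer than 4 taxa after refinement")

    sub = [(rid, rows[rid]) for rid in sorted(keep)]
    tree = bootstrap_support(sub, n_replicates=n_bootstrap, seed=seed)
    tree.groups = {rid: groups.get(rid, "") for rid, _ in sub}
    if species:
        tree.species = {rid: species.get(rid, rid) for rid, _ in sub}
    tree = midpoint_root(tree)
    return classify_topology(tree, [candidate_id], min_support=min_support)


def infer_donor(call: TopologyCall, blast_ranking: Sequence[str]) -> Donor:
    """Donor taxon from the decisive sister clade of an hgt call.

    A single sister species is the donor at species rank; several sister
    bacteria resolve to the genus of the one ranked best in
    ``blast_ranking`` (the candidate's bacterial hits, best first).
    """
    if call.call != "hgt":
        raise ValueError(f"donor inference requires an hgt call, got {call.call!r}")
    species = sorted({sp for sp, _ in call.sister_taxa})
    if not species:
        raise ValueError("hgt call with empty sister clade")
    if len(species) == 1:
        name = species[0]
        return Donor(genus=name.split()[0], species=name, rank="species")
    rank_of = {sp: i for i, sp in enumerate(blast_ranking)}
    best = min(species, key=lambda sp: (rank_of.get(sp, len(blast_ranking)), sp))
    return Donor(genus=best.split()[0], species=None, rank="genus")


def infer_transfer_depth(presence: Iterable[str]) -> str:
    """Most recent common ancestor label for the superfamilies carrying
    homologs of a transferred gene — a lower bound on the transfer age.
    """
    present = set(presence)
    if not present:
        raise ValueError("empty superfamily presence set")
    unknown = present - set(SUPERFAMILY_LEVEL)
    if unknown:
        raise ValueError(f"unknown superfamilies: {sorted(unknown)}")
    level = max(SUPERFAMILY_LEVEL[s] for s in present)
    return HIERARCHY_LABELS[level]


def write_call_table(calls: Iterable[HgtCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tcall\tsix_type\tsupport\tdonor\tdonor_rank\ttransfer_depth\ttype_group\n")
        for c in calls:
            t = c.topology
            donor = "" if c.donor is None else (c.donor.species or c.donor.genus)
            fh.write(
                "\t".join(
                    [
                        c.candidate_id,
                        t.call,
                        t.six_type or "",
                        "" if t.nesting_support is None else f"{t.nesting_support:.0f}",
                        donor,
                        "" if c.donor is None else c.donor.rank,
                        c.transfer_depth or "",
                        c.type_group or "",
                    ]
                )
                + "\n"
            )
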