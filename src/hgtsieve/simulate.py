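"""Synthetic multi-clade protein families with planted transfer events.

The generator emulates the structure the detection pipeline assumes: a
recipient insect clade of five superfamily lineages nested among other
eukaryotes, a panel of prokaryote lineages, gene families evolved along
those trees under a Poisson (uniform-replacement) amino-acid model, planted
transfer events at a chosen hierarchy depth (optionally tandem-duplicated
after integration and with GC metadata ameliorated toward the recipient
background), and metadata-free contaminant sequences that mimic the
assembly-contamination signature (near-identical to a bacterial source,
no transcript/anchoring/relative-genome evidence).  Every dataset carries a
truth table so end-to-end calls can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import yaml

from .records import CANONICAL_AA, AnnotationRecord, SequenceRecord
from .caller import SUPERFAMILY_LEVEL, HIERARCHY_LABELS

RECIPIENT_SPECIES = "Bombyx_mori"

#: species -> superfamily for the recipient clade
SPECIES_SUPERFAMILY = {
    "Bombyx_mori": "Bombycoidea",
    "Manduca_sexta": "Bombycoidea",
    "Danaus_plexippus": "Papilionoidea",
    "Papilio_xuthus": "Papilionoidea",
    "Helicoverpa_armigera": "Noctuoidea",
    "Spodoptera_frugiperda": "Noctuoidea",
    "Ostrinia_nubilalis": "Pyraloidea",
    "Cydia_pomonella": "Tortricoidea",
}

SPECIES_GROUP = {
    **{sp: "recipient_insect" for sp in SPECIES_SUPERFAMILY},
    "Drosophila_melanogaster": "other_insect",
    "Apis_mellifera": "other_insect",
    "Tribolium_castaneum": "other_insect",
    "Daphnia_pulex": "non_insect_arthropod",
    "Ixodes_scapularis": "non_insect_arthropod",
    "Homo_sapiens": "non_arthropod_metazoan",
    "Danio_rerio": "non_arthropod_metazoan",
    "Arabidopsis_thaliana": "plant",
    "Oryza_sativa": "plant",
    "Saccharomyces_cerevisiae": "fungus",
    "Neurospora_crassa": "fungus",
    "Aspergillus_nidulans": "fungus",
    "Plasmodium_falciparum": "protist",
    "Dictyostelium_discoideum": "protist",
    "Serratia_proteamaculans": "eubacterium",
    "Yersinia_pestis": "eubacterium",
    "Photorhabdus_luminescens": "eubacterium",
    "Pseudomonas_aeruginosa": "eubacterium",
    "Pseudomonas_fluorescens": "eubacterium",
    "Bacillus_licheniformis": "eubacterium",
    "Bacillus_subtilis": "eubacterium",
    "Listeria_grayi": "eubacterium",
    "Enterococcus_faecalis": "eubacterium",
    "Methylobacterium_radiotolerans": "eubacterium",
    "Wolbachia_pipientis": "eubacterium",
    "Methanosarcina_barkeri": "archaebacterium",
}

DONOR_SPECIES = (
    "Serratia_proteamaculans",
    "Photorhabdus_luminescens",
    "Pseudomonas_aeruginosa",
    "Bacillus_licheniformis",
    "Enterococcus_faecalis",
    "Listeria_grayi",
    "Methylobacterium_radiotolerans",
)

#: recipient clade (5 superfamily lineages), branch lengths in subs/site
_LEP_NEWICK = (
    "(((({B}:0.03,Manduca_sexta:0.03):0.04,"
    "((Danaus_plexippus:0.04,Papilio_xuthus:0.04):0.02,"
    "(Helicoverpa_armigera:0.04,Spodoptera_frugiperda:0.04):0.02):0.01):0.03,"
    "Ostrinia_nubilalis:0.10):0.03,Cydia_pomonella:0.13)"
).format(B=RECIPIENT_SPECIES)

_EUK_NEWICK = (
    "((((" + _LEP_NEWICK + ":0.22,"
    "(Drosophila_melanogaster:0.20,(Apis_mellifera:0.18,Tribolium_castaneum:0.18):0.03):0.12):0.10,"
    "(Daphnia_pulex:0.28,Ixodes_scapularis:0.28):0.10):0.08,"
    "(Homo_sapiens:0.22,Danio_rerio:0.22):0.18):0.12,"
    "(((Saccharomyces_cerevisiae:0.25,(Neurospora_crassa:0.18,Aspergillus_nidulans:0.18):0.08):0.18,"
    "(Arabidopsis_thaliana:0.20,Oryza_sativa:0.20):0.20):0.06,"
    "(Plasmodium_falciparum:0.35,Dictyostelium_discoideum:0.35):0.08):0.10)"
)

_BACT_NEWICK = (
    "(((((Serratia_proteamaculans:0.14,Yersinia_pestis:0.14):0.08,"
    "Photorhabdus_luminescens:0.20):0.08,"
    "(Pseudomonas_aeruginosa:0.12,Pseudomonas_fluorescens:0.12):0.14):0.12,"
    "(Methylobacterium_radiotolerans:0.26,Wolbachia_pipientis:0.30):0.10):0.08,"
    "(((Bacillus_licheniformis:0.12,Bacillus_subtilis:0.12):0.10,"
    "Listeria_grayi:0.20):0.06,Enterococcus_faecalis:0.24):0.12,"
    "Methanosarcina_barkeri:0.55)"
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``transfer_fraction`` of families carry one planted transfer event;
    ``contaminant_fraction`` adds metadata-free bacterial sequences labelled
    as recipient genes.  ``amelioration`` in [0, 1] moves the transferred
    gene's GC metadata from the donor's value (0) to the recipient
    background (1).  Branch lengths in the clade templates are expected
    substitutions/site; per-family rates modulate them.
    """

    seed: int = 0
    n_families: int = 200
    transfer_fraction: float = 0.15
    contaminant_fraction: float = 0.05
    sequence_length: int = 300
    model: str = "poisson"
    duplication_p: float = 0.3
    amelioration: float = 0.7
    transfer_stem: float = 0.30
    recipient_clade_newick: str = _LEP_NEWICK
    bacteria_clade_newick: str = _BACT_NEWICK
    eukaryote_clade_newick: str = _EUK_NEWICK
    euk_bact_stem: float = 0.55
    rate_log_mean: float = -0.7
    rate_log_sd: float = 0.45
    hgt_rate_log_mean: float = -0.1
    recipient_gc_mean: float = 0.478
    recipient_gc_sd: float = 0.03
    donor_gc_mean: float = 0.50
    donor_gc_sd: float = 0.11

    def __post_init__(self) -> None:
        for frac in (self.transfer_fraction, self.contaminant_fraction, self.amelioration):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.sequence_length < 50:
            raise ValueError("sequence_length must be >= 50")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TruthRecord:
    family_id: str
    status: str  # vertical | hgt | contaminant
    donor_lineage: Optional[str] = None
    transfer_node: Optional[str] = None
    duplicated: bool = False

    def __post_init__(self) -> None:
        if self.status == "hgt" and (self.donor_lineage is None or self.transfer_node is None):
            raise ValueError("hgt truth needs donor and transfer node")
        if self.status != "hgt" and (self.donor_lineage or self.transfer_node):
            raise ValueError("non-hgt truth must not carry donor/transfer node")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    records: List[SequenceRecord]
    species_info: Dict[str, Tuple[str, str]]  # seq id -> (species, group)
    annotations: Dict[str, AnnotationRecord]  # recipient gene id -> annotation
    families: Dict[str, List[str]]  # family id -> member seq ids
    truth: List[TruthRecord]

    def recipient_gene_ids(self) -> List[str]:
        return sorted(self.annotations)

    def family_of(self) -> Dict[str, str]:
        return {sid: fid for fid, members in self.families.items() for sid in members}


# ---------------------------------------------------------------------------
# Sequence evolution

_AA = np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)


def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson substitution: each site is redrawn from the stationary
    (uniform) distribution with probability 1 - exp(-t)."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    hit = rng.random(seq.size) < -np.expm1(-t)
    out = seq.copy()
    out[hit] = _AA[rng.integers(0, len(_AA), int(hit.sum()))]
    return out


def evolve_family(
    root_length: int,
    tree_with_rates: dendropy.Tree,
    model: str = "poisson",
    seed: int = 0,
) -> Dict[str, str]:
    """Evolve one family along a tree; returns leaf label -> sequence.

    Branch lengths are expected substitutions/site.  Under the uniform
    replacement model the expected p-distance between two leaves increases
    monotonically with their path length (saturating at 19/20).
    """
    if model != "poisson":
        raise ValueError(f"unknown substitution model {model!r}")
    rng = np.random.default_rng(seed)
    root_seq = _AA[rng.integers(0, len(_AA), root_length)]
    seqs: Dict[int, np.ndarray] = {id(tree_with_rates.seed_node): root_seq}
    out: Dict[str, str] = {}
    for node in tree_with_rates.preorder_node_iter():
        if node.parent_node is None:
            current = root_seq
        else:
            t = node.edge.length or 0.0
            current = _mutate(seqs[id(node.parent_node)], t, rng)
        seqs[id(node)] = current
        if node.is_leaf():
            out[node.taxon.label] = current.tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# Tree construction per family

def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick + ";", schema="newick", preserve_underscores=True)


def _scale(tree: dendropy.Tree, rate: float) -> dendropy.Tree:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= rate
    return tree


def vertical_family_tree(config: SimulationConfig, rate: float) -> dendropy.Tree:
    newick = (
        f"({config.eukaryote_clade_newick}:{config.euk_bact_stem},"
        f"{config.bacteria_clade_newick}:{config.euk_bact_stem})"
    )
    return _scale(_parse(newick), rate)


def hgt_family_tree(
    config: SimulationConfig,
    donor_lineage: str,
    transfer_node: str,
    rate: float,
) -> dendropy.Tree:
    """Bacteria clade with the carried recipient subtree regrafted onto the
    donor lineage's terminal edge."""
    if donor_lineage not in SPECIES_GROUP or SPECIES_GROUP[donor_lineage] not in (
        "eubacterium",
        "archaebacterium",
    ):
        raise ValueError(f"unknown donor lineage {donor_lineage!r}")
    if transfer_node not in HIERARCHY_LABELS:
        raise ValueError(f"unknown transfer node {transfer_node!r}")
    level = HIERARCHY_LABELS.index(transfer_node)
    tree = _parse(config.bacteria_clade_newick)
    lep = _parse(config.recipient_clade_newick)
    carried = [
        sp for sp, sf in SPECIES_SUPERFAMILY.items() if SUPERFAMILY_LEVEL[sf] <= level
    ]
    lep.retain_taxa_with_labels(carried)
    donor = next(
        lf for lf in tree.leaf_node_iter() if lf.taxon.label == donor_lineage
    )
    stem_parent = dendropy.Node()
    old_len = donor.edge.length or 0.1
    parent = donor.parent_node
    parent.remove_child(donor)
    parent.add_child(stem_parent)
    stem_parent.edge.length = old_len / 2
    donor.edge.length = old_len / 2
    stem_parent.add_child(donor)
    sub_root = lep.seed_node
    lep_tree_copy = sub_root
    stem_parent.add_child(lep_tree_copy)
    lep_tree_copy.edge.length = config.transfer_stem
    tree.update_taxon_namespace()
    return _scale(tree, rate)


def _tandem_duplicate(tree: dendropy.Tree, leaf_label: str, copy_label: str, split: float = 0.02) -> None:
    leaf = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == leaf_label)
    old_len = leaf.edge.length or split
    parent = leaf.parent_node
    cherry = dendropy.Node()
    parent.remove_child(leaf)
    parent.add_child(cherry)
    cherry.edge.length = max(old_len - split, 0.0)
    leaf.edge.length = split
    cherry.add_child(leaf)
    copy = dendropy.Node(taxon=dendropy.Taxon(label=copy_label))
    copy.edge.length = split
    cherry.add_child(copy)
    tree.update_taxon_namespace()


def plant_transfer(
    config: SimulationConfig,
    donor_lineage: str,
    transfer_node: str,
    duplication_p: float,
    amelioration: float,
    seed: int,
    family_id: str = "F0000",
) -> Tuple[dendropy.Tree, TruthRecord]:
    """Build one transferred family's tree and its truth record.

    The recipient subtree carrying the gene (the superfamilies at or below
    the transfer node in the hierarchy) is regrafted from the donor lineage;
    with probability ``duplication_p`` the recipient gene is tandem
    duplicated after integration.
    """
    rng = np.random.default_rng(seed)
    rate = float(np.exp(rng.normal(config.hgt_rate_log_mean, config.rate_log_sd)))
    tree = hgt_family_tree(config, donor_lineage, transfer_node, rate)
    duplicated = bool(rng.random() < duplication_p)
    if duplicated:
        _tandem_duplicate(tree, RECIPIENT_SPECIES, RECIPIENT_SPECIES + "__copy2")
    truth = TruthRecord(
        family_id=family_id,
        status="hgt",
        donor_lineage=donor_lineage,
        transfer_node=transfer_node,
        duplicated=duplicated,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# Dataset assembly

def _relabel(tree: dendropy.Tree, family_id: str) -> Dict[str, str]:
    """Prefix leaf labels with the family id; returns new id -> species."""
    mapping: Dict[str, str] = {}
    for lf in tree.leaf_node_iter():
        species = lf.taxon.label.replace("__copy2", "")
        new_id = f"{family_id}_{lf.taxon.label}"
        lf.taxon.label = new_id
        mapping[new_id] = species
    return mapping


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate families, annotations and the truth table for one run."""
    rng = np.random.default_rng(config.seed)
    donor_gc = {
        sp: float(np.clip(rng.normal(config.donor_gc_mean, config.donor_gc_sd), 0.25, 0.75))
        for sp in sorted(set(DONOR_SPECIES) | set(s for s, g in SPECIES_GROUP.items() if g == "eubacterium"))
    }

    n_hgt = round(config.n_families * config.transfer_fraction)
    n_contam = round(config.n_families * config.contaminant_fraction)
    statuses = ["hgt"] * n_hgt + ["contaminant"] * n_contam
    statuses += ["vertical"] * (config.n_families - len(statuses))
    rng.shuffle(statuses)

    records: List[SequenceRecord] = []
    species_info: Dict[str, Tuple[str, str]] = {}
    annotations: Dict[str, AnnotationRecord] = {}
    families: Dict[str, List[str]] = {}
    truth: List[TruthRecord] = []

    for idx, status in enumerate(statuses):
        fid = f"F{idx:04d}"
        fseed = int(rng.integers(0, 2**31 - 1))
        frng = np.random.default_rng(fseed)
        scaffold = f"scaf{idx:04d}"
        position = int(frng.integers(10_000, 5_000_000))

        if status == "vertical":
            rate = float(np.exp(frng.normal(config.rate_log_mean, config.rate_log_sd)))
            tree = vertical_family_tree(config, rate)
            truth.append(TruthRecord(fid, "vertical"))
            gc = float(np.clip(frng.normal(config.recipient_gc_mean, 0.079), 0.2, 0.8))
            intron_count = int(frng.poisson(2.5))
            if frng.random() < 0.1:
                intron_count = 0
            ann_extra = dict(gc=gc, intron_count=intron_count)
        elif status == "hgt":
            donor = DONOR_SPECIES[int(frng.integers(0, len(DONOR_SPECIES)))]
            depth = HIERARCHY_LABELS[int(frng.integers(0, len(HIERARCHY_LABELS)))]
            tree, rec = plant_transfer(
                config, donor, depth, config.duplication_p, config.amelioration,
                seed=int(frng.integers(0, 2**31 - 1)), family_id=fid,
            )
            truth.append(rec)
            background = float(frng.normal(config.recipient_gc_mean, config.recipient_gc_sd))
            gc = float(
                np.clip(
                    donor_gc[donor] + config.amelioration * (background - donor_gc[donor])
                    + frng.normal(0, 0.01),
                    0.2, 0.8,
                )
            )
            ann_extra = dict(gc=gc, intron_count=0)
        else:  # contaminant: a bacterial sequence masquerading as a host gene
            source = DONOR_SPECIES[int(frng.integers(0, len(DONOR_SPECIES)))]
            tree = _parse(config.bacteria_clade_newick)
            leaf = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == source)
            contam = dendropy.Node(taxon=dendropy.Taxon(label=RECIPIENT_SPECIES))
            contam.edge.length = 0.01
            old_len = leaf.edge.length or 0.1
            parent = leaf.parent_node
            holder = dendropy.Node()
            parent.remove_child(leaf)
            parent.add_child(holder)
            holder.edge.length = old_len - 0.01
            leaf.edge.length = 0.01
            holder.add_child(leaf)
            holder.add_child(contam)
            tree.update_taxon_namespace()
            truth.append(TruthRecord(fid, "contaminant"))
            ann_extra = dict(gc=float(np.clip(donor_gc[source] + frng.normal(0, 0.01), 0.2, 0.8)),
                             intron_count=0)

        id_to_species = _relabel(tree, fid)
        seqs = evolve_family(
            config.sequence_length, tree, config.model,
            seed=int(frng.integers(0, 2**31 - 1)),
        )
        member_ids = sorted(seqs)
        families[fid] = member_ids
        for sid in member_ids:
            species = id_to_species[sid]
            group = SPECIES_GROUP[species]
            records.append(SequenceRecord(sid, species, group, seqs[sid]))
            species_info[sid] = (species, group)

        # annotations for every recipient-proteome entry (B. mori labelled)
        recipient_ids = [
            sid for sid in member_ids if id_to_species[sid] == RECIPIENT_SPECIES
        ]
        for copy_i, sid in enumerate(sorted(recipient_ids)):
            length_bp = config.sequence_length * 3
            start = position + copy_i * (length_bp + 2_000)
            if status == "contaminant":
                ann = AnnotationRecord(
                    gene_id=sid, gc=ann_extra["gc"], intron_count=0,
                    est_count=0, cloned=False, probe_id=None,
                    chromosome=None, scaffold=None, start=None, end=None,
                    strand=None, protein_length=config.sequence_length,
                )
            else:
                est = int(frng.poisson(2.0))
                ann = AnnotationRecord(
                    gene_id=sid, gc=ann_extra["gc"],
                    intron_count=ann_extra["intron_count"],
                    est_count=est, cloned=False, probe_id=f"p{idx:04d}_{copy_i}",
                    chromosome=str(1 + idx % 28), scaffold=scaffold,
                    start=start, end=start + length_bp - 1,
                    strand="+" if frng.random() < 0.5 else "-",
                    protein_length=config.sequence_length,
                )
            annotations[sid] = ann

    return SyntheticDataset(config, records, species_info, annotations, families, truth)


# ---------------------------------------------------------------------------
# Output + evaluation

def write_dataset(ds: SyntheticDataset, outdir) -> None:
    from . import core_io  # deferred: core_io imports nothing from here

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    core_io.write_fasta(ds.records, outdir / "sequences.fasta")
    core_io.write_species_map(ds.species_info, outdir / "species_map.tsv")
    core_io.write_annotation_table(ds.annotations.values(), outdir / "annotations.tsv")
    with open(outdir / "families.tsv", "w") as fh:
        for fid, members in sorted(ds.families.items()):
            fh.write(f"{fid}\t{','.join(members)}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("family_id\tstatus\tdonor_lineage\ttransfer_node\tduplicated\n")
        for t in ds.truth:
            fh.write(
                f"{t.family_id}\t{t.status}\t{t.donor_lineage or ''}\t"
                f"{t.transfer_node or ''}\t{int(t.duplicated)}\n"
            )
    ds.config.to_yaml(outdir / "config.yaml")


def load_dataset(indir) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    from . import core_io

    indir = Path(indir)
    config = SimulationConfig.from_yaml(indir / "config.yaml")
    species_info = core_io.read_species_map(indir / "species_map.tsv")
    records = core_io.read_fasta(indir / "sequences.fasta", species_info)
    annotations = {a.gene_id: a for a in core_io.read_annotation_table(indir / "annotations.tsv")}
    families: Dict[str, List[str]] = {}
    with open(indir / "families.tsv") as fh:
        for line in fh:
            fid, members = line.rstrip("\n").split("\t")
            families[fid] = members.split(",")
    truth: List[TruthRecord] = []
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        with open(truth_path) as fh:
            next(fh)
            for line in fh:
                fid, status, donor, node, dup = line.rstrip("\n").split("\t")
                truth.append(
                    TruthRecord(fid, status, donor or None, node or None, bool(int(dup)))
                )
    return SyntheticDataset(config, records, dict(species_info), annotations, families, truth)


@dataclass
class EvaluationResult:
    hgt_sensitivity: float
    hgt_specificity: float
    contaminant_precision: float
    contaminant_recall: float
    confusion: Dict[str, Dict[str, int]]


def evaluate_calls(calls: Mapping[str, str], truth: Sequence[TruthRecord]) -> EvaluationResult:
    """Score family-level calls (hgt / vertical / contaminant) against truth.

    The hgt-vs-vertical axis and the contaminant-vs-genuine axis are scored
    separately: contaminant families are excluded from the hgt
    sensitivity/specificity, and vice versa.
    """
    truth_by_id = {t.family_id: t.status for t in truth}
    unknown = set(calls) - set(truth_by_id)
    if unknown:
        raise KeyError(f"calls for unknown families: {sorted(unknown)[:5]}")
    confusion: Dict[str, Dict[str, int]] = {}
    for fid, true_status in truth_by_id.items():
        called = calls.get(fid, "vertical")
        confusion.setdefault(true_status, {}).setdefault(called, 0)
        confusion[true_status][called] += 1

    def count(true_s: str, called_s: str) -> int:
        return confusion.get(true_s, {}).get(called_s, 0)

    n_hgt = sum(confusion.get("hgt", {}).values())
    n_vert = sum(confusion.get("vertical", {}).values())
    n_contam = sum(confusion.get("contaminant", {}).values())
    called_contam = sum(count(t, "contaminant") for t in confusion)
    sens = count("hgt", "hgt") / n_hgt if n_hgt else float("nan")
    spec = (n_vert - count("vertical", "hgt")) / n_vert if n_vert else float("nan")
    prec = count("contaminant", "contaminant") / called_contam if called_contam else float("nan")
    rec = count("contaminant", "contaminant") / n_contam if n_contam else float("nan")
    return EvaluationResult(sens, spec, prec, rec, confusion)
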