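"""Readers/writers for external formats plus loaders for packaged tables.

External formats: protein FASTA (with a sidecar species map TSV), 12-column
tabular homology-hit files (the common BLAST ``outfmt 6`` dialect), per-gene
annotation TSVs, and Newick trees.  The packaged tables are the published
candidate list (22 silkworm genes in 14 transfer-event types), the predicted
donor table, the composition of the 994-genome prokaryote panel, the sizes of
the six eukaryote species sets, and the per-proteome funnel counts.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .records import CANONICAL_AA, GROUPS, AnnotationRecord, HomologyHit, SequenceRecord
from .phylo import GeneTree, read_newick, write_newick  # noqa: F401  (module surface)

_PathLike = Union[str, Path]

_NONCANONICAL = re.compile(f"[^{CANONICAL_AA}X]")

FIXTURE_NAMES = (
    "table2_candidates",
    "table3_donors",
    "panel_composition",
    "species_set_sizes",
    "proteome_sizes",
)

HIT_TABLE_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# FASTA + species map

def read_species_map(path: _PathLike) -> Dict[str, Tuple[str, str]]:
    """Read a 3-column TSV (id, species, group) into id -> (species, group)."""
    out: Dict[str, Tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            seq_id, species, group = parts
            if group not in GROUPS:
                raise ValueError(f"{path}:{lineno}: unknown group {group!r}")
            out[seq_id] = (species, group)
    return out


def write_species_map(mapping: Mapping[str, Tuple[str, str]], path: _PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id, (species, group) in mapping.items():
            fh.write(f"{seq_id}\t{species}\t{group}\n")


def read_fasta(path: _PathLike, species_map: Mapping[str, Tuple[str, str]]) -> List[SequenceRecord]:
    """Read protein FASTA; every id must resolve through ``species_map``.

    Residues are upper-cased and any non-canonical letter is mapped to X.
    """
    records: List[SequenceRecord] = []
    with open(path) as fh:
        for entry in SeqIO.parse(fh, "fasta"):
            if entry.id not in species_map:
                raise KeyError(f"sequence id {entry.id!r} missing from species map")
            species, group = species_map[entry.id]
            residues = _NONCANONICAL.sub("X", str(entry.seq).upper())
            records.append(SequenceRecord(entry.id, species, group, residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: _PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular hits (BLAST outfmt-6 dialect)

def read_hit_table(
    path: _PathLike,
    query_lengths: Optional[Mapping[str, int]] = None,
) -> List[HomologyHit]:
    """Parse a 12-column tab-separated hit table.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Extra columns are ignored with a warning;
    fewer than 12 columns is an error naming the offending line.

    The tabular format does not carry an overlap value.  When
    ``query_lengths`` is given, overlap is reconstructed as the query span
    divided by the query length; otherwise it is set to 100 so that the
    overlap criterion of downstream filters cannot veto externally
    produced hits on missing information.
    """
    hits: List[HomologyHit] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            if len(parts) > 12 and not warned:
                warnings.warn(f"{path}: extra columns beyond 12 ignored", stacklevel=2)
                warned = True
            try:
                pident = float(parts[2])
                length = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from exc
            if query_lengths is not None and parts[0] in query_lengths:
                overlap = min(100.0, 100.0 * (abs(qend - qstart) + 1) / query_lengths[parts[0]])
            else:
                overlap = 100.0
            hits.append(
                HomologyHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    bit_score=bitscore,
                    evalue=evalue,
                    identity_pct=pident,
                    overlap_pct=overlap,
                    aligned_length=length,
                    query_cov_span=(qstart, qend),
                    subject_cov_span=(sstart, send),
                )
            )
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: _PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            mismatches = max(0, round(h.aligned_length * (1 - h.identity_pct / 100.0)))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        h.aligned_length,
                        mismatches,
                        0,
                        h.query_cov_span[0],
                        h.query_cov_span[1],
                        h.subject_cov_span[0],
                        h.subject_cov_span[1],
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation tables

_OPTIONAL_STR = ("probe_id", "chromosome", "scaffold", "strand", "type_group", "annotation", "top_hit_species")


def _parse_annotation_row(row: Mapping[str, object]) -> AnnotationRecord:
    def opt(key, cast=str):
        val = row.get(key)
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            return None
        return cast(val)

    return AnnotationRecord(
        gene_id=str(row["gene_id"]),
        gc=float(row["gc"]),
        intron_count=int(row.get("intron_count", 0) or 0),
        est_count=int(row.get("est_count", 0) or 0),
        cloned=bool(int(row.get("cloned", 0) or 0)),
        probe_id=opt("probe_id"),
        chromosome=opt("chromosome"),
        scaffold=opt("scaffold"),
        start=opt("start", int),
        end=opt("end", int),
        strand=opt("strand"),
        protein_length=int(row.get("protein_length", 1) or 1),
        type_group=opt("type_group"),
        annotation=opt("annotation"),
        microarray=bool(int(row.get("microarray", 0) or 0)),
        top_hit_species=opt("top_hit_species"),
        top_hit_score=opt("top_hit_score", float),
        top_hit_evalue=opt("top_hit_evalue", float),
        top_hit_identity_pct=opt("top_hit_identity_pct", float),
    )


def read_annotation_table(path: _PathLike) -> List[AnnotationRecord]:
    """Read a per-gene annotation TSV into AnnotationRecords."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "probe_id": str})
    return [_parse_annotation_row(row) for row in df.to_dict("records")]


def write_annotation_table(records: Iterable[AnnotationRecord], path: _PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "type_group": r.type_group or "",
                "annotation": r.annotation or "",
                "protein_length": r.protein_length,
                "gc": r.gc,
                "intron_count": r.intron_count,
                "est_count": r.est_count,
                "cloned": int(r.cloned),
                "microarray": int(r.microarray),
                "probe_id": r.probe_id or "",
                "chromosome": r.chromosome or "",
                "scaffold": r.scaffold or "",
                "start": "" if r.start is None else r.start,
                "end": "" if r.end is None else r.end,
                "strand": r.strand or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures

@dataclass(frozen=True)
class PanelComposition:
    """Taxonomic composition of the prokaryote genome panel.

    ``counts`` maps taxon name -> (organisms or None, species); totals are the
    panel-wide organism and species counts.
    """

    total_organisms: int
    total_species: int
    counts: Mapping[str, Tuple[Optional[int], int]]
    ranks: Mapping[str, str]

    def species(self, taxon: str) -> int:
        if taxon not in self.counts:
            raise KeyError(f"unknown taxon {taxon!r} in panel composition")
        return self.counts[taxon][1]

    def organisms(self, taxon: str) -> int:
        if taxon not in self.counts or self.counts[taxon][0] is None:
            raise KeyError(f"no organism count for taxon {taxon!r}")
        return self.counts[taxon][0]


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("hgtsieve") / "data" / filename))


def load_fixture(name: str):
    """Load one of the packaged published tables.

    ``table2_candidates`` -> list of 22 AnnotationRecords in 14 type groups;
    ``table3_donors`` -> DataFrame of 14 donor-evidence rows;
    ``panel_composition`` -> PanelComposition (994 organisms / 680 species);
    ``species_set_sizes`` -> dict set label -> species count;
    ``proteome_sizes`` -> DataFrame of per-proteome funnel counts.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    if name == "table2_candidates":
        df = pd.read_csv(_data_path("table2_candidates.tsv"), sep="\t",
                         dtype={"chromosome": str})
        return [_parse_annotation_row(row) for row in df.to_dict("records")]
    if name == "table3_donors":
        return pd.read_csv(_data_path("table3_donors.tsv"), sep="\t")
    if name == "species_set_sizes":
        df = pd.read_csv(_data_path("species_set_sizes.tsv"), sep="\t")
        return dict(zip(df["set_label"], df["n_species"].astype(int)))
    if name == "proteome_sizes":
        return pd.read_csv(_data_path("proteome_sizes.tsv"), sep="\t")
    df = pd.read_csv(_data_path("panel_composition.tsv"), sep="\t")
    counts: Dict[str, Tuple[Optional[int], int]] = {}
    ranks: Dict[str, str] = {}
    total_org = total_sp = 0
    for row in df.to_dict("records"):
        organisms = None if pd.isna(row["organisms"]) else int(row["organisms"])
        species = int(row["species"])
        if row["rank"] == "total":
            total_org, total_sp = int(row["organisms"]), species
            continue
        counts[str(row["taxon"])] = (organisms, species)
        ranks[str(row["taxon"])] = str(row["rank"])
        if organisms is not None and species > organisms:
            raise ValueError(f"panel fixture corrupt: species > organisms for {row['taxon']}")
    return PanelComposition(total_org, total_sp, counts, ranks)


# ---------------------------------------------------------------------------
# Newick round-trip convenience

def newick_roundtrip(tree_text: str) -> Tuple[GeneTree, str]:
    """Parse Newick text and serialise it back; returns (tree, text)."""
    tree = read_newick(tree_text)
    return tree, write_newick(tree)
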