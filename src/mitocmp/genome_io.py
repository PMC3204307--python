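"""Read/write circular genomes; composition statistics and gene-content tallies.

FASTA and GenBank parsing go through Biopython's SeqIO; this module only adds
the circular-coordinate conventions (0-based half-open, wrap via modulo) and
the tally/statistics logic on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .core import CircularGenome, Feature

__all__ = [
    "GenomeStats",
    "GeneContentTable",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "genome_stats",
    "tally_gene_content",
]


def _round2(x: float) -> float:
    """Round half-up to 2 decimals, matching printed-percentage conventions."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenomeStats:
    length: int
    gc_percent: float
    base_counts: dict


@dataclass(frozen=True)
class GeneContentTable:
    """Per-category gene species/copy counts and lengths (bp).

    "Species" collapses paralogous copies sharing a gene name to one;
    copy counts keep them separate.
    """

    protein_species: int
    protein_copies: int
    rrna_species: int
    rrna_copies: int
    trna_species: int
    trna_copies: int
    protein_exon_length: int
    protein_intron_length: int
    rrna_length: int
    trna_length: int
    total_gene_length: int
    percent_of_genome: float

    @property
    def total_species(self) -> int:
        return self.protein_species + self.rrna_species + self.trna_species

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("protein_species", self.protein_species),
            ("protein_copies", self.protein_copies),
            ("rRNA_species", self.rrna_species),
            ("rRNA_copies", self.rrna_copies),
            ("tRNA_species", self.trna_species),
            ("tRNA_copies", self.trna_copies),
            ("protein_exon_length", self.protein_exon_length),
            ("protein_intron_length", self.protein_intron_length),
            ("rRNA_length", self.rrna_length),
            ("tRNA_length", self.trna_length),
            ("total_gene_length", self.total_gene_length),
            ("percent_of_genome", self.percent_of_genome),
        ]
        return pd.DataFrame(rows, columns=["field", "value"])


def read_fasta(path) -> list[CircularGenome]:
    """Parse a FASTA file into circular genomes, one per record.

    Lowercase input is uppercased; the record id becomes the genome id.
    Raises ``ValueError`` on an empty file or on symbols outside {A,C,G,T,N}
    (the error names the offending symbol and its position).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [CircularGenome(r.id, str(r.seq)) for r in records]


def write_fasta(genomes, path, width: int = 70) -> None:
    """Write genomes as FASTA, sequence wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for g in genomes if isinstance(genomes, (list, tuple)) else [genomes]:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


_GB_KEYS = {"gene", "CDS", "exon", "intron", "rRNA", "tRNA"}


def read_genbank(path) -> CircularGenome:
    """Parse a GenBank flat file into a circular genome with features.

    join() locations become multi-interval features; GenBank's 1-based
    inclusive coordinates arrive from Biopython already converted to 0-based
    half-open.  Locations that wrap the origin (possible on records flagged
    circular) are normalized to a single interval whose end exceeds the
    genome length.
    """
    rec = SeqIO.read(str(path), "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: record has no ORIGIN sequence")
    L = len(rec.seq)
    feats: list[Feature] = []
    for f in rec.features:
        if f.type not in _GB_KEYS:
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", [None])[0]
            or f.qualifiers.get("product", [f.type])[0]
        )
        strand = "-" if f.location.strand == -1 else "+"
        parts = (
            list(f.location.parts)
            if isinstance(f.location, CompoundLocation)
            else [f.location]
        )
        ivs = [(int(p.start), int(p.end), strand) for p in parts]
        for s, e, _ in ivs:
            if e - s > L:
                raise ValueError(f"{path}: feature {name} exceeds sequence length")
        ivs = _merge_origin_wrap(ivs, L)
        feats.append(Feature(key=f.type, name=name, intervals=tuple(ivs)))
    return CircularGenome(rec.id, str(rec.seq), feats, origin_note=f"from {path}")


def _merge_origin_wrap(ivs, L):
    """Collapse a join(x..L, 1..y) pair into one wrapped interval (end > L)."""
    if len(ivs) >= 2:
        merged = []
        i = 0
        while i < len(ivs):
            s, e, st = ivs[i]
            if (
                e == L
                and i + 1 < len(ivs)
                and ivs[i + 1][0] == 0
                and ivs[i + 1][2] == st
            ):
                merged.append((s, L + ivs[i + 1][1], st))
                i += 2
            else:
                merged.append((s, e, st))
                i += 1
        return merged
    return ivs


def genome_stats(g: CircularGenome) -> GenomeStats:
    """Length, base counts and G+C percentage (half-up, 2 decimals).

    N bases are excluded from the GC denominator; an all-N sequence has no
    defined GC content and raises ``ValueError``.
    """
    counts = {b: g.seq.count(b) for b in "ACGTN"}
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        raise ValueError(f"genome {g.id!r}: all-N sequence, GC% undefined")
    gc = _round2(100.0 * (counts["C"] + counts["G"]) / denom)
    return GenomeStats(length=g.length, gc_percent=gc, base_counts=counts)


def _gene_category(name: str, feats: list[Feature]) -> str:
    keys = {f.key for f in feats}
    if "tRNA" in keys:
        return "tRNA"
    if "rRNA" in keys:
        return "rRNA"
    return "protein"


def tally_gene_content(g: CircularGenome) -> GeneContentTable:
    """Gene-content tally: species/copy counts and category lengths.

    Paralogous genes present in more than one copy count once as a species.
    Lengths sum feature intervals per category: protein exon length from
    CDS/exon features (CDS preferred when a gene has both), intron length
    from intron features, rRNA/tRNA lengths from their features.  An
    unannotated genome yields an all-zero table with a warning.
    """
    if not g.annotations:
        warnings.warn(f"genome {g.id!r}: no annotations; tally is all zero")
        return GeneContentTable(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0)

    by_name: dict[str, list[Feature]] = {}
    for f in g.annotations:
        by_name.setdefault(f.name, []).append(f)

    species = {"protein": set(), "rRNA": set(), "tRNA": set()}
    copies = {"protein": 0, "rRNA": 0, "tRNA": 0}
    exon_len = intron_len = 0
    cat_len = {"rRNA": 0, "tRNA": 0}

    for name, feats in by_name.items():
        cat = _gene_category(name, feats)
        species[cat].add(name)
        n_copies = max(
            1, sum(1 for f in feats if f.key in ("gene", "tRNA", "rRNA", "CDS"))
        )
        # a gene annotated with both a gene and a CDS feature is one copy
        keyed = {}
        for f in feats:
            keyed.setdefault(f.key, []).append(f)
        n_copies = max(len(v) for v in keyed.values())
        copies[cat] += n_copies
        if cat == "protein":
            coding = keyed.get("CDS") or keyed.get("exon") or keyed.get("gene") or []
            exon_len += sum(f.length for f in coding)
            intron_len += sum(f.length for f in keyed.get("intron", []))
        else:
            src = keyed.get(cat) or keyed.get("gene") or []
            cat_len[cat] += sum(f.length for f in src)

    total = exon_len + intron_len + cat_len["rRNA"] + cat_len["tRNA"]
    return GeneContentTable(
        protein_species=len(species["protein"]),
        protein_copies=copies["protein"],
        rrna_species=len(species["rRNA"]),
        rrna_copies=copies["rRNA"],
        trna_species=len(species["tRNA"]),
        trna_copies=copies["tRNA"],
        protein_exon_length=exon_len,
        protein_intron_length=intron_len,
        rrna_length=cat_len["rRNA"],
        trna_length=cat_len["tRNA"],
        total_gene_length=total,
        percent_of_genome=_round2(100.0 * total / g.length),
    )
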