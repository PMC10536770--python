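"""File formats and sequence utilities.

Covers FASTA, newick, the tab-separated gene-locus table, and an optional
GFF3 export, plus CDS translation and exon-structure helpers.

Coordinates are 0-based half-open in memory and 1-based inclusive on disk
(GFF convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .tree import Node, parse_newick

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


@dataclass
class SequenceRecord:
    """A named sequence (nucleotide or protein)."""

    id: str
    seq: str
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SequenceRecord {self.id!r} has an empty sequence")


@dataclass
class GeneLocus:
    """A gene copy anchored to genomic coordinates.

    ``start``/``end`` and exon segments are 0-based half-open.  ``exons``
    hold the CDS segments in genomic order; ``cds`` is the spliced coding
    sequence (already reverse-complemented for minus-strand genes).
    """

    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.gene_id!r}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"locus {self.gene_id!r}: empty exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"locus {self.gene_id!r}: exon ({s}, {e}) outside locus")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"locus {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = e
        if self.cds:
            if len(self.cds) % 3 != 0:
                raise ValueError(
                    f"locus {self.gene_id!r}: CDS length {len(self.cds)} not a multiple of 3"
                )
            if self.exons and len(self.cds) != sum(e - s for s, e in self.exons):
                raise ValueError(
                    f"locus {self.gene_id!r}: CDS length does not match total exon length"
                )


def exon_count(locus: GeneLocus) -> int:
    """Number of CDS segments of ``locus``."""
    if not locus.exons:
        raise ValueError(f"locus {locus.gene_id!r} has no exon annotation")
    return len(locus.exons)


# ----------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else ""
            if rid in seen:
                raise ValueError(f"duplicate FASTA id: {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq.upper(), alphabet))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, line_width: int = 60
) -> None:
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty FASTA file")
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id!r}")
            seen.add(rec.id)
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


# ----------------------------------------------------------------------
# Translation

def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard genetic code.

    A single terminal stop codon is stripped silently; an internal stop is
    an error (pseudogene handling is out of scope).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    n_codons = len(cds) // 3
    protein = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        try:
            protein.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"unrecognised codon {codon!r} at codon index {i}") from None
    return "".join(protein)


# ----------------------------------------------------------------------
# Newick

def read_newick(path: str | os.PathLike) -> Node:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(
    tree: Node, path: str | os.PathLike, with_support: bool = True, with_classes: bool = False
) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(with_support=with_support, with_classes=with_classes) + "\n")


# ----------------------------------------------------------------------
# Loci table (TSV, 1-based inclusive on disk)

LOCI_COLUMNS = ["gene_id", "species", "scaffold", "start", "end", "strand", "exons", "cds"]


def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_disk(start: int, end: int) -> tuple[int, int]:
    """Convert 0-based half-open coordinates to 1-based inclusive."""
    return start + 1, end


def read_loci_table(path: str | os.PathLike) -> list[GeneLocus]:
    loci: list[GeneLocus] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = LOCI_COLUMNS[:7]
        if header[: len(required)] != required:
            raise ValueError(f"{path}: unexpected loci-table header {header!r}")
        has_cds = len(header) > 7 and header[7] == "cds"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                gene_id, species, scaffold, start_s, end_s, strand = fields[:6]
                exons_s = fields[6] if len(fields) > 6 else ""
                cds = fields[7] if has_cds and len(fields) > 7 else ""
                start1, end1 = int(start_s), int(end_s)
                if start1 > end1:
                    raise ValueError(f"start ({start1}) > end ({end1})")
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                exons = []
                if exons_s:
                    for chunk in exons_s.split(";"):
                        a, b = chunk.split("-")
                        s0, e0 = to_internal(int(a), int(b))
                        exons.append((s0, e0))
                s0, e0 = to_internal(start1, end1)
                loci.append(GeneLocus(gene_id, species, scaffold, s0, e0, strand, exons, cds))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return loci


def write_loci_table(loci: Iterable[GeneLocus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LOCI_COLUMNS) + "\n")
        for loc in loci:
            s1, e1 = to_disk(loc.start, loc.end)
            exons_s = ";".join(
                f"{a}-{b}" for a, b in (to_disk(s, e) for s, e in loc.exons)
            )
            fh.write(
                "\t".join(
                    [loc.gene_id, loc.species, loc.scaffold, str(s1), str(e1), loc.strand,
                     exons_s, loc.cds]
                )
                + "\n"
            )


def write_gff3(loci: Iterable[GeneLocus], path: str | os.PathLike) -> None:
    """Export loci as GFF3 with gene and CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            s1, e1 = to_disk(loc.start, loc.end)
            fh.write(
                f"{loc.scaffold}\tgenefam\tgene\t{s1}\t{e1}\t.\t{loc.strand}\t."
                f"\tID={loc.gene_id};species={loc.species}\n"
            )
            for i, (s, e) in enumerate(loc.exons, start=1):
                cs, ce = to_disk(s, e)
                fh.write(
                    f"{loc.scaffold}\tgenefam\tCDS\t{cs}\t{ce}\t.\t{loc.strand}\t0"
                    f"\tID={loc.gene_id}.cds{i};Parent={loc.gene_id}\n"
                )
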