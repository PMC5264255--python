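"""Readers and writers for the file formats the pipeline touches.

FASTA goes through Biopython, SAM through pysam. The assembly graph is
serialized as GFA1 and variant calls as VCF 4.2 plus a per-bubble TSV
summary. Coordinates are 0-based half-open internally and only become
1-based at the VCF/GFA boundary.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N passes through)."""
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class SequenceRecord:
    """One FASTA record: uppercase DNA over {A,C,G,T,N}."""

    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ParseError("sequence record with empty id")
        if len(self.sequence) < 1:
            raise ParseError(f"record {self.id!r} has empty sequence")


@dataclass
class PairedAlignment:
    """Both mates of a read pair placed on (possibly different) contigs.

    Positions are 0-based leftmost coordinates; orientations are '+'/'-'.
    """

    pair_id: str
    contig_a: str
    pos_a: int
    orient_a: str
    contig_b: str
    pos_b: int
    orient_b: str
    aligned_len_a: int
    aligned_len_b: int

    def __post_init__(self):
        if self.pos_a < 0 or self.pos_b < 0:
            raise ParseError(f"pair {self.pair_id}: negative position")
        if self.aligned_len_a < 1 or self.aligned_len_b < 1:
            raise ParseError(f"pair {self.pair_id}: aligned length < 1")


@dataclass
class VariantRecord:
    """One called variant site derived from a bubble on a scaffold."""

    scaffold_id: str
    position: int  # 1-based on the recovered scaffold
    ref_allele: str
    alt_alleles: list
    allele_depths: list
    abundances: list
    bubble_id: str

    def __post_init__(self):
        if not self.alt_alleles:
            raise ParseError(f"variant at {self.scaffold_id}:{self.position} has no ALT")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ParseError(
                f"variant at {self.scaffold_id}:{self.position}: abundances do not sum to 1"
            )


def parse_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (lowercase is uppercased)."""
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            # find the offending line number for the error message
            fh.seek(0)
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    raise ParseError(f"{path}: line {lineno}: expected FASTA header '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(
                SequenceRecord(rec.id, rec.description, str(rec.seq).upper())
            )
    return records


def write_fasta(records, path, width: int = 80) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


_TSV_HEADER = [
    "pair_id", "contig_a", "pos_a", "orient_a",
    "contig_b", "pos_b", "orient_b", "aligned_len_a", "aligned_len_b",
]


def _parse_tsv_alignments(path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "pair_id":
                continue
            if len(parts) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            out.append(
                PairedAlignment(
                    parts[0], parts[1], int(parts[2]), parts[3],
                    parts[4], int(parts[5]), parts[6], int(parts[7]), int(parts[8]),
                )
            )
    return out


def write_tsv_alignments(alignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for a in alignments:
            fh.write(
                f"{a.pair_id}\t{a.contig_a}\t{a.pos_a}\t{a.orient_a}\t"
                f"{a.contig_b}\t{a.pos_b}\t{a.orient_b}\t{a.aligned_len_a}\t{a.aligned_len_b}\n"
            )


def _parse_sam_alignments(path):
    # Only primary, mapped, properly-recorded mates are used. Mates are joined
    # by query name; a pair is emitted once both mapped mates are seen.
    pending: dict[str, object] = {}
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                pending.pop(rec.query_name, None) if rec.is_unmapped else None
                continue
            if rec.mate_is_unmapped:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            a, b = (mate, rec) if mate.is_read1 else (rec, mate)
            out.append(
                PairedAlignment(
                    a.query_name,
                    a.reference_name, a.reference_start, "-" if a.is_reverse else "+",
                    b.reference_name, b.reference_start, "-" if b.is_reverse else "+",
                    a.reference_length or a.query_length,
                    b.reference_length or b.query_length,
                )
            )
    return out


def parse_paired_alignments(path, dialect: str) -> list[PairedAlignment]:
    """Read paired alignments from a SAM subset or the simulator's TSV."""
    if dialect == "tsv":
        return _parse_tsv_alignments(path)
    if dialect == "sam":
        return _parse_sam_alignments(path)
    raise ConfigError(f"unknown alignment dialect {dialect!r} (expected 'sam' or 'tsv')")


# --------------------------------------------------------------------------
# GFA1


def emit_gfa(graph, path) -> None:
    """Serialize a contig graph as GFA1.

    S-lines carry the sequence and a dp:f depth tag; L-lines carry
    orientations with the overlap length as cigar '<n>M'.
    """
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for cid in sorted(graph.contigs):
            c = graph.contigs[cid]
            fh.write(f"S\t{cid}\t{c.sequence}\tdp:f:{c.depth:.4f}\n")
        for e in sorted(graph.edges, key=lambda e: (e.from_id, e.to_id, e.from_orient, e.to_orient)):
            fh.write(
                f"L\t{e.from_id}\t{e.from_orient}\t{e.to_id}\t{e.to_orient}\t{e.overlap_len}M\n"
            )


def parse_gfa(path):
    """Parse a GFA1 file written by :func:`emit_gfa` back into a graph."""
    from .graph import Contig, ContigConnectionGraph, OverlapEdge

    contigs = {}
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                depth = 0.0
                for tag in parts[3:]:
                    if tag.startswith("dp:f:"):
                        depth = float(tag[5:])
                contigs[parts[1]] = Contig(parts[1], parts[2], depth=depth)
            elif parts[0] == "L":
                if len(parts) < 6 or not parts[5].endswith("M"):
                    raise ParseError(f"{path}: line {lineno}: bad L-line")
                edges.append(
                    OverlapEdge(parts[1], parts[2], parts[3], parts[4], int(parts[5][:-1]))
                )
    g = ContigConnectionGraph(contigs)
    for e in edges:
        g.add_edge(e)
    return g


# --------------------------------------------------------------------------
# VCF 4.2 + bubble TSV

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=minimeta
##INFO=<ID=AD,Number=R,Type=Float,Description="Allele depths (fold coverage)">
##INFO=<ID=AF,Number=R,Type=Float,Description="Estimated variant abundances">
##INFO=<ID=BUBBLE,Number=1,Type=String,Description="Bubble id the site derives from">
"""
_VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def emit_variants(records, vcf_path, tsv_path=None) -> None:
    """Write VariantRecords as VCF 4.2 (+ optional per-bubble TSV summary).

    Records must already be sorted by (scaffold, position).
    """
    keys = [(r.scaffold_id, r.position) for r in records]
    if keys != sorted(keys):
        raise ParseError("variant records must be sorted by (scaffold, position)")
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for scaffold in sorted({r.scaffold_id for r in records}):
            fh.write(f"##contig=<ID={scaffold}>\n")
        fh.write(_VCF_COLUMNS)
        for r in records:
            ad = ",".join(f"{d:.2f}" for d in r.allele_depths)
            af = ",".join(f"{a:.4f}" for a in r.abundances)
            alt = ",".join(r.alt_alleles)
            fh.write(
                f"{r.scaffold_id}\t{r.position}\t{r.bubble_id}\t{r.ref_allele}\t{alt}\t"
                f".\tPASS\tAD={ad};AF={af};BUBBLE={r.bubble_id}\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("bubble_id\tscaffold_id\tposition\tn_alleles\tabundances\talpha_diversity\n")
            from .variation import alpha_diversity

            for r in records:
                fh.write(
                    f"{r.bubble_id}\t{r.scaffold_id}\t{r.position}\t"
                    f"{1 + len(r.alt_alleles)}\t"
                    f"{','.join(f'{a:.4f}' for a in r.abundances)}\t"
                    f"{alpha_diversity(r.abundances):.4f}\n"
                )


# --------------------------------------------------------------------------
# Simple TSV tables


def write_depth_tsv(depths: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tdepth\n")
        for cid in sorted(depths):
            fh.write(f"{cid}\t{depths[cid]:.4f}\n")


def read_depth_tsv(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts[0] or parts[0] == "contig":
                continue
            out[parts[0]] = float(parts[1])
    return out


def write_scaffold_tsv(scaffolds, path) -> None:
    """AGP-like layout: scaffold, part order, contig, orientation, gap after."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tpart\tcontig\torientation\tgap_after\n")
        for s in scaffolds:
            for i, (cid, orient) in enumerate(s.parts):
                gap = s.gaps[i] if i < len(s.gaps) else 0
                fh.write(f"{s.id}\t{i}\t{cid}\t{orient}\t{gap}\n")


def write_bins_tsv(bins, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tbin\tprovenance\n")
        for b in bins:
            for cid in sorted(b.member_contig_ids):
                fh.write(f"{cid}\t{b.bin_id}\t{b.provenance}\n")
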