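"""Per-read alignment model and intron-retention calls.

A long cDNA read is reduced to its ordered aligned blocks and its splice
gaps, both derived from the CIGAR. Reference skips (``N``) are splice gaps;
deletions (``D``) interrupt a block but are never treated as splicing —
ONT aligners encode short indel noise as ``D`` and genuine introns as ``N``.

Against one intron a read is then one of:

``SPLICED``   a splice gap matches the intron boundaries (within tolerance);
``RETAINED``  the read covers the intron interior nearly completely, with
              no splice gap inside it, and aligns into both flanking exons;
``PARTIAL``   anything else (truncated reads, edge overlaps, messy ends).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import pysam

from .annotations import IntronRecord
from .intervals import GenomicInterval

DEFAULT_MAPQ_MIN = 10
DEFAULT_JUNCTION_TOL = 5
DEFAULT_MIN_INTERIOR_COV = 0.9

INTRON_STATUSES = ("RETAINED", "SPLICED", "PARTIAL")

# CIGAR op codes (pysam numeric): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_REF_BLOCK_OPS = {0, 7, 8}


@dataclass
class ReadAlignment:
    """One aligned read as blocks (aligned segments) and splice gaps."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[GenomicInterval]
    gaps: list[GenomicInterval]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    def aligned_overlap(self, interval: GenomicInterval) -> int:
        """Total aligned bases falling inside *interval*."""
        return sum(b.overlap_len(interval) for b in self.blocks)

    def five_prime_end(self) -> int:
        """Genomic coordinate of the read 5' end, transcript orientation."""
        return self.blocks[0].start if self.strand == "+" else self.blocks[-1].end - 1


@dataclass
class IntronCall:
    read_id: str
    gene_id: str
    intron: IntronRecord
    status: str


def blocks_and_gaps(
    cigartuples: list[tuple[int, int]], reference_start: int, chrom: str, strand: str
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Resolve CIGAR into aligned blocks and splice (N) gaps.

    Deletions split the current block without recording a gap; insertions
    and clips do not consume reference.
    """
    blocks: list[GenomicInterval] = []
    gaps: list[GenomicInterval] = []
    pos = reference_start
    block_start: Optional[int] = None
    for op, length in cigartuples:
        if op in _REF_BLOCK_OPS:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == 2:  # D: consumes reference, closes the block, no gap
            if block_start is not None:
                blocks.append(GenomicInterval(chrom, block_start, pos, strand))
                block_start = None
            pos += length
        elif op == 3:  # N: splice gap
            if block_start is not None:
                blocks.append(GenomicInterval(chrom, block_start, pos, strand))
                block_start = None
            gaps.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length
        # I (1), S (4), H (5), P (6): no reference consumed
    if block_start is not None:
        blocks.append(GenomicInterval(chrom, block_start, pos, strand))
    return blocks, gaps


def alignment_from_pysam(rec: pysam.AlignedSegment) -> ReadAlignment:
    strand = "-" if rec.is_reverse else "+"
    blocks, gaps = blocks_and_gaps(
        rec.cigartuples, rec.reference_start, rec.reference_name, strand
    )
    return ReadAlignment(rec.query_name, rec.reference_name, strand, blocks, gaps)


def extract_reads(
    bam_path: str | Path,
    locus: GenomicInterval,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> Iterator[ReadAlignment]:
    """Yield every primary alignment overlapping *locus*.

    Secondary and supplementary alignments are excluded, as are reads below
    ``mapq_min`` (suppresses multi-mapped host-gene paralogs). A missing
    BAM index is reported with remediation advice.
    """
    path = Path(bam_path)
    try:
        bam = pysam.AlignmentFile(str(path), "rb")
    except FileNotFoundError:
        raise FileNotFoundError(f"alignment file not found: {path}")
    with bam:
        if not bam.has_index():
            raise OSError(
                f"{path} has no index; run `samtools index {path}` first"
            )
        try:
            fetched = bam.fetch(locus.chrom, locus.start, locus.end)
        except ValueError:
            return  # contig absent from the header: no reads there
        for rec in fetched:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            yield alignment_from_pysam(rec)


def call_intron(
    read: ReadAlignment,
    intron: IntronRecord,
    min_interior_cov: float = DEFAULT_MIN_INTERIOR_COV,
    junction_tol: int = DEFAULT_JUNCTION_TOL,
) -> IntronCall:
    """Classify one read against one intron (RETAINED / SPLICED / PARTIAL).

    SPLICED requires a splice gap whose boundaries both fall within
    ``junction_tol`` nt of the intron boundaries (long-read aligners wobble
    at splice sites). RETAINED requires aligned coverage of at least
    ``min_interior_cov`` of the intron length, no splice gap inside the
    intron, and aligned bases in both flanking regions.
    """
    iv = intron.interval
    if not read.span.overlaps(iv):
        raise ValueError(
            f"read {read.read_id} does not overlap intron "
            f"{iv.chrom}:{iv.start}-{iv.end}"
        )
    status = "PARTIAL"
    spliced = any(
        abs(g.start - iv.start) <= junction_tol and abs(g.end - iv.end) <= junction_tol
        for g in read.gaps
    )
    if spliced:
        status = "SPLICED"
    else:
        interior_cov = read.aligned_overlap(iv) / iv.length
        gap_inside = any(g.overlaps(iv) for g in read.gaps)
        left_flank = any(b.start < iv.start for b in read.blocks)
        right_flank = any(b.end > iv.end for b in read.blocks)
        if (
            interior_cov >= min_interior_cov
            and not gap_inside
            and left_flank
            and right_flank
        ):
            status = "RETAINED"
    return IntronCall(read.read_id, intron.gene_id, intron, status)


def write_intron_calls(calls: list[IntronCall], path: str | Path) -> None:
    """Export per-read intron calls to a BED-like TSV."""
    with open(path, "w") as out:
        out.write("# snortools intron calls schema v1\n")
        out.write("chrom\tstart\tend\tread_id\tgene_id\tsnorna_id\tstatus\tstrand\n")
        for c in calls:
            iv = c.intron.interval
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.read_id}\t{c.gene_id}\t"
                f"{c.intron.snorna_id or '.'}\t{c.status}\t{iv.strand}\n"
            )
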