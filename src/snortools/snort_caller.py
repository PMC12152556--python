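"""Per-read snoRT calling and per-gene quantification.

A snoRT (snoRNA-retaining transcript) read must (i) cover the snoRNA
interval with its aligned blocks and (ii) extend into exonic sequence
downstream (transcript orientation) of the snoRNA-containing intron — a
3'-snoRT is a processed polyadenylated fragment running toward the
transcript 3' end, so a mature-snoRNA-only fragment does not qualify.

Classification of qualifying reads uses the 5' upstream extent: the number
of nucleotides the read 5' end reaches upstream of the snoRNA 5' start, in
transcript orientation. Reads spanning more than ``threshold_T`` (default
10) nucleotides upstream are full-length snoRTs (FL); reads spanning
``threshold_T`` or fewer are 3'-snoRTs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .annotations import HostGeneModel, SnoRNARecord
from .read_model import ReadAlignment

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_T = 10
DEFAULT_MIN_COV = 0.9

FORMS = ("FL", "THREE_PRIME", "NOT_SNORT")


@dataclass
class SnortCall:
    """Verdict for one read against one snoRNA of its host gene."""

    read_id: str
    snorna_id: str
    gene_id: str
    contains_snorna: bool
    snorna_coverage: float
    five_prime_offset: Optional[int]  # read 5' end minus snoRNA 5' start
    upstream_extent: int
    has_downstream_exon: bool
    form: str
    flags: set[str] = field(default_factory=set)


@dataclass
class GeneQuant:
    """FL / 3'-snoRT counts and relative abundances for one host gene."""

    gene_id: str
    snorna_id: str
    n_fl: int
    n_three_prime: int
    n_total_gene: int
    rel_fl: float
    rel_three_prime: float
    display: bool  # passes the >=1%-of-host-gene-expression display filter


@dataclass
class CutpointSummary:
    """Distribution of 3'-snoRT 5'-end offsets for one snoRNA box class."""

    box_class: str
    n: int
    median: float
    q1: float
    q3: float
    histogram: dict[int, int]


def check_snorna_containment(
    read: ReadAlignment, snorna: SnoRNARecord, min_cov: float = DEFAULT_MIN_COV
) -> tuple[bool, float]:
    """Fraction of the snoRNA interval covered by the read's aligned blocks.

    A read whose splice gap removes the snoRNA along with its intron scores
    zero: only aligned blocks count.
    """
    coverage = read.aligned_overlap(snorna.interval) / snorna.interval.length
    return coverage >= min_cov, coverage


def sequence_identity_check(
    read_seq: str,
    snorna_seq: str,
    min_identity: float = 0.8,
    min_span: float = 0.9,
) -> bool:
    """Optional re-verification of containment on the basecalled sequence.

    Locally aligns the snoRNA reference sequence inside the read sequence
    and requires ``min_identity`` identity over ``min_span`` of the snoRNA
    length; useful when coordinates are trusted less than basecalls.
    """
    import edlib

    need = int(np.ceil(min_span * len(snorna_seq)))
    res = edlib.align(snorna_seq.upper(), read_seq.upper(), mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return False
    start, end = res["locations"][0]
    span = end - start + 1
    identity = 1.0 - res["editDistance"] / len(snorna_seq)
    return span >= need and identity >= min_identity


def five_prime_offset(read: ReadAlignment, snorna: SnoRNARecord) -> int:
    """Signed distance from the read 5' end to the snoRNA 5' start.

    Negative means the read 5' end lies upstream (transcript orientation)
    of the snoRNA start. On '+' this is ``read_start - snorna_start``; on
    '-' the arithmetic is mirrored.
    """
    if read.chrom != snorna.interval.chrom:
        raise ValueError("read and snoRNA on different chromosomes")
    if snorna.interval.strand == "+":
        return read.blocks[0].start - snorna.interval.start
    return (snorna.interval.end - 1) - (read.blocks[-1].end - 1)


def classify_form(upstream_extent: int, threshold_t: int = DEFAULT_THRESHOLD_T) -> str:
    """FL when the read spans more than ``threshold_t`` nt upstream of the
    snoRNA start; 3'-snoRT at ``threshold_t`` nt or fewer."""
    return "FL" if upstream_extent > threshold_t else "THREE_PRIME"


def call_snort(
    read: ReadAlignment,
    gene: HostGeneModel,
    snorna: SnoRNARecord,
    threshold_t: int = DEFAULT_THRESHOLD_T,
    min_cov: float = DEFAULT_MIN_COV,
    require_downstream_exon: bool = True,
) -> SnortCall:
    """Full per-read verdict for one (gene, snoRNA) pair.

    Reads on the opposite strand from the host gene are excluded from
    classification (flagged STRAND_MISMATCH, form NOT_SNORT).
    """
    flags: set[str] = set()
    contains, coverage = check_snorna_containment(read, snorna, min_cov)
    intron = gene.snorna_intron(snorna.snorna_id)

    if read.strand != gene.strand:
        flags.add("STRAND_MISMATCH")
        return SnortCall(
            read.read_id, snorna.snorna_id, gene.gene_id, contains, coverage,
            None, 0, False, "NOT_SNORT", flags,
        )

    down = _downstream_region(gene, intron)
    has_downstream = down is not None and read.aligned_overlap(down) > 0
    if not require_downstream_exon:
        has_downstream = True

    offset = five_prime_offset(read, snorna)
    upstream_extent = max(0, -offset)

    if not contains or not has_downstream:
        form = "NOT_SNORT"
    else:
        form = classify_form(upstream_extent, threshold_t)
        if form == "THREE_PRIME" and offset > 0.5 * snorna.interval.length:
            flags.add("LOW_CONFIDENCE")  # 5' end deep inside the snoRNA body
    return SnortCall(
        read.read_id, snorna.snorna_id, gene.gene_id, contains, coverage,
        offset, upstream_extent, has_downstream, form, flags,
    )


def _downstream_region(gene, intron):
    """Gene region downstream (transcript orientation) of the snoRNA intron,
    or None when the intron abuts the transcript 3' end."""
    from .intervals import GenomicInterval

    if gene.strand == "+":
        start, end = intron.interval.end, gene.span.end
    else:
        start, end = gene.span.start, intron.interval.start
    if start >= end:
        return None
    return GenomicInterval(gene.span.chrom, start, end)


def quantify_gene(
    calls: Iterable[SnortCall], all_gene_reads: int, display_min: float = 0.01
) -> GeneQuant:
    """Aggregate calls of one (gene, snoRNA) pair into relative abundances.

    ``all_gene_reads`` is the total read count assigned to the host gene;
    the display flag marks genes where either form reaches ``display_min``
    of total host-gene expression. Reads with duplicate ids are counted
    once per (gene, snoRNA) pair.
    """
    seen: dict[str, SnortCall] = {}
    gene_id = snorna_id = ""
    for c in calls:
        gene_id, snorna_id = c.gene_id, c.snorna_id
        seen.setdefault(c.read_id, c)
    n_fl = sum(1 for c in seen.values() if c.form == "FL")
    n_3p = sum(1 for c in seen.values() if c.form == "THREE_PRIME")
    if all_gene_reads > 0:
        rel_fl = n_fl / all_gene_reads
        rel_3p = n_3p / all_gene_reads
        display = max(rel_fl, rel_3p) >= display_min
    else:
        rel_fl = rel_3p = 0.0
        display = False
    return GeneQuant(gene_id, snorna_id, n_fl, n_3p, all_gene_reads, rel_fl, rel_3p, display)


def cutpoint_distribution(
    calls: Iterable[SnortCall], box_class_of: Mapping[str, str]
) -> dict[str, CutpointSummary]:
    """Summarize 3'-snoRT 5'-end offsets per snoRNA box class.

    Returns median, quartiles and a per-offset histogram of the signed 5'
    offsets of THREE_PRIME calls, keyed by box class; classes with no
    observations are omitted with a logged notice.
    """
    offsets: dict[str, list[int]] = {}
    for c in calls:
        if c.form != "THREE_PRIME" or c.five_prime_offset is None:
            continue
        cls = box_class_of[c.snorna_id]
        offsets.setdefault(cls, []).append(c.five_prime_offset)

    out: dict[str, CutpointSummary] = {}
    for cls in ("CD", "HACA"):
        vals = offsets.get(cls)
        if not vals:
            logger.info("no 3'-snoRT calls for box class %s; omitted", cls)
            continue
        arr = np.asarray(vals)
        hist: dict[int, int] = {}
        for v in sorted(vals):
            hist[v] = hist.get(v, 0) + 1
        out[cls] = CutpointSummary(
            box_class=cls,
            n=len(vals),
            median=float(np.median(arr)),
            q1=float(np.percentile(arr, 25)),
            q3=float(np.percentile(arr, 75)),
            histogram=hist,
        )
    return out


def write_snort_calls(calls: Iterable[SnortCall], path: str | Path) -> None:
    """Per-read call TSV: one row per (read, gene, snoRNA)."""
    with open(path, "w") as out:
        out.write("# snortools snoRT calls schema v1\n")
        out.write(
            "read_id\tgene_id\tsnorna_id\tcontains_snorna\tsnorna_coverage\t"
            "five_prime_offset\tupstream_extent\thas_downstream_exon\tform\tflags\n"
        )
        for c in calls:
            out.write(
                f"{c.read_id}\t{c.gene_id}\t{c.snorna_id}\t"
                f"{str(c.contains_snorna).lower()}\t{c.snorna_coverage:.4f}\t"
                f"{'.' if c.five_prime_offset is None else c.five_prime_offset}\t"
                f"{c.upstream_extent}\t{str(c.has_downstream_exon).lower()}\t"
                f"{c.form}\t{','.join(sorted(c.flags)) or '.'}\n"
            )


def write_gene_quant(quants: Iterable[GeneQuant], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("# snortools gene quantification schema v1\n")
        out.write(
            "gene_id\tsnorna_id\tn_fl\tn_three_prime\tn_total_gene\t"
            "rel_fl\trel_three_prime\tdisplay\n"
        )
        for q in quants:
            out.write(
                f"{q.gene_id}\t{q.snorna_id}\t{q.n_fl}\t{q.n_three_prime}\t"
                f"{q.n_total_gene}\t{q.rel_fl:.6f}\t{q.rel_three_prime:.6f}\t"
                f"{str(q.display).lower()}\n"
            )


def write_cutpoints(summaries: Mapping[str, CutpointSummary], path: str | Path) -> None:
    """Histogram TSV: one row per (box class, offset)."""
    with open(path, "w") as out:
        out.write("# snortools 3'-snoRT cut-point histogram schema v1\n")
        out.write("box_class\toffset\tcount\tn\tmedian\tq1\tq3\n")
        for cls, s in sorted(summaries.items()):
            for offset, count in sorted(s.histogram.items()):
                out.write(
                    f"{cls}\t{offset}\t{count}\t{s.n}\t{s.median}\t{s.q1}\t{s.q3}\n"
                )
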