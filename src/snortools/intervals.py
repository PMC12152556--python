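"""Strand-aware genomic intervals.

All coordinates inside the package are 0-based, half-open ``[start, end)``,
the convention of BED and of pysam. GFF3 (1-based, inclusive) and the
snoRNA TSV (1-based, inclusive) are converted at the parsing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware coordinate span on one reference sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``start < end`` always
    (empty intervals are not representable, by design).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this span (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if disjoint or other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end in transcript orientation.

        On '+' this is ``start``; on '-' it is ``end - 1`` (the last base).
        """
        return self.start if self.strand == "+" else self.end - 1
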