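"""Host-gene annotation model.

Loads a GFF3 gene annotation plus a snoRNA table (TSV, 1-based inclusive
coordinates) into queryable :class:`HostGeneModel` objects, derives introns
as the gaps between consecutive exons of each transcript, assigns every
snoRNA to its containing intron, and classifies each host gene into one of
three structural categories:

``CDS_INTERNAL``
    the snoRNA-containing intron sits between two translated exons of at
    least one coding transcript (the configuration in which 5' cut points
    of truncated isoforms are cleanly measurable);
``UTR``
    the intron lies in untranslated exonic context of every coding
    transcript that contains it;
``NONCODING``
    no transcript of the gene is coding (e.g. SNHG-type host genes);
``UNRESOLVED``
    the transcripts disagree in a way the rules above cannot reconcile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import gffutils

from .intervals import GenomicInterval

CATEGORIES = ("CDS_INTERNAL", "UTR", "NONCODING", "UNRESOLVED")

SNORNA_TSV_COLUMNS = [
    "snorna_id",
    "host_gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "box_class",
    "canonical",
]


class AnnotationError(ValueError):
    """Raised when the annotation or snoRNA table violates the data contract."""


@dataclass
class TranscriptModel:
    """One transcript: exons in transcript 5'->3' order, optional CDS."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: Optional[list[GenomicInterval]] = None

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def exons_genomic(self) -> list[GenomicInterval]:
        """Exons sorted by ascending genomic coordinate."""
        return sorted(self.exons, key=lambda e: e.start)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, ascending genomic order."""
        ex = self.exons_genomic()
        out = []
        for a, b in zip(ex, ex[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out


@dataclass
class IntronRecord:
    """One intron of a host gene; the unit of retention-frequency analysis."""

    gene_id: str
    interval: GenomicInterval
    hosts_snorna: bool = False
    snorna_id: Optional[str] = None
    # True when this span is intronic in one transcript but exonic in another
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.hosts_snorna != (self.snorna_id is not None):
            raise ValueError("hosts_snorna must match presence of snorna_id")


@dataclass
class SnoRNARecord:
    """One snoRNA with its host assignment and functional class.

    ``canonical`` marks snoRNAs with at least one annotated RNA
    modification target; it is taken verbatim from the input table.
    """

    snorna_id: str
    host_gene_id: str
    interval: GenomicInterval
    box_class: str  # "CD" or "HACA"
    canonical: bool

    def __post_init__(self) -> None:
        if self.box_class not in ("CD", "HACA"):
            raise ValueError(f"box_class must be CD or HACA, got {self.box_class!r}")


@dataclass
class HostGeneModel:
    """A snoRNA host gene with transcripts, introns and embedded snoRNAs."""

    gene_id: str
    span: GenomicInterval
    transcripts: list[TranscriptModel]
    introns: list[IntronRecord] = field(default_factory=list)
    snornas: list[SnoRNARecord] = field(default_factory=list)
    category: str = "UNRESOLVED"

    @property
    def strand(self) -> str:
        return self.span.strand

    def snorna_intron(self, snorna_id: str) -> IntronRecord:
        for intron in self.introns:
            if intron.snorna_id == snorna_id:
                return intron
        raise KeyError(f"no intron hosts snoRNA {snorna_id!r} in {self.gene_id}")


def _derive_introns(gene_id: str, transcripts: list[TranscriptModel]) -> list[IntronRecord]:
    """Union of per-transcript introns, deduplicated by exact coordinates.

    A span intronic in one transcript but overlapping an exon of another is
    kept and flagged ``ambiguous``.
    """
    seen: dict[tuple[int, int], GenomicInterval] = {}
    for tx in transcripts:
        for iv in tx.introns():
            seen.setdefault((iv.start, iv.end), iv)
    all_exons = [e for tx in transcripts for e in tx.exons]
    records = []
    for key in sorted(seen):
        iv = seen[key]
        ambiguous = any(iv.overlaps(e) for e in all_exons)
        records.append(IntronRecord(gene_id, iv, ambiguous=ambiguous))
    return records


def _assign_snornas(gene: HostGeneModel, snornas: Iterable[SnoRNARecord]) -> None:
    for sno in snornas:
        host_introns = [i for i in gene.introns if i.interval.contains(sno.interval)]
        if not host_introns:
            raise AnnotationError(
                f"snoRNA {sno.snorna_id} at {sno.interval.chrom}:"
                f"{sno.interval.start}-{sno.interval.end} is not contained in any "
                f"intron of its declared host gene {gene.gene_id}"
            )
        # smallest containing intron wins when nested alternatives exist
        intron = min(host_introns, key=lambda i: i.interval.length)
        if intron.hosts_snorna and intron.snorna_id != sno.snorna_id:
            raise AnnotationError(
                f"intron {intron.interval.start}-{intron.interval.end} of "
                f"{gene.gene_id} would host two snoRNAs "
                f"({intron.snorna_id}, {sno.snorna_id})"
            )
        intron.hosts_snorna = True
        intron.snorna_id = sno.snorna_id
        gene.snornas.append(sno)


def classify_host_gene(gene: HostGeneModel) -> str:
    """Assign the structural category of a host gene.

    Per snoRNA intron and coding transcript, the flanking exons (the exon
    ending at the intron start and the one starting at the intron end) are
    checked for CDS overlap. The gene is CDS_INTERNAL as soon as one coding
    transcript places the intron between two translated exons; UTR when the
    flanking context is exonic but untranslated in every coding transcript
    that contains the intron; NONCODING when the gene has no coding
    transcript; UNRESOLVED otherwise.
    """
    if not gene.snornas:
        raise ValueError(f"gene {gene.gene_id} hosts no snoRNA")
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcript")
    coding = [tx for tx in gene.transcripts if tx.is_coding]
    if not coding:
        return "NONCODING"

    sno_introns = [i for i in gene.introns if i.hosts_snorna]
    verdicts = []
    for intron in sno_introns:
        per_tx = []
        for tx in coding:
            left = next(
                (e for e in tx.exons_genomic() if e.end == intron.interval.start), None
            )
            right = next(
                (e for e in tx.exons_genomic() if e.start == intron.interval.end), None
            )
            if left is None or right is None:
                continue  # this transcript does not contain the intron
            flanks_cds = [
                any(e.overlaps(c) for c in tx.cds or []) for e in (left, right)
            ]
            per_tx.append("CDS_INTERNAL" if all(flanks_cds) else "UTR")
        if not per_tx:
            verdicts.append("UNRESOLVED")
        elif "CDS_INTERNAL" in per_tx:
            verdicts.append("CDS_INTERNAL")
        else:
            verdicts.append("UTR")

    if "CDS_INTERNAL" in verdicts:
        return "CDS_INTERNAL"
    if verdicts and all(v == "UTR" for v in verdicts):
        return "UTR"
    return "UNRESOLVED"


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes", "t"):
        return True
    if t in ("false", "0", "no", "f"):
        return False
    raise AnnotationError(f"cannot parse boolean field {text!r}")


def read_snorna_tsv(path: str | Path) -> list[SnoRNARecord]:
    """Read the snoRNA table (1-based inclusive coordinates, header line)."""
    records = []
    with open(path) as handle:
        rows = [line for line in handle if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    missing = set(SNORNA_TSV_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise AnnotationError(f"snoRNA TSV missing columns: {sorted(missing)}")
    for lineno, row in enumerate(reader, start=2):
        try:
            start = int(row["start"]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(row["end"])
        except ValueError as exc:
            raise AnnotationError(
                f"snoRNA TSV line {lineno}: non-integer coordinates "
                f"({row['start']!r}, {row['end']!r})"
            ) from exc
        records.append(
            SnoRNARecord(
                snorna_id=row["snorna_id"],
                host_gene_id=row["host_gene_id"],
                interval=GenomicInterval(row["chrom"], start, end, row["strand"]),
                box_class=row["box_class"],
                canonical=_parse_bool(row["canonical"]),
            )
        )
    return records


def write_snorna_tsv(records: Iterable[SnoRNARecord], path: str | Path) -> None:
    """Write the snoRNA table back out (1-based inclusive coordinates)."""
    with open(path, "w") as out:
        out.write("# snoRNA table; coordinates 1-based inclusive\n")
        out.write("\t".join(SNORNA_TSV_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: r.snorna_id):
            out.write(
                "\t".join(
                    [
                        r.snorna_id,
                        r.host_gene_id,
                        r.interval.chrom,
                        str(r.interval.start + 1),
                        str(r.interval.end),
                        r.interval.strand,
                        r.box_class,
                        "true" if r.canonical else "false",
                    ]
                )
                + "\n"
            )


def load_annotation(
    gff3_path: str | Path, snorna_tsv_path: str | Path
) -> list[HostGeneModel]:
    """Build one :class:`HostGeneModel` per gene hosting at least one snoRNA.

    GFF3 must carry gene / mRNA-or-transcript / exon / CDS features with
    ID/Parent attributes. Introns are derived as gaps between consecutive
    exons per transcript and deduplicated per gene; every snoRNA from the
    table is assigned to its containing intron, raising
    :class:`AnnotationError` if none contains it.
    """
    snornas = read_snorna_tsv(snorna_tsv_path)
    by_gene: dict[str, list[SnoRNARecord]] = {}
    for sno in snornas:
        by_gene.setdefault(sno.host_gene_id, []).append(sno)

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[HostGeneModel] = []
    for gene_feat in db.features_of_type("gene"):
        gene_id = gene_feat.id
        if gene_id not in by_gene:
            continue
        transcripts = []
        for tx_feat in db.children(gene_feat, featuretype=("mRNA", "transcript")):
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(tx_feat, featuretype="exon", order_by="start")
            ]
            cds = [
                GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                for c in db.children(tx_feat, featuretype="CDS", order_by="start")
            ]
            if not exons:
                continue
            if tx_feat.strand == "-":
                exons = exons[::-1]  # transcript 5'->3' order
                cds = cds[::-1]
            transcripts.append(
                TranscriptModel(tx_feat.id, gene_id, exons, cds or None)
            )
        if not transcripts:
            raise AnnotationError(f"host gene {gene_id} has no transcript with exons")
        span = GenomicInterval(
            gene_feat.seqid, gene_feat.start - 1, gene_feat.end, gene_feat.strand
        )
        gene = HostGeneModel(gene_id, span, transcripts)
        gene.introns = _derive_introns(gene_id, transcripts)
        _assign_snornas(gene, by_gene[gene_id])
        gene.category = classify_host_gene(gene)
        genes.append(gene)

    assigned = {s.snorna_id for g in genes for s in g.snornas}
    unassigned = [s.snorna_id for s in snornas if s.snorna_id not in assigned]
    if unassigned:
        raise AnnotationError(
            f"snoRNAs reference host genes absent from the GFF3: {unassigned}"
        )
    return sorted(genes, key=lambda g: (g.span.chrom, g.span.start))


def write_gff3(genes: Iterable[HostGeneModel], path: str | Path) -> None:
    """Serialize host-gene models back to GFF3 (round-trips with load)."""

    def line(seqid, ftype, iv, attrs):
        return (
            f"{seqid}\tsnortools\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.span.chrom, g.span.start)):
            out.write(line(g.span.chrom, "gene", g.span, f"ID={g.gene_id}"))
            for tx in g.transcripts:
                tx_span = GenomicInterval(
                    g.span.chrom,
                    min(e.start for e in tx.exons),
                    max(e.end for e in tx.exons),
                    g.strand,
                )
                out.write(
                    line(
                        g.span.chrom,
                        "mRNA" if tx.is_coding else "transcript",
                        tx_span,
                        f"ID={tx.transcript_id};Parent={g.gene_id}",
                    )
                )
                for k, e in enumerate(tx.exons_genomic(), 1):
                    out.write(
                        line(
                            g.span.chrom,
                            "exon",
                            e,
                            f"ID={tx.transcript_id}.exon{k};Parent={tx.transcript_id}",
                        )
                    )
                for k, c in enumerate(sorted(tx.cds or [], key=lambda c: c.start), 1):
                    out.write(
                        line(
                            g.span.chrom,
                            "CDS",
                            c,
                            f"ID={tx.transcript_id}.cds{k};Parent={tx.transcript_id}",
                        )
                    )
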