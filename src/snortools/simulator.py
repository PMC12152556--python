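"""Synthetic snoRNA host-gene loci and pre-aligned long reads.

Generates, per host gene, a random multi-exon locus with one snoRNA
embedded in an internal intron, then emits a read mixture of the three
transcript forms the pipeline must distinguish:

* spliced host mRNA (all introns removed),
* FL-snoRT (full-length transcript retaining the snoRNA intron),
* 3'-snoRT (retains the snoRNA intron but is 5'-truncated at the class-
  dependent cut point: at the snoRNA start for C/D box, two bases upstream
  for H/ACA box, plus Gaussian jitter), running to the transcript 3' end.

Other introns are independently retained at a low background rate; a read
generated as spliced but retaining one of them is labelled OTHER_IR.
Basecall noise is injected as substitutions, insertions and deletions with
the CIGAR adjusted accordingly; indels are suppressed within a few bases of
block boundaries so that noise can never silently change a truth label.

Alignments are written directly as a coordinate-sorted, indexed BAM — no
external aligner is involved, so the truth table is exact. The same module
also provides count-level generators for the retention statistics, where
only per-intron retained/spliced totals matter and read-level simulation
would add nothing but cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .annotations import (
    HostGeneModel,
    IntronRecord,
    SnoRNARecord,
    TranscriptModel,
    write_gff3,
    write_snorna_tsv,
)
from .intervals import GenomicInterval
from .retention_stats import IntronRetentionSummary

BASES = np.array(list("ACGT"))
SNO_PAD = 20  # minimum distance from snoRNA to its intron boundaries, nt
INDEL_PROTECT = 5  # no indels within this many nt of a block boundary
GENE_FLANK = 100  # reference padding around each gene


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulation run.

    ``isoform_props`` is (p_spliced, p_fl, p_three_prime) and must sum
    to 1. Truncation offsets follow the observed cut-point law: C/D box
    3'-snoRTs start at the snoRNA start (offset 0), H/ACA box two bases
    upstream (offset -2), with integer-rounded Gaussian jitter.
    """

    seed: int = 0
    n_genes: int = 5
    exons_per_gene: int = 4
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (250, 600)
    snorna_len: tuple[int, int] = (70, 140)
    box_class_mix: float = 0.5  # fraction of snoRNAs that are C/D box
    canonical_frac: float = 0.5
    isoform_props: tuple[float, float, float] = (0.5, 0.2, 0.3)
    truncation_jitter_sd: float = 3.0
    cd_offset: int = 0
    haca_offset: int = -2
    reads_per_gene: int = 100
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    minus_strand_frac: float = 0.5
    retention_rate_other_introns: float = 0.0001
    noncoding_frac: float = 0.0
    mirror: bool = False  # two genes, identical geometry, opposite strands

    def validate(self) -> None:
        if self.exons_per_gene < 3:
            raise ConfigError("exons_per_gene must be >= 3")
        if abs(sum(self.isoform_props) - 1.0) > 1e-9:
            raise ConfigError("isoform_props must sum to 1")
        if any(not 0 <= p <= 1 for p in self.isoform_props):
            raise ConfigError("isoform_props must be in [0, 1]")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 0.2:
                raise ConfigError(f"{name} must be in [0, 0.2], got {r}")
        if self.intron_len[0] < self.snorna_len[1] + 2 * SNO_PAD:
            raise ConfigError(
                "infeasible geometry: minimum intron length must be at least "
                f"max snoRNA length + {2 * SNO_PAD} nt of padding"
            )
        if self.mirror and self.n_genes != 2:
            raise ConfigError("mirror mode requires n_genes == 2")


@dataclass
class TruthRecord:
    read_id: str
    gene_id: str
    true_form: str  # SPLICED | FL | THREE_PRIME | OTHER_IR
    true_offset: Optional[int]  # signed 5' offset, THREE_PRIME only


@dataclass
class SimGene:
    """Ground-truth geometry of one simulated host gene."""

    gene_id: str
    chrom: str
    strand: str
    chrom_len: int
    exons: list[GenomicInterval]  # ascending genomic order
    introns: list[GenomicInterval]
    sno_intron_idx: int
    snorna: SnoRNARecord
    coding: bool


@dataclass
class SimResult:
    config: SimConfig
    genes: list[SimGene]
    truth: list[TruthRecord]
    reference_fasta: Path
    annotation_gff3: Path
    snorna_tsv: Path
    bam: Path
    truth_tsv: Path


def _draw_len(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _make_gene_geometry(
    rng: np.random.Generator, config: SimConfig, index: int, strand: str, coding: bool
) -> SimGene:
    n_ex = config.exons_per_gene
    exon_lens = [_draw_len(rng, config.exon_len) for _ in range(n_ex)]
    intron_lens = [_draw_len(rng, config.intron_len) for _ in range(n_ex - 1)]
    sno_idx = (n_ex - 2) // 2  # an internal intron, deterministic choice
    sno_len = _draw_len(rng, config.snorna_len)
    # enlarge the hosting intron if the draw came out too small for padding
    intron_lens[sno_idx] = max(intron_lens[sno_idx], sno_len + 2 * SNO_PAD)

    chrom = f"chr{index + 1}"
    pos = GENE_FLANK
    exons, introns = [], []
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < n_ex - 1:
            introns.append(GenomicInterval(chrom, pos, pos + intron_lens[i], strand))
            pos += intron_lens[i]
    chrom_len = pos + GENE_FLANK

    host = introns[sno_idx]
    lo = host.start + SNO_PAD
    hi = host.end - SNO_PAD - sno_len
    sno_start = int(rng.integers(lo, hi + 1))
    box = "CD" if rng.random() < config.box_class_mix else "HACA"
    canonical = bool(rng.random() < config.canonical_frac)
    gene_id = f"simgene{index + 1}"
    snorna = SnoRNARecord(
        snorna_id=f"simsno{index + 1}",
        host_gene_id=gene_id,
        interval=GenomicInterval(chrom, sno_start, sno_start + sno_len, strand),
        box_class=box,
        canonical=canonical,
    )
    return SimGene(gene_id, chrom, strand, chrom_len, exons, introns, sno_idx, snorna, coding)


def _reflect_gene(g: SimGene, index: int) -> SimGene:
    """Reverse-complement image of a gene: same locus read from the other
    strand, so transcript-orientation distances are preserved exactly."""
    L = g.chrom_len
    chrom = f"chr{index + 1}"
    strand = "-" if g.strand == "+" else "+"

    def flip(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(chrom, L - iv.end, L - iv.start, strand)

    exons = [flip(e) for e in reversed(g.exons)]
    introns = [flip(i) for i in reversed(g.introns)]
    sno_idx = len(g.introns) - 1 - g.sno_intron_idx
    snorna = SnoRNARecord(
        snorna_id=f"simsno{index + 1}",
        host_gene_id=f"simgene{index + 1}",
        interval=flip(g.snorna.interval),
        box_class=g.snorna.box_class,
        canonical=g.snorna.canonical,
    )
    return SimGene(
        f"simgene{index + 1}", chrom, strand, L, exons, introns, sno_idx, snorna, g.coding
    )


def _gene_to_model(g: SimGene) -> HostGeneModel:
    exons = g.exons if g.strand == "+" else g.exons[::-1]
    tx = TranscriptModel(
        transcript_id=f"{g.gene_id}.t1",
        gene_id=g.gene_id,
        exons=exons,
        cds=list(exons) if g.coding else None,
    )
    span = GenomicInterval(g.chrom, g.exons[0].start, g.exons[-1].end, g.strand)
    model = HostGeneModel(g.gene_id, span, [tx])
    model.introns = [
        IntronRecord(
            g.gene_id,
            iv,
            hosts_snorna=(i == g.sno_intron_idx),
            snorna_id=g.snorna.snorna_id if i == g.sno_intron_idx else None,
        )
        for i, iv in enumerate(g.introns)
    ]
    model.snornas = [g.snorna]
    model.category = "CDS_INTERNAL" if g.coding else "NONCODING"
    return model


def _molecule_blocks(
    g: SimGene, retained: set[int], clip_5p: Optional[int]
) -> list[tuple[int, int]]:
    """Merged genomic blocks of one molecule; spliced introns become gaps.

    ``retained`` holds intron indices kept in the molecule; ``clip_5p`` is
    the genomic coordinate of the molecule 5' end (transcript orientation)
    for truncated molecules, or None for full-length ones.
    """
    pieces: list[tuple[int, int]] = []
    for i, ex in enumerate(g.exons):
        pieces.append((ex.start, ex.end))
        if i < len(g.introns) and i in retained:
            pieces.append((g.introns[i].start, g.introns[i].end))
    blocks: list[tuple[int, int]] = []
    for s, e in pieces:
        if blocks and blocks[-1][1] == s:
            blocks[-1] = (blocks[-1][0], e)
        else:
            blocks.append((s, e))
    if clip_5p is not None:
        if g.strand == "+":
            blocks = [(max(s, clip_5p), e) for s, e in blocks if e > clip_5p]
        else:
            blocks = [(s, min(e, clip_5p)) for s, e in blocks if s < clip_5p]
    return blocks


def _inject_errors(
    rng: np.random.Generator,
    blocks: list[tuple[int, int]],
    chrom_seq: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
) -> tuple[list[tuple[int, int]], str]:
    """Turn genomic blocks into (cigartuples, query sequence).

    Indels are suppressed within INDEL_PROTECT nt of block boundaries so
    that injected noise cannot mimic or destroy a splice junction.
    """
    ops: list[tuple[int, int]] = []  # pysam op codes
    seq_parts: list[str] = []

    if sub_rate == 0 and ins_rate == 0 and del_rate == 0:
        prev_end = None
        for bs, be in blocks:
            if prev_end is not None:
                ops.append((3, bs - prev_end))
            ops.append((0, be - bs))
            seq_parts.append("".join(chrom_seq[bs:be]))
            prev_end = be
        return ops, "".join(seq_parts)

    def emit(op: int, length: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    prev_end = None
    for bs, be in blocks:
        if prev_end is not None:
            emit(3, bs - prev_end)  # N
        blen = be - bs
        for k in range(bs, be):
            interior = INDEL_PROTECT <= (k - bs) and (be - k) > INDEL_PROTECT
            interior = interior and blen > 2 * INDEL_PROTECT
            if interior and rng.random() < del_rate:
                emit(2)  # D: reference base skipped
                continue
            base = chrom_seq[k]
            if rng.random() < sub_rate:
                base = BASES[(np.where(BASES == base)[0][0] + rng.integers(1, 4)) % 4]
            seq_parts.append(str(base))
            emit(0)  # M
            if interior and rng.random() < ins_rate:
                seq_parts.append(str(BASES[rng.integers(0, 4)]))
                emit(1)  # I
        prev_end = be
    return ops, "".join(seq_parts)


def _simulate_gene_reads(
    mol_rng: np.random.Generator,
    err_rng: np.random.Generator,
    config: SimConfig,
    g: SimGene,
    chrom_seq: np.ndarray,
) -> tuple[list[dict], list[TruthRecord]]:
    """Draw molecules and emit aligned-read records for one gene.

    Molecule identity (form, retained introns, truncation jitter) comes
    from ``mol_rng`` with a fixed number of draws per read, so two genes
    sharing a molecule stream produce read-for-read identical isoforms —
    the basis of the strand-mirror fixture. Basecall noise draws a
    variable amount of randomness and uses the separate ``err_rng``.
    """
    reads, truth = [], []
    p_spliced, p_fl, p_3p = config.isoform_props
    host = g.introns[g.sno_intron_idx]
    sno = g.snorna.interval
    class_offset = config.cd_offset if g.snorna.box_class == "CD" else config.haca_offset

    for k in range(config.reads_per_gene):
        u = mol_rng.random()
        form = "SPLICED" if u < p_spliced else ("FL" if u < p_spliced + p_fl else "THREE_PRIME")
        retained = {
            i
            for i in range(len(g.introns))
            if i != g.sno_intron_idx
            and mol_rng.random() < config.retention_rate_other_introns
        }
        jitter = mol_rng.normal(0.0, config.truncation_jitter_sd)
        clip = None
        true_offset: Optional[int] = None
        if form in ("FL", "THREE_PRIME"):
            retained.add(g.sno_intron_idx)
            true_form = form
        else:
            true_form = "OTHER_IR" if retained else "SPLICED"
        if form == "THREE_PRIME":
            off = class_offset + int(round(jitter))
            if g.strand == "+":
                off = max(off, host.start - sno.start + 1)
                clip = sno.start + off
            else:
                off = max(off, sno.end - host.end + 1)
                clip = sno.end - off
            true_offset = off
            # truncated molecules never include upstream retained introns
            retained = {i for i in retained if i >= g.sno_intron_idx} if g.strand == "+" else {
                i for i in retained if i <= g.sno_intron_idx
            }
        blocks = _molecule_blocks(g, retained, clip)
        cigar, seq = _inject_errors(
            err_rng, blocks, chrom_seq, config.sub_rate, config.ins_rate, config.del_rate
        )
        read_id = f"{g.gene_id}_r{k:05d}"
        reads.append(
            {
                "read_id": read_id,
                "chrom": g.chrom,
                "pos": blocks[0][0],
                "cigar": cigar,
                "seq": seq,
                "reverse": g.strand == "-",
            }
        )
        truth.append(TruthRecord(read_id, g.gene_id, true_form, true_offset))
    return reads, truth


def simulate(config: SimConfig, outdir: str | Path) -> SimResult:
    """Run one simulation and write all outputs under *outdir*.

    Writes reference FASTA (+ index), annotation GFF3, snoRNA TSV, a
    coordinate-sorted indexed BAM, and the truth TSV. Identical configs
    produce identical outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes: list[SimGene] = []
    if config.mirror:
        geo_rng = np.random.default_rng([config.seed % 2**31, 55, 0])
        proto = _make_gene_geometry(geo_rng, config, 0, "+", coding=True)
        genes = [proto, _reflect_gene(proto, 1)]
    else:
        for i in range(config.n_genes):
            strand = "-" if rng.random() < config.minus_strand_frac else "+"
            coding = not (rng.random() < config.noncoding_frac)
            geo_rng = np.random.default_rng([config.seed % 2**31, 55, i])
            genes.append(_make_gene_geometry(geo_rng, config, i, strand, coding))

    chrom_seqs = {
        g.chrom: BASES[rng.integers(0, 4, size=g.chrom_len)] for g in genes
    }

    all_reads, all_truth = [], []
    for i, g in enumerate(genes):
        mol_rng = np.random.default_rng(
            [config.seed % 2**31, 77, 0 if config.mirror else i]
        )
        err_rng = np.random.default_rng([config.seed % 2**31, 99, i])
        reads, truth = _simulate_gene_reads(
            mol_rng, err_rng, config, g, chrom_seqs[g.chrom]
        )
        all_reads.extend(reads)
        all_truth.extend(truth)

    fasta = outdir / "reference.fa"
    with open(fasta, "w") as out:
        for chrom in sorted(chrom_seqs):
            seq = "".join(chrom_seqs[chrom])
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta))

    models = [_gene_to_model(g) for g in genes]
    gff3 = outdir / "annotation.gff3"
    write_gff3(models, gff3)
    sno_tsv = outdir / "snornas.tsv"
    write_snorna_tsv([g.snorna for g in genes], sno_tsv)

    bam_path = outdir / "reads.bam"
    chroms = sorted(chrom_seqs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(chrom_seqs[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    all_reads.sort(key=lambda r: (tid[r["chrom"]], r["pos"], r["read_id"]))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for r in all_reads:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = r["read_id"]
            rec.reference_id = tid[r["chrom"]]
            rec.reference_start = r["pos"]
            rec.cigartuples = r["cigar"]
            rec.query_sequence = r["seq"]
            rec.mapping_quality = 60
            rec.flag = 16 if r["reverse"] else 0
            bam.write(rec)
    pysam.index(str(bam_path))

    truth_tsv = outdir / "truth.tsv"
    with open(truth_tsv, "w") as out:
        out.write("# snortools simulation truth schema v1\n")
        out.write("read_id\tgene_id\ttrue_form\ttrue_offset\n")
        for t in all_truth:
            off = "." if t.true_offset is None else str(t.true_offset)
            out.write(f"{t.read_id}\t{t.gene_id}\t{t.true_form}\t{off}\n")

    return SimResult(config, genes, all_truth, fasta, gff3, sno_tsv, bam_path, truth_tsv)


FIXTURES: dict[str, SimConfig] = {
    "tiny": SimConfig(
        seed=7, n_genes=1, reads_per_gene=30, minus_strand_frac=0.0,
        retention_rate_other_introns=0.0,
    ),
    "mirror": SimConfig(
        seed=11, n_genes=2, reads_per_gene=40, mirror=True,
        retention_rate_other_introns=0.0,
    ),
    "noisy": SimConfig(
        seed=13, n_genes=1, reads_per_gene=60, minus_strand_frac=0.0,
        sub_rate=0.05, ins_rate=0.01, del_rate=0.01,
    ),
}


def make_fixture(name: str, outdir: str | Path) -> SimResult:
    """Generate one of the registered deterministic test datasets."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choices: {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    return simulate(SimConfig(**asdict(cfg)), outdir)


def simulate_retention_summaries(
    rng: np.random.Generator, n_introns: int, depth: int, rate: float
) -> list[IntronRetentionSummary]:
    """Count-level retention draws for the group-comparison statistics.

    Each intron observes ``depth`` informative reads of which
    Binomial(depth, rate) are retained; only the per-intron frequencies
    matter to the t-test, so reads are not materialized.
    """
    retained = rng.binomial(depth, rate, size=n_introns)
    return [
        IntronRetentionSummary(None, int(k), depth - int(k)) for k in retained
    ]


def simulate_canonical_events(
    rng: np.random.Generator, n_events: int, rate_canonical: float, rate_noncanonical: float
) -> dict[str, tuple[int, int]]:
    """Pooled retained/spliced event counts for the canonical comparison."""
    k_c = int(rng.binomial(n_events, rate_canonical))
    k_n = int(rng.binomial(n_events, rate_noncanonical))
    return {
        "canonical": (k_c, n_events - k_c),
        "noncanonical": (k_n, n_events - k_n),
    }
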