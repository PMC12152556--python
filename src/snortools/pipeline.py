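"""End-to-end orchestration: BAM + annotation -> calls, quant, stats.

This is the programmatic face of the command-line `call` and `stats`
subcommands; each step is also usable on its own from the library modules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .annotations import HostGeneModel, load_annotation
from .read_model import (
    DEFAULT_JUNCTION_TOL,
    DEFAULT_MAPQ_MIN,
    DEFAULT_MIN_INTERIOR_COV,
    IntronCall,
    call_intron,
    extract_reads,
    write_intron_calls,
)
from .retention_stats import (
    CanonicalComparison,
    GroupComparison,
    IntronRetentionSummary,
    compare_canonical,
    compare_intron_groups,
    summarize_intron,
    write_comparison_report,
    write_intron_summaries,
)
from .snort_caller import (
    DEFAULT_MIN_COV,
    DEFAULT_THRESHOLD_T,
    GeneQuant,
    SnortCall,
    call_snort,
    cutpoint_distribution,
    quantify_gene,
    write_cutpoints,
    write_gene_quant,
    write_snort_calls,
)


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run."""

    threshold_t: int = DEFAULT_THRESHOLD_T
    min_cov: float = DEFAULT_MIN_COV
    min_interior_cov: float = DEFAULT_MIN_INTERIOR_COV
    junction_tolerance: int = DEFAULT_JUNCTION_TOL
    mapq_min: int = DEFAULT_MAPQ_MIN
    test_variant: str = "welch"
    require_downstream_exon: bool = True

    def validate(self) -> None:
        if self.threshold_t < 0:
            raise ValueError("threshold_t must be >= 0")
        for name in ("min_cov", "min_interior_cov"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.junction_tolerance < 0:
            raise ValueError("junction_tolerance must be >= 0")
        if self.test_variant not in ("welch", "student"):
            raise ValueError("test_variant must be welch or student")


@dataclass
class CallResult:
    """Everything one `call` run produced, in memory."""

    genes: list[HostGeneModel]
    intron_calls: list[IntronCall]
    snort_calls: list[SnortCall]
    gene_quants: list[GeneQuant]
    gene_read_totals: dict[str, int] = field(default_factory=dict)


def call_sample(
    bam_path: str | Path,
    genes: list[HostGeneModel],
    config: Optional[RunConfig] = None,
) -> CallResult:
    """Call snoRTs and intron retention over every host gene of a sample.

    For each gene: primary strand-matched reads overlapping the gene span
    define total host-gene expression; every read/intron overlap yields an
    IntronCall, and every read is scored against each snoRNA of the gene.
    """
    config = config or RunConfig()
    config.validate()
    intron_calls: list[IntronCall] = []
    snort_calls: list[SnortCall] = []
    quants: list[GeneQuant] = []
    totals: dict[str, int] = {}

    for gene in genes:
        reads = list(extract_reads(bam_path, gene.span, mapq_min=config.mapq_min))
        matched = [r for r in reads if r.strand == gene.strand]
        totals[gene.gene_id] = len(matched)
        for read in matched:
            for intron in gene.introns:
                if read.span.overlaps(intron.interval):
                    intron_calls.append(
                        call_intron(
                            read,
                            intron,
                            min_interior_cov=config.min_interior_cov,
                            junction_tol=config.junction_tolerance,
                        )
                    )
        per_sno: dict[str, list[SnortCall]] = {}
        for sno in gene.snornas:
            for read in matched:
                call = call_snort(
                    read,
                    gene,
                    sno,
                    threshold_t=config.threshold_t,
                    min_cov=config.min_cov,
                    require_downstream_exon=config.require_downstream_exon,
                )
                snort_calls.append(call)
                per_sno.setdefault(sno.snorna_id, []).append(call)
            quants.append(
                quantify_gene(per_sno[sno.snorna_id], totals[gene.gene_id])
            )
    return CallResult(genes, intron_calls, snort_calls, quants, totals)


@dataclass
class StatsResult:
    summaries: list[IntronRetentionSummary]
    group_comparison: Optional[GroupComparison]
    canonical_comparison: Optional[CanonicalComparison]


def compute_stats(
    result: CallResult, test_variant: str = "welch"
) -> StatsResult:
    """Per-intron retention summaries and the two global comparisons.

    The group t-test runs when both intron groups have >= 2 informative
    introns; the canonical chi-square when both snoRNA classes have pooled
    events with nonzero marginals. Missing preconditions yield None for
    that comparison rather than an error.
    """
    by_intron: dict[tuple, list[IntronCall]] = {}
    for c in result.intron_calls:
        key = (c.gene_id, c.intron.interval.start, c.intron.interval.end)
        by_intron.setdefault(key, []).append(c)
    summaries = [summarize_intron(calls) for calls in by_intron.values()]

    sno_group = [s for s in summaries if s.intron and s.intron.hosts_snorna]
    other_group = [s for s in summaries if s.intron and not s.intron.hosts_snorna]
    group_cmp = None
    if (
        sum(1 for s in sno_group if s.frequency is not None) >= 2
        and sum(1 for s in other_group if s.frequency is not None) >= 2
    ):
        group_cmp = compare_intron_groups(sno_group, other_group, test_variant)

    canonical_of = {
        s.snorna_id: s.canonical for g in result.genes for s in g.snornas
    }
    events = {"canonical": [0, 0], "noncanonical": [0, 0]}
    for s in sno_group:
        cls = "canonical" if canonical_of.get(s.intron.snorna_id) else "noncanonical"
        events[cls][0] += s.n_retained
        events[cls][1] += s.n_spliced
    canonical_cmp = None
    table = {k: tuple(v) for k, v in events.items()}
    if all(sum(v) > 0 for v in table.values()) and sum(
        v[0] for v in table.values()
    ) > 0 and sum(v[1] for v in table.values()) > 0:
        canonical_cmp = compare_canonical(table)
    return StatsResult(summaries, group_cmp, canonical_cmp)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_call(
    bam_path: str | Path,
    gff3_path: str | Path,
    snorna_tsv_path: str | Path,
    outdir: str | Path,
    config: Optional[RunConfig] = None,
    with_stats: bool = True,
) -> CallResult:
    """Full run: load annotation, call, quantify, summarize, write outputs.

    Writes per-read snoRT calls, per-read intron calls, per-gene
    quantification, the 3'-snoRT cut-point histogram, retention statistics
    and a run manifest (version, config, input checksums) under *outdir*.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = load_annotation(gff3_path, snorna_tsv_path)
    result = call_sample(bam_path, genes, config)

    write_snort_calls(result.snort_calls, outdir / "snort_calls.tsv")
    write_intron_calls(result.intron_calls, outdir / "intron_calls.tsv")
    write_gene_quant(result.gene_quants, outdir / "gene_quant.tsv")
    box_of = {s.snorna_id: s.box_class for g in genes for s in g.snornas}
    write_cutpoints(
        cutpoint_distribution(result.snort_calls, box_of), outdir / "cutpoints.tsv"
    )
    if with_stats:
        stats = compute_stats(result, config.test_variant)
        write_intron_summaries(stats.summaries, outdir / "intron_summary.tsv")
        write_comparison_report(
            stats.group_comparison, stats.canonical_comparison,
            outdir / "retention_comparisons.tsv",
        )

    manifest = {
        "tool": "snortools",
        "version": __version__,
        "config": vars(config),
        "inputs": {
            "bam": {"path": str(bam_path), "sha256": _checksum(bam_path)},
            "gff3": {"path": str(gff3_path), "sha256": _checksum(gff3_path)},
            "snorna_tsv": {
                "path": str(snorna_tsv_path),
                "sha256": _checksum(snorna_tsv_path),
            },
        },
    }
    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return result
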