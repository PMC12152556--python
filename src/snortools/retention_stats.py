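"""Intron-retention frequencies and the two group comparisons.

Per intron, the retention frequency is retained / (retained + spliced)
over informative reads (PARTIAL calls are excluded from both numerator and
denominator). Two comparisons are then available:

* snoRNA-hosting introns vs all other introns of the host genes: two-sided
  unpaired t-test on per-intron frequencies (Welch by default, Student's
  pooled-variance on request) plus the fold change of group means;
* canonical vs non-canonical snoRNAs: chi-square with Yates' continuity
  correction on the 2x2 table of pooled retained/spliced event counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .annotations import IntronRecord
from .read_model import IntronCall


@dataclass
class IntronRetentionSummary:
    """Retention counts and frequency for one intron."""

    intron: Optional[IntronRecord]
    n_retained: int
    n_spliced: int

    @property
    def n_informative(self) -> int:
        return self.n_retained + self.n_spliced

    @property
    def frequency(self) -> Optional[float]:
        """Retained fraction; None when no read was informative."""
        if self.n_informative == 0:
            return None
        return self.n_retained / self.n_informative


@dataclass
class GroupComparison:
    mean_snorna_freq: float
    mean_other_freq: float
    fold_change: float
    t_statistic: float
    degrees_freedom: float
    p_value: float
    test_variant: str


@dataclass
class CanonicalComparison:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows canonical/non; cols ret/spl
    chi_square_yates: float
    p_value: float


def summarize_intron(calls: Iterable[IntronCall]) -> IntronRetentionSummary:
    """Count retained and spliced events for one intron."""
    calls = list(calls)
    introns = {
        (c.gene_id, c.intron.interval.start, c.intron.interval.end) for c in calls
    }
    if len(introns) > 1:
        raise ValueError("calls passed to summarize_intron span multiple introns")
    n_ret = sum(1 for c in calls if c.status == "RETAINED")
    n_spl = sum(1 for c in calls if c.status == "SPLICED")
    return IntronRetentionSummary(calls[0].intron if calls else None, n_ret, n_spl)


def compare_intron_groups(
    snorna_introns: Iterable[IntronRetentionSummary],
    other_introns: Iterable[IntronRetentionSummary],
    test_variant: str = "welch",
) -> GroupComparison:
    """Unpaired t-test of per-intron retention frequencies, plus fold change.

    Introns with undefined frequency (no informative reads) are excluded
    listwise; each group must retain at least two defined frequencies.
    Fold change is mean(snoRNA-intron freq) / mean(other-intron freq).
    """
    if test_variant not in ("welch", "student"):
        raise ValueError(f"unknown test_variant {test_variant!r}")
    a = np.array([s.frequency for s in snorna_introns if s.frequency is not None])
    b = np.array([s.frequency for s in other_introns if s.frequency is not None])
    for name, g in (("snorna_introns", a), ("other_introns", b)):
        if g.size < 2:
            raise ValueError(
                f"group {name} has {g.size} defined frequencies; need at least 2"
            )
    res = stats.ttest_ind(a, b, equal_var=(test_variant == "student"))
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_a / mean_b if mean_b > 0 else float("inf")
    return GroupComparison(
        mean_snorna_freq=mean_a,
        mean_other_freq=mean_b,
        fold_change=fold,
        t_statistic=float(res.statistic),
        degrees_freedom=float(res.df),
        p_value=float(res.pvalue),
        test_variant=test_variant,
    )


def compare_canonical(
    events_by_class: Mapping[str, tuple[int, int]]
) -> CanonicalComparison:
    """Yates-corrected chi-square on pooled retention events.

    ``events_by_class`` maps 'canonical' and 'noncanonical' to
    (n_retained, n_spliced) event counts pooled across the snoRNA-hosting
    introns of each class. The continuity correction is floored: a cell
    with |O - E| < 0.5 contributes zero to the statistic.
    """
    try:
        table = np.array(
            [events_by_class["canonical"], events_by_class["noncanonical"]],
            dtype=float,
        )
    except KeyError as exc:
        raise ValueError(f"events_by_class missing key {exc}") from exc
    if (table < 0).any():
        raise ValueError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return CanonicalComparison(
        table=tuple(tuple(int(x) for x in row) for row in table),
        chi_square_yates=float(chi2),
        p_value=float(p),
    )


def write_intron_summaries(
    summaries: Iterable[IntronRetentionSummary], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("# snortools intron retention summary schema v1\n")
        out.write(
            "chrom\tstart\tend\tgene_id\tsnorna_id\tn_retained\tn_spliced\tfrequency\n"
        )
        for s in summaries:
            iv = s.intron.interval if s.intron else None
            freq = "NA" if s.frequency is None else f"{s.frequency:.6f}"
            out.write(
                f"{iv.chrom if iv else '.'}\t{iv.start if iv else '.'}\t"
                f"{iv.end if iv else '.'}\t{s.intron.gene_id if s.intron else '.'}\t"
                f"{(s.intron.snorna_id if s.intron else None) or '.'}\t"
                f"{s.n_retained}\t{s.n_spliced}\t{freq}\n"
            )


def write_comparison_report(
    group: Optional[GroupComparison],
    canonical: Optional[CanonicalComparison],
    path: str | Path,
) -> None:
    """One-line-per-test TSV report of the two global comparisons."""
    with open(path, "w") as out:
        out.write("# snortools retention comparison report schema v1\n")
        out.write("test\tstatistic\tdf\tp_value\tdetail\n")
        if group is not None:
            out.write(
                f"intron_groups_{group.test_variant}_t\t{group.t_statistic:.6g}\t"
                f"{group.degrees_freedom:.4f}\t{group.p_value:.6g}\t"
                f"mean_snorna={group.mean_snorna_freq:.6g};"
                f"mean_other={group.mean_other_freq:.6g};"
                f"fold_change={group.fold_change:.6g}\n"
            )
        if canonical is not None:
            (a, b), (c, d) = canonical.table
            out.write(
                f"canonical_chi2_yates\t{canonical.chi_square_yates:.6g}\t1\t"
                f"{canonical.p_value:.6g}\ttable={a},{b},{c},{d}\n"
            )
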