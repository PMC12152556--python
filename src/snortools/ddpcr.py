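"""Three-primer ddPCR isoform deconvolution.

Droplet digital PCR with three nested primer sets yields absolute
concentrations (copies/uL) of nested transcript populations:

* Full-Length primers amplify FL-snoRTs only             -> c_fl
* snoRT primers amplify FL- and 3'-snoRTs                -> c_snort
* snoRT+snoRNA primers amplify both snoRTs plus the
  mature snoRNA                                          -> c_all

Subtraction recovers each isoform: 3'-snoRT = c_snort - c_fl and mature
snoRNA = c_all - c_snort. Droplet noise can make a raw difference
negative; such values are clamped to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "target_id", "c_fl", "c_snort", "c_all"]


@dataclass
class DdpcrPanel:
    """Copies/uL for the three primer sets of one (sample, target) well."""

    sample_id: str
    target_id: str
    c_fl: float
    c_snort: float
    c_all: float

    def __post_init__(self) -> None:
        for name in ("c_fl", "c_snort", "c_all"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class IsoformQuant:
    """Deconvolved absolute quantities (copies/uL)."""

    fl: float
    three_prime: float
    snorna: float
    flags: set[str] = field(default_factory=set)

    @property
    def total(self) -> float:
        return self.fl + self.three_prime + self.snorna

    def fractions(self) -> Optional[tuple[float, float, float]]:
        """(fl, three_prime, snorna) each over their sum; None if total is 0."""
        if self.total <= 0:
            return None
        return (
            self.fl / self.total,
            self.three_prime / self.total,
            self.snorna / self.total,
        )


def deconvolve(panel: DdpcrPanel, clamp: bool = True) -> IsoformQuant:
    """Subtract nested primer-set concentrations into isoform quantities.

    fl = c_fl; three_prime = c_snort - c_fl; snorna = c_all - c_snort.
    With ``clamp`` (default) negative raw differences become 0 and are
    flagged; without clamping the raw differences are returned as-is, so
    fl + three_prime + snorna == c_all exactly.
    """
    three_prime = panel.c_snort - panel.c_fl
    snorna = panel.c_all - panel.c_snort
    flags: set[str] = set()
    if clamp:
        if three_prime < 0:
            flags.add("NEG_3PRIME_CLAMPED")
            three_prime = 0.0
        if snorna < 0:
            flags.add("NEG_SNORNA_CLAMPED")
            snorna = 0.0
    return IsoformQuant(panel.c_fl, three_prime, snorna, flags)


def batch_deconvolve(
    tsv_path: str | Path, clamp: bool = True, fractions: bool = True
) -> pd.DataFrame:
    """Deconvolve a TSV of replicate wells and aggregate per (sample, target).

    Replicate rows are deconvolved individually; the table reports the
    replicate median and standard deviation of each isoform quantity and,
    optionally, relative fractions of the medians (summing to 1 when the
    total is positive; flagged ZERO_TOTAL otherwise).
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ddPCR TSV missing columns: {sorted(missing)}")

    rows = []
    for _, r in df.iterrows():
        panel = DdpcrPanel(
            str(r["sample_id"]), str(r["target_id"]),
            float(r["c_fl"]), float(r["c_snort"]), float(r["c_all"]),
        )
        q = deconvolve(panel, clamp=clamp)
        rows.append(
            {
                "sample_id": panel.sample_id,
                "target_id": panel.target_id,
                "fl": q.fl,
                "three_prime": q.three_prime,
                "snorna": q.snorna,
                "flags": ",".join(sorted(q.flags)),
            }
        )
    per_rep = pd.DataFrame(rows)

    out = []
    for (sample, target), grp in per_rep.groupby(["sample_id", "target_id"], sort=True):
        rec: dict = {"sample_id": sample, "target_id": target, "n_replicates": len(grp)}
        for col in ("fl", "three_prime", "snorna"):
            rec[f"{col}_median"] = float(grp[col].median())
            rec[f"{col}_sd"] = float(grp[col].std(ddof=1)) if len(grp) > 1 else 0.0
        flags = sorted(set(",".join(grp["flags"]).split(",")) - {""})
        total = rec["fl_median"] + rec["three_prime_median"] + rec["snorna_median"]
        if fractions:
            if total > 0:
                rec["frac_fl"] = rec["fl_median"] / total
                rec["frac_three_prime"] = rec["three_prime_median"] / total
                rec["frac_snorna"] = rec["snorna_median"] / total
            else:
                rec["frac_fl"] = rec["frac_three_prime"] = rec["frac_snorna"] = float("nan")
                flags.append("ZERO_TOTAL")
        rec["flags"] = ",".join(flags) or "."
        out.append(rec)
    return pd.DataFrame(out)


def write_batch_results(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("# snortools ddPCR deconvolution schema v1\n")
        df.to_csv(out, sep="\t", index=False, float_format="%.6g")
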