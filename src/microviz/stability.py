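"""Detection of stable phylotypes.

An OTU is called stable within an individual when the coefficient of
variation of its relative abundance between the pre-diarrhea and diarrhea
samples is at most ``cv_max`` percent and it carries at least ``min_reads``
raw reads in that individual (summed over the two compared samples, the
default reading; per-sample available via ``reads_rule``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .data_model import OtuTable, relative_abundance, select_samples

DEFAULT_CV_MAX = 10.0  # percent
DEFAULT_MIN_READS = 10


@dataclass(frozen=True)
class StabilityCall:
    otu_id: str
    individual: str
    habitat: str
    cv_percent: float
    reads_total: int
    stable: bool


def cv_pair(x2: float, x3: float) -> float:
    """Two-point coefficient of variation in percent, sample sd (n-1):
    CV = 100 * (|x2 - x3| / sqrt(2)) / ((x2 + x3) / 2)."""
    if x2 < 0 or x3 < 0:
        raise ValueError("abundances must be non-negative")
    mean = (x2 + x3) / 2.0
    if mean == 0:
        raise ValueError("cv undefined when both abundances are zero")
    sd = abs(x2 - x3) / math.sqrt(2.0)
    return 100.0 * sd / mean


def stable_phylotypes(
    t: OtuTable,
    meta: pd.DataFrame,
    habitat: str = "stool",
    cv_max: float = DEFAULT_CV_MAX,
    min_reads: int = DEFAULT_MIN_READS,
    reads_rule: str = "total",
) -> pd.DataFrame:
    """Per-individual stability calls for one habitat (tp2 vs tp3 contrast).

    Individuals missing either time-point are skipped with a warning. OTUs
    absent from both compared samples of an individual are excluded (CV
    undefined). Returns one row per (otu, individual) evaluated.
    """
    if reads_rule not in ("total", "per_sample"):
        raise ValueError("reads_rule must be 'total' or 'per_sample'")
    abund = relative_abundance(t)
    rows: list[StabilityCall] = []
    for ind in sorted(meta.loc[meta["habitat"] == habitat, "individual"].unique()):
        s2 = select_samples(meta, habitat=habitat, timepoint=2, individual=ind)
        s3 = select_samples(meta, habitat=habitat, timepoint=3, individual=ind)
        if len(s2) != 1 or len(s3) != 1:
            warnings.warn(
                f"individual {ind}: missing {habitat} time-point 2 or 3; skipped",
                stacklevel=2,
            )
            continue
        a2, a3 = abund.col(s2[0]), abund.col(s3[0])
        c2 = t.counts[:, t.sample_index(s2[0])]
        c3 = t.counts[:, t.sample_index(s3[0])]
        for i, otu in enumerate(t.otu_ids):
            if a2[i] == 0 and a3[i] == 0:
                continue
            cv = cv_pair(a2[i], a3[i])
            reads = int(c2[i] + c3[i])
            if reads_rule == "total":
                enough = reads >= min_reads
            else:
                enough = c2[i] >= min_reads and c3[i] >= min_reads
            rows.append(
                StabilityCall(
                    otu_id=otu,
                    individual=ind,
                    habitat=habitat,
                    cv_percent=float(cv),
                    reads_total=reads,
                    stable=bool(cv <= cv_max and enough),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def shared_stable_counts(calls: pd.DataFrame) -> pd.Series:
    """How many OTUs are stable in exactly k individuals simultaneously,
    indexed by k (the cross-individual intersection statistic)."""
    if calls.empty:
        return pd.Series(dtype=int)
    stable = calls[calls["stable"]]
    per_otu = stable.groupby("otu_id")["individual"].nunique()
    return per_otu.value_counts().sort_index()
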