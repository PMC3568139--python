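"""Alpha-diversity estimators and rarefaction.

Nonparametric richness estimators (bias-corrected Chao1, classic ACE),
Shannon diversity in nats, Pielou evenness, and the analytic hypergeometric
rarefaction expectation with per-group mean/SEM curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    return c.astype(np.int64)


def observed_richness(counts) -> int:
    return int(_clean(counts).size)


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    Defined for F2 = 0, unlike the classic form.
    """
    c = _clean(counts)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(c.size + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator.

    Rare taxa are those with <= ``rare_cutoff`` reads. Falls back to S_obs
    when there are no rare taxa and to Chao1 when sample coverage is zero
    (all rare taxa are singletons).
    """
    c = _clean(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(c.size)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        return chao1(c)
    ssum = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    if n_rare > 1:
        gamma2 = max((s_rare / coverage) * ssum / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / coverage + (f1 / coverage) * gamma2)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), over positive counts."""
    c = _clean(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(counts) -> float:
    """J = H / ln(S_obs); NaN when only one taxon is observed."""
    c = _clean(counts)
    if c.size < 2:
        return float("nan")
    return shannon(c) / float(np.log(c.size))


def rarefy_expected_richness(counts, n: int) -> float:
    """Analytic expectation of richness in a random subsample of ``n`` reads:
    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] (hypergeometric)."""
    c = _clean(counts)
    total = int(c.sum())
    if not 1 <= n <= total:
        raise ValueError(f"subsample size {n} outside [1, {total}]")
    # log-space binomial ratio; C(N - Ni, n) = 0 when n > N - Ni
    rest = total - c
    with np.errstate(divide="ignore"):
        log_ratio = (
            special.gammaln(rest + 1)
            - special.gammaln(rest - n + 1)
            - special.gammaln(total + 1)
            + special.gammaln(total - n + 1)
        )
    prob_absent = np.where(rest >= n, np.exp(log_ratio), 0.0)
    return float((1.0 - prob_absent).sum())


@dataclass
class DiversityRecord:
    sample_id: str
    observed_richness: int
    chao1: float
    ace: float
    shannon: float
    evenness: float


def diversity_table(counts_by_sample: dict[str, np.ndarray]) -> pd.DataFrame:
    """One row of alpha-diversity summaries per sample."""
    rows = [
        DiversityRecord(
            sample_id=s,
            observed_richness=observed_richness(c),
            chao1=chao1(c),
            ace=ace(c),
            shannon=shannon(c),
            evenness=pielou_evenness(c),
        ).__dict__
        for s, c in counts_by_sample.items()
    ]
    return pd.DataFrame(rows)


def rarefaction_curve(
    group: Sequence[np.ndarray], depths: Sequence[int]
) -> pd.DataFrame:
    """Mean and SEM across samples of the analytic rarefaction expectation.

    Depths exceeding a sample's total are skipped for that sample (per-sample
    truncation); rows report how many samples contributed. A single-sample
    group gets SEM 0 by convention, flagged via n_samples = 1.
    """
    if len(group) == 0:
        raise ValueError("empty rarefaction group")
    rows = []
    for depth in depths:
        vals = [
            rarefy_expected_richness(c, depth)
            for c in group
            if int(np.asarray(c).sum()) >= depth
        ]
        if not vals:
            continue
        arr = np.asarray(vals)
        sem = float(stats.sem(arr)) if arr.size > 1 else 0.0
        rows.append(
            {"depth": int(depth), "mean": float(arr.mean()), "sem": sem, "n_samples": arr.size}
        )
    return pd.DataFrame(rows)


def compare_paired(metric_a: Sequence[float], metric_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test between per-individual metric values.

    Zero variance of the differences is guarded: returns (0.0, 1.0) with a
    warning rather than an infinite statistic.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired comparison needs two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        warnings.warn("zero variance of paired differences; p set to 1", stacklevel=2)
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
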