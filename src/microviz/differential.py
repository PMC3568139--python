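"""Differential-abundance detection and cross-method consensus.

Three detection legs share one interface:

* ``M`` — a permutation two-sample t-test on relative abundances in the
  spirit of Metastats: permutation tail probabilities (exact enumeration of
  label arrangements when feasible), with a pooled Fisher's exact branch
  for sparse OTUs.
* ``E`` — a paired log2-ratio one-sample t-test, a documented stand-in for
  a paired negative-binomial count model.
* ``V`` — the slope-scoring pattern association (see ``viz_scoring``).

An OTU's consensus score is the number of legs detecting it; score >= 2
forms the consensus set. Rank-level paired and ratio-paired t-tests and the
phylum/pattern Fisher's exact association live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    OtuTable,
    UNCLASSIFIED,
    ValidationError,
    relative_abundance,
)

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 1000
DEFAULT_SPARSE_TOTAL = 10
EXACT_ENUMERATION_LIMIT = 2000

METHOD_ORDER = "MEV"  # canonical letter order in consensus tables


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic; 0/0 (no variance, no difference) -> 0,
    d/0 with d != 0 -> +-inf."""
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / a.shape[1]
    vb = b.var(axis=1, ddof=1) / b.shape[1]
    denom = np.sqrt(va + vb)
    num = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    signed_inf = np.where(num > 0, np.inf, -np.inf)
    t = np.where((denom == 0) & (num == 0), 0.0, t)
    t = np.where((denom == 0) & (num != 0), signed_inf, t)
    return t


def permutation_t_test(
    t: OtuTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    sparse_total: int = DEFAULT_SPARSE_TOTAL,
) -> pd.DataFrame:
    """Per-OTU permutation t-test of relative abundances, group A vs B.

    The permutation null redistributes the group labels over the pooled
    samples; when the number of distinct arrangements is at most
    ``EXACT_ENUMERATION_LIMIT`` the full set is enumerated and the p-value
    is the exact tail fraction (observed arrangement included), otherwise
    ``n_perm`` random arrangements are drawn and the add-one estimate
    p = (b + 1)/(B + 1) is used. OTUs with fewer than ``sparse_total`` raw
    reads overall are tested instead with a two-sided Fisher's exact test
    on the pooled 2x2 (OTU reads vs other reads) x group table.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("both groups need at least 2 samples")
    all_samples = list(group_a) + list(group_b)
    sub = t.subset_samples(all_samples)
    abund = relative_abundance(sub).values
    n_a = len(group_a)
    n_tot = len(all_samples)

    a_obs = abund[:, :n_a]
    b_obs = abund[:, n_a:]
    t_obs = _welch_t(a_obs, b_obs)

    n_arrangements = comb(n_tot, n_a)

    abs_obs = np.abs(t_obs)
    if n_arrangements <= EXACT_ENUMERATION_LIMIT:
        count = np.zeros(sub.n_otus, dtype=np.int64)
        for idx_a in combinations(range(n_tot), n_a):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(idx_a)] = True
            t_perm = _welch_t(abund[:, mask], abund[:, ~mask])
            count += np.abs(t_perm) >= abs_obs - 1e-12
        p = count / n_arrangements
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(sub.n_otus, dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(n_tot)
            t_perm = _welch_t(abund[:, perm[:n_a]], abund[:, perm[n_a:]])
            count += np.abs(t_perm) >= abs_obs - 1e-12
        p = (count + 1) / (n_perm + 1)

    # zero-variance OTUs (identical values in both groups) carry no signal
    flat = (abund.std(axis=1) == 0)
    p = np.where(flat, 1.0, p)

    # sparse branch: pooled read counts, Fisher's exact
    reads = sub.counts
    totals = reads.sum(axis=1)
    depth_a = int(reads[:, :n_a].sum())
    depth_b = int(reads[:, n_a:].sum())
    branch = np.where(totals < sparse_total, "fisher", "permutation")
    stat = t_obs.astype(float)
    for i in np.flatnonzero(totals < sparse_total):
        oa = int(reads[i, :n_a].sum())
        ob = int(reads[i, n_a:].sum())
        table = [[oa, ob], [depth_a - oa, depth_b - ob]]
        odds, fp = stats.fisher_exact(table, alternative="two-sided")
        p[i] = fp
        stat[i] = odds
    return pd.DataFrame(
        {
            "otu_id": sub.otu_ids,
            "statistic": stat,
            "p": p,
            "branch": branch,
            "method": "permtest",
        }
    )


def paired_logratio_test(
    t: OtuTable,
    pairs: Sequence[tuple[str, str]],
    pseudo: float = 0.001,
    zero_var_p: float = 0.0,
) -> pd.DataFrame:
    """One-sample t-test of per-individual log2((x3 + pseudo)/(x2 + pseudo))
    against 0, two-sided; x are relative abundances in percent.

    ``pairs`` lists (pre-diarrhea, diarrhea) sample ids per individual.
    A constant nonzero log-ratio across all pairs has zero variance; such
    OTUs are flagged in the detected direction with p = ``zero_var_p``.
    """
    if len(pairs) < 2:
        raise ValidationError("paired log-ratio test needs at least 2 pairs")
    abund = relative_abundance(t)
    x2 = np.column_stack([abund.col(a) for a, _ in pairs])
    x3 = np.column_stack([abund.col(b) for _, b in pairs])
    ratios = np.log2((x3 + pseudo) / (x2 + pseudo))
    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1)
    n = ratios.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    zero_var = sd == 0
    signed_inf = np.where(mean > 0, np.inf, -np.inf)
    tstat = np.where(zero_var, signed_inf, tstat)
    tstat = np.where(zero_var & (mean == 0), 0.0, tstat)
    p = np.where(zero_var, np.where(mean == 0, 1.0, zero_var_p), p)
    return pd.DataFrame(
        {"otu_id": t.otu_ids, "statistic": tstat, "p": p, "method": "paired_lr"}
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detected_set(
    results: pd.DataFrame, alpha: float = DEFAULT_ALPHA, use: str = "p"
) -> set[str]:
    """OTUs called significant at ``alpha`` on raw ('p') or BH-adjusted
    ('p_adjusted') p-values; the adjusted column is computed on demand."""
    if use == "p_adjusted" and "p_adjusted" not in results:
        results = results.assign(p_adjusted=bh_adjust(results["p"].to_numpy()))
    return set(results.loc[results[use] < alpha, "otu_id"])


def aggregate_to_rank(
    t: OtuTable, rank: str, confidence_cutoff: float | None = None
) -> pd.DataFrame:
    """Sum relative abundances (percent) per taxon name at ``rank``.

    Taxonomy must be present; OTUs unresolved at the rank (truncated,
    missing, or below the confidence cutoff when one is given) fall into
    the explicit 'unclassified' bucket. Columns are samples.
    """
    from .data_model import apply_confidence_threshold

    if not t.taxonomy:
        raise ValidationError("aggregate_to_rank requires taxonomy")
    abund = relative_abundance(t)
    names = []
    for otu in t.otu_ids:
        tax = t.taxonomy.get(otu)
        if tax is None:
            names.append(UNCLASSIFIED)
            continue
        if confidence_cutoff is not None:
            tax = apply_confidence_threshold(tax, confidence_cutoff)
        names.append(tax.name_at(rank))
    df = abund.to_dataframe()
    df.index = pd.Index(names, name=rank)
    return df.groupby(level=0).sum()


def rank_members(t: OtuTable, rank: str, confidence_cutoff: float | None = None) -> pd.Series:
    """Number of member OTUs per taxon name at ``rank``."""
    from .data_model import apply_confidence_threshold

    if not t.taxonomy:
        raise ValidationError("rank_members requires taxonomy")
    names = []
    for otu in t.otu_ids:
        tax = t.taxonomy.get(otu)
        if tax is None:
            names.append(UNCLASSIFIED)
            continue
        if confidence_cutoff is not None:
            tax = apply_confidence_threshold(tax, confidence_cutoff)
        names.append(tax.name_at(rank))
    return pd.Series(names).value_counts()


def rank_paired_tests(
    rank_matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    kind: str = "paired_t",
) -> pd.DataFrame:
    """Per-taxon paired tests between the two samples of each pair.

    ``paired_t`` tests the abundance differences; ``ratio_paired_t`` tests
    the per-individual abundance ratios (diarrhea : pre-diarrhea) against 1.
    Individuals where a taxon is absent pre-diarrhea are excluded from that
    taxon's ratio test with a warning. BH adjustment across taxa.
    """
    if kind not in ("paired_t", "ratio_paired_t"):
        raise ValueError("kind must be 'paired_t' or 'ratio_paired_t'")
    if len(pairs) < 2:
        raise ValidationError("rank tests need at least 2 pairs")
    rows = []
    for taxon, row in rank_matrix.iterrows():
        x2 = np.array([row[a] for a, _ in pairs], dtype=float)
        x3 = np.array([row[b] for _, b in pairs], dtype=float)
        if kind == "paired_t":
            vals = x3 - x2
            target = 0.0
        else:
            ok = x2 > 0
            if not ok.all():
                warnings.warn(
                    f"taxon {taxon!r}: {int((~ok).sum())} individual(s) absent "
                    "pre-diarrhea excluded from ratio test",
                    stacklevel=2,
                )
            vals = (x3[ok] / x2[ok]) if ok.any() else np.array([])
            target = 1.0
        if vals.size < 2:
            rows.append({"taxon": taxon, "statistic": np.nan, "p": np.nan, "n": vals.size})
            continue
        if np.allclose(vals, vals[0]):
            stat_val = 0.0 if np.isclose(vals[0], target) else np.inf * np.sign(vals[0] - target)
            p_val = 1.0 if np.isclose(vals[0], target) else 0.0
        else:
            stat_val, p_val = stats.ttest_1samp(vals, target)
        rows.append(
            {"taxon": taxon, "statistic": float(stat_val), "p": float(p_val), "n": int(vals.size)}
        )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["p_adjusted"] = adj
    return out


@dataclass(frozen=True)
class ConsensusRecord:
    otu_id: str
    score: int
    methods: str  # subset of "MEV" in canonical order


def consensus(detections: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Combine per-method detection sets into consensus scores.

    ``detections`` maps a method letter (M, E, V) to its detected OTU set.
    Score = number of methods detecting the OTU; rows are sorted score-
    descending. The consensus set is conventionally score >= 2.
    """
    sets = {m: set(v) for m, v in detections.items()}
    letters = [m for m in METHOD_ORDER if m in sets] + sorted(set(sets) - set(METHOD_ORDER))
    all_otus = sorted(set().union(*sets.values())) if sets else []
    rows = [
        ConsensusRecord(
            otu_id=o,
            score=sum(o in sets[m] for m in letters),
            methods="".join(m for m in letters if o in sets[m]),
        ).__dict__
        for o in all_otus
    ]
    df = pd.DataFrame(rows, columns=["otu_id", "score", "methods"])
    return df.sort_values(["score", "otu_id"], ascending=[False, True]).reset_index(drop=True)


def consensus_table(
    detections: Mapping[str, Iterable[str]],
    t: OtuTable,
    pairs: Sequence[tuple[str, str]],
    min_score: int = 2,
) -> pd.DataFrame:
    """Consensus records with mean +- sd percent abundance at the pre-
    diarrhea and diarrhea time-points and the taxonomy string (the shape of
    the published consensus tables)."""
    df = consensus(detections)
    df = df[df["score"] >= min_score].reset_index(drop=True)
    abund = relative_abundance(t)
    x2 = np.column_stack([abund.col(a) for a, _ in pairs])
    x3 = np.column_stack([abund.col(b) for _, b in pairs])
    idx = {o: i for i, o in enumerate(t.otu_ids)}
    rows = []
    for otu in df["otu_id"]:
        i = idx.get(otu)
        if i is None:
            rows.append((np.nan,) * 4 + ("",))
            continue
        rows.append(
            (
                x2[i].mean(),
                x2[i].std(ddof=1),
                x3[i].mean(),
                x3[i].std(ddof=1),
                t.taxonomy[otu].to_string() if otu in t.taxonomy else "",
            )
        )
    extra = pd.DataFrame(
        rows, columns=["mean_pct_tp2", "sd_tp2", "mean_pct_tp3", "sd_tp3", "taxonomy"]
    )
    return pd.concat([df, extra], axis=1)


def pattern_group_of(label: str) -> str | None:
    """Map a pattern label to its diarrhea-phase direction group.

    The first slope (pre-diarrhea -> diarrhea) defines the response to
    diarrhea: 'increase-*' and 'increase' are increasing, 'decrease-*' and
    'decrease' decreasing; flat-first patterns belong to neither group.
    """
    first = label.split("-")[0]
    if first == "increase":
        return "increasing"
    if first == "decrease":
        return "decreasing"
    return None


def fisher_phylum_association(
    associations: pd.DataFrame,
    phylum_by_otu: Mapping[str, str],
    phylum: str,
    pattern_group: str = "increasing",
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of phylum membership against membership
    in a direction group, over the distinct OTUs of the association set.

    ``associations`` needs columns otu_id and pattern_label. An OTU belongs
    to the group when any of its associated patterns does. Returns
    (odds ratio, p); a degenerate table (empty margin) gives p = 1 with a
    warning.
    """
    if pattern_group not in ("increasing", "decreasing"):
        raise ValueError("pattern_group must be 'increasing' or 'decreasing'")
    if associations.empty:
        raise ValidationError("association set is empty")
    in_group: dict[str, bool] = {}
    for r in associations.itertuples():
        grp = pattern_group_of(r.pattern_label)
        in_group[r.otu_id] = in_group.get(r.otu_id, False) or (grp == pattern_group)
    a = b = c = d = 0
    for otu, grp in in_group.items():
        is_phylum = phylum_by_otu.get(otu, UNCLASSIFIED) == phylum
        if is_phylum and grp:
            a += 1
        elif is_phylum:
            b += 1
        elif grp:
            c += 1
        else:
            d += 1
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 table; p set to 1", stacklevel=2)
        return float("nan"), 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
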