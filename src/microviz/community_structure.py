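"""Ordination and community-level summaries.

PCA (column-centered, unscaled SVD on the normalized jittered-log2
abundances, samples as observations), a within- vs between-group distance
test for cluster separation in PC space, chi-square confidence ellipses,
phylotype/sequence overlap between samples, and per-group phylum
composition with an 'Other' pool for minor phyla.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    OtuTable,
    UNCLASSIFIED,
    ValidationError,
    apply_confidence_threshold,
    relative_abundance,
)


@dataclass
class OrdinationResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    variance_explained: np.ndarray  # percent per component, sums to 100
    n_components: int


def pca(m: np.ndarray) -> OrdinationResult:
    """PCA by SVD of the column-centered matrix (rows = observations).

    Deterministic sign convention: within each component the largest-
    magnitude loading is positive. Variance percentages are over all
    retained components (min(n_obs - 1, n_vars)) and sum to 100.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValidationError("pca needs a 2D matrix with at least 2 observations")
    centered = m - m.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValidationError("constant matrix: no variance to decompose")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(m.shape[0] - 1, m.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    var = s**2
    return OrdinationResult(
        scores=u * s,
        loadings=vt.T,
        variance_explained=100.0 * var / var.sum(),
        n_components=k,
    )


def group_separation_test(
    scores: np.ndarray, labels: Sequence[str], components: int = 2
) -> tuple[float, float]:
    """Student's t-test of within-group vs between-group pairwise Euclidean
    distances in the first ``components`` PCs."""
    pts = np.asarray(scores, dtype=float)[:, :components]
    labels = list(labels)
    if len(labels) != pts.shape[0]:
        raise ValidationError("labels must match the number of score rows")
    within, between = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            (within if labels[i] == labels[j] else between).append(d)
    if not within or not between:
        raise ValidationError("need both within-group and between-group pairs")
    w, b = np.asarray(within), np.asarray(between)
    if w.std() == 0 and b.std() == 0 and np.isclose(w.mean(), b.mean()):
        warnings.warn("all pairwise distances identical; p set to 1", stacklevel=2)
        return 0.0, 1.0
    t, p = stats.ttest_ind(w, b, equal_var=True)
    return float(t), float(p)


@dataclass
class ConfidenceEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_rad: float  # orientation of the major axis
    degenerate: bool


def confidence_ellipse(points: np.ndarray, level: float = 0.87) -> ConfidenceEllipse:
    """Chi-square (2 df) confidence ellipse of a 2D point cloud.

    Semi-axes are sqrt(eigenvalue * chi2.ppf(level, 2)) of the sample
    covariance; level = 0 degenerates to the center point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("confidence_ellipse needs >= 3 points in 2D")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-12 * max(evals[0], 1.0))
    if degenerate:
        warnings.warn("singular covariance; degenerate ellipse", stacklevel=2)
    q = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    semi = tuple(float(math.sqrt(max(ev, 0.0) * q)) for ev in evals)
    angle = float(math.atan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=semi,
        angle_rad=angle,
        degenerate=degenerate,
    )


@dataclass
class OverlapResult:
    sample_ids: tuple[str, ...]
    phylotype_overlap_pct: float
    sequence_overlap_pct: float


def phylotype_overlap(
    t: OtuTable, sample_ids: Sequence[str], denominator: str = "union"
) -> OverlapResult:
    """Shared-phylotype and shared-sequence fractions over a sample set.

    Phylotype overlap is 100 * |intersection| / |union| of the presence
    sets (presence = count > 0); ``denominator='mean_fraction'`` instead
    averages |intersection| / |sample| over the samples. Sequence overlap
    is the percentage of all reads in the set that belong to shared OTUs.
    """
    if len(sample_ids) < 2:
        raise ValidationError("overlap needs at least 2 samples")
    cols = np.column_stack([t.counts[:, t.sample_index(s)] for s in sample_ids])
    if (cols.sum(axis=0) == 0).any():
        raise ValidationError("empty sample in overlap set")
    present = cols > 0
    shared = present.all(axis=1)
    union = present.any(axis=1)
    if denominator == "union":
        phylo = 100.0 * shared.sum() / union.sum()
    elif denominator == "mean_fraction":
        phylo = float(100.0 * np.mean(shared.sum() / present.sum(axis=0)))
    else:
        raise ValueError("denominator must be 'union' or 'mean_fraction'")
    seq = 100.0 * cols[shared].sum() / cols.sum()
    return OverlapResult(
        sample_ids=tuple(sample_ids),
        phylotype_overlap_pct=float(phylo),
        sequence_overlap_pct=float(seq),
    )


def phylum_of(t: OtuTable, confidence_cutoff: float = 0.80) -> dict[str, str]:
    """Thresholded phylum name per OTU ('unclassified' when unresolved)."""
    out = {}
    for otu in t.otu_ids:
        tax = t.taxonomy.get(otu)
        if tax is None:
            out[otu] = UNCLASSIFIED
        else:
            out[otu] = apply_confidence_threshold(tax, confidence_cutoff).name_at("phylum")
    return out


def phylum_composition(
    t: OtuTable,
    group_by: Mapping[str, str],
    other_threshold_pct: float = 2.0,
    confidence_cutoff: float = 0.80,
) -> pd.DataFrame:
    """Per-group mean phylum composition in percent.

    ``group_by`` maps sample_id -> group label. Phyla whose mean abundance
    in a group falls below ``other_threshold_pct`` are pooled into 'Other';
    the 'unclassified' bucket (domain-only assignments) is kept separate.
    Rows are groups, columns phyla (plus 'Other'); each row sums to 100.
    """
    abund = relative_abundance(t)
    phyla = phylum_of(t, confidence_cutoff)
    df = abund.to_dataframe()
    df.index = pd.Index([phyla[o] for o in t.otu_ids], name="phylum")
    by_phylum = df.groupby(level=0).sum()
    rows = {}
    for group in sorted(set(group_by.values())):
        samples = [s for s, g in group_by.items() if g == group]
        mean = by_phylum[samples].mean(axis=1)
        pooled: dict[str, float] = {}
        for phylum, val in mean.items():
            if phylum != UNCLASSIFIED and val < other_threshold_pct:
                pooled["Other"] = pooled.get("Other", 0.0) + float(val)
            else:
                pooled[phylum] = float(val)
        rows[group] = pooled
    out = pd.DataFrame(rows).T.fillna(0.0)
    out.index.name = "group"
    return out
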