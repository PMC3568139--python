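"""Depth normalization and the jittered log2 transform.

Counts are scaled to the deepest sample in the analysis set (factor
max_depth / depth, so all column sums equal the maximum raw depth), and a
uniform jitter in [0.75, 1.25] is added before log2 so that zeros map near
0 and the transform downweights highly abundant OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import OtuTable, ValidationError


@dataclass
class NormalizationResult:
    otu_ids: list[str]
    sample_ids: list[str]
    scaled: np.ndarray  # real-valued counts x factor
    factors: dict[str, float]  # sample_id -> factor >= 1

    @property
    def max_depth(self) -> float:
        return float(self.scaled.sum(axis=0)[0])


def normalize_to_max_depth(
    t: OtuTable, scope: Sequence[str] | None = None
) -> NormalizationResult:
    """Scale each scoped sample's counts by max_depth / depth.

    ``scope`` restricts the analysis set (default: all samples); the deepest
    scoped sample gets factor 1 and every scaled column sums to its depth.
    """
    sub = t if scope is None else t.subset_samples(list(scope))
    if sub.n_samples == 0:
        raise ValidationError("empty normalization scope")
    depths = sub.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        raise ValidationError(
            f"zero-depth sample(s) in scope: {[sub.sample_ids[i] for i in zero]}"
        )
    factors = depths.max() / depths
    scaled = sub.counts * factors
    return NormalizationResult(
        otu_ids=list(sub.otu_ids),
        sample_ids=list(sub.sample_ids),
        scaled=scaled,
        factors={s: float(f) for s, f in zip(sub.sample_ids, factors)},
    )


def jittered_log2(
    m: np.ndarray, seed: int | None = None, jitter: str = "uniform"
) -> np.ndarray:
    """log2(x + u) with u ~ U(0.75, 1.25) drawn independently per entry.

    ``jitter='off'`` uses u = 1 exactly (deterministic test mode).
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("jittered_log2 requires non-negative entries")
    if jitter == "off":
        u = 1.0
    elif jitter == "uniform":
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.75, 1.25, size=m.shape)
    else:
        raise ValueError(f"jitter must be 'uniform' or 'off', got {jitter!r}")
    return np.log2(m + u)
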