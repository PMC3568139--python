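"""Dirichlet-multinomial simulator for longitudinal PEG wash-out studies.

The generator emulates the study design the analysis assumes: four
individuals sampled in stool at four time-points (two pre-diarrhea
baselines, one during osmotic diarrhea, one post-diarrhea) and, for all
but the first individual, sigmoid mucosa at the two time-points flanking
diarrhea onset. Communities are individualized Dirichlet draws around
habitat-level phylum templates (Bacteroidetes-dominant stool,
Firmicutes-dominant mucosa), partitioned into per-OTU log-normal
abundances. The diarrhea time-point applies planted responder fold
changes, wash-out dropout of rare OTUs, and a Proteobacteria multiplier on
the mucosa; counts are multinomial draws at negative-binomially
distributed depths (mean ~20,000 reads per sample). Planted responder,
stable and null OTU labels are emitted for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import OtuTable, TaxonomyAssignment, parse_taxonomy_string

STOOL_TEMPLATE = {
    "Bacteroidetes": 0.70,
    "Firmicutes": 0.22,
    "Proteobacteria": 0.02,
    "Actinobacteria": 0.02,
    "Verrucomicrobia": 0.02,
    "TM7": 0.01,
    "Fusobacteria": 0.01,
}

MUCOSA_TEMPLATE = {
    "Firmicutes": 0.75,
    "Bacteroidetes": 0.18,
    "Proteobacteria": 0.05,
    "Actinobacteria": 0.008,
    "Verrucomicrobia": 0.006,
    "TM7": 0.003,
    "Fusobacteria": 0.003,
}

# fraction of the OTU identity pool per phylum (taxon richness, not reads)
PHYLUM_POOL_FRACTIONS = {
    "Bacteroidetes": 0.34,
    "Firmicutes": 0.40,
    "Proteobacteria": 0.12,
    "Actinobacteria": 0.06,
    "Verrucomicrobia": 0.04,
    "TM7": 0.02,
    "Fusobacteria": 0.02,
}


@dataclass(frozen=True)
class ResponderSpec:
    """A block of planted responders: ``n`` OTUs changed ``fold``-fold at the
    diarrhea time-point; ``rebound`` restores baseline post-diarrhea."""

    n: int
    fold: float
    rebound: bool = True
    habitat: str = "stool"


@dataclass
class SimConfig:
    n_individuals: int = 4
    n_otus: int = 500
    stool_timepoints: tuple[int, ...] = (1, 2, 3, 4)
    mucosa_timepoints: tuple[int, ...] = (2, 3)
    depth_mean: float = 20000.0
    depth_size: float = 60.0  # negative-binomial size (overdispersion)
    dirichlet_concentration: float = 200.0
    lognormal_sigma: float = 1.5
    responders: tuple[ResponderSpec, ...] = (
        ResponderSpec(n=10, fold=5.0, rebound=True, habitat="stool"),
        ResponderSpec(n=10, fold=0.2, rebound=True, habitat="stool"),
    )
    responder_base_range: tuple[float, float] = (0.5, 1.0)  # percent
    n_stable_planted: int = 20
    stable_base_range: tuple[float, float] = (0.5, 1.2)  # percent
    stable_firmicutes_fraction: float = 0.6  # Firmicutes overrepresented among stable
    temporal_sigma: float = 0.4  # natural-log sd of day-to-day variability
    washout_prob: float = 0.3
    washout_threshold_pct: float = 0.05
    proteo_bloom_factor: float = 3.0  # mucosa diarrhea multiplier
    shared_baseline: bool = False  # one community for all individuals (calibration)
    seed: int = 0

    def __post_init__(self):
        if sum(r.n for r in self.responders) + self.n_stable_planted > self.n_otus:
            raise ValueError("more planted OTUs than n_otus")
        for r in self.responders:
            if r.fold <= 0:
                raise ValueError("fold changes must be positive")
        if not 0.0 <= self.washout_prob <= 1.0:
            raise ValueError("washout_prob must be in [0, 1]")

    @property
    def individuals(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_individuals)]

    @property
    def mucosa_individuals(self) -> list[str]:
        # biopsies from all but the first subject under the default design
        return self.individuals[1:] if self.n_individuals > 1 else []


@dataclass
class GroundTruth:
    """Planted labels: responder OTUs with their intended pattern, stable
    OTUs, OTUs the wash-out dropout actually removed in at least one
    individual (genuinely changed, though not pattern-planted), and the
    remaining null OTUs. The label sets are disjoint."""

    responders: dict[str, dict] = field(default_factory=dict)
    stable: set[str] = field(default_factory=set)
    washed_out: set[str] = field(default_factory=set)
    nulls: set[str] = field(default_factory=set)

    def __post_init__(self):
        sets = [set(self.responders), self.stable, self.washed_out, self.nulls]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("truth label sets must be disjoint")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "responders": self.responders,
                    "stable": sorted(self.stable),
                    "washed_out": sorted(self.washed_out),
                    "nulls": sorted(self.nulls),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            responders=d["responders"],
            stable=set(d["stable"]),
            washed_out=set(d.get("washed_out", [])),
            nulls=set(d["nulls"]),
        )


def _intended_pattern(fold: float, rebound: bool, habitat: str) -> str:
    if habitat == "mucosa":
        return "increase" if fold > 1 else "decrease"
    first = "increase" if fold > 1 else "decrease"
    second = ("decrease" if fold > 1 else "increase") if rebound else "flat"
    return f"{first}-{second}"


def _make_taxonomy(rng: np.random.Generator, phyla: Sequence[str]) -> list[str]:
    """RDP-style strings; a few OTUs get sub-cutoff phylum confidence so the
    'unclassified' bucket is exercised."""
    strings = []
    for i, ph in enumerate(phyla):
        low = rng.random() < 0.03
        ph_conf = round(float(rng.uniform(0.3, 0.7) if low else rng.uniform(0.85, 1.0)), 2)
        genus = f"{ph[:5]}Genus{i % 23}"
        strings.append(
            f"Bacteria1.0{ph}{ph_conf}{ph}_class0.95{ph}_order0.93"
            f"{ph}_family0.9{genus}0.88"
        )
    return strings


def simulate_study(cfg: SimConfig) -> tuple[OtuTable, pd.DataFrame, GroundTruth]:
    """Generate one study: OTU count table, sample sheet, planted truth.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_otus
    otu_ids = [f"OTU_{i + 1}" for i in range(n)]

    # phylum identity pool
    phyla_names = list(PHYLUM_POOL_FRACTIONS)
    pool_counts = np.floor(
        np.array([PHYLUM_POOL_FRACTIONS[p] for p in phyla_names]) * n
    ).astype(int)
    while pool_counts.sum() < n:
        pool_counts[np.argmax(pool_counts)] += 1
    phylum_idx = np.repeat(np.arange(len(phyla_names)), pool_counts)
    phylum_by_otu = np.array(phyla_names)[phylum_idx]

    tax_strings = _make_taxonomy(rng, phylum_by_otu)
    taxonomy: dict[str, TaxonomyAssignment] = {
        o: parse_taxonomy_string(s) for o, s in zip(otu_ids, tax_strings)
    }

    # planted labels drawn from realistic pools: responders from the two
    # dominant phyla, stable OTUs predominantly Firmicutes
    big = np.flatnonzero(np.isin(phylum_by_otu, ["Bacteroidetes", "Firmicutes"]))
    n_resp = sum(r.n for r in cfg.responders)
    resp_idx = rng.choice(big, size=n_resp, replace=False)
    n_firm_stable = int(round(cfg.stable_firmicutes_fraction * cfg.n_stable_planted))
    firm = np.setdiff1d(np.flatnonzero(phylum_by_otu == "Firmicutes"), resp_idx)
    bact = np.setdiff1d(np.flatnonzero(phylum_by_otu == "Bacteroidetes"), resp_idx)
    stable_idx = np.concatenate(
        [
            rng.choice(firm, size=n_firm_stable, replace=False),
            rng.choice(bact, size=cfg.n_stable_planted - n_firm_stable, replace=False),
        ]
    )

    responders: dict[str, dict] = {}
    k = 0
    resp_fold = np.ones(n)
    resp_rebound = np.zeros(n, dtype=bool)
    for spec in cfg.responders:
        for _ in range(spec.n):
            i = resp_idx[k]
            responders[otu_ids[i]] = {
                "habitat": spec.habitat,
                "fold": spec.fold,
                "rebound": spec.rebound,
                "pattern": _intended_pattern(spec.fold, spec.rebound, spec.habitat),
            }
            resp_fold[i] = spec.fold
            resp_rebound[i] = spec.rebound
            k += 1
    stable_set = {otu_ids[i] for i in stable_idx}
    is_resp = np.zeros(n, dtype=bool)
    is_resp[resp_idx] = True
    is_stable = np.zeros(n, dtype=bool)
    is_stable[stable_idx] = True
    is_proteo = phylum_by_otu == "Proteobacteria"

    def baseline(template: dict[str, float]) -> np.ndarray:
        """One individual's baseline composition (sums to 1)."""
        alpha = np.array([template[p] for p in phyla_names]) * cfg.dirichlet_concentration
        phylum_frac = rng.dirichlet(alpha)
        w = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=n)
        comp = np.zeros(n)
        for j in range(len(phyla_names)):
            members = phylum_idx == j
            comp[members] = phylum_frac[j] * w[members] / w[members].sum()
        # pin planted OTUs at their drawn baseline abundance
        pinned = np.zeros(n)
        pinned[resp_idx] = rng.uniform(*cfg.responder_base_range, size=n_resp) / 100.0
        pinned[stable_idx] = (
            rng.uniform(*cfg.stable_base_range, size=cfg.n_stable_planted) / 100.0
        )
        free = ~(is_resp | is_stable)
        comp[free] *= (1.0 - pinned.sum()) / comp[free].sum()
        comp[~free] = pinned[~free]
        return comp

    def close_composition(q: np.ndarray, p0: np.ndarray) -> np.ndarray:
        """Add day-to-day biological noise and close the composition while
        holding planted-stable OTUs at their baseline relative abundance
        (stable phylotypes are stable by definition)."""
        out = q.copy()
        if cfg.temporal_sigma > 0:
            noise = rng.lognormal(0.0, cfg.temporal_sigma, size=n)
            out[~is_stable] *= noise[~is_stable]
        out[is_stable] = p0[is_stable]
        s = p0[is_stable].sum()
        rest = out[~is_stable].sum()
        if rest > 0:
            out[~is_stable] *= (1.0 - s) / rest
        return out

    def diarrhea_comp(p0: np.ndarray, habitat: str) -> tuple[np.ndarray, np.ndarray]:
        q = p0.copy()
        if habitat == "stool":
            q[resp_idx] = p0[resp_idx] * resp_fold[resp_idx]
        washable = (p0 < cfg.washout_threshold_pct / 100.0) & ~is_resp & ~is_stable
        drop = washable & (rng.random(n) < cfg.washout_prob)
        if habitat == "mucosa":
            q[is_proteo] *= cfg.proteo_bloom_factor
        q = close_composition(q, p0)
        q[drop] = 0.0
        return q, drop

    def post_comp(p0: np.ndarray, q3: np.ndarray, dropped: np.ndarray) -> np.ndarray:
        q = p0.copy()
        nonrebound = is_resp & ~resp_rebound
        q[nonrebound] = q3[nonrebound]
        q = close_composition(q, p0)
        q[dropped] = 0.0  # wash-out persists one week post-diarrhea
        return q

    def draw_counts(comp: np.ndarray) -> np.ndarray:
        depth = 0
        while depth < 1:
            depth = int(
                rng.negative_binomial(
                    cfg.depth_size, cfg.depth_size / (cfg.depth_size + cfg.depth_mean)
                )
            )
        return rng.multinomial(depth, comp / comp.sum())

    shared: dict[str, np.ndarray] = {}
    if cfg.shared_baseline:
        shared["stool"] = baseline(STOOL_TEMPLATE)
        shared["mucosa"] = baseline(MUCOSA_TEMPLATE)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    dropped_any = np.zeros(n, dtype=bool)
    for ind in cfg.individuals:
        p0 = shared.get("stool") if cfg.shared_baseline else baseline(STOOL_TEMPLATE)
        q3, dropped = diarrhea_comp(p0, "stool")
        dropped_any |= dropped
        q4 = post_comp(p0, q3, dropped)
        comp_by_tp = {
            1: close_composition(p0, p0),
            2: close_composition(p0, p0),
            3: q3,
            4: q4,
        }
        for tp in cfg.stool_timepoints:
            sid = f"{ind}F{tp}"
            columns[sid] = draw_counts(comp_by_tp[tp])
            meta_rows.append((sid, ind, "stool", tp))
    for ind in cfg.mucosa_individuals:
        p0 = shared.get("mucosa") if cfg.shared_baseline else baseline(MUCOSA_TEMPLATE)
        q3, dropped = diarrhea_comp(p0, "mucosa")
        dropped_any |= dropped
        comp_by_tp = {2: close_composition(p0, p0), 3: q3}
        for tp in cfg.mucosa_timepoints:
            sid = f"{ind}M{tp}"
            columns[sid] = draw_counts(comp_by_tp[tp])
            meta_rows.append((sid, ind, "mucosa", tp))

    washed = {otu_ids[i] for i in np.flatnonzero(dropped_any)}
    truth = GroundTruth(
        responders=responders,
        stable=stable_set,
        washed_out=washed,
        nulls=set(otu_ids) - set(responders) - stable_set - washed,
    )

    sample_ids = list(columns)
    table = OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_ids,
        counts=np.column_stack([columns[s] for s in sample_ids]),
        taxonomy=taxonomy,
    )
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual", "habitat", "timepoint"]
    )
    return table, meta, truth


def null_config(seed: int = 0, n_otus: int = 200, **kwargs) -> SimConfig:
    """All effects off and one shared baseline community, so every sample of
    a habitat is independent and identically distributed: pre-diarrhea and
    diarrhea groups are fully exchangeable (calibration runs)."""
    return SimConfig(
        n_otus=n_otus,
        responders=(),
        n_stable_planted=0,
        washout_prob=0.0,
        proteo_bloom_factor=1.0,
        shared_baseline=True,
        seed=seed,
        **kwargs,
    )


@dataclass
class RecoveryMetrics:
    sensitivity: float
    fdr: float
    n_detected: int
    fdr_defined: bool


def recovery_metrics(detected: Sequence[str] | set, truth: GroundTruth) -> RecoveryMetrics:
    """Sensitivity = detected responders / planted responders;
    FDR = detected nulls / all detected (0, flagged, when nothing is
    detected)."""
    if not truth.responders and not truth.stable and not truth.nulls:
        raise ValueError("empty ground truth")
    det = set(detected)
    n_resp = len(truth.responders)
    sens = len(det & set(truth.responders)) / n_resp if n_resp else float("nan")
    if det:
        fdr = len(det & truth.nulls) / len(det)
        return RecoveryMetrics(sens, fdr, len(det), True)
    return RecoveryMetrics(sens, 0.0, 0, False)
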