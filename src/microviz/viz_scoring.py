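"""Slope scoring of abundance trajectories (*Viz*).

Each OTU gets, per individual, a trajectory profile in relative-abundance
percent: stool profiles have three points (pre-diarrhea = mean of the two
baseline time-points, diarrhea, post-diarrhea), mucosa profiles two points
(pre-diarrhea, diarrhea). Each slope between consecutive points is scored
-1 / 0 / +1 against a change threshold (0.05 percentage points by default;
changes of at least the threshold count). The first slope score times 3
plus the second maps bijectively onto 9 patterns; two-point profiles map
onto 3. OTUs whose pattern recurs in at least ``min_individuals``
individuals form the pattern-association network.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .data_model import AbundanceMatrix, UNCLASSIFIED

DEFAULT_THRESHOLD = 0.05  # percentage points
DEFAULT_MIN_INDIVIDUALS = 2

_SLOPE_WORD = {-1: "decrease", 0: "flat", 1: "increase"}

#: overall score -> pattern label, three-point profiles (score = 3*s1 + s2)
PATTERN_LABELS_3PT = {
    3 * s1 + s2: f"{_SLOPE_WORD[s1]}-{_SLOPE_WORD[s2]}"
    for s1 in (-1, 0, 1)
    for s2 in (-1, 0, 1)
}

#: overall score -> pattern label, two-point profiles
PATTERN_LABELS_2PT = {s: _SLOPE_WORD[s] for s in (-1, 0, 1)}


@dataclass(frozen=True)
class Profile:
    """Trajectory of one OTU in one individual/habitat."""

    otu_id: str
    individual: str
    habitat: str
    points: tuple[tuple[str, float], ...]  # (state label, percent)

    def __post_init__(self):
        if len(self.points) not in (2, 3):
            raise ValueError("profiles have 2 or 3 points")
        if any(v < 0 for _, v in self.points):
            raise ValueError("abundances must be non-negative")


@dataclass(frozen=True)
class PatternAssignment:
    otu_id: str
    individual: str
    slope_scores: tuple[int, ...]
    overall_score: int
    pattern_label: str
    included: bool


def build_stool_profile(
    a1: float, a2: float, a3: float, a4: float,
    otu_id: str = "", individual: str = "",
) -> Profile:
    """Three-point profile: pre = (a1 + a2)/2, diarrhea = a3, post = a4."""
    for v in (a1, a2, a3, a4):
        if v is None:
            raise ValueError("stool profiles require all four time-points")
    return Profile(
        otu_id=otu_id,
        individual=individual,
        habitat="stool",
        points=(("pre", (a1 + a2) / 2.0), ("diarrhea", a3), ("post", a4)),
    )


def build_mucosa_profile(
    a2: float, a3: float, otu_id: str = "", individual: str = ""
) -> Profile:
    """Two-point profile: pre-diarrhea and diarrhea states."""
    return Profile(
        otu_id=otu_id,
        individual=individual,
        habitat="mucosa",
        points=(("pre", a2), ("diarrhea", a3)),
    )


def slope_score(a: float, b: float, threshold: float = DEFAULT_THRESHOLD) -> int:
    """-1 / 0 / +1 for the slope a -> b; |b - a| >= threshold scores +-1
    (a change of at least the threshold counts, the boundary included)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    delta = b - a
    if abs(delta) < threshold:
        return 0
    return 1 if delta > 0 else -1


def profile_score(p: Profile, threshold: float = DEFAULT_THRESHOLD) -> PatternAssignment:
    """Score a profile's slopes and map to its pattern.

    Three-point: overall = 3*s1 + s2 over 9 patterns; two-point: overall = s1
    over 3 patterns. An OTU is included when at least one slope change
    reaches the threshold (so included profiles are never all-flat).
    """
    values = [v for _, v in p.points]
    slopes = tuple(
        slope_score(values[i], values[i + 1], threshold) for i in range(len(values) - 1)
    )
    if len(slopes) == 2:
        overall = 3 * slopes[0] + slopes[1]
        label = PATTERN_LABELS_3PT[overall]
    else:
        overall = slopes[0]
        label = PATTERN_LABELS_2PT[overall]
    included = any(
        abs(values[i + 1] - values[i]) >= threshold for i in range(len(values) - 1)
    )
    return PatternAssignment(
        otu_id=p.otu_id,
        individual=p.individual,
        slope_scores=slopes,
        overall_score=overall,
        pattern_label=label,
        included=included,
    )


def score_habitat(
    abund: AbundanceMatrix,
    meta: pd.DataFrame,
    habitat: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[PatternAssignment]:
    """Score every OTU in every individual of one habitat.

    Stool requires time-points 1-4 per individual, mucosa 2-3; individuals
    with missing time-points are skipped with a warning.
    """
    from .data_model import select_samples

    need = (1, 2, 3, 4) if habitat == "stool" else (2, 3)
    out: list[PatternAssignment] = []
    for ind in sorted(meta.loc[meta["habitat"] == habitat, "individual"].unique()):
        sample_by_tp = {}
        ok = True
        for tp in need:
            hits = select_samples(meta, habitat=habitat, timepoint=tp, individual=ind)
            if len(hits) != 1:
                warnings.warn(
                    f"individual {ind}: expected one {habitat} sample at "
                    f"time-point {tp}, found {len(hits)}; skipped",
                    stacklevel=2,
                )
                ok = False
                break
            sample_by_tp[tp] = hits[0]
        if not ok:
            continue
        cols = {tp: abund.col(s) for tp, s in sample_by_tp.items()}
        for i, otu in enumerate(abund.otu_ids):
            if habitat == "stool":
                prof = build_stool_profile(
                    cols[1][i], cols[2][i], cols[3][i], cols[4][i],
                    otu_id=otu, individual=ind,
                )
            else:
                prof = build_mucosa_profile(
                    cols[2][i], cols[3][i], otu_id=otu, individual=ind
                )
            out.append(profile_score(prof, threshold))
    return out


@dataclass(frozen=True)
class Association:
    otu_id: str
    pattern_label: str
    support: int  # number of individuals


def associate_patterns(
    assignments: Iterable[PatternAssignment],
    min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
) -> list[Association]:
    """(OTU, pattern) pairs whose included pattern recurs in at least
    ``min_individuals`` individuals.

    An OTU has at most one pattern per individual but may associate with
    different patterns through different individuals.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        if not a.included:
            continue
        support.setdefault((a.otu_id, a.pattern_label), set()).add(a.individual)
    return [
        Association(otu, label, len(inds))
        for (otu, label), inds in sorted(support.items())
        if len(inds) >= min_individuals
    ]


def associations_frame(associations: Sequence[Association]) -> pd.DataFrame:
    return pd.DataFrame(
        [a.__dict__ for a in associations],
        columns=["otu_id", "pattern_label", "support"],
    )


def mean_abundance_change(
    assignments: Iterable[PatternAssignment],
    abund: AbundanceMatrix,
    meta: pd.DataFrame,
    habitat: str,
    mode: str = "mean",
) -> dict[str, float]:
    """Per-OTU node size: mean (default) or sum over individuals of the
    absolute slope changes of that OTU's included profiles."""
    from .data_model import select_samples

    deltas: dict[str, list[float]] = {}
    need = (1, 2, 3, 4) if habitat == "stool" else (2, 3)
    idx = {o: i for i, o in enumerate(abund.otu_ids)}
    for ind in sorted(meta.loc[meta["habitat"] == habitat, "individual"].unique()):
        cols = {}
        ok = True
        for tp in need:
            hits = select_samples(meta, habitat=habitat, timepoint=tp, individual=ind)
            if len(hits) != 1:
                ok = False
                break
            cols[tp] = abund.col(hits[0])
        if not ok:
            continue
        for otu, i in idx.items():
            if habitat == "stool":
                pre = (cols[1][i] + cols[2][i]) / 2.0
                ds = [abs(cols[3][i] - pre), abs(cols[4][i] - cols[3][i])]
            else:
                ds = [abs(cols[3][i] - cols[2][i])]
            per_ind = sum(ds) if mode == "sum" else sum(ds) / len(ds)
            deltas.setdefault(otu, []).append(per_ind)
    return {o: sum(v) / len(v) for o, v in deltas.items()}


def build_network(
    associations: Sequence[Association],
    phylum_by_otu: Mapping[str, str] | None = None,
    size_by_otu: Mapping[str, float] | None = None,
    methods_by_otu: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Bipartite OTU / pattern graph; edge weight = supporting individuals."""
    g = nx.Graph()
    for a in associations:
        if not g.has_node(a.otu_id):
            g.add_node(
                a.otu_id,
                kind="otu",
                phylum=(phylum_by_otu or {}).get(a.otu_id, UNCLASSIFIED),
                mean_abundance_change=float((size_by_otu or {}).get(a.otu_id, 0.0)),
                methods_confirming=(methods_by_otu or {}).get(a.otu_id, ""),
            )
        if not g.has_node(a.pattern_label):
            g.add_node(a.pattern_label, kind="pattern")
        g.add_edge(a.otu_id, a.pattern_label, support=a.support)
    return g


def export_network(
    network: nx.Graph, out_prefix: str | Path, format: str = "sif"
) -> list[Path]:
    """Write the association network in a Cytoscape-loadable format.

    ``sif`` writes an edge file (otu  pattern_of  pattern) plus a
    node-attribute TSV; ``graphml`` writes a single file with the same
    attributes. Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    if network.number_of_edges() == 0:
        warnings.warn("empty association network; writing empty files", stacklevel=2)
    if format == "graphml":
        path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(network, path)
        return [path]
    if format != "sif":
        raise ValueError(f"format must be 'sif' or 'graphml', got {format!r}")
    sif = out_prefix.with_suffix(".sif")
    attrs = out_prefix.with_suffix(".node_attrs.tsv")
    with open(sif, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for u, v, d in sorted(network.edges(data=True)):
            otu, pattern = (u, v) if network.nodes[u].get("kind") == "otu" else (v, u)
            w.writerow([otu, "pattern_of", pattern, d.get("support", 1)])
    with open(attrs, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node", "kind", "phylum", "mean_abundance_change", "methods_confirming"])
        for n, d in sorted(network.nodes(data=True)):
            w.writerow([
                n,
                d.get("kind", ""),
                d.get("phylum", ""),
                d.get("mean_abundance_change", ""),
                d.get("methods_confirming", ""),
            ])
    return [sif, attrs]


def read_sif(path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a SIF edge file back into (otu, pattern, support) triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            otu, _, pattern = parts[:3]
            support = int(parts[3]) if len(parts) > 3 else 1
            out.append((otu, pattern, support))
    return out
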