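"""Core containers for longitudinal OTU-table studies.

The universal input is an integer OTU x sample count matrix with optional
RDP-style taxonomy strings, plus a sample sheet describing the longitudinal
design (individual, habitat, time-point). Taxonomy strings are concatenated
(name, confidence) pairs, e.g. ``Bacteria1.0Firmicutes0.98...``, where each
confidence is a bootstrap-style score in [0, 1] and ranks run positionally
domain -> genus.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANK_NAMES: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"

HABITATS = ("stool", "mucosa")


class ValidationError(ValueError):
    """Raised when a table or sample sheet violates its invariants."""


class TaxonomyParseError(ValueError):
    """Raised when a taxonomy string cannot be consumed by the grammar."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class SampleMeta:
    """Design labels for one sample."""

    sample_id: str
    individual: str
    habitat: str
    timepoint: int

    def __post_init__(self):
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"habitat must be one of {HABITATS}, got {self.habitat!r}"
            )


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Ordered (rank, taxon, confidence) triples, possibly truncated after any rank."""

    ranks: tuple[tuple[str, str, float], ...]

    def __post_init__(self):
        for i, (rank, _, conf) in enumerate(self.ranks):
            if rank != RANK_NAMES[i]:
                raise ValidationError(
                    f"ranks out of canonical order: position {i} is {rank!r}"
                )
            if not 0.0 <= conf <= 1.0:
                raise ValidationError(f"confidence {conf} outside [0, 1] at rank {rank}")

    def get(self, rank: str) -> tuple[str, float] | None:
        """Return (taxon, confidence) at ``rank``, or None if truncated above it."""
        for name, taxon, conf in self.ranks:
            if name == rank:
                return taxon, conf
        return None

    def name_at(self, rank: str) -> str:
        """Taxon name at ``rank``; 'unclassified' if absent."""
        hit = self.get(rank)
        return hit[0] if hit is not None else UNCLASSIFIED

    def to_string(self) -> str:
        """Serialize back to the concatenated name/confidence form."""
        return "".join(f"{taxon}{_fmt_conf(conf)}" for _, taxon, conf in self.ranks)


def _fmt_conf(conf: float) -> str:
    # shortest decimal that round-trips the stored value ("1.0", "0.98", "0.9")
    s = repr(conf)
    if "." not in s:
        s += ".0"
    return s


# A confidence token: integer part 0 or 1, a dot, then digits.
_CONF_RE = re.compile(r"(.+?)([01]\.\d+)")


def parse_taxonomy_string(s: str) -> TaxonomyAssignment:
    """Parse an RDP-style concatenated taxonomy string.

    The name is matched greedily-minimal and the confidence token is the
    right-anchored maximal ``[01].digits`` match, which uniquely resolves
    names that themselves end in digits (``TM70.53`` -> (TM7, 0.53),
    ``Incertae sedis 50.87`` -> (Incertae sedis 5, 0.87)).
    """
    ranks: list[tuple[str, str, float]] = []
    pos = 0
    while pos < len(s):
        m = _CONF_RE.match(s, pos)
        if m is None:
            raise TaxonomyParseError(f"cannot parse taxonomy string {s!r}", pos)
        if len(ranks) >= len(RANK_NAMES):
            raise TaxonomyParseError(
                f"more than {len(RANK_NAMES)} rank pairs in {s!r}", pos
            )
        ranks.append((RANK_NAMES[len(ranks)], m.group(1), float(m.group(2))))
        pos = m.end()
    if not ranks:
        raise TaxonomyParseError("empty taxonomy string", 0)
    return TaxonomyAssignment(tuple(ranks))


def apply_confidence_threshold(
    t: TaxonomyAssignment, cutoff: float = 0.80
) -> TaxonomyAssignment:
    """Replace the first rank with confidence < cutoff, and all deeper ranks,
    by the 'unclassified' sentinel (confidence kept for transparency)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    out: list[tuple[str, str, float]] = []
    failed = False
    for rank, taxon, conf in t.ranks:
        if failed or conf < cutoff:
            failed = True
            out.append((rank, UNCLASSIFIED, conf))
        else:
            out.append((rank, taxon, conf))
    return TaxonomyAssignment(tuple(out))


@dataclass
class OtuTable:
    """Integer count matrix (OTU x sample) with optional per-OTU taxonomy."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, TaxonomyAssignment] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        _check_unique(self.otu_ids, "otu_id")
        _check_unique(self.sample_ids, "sample_id")
        unknown = set(self.taxonomy) - set(self.otu_ids)
        if unknown:
            raise ValidationError(f"taxonomy keys not in otu_ids: {sorted(unknown)[:5]}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="depth")

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            otu_ids=list(self.otu_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            taxonomy=dict(self.taxonomy),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)
        df.index.name = "otu_id"
        return df


@dataclass
class AbundanceMatrix:
    """Real-valued OTU x sample matrix: percent of sample total, or transformed."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    units: str = "percent"  # "percent" | "transformed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError("values shape does not match ids")
        if self.units == "percent":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 100.0, atol=1e-9):
                raise ValidationError("percent columns must sum to 100 within 1e-9")

    def row(self, otu_id: str) -> np.ndarray:
        return self.values[self.otu_ids.index(otu_id)]

    def col(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)
        df.index.name = "otu_id"
        return df


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def relative_abundance(t: OtuTable) -> AbundanceMatrix:
    """Counts to percent-of-sample-total; every column then sums to 100."""
    sums = t.counts.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(
            f"zero-depth sample(s): {[t.sample_ids[i] for i in zero]}"
        )
    values = 100.0 * t.counts / sums
    return AbundanceMatrix(list(t.otu_ids), list(t.sample_ids), values, units="percent")


# ---------------------------------------------------------------------------
# I/O


def read_otu_table(path: str | Path, taxonomy_column: str | None = "taxonomy") -> OtuTable:
    """Read a tab-separated OTU table (first column OTU id, header sample ids,
    optional final taxonomy column holding the concatenated RDP string)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        raise ValidationError(f"duplicated column header in {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)

    taxonomy: dict[str, TaxonomyAssignment] = {}
    if taxonomy_column is not None and taxonomy_column in df.columns:
        for otu, s in df[taxonomy_column].items():
            if s:
                taxonomy[str(otu)] = parse_taxonomy_string(s)
        df = df.drop(columns=[taxonomy_column])

    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (otu, raw) in enumerate(df[col].items()):
            try:
                counts[i, j] = int(raw)
            except ValueError:
                raise ValidationError(
                    f"non-integer count {raw!r} at OTU {otu!r}, sample {col!r}"
                ) from None
    return OtuTable(
        otu_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        counts=counts,
        taxonomy=taxonomy,
    )


def write_otu_table(t: OtuTable, path: str | Path, taxonomy_column: str = "taxonomy") -> None:
    df = t.to_dataframe()
    if t.taxonomy:
        df[taxonomy_column] = [
            t.taxonomy[o].to_string() if o in t.taxonomy else "" for o in t.otu_ids
        ]
    df.to_csv(path, sep="\t")


META_COLUMNS = ("sample_id", "individual", "habitat", "timepoint")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (TSV with sample_id, individual, habitat, timepoint).

    Unknown extra columns are preserved but ignored by the pipeline.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual": str})
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    df["timepoint"] = df["timepoint"].astype(int)
    validate_metadata(df)
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_metadata(meta: pd.DataFrame) -> None:
    """Hard invariants raise; soft design expectations only warn, since
    longitudinal designs are configurable."""
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id: {dup!r}")
    bad = set(meta["habitat"]) - set(HABITATS)
    if bad:
        raise ValidationError(f"unknown habitat(s): {sorted(bad)}")
    mucosa = meta[meta["habitat"] == "mucosa"]
    odd = mucosa[~mucosa["timepoint"].isin([2, 3])]
    if len(odd):
        warnings.warn(
            f"mucosa samples outside time-points {{2,3}}: "
            f"{odd['sample_id'].tolist()}",
            stacklevel=2,
        )


def metadata_records(meta: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(r.sample_id, r.individual, r.habitat, int(r.timepoint))
        for r in meta.itertuples()
    ]


def select_samples(
    meta: pd.DataFrame,
    habitat: str | None = None,
    timepoint: int | None = None,
    individual: str | None = None,
) -> list[str]:
    """Sample ids matching the given design labels, in sheet order."""
    m = meta
    if habitat is not None:
        m = m[m["habitat"] == habitat]
    if timepoint is not None:
        m = m[m["timepoint"] == timepoint]
    if individual is not None:
        m = m[m["individual"] == individual]
    return m["sample_id"].tolist()
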