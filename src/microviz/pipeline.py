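"""Config-driven end-to-end analysis.

simulate/load -> normalize -> diversity -> slope scoring -> stability ->
differential tests -> consensus -> ordination -> overlap -> report tables.
All randomness flows from seeds recorded in the run log; a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community_structure as cs
from . import differential as diff
from . import diversity as dv
from . import stability as st
from . import synthetic_data as sd
from . import viz_scoring as vz
from .data_model import (
    OtuTable,
    read_metadata,
    read_otu_table,
    relative_abundance,
    select_samples,
    write_metadata,
    write_otu_table,
)
from .normalization import jittered_log2, normalize_to_max_depth

log = logging.getLogger("microviz")


@dataclass
class RunConfig:
    out_dir: str = "microviz_run"
    # inputs: either file paths or a simulation config
    otu_table: str | None = None
    metadata: str | None = None
    simulation: sd.SimConfig | None = None
    # thresholds (the study's working constants)
    viz_threshold: float = 0.05  # percent change per slope
    min_individuals: int = 2
    cv_max: float = 10.0
    min_reads: int = 10
    alpha: float = 0.05
    confidence_cutoff: float = 0.80
    pseudo: float = 0.001
    n_perm: int = 1000
    normalization_scope: str = "analysis_set"  # or "global"
    jitter: str = "uniform"
    jitter_seed: int = 0
    perm_seed: int = 0

    def validate(self) -> None:
        for name in ("viz_threshold", "cv_max", "alpha", "confidence_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulation is None and (self.otu_table is None or self.metadata is None):
            raise ValueError("need either input paths or a simulation config")


def _tp_pairs(meta: pd.DataFrame, habitat: str) -> list[tuple[str, str]]:
    """(pre-diarrhea, diarrhea) sample pairs per individual with both."""
    pairs = []
    for ind in sorted(meta.loc[meta["habitat"] == habitat, "individual"].unique()):
        s2 = select_samples(meta, habitat=habitat, timepoint=2, individual=ind)
        s3 = select_samples(meta, habitat=habitat, timepoint=3, individual=ind)
        if len(s2) == 1 and len(s3) == 1:
            pairs.append((s2[0], s3[0]))
    return pairs


def habitat_detections(
    table: OtuTable,
    meta: pd.DataFrame,
    habitat: str,
    cfg: RunConfig,
) -> tuple[dict[str, set[str]], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the three detection legs on one habitat's tp2 vs tp3 contrast.

    Returns (detection sets keyed M/E/V, permutation results, paired
    log-ratio results, pattern associations).
    """
    pairs = _tp_pairs(meta, habitat)
    if len(pairs) < 2:
        raise ValueError(f"habitat {habitat}: fewer than 2 complete individuals")
    group_a = [a for a, _ in pairs]
    group_b = [b for _, b in pairs]
    scoped = table.subset_samples(select_samples(meta, habitat=habitat))

    perm = diff.permutation_t_test(
        scoped, group_a, group_b, n_perm=cfg.n_perm, seed=cfg.perm_seed
    )
    lr = diff.paired_logratio_test(scoped, pairs, pseudo=cfg.pseudo)
    abund = relative_abundance(scoped)
    assignments = vz.score_habitat(abund, meta, habitat, threshold=cfg.viz_threshold)
    assoc = vz.associations_frame(
        vz.associate_patterns(assignments, min_individuals=cfg.min_individuals)
    )
    detections = {
        "M": diff.detected_set(perm, alpha=cfg.alpha, use="p"),
        "E": diff.detected_set(lr, alpha=cfg.alpha, use="p"),
        "V": set(assoc["otu_id"]) if not assoc.empty else set(),
    }
    return detections, perm, lr, assoc


def method_count_summary(
    perm: pd.DataFrame, lr: pd.DataFrame, assignments_assoc: pd.DataFrame,
    assoc_any: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    """Per-method OTU counts at p<0.01 / p<alpha and association support
    thresholds (the published performance-comparison table shape)."""
    rows = [
        {
            "method": "permtest",
            "p_lt_001": int((perm["p"] < 0.01).sum()),
            "p_lt_alpha": int((perm["p"] < alpha).sum()),
            "assoc_ge_2": None,
            "assoc_ge_1": None,
        },
        {
            "method": "paired_lr",
            "p_lt_001": int((lr["p"] < 0.01).sum()),
            "p_lt_alpha": int((lr["p"] < alpha).sum()),
            "assoc_ge_2": None,
            "assoc_ge_1": None,
        },
        {
            "method": "viz",
            "p_lt_001": None,
            "p_lt_alpha": None,
            "assoc_ge_2": int(assignments_assoc["otu_id"].nunique()),
            "assoc_ge_1": int(assoc_any["otu_id"].nunique()),
        },
    ]
    return pd.DataFrame(rows)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; write report tables; return the summary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    truth = None
    if cfg.simulation is not None:
        table, meta, truth = sd.simulate_study(cfg.simulation)
        write_otu_table(table, out / "otu_table.tsv")
        write_metadata(meta, out / "metadata.tsv")
        truth.to_json(out / "ground_truth.json")
        log.info("simulated study with seed %d", cfg.simulation.seed)
    else:
        table = read_otu_table(cfg.otu_table)
        meta = read_metadata(cfg.metadata)

    summary: dict = {"config": {k: str(v) for k, v in vars(cfg).items()}, "stages": {}}

    # run-log normalization factors over the full table; the ordination
    # below rescales within its own analysis set unless scope is global
    norm = normalize_to_max_depth(table)
    pd.Series(norm.factors, name="factor").rename_axis("sample_id").to_frame().to_csv(
        out / "normalization_factors.tsv", sep="\t"
    )
    log.info(
        "normalization factors in [%.3f, %.3f]",
        min(norm.factors.values()),
        max(norm.factors.values()),
    )
    summary["stages"]["normalization"] = {
        "factor_min": min(norm.factors.values()),
        "factor_max": max(norm.factors.values()),
    }

    # --- diversity
    counts_by_sample = {
        s: table.counts[:, j] for j, s in enumerate(table.sample_ids)
    }
    div = dv.diversity_table(counts_by_sample)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    curves = []
    depths = table.depths()
    grid = np.linspace(1, depths.min(), 20, dtype=int)
    for habitat in sorted(meta["habitat"].unique()):
        for tp in sorted(meta.loc[meta["habitat"] == habitat, "timepoint"].unique()):
            samples = select_samples(meta, habitat=habitat, timepoint=int(tp))
            curve = dv.rarefaction_curve(
                [counts_by_sample[s] for s in samples], grid
            )
            curve.insert(0, "group", f"{habitat}_tp{tp}")
            curves.append(curve)
    pd.concat(curves).to_csv(out / "rarefaction.tsv", sep="\t", index=False)

    richness = div.set_index("sample_id")["observed_richness"]
    stool_pairs = _tp_pairs(meta, "stool")
    if len(stool_pairs) >= 2:
        t_r, p_r = dv.compare_paired(
            [richness[a] for a, _ in stool_pairs], [richness[b] for _, b in stool_pairs]
        )
        summary["stages"]["richness_paired_t"] = {"t": t_r, "p": p_r}

    # --- per-habitat detection + consensus
    phylum_lookup = cs.phylum_of(table, cfg.confidence_cutoff)
    summary["stages"]["detection"] = {}
    for habitat in sorted(meta["habitat"].unique()):
        scoped = table.subset_samples(select_samples(meta, habitat=habitat))
        detections, perm, lr, assoc = habitat_detections(table, meta, habitat, cfg)
        perm.assign(p_adjusted=diff.bh_adjust(perm["p"].to_numpy())).to_csv(
            out / f"permtest_{habitat}.tsv", sep="\t", index=False
        )
        lr.assign(p_adjusted=diff.bh_adjust(lr["p"].to_numpy())).to_csv(
            out / f"paired_lr_{habitat}.tsv", sep="\t", index=False
        )
        abund = relative_abundance(scoped)
        assignments = vz.score_habitat(abund, meta, habitat, threshold=cfg.viz_threshold)
        pd.DataFrame([a.__dict__ for a in assignments]).to_csv(
            out / f"viz_patterns_{habitat}.tsv", sep="\t", index=False
        )
        assoc.to_csv(out / f"viz_associations_{habitat}.tsv", sep="\t", index=False)

        pairs = _tp_pairs(meta, habitat)
        cons = diff.consensus_table(detections, scoped, pairs)
        cons.to_csv(out / f"consensus_{habitat}.tsv", sep="\t", index=False)

        assoc_any = vz.associations_frame(
            vz.associate_patterns(assignments, min_individuals=1)
        )
        method_count_summary(perm, lr, assoc, assoc_any, cfg.alpha).to_csv(
            out / f"method_counts_{habitat}.tsv", sep="\t", index=False
        )

        sizes = vz.mean_abundance_change(assignments, abund, meta, habitat)
        methods_by_otu = {
            o: "".join(
                m for m in "ME" if o in detections[m]
            )
            for o in set(assoc["otu_id"]) if not assoc.empty
        } if not assoc.empty else {}
        net = vz.build_network(
            vz.associate_patterns(assignments, cfg.min_individuals),
            phylum_by_otu=phylum_lookup,
            size_by_otu=sizes,
            methods_by_otu=methods_by_otu,
        )
        vz.export_network(net, out / f"network_{habitat}", format="sif")
        vz.export_network(net, out / f"network_{habitat}", format="graphml")

        summary["stages"]["detection"][habitat] = {
            m: len(s) for m, s in detections.items()
        } | {"consensus_ge2": int(len(cons))}

        # stability
        calls = st.stable_phylotypes(
            table, meta, habitat=habitat, cv_max=cfg.cv_max, min_reads=cfg.min_reads
        )
        calls.to_csv(out / f"stability_{habitat}.tsv", sep="\t", index=False)
        summary["stages"]["detection"][habitat]["stable_calls"] = (
            int(calls["stable"].sum()) if not calls.empty else 0
        )

        # rank-level paired tests
        if table.taxonomy and len(pairs) >= 2:
            for rank in ("phylum", "family", "genus"):
                mat = diff.aggregate_to_rank(scoped, rank, cfg.confidence_cutoff)
                res = diff.rank_paired_tests(mat, pairs, kind="paired_t")
                res.to_csv(
                    out / f"rank_{rank}_paired_t_{habitat}.tsv", sep="\t", index=False
                )

        # Fisher phylum/pattern association
        if not assoc.empty:
            fisher = {}
            for grp in ("increasing", "decreasing"):
                for phylum in ("Proteobacteria", "Bacteroidetes"):
                    odds, p = diff.fisher_phylum_association(
                        assoc, phylum_lookup, phylum, grp
                    )
                    fisher[f"{phylum}_{grp}"] = {"odds_ratio": odds, "p": p}
            summary["stages"]["detection"][habitat]["fisher"] = fisher

    # --- ordination on normalized, jittered-log2 stool data
    stool_samples = select_samples(meta, habitat="stool")
    if cfg.normalization_scope == "global":
        # factors referenced to the deepest sample of the whole study
        cols = [norm.sample_ids.index(s) for s in stool_samples]
        scaled = norm.scaled[:, cols]
        stool_ids = stool_samples
    else:
        stool_norm = normalize_to_max_depth(table, stool_samples)
        scaled = stool_norm.scaled
        stool_ids = stool_norm.sample_ids
    transformed = jittered_log2(scaled, seed=cfg.jitter_seed, jitter=cfg.jitter)
    ord_res = cs.pca(transformed.T)  # samples as observations
    scores = pd.DataFrame(
        ord_res.scores[:, :5],
        index=stool_ids,
        columns=[f"PC{i+1}" for i in range(min(5, ord_res.n_components))],
    )
    ind_of = meta.set_index("sample_id")["individual"]
    scores["individual"] = [ind_of[s] for s in stool_ids]
    scores.rename_axis("sample_id").to_csv(out / "ordination_stool.tsv", sep="\t")
    t_sep, p_sep = cs.group_separation_test(
        ord_res.scores, scores["individual"].tolist()
    )
    ellipses = []
    for ind, grp in scores.groupby("individual"):
        if len(grp) >= 3:
            e = cs.confidence_ellipse(grp[["PC1", "PC2"]].to_numpy(), level=0.87)
            ellipses.append(
                {
                    "individual": ind,
                    "cx": e.center[0],
                    "cy": e.center[1],
                    "semi_major": e.semi_axes[0],
                    "semi_minor": e.semi_axes[1],
                    "angle_rad": e.angle_rad,
                    "degenerate": e.degenerate,
                }
            )
    pd.DataFrame(ellipses).to_csv(out / "ellipses_stool.tsv", sep="\t", index=False)
    summary["stages"]["ordination"] = {
        "pc1_pct": float(ord_res.variance_explained[0]),
        "pc2_pct": float(ord_res.variance_explained[1]),
        "interpersonal_t": t_sep,
        "interpersonal_p": p_sep,
    }

    # --- overlap between individuals, per habitat and time-point
    overlap_rows = []
    for habitat in sorted(meta["habitat"].unique()):
        for tp in sorted(meta.loc[meta["habitat"] == habitat, "timepoint"].unique()):
            samples = select_samples(meta, habitat=habitat, timepoint=int(tp))
            if len(samples) >= 2:
                o = cs.phylotype_overlap(table, samples)
                overlap_rows.append(
                    {
                        "habitat": habitat,
                        "timepoint": int(tp),
                        "phylotype_overlap_pct": o.phylotype_overlap_pct,
                        "sequence_overlap_pct": o.sequence_overlap_pct,
                    }
                )
    pd.DataFrame(overlap_rows).to_csv(out / "overlap.tsv", sep="\t", index=False)

    # --- phylum composition per individual/habitat
    group_by = {
        r.sample_id: f"{r.individual}_{r.habitat}" for r in meta.itertuples()
    }
    cs.phylum_composition(table, group_by, confidence_cutoff=cfg.confidence_cutoff).to_csv(
        out / "phylum_composition.tsv", sep="\t"
    )

    # --- recovery against planted truth
    if truth is not None:
        detections, _, _, _ = habitat_detections(table, meta, "stool", cfg)
        cons = diff.consensus(detections)
        cons_set = set(cons.loc[cons["score"] >= 2, "otu_id"])
        rec = sd.recovery_metrics(cons_set, truth)
        summary["stages"]["recovery"] = {
            "sensitivity": rec.sensitivity,
            "fdr": rec.fdr,
            "n_detected": rec.n_detected,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
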