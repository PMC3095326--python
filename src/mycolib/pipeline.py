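"""End-to-end pipeline: simulate -> QC -> cluster -> richness -> community.

Each stage reads only the configuration and the previous stage's artifacts,
writes plain-text outputs into a run directory, and contributes to a single
machine-readable summary.  All randomness derives from one seed, so a run is
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as cs
from . import io
from .cluster import OTUTable, cluster_otus
from .qc import QCResult, run_qc
from .reference import ReferenceDB
from .richness import TotalSpeciesEstimator, exact_accumulation
from .simulate import (
    SimulationConfig,
    config_from_dict,
    generate_metacommunity,
    sample_clone_library,
)

_RS_PATTERN = re.compile(r"^(M\d+)(S\d+)(R\d+)$")


def hierarchy_from_labels(root_systems) -> pd.DataFrame:
    """Recover the 3-level hierarchy from ``M<i>S<j>R<k>`` column labels."""
    rows = []
    for rs in root_systems:
        m = _RS_PATTERN.match(str(rs))
        if not m:
            raise ValueError(
                f"root-system label {rs!r} does not encode the hierarchy "
                "(expected M<i>S<j>R<k>); supply a sample map instead"
            )
        rows.append(
            {
                "root_system": rs,
                "sub_locality": m.group(1) + m.group(2),
                "main_locality": m.group(1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """One structured configuration for every stage."""

    out_dir: str = "run"
    seed: int = 0
    # inputs; when None the synthetic generator provides them
    clones_fasta: str | None = None
    sample_map: str | None = None
    reference_fasta: str | None = None
    simulate: SimulationConfig | None = None
    # QC
    min_region_identity: float = 0.80
    max_collapse_diffs: int = 2
    # clustering
    cluster_threshold: float = 0.97
    cluster_linkage: str = "single"
    # richness
    target_subareas: float = 1e6
    n_bootstrap: int = 100
    max_combinations: int = 200
    window: int | None = None
    # ordination
    nmds_starts: int = 100
    nmds_max_iter: int = 1000
    nmds_stress_ratio_stop: float = 0.99999

    def validate(self) -> None:
        if not 0.0 < self.cluster_threshold <= 1.0:
            raise ValueError("cluster_threshold must lie in (0, 1]")
        if not 0.0 <= self.min_region_identity <= 1.0:
            raise ValueError("min_region_identity must lie in [0, 1]")
        if self.max_collapse_diffs < 0:
            raise ValueError("max_collapse_diffs must be non-negative")
        if self.n_bootstrap < 0 or self.max_combinations < 1:
            raise ValueError("invalid richness settings")
        external = (self.clones_fasta, self.sample_map, self.reference_fasta)
        if any(external) and not all(external):
            raise ValueError(
                "clones_fasta, sample_map and reference_fasta must be "
                "configured together"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", cfg.seed)
            cfg.simulate = config_from_dict(sim)
        return cfg


def simulate_stage(config: PipelineConfig, out: Path) -> dict:
    sim = config.simulate or SimulationConfig(seed=config.seed)
    community = generate_metacommunity(sim)
    records, truth = sample_clone_library(community, sim)
    io.write_clones_fasta(records, out / "clones.fasta")
    io.write_sample_map(records, out / "sample_map.tsv")
    io.write_reference_fasta(
        ReferenceDB.from_metacommunity(community), out / "reference.fasta"
    )
    truth.clones.to_csv(out / "truth.tsv", sep="\t", index=False)
    return {
        "n_clones_emitted": len(records),
        "n_true_otus": sim.n_true_otus,
        "n_chimeric_true": int(truth.clones["is_chimera"].sum()),
    }


def qc_stage(config: PipelineConfig, out: Path) -> QCResult:
    clones = config.clones_fasta or out / "clones.fasta"
    smap = config.sample_map or out / "sample_map.tsv"
    ref = config.reference_fasta or out / "reference.fasta"
    records = io.read_clones(clones, smap)
    reference = io.read_reference_fasta(ref)
    result = run_qc(
        records,
        reference,
        min_region_identity=config.min_region_identity,
        max_collapse_diffs=config.max_collapse_diffs,
    )
    result.clone_status.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    io.write_genotypes(result.genotypes, out / "genotypes.fasta", out / "genotypes.tsv")
    return result


def cluster_stage(config: PipelineConfig, out: Path) -> OTUTable:
    genotypes = io.read_genotypes(out / "genotypes.tsv")
    reference = io.read_reference_fasta(config.reference_fasta or out / "reference.fasta")
    otus = cluster_otus(
        genotypes,
        reference,
        threshold=config.cluster_threshold,
        linkage=config.cluster_linkage,
    )
    otus.assignments.to_csv(out / "otu_summary.tsv", sep="\t", index=False)
    io.write_incidence(otus.incidence, out / "incidence.tsv")
    io.write_incidence(otus.clone_counts, out / "clone_counts.tsv")
    otus.genotype_otu.rename_axis("genotype_id").reset_index().to_csv(
        out / "otu_membership.tsv", sep="\t", index=False
    )
    return otus


def richness_stage(config: PipelineConfig, out: Path) -> dict:
    incidence = io.read_incidence(out / "incidence.tsv")
    hierarchy = hierarchy_from_labels(incidence.columns)

    reports = []
    curves = []
    results: dict[str, dict] = {}
    units = [("pooled", incidence)]
    for main, group in hierarchy.groupby("main_locality", sort=False):
        units.append((main, incidence[group["root_system"]]))
    for label, inc in units:
        X = inc.T.to_numpy()
        curve = exact_accumulation(X).to_frame()
        curve.insert(0, "locality", label)
        curves.append(curve)
        est = TotalSpeciesEstimator(
            target_subareas=config.target_subareas,
            max_combinations=config.max_combinations,
            n_bootstrap=config.n_bootstrap,
            window=config.window,
            random_state=config.seed,
        ).fit(X, groups=list(inc.columns))
        results[label] = {
            "observed_richness": est.observed_richness_,
            "ts_estimate": est.estimate_,
            "bootstrap_mean": est.bootstrap_mean_,
            "bootstrap_sd": est.bootstrap_sd_,
            "slope": est.slope_,
            "intercept": est.intercept_,
        }
        rep = est.terminal_points_.copy()
        rep.insert(0, "locality", label)
        reports.append(rep)
    pd.concat(curves).to_csv(out / "accumulation_curves.tsv", sep="\t", index=False)
    pd.concat(reports).to_csv(out / "ts_terminal_points.tsv", sep="\t", index=False)
    pd.DataFrame(results).T.rename_axis("locality").reset_index().to_csv(
        out / "ts_report.tsv", sep="\t", index=False
    )
    return results


def community_stage(config: PipelineConfig, out: Path) -> dict:
    incidence = io.read_incidence(out / "incidence.tsv")
    hierarchy = hierarchy_from_labels(incidence.columns)
    summary: dict = {}

    sharing = cs.shared_otu_stats(incidence, hierarchy)
    sharing.to_csv(out / "sharing_stats.tsv", sep="\t", index=False)
    summary["shared_otus"] = {
        row["stratum"]: row["mean_shared"] for _, row in sharing.iterrows()
    }

    venn_rows = []
    for main, group in hierarchy.groupby("main_locality", sort=False):
        pooled = cs.pool_sublocalities(incidence[group["root_system"]], group)
        sets = [set(pooled.index[pooled[c] > 0]) for c in pooled.columns]
        if len(sets) == 3:
            counts = cs.venn_counts(sets)
            venn_rows.append(counts.rename(main))
    if venn_rows:
        pd.DataFrame(venn_rows).rename_axis("main_locality").to_csv(
            out / "venn_counts.tsv", sep="\t"
        )

    counts_per_rs = incidence.sum(axis=0)
    groups = hierarchy.set_index("root_system").loc[counts_per_rs.index, "main_locality"]
    f_stat, p_value = cs.anova_richness(counts_per_rs.to_numpy(), groups.to_numpy())
    summary["anova"] = {"F": f_stat, "p": p_value}
    summary["mean_otus_per_root_system"] = {
        main: float(counts_per_rs[groups == main].mean())
        for main in groups.unique()
    }

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    score_frames = []
    concordance_rows = []
    pooled_sub = cs.pool_sublocalities(incidence, hierarchy)
    for level, inc, seed in (
        ("root_system", incidence, seeds[0]),
        ("sub_locality", pooled_sub, seeds[1]),
    ):
        X = inc.T.to_numpy()
        labels = list(inc.columns)
        dca = cs.dca_ordination(X, site_labels=labels)
        D = cs.sorensen_dissimilarity(X)
        pd.DataFrame(D, index=labels, columns=labels).to_csv(
            out / f"dissimilarity_{level}.tsv", sep="\t"
        )
        nm = cs.nmds(
            D,
            n_starts=config.nmds_starts,
            max_iter=config.nmds_max_iter,
            stress_ratio_stop=config.nmds_stress_ratio_stop,
            seed=int(np.random.default_rng(seed).integers(2**31)),
            site_labels=labels,
        )
        for r in (dca, nm):
            frame = r.to_frame().rename_axis("site").reset_index()
            frame.insert(0, "level", level)
            if r.method == "NMDS":
                frame["stress"] = r.stress
            else:
                frame["eigenvalue1"], frame["eigenvalue2"] = r.eigenvalues[:2]
            score_frames.append(frame)
        tau = cs.kendall_concordance(dca.scores[:, :2], nm.scores[:, :2])
        tau.insert(0, "level", level)
        concordance_rows.append(tau)
        summary[f"ordination_{level}"] = {
            "dca_eigenvalues": list(np.round(dca.eigenvalues[:2], 4)),
            "dca_gradient_lengths_approx": list(np.round(dca.gradient_lengths[:2], 2)),
            "nmds_stress": nm.stress,
            "nmds_accepted": bool(nm.accepted),
            "axis1_abs_tau": float(
                tau.loc[(tau["axis_a"] == 1) & (tau["axis_b"] == 1), "abs_tau"].iloc[0]
            ),
        }
    pd.concat(score_frames).to_csv(out / "ordination_scores.tsv", sep="\t", index=False)
    pd.concat(concordance_rows).to_csv(out / "concordance.tsv", sep="\t", index=False)
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return (and write) the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    if config.simulate is not None or config.clones_fasta is None:
        summary["simulation"] = simulate_stage(config, out)
    qc_result = qc_stage(config, out)
    status = qc_result.clone_status["status"]
    n_clones = len(status)
    summary["qc"] = {
        "n_clones": n_clones,
        "n_chimeric": qc_result.n_chimeric,
        "chimera_pct": 100.0 * qc_result.n_chimeric / n_clones,
        "n_genotypes": len(qc_result.genotypes.table),
        "n_collapsed": int(status.str.startswith("collapsed_into").sum()),
        "n_consensus_members": int((status == "consensus_member").sum()),
    }
    otus = cluster_stage(config, out)
    rs_per_otu = otus.incidence.sum(axis=1)
    summary["otus"] = {
        "n_otus": otus.n_otus,
        "pct_one_root_system": 100.0 * float((rs_per_otu == 1).mean()),
        "pct_two_root_systems": 100.0 * float((rs_per_otu == 2).mean()),
        "pct_three_root_systems": 100.0 * float((rs_per_otu == 3).mean()),
        "otus_per_locality": {
            main: int((otus.incidence[g["root_system"]].sum(axis=1) > 0).sum())
            for main, g in hierarchy_from_labels(otus.incidence.columns).groupby(
                "main_locality", sort=False
            )
        },
    }
    summary["richness"] = richness_stage(config, out)
    summary["community"] = community_stage(config, out)
    io.write_summary(summary, out / "summary.json")
    return summary
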