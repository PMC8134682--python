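"""End-to-end orchestration: simulate -> deconvolve -> cluster -> DEG ->
score -> cutoff -> survival/mutation/response, with a reproducible manifest.

Every stage writes a plain TSV into the output directory; the manifest
records the config, seeds and a SHA-256 hash of each artifact so a rerun
with the same config is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus, deconvolution, dge, mutation, response, score, simulate
from . import survival as surv
from .io import ExpressionMatrix, write_clinical, write_expression_matrix, write_maf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-cohort run; every default documented
    in the methods note."""

    seed: int = 0
    n_samples: int = 300
    n_cell_types: int = 22
    markers_per_type: int = 10
    noise_sd: float = 0.2
    log_hr_per_unit: float = -0.7
    censor_rate: float = 0.3
    k: int = 3  # pinned cluster count for both ICI and gene clusters
    reps: int = 200  # consensus resampling repetitions
    subsample: float = 0.8
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    fc_threshold: float = 1.0
    alpha: float = 0.05
    run_boruta: bool = True
    boruta_iter: int = 50
    min_group_fraction: float = 0.1
    mutation_top_n: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "nu_grid" in raw:
            raw["nu_grid"] = tuple(raw["nu_grid"])
        return cls(**raw)


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    cohort: "simulate.SyntheticCohort"
    fractions: deconvolution.CellFractionTable
    ici_clusters: pd.Series
    degs: dge.DEGTable
    gene_clusters: pd.Series
    partition: score.SignaturePartition
    scores: score.ICIScoreTable
    cutoff: surv.CutoffResult
    logrank_p: float
    truth_spearman: float = field(default=np.nan)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full analysis on a synthetic cohort and write all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("cohort", "deconvolve", "cluster_ici", "cluster_genes", "boruta"),
            rng.integers(0, 2**31 - 1, size=5),
        )
    }
    manifest: dict = {
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "stages": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["stages"].setdefault(stage, []).append(
            {"path": path.name, "sha256": _sha256(path)}
        )

    # 1. synthetic cohort
    cohort = simulate.simulate_cohort(
        n_samples=config.n_samples,
        n_cell_types=config.n_cell_types,
        markers_per_type=config.markers_per_type,
        noise_sd=config.noise_sd,
        log_hr_per_unit=config.log_hr_per_unit,
        censor_rate=config.censor_rate,
        seed=stage_seeds["cohort"],
    )
    write_expression_matrix(cohort.expression, out / "expression.tsv")
    write_clinical(cohort.clinical, out / "clinical.tsv")
    write_maf(cohort.mutations, out / "mutations.maf")
    cohort.true_fractions.data.to_csv(out / "truth_fractions.tsv", sep="\t")
    for p in ("expression.tsv", "clinical.tsv", "mutations.maf", "truth_fractions.tsv"):
        record("simulate", out / p)

    # 2. deconvolution
    fractions = deconvolution.svr_deconvolve(
        cohort.expression,
        cohort.signature,
        nu_grid=config.nu_grid,
        seed=stage_seeds["deconvolve"],
    )
    fractions.data.to_csv(out / "fractions.tsv", sep="\t")
    record("deconvolve", out / "fractions.tsv")

    # immune/stromal scores (used to canonicalize cluster labels)
    est = deconvolution.scores_from_gmt(cohort.expression, cohort.gene_sets)
    est.data.to_csv(out / "estimate_scores.tsv", sep="\t")
    record("estimate", out / "estimate_scores.tsv")
    immune_score = est.data["immune_score"]

    # 3. consensus clustering of cell fractions (ICI clusters)
    cc = consensus.consensus_cluster(
        fractions.data,
        k_range=range(2, 7),
        reps=config.reps,
        subsample=config.subsample,
        seed=stage_seeds["cluster_ici"],
    )
    ici_clusters = consensus.canonicalize_labels(cc.labels[config.k], immune_score)
    ici_clusters.to_frame().to_csv(out / "ici_clusters.tsv", sep="\t")
    pd.DataFrame(
        {"k": list(cc.cdf_area), "cdf_area": list(cc.cdf_area.values()),
         "delta_area": [cc.delta_area[k] for k in cc.cdf_area]}
    ).to_csv(out / "ici_consensus_cdf.tsv", sep="\t", index=False)
    record("cluster_ici", out / "ici_clusters.tsv")
    record("cluster_ici", out / "ici_consensus_cdf.tsv")

    # 4. DEGs among ICI clusters (log2 scale)
    log_expr = cohort.expression.to_log2()
    degs = dge.select_degs(
        log_expr, ici_clusters, fc_threshold=config.fc_threshold, alpha=config.alpha
    )
    degs.data.to_csv(out / "degs.tsv", sep="\t")
    record("deg", out / "degs.tsv")
    deg_genes = degs.genes
    if len(deg_genes) < 2:
        raise RuntimeError("pipeline aborted at stage 'deg': fewer than 2 DEGs")
    deg_expr = log_expr.subset_genes(deg_genes)

    # 5. consensus clustering of samples on DEG expression (gene clusters)
    zexpr = deg_expr.data.sub(deg_expr.data.mean(axis=1), axis=0)
    sds = deg_expr.data.std(axis=1).replace(0, 1.0)
    zexpr = zexpr.div(sds, axis=0)
    gc = consensus.consensus_cluster(
        zexpr.T,
        k_range=range(2, 7),
        reps=config.reps,
        subsample=config.subsample,
        seed=stage_seeds["cluster_genes"],
    )
    gene_clusters = consensus.canonicalize_labels(gc.labels[config.k], immune_score)
    gene_clusters.to_frame().to_csv(out / "gene_clusters.tsv", sep="\t")
    record("cluster_genes", out / "gene_clusters.tsv")

    # 6. signatures A/B (+ Boruta reduction)
    partition = score.assign_signatures(deg_expr, gene_clusters, immune_score)
    if config.run_boruta and len(deg_genes) > 2:
        kept = set(
            score.boruta_select(
                deg_expr,
                gene_clusters,
                n_iter=config.boruta_iter,
                alpha=config.alpha,
                seed=stage_seeds["boruta"],
            )["selected"]
        )
        partition = score.SignaturePartition(
            [g for g in partition.genes_A if g in kept],
            [g for g in partition.genes_B if g in kept],
            partition.association,
        )
    sig_df = pd.DataFrame(
        {
            "gene": partition.genes_A + partition.genes_B,
            "signature": ["A"] * len(partition.genes_A) + ["B"] * len(partition.genes_B),
        }
    )
    sig_df.to_csv(out / "signatures.tsv", sep="\t", index=False)
    record("signatures", out / "signatures.tsv")

    # 7. ICI score + best cutoff
    scores = score.compute_ici_score(deg_expr, partition)
    clin = cohort.clinical.data
    cut = surv.best_cutoff(
        scores.scores.loc[clin.index],
        clin["os_time"],
        clin["os_event"],
        min_group_fraction=config.min_group_fraction,
    )
    scores = scores.with_cutoff(cut.cutoff)
    scores.data.to_csv(out / "ici_scores.tsv", sep="\t")
    record("score", out / "ici_scores.tsv")

    # 8. survival by ICI group
    groups = scores.data["group"]
    chi2, logrank_p = surv.logrank_test(
        clin["os_time"], clin["os_event"], groups.loc[clin.index].to_numpy()
    )
    hr = surv.cox_hr(
        clin["os_time"], clin["os_event"],
        (groups.loc[clin.index] == "high").astype(float).to_numpy(),
    )
    pd.DataFrame(
        [{
            "cutoff": cut.cutoff, "logrank_chi2": chi2, "logrank_p": logrank_p,
            "hr_high_vs_low": hr.hazard_ratio, "hr_ci_low": hr.ci_low,
            "hr_ci_high": hr.ci_high, "hr_p": hr.p,
        }]
    ).to_csv(out / "survival_summary.tsv", sep="\t", index=False)
    record("survival", out / "survival_summary.tsv")

    # 9. mutation summary
    tmb = mutation.compute_tmb(cohort.mutations, list(groups.index))
    rho, rho_p = mutation.score_tmb_correlation(
        scores.scores.loc[tmb.data.index], tmb.data["nonsyn_count"]
    )
    freq, onco = mutation.mutation_frequency_table(
        cohort.mutations, groups, top_n=config.mutation_top_n
    )
    tmb.data.assign(spearman_rho=rho, spearman_p=rho_p).to_csv(
        out / "tmb.tsv", sep="\t"
    )
    freq.to_csv(out / "mutation_frequencies.tsv", sep="\t")
    record("mutation", out / "tmb.tsv")
    record("mutation", out / "mutation_frequencies.tsv")

    # 10. response evaluation
    resp_binary = response.dichotomize_response(cohort.response)
    roc = response.roc_auc(scores.scores.loc[resp_binary.index], resp_binary)
    props, resp_chi2, resp_p = response.response_rate_table(cohort.response, groups)
    props.assign(auc=roc.auc, chi2=resp_chi2, p=resp_p).to_csv(
        out / "response_rates.tsv", sep="\t"
    )
    record("response", out / "response_rates.tsv")

    truth_spearman = float(
        pd.Series(scores.scores).corr(cohort.immune_activity, method="spearman")
    )
    manifest["summary"] = {
        "n_degs": int(len(deg_genes)),
        "n_signature_a": len(partition.genes_A),
        "n_signature_b": len(partition.genes_B),
        "cutoff": cut.cutoff,
        "logrank_p": logrank_p,
        "truth_spearman": truth_spearman,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        cohort=cohort,
        fractions=fractions,
        ici_clusters=ici_clusters,
        degs=degs,
        gene_clusters=gene_clusters,
        partition=partition,
        scores=scores,
        cutoff=cut,
        logrank_p=logrank_p,
        truth_spearman=truth_spearman,
    )
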