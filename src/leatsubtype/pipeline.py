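"""End-to-end pipeline: cohort -> batch correction -> clustering ->
signatures -> enrichment -> clinical statistics.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage;
all randomness flows through named per-stage seeds so a rerun with the
same config reproduces the report exactly.  Each stage writes its tables
under the output directory and contributes to a consolidated summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clinical as clin
from . import clustering, enrichment, preprocess, signatures
from .cohort import CohortConfig, generate_cohort, generate_gene_sets
from .containers import ExpressionMatrix, read_clinical_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults."""

    outdir: str = "leat_run"
    # either a simulation block or explicit input paths must be present
    simulation: dict | None = None          # CohortConfig fields
    expression: str | list[str] | None = None
    batch: str | None = None
    clinical: str | None = None
    gene_sets: str | None = None            # GMT path (optional)

    top_n_genes: int = 1000
    k_min: int = 2
    k_max: int = 10
    metric: str = "pearson"
    cluster_seed: int = 0
    consensus_reps: int = 0                 # 0 disables consensus validation
    consensus_frac: float = 0.8

    n_folds: int = 5
    signature_seed: int = 0

    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    enrichment_seed: int = 0
    run_gsva: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulation is None and self.expression is None:
            raise ValueError("config needs either a simulation block or an expression path")


@dataclass
class PipelineReport:
    summary: dict
    selection: clustering.KSelection = field(repr=False)
    ranking: signatures.GeneRanking | None = field(repr=False, default=None)
    gsea: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    gsva: pd.DataFrame | None = field(repr=False, default=None)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("data")
def _load_data(config: PipelineConfig, outdir: Path):
    if config.simulation is not None:
        sim = dict(config.simulation)
        for key in ("subgroup_sizes", "recurrence_prob", "braf_prob", "batch_scale_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        cohort_cfg = CohortConfig(**sim)
        expr, clinical_table, truth = generate_cohort(cohort_cfg)
        sets = generate_gene_sets(
            truth,
            set_size=min(50, cohort_cfg.markers_per_subgroup),
            seed=cohort_cfg.seed,
        )
        truth.subgroup.rename("subgroup").to_frame().assign(batch=truth.batch).to_csv(
            outdir / "truth_labels.tsv", sep="\t"
        )
        return expr, clinical_table, sets, truth
    paths = config.expression if isinstance(config.expression, list) else [config.expression]
    matrices = [ExpressionMatrix.from_tsv(p, batch_path=config.batch) for p in paths]
    expr = matrices[0] if len(matrices) == 1 else preprocess.intersect_and_merge(matrices)
    clinical_table = read_clinical_tsv(config.clinical) if config.clinical else None
    sets = enrichment.read_gmt(config.gene_sets) if config.gene_sets else None
    return expr, clinical_table, sets, None


@_stage("preprocess")
def _preprocess(expr: ExpressionMatrix):
    n_batches = expr.batch.nunique()
    corrected, model = preprocess.combat_correct(expr, allow_single_batch=(n_batches == 1))
    return corrected, model


@_stage("cluster")
def _cluster(corrected: ExpressionMatrix, config: PipelineConfig, outdir: Path):
    # variable-gene selection runs on the corrected, unscaled matrix (row
    # scaling would equalise all variances); the selected rows are then
    # standardised before the distance computation
    top = clustering.top_variable_genes(corrected, min(config.top_n_genes, corrected.n_genes))
    top = preprocess.scale_genes(top)
    selection = clustering.select_k_by_silhouette(
        top, config.k_min, config.k_max, metric=config.metric, seed=config.cluster_seed
    )
    best = selection.results[selection.best_k]
    retained, excluded = clustering.filter_core_samples(best)
    pd.DataFrame({
        "cluster": best.assignment,
        "silhouette": best.silhouette,
        "core": best.core_mask,
    }).to_csv(outdir / "cluster_assignment.tsv", sep="\t")
    pd.Series(selection.mean_silhouettes, name="mean_silhouette").rename_axis("k").to_csv(
        outdir / "silhouette_by_k.tsv", sep="\t"
    )
    consensus = None
    if config.consensus_reps >= 2:
        consensus = clustering.consensus_cluster(
            top, config.k_min, config.k_max, reps=config.consensus_reps,
            subsample_frac=config.consensus_frac, metric=config.metric,
            seed=config.cluster_seed,
        )
        pd.DataFrame({"area": consensus.area, "delta_area": consensus.delta_area}).rename_axis(
            "k"
        ).to_csv(outdir / "consensus_cdf_area.tsv", sep="\t")
    return top, selection, retained, excluded, consensus


@_stage("signatures")
def _signatures(scaled: ExpressionMatrix, labels: pd.Series, config: PipelineConfig, outdir: Path):
    ranking = signatures.nsc_cv_rank(
        scaled, labels, n_folds=config.n_folds, seed=config.signature_seed
    )
    de = signatures.pairwise_de(scaled, labels)
    model = signatures.nsc_fit(scaled, labels, delta=ranking.selected_delta)
    scores = signatures.subclass_scores(model, scaled, de=de)
    sig = scores.gene_scores.merge(
        ranking.avg_rank.rename("avg_cv_rank"), left_on="gene", right_index=True
    )
    sig.sort_values("avg_cv_rank").to_csv(outdir / "signature_genes.tsv", sep="\t", index=False)
    scores.affiliation.to_csv(outdir / "affiliation.tsv", sep="\t")
    return ranking, de, model, scores


@_stage("enrichment")
def _enrich(ranking, sets, scaled, config: PipelineConfig, outdir: Path):
    gsea_results: dict[str, pd.DataFrame] = {}
    for subgroup in ranking.shrunken_scores.columns:
        scores = enrichment.rank_from_classifier(ranking, subgroup)
        if (scores == 0).all():
            logger.warning("subgroup %s: degenerate (all-zero) ranking, skipping GSEA", subgroup)
            continue
        res = enrichment.gsea_preranked(
            scores, sets, weight=config.gsea_weight,
            n_perm=config.gsea_permutations, seed=config.enrichment_seed,
        )
        res.drop(columns="leading_edge").to_csv(outdir / f"gsea_cluster{subgroup}.tsv", sep="\t")
        gsea_results[str(subgroup)] = res
    gsva = None
    if config.run_gsva:
        gsva = enrichment.gsva_scores(scaled, sets)
        gsva.to_csv(outdir / "gsva_scores.tsv", sep="\t")
    return gsea_results, gsva


@_stage("clinical")
def _clinical_stats(clinical_table: pd.DataFrame, labels: pd.Series, outdir: Path):
    table = clinical_table.set_index("sample_id").loc[labels.index]
    out: dict = {}
    for marker, column in (("braf", "braf"), ("recurrence", "recurrence")):
        if column not in table.columns:
            continue
        flag = table[column] == "V600E" if column == "braf" else table[column].astype(bool)
        try:
            _, assoc = clin.cluster_marker_association(labels, flag)
            assoc.to_csv(outdir / f"association_{marker}.tsv", sep="\t")
            out[f"{marker}_association_min_p"] = float(assoc["pval"].min())
        except ValueError as exc:
            logger.warning("association for %s skipped: %s", marker, exc)
    if {"pfs_time", "pfs_event", "braf"} <= set(table.columns):
        mutant = (table["braf"] == "V600E").to_numpy()
        t = table["pfs_time"].to_numpy()
        e = table["pfs_event"].to_numpy()
        if mutant.any() and (~mutant).any():
            km_wt = clin.km_estimate(t[~mutant], e[~mutant])
            km_mut = clin.km_estimate(t[mutant], e[mutant])
            out["median_pfs_wt"] = km_wt.median
            out["median_pfs_braf"] = km_mut.median
            if e[mutant].sum() >= 1 and e[~mutant].sum() >= 1:
                chi2, p = clin.logrank_test([(t[~mutant], e[~mutant]), (t[mutant], e[mutant])])
                out["logrank_p"] = p
                cox = clin.cox_hr(t, e, mutant.astype(int))
                out["braf_hr"] = cox.hr
                out["braf_hr_ci"] = [cox.ci_low, cox.ci_high]
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order and write a consolidated report.

    Stage failures abort with the failing stage named; outputs written by
    earlier stages are retained in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logging.getLogger("leatsubtype").addHandler(handler)
    try:
        expr, clinical_table, sets, truth = _load_data(config, outdir)
        corrected, batch_model = _preprocess(expr)
        scaled = preprocess.scale_genes(corrected)
        top, selection, retained, excluded, consensus = _cluster(corrected, config, outdir)
        best = selection.results[selection.best_k]
        core_labels = best.assignment.loc[retained]
        core_scaled = scaled.subset_samples(retained)
        ranking, de, model, scores = _signatures(core_scaled, core_labels, config, outdir)
        gsea_results, gsva = ({}, None)
        if sets is not None:
            gsea_results, gsva = _enrich(ranking, sets, core_scaled, config, outdir)
        clinical_summary = {}
        if clinical_table is not None:
            clinical_summary = _clinical_stats(clinical_table, core_labels, outdir)

        cluster_sizes = core_labels.value_counts().sort_index()
        top_genes = (
            scores.gene_scores.merge(
                ranking.avg_rank.rename("avg_cv_rank"), left_on="gene", right_index=True
            )
            .sort_values("avg_cv_rank")
            .groupby("subgroup", sort=True)
            .head(10)
        )
        summary = {
            "parameters": {k: v for k, v in asdict(config).items()},
            "n_samples": int(expr.n_samples),
            "n_genes": int(expr.n_genes),
            "selected_k": int(selection.best_k),
            "mean_silhouette": {int(k): float(v) for k, v in selection.mean_silhouettes.items()},
            "no_structure": bool(selection.no_structure),
            "cluster_sizes": {int(k): int(v) for k, v in cluster_sizes.items()},
            "core_samples": len(retained),
            "excluded_samples": len(excluded),
            "selected_delta": float(ranking.selected_delta),
            "cv_accuracy": float(ranking.cv_accuracy),
            "top_signature_genes": {
                str(g): grp["gene"].tolist() for g, grp in top_genes.groupby("subgroup")
            },
            "consensus_selected_k": int(consensus.selected_k) if consensus else None,
            "enriched_sets": {
                sub: res.index[res["qval"] < 0.25].tolist() for sub, res in gsea_results.items()
            },
            "clinical": clinical_summary,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        return PipelineReport(
            summary=summary, selection=selection, ranking=ranking,
            gsea=gsea_results, gsva=gsva,
        )
    finally:
        logging.getLogger("leatsubtype").removeHandler(handler)
        handler.close()
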