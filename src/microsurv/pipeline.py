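"""End-to-end orchestration of the analysis stages.

Stages (each also exposed as a CLI subcommand): cohort summary, alpha/beta
diversity with survival association, concordance risk clustering with
Kaplan-Meier/log-rank, stability-selected taxa, stability-selected functional
features with metatranscriptome gating, and per-species pathway integration.
Every stage writes plain TSV/JSON artifacts into the output directory and
draws randomness from a named substream of the root seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from ._rng import substream
from .cohortstats import cohort_summary
from .compositional import agglomerate_taxa, clr_transform, filter_features, to_relative_abundance
from .communitytest import KernelSurvivalTest
from .config import AnalysisConfig
from .containers import FeatureTable, StratifiedFunctionTable, SurvivalData
from .diversity import alpha_rarefied, alpha_unrarefied, jsd_matrix, pcoa, weighted_unifrac
from .funcintegration import (
    mgx_mtx_correlations,
    mgx_mtx_gate,
    per_species_pathway_cox,
    relative_expression,
    species_contribution,
)
from .riskcluster import assign_risk_groups, kaplan_meier, logrank_test, ward_cluster
from .survstats import StabilitySelector, cox_fit, select_features

logger = logging.getLogger("microsurv")


@dataclass
class PipelineInputs:
    table_16s: FeatureTable
    table_shotgun: FeatureTable
    tree: object
    survival: SurvivalData
    mgx: StratifiedFunctionTable | None = None
    mtx: StratifiedFunctionTable | None = None


def load_inputs(config: AnalysisConfig) -> PipelineInputs:
    """Load all inputs from the paths in the config."""
    t16 = msio.read_feature_table(config.table_16s, level="s-OTU",
                                  taxonomy_path=config.taxonomy_16s)
    tsg = msio.read_feature_table(config.table_shotgun, level="species",
                                  taxonomy_path=config.taxonomy_shotgun)
    tree = msio.read_tree(config.tree)
    survival = msio.read_metadata(config.metadata)
    mgx = mtx = None
    if config.mgx_total and config.mgx_stratified:
        mgx = msio.read_stratified_table(config.mgx_total, config.mgx_stratified)
    if config.mtx_total and config.mtx_stratified:
        mtx = msio.read_stratified_table(config.mtx_total, config.mtx_stratified)
    return PipelineInputs(t16, tsg, tree, survival, mgx, mtx)


def from_bundle(bundle) -> PipelineInputs:
    """Adapt a synthetic cohort bundle to pipeline inputs."""
    return PipelineInputs(bundle.table_16s, bundle.table_shotgun, bundle.tree,
                          bundle.survival, bundle.mgx, bundle.mtx)


def align_samples(inputs: PipelineInputs) -> PipelineInputs:
    """Restrict all tables to the metadata patients (metadata authoritative)."""
    patients = inputs.survival.patient_ids
    for name in ("table_16s", "table_shotgun"):
        table = getattr(inputs, name)
        missing = set(patients) - set(table.sample_ids)
        if missing:
            raise ValueError(
                f"{name} is missing metadata patients: {sorted(missing)}")
        extra = set(table.sample_ids) - set(patients)
        if extra:
            logger.warning("%s: dropping samples absent from metadata: %s",
                           name, sorted(extra))
        setattr(inputs, name, table.subset_samples(patients))
    return inputs


# ---------------------------------------------------------------------------
# stages

def stage_cohort(inputs: PipelineInputs, config: AnalysisConfig, outdir: Path) -> dict:
    summary = cohort_summary(inputs.survival.frame, grouping="event")
    summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return {"n_patients": inputs.survival.n, "n_events": inputs.survival.n_events}


def beta_distances(inputs: PipelineInputs) -> dict:
    """JSD (both platforms) and weighted UniFrac (16S) distance matrices."""
    rel16 = to_relative_abundance(inputs.table_16s)
    relsg = to_relative_abundance(inputs.table_shotgun)
    return {
        "jsd_16s": jsd_matrix(rel16),
        "jsd_shotgun": jsd_matrix(relsg),
        "wunifrac_16s": weighted_unifrac(inputs.table_16s, inputs.tree),
    }


def stage_diversity(inputs: PipelineInputs, config: AnalysisConfig, outdir: Path,
                    dms: dict | None = None) -> dict:
    rng = substream(config.seed, "alpha-rarefaction")
    alpha16 = alpha_rarefied(inputs.table_16s, depth=config.rarefaction_depth,
                             iters=config.rarefaction_iters, rng=rng)
    alphasg = alpha_unrarefied(inputs.table_shotgun)
    alpha = alpha16.join(alphasg, lsuffix="_16s", rsuffix="_shotgun")
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="patient_id")

    assoc_rows = []
    for col in alpha.columns:
        x = pd.DataFrame({col: alpha[col]})
        res = cox_fit(x, survival=inputs.survival)
        ci = res.conf_int().iloc[0]
        assoc_rows.append({"index": col, "HR": res.hazard_ratios.iloc[0],
                           "hr_lower": ci["hr_lower"], "hr_upper": ci["hr_upper"],
                           "p": res.pvalues.iloc[0], "converged": res.converged})
    pd.DataFrame(assoc_rows).to_csv(outdir / "alpha_survival.tsv", sep="\t", index=False)

    if dms is None:
        dms = beta_distances(inputs)
    for name, dm in dms.items():
        msio.write_distance_matrix(dm, outdir / f"beta_{name}.tsv")
        coords, eigvals = pcoa(dm, n_axes=3)
        coords.to_csv(outdir / f"pcoa_{name}.tsv", sep="\t", index_label="sample_id")
        msio.write_json({"eigenvalues": eigvals}, outdir / f"pcoa_{name}_eigenvalues.json")
    return {"alpha_association": {r["index"]: r["p"] for r in assoc_rows}}


def stage_cluster(inputs: PipelineInputs, config: AnalysisConfig, outdir: Path,
                  dms: dict | None = None) -> dict:
    if dms is None:
        dms = beta_distances(inputs)
    labels16 = ward_cluster(dms["jsd_16s"], k=config.n_clusters,
                            variant=config.ward_variant)
    labelssg = ward_cluster(dms["jsd_shotgun"], k=config.n_clusters,
                            variant=config.ward_variant)
    out = {"platform_logrank": {}}
    for name, lab in (("16s", labels16), ("shotgun", labelssg)):
        chi, df, p = logrank_test(inputs.survival, lab)
        out["platform_logrank"][name] = {"chi_square": chi, "df": df, "p": p}

    groups = assign_risk_groups(labels16, labelssg, inputs.survival)
    groups.to_csv(outdir / "cluster_assignments.tsv", sep="\t", index_label="patient_id")
    km = kaplan_meier(inputs.survival, groups["combined_group"])
    km_rows = []
    for g, curve in km.items():
        curve = curve.assign(group=g)
        km_rows.append(curve)
    pd.concat(km_rows).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    if groups["combined_group"].nunique() >= 2:
        chi, df, p = logrank_test(inputs.survival, groups["combined_group"])
        out["combined_logrank"] = {"chi_square": chi, "df": df, "p": p}
    else:
        out["combined_logrank"] = {"note": "single combined group; test skipped"}

    out["kernel_tests"] = {}
    for name, dm in dms.items():
        test = KernelSurvivalTest(dm, inputs.survival)
        res = test.fit(n_permutations=config.n_permutations,
                       rng=substream(config.seed, f"kernel-{name}"))
        out["kernel_tests"][name] = {"Q": res.q_statistic, "p": res.p_value}
    msio.write_json(out, outdir / "cluster_tests.json")
    return out


def _taxa_tables(inputs: PipelineInputs, config: AnalysisConfig) -> dict[str, FeatureTable]:
    tables = {}
    for level in config.taxa_levels_16s:
        tables[f"16s_{level}"] = agglomerate_taxa(inputs.table_16s, level)
    for level in config.taxa_levels_shotgun:
        tables[f"shotgun_{level}"] = agglomerate_taxa(inputs.table_shotgun, level)
    return tables


def _run_stability(table: FeatureTable, survival: SurvivalData,
                   config: AnalysisConfig, stream: str,
                   mean_relabund_min: float, variance_quantile=None):
    filt, report = filter_features(table, config.prevalence_min,
                                   mean_relabund_min, variance_quantile,
                                   pseudocount=config.pseudocount)
    if filt.n_features == 0:
        return None, report
    clr = clr_transform(filt, pseudocount=config.pseudocount)
    selector = StabilitySelector(
        clr.values, survival=survival, alpha=config.alpha_mixing,
        folds=config.cv_folds, repeats=config.cv_repeats,
        n_lambda=config.n_lambda, lambda_rule=config.lambda_rule)
    return selector.fit(rng=substream(config.seed, stream)), report


def stage_select_taxa(inputs: PipelineInputs, config: AnalysisConfig, outdir: Path) -> dict:
    tables = _taxa_tables(inputs, config)
    results = {}
    for name, table in tables.items():
        res, report = _run_stability(table, inputs.survival, config,
                                     f"stability-taxa-{name}",
                                     config.mean_relabund_min_taxa)
        report.to_csv(outdir / f"filter_report_{name}.tsv", sep="\t", index=False)
        if res is None:
            logger.warning("no %s features pass the filters", name)
            continue
        tab = res.summary()
        tab["selected"] = ((tab["selection_count"] >= config.selection_count_threshold)
                           & (tab["q"] < config.q_threshold).fillna(False))
        tab.to_csv(outdir / f"selection_{name}.tsv", sep="\t", index_label="feature")
        results[name] = res

    combined = {}
    levels = set(config.taxa_levels_16s) & set(config.taxa_levels_shotgun)
    for level in sorted(levels):
        by_dtype = {dt: results[f"{dt}_{level}"] for dt in ("16s", "shotgun")
                    if f"{dt}_{level}" in results}
        if not by_dtype:
            continue
        sel = select_features(by_dtype, config.selection_count_threshold,
                              config.q_threshold)
        sel.to_csv(outdir / f"selected_taxa_{level}.tsv", sep="\t", index=False)
        combined[level] = sel["feature"].tolist()
    return {"n_selected": {lvl: len(v) for lvl, v in combined.items()},
            "selected": combined}


def stage_select_functions(inputs: PipelineInputs, config: AnalysisConfig,
                           outdir: Path) -> dict:
    if inputs.mgx is None:
        return {"note": "no functional tables provided"}
    mgx_table = FeatureTable(inputs.mgx.total, level="pathway")
    res, report = _run_stability(mgx_table, inputs.survival, config,
                                 "stability-pathways",
                                 config.mean_relabund_min_pathways,
                                 variance_quantile=config.variance_quantile)
    report.to_csv(outdir / "filter_report_pathways.tsv", sep="\t", index=False)
    if res is None:
        return {"note": "no pathways pass the filters"}

    out = {}
    if inputs.mtx is not None:
        corr = mgx_mtx_correlations(inputs.mgx.total, inputs.mtx.total,
                                    features=res.table.index)
        corr.to_csv(outdir / "mgx_mtx_correlations.tsv", sep="\t",
                    index_label="feature")
        audit = mgx_mtx_gate(res, corr, config.selection_count_threshold,
                             config.q_threshold, config.correlation_p_threshold)
        audit.to_csv(outdir / "selection_pathways.tsv", sep="\t", index_label="feature")
        gated = list(audit.index[audit["gated"]])
        out["gated_pathways"] = gated
        rel_expr = relative_expression(inputs.mtx, inputs.mgx)
        msio.write_feature_table(rel_expr, outdir / "relative_expression.tsv")
    else:
        tab = res.summary()
        tab.to_csv(outdir / "selection_pathways.tsv", sep="\t", index_label="feature")
        gated = res.selected(config.selection_count_threshold, config.q_threshold)
        out["gated_pathways"] = gated
    return out


def stage_integrate(inputs: PipelineInputs, config: AnalysisConfig, outdir: Path,
                    gated_pathways: list | None = None) -> dict:
    if inputs.mgx is None:
        return {"note": "no functional tables provided"}
    contrib_mgx = species_contribution(inputs.mgx)
    contrib_mgx.to_csv(outdir / "species_contribution_mgx.tsv", sep="\t", index=False)
    if inputs.mtx is not None:
        contrib_mtx = species_contribution(inputs.mtx)
        contrib_mtx.to_csv(outdir / "species_contribution_mtx.tsv", sep="\t", index=False)

    pathways = gated_pathways if gated_pathways else list(inputs.mgx.pathways)
    strat_cols = [c for c in inputs.mgx.stratified.columns if c[0] in set(pathways)]
    if not strat_cols:
        return {"note": "no strata to test"}
    sub = StratifiedFunctionTable(
        total=inputs.mgx.total[[pw for pw in inputs.mgx.pathways if pw in set(pathways)]],
        stratified=inputs.mgx.stratified[strat_cols],
    )
    hr_table = per_species_pathway_cox(sub, inputs.survival,
                                       pseudocount=config.pseudocount)
    hr_table.to_csv(outdir / "per_species_pathway_cox.tsv", sep="\t", index=False)
    return {"n_strata_tested": len(hr_table)}


def run_all(config: AnalysisConfig, inputs: PipelineInputs | None = None,
            outdir="results") -> dict:
    """Run every stage; returns (and writes) the summary dictionary."""
    import microsurv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("seed=%d config_hash=%s version=%s numpy=%s",
                    config.seed, config.config_hash(), microsurv.__version__,
                    np.__version__)
        logger.info("config: %s", config.to_dict())
        if inputs is None:
            inputs = load_inputs(config)
        inputs = align_samples(inputs)
        summary = {"seed": config.seed, "config_hash": config.config_hash()}
        summary["cohort"] = stage_cohort(inputs, config, outdir)
        dms = beta_distances(inputs)
        summary["diversity"] = stage_diversity(inputs, config, outdir, dms=dms)
        summary["cluster"] = stage_cluster(inputs, config, outdir, dms=dms)
        summary["taxa"] = stage_select_taxa(inputs, config, outdir)
        summary["functions"] = stage_select_functions(inputs, config, outdir)
        summary["integration"] = stage_integrate(
            inputs, config, outdir,
            gated_pathways=summary["functions"].get("gated_pathways"))
        config.to_json(outdir / "config.json")
        msio.write_json(summary, outdir / "summary.json")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
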