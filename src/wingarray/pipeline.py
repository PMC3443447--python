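"""End-to-end pipeline: simulate -> preprocess -> fit -> score -> cluster.

One seeded :class:`~wingarray.config.RunConfig` drives the full analysis and
produces a :class:`RecoveryReport` scoring every pipeline gate against the
generator's planted truth, plus all intermediate artifacts (optionally
written to an output directory as TSV/JSON/newick).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import colorscore, datagen, diffexpr, modcluster, preprocess
from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class RecoveryReport:
    """Planted-truth audit of one pipeline run.

    ``funnel`` is the monotone gate chain on the score path: all contigs ->
    pairwise-significant -> score-retained -> final (score path).  The
    ANOVA-union branch is reported separately (``n_anova_hits``,
    ``n_overlap``, ``n_candidates``, ``n_final``) because uniting the
    score-retained list with the color-ANOVA hits can grow the candidate
    pool before the module filter shrinks it again.
    """

    funnel: dict[str, int] = field(default_factory=dict)
    n_anova_hits: int = 0
    n_overlap: int = 0
    n_candidates: int = 0
    n_final: int = 0
    #: per planted effect class: total, and how many survive to the final list
    class_counts: dict[str, dict] = field(default_factory=dict)
    #: sensitivity for planted red-up genes in the final color list (None if
    #: no red genes were planted)
    color_sensitivity_red: float | None = None
    #: fraction of the final list with no planted color effect
    color_realized_fdr: float | None = None
    #: fraction of the final list that is truth-labelled null
    color_realized_fdr_null: float | None = None
    #: proximal-distal list: sensitivity and realized FDR vs planted truth
    pd_sensitivity: float | None = None
    pd_realized_fdr: float | None = None
    #: fraction of morph-wide planted genes entering candidates that the
    #: module filter removed
    morph_leak_removed: float | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class PipelineResult:
    design: pd.DataFrame
    truth: pd.DataFrame
    qc_report: preprocess.QCReport
    expr: dict[str, pd.DataFrame]  # keys: forewing / hindwing / joint
    section_results: pd.DataFrame | None
    pairwise_results: pd.DataFrame
    color_results: pd.DataFrame
    pd_genes: pd.DataFrame | None
    scores: pd.DataFrame
    candidates: pd.DataFrame
    modules: modcluster.ModuleAssignment | None
    final: pd.DataFrame
    report: RecoveryReport


def _normalize(table: pd.DataFrame, design: pd.DataFrame, wing: str | None,
               span: float) -> pd.DataFrame | None:
    cols = (design["sample_id"] if wing is None
            else design.loc[design["wing"] == wing, "sample_id"]).tolist()
    cols = [c for c in cols if c in table.columns]
    if not cols:
        return None
    sub = table[preprocess.META_COLUMNS + cols]
    norm = preprocess.log2_loess_normalize(sub, span=span)
    return preprocess.summarize_probes(norm)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis on one simulated dataset; score against truth."""
    config.validate()
    gen = config.generator
    design = datagen.generate_design(gen)
    raw, probemap, truth = datagen.simulate_intensities(design, gen)
    logger.info("simulated %d samples, %d probes, %d contigs",
                len(design), len(raw), gen.n_contigs)

    pp = config.preprocess
    masked, qc_report = preprocess.qc_mask(
        raw, window=pp.qc_window, z_threshold=pp.qc_z_threshold,
        max_masked_fraction=pp.max_masked_fraction)
    if qc_report.flagged:
        logger.info("arrays flagged for rerun: %s", qc_report.flagged)

    # forewing and hindwing normalized separately; jointly for the color ANOVA
    expr = {}
    for wing in ("forewing", "hindwing"):
        e = _normalize(masked, design, wing, pp.loess_span)
        if e is not None:
            expr[wing] = e
    expr["joint"] = (_normalize(masked, design, None, pp.loess_span)
                     if len(expr) > 1 else next(iter(expr.values())))

    # proximal-distal analysis (forewing sections)
    section_results, pd_genes = None, None
    if "forewing" in expr:
        section_results = diffexpr.fit_anova(expr["forewing"], design, "section")
        pd_genes = diffexpr.proximal_distal_genes(section_results, fdr=config.fdr)
        logger.info("proximal-distal genes at FDR %.3g: %d", config.fdr, len(pd_genes))

    # pairwise tissue contrasts, per wing
    pairwise_parts = []
    for wing, family in (("forewing", "pairwise_forewing"),
                         ("hindwing", "pairwise_hindwing")):
        if wing in expr:
            pairwise_parts.append(diffexpr.fit_anova(expr[wing], design, family))
    pairwise_results = pd.concat(pairwise_parts, ignore_index=True)

    # capped Fisher color-consistency score over the red set
    scores = colorscore.score_table(pairwise_results, config=config.score,
                                    entry_fdr=config.fdr)
    score_retained = colorscore.retain_by_score(scores)
    if len(scores):
        logger.info("color score: k=%d T=%.3f, %d/%d retained",
                    int(scores["k"].iloc[0]), float(scores["T"].iloc[0]),
                    len(score_retained), len(scores))

    # color ANOVA on the jointly normalized data
    color_results = diffexpr.fit_anova(expr["joint"], design, "color")
    anova_hits = diffexpr.significant_contigs(color_results, config.fdr)
    candidates = colorscore.combine_with_anova(score_retained, anova_hits)

    # module clustering of the candidates; purge inconsistent modules
    profiles, conditions = modcluster.build_profiles(expr["joint"], design)
    modules, final = None, pd.DataFrame(columns=["contig_id", "module_id", "direction"])
    if len(candidates):
        cand_profiles = profiles.loc[profiles.index.intersection(candidates["contig_id"])]
        if len(cand_profiles):
            modules = modcluster.mmc_cluster(cand_profiles, config.cluster,
                                             seed=config.seed + 1)
            modcluster.summarize_modules(modules, cand_profiles, conditions,
                                         epsilon=config.cluster.epsilon)
            final = modcluster.filter_inconsistent(candidates["contig_id"], modules)
            logger.info("clustering: %d modules (s=%.1f, Q=%.3f); final list %d",
                        modules.membership.nunique(), modules.sharpness,
                        modules.modularity, len(final))

    report = _recovery_report(truth, pairwise_results, scores, score_retained,
                              anova_hits, candidates, final, pd_genes, config.fdr)
    result = PipelineResult(
        design=design, truth=truth, qc_report=qc_report, expr=expr,
        section_results=section_results, pairwise_results=pairwise_results,
        color_results=color_results, pd_genes=pd_genes, scores=scores,
        candidates=candidates, modules=modules, final=final, report=report,
    )
    if config.outdir:
        _write_artifacts(result, config)
    return result


def _rate(num: int, den: int) -> float | None:
    return (num / den) if den else None


def _recovery_report(truth, pairwise_results, scores, score_retained, anova_hits,
                     candidates, final, pd_genes, fdr) -> RecoveryReport:
    truth_idx = truth.set_index("contig_id")
    final_set = set(final["contig_id"])
    cand_set = set(candidates["contig_id"])
    pairwise_sig = set(diffexpr.significant_contigs(pairwise_results, fdr))
    score_set = set(score_retained)

    rep = RecoveryReport()
    rep.funnel = {
        "contigs": len(truth),
        "pairwise_significant": len(pairwise_sig),
        "score_retained": len(score_set),
        "final_score_path": len(final_set & score_set),
    }
    rep.n_anova_hits = len(anova_hits)
    rep.n_overlap = len(score_set & set(anova_hits))
    rep.n_candidates = len(cand_set)
    rep.n_final = len(final_set)

    by_class = truth.groupby("effect_class")["contig_id"].apply(set)
    for cls, members in by_class.items():
        rep.class_counts[cls] = {
            "planted": len(members),
            "pairwise_significant": len(members & pairwise_sig),
            "score_retained": len(members & score_set),
            "candidates": len(members & cand_set),
            "final": len(members & final_set),
        }

    red = by_class.get("color_red_up", set())
    rep.color_sensitivity_red = _rate(len(red & final_set), len(red))
    color_classes = {"color_red_up", "color_yellow_up"}
    if final_set:
        fp = sum(1 for c in final_set
                 if truth_idx.loc[c, "effect_class"] not in color_classes)
        rep.color_realized_fdr = fp / len(final_set)
        nulls = sum(1 for c in final_set
                    if truth_idx.loc[c, "effect_class"] == "null")
        rep.color_realized_fdr_null = nulls / len(final_set)
    morph = by_class.get("morph_global", set())
    leaked = morph & cand_set
    rep.morph_leak_removed = _rate(len(leaked - final_set), len(leaked))

    if pd_genes is not None:
        pd_set = set(pd_genes["contig_id"])
        planted_pd = by_class.get("proximal_up", set()) | by_class.get("distal_up", set())
        rep.pd_sensitivity = _rate(len(pd_set & planted_pd), len(planted_pd))
        if pd_set:
            section_free = {"null", "stage_only", "morph_global"}
            fp = sum(1 for c in pd_set
                     if truth_idx.loc[c, "effect_class"] in section_free)
            rep.pd_realized_fdr = fp / len(pd_set)
    return rep


def sample_clustering_report(
    expr: pd.DataFrame, design: pd.DataFrame
) -> tuple[str, pd.DataFrame, np.ndarray]:
    """Diagnostic sample clustering: dendrogram + PCA of arrays.

    Average-linkage hierarchical clustering on 1 - Pearson correlation
    between samples, and the first two principal-component coordinates of
    the sample x contig matrix.

    Returns ``(newick, pca_table, linkage_matrix)`` where ``pca_table`` has
    columns PC1, PC2 indexed by sample id.

    Raises
    ------
    ValueError
        If fewer than 3 samples are present.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for the clustering report")
    X = expr.dropna(axis=0).to_numpy(dtype=float).T  # samples x contigs
    samples = list(expr.columns)
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    newick = _tree_to_newick(hierarchy.to_tree(Z), samples)

    Xc = X - X.mean(axis=0, keepdims=True)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :2] * sv[:2]
    pca = pd.DataFrame(pcs, index=pd.Index(samples, name="sample_id"),
                       columns=["PC1", "PC2"])
    return newick, pca, Z


def _tree_to_newick(node, labels: list[str]) -> str:
    def rec(nd, parent_height: float) -> str:
        length = max(parent_height - nd.dist, 0.0)
        if nd.is_leaf():
            return f"{labels[nd.id]}:{length:.6g}"
        left = rec(nd.get_left(), nd.dist)
        right = rec(nd.get_right(), nd.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(node.get_left(), node.dist)},{rec(node.get_right(), node.dist)});"


def _write_artifacts(result: PipelineResult, config: RunConfig) -> None:
    from . import io as wio
    import os

    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    wio.write_table(result.design, f"{outdir}/design.tsv")
    wio.write_table(result.truth, f"{outdir}/truth.tsv")
    result.qc_report.to_json(f"{outdir}/qc.json")
    for key, e in result.expr.items():
        wio.write_table(e.reset_index(), f"{outdir}/expr_{key}.tsv")
    if result.section_results is not None:
        wio.write_table(result.section_results, f"{outdir}/results_section.tsv")
    wio.write_table(result.pairwise_results, f"{outdir}/results_pairwise.tsv")
    wio.write_table(result.color_results, f"{outdir}/results_color.tsv")
    if result.pd_genes is not None:
        wio.write_table(result.pd_genes, f"{outdir}/pd_genes.tsv")
    wio.write_table(result.scores, f"{outdir}/scores.tsv")
    wio.write_table(result.candidates, f"{outdir}/candidates.tsv")
    if result.modules is not None:
        wio.write_table(result.modules.membership.rename("module_id").reset_index(),
                        f"{outdir}/modules.tsv")
        result.modules.summaries.reset_index().pipe(
            wio.write_table, f"{outdir}/module_summary.tsv")
    wio.write_table(result.final, f"{outdir}/final_color_genes.tsv")
    result.report.to_json(f"{outdir}/recovery.json")
    newick, pca, _ = sample_clustering_report(result.expr["joint"], result.design)
    with open(f"{outdir}/sample_dendrogram.nwk", "w") as fh:
        fh.write(newick + "\n")
    wio.write_table(pca.reset_index(), f"{outdir}/sample_pca.tsv")
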