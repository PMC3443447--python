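"""Per-contig factorial ANOVA, within-stage contrasts, and FDR control.

Each contig's normalized expression is fit by ordinary least squares to the
factorial model of its analysis family; the factors the original mixed-model
analysis treated as random (morph, slide) enter as fixed blocking factors.
Within-stage two-group contrasts are tested on cell means with the full
model's residual mean square and residual degrees of freedom (protected
contrasts), and p-values are Benjamini-Hochberg adjusted within each
analysis family over exactly the comparisons that family retains.

The fits are vectorized across contigs: one design matrix per family, one
least-squares solve for all complete contigs, with a per-contig fallback for
contigs carrying missing cells from QC masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .registry import (
    Comparison,
    color_comparisons,
    pairwise_comparisons,
    section_comparisons,
)

_FAMILIES = {
    # family -> (design subset query, patsy RHS formula, comparison list factory)
    "section": ("wing == 'forewing'",
                "C(stage) * C(section) + C(morph)",
                section_comparisons),
    "color": (None,
              "C(color) * C(stage)",
              color_comparisons),
    "pairwise_forewing": ("wing == 'forewing'",
                          "C(morph) * C(stage) * C(section) + C(slide)",
                          lambda: pairwise_comparisons("forewing")),
    "pairwise_hindwing": ("wing == 'hindwing'",
                          "C(morph) * C(stage) + C(slide)",
                          lambda: pairwise_comparisons("hindwing")),
}

RESULT_COLUMNS = ["contig_id", "comparison_id", "estimate", "statistic", "df", "p", "note"]


@dataclass
class ModelSpec:
    """A fitted-model recipe: sample subset, fixed/blocking formula, contrasts."""

    family: str
    subset: str | None
    formula: str
    comparisons: list[Comparison]

    @classmethod
    def for_family(cls, family: str) -> "ModelSpec":
        try:
            subset, formula, comps = _FAMILIES[family]
        except KeyError:
            raise ValueError(
                f"unknown analysis family {family!r}; expected one of {sorted(_FAMILIES)}"
            ) from None
        return cls(family, subset, formula, comps())

    @classmethod
    def two_group(cls, column: str, level_a: str, level_b: str) -> "ModelSpec":
        """A minimal one-factor spec (used for oracle checks)."""
        comp = Comparison(f"{column}:{level_a}_vs_{level_b}", "",
                          ((column, level_a),), ((column, level_b),))
        return cls("two_group", None, f"C({column})", [comp])


def _solve(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Least-squares residuals and model rank for multi-response OLS."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid, int(rank)


def fit_anova(expr: pd.DataFrame, design: pd.DataFrame, spec: ModelSpec | str) -> pd.DataFrame:
    """Fit the family model per contig and test all registered contrasts.

    Parameters
    ----------
    expr
        Contig x sample log2 expression matrix.
    design
        Sample design table (must cover ``expr``'s columns).
    spec
        A :class:`ModelSpec` or a family name
        (``section`` / ``color`` / ``pairwise_forewing`` / ``pairwise_hindwing``).

    Returns
    -------
    DataFrame
        Tidy results: ``contig_id, comparison_id, estimate, statistic, df,
        p, q, note``.  ``note`` is "" for regular tests, "degenerate" when
        the contig has zero residual variance (p set to 1), and
        "empty_cell" when a contrast group has no samples (test reported
        missing).  ``q`` is the BH-adjusted p over the family's testable
        comparisons.
    """
    if isinstance(spec, str):
        spec = ModelSpec.for_family(spec)
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    if spec.subset is not None:
        design = design.query(spec.subset)
    samples = [s for s in expr.columns if s in design.index]
    if not samples:
        raise ValueError(f"no samples in expr match the {spec.family!r} design subset")
    design = design.loc[samples].reset_index().rename(columns={"index": "sample_id"})
    for col in {c for comp in spec.comparisons for c, _ in comp.a + comp.b}:
        if col not in design.columns:
            raise ValueError(f"design lacks factor {col!r} required by {spec.family!r}")

    Y = expr[samples].to_numpy(dtype=float).T  # samples x contigs
    X = np.asarray(dmatrix(spec.formula, design, return_type="dataframe"))
    n = len(samples)

    # group membership per comparison
    groups = []
    for comp in spec.comparisons:
        ma, mb = comp.masks(design)
        groups.append((comp.comparison_id, ma.to_numpy(), mb.to_numpy()))

    complete = ~np.isnan(Y).any(axis=0)
    mse = np.full(Y.shape[1], np.nan)
    dfr = np.zeros(Y.shape[1], dtype=int)
    if complete.any():
        resid, rank = _solve(X, Y[:, complete])
        d = n - rank
        dfr[complete] = d
        mse[complete] = (resid ** 2).sum(axis=0) / d if d > 0 else np.nan
    for j in np.flatnonzero(~complete):
        ok = np.isfinite(Y[:, j])
        if ok.sum() < 3:
            continue
        resid, rank = _solve(X[ok], Y[ok, j][:, None])
        d = int(ok.sum()) - rank
        dfr[j] = d
        mse[j] = float((resid ** 2).sum() / d) if d > 0 else np.nan

    finite = np.isfinite(Y)
    records = []
    contigs = expr.index.to_numpy()
    for comp_id, ma, mb in groups:
        na = (finite & ma[:, None]).sum(axis=0).astype(float)
        nb = (finite & mb[:, None]).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_a = np.nansum(np.where(ma[:, None], Y, 0.0), axis=0) / na
            mean_b = np.nansum(np.where(mb[:, None], Y, 0.0), axis=0) / nb
            est = mean_a - mean_b
            se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
            t = est / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(dfr, 1))
        note = np.where((na == 0) | (nb == 0), "empty_cell", "")
        degenerate = (note == "") & ((mse <= 1e-12) | (dfr <= 0) | ~np.isfinite(mse))
        note = np.where(degenerate, "degenerate", note)
        est = np.where(note == "empty_cell", np.nan, np.where(degenerate, np.nan_to_num(est), est))
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, 1.0, np.where(note == "empty_cell", np.nan, p))
        records.append(pd.DataFrame({
            "contig_id": contigs, "comparison_id": comp_id,
            "estimate": est, "statistic": t, "df": dfr, "p": p, "note": note,
        }))
    results = pd.concat(records, ignore_index=True)
    results["q"] = np.nan
    testable = results["p"].notna()
    if testable.any():
        results.loc[testable, "q"] = adjust_fdr(results.loc[testable, "p"].to_numpy())
    return results


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone in p-rank).

    Raises
    ------
    ValueError
        If any p lies outside (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_contigs(results: pd.DataFrame, fdr: float) -> list[str]:
    """Contigs with at least one comparison at q <= fdr, sorted."""
    hits = results.loc[results["q"] <= fdr, "contig_id"].unique()
    return sorted(hits)


def proximal_distal_genes(results: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Classify contigs with significant within-stage section contrasts.

    A contig enters the list if any forewing section contrast within a stage
    passes ``q <= fdr``.  Its pattern is read off the relative section means
    (averaged over the significant stages, morphs pooled, distal as
    reference): the end-to-end difference A = proximal - distal is compared
    with the medial offset B = medial - (proximal + distal)/2.  When the
    medial offset dominates (|B| > |A|) variation separates the medial
    section from the peripheral ones; otherwise the sign of A decides
    higher_proximal vs higher_distal.  Contigs whose section means are
    indistinguishable (both |A| and |B| <= 1e-9) are unclassifiable and
    dropped.

    Returns a DataFrame ``contig_id, pattern, stages_significant``.
    """
    if results.empty:
        return pd.DataFrame(columns=["contig_id", "pattern", "stages_significant"])
    sec = results[results["comparison_id"].str.startswith("sec:")].copy()
    if sec.empty:
        raise ValueError("results contain no section-family comparisons")
    parts = sec["comparison_id"].str.split(":", expand=True)
    sec["stage"] = parts[1]
    sec["pair"] = parts[2]
    sig = sec[sec["q"] <= fdr]
    out = []
    tol = 1e-9
    for contig, grp in sig.groupby("contig_id"):
        stages = sorted(grp["stage"].unique(), key=_stage_order)
        sub = sec[(sec["contig_id"] == contig) & sec["stage"].isin(stages)]
        est = sub.set_index(["stage", "pair"])["estimate"]
        # relative section means with distal = 0, averaged over stages
        m_p = np.nanmean([est.get((s, "proximal_vs_distal"), np.nan) for s in stages])
        m_m = np.nanmean([est.get((s, "medial_vs_distal"), np.nan) for s in stages])
        if np.isnan(m_p) or np.isnan(m_m):
            continue
        end_to_end = m_p
        medial_offset = m_m - m_p / 2.0
        if abs(end_to_end) <= tol and abs(medial_offset) <= tol:
            continue  # flat: unclassifiable
        if abs(medial_offset) > abs(end_to_end):
            pattern = "medial_vs_peripheral"
        else:
            pattern = "higher_proximal" if end_to_end > 0 else "higher_distal"
        out.append({"contig_id": contig, "pattern": pattern,
                    "stages_significant": ",".join(stages)})
    return pd.DataFrame(out, columns=["contig_id", "pattern", "stages_significant"])


def _stage_order(stage: str) -> int:
    from .config import STAGES
    return STAGES.index(stage)
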