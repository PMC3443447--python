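"""Capped Fisher color-consistency scoring and retention.

Genes can reach pairwise significance for reasons unrelated to color
(morph-wide differences, proximal-distal patterning).  The color filter
summarizes, per contig, the p-values of exactly those tissue comparisons in
which a truly red-specific gene must differ — the red-consistency set —
with Fisher's summation S = -2 * sum(ln p), flooring each p at a cap
(default 1e-4) so that extreme significance in one comparison cannot carry
the sum by itself.  A contig is retained when S strictly exceeds the score
that would be obtained if every comparison were exactly borderline at p0
(default 0.01): T = -2 k ln(p0).  The retained set is then united with the
hits of the color-based ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ScoreConfig
from .registry import red_consistency_set

SCORE_COLUMNS = ["contig_id", "S", "k", "T", "n_missing", "retained"]


def fisher_score(pvals, config: ScoreConfig | None = None) -> float:
    """Capped Fisher sum S = -2 * sum(ln(max(p, cap))) over one contig.

    Missing p-values (NaN) contribute ln(1) = 0 — absence of a comparison is
    never treated as evidence.

    Raises
    ------
    ValueError
        If any p is non-positive or exceeds 1.
    """
    if config is None:
        config = ScoreConfig()
    config.validate()
    p = np.asarray(list(pvals), dtype=float)
    present = np.isfinite(p)
    if np.any(p[present] <= 0) or np.any(p[present] > 1):
        raise ValueError("p-values must lie in (0, 1]")
    capped = np.clip(p[present], config.cap, None)
    return float(-2.0 * np.log(capped).sum())


def score_threshold(k: int, config: ScoreConfig | None = None) -> float:
    """Retention threshold T = -2 k ln(p0) for a k-comparison set."""
    if config is None:
        config = ScoreConfig()
    config.validate()
    if k < 1:
        raise ValueError("comparison set must have k >= 1 members")
    return float(-2.0 * k * np.log(config.p0))


def score_table(
    pairwise_results: pd.DataFrame,
    comparison_set: list[str] | None = None,
    config: ScoreConfig | None = None,
    entry_fdr: float | None = 0.01,
) -> pd.DataFrame:
    """Score contigs over a comparison set; apply the entry filter.

    Parameters
    ----------
    pairwise_results
        Tidy contrast results (must carry ``contig_id, comparison_id, p, q``)
        from the pairwise families.
    comparison_set
        Comparison ids to sum over; defaults to the red-consistency set
        (8 tissue pairs x 5 stages).  ``k`` is the realized member count.
    entry_fdr
        Only contigs significant (q <= entry_fdr) in at least one pairwise
        comparison are scored; None scores everything.

    Returns
    -------
    DataFrame sorted by S descending: ``contig_id, S, k, T, n_missing,
    retained`` where ``retained`` means S > T strictly.
    """
    if config is None:
        config = ScoreConfig()
    config.validate()
    if comparison_set is None:
        comparison_set = red_consistency_set()
    k = len(comparison_set)
    if k < 1:
        raise ValueError("comparison set is empty")

    if entry_fdr is not None:
        keep = pairwise_results.groupby("contig_id")["q"].min() <= entry_fdr
        contigs = sorted(keep.index[keep])
    else:
        contigs = sorted(pairwise_results["contig_id"].unique())
    sub = pairwise_results[
        pairwise_results["comparison_id"].isin(comparison_set)
        & pairwise_results["contig_id"].isin(contigs)
    ]
    pmat = sub.pivot_table(index="contig_id", columns="comparison_id",
                           values="p", aggfunc="first")
    pmat = pmat.reindex(index=contigs, columns=comparison_set)
    present = pmat.notna().to_numpy()
    capped = np.clip(pmat.to_numpy(dtype=float), config.cap, None)
    logs = np.where(present, np.log(capped), 0.0)  # missing -> ln(1)
    S = -2.0 * logs.sum(axis=1)
    T = score_threshold(k, config)
    out = pd.DataFrame({
        "contig_id": contigs,
        "S": S,
        "k": k,
        "T": T,
        "n_missing": (~present).sum(axis=1),
        "retained": S > T,
    })
    return out.sort_values(["S", "contig_id"], ascending=[False, True],
                           ignore_index=True)


def retain_by_score(scores: pd.DataFrame, T: float | None = None) -> list[str]:
    """Contigs with S strictly greater than T, ranked by S descending."""
    thr = scores["T"] if T is None else T
    kept = scores[scores["S"] > thr]
    kept = kept.sort_values(["S", "contig_id"], ascending=[False, True])
    return kept["contig_id"].tolist()


def combine_with_anova(score_retained, anova_color_hits) -> pd.DataFrame:
    """Union of the score-retained list and the color-ANOVA hit list.

    Returns a DataFrame ``contig_id, source`` with source in
    {``score``, ``anova``, ``both``}, sorted by contig id.
    """
    sset, aset = set(score_retained), set(anova_color_hits)
    rows = [
        {"contig_id": c,
         "source": "both" if c in sset and c in aset
         else "score" if c in sset else "anova"}
        for c in sorted(sset | aset)
    ]
    return pd.DataFrame(rows, columns=["contig_id", "source"])
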