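"""Gene module clustering on condition-mean profiles and the color filter.

Candidate color genes are clustered by the similarity of their expression
profiles over experimental conditions (all (wing, morph, section, stage)
cells).  Edge weights are a power-sharpened absolute Spearman correlation,
|rho|^s, with the sharpness s chosen from a small grid to maximize Newman
modularity; modules are found by deterministic greedy agglomeration.
Modules whose mean profile does not show a consistently signed red-vs-black
contrast of at least ``epsilon`` log2 units during the pigment-deposition
stages are judged inconsistent with a color-specific role, and their member
candidates are purged from the final list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import STAGES, ClusterConfig

logger = logging.getLogger(__name__)

#: stages at which pigments are being deposited; consistency is judged here
PIGMENT_STAGES = ("OMMO", "MELA")


def build_profiles(
    expr: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean expression per contig for each (wing, morph, section, stage) cell.

    Returns (profiles, conditions): ``profiles`` is contig x condition;
    ``conditions`` describes each condition column (wing, morph, section,
    stage, color, n_samples).  Missing cells (all samples of a condition
    masked for a contig) are mean-imputed from the contig's other
    conditions.

    Raises
    ------
    ValueError
        If any design condition has no expression samples.
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    keys = ["wing", "morph", "section", "stage"]
    meta_rows, blocks = [], []
    for vals, grp in sorted(design.groupby(keys, observed=True), key=lambda kv: kv[0]):
        samples = [s for s in grp.index if s in expr.columns]
        if not samples:
            raise ValueError(f"condition {vals} has no samples in the expression matrix")
        label = ":".join(vals)
        meta_rows.append(dict(zip(keys, vals), condition=label,
                              color=grp["color"].iloc[0], n_samples=len(samples)))
        blocks.append(expr[samples].mean(axis=1).rename(label))
    profiles = pd.concat(blocks, axis=1)
    missing = profiles.isna()
    if missing.any().any():
        row_means = profiles.mean(axis=1)
        profiles = profiles.apply(lambda col: col.fillna(row_means))
    conditions = pd.DataFrame(meta_rows).set_index("condition")
    return profiles, conditions


@dataclass
class ModuleAssignment:
    """A partition of contigs into modules plus per-module summaries."""

    membership: pd.Series  # contig_id -> module_id
    sharpness: float
    modularity: float
    summaries: pd.DataFrame = field(default=None)  # filled by summarize_modules

    def members(self, module_id: str) -> list[str]:
        return sorted(self.membership.index[self.membership == module_id])


def _greedy_modularity(W: np.ndarray, labels: list[str]) -> tuple[list[set[int]], float]:
    """CNM-style greedy agglomeration maximizing weighted Newman modularity.

    Starts from singletons and repeatedly merges the community pair with the
    largest positive modularity gain; ties are broken by the
    lexicographically smallest (community representative) pair, which makes
    the partition deterministic and invariant to input order once labels are
    sorted.  If the greedy local optimum has Q < 0 the one-module partition
    (Q = 0) is returned instead.
    """
    n = W.shape[0]
    two_m = W.sum()
    if two_m <= 0:
        return [{i} for i in range(n)], 0.0
    E = W / two_m  # community-pair edge fractions (diagonal = internal)
    np.fill_diagonal(E, 0.0)
    deg = E.sum(axis=1)
    q = float(-(deg ** 2).sum())
    comms: dict[int, set[int]] = {i: {i} for i in range(n)}
    reps = list(labels)  # smallest member label per community slot
    alive = np.ones(n, dtype=bool)
    while alive.sum() > 1:
        gain = 2.0 * (E - np.outer(deg, deg))
        gain[~alive] = -np.inf
        gain[:, ~alive] = -np.inf
        np.fill_diagonal(gain, -np.inf)
        gmax = gain.max()
        if not np.isfinite(gmax) or gmax <= 1e-12:
            break
        # tie-break: lexicographically smallest (label, label) pair
        ii, jj = np.nonzero(gain >= gmax - 1e-15)
        best = min(
            (tuple(sorted((reps[a_], reps[b_]))), int(a_), int(b_))
            for a_, b_ in zip(ii, jj) if a_ < b_
        )
        _, i, j = best
        if reps[j] < reps[i]:
            i, j = j, i
        q += float(gain[i, j])
        comms[i] |= comms.pop(j)
        E[i, :] += E[j, :]
        E[:, i] += E[:, j]
        E[i, i] = 0.0
        E[j, :] = 0.0
        E[:, j] = 0.0
        deg[i] += deg[j]
        deg[j] = 0.0
        alive[j] = False
    partition = [comms[c] for c in sorted(comms, key=lambda c: reps[c])]
    if q < 0:
        return [set(range(n))], 0.0
    return partition, q


def _modularity(W: np.ndarray, partition: list[set[int]]) -> float:
    two_m = W.sum()
    if two_m <= 0:
        return 0.0
    q = 0.0
    a = W.sum(axis=1) / two_m
    for comm in partition:
        idx = sorted(comm)
        q += W[np.ix_(idx, idx)].sum() / two_m - a[idx].sum() ** 2
    return float(q)


def mmc_cluster(
    profiles: pd.DataFrame,
    config: ClusterConfig | None = None,
    seed: int = 0,
) -> ModuleAssignment:
    """Cluster contigs by sharpened |Spearman| profile correlation.

    For each sharpness s in the grid, edge weights are |rho_ij|^s and the
    weighted Newman modularity is greedily maximized; the sharpness with the
    best modularity wins (ties to the smaller s).  Contigs with constant
    (zero-variance) profiles cannot be correlated and become singleton
    modules, logged.  Deterministic: contigs are processed in sorted id
    order and merge ties break lexicographically.
    """
    if config is None:
        config = ClusterConfig()
    config.validate()
    if len(profiles) < 1:
        raise ValueError("no contigs to cluster")
    order = sorted(profiles.index)
    P = profiles.loc[order].to_numpy(dtype=float)
    variances = P.var(axis=1)
    constant = variances <= 1e-24
    for cid in np.array(order)[constant]:
        logger.info("contig %s has a constant profile; assigned a singleton module", cid)
    active = [i for i in range(len(order)) if not constant[i]]

    best = None
    if len(active) >= 2:
        rho = stats.spearmanr(P[active].T).statistic
        rho = np.atleast_2d(np.asarray(rho, dtype=float))
        np.fill_diagonal(rho, 0.0)
        rho = np.nan_to_num(np.abs(rho))
        labels = [order[i] for i in active]
        for s in config.sharpness_grid:
            W = rho ** s
            partition, q = _greedy_modularity(W, labels)
            if best is None or q > best[1] + 1e-12:
                best = (partition, q, s, W)
    if best is None:  # fewer than two correlatable contigs
        partition = [{i} for i in range(len(active))]
        q, s = 0.0, config.sharpness_grid[0]
    else:
        partition, q, s, _ = best

    # module ids: by size desc, then smallest member id
    modules: list[list[str]] = [sorted(order[active[i]] for i in comm) for comm in partition]
    modules += [[order[i]] for i in range(len(order)) if constant[i]]
    modules.sort(key=lambda m: (-len(m), m[0]))
    membership = pd.Series(index=pd.Index(order, name="contig_id"), dtype=object)
    for rank, members in enumerate(modules, start=1):
        membership[members] = f"M{rank:03d}"
    return ModuleAssignment(membership=membership, sharpness=float(s), modularity=float(q))


def summarize_modules(
    assignment: ModuleAssignment,
    profiles: pd.DataFrame,
    conditions: pd.DataFrame,
    epsilon: float = 0.5,
) -> pd.DataFrame:
    """Per-module mean profile and red-vs-black pigment-stage consistency.

    For each module: the red-minus-black mean-profile contrast at each
    pigment stage (OMMO, MELA), whether the contrast is consistent (signs
    not opposite and the larger magnitude exceeds ``epsilon``), and the
    direction ("upregulated"/"downregulated" in red tissue) when it is.
    """
    red = conditions.index[conditions["color"] == "red"]
    black = conditions.index[conditions["color"] == "black"]
    rows = []
    for module_id in sorted(assignment.membership.unique()):
        members = assignment.members(module_id)
        mean_profile = profiles.loc[members].mean(axis=0)
        contrasts = {}
        for stage in PIGMENT_STAGES:
            rcols = [c for c in red if conditions.loc[c, "stage"] == stage]
            bcols = [c for c in black if conditions.loc[c, "stage"] == stage]
            contrasts[stage] = (
                float(mean_profile[rcols].mean() - mean_profile[bcols].mean())
                if rcols and bcols else np.nan
            )
        c = [contrasts[s] for s in PIGMENT_STAGES if np.isfinite(contrasts[s])]
        if not c:
            consistent, direction = False, ""
        else:
            opposite = len(c) == 2 and c[0] * c[1] < 0
            consistent = (not opposite) and max(abs(v) for v in c) > epsilon
            direction = ("upregulated" if sum(c) > 0 else "downregulated") if consistent else ""
        rows.append({
            "module_id": module_id, "size": len(members),
            **{f"red_vs_black_{s}": contrasts[s] for s in PIGMENT_STAGES},
            "consistent": consistent, "direction": direction,
        })
    summaries = pd.DataFrame(rows).set_index("module_id")
    assignment.summaries = summaries
    return summaries


def filter_inconsistent(
    candidates,
    assignment: ModuleAssignment,
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Keep candidates whose module shows a consistent red-vs-black contrast.

    The returned list is always a subset of ``candidates``; candidates not
    present in the clustering are dropped.  Returns ``contig_id, module_id,
    direction`` sorted by contig id.
    """
    if summaries is None:
        if assignment.summaries is None:
            raise ValueError("module summaries not computed; call summarize_modules")
        summaries = assignment.summaries
    rows = []
    for contig in sorted(set(candidates)):
        if contig not in assignment.membership.index:
            continue
        module_id = assignment.membership[contig]
        if bool(summaries.loc[module_id, "consistent"]):
            rows.append({"contig_id": contig, "module_id": module_id,
                         "direction": summaries.loc[module_id, "direction"]})
    return pd.DataFrame(rows, columns=["contig_id", "module_id", "direction"])
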