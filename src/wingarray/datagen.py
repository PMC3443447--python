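"""Seeded synthetic probe-level microarray data with planted effects.

The generator reproduces the two factorial hybridization designs of the
study system — forewing sections of two color morphs across five pupal
stages, and whole hindwings of three races — and plants known expression
effects (proximal/distal prepattern genes, red- and yellow-specific
pigmentation genes, morph-wide differences) on top of a stage-dominated
noise model, so that every downstream stage of the analysis can be scored
against ground truth.

Signal model, all on the log2 scale; intensity is ``2**signal``::

    signal[probe, sample] = baseline[contig] + probe_offset[probe]
                          + stage_walk[contig, stage]           (non-null contigs)
                          + wing_offset[contig] * is_hindwing   (non-null contigs)
                          + effect_size[contig] * indicator(contig class, sample)
                          + individual_effect[contig, individual]
                          + slide_artifact(probe, sample)
                          + N(0, sigma_probe)

The per-contig stage trajectory is a random walk over the five ordered
stages, which makes developmental stage the dominant axis of sample-to-
sample variation and makes adjacent stages most similar, matching the
hierarchical sample clustering seen in this kind of data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (
    EFFECT_CLASSES,
    FOREWING_MORPHS,
    FOREWING_SECTIONS,
    HINDWING_RACES,
    STAGES,
    SUBARRAYS_PER_SLIDE,
    GeneratorConfig,
)
from .phenotypes import load_phenotype_map, tissue_color

DESIGN_COLUMNS = ("sample_id", "wing", "morph", "section", "stage",
                  "individual", "slide", "color")

#: sentinel contig id of random quality-control probes
RANDOM_CONTIG = "RANDOM"


def generate_design(config: GeneratorConfig) -> pd.DataFrame:
    """Build the sample design table for the configured factorial designs.

    One row per hybridized sample (one subarray each).  Forewing individuals
    contribute three section samples unless listed in ``missing_wings``;
    hindwings are hybridized whole.  Slides hold 12 subarrays and replicate
    wings of the same condition are spread across different slides.

    Raises
    ------
    ValueError
        If a ``missing_wings`` entry does not match an existing forewing
        individual.
    """
    config.validate()
    pmap = load_phenotype_map()
    rows: list[dict] = []

    if "forewing" in config.wings and config.replicates_forewing > 0:
        reps = [f"r{i + 1}" for i in range(config.replicates_forewing)]
        valid = {(m, s, r) for m in FOREWING_MORPHS for s in STAGES for r in reps}
        for miss in config.missing_wings:
            if tuple(miss) not in valid:
                raise ValueError(
                    f"missing_wings entry {tuple(miss)} does not match any "
                    f"forewing individual (morph, stage, replicate)"
                )
        missing = {tuple(m) for m in config.missing_wings}
        for morph in FOREWING_MORPHS:
            for stage in STAGES:
                for rep in reps:
                    if (morph, stage, rep) in missing:
                        continue
                    individual = f"FW-{morph}-{stage}-{rep}"
                    for section in FOREWING_SECTIONS:
                        rows.append(dict(
                            sample_id=f"{individual}-{section}",
                            wing="forewing", morph=morph, section=section,
                            stage=stage, individual=individual,
                            slide="",  # assigned below
                            color=tissue_color("forewing", morph, section, pmap),
                        ))
    if "hindwing" in config.wings and config.replicates_hindwing > 0:
        for race in HINDWING_RACES:
            for stage in STAGES:
                for rep in range(1, config.replicates_hindwing + 1):
                    individual = f"HW-{race}-{stage}-r{rep}"
                    rows.append(dict(
                        sample_id=individual,
                        wing="hindwing", morph=race, section="whole",
                        stage=stage, individual=individual,
                        slide="",
                        color=tissue_color("hindwing", race, "whole", pmap),
                    ))

    design = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
    if design.empty:
        return design
    _assign_slides(design)
    return design


def _assign_slides(design: pd.DataFrame) -> None:
    """Assign 12-plex slides in place, per wing batch.

    Samples are ordered replicate-first, so the replicates of any one
    condition land on different slides — repeat conditions are spread apart
    rather than co-hybridized.
    """
    for wing, prefix in (("forewing", "FW"), ("hindwing", "HW")):
        idx = design.index[design["wing"] == wing]
        if len(idx) == 0:
            continue
        sub = design.loc[idx]
        rep = sub["individual"].str.rsplit("-", n=1).str[-1]
        order = sub.assign(_rep=rep).sort_values(
            ["_rep", "stage", "morph", "section"],
            key=lambda s: s.map({v: i for i, v in enumerate(STAGES)}) if s.name == "stage" else s,
        ).index
        for pos, row in enumerate(order):
            design.loc[row, "slide"] = f"{prefix}-slide{pos // SUBARRAYS_PER_SLIDE + 1:02d}"


def _effect_class_labels(n: int, fractions: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    """Deterministic class counts (largest-remainder) in a shuffled order."""
    classes = [c for c in EFFECT_CLASSES if fractions.get(c, 0.0) > 0]
    raw = np.array([fractions[c] * n for c in classes])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
    labels = np.repeat(classes, counts)
    return labels[rng.permutation(n)]


def _effect_indicator(cls: str, design: pd.DataFrame, active_color: tuple[str, ...]) -> np.ndarray:
    """0/1 vector over samples: where a planted effect of class `cls` acts."""
    wing = design["wing"].to_numpy()
    section = design["section"].to_numpy()
    color = design["color"].to_numpy()
    stage = design["stage"].to_numpy()
    morph = design["morph"].to_numpy()
    in_color_stage = np.isin(stage, active_color)
    if cls == "proximal_up":
        ind = (wing == "forewing") & (section == "proximal")
    elif cls == "distal_up":
        ind = (wing == "forewing") & (section == "distal")
    elif cls == "color_red_up":
        ind = (color == "red") & in_color_stage
    elif cls == "color_yellow_up":
        ind = (color == "yellow") & in_color_stage
    elif cls == "morph_global":
        ind = (wing == "forewing") & (morph == "hybrid")
    else:  # null, stage_only
        ind = np.zeros(len(design), dtype=bool)
    return ind.astype(float)


def _active_stages(cls: str, active_color: tuple[str, ...]) -> str:
    if cls in ("color_red_up", "color_yellow_up"):
        return ",".join(active_color)
    if cls in ("proximal_up", "distal_up", "morph_global", "stage_only"):
        return ",".join(STAGES)
    return ""


def simulate_intensities(
    design: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a probe-level intensity table for a design.

    Returns
    -------
    (intensities, probemap, truth)
        ``intensities``: DataFrame with columns ``probe_id, x, y, contig_id``
        and one positive-intensity column per sample.  ``probemap``: Series
        probe_id -> contig_id for transcript probes.  ``truth``: per-contig
        planted effect labels (``contig_id, effect_class, effect_size,
        active_stages``).

    Identical (design, config) including ``config.seed`` gives identical
    output.
    """
    config.validate()
    if design.empty:
        raise ValueError("design is empty; nothing to simulate")
    rng = np.random.default_rng(config.seed)
    n_contigs = config.n_contigs
    n_samples = len(design)
    contig_ids = np.array([f"ctg{i:05d}" for i in range(n_contigs)])

    # --- truth ---------------------------------------------------------
    classes = _effect_class_labels(n_contigs, config.effect_fractions, rng)
    effect_size = np.where(np.isin(classes, ("null", "stage_only")), 0.0, config.effect_size)
    truth = pd.DataFrame({
        "contig_id": contig_ids,
        "effect_class": classes,
        "effect_size": effect_size,
        "active_stages": [_active_stages(c, config.active_color_stages) for c in classes],
    })

    # --- contig-level signal over samples ------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_contigs)
    # stage trajectory: a contig-specific random walk blended with a walk
    # shared by its effect class (co-regulated genes track one trajectory)
    idio = np.cumsum(rng.normal(0.0, config.sigma_stage, (n_contigs, len(STAGES))), axis=1)
    class_walks = np.cumsum(
        rng.normal(0.0, config.sigma_stage, (len(EFFECT_CLASSES), len(STAGES))), axis=1)
    cls_idx = np.array([EFFECT_CLASSES.index(c) for c in classes])
    w = config.stage_share
    stage_walk = np.sqrt(1.0 - w) * idio + np.sqrt(w) * class_walks[cls_idx]
    wing_offset = rng.normal(0.0, config.sigma_wing, n_contigs)
    non_null = (classes != "null").astype(float)

    individuals = design["individual"].to_numpy()
    uniq_ind, ind_idx = np.unique(individuals, return_inverse=True)
    ind_effect = rng.normal(0.0, config.sigma_individual, (n_contigs, len(uniq_ind)))

    stage_idx = np.array([STAGES.index(s) for s in design["stage"]])
    is_hind = (design["wing"].to_numpy() == "hindwing").astype(float)

    signal = baseline[:, None] + np.zeros((n_contigs, n_samples))
    signal += non_null[:, None] * (stage_walk[:, stage_idx] + np.outer(wing_offset, is_hind))
    signal += ind_effect[:, ind_idx]
    for cls in np.unique(classes):
        ind = _effect_indicator(cls, design, config.active_color_stages)
        members = classes == cls
        signal[members] += np.outer(effect_size[members], ind)

    # --- probe level ----------------------------------------------------
    lo, hi = config.probes_per_contig
    ppc = rng.integers(lo, hi + 1, n_contigs)
    probe_contig_idx = np.repeat(np.arange(n_contigs), ppc)
    n_transcript = int(ppc.sum())
    n_probes = n_transcript + config.n_random_probes

    probe_offset = rng.normal(0.0, config.probe_offset_sd, n_transcript)
    probe_log2 = signal[probe_contig_idx] + probe_offset[:, None]
    probe_log2 += rng.normal(0.0, config.sigma_probe, (n_transcript, n_samples))

    random_log2 = rng.normal(6.0, 0.5, (config.n_random_probes, 1)) + rng.normal(
        0.0, config.sigma_probe, (config.n_random_probes, n_samples)
    )
    all_log2 = np.vstack([probe_log2, random_log2])

    # scatter probes across the subarray grid
    side = math.isqrt(n_probes - 1) + 1
    pos = rng.permutation(n_probes)
    x = pos % side
    y = pos // side

    if config.slide_artifact is not None:
        art = config.slide_artifact
        targets = art.samples if art.samples is not None else (design["sample_id"].iloc[0],)
        in_rect = ((x >= art.x0) & (x < art.x0 + art.width)
                   & (y >= art.y0) & (y < art.y0 + art.height))
        sample_ids = design["sample_id"].to_numpy()
        for target in targets:
            cols = np.flatnonzero(sample_ids == target)
            if cols.size == 0:
                raise ValueError(f"slide_artifact sample {target!r} not in design")
            all_log2[np.ix_(in_rect, cols)] += art.bias

    probe_ids = np.array([f"p{i:06d}" for i in range(n_probes)])
    contig_col = np.concatenate([contig_ids[probe_contig_idx],
                                 np.repeat(RANDOM_CONTIG, config.n_random_probes)])
    table = pd.DataFrame({"probe_id": probe_ids, "x": x, "y": y, "contig_id": contig_col})
    intensities = pd.DataFrame(
        np.exp2(all_log2), columns=design["sample_id"].to_numpy(), index=table.index
    )
    table = pd.concat([table, intensities], axis=1)

    probemap = pd.Series(contig_ids[probe_contig_idx],
                         index=probe_ids[:n_transcript], name="contig_id")
    probemap.index.name = "probe_id"
    return table, probemap, truth


def simulate(config: GeneratorConfig):
    """Convenience: design + intensities in one call."""
    design = generate_design(config)
    table, probemap, truth = simulate_intensities(design, config)
    return design, table, probemap, truth
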