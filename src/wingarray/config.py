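"""Configuration objects for the simulator and the analysis pipeline.

All configs are plain dataclasses with explicit validation and YAML
round-tripping, so a whole run is reproducible from a single file plus a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

#: Ordered pupal stages: days 1/3/5 after pupation, then the stage at which
#: orange/red ommochrome pigment first appears (~7 d) and the stage at which
#: black melanin starts to pepper the wing (~8 d).
STAGES = ("D1", "D3", "D5", "OMMO", "MELA")

WINGS = ("forewing", "hindwing")
FOREWING_MORPHS = ("petiverana", "hybrid")
HINDWING_RACES = ("emma", "favorinus", "amphitrite")
FOREWING_SECTIONS = ("proximal", "medial", "distal")

#: Planted per-contig effect classes known to the generator.
EFFECT_CLASSES = (
    "null",
    "stage_only",
    "proximal_up",
    "distal_up",
    "color_red_up",
    "color_yellow_up",
    "morph_global",
)

#: Number of subarrays per physical slide (12-plex array format).
SUBARRAYS_PER_SLIDE = 12


@dataclass
class SlideArtifact:
    """Rectangular additive log2 bias on the probe grid of selected arrays.

    Emulates a region of uneven hybridization intensity; minimal spatial
    structure sufficient to exercise QC masking.
    """

    x0: int = 0
    y0: int = 0
    width: int = 16
    height: int = 16
    bias: float = 2.0  # log2 units
    #: sample ids affected; None means the first sample of the design
    samples: tuple[str, ...] | None = None


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic probe-level dataset.

    Defaults mirror the study-scale factorial designs: a forewing set of
    3 replicates x 2 morphs x 3 wing sections x 5 stages with one replicate
    wing missing for Day-1 petiverana (87 samples), a hindwing set of
    4 replicates x 3 races x 5 stages (60 samples), and 12,450 transcript
    contigs represented by 1-6 probes each plus random control probes.
    """

    n_contigs: int = 12450
    probes_per_contig: tuple[int, int] = (1, 6)
    n_random_probes: int = 3248
    replicates_forewing: int = 3
    replicates_hindwing: int = 4
    wings: tuple[str, ...] = ("forewing", "hindwing")
    #: (morph, stage, replicate-label) wings dropped from the forewing design;
    #: each entry removes all 3 section samples of that individual.
    missing_wings: tuple[tuple[str, str, str], ...] = (("petiverana", "D1", "r3"),)
    effect_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.60,
            "stage_only": 0.20,
            "proximal_up": 0.04,
            "distal_up": 0.03,
            "color_red_up": 0.05,
            "color_yellow_up": 0.03,
            "morph_global": 0.05,
        }
    )
    #: planted log2 fold change for every non-null, non-stage-only contig
    effect_size: float = 1.5
    #: stages at which planted color effects are active: pigment-pathway
    #: transcription ramps up from day 5, ahead of visible pigment
    active_color_stages: tuple[str, ...] = ("D5", "OMMO", "MELA")
    sigma_probe: float = 0.3  # probe-level noise SD, log2
    sigma_individual: float = 0.3  # per (contig, individual) random effect SD
    sigma_stage: float = 0.6  # random-walk step SD across ordered stages
    #: fraction of stage-walk variance shared among contigs of the same
    #: effect class (co-regulated genes follow a common trajectory)
    stage_share: float = 0.5
    sigma_wing: float = 0.4  # per-contig hindwing-vs-forewing offset SD
    baseline_mean: float = 9.0
    baseline_sd: float = 1.2
    probe_offset_sd: float = 0.5  # fixed per-probe affinity offset SD
    slide_artifact: SlideArtifact | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs <= 0:
            raise ValueError("n_contigs must be positive")
        lo, hi = self.probes_per_contig
        if not (1 <= lo <= hi <= 6):
            raise ValueError("probes_per_contig must be a sub-range of 1..6")
        total = sum(self.effect_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"effect_fractions must sum to 1, got {total}")
        unknown = set(self.effect_fractions) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        # zero SDs are allowed: they give the exact noise-free limit
        for name in ("sigma_probe", "sigma_individual", "sigma_stage",
                     "sigma_wing", "probe_offset_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.stage_share <= 1:
            raise ValueError("stage_share must lie in [0, 1]")
        for wing in self.wings:
            if wing not in WINGS:
                raise ValueError(f"unknown wing {wing!r}")
        for stage in self.active_color_stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r} in active_color_stages")


def scaled_config(seed: int = 0, n_contigs: int = 2000, **overrides) -> GeneratorConfig:
    """A desk-scale generator config (default 2,000 contigs).

    Keeps the study's factorial structure, noise levels and effect sizes but
    reduces the number of contigs and control probes so full pipeline runs
    finish in minutes on one CPU.
    """
    cfg = GeneratorConfig(
        n_contigs=n_contigs,
        n_random_probes=max(50, int(round(n_contigs * 0.25))),
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


@dataclass
class PreprocessConfig:
    """QC-masking and normalization parameters."""

    qc_window: int = 16  # probes per side of a QC window
    qc_z_threshold: float = 4.0  # robust SDs of window-mean deviation
    max_masked_fraction: float = 0.25  # above this, array flagged "rerun"
    loess_span: float = 0.5
    #: normalize forewing and hindwing arrays together (used for the combined
    #: color analysis) instead of separately
    joint: bool = False

    def validate(self) -> None:
        if self.qc_window < 1:
            raise ValueError("qc_window must be >= 1")
        if self.qc_z_threshold <= 0:
            raise ValueError("qc_z_threshold must be positive")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must lie in (0, 1]")
        if not 0 < self.max_masked_fraction <= 1:
            raise ValueError("max_masked_fraction must lie in (0, 1]")


@dataclass
class ScoreConfig:
    """Capped Fisher color-consistency score parameters.

    ``cap`` floors small p-values at 1e-4 (close to the global FDR threshold)
    so no single comparison dominates the sum; ``p0`` defines the retention
    threshold T = -2 k ln(p0), i.e. the score obtained if every comparison
    were exactly borderline at p0.
    """

    cap: float = 1e-4
    p0: float = 0.01

    def validate(self) -> None:
        if not 0 < self.cap < self.p0 < 1:
            raise ValueError(f"need 0 < cap < p0 < 1, got cap={self.cap}, p0={self.p0}")


@dataclass
class ClusterConfig:
    """Module clustering and consistency-filter parameters."""

    sharpness_grid: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    #: minimum |red - black| module contrast (log2) during the pigment stages
    epsilon: float = 0.5

    def validate(self) -> None:
        if not self.sharpness_grid:
            raise ValueError("sharpness_grid must be non-empty")
        if any(s <= 0 for s in self.sharpness_grid):
            raise ValueError("sharpness values must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class RunConfig:
    """Whole-pipeline configuration: one seed, one config, one output tree."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    fdr: float = 0.01
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        self.generator.validate()
        self.preprocess.validate()
        self.score.validate()
        self.cluster.validate()
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr must lie in [0, 1]")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _tupled(value, depth: int = 1):
    if isinstance(value, list):
        return tuple(_tupled(v, depth - 1) if depth > 1 else v for v in value)
    return value


def run_config_from_yaml(path: str) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (inverse of ``RunConfig.to_yaml``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = dict(raw.get("generator", {}))
    for key in ("probes_per_contig", "wings", "active_color_stages"):
        if key in gen:
            gen[key] = _tupled(gen[key])
    if "missing_wings" in gen and gen["missing_wings"] is not None:
        gen["missing_wings"] = tuple(tuple(m) for m in gen["missing_wings"])
    if gen.get("slide_artifact") is not None:
        art = dict(gen["slide_artifact"])
        if art.get("samples") is not None:
            art["samples"] = tuple(art["samples"])
        gen["slide_artifact"] = SlideArtifact(**art)
    clu = dict(raw.get("cluster", {}))
    if "sharpness_grid" in clu:
        clu["sharpness_grid"] = tuple(clu["sharpness_grid"])
    cfg = RunConfig(
        generator=GeneratorConfig(**gen),
        preprocess=PreprocessConfig(**raw.get("preprocess", {})),
        score=ScoreConfig(**raw.get("score", {})),
        cluster=ClusterConfig(**clu),
        fdr=raw.get("fdr", 0.01),
        seed=raw.get("seed", 0),
        outdir=raw.get("outdir"),
    )
    cfg.validate()
    return cfg
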