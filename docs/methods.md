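# Methods

## The synthetic study

The generator (`wingarray.datagen`) emulates the two factorial hybridization
designs of the pupal-wing study system. All signal is built on the log2
scale and exponentiated, so intensities are lognormal and every downstream
log2-linear model is exactly specified:

    log2 intensity = baseline(contig) + probe offset
                   + stage trajectory(contig, stage)        [non-null contigs]
                   + wing offset(contig) · 1[hindwing]      [non-null contigs]
                   + Δ(contig) · indicator(effect class, sample)
                   + individual effect(contig, individual)
                   + slide artifact(probe, sample)
                   + N(0, σ_probe)

**Effect classes.** Each contig carries exactly one planted class:
`null` (flat), `stage_only` (stage trajectory only), `proximal_up` /
`distal_up` (higher in that forewing section, all stages), `color_red_up` /
`color_yellow_up` (higher in tissues of that color during the pigment-
programme stages), `morph_global` (higher in all hybrid forewing tissue —
the kind of morph-wide difference the color filter exists to reject).
Default class fractions are 0.60 / 0.20 / 0.04 / 0.03 / 0.05 / 0.03 / 0.05
and the planted log2 fold change is Δ = 1.5.

**Stage trajectories.** Per contig, the stage effect is a random walk over
the five ordered stages (step SD σ_stage = 0.6), blended with a walk shared
by the contig's effect class: with share w = 0.5,

    stage(contig) = √(1−w)·walk(contig) + √w·walk(class).

The per-contig component makes developmental stage the dominant axis of
array-to-array variation (and makes adjacent stages most similar, so sample
dendrograms recover the D1–D3 / D5–pigment-stage hierarchy); the shared
component expresses that co-regulated pathway genes track a common
trajectory, which is what gives profile-correlation module clustering its
signal in real data. With fully independent walks, within-class profile
correlations would sit near 0.2 and correlation modules would be
structurally meaningless.

**Color-effect window.** Planted color effects are active at D5, OMMO and
MELA: pigment-pathway transcription ramps up ahead of visible pigment (the
classic red-pattern marker is differential from mid-pupation). The window
also interacts with the score arithmetic: with one p-value per (tissue
pair, stage), a gene whose effect spans only the two pigment stages has an
expected capped Fisher sum of ≈ 16·18.42 + 24·2 ≈ 343, below the retention
threshold T = 368.4 — i.e. under this scoring granularity, "color-specific"
operationally means differential across at least ~3 of 5 stages.

**Noise defaults** (log2 units): σ_probe = 0.3, σ_individual = 0.3
(shared by the three sections of one forewing individual), σ_wing = 0.4,
per-probe affinity offsets SD 0.5, baselines N(9, 1.2). Zero SDs are
allowed and give the exact noise-free limit. The optional slide artifact is
a rectangular additive log2 bias on the probe grid of selected arrays.

**What the generator does not emulate:** probe sequence thermodynamics,
dye/channel effects (the arrays are single-channel), intensity-dependent
(nonlinear) technical bias, background, cross-hybridization, or
inter-laboratory batch structure beyond the per-slide blocking factor.
Passing tests therefore demonstrate correctness of the statistical
machinery under a faithful factorial structure, not robustness to every
artifact of real hybridizations.

## Preprocessing

**Spatial QC.** Each array's probe grid is tiled into windows (default
16×16 probes); a window whose mean log2 intensity deviates from the array's
median window mean by more than z = 4 robust SDs (1.4826·MAD) is masked.
Arrays with masked fraction > 0.25 are flagged `rerun`. The thresholds are
configuration, not estimates; random control probes participate (artifacts
are spatial, not biological) and their intensity quantiles are reported in
the QC JSON.

**Normalization.** Reference-array loess in MA space: the reference R is
the probe-wise mean of all log2 arrays, and each array's M = log2(x) − R is
detrended against the abundance covariate A = R using transcript probes
only. Two deliberate numerical choices:

* *Covariate A = R, not (log2(x)+R)/2.* The symmetric average puts the
  array's own biological deviations into the x-variable, which creates a
  genuine regression-to-the-mean slope; subtracting it would both distort
  the data and re-appear after every pass, so normalization could never be
  idempotent.
* *The smoother is a least-squares fit of piecewise-linear hat functions on
  Chebyshev-spaced abundance-quantile knots* (span 0.5 → 20 knots; knots
  denser at the abundance extremes). Being an orthogonal projection it is
  exactly idempotent — one pass reaches the fixed point, and re-normalizing
  normalized data is a numerical no-op — whereas iterating a raw local
  regression slowly amplifies boundary-leverage modes. The residual-trend
  diagnostic (`preprocess.ma_trend`) deliberately uses genuine lowess, so
  the "trend ≈ 0 after normalization" check is made with an *independent*
  smoother.

Forewing and hindwing arrays are normalized separately by default and
jointly for the combined color analysis. Contig expression is the mean of
non-missing probe values; a contig-sample cell is missing only when all its
probes are masked.

## Differential expression

Per contig, OLS fits of the family model; factors the original
mixed-model analysis treated as random (morph, slide) enter as fixed
blocking factors — with these balanced designs the within-stage cell-mean
contrasts are identical and no variance-component machinery is needed.
Contrasts use the full-model residual mean square and residual df
(protected contrasts); zero-residual-variance contigs report p = 1 flagged
`degenerate`; empty cells report the contrast as missing with a reason.
BH adjustment is applied per analysis family over exactly the comparisons
that family retains (the comparison registry is filtered *before*
adjustment).

One calibration consequence is documented rather than hidden: individual is
not a model factor (mirroring the original model terms), so forewing
within-morph section contrasts — whose groups share individuals — have
conservative p-values (the individual effect cancels in the estimate but
inflates the residual). Hindwing race contrasts, where every sample is an
independent individual, are exactly calibrated; null-calibration checks use
those.

Proximal–distal classification compares the end-to-end mean difference
A = proximal − distal with the medial offset B = medial − (proximal+distal)/2
over the significant stages: |B| > |A| → `medial_vs_peripheral`, otherwise
the sign of A decides. The ratio test is scale-free and robust to noise on
the medial mean (a pure proximal gene sits at |B| = |A|/2, a safe margin
from the boundary).

## Color-consistency score

S = −2 Σ ln max(pᵢ, cap) over the red-consistency comparison set — the 8
tissue pairs in which a truly red-specific gene must differ, crossed with
the 5 stages (k = 40; k is always the realized member count). cap = 10⁻⁴;
retention requires S strictly greater than T = −2k·ln(0.01). Only contigs
significant (q ≤ 0.01) in at least one pairwise comparison enter scoring;
missing comparisons contribute ln 1 = 0 (absence of evidence is never
evidence); the score ignores direction (two-sided p's) — directional
consistency is enforced by the module filter. Retained contigs are united
with the color-ANOVA hits, tagged by source.

Stage granularity was an open choice (sum over stage-specific p's, k = 40,
vs collapse stages per pair, k = 8); we score per stage and record k in the
output, since per-stage p's are what the pairwise families naturally
produce and the cap then limits each stage's influence separately.

## Module clustering and the consistency filter

Candidates are clustered on condition-mean profiles (all (wing, morph,
section, stage) cells; missing cells mean-imputed from the contig's other
conditions). Edge weights are |Spearman ρ|^s; the sharpness s ∈ {1, 2, 4, 8}
maximizing Newman modularity wins (ties to the smaller s). Modules come
from CNM-style greedy agglomeration written here rather than taken from a
graph library because determinism is contractual: contigs are processed in
sorted id order, merge ties break by the lexicographically smallest module
pair, and a final guard returns the one-module partition if the greedy
local optimum has Q < 0, so the returned modularity is never below the
trivial partition's. Zero-variance profiles become logged singletons.

A candidate survives the filter iff its module's mean-profile red-vs-black
contrast at the pigment stages (OMMO, MELA) has non-opposite signs and
max |contrast| > ε = 0.5 log2 (the floor is configuration; no criterion is
inherited from elsewhere). Known, accepted consequences: yellow-specific
genes are removed (their red−black contrast is ~0 — the filter, like the
comparison set, is red-centered), and position-driven genes elevated in
*black distal* tissue can survive as "downregulated-in-red", since a
profile contrast cannot distinguish position-driven from color-driven black
enrichment. The recovery report therefore publishes two error rates for the
final list: the fraction that is truth-null (the realized-FDR definition
used by the acceptance checks; ≈ 0.01 on scaled runs) and the stricter
fraction carrying no planted color effect (≈ 0.05–0.15, dominated by the
distal-module leak).

## Pipeline, problem sizes, determinism

`run_pipeline` chains simulate → QC → normalize (separate + joint) →
section/pairwise/color ANOVAs → score → union → cluster → filter, writes
all artifacts as TSV/JSON/newick, and scores every gate against planted
truth. The funnel reported as monotone is the score path (contigs →
pairwise-significant → score-retained → final-from-score); the ANOVA-union
branch is reported separately because a union can grow the candidate pool
before the module filter shrinks it.

Scaled problem sizes are used for routine runs and for the acceptance
script — 2,000 contigs with proportionally scaled control probes
(`scaled_config`), the size at which every recovery statistic stabilizes
while a full end-to-end run takes seconds; the defaults retain the
study-scale 12,450 contigs and 3,248 random probes. One seed drives
everything; identical configuration and seed give byte-identical tables,
reports and module assignments (clustering is seed-free and
order-invariant by construction).

## Limitations

* OLS blocking instead of REML means forewing within-individual correlation
  is absorbed conservatively, not modeled; quantities touching those
  contrasts (e.g. forewing power) are lower bounds.
* The module filter's red−black contrast cannot separate color-driven from
  position-driven black enrichment (see above).
* The greedy modularity optimizer is a deterministic approximation of the
  cited modulated-modularity method, not a bit-level reproduction; the
  adaptive weight transform is realized as the power-sharpness grid search.
* The "~10% of genes retained" figure reported for the original filter is
  ambiguous about its denominator and is not used as a contract anywhere.
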