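# Methods

This note records the statistical model behind each stage, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic studies do and do not establish.

## Synthetic study model

`moanet.simulate.generate_study` produces log2-scale expression for a
factorial design of `n_moas` modes of action (MOAs) × `chemicals_per_moa`
chemicals × `replicates` (defaults 5 × 3 × 3 = 45 treated samples), plus
matched vehicle-control groups. Each chemical carries a (vehicle, route)
pair cycled over corn oil/oral, saline/injection and CMC/oral, which yields
the three control-matching groups (nutritional-oral, non-nutritional-
injection, non-nutritional-oral) and makes route batches non-confounded
with MOA. Each chemical has its own study date, so the date term of the
ANOVA is nested one-per-chemical, the hardest (most aliased) realistic
case.

A treated sample's expression for gene g is

    baseline_g + batch_g(route) + moa_effect_g(moa) + l_g * F(sample) + noise

with per-gene baselines N(8, 1), per-gene route offsets N(0, batch_sd = 0.5)
(exactly what mean-centering on route removes), and Gaussian noise.
Controls receive baseline + batch + noise only.

**Background MOA effects.** A fraction `moa_affected_fraction` (default
0.10) of non-module genes get independent per-gene MOA effect vectors
N(0, `moa_effect_sd`), default 3× the noise sd. These are the "true
positives" for false-discovery-rate calibration.

**Module model and the loading convention.** A planted module's latent
eigengene factor is, per treated sample,

    F = (moa_sd * m[moa] + chem_sd * c[chem] + samp_sd * e) / ||·||,

normalized to unit variance: modules respond coherently to treatment (a
per-MOA and a per-chemical component, as co-regulated pathways do) on top
of per-sample biological variation (defaults 1/1/1; the demonstration
study uses 1/1/0.5). With the treatment scales at zero this reduces to a
pure per-sample factor, which is the model used by
`generate_class_pair` for operation-level calibration. A module gene with
loading l contributes `l·F` and receives residual noise
`sqrt(1 − l²)·noise_sd` — the kME convention, under which l equals the
gene–eigengene correlation at unit noise and two genes with loadings
l₁, l₂ have expected correlation l₁l₂ (in general
l₁l₂ / sqrt((l₁²+(1−l₁²)σ²)(l₂²+(1−l₂²)σ²)), the closed form the
factor-model property test asserts). This parameterization keeps the
noise-free and loading-1 limits exact (correlation → 1) and gives planted
modules realistic co-expression strength at realistic loadings; an
additive-coefficient convention (gene = l·F + σ·ε) at the same nominal
loadings produces correlations too weak to be visible through a
soft-power-10 adjacency.

Module MOA response profiles are drawn zero-mean and mutually orthogonal
across the MOA levels (up to the dimension of the centered contrast space),
so that distinct planted modules remain statistically identifiable at the
design's 5-MOA resolution and per-route centering cannot re-couple them.
The factor-implied per-MOA effect of every module gene is recorded in the
truth object, since these genes are genuinely MOA-responsive for the ANOVA
gate.

**Non-preserved modules.** Two break modes for the NRM treated samples:
`decohere` (default) gives each module gene a private, variance-matched
factor — co-expression disappears in the test class entirely, which is
what a preservation score must reject; `rewire` keeps a shared (freshly
drawn) factor but permutes, and optionally sign-flips, the gene loadings —
density survives while the gene-level connectivity pattern is destroyed,
which is the mode used to show that the connectivity Z family reacts
specifically. A redraw of the shared factor alone (without decoherence or
rewiring) would leave every preservation statistic unchanged and is
therefore not a break mode.

**Probe-level expansion.** `generate_probe_level` adds per-probe affinity
constants and probe noise; "rogue" probe sets replace their probes with
affinity plus independent noise whose variance matches signal-plus-noise,
so they carry no consistent signal and should fail the consistency filter.

## Preprocessing

Stage order follows the processing narrative: mean-center per route →
(optional) probe filter → log2 ratios → chemical averages. The probe
consistency score is the fraction of probe-level variance captured by the
first principal component of the probe × probe covariance across samples
(probes centered first, so affinity offsets are ignored); sets at or above
0.5 are kept and summarized as the probe-centered mean (the summarized
profile differs from the plain probe mean only by a per-set constant, which
cancels in ratio formation). Control matching collapses intraperitoneal,
intravenous and subcutaneous administration into one injection group and
classifies corn oil as the nutritional vehicle.

## MOA ANOVA gate

The per-gene model is fit by ordinary least squares with indicator coding
in the fixed order μ, MOA, vehicle, route, date(vehicle × route); linearly
dependent columns are dropped greedily left-to-right (pivoted elimination),
so with one date per chemical the date term absorbs what remains after MOA
rather than the reverse. The MOA F statistic is the sequential extra sum of
squares SS(MOA | μ) / df over the full-model residual mean square; p-values
come from F(df_MOA, df_resid). The default design yields df = (4, 30). Zero-
variance genes are reported with p = 1 and logged; a design with zero
residual degrees of freedom is a hard error. Under the default design the
route and control-group compositions are balanced across MOAs, so batch
offsets and shared control-mean noise cancel exactly in the MOA contrasts —
null p-values are uniform, which the test suite checks by
Kolmogorov–Smirnov across seeds.

The RM-vs-NRM differential test (chemical-level averages, 9 vs 6) is a
Welch two-sample t-test at p < 0.05 with |fold change| ≥ 1.30, fold change
reported as sign(Δ)·2^|Δ| (negative = down in RM relative to NRM). The test
and cutoffs are this package's choice of a conventional toxicogenomics
screen; they are deliberately simple and configurable.

## Network construction

Unsigned similarity (Pearson), soft power β = 10 fixed, weighted
topological overlap with the disconnected convention w = 0, and diagonals
of S, A and W fixed at 1 (connectivity excludes self). On a 0/1 adjacency
the weighted overlap reduces exactly to the neighbor-set cardinality form,
which the suite verifies against an independent set-arithmetic oracle.

**Dendrogram cut.** Average linkage on 1 − TOM; the static cut is placed at
`cut_height_fraction` (default 0.99) of the way from the first to the last
merge height, and branches below the minimum module size (default 30) stay
unassigned (grey). The cut is defined on the observed merge-height *range*
rather than on the absolute scale because a soft power of 10 compresses
TOM dissimilarities toward 1: module assembly can complete within the last
10⁻³ of the absolute scale, where an absolute-fraction cut either strands
every gene or returns a single cluster. The cut rule is pluggable; the
range-based static cut is the simplest rule that is fully specified by two
numbers and it recovers planted modules exactly in the separable-block
limit.

**Sample sizes and weak loadings.** At β = 10, modules whose within-module
correlation is ≈ 0.5 (loading 0.7) are recovered essentially perfectly
(adjusted Rand index ≥ 0.99) when correlations are well estimated; the
module-recovery test therefore uses 200 samples, where correlation
sampling error (sd ≈ 0.07) is small against the signal. At the reference
design's own 45 treated samples, recovery at loading 0.7 is partial
(measured ARI ≈ 0.83–0.97 across seeds) — a genuine limitation of a
power-10 adjacency at weak loadings and small n, not of the clustering
rule.

## Preservation Z

Five statistics per reference module, computed with the test-class network
at the same β — density family: mean within-module adjacency, variance
fraction explained by the test-class module eigengene, mean
|gene–eigengene correlation|; connectivity family: Pearson correlation of
intramodular connectivity vectors (reference vs test) and of the
vectorized within-module correlation matrices. The permutation null
relabels genes **in the test dataset only** (the reference module is held
fixed and row-pairing is positional), preserving the test network while
breaking membership; each statistic's Z is (observed − permutation mean) /
permutation sd, Z_density and Z_connectivity are family medians, and
Z_summary is their mean — the only composition the method's definition
fixes. Zero permutation sd maps to +∞ (observed above the null) or 0,
logged. Default 200 permutations: across pilot runs the sd of Z_summary
between permutation seeds is a few percent of its value; the count is
configurable and the CLI exposes it.

Calibration measured by the suite: a planted 60-gene module at loading 0.8
with 15 samples per class scores Z_summary ≈ 13–28 (above 10 in ≥ 95% of 40
seeds); size-matched random modules in independent noise have mean
Z_summary inside (−1, 1) and cross 10 in < 1% of trials. For a module with
*equal* loadings the connectivity statistics carry no expected signal
(genes are exchangeable, so there is no gene-level pattern to agree on) and
Z_connectivity fluctuates around 0; Z_summary is then driven by the density
family. With heterogeneous loadings both families respond, and rewire-mode
breakage lowers Z_connectivity specifically.

A caveat on the permutation universe: random relabeling draws from the
gated gene set, so if planted (or real) modules dominate that universe the
null is itself co-expressed and Z shrinks toward 0. The demonstration
study therefore plants modules amounting to ≈ 40% of the gated genes, in
line with the proportion a real gated set shows, with the remainder made of
moderately MOA-responsive background genes (effects 0.8× noise — strong
enough to pass the gate, far too weak to form β = 10 modules of their own).

## Pipeline

Stages run in the order preprocess → ANOVA gate → class split → reference
network (RM by default; direction configurable) → preservation against the
other class → optional enrichment; every stage consumes and produces plain
files (TSV / JSON / Newick), so any stage can be re-run standalone. Class
networks are built on replicate-level ratio columns by default; the
chemical-averaged option (9 RM / 6 NRM columns) is available but
correlation estimates from 6–9 points are too unstable for reliable module
detection at β = 10, and averaging also triples the apparent treatment
share of background genes. The run manifest stores the config snapshot,
seeds, SHA-256 of every output and stage timings; identical config + seed
reproduces bit-identical outputs (hash randomization is avoided by never
iterating unordered containers into random draws).

## Enrichment

One-sided hypergeometric tail P(overlap ≥ observed) per (module, set), with
sets intersected with the analysis universe first; expected count is
module × set / universe and fold enrichment is observed/expected; BH across
sets within each module. Under random modules the p-values match their
discrete null distribution and fold enrichment is centered at 1 (both
property-tested).

## What the synthetic tests do not show

The generator plants linear, Gaussian, single-factor modules with
orthogonal MOA responses; real co-expression has correlated pathway
responses, heavier-tailed noise, unbalanced designs and probe-level
artifacts beyond affinity offsets. Passing calibration here demonstrates
the statistical machinery is implemented and calibrated as specified, not
that any particular real dataset will yield the same module count or Z
values — on real data those depend on unstated tree-cut parameters and on
the full preprocessing provenance. Desk-scale defaults (2,000 genes) stand
in for full array scale (~31k probe sets); all stages are O(genes²) or
better and scale to array size in memory on a workstation.
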