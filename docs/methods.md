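# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Quality control and normalization

Cell filters run in a fixed order and a cell is attributed to the first
rule that removes it: (1) a doublet guard removing cells above the 99th
percentile of detected-gene count or total UMI count (linear-interpolation
percentiles, computed once on the input and frozen for the pass); (2) a
detected-gene floor (default 1500, which presumes a ~20k-gene
transcriptome — synthetic runs on the 2,000-gene panel scale it to 200);
(3) a mitochondrial-fraction cap (default 40%; a stricter 30% second-pass
value is available as a parameter). Gene filters remove symbols starting
with any of the mitochondrial/ribosomal prefixes (MTAT, MT-, MTCO, MTCY,
MTERF, MTND, MTRF, MTRN, MRPL, MRPS, RPL, RPS; exact string prefixes, so
MTX1 survives MT-) and genes detected — raw UMI count > 0, never a
normalized threshold — in fewer than 0.1% of cells.

Expression is depth-normalized to a fixed total (default 10,000) and
log1p-transformed. This replaces regression-based variance stabilization
(Pearson residuals) deliberately: every downstream stage is rank-based,
detection-based, or mean-based with a +1 stabilizer, and none is
sensitive to the variance-stabilization choice, while fixed-total
normalization is deterministic and dependency-free. Averages over gene
panels use the geometric mean of (value + 1), minus 1, so zeros are
defined and outliers are damped.

## Differential expression

Smoker-versus-non-smoker contrasts use the Wilcoxon rank-sum test: exact
null enumeration when the pooled sample has ≤ 25 tie-free observations,
otherwise the normal approximation with tie and continuity corrections.
(The exact path is routed by pooled size, not per-group size, because the
approximation's error at lopsided small splits exceeds the granularity of
the exact null.) Population contrasts use a likelihood-ratio test on
logistic models of group membership — `group ~ covariates` against
`group ~ expression + covariates` — so expression must explain membership
beyond latent covariates (smoking habit, or donor identity one-hot with
the first level dropped). The logistic fits use an in-package
Newton/IRLS solver; under perfect separation or non-convergence both
models are refit with a small L2 ridge so the statistic stays finite.

Genes enter testing only if |logFC| > 0.25 and detection > 10% in at
least one group, where logFC = log(mean(depth-normalized counts)_a + 1) −
log(mean(...)_b + 1) on the natural-log scale (the +1 pseudocount and
group-mean convention of the single-cell ecosystem's standard toolchain;
the choice matters only near the gate). **Multiplicity is adjusted over
the full gene universe**, with untested genes entering the BH step-up at
p = 1 (only tested genes report an FDR). This matters: gating on an
observed effect size selects genes whose rank statistics have already
fluctuated, and adjusting only within the gated set is strongly
anticonservative at a few hundred cells per group. With full-universe
adjustment the stage is calibrated on exchangeable nulls (zero flags in
the benchmark) while planted logFC-1.0 effects are still recovered at
>90%.

One-sided tests expose an `alternative` argument whose direction must be
declared in configuration, never inferred from the data.

## Marker genes and cell characterization

Markers come from pairwise DE between populations, with clusters larger
than the median cluster size downsampled to it (seeded, without
replacement, once per population). A gene is a marker of P only if
significantly upregulated (FDR < 0.05 after the gates) against *every*
other population — the strictest reading of "against all other clusters".
Each marker's summary p is the largest p across P's comparisons,
re-adjusted by BH within P (the adjustment pools within one population;
pooling across populations was the other defensible reading). Ranks are
dense by ascending FDR, ties broken by descending worst-case logFC then
gene name.

Signature scores are geometric means over the top 25 ranked markers (or
as many as exist). Characterization computes each population's mean
top-marker expression per cell and labels a cell P only when its P-score
reaches the 85th percentile of P-scores across **all** cells while every
other population's score stays below that population's threshold
(per-population overrides to the 95th percentile support transitional
populations). By construction at most ~15% of cells can be labeled per
population.

## Smoking-response taxonomy

Per direction (up/down, classified independently), a gene is significant
in a population when FDR < 0.05 with logFC of that sign. Core: significant
in ≥ 5 of the 8 roster populations. Unique: significant in exactly one,
and in every other roster population showing direction-signed
logFC < 0.25 **or** FDR > 0.2 (inclusive-or, evaluated per population) or
failing the test gates — gated-out genes count as "not affected", since
the gates already imply weak effect or low detection. Significant
somewhere but neither core nor unique: semi-unique. The default roster is
the eight main epithelial populations (three basal states, KRT8-high,
ciliated, SMG basal, SMG secretory, surface secretory); rare populations
are excluded by default because they rarely carry detectable smoking DE.

Composition shifts are donor-level: each donor's cells become population
proportions, each smoker donor's shift is measured in percent relative to
the mean non-smoker proportion, and the summary is the mean ± SEM over
smoker donors. Transcript shares divide a gene's summed raw UMIs by
population; per-cell fold differences are ratios of +1-stabilized
population means of depth-normalized expression.

## Mucin co-expression programs

Within the secretory subset — excluded-donor cells removed, and only
cells expressing both anchor mucins (raw count > 0) retained; at least 50
eligible cells required — each gene is correlated with each anchor by
partial Spearman correlation controlling for smoking habit (binary
heavy-vs-never indicator): rank-transform all three variables (average
ranks on ties), residualize the ranked gene and anchor on the ranked
confounder by least squares, correlate the residuals, and take p from the
t approximation with n − 3 degrees of freedom. A constant confounder
falls back to plain Spearman with a warning.

A gene joins an anchor's program when its correlation with that anchor is
BH-significant (FDR < 0.05) **and positive**, and not so for the other
anchor; significant for both → "both". The positivity requirement is part
of the program definition: a co-expression program is a set of genes that
rise and fall *with* its anchor, and depth normalization mechanically
anti-correlates every gene with a highly expressed anchor's swings (a
composition effect), so negative partial correlations are artifacts of
library-size closure, not co-expression. Genes with ρ > 0.15 carry a
`reportable` flag. Programs are ranked by descending ρ (not FDR — the
selection is by correlation magnitude); the smoking-shift test scores
each cell as the mean expression of the top-25 program genes and applies
one-sided rank-sum tests in pre-declared directions (A-program up in
smokers, B-program down).

## Trajectory and endpoint isolation

The reduced space is a deterministic PCA (top 10 components, full SVD
with a fixed sign convention) of scaled log-normalized expression
restricted to the 1,000 most dispersed genes, where dispersion
(variance/mean of depth-normalized counts) is standardized within 20
mean-quantile bins to remove the mean–dispersion trend. The lineage is
the root→end path through the Euclidean minimum spanning tree over
population centroids (root→farthest-leaf when no end is given); each
member cell's pseudotime is the arc-length of its orthogonal projection
onto the piecewise-linear path, clamped to the path ends; populations off
the chosen path get missing pseudotime.

Association testing fits, per gene, a Gaussian linear model on a natural
cubic spline basis of pseudotime (df = 3, truncated-power construction
with knots at evenly spaced quantiles) plus covariate against the
covariate-only model; the statistic n·log(RSS₀/RSS₁) is referred to
chi-square with 3 df, BH-adjusted, flagged at q < 1e−10. Smoothing is a
centered triangular-weighted moving average over a 100-cell window of
pseudotime-sorted cells, truncated symmetrically at the ends (the
triangular kernel is the documented choice of "weighted average").

Endpoint isolation fits a two-component 1-D Gaussian mixture to
pseudotime by EM: deterministic initialization (means at the 25th/75th
percentiles, pooled sd, equal weights), sd floored at 1e−6 of the data
range, components relabeled so μ₁ ≤ μ₂, convergence at log-likelihood
gain < 1e−8; the log-likelihood is asserted non-decreasing at every
step. The endpoint component is the one with the larger mean (the
interpretation chosen where weights are extreme), and mature cells are
those with pseudotime > μ₂ − 2σ₂. Isolation refuses to run when the fit
did not converge or the components are unseparated
(|μ₂ − μ₁| < 2·max(σ)).

## Enrichment

Over-representation uses the upper-tail hypergeometric probability of the
overlap between a query list and each term restricted to the background
universe (default: all genes surviving the gene filters), BH across
terms, significant at FDR < 0.05. The network view connects query genes
sharing at least one enriched term, with edge weight equal to the number
of shared terms; term-consolidation (metagroup clustering) is
presentation, not statistics, and is deliberately not implemented.

## The synthetic-data generator

Counts are gamma-Poisson: gene base means (lognormal background; planted
genes drawn from a moderate band of 0.4–2.0 expected counts so detection
gates are realistically passable), multiplied by per-donor lognormal
batch effects (sd 0.15), population marker effects, smoking effects in
affected populations only (natural-log fold-changes applied to heavy
smokers), a lognormal per-cell depth factor (sd 0.35), then NB-sampled at
dispersion 0.5. Mitochondrial genes receive a per-cell beta-distributed
(2, 38) share of the cell's output. Identical seeds give bit-identical
data.

The default study mirrors a 12-donor design (6 never / 6 heavy smokers,
420 cells each, ~5,000 cells, 2,000 genes): eight main populations plus
three rare types at 0.8% composite frequency; 30 markers per population
at logFC 1.5; 50 core smoking genes (25 up / 25 down, each affected in 6
of 8 roster populations at logFC 1.0); 20 unique genes per population
(10 up / 10 down, logFC 1.0); a four-population basal→secretory continuum
with Gaussian pseudotime around stage centers 0.8–3.2 and a separated
terminal component (mean 8, sd 0.5); three 15-gene phase waves (Gaussian
bumps at pseudotime 1, 4 and 6, width 2 — the late wave rises gradually
from mid-continuum so the planted lineage is an actual expression
gradient); and two 25-gene mucin programs whose log-means track their
anchor's latent activity (strength 0.9), with the two anchors' latents
shifted in opposite directions (±0.8) in smokers. Along the lineage,
marker expression is graded by pseudotime proximity to the population's
stage (triangular weight), because adjacent differentiation states share
partial marker expression — with disjoint equal-size blocks the
population centroids form a near-regular simplex and *no* method could
order them.

Benchmark variants isolate one structure each, so measured precision and
recall are attributable: `marker_benchmark_config` plants only marker
blocks (continuum and program genes are genuinely population-restricted
expression and would count against measured marker precision despite
being real markers); `mucin_benchmark_config` enriches the secretory
population so ~2,000 cells carry the programs, on the same 2,000-gene
panel as the default study (a smaller panel would exaggerate the anchors'
share of library size and with it compositional coupling);
`null_smoking_config` zeroes **all** planted effects including donor
batch effects, giving the exchangeable null on which type-I calibration
is meaningful — with donor effects restored, cell-level tests are
pseudoreplicated across donors and some false flags are expected, which
the suite exercises as a robustness observation, not a calibration claim.

What the generator does not emulate: ambient RNA, doublets as cell
mixtures, spliced/unspliced layers, donor-specific composition other than
multinomial sampling, and any integration/batch-correction step (the
taxonomy's robustness to batch structure rests on rank tests, not on
correcting the batches). Passing tests therefore demonstrate that the
implementations recover the structures they are defined on at realistic
noise levels — not that they would survive every artifact of real
droplet data.

## Problem sizes and determinism

The test suite and the acceptance script run the study at the sizes
above (~5,000 cells × 2,000 genes; one 30,000-cell run measures the
realized rare-cell percentage), with 20 independent null replicates for
the false-flag rate. All randomness flows from explicit seeds
(`numpy.random.default_rng`); simulation, both workflows, and every
written table are bit-reproducible, which the manifest verifies by
content checksum.
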