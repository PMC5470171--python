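# Methods

## Growth model and the kinematic estimators

The synthetic growth model is piecewise-exponential. Cell number grows
as N(t) = n₀·exp(r_div·min(t, t_arrest)): proliferation at a constant
relative rate r_div until an arrest day, then none. Mean cell area is
constant at a₀ during proliferation and grows as
ā(t) = a₀·exp(r_exp·(t − t_arrest)) between arrest and a maturity day
t_mature. Blade area is the product A(t) = N(t)·ā(t) (the identity
holds exactly in the truth tables). This makes the true rates
piecewise-constant — D(t) = r_div·1[t < t_arrest],
RLER(t) = D(t) + r_exp·1[t_arrest ≤ t < t_mature] — which is exactly
what is needed to validate rate estimators: away from the two
breakpoints any correct estimator must return the constants.

Observed replicate areas are truth × exp(σ·z), z ~ N(0,1), σ equal to
the noise coefficient of variation. Lognormal noise keeps areas
positive, makes error bars scale with the mean as they do in organ
growth data, and is unbiased in log space, so log-domain smoothing sees
zero-mean noise. The distribution of replicate leaf areas in real
experiments is not identifiable from published figures; lognormal is an
assumption of the generator, not an inference.

Defaults (per genotype preset): n₀ = 400 cells and a₀ = 75 µm² at
6 days after stratification (DAS), r_div = 0.40 day⁻¹ (a cell cycle of
~1.7 days), r_exp = 0.35 day⁻¹, t_mature = 24 DAS, days 6–28, six
replicate leaves per day, noise CV 0.05. Arrest days are the genotype
contrast: 15 DAS ("WT-like"), 12 ("OE-mild"), 10 ("OE-like"). The
rates and initial values are chosen at magnitudes typical for young
Arabidopsis first leaves so that final cell numbers land in the
10⁴–10⁵ range and mature blades at a few hundred mm².

Estimation: replicates are averaged per day before the log transform
(a config switch averages in log space instead; with lognormal noise
the geometric mean is the maximum-likelihood choice, but the arithmetic
mean is what growth studies plot, so it is the default). ln A and ln N
are smoothed by local quadratic regression over a centred 5-day window,
shrinking to no fewer than three points at the edges, and the analytic
derivative of the local fit at the centre day gives the rate. A
quadratic fit is exact for any log-quadratic series, hence exact on
exponential segments — the estimators reproduce the simulated constants
to < 1e-8 at days two or more from a breakpoint (the smoothing window
straddles a breakpoint for at most ±2 days around it).

**Proliferation-exit day.** The smoothed D(t) turns the true step at
t_arrest into a symmetric ramp. The estimator therefore reports the
interpolated day at which D(t) crosses half its proliferative plateau
(maximum of the smoothed series), floored at an absolute threshold of
0.02 day⁻¹; for a symmetric window the half-plateau crossing sits
exactly on the breakpoint (noise-free recovery is exact to machine
precision), whereas any small absolute threshold fires only once the
ramp has decayed, a deterministic lag of about half the window. The
0.02 day⁻¹ threshold still defines "division has ceased" for reporting
cell-cycle durations: T_c = ln 2/D is given only where D exceeds it.

## Pavement-cell morphometrics

Convexity is computed on areas — polygon area over convex-hull area
(solidity) — not on perimeters. Areas use the shoelace formula on the
traced vertex list (continuous µm coordinates, no pixel grid); hulls
use Andrew's monotone chain with collinear boundary points dropped
(area unaffected). Self-intersecting outlines are rejected with an
error rather than repaired: silent repair changes areas unpredictably.
Degenerate (collinear) vertex sets are rejected at construction (zero
area). Convexity is invariant under translation, rotation and uniform
scaling, which is tested property-based.

The synthetic outlines are radial perturbations of a circle,
r(θ) = R(1 + a·sin(kθ + φ)), sampled at 64 angles; a is the lobe
amplitude in [0,1), k the lobe count, R lognormal across cells and φ
uniform. Being single-valued in θ with r > 0, every generated outline
is simple by construction. Real pavement cells have lobes that are not
sinusoidal and neighbours that constrain each other; the generator
reproduces the solidity range and its amplitude dependence, not tissue
topology, so passing tests say nothing about segmentation quality or
cell packing.

## Endoreduplication index

EI = 0·f₂C + 1·f₄C + 2·f₈C + 3·f₁₆C on class fractions. The printed
form of this index is often written on raw counts with the
normalisation left implicit; fractions are used here so the index is
comparable across samples with different nuclei totals, and the
all-zero distribution is rejected. Classes above 16C are rejected
rather than truncated — the index as defined stops at three endocycles,
and silently folding 32C nuclei into it would bias EI downward. The
confidence interval is a multinomial percentile bootstrap (default
2000 resamples) of the observed counts; at 10,000 nuclei its coverage
of the true EI measures ≥ 93/100 in the validation runs.

## Expression statistics

RPKM is 10⁹·c/(L·T) with L the exon-model length (bp) and T the
sample's total counts. Depth scaling multiplies each sample by
10⁷/T (the conventional 10-million-read target). Fold changes are
log₂((mean_B + 1)/(mean_A + 1)) on depth-scaled expression; the
pseudocount of 1 bounds fold changes for zero-count genes and is
configurable.

**Two-group proportion test.** Each sample contributes a gene
proportion p_i = x_i/n_i. Under a beta-binomial model
Var(p_i) = p(1−p)(1 + φ(n_i−1))/n_i, so inverse-variance weights are
w_i = n_i/(1 + φ(n_i−1)); each group's proportion is the weighted mean
with variance p̂(1−p̂)/Σw, and the statistic is
(p̂_A − p̂_B)/√(V_A + V_B). The proportions are computed on raw counts
with raw totals — proportions are depth-free, so scaling would only
cancel.

φ is estimated per gene by the method of moments (equating the
group-wise weighted sums of squares to their expectations, pooled over
the two groups) and floored at zero. With two or three samples per
group this raw estimate has so few residual degrees of freedom that a
test weighted by it alone has essentially no power after multiple
testing correction, while its occasional collapse to zero inflates the
extreme tail. The estimator therefore shares information across genes,
as moderated-variance methods for small RNA-seq designs do: since φ
scales with abundance (φ ≈ γ·p/(1−p), with γ the abundance-free
squared biological coefficient of variation), the per-gene moment
estimates are mapped to the γ scale, shrunk toward the across-gene mean
with a prior weight of 50 pseudo-degrees of freedom, mapped back with
each group's pooled proportion, and floored at zero. P-values come
from a t distribution with Satterthwaite degrees of freedom plus the
prior 50 — the moderated reference accounts for the residual
uncertainty left after pooling. With all genes sharing one true
dispersion this is nearly an oracle test; on data whose dispersions
vary strongly across genes the single pooled γ is a simplification,
and genes far above the pooled value will be anticonservative (a
trended or empirical-Bayes per-gene prior would be the next step).
Measured on the synthetic conditions (2000 genes, 3 vs 3, dispersion
0.1, depth 10⁶): null type-I error 3.8–4.0% at the 5% level,
sensitivity ~90% for planted 4-fold changes and realized
false-discovery proportion < 1% under FDR < 0.05 and |log₂FC| > 0.75.
Genes with zero counts in both groups get statistic 0 and p = 1; two
exactly constant but unequal groups get p = 0.

FDR adjustment is Benjamini–Hochberg step-up (Bonferroni available as
an option). The significance filter uses strict inequalities: a gene
sitting exactly on the fold-change boundary is not called.

**QT clustering.** Distance is 1 − Pearson r of the per-sample
profiles; anticorrelated profiles are maximally distant, so up- and
down-regulated patterns separate (using 1 − |r| would merge them). For
every gene a candidate cluster is grown greedily — repeatedly adding
the gene whose addition keeps the full cluster diameter smallest, while
it stays within the bound (0.8 by default) — the largest candidate is
extracted, and the process repeats until the largest candidate falls
below the minimum size (15). Ties go to the lowest input index, making
the procedure deterministic for a fixed input order. Plain Pearson
correlation is used for the distance, not the jackknifed variant some
QT implementations offer. Constant profiles have undefined correlation
and are moved to the unclustered remainder with a warning. The greedy
growth is the classical quality-threshold heuristic: each candidate is
maximal but not guaranteed to be the globally largest diameter-bounded
set, although on small random instances it matches an exhaustive
maximum-clique search (asserted on a 30-profile instance in the test
suite).

## Synthetic counts

Baseline gene abundances are lognormal (σ = 1.2) normalised to an
expected per-sample depth (default 10⁶ reads in the validation runs;
the analysis scripts use the same). A seeded random subset of exactly
round(frac_de·n_genes) genes has its group-B mean multiplied by
2^(±log₂FC) with random sign. Counts are negative-binomial with a
single dispersion (default 0.1, a typical between-replicate value for
RNA-seq with biological replicates), falling back to Poisson at
dispersion 0. Gene lengths are uniform 200–5000 bp. The generator has
a common dispersion across genes and no correlation between genes, so
the measured operating characteristics are those of a well-specified
test; real libraries with gene-specific dispersion, outliers and
correlated modules will be harder.

## Determinism and numerics

Every stochastic step takes an explicit seed; derived child seeds come
from a seed sequence and stay below 2³¹. Pipeline outputs are
byte-identical for identical config and seed; polygon CSVs are written
at 17 significant digits and all readers parse floats in round-trip
mode, so CSV round trips are lossless at float64. Degenerate inputs
(zero-variance t-test groups, all-zero genes, collinear polygons,
empty ploidy distributions) are either given their conventional values
(p = 1 for no evidence, p = 0 for constant unequal groups) or rejected
with explicit errors, as documented per function.

## Problem sizes

The validation runs use 2 genotypes × 23 days × 6 replicates × 50
seeds for rate recovery, 500 random polygons for the hull oracle, 100
simulated samples of 10,000 nuclei for CI coverage, 20 null and 5
planted count matrices of 2000 genes (3 vs 3) for the DE operating
characteristics, and 30–80-profile instances for the clustering
checks — sizes at which the Monte-Carlo error of each reported
quantity is well below the margins being tested, while the whole
validation completes in seconds.
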