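# Methods

## Scope and model

`noisescape` reconstructs, for each gene, a continuous fitness landscape
over the two phenotypes of a protein expression distribution — log2 mean
expression (μ) and log2 expression noise (η, noise measured as the
coefficient of variation, CV = SD/mean) — from pooled-competition fitness
measurements of strains in which a panel of synthetic promoters drives the
gene. It then quantifies each gene's *expression sensitivity* (fitness loss
per two-fold change of mean at minimal noise) and *noise intolerance*
(fitness loss per two-fold increase of noise at wild-type mean), tests both
against permutation nulls, decomposes the set of landscapes into principal
topologies by PCA, and simulates cis-regulatory adaptive walks under
telegraph-model mutation moves.

## Per-strain fitness from read counts

Fitness of strain *i* at a later timepoint *t* of the competition is

    f_i^t = log2[ (n_i^t / n_wt^t) / (n_i^t0 / n_wt^t0) ]

with every read count incremented by a pseudo count of 0.1. The pseudo
count is applied inside the count-based error estimate

    σ_i^t = sqrt(1/n_i^t0 + 1/n_i^t + 1/n_wt^t0 + 1/n_wt^t)

as well, so both formulas operate on the same count scale and the error is
defined for zero counts. The two timepoints (23 h and 35 h) are put on a
common scale by a first-order least-squares fit f23 ≈ a·f35 + b across all
strains; the 35 h values are mapped onto the 23 h scale (the direction is a
fixed convention, recorded in output metadata). The combined fitness is the
weighted average with weights 1/σ (an `inverse_var` switch provides
inverse-variance weighting) and the combined error is the inverse-variance
combination (σ23⁻² + σ35⁻²)^(−1/2), which never exceeds either timepoint
error. All fitness values stay on the per-experiment (23 h) scale.

## Quality control

Promoters are calibrated between the two reporter platforms (plasmid vs
genomic locus) by a degree-1 fit of the log2 mean-expression estimates;
promoters deviating by more than 0.5 log2 units after the transform are
discarded, as are promoters whose median fitness error across genes exceeds
0.1 (strictly; a median exactly at 0.1 is retained) and promoters outside
the homogeneously populated window of 2–6 log2 expression units (16-fold;
boundaries inclusive). Genes are analysed only if their wild-type promoter
expression lies in the centre of that window (3–5 log2 units). Replicate-
derived expression errors are smoothed by loess (tricube-weighted local
linear regression, span 0.5) of the replicate SD against the read-based
error estimate, clipped at zero. Strains whose promoter carries a predicted
binding motif for the driven gene are removed from an explicit exclusion
list supplied in configuration; no motif scanning is performed.

## Landscape reconstruction

Each gene's landscape lives on a regular grid spanning wt ± 1.5 log2-mean
units (step 0.05) and −3 to −1 log2-CV units (step 0.025): 61 × 81 = 4941
points, endpoints inclusive, the wild-type mean always a grid column. The
fitness at grid point (x, y) is the weighted average of all strain fitness
values, with weight

    w = (1/σ_f²) · ∫∫ N((μ,η); (x,y), C_kernel) · N((μ,η); (μ_i,η_i), C_i) dμ dη

where C_kernel = diag(scale_μ², scale_η²) is the smoothing kernel (defaults
0.602 and 0.361 log2 units) and C_i = diag(err_μ², err_η²) is the
promoter's position-measurement covariance. Two evaluators are provided:

* **auxiliary** (default): a Riemann sum on a 21 × 21 lattice centred on
  the grid point, spacing 0.3·√scale_μ and 0.3·√scale_η, keeping only
  lattice points where the kernel density exceeds 1% of its central value —
  the original numerical scheme;
* **closed_form**: the exact Gaussian-product identity (the integral is the
  normal density of the promoter–gridpoint offset with covariance
  C_kernel + C_i), used as the oracle and for permutation-scale workloads.

The two agree to better than 0.5% when position errors are at or above the
lattice spacing (≈ 0.17–0.23 log2 units) and the offset is within about two
kernel standard deviations; this is the scheme's operating range. Narrower
likelihoods alias on the fixed lattice, and beyond ~2.5 kernel SD the 1%
cutoff truncates the integral by design, so weights there (which are
negligible in any weighted average with nearby strains) are unreliable in
relative terms. Strains with exactly zero position errors are collapsed
analytically in both evaluators. Grid points whose total weight underflows
are reported as undefined (NaN). The per-gridpoint uncertainty is the
weighted standard error sqrt(Σw²σ_f²)/Σw.

Kernel bandwidths are chosen by ten-fold cross-validation: held-out strain
fitness is predicted from the landscape built on the remaining strains,
evaluated at the held-out promoter's nearest grid point; a log-spaced grid
over both scales is refined by local search, ties breaking toward smaller
bandwidths. A caveat found while validating on synthetic data: when the
noise-direction signal is weak relative to the fitness noise, the
prediction-RMSE objective is indifferent to (or slightly favours)
flattening the noise axis entirely, which destroys the noise-intolerance
metric. CV bandwidth selection is therefore most trustworthy when the
noise-fitness structure is strong; for estimator-validation studies the
package uses an *error-matched* kernel instead (bandwidths equal to the
panel's median position errors), an instrument-free choice that resolves
all structure the measurements can support.

## Slope metrics and statistics

Expression sensitivity is the mean absolute slope ∂f/∂μ along the minimal-
noise row (η = −3), averaged over the full ±1.5 window; noise intolerance
is minus the mean slope ∂f/∂η along the wild-type column over η ∈ [−3, −1].
Both are normalized per one log2 unit (one two-fold change); noise-
beneficial genes yield negative intolerance and are not clipped. Slopes use
central differences with one-sided differences at the boundaries. Both
metrics are invariant to adding a constant to the landscape and scale
linearly with fitness rescaling.

Significance: fitness values are permuted across the gene's strains
(default 10⁴ randomizations; fewer than 100 is refused), the landscape is
rebuilt with the unchanged weights — only the two metric lines are needed,
so each permutation is two small matrix products — and p is the fraction of
permuted metrics ≥ observed, without add-one smoothing (resolution floor
1/n). Detection power depends on the kernel: permutation preserves the
fitness spread, and under a narrow kernel the permuted (rough) surfaces
carry larger mean-absolute slopes than a smooth systematic gradient; the
wide default kernel suppresses the permuted slopes while the systematic
gradient survives. q-values are Benjamini–Hochberg. The cross-gene Pearson
correlation between the two metrics is tested against the fraction of
randomization runs with a correlation at least as large.

Alternative estimates: first-order Pearson partial correlations of fitness
with mean (controlling noise) and noise (controlling mean) via the residual
method, two-sided p from the t transform with n − 3 degrees of freedom;
degenerate cases (residual variance at numerical-noise level) are reported
as r = 0, p = 1 with a flag so the cross-gene FDR stays defined. The
curvature metric is the minimal |μ − wt| at which fitness drops 5% below
its wild-type value (+∞ if never; the threshold comparison carries a 1e-12
float tolerance).

Endogenous-noise comparison: noise values from reference datasets are
DM-corrected (running median over an expression-rank window, odd-sized,
default half the points, truncated at the edges); Spearman ρ between a
landscape metric and DM noise is tested one-sided (alternative ρ < 0) by
label permutation with add-one smoothing (keeping Fisher's method finite),
and the per-dataset p-values are aggregated as −2Σln p against χ² with 2k
degrees of freedom.

## Principal topologies

Landscapes are first normalized to their fitness at (wild-type mean,
η = −3), then decomposed by PCA with the 4941 grid points as observations
and genes as variables (per-gene column centering; grids are compared in
wild-type-relative coordinates). Component score surfaces are the principal
topologies; PT1 is oriented as a shortage penalty (lower fitness at the
low-mean, low-noise corner), PT2 the opposite. Components with an
explained-variance ratio below 1e-12 are treated as numerically null.

Loadings are reported on an absolute scale by correcting for the mean
landscape: the centred loading — the gene's projection after subtracting
the cross-gene mean surface — plus the mean landscape's projection onto
each component. Algebraically this equals the raw per-gene PCA coefficient;
the decomposition stores both forms. A gene identical to the mean landscape
therefore reports exactly the mean's loadings, and when the mean landscape
is orthogonal to the components the correction is the identity.
Reconstruction is mean landscape + per-gene scalar offset (gene grid-mean
minus grand mean) + Σ centred loading × topology; the offset term is what
makes the full-rank reconstruction exact, and with zero components the
reconstruction is the mean landscape up to that scalar. Landscape shapes
are classified from the corrected (PT1, PT2) loadings by thresholded sign
patterns: above both thresholds "peaked", above only PT1 "shortage", only
PT2 "surplus", otherwise "flat".

## Adaptive walks

Cis-regulatory evolution is a Gillespie walk on the landscape grid with
four telegraph-model moves: burst-size mutations (s+, s−) shift mean
expression one grid step (±0.05) at constant noise; burst-frequency
mutations (f+, f−) shift mean one step and noise one step in the opposite
direction (∓0.025 — the noise axis is spaced twice as finely, encoding the
inverse square-root coupling of noise to burst frequency). A move's rate is
its fitness gain clipped at zero (zero-gain moves cannot be selected for)
times an optional relative-likelihood weight; waiting times are exponential
with mean 1/(summed rate), the proportionality constant set to one (time
units arbitrary). States with no positive gain are absorbing; a
configurable step cap guards against non-absorbing landscapes. Fitness is
non-decreasing along every trajectory by construction, and scaling all
likelihood weights by a constant leaves selection probabilities unchanged
while scaling waiting times inversely.

The *noise funnel* is the set of grid points where f+ and s− are both
beneficial; alternating these two moves lowers noise at constant mean.
Epistasis of a move pair at a state is observed fitness of the double step
minus (starting fitness + both single-move gains); on planar landscapes it
vanishes, repeated same-type moves on concave profiles are negatively
epistatic, and f+/s− pairs inside the funnel positively so.

## Synthetic study generator

The generator fabricates the study conditions so every stage is testable
offline. Ground-truth landscapes are expectations of a per-cell fitness
function over a log-normal abundance distribution with mean 2^μ and CV 2^η:

    w(x) = 1 − λ1/(1 + (x/K)^h) − λ2·(x/S)^g/(1 + (x/S)^g)

(shortage half-saturation K = 12, surplus half-saturation S = 21 in
abundance units where wild type ≈ 16; Hill coefficients h = g = 8). The
expectation is computed by Gauss–Hermite quadrature in log-abundance
(order 120, verified against a doubled-order rule to 1e-6 relative with an
absolute floor of 1e-3 for near-zero fitness values). This construction
makes noise intolerance a consequence of Jensen's inequality where w is
concave rather than an assumption; the sharp Hill saturation is what gives
noise-intolerance magnitudes a third to half of the expression sensitivity,
in line with the observation that short-lived deviations are nearly as
costly as sustained ones, and gives peaked truths (λ1, λ2 > 0) a non-empty,
vertically extended noise funnel. Smoother per-cell shapes make noise
effects an order of magnitude weaker than observed.

The promoter panel (default 120 promoters) draws log2 means uniformly on
[2, 6] (16-fold) and log2 CV as a coupling trend of slope −0.3 anchored at
η = −2 mid-range plus bounded uniform scatter of half-width 1.0 (s.d.
0.58), clipped to [−3, −1]; the panel thus populates the full 4-fold noise
range at every mean — the analysis window is by definition the
homogeneously populated core region — while the cross-promoter mean-noise
correlation is ≈ −0.5. Measurement-error baselines are σ_μ = 0.2 and
σ_η = 0.15 log2 units with bounded per-promoter scatter (×0.7–1.5;
loess-smoothed error estimates have limited dynamic range), consistent with
the auxiliary lattice resolving them, and σ_f = 0.01 on the per-generation
fitness scale (count-based error at a few hundred reads per strain).
Competition read counts follow deterministic exponential growth,
p_i(t) ∝ p_i(0)·2^(f_i·g(t)) with g(t) = (10/23)·t generations (10
generations by 23 h), Poisson-sampled at each timepoint; there is no
genetic drift, matching the count-based error model. All randomness flows
from one explicit seed per call, and identical seeds reproduce identical
tables byte for byte.

Rank-2 ensembles for validation are built from two orthogonal topology
surfaces: the shortage and surplus penalty expectations are centred over
the standard window, orthonormalized by Gram–Schmidt, oriented
(shortage-like / surplus-like) and scaled so each carries an expression
sensitivity of 0.0112 — making the ensemble-average sensitivity ≈ 1.4% per
two-fold for shortage loadings a ~ N(1.25, 0.45) truncated above 0.2
(shortage sensitivity is universally non-negative) and surplus loadings
b ~ N(0.05, 0.3) straddling zero. Because both surfaces are affine
combinations of two expectation surfaces, they evaluate consistently on any
grid (extended grids for strain sampling, the standard window for
analysis).

### What the generator does not emulate

No single-cell telegraph-model simulation (bursting appears only as the
mutation-move abstraction); no PCR/sequencing bias beyond Poisson counts;
no genetic drift in the competition; promoter noise has no sequence basis;
endogenous-noise reference datasets are synthetic stand-ins, so the
comparison procedure is exercised but no published correlation value is
reproduced. Passing tests therefore validate the estimators and statistics
under the stated noise model, not properties of any real dataset.

## Validation protocol and problem sizes

The recovery of the slope metrics is measured as the estimator's
Monte-Carlo mean over many independent ensembles (default 300 panels of 80
promoters × 30 genes; truths fixed, panel and noise redrawn). This is
deliberate: the study design shares one promoter panel across all genes, so
the ensemble-mean noise intolerance carries ±50% design noise from panel
placement alone — verified to persist with noise-free fitness values — and
a single-draw comparison would measure panel luck rather than estimator
quality. Under the defaults the Monte-Carlo recovery error is a few percent
for expression sensitivity and below ~15% for noise intolerance.

Other default problem sizes: permutation-null calibration uses 200
synthetic genes at 1000 permutations (p-value uniformity by
Kolmogorov–Smirnov, BH false-positive control at 10%); adaptive-walk
properties use 100 walks of at most 500 steps; the read-count round trip
uses 30 promoters × 3 genes at 10⁷ reads, where the recovered fitness per
generation matches the injected values to better than 0.01.

## Numerical choices and degenerate inputs

Grid steps must divide the extents to 1e-9 relative; weight totals below
1e-300 mark grid points undefined; PCA components below 1e-12 explained-
variance ratio are dropped; CV kernel ties break toward smaller bandwidths;
permutation p-values are exact fractions with floor 1/n; the curvature
threshold comparison and the quadrature convergence check carry explicit
float tolerances; degenerate partial correlations and zero-variance
normalization fits raise or flag rather than returning spurious values.

## Known limitations

Landscape values outside the convex hull of the promoter cloud are
extrapolations of the kernel average and are reported with their
uncertainty rather than suppressed. The wild-type noise level of endogenous
promoters is unknown; the generator places it mid-range (η = −2) without a
realism claim. The auxiliary weight scheme degrades for position errors
well below its lattice spacing (use `closed_form` there). Kernel CV can
flatten the noise axis when the noise-fitness signal is weak (see above).
The per-experiment fitness scale is 10× the per-generation scale under the
default generation rate; metrics computed through the pipeline inherit the
experiment scale.
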