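# Methods

## Setting

Tumor spheroids develop a radial gradient of oxygen, nutrients and waste:
cells at the periphery proliferate while cells in the core starve. Partial
diffusion of a membrane-permeant dye (Calcein-AM) from the growth medium
labels cells by their depth from the surface, so after dissociation and
sorting each sequenced cell carries a fluorescence readout of its original
radial position alongside its UMI counts. `spheromap` turns such data —
a genes × cells UMI matrix plus per-cell dye intensities and sequencing
depths — into per-gene spatial regulation functions, spatial-gene calls
with pattern labels, and non-parametric pathway-level spatial associations.

## Radial positioning

The radial coordinate is r = (log I − lo)/(hi − lo), clipped to [0, 1],
where I is Calcein-AM intensity and lo/hi are quantiles of the log
intensities (default: min and max; optional clipping, e.g. 1st/99th
percentile, for outlier robustness). r = 0 is the core, r = 1 the
periphery. The transform is invariant to rescaling all intensities by a
positive constant. In spheres, the number of cells in a shell of radius r
grows ∝ r², so valid positionings show r³ approximately uniform — the
synthetic generator reproduces this via inverse-CDF sampling (r = U^{1/3})
and the test suite checks it by a Kolmogorov–Smirnov test.

## Per-gene model

For gene g, cell c with position r_c and depth N_c (total UMIs):

    n_gc ~ NB(mean = f_g(r_c) · N_c, size = θ_g),
    f_g(r) = a + b·r + c·r²,  f_g > 0 on [0, 1].

f_g(r) is the gene's fractional abundance: its share of the transcriptome
at position r. The polynomial keeps three interpretable parameters —
a is core expression, b and c the linear and quadratic trends — while
capturing monotone gradients and single interior maxima/minima. θ_g is a
gene-specific NB size (variance μ + μ²/θ; θ → ∞ is Poisson) absorbing
transcriptional bursting and sampling noise beyond Poisson.

### Priors and numerical safeguards

The likelihood is flat for arbitrarily small a (when essentially no counts
are expected anywhere, halving a changes nothing), which ill-conditions the
Hessian. Two weak priors regularize the MAP fit:

* a **floor barrier**: a softplus penalty keeping min_{[0,1]} f above
  ε/median(N) with ε = 0.1 — a tenth of one expected UMI at median depth.
  The NB mean itself is passed through a softplus-smoothed floor at the
  same level, so the objective is finite and smooth for any coefficients.
* **"no trend" Gaussians** on b and c with scale 100 × max(pooled
  abundance, floor) — two orders of magnitude above the gene's own scale,
  hence negligible wherever the data have anything to say.

Both are this package's concrete choice of "weak"; their scales are
config-free because making them weaker changed no test outcome at
benchmark scale.

### Optimization, initialization, uncertainties

The MAP is found by L-BFGS-B over (x₀, x₁, x₂, log θ) where
f = ā·(x₀ + x₁ r + x₂ r²) and ā is the depth-weighted mean abundance —
rescaling keeps the problem well conditioned for abundances spanning
10⁻⁶–10⁻². Gradients are analytic; log θ is bounded to [log 0.01,
log 10⁴]; objective tolerance 1e-8. Initialization is staged: (1) assume
no trend, set a₀ = Σn/ΣN and estimate θ by the method of moments
θ̂ = Σμ²/max(Σ[(n−μ)² − μ], ε), clipped to [0.01, 10⁴]; (2) refit (a, b)
with c = 0 and θ fixed. Fits are deterministic given data and config; a
20-instance exhaustive 15⁴ grid search over the same posterior verifies
the optimizer never stops below the grid maximum.

Standard errors are Laplace: the inverse Hessian of the negative log
posterior at the MAP (central differences of the analytic gradient),
transformed back to the (a, b, c, log θ) scale. Fits whose Hessian is not
positive definite report NaN SEs and are excluded from spatial calling.

### Calling spatial genes

Gene fits are retained when the per-cell log likelihood at the MAP clears
a floor (default −4.91 per cell, applied as threshold × n_cells so it
transfers across dataset sizes); this drops genes the model cannot
describe. Each retained gene gets marginal two-sided Wald p-values for b
and c plus a gene-level p. The default gene-level test is the **joint 2-df
Wald chi-square** of (b, c) = (0, 0) using the Laplace covariance block.
This is a deliberate choice: under the r²-weighted cell density, r and r²
correlate above 0.95, so the marginal SEs of b and c are inflated by
collinearity even when the overall trend is sharply determined — combining
the marginal tests (Bonferroni of min(p_b, p_c), available via
`gene_test="bonferroni"`) costs roughly a factor of three in sensitivity
on benchmarks while the joint test stays calibrated on all-null data
(≈0% of 500 null genes called at q < 0.1). BH FDR is computed over
retained genes; a gene is called spatial when q < 0.1 **and** its
regulation magnitude exceeds 0.3, where magnitude = 1 − min f/max f over
[0, 1] with extrema found analytically (boundaries plus the vertex
r\* = −b/(2c) when interior). A fold-change alternative can be derived
from the same extrema if preferred.

### Pattern labels

Called genes are labelled: if the quadratic trend is not significant or
the vertex r\* sits within δ = 0.1 of a boundary (ties at the margin go to
the monotone branch), the sign of f(1) − f(0) decides *core* vs
*periphery*. Otherwise c < 0 gives *intermediate* (interior maximum) and
c > 0 *extrema* (interior minimum), provided the vertex-to-nearer-boundary
contrast relative to max f reaches τ = 0.1; shallower interior features
are labelled *other*. δ and τ are this package's operationalization of
"clearly fits a pattern"; both are exposed in config.

## Synthetic data generator

The generator emulates the statistical skeleton of the real assay:
r = U^{1/3} positions (r² density), lognormal depths parameterized by
their median (default 20,000 UMIs; the deep-transcriptome regime of
~130,000 is one config field away) with log-sd 0.4 and a floor of 100,
and NB counts via Gamma–Poisson with planted polynomial regulation
functions. Pattern blocks specify peak abundance (log-uniform, default
5×10⁻⁵–10⁻³, i.e. 1–20 UMIs/cell at default depth), magnitude (default
0.3–0.9) and θ (log-uniform 1–10). Interior patterns are built from anchor
values (f(0), f(0.5), f(1)), which guarantees positivity at the anchors;
positivity on all of [0, 1] is then verified analytically. Planted
per-cell fractions are checked to sum to ≤ 1.

What it does **not** emulate: doublets, ambient RNA, dye photophysics,
positioning error in r (intensities map exactly to position), cell-state
covariance between genes (counts are independent across genes given r and
N), and batch structure. Passing benchmarks therefore demonstrate correct
inference under the model's own assumptions plus the stated geometry — not
robustness to the full messiness of real spheroid data.

## Benchmark results, and what is information-limited

At the standard benchmark scale (1,500 cells, median depth 20,000, 400–600
genes), the stack recovers strong planted genes (magnitude ≥ 0.5, mean ≥ 1
UMI/cell) with a median worst-point relative error of ~0.17 across
r ∈ {0, 0.5, 1}; 95% Wald intervals for b cover the truth for ~95% of
genes; pattern accuracy is ~98%; all-null calling is ~0%. One caveat is
structural: because cell density ∝ r², almost no cells sit near r = 0, so
f(0) for periphery-expressed genes is estimated from very little data —
its point estimate is unbiased but noisy (roughly a quarter of strong
genes miss ±30% at r = 0, essentially none at r = 0.5 or 1), and the
reported SEs faithfully reflect this. Deeper sequencing does not fix it;
only more core cells would.

## Pathway-level analysis

A pathway's fractional abundance per cell is the sum of member-gene UMIs
divided by the cell's total UMIs. Aggregation across ≥ 5 member genes
(sets with fewer present genes are skipped) suppresses single-gene noise
by the law of large numbers, so association with r can be tested without a
parametric f: Chatterjee's Xi correlation, a rank statistic consistent
against arbitrary measurable dependence of the fraction on r, including
non-monotone profiles. Ties are handled by the tie-aware estimator with
seeded random tie-breaks on x; the p-value uses the asymptotic null
√n·ξ → N(0, 2/5) when n ≥ 100 with < 10% tied values, otherwise a seeded
permutation null (1,000 permutations). BH FDR is applied across sets
(significant at q < 0.1). Each tested set also gets avgR, its positional
summary: cells are split into 10 equal-width, right-closed bins on [0, 1]
(empty bins skipped — equal-width rather than equal-count is this
package's choice), and avgR is the mean bin position weighted by the mean
pathway fraction per bin; avgR > 0.5 places a pathway peripherally.

## Confound check

Spatial coefficients could in principle reflect intrinsic cell state
(cycle, stress) varying with position rather than position itself. The
check regresses each gene's counts (NB GLM, log link, log-depth offset,
per-gene moment-estimated dispersion) on r alone and on r plus per-cell
signature scores (log pathway fractions of user-supplied cell-cycle and
stress gene lists, normalized by the cell's recorded total UMIs). The
correlation between raw and adjusted space coefficients across genes
summarizes how much calls depend on intrinsic state; signature lists are
always user-supplied — none are hard-coded, since any fixed list would
bake in a species and annotation version.

## Downsampling

n'_gc ~ Binomial(n_gc, p) emulates sequencing at a fraction p of the
depth (default ladder p ∈ {0.3%, 1%, 3%, 10%, 30%}); the full pipeline —
including the mean ≥ 1 UMI/cell gene re-filter — is rerun per p. Binomial
thinning of NB counts keeps the NB size θ while scaling the mean by p
(Gamma–Poisson closure), so the curve isolates the effect of depth. On
benchmarks the spatial-gene count rises monotonically and saturates
toward full depth.

## Problem sizes and determinism

Default benchmark scale (1,500 cells, 400–600 genes, median depth 20,000)
fits a full validation pass in well under a minute per benchmark; this is
the package's chosen desk scale, with paper-scale depth available via
config. Every stochastic step takes an explicit seed; pipeline runs derive
child seeds deterministically from the run seed, and identical
config + seed reproduces output tables byte for byte.
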