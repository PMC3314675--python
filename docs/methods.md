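# Methods

This note documents the models, parameter defaults, and numerical choices
behind `crossnorm`, and states what the synthetic-data tests do and do not
establish.

## Data model and conventions

All expression values are natural-log scale. A `CombinedDataset` holds two
gene-aligned matrices (one per platform) plus a sample annotation
(platform, treatment, study). Merging two platforms intersects their gene
lists, sorts the intersection lexicographically (so every downstream
stochastic step is reproducible under a fixed seed), and averages duplicate
probes per gene on the log scale. Methods never see treatment labels
unless their definition requires a cluster count, in which case the number
of treatment labels is used as that count — mirroring the use case where
normalization must run without group knowledge.

## Normalization methods

**Rank/distribution methods.** The shared primitive maps a sample's rank-k
value onto entry k of a sorted reference vector; ties receive the mean of
their tied reference values (deterministic and symmetric). QN pools all
samples of both platforms and uses per-rank means. MRS sorts each
reference-platform sample and takes per-rank medians; only the query
platform is transformed. GQ runs MRS and then shifts each gene of the
query platform so both platforms share the reference platform's per-gene
median. Note that this second step moves each gene by a different amount,
so GQ — unlike MRS — does not preserve rank order within a sample; its
contract is the median equality (exact to 1e-12). QD partitions each
sample into `bins` (default 8) equiprobable groups; codes are centered
half-integers summing to ~0. NorDi strips outliers per sample by an
iterated two-sided Grubbs test at level `alpha` (default 0.05), fits a
normal to what remains, and codes values beyond the two-sided `p` tail
(default 0.01) as ±1. DisTran clusters all samples into k groups (k-means,
10 restarts, seeded; retried with fresh seeds until every cluster spans
both platforms) and rank-maps each sample onto the unweighted mean of the
two platforms' per-rank mean vectors within its cluster — platform-balanced
so a larger platform cannot dominate the target.

*Clustering features.* DisTran's k-means (and XPN's, below) runs on data
standardized gene-wise within each platform. On raw values the platform
signature dominates and every clustering splits by platform, leaving no
valid clustering at all; within-platform standardization removes exactly
the nuisance the methods are trying to estimate around while preserving
the biological grouping.

**Empirical Bayes.** Values are standardized per gene by the grand mean and
the pooled (equal-weight, no covariates) scale. Per platform, gene-wise
means γ̂ and variances δ̂² are shrunk toward a normal and an inverse-gamma
prior whose hyperparameters come from the method of moments over genes
(normal: empirical mean/variance of γ̂; inverse-gamma shape
λ = 2 + m²/s², scale θ = m(λ−1) from the empirical mean m and variance s²
of δ̂²). The coupled posterior updates

    γ* = (n τ̄² γ̂ + δ²* γ̄) / (n τ̄² + δ²*)
    δ²* = (θ + ½ Σ_j (z_j − γ*)²) / (n/2 + λ − 1)

iterate to a max-change tolerance of 1e-4 (cap 500 iterations; exceeding it
raises with the residual). The adjusted value removes γ* and rescales by
1/√δ²*. Limits behave as expected: n → ∞ recovers γ̂; τ̄² → 0 forces γ̄.

**XPN.** The block model `x_gj = A[α(g), β(j)]·b_gp + c_gp + σ_gp·ε` has a
*shared* block-mean matrix A across platforms and per-gene, per-platform
sensitivity/offset/noise. Sharing A during estimation removes the gauge
freedom (A → aA + d compensated by b, c) that would otherwise make the
cross-platform averaging of b and c incoherent; the reconstruction is
invariant to the remaining gauge. Fitting alternates two closed forms —
precision-weighted block means given (b, c, σ), gene-wise simple regression
of x on A given A — until the profile log-likelihood changes by < 1e-6
relative (cap 200). Each of the `iterations` (default 30) redraws gene
clusters (K, default 3) and assay clusters (L, default = number of
treatment labels); joint assay clustering is redrawn until every cluster
spans both platforms (cap 100), or, with `modified=True`, platforms are
clustered separately and clusters matched by greedy maximum centroid
correlation. Output is the mean of the per-iteration reconstructions
`A·b̄ + c̄ + σ̄·ε̂` with unweighted platform means of b and c and σ averaged
on the variance scale.

**DWD.** The program minimizes `Σ 1/r_i + C Σ ξ_i` with
`r_i = y_i(w·x_i + β) + ξ_i`, `r_i > 0`, `ξ_i ≥ 0`, `‖w‖ ≤ 1` — a
second-order cone program. The slacks are eliminated analytically: the
per-sample loss becomes `V(m) = 1/m` for `m ≥ 1/√C` and its tangent line
below, convex and C¹. Since the optimum lies in the span of the
(feature-centered) data, the problem is reduced by SVD to at most
`n_samples` dimensions and solved with a trust-region constrained
optimizer under the unit-ball constraint (gradient tolerance 1e-9; a
first-order residual above 1e-6 raises). The penalty default is
`C = 100 / median²` of the between-class pairwise distances. For platform
adjustment, classes are platforms; each platform's samples are shifted by
`η_j = μ_j·w` where `μ_j` is the platform's mean projection of
*pooled-mean-centered* data onto the unit direction. Centering matters:
it makes η carry the platform separation only, not the common expression
level, so the projected platform mean deviations are exactly zero after
adjustment and transferred shifts do not move the global scale. One pass
removes the mean-difference component along w; the orthogonal residual is
of sampling-noise order (~2 % of the shift norm in our fixtures), so
re-running contracts the shift by about an order of magnitude per pass
rather than annihilating it. Shift vectors serialize to TSV with
provenance headers; `scramble_shift` applies one shared gene permutation
across platforms, preserving each vector's norm and the inter-platform
difference structure while destroying gene correspondence.

## Evaluation statistics

Differential expression: gene-wise two-sided Welch t-tests. Genes with
zero variance in both groups get p = 1 (equal means) or p = 0 (unequal),
logged. Q-values follow the Storey–Tibshirani estimator:
π̂₀(λ) = #{p > λ}/(G(1−λ)) on λ = 0, 0.05, …, 0.95, smoothed by a cubic
smoothing spline with 3 effective degrees of freedom (the penalty is
bisected until the smoother's hat-matrix trace equals 3 — the
default-smoothing alternative tracks boundary noise and biases π̂₀ low),
evaluated at λ = 0.95, clamped to (0, 1]. With fewer than 20 p-values the
spline is unstable and π̂₀ is forced to 1 with a warning. The step-down
rule `q(p_(i)) = min(π̂₀ G p_(i)/i, q(p_(i+1)))` makes q non-decreasing in p.

ROC-like curves are empirical cdfs of q-values on the grid 0 to 1, step
0.001 (t = 0 included; its height is the fraction of exactly-zero
q-values). Union/intersection of two gene lists are gene-wise min/max of
their q-lists. Over-detection `o` is the trapezoid area between the
cross-platform curve and the curve of `max(q_cross, q_union)`;
under-detection `u` is the area between the native-intersection curve and
the curve of `max(q_int, q_cross)`. Both are non-negative by construction
(pointwise curve domination is exact), and the 0.001 grid agrees with a
1e-5 grid to within 2e-3.

Concordance is the squared Pearson correlation of per-gene treatment-group
means across platforms. r² is blind to scale and offset; Lin's concordance
correlation coefficient is available (`with_ccc=True`) for agreement with
the identity line, off by default to keep the primary statistic the
conventional one. Variance comparisons use the Brown–Forsythe Levene-type
test (ANOVA on absolute deviations from group medians). Method rankings
order by median and mark adjacent pairs by two-sided Mann–Whitney U at
`alpha_base/n²` (default alpha_base 0.05, n = number of methods including
controls): "<" significant, "," not.

## Smoothed bootstrap

Each replicate resamples columns with replacement within treatment groups
and adds N(0, 0.1²) noise to every value (the smoothing makes resampled
duplicates distinct; it inflates per-gene variance by almost exactly
0.01). Defaults: B = 100 replicates, 15 samples per group per platform;
tests and the acceptance script scale these down (B = 4–20, n = 6–10) to
stay within desk-scale budgets. Native single-platform curves are built
from same-platform resamples with the two compared groups' sizes summed
across platforms (doubled, in balanced designs) so every curve rests on
the same total sample size. Positive controls (`resample.1`, `resample.2`)
are two independent same-platform resamples treated as a platform pair and
left unadjusted; the negative control (`no.norm`) is the merged data
unadjusted. All controls are scored against the same native curves as the
methods. A method failure in a replicate is logged and recorded as NaN;
a method exceeding a 20 % failure budget is abandoned for the run. The
unequal-group design mirrors group sizes across platforms ((m, n) on
platform 1, (n, m) on platform 2). The missing-group transfer experiment
drops one treatment per platform and compares four ways of obtaining the
DWD shift: trained on the full test data (`self.transfer`), on a separate
training dataset (`transfer`), on the reduced set itself (`no.transfer`,
which removes the treatment difference), and the scrambled transfer shift
(`scrambled`). Native curves there come from the full test data, resampled
per platform — the construction is not dictated by the statistic itself,
so it is recorded in the run metadata. Concordance is undefined in that
design (each treatment lives on one platform) and is omitted.

## Platform-effect theory

The equilibrium hybridization signal `S = I·g0·p0·k/(1 + k·g0)` is linear
in `log g0` when `k·g0 ≪ 1` and saturates at `I·p0`. On the log scale
this motivates `y_ijk = T_i + P_j + C_ij + ε_ijk` per gene (i treatment,
j platform, k repetition). The interaction test compares the full
cell-means model against the additive model by the extra-sum-of-squares F
test; because all genes share one design, one QR factorization serves
every gene (the test is identical to type-II/III for the interaction,
which enters last; unbalanced designs are accepted). A constant
interaction is unidentifiable from the platform effect, so "C_ij = C" is
tested as zero interaction *variation*; with a single treatment group the
interaction is unidentifiable and the call errors out. π₁ = 1 − π̂₀ uses
the q-value machinery's estimator.

The least-squares optimal location shift is
`η_j = P_j + Σ_i n_ij C_ij / Σ_i n_ij`; subtracting it from the cell means
removes platform effects exactly when interactions vanish and minimizes
the weighted squared platform deviation otherwise. The transfer residual
for two equally sized treatments measured in the missing-group layout
(treatment 1 on platform 1 only, treatment 2 on platform 2 only) is
`T₁ − T₂ + ½ΣᵢΣⱼ(−1)^(j−1)(C_ij − C′_ij)` with C′ the training
interactions. The identity holds under two conventions made explicit
here: the training data share the platform effects (the premise of
parameter transfer), and interactions are row-centered (sum over platforms
zero per treatment) — the constraint under which C is identified
separately from T. The implementation enforces nothing silently; the
oracle tests construct truths under these conventions and agree to 1e-10.

## Synthetic worlds

`simulate_linear` draws, per gene: a baseline ~ N(7, 1), a treatment
effect ~ N(0, 1) for a `de_fraction` (default 0.3) of genes, a platform
shift ~ N(0, 0.5²) for platform 2, and a row-centered interaction
~ N(0, 0.5²)/2 for exactly `round(f·G)` genes (f default 0.25), plus
N(0, 0.1²) replicate noise; defaults G = 2000, two treatments, 15
replicates per group per platform. `simulate_mechanistic` draws per-gene
baselines `log10 g0 ~ N(0, 0.65²)`, per-gene per-platform offsets
`log(I·p0) ~ N(5, 0.2²)` and rate ratios with `log10 k ~ N(−2.5, 0.3²)`
(platform 1, near-linear) vs `N(0, 0.3²)` (platform 2, partially
saturating), emulating the chemiluminescence-saturation contrast between
detection chemistries. The offset spread was calibrated once so the raw
cross-platform mean–mean r² sits near 0.6 — the level typically observed
for unnormalized two-platform comparisons — and then frozen; most of the
raw discordance comes from the saturation curvature itself.
`simulate_xpn_model` emits data exactly from the XPN generative model with
known cluster assignments (round-robin assay clusters so each exists on
both platforms).

What a green test establishes — and what it does not: the generators
produce independent Gaussian replicate noise, exactly two platforms, no
missing values, no probe-level artifacts, and platform effects that are
either additive or smooth saturating curves. Real microarray data add
correlated genes, heavy-tailed noise, intensity-dependent variance, and
preprocessing artifacts; a method ranking reproduced on these worlds shows
the implementation expresses each method's intended mechanism, not that
the ranking holds universally.

## Numerical choices and degenerate inputs

- Tie handling everywhere: average rank with averaged reference values.
- k-means: 10 restarts per attempt, best inertia kept, seeded; cluster
  validity (both platforms present) retried with fresh seeds.
- EB: zero pooled variance for a gene is an error (scale undefined).
- XPN: genes with zero predictor variance in a cluster keep b = 1;
  residual variances are floored at 1e-8.
- DWD: identical samples across classes make the between-class median
  distance zero and the auto-penalty errors out; duplicated samples leave
  the optimum unchanged.
- Welch: zero-variance conventions as above; q-values clip to [0, 1].
- Detection areas: both `o` and `u` integrate over the full FDR axis
  [0, 1].
- All random steps accept a seed; every generator, the benchmark, and the
  CLI are bit-reproducible given one.

## Known limitations

- Exactly two platforms per run (pairwise, as in the benchmark design the
  package reproduces); more platforms require repeated pairwise runs.
- The EB variant is parametric-prior only and ignores covariates by
  design; the non-parametric prior variant is not implemented.
- The DWD backend asserts optimality by first-order residual, not by
  comparison of iterate paths with any particular published solver.
- `rank_methods` tests adjacent pairs only, as the ranking annotations
  are defined; it is not a full multiple-comparison procedure.
- Mean–mean r² is reported per treatment group; the benchmark averages
  over the compared groups.
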