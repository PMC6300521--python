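# Methods

## Model and assumptions

A composite model partitions K standardized observed variables into J
blocks; block j forms a composite `c_j = w_j' x_j` scaled to unit variance
(`w_j' Σ_jj w_j = 1`). Intra-block correlation matrices are free; every
inter-block submatrix is constrained to `Σ_jl = ρ_jl λ_j λ_l'` with
loadings `λ_j = Σ_jj w_j`. Observed variables outside every block ("free
variables") are handled as singleton blocks with weight 1, which makes the
covariance bookkeeping, the degrees-of-freedom count, and estimation a
single code path. The indicator matrix is positive-definite iff (i) every
intra-block matrix is PD and (ii) the composite (plus free-variable)
correlation matrix is PD; violations are reported by naming the failing
condition.

Everything runs on the correlation scale. Data are standardized to mean 0
and variance 1 **with the 1/N denominator**, so the sample matrix is
`S = X'X / N`. This convention is what makes the Bollen–Stine rotation
exact: the rotated data's 1/N covariance equals the estimated model-implied
matrix to machine precision.

## Identification

Weights are normalized (unit composite variance) and every composite must
be connected — correlate with at least one other composite or free
variable. Degrees of freedom are counted as: non-redundant off-diagonal
elements `K(K−1)/2`, minus free composite correlations, composite ×
free-variable covariances, free-variable pair covariances, intra-block
off-diagonals, and weights, plus the number of blocks (one weight per block
is redundant once its composite variance is fixed). The worked example —
one composite of two indicators plus two free variables — gives
`6 − 0 − 2 − 1 − 1 − 2 + 1 = 1`.

## Estimation (maxvar)

Weights maximize the largest eigenvalue of the composite correlation matrix
subject to unit composite variances. Closed form: let `Σ_D` be the block
diagonal of S; take the leading eigenvector `ã` of `Σ_D^{-1/2} S Σ_D^{-1/2}`
and set `w_j = Σ_jj^{-1/2} ã_j / sqrt(ã_j' ã_j)` from its per-block
subvectors. (The subvector `ã_j` has length K_j — the partition of the
K-vector.) Numerical choices:

* **Sign indeterminacy** — each `w_j` is flipped so its largest-magnitude
  entry is positive (first index on ties). `Σ̂` is invariant to these flips
  because `ρ̂_jl` and `λ̂_j` flip together.
* **Eigenvalue ties** — if the top two eigenvalues are within 1e-9 the
  eigenvector with lexicographically largest absolute pattern is chosen and
  a warning raised.
* **PD tolerance** — a matrix counts as PD when its smallest eigenvalue
  exceeds 1e-10 × its largest; matrix square roots are symmetric
  (spectral), never triangular, so results are bit-reproducible.
* A zero eigenvector subvector for some block signals an isolated
  composite and raises an error.

`Σ̂` keeps the sample intra-block blocks (those parameters are free and fit
at their sample values) and rebuilds all inter-block blocks as
`ρ̂_jl λ̂_j λ̂_l'`. Fitting the exact population matrix of a correctly
specified model reproduces it to machine precision; weight estimates from
finite samples are markedly noisier than composite-correlation estimates
when intra-block correlations are high (the maxvar objective is nearly flat
in w there).

## Fit testing

Discrepancies between S and `Σ̂`: squared Euclidean distance
`d_L = ½ Σ (s_ij − σ̂_ij)²`; geodesic distance
`d_G = sqrt(½ Σ log(φ_i)²)` with `φ_i` the eigenvalues of `S^{-1} Σ̂`
(computed as a symmetric generalized eigenproblem); SRMR, the root of the
average squared standardized residual over the lower triangle including the
diagonal. On standardized data SRMR is the monotone transform
`sqrt(2 d_L / (K(K+1)))` of `d_L`, so the two always produce identical
accept/reject decisions.

The test rotates the standardized data by `S^{-1/2} Σ̂^{1/2}` (symmetric
roots) so the rotated sample satisfies the null exactly, draws B row
resamples with replacement, re-standardizes and re-estimates each, and
computes each resample's distances against its own `Σ̂`. The p-value is the
plain proportion of bootstrap distances ≥ the observed one (no +1
smoothing); the model is rejected at level α when p < α, equivalently when
the observed distance exceeds the empirical (1−α) reference quantile.
Resamples failing estimation are dropped and counted; more than 5% failures
aborts the test with diagnostics.

Fit indices (descriptive only — no cut-off calibration is attempted): SRMR;
NFI = `1 − F(estimated)/F(baseline)` against the uncorrelated-indicators
baseline, with the geodesic distance as the default discrepancy (no
likelihood is estimated here, so a likelihood-based F is not offered); and
RMS_theta, the root mean square of cross-block residual correlations —
within-block residuals are excluded because they are unconstrained and
"root mean square" requires squaring before averaging.

## The simulation study

Five population conditions: (1) a correctly specified two-composite model —
weights (0.6, 0.2, 0.4) and (0.4, 0.2, 0.6), intra-block correlations 0.5,
composite correlation 0.3; (2) the model-1 matrix with indicators x13 and
x21 interchanged (wrong assignment); (3) the model-1 matrix with the
(x13, x21) correlation raised above its model-implied value 0.192;
(4) a correctly specified three-composite model — composite correlations
0.3/0.5/0.4, weights (0.6, 0.4, 0.2), (0.3, 0.5, 0.6), (0.4, 0.5, 0.5);
(5) the model-4 matrix with the (x13, x21) correlation set to 0.25 (a weak
violation).

Two generator inputs are not pinned down by the printed parameters and are
this package's own choices:

* **Models 4–5 intra-block matrices** are a *synthetic reconstruction*:
  equicorrelated blocks whose common off-diagonal solves the
  unit-composite-variance constraint for the printed weights (block 1: 1/2,
  block 2: 5/21, block 3: 17/65). They satisfy every stated constraint but
  are not canonical; callers may override them. One visible consequence:
  the model-implied (x13, x21) correlation in model 4 is 0.118 here rather
  than a previously reported 0.084, so model 5's violation (0.25) is
  slightly weaker in relative terms.
* **Model 3's replacement correlation** has no canonical value and must be
  supplied explicitly at the model level; the bundled study uses
  `MODEL3_UNEXPLAINED_CORRELATION = 0.40`, roughly double the model-implied
  0.192. The choice was fixed from population-level analysis alone: at 0.40
  the population discrepancy of model 3 (d_L = 0.043) stays below model 2's
  (d_L = 0.192), preserving the expected power ordering
  (wrong assignment ≥ unexplained correlation).

Samples are multivariate normal (Cholesky), standardized after drawing.
`run_study` crosses models × sample sizes × significance levels; its
defaults mirror the full design (n = 50…1450 by 100, α ∈ {0.01, 0.05,
0.10}, B = 200 bootstrap resamples) with `reps = 300` replications per cell
as the desk-scale default (the original design used 10,000). A master seed
spawns one independent substream per cell, so results are identical for any
worker count and each cell is reproducible in isolation. Rejection-rate
tables carry Wald binomial bands; for correctly specified models the band
is centered at the nominal α (where a calibrated test should land), for
misspecified models at the observed rate.

The test suite exercises the study at desk scale: the correctly specified
two-composite model at n = 500 (type-I error), the misspecified
two-composite models at n ∈ {50, 450} (power ordering and growth), and the
weakly misspecified three-composite model at n ∈ {100, 1000}, all at
300 replications × 200 resamples. A larger 2,000-replication diagnostic of
the model-1 cell puts the true type-I rates at n = 500, α = 0.05 near
0.030 for d_L/SRMR and 0.053 for d_G: the Euclidean/SRMR test is
conservative at moderate n (it under-rejects, approaching the nominal level
from below as n grows) while the geodesic test is close to nominal. A
300-replication estimate of a rate near 0.03 has a standard error of about
0.01, so single desk-scale runs of that cell scatter accordingly.

## What the generator does and does not emulate

The generator reproduces the study's population correlation structures and
multivariate-normal sampling exactly; it does not emulate non-normal data,
missing values, unequal indicator scales (everything is standardized), or
structural (directed) relations among composites. Passing tests therefore
speak to the method's behavior under normality with known block structure,
not to robustness against distributional violations.

## Known limitations

* Only the maxvar criterion is implemented (no sumcor/ssqcor/minvar/genvar,
  PLS-PM, RGCCA, or GSCA estimators).
* No fit-index cut-offs are provided; SRMR/NFI/RMS_theta are descriptive.
* Weight estimates are imprecise at moderate n when intra-block
  correlations are high, even though composite correlations are stable.
* The bootstrap p-value has granularity 1/B; with B = 200 and α = 0.05 the
  effective rejection rule is "at most 9 of 200 resamples exceed the
  observed distance".
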