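# cca — confirmatory composite analysis

Tools for specifying, estimating, and statistically testing **composite
models**: structural equation models in which each theoretical concept is an
*artifact* — a weighted linear combination (composite) of observed
indicators — rather than a latent common factor. Composite models arise
wherever a concept is designed to serve a purpose instead of assumed to
exist: public-health interventions, abiotic stress indices, treatment
programs, marketing mixes.

## The model

Indicators `x` are partitioned into `J` blocks; block *j* forms the
composite `c_j = w_j' x_j` with `Var(c_j) = w_j' Σ_jj w_j = 1`. The
intra-block correlation matrices `Σ_jj` are unconstrained, but the
composites carry *all* information between blocks, so every inter-block
submatrix is rank-one:

    Σ_jl = ρ_jl · λ_j λ_l' ,     λ_j = Σ_jj w_j ,

where `λ_j` holds the composite loadings and `ρ_jl` the composite
correlation. These rank-one restrictions are testable. The package:

* counts **degrees of freedom** (non-redundant covariance elements minus
  free parameters, regaining one per block for the fixed composite
  variance) and checks **identification** (normalized weights plus the
  non-isolation condition: every composite must correlate with at least one
  other composite or free variable);
* estimates weights by Kettenring's **maxvar** generalized canonical
  correlation criterion — the closed form whitens the sample matrix
  block-wise and takes the leading eigenvector:
  `w_j = Σ_jj^{-1/2} ã_j / sqrt(ã_j' ã_j)`;
* tests overall fit with a **Bollen–Stine bootstrap**: the data are rotated
  by `S^{-1/2} Σ̂^{1/2}` so they satisfy the null exactly, and the reference
  distributions of three discrepancy measures — squared Euclidean distance
  `d_L`, geodesic distance `d_G`, and SRMR — are built from resamples of the
  rotated data;
* ships the five-population-model **Monte Carlo study** (type-I error and
  power of the fit test) as a reusable, seeded experiment.

## Worked example

Draw a sample of n = 500 from the correctly specified two-composite
population model (composite correlation 0.3) and fit it:

```python
from cca import CompositeModelSpec, bootstrap_fit_test, estimate
from cca.simulation import draw_sample, population_sigma

spec = CompositeModelSpec({"c1": ["x11", "x12", "x13"],
                           "c2": ["x21", "x22", "x23"]})
x = draw_sample(population_sigma(1), n=500, seed=42)

result = estimate(x, spec)
print(result.composite_corr.loc["c1", "c2"])   # 0.31
print(result.identification.df)                # 4  (over-identified)

test = bootstrap_fit_test(x, spec, B=200, alpha=0.05, seed=42)
print(test.observed.as_dict())  # {'dL': 0.0027, 'dG': 0.0931, 'srmr': 0.0114}
print(test.p_values)            # {'dL': 0.455, 'dG': 0.355, 'srmr': 0.455}
print(test.rejected)            # {'dL': False, 'dG': False, 'srmr': False}
```

The estimated composite correlation (0.31) sits close to the population
value 0.3 and the bootstrap test keeps the true model at every measure
(p ≈ 0.35–0.46). Individual *weights* are far noisier than `ρ̂` at this
sample size — with intra-block correlations of 0.5 the maxvar objective is
nearly flat in `w` — so weight estimates should be interpreted with care at
moderate n. Fit indices are also reported (`test.indices`): SRMR 0.011,
NFI 0.93, RMS_theta 0.018.

The same workflow is available from the shell:

```sh
cca fit      --data x.csv --model model.yml --out estimate.json
cca test     --data x.csv --model model.yml --bootstrap 200 --alpha 0.05 \
             --seed 42 --out fit.json
cca simulate --models 1,2,3 --n 50:450:100 --alpha 0.05 --reps 300 \
             --bootstrap 200 --seed 7 --out rates.csv
```

`model.yml` lists the blocks and any free observed variables:

```yaml
blocks:
  c1: [x11, x12, x13]
  c2: [x21, x22, x23]
free: []
```

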