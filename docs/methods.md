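# Methods

## The model

A soil profile's ¹³⁷Cs content is treated as a composition: the activities of
the top five depth-ordered layers w₁…w₅, closed to relative activities
a_r summing to 1. The sample space is the 4-simplex with the Aitchison
geometry: perturbation x ⊕ v = C(x₁v₁, …, x_Dv_D) (C = closure) as addition,
powering t ⊗ v = C(v₁ᵗ, …, v_Dᵗ) as scalar multiplication, and the metric
induced by the centred log-ratio transform clr(x)_i = ln(x_i / g(x)). Under
this geometry:

- **Proportionality** of two layers across profiles is var(ln x_i/x_j) = 0;
  the matrix T of these pairwise log-ratio variances (variation matrix) is the
  package's association structure. It is subcompositionally coherent, unlike
  correlations of closed proportions.
- **Balances** z = √(rs/(r+s)) · ln(g(x₊)/g(x₋)) compare two disjoint layer
  groups of sizes r and s. Their coefficient vectors a are zero-sum with unit
  norm, so var(z) = −½·aᵀT a exactly; a whole balance screen can therefore be
  computed from a printed variation matrix with no raw data. Physically, a
  low-variance balance indicates a near-constant ratio of concentration
  products — mass-action equilibrium among those layers.
- **The linear process** x(t) = x₀ ⊕ (t ⊗ v) models a fixed transport
  mechanism observed at different stages of progress t. For a layer pair the
  fit is made on the 3-part subcomposition [x_i, x_j, g(rest)].

## Estimation choices

- **Direction v**: leading eigenvector of the clr sample covariance, mapped
  back by clr⁻¹ and closed. A simplex direction is defined only up to
  powering, so the canonical representative has unit clr norm (the published
  direction vectors have clr norm ≈ 1, consistent with this convention).
  Orientation: the clr coordinate of the first-named (shallower) layer is
  positive; an exact zero falls through to the second coordinate.
- **Variance estimator**: n−1 denominator throughout.
- **Quartiles**: linear interpolation between order statistics.
- **Zero replacement**: multiplicative — zeros in a layer become δ, the other
  parts are rescaled to preserve their ratios and the unit sum. Default
  δ = 0.65 × the layer's smallest positive value, a standard
  below-detection-limit convention; configurable per run. Geometric means in
  layer summaries use replaced values; order statistics use the raw ones.
- **Profiles deeper than five horizons** are truncated to the first five and
  re-closed over the retained horizons, fixing the layer system at D = 5;
  shallower profiles are rejected with a logged reason.
- **ilr basis**: Helmert contrasts by default; any orthonormal zero-sum
  contrast matrix (e.g. from a sequential binary partition) is accepted. All
  reported quantities that pass through ilr (distances, MCD flags, robust PCA)
  are basis-invariant, which the tests assert.
- **Clustering**: average-linkage agglomerative (scipy) and the DIANA
  splinter algorithm (implemented here; validated against R's
  `cluster::diana`, whose split heights it matches to 6 decimals on a fixture
  frozen in the tests). Dendrogram heights are cluster merge heights
  (agglomerative) or the diameter of the cluster being divided (divisive);
  Newick output is ultrametric with node age = height/2. Child order is
  lexicographic by smallest leaf, so output files are deterministic.
- **Robust estimation**: MCD via scikit-learn's FAST-MCD with subset size
  h = ⌊(n+p+1)/2⌋ (maximum breakdown), consistency-corrected scatter, run on
  ilr coordinates because the clr covariance is singular. Outliers are flagged
  at squared robust Mahalanobis distance above χ²₍p, 0.975₎; the quantile is
  configurable. Robust PCA eigendecomposes the MCD scatter mapped back to clr
  space through the contrast basis.
- **Rounded printed input**: the clr covariance implied by a variation matrix,
  Σ = −½·G T G, can be slightly indefinite when T was rounded for printing;
  negative eigenvalues are clipped at zero with a warning. (The published
  matrix happens to be positive semidefinite as printed.) Rounding to 2
  significant figures propagates about ±0.03 into reconstructed balance
  variances, which is the comparison tolerance used against the published
  ranking; the published extremes 0.43 and 4.2 are matched to their printed
  half-ulp (the reconstruction gives exactly 0.425 and 4.200).

## The synthetic generator

No raw profile table was deposited, so the generator emulates the survey from
its printed summaries: 39 profiles, logistic-normal (Gaussian in ilr)
compositions centred on the closed per-layer geometric means
[0.034, 0.379, 0.365, 0.031, 0.003]/Σ, with ilr covariance chosen so the
implied variation matrix equals the printed one exactly. A minority fraction
(default 0.25, matching the ~¼ cluster in the survey's dendrograms) is drawn
around the center perturbed by C([0.06, 0.01, 0.10, 0.60, 0.23]) — profiles
whose activity has moved below the litter. That shift has Mahalanobis length
≈ 2.6 under the target covariance; the printed log-ratio variances are large
enough that no compositionally plausible shift separates much further, so the
minority cluster overlaps the bulk about as much as real surveys do. Total
activity is lognormal (geometric mean 92.6 Bq/kg, log-sd 2.3, spanning the
published 0.01 Bq/kg–4 kBq/kg range) and independent of the closed
composition. Horizon names per layer follow the published frequency tables
(w₁ = Ol and w₂ = Of always; deeper layers mixed); soil-type counts are not
published, so a fixed podzol/brown-soil-dominated table is used. Soil type is
drawn independently of the composition, consistent with the survey's finding
that clustering does not follow soil type.

What the generator does **not** emulate: measurement error of the
gamma-spectrometry, spatial correlation between nearby profiles, genuine
zeros (the logistic-normal is strictly positive — zero handling is tested by
explicitly zeroing entries), and any dependence of composition on soil type.
Passing tests therefore demonstrate correctness of the estimators under the
published second-order calibration, not fidelity of any mechanistic transport
model.

## Test and problem sizes

Deterministic reconstructions (enumeration, screen from the printed matrix)
run at full size. Stochastic recovery checks use: n = 2000 profiles for
variation-matrix and center recovery; n = 500 for direction recovery under
ilr noise (sd 0.05) and for MCD location; n = 400 with a planted 25% outlier
fraction for flagging rates. Recovery of a sample variance has standard error
T_ij·√(2/(n−1)) — about 0.2 at n = 2000 for the largest published entry — so
variation-matrix recovery is asserted within max(0.15, 3.5 standard errors)
entrywise; all other tolerances are stated inline in the tests. All
randomness is seeded; the pipeline splits one top-level seed per stage and
records it in the run sidecar, so result bundles are byte-reproducible.

## Known limitations

- The divisive algorithm recomputes within-cluster averages naively (O(n³)
  worst case); fine for survey-sized n, not for thousands of profiles.
- The MCD reweighting refinement step is not applied; flags come from the raw
  consistency-corrected fit.
- Balance screening is exhaustive and exponential in D; it is intended for
  the handful-of-layers regime (D ≤ ~12).
- The linear-process fit reports a single dominant direction; it does not test
  linearity against curvature on the simplex.
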