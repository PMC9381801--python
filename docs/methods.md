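# Methods

## Model and assumptions

The package models an m-variate spatial random field that is second-order
stationary and isotropic: each variable's marginal distribution is the
same at every location, and dependence between two locations depends only
on their Euclidean separation h (planar metric coordinates; no geodesic
support). Dependence is described entirely through copulas, so marginal
shape and spatial/cross-variable association are estimated separately.

The dependence model is piecewise in distance. Location pairs are grouped
into K equal-width distance bins up to a cut-off h_K; each bin gets one
bivariate copula per variable, fitted to that bin's pseudo-observation
pairs, and the variables' copulas are mixed within the bin by convex
weights w_l. Adjacent bins are blended by λ_k = (h̄_k − h_{k−1}) /
(h_k − h_{k−1}), the position of the bin's mean pair distance inside the
bin, which makes the model respond to where the data actually sit within
each distance class. Two limits are built in exactly: below the first bin
edge the first bin's mixture is used alone (the near-comonotone, h → 0
regime is represented by whatever dependence the first bin supports), and
at or beyond the cut-off the copula is exactly the product uv. Every
piece is a convex combination of copulas, hence itself a copula; uniform
margins, Fréchet–Hoeffding bounds and 2-increasingness are inherited and
verified in the test suite.

## Parameters that matter

- **cutoff** (metres): separation beyond which pairs are independent.
  Default: automatic plateau rule — the smallest bin upper edge after
  which the per-bin Kendall tau (max across variables) stays below
  epsilon_tau = 0.05. The automated rule is a surrogate for the usual
  visual read of the correlogram; supplying the cut-off explicitly is the
  faithful way to reproduce a published analysis.
- **n_bins** K (default 10): more bins resolve the dependence decay more
  finely but leave fewer pairs per bin for copula fitting.
- **copula_families**: default gaussian, clayton, frank, gumbel, joe.
  student_t is a supported candidate but not a default: its degrees of
  freedom are profiled over the grid {2, …, 30} with the correlation
  optimised at each grid point, which multiplies fit cost by the grid
  size; enable it when heavy joint tails are plausible.
- **weights** w_l (default equal, 1/m): cross-variable mixture weights.
  Equal weights are appropriate when the variables' correlograms are
  similar. `optimize_weights` grid-searches w₁ (bivariate case) by
  faithful-mode RMSE of a designated primary variable at the sampled
  locations; it reuses the per-bin copula fits, since weights do not
  enter them.
- **pseudo_obs**: pseudo-observations use the fitted parametric marginal
  CDFs by default (consistent with predicting through F⁻¹); a rank-based
  option (`"rank"`) is available when marginal misspecification is a
  concern.

## Fitting details

Marginal candidates (Gamma, Weibull, Normal, Log-normal) all have two
free parameters, so raw maximum log-likelihood is a fair selection
criterion; ties break by registry order (gamma, weibull, normal,
lognormal) for determinism. Location parameters are fixed at zero for the
positive-support families. Copula fitting maximises the log-likelihood by
bounded scalar search (tolerance 1e-8 on θ) over each family's admissible
range; the sample Kendall tau picks the sign region for Frank and
triggers the 90° rotation for Clayton/Gumbel/Joe when negative. The pair
set is symmetrised before fitting — the two ends of a location pair have
no natural orientation — and the reported log-likelihood is the
symmetrised sum halved. Note that 90°/270° rotations are not exchangeable
copulas, so under symmetrisation their fitted θ is a compromise between
the copula and its transpose; this is inherent to orientation-free
spatial pairs. Clayton's θ is capped at 30 (τ ≈ 0.94) to keep u^(−θ)
finite at clipped pseudo-observations; CDF outputs are clipped to
[1e-10, 1 − 1e-10] before entering copula likelihoods.

## Numerical choices

- h-functions are analytic for every family; inverses are closed-form for
  independence, Gaussian, Student-t, Clayton and Frank, and a fixed
  60-step vectorised bisection elsewhere (u-error < 1e-18 in exact
  arithmetic, far below the 1e-9 contract). Mixture and spatial
  h-function inverses always use the vectorised bisection, since the
  mixture conditional has no closed inverse.
- The Student-t copula CDF is computed as ∫₀ᵛ h(u|w) dw with a 64-node
  Gauss–Legendre rule — deterministic, unlike randomised quasi-Monte
  Carlo bivariate-t integration.
- Boundary values are patched exactly: C(u, 1) = u, C(1, v) = v,
  C(u, 0) = 0, h(0|v) = 0, h(1|v) = 1, so the assembled model's margins
  and its beyond-cutoff product form hold to machine precision.
- λ_k is stored as an exact Fraction of the bin's mean distance; display
  rounding is half-away-from-zero to two decimals (so 46/80 = 0.575
  renders as 0.58). An empty bin's copula is replaced by independence
  (with a warning) and its λ falls back to the bin midpoint, ½.
- Kendall tau is tau-b (tie-corrected): real environmental tables are
  rounded and contain ties. Degenerate all-tied bins raise rather than
  return a silent value.
- Frank's tau uses the Debye-function form by quadrature; Joe's tau uses
  the Archimedean generator integral with the t → 1 endpoint stabilised
  analytically.

## Prediction modes and the co-located h

The inverse-conditional predictor evaluates C^m_h at a single shared
location, so the separation h at which the model is read is a genuine
modelling choice rather than a data quantity. The default policy
(`first-bin`) uses the h = 0 branch — the first bin's mixture, the
strongest-dependence regime — on the view that co-located variables are
at the near limit of the spatial model; fixed-h and nearest-neighbour
policies are selectable. Two conditional levels are offered: `faithful`
reconstructs t = C^m_h(F₁(z₁), r) from both observed values, which is a
cross-validation reconstruction (it needs the target observed) and is the
default for validation; `median` sets t = ½, the standard conditional
median predictor usable at locations where only the secondary variable is
known, and is the default for prediction. Conditional levels outside the
attainable range are clamped monotonically with a warning.

## Validation metrics

MAE, RMSE and MAPE are computed per variable from actual and predicted
values at the sampled locations, with the model fitted on all data (a
leave-one-out option would be the honest generalisation assessment; the
default mirrors the standard in-sample cross-validation of this model
family). MAPE is a ratio (0.5 = 50%) and excludes zero actuals, with the
exclusion count logged. KDE MSE evaluates a Gaussian-product-kernel
density for the actual and the predicted (z₁, z₂) clouds on a shared
50×50 grid spanning the union range padded by 10%, with per-cloud,
per-axis Silverman bandwidths, and averages the squared difference over
grid nodes. Grid, padding and bandwidth conventions all scale the
absolute value, so KDE MSE is comparable only across methods computed
with identical settings — it is never an exact target.

## Synthetic data: what it does and does not emulate

`simulate_bivariate_field` draws two jointly Gaussian random fields with
a shared isotropic covariance (exponential or spherical; sill, range,
nugget) and cross-variable correlation ρ, on uniformly random locations,
then applies monotone per-variable transforms. Defaults — n = 800 on a
1 km square, exponential covariance with 200 m range and unit sill, no
nugget, ρ = 0.8, identity/exponential transforms — give strong
short-range spatial dependence that decays well inside the domain, a
co-located cross tau of (2/π)arcsin(0.8) ≈ 0.59, a skewed second margin
and a curved bivariate scatter: the data regime the method is designed
for. Simulation is by exact Cholesky factorisation of the separable
covariance (correctness over speed; intended for n up to a few
thousand). Because monotone transforms preserve Kendall tau exactly, the
generated dependence structure is known in closed form, which the tests
exploit.

What it does not emulate: measurement error and nuggets of real surveys
(unless set), anisotropy, non-stationarity, preferential sampling, and
genuinely different spatial covariances per variable — both variables
share one spatial structure, so the cross-variable mixture's advantage
over the univariate baseline appears here mainly as variance reduction
from averaging two estimates of a common bin copula. Passing tests on
this generator therefore demonstrate correctness of the machinery and
the expected qualitative behaviour, not field performance on data whose
variables carry distinct spatial structures.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen so the full suite
completes in about a minute while keeping estimator noise well below the
asserted tolerances: copula property checks at 1000 random points per
family, parameter recovery and family selection at 2000 samples (50
replicates per family), and the end-to-end simulate–fit–validate loop at
n = 800 over ten seeds with the ten-bin, 800 m configuration.

## Known limitations

- Prediction is bivariate (m = 2); modelling supports m ≥ 2.
- No anisotropy, non-stationarity, geodesic coordinates, or prediction at
  unsampled locations from multiple neighbours (co-located prediction
  only).
- The faithful mode's in-sample character flatters all methods equally;
  comparisons between methods remain meaningful, absolute errors less so.
- Family selection by raw log-likelihood treats the two-parameter
  Student-t the same as one-parameter families (AIC is available on the
  marginal side as an alternative criterion conceptually, but raw
  log-likelihood is the default everywhere for fidelity to standard
  practice in this model family).
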