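# spmixcopula

Spatial mixture copulas for jointly modelling two (or more) spatially
correlated variables sampled at common planar locations — for example
co-located forest biomass pools, or several heavy-metal concentrations
measured in the same soil cores — and for predicting each variable at a
location from the correlated companion observed at the same spot.

Classical cokriging captures only linear, Gaussian spatial dependence.
This package instead describes dependence with copulas, which separate the
marginal distributions from the dependence structure and allow it to vary
across the quantiles of the data.

## The model

Let **Z**(x) = [Z₁(x), …, Z_m(x)] be a second-order stationary, isotropic
random field observed at locations x₁, …, x_n. The model is built in four
steps:

1. **Marginals.** Each variable gets one parametric CDF F_l (Gamma,
   Weibull, Normal or Log-normal, chosen by maximum log-likelihood);
   observations become pseudo-observations u = F_l(z) in (0, 1).
2. **Spatial binning.** All n(n−1)/2 location pairs are placed into K
   equally spaced distance bins [h_{k−1}, h_k) up to a cut-off h_K, beyond
   which pairs are treated as independent. The cut-off is read off a
   Kendall-tau correlogram (tau per bin against the bin's mean pair
   distance). For each bin and each variable, a bivariate copula
   C_{l,k}(u, v) is fitted to the bin's pseudo-observation pairs by
   maximum likelihood over competing families (Gaussian, Student-t,
   Clayton, Frank, Gumbel, Joe, with 90°/180°/270° rotations for negative
   dependence).
3. **Cross-variable mixture.** Within each bin the variables' copulas are
   mixed: C^m_k(u, v) = Σ_l w_l C_{l,k}(u, v) with weights w_l summing to
   one (equal by default).
4. **Distance-dependent assembly.** For a separation h in bin k ≥ 2,

       C^m_h(u, v) = (1 − λ_k) C^m_{k−1}(u, v) + λ_k C^m_k(u, v),
       λ_k = (h̄_k − h_{k−1}) / (h_k − h_{k−1}),

   where h̄_k is the bin's mean pair distance; below h₁ the first bin's
   mixture is used alone, and beyond the cut-off C^m_h(u, v) = uv exactly.

**Prediction** (bivariate case) inverts the conditional distribution: with
r = F₂(z₂) observed at the location, a conditional level t is either
reconstructed from both observed values, t = C^m_h(F₁(z₁), r) ("faithful"
mode, the cross-validation setting), or set to ½ ("median" mode); then s
solves ∂C^m_h/∂r (s, r) = t and the prediction is F₁⁻¹(s). Cross-validation
reports MAE, RMSE, MAPE (ratio scale) per variable and the mean squared
difference of bivariate kernel density estimates (KDE MSE) of the actual
vs predicted point clouds.

## Worked example

```python
from spmixcopula import (FieldSpec, simulate_bivariate_field, FitConfig,
                         fit_spatial_mixture, cross_validate, format_lambda)

ds = simulate_bivariate_field(FieldSpec(n=400, seed=7))   # 1 km × 1 km field
model = fit_spatial_mixture(ds, FitConfig(cutoff=800.0, n_bins=10))

print([(m.family, m.params) for m in model.marginals])
print([(c.family, c.theta) for c in model.bin_mixtures[0].components])
print([format_lambda(l) for l in model.lambdas])
print(cross_validate(ds, model=model).to_dict())
```

prints (abridged):

```
marginals: [('normal', {'mean': -0.876, 'sd': 0.869}),
            ('lognormal', {'mu': -0.803, 'sigma': 0.888})]
bin-1 copulas: [('gaussian', (0.69,)), ('gaussian', (0.69,))]
lambdas: ['0.55', '0.52', '0.51', '0.51', '0.51', '0.50', '0.50', '0.49', '0.49']
{'method': 'mixture', 'n': 400, 'kde_mse': 0.000435,
 'z1': {'mae': 0.515, 'rmse': 0.630, 'mape': 2.127},
 'z2': {'mae': 0.370, 'rmse': 0.913, 'mape': 0.440}}
```

The simulated field has a Gaussian first variable and a log-normally
transformed second variable; the marginal selection recovers both. The
bin-1 copulas show the strong short-range spatial dependence (correlation
≈ 0.69 at the ~40 m mean distance of the first bin), the λ values place
each bin's mean pair distance inside the bin, and the report gives the
cross-validated errors of predicting each variable from the other at the
sampled locations.

The same pipeline is scriptable from a shell:

```sh
spmixcopula simulate --seed 7 --n 400 -o field.csv
spmixcopula correlogram field.csv --cutoff 800 --bins 10
spmixcopula fit field.csv --cutoff 800 --bins 10 -o model.json
spmixcopula predict model.json field.csv --mode median -o predictions.csv
spmixcopula validate field.csv --cutoff 800 --bins 10 --baseline univariate
```

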