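# pulletgrowth

Growth-response modelling for egg-type pullets during rearing (weeks 1–18):
how much body-weight gain (BWG) a bird returns per unit of metabolizable-energy
(ME) intake, and how that response differs between commercial strains.

The package is aimed at poultry nutritionists and quantitative animal
scientists who work from strain management guides (weekly body weights and
weekly ME intakes per bird) and want to

1. scale those records to comparable per-gram-of-body-weight, per-day units,
2. fit the **monomolecular (Mitscherlich) response curve**

   *y = a − (a + b)·e^(−c·x)*

   where *y* is BWG (g/g BW/day), *x* is ME intake (kcal/g BW/day), *a* is the
   asymptotic gain, *−b* the gain at zero intake (fasting loss) and *c* a rate
   constant — all strictly positive,
3. derive bioenergetic traits from the fit: the maintenance requirement
   MEm (the intake at which predicted gain is zero, 1000·ln((a+b)/a)/c in
   kcal/kg BW/day), efficiencies of ME use for growth k_g between multiples of
   maintenance, and the net-energy cost of gain NEg = 0.62 / k_g(1–4),
4. benchmark the curve against a small **1-3-2-1 feed-forward neural network**
   (tanh activations, 17 free parameters, 33 % validation holdout) with a
   shared goodness-of-fit suite (adjusted R², RMSE, MAD, MAPE, AIC, BIC), and
5. pool the fitted parameters across strains with a **DerSimonian–Laird
   random-effects meta-analysis** (Cochran's Q, I², τ², 95 % CI, z-test,
   forest-plot tables).

Fitters follow scikit-learn conventions (`fit`/`predict`, `get_params`,
trailing-underscore attributes) and compose with sklearn tooling; module-level
functions wrap them for scripting, and a `pulletgrowth` CLI ties the stages
together.

## Worked example

Fit a synthetic strain with known truth (a, b, c) = (0.10, 0.15, 3.5) and
gain noise σ = 0.002, derive its traits, then pool the packaged six-strain
parameter estimates:

```python
from pulletgrowth import (MonomolecularRegressor, derive_traits,
                          strain_parameters_meta_input, dl_pool)
from pulletgrowth.profiles import observations_to_arrays
from pulletgrowth.synthetic import SyntheticSpec, generate_scaled

spec = SyntheticSpec(true_params=(0.10, 0.15, 3.5), noise_sd=0.002, seed=42)
x, y = observations_to_arrays(generate_scaled(spec))
reg = MonomolecularRegressor().fit(x, y)
print(f"a = {reg.a_:.4f} (SE {reg.se_a_:.4f})")   # a = 0.1012 (SE 0.0059)
print(f"b = {reg.b_:.4f} (SE {reg.se_b_:.4f})")   # b = 0.1504 (SE 0.0026)
print(f"c = {reg.c_:.4f} (SE {reg.se_c_:.4f})")   # c = 3.4723 (SE 0.1792)

traits = derive_traits(reg.params_)
print(f"MEm = {traits.me_maintenance:.1f} kcal/kg BW/day")  # MEm = 262.3
print(f"NEg = {traits.ne_growth:.2f} kcal/g")               # NEg = 5.16

res = dl_pool(strain_parameters_meta_input("c"))
print(f"pooled c = {res.pooled:.3f} (SE {res.se_pooled:.3f})")
# pooled c = 3.276 (SE 0.380), 95% CI (2.531, 4.022)
print(f"Q = {res.q:.3f}, I2 = {res.i_squared:.1f}% ({res.heterogeneity_label})")
# Q = 21.129, I2 = 76.3% (high)
```

The fitted (a, b, c) land on the generating values within sampling error;
MEm = 262.3 kcal/kg is the zero-gain intake implied by those parameters; and
the pooled rate constant c = 3.276 with I² = 76 % says the six strains share a
common response only loosely — most of the spread between their rate constants
is between-strain heterogeneity, not estimation noise.

The same pipeline from the shell:

```sh
pulletgrowth simulate --n-strains 6 --seed 1 --out profiles.csv
pulletgrowth run --profiles profiles.csv --out-dir out/
pulletgrowth meta --out-dir meta_out/          # packaged six-strain table
```

`run` writes `scaled.csv`, `fits.csv`, `traits.csv`, `criteria.csv`,
`meta.csv`, `forest_{a,b,c}.csv` and a `manifest.json` recording seed,
package versions and config hash.

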