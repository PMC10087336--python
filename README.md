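# tpcmeta

Hierarchical Bayesian meta-analysis of **thermal performance curve (TPC)
evolution** from experimental-evolution and artificial-selection studies.

Ectotherm fitness is a unimodal, negatively skewed function of temperature.
When populations are selected at a new temperature for many generations, does
the whole curve shift, grow ("Hotter is better"), widen, or trade height for
width? `tpcmeta` is a pipeline for answering these questions from extracted
before/after selection assays: it turns reported fitness means and
dispersions into relative-fitness effect sizes with propagated uncertainty,
fits Bayesian multilevel models that treat each effect as a noisy measurement
of a latent true effect, ranks candidate models by WAIC, decomposes
heterogeneity with multilevel I², and screens moderator collinearity and
publication bias. It is aimed at evolutionary ecologists running or
re-running meta-analyses of thermal selection experiments.

## The model

For the selected line *s* and its ancestor/control *a* assayed at temperature
*T*, relative fitness is computed per reproduction system (Chevin's
selection-coefficient formulation):

- discrete generations: `w = f_s/f_a − 1`
- continuous growth:   `w = (f_s − f_a)·G`, with generation time `G`
- binary fission:      `w = (f_s/f_a − 1)·ln 2`

with first-order error propagation assuming uncorrelated errors (the
relative-error quadrature form for the ratio modes, the exact linear form for
the continuous mode). Each observed effect `y_i` with known sampling SE `s_i`
then enters the measurement-error mixed model

```
y_i ~ Normal(θ_i, s_i²)
θ_i = x_iᵀβ + u_species(i) + u_study(i) + u_tpc(i),   u_ℓ ~ Normal(0, σ_ℓ²)
```

so effects are weighted by study precision and heterogeneity is split across
the species → study → TPC hierarchy. Moderators (`x_i`) include the source of
genetic variation (de novo vs standing), the number of generations, the sign
of the selection-vs-control temperature difference, and polynomials of the
relative assay temperature ΔT (assay − selection). Posterior sampling is a
blocked Gibbs sampler with conjugate updates and slice-sampled level SDs;
convergence is checked with split-R̂. Heterogeneity per level, per draw, is

```
I²_ℓ = σ_ℓ² / (Σ σ² + s̃²) × 100,   s̃² the Higgins–Thompson typical sampling variance
```

so level I² values add exactly to the total in every draw.

## Worked example

A synthetic "niche shift" experiment (selection 3 °C above the ancestral
regime, the bundled generator's defaults) pushed through the
at-selection-temperature analysis:

```python
from tpcmeta.synthetic_data import SimScenario, simulate_experiment
from tpcmeta.pipeline import prepare_effects
from tpcmeta.data_model import build_subsets
from tpcmeta.meta_model import (ModelSpec, McmcSettings, build_design, fit,
                                summarize, rank_models)
from tpcmeta.heterogeneity import typical_sampling_variance, i2_posterior

records = simulate_experiment(SimScenario(scenario="shift", seed=42))
effects, excluded = prepare_effects(records)
at_sel = build_subsets(effects)["at_selection"]

mc = McmcSettings(iterations=6000, warmup=1000, chains=2)
fits = []
for name, terms in (("intercept", ()), ("var", ("var",))):
    spec = ModelSpec(name, fixed_terms=terms,
                     random_levels=("species", "study"), mcmc=mc)
    design = build_design(at_sel, spec, "at_selection")
    draws = fit(design, spec, seed=1)
    fits.append(summarize(draws, design, name))
print(rank_models(fits).to_string(index=False))
```

which prints

```
    model        waic  waic_se   p_waic  converged  delta_waic   weight
intercept -103.127339 8.942703 12.25372       True    0.000000 0.501493
      var -103.115392 8.901440 12.24004       True    0.011947 0.498507
```

— the two models are effectively tied. The intercept model's posterior,

```
      parameter   median     q2.5    q97.5
beta[intercept] 0.137251 0.058652 0.220547
sigma2[species] 0.006727 0.000039 0.039013
  sigma2[study] 0.005663 0.001655 0.019893
```

says populations gained about 14% relative fitness at their selection
temperature (95% compatibility interval [0.06, 0.22], excluding zero: a
clear positive response to selection), and the heterogeneity decomposition

```
  level  sigma2_median  I2_mean   I2_lo   I2_hi
species         0.0067  48.3243  0.2754 89.4631
  study         0.0057  44.8139  7.7244 92.7119
  total         0.0137  93.1382 85.9998 97.9485
```

attributes ~93% of total variance to true between-species/between-study
differences rather than sampling error.

The same stages are available from the shell:

```sh
tpcmeta simulate --scenario shift --seed 42 --out assays.csv
tpcmeta report --input assays.csv --analysis at_selection --outdir out/ \
        --iterations 6000 --warmup 1000 --chains 2 --seed 1
```

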