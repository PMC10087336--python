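# Methods

## Effect sizes

Relative fitness compares a thermally selected line against its ancestor or
control at a common assay temperature, on a per-generation scale so that
studies with different fitness currencies are comparable:

| reproduction system | effect size | propagated SE |
|---|---|---|
| discrete generations | `f_s/f_a − 1` | `|f_s/f_a|·√((δf_s/f_s)² + (δf_a/f_a)²)` |
| continuous growth (rates) | `(f_s − f_a)·G` | `√(δf_s² + δf_a²)·G` |
| binary fission | `(f_s/f_a − 1)·ln 2` | ratio form × `ln 2` |

Errors are assumed uncorrelated between lines. The ratio-mode SE is a
first-order (delta-method) approximation, accurate to a few percent while
relative errors stay below ~10% (checked against a 10⁶-draw Monte-Carlo
oracle in the test suite); the continuous form is exact. Negative fitness
means are rejected in the ratio modes — a negative count/fecundity/growth
correlate makes the ratio uninterpretable — while the continuous mode admits
negative rates (declining populations). Reported standard deviations are
converted to standard errors by dividing by √n, 95% confidence half-widths
by 1.96.

Cleaning removes effects with relative fitness above 20 (implausible
outliers given typical effects of order 0.1), effects with a zero SE
(infinite weight in the measurement-error likelihood), and effects with no
reported error at all. Cleaning is idempotent and fully logged.

## Analysis subsets

Four analyses partition the cleaned effects. *At-selection*: assays at the
selection temperature, |ΔT| ≤ 0.25 °C — the tolerance absorbs rounding in
digitized temperatures while keeping the category essentially exact ties.
*Two-point*: TPCs assayed at exactly two temperatures (classical linear
reaction norms), analysed against |ΔT|. *Multipoint*: TPCs with three or
more assay temperatures, analysed against signed ΔT with polynomials up to
cubic. *Hotter-is-better*: TPCs with more than three assay temperatures,
reduced to one max-vs-max effect each — the maximal fitness of the selected
line (over its assay temperatures) against the maximal fitness of the
ancestor line, SEs propagated from the two argmax points; ties in the
maximum take the lowest temperature, a deterministic and conservative choice
(cooler flank, typically better-measured).

## The measurement-error mixed model

```
y_i ~ Normal(θ_i, s_i²)
θ_i = x_iᵀβ + Σ_ℓ u_ℓ(i),   u_ℓg ~ Normal(0, σ_ℓ²)
```

with known per-effect sampling variance s_i². Random levels are species and
study for the at-selection and hotter-is-better analyses, plus TPC for the
two- and multipoint analyses (several points share a curve). There is no
residual variance beyond the finest level: within-group scatter not
explained by moderators loads on the finest σ². Polynomial ΔT terms use raw
powers centered at ΔT = 0 (the selection temperature), so the intercept is
directly the predicted response at the selection temperature. The
generations moderator is z-standardized; prediction utilities carry the
centering constants. Analyses involving generations run twice — full data
without the moderator, reduced data (effects reporting a generations count)
with it — because experiment duration is not universally reported.

**Priors.** Normal(0, 1) on the intercept and coefficients of centered
predictors, Exponential(1) on level SDs. On the relative-fitness scale,
where |effect| rarely exceeds 2, these are vague but proper; both families
are configurable (`PriorSpec`), and the near-zero-heterogeneity limit used
in testing is reached by raising the Exponential rate.

**Sampling.** The model is conditionally conjugate, so the sampler is
blocked Gibbs: multivariate-normal update for β, per-group normal updates
for each u level, univariate slice sampling (stepping-out/shrinkage) for
each σ_ℓ. A translation move resamples the shift between the intercept and
each level's effects from its exact Gaussian conditional every sweep; the
likelihood is invariant under this reparameterization, so the move preserves
the posterior while removing the intercept/level-mean random-walk that
otherwise dominates the autocorrelation time. Defaults are 30 000 iterations
with 1 000 warmup per chain and 4 chains; tests and the acceptance script
use shorter chains (1 500–6 000 iterations, 2 chains), which this sampler's
mixing (split-R̂ ≈ 1.00 on the standard problems) makes ample. Every fit
takes an explicit seed; chains draw from spawned `SeedSequence` streams, so
runs are exactly reproducible. Convergence is flagged (never silently
ignored) when any split-R̂ exceeds 1.05.

**WAIC.** The pointwise log-likelihood conditions on the sampled β and
random effects and integrates the latent θ_i analytically; with every level
conditioned this reduces the predictive variance to s_i², and any level not
indexed by a design adds its σ² instead. `waic` uses log-sum-exp for the
per-point log predictive density; p_WAIC is the pointwise posterior
variance. Models are ranked ascending with Akaike-style weights
∝ exp(−ΔWAIC/2). Ranking refuses to compare fits over different effect
subsets.

## Heterogeneity

The typical sampling variance follows the Higgins–Thompson estimator
`s̃² = (k−1)·Σw_i / ((Σw_i)² − Σw_i²)` with `w_i = 1/se_i²` (the metafor
convention; a mean-of-variances alternative would differ only for very
skewed weight distributions). I² is computed per posterior draw and level,
so level values add exactly to the total within each draw and 95%
compatibility intervals come directly from posterior quantiles. Summaries
report both the posterior mean and median of I² (conventions differ across
the literature); effects are summarized by medians.

## Diagnostics

*Collinearity.* Binary–binary moderator pairs use the tetrachoric
correlation: thresholds from the margins via Φ⁻¹, and ρ maximizing the
bivariate-normal cell likelihood. The bivariate normal CDF is evaluated by
Gauss–Legendre integration of the conditional-normal form (120 nodes,
accurate to ~10⁻⁶, cross-checked against scipy's implementation in the
tests); a zero cell returns the signed boundary ±1 with a flag rather than a
continuity correction. Binary–continuous pairs use the point-biserial
correlation (the estimator the commonly used R helper actually computes,
despite its "biserial" name — a documented divergence from the strict
latent-normal biserial). Pairs with |r| > 0.7 are flagged and one
representative per correlated cluster recommended for retention.

*Publication bias.* The Egger-style test refits the main measurement-error
model with the centered sampling SE as an additional fixed moderator,
keeping the analysis's random-effect structure; "no consistent bias" means
the 95% interval of the SE slope covers zero. Funnel (effect, SE) pairs are
emitted for plotting. Zero SE spread makes the slope unidentifiable and is
flagged, not fitted.

## Synthetic data

The generator emulates the statistical structure of an extracted
thermal-selection dataset, not any particular biology. TPCs use a Gaussian
rise below the optimum, `r_max·exp(−((T−T_opt)/(2σ_rise))²)`, and a
quadratic fall to zero at the critical maximum — a standard negatively
skewed unimodal form (note σ_rise is half the usual Gaussian scale in this
parameterization); the form is one admissible choice among many and is
configurable. Scenario transforms of the derived curve: *null* (identical),
*shift* (optimum and critical limit move by the selection shift),
*hotter_is_better* (shift plus `r_max×(1+height_gain)`),
*generalist_specialist* (both flanks widen by `1+width_change`, height
scales by `1/(1+width_change)` — an area-preserving trade-off, this
package's own concretization of "wider but lower"), *hotter_is_wider*
(shift plus widening at preserved height).

Default conditions: 8 species × 2 studies × 2 TPCs, assay temperatures
19–31 °C around an ancestral optimum of 25 °C, selection +3 °C, replicate
noise SD 0.05 on r_max ≈ 1 with 6 replicates per mean (giving realistically
heteroscedastic SEs around 0.02, with sd/CI dispersion types mixed in to
exercise normalization), height gain 10% and width change 20% where the
scenario uses them, generations lognormal (longer for de-novo/microbial
designs) with 10% missing. The source of variation alternates at the
species level and deterministically sets reproduction/comparison metadata,
mirroring the strong Var–Rep–Comp confounding seen in real
experimental-evolution corpora (the tetrachoric screen therefore returns
the boundary value on these tables). Everything is deterministic given the
scenario seed.

`simulate_effects_direct` bypasses curves entirely and draws effects from
the fitted model's own generative process with the truth attached; parameter
recovery, coverage, model-selection and bias-test calibration checks all use
it. What passing these checks shows: the estimator machinery is correct and
calibrated *under the model's assumptions* (normal errors, correct SEs,
exchangeable random effects). What they cannot show: robustness to real-data
violations — correlated errors within studies, non-normal effect
distributions, digitization error in temperatures and dispersions, or
selection effects in which studies get published.

## Numerical and design notes

- Continuous-mode relative fitness multiplies the rate difference by
  generation time (the per-generation scaling that makes time units
  comparable across studies).
- The sampler stores per-group random-effect draws, so pointwise
  log-likelihoods and predictions are exact per draw; memory scales as
  draws × groups.
- The acceptance script runs 6 000-iteration, 2-chain fits on the default
  generator conditions (≈ 160 effects); these sizes keep the whole
  recomputation under a minute while leaving Monte-Carlo error well below
  the effects being measured.
- Degenerate inputs: empty effect subsets raise errors naming the analysis;
  a single effect cannot yield a typical sampling variance (k ≥ 2 required);
  all-equal SEs make the bias slope unidentifiable (flagged).

## Known limitations

- No explicit phylogenetic covariance beyond the species random effect (out
  of scope; weak phylogenetic signal makes it counterproductive on the kind
  of corpus this targets).
- WAIC only; no LOO-CV.
- The Gibbs sampler assumes the normal likelihood and normal random effects
  of the stated model; it is not a general-purpose PPL.
- Two-point reaction norms are analysed with |ΔT| as a linear predictor,
  which cannot capture curvature by construction.
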