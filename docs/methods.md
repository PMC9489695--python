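# Methods

## Scope and model

The package estimates the difference between two steady states of soil
organic carbon (SOC): the present one, represented by soils at today's mean
annual temperature (MAT), and a future one, represented by otherwise-matched
soils that are ΔT warmer today. The estimand is a percentage change per
standard depth interval (0–0.3, 0.3–1, 1–2 m) and warming level
(ΔT = 1..5 °C). Three assumptions carry the inference:

- **Steady state.** Ambient soils are at equilibrium with their climate, and
  warmed soils will eventually reach the equilibrium their warmer analogues
  occupy now. Transient trajectories are out of scope.
- **Exchangeability after matching.** Within a group sharing landform, soil
  order, precipitation seasonality and a narrow MAP band, the remaining
  differences between a cooler and a warmer MAT class are attributable to
  temperature.
- **Comparability of ratios.** Group mean SOC is positive and its log ratio
  across classes is approximately normal, which multiplicative (lognormal)
  profile-level variation delivers.

The mechanistic interpretation uses the one-pool model dC/dt = I − k·C with
steady state C = I/k. Warming multiplies the decay rate by Q10^(ΔT/10)
("log" in the rate law is the natural logarithm, making the scaling exactly
Q10^(ΔT/10)) and may scale inputs by I_w/I, so

    R = (I_w/I) · Q10^(−ΔT/10) − 1.

Input scenarios compound, I_w/I = (1+r)^ΔT. This choice is substantive: it
implies the exact algebraic identity q10(r) = q10(0)·(1+r)^10 between Q10
values fitted under different input scenarios, which a linear 1 + r·ΔT form
does not satisfy; the identity is asserted to numerical precision in the
tests. Q10 is fitted by bounded scalar least squares on [1, 10]
(convergence tolerance 1e−8) and cross-checked against a dense grid search.
When per-level mean responses are reconstructed from a reported 1 °C
response plus a linear slope rather than taken from per-level estimates, the
fitted Q10 carries an expected reconstruction uncertainty of about ±0.1.

## Harmonization

Laboratories report layer means on arbitrary depth schemes. The package fits
an equal-area (mass-preserving) smoothing spline: the discretized variational
problem

    min  Σ_i d_i (y_i − f̄_i)² + λ ∫ f′(z)² dz

over piecewise-constant f on a 1-cm depth grid, where y_i is the observed
mean of layer i, f̄_i the fitted mean over that layer and d_i its thickness
(normalized to mean 1). Thickness-weighting the fidelity term makes the
optimum conserve the total observed carbon mass exactly — the stationarity
condition along a constant shift of f is Σ d_i (y_i − f̄_i) = 0 — so the
standard-interval means redistribute but never create or destroy carbon
within the observed span. λ defaults to 0.1 on the centimetre depth scale on
which this spline family is conventionally parameterized; at that default the
fitted layer means track observations to a few percent on realistic
depth-decaying profiles. The solution is linear in y, and the solve operator
is cached per layer-boundary pattern, which makes harmonizing thousands of
identically-structured profiles a single matrix product each.

No extrapolation: intervals with no observed overlap are flagged absent
(NaN), and an interval only partially spanned is estimated over the overlap
but flagged uncovered. Bulk density and gravel are averaged over each
standard interval weighted by layer overlap; stock then follows
SOC_s = SOC_c/1000 · D · BD · (1 − G/100) in kg C m⁻² (×10 for Mg C ha⁻¹).
Note the mass fraction divisor is 1000 for SOC_c in g kg⁻¹ with D in m and
BD in kg m⁻³; the /100 form seen in parts of the literature presumes D in cm
or BD in g cm⁻³.

## Imputation

Missing BD and gravel are filled one-shot (no chained multiple imputation,
keeping the pipeline deterministic) by a gradient-boosted regression-tree
model trained on layers where the target is measured, with depth midpoint,
thickness, SOC content, location and, when available, site MAT/MAP as
covariates. At least 30 complete cases are required; covariates absent
everywhere are dropped. Imputed gravel is clamped to [0, 100] %, imputed BD
to a plausibility range (default 50–2700 kg m⁻³). An out-of-sample RMSE on a
20 % held-out split of the complete cases is reported with every fill.
Observed values are never altered.

## Pairing rules

MAT classes are half-open 1 °C bins: MAT t joins [floor(t), floor(t)+1).
Groups within a class share landform, soil order (suborder or other
vocabularies selectable), seasonality and a fixed-width 50-mm MAP bin. MAP
bins make groups well defined; the stated pairing criterion — group mean
MAPs differing by less than 50 mm (25 mm for the sensitivity variant) — is
enforced explicitly on top of the binning. Both groups need n ≥ 2 so a
standard deviation exists; the ≥ 20 floor used for sensitivity analysis is a
switch (`min_group_n`), as is cropland exclusion. The ratio is warm/ambient,
so negative lnRR means SOC loss under warming. One profile may contribute to
pairs at several warming levels; levels are analysed separately and no
cross-level independence correction is applied.

Seasonality uses the precipitation concentration index over the 12 monthly
totals, PCI = 100·Σp²/(Σp)², averaged across years where multi-year records
exist (years with zero total are excluded; an all-zero record is an error).
Below the threshold the regime is "uniform"; otherwise "summer" when the
April–September total (October–March in the southern hemisphere) strictly
exceeds the other half-year, else "winter" — ties resolve to winter. The
customary threshold 8.3 sits *below* the analytic PCI minimum of
100/12 ≈ 8.333, so with a single year of data the uniform branch cannot
fire; the threshold is configurable and the anomaly is surfaced here rather
than silently "fixed".

## Meta-analysis

Effect sizes are log response ratios with the standard delta-method variance
v = sd_w²/(n_w·m_w²) + sd_a²/(n_a·m_a²) — the ratio-of-means form the
mixed-effects machinery this design mirrors assumes by default. Pooling uses
weights 1/(v + τ²) with τ² by REML (profiled restricted likelihood,
bounded scalar optimization; DerSimonian–Laird available), SE = (Σw)^(−1/2)
and normal 95 % CIs (±1.96·SE). Effects with non-positive means or zero
sampling variance are excluded with recorded diagnostics rather than given
infinite weight. Moderator analysis fits per-level means under a shared τ²
estimated with the level-indicator design matrix, and tests equality with
the Wald-type Q_M on χ²(levels − 1). Field-warming comparisons bin warming
magnitudes half-open into {<1, 1–2, 2–3, 3–4, 4–5, >5} °C and reuse the same
effect-size and pooling machinery per bin and per ecosystem; empty bins
contribute no degrees of freedom.

## Meta-forest

The weighted forest draws each tree's bootstrap sample with probability
proportional to w_i = 1/(v_i + τ²) and passes the drawn multiplicities times
w_i as sample weights into the split criterion, so the stated weighting
principle acts in both places; with uniform weights the procedure reduces to
ordinary bagged trees (checked against scikit-learn's random forest).
Hyperparameters are searched on a small declared grid — trees {250, 500},
candidate predictors per split {⌈p/3⌉, ⌈√p⌉}, minimum leaf {3, 5} — by
k-fold cross-validated weighted RMSE (default 5 folds, configurable).
Variable importance is the split-improvement convention: weighted
squared-error decrease per split, summed per tree, averaged over the
ensemble, one-hot columns summed back into their parent categorical, and
normalized to total 1. Prediction uncertainty is the across-tree standard
deviation; rows with categorical levels unseen in training are flagged, not
coerced. The default predictor list has 14 entries (baseline SOC, soil
order, depth layer, MAT, MAP, aridity, PCI, summer-precipitation fraction,
ΔT, ΔMAP, elevation, landform, NPP, biome) and is configurable. The utility
`aggregate_absolute_loss` sums stock × percentage change over user-supplied
grid cells; real-raster ingestion is out of scope.

## Synthetic worlds

The generator emulates the statistical structure of a global profile
compilation, not its geography: per-profile MAT uniform over (−5, 25) °C by
default (uniform guarantees populated 1 °C classes; a bimodal mode mimics
latitudinal clustering), MAP uniform over (400, 600) mm, monthly
precipitation from three archetypes (summer-peaked, winter-peaked, uniform;
weights 0.4/0.3/0.3), three landforms, three soil orders, four biomes, 10 %
cropland with a fixed 0.8 SOC depletion factor, and 20 % missingness in BD
and gravel. Layer stocks follow C = I/(k0·Q10^(MAT/10)) with layer Q10
defaults (1.7, 1.4, 1.2), surface input 0.4 kg C m⁻² yr⁻¹ and base decay
0.02 yr⁻¹ declining with depth by fixed factors; multiplicative lognormal
noise (mean 1, CV 0.3 by default) preserves the law in group means while
making lnRR approximately normal. Observed layers use fixed breaks nested
within the standard intervals, so harmonization has real interpolation work
but introduces no systematic layer-scheme bias. The category-list sizes are
deliberately modest so that, at n = 2000 profiles, covariate groups retain
the few-to-tens of members per MAT class that make pairing possible.

What the generator does **not** emulate — spatial autocorrelation,
paleoclimate legacies, land-use history beyond a binary cropland flag, fire
and nitrogen deposition, soil-vs-air temperature attenuation, and covariance
between climate and soil type — bounds what passing tests show: they
demonstrate that the estimator recovers a known steady-state temperature law
under the stated sampling assumptions, not that real-world confounding is
absent.

## Problem sizes and numerical choices

Recovery checks run 20 replicate worlds of 2000 profiles (CV 0.3), each
through imputation, harmonization, pairing and pooling, yielding roughly 100
topsoil contrasts at 1 °C per replicate; forest recovery uses ~1500 effects,
the scale the pairing stage produces from such worlds. Spline grid 1 cm;
REML and Q10 optimizations use bounded scalar minimization (tolerances 1e−10
and 1e−8); ensembles and imputations are seeded and deterministic;
degenerate inputs (empty tables, all-missing targets, single effects,
constant outcomes) raise or warn explicitly rather than returning silent
zeros.

## Known limitations

Group-level pooling ignores within-group spatial dependence; the REML
subgroup model assumes a common τ² across levels; the compound input
scenario is an interpretation the data cannot distinguish from the linear
one at small r·ΔT; imputation is single-shot and its uncertainty is not
propagated into v; and the space-for-time estimand inherits all three core
assumptions above — none of which the synthetic worlds can falsify.
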