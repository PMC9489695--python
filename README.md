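# soc-sft

Depth-resolved steady-state responses of soil organic carbon (SOC) to climate
warming, estimated by **space-for-time substitution** combined with
**random-effects meta-analysis**, interpreted through a **one-pool Q10 model**
and explored with a **weighted random forest** — exercised end to end on a
synthetic soil-profile generator with known ground truth.

## Who this is for

Soil and carbon-cycle scientists who want to estimate how equilibrium SOC
stocks shift with mean annual temperature (MAT) from large georeferenced
profile compilations, without waiting decades for warming experiments to
equilibrate. The central idea: among sites matched on landform, soil type,
mean annual precipitation (MAP) and precipitation seasonality, a site 1 °C
warmer today is a statistical stand-in for the steady state a cooler site will
reach after 1 °C of warming.

## The method

1. **Harmonization.** Layered profiles on arbitrary depth schemes are
   interpolated with a mass-preserving (equal-area) spline and averaged over
   three standard intervals (0–0.3, 0.3–1, 1–2 m). Stock per interval is
   SOC_s = SOC_c/1000 · D · BD · (1 − G/100) (kg C m⁻²), with SOC content
   SOC_c in g C kg⁻¹, thickness D in m, bulk density BD in kg m⁻³ and gravel
   volume G in %. Missing BD and gravel are imputed with boosted regression
   trees trained on the complete cases.
2. **Pairing.** Profiles are binned into 1 °C MAT classes and, within class,
   into groups sharing landform, soil order, seasonality (from the
   precipitation concentration index, PCI = 100·Σp²/(Σp)²) and a 50-mm MAP
   bin. For warming level ΔT ∈ {1..5} °C, each group in class [i, i+1) is
   contrasted with the same group in class [i+ΔT, i+ΔT+1), provided group
   mean MAPs differ by less than 50 mm (25 mm as a sensitivity switch).
3. **Meta-analysis.** Each contrast yields a log response ratio
   lnRR = ln(SOC̄_warm / SOC̄_ambient) with delta-method variance v; contrasts
   are pooled with weights 1/(v + τ²), τ² estimated by REML (or
   DerSimonian–Laird), and reported as percentage change (e^lnRR − 1)·100.
   Subgroup (moderator) analyses use a shared τ² and the Q_M equality test.
4. **Q10 inversion.** Under the one-pool model dC/dt = I − kC, steady-state
   stock responds to warming as R = (I_w/I)·Q10^(−ΔT/10) − 1. Fitting Q10 to
   the pooled responses at ΔT = 1..5 °C translates the spatial gradient into
   the temperature sensitivity of decomposition, under carbon-input
   scenarios I_w/I = (1+r)^ΔT.
5. **Meta-forest.** A random forest of the effect sizes on environmental
   moderators, with the meta-analytic weights carried into both the bootstrap
   and the split criterion, gives variable importance, cross-validated skill
   and gridded predictions with across-tree uncertainty.

## Worked example

```python
from soc_sft import WorldConfig, generate_world, estimate_warming_responses, fit_q10

world = generate_world(WorldConfig(n_profiles=2000, seed=1))   # topsoil Q10 truth: 1.7
responses = estimate_warming_responses(
    world.profiles, world.environments,
    layers=("0-0.3",), warming_levels=(1, 2, 3), seed=1)
print(responses[["layer", "warming_level", "percent_change",
                 "ci_low", "ci_high", "k"]].round(2).to_string(index=False))
fit = fit_q10([(r.warming_level, r.percent_change) for r in responses.itertuples()])
print(f"fitted Q10: {fit.q10:.2f}   (generator truth: 1.7)")
```

prints

```
layer  warming_level  percent_change  ci_low  ci_high   k
0-0.3              1           -5.70  -10.74    -0.37 109
0-0.3              2          -11.09  -15.45    -6.50 121
0-0.3              3          -17.99  -22.25   -13.50 119
fitted Q10: 1.88   (generator truth: 1.7)
```

Reading: from 109 ambient/warm paired contrasts, topsoil SOC stock is
estimated to fall 5.7 % (95 % CI −10.7 to −0.4 %) per 1 °C of warming in this
synthetic world; the loss deepens with warming level, and inverting the
steady-state curve recovers a decomposition Q10 near the generator's true
value of 1.7. The same calls run from the shell via `soc-sft simulate`,
`soc-sft harmonize`, `soc-sft pair`, `soc-sft meta`, `soc-sft q10` and
`soc-sft forest` (see `soc-sft --help`).

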