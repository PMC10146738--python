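# releasefit

Release-kinetics analysis for drug-loaded fabrics: quantify cumulative drug
release from UV–vis absorbance, fit the four standard dissolution models,
pick the best one, read the transport mechanism off the power-law exponent,
and relate it all to drug polarity via group-contribution solubility
parameters.

The package targets the common experimental workflow around functional
(e.g. skincare) textiles: a drug is impregnated into a cellulose fabric, the
fabric is immersed in a release medium, timed absorbance readings are
converted to a cumulative-release curve Qt(t), and the curve's shape is used
to infer how the drug leaves the matrix.

## The models and statistics

Cumulative release Qt (% of the loaded amount) versus time t (min) is fitted
by least squares on the untransformed scale with four models:

| model | form | parameters |
|---|---|---|
| zero-order | Qt = K₀·t + b₀ | constant-rate release |
| first-order | Qt = K₁·e^(a·t) + b₁ | saturating exponential, plateau b₁ |
| Higuchi | Qt = K_H·√t + b_H | matrix diffusion |
| Korsmeyer–Peppas | Qt = K·tⁿ | power law, fitted only below 60 % release |

Loading capacity and cumulative release come from a linear calibration:
LA = (k·A + b)·V/G and Qt = [(k·A_t + b)·V₁/G₁]/LA × 100 %.

Each fit reports adjusted R², residual sum of squares (RSS), reduced χ²
(RSS/(N−p), unit weights) and Pearson's r between observed and predicted
values. Selection shortlists models within a relative tolerance of the best
adjusted R² and then minimises RSS (then reduced χ², then a fixed registry
order on exact ties).

For a cylindrical geometry (fibres), the release exponent n classifies the
transport mechanism: n < 0.45 Fickian diffusion, 0.45 ≤ n < 0.89
non-Fickian (anomalous) transport, n = 0.89 Case II, n > 0.89 super
Case II. A power-law rate constant K at or above a configurable threshold
(default 6.0 %·min⁻ⁿ) flags burst release.

Drug polarity is summarised by Hoftyzer–Van Krevelen solubility parameters
computed from group-fragment multisets: δd = ΣF_d/V, δp = √(ΣF_p²)/V,
δh = √(ΣE_h/V), δt = √(δd² + δp² + δh²), with Fedors group increments for
the molar volume V.

Because no raw release curves are distributed with the study this package
re-implements, a synthetic-data module generates curves from a registry of
the 36 published fitted equations (9 drugs × 4 models) with additive
Gaussian observation noise, so every stage is testable end to end.

## Worked example

Simulate a noisy power-law curve for p-hydroxybenzoic acid (PHBA) from its
published fitted equation and analyse it:

```python
import releasefit as rf

fx = rf.fixture("PHBA", "korsmeyer_peppas")          # K = 0.3556, n = 0.5381
grid = rf.default_time_grid("PHBA", "korsmeyer_peppas")
curve = rf.generate_curve(rf.SyntheticSpec(
    "korsmeyer_peppas", fx.params, tuple(grid), noise_sd=1.0, seed=7,
    drug_id="PHBA"))
print(rf.render_report(rf.analyze_curve(curve)))
```

```
## PHBA

| model | equation | Adj. R-Square | RSS | Reduced Chi-Sqr | Pearson's r |
|---|---|---|---|---|---|
| zero_order | Qt=0.0072·t+3.3399 | 0.93264 | 188.63147 | 5.89473 | 0.96679 |
| first_order | Qt=36.6070-34.7808·e^(-0.00041933·t) | 0.98629 | 37.18658 | 1.19957 | 0.99354 |
| higuchi | Qt=0.4806·t^1/2-0.8531 | 0.99102 | 25.14078 | 0.78565 | 0.99564 |
| korsmeyer_peppas | Qt=0.2905·t^0.5596 | 0.99296 | 19.70713 | 0.61585 | 0.99658 |

Selected model: **korsmeyer_peppas** (criteria: adj_r2 → rss)
Transport: **non_fickian** (n = 0.5596, thresholds 0.45/0.89); burst: no (K = 0.2905, threshold 6)
Solubility parameters (MJ/m³)^1/2: δd = 22.112, δp = 7.285, δh = 18.167, δt = 29.531 (V = 90.9 cm³/mol)
```

Reading the output: the power law wins (highest adjusted R², lowest RSS);
its fitted exponent 0.5596 is close to the generating 0.5381 at this noise
level and sits in the 0.45–0.89 band, so release is anomalous transport —
diffusion coupled to matrix swelling — and the small K means no burst. The
high total solubility parameter (29.5 vs ~29 for cellulose-like polymers)
is what makes this drug swell the matrix and release slowly.

The same stages are scriptable from a shell: `releasefit simulate`,
`releasefit quantify`, `releasefit fit`, `releasefit classify`,
`releasefit solubility` (see `releasefit --help`).

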