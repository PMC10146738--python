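# Methods

## Scope and data model

The package analyses cumulative-release curves Qt(t) — percent of the loaded
drug released by time t (minutes) — for drugs leaving a fibrous cellulose
matrix into a well-stirred medium. A curve is an ordered series with
strictly increasing times; Qt is not clipped to [0, 100]: values in
(100, 110] pass with a warning (calibration drift is evidence worth
keeping), values above 110 fail validation, and small negatives down to −10
pass with a warning because the additive-noise generator legitimately
produces them near t → 0. Anything below −10 fails.

Quantitation follows the linear-calibration identities
LA = (k·A + b)·V/G and Qt = [(k·A_t + b)·V₁/G₁]/LA × 100. Units are
internal conventions only (g·L⁻¹ and litres; the protocol's 250.0 mL and
150.0 mL are stored as 0.250 and 0.150) since the formulas need nothing
beyond concentration × volume = mass. No aliquot-replacement correction is
applied by default because the protocol returns each sampled aliquot; a
per-point volume hook exists on `build_release_curve`.

## Fitting

All four models are fitted by least squares on the untransformed percent
scale. The published equations are plainly nonlinear and the reported
metric set (reduced χ² alongside RSS) matches untransformed fitting, so
log-linearised regression is offered only as a sensitivity mode
(`fit_scale="linearized"`: log–log for the power law, ln(b₁ − Qt) for the
exponential); its metrics are still evaluated on the percent scale.

* zero-order and Higuchi are closed-form linear least squares (on t and √t).
* Korsmeyer–Peppas starts from log–log regression over positive pairs and is
  polished by Levenberg–Marquardt. Points at t = 0 are excluded from the
  power-law fit: with the 0ⁿ := 0 convention they carry no information and
  destabilise the optimizer when n goes negative during iteration.
* first-order starts are found by profiling the decay rate a over a 60-point
  log grid of timescales (the model is linear in K₁ and b₁ at fixed a, so
  each grid point is one linear solve), with the plateau heuristic
  b₁ ≈ 1.05·max(Qt) + ln(b₁ − Qt) regression as an extra candidate, then
  Levenberg–Marquardt polishing. Profiling was chosen because the plateau
  heuristic alone fails when a curve is observed only over its early rise
  (the plateau sits far above the data; the 4-methoxybenzoic-acid fixture
  observed over 5–200 min has max Qt ≈ 18 against a plateau of 43).
* Non-convergence triggers up to 3 jittered restarts (5 % multiplicative
  jitter, generator seeded by the `seed` option, default 0); if nothing
  converges the best point found is reported with `converged=False`.

The Korsmeyer–Peppas domain rule keeps the longest prefix of points with
Qt strictly below the cutoff (default 60 %). Truncation at the first
crossing is permanent — later points that dip back under the cutoff are not
re-admitted — because the power law describes an early-time validity
window, not a value band. The boundary value 60.0 itself is excluded.

Metrics: adjusted R² = 1 − (RSS/(N−p))/(TSS/(N−1)); Pearson's r is computed
between observed and predicted values for every model (one definition valid
for the nonlinear models too; for straight-line models it equals the usual
t–Qt correlation up to sign); reduced χ² = RSS/(N−p) with unit observation
weights, which reproduces the integer degrees of freedom implied by every
published (RSS, reduced χ²) pair. On perfectly flat observed data TSS = 0
and adjusted R²/Pearson's r are undefined; standalone metric functions
raise, while `fit_model` records NaN and carries on.

## Selection and classification

Selection shortlists fits whose adjusted R² is within a relative tolerance
of the maximum, then takes the smallest RSS, breaking exact ties by smallest
reduced χ² and finally by the fixed registry order
(zero-order, first-order, Higuchi, Korsmeyer–Peppas). RSS outranks reduced
χ² because the 60 %-window restriction lowers the power law's degrees of
freedom: its reduced χ² can exceed a rival's even when its RSS — and its
description of the data it is valid on — is far better.

The shortlist tolerance defaults to 0.05. In the published nine-drug
comparison the power-law fit trails the best adjusted R² by up to 4.5 %
(butyl p-aminobenzoate 3.0 %, o-methoxybenzoic acid 4.5 %) and is still the
preferred model on RSS grounds; a 2 % shortlist would flip those two
selections to first-order. The tolerance is a config key
(`adj_r2_tolerance`) for users who want stricter shortlisting.

Mechanism classification uses the cylinder thresholds on the release
exponent: n < 0.45 Fickian, 0.45 ≤ n < 0.89 non-Fickian, n = 0.89 (within
1e−6 absolute, configurable) Case II, n > 0.89 super Case II. The
boundary n = 0.45 is assigned to the non-Fickian class so the partition is
exhaustive; the choice is a convention (the defining inequalities are strict
on both sides) and is recorded in the call's `thresholds_used`. Only
cylinder thresholds ship; other geometries require a user-supplied table and
are rejected otherwise.

Burst release is flagged when K ≥ 6.0 %·min⁻ⁿ (inclusive boundary). The
threshold is a heuristic placed at the lower edge of the empirical burst
cluster (K > 6.09 for the five burst drugs, versus K < 0.87 for the four
slow ones); it is configurable and should be re-examined for other systems.

## Solubility parameters

Hoftyzer–Van Krevelen components from group-fragment multisets:
δd = ΣF_d/V, δp = √(ΣF_p²)/V, δh = √(ΣE_h/V), δt the Euclidean norm, in
(MJ/m³)^½. The molar volume V is built from Fedors group increments because
no densities are reported. The shipped table uses the canonical molar
attraction constants (aromatic p-phenylene 1270/110/0) and the shipped
multisets encode methoxy as −O− + −CH₃, esters as −COO− plus the alkyl
chain, and the disubstituted ring as one phenylene fragment; both files are
plain YAML and can be overridden per call. A per-molecule additive
correction hook (ΔΣF_d, ΔΣF_p², ΔΣE_h) exists for ring-conjugation
corrections present in some table editions; the default applies none.

Known limitation: group-contribution δt values carry the uncertainty of the
table edition, roughly the few-percent level. Against the nine published
values for these drugs, the shipped table agrees within 5 % for five of the
seven distinct values but computes p-hydroxybenzoic acid ~8 % high and the
methoxybenzoic acids ~14 % high, and consequently places the methoxy
isomers above, not below, butyl p-aminobenzoate. Back-solving the molar
volumes implied by the published values shows they are not group-additive
(the implied increment for −COO− + −CH₃ − (−COOH) differs by ~9 cm³·mol⁻¹
between two drug pairs), so no additive table can reproduce all seven
published values; the 0.5 % published gap between the closest pair is well
inside table uncertainty. The package therefore treats printed-value
agreement as a tolerance check, not an identity; the structural predictions
that drive the scientific conclusions (three-way isomer equality,
polarity drop along the methylene homologation series, the high-δ/low-δ
split between slowly and quickly released drugs) are all reproduced.

## Synthetic data

The generator emulates release assays, not transport physics: it evaluates
a model curve on a grid and adds independent homoscedastic Gaussian noise
on the percent scale (`noise_sd`, default 0); a multiplicative option
exists for sensitivity studies. It does not emulate autocorrelated
instrument drift, heteroscedastic early-time error, aliquot-handling
artefacts, or replicate structure — so passing round-trip tests demonstrate
estimator correctness and identifiability, not robustness to real
instrument pathologies.

Default grids are a synthetic convention: 34 points (the count implied by
the published degrees of freedom), log-spaced over 5–5000 min for the four
slow-release drugs and linear over 5–200 min for the five burst drugs, with
power-law grids capped per drug (e.g. 180 min for butyl p-aminobenzoate,
40 min for m-methoxybenzoic acid) so noiseless fixtures stay below the 60 %
window and round trips drop no points. One integer seed drives one
`numpy` generator per curve and is recorded in the curve metadata;
identical spec + seed is bit-identical by contract.

The fixture registry carries all 36 published fitted equations with their
printed metrics verbatim, and is exportable as a flat table
(`fixtures_table()`).

## Problem sizes and numerical choices

Round-trip and acceptance computations use 18–34-point grids and finish in
milliseconds per fit; the noise-recovery study uses 200 seeds per case.
Convergence uses Levenberg–Marquardt defaults with a generous evaluation
budget (≥ 40 000), 3 restarts, and closed-form solutions wherever the model
is linear in its parameters. Ties in selection are resolved exactly (no
epsilon), keeping `rank_models` permutation-invariant.
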