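# Methods

## Prediction equations

All equations return predicted peak V̇O2 in mL/min and live in an
editable YAML registry (`src/vo2compare/data/equations.yaml`). Four
functional forms cover the six equations:

| form | equations | shape |
|---|---|---|
| `per_kg_linear` | FRIEND, Bruce | relative V̇O2 (mL/kg/min) linear in age, weight, height, sex code, mode code; × body mass |
| `weight_linear` | Wasserman | (weight + offset) × (slope₀ + slope_age·age), per sex |
| `ideal_weight_branched` | Hansen | Wasserman slopes evaluated against ideal body weight (below IBW: mean of actual and ideal mass; above: +6 mL/min per excess kg), cycle value ×1.11 on a treadmill |
| `absolute_linear` | Jones, Neder | absolute V̇O2 linear in height/weight/age, per sex, with a unit scale |

Conventions: 1 lb = 0.453592 kg, 1 in = 2.54 cm; FRIEND's sex code is
male = 1 / female = 2 and mode code treadmill = 1 / cycle = 2; ideal
body weight is 0.79·height − 60.7 kg (men) and 0.65·height − 42.8 kg
(women). The Hansen branches meet continuously at the ideal weight, and
at exactly ideal weight Hansen's cycle branch equals Wasserman.

**Coefficient provenance.** Wasserman, Hansen, FRIEND and Jones use
their standard published coefficient sets; the two case-subject checks
(Wasserman 68%, FRIEND 114% for the 37-year-old treadmill case) pin the
Wasserman and FRIEND pathways end to end. Bruce ships the sedentary-adult
per-kg regressions (a clinical referral population is better matched by
the sedentary than the active variant; the registry makes swapping them a
data edit). The Neder entry is flagged `provenance: provisional`: its
original sedentary regressions could not be reconstructed verbatim here,
so the registry carries a linear weight+age form per sex of plausible
magnitude that preserves the equation's qualitative behavior (lowest
predictions of the six, hence the fewest "reduced" calls). Nothing
downstream — correction, classification, agreement machinery — depends
on these coefficients, and correcting them is a registry edit, not a
code change.

**Domains.** Subjects are validated to age 15–90 y, height 120–220 cm,
weight 30–250 kg. Each equation also records its source cohort's age
span; predictions outside it are produced with a warning rather than
refused, since clinical practice applies these equations well outside
their derivation ranges. The FRIEND linear form predicts non-positive
values for extreme joint combinations (short stature with very high body
mass, or tall stature with BMI ≳ 40); the evaluator raises a domain
error there instead of returning a negative prediction.

## Modality correction

Treadmill exercise elicits roughly 7–18% higher peak V̇O2 than cycle
ergometry; a single ±11% factor reconciles the two. A cycle-native
equation evaluated for a treadmill test is multiplied by 1.11; a
treadmill-native equation for a cycle test by 0.89. The −11% direction
is implemented literally as ×0.89 rather than ÷1.11; the two differ by
about 1% and the factors are named constants (`CYCLE_TO_TREADMILL`,
`TREADMILL_TO_CYCLE`). Modality-specific equations (FRIEND, Hansen) are
never corrected. A pipeline switch disables the correction entirely for
sensitivity analysis.

## Classification and display

Percent predicted is measured/predicted × 100, kept at full precision.
Classification ("normal" iff ≥ threshold, default 80%) always uses the
continuous value. Two display conventions coexist deliberately, both
named functions: the calculator dashboard truncates (floor: 68.33 → 68,
114.64 → 114), while metabolic-cart panels round half-up (81.5 → 82,
31.6 → 32). Derived-variable helpers (METs at 3.5 mL/kg/min per MET,
ventilatory equivalents, O2 pulse, percent of predicted) use the cart
convention.

The packaged worked-example panel stores the clinic printout verbatim,
including its two internal inconsistencies (peak O2 pulse prints 21
while 3560/174 = 20.5; relative peak prints 26.8 while 3560/127.0 =
28.0). The fixture is a record of a printed table, not a recomputation.

## Agreement statistics

- **Cohen's κ** uses the marginal-product chance correction; perfect
  observed agreement returns exactly 1, including two identical constant
  raters (where the usual formula is 0/0). Interpretive bands are
  half-open with inclusive lower edges: [0.01, 0.21) slight, [0.21,
  0.41) fair, [0.41, 0.61) moderate, [0.61, 0.81) substantial, [0.81, 1]
  almost perfect — the deterministic resolution of band endpoints that
  are sometimes quoted ambiguously.
- **Friedman test**: within-subject ranks (mean ranks on ties), χ² =
  12/(n·k·(k+1))·ΣR_j² − 3n(k+1) against χ²(k−1). No tie correction is
  applied, so Kendall's W = χ²/(n(k−1)) is exactly the concordance
  effect size; with ties this is mildly conservative relative to the
  tie-corrected statistic (scipy's version), and the test suite
  cross-checks equality on tie-free data.
- **Post hoc**: the all-pairs comparison is implemented as paired
  Wilcoxon signed-rank tests with Bonferroni adjustment (raw p × 15,
  capped at 1); an all-zero difference pair is p = 1 by convention. The
  method name is recorded in the report (`posthoc_method`) so an exact
  rank-difference procedure could be swapped in without changing the
  report schema.
- **Quartiles** everywhere use numpy's linear-interpolation convention,
  echoed in the report (`quartile_convention`).
- Reclassification is counted in both directions; by construction
  to-normal(A→B) = to-reduced(B→A), and the pipeline also reports the
  fraction of subjects reclassified by at least one of the 15 pairs.

## Difference regression

For each of the 15 ordered pairs, the signed difference in continuous
percent predicted (A − B, corrected values) is regressed by OLS on:
age/10, BMI/5, female (ref male), treadmill (ref cycle), and race
indicators black/asian/other (ref white; unknown labels map to other).
An intercept is always included; ethnicity is not a regressor. Indicator
columns that are constant in the cohort are dropped rather than
producing a singular fit; genuine collinearity raises an error naming
the columns. Estimates are reported on the scaled-covariate scale
(percentage points per decade, per 5 BMI units).

## Synthetic cohort generator

The generator emulates the marginal structure of a male-dominant,
obese, middle-aged veteran referral cohort:

| quantity | default | basis |
|---|---|---|
| male fraction | 0.89 | cohort marginal |
| treadmill fraction | 0.60 | cohort marginal |
| age | normal, median 44, IQR 37–51, clipped to 24–67 | cohort marginal |
| BMI | log-normal, median 31.0, IQR 28.2–34.9 | cohort marginal |
| height | N(176.5, 6.5) men, N(162.5, 6.0) women | chosen so the 89/11 mixture reproduces the overall median 175.3 (IQR 170.2–180.3) |
| weight | BMI·(height/100)² | derived |
| race / ethnicity | 81/10/1/8% and 10/82/8% | cohort marginals |
| fitness ratio | N(0.83, 0.15), floored at 0.2 | see below |

Measured V̇O2 is the Hansen mode-matched prediction times the fitness
ratio. This is a modeling choice, not an empirical claim: it makes
percent-predicted values realistically correlated with anthropometrics
and places the Hansen percent-predicted distribution astride the 80%
threshold (P(ratio < 0.8) ≈ 42% under the defaults, matching the
reduced-capacity fraction a Hansen-based classification should produce
in such a cohort). Normal and log-normal families are pragmatic; only
the median/IQR targets are anchored.

What the generator does **not** emulate: inter-site metabolic-cart
differences, V̇O2 averaging-window effects, within-subject repeat tests,
or any real covariance between fitness and demographics beyond what the
Hansen anchoring induces. A green cohort-level test therefore
establishes that the pipeline's statistics behave correctly on data with
the right marginals — not that the package reproduces the restricted
clinical cohort's published numbers, which are out of reach by design.

On the default synthetic cohort (n = 305) the pipeline nonetheless
lands close to the motivating study's qualitative picture: Wasserman
classifies the most subjects as reduced, Neder the fewest, and roughly
half the cohort is reclassified by at least one pair.

## Sweep curves

Weight curves evaluate percent predicted on a 50–150 kg grid (clipped
to the subject domain) holding sex, height, age, mode and measured V̇O2
constant, with markers at ideal (red) and actual (blue) body mass; BMI
is reported alongside each grid weight since a BMI slider at fixed
height is the same sweep. Age curves cover ±15 years. Grid points where
an equation leaves its domain are dropped with a warning, not fatal.

## Numerical and degenerate-input choices

- All statistics run on continuous percent values; rounding happens only
  at serialization (default 1 decimal).
- Friedman requires n ≥ 2, k ≥ 3 and refuses missing cells (no
  imputation).
- κ on vectors shorter than 2 is an error; band lookup outside [−1, 1]
  is an error.
- The registry loader rejects duplicate equation ids, unknown units,
  non-numeric coefficients, and (by default) registries missing any of
  the six canonical ids; a partial user file overlays the built-in
  default.
- Reports echo threshold, correction toggle, seed, and a SHA-256 prefix
  of the registry so results are traceable to a coefficient set.

## Known limitations

- Bruce activity-status variant and the exact Neder coefficients are
  registry data pending verification against their originals (above).
- The post hoc procedure is signed-rank, not an exact all-pairs rank
  distribution; the report records which was used.
- No weighted kappa, no multi-level capacity grades, no mixed models or
  site-clustered errors, no breath-by-breath signal processing, and no
  hosted interactive application — the CLI and data tables are the
  interface.
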