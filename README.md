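# vo2compare

Compare peak V̇O2 prediction equations for cardiopulmonary exercise test
(CPET) interpretation.

## The problem

CPET interpretation starts from percent-predicted peak oxygen uptake,

```
V̇O2peak-pp = measured V̇O2peak / predicted V̇O2peak × 100
```

with exercise capacity called *normal* when V̇O2peak-pp ≥ 80% (a
conservative fixed threshold). The predicted value, however, depends on
which reference equation the metabolic cart happens to use — equations
derived from different populations, eras, and exercise modalities can
disagree enough to flip a patient between "normal" and "reduced"
capacity, which changes the entire downstream interpretation. This
package makes that disagreement measurable: it evaluates six widely
used equations side by side, classifies capacity under each, and
quantifies inter-equation agreement over a cohort.

It is written for clinicians and exercise physiologists comparing
reference equations, and for methodologists studying classification
agreement in CPET.

## What it computes

- **Six prediction equations** (FRIEND, Wasserman, Hansen, Bruce,
  Jones, Neder) evaluated from age, sex, height, weight and test
  modality, with all coefficients in an editable YAML registry.
  Hansen uses the ideal-body-weight branching scheme
  (men: IBW = 0.79·height − 60.7 kg; women: 0.65·height − 42.8 kg);
  FRIEND uses its registry-wide equation in native imperial units with
  sex and mode codes.
- **Modality correction**: treadmill protocols elicit ~11% higher peak
  V̇O2 than cycle ergometry, so cycle-native equations are scaled ×1.11
  when the test was on a treadmill and treadmill-native equations ×0.89
  on a cycle test. FRIEND and Hansen are modality-specific and need no
  correction.
- **Agreement statistics**: Cohen's κ with the conventional interpretive
  bands, bidirectional reclassification counts, quartiles of the
  absolute percent-predicted difference, a Friedman rank test across all
  six equations with Kendall's W = χ²/(n(k−1)) as effect size, and
  all-pairs Wilcoxon signed-rank post hoc tests with Bonferroni
  adjustment.
- **Difference regression**: OLS of each pair's signed percent-predicted
  difference on scaled covariates (age per decade, BMI per 5 kg/m², sex,
  modality, race).
- **Synthetic cohorts** with the marginal structure of a veteran
  referral population (89% male, median age 44, median BMI 31,
  60% treadmill), since the motivating clinical dataset is restricted.
- **Sweep curves**: percent predicted versus body mass (50–150 kg) and
  age (±15 y) with ideal- and actual-weight markers, as data tables and
  optional static plots.

## Worked example

A 37-year-old man, 67 in (170.2 cm), 280 lb (127.0 kg), tested on a
treadmill, measured V̇O2peak 3560 mL/min:

```
$ vo2compare calc --age 37 --sex m --height 67 --weight 280 \
      --mode treadmill --vo2 3560 --units imperial
equation      predicted mL/min  % predicted     class
friend                    3105          114    normal
wasserman                 5210           68   reduced
hansen                    3380          105    normal
bruce                     5250           67   reduced
jones                     3043          116    normal
neder                     4051           87    normal
```

The Wasserman cycle-native prediction (127.0 × (50.72 − 0.372·37) =
4694 mL/min, ×1.11 treadmill correction = 5210 mL/min) puts the same
measurement at 68% — *reduced* capacity — while the modality-specific
FRIEND equation puts it at 114% — comfortably *normal*. Four of the six
equations classify this subject as normal. Which equation the cart
defaults to decides whether this patient's dyspnea work-up escalates or
ends in reassurance; displaying the full range is the point of the
package. (Percent-predicted display truncates to an integer: 68.33 → 68.)

Cohort-level use:

```
$ vo2compare simulate --n 305 --seed 1 --out cohort.csv
$ vo2compare cohort cohort.csv --out report/ --seed 1
```

writes per-equation summaries (`table4.csv`), the 15 pairwise agreement
rows (`table5.csv`), per-pair regression estimates (`table6.csv`) and a
structured `report.json` echoing the configuration and a hash of the
coefficient registry.

## Acceptance script

`scripts/acceptance.py` rebuilds the worked-example subject from its
printed inputs, runs the full prediction → modality-correction →
percent-predicted → display pipeline, and writes the resulting integer
percentages as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/vo2compare/equations.py`, `registry.py` — equation forms and the
  editable coefficient registry (`data/equations.yaml`)
- `agreement.py` — classification, κ, Friedman/Kendall W, post hoc
- `regression.py` — scaled-covariate difference models
- `pipeline.py` — cohort orchestration and report bundle
- `synthetic.py` — cohort generator
- `cpet.py` — derived CPET variables (METs, ventilatory equivalents,
  O2 pulse, disability screens) and the clinic worked-example panel
- `curves.py` — weight/age sweep data and plots
- `io.py`, `cli.py` — cohort files and the `vo2compare` CLI

See `docs/methods.md` for the statistical conventions, the generator's
assumptions, and known limitations (including coefficient provenance).
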