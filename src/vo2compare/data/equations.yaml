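# Default peak V̇O2 prediction-equation registry.
#
# One block per equation id. Coefficients are editable without code changes;
# `form` selects the evaluator:
#   per_kg_linear        rel (mL/kg/min) = intercept + age*A + weight*W + height*H
#                                          + sex_code*S + mode_code*M
#                        absolute value = rel * body mass (kg).
#                        W/H are in the block's native units; S codes
#                        male=1/female=2, M codes treadmill=1/cycle=2.
#   weight_linear        absolute (mL/min) = (W_kg + weight_offset)
#                                            * (slope_intercept + slope_age*A)
#   ideal_weight_branched  weight_linear evaluated against ideal body weight:
#                        below ideal weight the effective mass is the mean of
#                        actual and ideal; above it the ideal-weight prediction
#                        grows by surplus_rate mL/min per excess kg. The
#                        treadmill branch multiplies by treadmill_factor.
#   absolute_linear      absolute = scale * (intercept + age*A + weight*W_kg
#                                            + height*H_cm)
#
# source_age_range is the age span of the source cohort; predictions outside
# it are produced with a warning, not refused.

friend:
  name: FRIEND registry (2017/2018 pooled treadmill + cycle equation)
  form: per_kg_linear
  native_modes: [treadmill, cycle]
  weight_units: lb
  height_units: in
  coefficients:
    intercept: 45.2
    age: -0.35
    sex_code: -10.9
    weight: -0.15
    height: 0.68
    mode_code: -0.46
  source_age_range: [20, 79]

wasserman:
  name: Wasserman (cycle, weight-based form)
  form: weight_linear
  native_modes: [cycle]
  weight_units: kg
  height_units: cm
  coefficients:
    male:
      slope_intercept: 50.72
      slope_age: -0.372
      weight_offset: 0.0
    female:
      slope_intercept: 22.78
      slope_age: -0.17
      weight_offset: 43.0
  source_age_range: [34, 74]

hansen:
  name: Hansen (ideal-weight-branched revision of Wasserman)
  form: ideal_weight_branched
  native_modes: [cycle, treadmill]
  weight_units: kg
  height_units: cm
  treadmill_factor: 1.11
  coefficients:
    male:
      slope_intercept: 50.72
      slope_age: -0.372
      weight_offset: 0.0
      ibw_slope: 0.79
      ibw_intercept: -60.7
      surplus_rate: 6.0
    female:
      slope_intercept: 22.78
      slope_age: -0.17
      weight_offset: 43.0
      ibw_slope: 0.65
      ibw_intercept: -42.8
      surplus_rate: 6.0
  source_age_range: [34, 74]

bruce:
  name: Bruce (treadmill, sedentary per-kg age regressions)
  form: per_kg_linear
  native_modes: [treadmill]
  weight_units: kg
  height_units: cm
  coefficients:
    male:
      intercept: 57.8
      age: -0.445
    female:
      intercept: 42.3
      age: -0.356
  source_age_range: [29, 73]

jones:
  name: Jones (cycle, height/age regression in L/min)
  form: absolute_linear
  native_modes: [cycle]
  weight_units: kg
  height_units: cm
  scale: 1000.0
  coefficients:
    male:
      intercept: -4.31
      height: 0.046
      age: -0.021
    female:
      intercept: -4.93
      height: 0.046
      age: -0.021
  source_age_range: [15, 71]

neder:
  name: Neder (cycle, sedentary weight/age form)
  form: absolute_linear
  native_modes: [cycle]
  weight_units: kg
  height_units: cm
  scale: 1.0
  provenance: provisional
  coefficients:
    male:
      intercept: 1600.0
      weight: 24.0
      age: -27.0
    female:
      intercept: 1050.0
      weight: 16.0
      age: -15.0
  source_age_range: [20, 80]
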