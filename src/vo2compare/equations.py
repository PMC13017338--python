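"""Evaluation of peak V̇O2 prediction equations with modality handling.

Six reference equations predict peak oxygen uptake (mL/min) from age,
sex, height, weight and — for the modality-specific FRIEND and Hansen
equations — the exercise mode. Treadmill protocols elicit roughly 11%
higher peak V̇O2 than cycle ergometry, so a cycle-native equation applied
to a treadmill test is scaled by ×1.11 and a treadmill-native equation
applied to a cycle test by ×0.89. Modality-specific equations need no
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registry import CANONICAL_IDS, EquationSpec, RegistryError
from .subjects import Subject

__all__ = [
    "CYCLE_TO_TREADMILL",
    "TREADMILL_TO_CYCLE",
    "Prediction",
    "EquationDomainError",
    "ideal_body_weight",
    "predict_vo2",
    "apply_mode_correction",
    "predict_all",
]

# Cycle-native prediction compared against a treadmill test: +11%.
CYCLE_TO_TREADMILL = 1.11
# Treadmill-native prediction compared against a cycle test: −11%,
# read literally as ×0.89 (not ÷1.11; the ~1% difference is documented).
TREADMILL_TO_CYCLE = 0.89

# Ideal body weight (kg) as a linear function of height (cm), the
# Hansen/Wasserman scheme's reference mass.
_IBW = {"male": (0.79, -60.7), "female": (0.65, -42.8)}

_SEX_CODE = {"male": 1.0, "female": 2.0}
_MODE_CODE = {"treadmill": 1.0, "cycle": 2.0}


class EquationDomainError(ValueError):
    """Subject outside an equation's supported domain."""


@dataclass(frozen=True)
class Prediction:
    """A single equation's predicted peak V̇O2 for one subject.

    ``native_value`` is the prediction in the equation's native modality;
    ``corrected_value`` is after the cycle↔treadmill correction (equal to
    native for matching modes or modality-specific equations).
    ``correction_applied`` is the factor actually used (1.00, 1.11 or 0.89).
    """

    equation_id: str
    native_value: float
    corrected_value: float
    correction_applied: float
    warnings: tuple[str, ...] = ()


def ideal_body_weight(sex: str, height: float) -> float:
    """Ideal body weight in kg for a given sex and height in cm.

    Men: 0.79·height − 60.7; women: 0.65·height − 42.8.
    """
    try:
        slope, intercept = _IBW[sex]
    except KeyError:
        raise EquationDomainError(f"unknown sex {sex!r}") from None
    ibw = slope * height + intercept
    if ibw <= 0:
        raise EquationDomainError(
            f"ideal body weight non-positive for height {height} cm ({sex})"
        )
    return ibw


def _native_weight(spec: EquationSpec, subject: Subject) -> float:
    return subject.weight_lb if spec.weight_units == "lb" else subject.weight


def _native_height(spec: EquationSpec, subject: Subject) -> float:
    return subject.height_in if spec.height_units == "in" else subject.height


def _eval_per_kg_linear(spec: EquationSpec, subject: Subject) -> float:
    c = spec.coeffs_for(subject.sex)
    rel = (
        c.get("intercept", 0.0)
        + c.get("age", 0.0) * subject.age
        + c.get("weight", 0.0) * _native_weight(spec, subject)
        + c.get("height", 0.0) * _native_height(spec, subject)
        + c.get("sex_code", 0.0) * _SEX_CODE[subject.sex]
        + c.get("mode_code", 0.0) * _MODE_CODE[subject.mode]
    )
    return rel * subject.weight


def _slope(c: dict, age: float) -> float:
    return c["slope_intercept"] + c["slope_age"] * age


def _eval_weight_linear(spec: EquationSpec, subject: Subject) -> float:
    c = spec.coeffs_for(subject.sex)
    return (subject.weight + c.get("weight_offset", 0.0)) * _slope(c, subject.age)


def _eval_ideal_weight_branched(spec: EquationSpec, subject: Subject) -> float:
    c = spec.coeffs_for(subject.sex)
    ibw = c["ibw_slope"] * subject.height + c["ibw_intercept"]
    if ibw <= 0:
        raise EquationDomainError(
            f"ideal body weight non-positive for height {subject.height} cm"
        )
    offset = c.get("weight_offset", 0.0)
    slope = _slope(c, subject.age)
    if subject.weight < ibw:
        # Underweight: prediction at the mean of actual and ideal mass.
        value = ((subject.weight + ibw) / 2.0 + offset) * slope
    else:
        # At or above ideal mass: ideal-weight prediction plus a shallow
        # surplus_rate mL/min per kg of excess mass.
        value = (ibw + offset) * slope + c["surplus_rate"] * (subject.weight - ibw)
    if subject.mode == "treadmill" and spec.treadmill_factor is not None:
        value *= spec.treadmill_factor
    return value


def _eval_absolute_linear(spec: EquationSpec, subject: Subject) -> float:
    c = spec.coeffs_for(subject.sex)
    value = (
        c.get("intercept", 0.0)
        + c.get("age", 0.0) * subject.age
        + c.get("weight", 0.0) * _native_weight(spec, subject)
        + c.get("height", 0.0) * _native_height(spec, subject)
    )
    return value * spec.scale


_EVALUATORS = {
    "per_kg_linear": _eval_per_kg_linear,
    "weight_linear": _eval_weight_linear,
    "ideal_weight_branched": _eval_ideal_weight_branched,
    "absolute_linear": _eval_absolute_linear,
}


def predict_vo2(spec: EquationSpec, subject: Subject) -> Prediction:
    """Predicted peak V̇O2 in the equation's native modality, mL/min.

    For modality-specific equations (FRIEND, Hansen) the branch matching
    ``subject.mode`` is evaluated. Ages outside the source study's range
    are allowed but produce a warning on the result.
    """
    evaluate = _EVALUATORS[spec.form]
    value = evaluate(spec, subject)
    if not value > 0:
        raise EquationDomainError(
            f"equation {spec.id!r} predicts non-positive V̇O2 "
            f"({value:.1f} mL/min) for subject {subject.id!r}"
        )
    warnings: tuple[str, ...] = ()
    if spec.source_age_range is not None:
        lo, hi = spec.source_age_range
        if not (lo <= subject.age <= hi):
            warnings = (
                f"age {subject.age:g} outside {spec.id} source range [{lo:g}, {hi:g}]",
            )
    return Prediction(
        equation_id=spec.id,
        native_value=value,
        corrected_value=value,
        correction_applied=1.0,
        warnings=warnings,
    )


def apply_mode_correction(
    value: float, native_mode: str, test_mode: str
) -> tuple[float, float]:
    """Correct a native prediction for the test modality.

    Returns ``(corrected_value, factor)`` where the factor is 1.11 for a
    cycle-native prediction compared against a treadmill test, 0.89 for a
    treadmill-native prediction against a cycle test, and 1.00 when the
    modes match.
    """
    if value <= 0:
        raise EquationDomainError(f"cannot correct non-positive value {value!r}")
    if native_mode == test_mode:
        factor = 1.0
    elif native_mode == "cycle" and test_mode == "treadmill":
        factor = CYCLE_TO_TREADMILL
    elif native_mode == "treadmill" and test_mode == "cycle":
        factor = TREADMILL_TO_CYCLE
    else:
        raise EquationDomainError(
            f"unknown mode pair {native_mode!r} → {test_mode!r}"
        )
    return value * factor, factor


def _corrected(spec: EquationSpec, subject: Subject, *, correct: bool) -> Prediction:
    pred = predict_vo2(spec, subject)
    if not correct or subject.mode in spec.native_modes:
        return pred
    corrected, factor = apply_mode_correction(
        pred.native_value, spec.native_modes[0], subject.mode
    )
    return Prediction(
        equation_id=spec.id,
        native_value=pred.native_value,
        corrected_value=corrected,
        correction_applied=factor,
        warnings=pred.warnings,
    )


def predict_all(
    registry: dict[str, EquationSpec],
    subject: Subject,
    *,
    correct_for_mode: bool = True,
) -> dict[str, Prediction]:
    """All six predictions for a subject, corrected for the test modality.

    The registry must contain every canonical equation id; results are
    keyed in canonical order. ``correct_for_mode=False`` disables the
    cycle↔treadmill correction (sensitivity analysis), leaving
    modality-specific equations unchanged.
    """
    missing = [i for i in CANONICAL_IDS if i not in registry]
    if missing:
        raise RegistryError(f"registry is missing equations: {', '.join(missing)}")
    out: dict[str, Prediction] = {}
    for eq_id in CANONICAL_IDS:
        try:
            out[eq_id] = _corrected(registry[eq_id], subject, correct=correct_for_mode)
        except EquationDomainError as exc:
            raise EquationDomainError(f"[{eq_id}] {exc}") from exc
    return out
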