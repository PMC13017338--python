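"""Subject records for CPET percent-predicted analysis.

A :class:`Subject` is one cardiopulmonary exercise test: demographics,
anthropometrics, the exercise modality, and the measured peak oxygen
uptake in absolute units (mL/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Subject",
    "SubjectValidationError",
    "KG_PER_LB",
    "CM_PER_IN",
    "SEXES",
    "MODES",
    "AGE_BOUNDS",
    "HEIGHT_BOUNDS",
    "WEIGHT_BOUNDS",
]

# Fixed unit conversions (exact definitions used throughout the package).
KG_PER_LB = 0.453592
CM_PER_IN = 2.54

SEXES = ("male", "female")
MODES = ("treadmill", "cycle")

# Plausibility bounds for adult clinical CPET referrals.
AGE_BOUNDS = (15.0, 90.0)
HEIGHT_BOUNDS = (120.0, 220.0)
WEIGHT_BOUNDS = (30.0, 250.0)


class SubjectValidationError(ValueError):
    """Raised when a subject record violates the domain invariants."""


def _check_range(name: str, value: float, bounds: tuple[float, float]) -> None:
    lo, hi = bounds
    if not (lo <= value <= hi):
        raise SubjectValidationError(
            f"{name}={value!r} outside allowed range [{lo}, {hi}]"
        )


@dataclass(frozen=True)
class Subject:
    """One CPET record.

    Parameters
    ----------
    id : str
        Opaque subject label.
    age : float
        Age in years, within [15, 90].
    sex : {"male", "female"}
    height : float
        Standing height in cm, within [120, 220].
    weight : float
        Body mass in kg, within [30, 250].
    mode : {"treadmill", "cycle"}
        Exercise modality of the test.
    measured_vo2 : float
        Measured peak V̇O2 in mL/min, strictly positive.
    race, ethnicity : str, optional
        Free labels used only by the difference-regression design.
    """

    id: str
    age: float
    sex: str
    height: float
    weight: float
    mode: str
    measured_vo2: float
    race: str | None = None
    ethnicity: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SubjectValidationError(
                f"sex={self.sex!r} not one of {SEXES} (subject {self.id!r})"
            )
        if self.mode not in MODES:
            raise SubjectValidationError(
                f"mode={self.mode!r} not one of {MODES} (subject {self.id!r})"
            )
        _check_range("age", self.age, AGE_BOUNDS)
        _check_range("height", self.height, HEIGHT_BOUNDS)
        _check_range("weight", self.weight, WEIGHT_BOUNDS)
        if not self.measured_vo2 > 0:
            raise SubjectValidationError(
                f"measured_vo2={self.measured_vo2!r} must be positive "
                f"(subject {self.id!r})"
            )

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight / (self.height / 100.0) ** 2

    @property
    def weight_lb(self) -> float:
        """Body mass in pounds (1 lb = 0.453592 kg)."""
        return self.weight / KG_PER_LB

    @property
    def height_in(self) -> float:
        """Height in inches (1 in = 2.54 cm)."""
        return self.height / CM_PER_IN

    @property
    def relative_vo2(self) -> float:
        """Measured peak V̇O2 relative to body mass, mL/kg/min."""
        return self.measured_vo2 / self.weight


def worked_case_subject() -> Subject:
    """The dashboard's canonical demonstration subject.

    A 37-year-old man, 67 in (170.18 cm), 280 lb (127.006 kg), tested on a
    treadmill, who achieved a measured peak V̇O2 of 3560 mL/min.
    """
    return Subject(
        id="case-37M",
        age=37,
        sex="male",
        height=67 * CM_PER_IN,
        weight=280 * KG_PER_LB,
        mode="treadmill",
        measured_vo2=3560.0,
    )
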