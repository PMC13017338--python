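"""Standard CPET derived variables and the clinic worked-example panel.

Two display conventions coexist deliberately: metabolic-cart panels
round half-up to the printed precision (81.5% → 82), while the
percent-predicted calculator truncates (floor; 68.33% → 68). Both are
exposed as named functions so callers never re-implement rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .subjects import Subject, worked_case_subject

__all__ = [
    "ML_PER_KG_MIN_PER_MET",
    "round_half_up",
    "floor_display",
    "mets_from_relative_vo2",
    "ventilatory_equivalent",
    "percent_of_predicted",
    "oxygen_pulse",
    "disability_flags",
    "WorkedExample",
    "worked_example",
]

#: 1 MET = 3.5 mL O2 / kg / min by convention.
ML_PER_KG_MIN_PER_MET = 3.5

#: New York State disability screen: Hansen percent predicted below 85%.
NY_HANSEN_PP_CUTOFF = 85.0
#: VA disability screen: relative peak V̇O2 below 20 mL/kg/min.
VA_RELATIVE_VO2_CUTOFF = 20.0


def round_half_up(value: float, decimals: int = 0) -> float:
    """Cart display rounding: .5 always rounds away from zero upward."""
    scale = 10**decimals
    return math.floor(value * scale + 0.5) / scale


def floor_display(value: float) -> int:
    """Calculator display rule: truncate the continuous percent."""
    return math.floor(value)


def mets_from_relative_vo2(rel: float) -> float:
    """METs from relative V̇O2 (mL/kg/min), reported to 1 decimal."""
    if rel < 0:
        raise ValueError(f"relative V̇O2 must be non-negative, got {rel!r}")
    return round_half_up(rel / ML_PER_KG_MIN_PER_MET, 1)


def ventilatory_equivalent(ve: float, vgas: float) -> tuple[int, float]:
    """VE/V̇gas ratio: ``(display_integer, continuous)``.

    ``ve`` and ``vgas`` in L/min; display uses cart rounding.
    """
    if vgas <= 0:
        raise ValueError(f"gas exchange rate must be positive, got {vgas!r}")
    ratio = ve / vgas
    return int(round_half_up(ratio)), ratio


def percent_of_predicted(measured: float, predicted: float) -> int:
    """Cart percent-of-predicted: measured/predicted·100, rounded half-up."""
    if predicted <= 0:
        raise ValueError(f"predicted value must be positive, got {predicted!r}")
    return int(round_half_up(measured / predicted * 100.0))


def oxygen_pulse(vo2: float, hr: float) -> float:
    """O2 pulse in mL/beat (V̇O2 mL/min over HR bpm), 1 decimal."""
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr!r}")
    if vo2 < 0:
        raise ValueError(f"V̇O2 must be non-negative, got {vo2!r}")
    return round_half_up(vo2 / hr, 1)


def disability_flags(relative_vo2: float, hansen_pp: float) -> tuple[bool, bool]:
    """(NY-state flag, VA flag) disability screens.

    NY flags Hansen percent predicted < 85%; the VA flags relative peak
    V̇O2 < 20 mL/kg/min. Illustrative screens only — neither is a rating.
    """
    if relative_vo2 <= 0 or hansen_pp <= 0:
        raise ValueError("inputs must be positive")
    return hansen_pp < NY_HANSEN_PP_CUTOFF, relative_vo2 < VA_RELATIVE_VO2_CUTOFF


@dataclass(frozen=True)
class WorkedExample:
    """The clinic case: subject plus the printed metabolic-cart panel.

    The panel stores the printed values verbatim, including its two
    internal inconsistencies (peak O2 pulse prints 21 while 3560/174 =
    20.5; relative peak prints 26.8 while 3560/127.0 = 28.0); the
    fixture does not reconcile them.
    """

    subject: Subject
    panel: pd.DataFrame

    def _peak(self, variable: str) -> float:
        return float(self.panel.loc[variable, "peak"])

    @property
    def measured_vo2(self) -> float:
        return self.subject.measured_vo2

    @property
    def weight_kg(self) -> float:
        return self.subject.weight

    @property
    def peak_ve(self) -> float:
        return self._peak("ve_btps_l_min")

    @property
    def peak_hr(self) -> float:
        return self._peak("hr_bpm")

    @property
    def peak_vco2(self) -> float:
        return self._peak("vco2_l_min")

    @property
    def peak_vo2_l_min(self) -> float:
        return self._peak("vo2_l_min")

    @property
    def peak_relative_vo2(self) -> float:
        return self._peak("vo2_rel_ml_kg_min")


def worked_example() -> WorkedExample:
    """The 37-year-old treadmill case and its cart panel."""
    with resources.files("vo2compare.data").joinpath(
        "worked_example_panel.csv"
    ).open("r", encoding="utf-8") as fh:
        panel = pd.read_csv(fh, index_col="variable")
    return WorkedExample(subject=worked_case_subject(), panel=panel)
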