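"""Percent-predicted sweep curves over body mass and age.

For one subject and one equation, the percent-predicted value is
re-evaluated along a grid of body masses (default 50–150 kg) or ages
(±15 years), holding sex, height, mode and measured V̇O2 constant.
Weight curves carry markers at the subject's ideal body weight (red in
the rendered plots) and actual weight (blue). BMI is reported alongside
each grid weight since weight and BMI sweeps coincide at fixed height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .equations import (
    EquationDomainError,
    ideal_body_weight,
    predict_all,
)
from .registry import EquationSpec
from .subjects import AGE_BOUNDS, WEIGHT_BOUNDS, Subject

__all__ = ["SweepCurve", "weight_sweep", "age_sweep", "curves_frame", "render_static_plots"]


@dataclass(frozen=True)
class SweepCurve:
    equation_id: str
    axis: str  # "weight" | "age"
    grid: np.ndarray
    pp: np.ndarray
    bmi: np.ndarray | None = None
    ideal_marker: tuple[float, float] | None = None
    actual_marker: tuple[float, float] | None = None


def _pp_at(
    registry: dict[str, EquationSpec], equation_id: str, subject: Subject
) -> float:
    pred = predict_all(registry, subject)[equation_id]
    return subject.measured_vo2 / pred.corrected_value * 100.0


def _sweep(
    registry: dict[str, EquationSpec],
    equation_id: str,
    subject: Subject,
    field: str,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    values, kept = [], []
    for g in grid:
        try:
            values.append(_pp_at(registry, equation_id, replace(subject, **{field: float(g)})))
            kept.append(g)
        except EquationDomainError as exc:
            warnings.warn(f"{equation_id}: dropping {field}={g:g} ({exc})", stacklevel=3)
    return np.asarray(kept, dtype=float), np.asarray(values, dtype=float)


def weight_sweep(
    registry: dict[str, EquationSpec],
    equation_id: str,
    subject: Subject,
    lo: float = 50.0,
    hi: float = 150.0,
    step: float = 1.0,
) -> SweepCurve:
    """Percent predicted versus body mass, all else held constant."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    lo = max(lo, WEIGHT_BOUNDS[0])
    hi = min(hi, WEIGHT_BOUNDS[1])
    grid = np.arange(lo, hi + step / 2, step)
    grid, pp = _sweep(registry, equation_id, subject, "weight", grid)
    ibw = ideal_body_weight(subject.sex, subject.height)
    markers = {}
    for name, w in (("ideal_marker", ibw), ("actual_marker", subject.weight)):
        markers[name] = (
            w,
            _pp_at(registry, equation_id, replace(subject, weight=float(w))),
        )
    bmi = grid / (subject.height / 100.0) ** 2
    return SweepCurve(
        equation_id=equation_id,
        axis="weight",
        grid=grid,
        pp=pp,
        bmi=bmi,
        ideal_marker=markers["ideal_marker"],
        actual_marker=markers["actual_marker"],
    )


def age_sweep(
    registry: dict[str, EquationSpec],
    equation_id: str,
    subject: Subject,
    delta: float = 15.0,
    step: float = 1.0,
) -> SweepCurve:
    """Percent predicted over [age−delta, age+delta], all else constant."""
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    lo = max(subject.age - delta, AGE_BOUNDS[0])
    hi = min(subject.age + delta, AGE_BOUNDS[1])
    grid = np.arange(lo, hi + step / 2, step) if delta > 0 else np.array([subject.age])
    grid, pp = _sweep(registry, equation_id, subject, "age", grid)
    return SweepCurve(equation_id=equation_id, axis="age", grid=grid, pp=pp)


def curves_frame(curves: list[SweepCurve]) -> pd.DataFrame:
    """Long-format table: equation, axis, grid_value, bmi, pp."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "equation": c.equation_id,
                    "axis": c.axis,
                    "grid_value": c.grid,
                    "bmi": c.bmi if c.bmi is not None else np.nan,
                    "pp": c.pp,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["equation", "axis", "grid_value", "bmi", "pp"])
    return pd.concat(frames, ignore_index=True)


def render_static_plots(curves: list[SweepCurve], out_dir, threshold: float = 80.0) -> list[str]:
    """One PNG per curve, with the 80% threshold rule and weight markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not curves:
        warnings.warn("no curves to render")
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for c in curves:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(c.grid, c.pp, color="black", lw=1.5)
        ax.axhline(threshold, ls="--", color="gray", label=f"{threshold:g}% threshold")
        if c.ideal_marker is not None:
            ax.plot(*c.ideal_marker, "o", color="red", label="ideal weight")
        if c.actual_marker is not None:
            ax.plot(*c.actual_marker, "o", color="blue", label="actual weight")
        ax.set_xlabel("body mass (kg)" if c.axis == "weight" else "age (years)")
        ax.set_ylabel("percent predicted V̇O2peak (%)")
        ax.set_title(c.equation_id)
        ax.legend(loc="best", fontsize=8)
        path = out / f"{c.equation_id}_{c.axis}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))
    return written
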