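"""Cohort-level comparison pipeline.

Runs the six prediction equations over a cohort, classifies exercise
capacity at a fixed percent-predicted threshold, and assembles a report
bundle: per-equation summaries (predicted V̇O2 and percent-predicted
medians with quartiles, reduced-capacity counts), all 15 pairwise
agreement summaries (kappa with band, bidirectional reclassification,
absolute-difference quartiles, Bonferroni-adjusted post hoc p), the
Friedman test with Kendall's W, and per-pair covariate regressions of
the signed percent-predicted difference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from .equations import predict_all
from .registry import CANONICAL_IDS, EquationSpec, registry_hash
from .regression import DESIGN_COLUMNS, build_design, fit_difference_model
from .subjects import Subject

__all__ = [
    "PipelineConfig",
    "EquationSummary",
    "AgreementSummary",
    "CohortReport",
    "summarize_equation",
    "run_cohort_comparison",
    "write_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    threshold: float = ag.DEFAULT_THRESHOLD
    correction_enabled: bool = True
    precision: int = 1
    seed: int | None = None


@dataclass(frozen=True)
class EquationSummary:
    equation_id: str
    predicted_median: float
    predicted_q1: float
    predicted_q3: float
    pp_median: float
    pp_q1: float
    pp_q3: float
    n_reduced: int
    fraction_reduced: float


@dataclass(frozen=True)
class AgreementSummary:
    pair: tuple[str, str]
    kappa: float
    band: str
    n_to_normal: int
    frac_to_normal: float
    n_to_reduced: int
    frac_to_reduced: float
    ad_median: float
    ad_q1: float
    ad_q3: float
    posthoc_p: float


@dataclass(frozen=True)
class CohortReport:
    n: int
    equation_summaries: list[EquationSummary]
    pairwise: list[AgreementSummary]
    friedman: ag.FriedmanResult
    regression: dict[tuple[str, str], pd.Series]
    regression_pvalues: dict[tuple[str, str], pd.Series]
    n_reclassified_any: int
    frac_reclassified_any: float
    threshold: float
    correction_enabled: bool
    registry_hash: str
    seed: int | None
    posthoc_method: str
    quartile_convention: str
    pp_matrix: pd.DataFrame = field(repr=False)
    predicted: pd.DataFrame = field(repr=False)


def summarize_equation(
    pp_vector, predicted_vector, threshold: float = ag.DEFAULT_THRESHOLD
) -> dict:
    """Median (Q1–Q3) of predicted and percent-predicted values plus the
    reduced-capacity count at the threshold (continuous comparison)."""
    pp = np.asarray(pp_vector, dtype=float)
    pred = np.asarray(predicted_vector, dtype=float)
    if pp.size == 0 or pp.shape != pred.shape:
        raise ValueError("pp and predicted vectors must be equal-length, non-empty")
    pq1, pmed, pq3 = np.percentile(pred, [25, 50, 75])
    q1, med, q3 = np.percentile(pp, [25, 50, 75])
    n_reduced = int(np.sum(pp < threshold))
    return {
        "predicted_median": float(pmed),
        "predicted_q1": float(pq1),
        "predicted_q3": float(pq3),
        "pp_median": float(med),
        "pp_q1": float(q1),
        "pp_q3": float(q3),
        "n_reduced": n_reduced,
        "fraction_reduced": n_reduced / pp.size,
    }


def run_cohort_comparison(
    cohort: list[Subject],
    registry: dict[str, EquationSpec],
    config: PipelineConfig | None = None,
) -> CohortReport:
    """Full inter-equation comparison over a validated cohort."""
    cfg = config or PipelineConfig()
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)

    predicted = np.empty((n, len(CANONICAL_IDS)))
    for i, subj in enumerate(cohort):
        preds = predict_all(registry, subj, correct_for_mode=cfg.correction_enabled)
        for j, eq_id in enumerate(CANONICAL_IDS):
            predicted[i, j] = preds[eq_id].corrected_value
    measured = np.array([s.measured_vo2 for s in cohort])
    pp = measured[:, None] / predicted * 100.0

    ids = [s.id for s in cohort]
    pp_df = pd.DataFrame(pp, index=ids, columns=list(CANONICAL_IDS))
    pred_df = pd.DataFrame(predicted, index=ids, columns=list(CANONICAL_IDS))

    eq_summaries = [
        EquationSummary(equation_id=eq_id, **summarize_equation(
            pp_df[eq_id], pred_df[eq_id], cfg.threshold
        ))
        for eq_id in CANONICAL_IDS
    ]

    posthoc = ag.pairwise_posthoc(pp, list(CANONICAL_IDS))
    pairwise = []
    flipped_any = np.zeros(n, dtype=bool)
    for a, b in combinations(CANONICAL_IDS, 2):
        pa, pb = pp_df[a].to_numpy(), pp_df[b].to_numpy()
        kappa = ag.cohens_kappa(pa >= cfg.threshold, pb >= cfg.threshold)
        to_normal, to_reduced, _ = ag.reclassification(pa, pb, cfg.threshold)
        ad_med, ad_q1, ad_q3 = ag.absolute_difference_summary(pa, pb)
        flipped_any |= (pa >= cfg.threshold) != (pb >= cfg.threshold)
        pairwise.append(
            AgreementSummary(
                pair=(a, b),
                kappa=kappa,
                band=ag.kappa_band(max(-1.0, min(1.0, kappa))),
                n_to_normal=to_normal,
                frac_to_normal=to_normal / n,
                n_to_reduced=to_reduced,
                frac_to_reduced=to_reduced / n,
                ad_median=ad_med,
                ad_q1=ad_q1,
                ad_q3=ad_q3,
                posthoc_p=posthoc[(a, b)],
            )
        )

    friedman = ag.friedman_test(pp)

    design = build_design(cohort)
    regression: dict[tuple[str, str], pd.Series] = {}
    regression_p: dict[tuple[str, str], pd.Series] = {}
    for a, b in combinations(CANONICAL_IDS, 2):
        diff = pp_df[a].to_numpy() - pp_df[b].to_numpy()
        fit = fit_difference_model(diff, design)
        regression[(a, b)] = fit.params
        regression_p[(a, b)] = fit.pvalues

    n_any = int(flipped_any.sum())
    return CohortReport(
        n=n,
        equation_summaries=eq_summaries,
        pairwise=pairwise,
        friedman=friedman,
        regression=regression,
        regression_pvalues=regression_p,
        n_reclassified_any=n_any,
        frac_reclassified_any=n_any / n,
        threshold=cfg.threshold,
        correction_enabled=cfg.correction_enabled,
        registry_hash=registry_hash(registry),
        seed=cfg.seed,
        posthoc_method="wilcoxon-signed-rank+bonferroni",
        quartile_convention="linear-interpolation",
        pp_matrix=pp_df,
        predicted=pred_df,
    )


def _equation_table(report: CohortReport, precision: int) -> pd.DataFrame:
    rows = []
    for s in report.equation_summaries:
        rows.append(
            {
                "equation": s.equation_id,
                "predicted_median_ml_min": round(s.predicted_median, precision),
                "predicted_q1": round(s.predicted_q1, precision),
                "predicted_q3": round(s.predicted_q3, precision),
                "pp_median": round(s.pp_median, precision),
                "pp_q1": round(s.pp_q1, precision),
                "pp_q3": round(s.pp_q3, precision),
                "n_reduced": s.n_reduced,
                "pct_reduced": round(100 * s.fraction_reduced, precision),
            }
        )
    return pd.DataFrame(rows)


def _pairwise_table(report: CohortReport, precision: int) -> pd.DataFrame:
    rows = []
    for s in report.pairwise:
        rows.append(
            {
                "from": s.pair[0],
                "to": s.pair[1],
                "kappa": round(s.kappa, 2),
                "band": s.band,
                "n_to_normal": s.n_to_normal,
                "pct_to_normal": round(100 * s.frac_to_normal, precision),
                "n_to_reduced": s.n_to_reduced,
                "pct_to_reduced": round(100 * s.frac_to_reduced, precision),
                "ad_median": round(s.ad_median, precision),
                "ad_q1": round(s.ad_q1, precision),
                "ad_q3": round(s.ad_q3, precision),
                "posthoc_p_bonferroni": float(f"{s.posthoc_p:.3g}"),
            }
        )
    return pd.DataFrame(rows)


def _regression_table(report: CohortReport, precision: int) -> pd.DataFrame:
    rows = []
    for (a, b), params in report.regression.items():
        pvals = report.regression_pvalues[(a, b)]
        row: dict = {"from": a, "to": b}
        for col in DESIGN_COLUMNS:
            if col in params.index:
                est = params[col]
                p = pvals[col]
                flag = "***" if p < 0.001 else ("*" if p < 0.05 else "")
                row[col] = round(float(est), 2)
                row[f"{col}_sig"] = flag
            else:
                row[col] = float("nan")
                row[f"{col}_sig"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: CohortReport, out_dir: str | Path, precision: int = 1) -> dict:
    """Write table4/5/6 analogues plus a structured JSON report.

    Returns the paths written. Percent values are held at full precision
    internally and rounded only here.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table4": out / "table4.csv",
        "table5": out / "table5.csv",
        "table6": out / "table6.csv",
        "report": out / "report.json",
    }
    _equation_table(report, precision).to_csv(paths["table4"], index=False)
    _pairwise_table(report, precision).to_csv(paths["table5"], index=False)
    _regression_table(report, precision).to_csv(paths["table6"], index=False)

    payload = {
        "n": report.n,
        "threshold": report.threshold,
        "correction_enabled": report.correction_enabled,
        "registry_hash": report.registry_hash,
        "seed": report.seed,
        "posthoc_method": report.posthoc_method,
        "quartile_convention": report.quartile_convention,
        "friedman": asdict(report.friedman),
        "n_reclassified_any": report.n_reclassified_any,
        "pct_reclassified_any": round(100 * report.frac_reclassified_any, precision),
        "equations": _equation_table(report, precision).to_dict(orient="records"),
        "pairwise": _pairwise_table(report, precision).to_dict(orient="records"),
    }
    paths["report"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
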