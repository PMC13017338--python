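"""Percent-predicted classification and inter-equation agreement statistics.

Measured peak V̇O2 is expressed as a percentage of each equation's
prediction (percent predicted); exercise capacity is classified as
normal when percent predicted meets a fixed threshold (80% by default).
Agreement between equations is summarized by Cohen's kappa with the
conventional interpretive bands, bidirectional reclassification counts,
quartiles of the absolute percent-predicted difference, a Friedman test
across all equations with Kendall's W effect size, and all-pairs
post hoc tests with a Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_THRESHOLD",
    "PercentPredicted",
    "CapacityClass",
    "FriedmanResult",
    "percent_predicted",
    "classify_capacity",
    "cohens_kappa",
    "kappa_band",
    "reclassification",
    "absolute_difference_summary",
    "friedman_test",
    "kendall_w_from_chi2",
    "pairwise_posthoc",
]

#: Conservative fixed cut-off for normal exercise capacity, percent predicted.
DEFAULT_THRESHOLD = 80.0

#: Interpretive bands for kappa, lower-edge inclusive.
KAPPA_BANDS = (
    (0.81, "almost perfect"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (0.01, "slight"),
    (-math.inf, "none"),
)


@dataclass(frozen=True)
class PercentPredicted:
    """Percent-predicted V̇O2peak: continuous value plus display integer.

    The dashboard display convention truncates (floor), so 68.33% shows
    as 68 and 114.64% as 114. Classification always uses ``value``.
    """

    value: float

    @property
    def display(self) -> int:
        return math.floor(self.value)


@dataclass(frozen=True)
class CapacityClass:
    label: str  # "normal" | "reduced"
    threshold: float


@dataclass(frozen=True)
class FriedmanResult:
    """Friedman rank test over n subjects × k equations.

    ``kendall_w`` = chi2 / (n·(k−1)) is the effect size (Kendall's
    coefficient of concordance).
    """

    chi2: float
    df: int
    p_value: float
    kendall_w: float
    n: int
    k: int


def percent_predicted(measured: float, predicted: float) -> PercentPredicted:
    """measured / predicted × 100, both in mL/min."""
    if predicted <= 0:
        raise ValueError(f"predicted V̇O2 must be positive, got {predicted!r}")
    if measured <= 0:
        raise ValueError(f"measured V̇O2 must be positive, got {measured!r}")
    return PercentPredicted(measured / predicted * 100.0)


def classify_capacity(
    pp: PercentPredicted | float, threshold: float = DEFAULT_THRESHOLD
) -> CapacityClass:
    """Normal iff the continuous percent-predicted value is ≥ threshold."""
    if not (0 < threshold < 200):
        raise ValueError(f"threshold {threshold!r} outside (0, 200)")
    value = pp.value if isinstance(pp, PercentPredicted) else float(pp)
    label = "normal" if value >= threshold else "reduced"
    return CapacityClass(label=label, threshold=threshold)


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary classifications.

    κ = (po − pe) / (1 − pe) with pe from the marginal products. Perfect
    observed agreement returns exactly 1, including the degenerate case
    of two identical constant raters (pe = 1).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two paired labels")
    po = float(np.mean(a == b))
    if po == 1.0:
        return 1.0
    categories = np.union1d(a, b)
    pe = 0.0
    for cat in categories:
        pe += float(np.mean(a == cat)) * float(np.mean(b == cat))
    return (po - pe) / (1.0 - pe)


def kappa_band(kappa: float) -> str:
    """Interpretive label for a kappa value (half-open bands)."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa {kappa!r} outside [-1, 1]")
    for lower, label in KAPPA_BANDS:
        if kappa >= lower:
            return label
    raise AssertionError("unreachable")


def _labels(pp: np.ndarray, threshold: float) -> np.ndarray:
    return pp >= threshold  # True = normal


def reclassification(
    pp_a, pp_b, threshold: float = DEFAULT_THRESHOLD
) -> tuple[int, int, float]:
    """Counts of subjects whose class flips between two equations.

    Returns ``(n_to_normal, n_to_reduced, fraction_reclassified)`` where
    ``n_to_normal`` counts subjects reduced under A but normal under B,
    and vice versa for ``n_to_reduced``.
    """
    a = np.asarray(pp_a, dtype=float)
    b = np.asarray(pp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("percent-predicted vectors must be 1-D and of equal length")
    normal_a = _labels(a, threshold)
    normal_b = _labels(b, threshold)
    n_to_normal = int(np.sum(~normal_a & normal_b))
    n_to_reduced = int(np.sum(normal_a & ~normal_b))
    frac = (n_to_normal + n_to_reduced) / a.size if a.size else 0.0
    return n_to_normal, n_to_reduced, frac


def absolute_difference_summary(pp_a, pp_b) -> tuple[float, float, float]:
    """Median and quartiles of |pp_a − pp_b| (linear interpolation)."""
    a = np.asarray(pp_a, dtype=float)
    b = np.asarray(pp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("percent-predicted vectors must be 1-D, equal, non-empty")
    ad = np.abs(a - b)
    q1, med, q3 = np.percentile(ad, [25, 50, 75])
    return float(med), float(q1), float(q3)


def kendall_w_from_chi2(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance as the Friedman effect size.

    W = χ² / (n·(k−1)) for n subjects ranked over k conditions.
    """
    if n < 2 or k < 2:
        raise ValueError(f"need n ≥ 2 and k ≥ 2, got n={n}, k={k}")
    if chi2 < 0:
        raise ValueError(f"chi2 must be non-negative, got {chi2!r}")
    return chi2 / (n * (k - 1))


def friedman_test(pp_matrix) -> FriedmanResult:
    """Friedman rank test on an n-subjects × k-equations matrix.

    Within-subject ranks (mean ranks on ties) give column rank sums R_j;
    χ² = 12/(n·k·(k+1))·ΣR_j² − 3n(k+1), referred to a χ² distribution
    with k−1 degrees of freedom. No tie correction is applied, so W =
    χ²/(n(k−1)) is exactly the mean Spearman-concordance effect size.
    """
    m = np.asarray(pp_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("pp_matrix must be 2-D (subjects × equations)")
    n, k = m.shape
    if n < 2 or k < 3:
        raise ValueError(f"need n ≥ 2 subjects and k ≥ 3 equations, got {n}×{k}")
    if not np.isfinite(m).all():
        raise ValueError("pp_matrix contains missing or non-finite cells")
    ranks = stats.rankdata(m, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)  # guard tiny negative round-off under heavy ties
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    w = kendall_w_from_chi2(chi2, n, k)
    return FriedmanResult(chi2=chi2, df=df, p_value=p, kendall_w=w, n=n, k=k)


def pairwise_posthoc(
    pp_matrix, equation_ids: list[str] | None = None
) -> dict[tuple[str, str], float]:
    """All-pairs post hoc tests with a Bonferroni adjustment.

    Each pair is compared with a paired Wilcoxon signed-rank test on the
    percent-predicted differences; raw p-values are multiplied by the
    number of pairs and capped at 1. A pair with all-zero differences is
    reported as p = 1 by convention.
    """
    m = np.asarray(pp_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("pp_matrix must be n≥2 × k≥3")
    if not np.isfinite(m).all():
        raise ValueError("pp_matrix contains missing or non-finite cells")
    k = m.shape[1]
    ids = equation_ids if equation_ids is not None else [str(j) for j in range(k)]
    if len(ids) != k:
        raise ValueError("equation_ids length must match the number of columns")
    pairs = list(combinations(range(k), 2))
    n_pairs = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for i, j in pairs:
        diff = m[:, i] - m[:, j]
        if np.all(diff == 0):
            raw = 1.0
        else:
            raw = float(stats.wilcoxon(m[:, i], m[:, j], zero_method="wilcox").pvalue)
        out[(ids[i], ids[j])] = min(1.0, raw * n_pairs)
    return out
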