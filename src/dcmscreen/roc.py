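"""Empirical ROC analysis and Youden-index cutoff selection.

Both screening tests used here are *negatively oriented*: lower values
(fewer grip-and-release cycles, weaker grip) indicate disease, and a
measurement is called abnormal when it is **at or below** the cutoff.  All
routines in this module fix that orientation rather than taking it as a
parameter, so sensitivities are P(case value <= t) and specificities
P(control value > t).

The empirical AUC is the Mann-Whitney pair-counting statistic

    AUC = P(case < control) + 1/2 P(case = control),

which equals the trapezoidal area under the empirical ROC staircase; ties
receive weight 1/2 (relevant here because repetition counts are integers
with heavy ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import InsufficientDataError

__all__ = [
    "AucResult",
    "RocCurve",
    "CutoffResult",
    "empirical_auc",
    "roc_curve",
    "youden_cutoff",
    "likelihood_ratios",
    "binormal_auc",
]


@dataclass(frozen=True)
class AucResult:
    auc: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC staircase under the "value <= threshold is positive" rule.

    ``thresholds[0]`` is a ``-inf`` sentinel below every observation (nothing
    positive), so the curve always starts at (0, 0) and ends at (1, 1).
    """

    thresholds: np.ndarray  # ascending candidate cutoffs, -inf sentinel first
    fpr: np.ndarray  # 1 - specificity at each threshold
    tpr: np.ndarray  # sensitivity at each threshold

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def trapezoidal_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass(frozen=True)
class CutoffResult:
    """A selected cutoff with its operating characteristics.

    ``lr_pos`` is ``inf`` when specificity is exactly 1 (the false-positive
    denominator vanishes); ``lr_neg`` is NaN when specificity is 0.
    """

    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec) and LR- = (1-sens)/spec with degenerate handling.

    At specificity 1, LR+ is +inf when sensitivity is positive and NaN when
    both numerator and denominator vanish.  At specificity 0, LR- is NaN.
    """
    if math.isnan(sensitivity) or math.isnan(specificity):
        return math.nan, math.nan
    if specificity >= 1.0:
        lr_pos = math.inf if sensitivity > 0 else math.nan
    else:
        lr_pos = sensitivity / (1.0 - specificity)
    lr_neg = (1.0 - sensitivity) / specificity if specificity > 0 else math.nan
    return lr_pos, lr_neg


def _as_groups(case_values: Sequence[float], control_values: Sequence[float]):
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise InsufficientDataError("both case and control groups must be nonempty")
    return cases, controls


def empirical_auc(
    case_values: Sequence[float], control_values: Sequence[float]
) -> AucResult:
    """Mann-Whitney empirical AUC with lower-value-indicates-disease orientation.

    Computed from midranks in O(n log n); exactly equals brute-force pair
    counting with ties weighted 1/2.
    """
    cases, controls = _as_groups(case_values, control_values)
    ranks = rankdata(np.concatenate([cases, controls]))
    r_controls = ranks[cases.size:].sum()
    u = r_controls - controls.size * (controls.size + 1) / 2.0
    return AucResult(
        auc=float(u / (cases.size * controls.size)),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def roc_curve(
    case_values: Sequence[float], control_values: Sequence[float]
) -> RocCurve:
    """Empirical ROC staircase over the distinct observed values."""
    cases, controls = _as_groups(case_values, control_values)
    cases_sorted = np.sort(cases)
    controls_sorted = np.sort(controls)
    observed = np.unique(np.concatenate([cases_sorted, controls_sorted]))
    thresholds = np.concatenate([[-np.inf], observed])
    tpr = np.searchsorted(cases_sorted, thresholds, side="right") / cases.size
    fpr = np.searchsorted(controls_sorted, thresholds, side="right") / controls.size
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def youden_cutoff(
    case_values: Sequence[float],
    control_values: Sequence[float],
    tie_rule: str = "sensitivity",
) -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the distinct observed values: under the
    "abnormal if <= cutoff" rule every achievable operating point is reached
    at an observed value, and the selected cutoff is then an attainable
    measurement (an integer repetition count or a 0.5-kg grip value).

    When several thresholds tie on J, ``tie_rule="sensitivity"`` (default)
    prefers the higher-sensitivity point — i.e. the largest cutoff, fitting
    a screening tool meant to avoid missed cases — while
    ``tie_rule="specificity"`` prefers the smaller cutoff.

    J is maximized in exact integer arithmetic (confusion counts), so ties
    are detected without floating-point tolerance.
    """
    if tie_rule not in ("sensitivity", "specificity"):
        raise ValueError(f"unknown tie_rule: {tie_rule!r}")
    cases, controls = _as_groups(case_values, control_values)
    cases_sorted = np.sort(cases)
    controls_sorted = np.sort(controls)
    thresholds = np.unique(np.concatenate([cases_sorted, controls_sorted]))
    n1, n0 = cases.size, controls.size
    tp = np.searchsorted(cases_sorted, thresholds, side="right")
    fp = np.searchsorted(controls_sorted, thresholds, side="right")
    tn = n0 - fp
    # J * n1 * n0, as an integer: tp*n0 + tn*n1 - n1*n0
    score = tp * n0 + tn * n1
    best = np.flatnonzero(score == score.max())
    # sensitivity is nondecreasing in the threshold, so the last tied index
    # is simultaneously the max-sensitivity and largest-cutoff choice
    idx = best[-1] if tie_rule == "sensitivity" else best[0]
    sens = float(tp[idx] / n1)
    spec = float(tn[idx] / n0)
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return CutoffResult(
        cutoff=float(thresholds[idx]),
        youden_j=float(sens + spec - 1.0),
        sensitivity=float(sens),
        specificity=float(spec),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
    )


def binormal_auc(mu_case: float, sd_case: float, mu_control: float, sd_control: float) -> float:
    """Closed-form AUC when both groups are normal: Phi(|mu0-mu1| / sqrt(s0^2+s1^2)).

    Used as the large-sample limit against which the empirical AUC of
    simulated cohorts is checked.
    """
    delta = abs(mu_control - mu_case)
    return float(norm.cdf(delta / math.hypot(sd_case, sd_control)))
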