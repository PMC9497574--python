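"""Publication-style formatting of analysis outputs.

Reports round to conventional display precision — proportions and
likelihood ratios to 2 decimals, means/SDs to 1 — with half-up rounding so
printed values match the usual clinical-table convention (banker's rounding
would print 0.125 as 0.12).  JSON/CSV outputs keep full precision; rounding
is display-only.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "round_half_up",
    "fmt_proportion",
    "fmt_lr",
    "fmt_mean_sd",
    "format_performance_table",
    "format_derive_report",
    "format_summary_table",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13 at 2 digits)."""
    if math.isnan(value) or math.isinf(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_proportion(value: float) -> str:
    if math.isnan(value):
        return "NA"
    return f"{round_half_up(value, 2):.2f}"


def fmt_lr(value: float) -> str:
    """Likelihood ratios to 2 dp; an infinite LR+ prints as ``inf``."""
    if math.isnan(value):
        return "NA"
    if math.isinf(value):
        return "inf"
    return f"{round_half_up(value, 2):.2f}"


def fmt_mean_sd(mean: float, sd: float) -> str:
    if math.isnan(mean):
        return "NA"
    sd_part = "NA" if math.isnan(sd) else f"{round_half_up(sd, 1):.1f}"
    return f"{round_half_up(mean, 1):.1f} ± {sd_part}"


def _has_inf_lr(frame: pd.DataFrame) -> bool:
    return bool((frame["lr_pos"] == math.inf).any())


_INF_FOOTNOTE = (
    "inf: specificity is 1.00, so the LR+ denominator (1 - specificity) is 0."
)


def format_performance_table(frame: pd.DataFrame) -> str:
    """Text rendering of an evaluation table (per stratum plus total)."""
    lines = [
        f"{'Sex':<8}{'Age (y)':<9}{'Sens':>6}{'Spec':>6}{'LR+':>8}{'LR-':>8}"
        f"{'TP':>5}{'FP':>5}{'FN':>5}{'TN':>5}"
    ]
    lines.append("-" * len(lines[0]))
    for _, row in frame.iterrows():
        lines.append(
            f"{row['sex']:<8}{row['age_band']:<9}"
            f"{fmt_proportion(row['sensitivity']):>6}"
            f"{fmt_proportion(row['specificity']):>6}"
            f"{fmt_lr(row['lr_pos']):>8}{fmt_lr(row['lr_neg']):>8}"
            f"{row['tp']:>5}{row['fp']:>5}{row['fn']:>5}{row['tn']:>5}"
        )
    if _has_inf_lr(frame):
        lines.append(_INF_FOOTNOTE)
    return "\n".join(lines)


def format_derive_report(frame: pd.DataFrame) -> str:
    """Text rendering of the per-stratum single-test derivation report."""
    lines = [
        f"{'Sex':<8}{'Age (y)':<9}{'Test':<6}{'AUC':>6}{'Cutoff':>8}"
        f"{'Sens':>6}{'Spec':>6}{'LR+':>8}{'LR-':>8}"
    ]
    lines.append("-" * len(lines[0]))
    for _, row in frame.iterrows():
        cutoff = row["cutoff"]
        cutoff_s = str(int(cutoff)) if cutoff == int(cutoff) else f"{cutoff:g}"
        lines.append(
            f"{row['sex']:<8}{row['age_band']:<9}{row['test']:<6}"
            f"{fmt_proportion(row['auc']):>6}{cutoff_s:>8}"
            f"{fmt_proportion(row['sensitivity']):>6}"
            f"{fmt_proportion(row['specificity']):>6}"
            f"{fmt_lr(row['lr_pos']):>8}{fmt_lr(row['lr_neg']):>8}"
        )
    if _has_inf_lr(frame):
        lines.append(_INF_FOOTNOTE)
    return "\n".join(lines)


def format_summary_table(frame: pd.DataFrame) -> str:
    """Text rendering of the stratum descriptive table (mean ± SD, n, p)."""
    lines = [
        f"{'Sex':<8}{'Age (y)':<9}{'Test':<6}{'n ctrl':>7}{'n DCM':>7}"
        f"{'Control':>13}{'DCM':>13}{'p':>10}"
    ]
    lines.append("-" * len(lines[0]))
    for _, row in frame.iterrows():
        p = row["p_value"]
        p_s = "NA" if math.isnan(p) else ("<0.0001" if p < 1e-4 else f"{p:.4f}")
        lines.append(
            f"{row['sex']:<8}{row['age_band']:<9}{row['test']:<6}"
            f"{row['n_control']:>7}{row['n_dcm']:>7}"
            f"{fmt_mean_sd(row['mean_control'], row['sd_control']):>13}"
            f"{fmt_mean_sd(row['mean_dcm'], row['sd_dcm']):>13}"
            f"{p_s:>10}"
        )
    return "\n".join(lines)
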