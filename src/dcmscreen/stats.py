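"""Descriptive stratum summaries and the between-group rank-sum comparison."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Group, StratumKey, SubjectScore
from .errors import InsufficientDataError

__all__ = ["StratumSummary", "summarize", "summary_frame", "rank_sum_test"]

logger = logging.getLogger(__name__)

# exact enumeration is feasible and exact (even with ties) up to here
_EXACT_MAX_N = 10


@dataclass(frozen=True)
class StratumSummary:
    """n / mean / sample SD of one test in one (stratum, group) cell.

    ``sd`` is the n-1 (sample) standard deviation; NaN for singleton cells.
    """

    stratum: StratumKey
    group: Group
    test: str  # "grt" or "grip"
    n: int
    mean: float
    sd: float


def summarize(cohort: Sequence[SubjectScore]) -> list[StratumSummary]:
    """Per-(stratum, group, test) descriptive statistics of worse-hand scores."""
    if not cohort:
        raise InsufficientDataError("cannot summarize an empty cohort")
    cells: dict[tuple[StratumKey, Group], list[SubjectScore]] = {}
    for s in cohort:
        cells.setdefault((s.stratum, s.group), []).append(s)
    out: list[StratumSummary] = []
    for (stratum, group), members in sorted(cells.items()):
        for test, attr in (("grt", "grt_min"), ("grip", "grip_min")):
            values = np.array([getattr(m, attr) for m in members], dtype=float)
            sd = float(np.std(values, ddof=1)) if values.size > 1 else math.nan
            if values.size == 1:
                logger.warning(
                    "stratum %s/%s: single subject, SD undefined",
                    stratum.label(), group.value,
                )
            out.append(
                StratumSummary(
                    stratum=stratum,
                    group=group,
                    test=test,
                    n=int(values.size),
                    mean=float(values.mean()),
                    sd=sd,
                )
            )
    return out


def summary_frame(
    cohort: Sequence[SubjectScore], with_p: bool = True
) -> pd.DataFrame:
    """Stratum-by-group summary table, optionally with rank-sum p-values.

    One row per (stratum, test) with control and DCM columns side by side,
    mirroring the usual two-group descriptive table.  The p-value compares
    control vs DCM worse-hand scores and is NaN when a cell is empty.
    """
    summaries = summarize(cohort)
    by_key: dict[tuple[StratumKey, str], dict[Group, StratumSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.stratum, s.test), {})[s.group] = s
    values: dict[tuple[StratumKey, Group], dict[str, list[float]]] = {}
    for s in cohort:
        cell = values.setdefault((s.stratum, s.group), {"grt": [], "grip": []})
        cell["grt"].append(s.grt_min)
        cell["grip"].append(s.grip_min)
    rows = []
    for (stratum, test), groups in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        ctrl = groups.get(Group.CONTROL)
        dcm = groups.get(Group.DCM)
        p = math.nan
        if with_p and ctrl is not None and dcm is not None:
            p = rank_sum_test(
                values[(stratum, Group.CONTROL)][test],
                values[(stratum, Group.DCM)][test],
            )
        rows.append(
            {
                "sex": stratum.sex.value,
                "age_band": stratum.age_band.value,
                "test": test,
                "n_control": ctrl.n if ctrl else 0,
                "n_dcm": dcm.n if dcm else 0,
                "mean_control": ctrl.mean if ctrl else math.nan,
                "sd_control": ctrl.sd if ctrl else math.nan,
                "mean_dcm": dcm.mean if dcm else math.nan,
                "sd_dcm": dcm.sd if dcm else math.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Small samples (both n <= 10) use exact enumeration of all group
    assignments, which remains exact under ties; larger samples use the
    normal approximation with midrank tie-corrected variance and continuity
    correction (repetition counts are integers, so ties are heavy).  If
    every value in both groups is identical the p-value is 1 by convention.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("rank-sum test needs two nonempty samples")
    if np.unique(np.concatenate([x, y])).size == 1:
        return 1.0
    if x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N:
        # full enumeration: C(n_a+n_b, n_a) <= C(20,10) = 184,756 splits
        method = sps.PermutationMethod(n_resamples=200_000)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.pvalue)
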