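"""The screening rule: cutoff tables, classification and performance.

A subject is screened with two negatively-oriented tests.  Each test is
*abnormal* when the worse-hand value is at or below the stratum-specific
cutoff, and the combined tool flags a subject *positive* when **either**
test is abnormal (a parallel / OR combination).  Relative to each component
test this raises sensitivity and lowers specificity — the intended
trade-off for a screening instrument whose job is not to miss cases.

Performance is evaluated against case-control status (the DCM surgical
group is the condition-positive class), per stratum and pooled.  Pooled
metrics come from the elementwise sum of the stratum confusion tables — a
single overall 2x2 — never from averaging stratum-level proportions.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ALL_STRATA, AgeBand, Group, Sex, StratumKey, SubjectScore
from .errors import ConfigurationError, InsufficientDataError
from .reference import REFERENCE_CUTOFFS
from .roc import CutoffResult, empirical_auc, likelihood_ratios, youden_cutoff

__all__ = [
    "Classification",
    "Verdict",
    "TestSelector",
    "CutoffTable",
    "ConfusionTable",
    "ToolPerformance",
    "classify_single",
    "classify_combined",
    "evaluate_rule",
    "derive_tool",
    "derive_report",
    "split_cohort",
]


class Classification(str, enum.Enum):
    ABNORMAL = "abnormal"
    NORMAL = "normal"


class Verdict(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class TestSelector(str, enum.Enum):
    """Which test(s) drive the positive call in :func:`evaluate_rule`."""

    GRT_ONLY = "grt_only"
    GRIP_ONLY = "grip_only"
    COMBINED = "combined"


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with DCM as the condition-positive class.

    Metrics whose denominator is zero are NaN — flagged undefined rather
    than silently dropped.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def lr_pos(self) -> float:
        return likelihood_ratios(self.sensitivity, self.specificity)[0]

    @property
    def lr_neg(self) -> float:
        return likelihood_ratios(self.sensitivity, self.specificity)[1]

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class CutoffTable:
    """Stratum-specific cutoffs: the screening tool itself.

    ``cutoffs`` maps each stratum to ``(grt_cutoff, grip_cutoff)`` —
    repetitions per 10 s and kg respectively.  A table derived from a
    partial cohort may cover fewer than the eight strata; classifying a
    subject from an uncovered stratum is a configuration error.
    """

    cutoffs: Mapping[StratumKey, tuple[float, float]]

    @classmethod
    def published(cls) -> "CutoffTable":
        """The cutoff table reported by the tool's development study."""
        return cls(dict(REFERENCE_CUTOFFS))

    def __contains__(self, stratum: StratumKey) -> bool:
        return stratum in self.cutoffs

    def __getitem__(self, stratum: StratumKey) -> tuple[float, float]:
        try:
            return self.cutoffs[stratum]
        except KeyError:
            raise ConfigurationError(
                f"cutoff table has no entry for stratum {stratum.label()}"
            ) from None

    def is_complete(self) -> bool:
        return all(s in self.cutoffs for s in ALL_STRATA)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        entries = [
            {
                "sex": s.sex.value,
                "age_band": s.age_band.value,
                "grt_cutoff": grt,
                "grip_cutoff": grip,
            }
            for s, (grt, grip) in sorted(self.cutoffs.items())
        ]
        return json.dumps({"cutoffs": entries}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CutoffTable":
        payload = json.loads(text)
        cutoffs = {}
        for e in payload["cutoffs"]:
            key = StratumKey(Sex(e["sex"]), AgeBand(e["age_band"]))
            cutoffs[key] = (float(e["grt_cutoff"]), float(e["grip_cutoff"]))
        return cls(cutoffs)

    @classmethod
    def load(cls, path: str | Path) -> "CutoffTable":
        return cls.from_json(Path(path).read_text())

    def to_text(self) -> str:
        """Printable layout mirroring the published cutoff table."""
        lines = [
            f"{'Sex':<8}{'Age (y)':<10}{'GRT (times)':<13}{'Grip (kg)':<10}",
            "-" * 41,
        ]
        for sex in Sex:
            for band in AgeBand:
                key = StratumKey(sex, band)
                if key not in self.cutoffs:
                    continue
                grt, grip = self.cutoffs[key]
                lines.append(
                    f"{sex.value:<8}{band.value:<10}{_fmt_cut(grt):<13}{_fmt_cut(grip):<10}"
                )
        lines.append("A value equal to or below the cutoff is abnormal;")
        lines.append("either test abnormal makes the screen positive.")
        return "\n".join(lines)


def _fmt_cut(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else str(v)


@dataclass(frozen=True)
class ToolPerformance:
    """Per-stratum confusion tables plus the pooled overall table."""

    selector: TestSelector
    strata: Mapping[StratumKey, ConfusionTable]

    @property
    def pooled(self) -> ConfusionTable:
        out = ConfusionTable()
        for table in self.strata.values():
            out = out + table
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per stratum plus a pooled Total row."""
        rows = []
        for key in sorted(self.strata):
            rows.append(_perf_row(key.sex.value, key.age_band.value, self.strata[key]))
        rows.append(_perf_row("total", "", self.pooled))
        return pd.DataFrame(rows)


def _perf_row(sex: str, band: str, c: ConfusionTable) -> dict:
    return {
        "sex": sex,
        "age_band": band,
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "tn": c.tn,
        "sensitivity": c.sensitivity,
        "specificity": c.specificity,
        "lr_pos": c.lr_pos,
        "lr_neg": c.lr_neg,
    }


def classify_single(value: float, cutoff: float) -> Classification:
    """Abnormal iff the measured value is at or below the cutoff."""
    return Classification.ABNORMAL if value <= cutoff else Classification.NORMAL


def classify_combined(score: SubjectScore, table: CutoffTable) -> Verdict:
    """Positive iff either worse-hand test value is at or below its cutoff."""
    grt_cut, grip_cut = table[score.stratum]
    positive = (
        classify_single(score.grt_min, grt_cut) is Classification.ABNORMAL
        or classify_single(score.grip_min, grip_cut) is Classification.ABNORMAL
    )
    return Verdict.POSITIVE if positive else Verdict.NEGATIVE


def _is_positive(score: SubjectScore, table: CutoffTable, selector: TestSelector) -> bool:
    grt_cut, grip_cut = table[score.stratum]
    if selector is TestSelector.GRT_ONLY:
        return score.grt_min <= grt_cut
    if selector is TestSelector.GRIP_ONLY:
        return score.grip_min <= grip_cut
    return score.grt_min <= grt_cut or score.grip_min <= grip_cut


def evaluate_rule(
    cohort: Sequence[SubjectScore],
    table: CutoffTable,
    selector: TestSelector | str = TestSelector.COMBINED,
) -> ToolPerformance:
    """Diagnostic performance of a cutoff table on a scored cohort.

    Counts are accumulated per stratum; strata lacking cases or controls
    keep their counts but their undefined proportions surface as NaN.  Any
    stratum present in the cohort must be covered by ``table``.
    """
    selector = TestSelector(selector)
    if not cohort:
        raise InsufficientDataError("cannot evaluate an empty cohort")
    counts: dict[StratumKey, dict[str, int]] = {}
    for s in cohort:
        cell = counts.setdefault(s.stratum, {"tp": 0, "fp": 0, "fn": 0, "tn": 0})
        positive = _is_positive(s, table, selector)
        if s.group is Group.DCM:
            cell["tp" if positive else "fn"] += 1
        else:
            cell["fp" if positive else "tn"] += 1
    strata = {k: ConfusionTable(**v) for k, v in counts.items()}
    return ToolPerformance(selector=selector, strata=strata)


def _split_by_group(
    cohort: Sequence[SubjectScore],
) -> dict[StratumKey, dict[Group, list[SubjectScore]]]:
    cells: dict[StratumKey, dict[Group, list[SubjectScore]]] = {}
    for s in cohort:
        cells.setdefault(s.stratum, {}).setdefault(s.group, []).append(s)
    return cells


def derive_tool(
    cohort: Sequence[SubjectScore],
    tie_rule: str = "sensitivity",
) -> CutoffTable:
    """Derive per-stratum Youden cutoffs for both tests from a cohort.

    Each test's cutoff is selected independently (per test, per stratum) by
    maximizing Youden's J over the stratum's observed worse-hand values.
    Every stratum present in the cohort must contain at least one case and
    one control.
    """
    if not cohort:
        raise InsufficientDataError("cannot derive cutoffs from an empty cohort")
    cutoffs: dict[StratumKey, tuple[float, float]] = {}
    for stratum, groups in sorted(_split_by_group(cohort).items()):
        cases = groups.get(Group.DCM, [])
        controls = groups.get(Group.CONTROL, [])
        if not cases or not controls:
            raise InsufficientDataError(
                f"stratum {stratum.label()}: needs both cases and controls "
                f"({len(cases)} cases, {len(controls)} controls)"
            )
        grt = youden_cutoff([s.grt_min for s in cases], [s.grt_min for s in controls], tie_rule)
        grip = youden_cutoff([s.grip_min for s in cases], [s.grip_min for s in controls], tie_rule)
        cutoffs[stratum] = (grt.cutoff, grip.cutoff)
    return CutoffTable(cutoffs)


def split_cohort(
    cohort: Sequence[SubjectScore],
    test_fraction: float,
    seed: int = 0,
) -> tuple[list[SubjectScore], list[SubjectScore]]:
    """Stratified train/test split for held-out evaluation.

    Sampling is stratified on (stratum, group) so each cell keeps its
    case-control balance.  The default workflow is resubstitution
    (derive and evaluate on the same cohort); use this helper to measure
    the optimism of that choice: ``derive_tool(train)`` then
    ``evaluate_rule(test, ...)``.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ConfigurationError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    train: list[SubjectScore] = []
    test: list[SubjectScore] = []
    for _, groups in sorted(_split_by_group(cohort).items()):
        for _, members in sorted(groups.items()):
            n_test = int(round(test_fraction * len(members)))
            picks = set(rng.choice(len(members), size=n_test, replace=False))
            for i, s in enumerate(members):
                (test if i in picks else train).append(s)
    return train, test


def derive_report(
    cohort: Sequence[SubjectScore],
    tie_rule: str = "sensitivity",
) -> pd.DataFrame:
    """Per-stratum, per-test AUC and Youden-cutoff operating characteristics.

    One row per (stratum, test) with AUC, the selected cutoff, and its
    resubstitution sensitivity/specificity/likelihood ratios — the full
    single-test report from which a :class:`CutoffTable` is assembled.
    """
    if not cohort:
        raise InsufficientDataError("cannot derive cutoffs from an empty cohort")
    rows = []
    for stratum, groups in sorted(_split_by_group(cohort).items()):
        cases = groups.get(Group.DCM, [])
        controls = groups.get(Group.CONTROL, [])
        if not cases or not controls:
            raise InsufficientDataError(
                f"stratum {stratum.label()}: needs both cases and controls "
                f"({len(cases)} cases, {len(controls)} controls)"
            )
        for test, attr in (("grt", "grt_min"), ("grip", "grip_min")):
            case_vals = [getattr(s, attr) for s in cases]
            ctrl_vals = [getattr(s, attr) for s in controls]
            auc = empirical_auc(case_vals, ctrl_vals)
            cut: CutoffResult = youden_cutoff(case_vals, ctrl_vals, tie_rule)
            rows.append(
                {
                    "sex": stratum.sex.value,
                    "age_band": stratum.age_band.value,
                    "test": test,
                    "n_cases": auc.n_cases,
                    "n_controls": auc.n_controls,
                    "auc": auc.auc,
                    "cutoff": cut.cutoff,
                    "youden_j": cut.youden_j,
                    "sensitivity": cut.sensitivity,
                    "specificity": cut.specificity,
                    "lr_pos": cut.lr_pos,
                    "lr_neg": cut.lr_neg,
                }
            )
    return pd.DataFrame(rows)
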