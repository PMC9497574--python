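"""Reference values from the original development cohort of the tool.

These constants reproduce the published stratum-level summary statistics,
the derived cutoff table, and the reported diagnostic performance of the
screening rule in its development study (a single-center case-control
comparison of 247 surgical DCM patients against 721 health-checkup
controls).  They serve three purposes:

* parameterize the synthetic cohort generator (:mod:`dcmscreen.synthetic`)
  with realistic stratum means and SDs;
* ship the derived cutoff table so the screening rule can be applied to new
  subjects without re-derivation;
* provide published sensitivity/specificity pairs against which likelihood-
  ratio arithmetic can be cross-checked.

Only stratum-level summaries were ever published; no individual-level data
exist here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import AgeBand, Group, Sex, StratumKey

__all__ = [
    "ReferenceStratumStats",
    "REFERENCE_STRATUM_STATS",
    "REFERENCE_CUTOFFS",
    "ReportedPerformance",
    "REPORTED_GRT_PERFORMANCE",
    "REPORTED_GRIP_PERFORMANCE",
    "REPORTED_COMBINED_PERFORMANCE",
    "CONTROL_FLOW",
    "DCM_FLOW",
]


@dataclass(frozen=True)
class ReferenceStratumStats:
    """Published n / mean / SD for one (stratum, group) cell."""

    stratum: StratumKey
    group: Group
    n: int
    grt_mean: float
    grt_sd: float
    grip_mean: float
    grip_sd: float


def _cell(sex, band, group, n, grt_mean, grt_sd, grip_mean, grip_sd):
    return ReferenceStratumStats(
        StratumKey(sex, band), group, n, grt_mean, grt_sd, grip_mean, grip_sd
    )


_M, _F = Sex.MALE, Sex.FEMALE
_B1, _B2, _B3, _B4 = AgeBand.B40_59, AgeBand.B60_69, AgeBand.B70_79, AgeBand.B80_89
_CTRL, _DCM = Group.CONTROL, Group.DCM

#: Published per-cell summary statistics: GRT in repetitions/10 s, grip in kg.
REFERENCE_STRATUM_STATS: tuple[ReferenceStratumStats, ...] = (
    # controls
    _cell(_M, _B1, _CTRL, 82, 27.0, 5.6, 42.6, 7.7),
    _cell(_M, _B2, _CTRL, 62, 23.5, 4.7, 35.5, 7.8),
    _cell(_M, _B3, _CTRL, 97, 20.2, 5.2, 30.1, 7.5),
    _cell(_M, _B4, _CTRL, 34, 20.1, 5.0, 26.0, 5.7),
    _cell(_F, _B1, _CTRL, 119, 23.5, 4.8, 25.6, 6.8),
    _cell(_F, _B2, _CTRL, 132, 20.7, 4.7, 20.3, 4.6),
    _cell(_F, _B3, _CTRL, 154, 19.2, 4.8, 17.6, 4.8),
    _cell(_F, _B4, _CTRL, 41, 17.8, 4.3, 15.2, 3.8),
    # DCM (surgical) group
    _cell(_M, _B1, _DCM, 62, 18.5, 8.2, 23.3, 12.1),
    _cell(_M, _B2, _DCM, 48, 13.9, 6.0, 16.5, 9.1),
    _cell(_M, _B3, _DCM, 43, 15.0, 5.4, 16.5, 8.0),
    _cell(_M, _B4, _DCM, 12, 11.4, 4.7, 10.8, 6.6),
    _cell(_F, _B1, _DCM, 22, 16.6, 5.3, 14.5, 7.4),
    _cell(_F, _B2, _DCM, 18, 12.5, 4.8, 10.0, 6.2),
    _cell(_F, _B3, _DCM, 27, 12.2, 3.9, 8.5, 4.9),
    _cell(_F, _B4, _DCM, 15, 9.5, 3.8, 4.4, 4.0),
)

#: Published screening cutoffs: stratum -> (GRT repetitions, grip kg).
#: A measured value at or below the cutoff is abnormal.
REFERENCE_CUTOFFS: dict[StratumKey, tuple[float, float]] = {
    StratumKey(_M, _B1): (21, 32),
    StratumKey(_M, _B2): (17, 29),
    StratumKey(_M, _B3): (15, 21),
    StratumKey(_M, _B4): (11, 19),
    StratumKey(_F, _B1): (18, 20),
    StratumKey(_F, _B2): (17, 13),
    StratumKey(_F, _B3): (15, 15),
    StratumKey(_F, _B4): (12, 10),
}


@dataclass(frozen=True)
class ReportedPerformance:
    """Published diagnostic performance for one stratum (or pooled total).

    ``lr_consistent`` flags whether the printed LR+/LR- values are
    arithmetically consistent with the printed sensitivity/specificity pair;
    one published row (grip, male 40-59) carries LR values that cannot be
    derived from its printed sensitivity/specificity and is excluded from
    arithmetic cross-checks.  Pooled totals are computed from unpublished
    raw counts, so their printed LRs are not exactly recoverable from the
    rounded sensitivity/specificity either.
    """

    stratum: StratumKey | None  # None = pooled total
    auc: float | None
    cutoff: float | None
    sensitivity: float
    specificity: float
    lr_pos: float  # inf where specificity is 1.00
    lr_neg: float
    lr_consistent: bool = True


def _perf(sex, band, auc, cutoff, sens, spec, lrp, lrn, consistent=True):
    key = StratumKey(sex, band) if sex is not None else None
    return ReportedPerformance(key, auc, cutoff, sens, spec, lrp, lrn, consistent)


_INF = float("inf")

#: Published GRT-alone performance per stratum plus pooled total.
REPORTED_GRT_PERFORMANCE: tuple[ReportedPerformance, ...] = (
    _perf(_M, _B1, 0.82, 21, 0.68, 0.85, 4.53, 0.38),
    _perf(_M, _B2, 0.91, 17, 0.79, 0.90, 7.90, 0.23),
    _perf(_M, _B3, 0.75, 15, 0.58, 0.85, 3.87, 0.49),
    _perf(_M, _B4, 0.90, 11, 0.67, 1.00, _INF, 0.33),
    _perf(_F, _B1, 0.84, 18, 0.73, 0.89, 6.64, 0.30),
    _perf(_F, _B2, 0.91, 17, 0.94, 0.64, 2.61, 0.09),
    _perf(_F, _B3, 0.87, 15, 0.78, 0.75, 3.12, 0.29),
    _perf(_F, _B4, 0.92, 12, 0.87, 0.93, 12.43, 0.14),
    _perf(None, None, None, None, 0.73, 0.83, 4.31, 0.33, False),
)

#: Published grip-strength-alone performance per stratum plus pooled total.
REPORTED_GRIP_PERFORMANCE: tuple[ReportedPerformance, ...] = (
    # sens/spec cells of this row are inconsistent with its printed LRs
    _perf(_M, _B1, 0.92, 32, 0.68, 0.85, 11.57, 0.20, False),
    _perf(_M, _B2, 0.94, 29, 0.96, 0.81, 5.05, 0.05),
    _perf(_M, _B3, 0.89, 21, 0.70, 0.91, 7.78, 0.33),
    _perf(_M, _B4, 0.97, 19, 0.83, 0.94, 13.83, 0.18),
    _perf(_F, _B1, 0.87, 20, 0.73, 0.82, 4.06, 0.33),
    _perf(_F, _B2, 0.91, 13, 0.78, 0.96, 19.50, 0.23),
    _perf(_F, _B3, 0.91, 15, 0.96, 0.71, 3.31, 0.06),
    _perf(_F, _B4, 0.97, 10, 0.93, 0.90, 9.30, 0.08),
    _perf(None, None, None, None, 0.83, 0.86, 5.78, 0.19, False),
)

#: Published performance of the combined (either-test-abnormal) rule.
REPORTED_COMBINED_PERFORMANCE: tuple[ReportedPerformance, ...] = (
    _perf(_M, _B1, None, None, 0.90, 0.82, 4.94, 0.12, False),
    _perf(_M, _B2, None, None, 0.96, 0.74, 3.71, 0.06, False),
    _perf(_M, _B3, None, None, 0.79, 0.78, 3.65, 0.27, False),
    _perf(_M, _B4, None, None, 0.92, 0.94, 15.58, 0.09, False),
    _perf(_F, _B1, None, None, 0.91, 0.77, 4.01, 0.12, False),
    _perf(_F, _B2, None, None, 0.94, 0.70, 3.20, 0.08, False),
    # sens 1.00 forces LR- = 0.00 exactly, but the printed LR+ (2.26) needs
    # the unrounded specificity, so the full row is flagged inconsistent
    _perf(_F, _B3, None, None, 1.00, 0.56, 2.26, 0.00, False),
    _perf(_F, _B4, None, None, 0.93, 0.83, 5.47, 0.08, False),
    _perf(None, None, None, None, 0.91, 0.73, 3.37, 0.12, False),
)

#: Recruitment-flow counts for the control arm: screened minus exclusions.
CONTROL_FLOW = {
    "screened": 995,
    "excluded_cerebrovascular": 7,
    "excluded_possible_myelopathy": 212,
    "excluded_missing_data": 55,
}

#: Recruitment-flow counts for the DCM (surgical) arm.
DCM_FLOW = {
    "screened": 361,
    "excluded_clinical": 100,
    "excluded_missing_data": 14,
}


def analyzable_n(flow: dict[str, int]) -> int:
    """Screened count minus all exclusion counts."""
    return flow["screened"] - sum(v for k, v in flow.items() if k != "screened")
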