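"""Synthetic screening cohorts with published stratum-level structure.

No individual-level data from the development study were ever deposited;
only per-stratum sample sizes, means and SDs are public.  This module
generates cohorts that match exactly those published moments so every
downstream stage — scoring, ROC/Youden derivation, rule evaluation — can be
exercised end to end.

Per (stratum, group) cell, each subject's latent (GRT, grip) pair is drawn
from a bivariate normal with the cell's marginal means/SDs and a
within-subject correlation ``rho``.  The published tables report no
correlation between the two tests, but the combined OR-rule's performance
depends on it, so ``rho`` is a first-class parameter (default 0.5: both
tests measure overlapping aspects of hand function, so moderate positive
correlation is the realistic middle ground between redundant tests at
rho -> 1 and independent tests at rho = 0).

Two post-processing modes:

``raw``
    Latent values emitted untouched (continuous, possibly negative).  Use
    for distributional checks: moments and AUC converge to the binormal
    closed forms.
``realistic``
    Subjects whose latent pair has any negative component are redrawn until
    both are nonnegative (truncation by resampling — clamping would pile a
    point mass at zero and distort ROC tie structure), then GRT is rounded
    to an integer and grip to the 0.5-kg instrument grid.  Output satisfies
    every :class:`~dcmscreen.cohort.SubjectRecord` invariant.

Laterality is not modeled: only worse-hand minima were ever published, so
both hands are emitted equal to the drawn value.  The per-side-minimum code
path still runs; it is simply the identity on these records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import AgeBand, Group, Sex, StratumKey, SubjectRecord
from .errors import ConfigurationError
from .reference import REFERENCE_STRATUM_STATS

__all__ = [
    "StratumParams",
    "table1_defaults",
    "simulate_stratum",
    "simulate_study",
    "params_to_frame",
    "load_params",
]

MODES = ("raw", "realistic")


@dataclass(frozen=True)
class StratumParams:
    """Generator parameters for one (stratum, group) cell.

    Means/SDs are on the measurement scales (repetitions per 10 s; kg);
    ``rho`` is the latent GRT-grip correlation in [-1, 1].
    """

    stratum: StratumKey
    group: Group
    n: int
    grt_mean: float
    grt_sd: float
    grip_mean: float
    grip_sd: float
    rho: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"{self.stratum.label()}/{self.group.value}: n must be >= 1")
        if self.grt_sd <= 0 or self.grip_sd <= 0:
            raise ConfigurationError(
                f"{self.stratum.label()}/{self.group.value}: sd must be positive"
            )
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError(f"rho={self.rho} outside [-1, 1]")


def table1_defaults(rho: float = 0.5) -> list[StratumParams]:
    """The 16 published (stratum, group) cells as generator parameters.

    Sample sizes, means and SDs equal the published stratum summaries
    (82 + 62 + 97 + 34 + 119 + 132 + 154 + 41 = 721 controls and
    62 + 48 + 43 + 12 + 22 + 18 + 27 + 15 = 247 DCM cases).
    """
    return [
        StratumParams(
            stratum=s.stratum,
            group=s.group,
            n=s.n,
            grt_mean=s.grt_mean,
            grt_sd=s.grt_sd,
            grip_mean=s.grip_mean,
            grip_sd=s.grip_sd,
            rho=rho,
        )
        for s in REFERENCE_STRATUM_STATS
    ]


def _draw_latent(
    rng: np.random.Generator, p: StratumParams, size: int
) -> np.ndarray:
    """Draw `size` latent (grt, grip) pairs from the cell's bivariate normal."""
    z = rng.standard_normal((size, 2))
    # correlate via Cholesky of [[1, rho], [rho, 1]]
    z2 = p.rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - p.rho**2)) * z[:, 1]
    grt = p.grt_mean + p.grt_sd * z[:, 0]
    grip = p.grip_mean + p.grip_sd * z2
    return np.column_stack([grt, grip])


def simulate_stratum(
    params: StratumParams,
    seed: int | np.random.SeedSequence,
    mode: str = "realistic",
    id_prefix: str | None = None,
) -> list[SubjectRecord]:
    """Generate one (stratum, group) cell of subjects.

    Ages are uniform integers over the stratum's band (published tables
    give no within-band age distribution).  Left and right measurements are
    both set to the drawn value; see the module docstring.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    rng = np.random.default_rng(seed)
    pairs = _draw_latent(rng, params, params.n)
    if mode == "realistic":
        # resample any subject with a negative component until both are >= 0
        bad = np.flatnonzero((pairs < 0).any(axis=1))
        while bad.size:
            pairs[bad] = _draw_latent(rng, params, bad.size)
            bad = bad[(pairs[bad] < 0).any(axis=1)]
        grt = np.rint(pairs[:, 0])
        grip = np.rint(pairs[:, 1] * 2.0) / 2.0
    else:
        grt = pairs[:, 0]
        grip = pairs[:, 1]
    lo, hi = params.stratum.age_band.bounds
    ages = rng.integers(lo, hi + 1, size=params.n)
    if id_prefix is None:
        id_prefix = (
            f"{params.group.value}-{params.stratum.sex.value[0]}"
            f"{params.stratum.age_band.value}"
        )
    return [
        SubjectRecord(
            subject_id=f"{id_prefix}-{i:05d}",
            group=params.group,
            sex=params.stratum.sex,
            age=int(ages[i]),
            grt_left=float(grt[i]),
            grt_right=float(grt[i]),
            grip_left=float(grip[i]),
            grip_right=float(grip[i]),
        )
        for i in range(params.n)
    ]


def simulate_study(
    params: Sequence[StratumParams],
    seed: int,
    mode: str = "realistic",
) -> list[SubjectRecord]:
    """Generate a full cohort, one cell per parameter entry.

    The master seed spawns one independent substream per cell (in the order
    given), so a cell's draw is stable under re-runs and independent of the
    other cells' sample sizes.  Duplicate (stratum, group) entries are a
    configuration error.
    """
    seen: set[tuple[StratumKey, Group]] = set()
    for p in params:
        key = (p.stratum, p.group)
        if key in seen:
            raise ConfigurationError(
                f"duplicate parameter entry for {p.stratum.label()}/{p.group.value}"
            )
        seen.add(key)
    streams = np.random.SeedSequence(seed).spawn(len(params))
    cohort: list[SubjectRecord] = []
    for p, stream in zip(params, streams):
        cohort.extend(simulate_stratum(p, stream, mode=mode))
    return cohort


# ---------------------------------------------------------------------------
# parameter-file I/O (CSV with one row per (stratum, group) cell)

_PARAM_COLUMNS = (
    "sex", "age_band", "group", "n",
    "grt_mean", "grt_sd", "grip_mean", "grip_sd", "rho",
)


def params_to_frame(params: Iterable[StratumParams]) -> pd.DataFrame:
    rows = [
        {
            "sex": p.stratum.sex.value,
            "age_band": p.stratum.age_band.value,
            "group": p.group.value,
            "n": p.n,
            "grt_mean": p.grt_mean,
            "grt_sd": p.grt_sd,
            "grip_mean": p.grip_mean,
            "grip_sd": p.grip_sd,
            "rho": p.rho,
        }
        for p in params
    ]
    return pd.DataFrame(rows, columns=list(_PARAM_COLUMNS))


def load_params(path: str | Path, rho: float | None = None) -> list[StratumParams]:
    """Read generator parameters from CSV; ``rho`` column optional.

    An explicit ``rho`` argument overrides any value in the file.
    """
    frame = pd.read_csv(path)
    required = set(_PARAM_COLUMNS) - {"rho"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(
            f"{path}: parameter file missing column(s): {', '.join(sorted(missing))}"
        )
    params = []
    for i, row in frame.iterrows():
        try:
            stratum = StratumKey(Sex(row["sex"]), AgeBand(str(row["age_band"])))
            group = Group(row["group"])
        except ValueError as err:
            raise ConfigurationError(f"{path}: line {i + 2}: {err}") from None
        row_rho = rho
        if row_rho is None:
            row_rho = float(row["rho"]) if "rho" in frame.columns else 0.5
        params.append(
            StratumParams(
                stratum=stratum,
                group=group,
                n=int(row["n"]),
                grt_mean=float(row["grt_mean"]),
                grt_sd=float(row["grt_sd"]),
                grip_mean=float(row["grip_mean"]),
                grip_sd=float(row["grip_sd"]),
                rho=row_rho,
            )
        )
    return params


def with_rho(params: Sequence[StratumParams], rho: float) -> list[StratumParams]:
    """Copy a parameter set with a different latent correlation."""
    return [replace(p, rho=rho) for p in params]
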