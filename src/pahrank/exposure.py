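"""Person-time at risk, per resident and per facility.

Exposure can be computed exactly from entry/death/exit dates, or via the
care-level mean-survival approximation: mean observed survival per care
level, multiplied by current resident head-counts. The approximation is the
route to take when only a census head-count (not individual follow-up) is
available for the rate denominator.

Year length is 365.25 days throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohort import Facility, FollowUpWindow, Resident
from .errors import ExposureError

logger = logging.getLogger("pahrank")

DAYS_PER_YEAR = 365.25


def person_time(resident: Resident, window: FollowUpWindow) -> float:
    """Years at risk within the window, floored at 0.

    Follow-up runs from max(entry, window start) to the earliest of death,
    exit (move-away, when recorded) and window end.
    """
    start = max(resident.entry_date, window.start_date)
    end = window.end_date
    if resident.death_date is not None:
        end = min(end, resident.death_date)
    if resident.exit_date is not None:
        end = min(end, resident.exit_date)
    return max(0, (end - start).days) / DAYS_PER_YEAR


@dataclass(frozen=True)
class MeanSurvivalTable:
    """Mean observed survival (years, censored at window end) per care level."""

    mean_years: dict[str, float]

    def __post_init__(self) -> None:
        for level, years in self.mean_years.items():
            if years <= 0:
                raise ExposureError(f"non-positive mean survival for level {level!r}")


def estimate_mean_survival(
    residents: list[Resident], window: FollowUpWindow
) -> MeanSurvivalTable:
    """Mean person-time per care level over the cohort.

    Survival is observed from window start to death and censored at the
    window end (no extrapolation). Care levels with no residents are simply
    absent; requesting them later raises from
    :func:`approximate_facility_person_time`.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in residents:
        t = person_time(r, window)
        sums[r.care_level] = sums.get(r.care_level, 0.0) + t
        counts[r.care_level] = counts.get(r.care_level, 0) + 1
    if not counts:
        raise ExposureError("no residents: cannot estimate mean survival")
    means = {lvl: sums[lvl] / counts[lvl] for lvl in counts}
    logger.info(
        "stage=mean_survival %s",
        " ".join(f"{lvl}={m:.3f}" for lvl, m in sorted(means.items())),
    )
    return MeanSurvivalTable(means)


def approximate_facility_person_time(
    care_level_counts: dict[str, int],
    table: MeanSurvivalTable,
    window: FollowUpWindow,
) -> float:
    """Head-count x mean-survival approximation of facility person-years.

    Each care level contributes count x min(mean survival, window length);
    the cap keeps the approximation inside the observation period. Linear
    in the counts by construction.
    """
    cap = window.years
    total = 0.0
    for level, count in care_level_counts.items():
        if level not in table.mean_years:
            raise ExposureError(f"no mean-survival entry for care level {level!r}")
        total += count * min(table.mean_years[level], cap)
    return total


@dataclass
class FacilityAggregate:
    """Per-facility summary used for modelling and ranking."""

    facility_id: str
    n_residents: int
    pah_count: int
    person_years: float
    covariate_props: dict[str, float] = field(default_factory=dict)
    care_level_counts: dict[str, int] = field(default_factory=dict)
    n_beds: int | None = None
    stratum: str | None = None
    flagged: bool = False  # zero residents or zero exposure


def aggregate_facility(
    facility: Facility,
    residents: list[Resident],
    pah_counts: dict[str, int],
    window: FollowUpWindow,
    mode: str = "exact",
    survival_table: MeanSurvivalTable | None = None,
) -> FacilityAggregate:
    """Aggregate one facility's residents into a :class:`FacilityAggregate`.

    ``mode='exact'`` sums individual person-time; ``mode='approximate'``
    applies the care-level mean-survival table to head-counts (the table is
    then required). Covariate proportions are resident means of every
    numeric covariate. Zero-resident facilities come back flagged with
    zeros rather than raising, so ranking can list them.
    """
    mine = [r for r in residents if r.facility_id == facility.facility_id]
    if not mine:
        logger.warning("stage=aggregate facility=%s residents=0 flagged=1",
                       facility.facility_id)
        return FacilityAggregate(
            facility.facility_id, 0, 0, 0.0, {}, {},
            n_beds=facility.n_beds, stratum=facility.stratum, flagged=True,
        )

    level_counts: dict[str, int] = {}
    for r in mine:
        level_counts[r.care_level] = level_counts.get(r.care_level, 0) + 1

    if mode == "exact":
        py = sum(person_time(r, window) for r in mine)
    elif mode == "approximate":
        if survival_table is None:
            raise ExposureError("approximate mode requires a MeanSurvivalTable")
        py = approximate_facility_person_time(level_counts, survival_table, window)
    else:
        raise ExposureError(f"unknown exposure mode {mode!r}")

    names = sorted({k for r in mine for k in r.covariates})
    props = {
        name: sum(r.covariates.get(name, 0.0) for r in mine) / len(mine)
        for name in names
    }
    pah = sum(pah_counts.get(r.resident_id, 0) for r in mine)
    return FacilityAggregate(
        facility_id=facility.facility_id,
        n_residents=len(mine),
        pah_count=pah,
        person_years=py,
        covariate_props=props,
        care_level_counts=level_counts,
        n_beds=facility.n_beds,
        stratum=facility.stratum,
        flagged=py <= 0,
    )


def aggregate_cohort(
    facilities: list[Facility],
    residents: list[Resident],
    pah_counts: dict[str, int],
    window: FollowUpWindow,
    mode: str = "exact",
    survival_table: MeanSurvivalTable | None = None,
) -> list[FacilityAggregate]:
    """Aggregate every facility; estimates the survival table when needed."""
    if mode == "approximate" and survival_table is None:
        survival_table = estimate_mean_survival(residents, window)
    aggs = [
        aggregate_facility(f, residents, pah_counts, window, mode, survival_table)
        for f in facilities
    ]
    logger.info(
        "stage=aggregate facilities=%d pah_total=%d person_years=%.2f",
        len(aggs), sum(a.pah_count for a in aggs), sum(a.person_years for a in aggs),
    )
    return aggs


__all__ = [
    "DAYS_PER_YEAR", "person_time", "MeanSurvivalTable", "estimate_mean_survival",
    "approximate_facility_person_time", "FacilityAggregate", "aggregate_facility",
    "aggregate_cohort",
]
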