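"""Domain types for the long-term-care cohort, and cohort filtering.

The unit structure mirrors how the data arise: residents are nested within
facilities, and hospital discharge events are nested within residents. A
follow-up window bounds the observation period; a cohort filter expresses
the eligibility rules applied before ranking (e.g. dropping facilities that
only provide high-level care).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

from .errors import EmptyCohortError

logger = logging.getLogger("pahrank")

#: Recognised residential care levels.
CARE_LEVELS = ("low", "high", "dementia", "psychogeriatric")

#: Recognised ownership categories.
OWNERSHIP = ("for_profit", "not_for_profit", "public")


@dataclass(frozen=True)
class Facility:
    """A residential aged-care facility.

    ``care_levels`` is the set of care levels the facility is certified to
    provide; ``stratum`` is an opaque regional label (a district health
    board analogue) used for stratified selection.
    """

    facility_id: str
    care_levels: frozenset[str]
    n_beds: int
    ownership: str
    chain_member: bool
    distance_to_hospital_km: float
    stratum: str

    def __post_init__(self) -> None:
        if not self.care_levels:
            raise ValueError(f"facility {self.facility_id}: care_levels empty")
        bad = set(self.care_levels) - set(CARE_LEVELS)
        if bad:
            raise ValueError(f"facility {self.facility_id}: unknown care levels {sorted(bad)}")
        if self.n_beds < 1:
            raise ValueError(f"facility {self.facility_id}: n_beds must be >= 1")
        if self.distance_to_hospital_km < 0:
            raise ValueError(f"facility {self.facility_id}: negative distance")


#: Binary resident covariates that the predictive model always expects;
#: absent columns are filled with 0.
REQUIRED_COVARIATES = (
    "gp_urgent_2wk",
    "ed_visit_prior_window",
    "prior_diabetes_admission",
    "prior_dementia_admission",
)


@dataclass
class Resident:
    """A resident, nested in a facility.

    ``covariates`` holds every numeric resident-level variable beyond the
    structural fields, including the four predictors retained by the
    case-mix model (present with default 0). ``exit_date``, when known,
    censors exposure at discharge/move-out.
    """

    resident_id: str
    facility_id: str
    care_level: str
    age_years: float
    sex: str
    entry_date: dt.date
    death_date: dt.date | None = None
    exit_date: dt.date | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.care_level not in CARE_LEVELS:
            raise ValueError(f"resident {self.resident_id}: unknown care level {self.care_level!r}")
        if self.age_years < 0:
            raise ValueError(f"resident {self.resident_id}: negative age")
        if self.death_date is not None and self.death_date < self.entry_date:
            raise ValueError(f"resident {self.resident_id}: death_date before entry_date")
        for name in REQUIRED_COVARIATES:
            self.covariates.setdefault(name, 0.0)


@dataclass(frozen=True)
class HospitalEvent:
    """One hospital discharge with its ordered diagnosis codes.

    ``diagnosis_codes[0]`` is the primary diagnosis; positions are preserved
    exactly as read because the PAH rule depends on them.
    """

    event_id: str
    resident_id: str
    admission_date: dt.date
    acute: bool
    diagnosis_codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class FollowUpWindow:
    """Half-open observation window [start_date, end_date)."""

    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")

    @property
    def days(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def years(self) -> float:
        return self.days / 365.25

    def contains(self, day: dt.date) -> bool:
        return self.start_date <= day < self.end_date


@dataclass(frozen=True)
class CohortFilter:
    """Eligibility rules, composed conjunctively.

    ``whole_facility=True`` reproduces the published rule: any facility
    providing an excluded care level is dropped entirely. The default finer
    rule drops only residents in excluded levels and keeps mixed facilities
    that retain at least ``min_residents`` residents.
    """

    exclude_care_levels: frozenset[str] = frozenset()
    min_residents: int = 0
    strata_include: frozenset[str] | None = None
    whole_facility: bool = False

    def __post_init__(self) -> None:
        bad = set(self.exclude_care_levels) - set(CARE_LEVELS)
        if bad:
            raise ValueError(f"unknown care levels in filter: {sorted(bad)}")
        if self.min_residents < 0:
            raise ValueError("min_residents must be >= 0")


def apply_filter(
    facilities: list[Facility],
    residents: list[Resident],
    filt: CohortFilter,
) -> tuple[list[Facility], list[Resident]]:
    """Apply a :class:`CohortFilter`, returning the retained cohort.

    Filtering is idempotent and never enlarges either table. Raises
    :class:`EmptyCohortError` if no facility survives.
    """
    n_fac_in, n_res_in = len(facilities), len(residents)
    excl = set(filt.exclude_care_levels)

    kept_fac: list[Facility] = []
    for fac in facilities:
        if filt.strata_include is not None and fac.stratum not in filt.strata_include:
            continue
        if excl:
            if filt.whole_facility and (set(fac.care_levels) & excl):
                continue
            if set(fac.care_levels) <= excl:  # entirely excluded
                continue
        kept_fac.append(fac)

    kept_ids = {f.facility_id for f in kept_fac}
    kept_res = [
        r
        for r in residents
        if r.facility_id in kept_ids and r.care_level not in excl
    ]

    if filt.min_residents > 0:
        counts: dict[str, int] = {}
        for r in kept_res:
            counts[r.facility_id] = counts.get(r.facility_id, 0) + 1
        kept_fac = [f for f in kept_fac if counts.get(f.facility_id, 0) >= filt.min_residents]
        kept_ids = {f.facility_id for f in kept_fac}
        kept_res = [r for r in kept_res if r.facility_id in kept_ids]

    if not kept_fac:
        raise EmptyCohortError("filter excluded every facility")

    logger.info(
        "stage=filter facilities_in=%d facilities_kept=%d residents_in=%d "
        "residents_kept=%d residents_excluded=%d",
        n_fac_in, len(kept_fac), n_res_in, len(kept_res), n_res_in - len(kept_res),
    )
    return kept_fac, kept_res


__all__ = [
    "CARE_LEVELS",
    "OWNERSHIP",
    "REQUIRED_COVARIATES",
    "Facility",
    "Resident",
    "HospitalEvent",
    "FollowUpWindow",
    "CohortFilter",
    "apply_filter",
    "replace",
]
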