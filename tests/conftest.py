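import datetime as dt

import pytest

from pahrank.cohort import Facility, FollowUpWindow, HospitalEvent, Resident


@pytest.fixture
def window():
    """Two-year window, 731 days (2008 is a leap year)."""
    return FollowUpWindow(dt.date(2008, 1, 1), dt.date(2010, 1, 1))


@pytest.fixture
def hand_cohort(window):
    """Hand-built 3-facility / 10-resident / 12-event cohort.

    Facility A is low-care only, B mixed, C high-care only. Diagnosis-code
    positions are chosen to exercise the first/second/third-position rule:
    events 1-3 match at positions 1-3, event 4 matches only at position 4,
    events 5+ are non-PAH or out-of-window / non-acute variants.
    """
    d = dt.date
    facilities = [
        Facility("A", frozenset({"low"}), 30, "for_profit", True, 5.0, "DHB1"),
        Facility("B", frozenset({"low", "high"}), 45, "not_for_profit", False, 12.5, "DHB2"),
        Facility("C", frozenset({"high"}), 25, "public", False, 2.0, "DHB1"),
    ]
    def res(rid, fid, level, death=None, **cov):
        return Resident(
            resident_id=rid, facility_id=fid, care_level=level,
            age_years=85.0, sex="F", entry_date=d(2008, 1, 1),
            death_date=death, covariates=dict(cov),
        )
    residents = [
        res("A1", "A", "low", gp_urgent_2wk=1),
        res("A2", "A", "low"),
        res("A3", "A", "low", death=d(2009, 1, 1)),
        res("A4", "A", "low", ed_visit_prior_window=1),
        res("B1", "B", "low", gp_urgent_2wk=1),
        res("B2", "B", "high"),
        res("B3", "B", "high", death=d(2008, 7, 1)),
        res("C1", "C", "high"),
        res("C2", "C", "high", prior_diabetes_admission=1),
        res("C3", "C", "high", death=d(2009, 7, 2)),
    ]
    ev = HospitalEvent
    events = [
        ev("E01", "A1", d(2008, 3, 1), True, ("J18.9",)),                  # PAH pos 1
        ev("E02", "A1", d(2008, 6, 1), True, ("Z99", "I50",)),             # PAH pos 2
        ev("E03", "A2", d(2008, 9, 1), True, ("Z99", "Z98", "N39.0")),     # PAH pos 3
        ev("E04", "A3", d(2008, 4, 1), True, ("Z99", "Z98", "Z97", "J18")),# pos 4: not PAH
        ev("E05", "B1", d(2009, 2, 1), True, ("E86",)),                    # PAH
        ev("E06", "B1", d(2009, 3, 1), True, ("Z99",)),                    # not PAH
        ev("E07", "B2", d(2008, 2, 1), False, ("I50",)),                   # PAH code, non-acute
        ev("E08", "C1", d(2009, 12, 31), True, ("L03",)),                  # PAH last day
        ev("E09", "C1", d(2010, 1, 1), True, ("L03",)),                    # at window end: out
        ev("E10", "C2", d(2007, 12, 31), True, ("I50",)),                  # before start: out
        ev("E11", "C3", d(2009, 5, 1), True, ()),                          # no diagnoses
        ev("E12", "C3", d(2009, 6, 1), True, ("j44.1",)),                  # PAH lower-case
    ]
    return facilities, residents, events


@pytest.fixture
def cohort_csvs(tmp_path, hand_cohort):
    from pahrank import io

    facilities, residents, events = hand_cohort
    fp, rp, ep = (tmp_path / n for n in ("facilities.csv", "residents.csv", "events.csv"))
    io.write_facilities(facilities, fp)
    io.write_residents(residents, rp)
    io.write_events(events, ep)
    return fp, rp, ep
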