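"""CSV readers/writers and configuration parsing.

File contracts
--------------
``facilities.csv``
    facility_id, care_levels (semicolon-joined), n_beds, ownership,
    chain_member, distance_to_hospital_km, stratum
``residents.csv``
    resident_id, facility_id, care_level, age_years, sex, entry_date,
    death_date (blank if alive), the four model predictors, plus any number
    of extra covariate columns (sniffed as binary or real). An optional
    ``exit_date`` column censors exposure at discharge.
``events.csv``
    event_id, resident_id, admission_date, acute, dx1..dxN (blank-padded
    ordered diagnoses; position 1 is the primary diagnosis).

Dates are ISO-8601; internal representation is day precision.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .cohort import Facility, HospitalEvent, Resident
from .errors import ConfigError, SchemaError, ReferentialError

logger = logging.getLogger("pahrank")

_FACILITY_COLS = [
    "facility_id", "care_levels", "n_beds", "ownership", "chain_member",
    "distance_to_hospital_km", "stratum",
]
_RESIDENT_COLS = [
    "resident_id", "facility_id", "care_level", "age_years", "sex",
    "entry_date", "death_date",
]
_EVENT_COLS = ["event_id", "resident_id", "admission_date", "acute"]

_DX_RE = re.compile(r"^dx(\d+)$")
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _require(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_date(value: str, where: str) -> dt.date | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"{where}: bad ISO-8601 date {value!r}") from exc


def _parse_bool(value: str, where: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"{where}: bad boolean {value!r}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_facilities(path: str | Path) -> list[Facility]:
    path = Path(path)
    df = _read_csv(path)
    _require(df, _FACILITY_COLS, path)
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        fid = row.facility_id
        if fid in seen:
            raise SchemaError(f"{path}: duplicate facility_id {fid!r}")
        seen.add(fid)
        levels = frozenset(s.strip() for s in row.care_levels.split(";") if s.strip())
        out.append(
            Facility(
                facility_id=fid,
                care_levels=levels,
                n_beds=int(row.n_beds),
                ownership=row.ownership,
                chain_member=_parse_bool(row.chain_member, f"facility {fid}"),
                distance_to_hospital_km=float(row.distance_to_hospital_km),
                stratum=row.stratum,
            )
        )
    return out


def _sniff_numeric(values: pd.Series, col: str, path: Path) -> pd.Series:
    """Coerce an extra covariate column to float (binary stays 0/1)."""
    try:
        return pd.to_numeric(values.replace("", "0")).astype(float)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: extra covariate column {col!r} is not numeric") from exc


def read_residents(path: str | Path) -> list[Resident]:
    path = Path(path)
    df = _read_csv(path)
    _require(df, _RESIDENT_COLS, path)
    extra_cols = [c for c in df.columns if c not in _RESIDENT_COLS and c != "exit_date"]
    extras = {c: _sniff_numeric(df[c], c, path) for c in extra_cols}
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        rid = row.resident_id
        covs = {c: float(extras[c].iloc[i]) for c in extra_cols}
        exit_date = None
        if "exit_date" in df.columns:
            exit_date = _parse_date(df["exit_date"].iloc[i], f"resident {rid}")
        out.append(
            Resident(
                resident_id=rid,
                facility_id=row.facility_id,
                care_level=row.care_level,
                age_years=float(row.age_years),
                sex=row.sex,
                entry_date=_parse_date(row.entry_date, f"resident {rid}"),
                death_date=_parse_date(row.death_date, f"resident {rid}"),
                exit_date=exit_date,
                covariates=covs,
            )
        )
    return out


def read_events(path: str | Path) -> list[HospitalEvent]:
    path = Path(path)
    df = _read_csv(path)
    _require(df, _EVENT_COLS, path)
    dx_cols = sorted(
        (c for c in df.columns if _DX_RE.match(c)),
        key=lambda c: int(_DX_RE.match(c).group(1)),
    )
    out = []
    for row in df.itertuples(index=False):
        eid = row.event_id
        codes = []
        for c in dx_cols:
            v = getattr(row, c).strip()
            if v:
                codes.append(v)
            else:
                break  # blank-padded: first blank ends the ordered list
        out.append(
            HospitalEvent(
                event_id=eid,
                resident_id=row.resident_id,
                admission_date=_parse_date(row.admission_date, f"event {eid}"),
                acute=_parse_bool(row.acute, f"event {eid}"),
                diagnosis_codes=tuple(codes),
            )
        )
    return out


def read_cohort(
    facility_path: str | Path,
    resident_path: str | Path,
    event_path: str | Path,
) -> tuple[list[Facility], list[Resident], list[HospitalEvent]]:
    """Read and cross-validate the three cohort tables.

    Raises :class:`SchemaError` on missing columns / bad values and
    :class:`ReferentialError` on dangling foreign keys (all offending ids
    are listed).
    """
    facilities = read_facilities(facility_path)
    residents = read_residents(resident_path)
    events = read_events(event_path)

    fac_ids = {f.facility_id for f in facilities}
    bad_fac = sorted({r.facility_id for r in residents} - fac_ids)
    if bad_fac:
        raise ReferentialError(f"residents reference unknown facilities: {bad_fac}")
    res_ids = {r.resident_id for r in residents}
    bad_res = sorted({e.resident_id for e in events} - res_ids)
    if bad_res:
        raise ReferentialError(f"events reference unknown residents: {bad_res}")

    logger.info(
        "stage=read facilities=%d residents=%d events=%d",
        len(facilities), len(residents), len(events),
    )
    return facilities, residents, events


# ---------------------------------------------------------------------------
# writers

def write_facilities(facilities: list[Facility], path: str | Path) -> None:
    rows = [
        {
            "facility_id": f.facility_id,
            "care_levels": ";".join(sorted(f.care_levels)),
            "n_beds": f.n_beds,
            "ownership": f.ownership,
            "chain_member": str(f.chain_member).lower(),
            "distance_to_hospital_km": f.distance_to_hospital_km,
            "stratum": f.stratum,
        }
        for f in facilities
    ]
    pd.DataFrame(rows, columns=_FACILITY_COLS).to_csv(path, index=False)


def write_residents(residents: list[Resident], path: str | Path) -> None:
    extra = sorted({k for r in residents for k in r.covariates})
    rows = []
    for r in residents:
        row = {
            "resident_id": r.resident_id,
            "facility_id": r.facility_id,
            "care_level": r.care_level,
            "age_years": r.age_years,
            "sex": r.sex,
            "entry_date": r.entry_date.isoformat(),
            "death_date": r.death_date.isoformat() if r.death_date else "",
            "exit_date": r.exit_date.isoformat() if r.exit_date else "",
        }
        for k in extra:
            v = r.covariates.get(k, 0.0)
            row[k] = int(v) if float(v).is_integer() else v
        rows.append(row)
    cols = _RESIDENT_COLS + ["exit_date"] + extra
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_events(events: list[HospitalEvent], path: str | Path, n_dx: int = 10) -> None:
    rows = []
    for e in events:
        row = {
            "event_id": e.event_id,
            "resident_id": e.resident_id,
            "admission_date": e.admission_date.isoformat(),
            "acute": str(e.acute).lower(),
        }
        for i in range(n_dx):
            row[f"dx{i + 1}"] = e.diagnosis_codes[i] if i < len(e.diagnosis_codes) else ""
        rows.append(row)
    cols = _EVENT_COLS + [f"dx{i + 1}" for i in range(n_dx)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_rank_report(rank_table, path: str | Path, sort_by: str = "method2") -> None:
    """Write a tab-separated rank report, one row per facility.

    Rows are sorted by the chosen method's rank (ascending: rank 1 = lowest
    PAH use first), which makes the file directly plottable as a rank
    bar chart. Raises ``ValueError`` for an unknown sort method.
    """
    df = rank_table.frame
    col = f"rank_{sort_by}"
    if col not in df.columns:
        known = sorted(c[5:] for c in df.columns if c.startswith("rank_"))
        raise ValueError(f"unknown sort method {sort_by!r}; computed methods: {known}")
    out = df.sort_values([col, "facility_id"], kind="stable")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# configuration

def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"config {where}: unknown key(s) {sorted(unknown)}")


def _as_date(v, where: str) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return _parse_date(str(v), where)


def load_config(path: str | Path) -> dict:
    """Load and validate a pipeline config file (YAML).

    The whole file is validated before any stage runs; unknown keys are
    rejected so typos fail loudly. Returns a plain nested dict with dates
    parsed and defaults filled in.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(raw)


_TOP = {"paths", "window", "filters", "classification", "exposure", "model",
        "ranking", "selection", "simulate", "seed"}


def validate_config(raw: dict) -> dict:
    from .cohort import FollowUpWindow, CohortFilter, CARE_LEVELS

    _check_keys(raw, _TOP, "root")
    cfg: dict = {}

    paths = dict(raw.get("paths") or {})
    _check_keys(paths, {"facilities", "residents", "events", "code_list", "out_dir"}, "paths")
    cfg["paths"] = paths

    win = raw.get("window")
    if win is not None:
        _check_keys(dict(win), {"start", "end"}, "window")
        cfg["window"] = FollowUpWindow(
            _as_date(win["start"], "window.start"), _as_date(win["end"], "window.end")
        )
    else:
        cfg["window"] = None

    filt = dict(raw.get("filters") or {})
    _check_keys(filt, {"exclude_care_levels", "min_residents", "strata_include",
                       "whole_facility"}, "filters")
    cfg["filter"] = CohortFilter(
        exclude_care_levels=frozenset(filt.get("exclude_care_levels") or ()),
        min_residents=int(filt.get("min_residents", 0)),
        strata_include=(frozenset(filt["strata_include"])
                        if filt.get("strata_include") else None),
        whole_facility=bool(filt.get("whole_facility", False)),
    )

    cls = dict(raw.get("classification") or {})
    _check_keys(cls, {"acute_only", "max_position"}, "classification")
    cfg["classification"] = {
        "acute_only": bool(cls.get("acute_only", True)),
        "max_position": int(cls.get("max_position", 3)),
    }

    exp = dict(raw.get("exposure") or {})
    _check_keys(exp, {"mode"}, "exposure")
    mode = exp.get("mode", "exact")
    if mode not in ("exact", "approximate"):
        raise ConfigError(f"exposure.mode must be 'exact' or 'approximate', got {mode!r}")
    cfg["exposure"] = {"mode": mode}

    mdl = dict(raw.get("model") or {})
    _check_keys(mdl, {"unit", "covariates", "offset_mode", "quadrature_points",
                      "alpha", "backward"}, "model")
    unit = mdl.get("unit", "resident")
    if unit not in ("resident", "facility"):
        raise ConfigError(f"model.unit must be 'resident' or 'facility', got {unit!r}")
    from .cohort import REQUIRED_COVARIATES
    cfg["model"] = {
        "unit": unit,
        "covariates": list(mdl.get("covariates") or REQUIRED_COVARIATES),
        "offset_mode": mdl.get("offset_mode", "log_person_time"),
        "quadrature_points": int(mdl.get("quadrature_points", 15)),
        "alpha": float(mdl.get("alpha", 0.05)),
        "backward": bool(mdl.get("backward", True)),
    }
    if cfg["model"]["offset_mode"] not in ("log_person_time", "none"):
        raise ConfigError("model.offset_mode must be 'log_person_time' or 'none'")
    if not 0 < cfg["model"]["alpha"] <= 1:
        raise ConfigError("model.alpha must be in (0, 1]")

    rnk = dict(raw.get("ranking") or {})
    _check_keys(rnk, {"per_bed", "residual", "method4_absolute", "sort_by"}, "ranking")
    cfg["ranking"] = {
        "per_bed": bool(rnk.get("per_bed", False)),
        "residual": rnk.get("residual", "raw"),
        "method4_absolute": bool(rnk.get("method4_absolute", False)),
        "sort_by": rnk.get("sort_by", "method2"),
    }
    if cfg["ranking"]["residual"] not in ("raw", "pearson"):
        raise ConfigError("ranking.residual must be 'raw' or 'pearson'")

    sel = dict(raw.get("selection") or {})
    _check_keys(sel, {"method", "top_n", "stratified"}, "selection")
    cfg["selection"] = {
        "method": sel.get("method", "method4"),
        "top_n": int(sel.get("top_n", 10)),
        "stratified": bool(sel.get("stratified", False)),
    }

    sim = raw.get("simulate")
    if sim is not None:
        sim = dict(sim)
        _check_keys(sim, {"preset"}, "simulate")
        cfg["simulate"] = {"preset": sim["preset"]}
    else:
        cfg["simulate"] = None

    cfg["seed"] = int(raw.get("seed", 0))
    return cfg


__all__ = [
    "read_cohort", "read_facilities", "read_residents", "read_events",
    "write_facilities", "write_residents", "write_events", "write_rank_report",
    "load_config", "validate_config",
]
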