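"""Classification of potentially avoidable hospitalisations (PAH).

A discharge is classified PAH when any of its first ``max_diagnosis_position``
(default 3) diagnosis codes starts with a prefix from a condition code list.
Prefix matching is case-insensitive and ignores dots, so prefix ``J18``
covers ``J18.0``–``J18.9`` and ``j189`` alike. Diagnoses beyond the position
limit never influence the classification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import FollowUpWindow, HospitalEvent, Resident
from .errors import CodeListError, ReferentialError

logger = logging.getLogger("pahrank")

_PREFIX_RE = re.compile(r"^[A-Z0-9]+(\.[A-Z0-9]+)?$")


def _normalize(code: str) -> str:
    return code.replace(".", "").upper().strip()


@dataclass(frozen=True)
class PAHCodeList:
    """Condition code list for PAH classification.

    ``entries`` stores (condition_label, code_prefix) verbatim for
    reporting; matching uses normalized prefixes.
    """

    entries: tuple[tuple[str, str], ...]
    max_diagnosis_position: int = 3
    _normalized: tuple[str, ...] = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        if not self.entries:
            raise CodeListError("code list is empty; a PAH definition must exist")
        if self.max_diagnosis_position < 1:
            raise CodeListError("max_diagnosis_position must be >= 1")
        for label, prefix in self.entries:
            if not prefix or not _PREFIX_RE.match(prefix.upper()):
                raise CodeListError(
                    f"bad code prefix {prefix!r} for condition {label!r} "
                    "(expect uppercase alphanumeric with optional dot)"
                )
        object.__setattr__(
            self, "_normalized", tuple(sorted({_normalize(p) for _, p in self.entries}))
        )

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for label, _ in self.entries:
            seen.setdefault(label)
        return tuple(seen)

    def matches_code(self, code: str) -> bool:
        c = _normalize(code)
        return any(c.startswith(p) for p in self._normalized)


def load_code_list(path: str | Path, max_diagnosis_position: int = 3) -> PAHCodeList:
    """Load a condition code list from CSV (condition_label, code_prefix).

    Lines starting with ``#`` are comments. Duplicate rows are collapsed
    with a warning; an empty file is an error.
    """
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    for col in ("condition_label", "code_prefix"):
        if col not in df.columns:
            raise CodeListError(f"{path}: missing column {col!r}")
    entries: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dups = 0
    for row in df.itertuples(index=False):
        key = (row.condition_label.strip(), row.code_prefix.strip())
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        entries.append(key)
    if dups:
        logger.warning("stage=code_list duplicates_collapsed=%d path=%s", dups, path)
    if not entries:
        raise CodeListError(f"{path}: code list is empty")
    return PAHCodeList(tuple(entries), max_diagnosis_position)


def default_code_list(max_diagnosis_position: int = 3) -> PAHCodeList:
    """The bundled default condition list (a documented stand-in)."""
    ref = resources.files("pahrank.data") / "pah_codes.csv"
    with resources.as_file(ref) as path:
        return load_code_list(path, max_diagnosis_position)


def is_pah(event: HospitalEvent, code_list: PAHCodeList) -> bool:
    """True iff any diagnosis at position <= limit matches a list prefix."""
    limit = code_list.max_diagnosis_position
    return any(code_list.matches_code(c) for c in event.diagnosis_codes[:limit])


def count_pah_events(
    events: list[HospitalEvent],
    residents: list[Resident],
    code_list: PAHCodeList,
    window: FollowUpWindow,
    acute_only: bool = True,
) -> dict[str, int]:
    """Per-resident PAH counts within the half-open follow-up window.

    Every resident appears in the result (count 0 if eventless). Events
    outside [start, end) on admission date, and non-acute events when
    ``acute_only``, are ignored. Raises :class:`ReferentialError` for
    events whose resident is unknown.
    """
    counts = {r.resident_id: 0 for r in residents}
    bad = sorted({e.resident_id for e in events} - counts.keys())
    if bad:
        raise ReferentialError(f"events reference unknown residents: {bad}")
    n_pah = 0
    for e in events:
        if acute_only and not e.acute:
            continue
        if not window.contains(e.admission_date):
            continue
        if is_pah(e, code_list):
            counts[e.resident_id] += 1
            n_pah += 1
    logger.info(
        "stage=classify events=%d pah_events=%d residents=%d acute_only=%s",
        len(events), n_pah, len(residents), acute_only,
    )
    return counts


__all__ = [
    "PAHCodeList", "load_code_list", "default_code_list", "is_pah",
    "count_pah_events",
]
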