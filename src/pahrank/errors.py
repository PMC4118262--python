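"""Exception hierarchy for pahrank.

All package errors derive from :class:`PahrankError` so callers (and the
CLI) can catch one base class per stage.
"""

from __future__ import annotations


class PahrankError(Exception):
    """Base class for all pahrank errors."""


class SchemaError(PahrankError):
    """A required column or field is missing or malformed in an input table."""


class ReferentialError(PahrankError):
    """A foreign key points at an unknown record (facility or resident)."""


class EmptyCohortError(PahrankError):
    """A filter or stage left no facilities/residents to work with."""


class CodeListError(PahrankError):
    """The PAH condition code list is missing, empty or malformed."""


class ExposureError(PahrankError):
    """Person-time could not be computed (e.g. missing care-level entry)."""


class ModelError(PahrankError):
    """Model specification or evaluation failure (non-finite predictor etc.)."""


class RankingError(PahrankError):
    """Ranking inputs are inconsistent (facility-set mismatch, bad method)."""


class ConfigError(PahrankError):
    """Pipeline configuration is invalid (unknown keys, bad values)."""
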