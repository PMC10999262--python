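"""Typed exception hierarchy.

Readers and indicator operations never raise bare built-ins for foreseeable
input problems: anything a caller might want to branch on is an
:class:`IndicatorError` subclass. Row-level data problems are generally
*not* exceptions — they go into per-run error reports (see
:mod:`ias_indicators.formats_io`) so one bad row cannot abort an indicator
run.
"""

from __future__ import annotations


class IndicatorError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IndicatorError):
    """File could not be parsed at all (encoding, delimiter, JSON/TIFF structure)."""


class SchemaError(IndicatorError):
    """A required (mapped) column or property is missing from the input."""


class VocabularyError(IndicatorError):
    """A value lies outside a closed controlled vocabulary (e.g. EICAT magnitude)."""


class RegionError(IndicatorError):
    """Region geometry input is unusable (duplicate ids, irreparable geometry)."""


class ValidationError(IndicatorError):
    """A domain invariant is violated (e.g. suitability values outside [0, 1])."""


class AlignmentError(IndicatorError):
    """Gridded inputs do not share one geotransform/shape."""


class ParameterError(IndicatorError):
    """An operation was called with an unknown mode, mechanism or option."""


class MissingDataError(IndicatorError):
    """The requested indicator needs a data class that was not supplied.

    Raised e.g. for realized-mechanism or realized-worst subsets when no
    regional impact-assessment table is available; such assessments are not
    yet systematically published, so this error is an expected, documented
    outcome rather than a bug.
    """


class ConfigError(IndicatorError):
    """Run or scenario configuration is internally inconsistent."""
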