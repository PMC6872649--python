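"""Exception hierarchy shared across the pipeline stages."""


class GbmScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(GbmScreenError, ValueError):
    """An input violates a declared invariant; the message names the field."""


class InsufficientDataError(GbmScreenError, ValueError):
    """Too few observations for the requested fit or test."""


class DegenerateFitError(GbmScreenError, ValueError):
    """The data admit no informative fit (e.g. all responses identical)."""


class ExtrapolationError(GbmScreenError, ValueError):
    """A query dose lies outside the measured ladder."""


class IncompleteDesignError(GbmScreenError, ValueError):
    """A combination grid is missing a single-agent or combination arm."""


class UnitError(GbmScreenError, ValueError):
    """Concentration units are mixed or unrecognised."""


class SchemaError(GbmScreenError, ValueError):
    """A table is missing required columns or declares wrong dimensions."""


class UnusableSignatureError(GbmScreenError, ValueError):
    """A signature lost one sign class entirely (e.g. after cohort intersection)."""
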