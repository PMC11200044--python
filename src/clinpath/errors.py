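"""Exception hierarchy shared across the package.

Every error raised by clinpath derives from :class:`ClinPathError`, so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class ClinPathError(Exception):
    """Base class for all clinpath domain errors."""


class FormatError(ClinPathError):
    """A document does not conform to the expected dialect.

    ``path`` names the offending location (e.g. ``templates[2].urgency``).
    """

    def __init__(self, message: str, path: str = ""):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


class ReferentialIntegrityError(FormatError):
    """An id reference does not resolve; ``unresolved`` lists the ids."""

    def __init__(self, message: str, unresolved=(), path: str = ""):
        self.unresolved = tuple(unresolved)
        super().__init__(message, path=path)


class UnknownIdError(ClinPathError, KeyError):
    """Lookup of a symptom/finding/template id failed."""

    def __init__(self, kind: str, ident: str):
        self.kind = kind
        self.ident = ident
        ClinPathError.__init__(self, f"unknown {kind} id: {ident!r}")


class DuplicateMeasurementError(ClinPathError):
    """The same symptom was measured twice in one workspace."""


class ModeUnavailableError(ClinPathError):
    """An entry-point mode has no data to act on; fall back to RANDOM."""


class InsufficientDataError(ClinPathError):
    """Not enough records/respondents for the requested computation."""


class ParameterError(ClinPathError, ValueError):
    """An argument is outside its admissible range."""


class EmptyGroupError(ClinPathError):
    """A group selector matched no respondents."""


class DegenerateDataError(ClinPathError):
    """Data carry no variance where variance is required."""


class ConfigurationError(ClinPathError):
    """An item/construct mapping or run configuration is inconsistent."""


class SemSpecError(ClinPathError):
    """A structural-equation model specification is invalid."""
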