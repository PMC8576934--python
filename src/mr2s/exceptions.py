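"""Exception hierarchy for mr2s.

All package errors derive from :class:`Mr2sError` so callers can catch one
base class; subclasses distinguish format, validation, domain and
method-gating failures.
"""


class Mr2sError(Exception):
    """Base class for all mr2s errors."""


class FormatError(Mr2sError, ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(Mr2sError, ValueError):
    """A table or record violates a structural invariant."""


class HarmonizationError(Mr2sError, ValueError):
    """Exposure and outcome alleles at a shared rsid are irreconcilable."""


class DomainError(Mr2sError, ValueError):
    """A numeric argument is outside the mathematical domain of a formula."""


class ConfigurationError(Mr2sError, ValueError):
    """Required configuration (e.g. a trait variance) is missing or invalid."""


class MethodGatingError(Mr2sError, ValueError):
    """An estimator was invoked with fewer instruments than it supports."""


class DegenerateInstrumentError(Mr2sError, ValueError):
    """An instrument has a zero SNP-exposure effect, so no ratio exists."""


class CorrectionError(Mr2sError, RuntimeError):
    """Outlier correction removed every instrument."""
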